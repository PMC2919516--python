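"""Classify where exact 15-mer matches fall in an annotated genome.

Generates a genome fixture with one oligo planted per location category
(minus strand, intron, pseudogene, frameshifted CDS, UTR, in-frame CDS,
intergenic), classifies the corresponding 100%-identity gap-free hits against
the GFF3 annotation, and prints the per-organism summary with one '+' per
occurrence.  Every call matches its planted truth label.
"""

import tempfile

from pentamod import (
    CATEGORIES,
    FeatureAnnotation,
    GenomeFixtureSpec,
    GenomePlant,
    classify_hits,
    filter_hits,
    generate_genome_fixture,
    parse_hit_table,
    render_plus_marks,
    summarize_by_organism,
)
from pentamod.synthetic_data import random_oligos

oligos = random_oligos(len(CATEGORIES), seed=5)
fixture = generate_genome_fixture(GenomeFixtureSpec(
    plants=[GenomePlant(oligo=o, context=c, taxon="9606" if i % 2 else "10090")
            for i, (o, c) in enumerate(zip(oligos, CATEGORIES))],
    seed=5))

with tempfile.TemporaryDirectory() as tmp:
    paths = fixture.write(tmp)
    hits = filter_hits(parse_hit_table(paths["hits"]))
    annotation = FeatureAnnotation.from_gff3(paths["gff3"])
    calls = classify_hits(hits, annotation)

for call in calls:
    ok = "ok" if call.category == fixture.truth[call.hit.query_id] else "MISMATCH"
    print(f"{call.hit.query_id}: {call.category:<16s} [{ok}]  {call.evidence}")

print("\nper-organism summary (one '+' per occurrence):")
print(render_plus_marks(summarize_by_organism(calls)).to_string())
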
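"""Map pentapeptides to their coding 15-mer DNA sequences.

Enumerates the full degenerate coding set of two pentapeptides (its size is
the product of each residue's codon multiplicity under the standard genetic
code), then picks the single most-likely coding sequence under a toy codon
usage table.  Every enumerated sequence back-translates to the peptide.
"""

import tempfile
from pathlib import Path

from pentamod import degenerate_enumeration, load_usage_table, most_likely_cds, translate

for peptide in ("MWHMC", "WFQCM", "WWWWW"):
    cdss = degenerate_enumeration(peptide)
    assert all(translate(c) == peptide for c in cdss)
    print(f"{peptide}: {len(cdss)} degenerate coding 15-mers, e.g. {cdss[0]}")

usage_rows = [
    ("ATG", "M", 1.0), ("TGG", "W", 1.0),
    ("CAT", "H", 0.6), ("CAC", "H", 0.4),
    ("TGC", "C", 0.6), ("TGT", "C", 0.4),
]
with tempfile.TemporaryDirectory() as tmp:
    table = Path(tmp) / "usage.tsv"
    table.write_text("".join(f"{c}\t{a}\t{f}\n" for c, a, f in usage_rows))
    model = load_usage_table(table)
    print(f"\nmost likely CDS for MWHMC under the toy usage table: "
          f"{most_likely_cds('MWHMC', model)}")
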
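"""Genomic-context classification of exact oligonucleotide hits.

Each filtered alignment hit (full-length, 100% identity, gap-free) is joined
to GFF3 annotation and assigned exactly one location category, reproducing a
Table-1-style breakdown: minus strand, intron, pseudogene, frameshift, UTR,
in-frame coding (the translatable negative control), or intergenic.

Precedence when a hit overlaps several features: strand is evaluated first —
a hit antisense to every overlapping gene-level feature is ``minus_strand``
regardless of feature type; on the sense strand the ladder is pseudogene >
UTR > intron > CDS frame test (frameshift vs coding_in_frame).  "Frameshift"
means the hit lies in coding sequence but its codon boundaries disagree with
the CDS reading frame implied by the feature start and phase, or the hit
spans an exon-exon junction that interrupts the oligo.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .errors import AmbiguousAnnotationError, HitTableParseError, InvalidParameterError

CATEGORIES = ("minus_strand", "intron", "pseudogene", "frameshift", "UTR",
              "coding_in_frame", "intergenic")

_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR"}
_GENE_TYPES = {"gene", "pseudogene"}


@dataclass
class AlignmentHit:
    """One tabular alignment hit, 1-based inclusive subject coordinates."""

    query_id: str
    subject_id: str
    subject_taxon: str
    subject_start: int
    subject_end: int
    subject_strand: str  # '+' or '-'
    identity_fraction: float
    gap_count: int
    mismatch_count: int = 0
    alignment_length: int = 0

    def __post_init__(self) -> None:
        if self.subject_start > self.subject_end:
            # raw tables encode minus-strand hits as sstart > send
            self.subject_start, self.subject_end = self.subject_end, self.subject_start
            self.subject_strand = "-"
        if self.subject_strand not in "+-":
            raise InvalidParameterError(f"strand must be '+' or '-', got {self.subject_strand!r}")

    @property
    def span(self) -> int:
        return self.subject_end - self.subject_start + 1


def parse_hit_table(path: str | Path, default_taxon: str = "unknown") -> list[AlignmentHit]:
    """Parse a 12-column tabular alignment report, plus optional taxon/strand.

    Column order: query, subject, %identity, length, mismatches, gaps,
    qstart, qend, sstart, send, evalue, bitscore [, taxon [, strand]].
    Strand defaults to the orientation implied by sstart/send.
    """
    hits = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise HitTableParseError(f"{path} line {lineno}: expected >= 12 columns, got {len(parts)}")
        try:
            sstart, send = int(parts[8]), int(parts[9])
            hit = AlignmentHit(
                query_id=parts[0],
                subject_id=parts[1],
                subject_taxon=parts[12] if len(parts) > 12 else default_taxon,
                subject_start=sstart,
                subject_end=send,
                subject_strand=parts[13] if len(parts) > 13 else ("+" if sstart <= send else "-"),
                identity_fraction=float(parts[2]) / 100.0,
                gap_count=int(parts[5]),
                mismatch_count=int(parts[4]),
                alignment_length=int(parts[3]),
            )
        except (ValueError, InvalidParameterError) as exc:
            raise HitTableParseError(f"{path} line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def filter_hits(raw_hits: Iterable[AlignmentHit], span: int = 15) -> list[AlignmentHit]:
    """Keep only full-length, 100%-identity, gap-free, mismatch-free hits."""
    kept = []
    for hit in raw_hits:
        if (hit.identity_fraction >= 1.0 and hit.gap_count == 0
                and hit.mismatch_count == 0 and hit.span == span
                and (hit.alignment_length in (0, span))):
            kept.append(hit)
    return kept


@dataclass
class _Feature:
    type: str
    seqid: str
    start: int
    end: int
    strand: str
    phase: int | None
    feature_id: str
    gene_id: str  # top-level gene/pseudogene this feature belongs to

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


class FeatureAnnotation:
    """Per-sequence interval index over GFF3 features, introns derived.

    Introns are taken from explicit ``intron`` features when present,
    otherwise derived from the gaps between consecutive exons of each mRNA.
    """

    def __init__(self, features: Iterable[_Feature]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for f in features:
            # intervaltree is half-open; features are 1-based inclusive
            self._trees[f.seqid].addi(f.start, f.end + 1, f)

    @classmethod
    def from_gff3(cls, path: str | Path) -> "FeatureAnnotation":
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
        feats: list[_Feature] = []

        def top_gene(feature) -> str:
            current = feature
            while True:
                parents = list(db.parents(current, level=1))
                if not parents:
                    return current.id
                current = parents[0]

        for f in db.all_features():
            phase = int(f.frame) if f.frame not in (".", None, "") else None
            feats.append(_Feature(type=f.featuretype, seqid=f.seqid, start=f.start,
                                  end=f.end, strand=f.strand, phase=phase,
                                  feature_id=f.id, gene_id=top_gene(f)))
        # derive introns from exon gaps within each mRNA, if none annotated
        if not any(f.type == "intron" for f in feats):
            for mrna in db.features_of_type(("mRNA", "transcript")):
                exons = sorted(db.children(mrna, featuretype="exon"), key=lambda e: e.start)
                for left, right in zip(exons, exons[1:]):
                    if right.start > left.end + 1:
                        feats.append(_Feature(type="intron", seqid=mrna.seqid,
                                              start=left.end + 1, end=right.start - 1,
                                              strand=mrna.strand, phase=None,
                                              feature_id=f"{mrna.id}_intron",
                                              gene_id=top_gene(mrna)))
        return cls(feats)

    def overlapping(self, seqid: str, start: int, end: int) -> list[_Feature]:
        tree = self._trees.get(seqid)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end + 1)),
                      key=lambda f: (f.start, f.end, f.type))


@dataclass
class HitContextCall:
    """One hit joined to annotation and assigned a single location category."""

    hit: AlignmentHit
    category: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidParameterError(f"unknown category {self.category!r}")


def _in_frame(hit: AlignmentHit, cds: _Feature) -> bool:
    """Does the hit's first base fall on a codon boundary of this CDS?"""
    phase = cds.phase or 0
    if cds.strand == "+":
        return (hit.subject_start - (cds.start + phase)) % 3 == 0
    return ((cds.end - phase) - hit.subject_end) % 3 == 0


def classify_hit(hit: AlignmentHit, annotation: FeatureAnnotation) -> HitContextCall:
    """Assign one location category to a filtered hit.

    See the module docstring for the precedence ladder.  Raises
    :class:`AmbiguousAnnotationError` when gene-level features on both
    strands overlap the hit.
    """
    feats = annotation.overlapping(hit.subject_id, hit.subject_start, hit.subject_end)
    gene_like = [f for f in feats if f.type in _GENE_TYPES]
    if not gene_like:
        return HitContextCall(hit, "intergenic", "no overlapping gene-level feature")

    strands = {f.strand for f in gene_like}
    if strands == {"+", "-"}:
        ids = ", ".join(f.feature_id for f in gene_like)
        raise AmbiguousAnnotationError(
            f"hit {hit.query_id}@{hit.subject_id}:{hit.subject_start}-{hit.subject_end} "
            f"overlaps genes on both strands: {ids}")
    (gene_strand,) = strands
    if hit.subject_strand != gene_strand:
        ids = ", ".join(sorted({f.gene_id for f in gene_like}))
        return HitContextCall(hit, "minus_strand",
                              f"antisense to {gene_strand}-strand gene(s) {ids}")

    sense = [f for f in feats if f.strand == gene_strand]
    pseudo = [f for f in sense if f.type == "pseudogene"]
    if pseudo:
        return HitContextCall(hit, "pseudogene", f"within pseudogene {pseudo[0].feature_id}")
    utr = [f for f in sense if f.type in _UTR_TYPES]
    if utr:
        return HitContextCall(hit, "UTR", f"within {utr[0].type} {utr[0].feature_id}")
    introns = [f for f in sense if f.type == "intron"
               and f.contains(hit.subject_start, hit.subject_end)]
    if introns:
        return HitContextCall(hit, "intron", f"within intron {introns[0].feature_id}")

    cds = [f for f in sense if f.type == "CDS"]
    if cds:
        containing = [f for f in cds if f.contains(hit.subject_start, hit.subject_end)]
        if not containing:
            return HitContextCall(hit, "frameshift",
                                  "spans an exon-exon junction interrupting the oligo")
        if _in_frame(hit, containing[0]):
            return HitContextCall(hit, "coding_in_frame",
                                  f"in frame within CDS {containing[0].feature_id}")
        return HitContextCall(hit, "frameshift",
                              f"offset mod 3 disagrees with frame of CDS {containing[0].feature_id}")

    partial_intron = [f for f in sense if f.type == "intron"]
    if partial_intron:
        return HitContextCall(hit, "frameshift",
                              "spans an exon-intron boundary interrupting the oligo")
    return HitContextCall(hit, "intergenic", "within gene but no exonic/intronic feature")


def classify_hits(hits: Iterable[AlignmentHit],
                  annotation: FeatureAnnotation) -> list[HitContextCall]:
    return [classify_hit(h, annotation) for h in hits]


def summarize_by_organism(calls: Sequence[HitContextCall]) -> pd.DataFrame:
    """Taxon x category count matrix (Table-1-style layout)."""
    if not calls:
        return pd.DataFrame(columns=list(CATEGORIES))
    rows = [{"taxon": c.hit.subject_taxon, "category": c.category} for c in calls]
    df = pd.DataFrame(rows)
    matrix = (df.groupby(["taxon", "category"]).size().unstack(fill_value=0)
                .reindex(columns=list(CATEGORIES), fill_value=0))
    matrix.columns.name = None
    return matrix.sort_index()


def render_plus_marks(matrix: pd.DataFrame) -> pd.DataFrame:
    """Counts rendered as one '+' per occurrence, as in the original table."""
    return matrix.map(lambda n: "+" * int(n))


def write_calls_tsv(calls: Sequence[HitContextCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tsubject\ttaxon\tstart\tend\tstrand\tcategory\tevidence\n")
        for c in calls:
            h = c.hit
            fh.write(f"{h.query_id}\t{h.subject_id}\t{h.subject_taxon}\t"
                     f"{h.subject_start}\t{h.subject_end}\t{h.subject_strand}\t"
                     f"{c.category}\t{c.evidence}\n")


def write_summary_tsv(matrix: pd.DataFrame, path: str | Path,
                      plus_marks: bool = False) -> None:
    out = render_plus_marks(matrix) if plus_marks else matrix
    out.to_csv(path, sep="\t", index_label="taxon")
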
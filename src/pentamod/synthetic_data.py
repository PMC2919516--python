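"""Seeded generators for synthetic proteomes and annotated genome fixtures.

The proteome generator stands in for a large non-redundant protein collection:
it draws background residues from a controllable composition, contaminates a
fraction of positions with ambiguity letters, and plants chosen k-mers at
*exact* total occurrence counts (accidental background occurrences are
detected and resampled away, so truth tables are exact, not best-effort).

The genome generator stands in for a nucleotide collection plus annotation:
it writes 15-mer oligos into small contigs in declared genomic contexts
(minus strand, intron, pseudogene, frameshifted CDS, UTR, in-frame CDS,
intergenic), emits the GFF3 features realizing each context, and emits the
matching 100%-identity gap-free hit rows together with a truth label per hit.

Both generators are fully reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InfeasiblePlantError, InvalidParameterError
from .locclass import AlignmentHit
from .revtrans import reverse_complement
from .spectrum import RESIDUES, ProteinRecord, write_fasta

_AMBIGUITY_LETTERS = "BXZ"
_MAX_REPAIR_ROUNDS = 200


# ---------------------------------------------------------------------------
# Proteomes
# ---------------------------------------------------------------------------

@dataclass
class ProteomeSpec:
    """Parameters of one synthetic proteome.

    ``length_dist`` is ``("constant", {"length": L})``,
    ``("uniform", {"low": a, "high": b})`` (inclusive bounds) or
    ``("normal", {"mean": m, "sd": s, "min": lo})``.
    ``residue_freqs`` maps residues to sampling probabilities (sum 1);
    ``planted`` lists (k-mer, exact target occurrence count) pairs;
    ``reversal_closed`` additionally emits every record's letter-reversal.
    """

    n_proteins: int = 100
    length_dist: tuple[str, dict] = ("uniform", {"low": 80, "high": 400})
    residue_freqs: dict[str, float] | None = None
    ambiguity_rate: float = 0.0
    planted: list[tuple[str, int]] = field(default_factory=list)
    reversal_closed: bool = False
    seed: int = 0

    def freq_vector(self) -> np.ndarray:
        if self.residue_freqs is None:
            return np.full(20, 1 / 20)
        vec = np.array([self.residue_freqs.get(aa, 0.0) for aa in RESIDUES])
        if abs(vec.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(f"residue frequencies sum to {vec.sum()}, not 1")
        return vec


@dataclass
class SyntheticProteome:
    """Generated records plus the exact planted-count truth table."""

    records: list[ProteinRecord]
    truth: dict[str, int]
    spec: ProteomeSpec

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(self.records, path)


def _draw_lengths(spec: ProteomeSpec, rng: np.random.Generator) -> np.ndarray:
    name, params = spec.length_dist
    if name == "constant":
        return np.full(spec.n_proteins, int(params["length"]))
    if name == "uniform":
        return rng.integers(int(params["low"]), int(params["high"]) + 1, size=spec.n_proteins)
    if name == "normal":
        lo = int(params.get("min", 1))
        draws = rng.normal(params["mean"], params["sd"], size=spec.n_proteins)
        return np.maximum(np.round(draws).astype(int), lo)
    raise InvalidParameterError(f"unknown length distribution {name!r}")


def _occurrences(seq: str, kmer: str) -> list[int]:
    """All (overlapping) start positions of kmer in seq."""
    out, i = [], seq.find(kmer)
    while i != -1:
        out.append(i)
        i = seq.find(kmer, i + 1)
    return out


def generate_proteome(spec: ProteomeSpec) -> SyntheticProteome:
    """Generate a proteome realizing ``spec`` exactly.

    Planted k-mers end up with exactly their target total occurrence count
    across all emitted records.  Under ``reversal_closed`` every record's
    letter-reversal is also emitted, which adds occurrences of the *reversed*
    k-mer; palindromic plants therefore appear in pairs (even targets only),
    and a k-mer cannot be planted together with its distinct reversal.
    """
    rng = np.random.default_rng(spec.seed)
    ks = {len(p) for p, _ in spec.planted}
    if len(ks) > 1:
        raise InvalidParameterError("all planted k-mers must share one k")
    k = ks.pop() if ks else 0

    if spec.reversal_closed:
        planted_set = {p for p, _ in spec.planted}
        clashes = {p for p in planted_set if p[::-1] in planted_set and p != p[::-1]}
        if clashes:
            raise InfeasiblePlantError(
                f"reversal-closed planting cannot target a k-mer and its reversal "
                f"independently: {sorted(clashes)}")

    plant_copies: list[tuple[str, int]] = []  # (kmer, copies written forward)
    for kmer, target in spec.planted:
        if target < 0:
            raise InvalidParameterError(f"negative target for {kmer!r}")
        if spec.reversal_closed and kmer == kmer[::-1]:
            # a palindromic occurrence reappears identically in the reversed
            # record, so each forward copy counts twice
            if target % 2:
                raise InfeasiblePlantError(
                    f"palindromic {kmer!r} needs an even target under reversal "
                    f"closure; got {target}")
            plant_copies.append((kmer, target // 2))
        else:
            plant_copies.append((kmer, target))

    lengths = _draw_lengths(spec, rng)
    total_copies = sum(c for _, c in plant_copies)
    if k and total_copies * (2 * k) > int(lengths.sum()):
        raise InfeasiblePlantError(
            f"{total_copies} planted copies of {k}-mers do not fit in "
            f"{int(lengths.sum())} residues")

    # background residues + ambiguity contamination
    seqs = []
    for length in lengths:
        letters = rng.choice(list(RESIDUES), size=length, p=spec.freq_vector())
        if spec.ambiguity_rate > 0:
            mask = rng.random(length) < spec.ambiguity_rate
            letters[mask] = rng.choice(list(_AMBIGUITY_LETTERS), size=int(mask.sum()))
        seqs.append(list(letters))

    # reserve non-overlapping slots and write the planted copies
    protected: list[set[int]] = [set() for _ in seqs]
    reserved: dict[str, list[tuple[int, int]]] = {p: [] for p, _ in plant_copies}
    eligible = [i for i, L in enumerate(lengths) if L >= k] if k else []
    for kmer, copies in plant_copies:
        for _ in range(copies):
            placed = False
            for _attempt in range(2000):
                ri = int(rng.choice(eligible))
                pos = int(rng.integers(0, lengths[ri] - k + 1))
                span = set(range(pos, pos + k))
                # keep a k-1 buffer so reserved occurrences cannot overlap
                buffered = set(range(max(0, pos - k + 1), min(int(lengths[ri]), pos + 2 * k - 1)))
                if buffered & protected[ri]:
                    continue
                seqs[ri][pos : pos + k] = list(kmer)
                protected[ri] |= span
                reserved[kmer].append((ri, pos))
                placed = True
                break
            if not placed:
                raise InfeasiblePlantError(f"could not place a copy of {kmer!r}")

    # destroy accidental occurrences so counts are exact; watch reversals too
    watch = {p for p, _ in plant_copies}
    if spec.reversal_closed:
        watch |= {p[::-1] for p in watch}
    for _round in range(_MAX_REPAIR_ROUNDS):
        dirty = False
        for kmer in sorted(watch):
            wanted = set(reserved.get(kmer, []))
            for ri, seq_list in enumerate(seqs):
                seq = "".join(seq_list)
                for pos in _occurrences(seq, kmer):
                    if (ri, pos) in wanted:
                        continue
                    free = [j for j in range(pos, pos + len(kmer)) if j not in protected[ri]]
                    if not free:
                        raise InfeasiblePlantError(
                            f"accidental {kmer!r} occurrence overlaps reserved slots only")
                    j = int(rng.choice(free))
                    current = seq_list[j]
                    choices = [aa for aa in RESIDUES if aa != current]
                    seq_list[j] = choices[int(rng.integers(0, len(choices)))]
                    dirty = True
        if not dirty:
            break
    else:
        raise InfeasiblePlantError("could not stabilize planted occurrence counts")

    records = [ProteinRecord(id=f"syn{i:05d}", sequence="".join(s))
               for i, s in enumerate(seqs)]
    if spec.reversal_closed:
        records += [ProteinRecord(id=f"{r.id}_rev", sequence=r.sequence[::-1])
                    for r in records]

    truth = {kmer: target for kmer, target in spec.planted}
    # exactness guarantee: verify by brute scan before returning
    for kmer, target in truth.items():
        got = sum(len(_occurrences(r.sequence, kmer)) for r in records)
        if got != target:
            raise InfeasiblePlantError(
                f"verification failed for {kmer!r}: wanted {target}, got {got}")
    return SyntheticProteome(records=records, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

CONTEXTS = ("minus_strand", "intron", "pseudogene", "frameshift", "UTR",
            "coding_in_frame", "intergenic")

_SLOT = 400       # bp reserved per plant
_GENE_OFF = 50    # gene start within its slot
_GENE_LEN = 300


@dataclass
class GenomePlant:
    """One 15-mer to embed in a declared genomic context."""

    oligo: str
    context: str
    taxon: str = "9606"
    query_id: str = ""

    def __post_init__(self) -> None:
        self.oligo = self.oligo.upper()
        if self.context not in CONTEXTS:
            raise InvalidParameterError(f"unknown context {self.context!r}")
        if len(self.oligo) != 15 or any(b not in "ACGT" for b in self.oligo):
            raise InvalidParameterError(f"oligo must be a 15-mer over ACGT: {self.oligo!r}")


@dataclass
class GenomeFixtureSpec:
    n_contigs: int = 1
    contig_length: int = 10_000
    plants: list[GenomePlant] = field(default_factory=list)
    seed: int = 0


@dataclass
class GenomeFixture:
    """Contigs, GFF3 features, hit rows and per-hit truth labels."""

    contigs: dict[str, str]
    gff3: str
    hit_rows: list[str]
    truth: dict[str, str]  # query_id -> intended category
    spec: GenomeFixtureSpec

    @property
    def hits(self) -> list[AlignmentHit]:
        from .locclass import parse_hit_table  # cheap, avoids temp file here
        hits = []
        for lineno, row in enumerate(self.hit_rows, start=1):
            parts = row.split("\t")
            sstart, send = int(parts[8]), int(parts[9])
            hits.append(AlignmentHit(
                query_id=parts[0], subject_id=parts[1], subject_taxon=parts[12],
                subject_start=sstart, subject_end=send,
                subject_strand="+" if sstart <= send else "-",
                identity_fraction=float(parts[2]) / 100.0,
                gap_count=int(parts[5]), mismatch_count=int(parts[4]),
                alignment_length=int(parts[3])))
        return hits

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write genome FASTA, GFF3, hit TSV and truth TSV; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fasta",
            "gff3": out / "annotation.gff3",
            "hits": out / "hits.tsv",
            "truth": out / "truth.tsv",
        }
        with open(paths["genome"], "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name} seed={self.spec.seed}\n")
                for lo in range(0, len(seq), 80):
                    fh.write(seq[lo : lo + 80] + "\n")
        paths["gff3"].write_text(self.gff3)
        paths["hits"].write_text("".join(row + "\n" for row in self.hit_rows))
        with open(paths["truth"], "w") as fh:
            fh.write("query\tcategory\n")
            for query, category in self.truth.items():
                fh.write(f"{query}\t{category}\n")
        return paths

    def validate(self) -> None:
        """Self-check: every hit row matches the genome substring exactly."""
        oligo_of = {p.query_id: p.oligo for p in self.spec.plants}
        for hit in self.hits:
            seq = self.contigs[hit.subject_id]
            found = seq[hit.subject_start - 1 : hit.subject_end]
            want = oligo_of[hit.query_id]
            if hit.subject_strand == "-":
                found = reverse_complement(found)
            if found != want:
                raise InfeasiblePlantError(
                    f"hit {hit.query_id}: genome has {found!r}, expected {want!r}")


def _gff_row(seqid, source, ftype, start, end, strand, phase, attrs) -> str:
    phase_s = "." if phase is None else str(phase)
    attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t{phase_s}\t{attr_s}"


def generate_genome_fixture(spec: GenomeFixtureSpec) -> GenomeFixture:
    """Build contigs with each plant realized in its declared context.

    Each plant occupies its own non-overlapping slot; the emitted hit row is
    full-length (15), 100% identity, gap-free, with sstart > send encoding
    minus-strand orientation.
    """
    rng = np.random.default_rng(spec.seed)
    slots_per_contig = spec.contig_length // _SLOT
    if slots_per_contig * spec.n_contigs < len(spec.plants):
        raise InfeasiblePlantError(
            f"{len(spec.plants)} plants need more than "
            f"{slots_per_contig * spec.n_contigs} available slots")

    contigs = {f"contig{c:03d}": list(rng.choice(list("ACGT"), size=spec.contig_length))
               for c in range(spec.n_contigs)}
    names = list(contigs)
    gff_lines = ["##gff-version 3"]
    for name in names:
        gff_lines.append(f"##sequence-region {name} 1 {spec.contig_length}")
    hit_rows: list[str] = []
    truth: dict[str, str] = {}

    for i, plant in enumerate(spec.plants):
        if not plant.query_id:
            plant.query_id = f"plant{i:03d}"
        contig = names[i // slots_per_contig]
        seq = contigs[contig]
        slot = (i % slots_per_contig) * _SLOT  # 0-based slot origin
        g_start = slot + _GENE_OFF + 1         # 1-based gene start
        g_end = g_start + _GENE_LEN - 1
        gid = f"{plant.query_id}_gene"
        strand_of_hit = "+"

        def emit(ftype, start, end, strand, phase, feature_id, parent=None):
            attrs = {"ID": feature_id}
            if parent:
                attrs["Parent"] = parent
            gff_lines.append(_gff_row(contig, "pentamod", ftype, start, end,
                                      strand, phase, attrs))

        if plant.context == "intergenic":
            ins = slot + 100 + 1
        elif plant.context == "pseudogene":
            emit("pseudogene", g_start, g_end, "+", None, gid)
            ins = g_start + 50
        elif plant.context == "intron":
            emit("gene", g_start, g_end, "+", None, gid)
            emit("mRNA", g_start, g_end, "+", None, f"{gid}.t1", gid)
            exon1_end = g_start + 79
            exon2_start = g_end - 79
            emit("exon", g_start, exon1_end, "+", None, f"{gid}.e1", f"{gid}.t1")
            emit("exon", exon2_start, g_end, "+", None, f"{gid}.e2", f"{gid}.t1")
            emit("CDS", g_start, exon1_end, "+", 0, f"{gid}.c1", f"{gid}.t1")
            emit("CDS", exon2_start, g_end, "+", (3 - (exon1_end - g_start + 1) % 3) % 3,
                 f"{gid}.c2", f"{gid}.t1")
            ins = exon1_end + 41  # well inside the 140 bp intron
        elif plant.context == "UTR":
            emit("gene", g_start, g_end, "+", None, gid)
            emit("mRNA", g_start, g_end, "+", None, f"{gid}.t1", gid)
            emit("exon", g_start, g_end, "+", None, f"{gid}.e1", f"{gid}.t1")
            emit("five_prime_UTR", g_start, g_start + 99, "+", None, f"{gid}.u1", f"{gid}.t1")
            emit("CDS", g_start + 100, g_end, "+", 0, f"{gid}.c1", f"{gid}.t1")
            ins = g_start + 40
        else:  # single-exon coding gene: coding_in_frame / frameshift / minus_strand
            emit("gene", g_start, g_end, "+", None, gid)
            emit("mRNA", g_start, g_end, "+", None, f"{gid}.t1", gid)
            emit("exon", g_start, g_end, "+", None, f"{gid}.e1", f"{gid}.t1")
            emit("CDS", g_start, g_end, "+", 0, f"{gid}.c1", f"{gid}.t1")
            ins = g_start + 30  # (ins - g_start) % 3 == 0: on a codon boundary
            if plant.context == "frameshift":
                ins += 1
            elif plant.context == "minus_strand":
                strand_of_hit = "-"

        written = plant.oligo if strand_of_hit == "+" else reverse_complement(plant.oligo)
        seq[ins - 1 : ins + 14] = list(written)
        sstart, send = (ins, ins + 14) if strand_of_hit == "+" else (ins + 14, ins)
        hit_rows.append("\t".join(map(str, [
            plant.query_id, contig, "100.000", 15, 0, 0, 1, 15,
            sstart, send, "1e-05", "30.1", plant.taxon])))
        truth[plant.query_id] = plant.context

    fixture = GenomeFixture(contigs={n: "".join(s) for n, s in contigs.items()},
                            gff3="\n".join(gff_lines) + "\n",
                            hit_rows=hit_rows, truth=truth, spec=spec)
    fixture.validate()
    return fixture


def random_oligos(n: int, seed: int) -> list[str]:
    """n random ACGT 15-mers (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list("ACGT"), size=15)) for _ in range(n)]
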
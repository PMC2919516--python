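"""Overlapping peptide k-mer spectra over whole proteomes.

A proteome is decomposed into every length-k window at step 1 ("5-mers
sequentially overlapping by four residues" for k=5).  Windows containing any
letter outside the 20 standard one-letter residue codes (ambiguity codes B, X,
Z; selenocysteine U; pyrrolysine O; gaps '-'; stops '*'; anything else) are
dropped, not repaired.  The number of occurrences of a k-mer across the whole
collection — duplicates included — is its *proteomic frequency*.

Because the k-mer space over 20 residues is only 20**k strings (3,200,000 for
k=5), the spectrum is stored as a dense integer array indexed by the base-20
encoding of the k-mer.  This makes zero-count k-mers (the "never-expressed"
set) enumerable exactly, which the frequency-class and inverse-sequence
analyses rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CapacityError, FastaParseError, InvalidParameterError, InvalidResidueError

#: The 20 standard residues in alphabetical one-letter order.  The base-20
#: encoding below is therefore lexicographic-order preserving.
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

MAX_K = 6  # dense-array guard: 20**6 counters is the largest we allocate

_CODE = np.full(256, -1, dtype=np.int16)
for _i, _aa in enumerate(RESIDUES):
    _CODE[ord(_aa)] = _i


def encode_kmer(kmer: str) -> int:
    """Base-20 integer code of a k-mer over the standard residues."""
    code = 0
    for ch in kmer:
        v = _CODE[ord(ch)]
        if v < 0:
            raise InvalidResidueError(f"non-standard residue {ch!r} in {kmer!r}")
        code = code * 20 + int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    out = []
    for _ in range(k):
        code, r = divmod(code, 20)
        out.append(RESIDUES[r])
    return "".join(reversed(out))


def decode_kmers(codes: np.ndarray, k: int) -> list[str]:
    """Vectorized decode of an array of k-mer codes."""
    codes = np.asarray(codes, dtype=np.int64)
    digits = np.empty((codes.size, k), dtype=np.int64)
    rem = codes.copy()
    for j in range(k - 1, -1, -1):
        rem, digits[:, j] = np.divmod(rem, 20)
    letters = np.frombuffer(RESIDUES.encode(), dtype=np.uint8)[digits]
    return [bytes(row).decode() for row in letters]


def reversal_permutation(k: int) -> np.ndarray:
    """Permutation array mapping each k-mer code to its letter-reversal's code."""
    codes = np.arange(20**k, dtype=np.int64)
    rem = codes.copy()
    out = np.zeros_like(codes)
    for _ in range(k):
        rem, digit = np.divmod(rem, 20)
        out = out * 20 + digit
    return out


@dataclass
class ProteinRecord:
    """One protein sequence; the sequence is upper-cased on construction."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise InvalidParameterError(f"record {self.id!r} has an empty sequence")


def decompose(record: ProteinRecord | str, k: int) -> list[str]:
    """All length-k windows of the sequence at step 1, ambiguity-filtered.

    Windows containing any letter outside the 20 standard residues are
    dropped; order of the surviving windows is preserved.  A sequence shorter
    than k yields an empty list.
    """
    if k <= 0:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    seq = record.sequence if isinstance(record, ProteinRecord) else record.upper()
    codes = _CODE[np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)]
    out = []
    for i in range(len(seq) - k + 1):
        if (codes[i : i + k] >= 0).all():
            out.append(seq[i : i + k])
    return out


@dataclass
class KmerSpectrum:
    """Complete occurrence-count map over the full k-mer space.

    ``counts`` has exactly 20**k entries (zero-count k-mers included); its sum
    equals ``n_windows_kept``.
    """

    k: int
    counts: np.ndarray
    n_sequences: int = 0
    n_windows_kept: int = 0
    n_windows_dropped: int = 0

    @property
    def space_size(self) -> int:
        """Number of possible k-mers over the 20 standard residues."""
        return 20**self.k

    def count(self, kmer: str) -> int:
        """Proteomic frequency of one k-mer."""
        if len(kmer) != self.k:
            raise InvalidParameterError(f"expected a {self.k}-mer, got {kmer!r}")
        return int(self.counts[encode_kmer(kmer)])

    def nonzero_items(self) -> Iterator[tuple[str, int]]:
        """(k-mer, count) pairs for every k-mer seen at least once."""
        codes = np.flatnonzero(self.counts)
        for kmer, code in zip(decode_kmers(codes, self.k), codes):
            yield kmer, int(self.counts[code])


def _accumulate(counts: np.ndarray, seq: str, k: int) -> tuple[int, int]:
    """Add the valid windows of one sequence into ``counts``.

    Returns (windows_kept, windows_dropped).
    """
    codes = _CODE[np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)]
    n_win = len(seq) - k + 1
    if n_win <= 0:
        return 0, 0
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    powers = 20 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    enc = win[valid].astype(np.int64) @ powers
    np.add.at(counts, enc, 1)
    kept = int(valid.sum())
    return kept, n_win - kept


def build_spectrum(proteome: Iterable[ProteinRecord], k: int) -> KmerSpectrum:
    """Count every valid overlapping k-mer window across a proteome.

    Windows never span record boundaries; duplicate records are counted
    separately.  Guarded at k <= 6 so the dense count array stays small.
    """
    if k <= 0:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    if k > MAX_K:
        raise CapacityError(f"k={k} exceeds the dense-spectrum guard (k <= {MAX_K})")
    counts = np.zeros(20**k, dtype=np.int64)
    n_seq = kept_total = dropped_total = 0
    for record in proteome:
        n_seq += 1
        kept, dropped = _accumulate(counts, record.sequence, k)
        kept_total += kept
        dropped_total += dropped
    return KmerSpectrum(k=k, counts=counts, n_sequences=n_seq,
                        n_windows_kept=kept_total, n_windows_dropped=dropped_total)


def read_fasta(path: str | Path) -> Iterator[ProteinRecord]:
    """Stream ProteinRecords from a (multi-record, wrapped or not) FASTA file."""
    seen_any = False
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seen_any = True
            if len(rec.seq) == 0:
                raise FastaParseError(f"record {rec.id!r} in {path} has an empty sequence")
            yield ProteinRecord(id=rec.id, sequence=str(rec.seq))
    except FastaParseError:
        raise
    except Exception as exc:  # Biopython raises plain ValueError on bad FASTA
        raise FastaParseError(f"could not parse FASTA {path}: {exc}") from exc
    if not seen_any:
        # distinguish "no records" from a silent success on a non-FASTA file
        text = Path(path).read_text().lstrip()
        if text and not text.startswith(">"):
            raise FastaParseError(f"{path} does not look like FASTA (no '>' header)")


def build_spectrum_from_fasta(path: str | Path, k: int) -> KmerSpectrum:
    return build_spectrum(read_fasta(path), k)


def spectrum_histogram(spectrum: KmerSpectrum) -> list[tuple[int, int]]:
    """(occurrence_count, number_of_kmers) pairs, zero count always included.

    The number_of_kmers over all pairs sums to 20**k.
    """
    tally = np.bincount(spectrum.counts)
    pairs = [(0, int(tally[0]))]
    for occ in np.flatnonzero(tally[1:]) + 1:
        pairs.append((int(occ), int(tally[occ])))
    return pairs


@dataclass
class FrequencyClass:
    """All k-mers sharing one proteomic frequency (the lettered sets a..k).

    Member k-mers are held as sorted base-20 codes; ``members`` decodes them
    lazily because the zero class for k=5 can hold millions of k-mers.
    """

    label: str
    target_count: int
    k: int
    member_codes: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return int(self.member_codes.size)

    def __contains__(self, kmer: str) -> bool:
        code = encode_kmer(kmer)
        i = int(np.searchsorted(self.member_codes, code))
        return i < len(self.member_codes) and int(self.member_codes[i]) == code

    @property
    def members(self) -> list[str]:
        """Member k-mers in lexicographic order."""
        return decode_kmers(self.member_codes, self.k)


def frequency_classes(spectrum: KmerSpectrum,
                      targets: Sequence[int],
                      labels: Sequence[str] | None = None) -> list[FrequencyClass]:
    """One FrequencyClass per target occurrence count.

    The class for target 0 is the never-expressed set.  A target matched by no
    k-mer yields an empty class.  Targets must be distinct and non-negative.
    """
    if len(set(targets)) != len(targets):
        raise InvalidParameterError(f"frequency targets must be distinct: {list(targets)}")
    if any(t < 0 for t in targets):
        raise InvalidParameterError("frequency targets must be non-negative")
    if labels is None:
        # a, b, c ... in target order
        labels = [chr(ord("a") + i) for i in range(len(targets))]
    out = []
    for label, target in zip(labels, targets):
        codes = np.flatnonzero(spectrum.counts == target)
        out.append(FrequencyClass(label=label, target_count=int(target),
                                  k=spectrum.k, member_codes=codes))
    return out


def inverse_sequence(peptide: str) -> str:
    """Letter-reversal of a peptide: same residue composition, reversed order."""
    for ch in peptide:
        if _CODE[ord(ch)] < 0:
            raise InvalidResidueError(f"non-standard residue {ch!r} in {peptide!r}")
    return peptide[::-1]


@dataclass
class InverseProfile:
    """Spectrum counts of the reversals of one frequency class's members.

    Array-backed so the full k=5 never-expressed class (millions of members)
    stays cheap; ``profile`` materializes a dict and should only be used on
    small classes.
    """

    k: int
    member_codes: np.ndarray = field(repr=False)
    inverse_codes: np.ndarray = field(repr=False)
    inverse_counts: np.ndarray = field(repr=False)
    min_count: int = 0
    max_count: int = 0
    mean_count: float = 0.0

    def __len__(self) -> int:
        return int(self.member_codes.size)

    def __getitem__(self, kmer: str) -> tuple[str, int]:
        """(inverse k-mer, inverse count) of one class member."""
        code = encode_kmer(kmer)
        i = int(np.searchsorted(self.member_codes, code))
        if i >= len(self.member_codes) or int(self.member_codes[i]) != code:
            raise KeyError(kmer)
        return decode_kmer(int(self.inverse_codes[i]), self.k), int(self.inverse_counts[i])

    def items(self) -> Iterator[tuple[str, tuple[str, int]]]:
        for m, im, c in zip(decode_kmers(self.member_codes, self.k),
                            decode_kmers(self.inverse_codes, self.k),
                            self.inverse_counts):
            yield m, (im, int(c))

    @property
    def profile(self) -> dict[str, tuple[str, int]]:
        return dict(self.items())


def inverse_frequency_profile(freq_class: FrequencyClass,
                              spectrum: KmerSpectrum) -> InverseProfile:
    """For each class member, the proteomic frequency of its letter-reversal.

    Used to test whether residue composition alone explains a class: if it
    did, reversals of never-expressed peptides would also be absent.
    """
    if freq_class.k != spectrum.k:
        raise InvalidParameterError("class and spectrum must share k")
    empty = np.array([], dtype=np.int64)
    if len(freq_class) == 0:
        return InverseProfile(k=freq_class.k, member_codes=empty,
                              inverse_codes=empty, inverse_counts=empty)
    perm = reversal_permutation(spectrum.k)
    inv_codes = perm[freq_class.member_codes]
    inv_counts = spectrum.counts[inv_codes]
    return InverseProfile(k=freq_class.k,
                          member_codes=np.asarray(freq_class.member_codes),
                          inverse_codes=inv_codes, inverse_counts=inv_counts,
                          min_count=int(inv_counts.min()),
                          max_count=int(inv_counts.max()),
                          mean_count=float(inv_counts.mean()))


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def write_spectrum_tsv(spectrum: KmerSpectrum, path: str | Path,
                       include_zero_rows: bool = False,
                       header_meta: dict | None = None) -> None:
    """Write the spectrum as a (kmer, count) TSV; zero rows optional."""
    with open(path, "w") as fh:
        _write_meta(fh, header_meta)
        fh.write("kmer\tcount\n")
        if include_zero_rows:
            codes = np.arange(spectrum.space_size)
        else:
            codes = np.flatnonzero(spectrum.counts)
        # decode in chunks to bound memory on the full k=5 space
        for lo in range(0, codes.size, 200_000):
            chunk = codes[lo : lo + 200_000]
            for kmer, c in zip(decode_kmers(chunk, spectrum.k), spectrum.counts[chunk]):
                fh.write(f"{kmer}\t{int(c)}\n")


def write_histogram_tsv(spectrum: KmerSpectrum, path: str | Path,
                        header_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, header_meta)
        fh.write("occurrence_count\tn_kmers\n")
        for occ, n in spectrum_histogram(spectrum):
            fh.write(f"{occ}\t{n}\n")


def write_classes_tsv(classes: Iterable[FrequencyClass], path: str | Path,
                      header_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, header_meta)
        fh.write("label\ttarget\tkmer\n")
        for fc in classes:
            for kmer in fc.members:
                fh.write(f"{fc.label}\t{fc.target_count}\t{kmer}\n")


def _write_meta(fh, meta: dict | None) -> None:
    if meta:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write ProteinRecords as single-line FASTA."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="")
                   for r in records]
    SeqIO.write(seq_records, str(path), "fasta-2line")
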
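"""Reverse translation of peptides to coding DNA.

A pentapeptide corresponds at the DNA level to a pentadecamer (15-mer)
oligodeoxynucleotide.  Under the standard genetic code a residue may be
encoded by one to six codons, so a peptide maps to a *degenerate set* of
coding sequences whose size is the product of the per-residue codon
multiplicities.  Given a codon-usage table, a single "most likely" coding
sequence is obtained by picking the highest-usage codon for each residue.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .errors import InvalidModelError, InvalidParameterError, InvalidResidueError, TranslationError
from .spectrum import RESIDUES

_USAGE_TOL = 1e-9


@dataclass
class CodonModel:
    """Standard genetic code plus optional per-codon usage fractions.

    ``code`` maps each of the 61 sense codons to a residue; ``usage``, when
    present, maps codons to fractions that sum to 1 per residue.
    """

    code: dict[str, str] = field(default_factory=lambda: dict(standard_dna_table.forward_table))
    usage: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self._by_residue: dict[str, list[str]] = {aa: [] for aa in RESIDUES}
        for codon, aa in self.code.items():
            self._by_residue.setdefault(aa, []).append(codon)
        for aa, codons in self._by_residue.items():
            if not codons:
                raise InvalidModelError(f"residue {aa!r} has no codon in the model")
            codons.sort()
        if self.usage is not None:
            totals: dict[str, float] = {}
            for codon, frac in self.usage.items():
                if codon not in self.code:
                    raise InvalidModelError(f"usage given for non-sense codon {codon!r}")
                totals[self.code[codon]] = totals.get(self.code[codon], 0.0) + frac
            for aa, total in totals.items():
                if abs(total - 1.0) > _USAGE_TOL:
                    raise InvalidModelError(
                        f"usage fractions for residue {aa!r} sum to {total}, not 1")

    def codons_for(self, residue: str) -> list[str]:
        """Sense codons of one residue, lexicographically sorted."""
        if residue not in self._by_residue:
            raise InvalidResidueError(f"non-standard residue {residue!r}")
        return list(self._by_residue[residue])


def load_usage_table(path: str | Path) -> CodonModel:
    """Codon model from a Kazusa-style (codon, residue, fraction) TSV."""
    usage: dict[str, float] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise InvalidModelError(f"usage table {path} line {i}: expected 3 columns")
        codon, residue, frac = parts
        codon = codon.upper().replace("U", "T")
        if standard_dna_table.forward_table.get(codon) != residue.upper():
            raise InvalidModelError(
                f"usage table {path} line {i}: codon {codon} does not encode {residue}")
        usage[codon] = float(frac)
    return CodonModel(usage=usage)


def degenerate_enumeration(peptide: str, model: CodonModel | None = None) -> list[str]:
    """Every DNA sequence encoding the peptide, in lexicographic order.

    The result is the Cartesian product of per-residue codon sets; its size is
    the product of codon multiplicities (1 to 6**k for a k-mer).
    """
    model = model or CodonModel()
    codon_sets = [model.codons_for(aa) for aa in peptide]
    return ["".join(cds) for cds in itertools.product(*codon_sets)]


def degenerate_count(peptide: str, model: CodonModel | None = None) -> int:
    """Size of the degenerate set without materializing it."""
    model = model or CodonModel()
    n = 1
    for aa in peptide:
        n *= len(model.codons_for(aa))
    return n


def most_likely_cds(peptide: str, model: CodonModel) -> str:
    """Concatenation of each residue's highest-usage codon.

    Ties are broken toward the lexicographically smallest codon.  Requires a
    model with usage fractions; none is assumed silently.
    """
    if model.usage is None:
        raise InvalidModelError("most_likely_cds requires a codon model with usage fractions")
    out = []
    for aa in peptide:
        codons = model.codons_for(aa)
        missing = [c for c in codons if c not in model.usage]
        if missing:
            raise InvalidModelError(f"usage fractions missing for codons {missing} of {aa!r}")
        # max on (fraction, reversed-lexicographic) = argmax with smallest-codon ties
        out.append(min(codons, key=lambda c: (-model.usage[c], c)))
    return "".join(out)


def translate(dna: str, model: CodonModel | None = None) -> str:
    """Standard-code translation of an in-frame, sense-codon-only sequence."""
    model = model or CodonModel()
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise TranslationError(f"length {len(dna)} is not divisible by 3")
    peptide = []
    for offset in range(0, len(dna), 3):
        codon = dna[offset : offset + 3]
        aa = model.code.get(codon)
        if aa is None:
            kind = "stop codon" if codon in standard_dna_table.stop_codons else "invalid codon"
            raise TranslationError(f"{kind} {codon!r} at offset {offset}")
        peptide.append(aa)
    return "".join(peptide)


def reverse_complement(dna: str) -> str:
    """Standard reverse complement over {A, C, G, T}."""
    if any(base not in "ACGT" for base in dna.upper()):
        bad = sorted({b for b in dna.upper() if b not in "ACGT"})
        raise InvalidParameterError(f"non-ACGT letters {bad} in DNA input")
    return str(Seq(dna.upper()).reverse_complement())


def write_degenerate_tsv(peptides: Iterable[str], path: str | Path,
                         model: CodonModel | None = None,
                         count_only: bool = False) -> None:
    """TSV of (peptide, n_degenerate[, cds]) — one row per enumerated sequence."""
    model = model or CodonModel()
    with open(path, "w") as fh:
        if count_only:
            fh.write("peptide\tn_degenerate\n")
            for p in peptides:
                fh.write(f"{p}\t{degenerate_count(p, model)}\n")
        else:
            fh.write("peptide\tn_degenerate\tcds\n")
            for p in peptides:
                cdss = degenerate_enumeration(p, model)
                for cds in cdss:
                    fh.write(f"{p}\t{len(cdss)}\t{cds}\n")


def write_most_likely_tsv(peptides: Iterable[str], model: CodonModel,
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tcds\n")
        for p in peptides:
            fh.write(f"{p}\t{most_likely_cds(p, model)}\n")
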
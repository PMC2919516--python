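"""Physico-chemical scoring of peptide sets and group comparison.

Each frequency class of pentapeptides is scored residue-by-residue with a
numeric scale — codon number (how many sense codons the standard genetic code
assigns each residue), hydrophobicity, bulkiness, or a user-supplied table
such as precomputed peptide-bond formation energies — and the classes are
compared with a classical one-way fixed-effects ANOVA plus Tukey boxplot
statistics, mirroring the boxplot-and-F-test treatment used for proteome
frequency classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateVarianceError, InvalidParameterError, ScaleError
from .spectrum import RESIDUES, FrequencyClass

ScoreMode = Literal["sum", "mean"]

#: Sense-codon multiplicity of each residue in the standard genetic code
#: (NCBI translation table 1); the 20 values sum to 61.
STANDARD_CODON_COUNTS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue numeric scale covering all 20 standard residues."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(RESIDUES) - set(self.values)
        if missing:
            raise ScaleError(f"scale {self.name!r} missing residues {sorted(missing)}")
        extra = set(self.values) - set(RESIDUES)
        if extra:
            raise ScaleError(f"scale {self.name!r} has non-standard residues {sorted(extra)}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise ScaleError(f"residue {residue!r} absent from scale {self.name!r}") from None


def codon_number_scale() -> ResidueScale:
    """Codon multiplicities of the standard genetic code as a scale."""
    return ResidueScale("codon_number", {aa: float(n) for aa, n in STANDARD_CODON_COUNTS.items()})


def load_scale(path: str | Path, name: str | None = None) -> ResidueScale:
    """Load a (residue, value) TSV with '#' comment headers."""
    values: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            residue, value = line.split("\t")
            values[residue.strip()] = float(value)
        except ValueError as exc:
            raise ScaleError(f"malformed scale row {line!r} in {path}") from exc
    return ResidueScale(name or Path(path).stem, values)


def builtin_scale(name: Literal["hydrophobicity", "bulkiness", "codon_number"]) -> ResidueScale:
    """One of the scales shipped with the package."""
    if name == "codon_number":
        return codon_number_scale()
    files = {
        "hydrophobicity": "hydrophobicity_kyte_doolittle.tsv",
        "bulkiness": "bulkiness_zimmerman.tsv",
    }
    if name not in files:
        raise ScaleError(f"unknown builtin scale {name!r}")
    ref = resources.files("pentamod.data") / files[name]
    with resources.as_file(ref) as path:
        return load_scale(path, name)


def load_peptide_energy_table(path: str | Path) -> dict[str, float]:
    """Per-peptide precomputed energies (peptide, kJ/mol) from a TSV.

    Stands behind the energetics analysis: formation energies are computed
    externally (quantum chemistry) and consumed here as a lookup table.
    """
    table: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        peptide, value = line.split("\t")
        table[peptide.strip().upper()] = float(value)
    return table


def score_peptide(peptide: str, scale: ResidueScale, mode: ScoreMode = "sum") -> float:
    """Sum or mean of per-residue scale values over a peptide.

    Codon-number scoring always uses ``sum`` (the codon number of a peptide is
    the summed multiplicity of its residues).
    """
    if mode not in ("sum", "mean"):
        raise InvalidParameterError(f"mode must be 'sum' or 'mean', got {mode!r}")
    if not peptide:
        raise InvalidParameterError("cannot score an empty peptide")
    total = sum(scale[aa] for aa in peptide)
    return total if mode == "sum" else total / len(peptide)


def score_class(freq_class: FrequencyClass | Iterable[str], scale: ResidueScale,
                mode: ScoreMode = "sum") -> list[float]:
    """One score per class member, in lexicographic member order."""
    if isinstance(freq_class, FrequencyClass):
        members = freq_class.members  # already lexicographic (sorted codes)
    else:
        members = sorted(freq_class)
    return [score_peptide(p, scale, mode) for p in members]


@dataclass
class BoxplotStats:
    """Tukey five-number summary: quartiles, 1.5*IQR whiskers, outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    """Quartiles by linear interpolation (type 7) with Tukey 1.5*IQR whiskers.

    Whiskers sit on the most extreme data points inside the fences; values
    outside the fences are reported individually as outliers.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("boxplot_stats requires at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return BoxplotStats(median=float(med), q1=float(q1), q3=float(q3),
                        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
                        outliers=[float(v) for v in np.sort(outliers)])


@dataclass
class GroupComparison:
    """One-way ANOVA across groups plus per-group boxplot statistics."""

    group_labels: list[str]
    F: float
    p: float
    df_between: int
    df_within: int
    boxplots: list[BoxplotStats]

    def to_json(self) -> str:
        payload = {
            "group_labels": self.group_labels,
            "F": self.F, "p": self.p,
            "df_between": self.df_between, "df_within": self.df_within,
            "boxplots": [asdict(b) for b in self.boxplots],
        }
        return json.dumps(payload, indent=2)


def anova_oneway(groups: Sequence[Sequence[float]],
                 labels: Sequence[str] | None = None) -> GroupComparison:
    """Classical one-way fixed-effects ANOVA (F-test of equal group means).

    F = MS_between / MS_within with degrees of freedom (g-1, N-g); the
    p-value is the upper tail of the F distribution.  Identical-mean groups
    with zero between variance give F=0, p=1; zero pooled within-group
    variance with unequal means is degenerate and raises.
    """
    if len(groups) < 2:
        raise InvalidParameterError("ANOVA requires at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InvalidParameterError("each group needs at least 2 values")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    n_total = sum(a.size for a in arrs)
    grand = sum(a.sum() for a in arrs) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_between = len(arrs) - 1
    df_within = n_total - len(arrs)
    if ss_within == 0.0:
        if ss_between > 0.0:
            raise DegenerateVarianceError(
                "zero pooled within-group variance with unequal group means")
        f_stat, p = 0.0, 1.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f_stat, df_between, df_within))
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    return GroupComparison(group_labels=list(labels), F=float(f_stat), p=p,
                           df_between=df_between, df_within=df_within,
                           boxplots=[boxplot_stats(a) for a in arrs])


def compare_classes(classes: Sequence[FrequencyClass], scale: ResidueScale,
                    mode: ScoreMode = "sum") -> GroupComparison:
    """Score each frequency class and run the one-way ANOVA across them.

    Classes with fewer than 2 members are excluded (they carry no
    within-group information); at least two scorable classes are required.
    """
    labels, score_groups = [], []
    for fc in classes:
        if len(fc) >= 2:
            labels.append(fc.label)
            score_groups.append(score_class(fc, scale, mode))
    if len(score_groups) < 2:
        raise InvalidParameterError("need at least two classes with >= 2 members")
    return anova_oneway(score_groups, labels)


def write_scores_tsv(classes: Sequence[FrequencyClass], scale: ResidueScale,
                     mode: ScoreMode, path: str | Path) -> None:
    """Long-format (class_label, peptide, score) TSV across all classes."""
    with open(path, "w") as fh:
        fh.write(f"# scale: {scale.name}\tmode: {mode}\n")
        fh.write("class_label\tpeptide\tscore\n")
        for fc in classes:
            for peptide, score in zip(fc.members, score_class(fc, scale, mode)):
                fh.write(f"{fc.label}\t{peptide}\t{score:g}\n")
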
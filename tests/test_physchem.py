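"""Residue scales, peptide scoring, boxplot statistics and one-way ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pentamod.errors import DegenerateVarianceError, InvalidParameterError, ScaleError
from pentamod.physchem import (
    ResidueScale,
    anova_oneway,
    boxplot_stats,
    builtin_scale,
    codon_number_scale,
    compare_classes,
    load_scale,
    score_class,
    score_peptide,
)
from pentamod.spectrum import RESIDUES, ProteinRecord, build_spectrum, frequency_classes

peptides = st.text(alphabet=RESIDUES, min_size=1, max_size=10)


class TestScales:
    def test_codon_number_scale_matches_standard_code(self):
        scale = codon_number_scale()
        assert scale["W"] == 1 and scale["M"] == 1
        assert scale["L"] == 6 and scale["R"] == 6 and scale["S"] == 6
        assert sum(scale.values.values()) == 61  # sense codons of the standard code

    @pytest.mark.parametrize("name", ["hydrophobicity", "bulkiness"])
    def test_builtin_scales_cover_all_residues(self, name):
        scale = builtin_scale(name)
        assert set(scale.values) == set(RESIDUES)

    def test_incomplete_scale_rejected(self):
        with pytest.raises(ScaleError):
            ResidueScale("partial", {"A": 1.0})

    def test_load_scale_tsv(self, tmp_path):
        path = tmp_path / "scale.tsv"
        path.write_text("# citation line\n" +
                        "".join(f"{aa}\t{i}\n" for i, aa in enumerate(RESIDUES)))
        scale = load_scale(path)
        assert scale["A"] == 0 and scale["Y"] == 19


class TestScoring:
    @pytest.mark.parametrize("pep,expected", [
        ("WWWWW", 5), ("MMMMM", 5), ("MWHMC", 7), ("LLLLL", 30),
    ])
    def test_codon_number_sum(self, pep, expected):
        assert score_peptide(pep, codon_number_scale(), "sum") == expected

    def test_homopolymer_mean_is_scale_value(self):
        scale = builtin_scale("bulkiness")
        assert score_peptide("AAAAA", scale, "mean") == pytest.approx(scale["A"])

    @given(pep=peptides)
    @settings(max_examples=200, deadline=None)
    def test_sum_score_invariant_under_reversal(self, pep):
        for name in ("codon_number", "hydrophobicity", "bulkiness"):
            scale = builtin_scale(name)
            assert score_peptide(pep, scale, "sum") == pytest.approx(
                score_peptide(pep[::-1], scale, "sum"))

    @given(pep=st.text(alphabet=RESIDUES, min_size=5, max_size=5))
    @settings(max_examples=200, deadline=None)
    def test_pentapeptide_codon_number_bounds(self, pep):
        score = score_peptide(pep, codon_number_scale(), "sum")
        assert score == int(score) and 5 <= score <= 30

    def test_score_class_is_lexicographic_and_oracle_equal(self):
        members = ["WFQCM", "AAAAA", "MWHMC"]
        scale = codon_number_scale()
        scores = score_class(members, scale, "sum")
        expected = [sum(scale[aa] for aa in p) for p in sorted(members)]
        assert scores == expected

    def test_empty_class_scores_empty(self):
        s = build_spectrum(iter([ProteinRecord("r", "MWHMC")]), 5)
        (five,) = frequency_classes(s, [5])
        assert score_class(five, codon_number_scale()) == []


class TestBoxplotStats:
    def test_simple_five_numbers(self):
        b = boxplot_stats([1, 2, 3, 4, 5])
        assert (b.median, b.q1, b.q3) == (3, 2, 4)
        assert b.outliers == [] and b.whisker_low == 1 and b.whisker_high == 5

    def test_all_equal(self):
        b = boxplot_stats([0, 0, 0, 0])
        assert b.median == b.q1 == b.q3 == 0 and b.outliers == []

    def test_outlier_with_zero_iqr(self):
        b = boxplot_stats([1, 1, 1, 1, 100])
        assert b.outliers == [100]
        assert b.whisker_high == 1

    def test_quantiles_match_type7_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=101)
        b = boxplot_stats(values)
        q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
        assert (b.q1, b.median, b.q3) == pytest.approx((q1, med, q3))

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            boxplot_stats([])


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        gc = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert gc.F == 0.0 and gc.p == 1.0

    def test_matches_textbook_sum_of_squares_oracle(self):
        groups = [[1, 2, 3], [2, 3, 4]]
        gc = anova_oneway(groups)
        # explicit SS decomposition, written out independently
        flat = [v for g in groups for v in g]
        grand = sum(flat) / len(flat)
        ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
        ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
        f_oracle = (ssb / 1) / (ssw / 4)
        assert gc.F == pytest.approx(f_oracle, abs=1e-9)
        assert gc.p == pytest.approx(float(sps.f.sf(f_oracle, 1, 4)), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_f_oneway(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(loc=m, size=12).tolist() for m in (0, 0.3, 1.0)]
        gc = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert gc.F == pytest.approx(float(ref.statistic), abs=1e-9)
        assert gc.p == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=8).tolist() for _ in range(4)]
        a = anova_oneway(groups)
        b = anova_oneway(groups[::-1])
        assert a.F == pytest.approx(b.F) and a.p == pytest.approx(b.p)

    def test_degenerate_variance_raises(self):
        with pytest.raises(DegenerateVarianceError):
            anova_oneway([[1, 1, 1], [2, 2, 2]])

    def test_too_few_groups_or_values(self):
        with pytest.raises(InvalidParameterError):
            anova_oneway([[1, 2, 3]])
        with pytest.raises(InvalidParameterError):
            anova_oneway([[1], [2, 3]])

    def test_null_type_one_error_calibrated(self):
        # 300 null replicates of 11 equal-mean groups: quick calibration check
        rng = np.random.default_rng(12)
        hits = sum(
            anova_oneway([rng.normal(size=20).tolist() for _ in range(11)]).p < 0.05
            for _ in range(300))
        assert 0.02 <= hits / 300 <= 0.09


def test_compare_classes_runs_anova_over_frequency_classes():
    recs = ([ProteinRecord(f"a{i}", "MWHMC") for i in range(2)]
            + [ProteinRecord(f"b{i}", "AAAAA") for i in range(2)]
            + [ProteinRecord("c", "WFQCM"), ProteinRecord("d", "LLLLL")])
    s = build_spectrum(iter(recs), 5)
    classes = frequency_classes(s, [1, 2])
    gc = compare_classes(classes, codon_number_scale(), "sum")
    # the count-1 class is {LLLLL, WFQCM}, the count-2 class is {AAAAA, MWHMC}
    assert gc.group_labels == ["a", "b"]
    assert gc.F >= 0 and 0 <= gc.p <= 1
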
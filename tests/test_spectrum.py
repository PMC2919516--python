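"""Spectrum construction, frequency classes and inverse-sequence analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentamod.errors import (
    CapacityError,
    FastaParseError,
    InvalidParameterError,
    InvalidResidueError,
)
from pentamod.spectrum import (
    RESIDUES,
    ProteinRecord,
    build_spectrum,
    build_spectrum_from_fasta,
    decode_kmer,
    decompose,
    encode_kmer,
    frequency_classes,
    inverse_frequency_profile,
    inverse_sequence,
    read_fasta,
    reversal_permutation,
    spectrum_histogram,
    write_spectrum_tsv,
)
from pentamod.synthetic_data import ProteomeSpec, generate_proteome

from conftest import brute_force_counts

peptides = st.text(alphabet=RESIDUES, min_size=1, max_size=12)


class TestDecompose:
    @pytest.mark.parametrize("seq,k,expected", [
        ("MWHMC", 5, ["MWHMC"]),
        ("MWHMCA", 5, ["MWHMC", "WHMCA"]),
        ("MWXMCA", 5, []),                      # X poisons both windows
        ("ACDE", 5, []),                        # shorter than k
        ("MWUMCA", 5, []),                      # selenocysteine is non-standard
        ("MW-MC*A", 3, []),                     # gaps and stops filtered
        ("ACDEF", 1, list("ACDEF")),
    ])
    def test_windows_and_filtering(self, seq, k, expected):
        assert decompose(seq, k) == expected

    def test_lower_case_is_normalized(self):
        assert decompose(ProteinRecord("r", "mwhmca"), 5) == ["MWHMC", "WHMCA"]

    def test_invalid_k_rejected(self):
        with pytest.raises(InvalidParameterError):
            decompose("MWHMC", 0)

    @given(seq=st.text(alphabet=RESIDUES + "BXZU*-", min_size=0, max_size=40),
           k=st.integers(1, 6))
    @settings(max_examples=200, deadline=None)
    def test_matches_naive_window_scan(self, seq, k):
        standard = set(RESIDUES)
        expected = [seq[i:i + k] for i in range(len(seq) - k + 1)
                    if set(seq[i:i + k]) <= standard]
        assert decompose(seq, k) == expected


class TestBuildSpectrum:
    def test_single_record(self):
        s = build_spectrum(iter([ProteinRecord("r", "MWHMC")]), 5)
        assert s.space_size == 20**5 == 3_200_000
        assert s.count("MWHMC") == 1
        assert int(s.counts.sum()) == s.n_windows_kept == 1

    def test_duplicate_records_counted_separately(self):
        recs = [ProteinRecord("a", "MWHMCA"), ProteinRecord("b", "MWHMCA")]
        s = build_spectrum(iter(recs), 5)
        assert s.count("MWHMC") == 2 and s.count("WHMCA") == 2

    def test_windows_do_not_span_records(self):
        joined = build_spectrum(iter([ProteinRecord("r", "MWHMCAWFQCM")]), 5)
        split = build_spectrum(iter([ProteinRecord("a", "MWHMCA"),
                                     ProteinRecord("b", "WFQCM")]), 5)
        assert split.n_windows_kept == 3 < joined.n_windows_kept

    def test_k_guard(self):
        with pytest.raises(CapacityError):
            build_spectrum(iter([]), 7)

    @pytest.mark.parametrize("seed", [1, 42])
    def test_equals_brute_force_oracle(self, seed):
        proteome = generate_proteome(ProteomeSpec(
            n_proteins=100, length_dist=("uniform", {"low": 5, "high": 120}),
            ambiguity_rate=0.02, seed=seed))
        s = build_spectrum(iter(proteome.records), 5)
        oracle, kept, dropped = brute_force_counts(proteome.records, 5)
        assert s.n_windows_kept == kept and s.n_windows_dropped == dropped
        for kmer, n in oracle.items():
            assert s.count(kmer) == n
        rng = np.random.default_rng(seed)
        for code in rng.integers(0, 20**5, size=1000):
            kmer = decode_kmer(int(code), 5)
            if kmer not in oracle:
                assert s.count(kmer) == 0

    def test_window_accounting_invariant(self):
        proteome = generate_proteome(ProteomeSpec(
            n_proteins=40, ambiguity_rate=0.1, seed=9))
        s = build_spectrum(iter(proteome.records), 5)
        total = sum(max(0, len(r.sequence) - 4) for r in proteome.records)
        assert int(s.counts.sum()) == total - s.n_windows_dropped

    def test_fasta_round_trip(self, small_fasta):
        s = build_spectrum_from_fasta(small_fasta, 5)
        # p1 gives 2 windows; p2 (MWXMCAWHMCA) loses the X windows
        assert s.count("MWHMC") == 1 and s.count("WHMCA") == 2

    def test_malformed_fasta_raises(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("this is not fasta\n")
        with pytest.raises(FastaParseError):
            list(read_fasta(bad))


class TestHistogram:
    def test_single_record(self):
        s = build_spectrum(iter([ProteinRecord("r", "MWHMC")]), 5)
        assert spectrum_histogram(s) == [(0, 3_199_999), (1, 1)]

    def test_mixed_counts(self):
        recs = [ProteinRecord("a", "AAAAA"), ProteinRecord("b", "AAAAA"),
                ProteinRecord("c", "MWHMC"), ProteinRecord("d", "WFQCM")]
        s = build_spectrum(iter(recs), 5)
        assert spectrum_histogram(s) == [(0, 3_199_997), (1, 2), (2, 1)]

    def test_mass_sums_to_space_size(self):
        proteome = generate_proteome(ProteomeSpec(n_proteins=30, seed=2))
        s = build_spectrum(iter(proteome.records), 5)
        assert sum(n for _, n in spectrum_histogram(s)) == 20**5

    def test_equals_oracle_tally(self):
        proteome = generate_proteome(ProteomeSpec(n_proteins=30, seed=8))
        s = build_spectrum(iter(proteome.records), 5)
        oracle, _, _ = brute_force_counts(proteome.records, 5)
        from collections import Counter
        tally = Counter(oracle.values())
        tally[0] = 20**5 - len(oracle)
        assert dict(spectrum_histogram(s)) == dict(tally)


class TestFrequencyClasses:
    def test_zero_class_is_never_expressed_set(self):
        s = build_spectrum(iter([ProteinRecord("r", "MWHMC")]), 5)
        zero, one = frequency_classes(s, [0, 1])
        assert len(one) == 1 and "MWHMC" in one
        assert len(zero) == 3_199_999 and "MWHMC" not in zero

    def test_unmatched_target_gives_empty_class(self):
        s = build_spectrum(iter([ProteinRecord("r", "MWHMC")]), 5)
        (five,) = frequency_classes(s, [5])
        assert len(five) == 0 and five.members == []

    def test_planted_kmer_lands_in_its_class(self):
        proteome = generate_proteome(ProteomeSpec(
            n_proteins=60, planted=[("AAAAA", 50)], seed=3))
        s = build_spectrum(iter(proteome.records), 5)
        (fifty,) = frequency_classes(s, [50])
        assert "AAAAA" in fifty

    def test_duplicate_targets_rejected(self):
        s = build_spectrum(iter([ProteinRecord("r", "MWHMC")]), 5)
        with pytest.raises(InvalidParameterError):
            frequency_classes(s, [0, 0])

    def test_members_are_lexicographic(self):
        recs = [ProteinRecord("a", "WFQCM"), ProteinRecord("b", "AAAAA")]
        s = build_spectrum(iter(recs), 5)
        (one,) = frequency_classes(s, [1])
        assert one.members == sorted(one.members)


class TestInverseSequences:
    @pytest.mark.parametrize("pep,expected", [
        ("MWHMC", "CMHWM"), ("WFQCM", "MCQFW"), ("WWWWW", "WWWWW"),
    ])
    def test_reversal(self, pep, expected):
        assert inverse_sequence(pep) == expected

    def test_non_standard_letter_rejected(self):
        with pytest.raises(InvalidResidueError):
            inverse_sequence("MWXMC")

    @given(pep=peptides)
    @settings(max_examples=200, deadline=None)
    def test_involution_and_composition(self, pep):
        inv = inverse_sequence(pep)
        assert inverse_sequence(inv) == pep
        assert sorted(inv) == sorted(pep)

    def test_profile_reports_inverse_counts(self):
        # proteome contains CMHWM three times but never MWHMC
        proteome = generate_proteome(ProteomeSpec(
            n_proteins=40, planted=[("CMHWM", 3), ("MWHMC", 0)], seed=4))
        s = build_spectrum(iter(proteome.records), 5)
        (zero,) = frequency_classes(s, [0])
        prof = inverse_frequency_profile(zero, s)
        assert prof["MWHMC"] == ("CMHWM", 3)
        assert prof.max_count >= 3 and prof.min_count == 0

    def test_palindromic_zero_class_member_has_zero_inverse(self):
        proteome = generate_proteome(ProteomeSpec(n_proteins=10, seed=6))
        s = build_spectrum(iter(proteome.records), 5)
        (zero,) = frequency_classes(s, [0])
        prof = inverse_frequency_profile(zero, s)
        palindromic = prof.member_codes == prof.inverse_codes
        assert palindromic.any()
        assert (prof.inverse_counts[palindromic] == 0).all()

    def test_reversal_closed_proteome_is_symmetric(self):
        proteome = generate_proteome(ProteomeSpec(
            n_proteins=25, reversal_closed=True, seed=7))
        s = build_spectrum(iter(proteome.records), 5)
        perm = reversal_permutation(5)
        assert (s.counts == s.counts[perm]).all()


class TestEncoding:
    @given(pep=st.text(alphabet=RESIDUES, min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_encode_decode_round_trip(self, pep):
        assert decode_kmer(encode_kmer(pep), len(pep)) == pep


def test_spectrum_tsv_export(tmp_path):
    s = build_spectrum(iter([ProteinRecord("r", "MWHMCA")]), 5)
    out = tmp_path / "spec.tsv"
    write_spectrum_tsv(s, out, include_zero_rows=False, header_meta={"k": 5})
    lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
    assert lines == ["kmer\tcount", "MWHMC\t1", "WHMCA\t1"]
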
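"""Shared fixtures and independent oracles.

The brute-force oracle counts k-mers by a naive per-position substring scan,
deliberately independent of the dense-array implementation it checks.
"""

from __future__ import annotations

from collections import Counter

import pytest

from pentamod.spectrum import RESIDUES, ProteinRecord

STANDARD = set(RESIDUES)


def brute_force_counts(records, k):
    """Naive per-position window scan: the independent spectrum oracle."""
    counts = Counter()
    kept = dropped = 0
    for rec in records:
        seq = rec.sequence if isinstance(rec, ProteinRecord) else rec.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if set(window) <= STANDARD:
                counts[window] += 1
                kept += 1
            else:
                dropped += 1
    return counts, kept, dropped


@pytest.fixture
def small_fasta(tmp_path):
    """Two-record FASTA with one ambiguity letter and a wrapped sequence."""
    path = tmp_path / "small.fasta"
    path.write_text(
        ">p1 first\nMWHMCA\n"
        ">p2 wrapped\nMWXMC\nAWHMCA\n"
    )
    return path


@pytest.fixture
def toy_usage_table(tmp_path):
    """Minimal codon-usage TSV covering the residues of MWHMC and WWWWW."""
    rows = [
        ("ATG", "M", 1.0),
        ("TGG", "W", 1.0),
        ("CAT", "H", 0.6), ("CAC", "H", 0.4),
        ("TGC", "C", 0.6), ("TGT", "C", 0.4),
    ]
    path = tmp_path / "usage.tsv"
    path.write_text("# codon\tresidue\tfraction\n" +
                    "".join(f"{c}\t{a}\t{f}\n" for c, a, f in rows))
    return path
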
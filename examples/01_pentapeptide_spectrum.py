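"""Build a pentapeptide frequency spectrum from a synthetic proteome.

Generates a small proteome with three k-mers planted at known occurrence
counts, counts every overlapping 5-residue window, and prints the head of the
occurrence histogram plus the planted counts.  The histogram's second column
sums to 3,200,000 — the complete pentapeptide space, zero-count k-mers
included.
"""

from pentamod import ProteomeSpec, build_spectrum, generate_proteome, spectrum_histogram

proteome = generate_proteome(ProteomeSpec(
    n_proteins=120,
    planted=[("AAAAA", 50), ("MWHMC", 5), ("WFQCM", 0)],
    ambiguity_rate=0.01,
    seed=42,
))

spectrum = build_spectrum(iter(proteome.records), k=5)
print(f"records: {spectrum.n_sequences}, windows kept: {spectrum.n_windows_kept}, "
      f"dropped (ambiguous): {spectrum.n_windows_dropped}")

print("\noccurrence_count  n_kmers   (head of histogram)")
for occ, n in spectrum_histogram(spectrum)[:5]:
    print(f"{occ:>16d}  {n}")

print("\nplanted truth vs measured proteomic frequency:")
for kmer, want in proteome.truth.items():
    print(f"  {kmer}: planted {want}, measured {spectrum.count(kmer)}")
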
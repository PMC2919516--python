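"""Select frequency classes and compare their physico-chemical scores.

Frequency classes group all pentapeptides sharing one proteomic frequency
(the class at 0 is the never-expressed set).  Here the singleton and
five-occurrence classes of a synthetic proteome are scored by codon number
(summed codon multiplicity of the five residues, an integer in [5, 30]) and
compared with a one-way ANOVA.  A small p-value says the class means differ;
with random background both classes are composition-matched, so p is usually
large.
"""

from pentamod import (
    ProteomeSpec,
    anova_oneway,
    build_spectrum,
    codon_number_scale,
    frequency_classes,
    generate_proteome,
    score_class,
)

# plant six pentapeptides at exactly five occurrences so the 5x class is
# populated; the singleton class fills itself from random background
proteome = generate_proteome(ProteomeSpec(
    n_proteins=200,
    planted=[(p, 5) for p in ("MWHMC", "WFQCM", "AAAAA", "WYWYW", "LKKHG", "PQRST")],
    seed=11))
spectrum = build_spectrum(iter(proteome.records), k=5)

one, five = frequency_classes(spectrum, [1, 5], labels=["once", "5x"])
print(f"class 'once' ({one.target_count} occurrence): {len(one)} pentapeptides")
print(f"class '5x'   ({five.target_count} occurrences): {len(five)} pentapeptides")

scale = codon_number_scale()
groups = [score_class(one, scale, "sum"), score_class(five, scale, "sum")]
result = anova_oneway(groups, labels=["once", "5x"])
print(f"\ncodon-number ANOVA: F = {result.F:.3f}, p = {result.p:.3f} "
      f"(df = {result.df_between}, {result.df_within})")
for label, box in zip(result.group_labels, result.boxplots):
    print(f"  {label}: median {box.median:.0f}, IQR [{box.q1:.0f}, {box.q3:.0f}], "
          f"{len(box.outliers)} outliers")
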
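"""Rater agreement on the bundled 1958-tumor grade-assignment table.

Computes observed agreement and Cohen's kappa (plain and linear-weighted)
between the automated overall grades and a human rater.
"""

from lunggrade import synthetic
from lunggrade.evaluation import cohens_kappa

cm = synthetic.table1_fixture()
print(cm.to_dataframe())

plain = cohens_kappa(cm)
weighted = cohens_kappa(cm, weighting="linear")
matched = sum(cm.counts[cm.categories_rows.index(f"Grade {g}"), g - 1] for g in range(1, 5))
print(f"\nmatched grades: {matched} of {cm.n} ({matched / cm.n:.1%})")
print(f"kappa = {plain.kappa:.3f} (95% CI {plain.ci95[0]:.3f}-{plain.ci95[1]:.3f})")
print(f"linear-weighted kappa = {weighted.kappa:.3f}")
# Weighted kappa credits near-miss calls (e.g. Grade 2 vs Grade 3), so it
# exceeds the unweighted value when disagreements cluster near the diagonal.
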
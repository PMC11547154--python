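"""Tumor-vs-normal methylation comparisons on a synthetic cohort.

Simulates the default 140-tumor cohort, tests each lncRNA gene with the
Mann-Whitney U (BH-adjusted across the panel), and correlates methylation
with expression.
"""

from lncmeth import (
    CohortSpec,
    compare_design,
    methylation_expression_correlation,
    simulate_cohort,
)

frame, _ = simulate_cohort(CohortSpec(seed=1))

print("design: primary tumors (T) vs matched normal tissue (N)")
for r in compare_design(frame, "T_vs_N"):
    print(f"  {r.gene:<12} U={r.U:7.0f}  p={r.p:9.2e}  q={r.q:9.2e}  {r.tier}")
# '#' marks p < 1e-4: with the planted +30-point PMR shift every gene is
# detected as hypermethylated in tumors.

print("\nmethylation-expression coupling (Spearman, T+N samples):")
for c in methylation_expression_correlation(frame):
    print(f"  {c.gene:<12} rs={c.rs:+.2f}  p={c.p:.2e}  n={c.n}")
# Negative rs throughout: higher promoter methylation, lower transcript.
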
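"""Simulate a three-group cohort and compare group orderness.

Emulates a genotype comparison: three groups of fibres generated at
different order levels (best-candidate k = 12, 4 and 1), scored per fibre,
then summarized with a one-way ANOVA and Bonferroni pairwise comparisons —
the same aggregation used for real coordinate files via run_pipeline or the
`fibreorder run` command.
"""

import fibreorder as fo
from fibreorder.io import RunConfig

spec = fo.GeneratorSpec(
    groups=(
        fo.GroupSpec("organized", 10, order_k=12),
        fo.GroupSpec("intermediate", 10, order_k=4),
        fo.GroupSpec("random", 10, order_k=1),
    ),
    n_nuclei=100,
    radius=20.0,
    length=500.0,
    master_seed=3,
)
config = RunConfig(mr_reps=300, mo_restarts=2, mo_iterations=1000, master_seed=3)

results = [fo.score_fibre(f, config) for f in fo.simulate_cohort(spec)]
summaries, anova = fo.compare_groups(results)

for s in summaries:
    print(f"{s.group:13s} mean g = {s.mean_g_percent:6.2f} % +- {s.se_g_percent:.2f} (n={s.n_fibres})")
print(f"\nANOVA: F({anova.df_between}, {anova.df_within}) = {anova.F:.2f}, p = {anova.p:.2e}")
for (a, b), p in sorted(anova.pairwise_bonferroni_p.items()):
    print(f"  {a} vs {b}: Bonferroni p = {p:.2e}")
print()
print("Group means separate in the generated order (k = 12 > 4 > 1); the")
print("ANOVA p-value says the separation far exceeds the per-fibre noise.")
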
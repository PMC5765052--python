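"""Two-group study statistics on a simulated WT-vs-Ach table.

Simulates a 40-animal study where the growth-plate volume is reduced by
2 SD in the Ach group at 3 weeks only, then runs the Welch comparisons —
reproducing the 3-week-significant / 6-week-not pattern typical of this
disease model.
"""

from skelemorph import phantoms, stats

table = phantoms.generate_study(
    n_per_group=10,
    effects={"gp_volume_mm3": (-2.0, 0.0)},
    seed=42,
)
for c in stats.summarize_groups(table):
    if c.measurement_name != "gp_volume_mm3":
        continue
    print(f"{c.measurement_name} at {c.age_weeks} wk: "
          f"WT {c.mean_wt:.3f}±{c.sem_wt:.3f} vs Ach {c.mean_ach:.3f}±{c.sem_ach:.3f} "
          f"(mean±SEM), t={c.t_stat:.2f}, df={c.df_welch:.1f}, p={c.p_value:.2g} {c.stars}")

chi2, df, p = stats.chi_square_gof([640, 920], [0.5, 0.5])
print(f"birth genotype ratio 640:920 vs Mendelian 50:50 -> chi2={chi2:.2f}, p={p:.2g}")
print("Stars: * 0.01<p<0.05, ** 0.001<p<0.01, *** 0.0001<p<0.001, **** p<0.0001.")
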
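"""Full pipeline: generate, measure and analyse a synthetic corpus.

Runs the desk-scale study conditions (four occasional drawers plus one
longitudinal individual balanced over 19 three-month periods), then
prints what the statistics stage found: retained PCA dimensions, the
inter-individual test on the first dimension, and the permutation
linear model of season and period for the longitudinal individual.
"""
import numpy as np

from apedraw import AnalysisConfig, RunConfig, run_pipeline

config = RunConfig(
    seed=3,
    counts={"Gypsy": 8, "Julie": 8, "Yuki": 8, "Kiki": 8, "Molly": 114},
    px_per_mm=1.0,
    stats=AnalysisConfig(B=999, seed=3),
)
metrics, report = run_pipeline(config)

print(f"measured {len(metrics)} drawings; 11 quantitative variables enter the PCA")
pca = report.pca_inter
print(f"\ninter-individual PCA: {pca.retained} dimensions retained "
      f"(leading eigenvalues {np.round(pca.eigenvalues[:4], 2)}; "
      f"{pca.explained_pct_retained.sum():.1f}% of variance)")
kw = report.kruskal_dims["Dim1"]
print(f"Kruskal-Wallis on Dim1: chi2({kw.df}) = {kw.statistic:.2f}, p = {kw.p_value:.2g}")
print("letter groups (shared letter = not separable):", kw.letters)

print(f"\nlongitudinal arm ({report.longitudinal_individual}):")
for dim, lm in report.perm_lm_dims.items():
    print(f"  {dim}: season p = {lm.p_perm['season']:.4g}, period p = {lm.p_perm['period']:.4g}, "
          f"VIF = {max(lm.vif.values()):.2f}")
# Expected at these defaults: three retained dimensions; a strong
# individual effect on the filling dimension (p << 0.001); season and
# period significant only on the filling dimension, reflecting the
# planted winter deficit and declining filling trend.
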
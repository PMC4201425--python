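"""Fit the 15-model GLMM candidate set over pseudo-absence iterations.

Each candidate is a weighted binomial GLMM (logit link, effort offset,
2x2-cell random intercept) fitted on every pseudo-absence draw; models are
ranked by AICc and the table aggregates median rank, evidence weights,
deviance explained, Cohen's kappa and Nakagawa-Schielzeth R² across draws.
"""

import koalasdm as k

grid = k.make_landscape(40, 40, seed=1)
_, presence = k.simulate_occupancy(grid, k.DEFAULT_TRUTH, seed=2)
reports = k.simulate_reports(presence, grid, n_reports=700, seed=3)
occurrence, _ = k.rasterize_reports(k.clean_reports(reports)[0], grid)

designs = k.build_design_iterations(occurrence, grid, n_iterations=5, base_seed=10)
specs = k.build_model_set()
result = k.rank_models(designs, specs, n_folds=5)

cols = ["model", "median_rank", "waicc_mean", "pct_deviance",
        "cv_error_mean", "kappa_mean", "r2m", "r2c"]
print(result.table[cols].head(5).round(3).to_string(index=False))
print()

top = result.table.iloc[0]
print(f"top-ranked model: {top['model']} (wAICc {top['waicc_mean']:.3f})")
print("-> with data generated from the full environmental+roads structure,")
print("   that structure wins the AICc ranking; its evidence weight is the")
print("   probability it is the best model in the candidate set.")

eff = k.effect_sizes(result.fits, result.weights)
print("\nmodel-averaged effect sizes (beta/SE, weight-averaged):")
print(eff.round(2).to_string(index=False))
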
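"""Two-stage model selection: 15-variant univariate screen, then a model set.

Stage 1 picks each covariate's best surface parameterization (transformation
x window) by consensus mean rank across AICc, DIC, R2_beta and R2_m;
stage 2 ranks a declarative multivariate model set on the winners.
"""

from ibrkit import (
    LandscapeParams,
    MCMCSettings,
    PairwiseSimParams,
    build_model_set,
    build_variant_family,
    pairwise_resistance_matrix,
    place_groups,
    simulate_landscape,
    simulate_pairwise_response,
    univariate_screen,
    run_model_set,
)

mcmc = MCMCSettings(chains=2, iterations=1500, burnin=500)
land_a = simulate_landscape(LandscapeParams(nrows=40, ncols=40, cell_size=1000.0,
                                            correlation_range=8000.0,
                                            value_range=(1.0, 100.0), seed=61))
land_b = simulate_landscape(LandscapeParams(nrows=40, ncols=40, cell_size=1000.0,
                                            correlation_range=8000.0,
                                            value_range=(1.0, 100.0), seed=62))
groups = place_groups(land_a, 15, min_separation=4000.0, seed=63)

fam_a = build_variant_family("VARA", land_a)
resist_a = {v.label: pairwise_resistance_matrix(s, groups) for v, s in fam_a}
gen = next(v for v, _ in fam_a if v.transformation == "high" and v.alpha == 10.0
           and v.window_radius == 1500.0)
y = simulate_pairwise_response(
    resist_a[gen.label],
    PairwiseSimParams(beta=(1.0,), sigma_u=0.1, sigma_e=0.1, seed=64),
)

table, best, _ = univariate_screen(fam_a, groups, y, mcmc=mcmc, seed=65,
                                   resistances=resist_a)
print(f"screen over {len(table)} variants; generative variant: {gen.label}")
print(table.sort_values("mean_rank")[["mean_rank", "sd_rank"]].head(3)
      .to_string(float_format=lambda v: f"{v:.2f}"))
print(f"winner: {best.label}")
print("  -> the variant the data were generated from wins the consensus rank")

fam_b = build_variant_family("VARB", land_b)
surf_b = next(s for v, s in fam_b
              if v.label == gen.label.replace("VARA", "VARB"))
resist_b = pairwise_resistance_matrix(surf_b, groups)
models = build_model_set([(), ("VARA",), ("VARB",)])
ranked, fits = run_model_set(models, y, {"VARA": resist_a[best.label],
                                         "VARB": resist_b},
                             mcmc=mcmc, seed=66)
print("\nmodel set (UNDIF null, VARA, VARB):")
print(ranked[["model", "mean_rank", "sd_rank"]]
      .to_string(float_format=lambda v: f"{v:.2f}"))
print("  -> the null ranks last when the data carry a landscape signal")
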
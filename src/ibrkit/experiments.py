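"""Simulation studies validating the pipeline end to end.

Each function builds its own synthetic inputs, runs the relevant pipeline
stages and returns summary statistics (error bounds, recovery rates). They
are the package's reproducible validation suite: the acceptance tests and
the acceptance script both call them.

Study conditions are fixed here as the package's reference conditions. The
desk-scale end-to-end runs use 40 x 40 rasters with 1-km cells (so the fixed
focal-window radii of 1.5 / 6.44 / 17.33 km remain distinguishable on the
extent), 15 focal groups, and invented strong effect sizes (there is no
empirical generative model for how differentiation scales with resistance);
see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuits import (
    build_network,
    effective_resistance,
    effective_resistance_dense,
    pairwise_resistance_matrix,
)
from .combine import coefficient_weights, combine_surfaces, validate_combined
from .errors import CombinationError
from .mlpe import PairwiseModelData, dic, fit_mlpe_mcmc, fit_mlpe_reml
from .popgen import PairwiseMatrix
from .raster import Raster
from .selection import (
    MCMCSettings,
    build_model_set,
    rank_models,
    run_model_set,
    univariate_screen,
)
from .surfaces import SurfaceVariant, build_variant_family
from .synthetic import (
    LandscapeParams,
    PairwiseSimParams,
    place_groups,
    simulate_landscape,
    simulate_pairwise_response,
)

__all__ = [
    "circuit_oracle_check",
    "mlpe_recovery",
    "reml_ols_equivalence",
    "mcmc_agreement",
    "EndToEndConditions",
    "selection_recovery",
]


def circuit_oracle_check(
    n_rasters: int = 50, max_size: int = 20, seed: int = 0
) -> dict[str, float]:
    """Sparse circuit solver vs dense Laplacian-pseudoinverse oracle.

    Random strictly positive rasters up to ``max_size`` square, alternating
    4- and 8-connectivity, three random node pairs each; returns the maximum
    relative disagreement observed.
    """
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    checked = 0
    for k in range(n_rasters):
        nr = int(rng.integers(3, max_size + 1))
        nc = int(rng.integers(3, max_size + 1))
        vals = np.exp(rng.normal(0.0, 1.0, size=(nr, nc)))
        raster = Raster(values=vals, cell_size=100.0)
        net = build_network(raster, connectivity=4 if k % 2 == 0 else 8)
        for _ in range(3):
            s, t = rng.choice(net.n_nodes, size=2, replace=False)
            sparse_r = effective_resistance(net, int(s), int(t))
            dense_r = effective_resistance_dense(net, int(s), int(t))
            max_rel = max(max_rel, abs(sparse_r - dense_r) / abs(dense_r))
            checked += 1
    return {"max_rel_err": max_rel, "n_checked": checked}


def _reference_resistance(n_groups: int, seed: int) -> PairwiseMatrix:
    """Circuit resistances on one simulated landscape, reused across reps."""
    land = simulate_landscape(
        LandscapeParams(nrows=40, ncols=40, cell_size=1000.0,
                        correlation_range=8000.0, value_range=(1.0, 100.0),
                        seed=seed)
    )
    groups = place_groups(land, n_groups, min_separation=3000.0, seed=seed)
    return pairwise_resistance_matrix(land, groups)


def mlpe_recovery(
    n_reps: int = 500,
    seed: int = 0,
    n_groups: int = 30,
    beta1: float = 0.5,
    sigma_u: float = 0.2,
    sigma_e: float = 0.1,
) -> dict[str, float]:
    """Parameter recovery of the REML fit on MLPE-structured data.

    One circuit-resistance predictor matrix is computed once; each replicate
    draws a fresh response at the stated truth, fits by REML, and the mean
    slope bias and 95%-interval coverage are returned.
    """
    resist = _reference_resistance(n_groups, seed)
    betas = np.empty(n_reps)
    covered = np.zeros(n_reps, dtype=bool)
    for rep in range(n_reps):
        y = simulate_pairwise_response(
            resist,
            PairwiseSimParams(beta0=0.0, beta=(beta1,), sigma_u=sigma_u,
                              sigma_e=sigma_e, seed=int(seed + 1000 + rep)),
        )
        data = PairwiseModelData.from_matrices(y, {"resist": resist})
        fit = fit_mlpe_reml(data)
        b = fit.beta[1]
        betas[rep] = b
        lo, hi = fit.confint(0.95)[1]
        covered[rep] = lo <= beta1 <= hi
    return {
        "mean_bias": float(betas.mean() - beta1),
        "coverage": float(covered.mean()),
        "mean_beta": float(betas.mean()),
        "sd_beta": float(betas.std(ddof=1)),
        "n_reps": n_reps,
    }


def reml_ols_equivalence(seed: int = 0, n_groups: int = 30) -> dict[str, float]:
    """REML at sigma_u^2 = 0 vs closed-form OLS on sigma_u = 0 data.

    The variance ratio is pinned at the boundary (the identity the model
    guarantees); returns the largest coefficient and residual-variance
    disagreement against the normal-equation solution.
    """
    resist = _reference_resistance(n_groups, seed)
    y = simulate_pairwise_response(
        resist,
        PairwiseSimParams(beta0=0.1, beta=(0.5,), sigma_u=0.0, sigma_e=0.1,
                          seed=seed + 17),
    )
    data = PairwiseModelData.from_matrices(y, {"resist": resist})
    fit = fit_mlpe_reml(data, fix_gamma=0.0)
    x, _ = data.design(None)
    beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta_ols
    s2_ols = float(resid @ resid) / (len(y) - x.shape[1])
    return {
        "max_beta_diff": float(np.max(np.abs(fit.beta - beta_ols))),
        "sigma_e2_diff": abs(fit.sigma_e2 - s2_ols),
        "free_fit_sigma_u2": fit_mlpe_reml(data).sigma_u2,
    }


def mcmc_agreement(
    seed: int = 0,
    n_groups: int = 30,
    iterations: int = 11000,
    burnin: int = 1000,
) -> dict[str, float]:
    """REML vs Gibbs posterior means, and DIC stability across runs.

    One recovery-style dataset; the posterior-mean slope is compared with the
    REML estimate, and DIC from two independently seeded samplers (10^4
    post-burnin draws each by default) is compared run to run.
    """
    resist = _reference_resistance(n_groups, seed)
    y = simulate_pairwise_response(
        resist,
        PairwiseSimParams(beta0=0.0, beta=(0.5,), sigma_u=0.2, sigma_e=0.1,
                          seed=seed + 29),
    )
    data = PairwiseModelData.from_matrices(y, {"resist": resist})
    fit = fit_mlpe_reml(data)
    m1 = fit_mlpe_mcmc(data, iterations=iterations, burnin=burnin, seed=seed + 1)
    m2 = fit_mlpe_mcmc(data, iterations=iterations, burnin=burnin, seed=seed + 2)
    d1, d2 = dic(m1), dic(m2)
    return {
        "beta_reml": float(fit.beta[1]),
        "beta_mcmc": float(m1.posterior_mean_beta()[1]),
        "beta_abs_diff": abs(fit.beta[1] - m1.posterior_mean_beta()[1]),
        "dic_run1": d1,
        "dic_run2": d2,
        "dic_abs_diff": abs(d1 - d2),
    }


@dataclass(frozen=True)
class EndToEndConditions:
    """Desk-scale study conditions for the selection-recovery experiment."""

    nrows: int = 40
    ncols: int = 40
    cell_size: float = 1000.0
    correlation_range: float = 8000.0
    n_groups: int = 15
    min_separation: float = 4000.0
    generative_transformation: str = "high"
    generative_alpha: float = 10.0
    generative_window: float = 1500.0
    beta_uni: float = 1.0
    beta_multi: tuple[float, float] = (0.7, 0.7)
    sigma_u: float = 0.1
    sigma_e: float = 0.1
    mcmc: MCMCSettings = MCMCSettings(chains=2, iterations=1500, burnin=500)


def _generative_label(cond: EndToEndConditions, variable: str) -> str:
    return SurfaceVariant(
        variable=variable,
        transformation=cond.generative_transformation,
        alpha=cond.generative_alpha,
        window_radius=cond.generative_window,
    ).label


def selection_recovery(
    n_reps: int = 20,
    seed: int = 0,
    conditions: EndToEndConditions = EndToEndConditions(),
) -> dict[str, float]:
    """End-to-end recovery of the generative surface variant and model.

    Per replicate: two synthetic covariate landscapes, one focal-group set,
    both 15-variant families and their circuit resistances. A univariate
    response generated from variable A's generative variant feeds the
    15-variant screen; a two-variable response feeds a 4-model set (UNDIF,
    A, B, A+B) and the coefficient-weighted combined surface. Returns the
    fractions of replicates in which (i) the generative variant wins the
    screen, (ii) the undifferentiated null ranks last, (iii) the generative
    two-variable model attains best or tied-best mean rank, and (iv) the
    combined surface out-ranks both single-component models.
    """
    cond = conditions
    screen_hits = undif_last = multi_best = combined_best = 0
    combined_errors = 0
    gen_a = _generative_label(cond, "VARA")
    gen_b = _generative_label(cond, "VARB")

    for rep in range(n_reps):
        rep_seed = int(seed + 10_000 * (rep + 1))
        land_a = simulate_landscape(LandscapeParams(
            nrows=cond.nrows, ncols=cond.ncols, cell_size=cond.cell_size,
            correlation_range=cond.correlation_range, value_range=(1.0, 100.0),
            seed=rep_seed,
        ))
        land_b = simulate_landscape(LandscapeParams(
            nrows=cond.nrows, ncols=cond.ncols, cell_size=cond.cell_size,
            correlation_range=cond.correlation_range, value_range=(1.0, 100.0),
            seed=rep_seed + 1,
        ))
        groups = place_groups(land_a, cond.n_groups,
                              min_separation=cond.min_separation,
                              seed=rep_seed + 2)

        fam_a = build_variant_family("VARA", land_a)
        fam_b = build_variant_family("VARB", land_b)
        resist_a = {
            v.label: pairwise_resistance_matrix(surf, groups)
            for v, surf in fam_a
        }
        resist_b = {
            v.label: pairwise_resistance_matrix(surf, groups)
            for v, surf in fam_b
        }

        # (i) univariate screen recovery
        y_uni = simulate_pairwise_response(
            resist_a[gen_a],
            PairwiseSimParams(beta0=0.0, beta=(cond.beta_uni,),
                              sigma_u=cond.sigma_u, sigma_e=cond.sigma_e,
                              seed=rep_seed + 3),
        )
        _, winner, _ = univariate_screen(
            fam_a, groups, y_uni, mcmc=cond.mcmc, seed=rep_seed + 4,
            resistances=resist_a,
        )
        screen_hits += winner.label == gen_a

        # (ii, iii) 4-model multivariate set on a two-variable response
        y_multi = simulate_pairwise_response(
            [resist_a[gen_a], resist_b[gen_b]],
            PairwiseSimParams(beta0=0.0, beta=cond.beta_multi,
                              sigma_u=cond.sigma_u, sigma_e=cond.sigma_e,
                              seed=rep_seed + 5),
        )
        models = build_model_set([(), ("VARA",), ("VARB",), ("VARA", "VARB")])
        preds = {"VARA": resist_a[gen_a], "VARB": resist_b[gen_b]}
        ranked, fits = run_model_set(models, y_multi, preds, mcmc=cond.mcmc,
                                     seed=rep_seed + 6)
        undif_last += ranked.loc[1, "mean_rank"] == ranked["mean_rank"].max()
        multi_best += ranked.loc[4, "mean_rank"] == ranked["mean_rank"].min()

        # (iv) coefficient-weighted combined surface vs single components;
        # combination acts on the pre-window surfaces of the generative
        # transformation family, the window is applied afterwards
        try:
            weights = coefficient_weights(
                fits[4], ["VARA", "VARB"],
                transformation_family=(
                    f"{cond.generative_transformation}{cond.generative_alpha:g}"
                ),
            )
            combined = combine_surfaces(weights, {
                "VARA": _transformed_base(land_a, cond),
                "VARB": _transformed_base(land_b, cond),
            })
            crit_comb, _, _ = validate_combined(
                combined, groups, y_multi,
                window_radius=cond.generative_window,
                mcmc=cond.mcmc, seed=rep_seed + 7,
            )
            crit_a = _univariate_criteria(resist_a[gen_a], y_multi, cond,
                                          rep_seed + 8)
            crit_b = _univariate_criteria(resist_b[gen_b], y_multi, cond,
                                          rep_seed + 9)
            tbl = pd.DataFrame.from_dict(
                {"combined": crit_comb, "VARA": crit_a, "VARB": crit_b},
                orient="index",
            )
            mean_rank = rank_models(tbl)["mean_rank"]
            combined_best += (
                mean_rank["combined"] < mean_rank["VARA"]
                and mean_rank["combined"] < mean_rank["VARB"]
            )
        except CombinationError:
            combined_errors += 1

    return {
        "screen_recovery_rate": screen_hits / n_reps,
        "undif_last_rate": undif_last / n_reps,
        "multivariate_best_rate": multi_best / n_reps,
        "combined_beats_components_rate": combined_best / n_reps,
        "combined_weight_errors": combined_errors,
        "n_reps": n_reps,
    }


def _transformed_base(land: Raster, cond: EndToEndConditions) -> Raster:
    from .surfaces import transform_high, transform_low

    if cond.generative_transformation == "high":
        return transform_high(land, cond.generative_alpha)
    if cond.generative_transformation == "low":
        return transform_low(land, cond.generative_alpha)
    return land


def _univariate_criteria(resist: PairwiseMatrix, y, cond: EndToEndConditions,
                         seed: int) -> dict[str, float]:
    from .selection import compute_criteria

    data = PairwiseModelData.from_matrices(y, {"resist": resist})
    crit, _, _ = compute_criteria(data, ["resist"], mcmc=cond.mcmc, seed=seed)
    return crit
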
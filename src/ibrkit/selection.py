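"""Two-stage model selection by four-criterion consensus rank.

Stage 1 (:func:`univariate_screen`) fits a univariate MLPE model of genetic
differentiation against the pairwise resistances of every member of a
covariate's surface family (15 variants, or 5 for window-free road
surfaces) and keeps the variant with the best (lowest) mean rank across the
four criteria — AICc, DIC, R2_beta and R2_m.

Stage 2 (:func:`run_model_set`) fits a declarative multivariate model set —
by default the 22 dispersal-hypothesis models over three seasonal habitat
suitability indices (NEST, SUMMER, WINTER), five landscape components (FOR,
SAGE, AGRIC, ROAD, RUGG) and the undifferentiated null UNDIF — using each
variable's screen-winning resistances, and ranks the set the same way.

Because the four criteria disagree in known ways (the F-based marginal R^2
prefers complex models, REML information criteria are contested), no single
criterion is trusted: models are ranked per criterion, and the mean and SD of
the four ranks give a consensus value and an agreement estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circuits import FocalGroup, pairwise_resistance_matrix
from .errors import ConnectivityError, ParameterError
from .mlpe import (
    MCMCFit,
    MLPEFit,
    PairwiseModelData,
    aicc,
    dic,
    fit_mlpe_mcmc,
    fit_mlpe_reml,
    r2_beta,
    r2_m,
)
from .popgen import PairwiseMatrix
from .raster import Raster
from .surfaces import SurfaceVariant

__all__ = [
    "ModelSpec",
    "MCMCSettings",
    "build_model_set",
    "compute_criteria",
    "rank_models",
    "univariate_screen",
    "run_model_set",
    "criterion_rank_correlations",
]

CRITERIA = ("aicc", "dic", "r2beta", "r2m")
#: higher is better for the marginal R^2 criteria, lower for AICc and DIC
_ASCENDING = {"aicc": True, "dic": True, "r2beta": False, "r2m": False}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: an id and its predictor variables.

    An empty predictor tuple is the undifferentiated null (intercept plus the
    MLPE random structure only).
    """

    id: int
    predictors: tuple[str, ...]

    @property
    def label(self) -> str:
        return "GEN~" + ("+".join(self.predictors) if self.predictors else "UNDIF")


#: The default 22-model dispersal-hypothesis set (UNDIF null, three habitat
#: suitability indices, and all considered landscape-component combinations).
_DEFAULT_MODELS: tuple[tuple[str, ...], ...] = (
    (),  # 1  UNDIF
    ("NEST",),  # 2
    ("SUMMER",),  # 3
    ("WINTER",),  # 4
    ("FOR",),  # 5
    ("FOR", "RUGG"),  # 6
    ("FOR", "ROAD"),  # 7
    ("FOR", "ROAD", "AGRIC"),  # 8
    ("FOR", "AGRIC"),  # 9
    ("SAGE",),  # 10
    ("SAGE", "RUGG"),  # 11
    ("SAGE", "ROAD"),  # 12
    ("SAGE", "ROAD", "AGRIC"),  # 13
    ("SAGE", "AGRIC"),  # 14
    ("FOR", "SAGE"),  # 15
    ("FOR", "SAGE", "RUGG"),  # 16
    ("FOR", "SAGE", "ROAD"),  # 17
    ("FOR", "SAGE", "ROAD", "AGRIC"),  # 18
    ("FOR", "SAGE", "AGRIC"),  # 19
    ("ROAD",),  # 20
    ("ROAD", "AGRIC"),  # 21
    ("AGRIC",),  # 22
)


@dataclass(frozen=True)
class MCMCSettings:
    """Gibbs-sampler settings used wherever DIC is needed."""

    chains: int = 2
    iterations: int = 5000
    burnin: int = 1000


def build_model_set(
    variables: list[tuple[str, ...]] | None = None,
) -> list[ModelSpec]:
    """Build the candidate model set (default: the standard 22 models).

    ``variables`` overrides the default with a custom list of predictor
    tuples (an empty tuple is the undifferentiated null); ids are assigned
    1..M in order.
    """
    specs = _DEFAULT_MODELS if variables is None else [tuple(v) for v in variables]
    seen = set()
    for preds in specs:
        if len(set(preds)) != len(preds):
            raise ParameterError(f"duplicate predictor in model {preds}")
        if preds in seen:
            raise ParameterError(f"duplicate model {preds}")
        seen.add(preds)
    return [ModelSpec(id=i + 1, predictors=tuple(p)) for i, p in enumerate(specs)]


def compute_criteria(
    data: PairwiseModelData,
    predictors: list[str],
    mcmc: MCMCSettings = MCMCSettings(),
    seed: int = 0,
    ddf_method: str = "satterthwaite",
) -> tuple[dict[str, float], MLPEFit, MCMCFit]:
    """All four model-assessment criteria for one predictor subset."""
    fit = fit_mlpe_reml(data, predictors)
    mfit = fit_mlpe_mcmc(
        data, predictors, chains=mcmc.chains, iterations=mcmc.iterations,
        burnin=mcmc.burnin, seed=seed,
    )
    crit = dict(
        aicc=aicc(fit),
        dic=dic(mfit),
        r2beta=r2_beta(fit, ddf_method=ddf_method),
        r2m=r2_m(fit),
    )
    return crit, fit, mfit


def rank_models(criteria: pd.DataFrame) -> pd.DataFrame:
    """Consensus-rank a criteria table.

    ``criteria`` needs columns ``aicc, dic, r2beta, r2m`` (lower is better
    for the first two, higher for the last two). Adds per-criterion ranks
    (ties get average ranks), ``mean_rank`` and ``sd_rank``; a model with any
    missing criterion gets NaN ranks for it, a NaN mean rank and
    ``incomplete = True`` rather than being dropped.
    """
    if len(criteria) < 2:
        raise ParameterError("need at least two models to rank")
    missing = [c for c in CRITERIA if c not in criteria.columns]
    if missing:
        raise ParameterError(f"criteria table lacks columns {missing}")
    out = criteria.copy()
    rank_cols = []
    for c in CRITERIA:
        vals = out[c].to_numpy(dtype=float)
        signed = vals if _ASCENDING[c] else -vals
        ranks = np.full(vals.shape, np.nan)
        ok = np.isfinite(signed)
        if ok.any():
            ranks[ok] = stats.rankdata(signed[ok], method="average")
        col = f"rank_{c}"
        out[col] = ranks
        rank_cols.append(col)
    ranks = out[rank_cols].to_numpy()
    out["mean_rank"] = ranks.mean(axis=1)
    out["sd_rank"] = ranks.std(axis=1, ddof=1)
    out["incomplete"] = ~np.isfinite(ranks).all(axis=1)
    if out["incomplete"].any():
        warnings.warn("some models have missing criteria; their mean rank is NaN",
                      stacklevel=2)
    return out


def _pick_best(ranked: pd.DataFrame) -> object:
    """Index label of the best model: lowest mean rank, ties broken by lower
    AICc, then by fewer predictors when an ``n_predictors`` column exists."""
    df = ranked[~ranked["incomplete"]] if "incomplete" in ranked else ranked
    by = ["mean_rank", "aicc"] + (["n_predictors"] if "n_predictors" in df else [])
    return df.sort_values(by=by, kind="mergesort").index[0]


def univariate_screen(
    family: list[tuple[SurfaceVariant, Raster]],
    groups: list[FocalGroup],
    response: np.ndarray | PairwiseMatrix,
    connectivity: int = 8,
    mcmc: MCMCSettings = MCMCSettings(),
    seed: int = 0,
    resistances: dict[str, PairwiseMatrix] | None = None,
) -> tuple[pd.DataFrame, SurfaceVariant, dict[str, PairwiseMatrix]]:
    """Screen a covariate's surface family with univariate MLPE fits.

    For each variant the pairwise circuit resistance between ``groups`` is
    computed (or taken from ``resistances``, keyed by variant label, when
    already cached), a univariate model of the response is fitted, and the
    variants are consensus-ranked. Returns the rank table (indexed by variant
    label), the winning variant, and the resistance cache. Variants whose
    network is disconnected are dropped with a warning.
    """
    if not family:
        raise ParameterError("empty surface family")
    resistances = dict(resistances or {})
    rows = {}
    kept: dict[str, SurfaceVariant] = {}
    for variant, surf in family:
        label = variant.label
        try:
            if label not in resistances:
                resistances[label] = pairwise_resistance_matrix(
                    surf, groups, connectivity=connectivity
                )
            data = PairwiseModelData.from_matrices(
                response, {"resist": resistances[label]}
            )
            crit, fit, _ = compute_criteria(data, ["resist"], mcmc=mcmc, seed=seed)
        except ConnectivityError as exc:
            warnings.warn(f"variant {label} dropped: {exc}", stacklevel=2)
            continue
        rows[label] = crit
        kept[label] = variant
    if len(rows) < 2:
        raise ParameterError("fewer than two variants survived the screen")
    table = pd.DataFrame.from_dict(rows, orient="index")
    ranked = rank_models(table)
    best = kept[_pick_best(ranked)]
    return ranked, best, resistances


def run_model_set(
    models: list[ModelSpec],
    response: np.ndarray | PairwiseMatrix,
    predictors: dict[str, PairwiseMatrix],
    mcmc: MCMCSettings = MCMCSettings(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[int, MLPEFit]]:
    """Fit and consensus-rank a multivariate model set.

    ``predictors`` maps each variable name to its (screen-winning) pairwise
    resistance matrix. Returns the rank table indexed by model id (with the
    model label and predictor count) and the REML fit of every model, whose
    standardized coefficients and intervals feed the coefficient plot.
    """
    needed = sorted({v for m in models for v in m.predictors})
    absent = [v for v in needed if v not in predictors]
    if absent:
        raise ParameterError(f"no resistance matrix supplied for {absent}")
    data = PairwiseModelData.from_matrices(response, predictors)
    rows = {}
    fits: dict[int, MLPEFit] = {}
    labels = {}
    for spec in models:
        crit, fit, _ = compute_criteria(
            data, list(spec.predictors), mcmc=mcmc, seed=seed
        )
        rows[spec.id] = crit | {"n_predictors": len(spec.predictors)}
        fits[spec.id] = fit
        labels[spec.id] = spec.label
    table = pd.DataFrame.from_dict(rows, orient="index")
    ranked = rank_models(table)
    ranked.insert(0, "model", pd.Series(labels))
    return ranked, fits


def criterion_rank_correlations(ranked: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations between the four criteria's rank columns.

    Reported, not asserted: the criteria are known to disagree (the F-based
    marginal R^2 prefers complex models), which is why the consensus mean
    rank exists.
    """
    cols = [f"rank_{c}" for c in CRITERIA]
    return ranked[cols].corr(method="spearman")
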
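"""Coefficient-weighted combination of component resistance surfaces.

A top multivariate model does not by itself yield a single resistance map.
Because its predictors are standardized, the fitted slopes are comparable,
and each variable's relative weight is its coefficient divided by the sum of
the model's coefficients; the combined surface is the cellwise weighted sum
of the component surfaces. Surfaces entering one combination must share one
transformation family (e.g. all high10) — differently parameterized surfaces
are not on a common resistance scale.

The recipe is only defined when all slopes share one sign (weights then sum
to 1 and are positive); mixed signs raise :class:`CombinationError` rather
than being absorbed by an absolute-value convention the recipe never defined.

:func:`validate_combined` closes the loop: circuit resistances on the
combined surface are fitted against the genetic response and the resulting
criteria row can be ranked against the component and multivariate models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuits import FocalGroup, pairwise_resistance_matrix
from .errors import CombinationError, ParameterError
from .mlpe import MCMCFit, MLPEFit, PairwiseModelData
from .popgen import PairwiseMatrix
from .raster import Raster
from .selection import MCMCSettings, compute_criteria
from .surfaces import SurfaceVariant, moving_window_mean

__all__ = ["WeightSet", "coefficient_weights", "combine_surfaces", "validate_combined"]


@dataclass(frozen=True)
class WeightSet:
    """Relative variable weights derived from standardized coefficients."""

    weights: dict[str, float]  # variable -> weight, sums to 1
    source_model: str = ""
    transformation_family: str = ""  # e.g. "high5" / "high10"

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ParameterError(f"weights must sum to 1, got {total!r}")


def coefficient_weights(
    fit: MLPEFit,
    variables: list[str] | None = None,
    transformation_family: str = "",
) -> WeightSet:
    """Relative weights ``w_i = beta_i / sum_j beta_j`` over the named slopes.

    ``variables`` defaults to all non-intercept terms of the fit. All slopes
    must share one sign; otherwise (or with a zero sum) the combination is
    undefined and :class:`CombinationError` is raised.
    """
    names = fit.beta_names[1:] if variables is None else list(variables)
    if not names:
        raise CombinationError("no slope coefficients to combine")
    betas = []
    for name in names:
        if name not in fit.beta_names:
            raise ParameterError(f"{name!r} is not a term of this fit")
        betas.append(fit.beta[fit.beta_names.index(name)])
    betas = np.asarray(betas)
    if np.any(betas == 0) or (np.any(betas > 0) and np.any(betas < 0)):
        raise CombinationError(
            "coefficient weighting is undefined for mixed-sign or zero "
            f"coefficients: {dict(zip(names, betas))}"
        )
    weights = betas / betas.sum()
    return WeightSet(
        weights=dict(zip(names, (float(w) for w in weights))),
        source_model="+".join(names),
        transformation_family=transformation_family,
    )


def combine_surfaces(
    weights: WeightSet,
    surfaces: dict[str, Raster] | dict[str, tuple[SurfaceVariant, Raster]],
) -> Raster:
    """Cellwise weighted sum of aligned, strictly positive component surfaces.

    ``surfaces`` maps variable names to rasters, or to ``(variant, raster)``
    pairs — in the latter case all variants must share one transformation
    family (same transformation and alpha). Equal weights reduce to the
    cellwise mean; the output is strictly positive.
    """
    missing = [v for v in weights.weights if v not in surfaces]
    if missing:
        raise ParameterError(f"no surface supplied for {missing}")
    rasters: dict[str, Raster] = {}
    families = set()
    for name in weights.weights:
        entry = surfaces[name]
        if isinstance(entry, tuple):
            variant, raster = entry
            families.add((variant.transformation, variant.alpha))
        else:
            raster = entry
        rasters[name] = raster
    if len(families) > 1:
        raise CombinationError(
            f"surfaces from different transformation families: {sorted(families)}"
        )
    ref = next(iter(rasters.values()))
    acc = np.zeros_like(ref.values)
    for name, w in weights.weights.items():
        r = rasters[name]
        if (r.values.shape != ref.values.shape or r.cell_size != ref.cell_size
                or r.origin != ref.origin):
            raise ParameterError(f"surface {name!r} is not aligned with the others")
        if np.nanmin(r.values) <= 0:
            raise ParameterError(f"surface {name!r} is not strictly positive")
        acc = acc + w * r.values
    return ref.with_values(acc)


def validate_combined(
    combined: Raster,
    groups: list[FocalGroup],
    response: np.ndarray | PairwiseMatrix,
    window_radius: float | None = None,
    connectivity: int = 8,
    mcmc: MCMCSettings = MCMCSettings(),
    seed: int = 0,
) -> tuple[dict[str, float], MLPEFit, MCMCFit]:
    """Criteria row for the combined surface's univariate fit.

    Optionally applies a focal-mean window (when the combination was done on
    pre-window surfaces), computes pairwise circuit resistance, fits the
    univariate MLPE model and returns the four criteria — schema-compatible
    with the model-set rank table.
    """
    surf = combined if window_radius is None else moving_window_mean(
        combined, window_radius
    )
    resist = pairwise_resistance_matrix(surf, groups, connectivity=connectivity)
    data = PairwiseModelData.from_matrices(response, {"combined": resist})
    return compute_criteria(data, ["combined"], mcmc=mcmc, seed=seed)
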
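"""Resistance-surface parameterization.

Covariate rasters become families of candidate resistance surfaces through
four building blocks:

* **reversal** — for covariates whose high values *facilitate* gene flow
  (e.g. sagebrush cover, habitat suitability), resistance is ``max - value +
  0.1``; the 0.1 floor keeps every cell traversable for the circuit solver.
* **high-resistance transformation** — ``exp(alpha * R / R_max)``: compresses
  differences among low-resistance cells and spreads differences among
  high-resistance cells. ``alpha`` controls steepness; normalising by the
  surface maximum makes the transform comparable across covariates with
  different native ranges.
* **low-resistance transformation** — the converse: reverse, apply the same
  exponential, reverse back and add 0.1, so variation among *favourable*
  (low-resistance) cells is emphasised and high-resistance cells are
  homogenised.
* **moving-window (focal) mean** — per-cell average over a circular window,
  setting the operational scale of the covariate.

The standard variant family crosses five parameterizations (untransformed,
high/low at alpha 5 and 10) with three window radii (1.5, 6.44 and 17.33 km),
giving 15 surfaces per covariate; distance-decay road surfaces skip the
windows and yield 5.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .raster import Raster, write_ascii_grid

__all__ = [
    "SurfaceVariant",
    "reverse_surface",
    "transform_high",
    "transform_low",
    "moving_window_mean",
    "road_decay",
    "build_variant_family",
    "write_variant_family",
    "TRANSFORMATIONS",
    "DEFAULT_WINDOW_RADII_M",
    "ROAD_DECAY_ALPHA_KM",
]

#: (transformation, alpha) labels in family order.
TRANSFORMATIONS: tuple[tuple[str, float | None], ...] = (
    ("untransformed", None),
    ("high", 5.0),
    ("high", 10.0),
    ("low", 5.0),
    ("low", 10.0),
)

#: Default focal-window radii in meters (1.5, 6.44 and 17.33 km).
DEFAULT_WINDOW_RADII_M: tuple[float, ...] = (1500.0, 6440.0, 17330.0)

#: Default e-folding distance of the road decay surface, in km.
ROAD_DECAY_ALPHA_KM: float = 0.564

_MAX_ALPHA = 50.0  # exp overflow guard


@dataclass(frozen=True)
class SurfaceVariant:
    """One member of a covariate's resistance-surface family."""

    variable: str
    transformation: str  # untransformed | high | low
    alpha: float | None  # exponent scale; None iff untransformed
    window_radius: float | None  # meters; None for road-style variables

    @property
    def label(self) -> str:
        t = (
            self.transformation
            if self.alpha is None
            else f"{self.transformation}{self.alpha:g}"
        )
        w = "nowindow" if self.window_radius is None else f"w{self.window_radius:g}m"
        return f"{self.variable}:{t}:{w}"


def reverse_surface(r: Raster) -> Raster:
    """Reverse a surface so high covariate values become low resistance.

    ``out = max(r) - r + 0.1``; the output minimum is exactly 0.1 and cell
    rank order is inverted.
    """
    if r.n_valid == 0:
        raise ParameterError("cannot reverse an all-nodata raster")
    top = np.nanmax(r.values)
    return r.with_values(top - r.values + 0.1)


def _check_transform_input(r: Raster, alpha: float) -> None:
    if r.n_valid == 0:
        raise ParameterError("cannot transform an all-nodata raster")
    if alpha < 0:
        raise ParameterError("alpha must be non-negative")
    if alpha > _MAX_ALPHA:
        raise ParameterError(f"alpha > {_MAX_ALPHA} would overflow exp()")


def transform_high(r: Raster, alpha: float) -> Raster:
    """Exponential high-resistance transformation ``exp(alpha * R / R_max)``.

    Strictly increasing and convex in the input, so low-resistance cells are
    homogenised and differences among high-resistance cells are emphasised.
    The maximum cell maps to ``exp(alpha)``; rescaling the input by a positive
    constant leaves the output unchanged.
    """
    _check_transform_input(r, alpha)
    if np.nanmin(r.values) <= 0:
        raise ParameterError("high transformation requires strictly positive input")
    rmax = np.nanmax(r.values)
    return r.with_values(np.exp(alpha * r.values / rmax))


def transform_low(r: Raster, alpha: float) -> Raster:
    """Exponential low-resistance transformation.

    Reverse (``max - R``), apply the high transformation, reverse back and add
    0.1. Monotone increasing in the input with a concave spread: differences
    among low-resistance cells are emphasised, high-resistance cells are
    homogenised, and the output minimum is exactly 0.1. A constant input
    (degenerate reversal) maps to the constant 0.1.
    """
    _check_transform_input(r, alpha)
    rev = np.nanmax(r.values) - r.values
    rev_max = np.nanmax(rev)
    if rev_max == 0:  # constant surface
        return r.with_values(np.full_like(r.values, 0.1) + 0.0 * r.values)
    f = np.exp(alpha * rev / rev_max)
    return r.with_values(np.nanmax(f) - f + 0.1)


def moving_window_mean(r: Raster, radius: float) -> Raster:
    """Circular focal mean with the given radius in map units.

    Each output cell is the mean of unmasked input cells whose centers lie
    within ``radius`` of the focal cell center. Near edges (and next to
    nodata cells) the mean is taken over the available cells only.
    """
    if radius <= 0:
        raise ParameterError("window radius must be positive")
    if radius < r.cell_size / 2:
        warnings.warn(
            "window radius smaller than half a cell: focal mean is the identity",
            stacklevel=2,
        )
        return r.copy()
    n = int(np.floor(radius / r.cell_size))
    ii, jj = np.meshgrid(np.arange(-n, n + 1), np.arange(-n, n + 1), indexing="ij")
    kernel = ((ii**2 + jj**2) * r.cell_size**2 <= radius**2).astype(float)
    valid = (~r.mask).astype(float)
    filled = np.where(r.mask, 0.0, r.values)
    sums = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1e-300), np.nan)
    out[r.mask] = np.nan
    return r.with_values(out)


def road_decay(distance_raster: Raster, alpha_km: float = ROAD_DECAY_ALPHA_KM) -> Raster:
    """Exponential distance-to-road decay ``exp(-d / alpha)``.

    ``distance_raster`` holds the distance of each cell to the nearest road in
    km (same units as ``alpha_km``). Cells on a road (d = 0) map to 1; the
    value decays by 1/e every ``alpha_km``.
    """
    if alpha_km <= 0:
        raise ParameterError("alpha_km must be positive")
    d = distance_raster.values
    if np.nanmin(d) < 0:
        raise ParameterError("distances must be non-negative")
    return distance_raster.with_values(np.exp(-d / alpha_km))


def build_variant_family(
    variable: str,
    raster: Raster,
    has_windows: bool = True,
    window_radii: tuple[float, ...] = DEFAULT_WINDOW_RADII_M,
    alphas: tuple[float, ...] = (5.0, 10.0),
) -> list[tuple[SurfaceVariant, Raster]]:
    """Build a covariate's full resistance-surface family.

    The transformation is applied first, then the focal window. Windowed
    variables yield ``5 transformations x len(window_radii)`` variants
    (15 by default); window-free (road-style) variables yield 5. Any input
    that needs reversal must be reversed *before* this call. Every output is
    strictly positive.
    """
    if raster.n_valid and np.nanmin(raster.values) <= 0:
        raise ParameterError(
            f"{variable}: resistance input must be strictly positive "
            "(apply reverse_surface first if needed)"
        )
    transforms: list[tuple[str, float | None]] = [
        t for t in TRANSFORMATIONS if t[1] is None or t[1] in alphas
    ]
    family: list[tuple[SurfaceVariant, Raster]] = []
    for name, alpha in transforms:
        if name == "untransformed":
            base = raster.copy()
        elif name == "high":
            base = transform_high(raster, alpha)
        else:
            base = transform_low(raster, alpha)
        radii: tuple[float | None, ...] = window_radii if has_windows else (None,)
        for radius in radii:
            surf = base if radius is None else moving_window_mean(base, radius)
            variant = SurfaceVariant(
                variable=variable,
                transformation=name,
                alpha=alpha,
                window_radius=radius,
            )
            family.append((variant, surf))
    return family


def write_variant_family(
    family: list[tuple[SurfaceVariant, Raster]],
    directory: str | Path,
) -> Path:
    """Write a variant family as ESRI ASCII grids plus a manifest CSV.

    The manifest (``manifest.csv``) records variable, transformation, alpha,
    window radius and the relative raster path of every variant; returns the
    manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["variable", "transformation", "alpha",
                        "window_radius_m", "path"])
        for variant, surf in family:
            fname = variant.label.replace(":", "_") + ".asc"
            write_ascii_grid(surf, directory / fname)
            writer.writerow([
                variant.variable, variant.transformation,
                "" if variant.alpha is None else f"{variant.alpha:g}",
                "" if variant.window_radius is None
                else f"{variant.window_radius:g}",
                fname,
            ])
    return manifest
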
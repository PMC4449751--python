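"""Synthetic landscapes, focal groups, genotypes and pairwise responses.

No empirical rasters or genotypes ship with this package; this module
generates inputs with the statistical structure the downstream analysis
assumes, so that every stage — surface parameterization, circuit solves,
MLPE fits, model selection — is testable end to end.

* :func:`simulate_landscape` draws a Gaussian random field with exponential
  spatial covariance (circulant embedding / spectral synthesis) and rescales
  it linearly to a value range, emulating percent-cover or terrain-ruggedness
  style covariate rasters.
* :func:`place_groups` scatters focal groups (lek-group analogues) with a
  minimum pairwise separation.
* :func:`simulate_genotypes` draws group allele frequencies from a
  Balding–Nichols style Dirichlet drift model around shared ancestral
  frequencies (concentration ``(1 - F) / F``), then samples diploid
  genotypes; expected differentiation is tuned by ``F``.
* :func:`simulate_pairwise_response` draws pairwise responses that are linear
  in standardized resistance with the MLPE (shared-group) covariance
  structure: ``y_ij = b0 + sum_k b_k z_ijk + u_i + u_j + e_ij``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuits import FocalGroup
from .errors import ParameterError, PlacementError
from .genepop import GenotypeTable
from .mlpe import standardize_columns
from .popgen import PairwiseMatrix
from .raster import Raster

__all__ = [
    "LandscapeParams",
    "GeneticSimParams",
    "PairwiseSimParams",
    "simulate_landscape",
    "place_groups",
    "simulate_genotypes",
    "simulate_pairwise_response",
]


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the Gaussian-random-field landscape generator.

    ``correlation_range`` is the e-folding scale (meters) of the exponential
    spatial covariance; ``value_range`` the (min, max) of the rescaled output.
    The default cell size is 300 m, the working resolution of the analysis
    rasters this generator emulates.
    """

    nrows: int = 100
    ncols: int = 100
    cell_size: float = 300.0
    correlation_range: float = 5000.0
    value_range: tuple[float, float] = (0.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 2 or self.ncols < 2:
            raise ParameterError("nrows and ncols must be >= 2")
        if self.cell_size <= 0:
            raise ParameterError("cell_size must be positive")
        if self.correlation_range <= 0:
            raise ParameterError("correlation_range must be positive")
        if self.value_range[0] > self.value_range[1]:
            raise ParameterError("value_range must satisfy min <= max")


@dataclass(frozen=True)
class GeneticSimParams:
    """Parameters of the Dirichlet-drift genotype simulator.

    ``differentiation`` is the drift intensity F in (0, 1): group allele
    frequencies are Dirichlet-distributed around shared ancestral frequencies
    with concentration ``(1 - F) / F``, so expected F_ST is approximately F.
    Defaults emulate a microsatellite panel: 14 loci, 37 groups, ~2% missing.
    """

    n_groups: int = 37
    loci: int = 14
    alleles_per_locus: int = 8
    individuals_per_group: int = 18
    differentiation: float = 0.05
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.differentiation < 1.0:
            raise ParameterError("differentiation F must lie strictly in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must lie in [0, 1)")
        if self.loci < 1:
            raise ParameterError("need at least one locus")
        if self.alleles_per_locus < 2:
            raise ParameterError("need at least two alleles per locus")
        if self.n_groups < 1 or self.individuals_per_group < 1:
            raise ParameterError("need at least one group and one individual")


@dataclass(frozen=True)
class PairwiseSimParams:
    """Parameters of the MLPE-structured pairwise response simulator."""

    beta0: float = 0.0
    beta: tuple[float, ...] = (0.5,)
    sigma_u: float = 0.2
    sigma_e: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_u < 0:
            raise ParameterError("sigma_u must be >= 0")
        if self.sigma_e <= 0:
            raise ParameterError("sigma_e must be > 0")


def simulate_landscape(params: LandscapeParams) -> Raster:
    """Simulate a spatially autocorrelated covariate raster.

    Circulant embedding: the exponential covariance ``exp(-d / range)`` is
    laid out on a doubled torus, its FFT gives the spectral density, and a
    complex white-noise field filtered by its square root yields an exact
    stationary Gaussian field (negative spectral mass, if any, is clipped).
    The field is rescaled linearly so its min/max hit ``value_range``.
    """
    rng = np.random.default_rng(params.seed)
    n, m = params.nrows, params.ncols
    n2, m2 = 2 * n, 2 * m
    di = np.minimum(np.arange(n2), n2 - np.arange(n2))
    dj = np.minimum(np.arange(m2), m2 - np.arange(m2))
    dist = np.hypot(di[:, None], dj[None, :]) * params.cell_size
    cov = np.exp(-dist / params.correlation_range)
    spectrum = np.fft.fft2(cov).real
    spectrum = np.maximum(spectrum, 0.0)
    noise = rng.normal(size=(n2, m2)) + 1j * rng.normal(size=(n2, m2))
    grid = np.fft.fft2(noise * np.sqrt(spectrum / (n2 * m2))).real[:n, :m]

    lo, hi = params.value_range
    span = grid.max() - grid.min()
    if hi == lo or span == 0:
        values = np.full((n, m), float(lo))
    else:
        values = lo + (grid - grid.min()) * (hi - lo) / span
    return Raster(values=values, cell_size=params.cell_size, origin=(0.0, 0.0))


def place_groups(
    raster: Raster,
    n: int,
    min_separation: float,
    seed: int = 0,
    max_attempts_per_group: int = 2000,
) -> list[FocalGroup]:
    """Place ``n`` focal groups on unmasked cells, pairwise >= min_separation.

    Dart-throwing with bounded retries; raises :class:`PlacementError` when
    the extent cannot accommodate the requested packing.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if min_separation < 0:
        raise ParameterError("min_separation must be >= 0")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(~raster.mask)
    if rows.size < n:
        raise PlacementError("fewer unmasked cells than requested groups")
    placed: list[tuple[float, float]] = []
    groups: list[FocalGroup] = []
    for k in range(n):
        for _ in range(max_attempts_per_group):
            pick = rng.integers(rows.size)
            x, y = raster.cell_center(int(rows[pick]), int(cols[pick]))
            if all(np.hypot(x - px, y - py) >= min_separation for px, py in placed):
                placed.append((x, y))
                groups.append(FocalGroup(id=f"g{k + 1:02d}", x=x, y=y))
                break
        else:
            raise PlacementError(
                f"could not place group {k + 1}/{n} with separation "
                f"{min_separation} after {max_attempts_per_group} attempts"
            )
    return groups


def simulate_genotypes(
    groups: list[FocalGroup] | list[str],
    params: GeneticSimParams,
) -> GenotypeTable:
    """Simulate diploid multi-allelic genotypes under Dirichlet drift.

    Ancestral allele frequencies per locus are drawn from a flat Dirichlet;
    each group's frequencies are Dirichlet with concentration
    ``p_ancestral * (1 - F) / F`` (Balding–Nichols), so differentiation
    increases with F. Genotypes are two independent draws per individual and
    locus; calls are then masked completely at random at ``missing_rate``.
    """
    rng = np.random.default_rng(params.seed)
    ids = [g.id if isinstance(g, FocalGroup) else str(g) for g in groups]
    if len(ids) == 0:
        ids = [f"g{k + 1:02d}" for k in range(params.n_groups)]
    if len(ids) != params.n_groups:
        raise ParameterError(
            f"{len(ids)} groups passed but params.n_groups = {params.n_groups}"
        )
    f_drift = params.differentiation
    conc = (1.0 - f_drift) / f_drift
    n_ind = params.individuals_per_group
    k_all = params.alleles_per_locus

    calls = np.zeros((params.n_groups * n_ind, params.loci, 2), dtype=int)
    for locus in range(params.loci):
        ancestral = rng.dirichlet(np.ones(k_all))
        for g in range(params.n_groups):
            p_g = rng.dirichlet(np.maximum(ancestral * conc, 1e-8))
            draw = rng.choice(k_all, size=(n_ind, 2), p=p_g) + 1
            calls[g * n_ind:(g + 1) * n_ind, locus, :] = draw
    miss = rng.random((calls.shape[0], params.loci)) < params.missing_rate
    calls[miss] = 0

    return GenotypeTable(
        individual_ids=[
            f"{ids[g]}_i{i + 1:03d}" for g in range(params.n_groups)
            for i in range(n_ind)
        ],
        group_ids=[ids[g] for g in range(params.n_groups) for _ in range(n_ind)],
        locus_names=[f"loc{l + 1:02d}" for l in range(params.loci)],
        calls=calls,
    )


def simulate_pairwise_response(
    resist: PairwiseMatrix | list[PairwiseMatrix],
    params: PairwiseSimParams,
) -> np.ndarray:
    """Simulate pairwise responses linear in standardized resistance.

    ``y_ij = b0 + sum_k b_k z_ijk + u_i + u_j + e_ij`` over ordered pairs
    (i < j), with group effects ``u ~ N(0, sigma_u^2)`` and residuals
    ``e ~ N(0, sigma_e^2)``; ``z`` are the 2-SD-standardized condensed
    resistances.
    """
    mats = [resist] if isinstance(resist, PairwiseMatrix) else list(resist)
    if len(params.beta) != len(mats):
        raise ParameterError(
            f"{len(params.beta)} slopes given for {len(mats)} predictor matrices"
        )
    base = mats[0]
    for m in mats[1:]:
        if m.group_ids != base.group_ids:
            raise ParameterError("predictor matrices must share group ids")
    rng = np.random.default_rng(params.seed)
    z = np.column_stack([m.condensed() for m in mats])
    z, _, _ = standardize_columns(z)
    members = base.pair_members()
    n_groups = base.n_groups
    u = rng.normal(0.0, params.sigma_u, size=n_groups)
    eps = rng.normal(0.0, params.sigma_e, size=z.shape[0])
    return (
        params.beta0
        + z @ np.asarray(params.beta)
        + u[members[:, 0]]
        + u[members[:, 1]]
        + eps
    )
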
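"""Genetic diversity and differentiation statistics for grouped genotypes.

Implements the plug-in (frequency) estimators: expected/observed
heterozygosity, F_IS, rarefied allelic richness, and the pairwise
differentiation statistics Nei's G_ST and Jost's D_est. Estimators are the
straightforward frequency plug-ins so small worked examples are exact; an
unbiased small-sample correction of H_S/H_T (Nei 1987) can be switched on
where noted.

Multilocus aggregation follows the conventions usual for microsatellite
panels: G_ST from the across-locus means of H_S and H_T (Takezaki–Nei
style), D_est as the harmonic mean of per-locus D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedStatisticError
from .genepop import MISSING, GenotypeTable

__all__ = [
    "PairwiseMatrix",
    "allele_frequencies",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "fis",
    "diversity_summary",
    "allelic_richness",
    "pairwise_gst",
    "pairwise_jost_d",
]

_JOST_EPS = 1e-12  # floor for non-positive per-locus D before harmonic averaging


@dataclass
class PairwiseMatrix:
    """Symmetric zero-diagonal matrix over group ids (distance or ohms)."""

    group_ids: list[str]
    values: np.ndarray
    kind: str = "other"  # GST | Dest | resistance-ohms | other

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.group_ids)
        if self.values.shape != (m, m):
            raise ParameterError("matrix shape must match number of group ids")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=True):
            raise ParameterError("diagonal must be zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ParameterError("matrix must be symmetric")

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values ordered by pairs (i < j)."""
        iu = np.triu_indices(self.n_groups, k=1)
        return self.values[iu]

    def pair_members(self) -> np.ndarray:
        """(n_pairs, 2) array of group indices, same order as :meth:`condensed`."""
        iu = np.triu_indices(self.n_groups, k=1)
        return np.column_stack(iu)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.group_ids, columns=self.group_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "other") -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(group_ids=[str(c) for c in df.columns], values=df.to_numpy(),
                   kind=kind)


# ---------------------------------------------------------------------------
# per-locus primitives


def allele_frequencies(table: GenotypeTable, group: str, locus: int) -> dict[int, float]:
    """Allele frequencies in ``group`` at ``locus`` (missing calls excluded)."""
    rows = table.group_rows(group)
    alleles = table.calls[rows, locus, :].ravel()
    alleles = alleles[alleles != MISSING]
    if alleles.size == 0:
        raise UndefinedStatisticError(
            f"group {group!r} has no data at locus {table.locus_names[locus]!r}"
        )
    codes, counts = np.unique(alleles, return_counts=True)
    total = counts.sum()
    return {int(c): n / total for c, n in zip(codes, counts)}


def expected_heterozygosity(freqs: dict[int, float] | np.ndarray) -> float:
    """Hexp = 1 - sum(p^2) over allele frequencies."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs,
                   dtype=float)
    return float(1.0 - np.sum(p**2))


def observed_heterozygosity(table: GenotypeTable, group: str, locus: int) -> float:
    """Fraction of heterozygous non-missing calls in ``group`` at ``locus``."""
    rows = table.group_rows(group)
    calls = table.calls[rows, locus, :]
    ok = calls[:, 0] != MISSING
    if not np.any(ok):
        raise UndefinedStatisticError(
            f"group {group!r} has no data at locus {table.locus_names[locus]!r}"
        )
    return float(np.mean(calls[ok, 0] != calls[ok, 1]))


def fis(hobs: float, hexp: float) -> float:
    """Inbreeding coefficient F_IS = 1 - Hobs / Hexp (undefined at Hexp = 0)."""
    if hexp == 0:
        raise UndefinedStatisticError("FIS is undefined when Hexp = 0")
    return 1.0 - hobs / hexp


# ---------------------------------------------------------------------------
# per-group summaries


def diversity_summary(
    table: GenotypeTable,
    subsample_individuals: int = 10,
    replicates: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-group multilocus Hexp, Hobs, FIS and rarefied allelic richness.

    Multilocus Hexp and Hobs are unweighted means across loci; FIS is computed
    from those means. Richness columns are NaN for groups smaller than the
    subsample size (or when no seed is given, richness is still computed with
    an unseeded generator only if ``seed`` is provided — pass a seed for
    reproducible output).
    """
    records = []
    for group in table.groups:
        hexps, hobss = [], []
        for locus in range(table.n_loci):
            try:
                f = allele_frequencies(table, group, locus)
            except UndefinedStatisticError:
                continue
            hexps.append(expected_heterozygosity(f))
            hobss.append(observed_heterozygosity(table, group, locus))
        hexp = float(np.mean(hexps))
        hobs = float(np.mean(hobss))
        try:
            f_is = fis(hobs, hexp)
        except UndefinedStatisticError:
            f_is = np.nan
        try:
            rich_mean, rich_sd = allelic_richness(
                table, group,
                subsample_individuals=subsample_individuals,
                replicates=replicates,
                seed=seed,
            )
        except ParameterError:
            rich_mean = rich_sd = np.nan
        records.append(
            dict(group=group, hexp=hexp, hobs=hobs, fis=f_is,
                 allelic_richness=rich_mean, allelic_richness_sd=rich_sd)
        )
    return pd.DataFrame.from_records(records)


def allelic_richness(
    table: GenotypeTable,
    group: str,
    subsample_individuals: int = 10,
    replicates: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Rarefied allelic richness by repeated subsampling of individuals.

    Each replicate draws ``subsample_individuals`` individuals without
    replacement, counts the distinct alleles per locus in the subsample
    (ignoring missing calls) and averages across loci; the mean and SD over
    replicates are returned. When the subsample is the whole group the SD is
    exactly 0.
    """
    rows = table.group_rows(group)
    if subsample_individuals < 1:
        raise ParameterError("subsample size must be >= 1")
    if rows.size < subsample_individuals:
        raise ParameterError(
            f"group {group!r} has {rows.size} individuals, "
            f"fewer than the subsample size {subsample_individuals}"
        )
    rng = np.random.default_rng(seed)
    per_rep = np.empty(replicates)
    for rep in range(replicates):
        pick = rng.choice(rows, size=subsample_individuals, replace=False)
        counts = []
        for locus in range(table.n_loci):
            alleles = table.calls[pick, locus, :].ravel()
            alleles = alleles[alleles != MISSING]
            counts.append(len(np.unique(alleles)) if alleles.size else np.nan)
        per_rep[rep] = np.nanmean(counts)
    return float(per_rep.mean()), float(per_rep.std(ddof=0))


# ---------------------------------------------------------------------------
# pairwise differentiation


def _pair_locus_hs_ht(
    table: GenotypeTable, g1: str, g2: str, locus: int, unbiased: bool
) -> tuple[float, float] | None:
    """(H_S, H_T) for one locus and one pair; None if either group lacks data."""
    try:
        f1 = allele_frequencies(table, g1, locus)
        f2 = allele_frequencies(table, g2, locus)
    except UndefinedStatisticError:
        return None
    alleles = sorted(set(f1) | set(f2))
    p1 = np.array([f1.get(a, 0.0) for a in alleles])
    p2 = np.array([f2.get(a, 0.0) for a in alleles])
    h1 = 1.0 - np.sum(p1**2)
    h2 = 1.0 - np.sum(p2**2)
    if unbiased:
        n1 = _gene_copies(table, g1, locus)
        n2 = _gene_copies(table, g2, locus)
        h1 *= n1 / (n1 - 1)
        h2 *= n2 / (n2 - 1)
    hs = (h1 + h2) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 1.0 - np.sum(pbar**2)
    return float(hs), float(ht)


def _gene_copies(table: GenotypeTable, group: str, locus: int) -> int:
    rows = table.group_rows(group)
    alleles = table.calls[rows, locus, :].ravel()
    return int(np.count_nonzero(alleles != MISSING))


def pairwise_gst(table: GenotypeTable, unbiased: bool = False) -> PairwiseMatrix:
    """Pairwise multilocus Nei's G_ST between all groups.

    Per pair: per-locus H_S is the mean within-group Hexp and H_T the Hexp of
    the mean allele frequencies; the multilocus value is
    ``(mean H_T - mean H_S) / mean H_T`` with unweighted means across loci.
    A pair with mean H_T = 0 (both groups fixed for one shared allele at every
    locus) is undefined and set to NaN with a warning.
    """
    groups = table.groups
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    m = len(groups)
    out = np.zeros((m, m))
    for i, j in combinations(range(m), 2):
        hs_list, ht_list = [], []
        for locus in range(table.n_loci):
            pair = _pair_locus_hs_ht(table, groups[i], groups[j], locus, unbiased)
            if pair is not None:
                hs_list.append(pair[0])
                ht_list.append(pair[1])
        if not ht_list:
            raise UndefinedStatisticError(
                f"no locus with data in both {groups[i]!r} and {groups[j]!r}"
            )
        ht_bar = float(np.mean(ht_list))
        if ht_bar == 0:
            warnings.warn(
                f"G_ST undefined for pair ({groups[i]}, {groups[j]}): H_T = 0",
                stacklevel=2,
            )
            out[i, j] = out[j, i] = np.nan
        else:
            gst = (ht_bar - float(np.mean(hs_list))) / ht_bar
            out[i, j] = out[j, i] = gst
    return PairwiseMatrix(group_ids=groups, values=out, kind="GST")


def pairwise_jost_d(
    table: GenotypeTable,
    unbiased: bool = False,
    aggregation: str = "arithmetic",
) -> PairwiseMatrix:
    """Pairwise multilocus Jost's D_est between all groups.

    Per locus (two groups, n = 2): ``D = (H_T - H_S) / (1 - H_S) * 2``. Loci
    with H_S = 1 are dropped with a warning.

    ``aggregation`` sets the across-locus average of per-locus D:
    ``"arithmetic"`` (default, the convention of the standard differentiation
    packages) or ``"harmonic"`` (Jost's own suggestion; unstable on short
    noisy panels because one near-zero locus dominates — non-positive values
    are floored at a tiny epsilon first, and pairs where every locus is
    non-positive give exactly 0).
    """
    if aggregation not in ("arithmetic", "harmonic"):
        raise ParameterError("aggregation must be 'arithmetic' or 'harmonic'")
    groups = table.groups
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    m = len(groups)
    out = np.zeros((m, m))
    for i, j in combinations(range(m), 2):
        d_loci = []
        for locus in range(table.n_loci):
            pair = _pair_locus_hs_ht(table, groups[i], groups[j], locus, unbiased)
            if pair is None:
                continue
            hs, ht = pair
            if hs >= 1.0:
                warnings.warn(
                    f"locus {table.locus_names[locus]!r} dropped for pair "
                    f"({groups[i]}, {groups[j]}): H_S = 1",
                    stacklevel=2,
                )
                continue
            d_loci.append((ht - hs) / (1.0 - hs) * 2.0)
        if not d_loci:
            raise UndefinedStatisticError(
                f"no usable locus for pair ({groups[i]!r}, {groups[j]!r})"
            )
        d_arr = np.asarray(d_loci)
        if aggregation == "arithmetic":
            d_multi = float(np.mean(d_arr))
        elif np.all(d_arr <= 0):
            d_multi = 0.0
        else:
            d_arr = np.maximum(d_arr, _JOST_EPS)
            d_multi = float(len(d_arr) / np.sum(1.0 / d_arr))
        out[i, j] = out[j, i] = d_multi
    return PairwiseMatrix(group_ids=groups, values=out, kind="Dest")
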
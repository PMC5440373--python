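"""Conditional Q-Q curves, fold enrichment, and conditional TDR.

All three views stratify the primary trait's p-values (``p1``) by nested
significance strata of the secondary trait (``p2 < 0.1, 0.01, 0.001`` by
default, plus the all-SNP stratum at threshold 1.0).  Successive leftward
deflection of the stratified Q-Q curves — equivalently fold enrichment > 1 —
is the signature of polygenic overlap between the traits.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import OrderedDict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ld import LDReference, random_prune

logger = logging.getLogger("condconj")

DEFAULT_STRATA = (1.0, 0.1, 0.01, 0.001)
#: display cap at -log10(p) = 7.3, i.e. p > 5e-8: the Q-Q and fold views
#: deliberately focus on sub-genome-wide-significant polygenic signal
MAX_NOMINAL_LOG10P = 7.3
DEFAULT_GRID_POINTS = 1000
MIN_STRATUM_SIZE = 50


@dataclasses.dataclass
class EnrichmentCurves:
    """Per-stratum curves on a common nominal -log10(p) grid.

    Strata with fewer SNPs than the minimum size are flagged in
    ``low_confidence``; empty strata carry all-NaN curves.
    """

    strata_thresholds: tuple
    grid: np.ndarray
    qq: Optional[dict] = None
    fold: Optional[dict] = None
    tdr: Optional[dict] = None
    n_per_stratum: Optional[dict] = None
    low_confidence: frozenset = frozenset()

    def to_frame(self, which: str) -> pd.DataFrame:
        """Tidy (stratum, x, value, n) table for one curve family."""
        curves = getattr(self, which)
        if curves is None:
            raise ValueError(f"curves {which!r} not computed")
        rows = []
        for t, y in curves.items():
            rows.append(
                pd.DataFrame(
                    {
                        "stratum": t,
                        "x": self.grid,
                        "value": y,
                        "n": self.n_per_stratum.get(t) if self.n_per_stratum else np.nan,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def default_grid(max_x: float = MAX_NOMINAL_LOG10P, n: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    return np.linspace(0.0, max_x, n)


def make_strata(
    pairs: pd.DataFrame, thresholds: Sequence[float] = DEFAULT_STRATA
) -> "OrderedDict[float, pd.Index]":
    """Nested SNP-id sets {i : p2_i < t} for strictly descending thresholds.

    The threshold-1.0 stratum is the all-SNP set (p <= 1 by convention, so
    records with p exactly 1 are included there); every other stratum uses
    the strict inequality as printed.
    """
    thresholds = tuple(thresholds)
    if any(not (0.0 < t <= 1.0) for t in thresholds):
        raise ValueError("strata thresholds must lie in (0, 1]")
    if any(later >= earlier for earlier, later in zip(thresholds, thresholds[1:])):
        raise ValueError("strata thresholds must be strictly descending")
    p2 = pairs["p2"].to_numpy(dtype=float)
    ids = pairs["snp_id"].astype(str)
    strata: "OrderedDict[float, pd.Index]" = OrderedDict()
    for t in thresholds:
        mask = p2 <= 1.0 if t == 1.0 else p2 < t
        strata[t] = pd.Index(ids[mask])
        if mask.sum() == 0:
            logger.warning("stratum p2 < %g is empty; its curves will be undefined", t)
    return strata


def _survival_fraction(lp: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Fraction of values >= x for each grid point (lp sorted internally)."""
    s = np.sort(lp)
    n = len(s)
    if n == 0:
        return np.full(len(grid), np.nan)
    return (n - np.searchsorted(s, grid, side="left")) / n


def _qq_curve(p: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Empirical -log10 quantile of p at the uniform quantile level 10**-x."""
    if len(p) == 0:
        return np.full(len(grid), np.nan)
    u = np.power(10.0, -grid)
    q = np.quantile(p, u, method="inverted_cdf")
    return -np.log10(np.clip(q, 1e-300, None))


def conditional_qq(
    pairs: pd.DataFrame,
    strata: "OrderedDict[float, pd.Index]",
    ld: Optional[LDReference] = None,
    seed: int = 0,
    prune_iters: int = 100,
    grid: Optional[np.ndarray] = None,
    min_stratum_size: int = MIN_STRATUM_SIZE,
) -> EnrichmentCurves:
    """Conditional Q-Q curves averaged over random prunings.

    For each stratum the curve maps a nominal -log10 p (expected uniform
    quantile) to the empirical -log10 quantile of the stratum's p1 values;
    points beyond -log10(p) = 7.3 are not displayed.  With an LD reference
    the curve is the average over ``prune_iters`` seeded random prunings
    (one SNP per LD block per draw); without one, a single pass is used.
    """
    if grid is None:
        grid = default_grid()
    p1 = pd.Series(pairs["p1"].to_numpy(dtype=float), index=pairs["snp_id"].astype(str))
    iters = prune_iters if ld is not None else 1
    rng = np.random.default_rng(seed)
    acc = {t: np.zeros(len(grid)) for t in strata}
    n_eff = {t: 0.0 for t in strata}
    for _ in range(iters):
        if ld is not None:
            kept = random_prune(p1.index, ld, seed=int(rng.integers(2**31)))
            psub = p1.loc[kept]
        else:
            psub = p1
        for t, ids in strata.items():
            ps = psub.reindex(ids).dropna().to_numpy()
            acc[t] += _qq_curve(ps, grid)
            n_eff[t] += len(ps)
    qq = {t: acc[t] / iters for t in strata}
    n_per = {t: int(round(n_eff[t] / iters)) for t in strata}
    low = frozenset(t for t, n in n_per.items() if n < min_stratum_size)
    for t in low:
        logger.warning("stratum p2 < %g has only %d pruned SNPs; low confidence", t, n_per[t])
    return EnrichmentCurves(
        strata_thresholds=tuple(strata),
        grid=grid,
        qq=qq,
        n_per_stratum=n_per,
        low_confidence=low,
    )


def fold_enrichment(
    pairs: pd.DataFrame,
    strata: "OrderedDict[float, pd.Index]",
    grid: Optional[np.ndarray] = None,
    min_stratum_size: int = MIN_STRATUM_SIZE,
) -> EnrichmentCurves:
    """Fold enrichment: stratum exceedance fraction over all-SNP exceedance.

    fold_k(x) = [#{i in stratum_k : -log10 p1_i >= x} / |stratum_k|]
              / [#{i : -log10 p1_i >= x} / N], undefined (NaN) where the
    all-SNP exceedance count is zero.
    """
    if grid is None:
        grid = default_grid()
    p1 = pd.Series(pairs["p1"].to_numpy(dtype=float), index=pairs["snp_id"].astype(str))
    lp_all = -np.log10(np.clip(p1.to_numpy(), 1e-300, None))
    s_all = _survival_fraction(lp_all, grid)
    denom_count = s_all * len(lp_all)
    fold = {}
    n_per = {}
    for t, ids in strata.items():
        ps = p1.reindex(ids).dropna().to_numpy()
        n_per[t] = len(ps)
        if len(ps) == 0:
            fold[t] = np.full(len(grid), np.nan)
            continue
        s_k = _survival_fraction(-np.log10(np.clip(ps, 1e-300, None)), grid)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(denom_count > 0, s_k / s_all, np.nan)
        fold[t] = f
    low = frozenset(t for t, n in n_per.items() if n < min_stratum_size)
    return EnrichmentCurves(
        strata_thresholds=tuple(strata),
        grid=grid,
        fold=fold,
        n_per_stratum=n_per,
        low_confidence=low,
    )


def conditional_tdr(
    pairs: pd.DataFrame,
    strata: "OrderedDict[float, pd.Index]",
    grid: Optional[np.ndarray] = None,
) -> EnrichmentCurves:
    """Conditional true discovery rate TDR(p) = 1 - min(1, p / F_k(p)).

    F_k is the stratum's empirical CDF of p1 and pi0 is bounded at 1, so the
    estimate is conservative.  Curves are monotonized to be non-increasing
    in p (running maximum along ascending -log10 p); points where F_k = 0
    are undefined.
    """
    if grid is None:
        grid = default_grid()
    p_grid = np.power(10.0, -grid)
    p1 = pd.Series(pairs["p1"].to_numpy(dtype=float), index=pairs["snp_id"].astype(str))
    tdr = {}
    n_per = {}
    for t, ids in strata.items():
        ps = np.sort(p1.reindex(ids).dropna().to_numpy())
        n_per[t] = len(ps)
        if len(ps) == 0:
            tdr[t] = np.full(len(grid), np.nan)
            continue
        cdf = np.searchsorted(ps, p_grid, side="right") / len(ps)
        with np.errstate(invalid="ignore", divide="ignore"):
            fdr = np.where(cdf > 0, np.minimum(1.0, p_grid / cdf), np.nan)
        y = 1.0 - fdr
        defined = ~np.isnan(y)
        if defined.any():
            y[defined] = np.maximum.accumulate(y[defined])
        tdr[t] = y
    return EnrichmentCurves(
        strata_thresholds=tuple(strata), grid=grid, tdr=tdr, n_per_stratum=n_per
    )


def compute_enrichment(
    pairs: pd.DataFrame,
    ld: Optional[LDReference] = None,
    thresholds: Sequence[float] = DEFAULT_STRATA,
    seed: int = 0,
    prune_iters: int = 100,
    grid: Optional[np.ndarray] = None,
) -> EnrichmentCurves:
    """Convenience wrapper computing Q-Q, fold, and TDR on a shared grid."""
    strata = make_strata(pairs, thresholds)
    qq = conditional_qq(pairs, strata, ld=ld, seed=seed, prune_iters=prune_iters, grid=grid)
    fold = fold_enrichment(pairs, strata, grid=qq.grid)
    tdr = conditional_tdr(pairs, strata, grid=qq.grid)
    return EnrichmentCurves(
        strata_thresholds=qq.strata_thresholds,
        grid=qq.grid,
        qq=qq.qq,
        fold=fold.fold,
        tdr=tdr.tdr,
        n_per_stratum=qq.n_per_stratum,
        low_confidence=qq.low_confidence,
    )
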
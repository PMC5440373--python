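"""Conditional and conjunction FDR via a 2D empirical lookup grid.

The conditional FDR of trait 1 given trait 2 is estimated by the
conservative empirical-Bayes form

    cFDR(p1 | p2 <= t) = min(1, p1 / F(p1 | p2 <= t)),

where F is the empirical conditional CDF of trait-1 p-values among SNPs
whose trait-2 p-value is at most t, and the null proportion pi0 is bounded
at 1 (an upper bound, hence conservative).  The conjunction FDR of a SNP is
the maximum of the two conditional FDRs taken in both directions; it is
small only when the SNP is non-null in both traits jointly.

The grid is estimated on a random-pruned, region-excluded SNP set (to limit
the bias from correlated test statistics in long-range LD), but final
per-SNP values are assigned to *all* SNPs by bilinear interpolation in
(-log10 p1, -log10 p2) — exclusion applies to estimation, not to scoring.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .ld import GenomicRegion, LDReference, exclude_regions, random_prune

logger = logging.getLogger("condconj")

DEFAULT_GRID_NODES = 201
MAX_LOG10P = 300.0
DEFAULT_FDR_THRESHOLD = 0.05


@dataclasses.dataclass
class CFDRGrid:
    """Empirical conditional CDF and conditional FDR on a 2D -log10 p grid.

    ``axis1`` indexes the primary trait (the one whose FDR is estimated),
    ``axis2`` the conditioning trait; both ascend in -log10 p.  ``cfdr`` is
    monotone non-decreasing in p1 at fixed conditioning threshold and
    non-increasing in the stringency of the p2 threshold.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    cond_cdf: np.ndarray  # shape (len(axis1), len(axis2))
    cfdr: np.ndarray
    direction: str  # "1|2" or "2|1"
    n_estimation_snps: int = 0

    def __post_init__(self):
        self._interp = None

    def interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                (self.axis1, self.axis2), self.cfdr, method="linear", bounds_error=False
            )
        return self._interp


def _survival_counts(lp1: np.ndarray, lp2: np.ndarray, axis1: np.ndarray, axis2: np.ndarray):
    """S[i, j] = #{lp1 >= axis1[i] and lp2 >= axis2[j]} via a 2D histogram."""
    e1 = np.append(axis1, np.inf)
    e2 = np.append(axis2, np.inf)
    hist, _, _ = np.histogram2d(lp1, lp2, bins=[e1, e2])
    s = hist[::-1, ::-1].cumsum(axis=0).cumsum(axis=1)[::-1, ::-1]
    return s


def _forward_fill_positive(values: np.ndarray, positive: np.ndarray, axis: int) -> np.ndarray:
    """Along ``axis``, replace non-positive cells by the last positive cell above."""
    n = values.shape[axis]
    idx = np.where(positive, np.arange(n).reshape([-1 if a == axis else 1 for a in range(values.ndim)]), 0)
    idx = np.maximum.accumulate(idx, axis=axis)
    return np.take_along_axis(values, idx, axis=axis)


#: a conditioning stratum estimated from fewer SNPs than this inherits the
#: nearest less-stringent stratum instead: a 2-SNP empirical CDF would make
#: the conditional FDR anti-conservative exactly where it matters most
MIN_CONDITION_COUNT = 50


def build_cfdr_grid(
    pairs: pd.DataFrame,
    ld: Optional[LDReference] = None,
    exclude: Optional[Sequence[GenomicRegion]] = None,
    seed: int = 0,
    direction: str = "1|2",
    n_grid: int = DEFAULT_GRID_NODES,
    cap: float = MAX_LOG10P,
    min_condition_count: int = MIN_CONDITION_COUNT,
) -> CFDRGrid:
    """Estimate the conditional-FDR lookup grid on pruned, region-excluded SNPs.

    ``direction = "1|2"`` estimates FDR of trait 1 conditional on trait 2;
    ``"2|1"`` swaps the roles.  Axes span 0 to the maximum observed
    -log10 p (capped), with ``n_grid`` equally spaced nodes.  Conditioning
    columns with fewer than ``min_condition_count`` SNPs inherit the nearest
    less-stringent column, and the empirical CDF is extended as a constant
    beyond the most significant observed p1, keeping cfdr -> 0 as p1 -> 0.
    """
    if direction not in ("1|2", "2|1"):
        raise ValueError("direction must be '1|2' or '2|1'")
    est = pairs
    if ld is not None:
        kept = random_prune(pairs["snp_id"], ld, seed=seed)
        if exclude:
            kept = exclude_regions(kept, ld, exclude, pairs[["snp_id", "chrom", "pos"]])
        est = pairs[pairs["snp_id"].astype(str).isin(kept)]
    if len(est) == 0:
        raise ValueError("no SNPs left for cFDR grid estimation")

    pa = est["p1"] if direction == "1|2" else est["p2"]
    pb = est["p2"] if direction == "1|2" else est["p1"]
    lp1 = -np.log10(np.clip(pa.to_numpy(dtype=float), 1e-300, 1.0))
    lp2 = -np.log10(np.clip(pb.to_numpy(dtype=float), 1e-300, 1.0))
    # axes span the observed range, capped; floor of 1 keeps the grid
    # non-degenerate when a trait has no signal at all
    axis1 = np.linspace(0.0, min(cap, max(float(lp1.max()), 1.0)), n_grid)
    axis2 = np.linspace(0.0, min(cap, max(float(lp2.max()), 1.0)), n_grid)

    s = _survival_counts(lp1, lp2, axis1, axis2)
    d = s[0, :]
    adequate = d >= max(1, min_condition_count)
    if not adequate.any():  # tiny panels: keep the best-populated column
        adequate = d == d.max()
    if not adequate.all():  # under-populated conditioning columns inherit leftward
        s = _forward_fill_positive(
            s.T, adequate[:, None] & np.ones_like(s.T, dtype=bool), axis=0
        ).T
        d = s[0, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = s / d[None, :]
    f = _forward_fill_positive(f, s > 0, axis=0)  # constant ECDF beyond min observed p1

    p1_nodes = np.power(10.0, -axis1)
    raw = np.minimum(1.0, p1_nodes[:, None] / f)
    # q-value-style monotonization, first along p1 then along the p2
    # threshold: cfdr(p1) = min over p1' >= p1 of raw(p1') flattens the
    # sawtooth of the empirical estimator and makes cfdr non-decreasing in
    # p1; the second pass makes it non-increasing in conditioning stringency
    mono = np.minimum.accumulate(raw, axis=0)
    cfdr = np.minimum.accumulate(mono, axis=1)
    return CFDRGrid(
        axis1=axis1,
        axis2=axis2,
        cond_cdf=f,
        cfdr=cfdr,
        direction=direction,
        n_estimation_snps=len(est),
    )


def lookup_cfdr(grid: CFDRGrid, p_primary, p_secondary):
    """Bilinear interpolation of the conditional FDR at (p1, p2).

    Queries are clamped to the grid boundary; values are exact at nodes.
    """
    p1 = np.asarray(p_primary, dtype=float)
    p2 = np.asarray(p_secondary, dtype=float)
    scalar = p1.ndim == 0
    p1, p2 = np.atleast_1d(p1), np.atleast_1d(p2)
    if np.any((p1 <= 0) | (p1 > 1) | (p2 <= 0) | (p2 > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    lp1 = np.clip(-np.log10(p1), grid.axis1[0], grid.axis1[-1])
    lp2 = np.clip(-np.log10(p2), grid.axis2[0], grid.axis2[-1])
    out = grid.interpolator()(np.column_stack([lp1, lp2]))
    return float(out[0]) if scalar else out


@dataclasses.dataclass
class ConjunctionResult:
    """Per-SNP conditional/conjunction FDR table plus bookkeeping counts."""

    table: pd.DataFrame
    threshold: float
    n_excluded: int


def conjunction_fdr(
    grid12: CFDRGrid,
    grid21: CFDRGrid,
    pairs: pd.DataFrame,
    threshold: float = DEFAULT_FDR_THRESHOLD,
) -> ConjunctionResult:
    """Conjunction FDR = max of the two conditional FDRs; strict significance.

    Each SNP's conjunction FDR is max(cFDR_1|2(p1, p2), cFDR_2|1(p2, p1)),
    a conservative estimate of the probability that it is null for either or
    both traits.  SNPs missing a p-value in either trait are excluded and
    counted.  Significance is strict: conj_fdr < threshold.
    """
    if grid12.direction != "1|2" or grid21.direction != "2|1":
        raise ValueError("grid12 must have direction '1|2' and grid21 '2|1'")
    valid = pairs["p1"].notna() & pairs["p2"].notna()
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning("conjunction_fdr: %d SNP(s) missing a p-value; excluded", n_excluded)
    sub = pairs[valid].reset_index(drop=True)
    c12 = lookup_cfdr(grid12, sub["p1"].to_numpy(), sub["p2"].to_numpy())
    c21 = lookup_cfdr(grid21, sub["p2"].to_numpy(), sub["p1"].to_numpy())
    table = sub[
        [c for c in ("snp_id", "chrom", "pos", "a1", "a2", "z1", "p1", "z2", "p2", "direction_defined") if c in sub.columns]
    ].copy()
    table["cfdr_1g2"] = c12
    table["cfdr_2g1"] = c21
    table["conj_fdr"] = np.maximum(c12, c21)
    table["significant"] = table["conj_fdr"] < threshold
    return ConjunctionResult(table=table, threshold=threshold, n_excluded=n_excluded)
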
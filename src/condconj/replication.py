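"""Substudy-based replication-rate validation.

The primary trait's meta-analysis is decomposed into substudies; repeated
random half-partitions yield discovery and replication halves whose z-scores
are combined by sample-size-weighted Stouffer meta-analysis.  Cumulative
replication rates per discovery-significance bin, computed separately inside
each secondary-trait enrichment stratum, show whether pleiotropically
enriched SNPs generalize better than the genome-wide background.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sumstats import read_sumstats, z_to_p

logger = logging.getLogger("condconj")

DEFAULT_N_PARTITIONS = 500
DEFAULT_N_BINS = 1000
REPLICATION_ALPHA = 0.05


@dataclasses.dataclass
class SubstudyPanel:
    """Per-substudy z-scores aligned to a common effect allele.

    ``z`` has shape (n_substudies, n_snps); ``n`` holds per-substudy sample
    sizes.  Missing per-substudy z-scores may be NaN; combination then runs
    over the available members.
    """

    labels: tuple
    n: np.ndarray
    z: np.ndarray
    snp_ids: pd.Index

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if np.any(self.n <= 0):
            raise ValueError("substudy sample sizes must be > 0")
        if self.z.shape != (len(self.labels), len(self.snp_ids)):
            raise ValueError("z matrix shape must be (n_substudies, n_snps)")

    @property
    def n_substudies(self) -> int:
        return len(self.labels)


def load_panel(manifest_path) -> SubstudyPanel:
    """Load a panel from a manifest (columns: label, n, path) of sumstats files.

    The SNP universe is the intersection across substudies; z-scores are
    taken as stored (the caller is responsible for common allele alignment,
    e.g. via :func:`condconj.sumstats.intersect_traits` against a reference).
    Relative paths in the manifest are resolved against its directory.
    """
    from pathlib import Path

    man = pd.read_csv(manifest_path, sep=r"\s+")
    base = Path(manifest_path).parent
    frames = []
    for r in man.itertuples():
        path = Path(r.path)
        rec, _ = read_sumstats(path if path.is_absolute() else base / path)
        frames.append(rec.set_index("snp_id")["z"].rename(str(r.label)))
    joined = pd.concat(frames, axis=1, join="inner")
    return SubstudyPanel(
        labels=tuple(man["label"].astype(str)),
        n=man["n"].to_numpy(dtype=float),
        z=joined.T.to_numpy(),
        snp_ids=joined.index,
    )


def partition_substudies(
    panel: SubstudyPanel | int, n_partitions: int = DEFAULT_N_PARTITIONS, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random half-partitions of the substudies into discovery/replication.

    Each partition splits the K substudies into floor(K/2) discovery and
    ceil(K/2) replication members (disjoint, covering all).  Seeded and
    reproducible.
    """
    k = panel if isinstance(panel, int) else panel.n_substudies
    if k < 2:
        raise ValueError("need at least 2 substudies to partition")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_partitions):
        perm = rng.permutation(k)
        out.append((np.sort(perm[: k // 2]), np.sort(perm[k // 2 :])))
    return out


def combine_z(
    panel: SubstudyPanel, subset: Sequence[int], equal_weights: bool = False
) -> np.ndarray:
    """Sample-size-weighted Stouffer combination over a substudy subset.

    z_comb = sum(w_k z_k) / sqrt(sum(w_k^2)) with w_k = sqrt(n_k) (or 1 with
    ``equal_weights``).  Null-preserving: independent N(0,1) inputs combine
    to N(0,1).  SNPs missing in some members are combined over the rest.
    """
    subset = np.asarray(subset, dtype=int)
    z = panel.z[subset]
    w = np.sqrt(panel.n[subset]) if not equal_weights else np.ones(len(subset))
    available = np.isfinite(z)
    if not available.all():
        logger.warning(
            "combine_z: %d missing z-score(s); combining over available members",
            int((~available).sum()),
        )
    wz = np.where(available, z, 0.0) * w[:, None]
    w2 = (available * (w**2)[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return wz.sum(axis=0) / np.sqrt(w2)


@dataclasses.dataclass
class ReplicationCurves:
    """Average cumulative replication-rate curves per enrichment stratum."""

    strata_thresholds: tuple
    n_partitions: int
    bins: int
    bin_centers: np.ndarray  # mean over partitions, -log10 p scale
    rates: dict  # threshold -> (bins,) mean cumulative rate
    alpha: float
    require_sign: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, y in self.rates.items():
            rows.append(pd.DataFrame({"stratum": t, "x": self.bin_centers, "rate": y}))
        return pd.concat(rows, ignore_index=True)


def align_strata(strata: Mapping[float, pd.Index], snp_ids: pd.Index) -> dict:
    """Convert id-set strata to boolean masks over the panel's SNP order."""
    return {t: snp_ids.isin(ids) for t, ids in strata.items()}


def replication_curves(
    panel: SubstudyPanel,
    strata: Mapping[float, np.ndarray],
    n_partitions: int = DEFAULT_N_PARTITIONS,
    bins: int = DEFAULT_N_BINS,
    seed: int = 0,
    require_sign: bool = True,
    alpha: float = REPLICATION_ALPHA,
) -> ReplicationCurves:
    """Cumulative replication rate versus discovery significance, by stratum.

    Per partition: discovery/replication combined z-scores; replication
    success means replication two-sided p < alpha and (by default) the same
    effect sign as discovery.  SNPs are binned by discovery -log10 p into
    ``bins`` equal-width bins over the observed range; the cumulative rate
    at a bin is the success proportion among SNPs at least that significant.
    Curves are averaged over partitions; bins empty in a partition are
    carried as undefined there, not interpolated.
    """
    strata = {
        t: (m if m.dtype == bool else panel.snp_ids.isin(m)) for t, m in strata.items()
    }
    parts = partition_substudies(panel, n_partitions, seed=seed)
    rate_sum = {t: np.zeros(bins) for t in strata}
    rate_cnt = {t: np.zeros(bins) for t in strata}
    center_sum = np.zeros(bins)
    for disc, rep in parts:
        zd = combine_z(panel, disc)
        zr = combine_z(panel, rep)
        lpd = -np.log10(z_to_p(zd))
        success = z_to_p(zr) < alpha
        if require_sign:
            success &= np.sign(zd) * np.sign(zr) > 0
        lo, hi = float(lpd.min()), float(lpd.max())
        width = (hi - lo) or 1.0
        idx = np.clip(((lpd - lo) / width * bins).astype(int), 0, bins - 1)
        center_sum += lo + (np.arange(bins) + 0.5) / bins * width
        for t, mask in strata.items():
            tot = np.bincount(idx[mask], minlength=bins)
            suc = np.bincount(idx[mask], weights=success[mask].astype(float), minlength=bins)
            ctot = tot[::-1].cumsum()[::-1]
            csuc = suc[::-1].cumsum()[::-1]
            defined = ctot > 0
            rate_sum[t][defined] += csuc[defined] / ctot[defined]
            rate_cnt[t][defined] += 1
    rates = {}
    for t in strata:
        with np.errstate(invalid="ignore", divide="ignore"):
            rates[t] = np.where(rate_cnt[t] > 0, rate_sum[t] / rate_cnt[t], np.nan)
    return ReplicationCurves(
        strata_thresholds=tuple(strata),
        n_partitions=n_partitions,
        bins=bins,
        bin_centers=center_sum / len(parts),
        rates=rates,
        alpha=alpha,
        require_sign=require_sign,
    )


def effect_size_agreement(
    panel: SubstudyPanel,
    strata: Mapping[float, np.ndarray],
    n_partitions: int = DEFAULT_N_PARTITIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Through-origin slope of replication z on discovery z, per stratum.

    Winner's-curse diagnostic: pure-null SNPs give slope ~ 0, perfectly
    replicating effects give slope ~ 1.  Returns per-stratum mean slope and
    Monte-Carlo standard error over partitions.
    """
    strata = {
        t: (m if m.dtype == bool else panel.snp_ids.isin(m)) for t, m in strata.items()
    }
    parts = partition_substudies(panel, n_partitions, seed=seed)
    slopes = {t: [] for t in strata}
    for disc, rep in parts:
        zd = combine_z(panel, disc)
        zr = combine_z(panel, rep)
        for t, mask in strata.items():
            denom = float(np.sum(zd[mask] ** 2))
            if denom == 0.0:
                slopes[t].append(np.nan)
                continue
            slopes[t].append(float(np.sum(zd[mask] * zr[mask]) / denom))
    rows = []
    for t, vals in slopes.items():
        v = np.asarray(vals)
        k = int(np.sum(np.isfinite(v)))
        rows.append(
            {
                "stratum": t,
                "slope": float(np.nanmean(v)) if k else np.nan,
                "mc_se": float(np.nanstd(v, ddof=1) / np.sqrt(k)) if k > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
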
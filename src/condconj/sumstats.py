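"""Reading, validation, harmonization and inflation control of GWAS summary statistics.

Summary statistics are carried as pandas DataFrames with canonical columns
``snp_id, chrom, pos, a1, a2, z, p, n`` (one trait) or
``snp_id, chrom, pos, a1, a2, z1, p1, z2, p2, n1, n2, direction_defined``
(two harmonized traits). Positions are 1-based; alleles are upper-case
A/C/G/T with ``a1`` the effect allele; ``z`` is the signed association
z-score and ``p`` the two-sided p-value.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("condconj")

#: floor applied to p-values in z <-> p conversions so that log-space grids
#: never see an exact zero
P_FLOOR = 1e-300

#: median of the chi-squared distribution with 1 degree of freedom
#: (0.4549... ; denominator of the genomic-control lambda)
CHI2_MEDIAN_1DF = float(stats.chi2(1).median())

#: relative tolerance for the z/p consistency check; printed tables round z
#: to two decimals, which perturbs the implied p by roughly this much
ZP_CONSISTENCY_RTOL = 0.05

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default header names for tab-delimited summary-statistics files
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "z": "Z",
    "p": "P",
    "n": "N",
}

REQUIRED_FIELDS = ("snp_id", "chrom", "pos", "a1", "a2")


@dataclasses.dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association statistics in one trait."""

    snp_id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    z: Optional[float] = None
    p: Optional[float] = None
    n: Optional[float] = None


@dataclasses.dataclass(frozen=True)
class HarmonizedPair:
    """Allele-aligned joint record for two traits.

    ``a1``/``a2`` are in trait-1 orientation and ``z2`` has been re-oriented
    to trait 1's effect allele.  ``direction_defined`` is False for
    strand-ambiguous palindromic (A/T, C/G) SNPs, in which case ``z2`` is
    carried as NaN and any concordance computed from it is undefined.
    """

    snp_id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    z1: float
    p1: float
    z2: float
    p2: float
    direction_defined: bool


@dataclasses.dataclass(frozen=True)
class InflationFactor:
    """Genomic inflation factor lambda = median(z^2) / 0.4549 on a SNP subset."""

    lambda_gc: float
    subset: str


# ---------------------------------------------------------------------------
# z <-> p conversion
# ---------------------------------------------------------------------------


def z_to_p(z, floor: float = P_FLOOR):
    """Two-sided p-value 2*Phi(-|z|), clipped below at ``floor``."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z_to_p requires finite z-scores")
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, floor, 1.0)
    return p if p.ndim else float(p)


def p_to_z(p, floor: float = P_FLOOR):
    """Magnitude |z| implied by a two-sided p-value (sign is not recoverable)."""
    p = np.clip(np.asarray(p, dtype=float), floor, 1.0)
    z = stats.norm.isf(p / 2.0)
    return z if z.ndim else float(z)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------


def read_sumstats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    sep: str = r"\s+",
    reject_path=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a whitespace/tab-delimited summary-statistics file.

    Returns ``(records, rejected)``: the validated records in canonical
    columns and a per-row rejection report (columns ``row, snp_id, reason``).
    Rows failing invariants (p outside (0,1], invalid alleles, inconsistent
    z/p, duplicate positions) are rejected and counted; a duplicated
    ``snp_id`` is fatal.  A missing z with a present p yields a
    magnitude-only record (z = NaN); a missing p with a present z is filled
    from ``z_to_p``.  Unknown extra columns are ignored.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep)
    missing = [cmap[f] for f in REQUIRED_FIELDS if cmap[f] not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mapped column(s) {missing}")
    if cmap["z"] not in raw.columns and cmap["p"] not in raw.columns:
        raise ValueError(f"{path}: need at least one of {cmap['z']!r}, {cmap['p']!r}")

    df = pd.DataFrame(
        {
            "snp_id": raw[cmap["snp_id"]].astype(str),
            "chrom": raw[cmap["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[cmap["pos"]], errors="coerce"),
            "a1": raw[cmap["a1"]].astype(str).str.upper(),
            "a2": raw[cmap["a2"]].astype(str).str.upper(),
            "z": pd.to_numeric(raw[cmap["z"]], errors="coerce")
            if cmap["z"] in raw.columns
            else np.nan,
            "p": pd.to_numeric(raw[cmap["p"]], errors="coerce")
            if cmap["p"] in raw.columns
            else np.nan,
            "n": pd.to_numeric(raw[cmap["n"]], errors="coerce")
            if cmap["n"] in raw.columns
            else np.nan,
        }
    )
    dup = df["snp_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate snp_id(s), e.g. {df.loc[dup, 'snp_id'].iloc[0]!r}"
        )
    records, rejected = validate_sumstats(df)
    if len(rejected):
        logger.warning("%s: rejected %d row(s)", path, len(rejected))
    if reject_path is not None:
        rejected.to_csv(reject_path, sep="\t", index=False)
    return records, rejected


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply row-level invariants; return (accepted, rejection report)."""
    df = df.copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    def _flag(mask, reason):
        mask = mask & (reasons == "")
        reasons[mask] = reason

    _flag(df["pos"].isna() | (df["pos"] <= 0), "invalid position")
    _flag(~df["a1"].isin(VALID_ALLELES) | ~df["a2"].isin(VALID_ALLELES), "invalid allele")
    _flag(df["a1"] == df["a2"], "a1 == a2")
    # fill p from z where absent, then range-check
    fill = df["p"].isna() & df["z"].notna() & np.isfinite(df["z"].fillna(0.0))
    df.loc[fill, "p"] = z_to_p(df.loc[fill, "z"].to_numpy())
    _flag(df["p"].isna(), "missing p and z")
    _flag(df["p"].notna() & ((df["p"] <= 0) | (df["p"] > 1)), "p outside (0, 1]")
    _flag(df["z"].notna() & ~np.isfinite(df["z"].fillna(0.0)), "non-finite z")
    both = (reasons == "") & df["z"].notna() & df["p"].notna()
    if both.any():
        implied = z_to_p(df.loc[both, "z"].to_numpy())
        rel = np.abs(implied - df.loc[both, "p"].to_numpy()) / df.loc[both, "p"].to_numpy()
        bad = both.index[both][rel > ZP_CONSISTENCY_RTOL]
        reasons[bad] = "z/p inconsistent"
    _flag(df["n"].notna() & (df["n"] <= 0), "n <= 0")
    _flag(df.duplicated(subset=["chrom", "pos"], keep="first"), "duplicate (chrom, pos)")

    bad = reasons != ""
    rejected = pd.DataFrame(
        {"row": df.index[bad], "snp_id": df.loc[bad, "snp_id"], "reason": reasons[bad]}
    ).reset_index(drop=True)
    accepted = df.loc[~bad].reset_index(drop=True)
    accepted["pos"] = accepted["pos"].astype(np.int64)
    return accepted, rejected


def write_sumstats(records: pd.DataFrame, path, column_map: Optional[Mapping[str, str]] = None):
    """Write canonical records back to a tab-delimited file (round-trip safe)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = records.rename(columns={k: v for k, v in cmap.items() if k in records.columns})
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.map(COMPLEMENT)


def harmonize_frames(df1: pd.DataFrame, df2: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two canonical single-trait frames on snp_id and align alleles.

    Trait-2 z-scores are sign-flipped when trait 2 reports the swapped allele
    pair (directly or as strand complements).  Palindromic SNPs are retained
    with ``direction_defined = False`` and z2 = NaN (p-values are unchanged
    by harmonization, so FDR magnitudes remain valid).  Pairs whose allele
    sets do not match, or whose positions disagree, are dropped and counted
    in ``result.attrs['counts']``.
    """
    merged = df1.merge(df2, on="snp_id", suffixes=("_1", "_2"), how="inner")
    counts = {
        "trait1_total": len(df1),
        "trait2_total": len(df2),
        "shared": len(merged),
        "trait1_only": len(df1) - len(merged),
        "trait2_only": len(df2) - len(merged),
    }
    if len(merged) == 0:
        raise ValueError("no SNPs shared between the two traits")

    pos_ok = merged["pos_1"] == merged["pos_2"]
    a1, a2 = merged["a1_1"], merged["a2_1"]
    b1, b2 = merged["a1_2"], merged["a2_2"]
    c1, c2 = a1.map(COMPLEMENT), a2.map(COMPLEMENT)
    same = ((b1 == a1) & (b2 == a2)) | ((b1 == c1) & (b2 == c2))
    swap = ((b1 == a2) & (b2 == a1)) | ((b1 == c2) & (b2 == c1))
    match = (same | swap) & pos_ok
    palin = _is_palindromic(a1, a2)

    counts["dropped_allele_mismatch"] = int((~(same | swap)).sum())
    counts["dropped_position_mismatch"] = int(((same | swap) & ~pos_ok).sum())

    kept = merged[match].reset_index(drop=True)
    z2 = kept["z_2"].to_numpy(dtype=float).copy()
    flip = (swap & ~same)[match].to_numpy()
    z2[flip] = -z2[flip]
    direction = ~palin[match].to_numpy()
    z2[~direction] = np.nan

    pairs = pd.DataFrame(
        {
            "snp_id": kept["snp_id"],
            "chrom": kept["chrom_1"],
            "pos": kept["pos_1"],
            "a1": kept["a1_1"],
            "a2": kept["a2_1"],
            "z1": kept["z_1"],
            "p1": kept["p_1"],
            "z2": z2,
            "p2": kept["p_2"],
            "n1": kept["n_1"],
            "n2": kept["n_2"],
            "direction_defined": direction,
        }
    )
    counts["harmonized"] = len(pairs)
    counts["palindromic"] = int((~direction).sum())
    pairs.attrs["counts"] = counts
    return pairs


def harmonize_alleles(trait1: SummaryRecord, trait2: SummaryRecord) -> Optional[HarmonizedPair]:
    """Harmonize a single SNP pair; returns None when allele sets do not match."""
    if trait1.snp_id != trait2.snp_id:
        raise ValueError(f"snp_id mismatch: {trait1.snp_id!r} vs {trait2.snp_id!r}")
    df1 = pd.DataFrame([dataclasses.asdict(trait1)])
    df2 = pd.DataFrame([dataclasses.asdict(trait2)])
    try:
        pairs = harmonize_frames(df1, df2)
    except ValueError:
        return None
    if len(pairs) == 0:
        logger.warning("allele mismatch for %s; pair dropped", trait1.snp_id)
        return None
    r = pairs.iloc[0]
    return HarmonizedPair(
        snp_id=r["snp_id"],
        chrom=r["chrom"],
        pos=int(r["pos"]),
        a1=r["a1"],
        a2=r["a2"],
        z1=float(r["z1"]) if pd.notna(r["z1"]) else np.nan,
        p1=float(r["p1"]),
        z2=float(r["z2"]) if pd.notna(r["z2"]) else np.nan,
        p2=float(r["p2"]),
        direction_defined=bool(r["direction_defined"]),
    )


def intersect_traits(records1: pd.DataFrame, records2: pd.DataFrame) -> pd.DataFrame:
    """Inner join of two validated trait frames followed by harmonization."""
    pairs = harmonize_frames(records1, records2)
    c = pairs.attrs["counts"]
    logger.info(
        "intersect: %d shared, %d trait1-only, %d trait2-only, %d dropped",
        c["shared"],
        c["trait1_only"],
        c["trait2_only"],
        c["dropped_allele_mismatch"] + c["dropped_position_mismatch"],
    )
    return pairs


# ---------------------------------------------------------------------------
# genomic control
# ---------------------------------------------------------------------------


def genomic_control(
    records: pd.DataFrame,
    ld=None,
    null_subset: Optional[Iterable[str]] = None,
    seed: int = 0,
    min_subset: int = 100,
) -> tuple[pd.DataFrame, InflationFactor]:
    """Median-chi2 genomic control: lambda = median(z^2)/0.4549, z' = z/sqrt(lambda).

    The inflation factor is estimated on ``null_subset`` if given, otherwise
    on one random SNP per LD block when an :class:`~condconj.ld.LDReference`
    is supplied, otherwise on all SNPs.  Corrected p-values are recomputed
    from the deflated z-scores.  Records lacking z use the magnitude implied
    by p (sign stays undefined).
    """
    from .ld import random_prune  # local import to avoid a cycle

    df = records.copy()
    absz = np.abs(df["z"].to_numpy(dtype=float))
    from_p = ~np.isfinite(absz)
    if from_p.any():
        absz[from_p] = p_to_z(df.loc[from_p, "p"].to_numpy())

    if null_subset is not None:
        subset_ids = pd.Index(null_subset)
        label = "null_subset"
    elif ld is not None:
        subset_ids = pd.Index(random_prune(df["snp_id"], ld, seed=seed))
        label = "random_pruned"
    else:
        subset_ids = pd.Index(df["snp_id"])
        label = "all"
    mask = df["snp_id"].isin(subset_ids).to_numpy()
    if mask.sum() < min_subset:
        logger.warning(
            "genomic control subset has %d < %d SNPs; falling back to all SNPs",
            int(mask.sum()),
            min_subset,
        )
        mask = np.ones(len(df), dtype=bool)
        label = "all(fallback)"
    lam = float(np.median(absz[mask] ** 2) / CHI2_MEDIAN_1DF)
    scale = np.sqrt(lam)
    df["z"] = df["z"] / scale
    df["p"] = z_to_p(absz / scale)
    factor = InflationFactor(lambda_gc=lam, subset=f"{label}(n={int(mask.sum())})")
    logger.info("genomic control: lambda = %.4f on %s", lam, factor.subset)
    return df, factor
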
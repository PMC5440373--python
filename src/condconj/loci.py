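"""Shared-locus definition, nearest-gene annotation, direction concordance.

Significant SNPs (conjunction FDR below threshold) are clustered into LD
blocks — connected components of the r^2 > threshold graph restricted to the
significant set — and each block becomes one locus led by its SNP with the
smallest conjunction FDR.  The exported locus table mirrors the usual
shared-variants summary: lead marker, nearest gene, alleles, conjFDR,
z-scores and p-values in both traits, and the allelic-direction flag
(undefined for palindromic leads).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cfdr import ConjunctionResult
from .ld import LDReference, _UnionFind

logger = logging.getLogger("condconj")


@dataclasses.dataclass(frozen=True)
class Locus:
    """One independent shared locus (an LD block of significant SNPs)."""

    locus_index: int
    lead_snp: str
    members: tuple
    chrom: str
    pos: int
    a1: str
    a2: str
    conj_fdr: float
    z1: float
    z2: float
    p1: float
    p2: float
    direction_defined: bool
    nearest_gene: Optional[str] = None
    gene_distance: Optional[int] = None
    chrom_band: Optional[str] = None
    concordant: Optional[bool] = None


def _chrom_key(chrom: str):
    c = str(chrom).removeprefix("chr")
    if c.isdigit():
        return (int(c), "")
    return ({"X": 23, "Y": 24, "MT": 25, "M": 25}.get(c, 26), c)


def define_loci(result: ConjunctionResult, ld: LDReference) -> list[Locus]:
    """Cluster significant SNPs into LD blocks and pick the lead per block.

    Components are taken in the subgraph induced on the significant set;
    a block may contain more than one significant SNP.  The lead minimizes
    (conj_fdr, p1, snp_id); loci are numbered by genomic order of the lead.
    Returns an empty list when nothing is significant.
    """
    table = result.table
    sig = table[table["significant"]].copy()
    if len(sig) == 0:
        return []
    sig["snp_id"] = sig["snp_id"].astype(str)
    ids = sig["snp_id"].tolist()
    if ld.clique_blocks:
        comp = ld.block_codes(ids)
    else:
        uf = _UnionFind()
        idset = set(ids)
        for s in ids:
            uf.find(s)
            for nb in ld.partners(s) & idset:
                uf.union(s, nb)
        comp = pd.factorize(np.array([uf.find(s) for s in ids], dtype=object))[0]
    sig["component"] = comp

    loci = []
    for _, grp in sig.groupby("component"):
        grp = grp.sort_values(["conj_fdr", "p1", "snp_id"], kind="mergesort")
        lead = grp.iloc[0]
        loci.append(
            Locus(
                locus_index=0,
                lead_snp=lead["snp_id"],
                members=tuple(sorted(grp["snp_id"])),
                chrom=str(lead["chrom"]),
                pos=int(lead["pos"]),
                a1=str(lead.get("a1", "")),
                a2=str(lead.get("a2", "")),
                conj_fdr=float(lead["conj_fdr"]),
                z1=float(lead["z1"]) if pd.notna(lead["z1"]) else np.nan,
                z2=float(lead["z2"]) if pd.notna(lead["z2"]) else np.nan,
                p1=float(lead["p1"]),
                p2=float(lead["p2"]),
                direction_defined=bool(lead.get("direction_defined", True)),
            )
        )
    loci.sort(key=lambda L: (_chrom_key(L.chrom), L.pos))
    return [dataclasses.replace(L, locus_index=i + 1) for i, L in enumerate(loci)]


def annotate_nearest_gene(locus: Locus, genes: pd.DataFrame) -> Locus:
    """Label the locus with the gene nearest its lead SNP.

    ``genes`` needs columns (chrom, start, end, name) in the same 1-based
    coordinate convention as the SNPs.  Distance is 0 when the lead lies
    inside the gene span; ties break on smaller start, then name.  With no
    gene on the lead's chromosome the label is ``intergenic-unassigned``.
    """
    sub = genes[genes["chrom"].astype(str) == locus.chrom]
    if len(sub) == 0:
        logger.warning("no gene on chromosome %s; locus %s unassigned", locus.chrom, locus.lead_snp)
        return dataclasses.replace(locus, nearest_gene="intergenic-unassigned", gene_distance=None)
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    pos = locus.pos
    inside = (start <= pos) & (pos <= end)
    dist = np.where(inside, 0, np.minimum(np.abs(pos - start), np.abs(pos - end)))
    order = np.lexsort((sub["name"].astype(str).to_numpy(), start, dist))
    best = sub.iloc[order[0]]
    return dataclasses.replace(
        locus, nearest_gene=str(best["name"]), gene_distance=int(dist[order[0]])
    )


def direction_concordance(locus: Locus) -> Optional[bool]:
    """True when the lead's allelic effects point the same way in both traits.

    Undefined (None) for palindromic leads — the strand, hence the relative
    effect direction, cannot be resolved from the alleles — and for zero or
    missing z-scores.
    """
    if not locus.direction_defined:
        return None
    if not np.isfinite(locus.z1) or not np.isfinite(locus.z2) or locus.z1 == 0 or locus.z2 == 0:
        logger.warning("locus %s: zero or missing z-score; concordance undefined", locus.lead_snp)
        return None
    return bool(np.sign(locus.z1) * np.sign(locus.z2) > 0)


def annotate_loci(
    loci: Sequence[Locus], genes: Optional[pd.DataFrame] = None
) -> list[Locus]:
    """Attach nearest genes (when provided) and concordance flags to all loci."""
    out = []
    for L in loci:
        if genes is not None:
            L = annotate_nearest_gene(L, genes)
        out.append(dataclasses.replace(L, concordant=direction_concordance(L)))
    return out


def loci_table(loci: Sequence[Locus]) -> pd.DataFrame:
    """Tab-delimited-ready locus table (one row per locus, Table-style columns)."""
    rows = []
    for L in loci:
        rows.append(
            {
                "locus": L.locus_index,
                "lead_snp": L.lead_snp,
                "nearest_gene": L.nearest_gene,
                "gene_distance": L.gene_distance,
                "chrom": L.chrom,
                "pos": L.pos,
                "a1_a2": f"{L.a1}/{L.a2}",
                "conj_fdr": L.conj_fdr,
                "z1": L.z1,
                "z2": L.z2,
                "p1": L.p1,
                "p2": L.p2,
                "n_members": len(L.members),
                "members": ",".join(L.members),
                "concordant": {True: "yes", False: "no", None: "NaN"}[L.concordant],
            }
        )
    return pd.DataFrame(rows)


def manhattan_export(
    result: ConjunctionResult,
    loci: Sequence[Locus],
    kind: str = "conjunction",
) -> pd.DataFrame:
    """Plot-ready per-SNP table in genome order.

    ``kind`` selects the plotted value: ``conjunction`` (conj_fdr),
    ``conditional_1g2`` or ``conditional_2g1``.  Leads are flagged so the
    strongest signal per LD block can be encircled; significant SNPs can be
    drawn enlarged.
    """
    col = {
        "conjunction": "conj_fdr",
        "conditional_1g2": "cfdr_1g2",
        "conditional_2g1": "cfdr_2g1",
    }.get(kind)
    if col is None:
        raise ValueError(f"unknown kind {kind!r}")
    t = result.table
    leads = {L.lead_snp for L in loci}
    out = pd.DataFrame(
        {
            "snp_id": t["snp_id"].astype(str),
            "chrom": t["chrom"].astype(str),
            "pos": t["pos"],
            "neg_log10_fdr": -np.log10(np.clip(t[col].to_numpy(dtype=float), 1e-300, None)),
            "significant": t["significant"],
            "is_lead": t["snp_id"].astype(str).isin(leads),
        }
    )
    out["_ck"] = out["chrom"].map(_chrom_key)
    out = out.sort_values(["_ck", "pos"], kind="mergesort").drop(columns="_ck")
    return out.reset_index(drop=True)
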
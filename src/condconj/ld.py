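"""LD structure: r^2 partner graph, blocks, random pruning, region exclusion, clumping.

An LD block is a connected component of the graph whose edges are SNP pairs
with pairwise r^2 strictly greater than the threshold (default 0.1, as the
analysis rules are printed with a strict inequality).  The reference can be
built either from an explicit pairwise r^2 table or from a precomputed block
assignment, in which case each block is treated as a clique.
"""

from __future__ import annotations

import dataclasses
import logging
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("condconj")

DEFAULT_R2_THRESHOLD = 0.1


@dataclasses.dataclass(frozen=True)
class GenomicRegion:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region {self.label!r}: start > end")

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


def default_exclusion_regions() -> list[GenomicRegion]:
    """High-LD regions excluded from model estimation (editable data file).

    Ships with the extended MHC (chr6:25,652,429-33,368,333) and 8p23.1
    (chr8:7,242,715-12,483,982).
    """
    path = resources.files("condconj").joinpath("data/exclusion_regions.tsv")
    with resources.as_file(path) as f:
        df = pd.read_csv(f, sep="\t")
    return [
        GenomicRegion(str(r.chrom), int(r.start), int(r.end), str(r.label))
        for r in df.itertuples()
    ]


def load_regions(path, one_based: bool = True) -> list[GenomicRegion]:
    """Read a BED-like 4-column region file (chrom, start, end, label).

    With ``one_based=False`` the input is interpreted as 0-based half-open
    (BED convention) and converted to the internal 1-based inclusive canon.
    """
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.lower() for c in df.columns]
    regions = []
    for r in df.itertuples():
        start, end = int(r.start), int(r.end)
        if not one_based:
            start += 1
        regions.append(GenomicRegion(str(r.chrom), start, end, str(getattr(r, "label", ""))))
    return regions


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        if p != x:
            p = self.parent[x] = self.find(p)
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


class LDReference:
    """SNP graph of r^2 > threshold partners and derived LD-block assignment."""

    def __init__(
        self,
        block_of: pd.Series,
        adjacency: Optional[dict] = None,
        r2_threshold: float = DEFAULT_R2_THRESHOLD,
    ):
        # block_of: Series indexed by snp_id with integer block codes
        self._block_of = block_of
        self._adj = adjacency  # None => blocks are cliques
        self.r2_threshold = float(r2_threshold)
        self._groups = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        pairs,
        r2_threshold: float = DEFAULT_R2_THRESHOLD,
        snps: Optional[Iterable[str]] = None,
    ) -> "LDReference":
        """Build from (id_a, id_b, r2) triples; edges with r2 <= threshold are discarded.

        ``snps`` optionally declares the full panel so that SNPs absent from
        every retained pair still form singleton blocks.
        """
        if isinstance(pairs, pd.DataFrame):
            triples = pairs.itertuples(index=False)
        else:
            triples = pairs
        adj: dict = {}
        uf = _UnionFind()
        if snps is not None:
            for s in snps:
                uf.find(str(s))
        for a, b, r2 in triples:
            a, b = str(a), str(b)
            r2 = float(r2)
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"r^2 = {r2} outside [0, 1] for pair ({a}, {b})")
            if a == b:
                logger.warning("self-pair for %s ignored", a)
                continue
            uf.find(a)
            uf.find(b)
            if r2 <= r2_threshold:  # strict: only r^2 > threshold are partners
                continue
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
            uf.union(a, b)
        ids = sorted(uf.parent)
        roots = pd.factorize(np.array([uf.find(i) for i in ids], dtype=object))[0]
        block_of = pd.Series(roots, index=pd.Index(ids, name="snp_id"))
        return cls(block_of, adjacency=adj, r2_threshold=r2_threshold)

    @classmethod
    def from_blocks(
        cls, block_of: Mapping[str, int] | pd.Series, r2_threshold: float = DEFAULT_R2_THRESHOLD
    ) -> "LDReference":
        """Build from a precomputed SNP -> block assignment (blocks as cliques)."""
        s = pd.Series(block_of) if not isinstance(block_of, pd.Series) else block_of.copy()
        s.index = s.index.astype(str)
        s = pd.Series(pd.factorize(s.to_numpy())[0], index=s.index)
        return cls(s, adjacency=None, r2_threshold=r2_threshold)

    # -- basic queries ------------------------------------------------------

    @property
    def snps(self) -> pd.Index:
        return self._block_of.index

    @property
    def n_blocks(self) -> int:
        return int(self._block_of.max()) + 1 if len(self._block_of) else 0

    @property
    def clique_blocks(self) -> bool:
        return self._adj is None

    def block_id(self, snp: str) -> Optional[int]:
        try:
            return int(self._block_of[str(snp)])
        except KeyError:
            return None

    def block_codes(self, ids: Sequence[str]) -> np.ndarray:
        """Block codes for ``ids``; unknown SNPs get fresh singleton codes."""
        codes = self._block_of.reindex(pd.Index(ids)).to_numpy(dtype=float)
        unknown = np.isnan(codes)
        if unknown.any():
            logger.warning("%d SNP(s) unknown to the LD reference become singletons", int(unknown.sum()))
            codes[unknown] = self.n_blocks + np.arange(int(unknown.sum()))
        return codes.astype(np.int64)

    def _block_groups(self) -> dict:
        if self._groups is None:
            self._groups = {
                b: tuple(g.index) for b, g in self._block_of.groupby(self._block_of)
            }
        return self._groups

    def block_members(self, block: int) -> tuple:
        return self._block_groups().get(block, ())

    def partners(self, snp: str) -> set:
        """SNPs with pairwise r^2 > threshold to ``snp``."""
        snp = str(snp)
        if self._adj is not None:
            return set(self._adj.get(snp, ()))
        b = self.block_id(snp)
        if b is None:
            return set()
        return set(self.block_members(b)) - {snp}

    def partners_of_set(self, ids: Iterable[str]) -> set:
        """Union of partners over a set of SNPs (one edge step, not transitive)."""
        ids = set(map(str, ids))
        if self._adj is not None:
            out = set()
            for s in ids:
                out |= self._adj.get(s, set())
            return out
        blocks = {b for b in (self.block_id(s) for s in ids) if b is not None}
        out = set()
        for b in blocks:
            out |= set(self.block_members(b))
        return out - ids


def load_ld(path, r2_threshold: float = DEFAULT_R2_THRESHOLD) -> LDReference:
    """Load an LD reference; dialect auto-detected from the header.

    Three columns (id_a, id_b, r2) are read as pairwise r^2; two columns
    (id, block) as a precomputed block assignment.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] >= 3:
        return LDReference.from_pairs(df.iloc[:, :3], r2_threshold=r2_threshold)
    if df.shape[1] == 2:
        return LDReference.from_blocks(
            pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str)),
            r2_threshold=r2_threshold,
        )
    raise ValueError(f"{path}: expected 2 (block) or 3 (pairwise) columns")


# ---------------------------------------------------------------------------
# pruning / exclusion / clumping
# ---------------------------------------------------------------------------


def random_prune(snps: Iterable[str], ld: LDReference, seed: int = 0) -> pd.Index:
    """Select one uniformly random SNP per LD block intersecting ``snps``.

    Deterministic per seed and invariant to the input order (ids are sorted
    before drawing).  SNPs unknown to the reference count as singletons.
    """
    ids = np.asarray(sorted(set(map(str, snps))))
    if len(ids) == 0:
        raise ValueError("random_prune: empty input")
    rng = np.random.default_rng(seed)
    codes = ld.block_codes(ids)
    u = rng.random(len(ids))
    order = np.lexsort((u, codes))  # within block, random order
    codes_sorted = codes[order]
    first = np.ones(len(ids), dtype=bool)
    first[1:] = codes_sorted[1:] != codes_sorted[:-1]
    chosen = ids[order[first]]
    return pd.Index(np.sort(chosen))


def exclude_regions(
    snps: Iterable[str],
    ld: LDReference,
    regions: Sequence[GenomicRegion],
    positions,
) -> pd.Index:
    """Drop SNPs inside any region and SNPs sharing an r^2 edge with them.

    ``positions`` maps snp_id -> (chrom, pos); a DataFrame with columns
    ``snp_id, chrom, pos`` is also accepted.  Bounds are 1-based inclusive.
    The in-region seed set is found among all SNPs with known positions, so
    an out-of-region SNP is removed as soon as it has an LD partner inside.
    """
    if isinstance(positions, pd.DataFrame):
        pos_df = positions.set_index(positions["snp_id"].astype(str))[["chrom", "pos"]]
    else:
        pos_df = pd.DataFrame.from_dict(dict(positions), orient="index", columns=["chrom", "pos"])
    chroms = pos_df["chrom"].astype(str).to_numpy()
    pos = pos_df["pos"].to_numpy()

    in_region = np.zeros(len(pos_df), dtype=bool)
    for region in regions:
        on_chrom = chroms == region.chrom
        if not on_chrom.any():
            logger.warning("region %r: chromosome %s not present; skipped", region.label, region.chrom)
            continue
        in_region |= on_chrom & (pos >= region.start) & (pos <= region.end)
    seed_ids = set(pos_df.index[in_region])
    removed = seed_ids | ld.partners_of_set(seed_ids)
    return pd.Index([s for s in map(str, snps) if s not in removed])


def greedy_clump(
    scores,
    ld: LDReference,
    p1=None,
) -> list:
    """Greedy selection of index SNPs by ascending score under the r^2 graph.

    Iterates SNPs from strongest (lowest score); a SNP is kept iff it has no
    r^2 > threshold edge to any already-kept SNP.  Ties break on smaller
    ``p1`` (when provided), then lexicographic id, making the output
    deterministic and invariant to input order.
    """
    scores = pd.Series(scores)
    scores.index = scores.index.astype(str)
    if not np.all(np.isfinite(scores.to_numpy(dtype=float))):
        raise ValueError("greedy_clump: scores must be finite")
    if p1 is not None:
        p1 = pd.Series(p1)
        p1.index = p1.index.astype(str)
        tie = p1.reindex(scores.index).fillna(np.inf)
    else:
        tie = pd.Series(np.inf, index=scores.index)
    order = sorted(scores.index, key=lambda s: (scores[s], tie[s], s))

    kept: list = []
    if ld.clique_blocks:
        used_blocks = set()
        for s in order:
            b = ld.block_id(s)
            if b is None or b not in used_blocks:
                kept.append(s)
                if b is not None:
                    used_blocks.add(b)
    else:
        kept_set: set = set()
        for s in order:
            if not (ld.partners(s) & kept_set):
                kept.append(s)
                kept_set.add(s)
    return kept
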
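"""Synthetic paired GWAS summary statistics with known ground truth.

The generator emulates two polygenic traits measured in two independent
cohorts.  Per-SNP causal states follow a four-component mixture (null /
trait-1-only / trait-2-only / shared with correlated standardized effects);
z-scores acquire LD structure through block-level mixing: each SNP's mean is
its own causal effect plus r times the average of its block-mates' effects
(r = sqrt(within-block r^2)), and the N(0,1) noise is exchangeably
correlated (correlation r) within blocks.  Two high-LD regions with
inflated block sizes mimic the extended MHC and 8p23.1.  A substudy panel
decomposes trait 1 into K cohorts whose Stouffer combination reproduces the
full-sample mean structure.

Defaults mirror the scale class of a large psychiatric-genetics cross-trait
analysis, shrunk for desk use: 2e5 SNPs, n1 = 82,315, n2 = 59,225,
52 substudies; all overridable.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ld import GenomicRegion, LDReference
from .replication import SubstudyPanel
from .sumstats import z_to_p, write_sumstats

logger = logging.getLogger("condconj")

COMPONENTS = ("null", "trait1", "trait2", "shared")
_NONPALINDROMIC = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                   ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: median of |N(0,1)|; a causal-effect scale sigma gives median causal
#: z-score magnitude sqrt(n) * sigma * 0.6745
HALF_NORMAL_MEDIAN = float(stats.norm.ppf(0.75))

DEFAULT_SPECIAL_REGIONS = (
    (GenomicRegion("6", 25652429, 33368333, "MHC"), 10.0),
    (GenomicRegion("8", 7242715, 12483982, "8p23.1"), 10.0),
)


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the paired-GWAS simulator.

    ``sigma_beta*`` default to the scale at which the median causal z-score
    magnitude is 4 (i.e. 4 / (0.6745 sqrt(n))), placing non-null SNPs in the
    discoverable-but-subtle regime the conditional-FDR method targets.
    """

    n_snps: int = 200_000
    pi: tuple = (0.90, 0.04, 0.04, 0.02)
    rho_shared: float = 0.9
    sigma_beta1: Optional[float] = None
    sigma_beta2: Optional[float] = None
    n1: int = 82_315
    n2: int = 59_225
    ld_block_mean: float = 10.0
    r2_within: float = 0.6
    palindromic_fraction: float = 0.1
    special_regions: tuple = DEFAULT_SPECIAL_REGIONS
    n_substudies: int = 52
    substudy_n: Optional[Sequence[float]] = None
    n_chrom: int = 22
    snp_spacing: int = 5000
    median_causal_z: float = 4.0
    seed: int = 0

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or np.any(pi < 0) or np.any(pi > 1):
            raise ValueError("pi must be four proportions in [0, 1]")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        if not -1.0 <= self.rho_shared <= 1.0:
            raise ValueError("rho_shared must lie in [-1, 1]")
        if not 0.0 <= self.r2_within < 1.0:
            raise ValueError("r2_within must lie in [0, 1)")
        if self.sigma_beta1 is None:
            self.sigma_beta1 = self.median_causal_z / (HALF_NORMAL_MEDIAN * np.sqrt(self.n1))
        if self.sigma_beta2 is None:
            self.sigma_beta2 = self.median_causal_z / (HALF_NORMAL_MEDIAN * np.sqrt(self.n2))
        if self.sigma_beta1 <= 0 or self.sigma_beta2 <= 0:
            raise ValueError("effect scales must be > 0")
        if self.substudy_n is None:
            self.substudy_n = tuple([self.n1 / self.n_substudies] * self.n_substudies)
        sn = np.asarray(self.substudy_n, dtype=float)
        if len(sn) != self.n_substudies or abs(sn.sum() - self.n1) > 1e-6 * self.n1:
            raise ValueError("substudy sizes must number n_substudies and sum to n1")


class SimulatedPair(NamedTuple):
    trait1: pd.DataFrame
    trait2: pd.DataFrame
    truth: pd.DataFrame
    ld: LDReference
    regions: list


def _genome_layout(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome labels and 1-based positions for n_snps on n_chrom chromosomes."""
    n, k = config.n_snps, config.n_chrom
    per = np.full(k, n // k)
    per[: n % k] += 1
    chrom = np.repeat(np.arange(1, k + 1), per)
    pos = np.concatenate([1 + config.snp_spacing * np.arange(c) for c in per])
    return chrom.astype(str), pos.astype(np.int64)


def _draw_blocks(config: SimConfig, chrom: np.ndarray, pos: np.ndarray, rng) -> np.ndarray:
    """Sequential geometric block sizes; special regions inflate the mean size."""
    n = len(pos)
    block = np.empty(n, dtype=np.int64)
    special = [(r, mult) for r, mult in config.special_regions]
    b = 0
    i = 0
    while i < n:
        mean = config.ld_block_mean
        for region, mult in special:
            if region.contains(chrom[i], pos[i]):
                mean = config.ld_block_mean * mult
                break
        size = int(rng.geometric(1.0 / mean))
        j = min(i + size, n)
        # blocks do not cross chromosome boundaries
        while j > i + 1 and chrom[j - 1] != chrom[i]:
            j -= 1
        block[i:j] = b
        b += 1
        i = j
    return block


def _draw_alleles(n: int, palindromic_fraction: float, rng):
    pal = rng.random(n) < palindromic_fraction
    a1 = np.empty(n, dtype=object)
    a2 = np.empty(n, dtype=object)
    idx_np = rng.integers(len(_NONPALINDROMIC), size=n)
    idx_p = rng.integers(len(_PALINDROMIC), size=n)
    for k, (x, y) in enumerate(_NONPALINDROMIC):
        m = ~pal & (idx_np == k)
        a1[m], a2[m] = x, y
    for k, (x, y) in enumerate(_PALINDROMIC):
        m = pal & (idx_p == k)
        a1[m], a2[m] = x, y
    return a1, a2, pal


def _block_mixed_z(beta: np.ndarray, block: np.ndarray, n_sample: float, r: float, rng) -> np.ndarray:
    """Single-factor block tagging plus exchangeable within-block noise.

    z_i = sqrt(n) * (beta_i + r * mean_{j in block, j != i} beta_j) + e_i with
    e_i = sqrt(r) G_block + sqrt(1-r) eps_i, so cor(e_i, e_j) = r within a
    block.  Each SNP tags the block's average causal effect, scaled by the
    representative correlation r = sqrt(r2_within); leakage stays bounded as
    blocks grow.  Coherent summation over all mates would instead make the
    tagged signal grow with block size times causal density — the
    long-range-LD pathology that the analysis masks out by region exclusion
    rather than something ordinary LD blocks exhibit.
    """
    nb = block.max() + 1
    block_sum = np.bincount(block, weights=beta, minlength=nb)
    block_cnt = np.bincount(block, minlength=nb)
    mates_mean = np.where(
        block_cnt[block] > 1,
        (block_sum[block] - beta) / np.maximum(block_cnt[block] - 1, 1),
        0.0,
    )
    mu = np.sqrt(n_sample) * (beta + r * mates_mean)
    shared = rng.standard_normal(nb)[block]
    noise = np.sqrt(r) * shared + np.sqrt(1.0 - r) * rng.standard_normal(len(beta))
    return mu + noise


def simulate_pair(config: SimConfig) -> SimulatedPair:
    """Generate harmonizable summary statistics for two traits plus ground truth.

    Trait 2 is emitted in a random allele orientation per SNP (same, swapped,
    strand-complemented, or both) with the z-score sign adjusted accordingly,
    so that harmonization is exercised end to end; palindromic SNPs (default
    fraction 0.1) exercise the direction-undefined path.
    """
    rng = np.random.default_rng(config.seed)
    chrom, pos = _genome_layout(config)
    n = config.n_snps
    snp_id = np.array([f"rs{i + 1}" for i in range(n)], dtype=object)

    block = _draw_blocks(config, chrom, pos, rng)
    comp = rng.choice(4, size=n, p=np.asarray(config.pi, dtype=float))

    beta1 = np.zeros(n)
    beta2 = np.zeros(n)
    t1 = comp == 1
    t2 = comp == 2
    sh = comp == 3
    beta1[t1] = config.sigma_beta1 * rng.standard_normal(t1.sum())
    beta2[t2] = config.sigma_beta2 * rng.standard_normal(t2.sum())
    g1 = rng.standard_normal(sh.sum())
    g2 = config.rho_shared * g1 + np.sqrt(1.0 - config.rho_shared**2) * rng.standard_normal(sh.sum())
    beta1[sh] = config.sigma_beta1 * g1
    beta2[sh] = config.sigma_beta2 * g2

    r = float(np.sqrt(config.r2_within))
    z1 = _block_mixed_z(beta1, block, config.n1, r, rng)
    z2 = _block_mixed_z(beta2, block, config.n2, r, rng)

    a1, a2, pal = _draw_alleles(n, config.palindromic_fraction, rng)

    trait1 = pd.DataFrame(
        {
            "snp_id": snp_id,
            "chrom": chrom,
            "pos": pos,
            "a1": a1,
            "a2": a2,
            "z": z1,
            "p": z_to_p(z1),
            "n": float(config.n1),
        }
    )

    # trait 2 representation: random orientation, sign-adjusted z
    orient = rng.integers(4, size=n)  # 0 same, 1 swap, 2 complement, 3 complement+swap
    b1 = np.where(orient % 2 == 0, a1, a2)
    b2 = np.where(orient % 2 == 0, a2, a1)
    compl = orient >= 2
    b1[compl] = pd.Series(b1[compl]).map(_COMP).to_numpy(dtype=object)
    b2[compl] = pd.Series(b2[compl]).map(_COMP).to_numpy(dtype=object)
    z2_rep = np.where(orient % 2 == 1, -z2, z2)
    trait2 = pd.DataFrame(
        {
            "snp_id": snp_id,
            "chrom": chrom,
            "pos": pos,
            "a1": b1,
            "a2": b2,
            "z": z2_rep,
            "p": z_to_p(z2),
            "n": float(config.n2),
        }
    )

    truth = pd.DataFrame(
        {
            "snp_id": snp_id,
            "component": np.array(COMPONENTS, dtype=object)[comp],
            "beta1": beta1,
            "beta2": beta2,
            "block": block,
            "palindromic": pal,
        }
    )
    ld = LDReference.from_blocks(pd.Series(block, index=pd.Index(snp_id.astype(str))))
    regions = [region for region, _ in config.special_regions]
    return SimulatedPair(trait1, trait2, truth, ld, regions)


def simulate_substudies(
    config: SimConfig, truth: pd.DataFrame, seed: Optional[int] = None
) -> SubstudyPanel:
    """Substudy panel for trait 1: z_k ~ N(sqrt(n_k) beta1, 1), independent.

    Stouffer combination over all substudies has mean sqrt(n1) * beta1,
    consistent with the full-sample mean structure of trait 1.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    beta1 = truth["beta1"].to_numpy(dtype=float)
    nk = np.asarray(config.substudy_n, dtype=float)
    z = np.sqrt(nk)[:, None] * beta1[None, :] + rng.standard_normal((len(nk), len(beta1)))
    return SubstudyPanel(
        labels=tuple(f"sub{k + 1}" for k in range(len(nk))),
        n=nk,
        z=z,
        snp_ids=pd.Index(truth["snp_id"].astype(str)),
    )


def simulate_genes(
    config: SimConfig, gene_length: int = 20_000, gene_spacing: int = 50_000
) -> pd.DataFrame:
    """Deterministic tiled gene annotation covering the simulated genome."""
    chrom, pos = _genome_layout(config)
    rows = []
    for c in pd.unique(chrom):
        extent = int(pos[chrom == c].max())
        starts = np.arange(1, extent + 1, gene_spacing)
        for k, s in enumerate(starts):
            rows.append({"chrom": c, "start": int(s), "end": int(s + gene_length - 1),
                         "name": f"G{c}_{k + 1}"})
    return pd.DataFrame(rows)


def write_dataset(
    sim: SimulatedPair,
    outdir,
    panel: Optional[SubstudyPanel] = None,
    genes: Optional[pd.DataFrame] = None,
):
    """Write the simulated dataset in the file dialects the readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_sumstats(sim.trait1, out / "trait1.tsv")
    write_sumstats(sim.trait2, out / "trait2.tsv")
    sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"snp_id": sim.ld.snps, "block": sim.ld._block_of.to_numpy()}
    ).to_csv(out / "ld_blocks.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end, "label": r.label} for r in sim.regions]
    ).to_csv(out / "regions.tsv", sep="\t", index=False)
    if genes is not None:
        genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    if panel is not None:
        sub = out / "substudies"
        sub.mkdir(exist_ok=True)
        man = []
        template = sim.trait1[["snp_id", "chrom", "pos", "a1", "a2"]]
        for k, label in enumerate(panel.labels):
            df = template.copy()
            df["z"] = panel.z[k]
            df["p"] = z_to_p(panel.z[k])
            df["n"] = panel.n[k]
            write_sumstats(df, sub / f"{label}.tsv")
            # manifest paths are relative to the manifest itself
            man.append({"label": label, "n": panel.n[k], "path": f"substudies/{label}.tsv"})
        pd.DataFrame(man).to_csv(out / "substudy_manifest.tsv", sep="\t", index=False)
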
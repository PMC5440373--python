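import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

import condconj as cc
from condconj.cfdr import ConjunctionResult
from condconj.loci import Locus


def result_from(df, threshold=0.05):
    df = df.copy()
    df["significant"] = df["conj_fdr"] < threshold
    for col, default in (
        ("chrom", "1"),
        ("pos", 0),
        ("a1", "A"),
        ("a2", "G"),
        ("z1", 1.0),
        ("z2", 1.0),
        ("p2", 0.01),
        ("direction_defined", True),
    ):
        if col not in df.columns:
            df[col] = default
    if "p1" not in df.columns:
        df["p1"] = df["conj_fdr"]
    return ConjunctionResult(table=df, threshold=threshold, n_excluded=0)


def make_locus(**kw):
    base = dict(
        locus_index=1, lead_snp="s1", members=("s1",), chrom="1", pos=100,
        a1="A", a2="G", conj_fdr=0.01, z1=1.0, z2=1.0, p1=1e-4, p2=1e-3,
        direction_defined=True,
    )
    base.update(kw)
    return Locus(**base)


class TestDefineLoci:
    def test_linked_and_isolated(self):
        df = pd.DataFrame(
            {"snp_id": ["a", "b", "c"], "conj_fdr": [0.01, 0.02, 0.03],
             "pos": [100, 200, 5000]}
        )
        ld = cc.LDReference.from_pairs([("a", "b", 0.4)], snps=["a", "b", "c"])
        loci = cc.define_loci(result_from(df), ld)
        assert sorted(len(L.members) for L in loci) == [1, 2]

    def test_lead_minimizes_conj_fdr(self):
        # a linked pair keeps both members but is led by the smaller conjFDR
        df = pd.DataFrame(
            {"snp_id": ["rs2945232", "rs2048656"], "conj_fdr": [1.48e-3, 5.80e-3],
             "pos": [100, 200]}
        )
        ld = cc.LDReference.from_pairs([("rs2945232", "rs2048656", 0.5)])
        (locus,) = cc.define_loci(result_from(df), ld)
        assert locus.lead_snp == "rs2945232"
        assert locus.members == ("rs2048656", "rs2945232")

    def test_no_significant_snps_gives_empty_list(self):
        df = pd.DataFrame({"snp_id": ["a"], "conj_fdr": [0.5], "pos": [1]})
        ld = cc.LDReference.from_blocks({"a": 0})
        assert cc.define_loci(result_from(df), ld) == []

    def test_random_graphs_match_component_minimum_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(2, 15))
            ids = [f"v{i}" for i in range(n)]
            edges = [
                (a, b) for a, b in itertools.combinations(ids, 2) if rng.random() < 0.3
            ]
            fdr = {s: float(rng.uniform(0, 0.049)) for s in ids}
            df = pd.DataFrame(
                {"snp_id": ids, "conj_fdr": [fdr[s] for s in ids],
                 "pos": np.arange(n) * 10}
            )
            ld = cc.LDReference.from_pairs([(a, b, 0.5) for a, b in edges], snps=ids)
            loci = cc.define_loci(result_from(df), ld)
            # oracle: exhaustive component search + minimum
            adj = {i: set() for i in ids}
            for a, b in edges:
                adj[a].add(b)
                adj[b].add(a)
            seen, expected_leads = set(), set()
            for s in ids:
                if s in seen:
                    continue
                comp, frontier = {s}, [s]
                while frontier:
                    nxt = [x for f in frontier for x in adj[f] if x not in comp]
                    comp.update(nxt)
                    frontier = nxt
                seen |= comp
                expected_leads.add(min(comp, key=lambda x: (fdr[x], x)))
            assert {L.lead_snp for L in loci} == expected_leads

    def test_partition_of_significant_set(self):
        rng = np.random.default_rng(14)
        ids = [f"s{i}" for i in range(30)]
        df = pd.DataFrame(
            {"snp_id": ids, "conj_fdr": rng.uniform(0, 0.1, size=30),
             "pos": np.arange(30)}
        )
        ld = cc.LDReference.from_blocks({s: i // 3 for i, s in enumerate(ids)})
        res = result_from(df)
        loci = cc.define_loci(res, ld)
        members = [m for L in loci for m in L.members]
        assert sorted(members) == sorted(res.table.loc[res.table.significant, "snp_id"])

    def test_leads_agree_with_greedy_clump_when_minima_unique(self):
        rng = np.random.default_rng(15)
        ids = [f"s{i}" for i in range(40)]
        fdr = rng.permutation(np.linspace(1e-4, 0.049, 40))  # all distinct
        df = pd.DataFrame({"snp_id": ids, "conj_fdr": fdr, "pos": np.arange(40)})
        ld = cc.LDReference.from_blocks({s: i // 4 for i, s in enumerate(ids)})
        loci = cc.define_loci(result_from(df), ld)
        clumped = cc.greedy_clump(pd.Series(fdr, index=ids), ld)
        assert {L.lead_snp for L in loci} == set(clumped)
        # leads are pairwise unlinked
        for a, b in itertools.combinations([L.lead_snp for L in loci], 2):
            assert b not in ld.partners(a)


GENES = pd.DataFrame(
    {
        "chrom": ["1", "1", "1", "2", "2"],
        "start": [1000, 5000, 9000, 100, 4000],
        "end": [2000, 6000, 9500, 200, 4100],
        "name": ["gA", "gB", "gC", "gD", "gE"],
    }
)


class TestNearestGene:
    def test_inside_span_distance_zero(self):
        L = cc.annotate_nearest_gene(make_locus(pos=1500), GENES)
        assert (L.nearest_gene, L.gene_distance) == ("gA", 0)

    def test_equidistant_tie_breaks_on_start(self):
        L = cc.annotate_nearest_gene(make_locus(pos=3500), GENES)  # 1500 from gA and gB
        assert L.nearest_gene == "gA"

    def test_no_gene_on_chromosome(self):
        L = cc.annotate_nearest_gene(make_locus(chrom="9"), GENES)
        assert L.nearest_gene == "intergenic-unassigned"

    def test_random_positions_match_linear_scan(self):
        rng = np.random.default_rng(16)
        for pos in rng.integers(1, 12_000, size=10):
            L = cc.annotate_nearest_gene(make_locus(pos=int(pos)), GENES)
            best = None
            for g in GENES[GENES.chrom == "1"].itertuples():
                d = 0 if g.start <= pos <= g.end else min(abs(pos - g.start), abs(pos - g.end))
                key = (d, g.start, g.name)
                if best is None or key < best:
                    best = key
            assert (L.gene_distance, L.nearest_gene) == (best[0], best[2])


class TestConcordance:
    @pytest.mark.parametrize(
        "z1,z2,expected",
        [(-4.49, -4.95, True), (-4.46, 5.47, False), (3.0, 2.0, True)],
    )
    def test_sign_agreement(self, z1, z2, expected):
        assert cc.direction_concordance(make_locus(z1=z1, z2=z2)) is expected

    def test_palindromic_lead_undefined(self):
        L = make_locus(a1="T", a2="A", direction_defined=False, z2=np.nan)
        assert cc.direction_concordance(L) is None

    def test_zero_z_undefined(self):
        assert cc.direction_concordance(make_locus(z1=0.0)) is None

    def test_invariant_to_effect_allele_relabeling(self):
        # flipping which allele is called the effect allele on either trait
        # flips both z's representation but not the concordance flag
        L = make_locus(z1=2.0, z2=-1.0)
        flipped = dataclasses.replace(L, a1=L.a2, a2=L.a1, z1=-L.z1, z2=-L.z2)
        assert cc.direction_concordance(L) is cc.direction_concordance(flipped)

    def test_table_prints_nan_for_undefined(self):
        L = make_locus(a1="T", a2="A", direction_defined=False, z2=np.nan)
        (annotated,) = cc.annotate_loci([L])
        assert cc.loci_table([annotated])["concordant"].iloc[0] == "NaN"


class TestManhattanExport:
    def _setup(self):
        rng = np.random.default_rng(17)
        n = 50
        df = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "conj_fdr": rng.uniform(0, 0.2, size=n),
                "cfdr_1g2": rng.uniform(0, 0.2, size=n),
                "cfdr_2g1": rng.uniform(0, 0.2, size=n),
                "pos": rng.permutation(n) * 100,
                "chrom": ["2"] * 25 + ["1"] * 25,
            }
        )
        res = result_from(df)
        ld = cc.LDReference.from_blocks({f"s{i}": i // 5 for i in range(n)})
        return res, cc.define_loci(res, ld)

    def test_every_snp_once_in_genome_order(self):
        res, loci = self._setup()
        out = cc.manhattan_export(res, loci)
        assert len(out) == len(res.table)
        assert out["snp_id"].is_unique
        grouped = out.groupby("chrom", sort=False)["pos"].apply(lambda s: s.is_monotonic_increasing)
        assert grouped.all() and list(out["chrom"].unique()) == ["1", "2"]

    def test_lead_count_matches_loci(self):
        res, loci = self._setup()
        out = cc.manhattan_export(res, loci)
        assert out["is_lead"].sum() == len(loci)

    def test_significance_flags_consistent(self):
        res, loci = self._setup()
        out = cc.manhattan_export(res, loci).set_index("snp_id")
        expect = res.table.set_index("snp_id")["significant"]
        assert (out["significant"] == expect.reindex(out.index)).all()

    def test_conditional_kind_uses_conditional_values(self):
        res, loci = self._setup()
        out = cc.manhattan_export(res, loci, kind="conditional_1g2").set_index("snp_id")
        expect = -np.log10(res.table.set_index("snp_id")["cfdr_1g2"])
        np.testing.assert_allclose(out["neg_log10_fdr"], expect.reindex(out.index))
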
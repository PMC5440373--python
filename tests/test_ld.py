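import io
import itertools

import numpy as np
import pandas as pd
import pytest

import condconj as cc
from condconj.ld import GenomicRegion


def _components_oracle(ids, edges):
    """Connected components by exhaustive breadth-first traversal."""
    adj = {i: set() for i in ids}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for i in ids:
        if i in seen:
            continue
        comp, frontier = {i}, [i]
        while frontier:
            nxt = [n for f in frontier for n in adj[f] if n not in comp]
            comp.update(nxt)
            frontier = nxt
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def _blocks_of(ld):
    out = {}
    for s in ld.snps:
        out.setdefault(ld.block_id(s), set()).add(s)
    return {frozenset(v) for v in out.values()}


class TestLoadAndBlocks:
    def test_single_edge_blocks(self):
        ld = cc.LDReference.from_pairs([("s1", "s2", 0.5)], snps=["s1", "s2", "s3"])
        assert _blocks_of(ld) == {frozenset({"s1", "s2"}), frozenset({"s3"})}

    def test_threshold_is_strict(self):
        ld = cc.LDReference.from_pairs([("s1", "s2", 0.1)], r2_threshold=0.1)
        assert ld.partners("s1") == set()
        assert ld.block_id("s1") != ld.block_id("s2")

    def test_chain_is_one_component(self):
        edges = [("s1", "s2", 0.9), ("s2", "s3", 0.9)]
        ld = cc.LDReference.from_pairs(edges)
        expected = _components_oracle(["s1", "s2", "s3"], [("s1", "s2"), ("s2", "s3")])
        assert _blocks_of(ld) == expected
        assert ld.partners("s1") == {"s2"}  # edge relation is not transitive

    def test_random_graphs_match_traversal_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 12))
            ids = [f"v{i}" for i in range(n)]
            edges = [
                (a, b)
                for a, b in itertools.combinations(ids, 2)
                if rng.random() < 0.25
            ]
            ld = cc.LDReference.from_pairs([(a, b, 0.5) for a, b in edges], snps=ids)
            assert _blocks_of(ld) == _components_oracle(ids, edges)

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            cc.LDReference.from_pairs([("a", "b", 1.2)])

    def test_self_pair_warned_and_ignored(self, caplog):
        with caplog.at_level("WARNING", logger="condconj"):
            ld = cc.LDReference.from_pairs([("a", "a", 0.9), ("a", "b", 0.9)])
        assert "self-pair" in caplog.text
        assert ld.partners("a") == {"b"}

    def test_load_ld_autodetects_dialect(self, tmp_path):
        pairs = tmp_path / "pairs.tsv"
        pairs.write_text("id_a\tid_b\tr2\ns1\ts2\t0.5\n")
        blocks = tmp_path / "blocks.tsv"
        blocks.write_text("snp_id\tblock\ns1\t0\ns2\t0\ns3\t1\n")
        ld_p = cc.load_ld(pairs)
        ld_b = cc.load_ld(blocks)
        assert ld_p.block_id("s1") == ld_p.block_id("s2")
        assert ld_b.partners("s1") == {"s2"} and ld_b.partners("s3") == set()


class TestRandomPrune:
    def test_one_snp_per_block(self):
        ld = cc.LDReference.from_blocks(
            {"a1": 0, "a2": 0, "a3": 0, "b1": 1}
        )
        pruned = cc.random_prune(["a1", "a2", "a3", "b1"], ld, seed=3)
        assert len(pruned) == 2 and "b1" in pruned
        assert len(set(pruned) & {"a1", "a2", "a3"}) == 1

    def test_deterministic_per_seed_and_order_invariant(self):
        ld = cc.LDReference.from_blocks({f"s{i}": i // 4 for i in range(40)})
        ids = [f"s{i}" for i in range(40)]
        a = cc.random_prune(ids, ld, seed=9)
        b = cc.random_prune(ids[::-1], ld, seed=9)
        c = cc.random_prune(ids, ld, seed=10)
        assert list(a) == list(b)
        assert list(a) != list(c)

    def test_singleton_blocks_identity(self):
        ld = cc.LDReference.from_blocks({f"s{i}": i for i in range(10)})
        pruned = cc.random_prune([f"s{i}" for i in range(10)], ld, seed=0)
        assert sorted(pruned) == sorted(f"s{i}" for i in range(10))

    def test_output_size_equals_blocks_for_every_seed(self):
        ld = cc.LDReference.from_blocks({f"s{i}": i % 7 for i in range(30)})
        for seed in range(20):
            assert len(cc.random_prune([f"s{i}" for i in range(30)], ld, seed=seed)) == 7

    def test_empty_input_errors(self):
        ld = cc.LDReference.from_blocks({"a": 0})
        with pytest.raises(ValueError, match="empty"):
            cc.random_prune([], ld, seed=0)


MHC = GenomicRegion("6", 25652429, 33368333, "MHC")


class TestExcludeRegions:
    def _positions(self, mapping):
        return pd.DataFrame(
            [{"snp_id": k, "chrom": c, "pos": p} for k, (c, p) in mapping.items()]
        )

    def test_inclusive_bounds(self):
        ld = cc.LDReference.from_blocks({"in_lo": 0, "in_hi": 1, "out_lo": 2, "out_hi": 3})
        pos = self._positions(
            {
                "in_lo": ("6", 25652429),
                "in_hi": ("6", 33368333),
                "out_lo": ("6", 25652428),
                "out_hi": ("6", 33368334),
            }
        )
        kept = cc.exclude_regions(list(pos["snp_id"]), ld, [MHC], pos)
        assert sorted(kept) == ["out_hi", "out_lo"]

    def test_ld_partner_of_region_snp_removed(self):
        ld = cc.LDReference.from_pairs([("far", "inside", 0.2)])
        pos = self._positions({"far": ("8", 20_000_000), "inside": ("8", 8_000_000)})
        region = GenomicRegion("8", 7242715, 12483982, "8p23.1")
        kept = cc.exclude_regions(["far", "inside"], ld, [region], pos)
        assert list(kept) == []

    def test_unlinked_snp_outside_retained(self):
        ld = cc.LDReference.from_blocks({"a": 0, "b": 1})
        pos = self._positions({"a": ("6", 25652428), "b": ("6", 30_000_000)})
        kept = cc.exclude_regions(["a", "b"], ld, [MHC], pos)
        assert list(kept) == ["a"]

    def test_unknown_chromosome_warned_and_skipped(self, caplog):
        ld = cc.LDReference.from_blocks({"a": 0})
        pos = self._positions({"a": ("1", 100)})
        with caplog.at_level("WARNING", logger="condconj"):
            kept = cc.exclude_regions(["a"], ld, [GenomicRegion("99", 1, 2, "x")], pos)
        assert "skipped" in caplog.text and list(kept) == ["a"]

    def test_monotone_in_regions(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(50)]
        ld = cc.LDReference.from_blocks({s: i // 5 for i, s in enumerate(ids)})
        pos = self._positions({s: ("1", int(rng.integers(1, 10_000))) for s in ids})
        r1 = [GenomicRegion("1", 1, 3000, "a")]
        r2 = r1 + [GenomicRegion("1", 5000, 8000, "b")]
        assert set(cc.exclude_regions(ids, ld, r2, pos)) <= set(
            cc.exclude_regions(ids, ld, r1, pos)
        )

    def test_packaged_defaults(self):
        regions = cc.default_exclusion_regions()
        assert [(r.chrom, r.start, r.end) for r in regions] == [
            ("6", 25652429, 33368333),
            ("8", 7242715, 12483982),
        ]


def _clump_oracle(scores, tie, edges):
    """Independent rank-greedy oracle over a dense adjacency matrix."""
    ids = sorted(scores, key=lambda s: (scores[s], tie.get(s, np.inf), s))
    adj = {i: set() for i in scores}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    kept = []
    for s in ids:
        if all(k not in adj[s] for k in kept):
            kept.append(s)
    return kept


class TestGreedyClump:
    def test_linked_pair_keeps_stronger(self):
        ld = cc.LDReference.from_pairs([("a", "b", 0.5)])
        assert cc.greedy_clump({"a": 0.01, "b": 0.03}, ld) == ["a"]

    def test_unlinked_pair_keeps_both(self):
        ld = cc.LDReference.from_pairs([("a", "b", 0.05)], snps=["a", "b"])
        assert cc.greedy_clump({"a": 0.01, "b": 0.03}, ld) == ["a", "b"]

    def test_chain_matches_oracle(self):
        edges = [(f"s{i}", f"s{i+1}") for i in range(4)]
        scores = {"s0": 0.01, "s1": 0.05, "s2": 0.02, "s3": 0.06, "s4": 0.03}
        ld = cc.LDReference.from_pairs([(a, b, 0.9) for a, b in edges])
        assert cc.greedy_clump(scores, ld) == _clump_oracle(scores, {}, edges)

    def test_random_graphs_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 15))
            ids = [f"v{i}" for i in range(n)]
            edges = [
                (a, b) for a, b in itertools.combinations(ids, 2) if rng.random() < 0.3
            ]
            scores = {s: float(np.round(rng.random(), 3)) for s in ids}
            p1 = {s: float(rng.random()) for s in ids}
            ld = cc.LDReference.from_pairs([(a, b, 0.5) for a, b in edges], snps=ids)
            assert cc.greedy_clump(scores, ld, p1=p1) == _clump_oracle(scores, p1, edges)

    def test_kept_set_is_independent_and_order_invariant(self):
        rng = np.random.default_rng(8)
        ids = [f"v{i}" for i in range(20)]
        edges = [(a, b) for a, b in itertools.combinations(ids, 2) if rng.random() < 0.2]
        scores = pd.Series(rng.random(20), index=ids)
        ld = cc.LDReference.from_pairs([(a, b, 0.5) for a, b in edges], snps=ids)
        kept = cc.greedy_clump(scores, ld)
        for a, b in itertools.combinations(kept, 2):
            assert b not in ld.partners(a)
        assert cc.greedy_clump(scores.sample(frac=1, random_state=1), ld) == kept

    def test_nonfinite_scores_rejected(self):
        ld = cc.LDReference.from_blocks({"a": 0})
        with pytest.raises(ValueError, match="finite"):
            cc.greedy_clump({"a": np.nan}, ld)


class TestRegions:
    def test_zero_based_conversion(self, tmp_path):
        f = tmp_path / "regions.bed"
        f.write_text("chrom\tstart\tend\tlabel\n1\t99\t200\tx\n")
        (one,) = cc.load_regions(f, one_based=False)
        assert (one.start, one.end) == (100, 200)

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError, match="start > end"):
            GenomicRegion("1", 10, 5, "bad")
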
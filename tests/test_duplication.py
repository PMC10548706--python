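"""Paralog pairs, collinear chaining (vs exhaustive search), mode calls."""

from itertools import combinations

import numpy as np
import pytest

from cypkit.duplication import (
    AnchorPair,
    SyntenyConfig,
    chain_collinear_blocks,
    classify_modes,
    find_paralog_pairs,
    gene_order_from_models,
    make_pair,
)


def _anchor(i, ra, rb, ca="chrA", cb="chrB"):
    # ids sort so that gene_a is on ca
    return AnchorPair(f"a{i:02d}", f"b{i:02d}", 0.8, 400), {
        f"a{i:02d}": (ca, ra),
        f"b{i:02d}": (cb, rb),
    }


def _mk(points, ca="chrA", cb="chrB"):
    anchors = []
    order = {}
    for i, (ra, rb) in enumerate(points):
        a, o = _anchor(i, ra, rb, ca, cb)
        anchors.append(a)
        order.update(o)
    return anchors, order


def exhaustive_best_chain(points, max_gap, min_block):
    """Maximum chain cardinality over all anchor subsets (test oracle)."""
    best = 0
    idx = range(len(points))
    for k in range(len(points), 0, -1):
        if k <= best:
            break
        for sub in combinations(idx, k):
            for inverted in (False, True):
                pts = sorted((points[i] for i in sub))
                ok = True
                for (ra1, rb1), (ra2, rb2) in zip(pts, pts[1:]):
                    if ra2 <= ra1 or ra2 - ra1 > max_gap:
                        ok = False
                        break
                    if inverted:
                        if rb2 >= rb1 or rb1 - rb2 > max_gap:
                            ok = False
                            break
                    elif rb2 <= rb1 or rb2 - rb1 > max_gap:
                        ok = False
                        break
                if ok:
                    best = max(best, k)
                    break
    return best if best >= min_block else 0


class TestPairs:
    def test_identical_members(self):
        prot = {"g1": "MKVLHAGRRT" * 30, "g2": "MKVLHAGRRT" * 30}
        fams = {"g1": "CYP71", "g2": "CYP71"}
        (pair,) = find_paralog_pairs(prot, fams)
        assert pair.identity == 1.0 and pair.key == ("g1", "g2")

    def test_combinatorial_count(self):
        seq = "MKVLHAGRRT" * 30
        prot = {f"g{i}": seq for i in range(5)}
        fams = {f"g{i}": "CYP71" for i in range(5)}
        assert len(find_paralog_pairs(prot, fams)) == 10  # 5 choose 2

    def test_matches_brute_force_threshold(self, default_genome):
        """Pair set equals all-vs-all within-family filtering at the floor."""
        from cypkit.align import global_identity

        prot = default_genome.protein_map()
        fams = {
            g: t.family for g, t in default_genome.truth.genes.items() if t.is_p450
        }
        config = SyntenyConfig()
        got = {p.key for p in find_paralog_pairs(prot, fams, config)}
        want = set()
        by_fam = {}
        for g, f in fams.items():
            by_fam.setdefault(f, []).append(g)
        for members in by_fam.values():
            for a, b in combinations(sorted(members), 2):
                ident, _ = global_identity(prot[a], prot[b])
                if ident >= config.pair_min_identity:
                    want.add((a, b))
        assert got == want

    def test_new_family_skipped(self):
        prot = {"g1": "MKVL" * 50, "g2": "MKVL" * 50}
        assert find_paralog_pairs(prot, {"g1": "NEW_FAMILY", "g2": "NEW_FAMILY"}) == []


class TestChaining:
    def test_perfect_diagonal(self):
        anchors, order = _mk([(i, i) for i in range(5)])
        (block,) = chain_collinear_blocks(anchors, order)
        assert block.score == 5 and block.orientation == "same"

    def test_below_min_block(self):
        anchors, order = _mk([(i, i) for i in range(4)])
        assert chain_collinear_blocks(anchors, order) == []

    def test_inverted_diagonal(self):
        anchors, order = _mk([(i, 10 - i) for i in range(6)])
        (block,) = chain_collinear_blocks(anchors, order)
        assert block.score == 6 and block.orientation == "inverted"

    def test_gap_constraint_breaks_chain(self):
        pts = [(0, 0), (1, 1), (2, 2), (40, 40), (41, 41)]
        anchors, order = _mk(pts)
        assert chain_collinear_blocks(anchors, order, SyntenyConfig(min_block=4)) == []

    def test_matches_exhaustive_on_small_instances(self):
        """DP chain length equals exhaustive subset search (100 replicates)."""
        rng = np.random.default_rng(19)
        config = SyntenyConfig(min_block=3, max_gene_gap=6)
        for _ in range(100):
            n = int(rng.integers(3, 13))
            pts = [
                (int(rng.integers(0, 20)), int(rng.integers(0, 20)))
                for _ in range(n)
            ]
            # unique gene ranks per axis (one gene, one rank)
            if len({p[0] for p in pts}) < n or len({p[1] for p in pts}) < n:
                continue
            anchors, order = _mk(pts)
            blocks = chain_collinear_blocks(anchors, order, config)
            got = max((b.score for b in blocks), default=0)
            assert got == exhaustive_best_chain(pts, config.max_gene_gap, config.min_block)

    def test_missing_gene_rank_errors(self):
        anchors, order = _mk([(0, 0)])
        del order["a00"]
        with pytest.raises(ValueError, match="a00"):
            chain_collinear_blocks(anchors, order)

    def test_monotone_adding_compatible_anchor(self):
        """Adding a chain-compatible anchor never shortens the best chain."""
        base = [(i, i) for i in range(6)]
        anchors, order = _mk(base)
        (b1,) = chain_collinear_blocks(anchors, order)
        anchors2, order2 = _mk(base + [(6, 6)])
        (b2,) = chain_collinear_blocks(anchors2, order2)
        assert b2.score >= b1.score


class TestModes:
    def _setup(self):
        """A genome with one 5-anchor block plus TD/PD/TRD/DSD pairs."""
        order = {}
        for i in range(5):
            order[f"w{i}a"] = ("chr1", 10 + i)
            order[f"w{i}b"] = ("chr2", 20 + i)
        anchors = [make_pair(f"w{i}a", f"w{i}b", 0.8, 400) for i in range(5)]
        order.update({
            "t1": ("chr3", 5), "t2": ("chr3", 6),        # adjacent
            "p1": ("chr3", 10), "p2": ("chr3", 14),      # 3 intervening
            "x1": ("chr4", 2),                            # partner of w0a -> TRD
            "d1": ("chr4", 30), "d2": ("chr5", 7),       # dispersed
        })
        blocks = chain_collinear_blocks(anchors, order)
        return anchors, blocks, order

    def test_precedence_and_rules(self):
        anchors, blocks, order = self._setup()
        pairs = anchors + [
            make_pair("t1", "t2", 0.9, 400),
            make_pair("p1", "p2", 0.9, 400),
            make_pair("w0a", "x1", 0.7, 400),
            make_pair("d1", "d2", 0.6, 400),
        ]
        calls = {c.pair.key: c.mode for c in classify_modes(pairs, blocks, order)}
        for i in range(5):
            assert calls[tuple(sorted((f"w{i}a", f"w{i}b")))] == "WGD"
        assert calls[("t1", "t2")] == "TD"
        assert calls[("p1", "p2")] == "PD"
        assert calls[tuple(sorted(("w0a", "x1")))] == "TRD"
        assert calls[("d1", "d2")] == "DSD"

    def test_block_anchor_beats_proximal(self):
        """A pair that is a block anchor is WGD even when also proximal."""
        order = {}
        anchors = []
        for i in range(6):
            ga, gb = f"g{2 * i:02d}", f"g{2 * i + 1:02d}"
            order[ga] = ("chr1", 2 * i)
            order[gb] = ("chr1", 2 * i + 1)  # adjacent on the same chromosome
            anchors.append(make_pair(ga, gb, 0.8, 400))
        blocks = chain_collinear_blocks(anchors, order)
        assert blocks, "expected a same-chromosome block"
        calls = classify_modes(anchors, blocks, order)
        assert all(c.mode == "WGD" for c in calls)

    def test_partition_and_order_invariance(self, default_genome, survey_result):
        calls = survey_result.calls
        assert len(calls) == len(survey_result.pairs)
        counts = {}
        for c in calls:
            counts[c.mode] = counts.get(c.mode, 0) + 1
        assert sum(counts.values()) == len(calls)
        # re-run with shuffled pair order
        rng = np.random.default_rng(23)
        pairs = list(survey_result.pairs)
        rng.shuffle(pairs)
        order = gene_order_from_models(default_genome.models)
        calls2 = classify_modes(pairs, survey_result.blocks, order)
        assert {c.pair.key: c.mode for c in calls2} == {
            c.pair.key: c.mode for c in calls
        }

    def test_mode_recovery_on_planted_genome(self, default_genome, survey_result):
        """>=95% of planted WGD/TD/PD/TRD/DSD pairs get their true mode."""
        truth = {(p.gene_a, p.gene_b): p.mode for p in default_genome.truth.pairs}
        got = {c.pair.key: c.mode for c in survey_result.calls}
        hit = sum(1 for k, v in truth.items() if got.get(k) == v)
        assert hit / len(truth) >= 0.95
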
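"""FPKM, Pearson screening, retention classes, ddCt."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from cypkit.expression import (
    AssociationConfig,
    classify_retention,
    compute_fpkm,
    pearson_two_sided,
    relative_expression_ddct,
    screen_flavonoid_candidates,
)


class TestFpkm:
    def test_unit_instantiation(self):
        # count 10 on a 1 kb gene in a 1e6-fragment library -> FPKM 10
        counts = pd.DataFrame({"s1": [10, 10**6 - 10]}, index=["g1", "filler"])
        fpkm = compute_fpkm(counts, {"g1": 1000.0, "filler": 5000.0})
        assert fpkm.loc["g1", "s1"] == pytest.approx(10.0)

    def test_library_scale_invariance(self):
        rng = np.random.default_rng(41)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("abcd"),
        )
        lengths = pd.Series(rng.integers(300, 3000, size=30).astype(float),
                            index=counts.index)
        f1 = compute_fpkm(counts, lengths)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 7
        f2 = compute_fpkm(scaled, lengths)
        assert np.allclose(f1["b"], f2["b"])

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(43)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(50, 6)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(6)],
        )
        lengths = pd.Series(rng.integers(200, 5000, size=50).astype(float),
                            index=counts.index)
        fpkm = compute_fpkm(counts, lengths)
        totals = counts.sum(axis=0)
        for g in counts.index[::7]:
            for s in counts.columns:
                want = counts.loc[g, s] * 1e9 / (lengths[g] * totals[s])
                assert fpkm.loc[g, s] == pytest.approx(want)

    def test_replicate_averaging(self):
        counts = pd.DataFrame(
            {"st1_r1": [10], "st1_r2": [30], "st2_r1": [20]}, index=["g1"]
        )
        fpkm = compute_fpkm(
            counts, {"g1": 1000.0},
            replicate_map={"st1_r1": "st1", "st1_r2": "st1", "st2_r1": "st2"},
        )
        assert list(fpkm.columns) == ["st1", "st2"]
        # replicates normalised per sample first, then averaged
        assert fpkm.loc["g1", "st1"] == pytest.approx((1e9 / 1000 + 1e9 / 1000) / 2)

    def test_missing_length_errors(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError, match="length"):
            compute_fpkm(counts, {"g2": 100.0})


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(5.0)
        res = pearson_two_sided(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_two_sided < 1e-12

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_two_sided([1, 1, 1, 1], [1, 2, 3, 4])

    def test_p_matches_quadrature(self):
        """Closed-form t tail equals numerical integration of the t density."""
        rng = np.random.default_rng(47)
        for _ in range(10):
            n = int(rng.integers(4, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            res = pearson_two_sided(x, y)
            df = n - 2
            tail, _ = integrate.quad(
                lambda u: stats.t.pdf(u, df), abs(res.t_stat), np.inf
            )
            assert res.p_two_sided == pytest.approx(2 * tail, abs=1e-6)

    def test_p_decreasing_in_abs_r_and_n(self):
        def p_of(r, n):
            t = r * np.sqrt((n - 2) / (1 - r * r))
            return 2 * stats.t.sf(abs(t), n - 2)

        rs = [0.3, 0.5, 0.7, 0.9]
        ps = [p_of(r, 6) for r in rs]
        assert ps == sorted(ps, reverse=True)
        ns = [4, 6, 10, 20]
        ps_n = [p_of(0.6, n) for n in ns]
        assert ps_n == sorted(ps_n, reverse=True)


class TestScreen:
    def _series(self, total, comp=None, stages=None):
        stages = stages or [f"s{i}" for i in range(len(total))]
        return pd.DataFrame(
            {"total_flavonoid": total,
             "component_sum": comp if comp is not None else 0.6 * np.asarray(total)},
            index=stages,
        )

    def test_low_fpkm_removed_before_correlation(self):
        expr = pd.DataFrame(
            {"s0": [9.9, 20], "s1": [5.0, 40], "s2": [1.0, 60], "s3": [2.0, 80],
             "s4": [3.0, 100]},
            index=["low", "hi"],
        )
        series = self._series([1.0, 2.0, 3.0, 4.0, 5.0])
        out = screen_flavonoid_candidates(expr, series)
        assert "low" not in set(out["gene_id"])
        assert "hi" in set(out[out["candidate"]]["gene_id"])

    def test_planted_driver_noise_free(self):
        """metabolite = a * FPKM exactly -> the driver passes both stages with r=1."""
        rng = np.random.default_rng(49)
        profile = np.array([20.0, 50.0, 90.0, 140.0, 200.0])
        noise_genes = {
            f"n{i}": rng.permutation(profile) * 0.5 + 10 for i in range(5)
        }
        expr = pd.DataFrame({"drv": profile, **noise_genes}).T
        expr.columns = [f"s{i}" for i in range(5)]
        series = self._series(0.05 * profile)
        out = screen_flavonoid_candidates(expr, series).set_index("gene_id")
        assert bool(out.loc["drv", "candidate"])
        assert out.loc["drv", "r_total"] == pytest.approx(1.0)

    def test_monotone_in_alpha_and_min_fpkm(self):
        rng = np.random.default_rng(51)
        expr = pd.DataFrame(
            rng.uniform(5, 100, size=(40, 5)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(5)],
        )
        series = self._series(rng.uniform(1, 10, size=5))
        strict = AssociationConfig(alpha=0.01)
        loose = AssociationConfig(alpha=0.2)
        c_strict = set(
            screen_flavonoid_candidates(expr, series, strict)
            .query("candidate")["gene_id"]
        )
        c_loose = set(
            screen_flavonoid_candidates(expr, series, loose)
            .query("candidate")["gene_id"]
        )
        assert c_strict <= c_loose
        hi_fpkm = AssociationConfig(min_fpkm=60)
        c_hi = set(
            screen_flavonoid_candidates(expr, series, hi_fpkm)
            .query("candidate")["gene_id"]
        )
        base = set(
            screen_flavonoid_candidates(expr, series).query("candidate")["gene_id"]
        )
        assert c_hi <= base

    def test_too_few_stages(self):
        expr = pd.DataFrame({"s0": [10], "s1": [20]}, index=["g"])
        with pytest.raises(ValueError, match="3 shared stages"):
            screen_flavonoid_candidates(expr, self._series([1.0, 2.0]))


class TestRetention:
    def test_subfunctionalization(self):
        call = classify_retention("a", [10, 10, 0, 0, 0], "b", [0, 0, 10, 10, 10])
        assert call.mechanism == "subfunctionalization"

    def test_dosage_balance_flat_parallel(self):
        call = classify_retention("a", [5, 5, 5, 5, 5], "b", [6, 6, 6, 6, 6])
        assert call.mechanism == "dosage_balance"

    def test_specialization_one_silent(self):
        call = classify_retention("a", [50, 40, 60, 55, 45], "b", [0, 0, 0, 0, 0])
        assert call.mechanism == "specialization_or_nonfunctionalization"

    def test_symmetric_up_to_roles(self):
        rng = np.random.default_rng(53)
        for _ in range(50):
            e1 = rng.uniform(0, 30, size=5)
            e2 = rng.uniform(0, 30, size=5)
            c1 = classify_retention("a", e1, "b", e2)
            c2 = classify_retention("b", e2, "a", e1)
            assert c1.mechanism == c2.mechanism

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            classify_retention("a", [1, 2], "b", [1, 2, 3])


class TestDdct:
    def _table(self):
        return pd.DataFrame(
            [
                ("tub", "cal", 20.0), ("tub", "trt", 21.0),
                ("gene1", "cal", 24.0), ("gene1", "trt", 23.0),
            ],
            columns=["gene", "sample", "ct"],
        )

    def test_calibrator_is_one(self):
        folds = relative_expression_ddct(self._table(), "tub", "cal")
        assert folds.loc["gene1", "cal"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # dCt: trt 23-21=2, cal 24-20=4 -> ddCt=-2 -> fold 4
        folds = relative_expression_ddct(self._table(), "tub", "cal")
        assert folds.loc["gene1", "trt"] == pytest.approx(4.0)

    def test_invariant_to_per_sample_ct_shift(self):
        t = self._table()
        shifted = t.copy()
        shifted.loc[shifted["sample"] == "trt", "ct"] += 3.0
        f1 = relative_expression_ddct(t, "tub", "cal")
        f2 = relative_expression_ddct(shifted, "tub", "cal")
        assert np.allclose(f1.loc["gene1"], f2.loc["gene1"])

    def test_missing_reference(self):
        t = self._table()[lambda d: d["gene"] != "tub"]
        with pytest.raises(ValueError):
            relative_expression_ddct(t, "tub", "cal")
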
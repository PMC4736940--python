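"""Concordance statistics: likelihoods, AICc, Akaike weights and the
nonparametric group tests, each against an independent oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from msatgbs import stats as st


def _records(matches):
    rows = []
    for i, m in enumerate(matches):
        depth = 12
        rows.append(
            {
                "individual": f"i{i}", "locus": "L", "match": int(m), "depth": depth,
                "depth_bin2": st.depth_bin2(depth), "depth_bin3": st.depth_bin3(depth),
                "mst": "di", "scheme": "3-PCR",
            }
        )
    return pd.DataFrame(rows)


class TestBinomialLoglik:
    def test_all_matches_give_zero(self):
        logL, K = st.binomial_loglik(_records([1] * 10), st.ModelSpec("null"))
        assert K == 1 and logL == 0.0

    def test_half_matches_closed_form(self):
        logL, _ = st.binomial_loglik(_records([1] * 5 + [0] * 5), st.ModelSpec("null"))
        assert logL == pytest.approx(10 * math.log(0.5), abs=1e-9)

    def test_finer_partition_never_worse(self):
        rng = np.random.default_rng(0)
        df = _records(rng.integers(0, 2, 60))
        df["mst"] = rng.choice(["di", "tri", "tetra"], size=60)
        coarse, _ = st.binomial_loglik(df, st.ModelSpec("null"))
        fine, _ = st.binomial_loglik(df, st.ModelSpec("mst", ("mst",)))
        assert fine >= coarse - 1e-12
        # brute-force per-cell recomputation
        brute = 0.0
        for _, g in df.groupby("mst"):
            k, n = g["match"].sum(), len(g)
            p = k / n
            if 0 < p:
                brute += k * math.log(p)
            if p < 1:
                brute += (n - k) * math.log(1 - p)
        assert fine == pytest.approx(brute, abs=1e-9)


class TestMultinomialLoglik:
    def test_single_cell_zero(self):
        df = pd.DataFrame({"read_count": [50], "scheme": ["a"]})
        logL, K = st.multinomial_loglik(df, st.ModelSpec("null"))
        assert (logL, K) == (0.0, 1)

    def test_two_equal_cells(self):
        df = pd.DataFrame({"read_count": [50, 50], "scheme": ["a", "b"]})
        logL, K = st.multinomial_loglik(df, st.ModelSpec("scheme", ("scheme",)))
        assert K == 2
        assert logL == pytest.approx(100 * math.log(0.5), abs=1e-9)

    def test_arbitrary_counts_vs_direct_sum(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 500, size=7)
        df = pd.DataFrame({"read_count": counts, "locus": [f"L{i}" for i in range(7)]})
        logL, K = st.multinomial_loglik(df, st.ModelSpec("locus", ("locus",)))
        N = counts.sum()
        assert K == 7
        assert logL == pytest.approx(sum(c * math.log(c / N) for c in counts), rel=1e-12)


class TestAicc:
    @pytest.mark.parametrize(
        "K,logL,n,expected,places",
        [
            (1, -1724.64, 3196, 3451.28, 2),
            (3, -87627, 90194, 175260, 0),
            (6, -143882, 90194, 287776, 0),
            (2, 0.0, 10**9, 4.000, 3),
        ],
    )
    def test_worked_examples(self, K, logL, n, expected, places):
        assert round(st.aicc(logL, K, n), places) == pytest.approx(expected)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            st.aicc(-10.0, 5, 6)

    def test_monotone_in_logL_and_K(self):
        assert st.aicc(-10, 2, 100) > st.aicc(-5, 2, 100)
        assert st.aicc(-10, 3, 100) > st.aicc(-10, 2, 100)


class TestRankModels:
    def test_single_model(self):
        out = st.rank_models([st.ModelFit("m", 1, -5.0, 12.0)])
        assert out[0].daicc == 0.0 and out[0].weight == 1.0

    def test_equal_models_split_weight(self):
        out = st.rank_models(
            [st.ModelFit("a", 1, -5.0, 12.0), st.ModelFit("b", 1, -5.0, 12.0)]
        )
        assert [f.weight for f in out] == [0.5, 0.5]

    def test_weights_sum_to_one_and_order_invariant(self):
        rng = np.random.default_rng(2)
        fits = [st.ModelFit(f"m{i}", i + 1, 0.0, float(a)) for i, a in enumerate(rng.uniform(10, 90, 8))]
        out1 = st.rank_models(fits)
        out2 = st.rank_models(list(reversed(fits)))
        assert sum(f.weight for f in out1) == pytest.approx(1.0, abs=1e-12)
        assert [(f.name, f.weight) for f in out1] == [(f.name, f.weight) for f in out2]
        assert min(f.daicc for f in out1) == 0.0


class TestProportionZTests:
    def test_identical_proportions(self):
        out = st.proportion_ztests({"a": (30, 100), "b": (30, 100)})
        assert out.loc[0, "z"] == 0.0 and out.loc[0, "p_bonferroni"] == 1.0

    def test_hand_computed_pooled_formula(self):
        out = st.proportion_ztests({"a": (30, 100), "b": (50, 100)})
        p_pool = 80 / 200
        z_hand = (0.3 - 0.5) / math.sqrt(p_pool * (1 - p_pool) * (2 / 100))
        assert out.loc[0, "z"] == pytest.approx(z_hand, rel=1e-12)
        sm = pytest.importorskip("statsmodels.stats.proportion")
        z_sm, p_sm = sm.proportions_ztest([30, 50], [100, 100])
        assert out.loc[0, "z"] == pytest.approx(z_sm, rel=1e-9)
        assert out.loc[0, "p_value"] == pytest.approx(p_sm, rel=1e-9)

    def test_bonferroni_factor_counts_pairs(self):
        out = st.proportion_ztests({"a": (10, 40), "b": (20, 40), "c": (30, 40)})
        assert len(out) == 3
        assert (out["p_bonferroni"] <= 1.0).all()
        loose = out[out["p_value"] * 3 < 1]
        assert np.allclose(loose["p_bonferroni"], loose["p_value"] * 3)

    def test_degenerate_pair_flagged(self):
        out = st.proportion_ztests({"a": (0, 10), "b": (0, 10)})
        assert bool(out.loc[0, "degenerate"]) and out.loc[0, "p_value"] == 1.0


class TestMannWhitney:
    def test_identical_samples_midpoint_u(self):
        out = st.mannwhitney_tests({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert out.loc[0, "U"] == 8.0  # n1*n2/2

    def test_complete_separation(self):
        out = st.mannwhitney_tests({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert out.loc[0, "U"] in (0.0, 9.0)

    def test_all_tied_flagged(self):
        out = st.mannwhitney_tests({"a": [5, 5], "b": [5, 5, 5]})
        assert bool(out.loc[0, "all_tied"]) and out.loc[0, "p_value"] == 1.0

    def test_exact_p_matches_full_permutation_enumeration(self):
        x, y = [3.1, 9.4, 1.2, 7.7], [5.5, 2.2, 8.8]
        out = st.mannwhitney_tests({"a": x, "b": y}, method="exact")
        pooled = x + y
        n1 = len(x)

        def u_stat(xs, ys):
            return sum(sum(a > b for b in ys) + 0.5 * sum(a == b for b in ys) for a in xs)

        u_obs = u_stat(x, y)
        n2 = len(y)
        mid = n1 * n2 / 2
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            xs = [pooled[i] for i in idx]
            ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
            u = u_stat(xs, ys)
            total += 1
            if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
                count += 1
        assert out.loc[0, "p_value"] == pytest.approx(count / total, rel=1e-9)


class TestCorrespondence:
    def _tables(self, offset=0, break_some=0):
        rows, ref = [], []
        rng = np.random.default_rng(3)
        for i in range(20):
            a1 = 150 + 2 * int(rng.integers(0, 6))
            a2 = a1 + 2 * int(rng.integers(0, 3))
            rows.append(
                {"individual": f"i{i}", "locus": "L1", "status": "called",
                 "allele1": a1, "allele2": a2, "depth": int(rng.integers(5, 40))}
            )
            r1, r2 = a1 + offset, a2 + offset
            if i < break_some:
                r1 += 2
            ref.append({"individual": f"i{i}", "locus": "L1", "allele1": r1, "allele2": r2})
        return pd.DataFrame(rows), pd.DataFrame(ref)

    def test_identical_tables_all_match(self):
        calls, ref = self._tables()
        rec = st.build_correspondence(calls, ref)
        assert rec["match"].all()

    def test_uniform_offset_recovered(self):
        calls, ref = self._tables(offset=2)
        rec = st.build_correspondence(calls, ref)
        assert rec["match"].all()

    def test_calibration_off_exposes_offset(self):
        calls, ref = self._tables(offset=2)
        rec = st.build_correspondence(calls, ref, calibrate=False)
        assert not rec["match"].any()

    def test_mismatches_counted(self):
        calls, ref = self._tables(break_some=5)
        rec = st.build_correspondence(calls, ref)
        assert rec["match"].sum() == 15

    def test_curve_flat_when_all_match(self):
        calls, ref = self._tables()
        rec = st.build_correspondence(calls, ref)
        curve = st.correspondence_curve(rec, thresholds=(5, 10, 20))
        good = curve[curve["n_genotypes"] > 0]
        assert (good["pct_corresponding"] == 100.0).all()

    def test_curve_empty_thresholds_flagged(self):
        rec = _shallow = st.build_correspondence(*self._tables())
        rec = rec.assign(depth=3)
        curve = st.correspondence_curve(rec, thresholds=(5, 10))
        assert (curve["n_genotypes"] == 0).all()
        assert curve["pct_corresponding"].isna().all()
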
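"""Enrichment statistics vs independent high-precision oracles."""

import math
import random
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from dmsflow.scoring import (
    bin_score,
    combine_replicates,
    combine_replicates_table,
    ratio_score,
    regression_score,
)
from dmsflow.table import Table


def wls_oracle(x, y, w):
    """Exact-rational weighted normal equations on float inputs."""
    xF = [Fraction(v) for v in x]
    yF = [Fraction(v) for v in y]
    wF = [Fraction(v) for v in w]
    sw = sum(wF)
    swx = sum(a * b for a, b in zip(wF, xF))
    swy = sum(a * b for a, b in zip(wF, yF))
    swxx = sum(a * b * b for a, b in zip(wF, xF))
    swxy = sum(a * b * c for a, b, c in zip(wF, xF, yF))
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    var = sw / det
    return float(slope), math.sqrt(float(var))


def _two_cond(counts, wt_counts):
    return Table(
        pd.DataFrame(
            {
                "variant": ["c.1A>T", "c.="],
                "count_0": [counts[0], wt_counts[0]],
                "count_1": [counts[1], wt_counts[1]],
            }
        )
    )


class TestRatioScore:
    def test_worked_example(self):
        # oracle: ln(20.5/10.5) - ln(100.5/100.5), sqrt(1/10.5+1/20.5+2/100.5)
        out = ratio_score(_two_cond((10, 20), (100, 100)), "variant", ["count_0", "count_1"])
        row = out.df.set_index("variant").loc["c.1A>T"]
        assert float(row["score"]) == pytest.approx(0.6690496289808848, abs=1e-12)
        assert float(row["SE"]) == pytest.approx(0.40486921413638144, abs=1e-12)

    def test_wt_scores_exactly_zero(self):
        out = ratio_score(_two_cond((10, 20), (100, 100)), "variant", ["count_0", "count_1"])
        assert float(out.df.set_index("variant").loc["c.=", "score"]) == 0.0

    def test_variant_equal_to_wt_scores_zero(self):
        out = ratio_score(_two_cond((100, 100), (100, 100)), "variant", ["count_0", "count_1"])
        assert float(out.df["score"].iloc[0]) == 0.0

    def test_zero_counts_score_zero_finite_se(self):
        out = ratio_score(_two_cond((0, 0), (100, 100)), "variant", ["count_0", "count_1"])
        row = out.df.set_index("variant").loc["c.1A>T"]
        assert float(row["score"]) == 0.0 and np.isfinite(float(row["SE"]))

    def test_missing_wt_errors(self):
        t = Table(pd.DataFrame({"variant": ["v1"], "count_0": [1], "count_1": [2]}))
        with pytest.raises(ValueError, match="wild-type"):
            ratio_score(t, "variant", ["count_0", "count_1"])

    def test_unnormalized_monotone_in_final_count(self):
        t = Table(pd.DataFrame({"variant": ["v"], "count_0": [10], "count_1": [20]}))
        lo = ratio_score(t, "variant", ["count_0", "count_1"], normalize_wt=False)
        t2 = Table(pd.DataFrame({"variant": ["v"], "count_0": [10], "count_1": [21]}))
        hi = ratio_score(t2, "variant", ["count_0", "count_1"], normalize_wt=False)
        assert float(hi.df["score"][0]) > float(lo.df["score"][0])

    def test_depth_factor_absorbed_by_wt(self):
        base = _two_cond((10, 20), (100, 100))
        doubled = _two_cond((10, 40), (100, 200))
        a = ratio_score(base, "variant", ["count_0", "count_1"])
        b = ratio_score(doubled, "variant", ["count_0", "count_1"])
        # doubling every final-condition count is pseudocount-perturbed only
        assert float(a.df["score"][0]) == pytest.approx(float(b.df["score"][0]), abs=2e-2)

    def test_oracle_equivalence_random_instances(self):
        rnd = random.Random(101)
        for _ in range(100):
            cv = (rnd.randrange(0, 500), rnd.randrange(0, 500))
            cw = (rnd.randrange(1, 500), rnd.randrange(1, 500))
            d = rnd.choice([0.5, 1.0, 0.25])
            out = ratio_score(
                _two_cond(cv, cw), "variant", ["count_0", "count_1"], pseudocount=d
            )
            row = out.df.set_index("variant").loc["c.1A>T"]
            score = math.log((cv[1] + d) / (cv[0] + d)) - math.log((cw[1] + d) / (cw[0] + d))
            se = math.sqrt(
                1 / (cv[0] + d) + 1 / (cv[1] + d) + 1 / (cw[0] + d) + 1 / (cw[1] + d)
            )
            assert float(row["score"]) == pytest.approx(score, abs=1e-10)
            assert float(row["SE"]) == pytest.approx(se, abs=1e-10)


def _three_cond(counts, wt_counts):
    return Table(
        pd.DataFrame(
            {
                "variant": ["c.1A>T", "c.="],
                "count_0": [counts[0], wt_counts[0]],
                "count_1": [counts[1], wt_counts[1]],
                "count_2": [counts[2], wt_counts[2]],
            }
        )
    )


COUNT3 = ["count_0", "count_1", "count_2"]


class TestRegressionScore:
    def test_worked_example(self):
        # frozen from the exact-rational WLS oracle on y=ln((c+.5)/100.5),
        # V=1/(1/(c+.5)+1/100.5), x=(0,.5,1)
        out = regression_score(
            _three_cond((10, 20, 40), (100, 100, 100)), "variant", COUNT3, times=[0, 1, 2]
        )
        row = out.df.set_index("variant").loc["c.1A>T"]
        assert float(row["score"]) == pytest.approx(1.352153220460293, abs=1e-12)
        assert float(row["SE"]) == pytest.approx(0.35573813515050556, abs=1e-12)

    def test_flat_counts_zero_slope(self):
        out = regression_score(
            _three_cond((100, 100, 100), (100, 100, 100)), "variant", COUNT3
        )
        assert float(out.df["score"].iloc[0]) == pytest.approx(0.0, abs=1e-14)

    def test_wt_slope_zero_for_any_pseudocount(self):
        for d in (0.5, 1.0, 2.0):
            out = regression_score(
                _three_cond((10, 20, 40), (90, 110, 100)),
                "variant",
                COUNT3,
                pseudocount=d,
            )
            assert float(out.df.set_index("variant").loc["c.=", "score"]) == 0.0

    def test_two_timepoints_rejected(self):
        with pytest.raises(ValueError, match="ratio_score"):
            regression_score(
                _two_cond((1, 2), (3, 4)), "variant", ["count_0", "count_1"]
            )

    def test_oracle_equivalence_random_instances(self):
        rnd = random.Random(77)
        for _ in range(100):
            T = rnd.choice([3, 4, 5])
            cv = [rnd.randrange(0, 400) for _ in range(T)]
            cw = [rnd.randrange(5, 400) for _ in range(T)]
            d = 0.5
            cols = [f"count_{i}" for i in range(T)]
            df = pd.DataFrame({"variant": ["v", "c.="]})
            for i, c in enumerate(cols):
                df[c] = [cv[i], cw[i]]
            out = regression_score(Table(df), "variant", cols)
            row = out.df.set_index("variant").loc["v"]
            x = [i / (T - 1) for i in range(T)]
            y = [math.log(a + d) - math.log(b + d) for a, b in zip(cv, cw)]
            w = [1 / (1 / (a + d) + 1 / (b + d)) for a, b in zip(cv, cw)]
            slope, se = wls_oracle(x, y, w)
            assert float(row["score"]) == pytest.approx(slope, abs=1e-10)
            assert float(row["SE"]) == pytest.approx(se, abs=1e-10)

    def test_slope_point_estimate_matches_statsmodels(self):
        import statsmodels.api as sm

        cv, cw, d = (12, 33, 70), (200, 180, 190), 0.5
        out = regression_score(_three_cond(cv, cw), "variant", COUNT3)
        x = np.array([0.0, 0.5, 1.0])
        y = np.array([math.log(a + d) - math.log(b + d) for a, b in zip(cv, cw)])
        w = np.array([1 / (1 / (a + d) + 1 / (b + d)) for a, b in zip(cv, cw)])
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        assert float(out.df["score"].iloc[0]) == pytest.approx(fit.params[1], abs=1e-10)

    def test_reduces_to_ratio_with_two_points(self):
        """With x=(0,1) the WLS slope is algebraically the log-ratio."""
        rnd = random.Random(5)
        for _ in range(20):
            cv = (rnd.randrange(0, 300), rnd.randrange(0, 300))
            cw = (rnd.randrange(1, 300), rnd.randrange(1, 300))
            ratio = ratio_score(
                _two_cond(cv, cw), "variant", ["count_0", "count_1"]
            )
            d = 0.5
            x = [0.0, 1.0]
            y = [math.log(a + d) - math.log(b + d) for a, b in zip(cv, cw)]
            w = [1 / (1 / (a + d) + 1 / (b + d)) for a, b in zip(cv, cw)]
            slope, _ = wls_oracle(x, y, w)
            assert float(
                ratio.df.set_index("variant").loc["c.1A>T", "score"]
            ) == pytest.approx(slope, abs=1e-10)


class TestCombineReplicates:
    def test_identical_replicates(self):
        c = combine_replicates([1.0, 1.0], [0.2, 0.2])
        assert c.score == pytest.approx(1.0)
        assert c.sigma2_s == 0.0
        assert c.se == pytest.approx(0.2 / math.sqrt(2), abs=1e-12)

    def test_heterogeneous_worked_example(self):
        # hand evaluation: w=(4,4), ybar=1, Q=8, sigma2=(8-1)/(8-4)=1.75,
        # w*=1/(.25+1.75)=.5 each, beta=1, SE=sqrt(1/1)=1
        c = combine_replicates([0.0, 2.0], [0.5, 0.5])
        assert c.score == pytest.approx(1.0, abs=1e-12)
        assert c.q == pytest.approx(8.0, abs=1e-12)
        assert c.sigma2_s == pytest.approx(1.75, abs=1e-12)
        assert c.se == pytest.approx(1.0, abs=1e-12)

    def test_three_identical(self):
        c = combine_replicates([1.0, 1.0, 1.0], [0.3, 0.3, 0.3])
        assert c.score == pytest.approx(1.0)
        assert c.se == pytest.approx(0.3 / math.sqrt(3), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            combine_replicates([1.0], [0.1])
        with pytest.raises(ValueError):
            combine_replicates([1.0, 2.0], [0.1, 0.0])

    def test_combined_within_replicate_range(self):
        rnd = random.Random(31)
        for _ in range(100):
            n = rnd.randrange(2, 6)
            b = [rnd.uniform(-3, 3) for _ in range(n)]
            s = [rnd.uniform(0.05, 1.0) for _ in range(n)]
            c = combine_replicates(b, s)
            assert min(b) - 1e-12 <= c.score <= max(b) + 1e-12
            assert c.sigma2_s >= 0 and c.q >= 0 and c.n == n

    def test_oracle_equivalence_random_instances(self):
        rnd = random.Random(55)
        for _ in range(100):
            n = rnd.randrange(2, 7)
            b = [rnd.uniform(-2, 2) for _ in range(n)]
            s = [rnd.uniform(0.05, 0.8) for _ in range(n)]
            c = combine_replicates(b, s)
            w = [1 / x**2 for x in s]
            ybar = sum(wi * bi for wi, bi in zip(w, b)) / sum(w)
            q = sum(wi * (bi - ybar) ** 2 for wi, bi in zip(w, b))
            sig = max(0.0, (q - (n - 1)) / (sum(w) - sum(x**2 for x in w) / sum(w)))
            ws = [1 / (x**2 + sig) for x in s]
            beta = sum(wi * bi for wi, bi in zip(ws, b)) / sum(ws)
            se = math.sqrt(1 / sum(ws))
            assert c.score == pytest.approx(beta, abs=1e-10)
            assert c.se == pytest.approx(se, abs=1e-10)
            assert c.q == pytest.approx(q, abs=1e-10)
            assert c.sigma2_s == pytest.approx(sig, abs=1e-10)

    def test_table_combination_groups_by_variant(self):
        t = Table(
            pd.DataFrame(
                {
                    "variant": ["v1", "v1", "v2", "v2"],
                    "score": [0.0, 2.0, 1.0, 1.0],
                    "SE": [0.5, 0.5, 0.2, 0.2],
                }
            )
        )
        out = combine_replicates_table(t, "variant").df.set_index("variant")
        assert float(out.loc["v1", "score"]) == pytest.approx(1.0)
        assert float(out.loc["v1", "sigma2_s"]) == pytest.approx(1.75)
        assert int(out.loc["v2", "n_reps"]) == 2


def _bins_table(variant_counts, other_counts):
    cols = {"variant": ["v", "rest"]}
    for i, (a, b) in enumerate(zip(variant_counts, other_counts), start=1):
        cols[f"bin_{i}"] = [a, b]
    return Table(pd.DataFrame(cols))


BIN4 = ["bin_1", "bin_2", "bin_3", "bin_4"]
W4 = [0.25, 0.5, 0.75, 1.0]


class TestBinScore:
    def test_all_mass_in_top_bin(self):
        t = _bins_table((0, 0, 0, 50), (1000, 1000, 1000, 950))
        out = bin_score(t, "variant", BIN4, weights=W4)
        assert float(out.df.set_index("variant").loc["v", "score"]) == pytest.approx(1.0)

    def test_uniform_occupancy_mean_weight(self):
        t = _bins_table((10, 10, 10, 10), (990, 990, 990, 990))
        out = bin_score(t, "variant", BIN4, weights=W4)
        assert float(out.df.set_index("variant").loc["v", "score"]) == pytest.approx(0.625)

    def test_bin_depth_invariance(self):
        a = _bins_table((10, 20, 30, 40), (990, 980, 970, 960))
        doubled = _bins_table((20, 20, 30, 40), (1980, 980, 970, 960))
        sa = bin_score(a, "variant", BIN4, weights=W4).df["score"]
        sb = bin_score(doubled, "variant", BIN4, weights=W4).df["score"]
        # doubling every count in bin 1 leaves within-bin frequencies there unchanged
        assert float(sa[0]) == pytest.approx(float(sb[0]), abs=1e-12)

    def test_score_within_weight_bounds(self):
        rnd = random.Random(17)
        for _ in range(50):
            vc = tuple(rnd.randrange(0, 100) for _ in range(4))
            oc = tuple(rnd.randrange(1, 1000) for _ in range(4))
            if sum(vc) == 0:
                continue
            out = bin_score(_bins_table(vc, oc), "variant", BIN4, weights=W4)
            s = float(out.df.set_index("variant").loc["v", "score"])
            assert min(W4) - 1e-12 <= s <= max(W4) + 1e-12

    def test_default_weights_equally_spaced(self):
        t = _bins_table((0, 0, 0, 50), (100, 100, 100, 50))
        out = bin_score(t, "variant", BIN4)  # default w_b = b/B
        assert float(out.df.set_index("variant").loc["v", "score"]) == pytest.approx(1.0)

    def test_min_total_count_flags_missing(self):
        t = _bins_table((1, 0, 0, 1), (500, 500, 500, 500))
        out = bin_score(t, "variant", BIN4, weights=W4, min_total_count=5)
        row = out.df.set_index("variant").loc["v"]
        assert bool(row["low_count"]) and row["score"] is pd.NA

    def test_absent_variant_missing_score(self):
        t = _bins_table((0, 0, 0, 0), (10, 10, 10, 10))
        out = bin_score(t, "variant", BIN4, weights=W4)
        assert out.df.set_index("variant").loc["v", "score"] is pd.NA
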
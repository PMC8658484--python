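from __future__ import annotations

import math

import mpmath as mp
import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from pvsignal.bcpnn import (
    Classification,
    PriorSpec,
    calibrate_margin,
    classify,
    credible_interval,
    expectation_ic,
    ic_result,
    ror,
    score_frame,
    variance_ic,
)
from pvsignal.contingency import ContingencyTable

mp.mp.dps = 50


def oracle_moments(n11, n1p, np1, npp, priors=PriorSpec()):
    """Independent arbitrary-precision transcription of the IC moments."""
    g11, a1, b1, a, b = (mp.mpf(priors.gamma11), mp.mpf(priors.alpha1),
                         mp.mpf(priors.beta1), mp.mpf(priors.alpha),
                         mp.mpf(priors.beta))
    n11, n1p, np1, npp = map(mp.mpf, (n11, n1p, np1, npp))
    g = g11 * (npp + a) * (npp + b) / ((n1p + a1) * (np1 + b1))
    e = mp.log((n11 + g11) * (npp + a) * (npp + b)
               / ((npp + g) * (n1p + a1) * (np1 + b1))) / mp.log(2)
    v = (1 / mp.log(2)) ** 2 * (
        (npp - n11 + g - g11) / ((n11 + g11) * (1 + npp + g))
        + (npp - n1p + a - a1) / ((n1p + a1) * (1 + npp + a))
        + (npp - np1 + b - b1) / ((np1 + b1) * (1 + npp + b)))
    return e, v


def random_small_tables(n, seed):
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < n:
        cells = rng.integers(0, 50, size=4)
        if cells.sum() > 0:
            tables.append(ContingencyTable(*map(int, cells)))
    return tables


class TestOracleEquivalence:
    def test_moments_match_high_precision_oracle_on_random_tables(self):
        """E(IC) and V(IC) agree with the mpmath oracle to 1e-10 bits."""
        for t in random_small_tables(100, seed=20_000_024):
            e_ref, v_ref = oracle_moments(t.n11, t.n1plus, t.nplus1, t.nplusplus)
            assert abs(expectation_ic(t) - float(e_ref)) < 1e-10
            assert abs(variance_ic(t) - float(v_ref)) < 1e-10

    def test_frozen_oracle_values_for_reference_table(self):
        """(5, 10, 10, 100): values frozen from the 50-digit oracle."""
        t = ContingencyTable.from_margins(5, 10, 10, 100)
        assert expectation_ic(t) == pytest.approx(1.4719193473494476, abs=1e-12)
        assert variance_ic(t) == pytest.approx(0.6682500217674969, abs=1e-12)

    def test_nondefault_priors_follow_oracle(self):
        priors = PriorSpec(gamma11=2.0, alpha1=0.5, beta1=1.5, alpha=3.0,
                           beta=1.0)
        t = ContingencyTable.from_margins(7, 40, 25, 500)
        e_ref, v_ref = oracle_moments(7, 40, 25, 500, priors)
        assert expectation_ic(t, priors) == pytest.approx(float(e_ref), abs=1e-12)
        assert variance_ic(t, priors) == pytest.approx(float(v_ref), abs=1e-12)


class TestExpectationProperties:
    @given(st.integers(0, 399), st.integers(0, 399))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_n11(self, a, b):
        """With margins fixed, E(IC) strictly increases in N11."""
        assume(a != b)
        a, b = min(a, b), max(a, b)
        n1p, np1, npp = 500, 400, 100_000
        lo = ContingencyTable.from_margins(a, n1p, np1, npp)
        hi = ContingencyTable.from_margins(b, n1p, np1, npp)
        assert expectation_ic(hi) > expectation_ic(lo)

    def test_independence_limit_is_near_zero(self):
        """N11·N++ = N1+·N+1 with N11 ≥ 100 gives |IC| < 0.05."""
        for n11, n1p, np1 in [(100, 1000, 1000), (400, 2000, 4000),
                              (2500, 5000, 25_000)]:
            npp = n1p * np1 // n11
            t = ContingencyTable.from_margins(n11, n1p, np1, npp)
            assert abs(expectation_ic(t)) < 0.05

    def test_zero_cell_is_finite(self):
        t = ContingencyTable.from_margins(0, 10, 11_000, 534_287)
        e, v = expectation_ic(t), variance_ic(t)
        assert math.isfinite(e) and math.isfinite(v) and v > 0

    def test_shrinkage_bounded_by_crude_ratio(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            npp = int(rng.integers(10_000, 1_000_000))
            n1p = int(rng.integers(1, npp // 100))
            np1 = int(rng.integers(1, npp // 100))
            n11 = int(rng.integers(1, min(n1p, np1) + 1))
            t = ContingencyTable.from_margins(n11, n1p, np1, npp)
            crude = math.log2(n11 * npp / (n1p * np1))
            assert abs(expectation_ic(t)) <= abs(crude) + 0.5

    def test_converges_to_crude_ratio_under_scaling(self):
        """Shrinkage vanishes as all counts scale up proportionally."""
        base = (8, 100, 200, 10_000)
        crude = math.log2(base[0] * base[3] / (base[1] * base[2]))
        errs = []
        for scale in (10, 100, 1000):
            t = ContingencyTable.from_margins(*(c * scale for c in base))
            errs.append(abs(expectation_ic(t) - crude))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01

    def test_variance_decreases_when_counts_double(self):
        t1 = ContingencyTable.from_margins(20, 200, 300, 50_000)
        t2 = ContingencyTable.from_margins(40, 400, 600, 50_000)
        assert variance_ic(t2) < variance_ic(t1)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            expectation_ic(ContingencyTable(0, 0, 0, 0))


class TestCredibleInterval:
    def test_zero_variance_degenerates_to_point(self):
        assert credible_interval(1.3, 0.0) == (1.3, 1.3)

    @given(st.floats(-5, 5), st.floats(0, 4))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_with_width_four_sd(self, e, v):
        lo, hi = credible_interval(e, v)
        assert lo <= e <= hi
        assert (lo + hi) / 2 == pytest.approx(e, abs=1e-9)
        assert hi - lo == pytest.approx(4 * math.sqrt(v), abs=1e-9)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            credible_interval(0.0, -1e-9)


class TestClassify:
    @pytest.mark.parametrize("lo,hi,expected", [
        (2.19, 2.65, Classification.SIGNAL),
        (-0.75, -0.17, Classification.INVERSE),
        (-0.10, 2.20, Classification.NONE),
        (0.0, 1.0, Classification.NONE),   # boundary: strictly > 0
        (-1.0, 0.0, Classification.NONE),  # boundary: strictly < 0
    ])
    def test_threshold_rules(self, lo, hi, expected):
        assert classify(lo, hi) is expected

    def test_ic_result_is_internally_consistent(self):
        r = ic_result(ContingencyTable.from_margins(30, 100, 200, 100_000))
        assert r.ic025 <= r.e_ic <= r.ic975
        assert r.ic975 - r.ic025 == pytest.approx(4 * math.sqrt(r.v_ic))
        assert r.classification is classify(r.ic025, r.ic975)


class TestROR:
    def test_proportional_table_gives_unity(self):
        r = ror(ContingencyTable(10, 90, 100, 900))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_hand_computed_value(self):
        r = ror(ContingencyTable(20, 80, 100, 900))
        assert r.ror == pytest.approx(2.25)  # (20*900)/(80*100)

    def test_zero_cell_leaves_ci_undefined(self):
        r = ror(ContingencyTable(0, 80, 100, 900))
        assert r.ror == 0.0 and r.ci_low is None and r.ci_high is None
        r2 = ror(ContingencyTable(5, 0, 100, 900))
        assert math.isinf(r2.ror) and r2.ci_low is None


class TestCalibrateMargin:
    def test_recovers_margin_from_self_generated_rows(self):
        """Rows scored at a known N+1 calibrate back to it exactly."""
        npp, true_margin = 200_000, 5000
        rows = []
        for n11, n1p in [(40, 300), (5, 100), (0, 50), (120, 900)]:
            t = ContingencyTable.from_margins(n11, n1p, true_margin, npp)
            rows.append((n11, n1p, expectation_ic(t)))
        assert calibrate_margin(rows, npp, (1, 20_000)) == true_margin

    def test_recovers_margin_from_rounded_rows(self):
        """ICs rounded to 2 decimals still pin the margin closely.

        Rounding leaves ±0.005-bit slack per row, which at this margin
        corresponds to a handful of counts.
        """
        npp, true_margin = 200_000, 5000
        rows = []
        for n11, n1p in [(40, 300), (5, 100), (120, 900), (70, 500),
                         (12, 222), (33, 150)]:
            t = ContingencyTable.from_margins(n11, n1p, true_margin, npp)
            rows.append((n11, n1p, round(expectation_ic(t), 2)))
        assert abs(calibrate_margin(rows, npp, (1, 20_000)) - true_margin) <= 10

    def test_boundary_minimum_warns(self):
        rows = [(40, 300, 10.0)]  # implausibly large IC pushes to the low edge
        with pytest.warns(UserWarning, match="boundary"):
            calibrate_margin(rows, 200_000, (100, 200))

    def test_requires_rows(self):
        with pytest.raises(ValueError):
            calibrate_margin([], 1000)


def test_score_frame_round_trips(tmp_path):
    import pandas as pd
    counts = pd.DataFrame([
        {"group_name": "a", "n11": 10, "n1plus": 100, "nplus1": 500,
         "nplusplus": 100_000},
        {"group_name": "b", "n11": 0, "n1plus": 40, "nplus1": 500,
         "nplusplus": 100_000},
    ])
    scored = score_frame(counts)
    path = tmp_path / "scored.tsv"
    scored.to_csv(path, sep="\t", index=False)
    again = score_frame(pd.read_csv(path, sep="\t")[counts.columns])
    assert list(again.classification) == list(scored.classification)
    assert np.allclose(again.e_ic, scored.e_ic)
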
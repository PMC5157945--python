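"""Behavioural-analysis tests: d', Naka-Rushton fits, gains, binning, JND."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special

from nmoa.psychometrics import (
    circular_difference,
    dprime,
    dprime_from_rates,
    exclusion_filter,
    fit_crf_joint,
    fit_cumulative_gaussian,
    gain_summary,
    group_by_offset,
    modulation_index,
    naka_rushton,
    paired_tests,
)


def quantile_oracle(p: float) -> float:
    """High-precision standard-normal quantile, independent of scipy.stats."""
    return float(optimize.brentq(lambda z: 0.5 * special.erfc(-z / np.sqrt(2)) - p, -10, 10,
                                 xtol=1e-13))


class TestDprime:
    def test_chance_is_zero(self):
        assert dprime(50, 50, 100, 100) == pytest.approx(0.0, abs=1e-12)

    def test_phi_symmetry_gives_two(self):
        assert dprime_from_rates(0.841345, 0.158655) == pytest.approx(2.0, abs=1e-4)

    def test_extreme_correction_matches_quantile_oracle(self):
        # 50/50 hits, 0/50 false alarms: p_fa corrected to 1/100
        d = dprime(50, 0, 50, 50)
        expected = quantile_oracle(1 - 1 / 100) - quantile_oracle(1 / 100)
        assert d == pytest.approx(expected, abs=1e-8)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            dprime(0, 0, 0, 10)

    @settings(deadline=None, derandomize=True)
    @given(h=st.integers(1, 99), f=st.integers(1, 99))
    def test_antisymmetric_under_rate_swap(self, h, f):
        assert dprime(h, f, 100, 100) == pytest.approx(-dprime(f, h, 100, 100), abs=1e-12)

    def test_proportion_correct_measure(self):
        from nmoa.psychometrics import dprime_table
        t = pd.DataFrame({
            "subject": 1, "cue_type": "narrow", "validity": "valid",
            "coherence": 0.5,
            "change_sign": ["CW", "CW", "CCW", "CCW"] * 3,
            "response": ["CW", "CCW", "CCW", "CW"] * 3,  # 50% correct
        })
        out = dprime_table(t, measure="pc")
        assert out["dprime"].iloc[0] == pytest.approx(0.0)
        out_cw = dprime_table(t.assign(response=t["change_sign"]), measure="pc")
        assert out_cw["dprime"].iloc[0] == pytest.approx(0.5)


class TestNakaRushton:
    def test_half_saturation(self):
        assert naka_rushton(0.1, 2.0, 0.1, 1.7) == pytest.approx(1.0)

    def test_zero_and_direct_value(self):
        assert naka_rushton(0.0, 2.0, 0.1, 1.0) == 0.0
        assert naka_rushton(0.3, 2.0, 0.1, 1.0) == pytest.approx(1.5)

    def test_monotone_below_asymptote(self):
        c = np.linspace(0, 1, 50)
        d = naka_rushton(c, 2.0, 0.2, 1.5)
        assert np.all(np.diff(d) > 0)
        assert np.all(d < 2.0)


def _noise_free_table(curves, n, coherences=(0.016, 0.064, 0.128, 0.256, 0.512, 1.0)):
    rows = []
    for (ct, val), (dmax, c50) in curves.items():
        for c in coherences:
            rows.append((ct, val, c, naka_rushton(c, dmax, c50, n)))
    return pd.DataFrame(rows, columns=["cue_type", "validity", "coherence", "dprime"])


class TestJointCRFFit:
    curves = {
        ("narrow", "valid"): (3.1, 0.12),
        ("narrow", "invalid"): (2.2, 0.30),
        ("broad", "valid"): (2.8, 0.22),
        ("broad", "invalid"): (2.2, 0.28),
    }

    def test_noise_free_recovery(self):
        table = _noise_free_table(self.curves, 1.6)
        fit = fit_crf_joint(table, seed=1)
        assert fit.sse < 1e-10
        assert fit.exponent() == pytest.approx(1.6, rel=5e-3)
        for cell, (dmax, c50) in self.curves.items():
            got_d, got_c = fit.coefficients[cell]
            assert got_d == pytest.approx(dmax, rel=5e-3)
            assert got_c == pytest.approx(c50, rel=5e-3)

    def test_identical_curves_fit_identically(self):
        curves = {cell: (2.5, 0.2) for cell in self.curves}
        fit = fit_crf_joint(_noise_free_table(curves, 1.5), seed=2)
        coeffs = np.array(list(fit.coefficients.values()))
        assert np.allclose(coeffs, coeffs[0], rtol=1e-4)

    def test_shared_slope_never_beats_free_slopes(self, rng):
        table = _noise_free_table(self.curves, 1.6)
        table["dprime"] += rng.normal(0, 0.15, len(table))
        shared = fit_crf_joint(table, slope_mode="shared", seed=3)
        free = fit_crf_joint(table, slope_mode="free", seed=3)
        assert free.sse <= shared.sse + 1e-6
        assert shared.k == 9 and free.k == 12

    def test_bic_prefers_shared_slope_on_shared_truth(self, rng):
        table = _noise_free_table(self.curves, 1.6)
        table["dprime"] += rng.normal(0, 0.1, len(table))
        shared = fit_crf_joint(table, slope_mode="shared", seed=4)
        free = fit_crf_joint(table, slope_mode="free", seed=4)
        assert shared.aic_bic()[1] < free.aic_bic()[1]

    def test_too_few_levels_rejected(self):
        table = _noise_free_table(self.curves, 1.6, coherences=(0.1, 0.3, 1.0))
        with pytest.raises(ValueError, match="4 coherence"):
            fit_crf_joint(table)


class TestModulationIndex:
    @pytest.mark.parametrize("a,b,expected", [(2.0, 2.0, 0.0), (3.0, 1.0, 0.5), (1.0, 3.0, -0.5)])
    def test_values(self, a, b, expected):
        assert modulation_index(a, b) == pytest.approx(expected)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            modulation_index(1.0, -1.0)

    def test_gain_summary_signs(self):
        fit = fit_crf_joint(_noise_free_table(TestJointCRFFit.curves, 1.6), seed=5)
        g = gain_summary(fit).set_index("condition")
        assert g.loc["narrow", "mi_c50"] < 0  # coherence gain
        assert g.loc["narrow", "mi_dmax"] > 0  # response gain


class TestExclusion:
    @staticmethod
    def _table(top_two):
        rows = []
        for ct in ("narrow", "broad"):
            for val in ("valid", "invalid"):
                for c, d in zip((0.256, 0.512, 1.0), (1.0, *top_two)):
                    rows.append((ct, val, c, d))
        return pd.DataFrame(rows, columns=["cue_type", "validity", "coherence", "dprime"])

    def test_saturating_subject_kept(self):
        exclude, deltas = exclusion_filter(self._table((2.0, 2.1)))
        assert not exclude
        assert np.allclose(deltas["delta_dprime"], 0.1)

    def test_boundary_increase_excludes(self):
        exclude, _ = exclusion_filter(self._table((1.0, 2.0)))
        assert exclude  # delta exactly 1 triggers the >= rule

    def test_decrease_keeps(self):
        exclude, _ = exclusion_filter(self._table((2.2, 2.0)))
        assert not exclude


class TestOffsetBinning:
    @staticmethod
    def _trials(offsets, validity="valid", mode="cue_sample"):
        rows = []
        for i, off in enumerate(offsets):
            cue = 40.0
            sample = (cue + off) % 360.0
            test = (sample + 5.0) % 360.0
            rows.append((1, 1, "narrow", validity, 1.0, cue, sample,
                         test if mode == "cue_sample" else (cue + off) % 360.0,
                         "CCW", "CCW"))
        return pd.DataFrame(rows, columns=[
            "subject", "session", "cue_type", "validity", "coherence",
            "cued_direction", "sample_direction", "test_direction",
            "change_sign", "response"])

    def test_cue_sample_bins_one_trial_each(self):
        out = group_by_offset(self._trials([1.0, 5.0, 9.0]), "cue_sample")
        counts = out[out["validity"] == "valid"].set_index("offset_bin")["n_trials"]
        assert counts.loc["close"] == 1 and counts.loc["medium"] == 1 and counts.loc["far"] == 1

    def test_all_trials_close_when_no_offset(self):
        out = group_by_offset(self._trials([0.0] * 6), "cue_test", jnd=12.0)
        valid = out[out["validity"] == "valid"].set_index("offset_bin")
        assert valid.loc["close", "n_trials"] == 6
        assert valid.loc["medium", "n_trials"] == 0

    def test_binning_invariant_under_full_turns(self):
        t1 = self._trials([1.0, 5.0, 9.0])
        t2 = t1.copy()
        t2["sample_direction"] += 360.0
        a = group_by_offset(t1, "cue_sample")
        b = group_by_offset(t2, "cue_sample")
        pd.testing.assert_frame_equal(a, b)

    def test_cue_test_requires_jnd(self):
        with pytest.raises(ValueError, match="JND"):
            group_by_offset(self._trials([1.0]), "cue_test", jnd=None)

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(0, 720), b=st.floats(0, 720))
    def test_circular_difference_range_and_symmetry(self, a, b):
        d = float(circular_difference(a, b))
        assert 0.0 <= d <= 180.0
        assert d == pytest.approx(float(circular_difference(b, a)), abs=1e-9)


class TestCumulativeGaussian:
    def test_recovers_jnd_at_pretest_scale(self, rng):
        # pre-test protocol: 450 trials per session, 15 change magnitudes
        # spanning -14..14 degrees. A single session pins the slope only to
        # ~10% (the range covers barely one sigma), so accuracy at the 5%
        # level is asserted on the mean estimate over sessions.
        x = np.tile(np.linspace(-14, 14, 15), 30)
        p = 0.5 * special.erfc(-(x - 0.0) / (12.86 * np.sqrt(2)))
        jnds, biases = [], []
        for _ in range(40):
            y = rng.random(len(x)) < p
            bias, jnd = fit_cumulative_gaussian(x, y)
            jnds.append(jnd)
            biases.append(bias)
        assert np.mean(jnds) == pytest.approx(12.86, rel=0.05)
        assert abs(np.mean(biases)) < 1.0

    def test_symmetric_responses_give_zero_bias(self):
        x = np.array([-10.0, -5.0, -1.0, 1.0, 5.0, 10.0] * 2)
        y = np.array([0, 0, 0, 1, 1, 1] * 2, dtype=bool)
        y[[2, 9]] = [True, False]  # break separation symmetrically
        bias, _ = fit_cumulative_gaussian(x, y)
        assert bias == pytest.approx(0.0, abs=1e-6)

    def test_matches_likelihood_grid_oracle(self, rng):
        x = np.tile(np.linspace(-14, 14, 15), 20)
        p = 0.5 * special.erfc(-(x - 1.5) / (10.0 * np.sqrt(2)))
        y = rng.random(len(x)) < p
        bias, jnd = fit_cumulative_gaussian(x, y)

        def nll(mu, sigma):
            q = np.clip(0.5 * special.erfc(-(x - mu) / (sigma * np.sqrt(2))), 1e-12, 1 - 1e-12)
            return -np.sum(np.where(y, np.log(q), np.log(1 - q)))

        # the fitted optimum beats every point of a surrounding grid
        best = nll(bias, jnd)
        for mu in np.linspace(bias - 3, bias + 3, 13):
            for sigma in np.linspace(max(jnd - 3, 1.0), jnd + 3, 13):
                assert best <= nll(mu, sigma) + 1e-6

    def test_constant_responses_diverge(self):
        x = np.linspace(-10, 10, 9)
        with pytest.raises(FloatingPointError):
            fit_cumulative_gaussian(x, np.ones(9, dtype=bool))


class TestPairedTests:
    def test_identical_pairs_degenerate(self):
        res = paired_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and np.isnan(res.t_p)

    def test_constant_positive_differences_one_tailed(self):
        res = paired_tests([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6], alternative="greater")
        assert res.degenerate
        assert res.t_p < 0.001

    def test_bonferroni_threshold(self):
        res = paired_tests([1.0, 2.0, 3.5], [0.5, 2.5, 1.0], alpha=0.05, m=4)
        assert res.alpha_corrected == pytest.approx(0.0125)

    def test_t_matches_closed_form(self, rng):
        a = rng.normal(1.0, 1.0, 8)
        b = rng.normal(0.0, 1.0, 8)
        res = paired_tests(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.t_stat == pytest.approx(t, abs=1e-10)
        # two-sided p from the regularized incomplete beta (t CDF identity)
        nu = len(d) - 1
        p = special.betainc(nu / 2, 0.5, nu / (nu + t ** 2))
        assert res.t_p == pytest.approx(p, abs=1e-10)
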
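"""Aalen-Johansen cumulative incidence and weighted survival curves."""

import numpy as np
import pandas as pd
import pytest

from empyema_pba.cox import (
    cumulative_incidence,
    fit_weighted_cox,
    weighted_survival_curves,
)


def competing_frame(rows):
    """rows: (time_surgery, event_surgery, time_death, event_death, label)"""
    return pd.DataFrame(rows, columns=["time_surgery", "event_surgery",
                                       "time_death", "event_death",
                                       "exposure_label"])


class TestCIF:
    def test_single_cause_equals_one_minus_km(self, rng):
        """With death as the only cause the CIF is 1 - Kaplan-Meier."""
        from lifelines import KaplanMeierFitter

        n = 120
        t = rng.integers(1, 30, n).astype(float)
        e = rng.integers(0, 2, n)
        df = competing_frame([(t[i], 0, t[i], e[i], "g") for i in range(n)])
        # death-only: recode as the first event on the surgery timescale too
        df["time_surgery"] = df["time_death"]
        est = cumulative_incidence(df, "g")
        km = KaplanMeierFitter().fit(t, e)
        for tau, cif in zip(est.time_grid, est.cif_death):
            assert cif == pytest.approx(
                1 - float(km.survival_function_at_times(tau).iloc[0]), abs=1e-12)
        assert np.all(est.cif_surgery == 0)

    def test_hand_computed_four_records(self):
        """One event per cause plus censoring, risk sets enumerated by hand:
        t=2 surgery (Y=4), t=5 censor, t=7 death (Y=2)."""
        df = competing_frame([
            (2.0, 1, 90.0, 0, "g"),
            (5.0, 0, 5.0, 0, "g"),
            (7.0, 0, 7.0, 1, "g"),
            (90.0, 0, 90.0, 0, "g"),
        ])
        est = cumulative_incidence(df, "g")
        np.testing.assert_allclose(est.time_grid, [2.0, 7.0])
        np.testing.assert_allclose(est.cif_surgery, [0.25, 0.25])
        # at t=7: S(7-) = 0.75, Y=2, dN_death=1 -> increment 0.375
        np.testing.assert_allclose(est.cif_death, [0.0, 0.375])
        np.testing.assert_allclose(est.event_free, [0.75, 0.375])

    def test_all_censored_gives_zero_cifs(self):
        df = competing_frame([(90.0, 0, 90.0, 0, "g")] * 5)
        est = cumulative_incidence(df, "g")
        assert np.all(est.cif_surgery == 0) and np.all(est.cif_death == 0)

    def test_empty_group_empty_grid(self):
        df = competing_frame([(2.0, 1, 90.0, 0, "g")])
        est = cumulative_incidence(df, "other")
        assert len(est.time_grid) == 0

    def test_conservation_on_simulated_cohort(self, default_cohort):
        _, df = default_cohort
        for group in ("anti_pseudomonal", "non_anti_pseudomonal"):
            est = cumulative_incidence(df, group)
            total = est.cif_surgery + est.cif_death + est.event_free
            assert np.abs(total - 1.0).max() < 1e-10
            assert np.all(np.diff(est.cif_surgery) >= 0)
            assert np.all(np.diff(est.cif_death) >= 0)

    def test_bands_bracket_estimate(self, default_cohort):
        _, df = default_cohort
        est = cumulative_incidence(df, "anti_pseudomonal")
        lo, hi = est.band_death
        pos = est.cif_death > 0
        assert np.all(lo[pos] <= est.cif_death[pos] + 1e-12)
        assert np.all(hi[pos] >= est.cif_death[pos] - 1e-12)


class TestWeightedCurves:
    def survival_frame(self, rng, n=100):
        return pd.DataFrame({
            "time_death": rng.integers(1, 25, n).astype(float),
            "event_death": rng.integers(0, 2, n),
            "exposure": rng.integers(0, 2, n),
        })

    def test_null_effect_identical_groups(self, rng):
        df = self.survival_frame(rng)
        fit = fit_weighted_cox(df, None, "death")
        fit.log_hr = 0.0
        curves = weighted_survival_curves(df, None, "death", fit=fit)
        g0 = curves[curves.group == "non_anti_pseudomonal"].estimate.to_numpy()
        g1 = curves[curves.group == "anti_pseudomonal"].estimate.to_numpy()
        np.testing.assert_allclose(g0, g1)

    def test_no_censoring_single_group_equals_empirical(self):
        """Unit weights, all events, one group: the baseline curve is the
        empirical survival function."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df = pd.DataFrame({"time_death": np.r_[t, t + 0.0],
                           "event_death": 1, "exposure": 0})
        df.loc[0, "exposure"] = 1  # minimal contrast so the fit is defined
        fit = fit_weighted_cox(df, None, "death")
        fit.log_hr = 0.0
        curves = weighted_survival_curves(df, None, "death", fit=fit)
        g0 = curves[curves.group == "non_anti_pseudomonal"]
        emp = 1.0 - np.arange(2, 11, 2) / 10.0
        np.testing.assert_allclose(g0.estimate.to_numpy(), emp, atol=1e-12)

    def test_product_integral_oracle_six_records(self):
        """Curve values match a direct product-integral computation."""
        df = pd.DataFrame({"time_death": [1.0, 2, 3, 4, 5, 6],
                           "event_death": 1,
                           "exposure": [1, 0, 1, 0, 1, 0]})
        fit = fit_weighted_cox(df, None, "death")
        curves = weighted_survival_curves(df, None, "death", fit=fit)
        b = fit.log_hr
        wr = np.exp(b * np.array([1, 0, 1, 0, 1, 0]))
        S0 = wr[::-1].cumsum()[::-1]
        base = np.cumprod(1 - 1.0 / S0)
        g0 = curves[curves.group == "non_anti_pseudomonal"].estimate.to_numpy()
        g1 = curves[curves.group == "anti_pseudomonal"].estimate.to_numpy()
        np.testing.assert_allclose(g0, base, atol=1e-6)
        np.testing.assert_allclose(
            g1, np.cumprod(np.clip(1 - np.exp(b) / S0, 0, 1)), atol=1e-6)

    def test_band_ordering(self, rng):
        df = self.survival_frame(rng, n=200)
        curves = weighted_survival_curves(df, None, "death")
        g1 = curves[curves.group == "anti_pseudomonal"]
        assert (g1.low <= g1.estimate + 1e-12).all()
        assert (g1.high >= g1.estimate - 1e-12).all()
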
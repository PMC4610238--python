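"""Logistic fitting, DSS/AUC/pIC50 scoring and the response matrix."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import tascore as tc
from tascore.errors import FitError, InvalidConfigError


def make_series(rmax, slope, m, x, noise=None, rng=None):
    y = tc.logistic_inhibition(x, rmax, slope, m)
    if noise:
        y = y + rng.normal(0.0, noise, size=x.shape)
    return tc.DoseResponseSeries("s", "c", 10.0**x, y)


class TestFitLogistic:
    def test_noiseless_recovery(self):
        x = np.linspace(0.0, 3.5, 8)
        fit = tc.fit_logistic(make_series(80.0, 1.0, 2.0, x))
        assert fit.converged
        assert abs(fit.rmax - 80.0) < 1e-4
        assert abs(fit.slope - 1.0) < 1e-4
        assert abs(fit.log10_ic50 - 2.0) < 1e-4

    def test_all_zero_response_gives_zero_rmax(self):
        series = tc.DoseResponseSeries("s", "c", [1.0, 10.0, 100.0, 1000.0], [0.0] * 4)
        fit = tc.fit_logistic(series)
        assert fit.converged
        assert fit.rmax == 0.0
        assert fit.slope == pytest.approx(0.2)

    def test_saturated_curve_predicts_full_inhibition(self):
        # true IC50 far below the lowest dose: the fit must stay saturated
        x = np.linspace(1.0, 4.0, 6)
        fit = tc.fit_logistic(make_series(100.0, 1.0, -2.0, x))
        assert np.all(fit.predict(x) >= 99.0)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(FitError):
            tc.fit_logistic(tc.DoseResponseSeries("s", "c", [1.0, 10.0], [5.0, 50.0]))

    def test_viability_orientation(self):
        s = tc.DoseResponseSeries.from_viability("s", "c", [1, 10, 100], [90.0, 50.0, 10.0])
        assert np.allclose(s.responses, [10.0, 50.0, 90.0])

    def test_descending_concentrations_rejected(self):
        with pytest.raises(InvalidConfigError):
            tc.DoseResponseSeries("s", "c", [100.0, 10.0, 1.0], [1.0, 2.0, 3.0])


class TestDSS:
    def test_below_threshold_scores_zero(self):
        assert tc.dss(tc.LogisticFit(0.0, 1.0, 2.0), tc.DSSConfig(x_min=0, x_max=4)) == 0.0
        assert tc.dss(tc.LogisticFit(9.9, 1.0, 2.0), tc.DSSConfig(amin=10, x_min=0, x_max=4)) == 0.0

    def test_saturated_limit_approaches_100(self):
        fit = tc.LogisticFit(100.0, 1.0, -20.0)
        score = tc.dss(fit, tc.DSSConfig(amin=10.0, x_min=0.0, x_max=4.0))
        assert score == pytest.approx(100.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_matches_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        rmax = rng.uniform(5, 100)
        slope = rng.uniform(0.2, 6)
        m = rng.uniform(-1, 5)
        amin = rng.uniform(0, 30)
        cfg = tc.DSSConfig(amin=amin, x_min=0.0, x_max=4.0)
        got = tc.dss(tc.LogisticFit(rmax, slope, m), cfg)
        if rmax <= amin:
            assert got == 0.0
            return
        x1 = m - (1 / slope) * math.log10(rmax / amin - 1) if amin > 0 else 0.0
        x1 = min(max(x1, 0.0), 4.0)
        integral, _ = quad(lambda x: tc.logistic_inhibition(x, rmax, slope, m) - amin, x1, 4.0)
        expected = max(100.0 * integral / ((100.0 - amin) * 4.0), 0.0)
        assert got == pytest.approx(expected, rel=1e-6, abs=1e-9)

    def test_monotone_in_ic50_and_rmax(self):
        cfg = tc.DSSConfig(amin=10.0, x_min=0.0, x_max=4.0)
        scores_m = [tc.dss(tc.LogisticFit(80.0, 1.0, m), cfg) for m in np.linspace(-1, 5, 25)]
        assert all(a >= b - 1e-12 for a, b in zip(scores_m, scores_m[1:]))
        scores_r = [tc.dss(tc.LogisticFit(r, 1.0, 2.0), cfg) for r in np.linspace(5, 100, 25)]
        assert all(b >= a - 1e-12 for a, b in zip(scores_r, scores_r[1:]))

    def test_dss2_downweights_partial_efficacy(self):
        cfg1 = tc.DSSConfig(amin=10.0, x_min=0.0, x_max=4.0, variant="DSS1")
        cfg2 = tc.DSSConfig(amin=10.0, x_min=0.0, x_max=4.0, variant="DSS2")
        full = tc.LogisticFit(100.0, 1.0, 2.0)
        partial = tc.LogisticFit(50.0, 1.0, 2.0)
        assert tc.dss(full, cfg2) == pytest.approx(tc.dss(full, cfg1))
        assert tc.dss(partial, cfg2) < tc.dss(partial, cfg1)


class TestAUC:
    @pytest.mark.parametrize(
        "responses,expected",
        [([0.0, 0.0, 0.0], 0.0), ([100.0, 100.0, 100.0], 1.0), ([0.0, 50.0, 100.0], 0.5)],
    )
    def test_known_areas(self, responses, expected):
        series = tc.DoseResponseSeries("s", "c", [1.0, 10.0, 100.0], responses)
        assert tc.auc_normalized(series) == pytest.approx(expected)

    def test_single_dose_rejected(self):
        with pytest.raises(FitError):
            tc.auc_normalized(tc.DoseResponseSeries("s", "c", [10.0], [50.0]))


@pytest.mark.parametrize(
    "molar,expected", [(1e-6, 6.0), (1.0, 0.0), (3.5e-8, 7.455931955649724)]
)
def test_pic50_definition(molar, expected):
    assert tc.pic50(molar) == pytest.approx(expected, abs=1e-9)


def test_pic50_rejects_nonpositive():
    with pytest.raises(ValueError):
        tc.pic50(0.0)


class TestResponseMatrix:
    def test_complete_and_missing_layout(self):
        x = np.array([0.0, 1.0, 2.0])
        series = [
            tc.DoseResponseSeries(s, c, 10.0**x, tc.logistic_inhibition(x, 80, 1, 1))
            for s in ("s1", "s2")
            for c in ("c1", "c2", "c3")
        ]
        full = tc.build_response_matrix(series, "AUC")
        assert full.data.shape == (2, 3)
        assert not full.data.isna().any().any()
        partial = tc.build_response_matrix(series[:-1], "AUC")
        assert int(partial.data.isna().sum().sum()) == 1
        assert np.isnan(partial.data.at["s2", "c3"])

    def test_duplicate_pair_rejected(self):
        s = tc.DoseResponseSeries("a", "b", [1.0, 10.0, 100.0], [0.0, 50.0, 90.0])
        with pytest.raises(InvalidConfigError):
            tc.build_response_matrix([s, s], "AUC")

    def test_dss_entries_match_per_series_scoring(self, small_screen):
        _, series, _, _ = small_screen
        subset = series[:12]
        cfg = tc.DSSConfig(amin=10.0)
        matrix = tc.build_response_matrix(subset, "DSS", cfg)
        for s in subset:
            expected = tc.dss(tc.fit_logistic(s), cfg, series=s)
            assert matrix.data.at[s.sample_id, s.compound_id] == pytest.approx(expected)
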
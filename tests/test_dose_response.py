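"""Concentration-response fitting: recovery, oracle equivalence, ECp math."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from isobolo.dose_response import (
    CurveData,
    build_curve_data,
    effective_concentration,
    fit_concentration_response,
    log_likelihood,
)
from isobolo.errors import InsufficientDesignError

STUDY_GRID_A = np.array([6.04, 7.65, 9.66, 12.08, 15.30, 19.33, 24.16, 30.6])


def make_curve(ec50=10.0, slope=2.0, link="probit", conc=STUDY_GRID_A, n=9):
    """Noiseless effect fractions generated from the stated link model."""
    x = np.log10(conc / ec50) * slope
    e = stats.norm.cdf(x) if link == "probit" else 1 / (1 + np.exp(-x))
    return CurveData("synthetic", conc, e, np.full(len(conc), n))


def grid_oracle(data, link, n_grid=200):
    """Brute-force (slope, log_ec50) grid maximiser of the same likelihood."""
    slopes = np.linspace(0.1, 10.0, n_grid)
    lecs = np.linspace(-3.0, 3.0, n_grid)
    ll = log_likelihood(data, slopes[:, None], lecs[None, :], link)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(ll[i, j]), float(slopes[i]), float(lecs[j])


@pytest.mark.parametrize("link", ["probit", "logit"])
def test_noiseless_self_consistency(link):
    """Exact model data must be recovered to numerical precision."""
    data = make_curve(ec50=10.0, slope=2.0, link=link)
    fit = fit_concentration_response(data, link=link)
    est = effective_concentration(fit, 0.5)
    assert est.value == pytest.approx(10.0, rel=1e-6)
    assert fit.slope == pytest.approx(2.0, rel=1e-6)


def test_optimizer_matches_grid_oracle(rng):
    """The continuous optimiser can never fall below the grid maximiser."""
    for _ in range(5):
        ec50 = 10 ** rng.uniform(-1.5, 1.5)
        slope = rng.uniform(0.5, 5.0)
        conc = ec50 * np.logspace(-0.7, 0.7, 8)
        data = make_curve(ec50=ec50, slope=slope, conc=conc)
        data.effect_fraction = np.clip(
            data.effect_fraction + rng.normal(0, 0.02, 8), 0, 1
        )
        fit = fit_concentration_response(data, link="probit")
        ll_fit = float(log_likelihood(data, fit.slope, fit.log_ec50, "probit"))
        ll_grid, _, _ = grid_oracle(data, "probit")
        assert ll_fit >= ll_grid - 1e-6


def test_decreasing_data_warns_negative_slope():
    data = make_curve(ec50=10.0, slope=2.0)
    data.effect_fraction = data.effect_fraction[::-1].copy()
    with pytest.warns(UserWarning, match="slope"):
        fit = fit_concentration_response(data)
    assert fit.slope < 0


def test_insufficient_design():
    data = CurveData("d", [1.0, 2.0, 4.0], [0.2, 0.5, 0.8], [9, 9, 9])
    with pytest.raises(InsufficientDesignError):
        fit_concentration_response(data)


def test_extrapolation_warning():
    data = make_curve(ec50=0.5, slope=2.0)  # all points far above 50% effect
    with pytest.warns(UserWarning, match="50%"):
        fit_concentration_response(data)


class TestEffectiveConcentration:
    @pytest.mark.parametrize("link", ["probit", "logit"])
    def test_median_equals_ec50(self, link):
        fit = fit_concentration_response(make_curve(link=link), link=link)
        est = effective_concentration(fit, 0.5)
        assert est.value == pytest.approx(10.0 ** fit.log_ec50, rel=1e-12)

    def test_ec90_closed_form(self):
        """probit slope 2, log EC50 = 1 -> EC90 = 10^(1 + z_0.90 / 2)."""
        fit = fit_concentration_response(
            make_curve(ec50=10.0, slope=2.0, conc=10 * np.logspace(-0.5, 0.5, 8))
        )
        est = effective_concentration(fit, 0.90)
        expected = 10 ** (1 + stats.norm.ppf(0.90) / 2)
        assert expected == pytest.approx(43.73, abs=0.01)
        assert est.value == pytest.approx(expected, rel=1e-6)

    def test_monotone_in_p(self):
        fit = fit_concentration_response(make_curve())
        values = [effective_concentration(fit, p).value for p in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert np.all(np.diff(values) > 0)

    def test_invalid_p(self):
        fit = fit_concentration_response(make_curve())
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                effective_concentration(fit, bad)


@given(k=st.floats(0.01, 100))
@settings(max_examples=25, deadline=None)
def test_unit_equivariance(k):
    """Scaling all concentrations by k scales every ECp by exactly k."""
    base = fit_concentration_response(make_curve())
    scaled = fit_concentration_response(
        CurveData("s", STUDY_GRID_A * k, make_curve().effect_fraction, np.full(8, 9))
    )
    assert scaled.slope == pytest.approx(base.slope, rel=1e-6)
    for p in (0.5, 0.9):
        assert effective_concentration(scaled, p).value == pytest.approx(
            k * effective_concentration(base, p).value, rel=1e-6
        )


def test_probit_logit_agree_at_median():
    """On symmetric noiseless data the two links give EC50s within 2%."""
    data = make_curve(ec50=10.0, slope=2.0, link="probit",
                      conc=10 * np.logspace(-0.6, 0.6, 9))
    ec50_probit = effective_concentration(
        fit_concentration_response(data, "probit"), 0.5).value
    ec50_logit = effective_concentration(
        fit_concentration_response(data, "logit"), 0.5).value
    assert ec50_logit == pytest.approx(ec50_probit, rel=0.02)


class TestBuildCurveData:
    def make_endpoints(self, values):
        return pd.DataFrame(
            {
                "group": "ogdr_treated",
                "drug_id": "DDS",
                "concentration_uM": np.arange(1.0, len(values) + 1),
                "endpoint": "viability_pct",
                "value": values,
                "sem": 1.0,
                "n": 9,
            }
        )

    def test_baseline_and_ceiling_map_to_0_and_1(self):
        data = build_curve_data(
            self.make_endpoints([47.19, 100.0]), "DDS", baseline=47.19, ceiling=100.0
        )
        assert data.effect_fraction == pytest.approx([0.0, 1.0])

    def test_group_mean_fraction(self):
        data = build_curve_data(
            self.make_endpoints([89.37]), "DDS", baseline=47.19, ceiling=100.0
        )
        assert data.effect_fraction[0] == pytest.approx(0.7987, abs=1e-4)

    def test_out_of_range_clipped(self):
        data = build_curve_data(
            self.make_endpoints([40.0, 105.0]), "DDS", baseline=47.19, ceiling=100.0
        )
        assert data.effect_fraction == pytest.approx([0.0, 1.0])

    def test_rejects_bad_window(self):
        with pytest.raises(ValueError):
            build_curve_data(self.make_endpoints([50.0]), "DDS", baseline=100.0, ceiling=90.0)
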
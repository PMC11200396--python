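"""Plate-signal endpoint math: viability, lethality, LDH, standard curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isobolo.endpoints import (
    compute_endpoints,
    cytoprotection_percent,
    fit_standard_curve,
    ldh_cytotoxicity_percent,
    lethality_percent,
    percent_of_control,
    quantify_from_curve,
    validate_plate,
    viability_percent,
)
from isobolo.errors import (
    DegenerateWindowError,
    InvalidControlError,
    NonInvertibleCurveError,
    RankDeficiencyError,
)

finite_pct = st.floats(min_value=-500, max_value=500, allow_nan=False)


@pytest.mark.parametrize(
    "treatment,control,expected",
    [(0.5, 0.5, 100.0), (0.0, 0.5, 0.0), (0.236, 0.5, 47.2)],
)
def test_viability_percent(treatment, control, expected):
    assert viability_percent(treatment, control) == pytest.approx(expected)


def test_viability_rejects_nonpositive_control():
    with pytest.raises(InvalidControlError):
        viability_percent(0.5, 0.0)
    with pytest.raises(InvalidControlError):
        viability_percent(0.5, -1.0)


@pytest.mark.parametrize(
    "viability,expected", [(100.0, 0.0), (0.0, 100.0), (88.18, 11.82)]
)
def test_lethality_percent(viability, expected):
    assert lethality_percent(viability) == pytest.approx(expected)


@given(v=finite_pct)
def test_viability_lethality_conservation(v):
    assert v + lethality_percent(v) == pytest.approx(100.0)


@pytest.mark.parametrize(
    "treated,ogdr,expected",
    [(47.19, 47.19, 0.0), (89.37, 47.19, 42.18), (100.0, 47.19, 52.81)],
)
def test_cytoprotection_percent(treated, ogdr, expected):
    assert cytoprotection_percent(treated, ogdr) == pytest.approx(expected)


@given(a=finite_pct, b=finite_pct)
def test_cytoprotection_antisymmetric(a, b):
    assert cytoprotection_percent(a, b) == pytest.approx(-cytoprotection_percent(b, a))


@pytest.mark.parametrize(
    "od_t,od_b,od_m,expected",
    [(0.1, 0.1, 1.1, 0.0), (1.1, 0.1, 1.1, 100.0), (0.6, 0.1, 1.1, 50.0)],
)
def test_ldh_cytotoxicity(od_t, od_b, od_m, expected):
    assert ldh_cytotoxicity_percent(od_t, od_b, od_m) == pytest.approx(expected)


def test_ldh_degenerate_window():
    with pytest.raises(DegenerateWindowError):
        ldh_cytotoxicity_percent(0.5, 1.0, 1.0)


@given(
    od_t=st.floats(0.1, 1.0),
    shift=st.floats(-0.5, 2.0),
)
@settings(max_examples=50)
def test_ldh_affine_invariance(od_t, shift):
    base = ldh_cytotoxicity_percent(od_t, 0.1, 1.1)
    shifted = ldh_cytotoxicity_percent(od_t + shift, 0.1 + shift, 1.1 + shift)
    assert shifted == pytest.approx(base, abs=1e-9)


class TestStandardCurve:
    def test_exact_line(self):
        curve = fit_standard_curve([(0, 0), (1, 2), (2, 4)])
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_closed_form_ols(self):
        curve = fit_standard_curve([(0, 0.05), (5, 1.05), (10, 2.05)], analyte="pNA")
        assert curve.slope == pytest.approx(0.2)
        assert curve.intercept == pytest.approx(0.05)

    def test_degenerate_inputs(self):
        with pytest.raises(RankDeficiencyError):
            fit_standard_curve([(1, 0.2), (1, 0.4)])
        with pytest.raises(RankDeficiencyError):
            fit_standard_curve([(0, 1), (10, 1)])  # zero slope

    def test_inverse_quantification(self):
        curve = fit_standard_curve([(0, 0.05), (5, 1.05), (10, 2.05)])
        assert quantify_from_curve(curve, 1.05) == pytest.approx(5.0)
        curve.slope, curve.intercept = 2.0, 0.0
        assert quantify_from_curve(curve, 4.0) == pytest.approx(2.0)

    def test_negative_quantification_warns(self):
        curve = fit_standard_curve([(0, 1.0), (1, 3.0)])  # slope 2, intercept 1
        with pytest.warns(UserWarning, match="negative"):
            assert quantify_from_curve(curve, 0.0) == pytest.approx(-0.5)

    def test_non_invertible(self):
        curve = fit_standard_curve([(0, 0.0), (1, 2.0)])
        curve.slope = 0.0
        with pytest.raises(NonInvertibleCurveError):
            quantify_from_curve(curve, 1.0)

    @given(conc=st.floats(0.01, 100), slope=st.floats(0.1, 10), intercept=st.floats(-1, 1))
    @settings(max_examples=50)
    def test_round_trip_identity(self, conc, slope, intercept):
        curve = fit_standard_curve([(0, intercept), (1, slope + intercept)])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert quantify_from_curve(curve, curve.predict(conc)) == pytest.approx(
                conc, rel=1e-9, abs=1e-9
            )


class TestPercentOfControl:
    def test_identity(self):
        mean, sem, n = percent_of_control([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (mean, sem, n) == (pytest.approx(100.0), pytest.approx(0.0), 3)

    def test_doubling(self):
        mean, _, _ = percent_of_control([2.0, 2.0], [1.0, 1.0])
        assert mean == pytest.approx(200.0)

    def test_ros_fold_change(self):
        # OGD/R raises the ROS signal ~1.737-fold over control
        mean, _, _ = percent_of_control([1.737], [1.0])
        assert mean == pytest.approx(173.7)

    def test_empty_control(self):
        with pytest.raises(InvalidControlError):
            percent_of_control([1.0], [])


class TestComputeEndpoints:
    def test_mtt_viability_and_cytoprotection(self, additive_experiment):
        table = compute_endpoints(additive_experiment.plate, assay="mtt")
        viab = table[table["endpoint"] == "viability_pct"]
        assert (viab["n"] == 9).all()
        ogdr = viab[viab["group"] == "ogdr"]["value"].iloc[0]
        assert ogdr == pytest.approx(47.19, abs=5.0)
        # lethality complements viability row-by-row
        leth = table[table["endpoint"] == "lethality_pct"]
        merged = viab.merge(leth, on=["group", "drug_id", "concentration_uM"])
        assert np.allclose(merged["value_x"] + merged["value_y"], 100.0)
        # cytoprotection anchored to the untreated OGD/R group
        cyto = table[table["endpoint"] == "cytoprotection_pct"]
        sub = viab.merge(cyto, on=["group", "drug_id", "concentration_uM"])
        assert np.allclose(sub["value_y"], sub["value_x"] - ogdr)

    def test_control_normalises_to_100(self, noiseless_experiment):
        table = compute_endpoints(noiseless_experiment.plate, assay="mtt")
        control = table[
            (table["group"] == "control") & (table["endpoint"] == "viability_pct")
        ]
        assert control["value"].iloc[0] == pytest.approx(100.0)

    def test_ldh_endpoint(self, small_ldh_plate):
        table = compute_endpoints(small_ldh_plate, assay="ldh")
        assert table["endpoint"].unique().tolist() == ["ldh_cytotoxicity_pct"]
        assert table["value"].iloc[0] == pytest.approx(50.0)

    def test_ldh_requires_blank_and_maximum(self, small_ldh_plate):
        broken = small_ldh_plate[small_ldh_plate["group"] != "blank"]
        with pytest.raises(ValueError, match="blank"):
            validate_plate(broken)
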
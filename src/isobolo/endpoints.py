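"""Plate-signal -> derived-endpoint math for cytoprotection experiments.

Raw optical-density / fluorescence wells (long format, one row per well) are
converted into the endpoints used throughout the analysis: viability % and
lethality % (MTT), cytoprotection % relative to the untreated OGD/R group,
LDH cytotoxicity %, percent-of-control readouts (ROS, GSH, caspase-3) and
linear standard-curve quantification (GSH, pNA).

Replicates are aggregated by arithmetic mean; dispersion is reported as the
standard error of the mean (sd/sqrt(n)). Viability above 100% is reported
as-is and only clipped later, at the dose-response fitting stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateWindowError,
    InvalidControlError,
    NonInvertibleCurveError,
    RankDeficiencyError,
)

GROUPS = ("control", "ogdr", "ogdr_treated", "blank", "maximum_release")
ASSAYS = ("mtt", "ldh", "ros", "gsh", "caspase3")

#: column order of the long-format plate table (one well per row)
PLATE_COLUMNS = ["group", "drug_id", "concentration_uM", "replicate", "assay", "signal"]

#: column order of the derived endpoint table
ENDPOINT_COLUMNS = ["group", "drug_id", "concentration_uM", "endpoint", "value", "sem", "n"]


# ---------------------------------------------------------------------------
# plate table I/O and validation
# ---------------------------------------------------------------------------

def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Check a plate table against its structural invariants.

    Returns the table unchanged on success so the call can be chained.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    bad_groups = set(plate["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown groups: {sorted(bad_groups)}")
    bad_assays = set(plate["assay"]) - set(ASSAYS)
    if bad_assays:
        raise ValueError(f"unknown assays: {sorted(bad_assays)}")
    conc = plate["concentration_uM"].to_numpy(float)
    if not np.all(np.isfinite(conc)) or (conc < 0).any():
        raise ValueError("concentrations must be finite and >= 0")
    sig = plate["signal"].to_numpy(float)
    if not np.all(np.isfinite(sig)) or (sig < 0).any():
        raise ValueError("signals must be finite and >= 0")
    ldh = plate[plate["assay"] == "ldh"]
    if len(ldh):
        if not (ldh["group"] == "blank").any() or not (ldh["group"] == "maximum_release").any():
            raise ValueError("ldh assay requires blank and maximum_release wells")
    return plate


def read_plate_csv(path) -> pd.DataFrame:
    """Read and validate a long-format plate CSV (one well per row)."""
    plate = pd.read_csv(path, dtype={"group": str, "drug_id": str, "assay": str})
    return validate_plate(plate)


def write_plate_csv(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, index=False, columns=PLATE_COLUMNS)


# ---------------------------------------------------------------------------
# scalar endpoint formulas
# ---------------------------------------------------------------------------

def viability_percent(signal_treatment: float, signal_control: float) -> float:
    """Cell viability as percent of the control-group signal.

    ``100 * signal_treatment / signal_control``; values above 100 are
    reported as-is.
    """
    if not np.all(np.asarray(signal_control) > 0):
        raise InvalidControlError("control signal must be > 0")
    if np.any(np.asarray(signal_treatment) < 0):
        raise ValueError("treatment signal must be >= 0")
    return 100.0 * signal_treatment / signal_control


def lethality_percent(viability: float) -> float:
    """Lethality % = 100 - viability %."""
    return 100.0 - viability


def cytoprotection_percent(viability_treatment: float, viability_ogdr: float) -> float:
    """Cytoprotection % = treated viability % minus untreated OGD/R viability %.

    Negative values (treatment worse than the insult alone) are allowed.
    """
    return viability_treatment - viability_ogdr


def ldh_cytotoxicity_percent(od_treatment: float, od_blank: float, od_maximum: float) -> float:
    """LDH release as percent of the blank-to-maximum window.

    ``100 * (OD_treatment - OD_blank) / (OD_maximum - OD_blank)``. Invariant
    under adding a constant to all three ODs.
    """
    if not np.all(np.asarray(od_maximum) > np.asarray(od_blank)):
        raise DegenerateWindowError("maximum-release OD must exceed blank OD")
    return 100.0 * (od_treatment - od_blank) / (od_maximum - od_blank)


# ---------------------------------------------------------------------------
# standard curves
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve:
    """Linear calibration ``signal = slope * concentration + intercept``."""

    analyte: str
    points: list[tuple[float, float]] = field(repr=False)
    slope: float = 0.0
    intercept: float = 0.0
    r_squared: float = 0.0

    def predict(self, concentration: float) -> float:
        return self.slope * np.asarray(concentration) + self.intercept


def fit_standard_curve(points, analyte: str = "") -> StandardCurve:
    """Ordinary least-squares line through (known concentration, signal) pairs."""
    pts = [(float(c), float(s)) for c, s in points]
    conc = np.array([p[0] for p in pts])
    sig = np.array([p[1] for p in pts])
    if len(np.unique(conc)) < 2:
        raise RankDeficiencyError("need >= 2 distinct concentrations")
    res = stats.linregress(conc, sig)
    if res.slope == 0:
        raise RankDeficiencyError("fitted slope is zero; curve is not invertible")
    return StandardCurve(
        analyte=analyte,
        points=pts,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def quantify_from_curve(curve: StandardCurve, signal: float) -> float:
    """Invert a standard curve: concentration = (signal - intercept) / slope.

    Negative results (signal below the blank intercept) are returned with a
    warning, not clipped.
    """
    if curve.slope == 0:
        raise NonInvertibleCurveError("slope is zero")
    value = (signal - curve.intercept) / curve.slope
    if np.any(np.asarray(value) < 0):
        warnings.warn(
            f"quantified {curve.analyte or 'analyte'} concentration is negative "
            "(signal below blank); extrapolation outside the calibrated range",
            UserWarning,
            stacklevel=2,
        )
    return value


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------

def _mean_sem(values: np.ndarray) -> tuple[float, float, int]:
    values = np.asarray(values, float)
    n = len(values)
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem, n


def percent_of_control(values, control_values) -> tuple[float, float, int]:
    """Per-group mean +/- SEM of 100 * value / mean(control).

    The control group itself maps to 100 with its own SEM.
    """
    control_values = np.asarray(control_values, float)
    if control_values.size == 0:
        raise InvalidControlError("empty control group")
    cmean = control_values.mean()
    if cmean <= 0:
        raise InvalidControlError("control mean must be > 0")
    return _mean_sem(100.0 * np.asarray(values, float) / cmean)


# ---------------------------------------------------------------------------
# plate -> endpoint table
# ---------------------------------------------------------------------------

def compute_endpoints(plate: pd.DataFrame, assay: str = "mtt") -> pd.DataFrame:
    """Reduce a plate table to the derived endpoints for one assay.

    * ``mtt``: viability % (all groups), lethality %, and cytoprotection %
      relative to the mean viability of the untreated OGD/R group.
    * ``ldh``: LDH cytotoxicity % against the averaged blank / maximum wells.
    * ``ros`` / ``gsh`` / ``caspase3``: percent of the control group.

    Returns a long EndpointTable DataFrame (see :data:`ENDPOINT_COLUMNS`).
    """
    validate_plate(plate)
    sub = plate[plate["assay"] == assay]
    if sub.empty:
        raise ValueError(f"no wells for assay {assay!r}")
    rows: list[dict] = []

    if assay == "mtt":
        control = sub[sub["group"] == "control"]["signal"].to_numpy(float)
        if control.size == 0 or control.mean() <= 0:
            raise InvalidControlError("mtt endpoints need a control group with positive mean signal")
        cmean = control.mean()
        cells = sub[~sub["group"].isin(["blank", "maximum_release"])]
        grouped = cells.groupby(["group", "drug_id", "concentration_uM"], sort=True)
        viability: dict[tuple, tuple[float, float, int]] = {}
        for key, g in grouped:
            viability[key] = _mean_sem(100.0 * g["signal"].to_numpy(float) / cmean)
        ogdr_rows = [v for k, v in viability.items() if k[0] == "ogdr"]
        v_ogdr, sem_ogdr = (ogdr_rows[0][0], ogdr_rows[0][1]) if ogdr_rows else (np.nan, np.nan)
        for (group, drug, conc), (mean, sem, n) in viability.items():
            rows.append(dict(group=group, drug_id=drug, concentration_uM=conc,
                             endpoint="viability_pct", value=mean, sem=sem, n=n))
            rows.append(dict(group=group, drug_id=drug, concentration_uM=conc,
                             endpoint="lethality_pct", value=lethality_percent(mean), sem=sem, n=n))
            if group == "ogdr_treated" and np.isfinite(v_ogdr):
                rows.append(dict(group=group, drug_id=drug, concentration_uM=conc,
                                 endpoint="cytoprotection_pct",
                                 value=cytoprotection_percent(mean, v_ogdr),
                                 sem=float(np.hypot(sem, sem_ogdr)), n=n))

    elif assay == "ldh":
        blank = sub[sub["group"] == "blank"]["signal"].to_numpy(float).mean()
        maximum = sub[sub["group"] == "maximum_release"]["signal"].to_numpy(float).mean()
        cells = sub[~sub["group"].isin(["blank", "maximum_release"])]
        for (group, drug, conc), g in cells.groupby(["group", "drug_id", "concentration_uM"], sort=True):
            pct = ldh_cytotoxicity_percent(g["signal"].to_numpy(float), blank, maximum)
            mean, sem, n = _mean_sem(pct)
            rows.append(dict(group=group, drug_id=drug, concentration_uM=conc,
                             endpoint="ldh_cytotoxicity_pct", value=mean, sem=sem, n=n))

    else:  # ros / gsh / caspase3 readouts, expressed as percent of control
        control = sub[sub["group"] == "control"]["signal"].to_numpy(float)
        for (group, drug, conc), g in sub.groupby(["group", "drug_id", "concentration_uM"], sort=True):
            mean, sem, n = percent_of_control(g["signal"].to_numpy(float), control)
            rows.append(dict(group=group, drug_id=drug, concentration_uM=conc,
                             endpoint="pct_of_control", value=mean, sem=sem, n=n))

    return pd.DataFrame(rows, columns=ENDPOINT_COLUMNS)


def write_endpoint_csv(endpoints: pd.DataFrame, path) -> None:
    endpoints.to_csv(path, index=False, columns=ENDPOINT_COLUMNS)
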
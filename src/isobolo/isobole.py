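"""Loewe isobolographic synergy assessment for a fixed-ratio mixture.

Given monotherapy potencies EC50_A and EC50_B and a mixture ray at EC50
fraction f, the theoretical additive potency of the mixture is

    EC50T = f * EC50_A + (1 - f) * EC50_B

with SEM by independent linear error propagation. The experimentally fitted
mixture potency EC50E is compared to EC50T by Welch's t-test, and the
interaction index

    I = EC50E / EC50T

classifies the interaction (Tallarida): I < 1 synergy, I = 1 additivity,
I > 1 antagonism — with the call additionally requiring the t-test to reject
equality, so a ratio statistically indistinguishable from the additivity
line stays "additive". The additivity index of any concentration pair,

    i = C_A / EC50_A + C_B / EC50_B,

equals 1 exactly for points on the additivity line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import MixtureDesign
from .dose_response import PotencyEstimate
from .errors import DegenerateVarianceError

CLASSIFICATIONS = ("synergistic", "additive", "antagonistic")


def theoretical_additive_ec50(
    est_a: PotencyEstimate, est_b: PotencyEstimate, f_a: float
) -> PotencyEstimate:
    """Additive-theory mixture potency EC50T = f*EC50_A + (1-f)*EC50_B.

    SEM = sqrt(f^2 sem_A^2 + (1-f)^2 sem_B^2) (independent errors); the 95%
    CI uses the normal quantile on that composite SEM.
    """
    if est_a.value <= 0 or est_b.value <= 0:
        raise ValueError("potency inputs must be > 0")
    if not 0.0 <= f_a <= 1.0:
        raise ValueError("f_a must be in [0, 1]")
    value = f_a * est_a.value + (1.0 - f_a) * est_b.value
    sem = float(np.sqrt((f_a * est_a.sem) ** 2 + ((1.0 - f_a) * est_b.sem) ** 2))
    return PotencyEstimate(
        kind="EC50",
        p_level=0.5,
        value=value,
        sem=sem,
        ci95=(value - 1.96 * sem, value + 1.96 * sem),
        drug_id=f"{est_a.drug_id}+{est_b.drug_id} (theoretical, f={f_a:g})",
    )


def additivity_index(c_a: float, c_b: float, ec50_a: float, ec50_b: float) -> float:
    """i = C_A/EC50_A + C_B/EC50_B; 1 on the Loewe additivity line."""
    if ec50_a <= 0 or ec50_b <= 0:
        raise ValueError("EC50s must be > 0")
    if c_a < 0 or c_b < 0:
        raise ValueError("concentrations must be >= 0")
    return c_a / ec50_a + c_b / ec50_b


def interaction_index(ec50_e: float, ec50_t: float) -> float:
    """I = EC50E / EC50T (experimental over theoretical mixture potency)."""
    if ec50_e <= 0 or ec50_t <= 0:
        raise ValueError("potencies must be > 0")
    return ec50_e / ec50_t


def compare_potencies(
    est_e: PotencyEstimate, est_t: PotencyEstimate, n_e: int = 9, n_t: int = 9
) -> tuple[float, float, float]:
    """Welch's t-test of EC50T vs EC50E from (value, SEM, n) summaries.

    t = (EC50T - EC50E) / sqrt(sem_T^2 + sem_E^2); degrees of freedom by
    Welch-Satterthwaite; two-sided p.
    """
    if n_e < 2 or n_t < 2:
        raise ValueError("need n >= 2 per group")
    se2_e, se2_t = est_e.sem**2, est_t.sem**2
    if se2_e + se2_t == 0:
        raise DegenerateVarianceError("both SEMs are zero")
    t = (est_t.value - est_e.value) / np.sqrt(se2_e + se2_t)
    denom = se2_e**2 / (n_e - 1) + se2_t**2 / (n_t - 1)
    dof = (se2_e + se2_t) ** 2 / denom if denom > 0 else float(min(n_e, n_t) - 1)
    p = 2.0 * float(stats.t.sf(abs(t), dof))
    return float(t), float(dof), p


def classify_interaction(interaction_idx: float, p_value: float, alpha: float = 0.05) -> str:
    """Synergy call from the interaction index and the t-test p-value.

    Synergistic iff I < 1 AND p < alpha; antagonistic iff I > 1 AND
    p < alpha; otherwise additive (the ratio is statistically
    indistinguishable from the additivity line).
    """
    if interaction_idx <= 0:
        raise ValueError("interaction index must be > 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if p_value < alpha:
        if interaction_idx < 1.0:
            return "synergistic"
        if interaction_idx > 1.0:
            return "antagonistic"
    return "additive"


@dataclass
class InteractionAssessment:
    """Full synergy verdict for one fixed-ratio mixture."""

    ec50_t: PotencyEstimate
    ec50_e: PotencyEstimate
    f_a: float
    additivity_index_i: float
    interaction_index_I: float
    t_statistic: float
    dof: float
    p_value: float
    classification: str

    @property
    def fold_reduction(self) -> float:
        """How many-fold less total drug the mixture needs vs additivity."""
        return 1.0 / self.interaction_index_I

    def to_dict(self) -> dict:
        return {
            "f_a": self.f_a,
            "ec50_t": {"value": self.ec50_t.value, "sem": self.ec50_t.sem},
            "ec50_e": {"value": self.ec50_e.value, "sem": self.ec50_e.sem},
            "additivity_index": self.additivity_index_i,
            "interaction_index": self.interaction_index_I,
            "fold_reduction": self.fold_reduction,
            "t": self.t_statistic,
            "dof": self.dof,
            "p_value": self.p_value,
            "classification": self.classification,
        }


def assess_interaction(
    est_a: PotencyEstimate,
    est_b: PotencyEstimate,
    est_e: PotencyEstimate,
    f_a: float,
    n_e: int = 9,
    n_t: int = 9,
    alpha: float = 0.05,
    ec50_t: PotencyEstimate | None = None,
) -> InteractionAssessment:
    """Assemble the complete assessment for one ray.

    ``ec50_t`` may be supplied directly (e.g. with a user-chosen SEM);
    otherwise it is computed from the monotherapy potencies by
    :func:`theoretical_additive_ec50`.
    """
    if ec50_t is None:
        ec50_t = theoretical_additive_ec50(est_a, est_b, f_a)
    # additivity index of the experimental mixture point, decomposed on the ray
    c_a = f_a * est_a.value * est_e.value / ec50_t.value
    c_b = (1.0 - f_a) * est_b.value * est_e.value / ec50_t.value
    idx_i = additivity_index(c_a, c_b, est_a.value, est_b.value)
    idx_I = interaction_index(est_e.value, ec50_t.value)
    t, dof, p = compare_potencies(est_e, ec50_t, n_e=n_e, n_t=n_t)
    return InteractionAssessment(
        ec50_t=ec50_t,
        ec50_e=est_e,
        f_a=f_a,
        additivity_index_i=idx_i,
        interaction_index_I=idx_I,
        t_statistic=t,
        dof=dof,
        p_value=p,
        classification=classify_interaction(idx_I, p, alpha=alpha),
    )


@dataclass
class IsobologramGeometry:
    """Coordinates for a 50%-effect isobologram, drug A on y, drug B on x."""

    axis_y: tuple[str, float, float]  # (drug, EC50, SEM) of drug A
    axis_x: tuple[str, float, float]  # (drug, EC50, SEM) of drug B
    line_start: tuple[float, float]  # (x=0, y=EC50_A)
    line_end: tuple[float, float]  # (x=EC50_B, y=0)
    points: list[dict]  # {label, c_b, c_a}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"element": "axis_a", "x_conc_b_uM": 0.0, "y_conc_a_uM": self.axis_y[1]},
            {"element": "axis_b", "x_conc_b_uM": self.axis_x[1], "y_conc_a_uM": 0.0},
            {"element": "line_start", "x_conc_b_uM": self.line_start[0], "y_conc_a_uM": self.line_start[1]},
            {"element": "line_end", "x_conc_b_uM": self.line_end[0], "y_conc_a_uM": self.line_end[1]},
        ]
        for pt in self.points:
            rows.append(
                {"element": pt["label"], "x_conc_b_uM": pt["c_b"], "y_conc_a_uM": pt["c_a"]}
            )
        return pd.DataFrame(rows, columns=["element", "x_conc_b_uM", "y_conc_a_uM"])


def isobologram_coordinates(
    est_a: PotencyEstimate,
    est_b: PotencyEstimate,
    assessment: InteractionAssessment,
    design: MixtureDesign,
) -> IsobologramGeometry:
    """Additivity line plus theoretical and experimental mixture points.

    The theoretical point sits at the ray's design components; the
    experimental point is EC50E decomposed along the same ray.
    """
    ca_t, cb_t = design.c_a, design.c_b
    ca_e, cb_e = design.components_at_total(assessment.ec50_e.value)
    return IsobologramGeometry(
        axis_y=(design.drug_a, est_a.value, est_a.sem),
        axis_x=(design.drug_b, est_b.value, est_b.sem),
        line_start=(0.0, est_a.value),
        line_end=(est_b.value, 0.0),
        points=[
            {"label": "theoretical_point", "c_a": ca_t, "c_b": cb_t},
            {"label": "experimental_point", "c_a": ca_e, "c_b": cb_e},
        ],
    )
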
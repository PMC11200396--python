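"""Synthetic OGD/R plate experiments with a controllable Loewe interaction.

The generator emulates the statistical structure the analysis assumes:

* a control arm at 100% viability and an untreated OGD/R arm at a reduced
  baseline (default 47.19% of control),
* monotherapy cytoprotection arms following Hill curves on the two drugs'
  8-point concentration series,
* fixed-ratio mixture design points and a geometric dilution series along
  one ray, whose joint effect follows a Loewe model with a single scalar
  interaction parameter psi (1 = additive, < 1 = synergistic, > 1 =
  antagonistic),
* Gaussian well noise on the raw signal scale, nine replicates per group.

With the ray through the additive design point, the mixture's true 50%
total concentration is exactly psi * (f * EC50_A + (1 - f) * EC50_B), so
the pipeline's interaction index estimates psi directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq

from .design import MixtureDesign, dilution_series, fixed_ratio_components, ratio_label
from .endpoints import PLATE_COLUMNS, validate_plate

_EFFECT_EPS = 1e-12


class SimulationConfig(BaseModel):
    """True curve parameters, interaction parameter, noise model and seed.

    Defaults mirror the study design the analysis targets: dapsone-like
    drug A (EC50 10.06 uM) and cannabidiol-like drug B (EC50 0.07 uM),
    OGD/R baseline 47.19% of control, 8-point monotherapy series, nine
    replicates, 5% Gaussian signal noise, and a 1:4 (f = 0.25) mixture ray.
    """

    drug_a: str = "DDS"
    drug_b: str = "CBD"
    ec50_a: float = Field(default=10.06, gt=0)
    ec50_b: float = Field(default=0.07, gt=0)
    hill_a: float = Field(default=2.0, gt=0)
    hill_b: float = Field(default=2.0, gt=0)
    psi: float = Field(default=1.0, gt=0)
    viability_control: float = Field(default=100.0, gt=0)
    viability_ogdr: float = Field(default=47.19, gt=0)
    max_protection: float = Field(default=1.0, gt=0, le=1.0)
    noise_sd: float = Field(default=5.0, ge=0)  # percent of control signal
    n_replicates: int = Field(default=9, ge=1)
    concentrations_a: list[float] = Field(
        default=[6.04, 7.65, 9.66, 12.08, 15.30, 19.33, 24.16, 30.6]
    )
    concentrations_b: list[float] = Field(
        default=[0.047, 0.06, 0.07, 0.09, 0.11, 0.15, 0.18, 0.24]
    )
    candidate_f_a: list[float] = Field(default=[0.5, 0.25, 0.75])
    ray_f_a: float = Field(default=0.25, ge=0.0, le=1.0)
    dilution_factor: float = Field(default=2.0, gt=1.0)
    dilution_n_each_side: int = Field(default=4, ge=1)
    exclude_center: bool = True
    control_signal: float = Field(default=0.5, gt=0)  # OD of healthy control wells
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.viability_control <= self.viability_ogdr:
            raise ValueError("viability_control must exceed viability_ogdr")
        if any(c <= 0 for c in self.concentrations_a + self.concentrations_b):
            raise ValueError("concentration series must be positive")
        return self


def monotherapy_effect(concentration, ec50: float, hill: float):
    """Hill effect fraction c^h / (c^h + EC50^h); 0.5 at c = EC50."""
    c = np.asarray(concentration, float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ec50) ** hill, 0.0)
    return ratio / (1.0 + ratio)


def _inverse_hill(effect: float, ec50: float, hill: float) -> float:
    """Concentration producing a given monotherapy effect fraction."""
    return ec50 * (effect / (1.0 - effect)) ** (1.0 / hill)


def loewe_combination_effect(c_a: float, c_b: float, config: SimulationConfig) -> float:
    """Joint effect of (c_a, c_b) under the Loewe model with parameter psi.

    Solves c_a/ECe_A + c_b/ECe_B = psi for the effect fraction e, where
    ECe_X = EC50_X * (e/(1-e))^(1/h_X) is the inverse Hill curve. The left
    side decreases monotonically in e, so the root is unique; it is found
    by bracketed root-finding on e in (eps, 1-eps). With one concentration
    zero and psi = 1 this reduces exactly to the monotherapy Hill effect.
    """
    if c_a < 0 or c_b < 0:
        raise ValueError("concentrations must be >= 0")
    if c_a == 0 and c_b == 0:
        return 0.0

    def excess(e: float) -> float:
        total = 0.0
        if c_a > 0:
            total += c_a / _inverse_hill(e, config.ec50_a, config.hill_a)
        if c_b > 0:
            total += c_b / _inverse_hill(e, config.ec50_b, config.hill_b)
        return total - config.psi

    lo, hi = _EFFECT_EPS, 1.0 - _EFFECT_EPS
    if excess(lo) < 0:  # even the weakest effect over-satisfies: boundary
        return lo
    if excess(hi) > 0:
        return hi
    return float(brentq(excess, lo, hi, xtol=1e-12, rtol=1e-12))


def viability_from_effect(effect, config: SimulationConfig):
    """Map an effect fraction onto the viability scale.

    viability = v_OGDR + e * max_protection * (v_control - v_OGDR).
    """
    gap = config.viability_control - config.viability_ogdr
    return config.viability_ogdr + np.asarray(effect, float) * config.max_protection * gap


@dataclass
class SimulatedExperiment:
    """A generated plate plus the ground truth that produced it."""

    plate: pd.DataFrame
    truth: SimulationConfig
    derived_truth: dict

    def write(self, out_dir) -> tuple[Path, Path]:
        """Write plate CSV + truth-sidecar JSON; returns both paths."""
        import json

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        plate_path = out_dir / "plate.csv"
        truth_path = out_dir / "truth.json"
        self.plate.to_csv(plate_path, index=False, columns=PLATE_COLUMNS)
        payload = {"config": self.truth.model_dump(), "derived_truth": self.derived_truth}
        truth_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return plate_path, truth_path


def _wells(group, drug_id, concentration, viability, config, rng) -> list[dict]:
    signal_mean = viability / 100.0 * config.control_signal
    noise = rng.normal(0.0, config.noise_sd / 100.0 * config.control_signal,
                       size=config.n_replicates)
    signals = np.maximum(signal_mean + noise, 0.0)
    return [
        dict(group=group, drug_id=drug_id, concentration_uM=concentration,
             replicate=r + 1, assay="mtt", signal=float(s))
        for r, s in enumerate(signals)
    ]


def ray_design(config: SimulationConfig) -> MixtureDesign:
    """The fixed-ratio ray (at true EC50s) whose dilution series is simulated."""
    return fixed_ratio_components(
        config.ec50_a, config.ec50_b, config.ray_f_a,
        drug_a=config.drug_a, drug_b=config.drug_b,
    )


def true_mixture_ec50(config: SimulationConfig) -> float:
    """Closed-form true 50% total concentration on the simulated ray.

    At e = 0.5 the inverse Hill equals the EC50 for any slope, so the Loewe
    condition gives total = psi / (p_a/EC50_A + p_b/EC50_B), which on the
    ray through the additive design point is exactly psi * EC50T.
    """
    design = ray_design(config)
    p_a, p_b = design.c_a / design.total, design.c_b / design.total
    return config.psi / (p_a / config.ec50_a + p_b / config.ec50_b)


def simulate_ogdr_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate one complete plate experiment; deterministic given the seed.

    Arms: control and untreated OGD/R (concentration 0), both monotherapy
    series (Hill curves), candidate fixed-ratio design points, and the
    geometric dilution series along the configured ray (Loewe model with
    psi). Per-arm random streams are spawned deterministically from the
    root seed, so arms are independently reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(child) for child in ss.spawn(6)]
    rng_control, rng_ogdr, rng_a, rng_b, rng_cand, rng_ray = streams
    rows: list[dict] = []

    rows += _wells("control", "none", 0.0, config.viability_control, config, rng_control)
    rows += _wells("ogdr", "none", 0.0, config.viability_ogdr, config, rng_ogdr)

    for conc in config.concentrations_a:
        e = float(monotherapy_effect(conc, config.ec50_a, config.hill_a))
        rows += _wells("ogdr_treated", config.drug_a, conc,
                       float(viability_from_effect(e, config)), config, rng_a)
    for conc in config.concentrations_b:
        e = float(monotherapy_effect(conc, config.ec50_b, config.hill_b))
        rows += _wells("ogdr_treated", config.drug_b, conc,
                       float(viability_from_effect(e, config)), config, rng_b)

    for f_a in config.candidate_f_a:
        d = fixed_ratio_components(config.ec50_a, config.ec50_b, f_a,
                                   drug_a=config.drug_a, drug_b=config.drug_b)
        e = loewe_combination_effect(d.c_a, d.c_b, config)
        rows += _wells("ogdr_treated", f"mix_{ratio_label(f_a)}", d.total,
                       float(viability_from_effect(e, config)), config, rng_cand)

    design = ray_design(config)
    series = dilution_series(
        design, design.total,
        n_each_side=config.dilution_n_each_side,
        factor=config.dilution_factor,
        exclude_center=config.exclude_center,
    )
    for total, (c_a, c_b) in zip(series.totals, series.components()):
        e = loewe_combination_effect(c_a, c_b, config)
        rows += _wells("ogdr_treated", "mixture", float(total),
                       float(viability_from_effect(e, config)), config, rng_ray)

    plate = validate_plate(pd.DataFrame(rows, columns=PLATE_COLUMNS))
    ec50t_true = design.total
    ec50e_true = true_mixture_ec50(config)
    return SimulatedExperiment(
        plate=plate,
        truth=config,
        derived_truth={
            "ec50t_true": ec50t_true,
            "ec50e_true": ec50e_true,
            "I_true": ec50e_true / ec50t_true,
        },
    )
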
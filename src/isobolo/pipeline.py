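"""End-to-end orchestration: plate -> endpoints -> fits -> ray design -> synergy.

Two input routes produce the same :class:`AnalysisReport`:

* the full route reads a long-format plate CSV (or an in-memory simulated
  experiment), derives endpoints, fits both monotherapy curves and the
  mixture-ray curve, and assesses the interaction;
* the shortcut route accepts pre-computed potency summaries (value +/- SEM)
  from a JSON file and skips straight to the isobole stage.

All stages are deterministic given the config and inputs; the report embeds
a config hash and package version for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .design import MixtureDesign, designs_to_frame, dilution_series, fixed_ratio_components
from .dose_response import (
    PotencyEstimate,
    PotencyFit,
    build_curve_data,
    effective_concentration,
    fit_concentration_response,
    potency_to_dict,
)
from .endpoints import compute_endpoints, read_plate_csv, write_endpoint_csv
from .isobole import (
    InteractionAssessment,
    additivity_index,
    assess_interaction,
    classify_interaction,
    compare_potencies,
    interaction_index,
    isobologram_coordinates,
)
from .simulate import SimulatedExperiment, SimulationConfig, simulate_ogdr_experiment

logger = logging.getLogger("isobolo")


class RunConfig(BaseModel):
    """Analysis configuration; defaults mirror the study design."""

    plate_csv: str | None = None
    potency_json: str | None = None
    drug_a: str = "DDS"
    drug_b: str = "CBD"
    link: str = "probit"
    f_a_candidates: list[float] = Field(default=[0.5, 0.25, 0.75])
    ray_f_a: float = Field(default=0.25, ge=0.0, le=1.0)  # ray the dilution series follows
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    n_e: int = Field(default=9, ge=2)
    n_t: int = Field(default=9, ge=2)
    dilution_factor: float = Field(default=2.0, gt=1.0)
    dilution_n_each_side: int = Field(default=3, ge=1)
    out_dir: str | None = None
    seed: int = 0

    def content_hash(self) -> str:
        """Hash of the analysis parameters (filesystem paths excluded, so
        the same analysis of the same data hashes identically anywhere)."""
        payload = json.dumps(
            self.model_dump(exclude={"plate_csv", "potency_json", "out_dir"}),
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Machine-readable result of one full analysis run."""

    potencies: list[dict]
    designs: list[MixtureDesign]
    chosen_ray: str
    assessment: InteractionAssessment
    ec90_components: dict | None
    isobologram: pd.DataFrame | None
    provenance: dict
    endpoint_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "potencies": self.potencies,
            "designs": designs_to_frame(self.designs).to_dict(orient="records"),
            "chosen_ray": self.chosen_ray,
            "assessment": self.assessment.to_dict(),
            "ec90_components": self.ec90_components,
            "provenance": self.provenance,
        }

    def write(self, out_dir) -> Path:
        """Write report JSON plus design/assessment/isobologram CSV tables."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        designs_to_frame(self.designs).to_csv(out_dir / "combination_designs.csv", index=False)
        pd.DataFrame([self.assessment.to_dict() | {
            "ec50_t": self.assessment.ec50_t.value, "ec50_t_sem": self.assessment.ec50_t.sem,
            "ec50_e": self.assessment.ec50_e.value, "ec50_e_sem": self.assessment.ec50_e.sem,
        }]).to_csv(out_dir / "interaction_assessment.csv", index=False)
        if self.isobologram is not None:
            self.isobologram.to_csv(out_dir / "isobologram_coordinates.csv", index=False)
        if self.endpoint_table is not None:
            write_endpoint_csv(self.endpoint_table, out_dir / "endpoints.csv")
        return report_path


def _stage(name: str):
    """Context manager logging one structured line per pipeline stage."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            status = "failed" if exc[0] else "ok"
            logger.info("stage=%s status=%s elapsed_s=%.3f", name, status,
                        time.perf_counter() - self.t0)
            return False

    return _Ctx()


# ---------------------------------------------------------------------------
# full route (plate data)
# ---------------------------------------------------------------------------

def fit_potencies_from_plate(
    plate: pd.DataFrame, config: RunConfig
) -> tuple[dict[str, tuple[PotencyFit, PotencyEstimate]], pd.DataFrame, float]:
    """Endpoints + monotherapy and mixture-ray EC50 fits from one plate.

    Returns (fits keyed by drug id, endpoint table, OGD/R baseline
    viability). The effect fraction normalises viability between the
    untreated OGD/R baseline and the control ceiling (100%).
    """
    endpoints = compute_endpoints(plate, assay="mtt")
    ogdr = endpoints[(endpoints["group"] == "ogdr") & (endpoints["endpoint"] == "viability_pct")]
    if ogdr.empty:
        raise ValueError("plate has no untreated OGD/R group; cannot anchor cytoprotection")
    baseline = float(ogdr["value"].iloc[0])
    fits: dict[str, tuple[PotencyFit, PotencyEstimate]] = {}
    for drug in (config.drug_a, config.drug_b, "mixture"):
        if not ((endpoints["drug_id"] == drug) & (endpoints["concentration_uM"] > 0)).any():
            continue
        data = build_curve_data(endpoints, drug, "cytoprotection", baseline=baseline, ceiling=100.0)
        fit = fit_concentration_response(data, link=config.link)
        fits[drug] = (fit, effective_concentration(fit, 0.5))
    return fits, endpoints, baseline


def _choose_ray(endpoints: pd.DataFrame) -> str:
    """Label of the candidate mixture with the highest mean cytoprotection."""
    mixes = endpoints[
        endpoints["drug_id"].str.startswith("mix_")
        & (endpoints["endpoint"] == "cytoprotection_pct")
    ]
    if mixes.empty:
        return ""
    best = mixes.loc[mixes["value"].idxmax()]
    return str(best["drug_id"]).removeprefix("mix_")


def analyze_experiment(
    plate: pd.DataFrame, config: RunConfig
) -> AnalysisReport:
    """Full analysis of one plate table (already in memory)."""
    with _stage("endpoints+fits"):
        fits, endpoints, baseline = fit_potencies_from_plate(plate, config)
    for drug in (config.drug_a, config.drug_b, "mixture"):
        if drug not in fits:
            raise ValueError(f"plate lacks a fittable concentration series for {drug!r}")
    fit_a, est_a = fits[config.drug_a]
    fit_b, est_b = fits[config.drug_b]
    fit_e, est_e = fits["mixture"]

    with _stage("design"):
        designs = [
            fixed_ratio_components(est_a.value, est_b.value, f_a,
                                   drug_a=config.drug_a, drug_b=config.drug_b)
            for f_a in config.f_a_candidates
        ]
        chosen = _choose_ray(endpoints)

    with _stage("isobole"):
        assessment = assess_interaction(
            est_a, est_b, est_e, f_a=config.ray_f_a,
            n_e=config.n_e, n_t=config.n_t, alpha=config.alpha,
        )
        ray = fixed_ratio_components(est_a.value, est_b.value, config.ray_f_a,
                                     drug_a=config.drug_a, drug_b=config.drug_b)
        iso = isobologram_coordinates(est_a, est_b, assessment, ray)
        ec90 = effective_concentration(fit_e, 0.9, kind="ECp")
        c_a90, c_b90 = ray.components_at_total(ec90.value)
        ec90_components = {
            "total_uM": ec90.value, "sem_uM": ec90.sem,
            "c_a_uM": c_a90, "c_b_uM": c_b90,
        }

    return AnalysisReport(
        potencies=[
            potency_to_dict(est_a, fit_a),
            potency_to_dict(est_b, fit_b),
            potency_to_dict(est_e, fit_e),
        ],
        designs=designs,
        chosen_ray=chosen,
        assessment=assessment,
        ec90_components=ec90_components,
        isobologram=iso.to_frame(),
        provenance={
            "version": __version__,
            "config_hash": RunConfig.content_hash(config),
            "seed": config.seed,
            "ogdr_baseline_viability_pct": baseline,
        },
        endpoint_table=endpoints,
    )


# ---------------------------------------------------------------------------
# shortcut route (potency summaries)
# ---------------------------------------------------------------------------

def _estimate_from_record(rec: dict, kind: str = "EC50", drug_id: str = "") -> PotencyEstimate:
    value = float(rec["value_uM"] if "value_uM" in rec else rec["value"])
    sem = float(rec.get("sem_uM", rec.get("sem", 0.0)))
    return PotencyEstimate(kind=kind, p_level=0.5, value=value, sem=sem,
                           ci95=(value - 1.96 * sem, value + 1.96 * sem),
                           drug_id=drug_id or rec.get("drug_id", ""))


def assess_from_potency_records(records: dict, config: RunConfig) -> AnalysisReport:
    """Isobole assessment from pre-computed potency summaries.

    ``records`` needs ``ec50_e`` plus either ``ec50_t`` directly or both
    monotherapy entries ``ec50_a``/``ec50_b`` (each ``{value_uM, sem_uM}``);
    ``f_a`` defaults to the config's ray.
    """
    f_a = float(records.get("f_a", config.ray_f_a))
    est_e = _estimate_from_record(records["ec50_e"], drug_id="mixture")
    est_a = est_b = None
    if "ec50_a" in records and "ec50_b" in records:
        est_a = _estimate_from_record(records["ec50_a"], drug_id=config.drug_a)
        est_b = _estimate_from_record(records["ec50_b"], drug_id=config.drug_b)
    ec50_t = _estimate_from_record(records["ec50_t"], drug_id="theoretical") \
        if "ec50_t" in records else None

    if est_a is not None and est_b is not None:
        assessment = assess_interaction(
            est_a, est_b, est_e, f_a=f_a,
            n_e=config.n_e, n_t=config.n_t, alpha=config.alpha, ec50_t=ec50_t,
        )
        designs = [fixed_ratio_components(est_a.value, est_b.value, f,
                                          drug_a=config.drug_a, drug_b=config.drug_b)
                   for f in config.f_a_candidates]
        ray = fixed_ratio_components(est_a.value, est_b.value, f_a,
                                     drug_a=config.drug_a, drug_b=config.drug_b)
        iso = isobologram_coordinates(est_a, est_b, assessment, ray).to_frame()
        potencies = [potency_to_dict(est_a), potency_to_dict(est_b), potency_to_dict(est_e)]
    else:
        if ec50_t is None:
            raise ValueError("potency records need ec50_t or both monotherapy potencies")
        idx_I = interaction_index(est_e.value, ec50_t.value)
        t, dof, p = compare_potencies(est_e, ec50_t, n_e=config.n_e, n_t=config.n_t)
        assessment = InteractionAssessment(
            ec50_t=ec50_t, ec50_e=est_e, f_a=f_a,
            # the experimental point decomposed on the ray has i identically
            # equal to the interaction index
            additivity_index_i=idx_I,
            interaction_index_I=idx_I,
            t_statistic=t, dof=dof, p_value=p,
            classification=classify_interaction(idx_I, p, alpha=config.alpha),
        )
        designs, iso, potencies = [], None, [potency_to_dict(est_e)]

    return AnalysisReport(
        potencies=potencies,
        designs=designs,
        chosen_ray=records.get("chosen_ray", ""),
        assessment=assessment,
        ec90_components=None,
        isobologram=iso,
        provenance={
            "version": __version__,
            "config_hash": RunConfig.content_hash(config),
            "seed": config.seed,
        },
    )


# ---------------------------------------------------------------------------
# entry points
# ---------------------------------------------------------------------------

def run_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the full pipeline from a RunConfig; writes outputs if out_dir set."""
    if config.potency_json:
        with _stage("load-potencies"):
            records = json.loads(Path(config.potency_json).read_text())
        report = assess_from_potency_records(records, config)
    elif config.plate_csv:
        with _stage("load-plate"):
            plate = read_plate_csv(config.plate_csv)
        report = analyze_experiment(plate, config)
    else:
        raise ValueError("config must provide plate_csv or potency_json")
    if config.out_dir:
        with _stage("write-report"):
            report.write(config.out_dir)
    return report


def run_simulation(config: SimulationConfig, out_dir) -> tuple[Path, Path]:
    """Generate a synthetic experiment and write plate CSV + truth JSON."""
    with _stage("simulate"):
        exp = simulate_ogdr_experiment(config)
    return exp.write(out_dir)


def estimate_interaction(
    experiment: SimulatedExperiment, config: RunConfig | None = None
) -> InteractionAssessment:
    """Convenience: full in-memory pipeline on a simulated experiment."""
    cfg = config or RunConfig(drug_a=experiment.truth.drug_a,
                              drug_b=experiment.truth.drug_b,
                              ray_f_a=experiment.truth.ray_f_a)
    return analyze_experiment(experiment.plate, cfg).assessment
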
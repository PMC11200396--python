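"""Sigmoidal concentration-response fitting and potency estimation.

Effect fractions (0-1) are regressed on log10 concentration through a probit
or logit link.  The fitted line

    link(effect) = intercept + slope * log10(concentration [uM])

yields ``log_ec50 = -intercept / slope`` and, for any fraction p in (0, 1),

    ECp = 10 ** ((link_quantile(p) - intercept) / slope)

with a delta-method standard error propagated from the parameter covariance.
The log10 metameter makes every ECp exactly equivariant under a change of
concentration units.

Because the effects are continuous normalised viability means (not quantal
counts), each per-concentration mean is modelled as Gaussian around the link
curve with variance sigma^2 / n_i (n_i = replicate count): the parameters
maximise the replicate-weighted Gaussian likelihood, i.e. minimise
sum_i n_i (e_i - mu_i)^2.  A binomial-variance weighting would let
near-saturated points dominate and biases EC50 by ~10% at this design;
homoscedastic weighting matches the plate noise and is essentially unbiased.
The residual variance is estimated with k - 2 degrees of freedom and the
95% CI uses the matching t quantile on the log-concentration scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitFailureError, InsufficientDesignError

#: clip for link transforms of observed effects (initialisation only)
EPS = 1e-6

_LINKS = ("probit", "logit")


def _link_quantile(p: float, link: str) -> float:
    if link == "probit":
        return float(stats.norm.ppf(p))
    if link == "logit":
        return float(np.log(p / (1.0 - p)))
    raise ValueError(f"unknown link {link!r}")


def _link_cdf(eta: np.ndarray, link: str) -> np.ndarray:
    if link == "probit":
        return stats.norm.cdf(eta)
    if link == "logit":
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))
    raise ValueError(f"unknown link {link!r}")


def _link_pdf(eta: np.ndarray, link: str) -> np.ndarray:
    """d mu / d eta, used for the Jacobian of the mean curve."""
    if link == "probit":
        return stats.norm.pdf(eta)
    if link == "logit":
        mu = _link_cdf(eta, "logit")
        return mu * (1.0 - mu)
    raise ValueError(f"unknown link {link!r}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CurveData:
    """One drug's (or mixture ray's) concentration-effect points.

    ``effect_fraction`` holds per-concentration mean effects in [0, 1];
    ``n`` the replicate count behind each mean. Mixture rays use the total
    (summed) concentration.
    """

    drug_id: str
    concentration: np.ndarray
    effect_fraction: np.ndarray
    n: np.ndarray
    effect_kind: str = "cytoprotection"  # or "lethality"

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, float)
        self.effect_fraction = np.asarray(self.effect_fraction, float)
        self.n = np.asarray(self.n, int)
        if np.any(self.concentration <= 0):
            raise ValueError("curve concentrations must be > 0 (drop zero-dose controls)")


@dataclass
class PotencyFit:
    """Fitted link-scale line with its covariance.

    ``covariance`` is ordered (intercept, slope); ``scale`` is the
    estimated per-replicate residual variance on the effect scale.
    """

    drug_id: str
    link: str
    slope: float
    intercept: float
    covariance: np.ndarray
    converged: bool
    log_ec50: float
    n_points: int
    scale: float
    effect_kind: str = "cytoprotection"


@dataclass
class PotencyEstimate:
    """A potency (LC50/EC50/ECp) in uM with SEM and 95% CI."""

    kind: str  # "LC50" | "EC50" | "ECp"
    p_level: float
    value: float
    sem: float
    ci95: tuple[float, float]
    drug_id: str = ""

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("potency value must be > 0")
        if self.sem < 0:
            raise ValueError("potency SEM must be >= 0")


# ---------------------------------------------------------------------------
# curve construction
# ---------------------------------------------------------------------------

def build_curve_data(
    endpoints: pd.DataFrame,
    drug_id: str,
    effect_kind: str = "cytoprotection",
    baseline: float = 0.0,
    ceiling: float = 100.0,
) -> CurveData:
    """Map an endpoint table onto a 0-1 effect fraction curve.

    ``effect_fraction = clip((value - baseline) / (ceiling - baseline), 0, 1)``.
    For cytoprotection, pass the viability rows with baseline = untreated
    OGD/R viability and ceiling = control viability (100); for lethality the
    natural scale is baseline 0, ceiling 100.
    """
    if ceiling <= baseline:
        raise ValueError("ceiling must exceed baseline")
    endpoint = {"cytoprotection": "viability_pct", "lethality": "lethality_pct"}[effect_kind]
    sub = endpoints[
        (endpoints["drug_id"] == drug_id)
        & (endpoints["endpoint"] == endpoint)
        & (endpoints["concentration_uM"] > 0)
    ].sort_values("concentration_uM")
    frac = np.clip(
        (sub["value"].to_numpy(float) - baseline) / (ceiling - baseline), 0.0, 1.0
    )
    return CurveData(
        drug_id=drug_id,
        concentration=sub["concentration_uM"].to_numpy(float),
        effect_fraction=frac,
        n=sub["n"].to_numpy(int),
        effect_kind=effect_kind,
    )


# ---------------------------------------------------------------------------
# likelihood (shared by the fitter and by brute-force oracles in tests)
# ---------------------------------------------------------------------------

def log_likelihood(data: CurveData, slope, log_ec50, link: str = "probit"):
    """Replicate-weighted Gaussian log-likelihood kernel at (slope, log_ec50).

    ``-0.5 * sum_i n_i * (e_i - mu_i)^2`` with
    ``mu_i = link_cdf(slope * (log10 c_i - log_ec50))`` — the Gaussian
    log-likelihood up to terms that do not involve (slope, log_ec50), so it
    shares its maximiser with the fit.  Broadcasts over array-valued
    parameters, so a grid search can evaluate it in one call.
    """
    slope = np.asarray(slope, float)[..., None]
    log_ec50 = np.asarray(log_ec50, float)[..., None]
    x = np.log10(data.concentration)
    mu = _link_cdf(slope * (x - log_ec50), link)
    sq = data.n * (data.effect_fraction - mu) ** 2
    return np.squeeze(-0.5 * sq.sum(axis=-1))


def _initial_params(x: np.ndarray, e: np.ndarray, link: str) -> np.ndarray:
    """Deterministic start: least-squares line of the link-transformed
    effects on log10 concentration (the classical first iterate of probit
    analysis)."""
    z = stats.norm.ppf(np.clip(e, EPS, 1 - EPS)) if link == "probit" \
        else np.log(np.clip(e, EPS, 1 - EPS) / np.clip(1 - e, EPS, 1 - EPS))
    slope0, intercept0 = np.polyfit(x, z, 1)
    if slope0 == 0:
        slope0 = 1.0
    return np.array([float(intercept0), float(slope0)])


def fit_concentration_response(data: CurveData, link: str = "probit") -> PotencyFit:
    """Fit effect fraction vs log10 concentration with a probit/logit link.

    Minimises the replicate-weighted residual sum of squares
    sum_i n_i (e_i - mu_i)^2 by Levenberg-Marquardt from a deterministic
    link-scale least-squares start (no random restarts). The parameter
    covariance is sigma_hat^2 (J' W J)^-1 with sigma_hat^2 estimated on
    n_points - 2 degrees of freedom. Raises
    :class:`InsufficientDesignError` for fewer than 4 distinct
    concentrations and :class:`FitFailureError` on non-convergence; a
    negative fitted slope (response decreasing with concentration) is
    returned with a warning, not an error.
    """
    if link not in _LINKS:
        raise ValueError(f"link must be one of {_LINKS}")
    if len(np.unique(data.concentration)) < 4:
        raise InsufficientDesignError(
            f"{data.drug_id}: need >= 4 distinct concentrations, "
            f"got {len(np.unique(data.concentration))}"
        )
    x = np.log10(data.concentration)
    e = np.clip(data.effect_fraction, 0.0, 1.0)
    if e.min() > 0.5 or e.max() < 0.5:
        warnings.warn(
            f"{data.drug_id}: no observed effect on both sides of 50%; "
            "the EC50 is an extrapolation",
            UserWarning,
            stacklevel=2,
        )
    sqrt_w = np.sqrt(np.asarray(data.n, float))

    def residuals(params: np.ndarray) -> np.ndarray:
        eta = params[0] + params[1] * x
        return sqrt_w * (e - _link_cdf(eta, link))

    def jacobian(params: np.ndarray) -> np.ndarray:
        eta = params[0] + params[1] * x
        d = _link_pdf(eta, link)
        return -sqrt_w[:, None] * np.column_stack([d, d * x])

    sol = optimize.least_squares(
        residuals,
        _initial_params(x, e, link),
        jac=jacobian,
        method="lm",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=200 * 3,
    )
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise FitFailureError(
            f"{data.drug_id}: least-squares fit did not converge",
            {"link": link, "status": int(sol.status), "message": sol.message},
        )
    intercept, slope = float(sol.x[0]), float(sol.x[1])
    if slope <= 0:
        warnings.warn(
            f"{data.drug_id}: fitted slope {slope:.3g} <= 0 "
            "(effect decreases with concentration); check the effect coding",
            UserWarning,
            stacklevel=2,
        )
    k = len(x)
    rss = float(sol.fun @ sol.fun)  # weighted: residuals already carry sqrt(n)
    sigma2 = rss / max(k - 2, 1)
    jtj = sol.jac.T @ sol.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(jtj)
    return PotencyFit(
        drug_id=data.drug_id,
        link=link,
        slope=slope,
        intercept=intercept,
        covariance=cov,
        converged=bool(sol.success),
        log_ec50=-intercept / slope if slope != 0 else np.nan,
        n_points=k,
        scale=sigma2,
        effect_kind=data.effect_kind,
    )


def effective_concentration(fit: PotencyFit, p: float = 0.5, kind: str | None = None) -> PotencyEstimate:
    """ECp (uM) from a fitted curve, with delta-method SEM and 95% CI.

    log10 ECp = (link_quantile(p) - intercept) / slope; its variance follows
    from the (intercept, slope) covariance by the delta method. The CI is
    formed on the log scale with a t quantile on n_points - 2 degrees of
    freedom (the residual variance is estimated from the same few design
    points) and then exponentiated; the SEM is mapped to the uM scale as
    value * ln(10) * sd(log10 ECp).
    """
    if not fit.converged:
        raise FitFailureError(f"{fit.drug_id}: cannot derive ECp from a non-converged fit")
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if fit.slope <= 0:
        raise ValueError("ECp requires a positive fitted slope")
    z = _link_quantile(p, fit.link)
    a, b = fit.intercept, fit.slope
    log_ecp = (z - a) / b
    grad = np.array([-1.0 / b, -(z - a) / b**2])
    var_log = float(grad @ fit.covariance @ grad)
    sd_log = float(np.sqrt(max(var_log, 0.0)))
    value = float(10.0**log_ecp)
    dof = max(fit.n_points - 2, 1)
    tcrit = float(stats.t.ppf(0.975, dof))
    with np.errstate(over="ignore"):
        ci = (
            float(np.power(10.0, log_ecp - tcrit * sd_log)),
            float(np.power(10.0, log_ecp + tcrit * sd_log)),
        )
    sem = value * np.log(10.0) * sd_log
    if kind is None:
        if p == 0.5:
            kind = "LC50" if fit.effect_kind == "lethality" else "EC50"
        else:
            kind = "ECp"
    return PotencyEstimate(kind=kind, p_level=p, value=value, sem=float(sem), ci95=ci,
                           drug_id=fit.drug_id)


def potency_to_dict(est: PotencyEstimate, fit: PotencyFit | None = None) -> dict:
    """JSON-ready record for one potency estimate."""
    rec = {
        "drug_id": est.drug_id,
        "kind": est.kind,
        "p_level": est.p_level,
        "value_uM": est.value,
        "sem_uM": est.sem,
        "ci95": list(est.ci95),
    }
    if fit is not None:
        rec.update(link=fit.link, slope=fit.slope, converged=fit.converged)
    return rec
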
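"""Fixed-ratio (ray) two-drug combination design.

A fixed-ratio mixture is parameterised by the EC50 fraction f of drug A:
its components are f * EC50_A and (1 - f) * EC50_B, so the design point
always lies on the Loewe additivity line (additivity index = 1). Ratio
labels like "1:4" are metadata; f is the controlling parameter (f = 0.25
for a 1:4 mixture, 0.5 for 1:1, 0.75 for 4:1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MixtureDesign:
    """A fixed-ratio two-drug combination point.

    ``c_a = f_a * ec50_a`` and ``c_b = (1 - f_a) * ec50_b`` hold when built
    via :func:`fixed_ratio_components`; direct construction only requires
    nonnegative components.
    """

    drug_a: str
    drug_b: str
    f_a: float
    c_a: float
    c_b: float
    label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.f_a <= 1.0:
            raise ValueError("f_a must be in [0, 1]")
        if self.c_a < 0 or self.c_b < 0:
            raise ValueError("component concentrations must be >= 0")

    @property
    def f_b(self) -> float:
        return 1.0 - self.f_a

    @property
    def total(self) -> float:
        return self.c_a + self.c_b

    def components_at_total(self, total: float) -> tuple[float, float]:
        """Decompose a total concentration on this ray, preserving the
        component proportions c_a/total, c_b/total."""
        if self.total <= 0:
            raise ValueError("ray has zero total; proportions undefined")
        return total * self.c_a / self.total, total * self.c_b / self.total


def fixed_ratio_components(
    ec50_a: float,
    ec50_b: float,
    f_a: float,
    label: str = "",
    drug_a: str = "DDS",
    drug_b: str = "CBD",
) -> MixtureDesign:
    """Combination design point at EC50 fraction f_a.

    total = f_a * ec50_a + (1 - f_a) * ec50_b — the additivity-line
    parametrisation. Full precision is retained; rounding for display is
    a separate concern (:func:`format_component`).
    """
    if ec50_a <= 0 or ec50_b <= 0:
        raise ValueError("EC50s must be > 0")
    if not 0.0 <= f_a <= 1.0:
        raise ValueError("f_a must be in [0, 1]")
    return MixtureDesign(
        drug_a=drug_a,
        drug_b=drug_b,
        f_a=f_a,
        c_a=f_a * ec50_a,
        c_b=(1.0 - f_a) * ec50_b,
        label=label or ratio_label(f_a),
    )


def ratio_label(f_a: float) -> str:
    """Conventional ratio label for common EC50 fractions (0.25 -> "1:4")."""
    named = {0.5: "1:1", 0.25: "1:4", 0.75: "4:1", 1.0: "A only", 0.0: "B only"}
    return named.get(round(f_a, 6), f"f={f_a:g}")


def format_component(value: float, decimals: int) -> float:
    """Round a component for table display (machine output stays exact)."""
    return round(value, decimals)


@dataclass
class DilutionSeries:
    """Geometric dilution series of total concentration along one ray."""

    design: MixtureDesign
    totals: np.ndarray
    factor: float
    center_excluded: bool
    center_total: float = field(default=np.nan)

    def components(self) -> list[tuple[float, float]]:
        return [self.design.components_at_total(t) for t in self.totals]

    def to_frame(self) -> pd.DataFrame:
        comp = self.components()
        return pd.DataFrame(
            {
                "level": np.arange(1, len(self.totals) + 1),
                "total_uM": self.totals,
                "c_a_uM": [c[0] for c in comp],
                "c_b_uM": [c[1] for c in comp],
            }
        )


def dilution_series(
    design: MixtureDesign,
    center_total: float,
    n_each_side: int = 3,
    factor: float = 2.0,
    exclude_center: bool = True,
) -> DilutionSeries:
    """Geometric series ``center * factor**k`` around a chosen mixture total.

    Levels run k = -n..-1 and 1..n, with the center itself included only
    when ``exclude_center`` is False (the assay that produced the center
    value is not re-run). Components at every level keep the ray's
    proportions, so c_a/c_b is constant across the series.
    """
    if center_total <= 0:
        raise ValueError("center_total must be > 0")
    if factor <= 1.0:
        raise ValueError("dilution factor must be > 1")
    if n_each_side < 1:
        raise ValueError("n_each_side must be >= 1")
    ks = [k for k in range(-n_each_side, n_each_side + 1) if k != 0 or not exclude_center]
    totals = np.array([center_total * factor**k for k in ks])
    return DilutionSeries(
        design=design,
        totals=totals,
        factor=factor,
        center_excluded=exclude_center,
        center_total=center_total,
    )


def designs_to_frame(designs: list[MixtureDesign]) -> pd.DataFrame:
    """Design table (`label,f_a,c_a_uM,c_b_uM,total_uM`) for export."""
    return pd.DataFrame(
        {
            "label": [d.label for d in designs],
            "f_a": [d.f_a for d in designs],
            "c_a_uM": [d.c_a for d in designs],
            "c_b_uM": [d.c_b for d in designs],
            "total_uM": [d.total for d in designs],
        }
    )
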
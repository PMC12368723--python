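"""Production-cost model for the batch synthesis.

Total cost (abstract currency units) is the sum of seven components driven
by the design variables ``x`` and the simulated process metrics ``y1``
(reaction time, hours) and ``y2`` (conversion fraction)::

    C_catalyst = 8000 * x5**1.2        (precious-metal precursor)
    C_reagent  = 40*x1 + 20*x2 + 30*x3 + 10*x4
    C_fixed    = 200
    C_energy   = 15 * sqrt(y1)
    C_maint    = 10 * (1 + 0.05 * y1**1.5)
    C_purif    = 500 * (1 - y2)**1.5   (separation burden at low conversion)
    C_labor    = 150 + 5 * y1

The model is a relative comparator between operating points, not an
absolute cost prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

from .kinetics import SimulationInput

__all__ = ["CostBreakdown", "compute_cost", "COST_FLOOR"]

#: Minimum attainable total (x -> 0, y1 = 0, y2 = 1): fixed + maint + labor base.
COST_FLOOR = 360.0


@dataclass(frozen=True)
class CostBreakdown:
    c_catalyst: float
    c_reagent: float
    c_fixed: float
    c_energy: float
    c_maint: float
    c_purif: float
    c_labor: float

    @property
    def total(self) -> float:
        return (
            self.c_catalyst + self.c_reagent + self.c_fixed + self.c_energy
            + self.c_maint + self.c_purif + self.c_labor
        )

    def to_dict(self) -> dict[str, float]:
        d = asdict(self)
        d["total"] = self.total
        return d


def compute_cost(
    x: SimulationInput | "object", y1: float, y2: float, clamp_cr: bool = True
) -> CostBreakdown:
    """Cost breakdown for design ``x`` with reaction time ``y1`` (h) and
    conversion ``y2`` (fraction).

    Surrogate-predicted conversions can stray slightly outside [0, 1]; they
    are clamped (with a warning) when ``clamp_cr`` is set, since the
    purification term is undefined for y2 > 1.
    """
    if y1 < 0:
        raise ValueError(f"reaction time y1 must be nonnegative, got {y1}")
    if not 0.0 <= y2 <= 1.0:
        if not clamp_cr:
            raise ValueError(f"conversion y2 must lie in [0, 1], got {y2}")
        warnings.warn(
            f"conversion y2={y2:.6g} outside [0, 1]; clamped before costing",
            stacklevel=2,
        )
        y2 = min(max(y2, 0.0), 1.0)
    try:
        x1, x2, x3, x4, x5 = (float(x[k]) for k in ("x1", "x2", "x3", "x4", "x5"))
    except (TypeError, KeyError, IndexError):
        x1, x2, x3, x4, x5 = (float(v) for v in list(x)[:5])
    if min(x1, x2, x3, x4, x5) < 0:
        raise ValueError("concentrations must be nonnegative")
    return CostBreakdown(
        c_catalyst=8000.0 * x5 ** 1.2,
        c_reagent=40.0 * x1 + 20.0 * x2 + 30.0 * x3 + 10.0 * x4,
        c_fixed=200.0,
        c_energy=15.0 * math.sqrt(y1),
        c_maint=10.0 * (1.0 + 0.05 * y1 ** 1.5),
        c_purif=500.0 * (1.0 - y2) ** 1.5,
        c_labor=150.0 + 5.0 * y1,
    )
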
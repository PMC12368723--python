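"""Mass-action kinetics engine for batch ibuprofen synthesis.

The engine integrates ``dc/dt = S^T r(c)`` for an arbitrary
:class:`~ibusynth.mechanism.MechanismSpec`, where ``r_j = k_j * prod_s
c_s**o_js`` is the mass-action rate of reaction *j*.  The shipped mechanism
models the Pd-catalysed carbonylation route: acid-catalysed dehydration of
1-(4-isobutylphenyl)ethanol (``roh``), hydrohalogenation of the resulting
alkene (``ren``) to the benzylic chloride (``rcl``), activation of the
L2PdCl2 precursor (``pd1``) to the active species (``pd2``), oxidative
addition (``pd3``), CO insertion (``pd4``), hydrolysis releasing ibuprofen
(``ibu``), and a reversible esterification of ibuprofen with the substrate
alcohol (``ester``).

Two process metrics are read off each trajectory:

* reaction time ``RT`` — the first time the product concentration reaches a
  fraction ``theta`` (default 0.99) of its terminal plateau value, reported
  in hours;
* conversion rate ``CR`` — product concentration at ``RT`` divided by the
  initial substrate concentration, a fraction in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .mechanism import MechanismSpec

__all__ = [
    "DESIGN_BOUNDS",
    "INPUT_NAMES",
    "INPUT_DESCRIPTIONS",
    "reference_inputs",
    "SimulationInput",
    "KineticsConfig",
    "Trajectory",
    "ProcessMetrics",
    "IntegrationError",
    "compile_mechanism",
    "rate_vector",
    "simulate",
    "extract_metrics",
    "trajectory_to_frame",
]

# Design-variable bounds (min, max); minima are 0.1x and maxima 10x the
# reference operating point of the batch carbonylation model.
DESIGN_BOUNDS: dict[str, tuple[float, float]] = {
    "x1": (0.01, 1.0),        # c0(B) substrate alcohol roh, mol/m^3
    "x2": (0.02, 2.0),        # c0(Cl-), mol/m^3
    "x3": (0.02, 2.0),        # c0(H+), mol/m^3
    "x4": (0.3, 30.0),        # c0(H2O), mol/m^3
    "x5": (0.00121, 0.121),   # c0(L2PdCl2), mol/m^3
    "x6": (7.45e-4, 7.45e-2),  # k1, m^3/(s mol)
    "x7": (1.25e-3, 1.25e-1),  # k2, m^6/(s mol^2)
    "x8": (1.60e-4, 1.60e-2),  # k3, m^3/(s mol)
    "x9": (1.5e-2, 1.5),       # k4, m^6/(s mol^2)
    "x10": (0.159, 15.9),      # k5, m^3/(s mol)
    "x11": (2.14e-2, 2.14),    # k6, m^3/(s mol)
    "x12": (9.52e-2, 9.52),    # k7, m^3/(s mol)
    "x13": (5e-2, 5.0),        # k8f, m^6/(s mol^2)
    "x14": (1e-3, 1e-1),       # k8r, m^6/(s mol^2)
}

INPUT_NAMES: tuple[str, ...] = tuple(DESIGN_BOUNDS)

INPUT_DESCRIPTIONS: dict[str, str] = {
    "x1": "c0(B) initial substrate alcohol",
    "x2": "c0(Cl-)",
    "x3": "c0(H+)",
    "x4": "c0(H2O)",
    "x5": "c0(L2PdCl2) catalyst precursor",
    "x6": "k1 dehydration",
    "x7": "k2 hydrohalogenation",
    "x8": "k3 dehydrohalogenation",
    "x9": "k4 catalyst activation",
    "x10": "k5 oxidative addition",
    "x11": "k6 carbonylation",
    "x12": "k7 hydrolysis",
    "x13": "k8f esterification (forward)",
    "x14": "k8r esterification (reverse)",
}

_RATE_CONSTANT_FIELDS = {
    "k1": "x6", "k2": "x7", "k3": "x8", "k4": "x9", "k5": "x10",
    "k6": "x11", "k7": "x12", "k8f": "x13", "k8r": "x14",
}


def reference_inputs() -> "SimulationInput":
    """Reference operating point: 10x each lower bound (= the nominal values)."""
    return SimulationInput.from_array(
        np.array([10.0 * lo for lo, _ in DESIGN_BOUNDS.values()])
    )


@dataclass(frozen=True)
class SimulationInput:
    """The 14 design variables: 5 initial concentrations + 9 rate constants."""

    values: tuple[float, ...]
    perturbed: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != 14:
            raise ValueError(f"expected 14 design variables, got {len(self.values)}")
        arr = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("all design variables must be finite")
        # perturbed points may sit at zero (e.g. catalyst knocked out); the
        # nominal design space is strictly positive and inside the bounds
        if np.any(arr < 0) or (not self.perturbed and np.any(arr <= 0)):
            raise ValueError("design variables must be strictly positive")
        if not self.perturbed:
            lo, hi = _bounds_arrays()
            # tiny slack for round-tripped floats
            if np.any(arr < lo * (1 - 1e-12)) or np.any(arr > hi * (1 + 1e-12)):
                bad = [
                    INPUT_NAMES[i]
                    for i in range(14)
                    if not lo[i] <= arr[i] <= hi[i]
                ]
                raise ValueError(
                    f"variables outside their design bounds: {bad}; pass "
                    "perturbed=True for deliberately out-of-range points"
                )

    @classmethod
    def from_array(cls, arr: Sequence[float], perturbed: bool = False) -> "SimulationInput":
        return cls(values=tuple(float(v) for v in arr), perturbed=perturbed)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[INPUT_NAMES.index(name)]

    def rate_constant(self, ref: str) -> float:
        """Value of a named rate constant (``k1`` .. ``k8r``)."""
        try:
            return self[_RATE_CONSTANT_FIELDS[ref]]
        except KeyError:
            raise KeyError(f"unknown rate constant {ref!r}") from None


def _bounds_arrays() -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([b[0] for b in DESIGN_BOUNDS.values()])
    hi = np.array([b[1] for b in DESIGN_BOUNDS.values()])
    return lo, hi


@dataclass(frozen=True)
class KineticsConfig:
    """Integration horizon, tolerances and metric-extraction thresholds."""

    t_end: float = 259_200.0        # 72 h in seconds
    rtol: float = 1e-7
    atol: float = 1e-12             # mol/m^3; far below any concentration of interest
    n_grid: int = 400
    t_first: float = 0.1            # first positive grid time, s (grid is geometric)
    theta: float = 0.99             # plateau fraction defining RT
    eps_ibu: float = 1e-9           # censoring threshold on terminal product, mol/m^3
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if not 0 < self.t_first < self.t_end:
            raise ValueError("t_first must lie in (0, t_end)")

    def time_grid(self) -> np.ndarray:
        grid = np.geomspace(self.t_first, self.t_end, self.n_grid - 1)
        return np.concatenate(([0.0], grid))


_NEG_TOL = 1e-12  # mol/m^3; solver outputs below this are clipped to zero


@dataclass(frozen=True)
class Trajectory:
    """Dense solution on the output grid: time (s) x species (mol/m^3)."""

    time_grid: np.ndarray
    concentrations: np.ndarray
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.concentrations.shape != (len(self.time_grid), len(self.species)):
            raise ValueError("concentration matrix shape mismatch")

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def concentration(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.species_index(name)]


class ProcessMetrics(NamedTuple):
    rt_hours: float
    cr: float
    censored: bool


class IntegrationError(RuntimeError):
    """Stiff-solver failure; carries the offending input vector for triage."""

    def __init__(self, message: str, input: SimulationInput):
        super().__init__(f"{message} (inputs: {np.asarray(input.values)})")
        self.input = input


class CompiledMechanism(NamedTuple):
    """Index-based view of a MechanismSpec for fast rate/Jacobian evaluation."""

    species: tuple[str, ...]
    orders: np.ndarray          # (n_rxn, n_tracked) integer kinetic orders
    stoich: np.ndarray          # (n_rxn, n_tracked) net concentration change
    const_factor: np.ndarray    # (n_rxn,) product of constant-species terms
    rate_refs: tuple[str, ...]


def compile_mechanism(mech: MechanismSpec) -> CompiledMechanism:
    """Flatten a mechanism into index arrays; constant species fold into k."""
    idx = {s: i for i, s in enumerate(mech.species)}
    n_rxn, n_sp = mech.n_reactions, mech.n_species
    orders = np.zeros((n_rxn, n_sp), dtype=np.int64)
    stoich = np.zeros((n_rxn, n_sp), dtype=float)
    const_factor = np.ones(n_rxn)
    for j, rxn in enumerate(mech.reactions):
        for spc, order in rxn.orders.items():
            if spc in mech.constant_species:
                const_factor[j] *= mech.constant_species[spc] ** order
            else:
                orders[j, idx[spc]] = order
        for spc, nu in rxn.stoichiometry.items():
            stoich[j, idx[spc]] = nu
    return CompiledMechanism(
        species=mech.species,
        orders=orders,
        stoich=stoich,
        const_factor=const_factor,
        rate_refs=tuple(r.rate_constant for r in mech.reactions),
    )


def _rate_constants(compiled: CompiledMechanism, inp: SimulationInput) -> np.ndarray:
    return np.array([inp.rate_constant(ref) for ref in compiled.rate_refs])


def rate_vector(
    conc: np.ndarray | Sequence[float],
    mech: MechanismSpec | CompiledMechanism,
    input: SimulationInput,
) -> np.ndarray:
    """Per-reaction mass-action rates ``k_j * prod_s c_s**o_js``, mol/(m^3 s)."""
    compiled = mech if isinstance(mech, CompiledMechanism) else compile_mechanism(mech)
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("negative concentration passed to rate_vector")
    k = _rate_constants(compiled, input) * compiled.const_factor
    return k * np.prod(conc[None, :] ** compiled.orders, axis=1)


def _initial_state(compiled: CompiledMechanism, inp: SimulationInput) -> np.ndarray:
    c0 = np.zeros(len(compiled.species))
    seeds = {"roh": "x1", "cl": "x2", "hp": "x3", "h2o": "x4", "pd1": "x5"}
    for spc, xname in seeds.items():
        if spc in compiled.species:
            c0[compiled.species.index(spc)] = inp[xname]
    return c0


def simulate(
    input: SimulationInput,
    mech: MechanismSpec | CompiledMechanism,
    cfg: KineticsConfig | None = None,
) -> Trajectory:
    """Integrate the batch reactor from t=0 to the configured horizon.

    Uses a stiff-capable adaptive solver (LSODA by default) with an
    analytical Jacobian assembled from the mechanism's kinetic orders.
    """
    cfg = cfg or KineticsConfig()
    compiled = mech if isinstance(mech, CompiledMechanism) else compile_mechanism(mech)
    k_eff = _rate_constants(compiled, input) * compiled.const_factor
    orders = compiled.orders
    stoich_T = compiled.stoich.T.copy()
    participants = [np.nonzero(orders[j])[0] for j in range(orders.shape[0])]

    # The RHS is left in raw polynomial form (no clipping): with integer
    # kinetic orders it is smooth everywhere and self-correcting for the
    # tiny negative excursions adaptive solvers produce, which keeps the
    # stiff solver's step-size control stable.
    def rhs(t: float, c: np.ndarray) -> np.ndarray:
        rates = k_eff * np.prod(c[None, :] ** orders, axis=1)
        return stoich_T @ rates

    def jac(t: float, c: np.ndarray) -> np.ndarray:
        n_rxn, n_sp = orders.shape
        drate = np.zeros((n_rxn, n_sp))
        for j in range(n_rxn):
            for s in participants[j]:
                term = k_eff[j] * orders[j, s] * c[s] ** (orders[j, s] - 1)
                for s2 in participants[j]:
                    if s2 != s:
                        term *= c[s2] ** orders[j, s2]
                drate[j, s] = term
        return stoich_T @ drate

    c0 = _initial_state(compiled, input)
    grid = cfg.time_grid()
    sol = solve_ivp(
        rhs,
        (0.0, cfg.t_end),
        c0,
        method=cfg.method,
        t_eval=grid,
        rtol=cfg.rtol,
        atol=cfg.atol,
        jac=jac,
    )
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}", input)
    conc = sol.y.T.copy()
    conc[np.abs(conc) < _NEG_TOL] = 0.0
    if np.any(conc < -_NEG_TOL):
        # adaptive solvers can undershoot zero slightly; clip but keep magnitude check
        worst = conc.min()
        if worst < -1e-6:
            raise IntegrationError(
                f"solution went significantly negative (min {worst:g})", input
            )
        conc = np.maximum(conc, 0.0)
    return Trajectory(time_grid=grid, concentrations=conc, species=compiled.species)


def extract_metrics(
    traj: Trajectory,
    input: SimulationInput,
    cfg: KineticsConfig | None = None,
    product: str = "ibu",
) -> ProcessMetrics:
    """Reaction time (h) and conversion rate from a product trajectory.

    RT is the first time the product reaches ``theta`` of its terminal value,
    refined by linear interpolation between grid points; CR is the product
    concentration at RT over the initial substrate concentration.  Runs whose
    terminal product stays below ``eps_ibu`` are censored at the horizon.
    """
    cfg = cfg or KineticsConfig()
    x1 = input["x1"]
    if x1 <= 0:
        raise ValueError("initial substrate concentration x1 must be positive")
    c_prod = traj.concentration(product)
    t = traj.time_grid
    if t[-1] < cfg.t_end * (1 - 1e-9):
        raise ValueError("trajectory does not cover the configured horizon")
    c_end = c_prod[-1]
    if c_end < cfg.eps_ibu:
        return ProcessMetrics(rt_hours=cfg.t_end / 3600.0, cr=c_end / x1, censored=True)
    threshold = cfg.theta * c_end
    above = np.nonzero(c_prod >= threshold)[0]
    i = int(above[0])
    if i == 0:
        rt_s = t[0]
    else:
        # linear interpolation of the crossing between grid neighbours
        c_lo, c_hi = c_prod[i - 1], c_prod[i]
        frac = (threshold - c_lo) / (c_hi - c_lo) if c_hi > c_lo else 1.0
        rt_s = t[i - 1] + frac * (t[i] - t[i - 1])
    cr = min(threshold / x1, 1.0)
    return ProcessMetrics(rt_hours=rt_s / 3600.0, cr=cr, censored=False)


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy (time_s, species, concentration) table for export."""
    n_t, n_s = traj.concentrations.shape
    return pd.DataFrame(
        {
            "time_s": np.repeat(traj.time_grid, n_s),
            "species": np.tile(traj.species, n_t),
            "concentration": traj.concentrations.ravel(),
        }
    )
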
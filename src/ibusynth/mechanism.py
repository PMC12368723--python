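"""Reaction-mechanism definitions for the mass-action ODE engine.

A mechanism is an ordered list of species, an optional set of species held
at a fixed concentration (dissolved gases, solvent buffers), and a table of
elementary reactions.  Each reaction carries

* ``orders`` — the kinetic order of every participating species (the rate is
  ``k * prod(c_s ** order_s)``),
* ``stoichiometry`` — the net concentration change per unit of reaction
  extent, and
* ``rate_constant`` — the name of the rate constant supplied at simulation
  time (``k1`` .. ``k7``, ``k8f``, ``k8r`` for the shipped mechanism).

Mechanisms are stored as YAML so the shipped ibuprofen carbonylation network
can be edited or replaced without touching the engine.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "Reaction",
    "MechanismSpec",
    "MechanismError",
    "load_mechanism",
    "save_mechanism",
    "canonical_mechanism",
    "canonical_mechanism_path",
]


class MechanismError(ValueError):
    """Raised when a mechanism file violates the schema."""


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: mass-action orders, net stoichiometry, k ref."""

    name: str
    orders: Mapping[str, int]
    stoichiometry: Mapping[str, float]
    rate_constant: str

    @property
    def total_order(self) -> int:
        return int(sum(self.orders.values()))


@dataclass(frozen=True)
class MechanismSpec:
    """Validated reaction network driving the ODE right-hand side."""

    species: tuple[str, ...]
    constant_species: Mapping[str, float]
    reactions: tuple[Reaction, ...]
    rate_constants: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        known = set(self.species) | set(self.constant_species)
        overlap = set(self.species) & set(self.constant_species)
        if overlap:
            raise MechanismError(
                f"species listed both as tracked and constant: {sorted(overlap)}"
            )
        names = [r.name for r in self.reactions]
        if len(set(names)) != len(names):
            raise MechanismError("duplicate reaction names")
        refs = []
        for rxn in self.reactions:
            for spc in list(rxn.orders) + list(rxn.stoichiometry):
                if spc not in known:
                    raise MechanismError(
                        f"reaction {rxn.name!r} references undeclared species {spc!r}"
                    )
            for spc, order in rxn.orders.items():
                if not float(order).is_integer() or order < 0:
                    raise MechanismError(
                        f"reaction {rxn.name!r}: order for {spc!r} must be a "
                        f"nonnegative integer, got {order!r}"
                    )
            for spc in rxn.stoichiometry:
                if spc in self.constant_species and rxn.stoichiometry[spc] != 0:
                    raise MechanismError(
                        f"reaction {rxn.name!r} changes constant species {spc!r}"
                    )
            refs.append(rxn.rate_constant)
        declared = self.rate_constants or tuple(dict.fromkeys(refs))
        object.__setattr__(self, "rate_constants", declared)
        unknown = set(refs) - set(declared)
        if unknown:
            raise MechanismError(f"undeclared rate-constant references: {sorted(unknown)}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "constant_species": dict(self.constant_species),
            "rate_constants": list(self.rate_constants),
            "reactions": [
                {
                    "name": r.name,
                    "orders": dict(r.orders),
                    "stoichiometry": dict(r.stoichiometry),
                    "rate_constant": r.rate_constant,
                }
                for r in self.reactions
            ],
        }


def _from_dict(raw: dict, source: str) -> MechanismSpec:
    for key in ("species", "reactions"):
        if key not in raw:
            raise MechanismError(f"{source}: missing top-level key {key!r}")
    reactions = []
    for i, entry in enumerate(raw["reactions"]):
        try:
            reactions.append(
                Reaction(
                    name=str(entry["name"]),
                    orders={str(k): int(v) for k, v in entry["orders"].items()},
                    stoichiometry={
                        str(k): float(v) for k, v in entry["stoichiometry"].items()
                    },
                    rate_constant=str(entry["rate_constant"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            name = entry.get("name", f"#{i}") if isinstance(entry, dict) else f"#{i}"
            raise MechanismError(f"{source}: malformed reaction {name!r}: {exc}") from exc
    try:
        return MechanismSpec(
            species=tuple(str(s) for s in raw["species"]),
            constant_species={
                str(k): float(v) for k, v in (raw.get("constant_species") or {}).items()
            },
            reactions=tuple(reactions),
            rate_constants=tuple(raw.get("rate_constants") or ()),
        )
    except MechanismError as exc:
        raise MechanismError(f"{source}: {exc}") from exc


def load_mechanism(path: str | Path) -> MechanismSpec:
    """Load and validate a mechanism from a YAML (or JSON) file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise MechanismError(f"{path}: mechanism file must contain a mapping")
    return _from_dict(raw, str(path))


def save_mechanism(mech: MechanismSpec, path: str | Path) -> None:
    """Write a mechanism back to YAML; ``load_mechanism`` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(mech.to_dict(), fh, sort_keys=False)


def canonical_mechanism_path() -> Path:
    """Path of the shipped ibuprofen Pd-carbonylation mechanism file."""
    return Path(
        importlib.resources.files("ibusynth.data") / "ibuprofen_carbonylation.yaml"
    )


def canonical_mechanism() -> MechanismSpec:
    """The shipped ibuprofen carbonylation network (13 tracked species, 9 reactions)."""
    return load_mechanism(canonical_mechanism_path())
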
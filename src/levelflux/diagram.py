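"""Data model for energy-level diagrams.

A system is described by an energy-level diagram: populations ``N_j`` of
entities sitting on levels of energy ``G_j``, connected by transformations
that move matter between levels while exchanging quanta of energy ``deltaQ``
with the surroundings.  Each species carries an integer composition ``c``
(number of elemental constituents), and every transformation must balance
composition exactly: quanta carry energy, never matter.

Energies are expressed in units of the thermal energy ``kT`` (Boltzmann's
constant is taken as 1), so a spec with ``kT = 1`` works directly in
dimensionless units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Species",
    "Transformation",
    "SystemSpec",
    "SystemState",
    "DiagramError",
    "ParseError",
    "ValidationError",
    "validate_system",
    "read_system",
    "write_system",
]


class DiagramError(Exception):
    """Base class for diagram-level errors."""


class ParseError(DiagramError):
    """A system config file is malformed (missing/ill-typed field)."""


class ValidationError(DiagramError):
    """A structurally parseable system violates a diagram invariant."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


@dataclass(frozen=True)
class Species:
    """One level of the diagram.

    Parameters
    ----------
    id:
        Short unique label.
    G:
        Level energy, in units of the reference thermal energy.
    c:
        Number of elemental constituents (>= 1); an entity of composition
        ``c`` stands for ``c`` elemental units of matter.
    N0:
        Initial population (>= 0).
    """

    id: str
    G: float
    c: int = 1
    N0: float = 0.0


@dataclass(frozen=True)
class Transformation:
    """A quantum-coupled conversion between multisets of species.

    ``substrates`` and ``products`` map species ids to positive integer
    stoichiometric coefficients.  ``deltaQ`` is the energy absorbed from the
    surroundings per forward event (negative when the event radiates energy
    out).  ``sigma`` is the nonnegative conductance of the mechanism carrying
    the transformation; flux is linear in the driving affinity with this
    coefficient.
    """

    substrates: Mapping[str, int]
    products: Mapping[str, int]
    deltaQ: float = 0.0
    sigma: float = 1.0
    label: str = ""

    def reversed(self) -> "Transformation":
        """The same channel run backwards: swap sides, negate deltaQ."""
        return Transformation(
            substrates=dict(self.products),
            products=dict(self.substrates),
            deltaQ=-self.deltaQ,
            sigma=self.sigma,
            label=self.label + "(rev)" if self.label else "",
        )


@dataclass(frozen=True)
class SystemSpec:
    """A complete energy-level diagram plus the thermal energy scale."""

    species: tuple[Species, ...]
    transformations: tuple[Transformation, ...]
    kT: float = 1.0
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "transformations", tuple(self.transformations))

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self, species_id: str) -> int:
        return self.species_ids.index(species_id)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_transformations(self) -> int:
        return len(self.transformations)

    def compositions(self) -> np.ndarray:
        return np.array([s.c for s in self.species], dtype=float)

    def energies(self) -> np.ndarray:
        return np.array([s.G for s in self.species], dtype=float)

    def initial_state(self) -> "SystemState":
        return SystemState(
            populations=np.array([s.N0 for s in self.species], dtype=float),
            time=0.0,
        )

    def stoichiometry(self) -> np.ndarray:
        """Net stoichiometric matrix S (species x transformations).

        ``S[j, r]`` = product coefficient minus substrate coefficient of
        species j in transformation r.  Columns of an elementally balanced
        system satisfy ``c @ S == 0`` exactly (integer arithmetic).
        """
        S = np.zeros((self.n_species, self.n_transformations))
        index = {s.id: i for i, s in enumerate(self.species)}
        for r, tr in enumerate(self.transformations):
            for sid, coeff in tr.substrates.items():
                S[index[sid], r] -= coeff
            for sid, coeff in tr.products.items():
                S[index[sid], r] += coeff
        return S


@dataclass
class SystemState:
    """Populations at an instant; the object all state functions evaluate."""

    populations: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.populations = np.asarray(self.populations, dtype=float)

    def copy(self) -> "SystemState":
        return SystemState(self.populations.copy(), self.time)


def _tname(r: int, tr: Transformation) -> str:
    if tr.label:
        return f"transformation {r} ({tr.label})"
    return f"transformation {r}"


def validate_system(spec: SystemSpec) -> list[str]:
    """Check every diagram invariant; return one message per violation.

    Pure reporting function: an empty list means the spec is valid.
    """
    messages: list[str] = []
    if spec.n_species == 0:
        messages.append("system has no species")
    if not spec.kT > 0:
        messages.append(f"kT must be positive, got {spec.kT}")

    seen: set[str] = set()
    comp: dict[str, int] = {}
    for s in spec.species:
        if s.id in seen:
            messages.append(f"duplicate species id '{s.id}'")
        seen.add(s.id)
        comp[s.id] = s.c
        if s.c < 1 or int(s.c) != s.c:
            messages.append(f"species '{s.id}': composition c must be a positive integer, got {s.c}")
        if s.N0 < 0:
            messages.append(f"species '{s.id}': initial population N0 must be >= 0, got {s.N0}")

    for r, tr in enumerate(spec.transformations):
        if tr.sigma < 0:
            messages.append(f"{_tname(r, tr)}: conductance sigma must be >= 0, got {tr.sigma}")
        if not tr.substrates or not tr.products:
            messages.append(f"{_tname(r, tr)}: substrates and products must both be nonempty")
        unknown = [sid for sid in list(tr.substrates) + list(tr.products) if sid not in comp]
        for sid in unknown:
            messages.append(f"{_tname(r, tr)}: references unknown species id '{sid}'")
        for side_name, side in (("substrate", tr.substrates), ("product", tr.products)):
            for sid, coeff in side.items():
                if coeff < 1 or int(coeff) != coeff:
                    messages.append(
                        f"{_tname(r, tr)}: {side_name} coefficient for '{sid}' "
                        f"must be a positive integer, got {coeff}"
                    )
        if not unknown:
            left = sum(coeff * comp[sid] for sid, coeff in tr.substrates.items())
            right = sum(coeff * comp[sid] for sid, coeff in tr.products.items())
            if left != right:
                messages.append(
                    f"{_tname(r, tr)}: elemental balance violated "
                    f"(substrates carry {left} elemental units, products {right})"
                )
    return messages


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise ParseError(f"missing required field '{key}' in {where}")
    return mapping[key]


def _coerce_coeffs(raw: Mapping, where: str) -> dict[str, int]:
    if not isinstance(raw, Mapping):
        raise ParseError(f"{where} must be a mapping of species id -> coefficient")
    out: dict[str, int] = {}
    for sid, coeff in raw.items():
        try:
            out[str(sid)] = int(coeff)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{where}: coefficient for '{sid}' is not an integer") from exc
    return out


def spec_from_dict(doc: Mapping) -> SystemSpec:
    """Build a SystemSpec from a parsed config mapping (no validation)."""
    if not isinstance(doc, Mapping):
        raise ParseError("system config must be a mapping at top level")
    kT = _require(doc, "kT", "system config")
    try:
        kT = float(kT)
    except (TypeError, ValueError) as exc:
        raise ParseError("field 'kT' must be a number") from exc
    label = str(doc.get("label", ""))
    species = []
    for i, raw in enumerate(_require(doc, "species", "system config") or []):
        where = f"species[{i}]"
        species.append(
            Species(
                id=str(_require(raw, "id", where)),
                G=float(_require(raw, "G", where)),
                c=int(raw.get("c", 1)),
                N0=float(raw.get("N0", 0.0)),
            )
        )
    transformations = []
    for i, raw in enumerate(doc.get("transformations", []) or []):
        where = f"transformations[{i}]"
        transformations.append(
            Transformation(
                substrates=_coerce_coeffs(_require(raw, "substrates", where), where + ".substrates"),
                products=_coerce_coeffs(_require(raw, "products", where), where + ".products"),
                deltaQ=float(raw.get("deltaQ", 0.0)),
                sigma=float(raw.get("sigma", 1.0)),
                label=str(raw.get("label", "")),
            )
        )
    return SystemSpec(
        species=tuple(species), transformations=tuple(transformations), kT=kT, label=label
    )


def spec_to_dict(spec: SystemSpec) -> dict:
    return {
        "label": spec.label,
        "kT": float(spec.kT),
        "species": [
            {"id": s.id, "G": float(s.G), "c": int(s.c), "N0": float(s.N0)}
            for s in spec.species
        ],
        "transformations": [
            {
                "substrates": {k: int(v) for k, v in tr.substrates.items()},
                "products": {k: int(v) for k, v in tr.products.items()},
                "deltaQ": float(tr.deltaQ),
                "sigma": float(tr.sigma),
                "label": tr.label,
            }
            for tr in spec.transformations
        ],
    }


def read_system(path) -> SystemSpec:
    """Read and validate a system config (YAML).

    Raises ParseError for malformed files and ValidationError (listing every
    violation) for structurally sound but invalid systems.
    """
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParseError(f"could not parse {path}: {exc}") from exc
    spec = spec_from_dict(doc)
    messages = validate_system(spec)
    if messages:
        raise ValidationError(messages)
    return spec


def write_system(spec: SystemSpec, path) -> None:
    """Write a system config; read_system(write_system(spec)) round-trips."""
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)
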
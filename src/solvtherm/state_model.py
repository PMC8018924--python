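"""Domain types and validation shared by all pipeline stages.

The central record is :class:`StateThermo`: one tautomer/conformer state of a
compound in one solvent phase, carrying the solution-phase electronic energy,
the uncorrected excess chemical potential from the integral-equation solvent
model, the partial molar volume, the net charge, and optional gas-phase
quantities. All energies are kept in kcal/mol internally; tables may declare
hartree columns which are converted at read time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HARTREE_TO_KCAL",
    "Constants",
    "SolventPhase",
    "GAS",
    "WATER",
    "CYCLOHEXANE",
    "OCTANOL",
    "StateThermo",
    "CorrectionParams",
    "VARIANTS",
    "SpeciesEnsemble",
    "IonizationInfo",
    "StateDataset",
    "validate_dataset",
    "read_state_table",
    "write_state_table",
]

#: Conversion factor from hartree to kcal/mol.
HARTREE_TO_KCAL = 627.5095

#: Columns of the canonical state table, in order.
STATE_COLUMNS = (
    "compound_id",
    "tautomer_id",
    "conformer_id",
    "phase",
    "E_sol",
    "E_gas",
    "mu_ex",
    "V_m",
    "q",
    "G_thermal_gas",
    "E_gas_highlevel",
)

_ENERGY_COLUMNS = ("E_sol", "E_gas", "mu_ex", "G_thermal_gas", "E_gas_highlevel")
_OPTIONAL_COLUMNS = ("E_gas", "G_thermal_gas", "E_gas_highlevel")


@dataclass(frozen=True)
class Constants:
    """Thermodynamic constants: molar gas constant and temperature.

    Defaults correspond to 25 °C; ``RT·ln10`` ≈ 1.3643 kcal/mol, the factor
    converting free-energy differences to decadic log units.
    """

    R: float = 1.987204e-3  # kcal/(mol·K)
    T: float = 298.15  # K

    @property
    def RT(self) -> float:
        return self.R * self.T

    @property
    def RT_ln10(self) -> float:
        return self.RT * math.log(10.0)


@dataclass(frozen=True)
class SolventPhase:
    """A solvent phase label. ``gas`` is reserved and carries no correction."""

    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("phase name must be non-empty")

    @property
    def is_gas(self) -> bool:
        return self.name == "gas"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


GAS = SolventPhase("gas")
WATER = SolventPhase("water")
CYCLOHEXANE = SolventPhase("cyclohexane")
OCTANOL = SolventPhase("octanol")


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class StateThermo:
    """One tautomer/conformer state of a compound in one solvent phase.

    Parameters
    ----------
    E_sol : float
        Solvent-polarized electronic energy in solution, kcal/mol.
    mu_ex : float
        Uncorrected excess chemical potential, kcal/mol.
    V_m : float
        Partial molar volume, Å³ (computed upstream; an input here).
    q : float
        Net charge in units of e; validated to be integer-valued.
    E_gas, G_thermal_gas, E_gas_highlevel : float, optional
        Gas-phase electronic energy of the same state, gas-phase thermal
        correction, and a higher-level (coupled-cluster grade) gas-phase
        energy. Required only by operations that use them.
    """

    compound_id: str
    tautomer_id: str
    conformer_id: str
    phase: SolventPhase
    E_sol: float
    mu_ex: float
    V_m: float
    q: float = 0.0
    E_gas: Optional[float] = None
    G_thermal_gas: Optional[float] = None
    E_gas_highlevel: Optional[float] = None

    def __post_init__(self) -> None:
        _require_finite("E_sol", self.E_sol)
        _require_finite("mu_ex", self.mu_ex)
        _require_finite("V_m", self.V_m)
        _require_finite("q", self.q)
        if abs(self.q - round(self.q)) > 1e-6:
            raise ValueError(
                f"net charge q must be integer-valued within 1e-6, got {self.q}"
            )
        for name in _OPTIONAL_COLUMNS:
            value = getattr(self, name)
            if value is not None:
                _require_finite(name, value)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.compound_id, self.tautomer_id, self.conformer_id, self.phase.name)


#: Free/fixed structure of each correction-model variant. A ``None`` entry
#: means the parameter is free; a number means it is fixed at that value.
VARIANTS: dict[str, dict[str, Optional[float]]] = {
    "1-par": {"c_mu": 1.0, "c_V": None, "c_q": 0.0, "d": 0.0},
    "2-par": {"c_mu": None, "c_V": None, "c_q": 0.0, "d": 0.0},
    "2-par-I": {"c_mu": 1.0, "c_V": None, "c_q": 0.0, "d": None},
    "3-par": {"c_mu": None, "c_V": None, "c_q": 0.0, "d": None},
    "water-3-par-q": {"c_mu": None, "c_V": None, "c_q": None, "d": 0.0},
}


@dataclass(frozen=True)
class CorrectionParams:
    """Linear correction to the excess chemical potential for one solvent.

    ``mu_corr = c_mu * mu_ex + c_V * V_m + c_q * q + d``

    The ``variant`` tag pins which entries are free versus fixed (see
    :data:`VARIANTS`); construction rejects values inconsistent with the
    variant's fixed entries.
    """

    variant: str
    phase: SolventPhase
    c_mu: float = 1.0
    c_V: float = 0.0
    c_q: float = 0.0
    d: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; known: {sorted(VARIANTS)}"
            )
        if self.phase.is_gas:
            raise ValueError("the gas phase carries no correction parameters")
        for name, fixed in VARIANTS[self.variant].items():
            value = getattr(self, name)
            _require_finite(name, value)
            if fixed is not None and abs(value - fixed) > 1e-12:
                raise ValueError(
                    f"variant {self.variant!r} fixes {name}={fixed}, got {value}"
                )

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n, v in VARIANTS[self.variant].items() if v is None)


@dataclass(frozen=True)
class SpeciesEnsemble:
    """All states of one chemical species in one phase.

    ``scope`` distinguishes the per-species partition function (one tautomer,
    summing over its conformers — used for tautomerization and pKa) from the
    per-compound one (all tautomers and conformers — used for logP/logD).
    """

    compound_id: str
    scope: str  # "single-tautomer" | "all-tautomers"
    phase: SolventPhase
    states: tuple[StateThermo, ...]

    def __post_init__(self) -> None:
        if self.scope not in ("single-tautomer", "all-tautomers"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if not self.states:
            raise ValueError("ensemble must contain at least one state")
        object.__setattr__(self, "states", tuple(self.states))
        for s in self.states:
            if s.compound_id != self.compound_id:
                raise ValueError(
                    f"state compound {s.compound_id!r} != ensemble {self.compound_id!r}"
                )
            if s.phase != self.phase:
                raise ValueError(
                    f"state phase {s.phase.name!r} != ensemble {self.phase.name!r}"
                )
        if self.scope == "single-tautomer":
            tauts = {s.tautomer_id for s in self.states}
            if len(tauts) > 1:
                raise ValueError(
                    f"single-tautomer ensemble spans tautomers {sorted(tauts)}"
                )

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class IonizationInfo:
    """Macroscopic ionization annotation for one compound (input, not computed)."""

    compound_id: str
    site_type: str  # "acid" | "base" | "none"
    pKa: Optional[float] = None

    def __post_init__(self) -> None:
        if self.site_type not in ("acid", "base", "none"):
            raise ValueError(f"site_type must be acid|base|none, got {self.site_type!r}")
        if self.site_type == "none" and self.pKa is not None:
            raise ValueError("site_type 'none' must not carry a pKa")
        if self.pKa is not None:
            _require_finite("pKa", self.pKa)


class StateDataset:
    """A validated collection of :class:`StateThermo` records.

    Indexed by the unique key (compound, tautomer, conformer, phase); provides
    ensemble assembly for the partition-function layer. Construction order of
    the input records is immaterial: the dataset is keyed, not positional.
    """

    def __init__(self, records: Iterable[StateThermo]):
        self._by_key: dict[tuple[str, str, str, str], StateThermo] = {}
        for rec in records:
            if not isinstance(rec, StateThermo):
                raise TypeError(f"expected StateThermo, got {type(rec).__name__}")
            if rec.key in self._by_key:
                raise ValueError(f"duplicate state key {rec.key}")
            self._by_key[rec.key] = rec

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self.records)

    @property
    def records(self) -> list[StateThermo]:
        return sorted(self._by_key.values(), key=lambda r: r.key)

    def __getitem__(self, key: tuple[str, str, str, str]) -> StateThermo:
        return self._by_key[key]

    def compounds(self) -> list[str]:
        return sorted({k[0] for k in self._by_key})

    def phases(self) -> list[str]:
        return sorted({k[3] for k in self._by_key})

    def select(
        self,
        compound_id: str,
        phase: SolventPhase,
        tautomer_id: Optional[str] = None,
    ) -> list[StateThermo]:
        out = [
            r
            for r in self.records
            if r.compound_id == compound_id
            and r.phase == phase
            and (tautomer_id is None or r.tautomer_id == tautomer_id)
        ]
        return out

    def ensemble(
        self,
        compound_id: str,
        phase: SolventPhase,
        tautomer_id: Optional[str] = None,
    ) -> SpeciesEnsemble:
        """Assemble a species ensemble; single-tautomer scope when a tautomer
        id is given, all-tautomers scope otherwise."""
        states = self.select(compound_id, phase, tautomer_id)
        if not states:
            raise KeyError(
                f"no states for compound={compound_id!r} phase={phase.name!r}"
                + (f" tautomer={tautomer_id!r}" if tautomer_id else "")
            )
        scope = "single-tautomer" if tautomer_id is not None else "all-tautomers"
        return SpeciesEnsemble(compound_id, scope, phase, tuple(states))


def validate_dataset(records: Iterable[StateThermo]) -> StateDataset:
    """Validate a collection of state records into an indexed dataset.

    Raises on duplicate (compound, tautomer, conformer, phase) keys; each
    record's own invariants (finite energies, integer charge) are enforced at
    record construction.
    """
    return StateDataset(records)


# ---------------------------------------------------------------------------
# Delimited-table I/O


def _detect_sep(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_state_table(path: str, energy_unit: str = "kcal/mol") -> StateDataset:
    """Read a state table (comma- or tab-delimited, auto-detected).

    Header names are fixed (see :data:`STATE_COLUMNS`); empty cells denote
    absent optional fields. ``energy_unit="hartree"`` converts every energy
    column (E_sol, E_gas, mu_ex, G_thermal_gas, E_gas_highlevel) to kcal/mol
    at read time; V_m stays in Å³ either way.
    """
    if energy_unit not in ("kcal/mol", "hartree"):
        raise ValueError(f"energy_unit must be 'kcal/mol' or 'hartree', got {energy_unit!r}")
    df = pd.read_csv(path, sep=_detect_sep(path), dtype={c: str for c in STATE_COLUMNS[:4]})
    required = [c for c in STATE_COLUMNS if c not in _OPTIONAL_COLUMNS]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    factor = HARTREE_TO_KCAL if energy_unit == "hartree" else 1.0
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for col in STATE_COLUMNS[4:]:
            value = getattr(row, col, None)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                value = None
            else:
                value = float(value)
                if col in _ENERGY_COLUMNS:
                    value *= factor
            if value is None:
                if col in _OPTIONAL_COLUMNS:
                    continue
                raise ValueError(f"empty cell in required column {col!r}")
            kwargs[col] = value
        records.append(
            StateThermo(
                compound_id=str(row.compound_id),
                tautomer_id=str(row.tautomer_id),
                conformer_id=str(row.conformer_id),
                phase=SolventPhase(str(row.phase)),
                **kwargs,
            )
        )
    return validate_dataset(records)


def write_state_table(dataset: StateDataset | Iterable[StateThermo], path: str, sep: str = ",") -> None:
    """Write a state table; floats at full round-trip precision."""
    records = dataset.records if isinstance(dataset, StateDataset) else list(dataset)
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "tautomer_id": r.tautomer_id,
                "conformer_id": r.conformer_id,
                "phase": r.phase.name,
                "E_sol": r.E_sol,
                "E_gas": r.E_gas,
                "mu_ex": r.mu_ex,
                "V_m": r.V_m,
                "q": r.q,
                "G_thermal_gas": r.G_thermal_gas,
                "E_gas_highlevel": r.E_gas_highlevel,
            }
        )
    df = pd.DataFrame(rows, columns=list(STATE_COLUMNS))
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
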
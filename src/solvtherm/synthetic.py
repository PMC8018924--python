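"""Synthetic datasets with known ground truth for every pipeline stage.

Emulates the *shape* of quantum-chemical solvation output — per-state
electronic energies, excess chemical potentials, partial molar volumes,
charges — with reference solvation free energies, pKa values and conformer
geometries constructed exactly from the generating equations, so that the
calibration and evaluation layers can be validated by parameter recovery.
No real chemistry is mimicked: identifiers are opaque, geometries are random
point clouds with controlled RMSD structure.

Energy scales follow the regimes of real data: excess chemical potentials in
[-80, +20] kcal/mol, partial molar volumes in [50, 400] Å³ (shared within a
species to ±2%), conformer spreads below 5 kcal/mol, so that the correction
terms have realistic magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .calibration import ReferenceRecord
from .conformers import Conformer, kabsch_rmsd
from .observables import PkaModelParams
from .solvation import ensemble_gibbs, gas_ensemble_gibbs
from .state_model import (
    CYCLOHEXANE,
    GAS,
    WATER,
    Constants,
    CorrectionParams,
    IonizationInfo,
    SolventPhase,
    SpeciesEnsemble,
    StateDataset,
    StateThermo,
    validate_dataset,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticSolvationData",
    "TitratableCompound",
    "ConformerSet",
    "generate_states",
    "generate_titratable",
    "generate_conformers",
    "default_true_params",
]


def default_true_params() -> dict[str, CorrectionParams]:
    """Ground-truth correction parameters used by default.

    The cyclohexane set is the published three-parameter model; the water set
    is a plausible charged-species-aware model (scaling near one, a small
    negative volume coefficient, an ion correction of order 10 kcal/mol per
    unit charge).
    """
    return {
        "cyclohexane": CorrectionParams(
            "3-par", CYCLOHEXANE, c_mu=1.8516, c_V=-0.14692, d=-1.0842
        ),
        "water": CorrectionParams(
            "water-3-par-q", WATER, c_mu=0.95, c_V=-0.08, c_q=-9.0
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions under which synthetic datasets are generated."""

    n_compounds: int = 500
    tautomers_per_compound: tuple[int, int] = (1, 1)  # inclusive range
    conformers_per_state: tuple[int, int] = (1, 1)
    true_params: Optional[dict[str, CorrectionParams]] = None
    true_pka_params: PkaModelParams = PkaModelParams(a=0.6, b=-160.0)
    noise_sd: float = 0.5  # kcal/mol on reference solvation free energies
    fraction_acids: float = 0.27
    fraction_bases: float = 0.63
    fraction_anions: float = 0.15  # water-phase charged subsets
    fraction_cations: float = 0.15
    pka_range: tuple[float, float] = (2.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        for name in ("tautomers_per_compound", "conformers_per_state"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for pair in ((self.fraction_acids, self.fraction_bases),
                     (self.fraction_anions, self.fraction_cations)):
            if min(pair) < 0 or sum(pair) > 1:
                raise ValueError("fractions must be in [0,1] and sum to <= 1")

    def resolved_params(self) -> dict[str, CorrectionParams]:
        return dict(self.true_params) if self.true_params else default_true_params()


@dataclass(frozen=True)
class SyntheticSolvationData:
    """States plus exact-equation references for one solvent phase."""

    phase: SolventPhase
    states: tuple[StateThermo, ...]  # solution- and gas-phase records
    references: tuple[ReferenceRecord, ...]
    true_params: CorrectionParams
    config: GeneratorConfig

    @property
    def dataset(self) -> StateDataset:
        return validate_dataset(self.states)

    def compounds(self) -> list[str]:
        return [r.compound_id for r in self.references]

    def ensembles(self) -> list[tuple[SpeciesEnsemble, SpeciesEnsemble]]:
        """(solution, gas) all-tautomers ensemble pairs, reference order."""
        ds = self.dataset
        return [
            (ds.ensemble(cid, self.phase), ds.ensemble(cid, GAS))
            for cid in self.compounds()
        ]

    def representative_states(self) -> list[StateThermo]:
        """Lowest-E_sol solution state per compound (E_gas populated)."""
        ds = self.dataset
        return [
            min(ds.select(cid, self.phase), key=lambda s: s.E_sol)
            for cid in self.compounds()
        ]

    def reference_values(self) -> np.ndarray:
        return np.array([r.value for r in self.references])


def generate_states(
    config: GeneratorConfig,
    phase_name: str = "cyclohexane",
    const: Constants = Constants(),
) -> SyntheticSolvationData:
    """Draw per-state thermodynamic records and exact-model references.

    For every compound/tautomer/conformer the gas-phase energy, solution
    energy, excess chemical potential and (species-shared, ±2%) partial molar
    volume are drawn; the reference solvation free energy is the Boltzmann
    ensemble Gibbs energy under the ground-truth correction minus the
    gas-phase ensemble Gibbs energy, plus Gaussian noise of sd ``noise_sd``.
    Deterministic for a fixed seed.
    """
    params = config.resolved_params()
    if phase_name not in params:
        raise ValueError(f"no true parameters declared for phase {phase_name!r}")
    true = params[phase_name]
    phase = true.phase
    rng = np.random.default_rng(config.seed)
    charged_allowed = phase.name == "water" and true.c_q != 0.0
    states: list[StateThermo] = []
    refs: list[ReferenceRecord] = []
    t_lo, t_hi = config.tautomers_per_compound
    c_lo, c_hi = config.conformers_per_state
    for i in range(config.n_compounds):
        cid = f"CMP{i:04d}"
        if charged_allowed:
            u = rng.uniform()
            subset = (
                "anion" if u < config.fraction_anions
                else "cation" if u < config.fraction_anions + config.fraction_cations
                else "neutral"
            )
        else:
            subset = "neutral"
        q = {"neutral": 0.0, "anion": -1.0, "cation": 1.0}[subset]
        V_base = rng.uniform(50.0, 400.0)
        mu_base = rng.uniform(-80.0, 20.0)
        n_taut = int(rng.integers(t_lo, t_hi + 1))
        sol_states, gas_states = [], []
        for t in range(n_taut):
            tid = f"t{t}"
            e_taut = rng.uniform(-20.0, 20.0)
            n_conf = int(rng.integers(c_lo, c_hi + 1))
            for c in range(n_conf):
                conf = f"c{c}"
                e_gas = e_taut + rng.uniform(0.0, 5.0)
                e_sol = e_gas + rng.uniform(-3.0, 1.0)
                mu_ex = mu_base + rng.uniform(-1.0, 1.0)
                v_m = V_base * (1.0 + rng.uniform(-0.02, 0.02))
                sol_states.append(
                    StateThermo(cid, tid, conf, phase, E_sol=e_sol, mu_ex=mu_ex,
                                V_m=v_m, q=q, E_gas=e_gas)
                )
                gas_states.append(
                    StateThermo(cid, tid, conf, GAS, E_sol=e_gas, mu_ex=0.0,
                                V_m=v_m, q=q, E_gas=e_gas)
                )
        ens_sol = SpeciesEnsemble(cid, "all-tautomers", phase, tuple(sol_states))
        ens_gas = SpeciesEnsemble(cid, "all-tautomers", GAS, tuple(gas_states))
        g_sol = ensemble_gibbs(ens_sol, true, const).G
        g_gas = gas_ensemble_gibbs(ens_gas, const).G
        value = g_sol - g_gas
        if config.noise_sd > 0:
            value += config.noise_sd * rng.standard_normal()
        states.extend(sol_states)
        states.extend(gas_states)
        refs.append(ReferenceRecord(cid, phase, "dG_solv", float(value), subset))
    return SyntheticSolvationData(
        phase=phase, states=tuple(states), references=tuple(refs),
        true_params=true, config=config,
    )


@dataclass(frozen=True)
class TitratableCompound:
    """A protonation pair with ground-truth pKa and neutral-state logP."""

    compound_id: str
    ion: IonizationInfo  # carries the true pKa
    dG_deprot_true: float  # kcal/mol, exact under the true pKa model
    ens_protonated_W: SpeciesEnsemble
    ens_deprotonated_W: SpeciesEnsemble
    logP_true: float
    G_neutral_W: float  # noisy observables for the partitioning layer
    G_neutral_organic: float


def generate_titratable(
    config: GeneratorConfig,
    const: Constants = Constants(),
) -> list[TitratableCompound]:
    """Protonated/deprotonated ensemble pairs with exact ground-truth pKa.

    The deprotonation Gibbs-energy difference of each compound is constructed
    so the true pKa model maps it exactly onto the drawn pKa; Gaussian noise
    of sd ``noise_sd`` perturbs the state energies (hence the recomputed ΔG)
    but never the ground truth. Neutral-species Gibbs energies in water and
    in an organic phase encode a drawn true logP the same way.
    """
    if config.fraction_acids + config.fraction_bases <= 0:
        raise ValueError("need a positive acid or base fraction")
    params = config.resolved_params()
    if "water" not in params:
        raise ValueError("titratable generation needs true water parameters")
    true_w = params["water"]
    pk = config.true_pka_params
    if pk.a == 0:
        raise ValueError("true pKa slope must be nonzero to invert the model")
    rng = np.random.default_rng(config.seed + 1)
    out: list[TitratableCompound] = []
    lo, hi = config.pka_range

    def water_state(cid: str, tag: str, g_target: float, q: float) -> StateThermo:
        """Single state whose free energy under true_w equals g_target."""
        mu = rng.uniform(-80.0, 20.0)
        v = rng.uniform(50.0, 400.0)
        corr = true_w.c_mu * mu + true_w.c_V * v + true_w.c_q * q + true_w.d
        e_sol = g_target - corr + config.noise_sd * rng.standard_normal()
        return StateThermo(cid, tag, "c0", true_w.phase, E_sol=e_sol,
                           mu_ex=mu, V_m=v, q=q)

    for i in range(config.n_compounds):
        cid = f"TIT{i:04d}"
        u = rng.uniform()
        if u < config.fraction_acids:
            site = "acid"
        elif u < config.fraction_acids + config.fraction_bases:
            site = "base"
        else:
            site = "none"
        pka_true = float(rng.uniform(lo, hi))
        dG = (pka_true - pk.b) / pk.a
        g_prot = rng.uniform(-120.0, -40.0)
        g_deprot = g_prot + dG
        q_prot, q_deprot = (0.0, -1.0) if site != "base" else (1.0, 0.0)
        ens_p = SpeciesEnsemble(
            cid, "single-tautomer", true_w.phase,
            (water_state(cid, "prot", g_prot, q_prot),),
        )
        ens_d = SpeciesEnsemble(
            cid, "single-tautomer", true_w.phase,
            (water_state(cid, "deprot", g_deprot, q_deprot),),
        )
        logp_true = float(rng.uniform(-4.0, 4.0))
        g_w = rng.uniform(-80.0, -20.0)
        g_o = g_w - logp_true * const.RT_ln10
        noise = config.noise_sd * rng.standard_normal(2)
        ion = IonizationInfo(cid, site, None if site == "none" else pka_true)
        out.append(
            TitratableCompound(
                compound_id=cid,
                ion=ion,
                dG_deprot_true=dG,
                ens_protonated_W=ens_p,
                ens_deprotonated_W=ens_d,
                logP_true=logp_true,
                G_neutral_W=g_w + float(noise[0]),
                G_neutral_organic=g_o + float(noise[1]),
            )
        )
    return out


@dataclass(frozen=True)
class ConformerSet:
    """Conformers with a planted cluster structure and known truth."""

    conformers: tuple[Conformer, ...]
    true_assignments: dict[str, int]
    n_true_clusters: int


def generate_conformers(
    n: int,
    n_atoms: int,
    spread: float = 1.0,
    seed: int = 0,
    n_clusters: int = 3,
    jitter: float = 0.06,
    cluster_energy_offsets: Optional[Sequence[float]] = None,
) -> ConformerSet:
    """Random geometries in ``n_clusters`` planted clusters.

    ``spread`` is the target inter-cluster RMSD: 0 collapses everything onto
    one geometry (true cluster count 1); values >= 0.8 Å give well-separated
    clusters (members within ~0.2 Å of their center, centers pairwise at
    least ``spread`` apart after optimal superposition, verified at
    generation time). Intermediate spreads would make the planted truth
    ambiguous against the 0.5 Å clustering cutoff and are rejected.
    ``cluster_energy_offsets`` shifts whole clusters (e.g. beyond the energy
    window) on top of the default per-cluster energy ladder.
    """
    if n_atoms < 3:
        raise ValueError("n_atoms must be >= 3")
    if n < 1 or n_clusters < 1 or n < n_clusters:
        raise ValueError("need n >= n_clusters >= 1")
    if spread != 0.0 and spread < 0.8:
        raise ValueError("spread must be 0 or >= 0.8 Å for an unambiguous truth")
    rng = np.random.default_rng(seed)
    labels = tuple(rng.choice(["C", "N", "O", "S"], size=n_atoms))
    base = rng.normal(scale=2.0, size=(n_atoms, 3))

    def as_conf(coords, cid="x", energy=0.0):
        return Conformer(cid, coords, energy, labels)

    centers = [base.copy()]
    if spread > 0:
        for k in range(1, n_clusters):
            direction = rng.normal(size=(n_atoms, 3))
            direction /= np.sqrt(np.mean(np.sum(direction**2, axis=1)))
            scale = spread
            for _ in range(60):
                cand = base + scale * direction
                dists = [kabsch_rmsd(as_conf(c), as_conf(cand)) for c in centers]
                if min(dists) >= spread:
                    break
                scale *= 1.25
            else:
                raise RuntimeError("failed to plant a sufficiently separated cluster")
            centers.append(cand)
    else:
        centers = [base.copy() for _ in range(n_clusters)]

    offsets = list(cluster_energy_offsets) if cluster_energy_offsets else [0.0] * n_clusters
    if len(offsets) != n_clusters:
        raise ValueError("cluster_energy_offsets must have one entry per cluster")
    conformers: list[Conformer] = []
    assignments: dict[str, int] = {}
    for i in range(n):
        k = i % n_clusters
        coords = centers[k] + rng.normal(scale=jitter, size=(n_atoms, 3))
        # per-cluster energy ladder keeps representatives identifiable
        energy = 0.5 * k + rng.uniform(0.0, 0.4) + offsets[k]
        cid = f"conf{i:03d}"
        conformers.append(Conformer(cid, coords, float(energy), labels))
        assignments[cid] = k
    n_true = n_clusters if spread > 0 else 1
    if spread == 0:
        assignments = {cid: 0 for cid in assignments}
    return ConformerSet(tuple(conformers), assignments, n_true)
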
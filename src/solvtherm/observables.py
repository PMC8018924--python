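"""Physicochemical observables: log P, log D at pH 7.4, pKa, tautomer ΔG.

The partition coefficient between water (W) and an organic phase (O) follows
directly from the two ensemble Gibbs energies,

    log P = (G(W) - G(O)) / (RT ln 10),

and is reduced to the distribution coefficient at a given pH by the ionized
fraction: for bases log D = log P - log10(1 + 10^(pKa - pH)), for acids
log D = log P - log10(1 + 10^(pH - pKa)). The ionized species is assumed
unable to enter the organic phase, so log D <= log P always.

Acidity constants come from a calibrated two-parameter affine map on the
deprotonation Gibbs-energy difference in water: pKa = a * ΔG_deprot + b,
where the slope scales the computed free energy difference and the intercept
absorbs the free-proton contribution.

Tautomerization ΔG⁰ (water) is provided both directly, as the difference of
solution-phase partition-function Gibbs energies, and via an explicit
thermodynamic cycle combining a high-level gas-phase leg (with thermal
corrections) with the difference of hydration free energies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .solvation import ensemble_gibbs, gas_ensemble_gibbs, solvation_free_energy
from .state_model import Constants, CorrectionParams, IonizationInfo, SpeciesEnsemble

__all__ = [
    "PkaModelParams",
    "TautomerReaction",
    "log_p",
    "log_d",
    "pka_from_gibbs",
    "tautomer_dG_direct",
    "tautomer_dG_cycle",
]


@dataclass(frozen=True)
class PkaModelParams:
    """Slope/intercept of the linear pKa model: pKa = a·ΔG_deprot + b."""

    a: float  # per (kcal/mol)
    b: float  # pK units

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("pKa model parameters must be finite")
        if self.a <= 0:
            warnings.warn(
                "pKa model slope a <= 0: deprotonation becoming easier would "
                "raise the predicted pKa; model is not physically oriented",
                stacklevel=2,
            )


@dataclass(frozen=True)
class TautomerReaction:
    """A tautomerization a → b with its reaction Gibbs energy (kcal/mol)."""

    reaction_id: str
    species_a: str
    species_b: str
    dG: float

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise ValueError("tautomer reaction requires two distinct species")


def log_p(G_water: float, G_organic: float, const: Constants = Constants()) -> float:
    """Partition coefficient from the two phase Gibbs energies.

    Positive when the organic phase is favored (G_organic < G_water); a very
    hydrophilic compound (G_water << G_organic) gets a negative log P.
    """
    if not (math.isfinite(G_water) and math.isfinite(G_organic)):
        raise ValueError("Gibbs energies must be finite")
    return (G_water - G_organic) / const.RT_ln10


def log_d(logP: float, ion: IonizationInfo, pH: float = 7.4) -> float:
    """Distribution coefficient at the given pH (default 7.4).

    Uses np.logaddexp for the log10(1 + 10^x) term so extreme pKa values
    neither overflow nor lose the log D <= log P guarantee.
    """
    if ion.site_type == "none":
        return logP
    if ion.pKa is None:
        raise ValueError(
            f"compound {ion.compound_id!r}: site_type {ion.site_type!r} requires a pKa"
        )
    x = ion.pKa - pH if ion.site_type == "base" else pH - ion.pKa
    shift = np.logaddexp(0.0, x * math.log(10.0)) / math.log(10.0)
    return logP - float(shift)


def pka_from_gibbs(
    G_protonated_W: float,
    G_deprotonated_W: float,
    params: PkaModelParams,
) -> float:
    """pKa from the water-phase deprotonation Gibbs-energy difference."""
    dG = G_deprotonated_W - G_protonated_W
    if not math.isfinite(dG):
        raise ValueError("Gibbs energies must be finite")
    return params.a * dG + params.b


def tautomer_dG_direct(
    ens_a: SpeciesEnsemble,
    ens_b: SpeciesEnsemble,
    params: CorrectionParams,
    const: Constants = Constants(),
) -> TautomerReaction:
    """ΔG⁰(a→b) = G_b(W) − G_a(W) from solution-phase partition functions."""
    if ens_a.phase != ens_b.phase:
        raise ValueError(
            f"phase mismatch: {ens_a.phase.name!r} vs {ens_b.phase.name!r}"
        )
    G_a = ensemble_gibbs(ens_a, params, const).G
    G_b = ensemble_gibbs(ens_b, params, const).G
    return TautomerReaction(
        reaction_id=f"{ens_a.compound_id} -> {ens_b.compound_id}",
        species_a=ens_a.compound_id,
        species_b=ens_b.compound_id,
        dG=G_b - G_a,
    )


def tautomer_dG_cycle(
    ens_a_gas: SpeciesEnsemble,
    ens_a_sol: SpeciesEnsemble,
    ens_b_gas: SpeciesEnsemble,
    ens_b_sol: SpeciesEnsemble,
    params: CorrectionParams,
    const: Constants = Constants(),
) -> TautomerReaction:
    """ΔG⁰(a→b) by the explicit thermodynamic cycle.

    Combines the high-level gas-phase free-energy difference (coupled-cluster
    grade electronic energies plus thermal corrections, partition-function
    averaged over rotamers) with the hydration free-energy difference
    ΔG_hyd(b) − ΔG_hyd(a), where each hydration leg is the solution-phase
    partition function minus the standard gas-phase one.
    """
    if ens_a_sol.phase != ens_b_sol.phase:
        raise ValueError("solution phases of the two species differ")
    G_gas_a = gas_ensemble_gibbs(ens_a_gas, const, high_level=True, thermal=True).G
    G_gas_b = gas_ensemble_gibbs(ens_b_gas, const, high_level=True, thermal=True).G
    dG_hyd_a = solvation_free_energy(ens_a_sol, ens_a_gas, params, const)
    dG_hyd_b = solvation_free_energy(ens_b_sol, ens_b_gas, params, const)
    return TautomerReaction(
        reaction_id=f"{ens_a_sol.compound_id} -> {ens_b_sol.compound_id}",
        species_a=ens_a_sol.compound_id,
        species_b=ens_b_sol.compound_id,
        dG=(G_gas_b - G_gas_a) + (dG_hyd_b - dG_hyd_a),
    )
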
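"""Corrected excess chemical potentials and partition-function Gibbs energies.

The free energy of a species in solvent *i* is a Boltzmann-weighted sum over
its tautomer/conformer states::

    G(i) = -RT ln sum_tc exp[-(E_sol_tc(i) + mu_corr_tc(i)) / RT]

with the empirically corrected excess chemical potential::

    mu_corr = c_mu * mu_ex + c_V * V_m + c_q * q + d

The log-sum-exp is evaluated shift-stably; naive exponentiation overflows for
per-state free energies beyond a few hundred RT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .state_model import Constants, CorrectionParams, SpeciesEnsemble, StateThermo

__all__ = [
    "GibbsResult",
    "corrected_mu_ex",
    "state_free_energy",
    "ensemble_gibbs",
    "gas_ensemble_gibbs",
    "solvation_free_energy",
]


@dataclass(frozen=True, eq=False)
class GibbsResult:
    """Ensemble Gibbs energy with per-state Boltzmann populations."""

    G: float  # kcal/mol
    n_states: int
    weights: np.ndarray  # populations, sum to 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


def _check_phase(state: StateThermo, params: CorrectionParams) -> None:
    if state.phase != params.phase:
        raise ValueError(
            f"phase mismatch: state in {state.phase.name!r}, "
            f"parameters for {params.phase.name!r}"
        )


def corrected_mu_ex(state: StateThermo, params: CorrectionParams) -> float:
    """Empirically corrected excess chemical potential, kcal/mol."""
    _check_phase(state, params)
    return params.c_mu * state.mu_ex + params.c_V * state.V_m + params.c_q * state.q + params.d


def state_free_energy(state: StateThermo, params: CorrectionParams) -> float:
    """Per-state free energy g = E_sol + mu_corr (the exponent argument)."""
    _check_phase(state, params)
    return state.E_sol + corrected_mu_ex(state, params)


def _partition_gibbs(g: np.ndarray, const: Constants) -> GibbsResult:
    g = np.asarray(g, dtype=float)
    if g.size == 0:
        raise ValueError("empty ensemble")
    RT = const.RT
    # shift-stable: logsumexp subtracts the max internally
    lse = logsumexp(-g / RT)
    log_w = -g / RT - lse
    return GibbsResult(G=float(-RT * lse), n_states=int(g.size), weights=np.exp(log_w))


def ensemble_gibbs(
    ensemble: SpeciesEnsemble,
    params: CorrectionParams,
    const: Constants = Constants(),
) -> GibbsResult:
    """Partition-function Gibbs energy of a solution-phase ensemble."""
    if ensemble.phase.is_gas:
        raise ValueError("gas-phase ensembles take no correction; use gas_ensemble_gibbs")
    g = np.array([state_free_energy(s, params) for s in ensemble.states])
    return _partition_gibbs(g, const)


def gas_ensemble_gibbs(
    ensemble: SpeciesEnsemble,
    const: Constants = Constants(),
    high_level: bool = False,
    thermal: bool = False,
) -> GibbsResult:
    """Partition-function Gibbs energy over gas-phase states.

    Uses the uncorrected gas-phase electronic energy E_gas (no excess
    chemical potential: the gas state is solvent-independent). With
    ``high_level=True`` the coupled-cluster grade energy E_gas_highlevel is
    used instead; ``thermal=True`` adds the per-state thermal correction.
    Missing required fields raise, naming the offending state.
    """
    g = []
    for s in ensemble.states:
        e = s.E_gas_highlevel if high_level else s.E_gas
        if e is None:
            name = "E_gas_highlevel" if high_level else "E_gas"
            raise ValueError(f"state {s.key} lacks {name}")
        if thermal:
            if s.G_thermal_gas is None:
                raise ValueError(f"state {s.key} lacks G_thermal_gas")
            e = e + s.G_thermal_gas
        g.append(e)
    return _partition_gibbs(np.array(g), const)


def solvation_free_energy(
    ensemble_sol: SpeciesEnsemble,
    ensemble_gas: SpeciesEnsemble,
    params: CorrectionParams,
    const: Constants = Constants(),
) -> float:
    """Solvation free energy: solution-phase G minus gas-phase G.

    The gas leg is the partition function over E_gas only — thermal
    corrections are deliberately ignored on this (direct) route; they enter
    only the explicit thermodynamic-cycle route for tautomerization.
    """
    g_sol = ensemble_gibbs(ensemble_sol, params, const)
    g_gas = gas_ensemble_gibbs(ensemble_gas, const)
    return g_sol.G - g_gas.G
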
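"""Least-squares calibration of the correction model and the pKa model.

The solvation-model fit minimizes, over the variant's free parameters,

    sum_i [ (E_sol_i - E_gas_i + c_mu*mu_ex_i + c_V*V_m_i + c_q*q_i + d) - dG_ref_i ]^2

with one representative state per training compound (ordinary least squares,
the default pathway), or — for multi-conformer training data — with the
predicted solvation free energy evaluated through the Boltzmann partition
function (nonlinear least squares, initialized from the linear fit).

The pKa fit is plain OLS of reference pKa values on deprotonation
Gibbs-energy differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .evaluation import MetricSet, PredictionTable, metrics
from .observables import PkaModelParams
from .solvation import corrected_mu_ex, ensemble_gibbs, gas_ensemble_gibbs
from .state_model import (
    VARIANTS,
    Constants,
    CorrectionParams,
    SolventPhase,
    SpeciesEnsemble,
    StateThermo,
)

__all__ = [
    "ReferenceRecord",
    "FitReport",
    "single_state_dG",
    "fit_correction",
    "fit_pka",
    "fit_correction_ensemble",
]


@dataclass(frozen=True)
class ReferenceRecord:
    """One experimental reference value for training or evaluation."""

    compound_id: str
    phase: SolventPhase
    observable: str  # "dG_solv" | "pKa"
    value: float
    subset: str = "neutral"  # "neutral" | "anion" | "cation"

    def __post_init__(self) -> None:
        if self.observable not in ("dG_solv", "pKa"):
            raise ValueError(f"unknown observable {self.observable!r}")
        if self.subset not in ("neutral", "anion", "cation"):
            raise ValueError(f"unknown subset {self.subset!r}")
        if not np.isfinite(self.value):
            raise ValueError("reference value must be finite")


@dataclass(frozen=True)
class FitReport:
    """Fitted parameters together with training-set metrics."""

    params: object  # CorrectionParams or PkaModelParams
    rmse: float
    mae: float
    mse: float
    n: int
    m_prime: Optional[float] = None
    b_prime: Optional[float] = None
    r2: Optional[float] = None
    nfev: Optional[int] = None  # nonlinear fits only

    @property
    def metrics(self) -> MetricSet:
        return MetricSet(
            rmse=self.rmse, mae=self.mae, mse=self.mse, n=self.n,
            m_prime=self.m_prime, b_prime=self.b_prime, r2=self.r2,
        )


def single_state_dG(state: StateThermo, params: CorrectionParams) -> float:
    """Predicted solvation free energy of a single representative state."""
    if state.E_gas is None:
        raise ValueError(f"state {state.key} lacks E_gas")
    return state.E_sol - state.E_gas + corrected_mu_ex(state, params)


_COLUMN_OF = {"c_mu": "mu_ex", "c_V": "V_m", "c_q": "q", "d": None}


def _report(params, ids, y_ref, y_pred, nfev=None) -> FitReport:
    # row index in the id guards against repeated training compounds
    uids = tuple(f"{i}:{cid}" for i, cid in enumerate(ids))
    table = PredictionTable(ids=uids, y_exp=np.asarray(y_ref), y_calc=np.asarray(y_pred))
    m = metrics(table)
    return FitReport(
        params=params, rmse=m.rmse, mae=m.mae, mse=m.mse, n=m.n,
        m_prime=m.m_prime, b_prime=m.b_prime, r2=m.r2, nfev=nfev,
    )


def fit_correction(
    states: Sequence[StateThermo],
    dG_ref: Sequence[float],
    variant: str,
) -> FitReport:
    """Ordinary least squares for one correction-model variant.

    One representative state per training compound; all states must share a
    phase (the fitted parameters' phase). Fixed entries of the variant are
    honored exactly; rank-deficient designs are rejected naming the
    degenerate column.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; known: {sorted(VARIANTS)}")
    states = list(states)
    y_ref = np.asarray(dG_ref, dtype=float)
    if len(states) != y_ref.size:
        raise ValueError("states and dG_ref must have equal lengths")
    phases = {s.phase for s in states}
    if len(phases) != 1:
        raise ValueError(f"training states span phases {sorted(p.name for p in phases)}")
    (phase,) = phases
    spec = VARIANTS[variant]
    free = [name for name, fixed in spec.items() if fixed is None]
    if len(states) < len(free):
        raise ValueError(
            f"{len(states)} records cannot determine {len(free)} free parameters"
        )

    def columns(sts: Sequence[StateThermo]) -> dict[str, np.ndarray]:
        return {
            "mu_ex": np.array([s.mu_ex for s in sts]),
            "V_m": np.array([s.V_m for s in sts]),
            "q": np.array([s.q for s in sts]),
        }

    cols = columns(states)
    for s in states:
        if s.E_gas is None:
            raise ValueError(f"state {s.key} lacks E_gas")
    base = np.array([s.E_sol - s.E_gas for s in states])
    # move fixed contributions to the left-hand side
    offset = np.zeros(len(states))
    for name, fixed in spec.items():
        if fixed:
            offset += fixed * cols[_COLUMN_OF[name]]
    design = []
    has_intercept = "d" in free
    for name in free:
        col = np.ones(len(states)) if name == "d" else cols[_COLUMN_OF[name]]
        if name != "d":
            if np.all(col == 0.0) or (has_intercept and np.ptp(col) == 0.0):
                raise ValueError(
                    f"degenerate design column for {name} "
                    f"({_COLUMN_OF[name]} constant{' (zero)' if np.all(col == 0) else ''})"
                )
        design.append(col)
    A = np.column_stack(design)
    if np.linalg.matrix_rank(A) < len(free):
        raise ValueError(f"rank-deficient design for free parameters {free}")
    y = y_ref - base - offset
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    values = {name: float(fixed) for name, fixed in spec.items() if fixed is not None}
    values.update({name: float(b) for name, b in zip(free, beta)})
    params = CorrectionParams(variant=variant, phase=phase, **values)
    y_pred = np.array([single_state_dG(s, params) for s in states])
    return _report(params, [s.compound_id for s in states], y_ref, y_pred)


def fit_pka(pairs: Sequence[tuple[float, float]]) -> FitReport:
    """OLS of reference pKa on deprotonation ΔG: pKa = a·ΔG + b."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (dG, pKa) pairs")
    dG, pka = arr[:, 0], arr[:, 1]
    if np.ptp(dG) == 0.0:
        raise ValueError("all ΔG values equal: slope is undetermined")
    a, b = np.polyfit(dG, pka, 1)
    params = PkaModelParams(a=float(a), b=float(b))
    y_pred = params.a * dG + params.b
    ids = [f"pair{i}" for i in range(arr.shape[0])]
    return _report(params, ids, pka, y_pred)


def fit_correction_ensemble(
    ensembles: Sequence[tuple[SpeciesEnsemble, SpeciesEnsemble]],
    dG_ref: Sequence[float],
    variant: str,
    const: Constants = Constants(),
    max_nfev: int = 200,
    xtol: float = 1e-12,
) -> FitReport:
    """Nonlinear fit where the prediction runs through the partition function.

    Each training compound contributes a (solution, gas) ensemble pair; the
    predicted solvation free energy is the Boltzmann-weighted solution Gibbs
    energy minus the gas-phase one. Initialized from the linear fit on each
    compound's lowest-E_sol state; for all-singleton ensembles the result
    coincides with :func:`fit_correction`.
    """
    ensembles = list(ensembles)
    y_ref = np.asarray(dG_ref, dtype=float)
    if len(ensembles) != y_ref.size:
        raise ValueError("ensembles and dG_ref must have equal lengths")
    reps = []
    for ens_sol, ens_gas in ensembles:
        if ens_sol.phase.is_gas or not ens_gas.phase.is_gas:
            raise ValueError("each pair must be (solution ensemble, gas ensemble)")
        best = min(ens_sol.states, key=lambda s: s.E_sol)
        gas_e = min(s.E_gas for s in ens_gas.states if s.E_gas is not None)
        reps.append(replace(best, E_gas=gas_e))
    linear = fit_correction(reps, y_ref, variant)
    p0: CorrectionParams = linear.params
    free = p0.free_names
    x0 = np.array([getattr(p0, name) for name in free])

    def build(x: np.ndarray) -> CorrectionParams:
        values = {name: getattr(p0, name) for name in ("c_mu", "c_V", "c_q", "d")}
        values.update({name: float(v) for name, v in zip(free, x)})
        return CorrectionParams(variant=variant, phase=p0.phase, **values)

    def predict(params: CorrectionParams) -> np.ndarray:
        out = []
        for ens_sol, ens_gas in ensembles:
            g_sol = ensemble_gibbs(ens_sol, params, const).G
            g_gas = gas_ensemble_gibbs(ens_gas, const).G
            out.append(g_sol - g_gas)
        return np.array(out)

    def residuals(x: np.ndarray) -> np.ndarray:
        return predict(build(x)) - y_ref

    sol = least_squares(residuals, x0, xtol=xtol, ftol=1e-14, gtol=1e-14, max_nfev=max_nfev)
    if sol.status == 0:
        raise RuntimeError(
            f"ensemble fit did not converge within {max_nfev} evaluations; "
            f"last iterate {dict(zip(free, sol.x))}"
        )
    params = build(sol.x)
    y_pred = predict(params)
    ids = [pair[0].compound_id for pair in ensembles]
    return _report(params, ids, y_ref, y_pred, nfev=int(sol.nfev))
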
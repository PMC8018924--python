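"""Challenge-style statistics: error metrics, subgroups, exclusion, consensus.

Conventions (chosen to reproduce blind-challenge reporting):

* errors are calculated − experimental;
* MSE is the **mean signed error** (bias), not mean squared error;
* all means and variances use the population (divide-by-n) convention;
* the descriptive regression fits calculated = m'·experimental + b' and
  reports R² as the squared Pearson correlation (always in [0, 1]).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["PredictionTable", "MetricSet", "metrics", "exclude", "consensus", "grouped_metrics"]


@dataclass(frozen=True)
class MetricSet:
    """Error metrics plus descriptive-regression diagnostics.

    Regression fields (``m_prime``, ``b_prime``, ``r2``) are ``None`` when
    undefined (fewer than two points or zero variance in the experimental
    values) — an explicit marker, never silent NaN.
    """

    rmse: float
    mae: float
    mse: float  # mean signed error (bias)
    n: int
    m_prime: Optional[float] = None
    b_prime: Optional[float] = None
    r2: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "mse": self.mse,
            "m_prime": self.m_prime,
            "b_prime": self.b_prime,
            "r2": self.r2,
            "n": self.n,
        }


@dataclass(frozen=True, eq=False)
class PredictionTable:
    """Paired experimental/calculated values with ids and optional groups.

    Missing predictions are flagged through ``missing`` (their ``y_calc``
    entries are ignored, typically NaN); they stay in the table — visible,
    never silently dropped — and are excluded from metric computation.
    ``provenance`` accumulates a human-readable audit trail (exclusions,
    consensus construction).
    """

    ids: tuple[str, ...]
    y_exp: np.ndarray
    y_calc: np.ndarray
    group: Optional[tuple[str, ...]] = None
    units: str = ""
    missing: frozenset[str] = frozenset()
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        y_exp = np.asarray(self.y_exp, dtype=float)
        y_calc = np.asarray(self.y_calc, dtype=float)
        if not (len(ids) == y_exp.size == y_calc.size):
            raise ValueError("ids, y_exp, y_calc must have equal lengths")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ids: {dupes}")
        if self.group is not None and len(self.group) != len(ids):
            raise ValueError("group labels must match table length")
        bad = [
            i
            for i, c in zip(ids, y_calc)
            if not math.isfinite(c) and i not in self.missing
        ]
        if bad:
            raise ValueError(
                f"non-finite predictions for {bad}; flag them via 'missing'"
            )
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "y_exp", y_exp)
        object.__setattr__(self, "y_calc", y_calc)
        if self.group is not None:
            object.__setattr__(self, "group", tuple(str(g) for g in self.group))
        object.__setattr__(self, "missing", frozenset(self.missing))
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def __len__(self) -> int:
        return len(self.ids)

    def usable_mask(self) -> np.ndarray:
        return np.array([i not in self.missing for i in self.ids], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "y_exp": self.y_exp, "y_calc": self.y_calc})
        if self.group is not None:
            df["group"] = self.group
        df["missing"] = [i in self.missing for i in self.ids]
        return df


def metrics(table: PredictionTable) -> MetricSet:
    """RMSE / MAE / MSE and descriptive regression for one table.

    Flagged-missing ids are excluded before any computation.
    """
    mask = table.usable_mask()
    if not mask.any():
        raise ValueError("no usable (non-missing) rows")
    x = table.y_exp[mask]
    y = table.y_calc[mask]
    e = y - x
    n = int(mask.sum())
    out = dict(
        rmse=float(np.sqrt(np.mean(e**2))),
        mae=float(np.mean(np.abs(e))),
        mse=float(np.mean(e)),
        n=n,
    )
    if n >= 2 and np.ptp(x) > 0:
        # explicit population moments: robust where generic least-squares
        # scaling degenerates (subnormal spreads)
        vx = float(np.var(x))
        cov = float(np.mean((x - x.mean()) * (y - y.mean())))
        m = cov / vx if vx > 0 else math.inf
        if math.isfinite(m):
            b = float(y.mean() - m * x.mean())
            vy = float(np.var(y))
            r2 = cov**2 / (vx * vy) if vy > 0 else None
            if r2 is not None and not math.isfinite(r2):
                r2 = None
            out.update(m_prime=m, b_prime=b, r2=r2)
    return MetricSet(**out)


def exclude(table: PredictionTable, ids: Iterable[str]) -> PredictionTable:
    """Drop the listed ids, recording the exclusion in provenance.

    Unknown ids are reported with a warning; dropping every row is an error.
    """
    ids = [str(i) for i in ids]
    unknown = sorted(set(ids) - set(table.ids))
    if unknown:
        warnings.warn(f"exclude: unknown ids {unknown}", stacklevel=2)
    keep = [i for i, cid in enumerate(table.ids) if cid not in set(ids)]
    if not keep:
        raise ValueError("exclusion would remove every row")
    dropped = sorted(set(ids) & set(table.ids))
    return PredictionTable(
        ids=tuple(table.ids[i] for i in keep),
        y_exp=table.y_exp[keep],
        y_calc=table.y_calc[keep],
        group=tuple(table.group[i] for i in keep) if table.group else None,
        units=table.units,
        missing=table.missing & {table.ids[i] for i in keep},
        provenance=table.provenance + (f"excluded ids: {dropped}",),
    )


def consensus(a: PredictionTable, b: PredictionTable) -> tuple[PredictionTable, MetricSet]:
    """Average two prediction tables id-wise; quantify their agreement.

    Returns the consensus table (y_calc = (a + b)/2 over the id
    intersection, keeping a's experimental values) together with the metrics
    of b against a — the cross-method RMSE measures inter-method agreement
    and is symmetric in the two tables.
    """
    ia = {cid: k for k, cid in enumerate(a.ids) if cid not in a.missing}
    ib = {cid: k for k, cid in enumerate(b.ids) if cid not in b.missing}
    common = [cid for cid in a.ids if cid in ia and cid in ib]
    if not common:
        raise ValueError("no common ids between the two tables")
    mismatched = sorted((set(ia) | set(ib)) - set(common))
    if mismatched:
        warnings.warn(f"consensus: ids present in only one table: {mismatched}", stacklevel=2)
    ya = np.array([a.y_calc[ia[c]] for c in common])
    yb = np.array([b.y_calc[ib[c]] for c in common])
    cons = PredictionTable(
        ids=tuple(common),
        y_exp=np.array([a.y_exp[ia[c]] for c in common]),
        y_calc=(ya + yb) / 2.0,
        group=tuple(a.group[ia[c]] for c in common) if a.group else None,
        units=a.units,
        provenance=a.provenance + (f"consensus of two methods over {len(common)} ids",),
    )
    cross = metrics(PredictionTable(ids=tuple(common), y_exp=ya, y_calc=yb, units=a.units))
    return cons, cross


def grouped_metrics(table: PredictionTable) -> dict[str, MetricSet]:
    """Per-group metrics plus a pooled set over all usable rows.

    The pooled entry (key ``"all"``) spans the union of the groups, so rows
    whose label places them outside every named subgroup still count there.
    Empty groups are skipped with a warning.
    """
    if table.group is None:
        raise ValueError("table carries no group labels")
    out: dict[str, MetricSet] = {}
    for g in dict.fromkeys(table.group):  # preserve first-seen order
        idx = [i for i, lab in enumerate(table.group) if lab == g]
        sub = PredictionTable(
            ids=tuple(table.ids[i] for i in idx),
            y_exp=table.y_exp[idx],
            y_calc=table.y_calc[idx],
            units=table.units,
            missing=table.missing & {table.ids[i] for i in idx},
        )
        if not sub.usable_mask().any():
            warnings.warn(f"group {g!r} has no usable rows; skipped", stacklevel=2)
            continue
        out[g] = metrics(sub)
    out["all"] = metrics(table)
    return out
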
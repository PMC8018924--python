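"""Conformer-ensemble reduction: energy window, greedy RMSD clustering, selection.

Mirrors the standard pre-processing protocol for quantum-chemical conformer
ensembles: conformers more than an energy window above the minimum are
discarded; the remainder are clustered greedily in order of increasing energy
with a rigid-body RMSD cutoff; finally up to *k* lowest-energy representatives
are retained for the expensive downstream calculations.

RMSD is the plain optimal-superposition (Kabsch) value over heavy atoms by
default; no atom-symmetry permutation search is attempted, so symmetric
duplicates may land in distinct clusters. Hydrogens can be included by flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Conformer",
    "ClusterResult",
    "kabsch_rmsd",
    "energy_window_filter",
    "greedy_rmsd_cluster",
    "select_lowest",
    "read_xyz",
    "write_xyz",
]


@dataclass(frozen=True, eq=False)
class Conformer:
    """A Cartesian geometry with an associated ranking energy (kcal/mol)."""

    conformer_id: str
    coords: np.ndarray  # (N, 3) Å
    energy: float
    atom_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError(f"coords must be (N>=1, 3), got {coords.shape}")
        if len(self.atom_labels) != coords.shape[0]:
            raise ValueError(
                f"{len(self.atom_labels)} atom labels for {coords.shape[0]} atoms"
            )
        if not np.isfinite(coords).all() or not np.isfinite(self.energy):
            raise ValueError("coordinates and energy must be finite")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "atom_labels", tuple(self.atom_labels))

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class ClusterResult:
    """Outcome of greedy clustering: representatives, assignments, discards."""

    representatives: tuple[Conformer, ...]
    assignments: dict[str, int]  # conformer_id -> cluster index
    discarded: tuple[str, ...] = ()

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def _heavy_mask(labels: Sequence[str]) -> np.ndarray:
    return np.array([lab.strip().upper() != "H" for lab in labels], dtype=bool)


def kabsch_rmsd(a: Conformer, b: Conformer, include_hydrogens: bool = False) -> float:
    """Minimal RMSD of b superposed onto a over all rotations/translations.

    Symmetric in its arguments and non-negative; hydrogens are excluded by
    default. Atom counts and ordering must match.
    """
    if a.n_atoms != b.n_atoms:
        raise ValueError(f"atom-count mismatch: {a.n_atoms} vs {b.n_atoms}")
    if a.atom_labels != b.atom_labels:
        raise ValueError("atom labels/ordering differ between conformers")
    xa, xb = a.coords, b.coords
    if not include_hydrogens:
        mask = _heavy_mask(a.atom_labels)
        if not mask.any():
            mask = np.ones(a.n_atoms, dtype=bool)  # all-H edge case: use all atoms
        xa, xb = xa[mask], xb[mask]
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    # align_vectors solves the orthogonal Procrustes (Kabsch) problem; the
    # deviation is re-evaluated explicitly because the internally returned
    # rssd loses precision to cancellation near zero
    rot, _ = Rotation.align_vectors(xa, xb)
    diff = xa - rot.apply(xb)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def energy_window_filter(
    confs: Sequence[Conformer], window: float = 5.0
) -> list[Conformer]:
    """Drop conformers at least ``window`` kcal/mol above the minimum.

    Retention is strict (``E - E_min < window``); the minimum-energy
    conformer always survives. Input order is preserved.
    """
    confs = list(confs)
    if not confs:
        raise ValueError("empty conformer list")
    e_min = min(c.energy for c in confs)
    return [c for c in confs if c.energy - e_min < window]


def greedy_rmsd_cluster(
    confs: Sequence[Conformer],
    rmsd_cut: float = 0.5,
    include_hydrogens: bool = False,
) -> ClusterResult:
    """Greedy energy-ordered clustering with an RMSD cutoff.

    Conformers are visited in ascending energy (stable on ties). The minimum
    seeds cluster 0; each subsequent conformer joins the first existing
    cluster whose representative lies within ``rmsd_cut``, else seeds a new
    cluster. Representatives are therefore their clusters' lowest-energy
    members and pairwise at least ``rmsd_cut`` apart.
    """
    confs = list(confs)
    if not confs:
        raise ValueError("empty conformer list")
    order = sorted(range(len(confs)), key=lambda i: (confs[i].energy, i))
    reps: list[Conformer] = []
    assignments: dict[str, int] = {}
    for i in order:
        c = confs[i]
        for ci, rep in enumerate(reps):
            if kabsch_rmsd(rep, c, include_hydrogens=include_hydrogens) < rmsd_cut:
                assignments[c.conformer_id] = ci
                break
        else:
            assignments[c.conformer_id] = len(reps)
            reps.append(c)
    return ClusterResult(representatives=tuple(reps), assignments=assignments)


def select_lowest(confs: Sequence[Conformer], k: int = 5) -> list[Conformer]:
    """Up to ``k`` lowest-energy conformers, ascending; ties keep input order.

    ``k=1`` reproduces the global-minimum-only selection; the default keeps
    five, matching the downstream ensemble size.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    confs = list(confs)
    order = sorted(range(len(confs)), key=lambda i: (confs[i].energy, i))
    return [confs[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# Multi-structure XYZ I/O (comment line carries "energy=<value>")

_ENERGY_RE = re.compile(r"energy\s*=\s*([-+0-9.eEdD]+)")


def read_xyz(path: str) -> list[Conformer]:
    """Read a multi-structure XYZ file.

    Each frame: atom count, a comment line containing ``energy=<value>``
    (kcal/mol) and optionally a leading conformer id, then one
    ``element x y z`` line per atom.
    """
    conformers: list[Conformer] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as err:
            raise ValueError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}") from err
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _ENERGY_RE.search(comment)
        if m is None:
            raise ValueError(f"{path}:{i + 2}: comment line lacks 'energy=<value>'")
        energy = float(m.group(1).replace("D", "E").replace("d", "e"))
        cid = comment.split()[0] if comment.split() and "=" not in comment.split()[0] else f"conf{frame}"
        labels, coords = [], []
        for j in range(n):
            k = i + 2 + j
            if k >= len(lines):
                raise ValueError(f"{path}: truncated frame starting at line {i + 1}")
            parts = lines[k].split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{k + 1}: expected 'element x y z'")
            labels.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        conformers.append(Conformer(cid, np.array(coords), energy, tuple(labels)))
        i += 2 + n
        frame += 1
    return conformers


def write_xyz(confs: Iterable[Conformer], path: str) -> None:
    """Write conformers as multi-structure XYZ (full float precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in confs:
            fh.write(f"{c.n_atoms}\n")
            fh.write(f"{c.conformer_id} energy={c.energy:.17g}\n")
            for lab, (x, y, z) in zip(c.atom_labels, c.coords):
                fh.write(f"{lab} {x:.12f} {y:.12f} {z:.12f}\n")
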
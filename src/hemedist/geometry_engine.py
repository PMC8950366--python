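"""Rigid-body superposition, RMSD time series and interatomic distance series.

The core signal of the pipeline is the per-frame distance between the ligand's
reactive atom and the heme iron (:func:`distance_series`); RMSD series over
protein C-alpha or ligand atoms (:func:`rmsd_series`) monitor complex
stability. Superposition uses the Kabsch algorithm (:func:`kabsch`), mass
unweighted, with reflections excluded so only proper rigid motions are fitted.

Trajectory coordinates are in Å; all reported series values are in nm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure_io import Trajectory

logger = logging.getLogger(__name__)

A_PER_NM = 10.0


@dataclass
class DistanceSeries:
    """Per-frame Fe–reactive-atom distances in nm at strictly increasing times."""

    times_ps: np.ndarray
    values_nm: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.values_nm = np.asarray(self.values_nm, dtype=float)
        if self.times_ps.shape != self.values_nm.shape or self.times_ps.ndim != 1:
            raise ValueError("times_ps and values_nm must be 1-D arrays of equal length")
        if self.times_ps.size and np.any(np.diff(self.times_ps) <= 0):
            raise ValueError("times_ps must be strictly increasing")
        if np.any(~np.isfinite(self.values_nm)) or np.any(self.values_nm < 0):
            raise ValueError("values_nm must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return int(self.values_nm.size)

    def dt_ps(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need at least two frames to infer dt")
        return float(np.median(np.diff(self.times_ps)))

    def after(self, t_ps: float) -> "DistanceSeries":
        """Sub-series at times >= ``t_ps`` (burn-in removal)."""
        mask = self.times_ps >= t_ps
        return DistanceSeries(self.times_ps[mask], self.values_nm[mask], self.label)


@dataclass
class RMSDSeries:
    """Per-frame RMSD (nm) against a reference frame, for a named selection."""

    times_ps: np.ndarray
    values_nm: np.ndarray
    selection_label: str = "protein_calpha"

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.values_nm = np.asarray(self.values_nm, dtype=float)
        if self.times_ps.shape != self.values_nm.shape or self.times_ps.ndim != 1:
            raise ValueError("times_ps and values_nm must be 1-D arrays of equal length")
        if self.times_ps.size and np.any(np.diff(self.times_ps) <= 0):
            raise ValueError("times_ps must be strictly increasing")


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of point set P onto Q.

    Returns ``(rotation, translation, rmsd_nm)`` such that ``P @ rotation.T +
    translation`` minimises the RMSD to ``Q`` over all proper rigid transforms
    (rotation determinant +1; reflections are corrected away). Inputs are in
    Å; the returned RMSD is in nm.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("at least 3 points are required for a unique rotation")
    p_mean = P.mean(axis=0)
    q_mean = Q.mean(axis=0)
    Pc = P - p_mean
    Qc = Q - q_mean
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = q_mean - R @ p_mean
    diff = Pc @ R.T - Qc
    rmsd_nm = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))) / A_PER_NM)
    return R, t, rmsd_nm


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ R.T + t


def rmsd_series(
    traj: Trajectory,
    analyse: np.ndarray,
    superpose_on: np.ndarray,
    reference: int = 0,
    selection_label: str = "protein_calpha",
) -> RMSDSeries:
    """RMSD of the ``analyse`` atoms against a reference frame, after Kabsch
    superposition of each frame onto the reference using ``superpose_on``.

    Protein mode uses C-alpha atoms for both selections; ligand mode
    superposes on C-alpha and analyses ligand atoms, so ligand RMSD is
    measured in the protein frame and a drifting ligand registers even when
    the protein is rigid.
    """
    analyse = np.asarray(analyse, dtype=int)
    superpose_on = np.asarray(superpose_on, dtype=int)
    if analyse.size == 0 or superpose_on.size == 0:
        raise ValueError("atom selections must be non-empty")
    if not (0 <= reference < traj.n_frames):
        raise ValueError(f"reference frame {reference} out of range")
    ref_fit = traj.frames[reference][superpose_on]
    ref_analyse = traj.frames[reference][analyse]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t, _ = kabsch(traj.frames[f][superpose_on], ref_fit)
        moved = apply_transform(traj.frames[f][analyse], R, t)
        diff = moved - ref_analyse
        values[f] = np.sqrt(np.mean(np.sum(diff**2, axis=1))) / A_PER_NM
    return RMSDSeries(traj.times_ps(), values, selection_label=selection_label)


def distance_series(traj: Trajectory, i: int, j: int, label: str = "") -> DistanceSeries:
    """Per-frame Euclidean distance between atoms ``i`` and ``j``, in nm."""
    n_atoms = traj.structure.n_atoms
    if i == j:
        raise ValueError("atom indices must be distinct")
    for k in (i, j):
        if not (0 <= k < n_atoms):
            raise ValueError(f"atom index {k} out of range (n_atoms={n_atoms})")
    d = np.linalg.norm(traj.frames[:, i, :] - traj.frames[:, j, :], axis=1) / A_PER_NM
    n_zero = int(np.sum(d == 0.0))
    if n_zero:
        logger.warning(
            "distance_series %r: atoms %d and %d coincide in %d frame(s)",
            label, i, j, n_zero,
        )
    return DistanceSeries(traj.times_ps(), d, label=label)


def write_series_tsv(series: DistanceSeries | RMSDSeries, path) -> None:
    """Export a series as TSV with columns time_ps, value_nm, label."""
    label = getattr(series, "label", None)
    if label is None:
        label = series.selection_label  # type: ignore[union-attr]
    with open(path, "w") as fh:
        fh.write("time_ps\tvalue_nm\tlabel\n")
        for t, v in zip(series.times_ps, series.values_nm):
            fh.write(f"{t:.6g}\t{v:.6f}\t{label}\n")
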
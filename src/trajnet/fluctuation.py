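"""Superposition and per-node / per-pair fluctuation statistics.

All statistics assume (or perform) a least-squares superposition onto a
reference frame so that global rotation/translation does not masquerade
as internal motion.  Distance-based maps are rigid-motion invariant and
need no alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSelectionError, SelectionError
from .model import NodeMap, Selection, Structure, Trajectory

_EIGHT_PI2_OVER_3 = 8.0 * np.pi**2 / 3.0


@dataclass
class FluctuationProfile:
    """Per-node RMSF (Å), optionally alongside RMSF converted from
    crystallographic B-factors."""

    labels: list[str]
    rmsf: np.ndarray
    b_converted_rmsf: np.ndarray | None = None


@dataclass
class DistanceSeries:
    pair: tuple[str, str]
    values: np.ndarray  # per-frame distance, Å


@dataclass
class DistanceDeviationMap:
    """Per-pair standard deviation of inter-node distance over frames."""

    labels: list[str]
    sigma: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be square")
        self.sigma = s


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` minimises the RMSD to
    ``reference``; the rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateSelectionError("superposition needs at least 3 points")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    scale = max(np.abs(ref_c).max(), np.abs(mob_c).max(), 1e-300)
    if (np.linalg.matrix_rank(ref_c, tol=1e-8 * scale) < 2
            or np.linalg.matrix_rank(mob_c, tol=1e-8 * scale) < 2):
        raise DegenerateSelectionError("points are collinear: rotation underdetermined")
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = reference.mean(axis=0) - mobile.mean(axis=0) @ rot.T
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def align_trajectory(
    traj: Trajectory,
    selection: Selection | None = None,
    reference_frame: int = 0,
) -> Trajectory:
    """Superpose every frame onto ``reference_frame`` on ``selection``.

    The fitted transform is applied to all atoms; default selection is
    the whole topology.
    """
    idx = _selection_indices(traj, selection)
    ref = traj.frames[reference_frame][idx]
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.frames[f][idx], ref)
        out[f] = traj.frames[f] @ rot.T + trans
    return traj.with_frames(out)


def _selection_indices(traj: Trajectory, selection: Selection | None) -> np.ndarray:
    if selection is None:
        return np.arange(traj.n_atoms)
    selection.validate(traj.n_atoms)
    return selection.array


def rmsd_series(
    traj: Trajectory,
    reference: Structure | np.ndarray,
    selection: Selection | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference structure on a selection."""
    idx = _selection_indices(traj, selection)
    ref = reference.coords if isinstance(reference, Structure) else np.asarray(reference)
    if ref.shape[0] == traj.n_atoms:
        ref = ref[idx]
    elif ref.shape[0] != len(idx):
        raise SelectionError(
            f"reference has {ref.shape[0]} atoms; selection expects {len(idx)}"
        )
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.frames[f][idx]
        if superpose:
            out[f] = kabsch_superpose(mob, ref)[2]
        else:
            out[f] = np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1)))
    return out


def rmsf_profile(
    traj: Trajectory,
    selection: Selection | None = None,
    aligned: bool = False,
    labels: list[str] | None = None,
) -> FluctuationProfile:
    """Root-mean-square fluctuation of each selected atom about its mean.

    If the trajectory is not flagged as aligned, a warning is emitted and
    the alignment is applied internally before computing fluctuations.
    """
    if not aligned:
        warnings.warn(
            "trajectory not flagged as aligned; applying least-squares "
            "superposition to the first frame before RMSF",
            stacklevel=2,
        )
        traj = align_trajectory(traj, selection)
    idx = _selection_indices(traj, selection)
    xyz = traj.frames[:, idx, :]
    disp = xyz - xyz.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum(disp**2, axis=2), axis=0))
    if labels is None:
        labels = [
            f"{a.chain_id}:{a.residue_name}{a.residue_seq}"
            for a in (traj.topology.atoms[i] for i in idx)
        ]
    b = np.array([traj.topology.atoms[i].b_factor for i in idx])
    b_rmsf = bfactor_to_rmsf(b) if np.any(b > 0) else None
    return FluctuationProfile(labels=labels, rmsf=rmsf, b_converted_rmsf=b_rmsf)


def bfactor_to_rmsf(b):
    """Isotropic harmonic conversion RMSF = sqrt(3 B / 8π²)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("B-factor must be non-negative")
    out = np.sqrt(b / _EIGHT_PI2_OVER_3)
    return float(out) if out.ndim == 0 else out


def rmsf_to_bfactor(rmsf):
    """Inverse of :func:`bfactor_to_rmsf`: B = (8π²/3)·RMSF²."""
    rmsf = np.asarray(rmsf, dtype=float)
    if np.any(rmsf < 0):
        raise ValueError("RMSF must be non-negative")
    out = _EIGHT_PI2_OVER_3 * rmsf**2
    return float(out) if out.ndim == 0 else out


def distance_series(
    traj: Trajectory, node_map: NodeMap, node_a: str, node_b: str
) -> DistanceSeries:
    """Per-frame Euclidean distance between two node anchor atoms."""
    ia = node_map.anchor_indices[node_map.index_of(node_a)]
    ib = node_map.anchor_indices[node_map.index_of(node_b)]
    d = np.linalg.norm(traj.frames[:, ia, :] - traj.frames[:, ib, :], axis=1)
    return DistanceSeries(pair=(node_a, node_b), values=d)


def distance_deviation_map(
    traj: Trajectory, node_map: NodeMap, chunk: int = 200
) -> DistanceDeviationMap:
    """Standard deviation of every pairwise node distance over frames.

    Rigid-motion invariant; no prior alignment required.  Frames are
    processed in chunks to bound memory at O(chunk · N²).
    """
    idx = node_map.anchor_indices
    n = len(idx)
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    f_total = traj.n_frames
    for start in range(0, f_total, chunk):
        xyz = traj.frames[start:start + chunk, idx, :]
        diff = xyz[:, :, None, :] - xyz[:, None, :, :]
        d = np.sqrt(np.sum(diff**2, axis=3))
        s1 += d.sum(axis=0)
        s2 += (d**2).sum(axis=0)
    var = s2 / f_total - (s1 / f_total) ** 2
    sigma = np.sqrt(np.clip(var, 0.0, None))
    np.fill_diagonal(sigma, 0.0)
    return DistanceDeviationMap(labels=list(node_map.labels), sigma=sigma)


def block_deviation_ratio(
    dmap: DistanceDeviationMap,
    block: tuple[np.ndarray | list[int], np.ndarray | list[int]],
) -> float:
    """Mean σ over the cross pairs of a node-set pair, divided by the mean
    σ over all off-diagonal pairs."""
    a = np.asarray(block[0], dtype=int)
    b = np.asarray(block[1], dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("block sets must be non-empty")
    if set(a.tolist()) & set(b.tolist()):
        raise ValueError("block sets must be disjoint")
    s = dmap.sigma
    cross = s[np.ix_(a, b)].mean()
    off = s[~np.eye(s.shape[0], dtype=bool)].mean()
    if off == 0:
        raise ZeroDivisionError("all-zero deviation map has no background level")
    return float(cross / off)
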
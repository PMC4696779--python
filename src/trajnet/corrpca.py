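"""Cross-correlation maps, Cartesian-covariance PCA and PC-space clustering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .errors import SelectionError
from .model import NodeMap, Trajectory


@dataclass
class CorrelationMatrix:
    """Normalized displacement covariance C_ij ∈ [−1, 1], unit diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.values, dtype=float)
        if c.shape[0] != c.shape[1] or c.shape[0] != len(self.labels):
            raise ValueError("correlation matrix / label size mismatch")
        if not np.allclose(c, c.T, atol=1e-9):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-9):
            raise ValueError("correlation matrix diagonal must be 1")
        if c.min() < -1 - 1e-9 or c.max() > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.values = np.clip(c, -1.0, 1.0)


@dataclass
class PCAResult:
    """Eigen-decomposition of the 3N×3N Cartesian coordinate covariance.

    ``eigenvalues`` are descending (Å²); ``eigenvectors`` columns are
    orthonormal; ``projections`` are per-frame coordinates along every
    component.  Covariance uses the ddof=1 normalisation, matched by the
    projection-variance identity.
    """

    mean: np.ndarray                # (N, 3)
    eigenvalues: np.ndarray         # (3N,)
    eigenvectors: np.ndarray        # (3N, 3N), columns
    projections: np.ndarray         # (F, 3N)
    labels: list[str] = field(default_factory=list)

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues * 0.0


@dataclass
class ClusterAssignment:
    labels: np.ndarray       # per-frame cluster index, 0-based
    k: int
    bss_tss: float
    method: str              # "kmeans" | "hierarchical-complete"
    centers: np.ndarray | None = None
    wss: float = 0.0


def dccm(traj: Trajectory, node_map: NodeMap | None = None) -> CorrelationMatrix:
    """Dynamic cross-correlation map over node anchor atoms.

    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩) with Δr the
    displacement from the time-mean position.  The caller is responsible
    for prior superposition when global motion is present.
    """
    if node_map is None:
        from .model import identity_node_map

        node_map = identity_node_map(traj.n_atoms)
    idx = node_map.anchor_indices
    xyz = traj.frames[:, idx, :]
    disp = xyz - xyz.mean(axis=0)
    cov = np.einsum("fia,fja->ij", disp, disp) / traj.n_frames
    var = np.diag(cov).copy()
    dead = var <= 1e-12 * max(float(var.max()), 1e-30)
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} node(s) have zero variance; their correlation "
            "rows are set to 0",
            stacklevel=2,
        )
        var[dead] = 1.0
    norm = np.sqrt(np.outer(var, var))
    c = cov / norm
    c[dead, :] = 0.0
    c[:, dead] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(labels=list(node_map.labels), values=c)


def pca_fit(traj: Trajectory, node_map: NodeMap | None = None) -> PCAResult:
    """PCA of the 3N×3N covariance of node Cartesian coordinates."""
    if node_map is None:
        from .model import identity_node_map

        node_map = identity_node_map(traj.n_atoms)
    idx = node_map.anchor_indices
    x = traj.frames[:, idx, :].reshape(traj.n_frames, -1)
    mean = x.mean(axis=0)
    centered = x - mean
    cov = centered.T @ centered / (traj.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals, kind="stable")[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    proj = centered @ evecs
    return PCAResult(
        mean=mean.reshape(-1, 3),
        eigenvalues=evals,
        eigenvectors=evecs,
        projections=proj,
        labels=list(node_map.labels),
    )


def project(
    traj: Trajectory, pca: PCAResult, components: list[int],
    node_map: NodeMap | None = None,
) -> np.ndarray:
    """Project frames onto selected components (F × K)."""
    dim = pca.eigenvectors.shape[0]
    for c in components:
        if not 0 <= c < dim:
            raise SelectionError(f"component {c} out of range (0..{dim - 1})")
    if node_map is None:
        x = traj.frames.reshape(traj.n_frames, -1)
    else:
        x = traj.frames[:, node_map.anchor_indices, :].reshape(traj.n_frames, -1)
    if x.shape[1] != dim:
        raise SelectionError("trajectory dimensionality does not match PCA")
    centered = x - pca.mean.reshape(-1)
    return centered @ pca.eigenvectors[:, components]


def interpolate_along_pc(
    pca: PCAResult, component: int, n_steps: int
) -> np.ndarray:
    """Structures mean + t·v_k for t spanning the observed projection range.

    Returns an (n_steps, N, 3) coordinate array; n_steps = 1 gives the
    midpoint structure.
    """
    dim = pca.eigenvectors.shape[0]
    if not 0 <= component < dim:
        raise SelectionError(f"component {component} out of range")
    p = pca.projections[:, component]
    lo, hi = float(p.min()), float(p.max())
    ts = np.array([(lo + hi) / 2.0]) if n_steps == 1 else np.linspace(lo, hi, n_steps)
    v = pca.eigenvectors[:, component]
    flat = pca.mean.reshape(-1)[None, :] + ts[:, None] * v[None, :]
    return flat.reshape(n_steps, -1, 3)


def _bss_tss(points: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(bss/tss, wss) for a hard partition."""
    grand = points.mean(axis=0)
    tss = float(np.sum((points - grand) ** 2))
    wss = 0.0
    for lab in np.unique(labels):
        members = points[labels == lab]
        wss += float(np.sum((members - members.mean(axis=0)) ** 2))
    if tss <= 0:
        return 1.0, 0.0
    return 1.0 - wss / tss, wss


def kmeans_cluster(
    points: np.ndarray, k: int, restarts: int = 25, seed: int = 0
) -> ClusterAssignment:
    """Best-of-restarts Lloyd k-means; centers initialised by sampling
    distinct observations.  Deterministic for a given seed."""
    points = np.asarray(points, dtype=float)
    f = points.shape[0]
    if k > f:
        raise ValueError(f"k={k} exceeds the number of observations F={f}")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, init="random", n_init=restarts, random_state=seed)
    labels = km.fit_predict(points)
    ratio, wss = _bss_tss(points, labels)
    return ClusterAssignment(
        labels=labels, k=k, bss_tss=ratio, method="kmeans",
        centers=km.cluster_centers_, wss=wss,
    )


def hierarchical_cluster(points: np.ndarray, k: int) -> ClusterAssignment:
    """Complete-linkage Euclidean hierarchical clustering cut at k."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < k:
        raise ValueError("k exceeds the number of observations")
    z = linkage(points, method="complete")
    labels = fcluster(z, t=k, criterion="maxclust") - 1
    ratio, wss = _bss_tss(points, labels)
    return ClusterAssignment(
        labels=labels, k=k, bss_tss=ratio, method="hierarchical-complete", wss=wss,
    )


@dataclass
class ElbowResult:
    ks: np.ndarray
    bss_tss: np.ndarray
    suggested_k: int
    low_confidence: bool


def elbow_scan(
    points: np.ndarray, k_max: int, seed: int = 0, restarts: int = 10
) -> ElbowResult:
    """BSS/TSS against k with nested best solutions (monotone curve).

    The suggestion is the k after which the marginal BSS/TSS gain
    collapses (largest drop in successive gains, measured as a ratio so
    the rule is scale-free); it is advisory, and flagged low-confidence
    when no gain drop is pronounced.
    """
    points = np.asarray(points, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_max = min(k_max, points.shape[0])
    ks = np.arange(1, k_max + 1)
    ratios = np.empty(len(ks))
    prev: ClusterAssignment | None = None
    for i, k in enumerate(ks):
        cand = kmeans_cluster(points, int(k), restarts=restarts, seed=seed + int(k))
        if prev is not None and prev.centers is not None and k > 1:
            # nested candidate: previous centers plus the worst-fit point,
            # guaranteeing the curve can only improve with k
            d = np.min(
                np.sum((points[:, None, :] - prev.centers[None, :, :]) ** 2, axis=2),
                axis=1,
            )
            init = np.vstack([prev.centers, points[int(np.argmax(d))]])
            km = KMeans(n_clusters=int(k), init=init, n_init=1)
            lab = km.fit_predict(points)
            ratio, wss = _bss_tss(points, lab)
            if wss < cand.wss:
                cand = ClusterAssignment(
                    labels=lab, k=int(k), bss_tss=ratio, method="kmeans",
                    centers=km.cluster_centers_, wss=wss,
                )
        ratios[i] = cand.bss_tss
        prev = cand
    if len(ks) >= 3:
        gains = np.diff(ratios)                      # gain[i] = going to ks[i+1]
        drop = (gains[:-1] + 1e-12) / (gains[1:] + 1e-12)  # indexed at ks[1:-1]
        best = int(np.argmax(drop))
        suggested = int(ks[best + 1])
        low_conf = bool(drop[best] < 5.0)
    else:
        suggested = int(ks[-1])
        low_conf = True
    return ElbowResult(ks=ks, bss_tss=ratios, suggested_k=suggested,
                       low_confidence=low_conf)
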
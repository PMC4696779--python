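"""Synthetic trajectories and graphs with planted, analytically known
structure.

Statistics, not physics, are planted: the Gaussian ensemble realises an
exact displacement covariance; the two-lobe mechanism realises rigid-body
clamshell/twist motions over a contact topology in which two dense lobes
communicate only through a narrow bridge.  Every generator is a pure
function of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import SpecError
from .model import AtomRecord, Structure, Trajectory
from .network import DynamicalNetwork

import networkx as nx


# ---------------------------------------------------------------------------
# Gaussian ensembles
# ---------------------------------------------------------------------------

@dataclass
class GaussianEnsembleSpec:
    """Ensemble with frames = mean + Δr, Δr ~ N(0, displacement_covariance)."""

    mean_structure: np.ndarray         # (N, 3), Å
    displacement_covariance: np.ndarray  # (3N, 3N), Å²
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.mean_structure = np.asarray(self.mean_structure, dtype=float)
        self.displacement_covariance = np.asarray(
            self.displacement_covariance, dtype=float
        )
        n = self.mean_structure.shape[0]
        if self.mean_structure.shape != (n, 3):
            raise SpecError("mean_structure must be (N, 3)")
        if self.displacement_covariance.shape != (3 * n, 3 * n):
            raise SpecError("displacement_covariance must be (3N, 3N)")
        if not np.allclose(
            self.displacement_covariance, self.displacement_covariance.T, atol=1e-8
        ):
            raise SpecError("displacement covariance must be symmetric")
        if self.n_frames < 2:
            raise SpecError("n_frames must be >= 2")

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean_structure": self.mean_structure.tolist(),
                "displacement_covariance": self.displacement_covariance.tolist(),
                "n_frames": self.n_frames,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GaussianEnsembleSpec":
        d = json.loads(text)
        return cls(
            mean_structure=np.array(d["mean_structure"]),
            displacement_covariance=np.array(d["displacement_covariance"]),
            n_frames=int(d["n_frames"]),
            seed=int(d["seed"]),
        )


def _ca_chain_topology(coords: np.ndarray, b_factors: np.ndarray | None = None,
                       resname: str = "GLY") -> Structure:
    """Cα-trace topology for a bare coordinate set (one residue per node)."""
    n = coords.shape[0]
    b = np.zeros(n) if b_factors is None else b_factors
    atoms = [
        AtomRecord(
            serial=i + 1, name="CA", residue_name=resname, chain_id="A",
            residue_seq=i + 1, coords=coords[i], b_factor=float(max(b[i], 0.0)),
            element="C",
        )
        for i in range(n)
    ]
    return Structure(atoms)


def generate_gaussian_ensemble(spec: GaussianEnsembleSpec) -> Trajectory:
    """Draw n_frames displacements from the planted covariance.

    Sampling goes through the eigen-decomposition of the covariance;
    eigenvalues slightly below zero (numerical noise on a PSD matrix) are
    clipped at zero, permitting rank-deficient planted modes.
    """
    cov = spec.displacement_covariance
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        raise SpecError(
            f"displacement covariance is not PSD (min eigenvalue {evals.min():.3g})"
        )
    evals = np.clip(evals, 0.0, None)
    scale = evecs * np.sqrt(evals)[None, :]   # (3N, 3N)
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, cov.shape[0]))
    disp = z @ scale.T
    frames = spec.mean_structure[None, :, :] + disp.reshape(spec.n_frames, -1, 3)
    # B-factors record the planted per-node variance for conversion checks
    n = spec.mean_structure.shape[0]
    per_node_msf = np.array(
        [np.trace(cov[3 * i:3 * i + 3, 3 * i:3 * i + 3]) for i in range(n)]
    )
    b = (8.0 * np.pi**2 / 3.0) * per_node_msf
    topo = _ca_chain_topology(spec.mean_structure, b_factors=b)
    return Trajectory(frames, topo)


def make_block_covariance(
    block_sizes: list[int],
    intra: float,
    inter: float,
    sigma2: float = 1.0,
) -> np.ndarray:
    """Isotropic 3N×3N covariance with planted node-level correlations.

    Node correlation = 1 on the diagonal, ``intra`` within a block and
    ``inter`` across blocks; each node is isotropic with per-axis variance
    sigma2.  The expected DCCM equals the node correlation matrix exactly.
    """
    n = sum(block_sizes)
    c = np.full((n, n), float(inter))
    start = 0
    for size in block_sizes:
        c[start:start + size, start:start + size] = intra
        start += size
    np.fill_diagonal(c, 1.0)
    evals = np.linalg.eigvalsh(c)
    if evals.min() < -1e-10:
        raise SpecError(
            f"block correlation (intra={intra}, inter={inter}) is not PSD; "
            f"min eigenvalue {evals.min():.3g}"
        )
    return sigma2 * np.kron(c, np.eye(3))


def make_spectrum_covariance(
    n_nodes: int, leading_eigenvalues: list[float], tail_eigenvalue: float,
    seed: int = 0,
) -> np.ndarray:
    """3N×3N covariance with a planted eigenvalue spectrum and random
    (seeded) orthonormal eigenvectors."""
    dim = 3 * n_nodes
    if len(leading_eigenvalues) > dim:
        raise SpecError("more leading eigenvalues than dimensions")
    spectrum = np.full(dim, float(tail_eigenvalue))
    spectrum[: len(leading_eigenvalues)] = leading_eigenvalues
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    return (q * spectrum[None, :]) @ q.T


# ---------------------------------------------------------------------------
# Two-lobe mechanism
# ---------------------------------------------------------------------------

@dataclass
class TwoLobeMechanismSpec:
    """Two dense lobes joined by a narrow bridge, moved by rigid-body
    clamshell (hinge rotation) and twist (inter-lobe axis rotation) modes.

    Amplitudes are standard deviations in degrees; per-frame angles are
    drawn from N(0, amplitude²).
    """

    lobe_a_nodes: int = 13
    lobe_b_nodes: int = 13
    bridge_nodes: int = 1
    hinge_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    clamshell_amplitude: float = 5.0     # degrees, std
    twist_amplitude: float = 3.0         # degrees, std
    noise_sigma: float = 0.3             # Å, per coordinate
    n_frames: int = 400
    seed: int = 0
    lattice_spacing: float = 3.0         # Å, intra-lobe grid constant
    gap: float = 7.0                     # Å, between facing anchor nodes
    hinge_offset: float = 14.0           # Å, hinge below the lobe axis

    def __post_init__(self) -> None:
        if self.lobe_a_nodes < 1 or self.lobe_b_nodes < 1:
            raise SpecError("lobes must be non-empty")
        if self.bridge_nodes < 1:
            raise SpecError("bridge must contain at least one node")
        if self.clamshell_amplitude < 0 or self.twist_amplitude < 0:
            raise SpecError("amplitudes must be non-negative")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be non-negative")
        if self.n_frames < 2:
            raise SpecError("n_frames must be >= 2")
        axis = np.asarray(self.hinge_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm <= 0:
            raise SpecError("hinge_axis must be a non-zero vector")
        object.__setattr__(self, "hinge_axis", tuple(axis / norm))

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["hinge_axis"] = list(self.hinge_axis)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TwoLobeMechanismSpec":
        d = json.loads(text)
        d["hinge_axis"] = tuple(d.get("hinge_axis", (0.0, 0.0, 1.0)))
        return cls(**d)


def _lattice_cluster(n: int, spacing: float) -> np.ndarray:
    """The n integer-lattice points closest to the origin (deterministic
    order), scaled by the lattice constant."""
    r = int(np.ceil(n ** (1.0 / 3.0))) + 2
    pts = [
        (x * x + y * y + z * z, x, y, z)
        for x in range(-r, r + 1)
        for y in range(-r, r + 1)
        for z in range(-r, r + 1)
    ]
    pts.sort()
    return spacing * np.array([[x, y, z] for _, x, y, z in pts[:n]], dtype=float)


@dataclass
class TwoLobeLayout:
    """Static geometry and planted groups of the two-lobe scaffold."""

    coords: np.ndarray                  # (N, 3) base coordinates
    fractions: np.ndarray               # per-node motion fraction: A=0 … B=1
    lobe_a: list[int]
    bridge: list[int]
    lobe_b: list[int]
    anchors: tuple[int, int]            # lobe surface nodes the bridge joins
    hinge_point: np.ndarray
    hinge_axis: np.ndarray
    twist_axis: np.ndarray
    twist_point: np.ndarray

    @property
    def connectors(self) -> list[int]:
        """Nodes of the unique inter-lobe route: bridge plus its anchors."""
        return sorted({self.anchors[0], self.anchors[1], *self.bridge})


def two_lobe_layout(spec: TwoLobeMechanismSpec) -> TwoLobeLayout:
    """Deterministic scaffold geometry for a two-lobe spec.

    Lobes are lattice clusters on either side of a gap along x; the bridge
    nodes lie evenly spaced on the segment between the two facing surface
    (anchor) nodes, so the bridge is the only inter-lobe contact route.
    """
    cluster_a = _lattice_cluster(spec.lobe_a_nodes, spec.lattice_spacing)
    cluster_b = _lattice_cluster(spec.lobe_b_nodes, spec.lattice_spacing)
    shift_a = np.array([-spec.gap / 2.0 - cluster_a[:, 0].max(), 0.0, 0.0])
    shift_b = np.array([spec.gap / 2.0 - cluster_b[:, 0].min(), 0.0, 0.0])
    a = cluster_a + shift_a
    b = cluster_b + shift_b

    def facing(cluster: np.ndarray, toward: float) -> int:
        key = toward * cluster[:, 0] - 1e-3 * (cluster[:, 1] ** 2 + cluster[:, 2] ** 2)
        return int(np.argmax(key))

    ia, ib = facing(a, +1.0), facing(b, -1.0)
    m = spec.bridge_nodes
    ts = np.arange(1, m + 1) / (m + 1.0)
    seg = b[ib] - a[ia]
    bridge = a[ia][None, :] + ts[:, None] * seg[None, :]

    coords = np.vstack([a, bridge, b])
    na, nb = spec.lobe_a_nodes, spec.lobe_b_nodes
    lobe_a = list(range(na))
    bridge_idx = list(range(na, na + m))
    lobe_b = list(range(na + m, na + m + nb))
    fractions = np.concatenate([np.zeros(na), ts, np.ones(nb)])
    centroid_axis = b.mean(axis=0) - a.mean(axis=0)
    twist_axis = centroid_axis / np.linalg.norm(centroid_axis)
    return TwoLobeLayout(
        coords=coords,
        fractions=fractions,
        lobe_a=lobe_a,
        bridge=bridge_idx,
        lobe_b=lobe_b,
        anchors=(ia, na + m + ib),
        hinge_point=np.array([0.0, -spec.hinge_offset, 0.0]),
        hinge_axis=np.asarray(spec.hinge_axis, dtype=float),
        twist_axis=twist_axis,
        twist_point=np.zeros(3),
    )


def generate_two_lobe_trajectory(
    spec: TwoLobeMechanismSpec,
) -> tuple[Trajectory, TwoLobeLayout]:
    """Trajectory of the two-lobe mechanism plus its planted layout.

    Per frame, lobe B is rigid-rotated about the hinge axis (clamshell)
    and about the inter-lobe axis (twist) while lobe A stays put; bridge
    nodes interpolate the rotation by their position fraction; isotropic
    Gaussian noise is added to every coordinate.
    """
    layout = two_lobe_layout(spec)
    rng = np.random.default_rng(spec.seed)
    thetas_c = rng.normal(0.0, np.deg2rad(spec.clamshell_amplitude), spec.n_frames)
    thetas_t = rng.normal(0.0, np.deg2rad(spec.twist_amplitude), spec.n_frames)
    n = layout.coords.shape[0]
    frames = np.empty((spec.n_frames, n, 3))
    unique_fracs = np.unique(layout.fractions)
    groups = {u: np.where(layout.fractions == u)[0] for u in unique_fracs}
    for f in range(spec.n_frames):
        frame = layout.coords.copy()
        for u, idx in groups.items():
            if u == 0.0:
                continue
            rot_t = Rotation.from_rotvec(layout.twist_axis * (u * thetas_t[f]))
            rot_c = Rotation.from_rotvec(layout.hinge_axis * (u * thetas_c[f]))
            pts = frame[idx]
            pts = layout.twist_point + rot_t.apply(pts - layout.twist_point)
            pts = layout.hinge_point + rot_c.apply(pts - layout.hinge_point)
            frame[idx] = pts
        frames[f] = frame
    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, frames.shape)
    topo = _ca_chain_topology(layout.coords)
    return Trajectory(frames, topo), layout


# ---------------------------------------------------------------------------
# Planted community graphs
# ---------------------------------------------------------------------------

def generate_planted_graph(
    n_communities: int,
    nodes_per_community: int,
    bridge_edges: list[tuple[int, int]],
    seed: int = 0,
    intra_correlation: tuple[float, float] = (0.55, 0.9),
    inter_correlation: tuple[float, float] = (0.05, 0.2),
) -> tuple[DynamicalNetwork, np.ndarray]:
    """Dense intra-community cliques plus the listed sparse bridges.

    Edge correlations are drawn high within communities and low on the
    bridges; returns the network and the planted community labels.
    """
    if n_communities < 2:
        raise SpecError("need at least 2 communities")
    if nodes_per_community < 1:
        raise SpecError("communities must be non-empty")
    seen = set()
    for u, v in bridge_edges:
        key = (min(u, v), max(u, v))
        if key in seen:
            raise SpecError(f"duplicate bridge edge {key}")
        seen.add(key)
    n = n_communities * nodes_per_community
    labels = [f"n{i}" for i in range(n)]
    planted = np.repeat(np.arange(n_communities), nodes_per_community)
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(labels)

    def add(u: int, v: int, lo: float, hi: float) -> None:
        c = float(rng.uniform(lo, hi))
        g.add_edge(labels[u], labels[v], correlation=c, strength=c,
                   distance=float(-np.log(c)))

    for comm in range(n_communities):
        base = comm * nodes_per_community
        for i in range(nodes_per_community):
            for j in range(i + 1, nodes_per_community):
                add(base + i, base + j, *intra_correlation)
    for u, v in bridge_edges:
        if not (0 <= u < n and 0 <= v < n):
            raise SpecError(f"bridge edge ({u}, {v}) out of range")
        add(u, v, *inter_correlation)
    return DynamicalNetwork(labels=labels, graph=g), planted
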
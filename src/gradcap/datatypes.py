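"""Core containers shared across the pipeline.

All containers are plain dataclasses around numpy arrays / pandas frames;
they validate their invariants at construction and are cheap to copy.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: Canonical seven-network partition of cortex, ordered along the
#: unimodal -> transmodal hierarchy.
NETWORKS: tuple[str, ...] = ("VIS", "SMN", "DAT", "VAT", "LIM", "FPN", "DMN")

#: Default hierarchy position of each network on the principal axis
#: (0 = unimodal sensory, 1 = transmodal association cortex).
DEFAULT_HIERARCHY: dict[str, float] = {
    net: i / (len(NETWORKS) - 1) for i, net in enumerate(NETWORKS)
}

#: Canonical names of the eight co-activation patterns: six network motifs
#: plus global activation / deactivation.
CAP_NAMES: tuple[str, ...] = (
    "DMN+", "DAT+", "FPN+", "SMN+", "VIS+", "VAT+", "GN+", "GN-",
)

#: Mirror-motif pairing: each CAP's topography is strongly anticorrelated
#: with its partner's.  Pairs contrast networks that sit far apart on the
#: hierarchy, so the state-driven covariance reinforces (rather than
#: fights) the unimodal->transmodal connectivity gradient.
MIRROR_PAIRS: tuple[tuple[str, str], ...] = (
    ("DMN+", "DAT+"), ("FPN+", "SMN+"), ("VIS+", "VAT+"), ("GN+", "GN-"),
)


@dataclass
class Parcellation:
    """Node-level parcellation: network labels, hierarchy, lattice coordinates.

    Attributes
    ----------
    node_id:
        Integer node index, ``0..n_nodes-1``.
    network:
        Network label per node; exactly the seven canonical networks appear.
    hierarchy_position:
        Position of the node's network on the unimodal->transmodal axis,
        in ``[0, 1]``.
    lattice_xyz:
        Integer ``(n, 3)`` voxel coordinates; unique per node, contiguous
        within a network so that cluster-extent analysis is meaningful.
    """

    node_id: np.ndarray
    network: np.ndarray
    hierarchy_position: np.ndarray
    lattice_xyz: np.ndarray

    def __post_init__(self) -> None:
        self.node_id = np.asarray(self.node_id, dtype=int)
        self.network = np.asarray(self.network, dtype=object)
        self.hierarchy_position = np.asarray(self.hierarchy_position, float)
        self.lattice_xyz = np.asarray(self.lattice_xyz, dtype=int)
        n = self.node_id.size
        if not (self.network.size == n and self.hierarchy_position.size == n
                and self.lattice_xyz.shape == (n, 3)):
            raise ValueError("parcellation fields have inconsistent lengths")
        if set(self.network) != set(NETWORKS):
            raise ValueError("parcellation must contain exactly the 7 canonical networks")
        if len({tuple(c) for c in self.lattice_xyz}) != n:
            raise ValueError("lattice coordinates must be unique per node")

    @property
    def n_nodes(self) -> int:
        return self.node_id.size

    def nodes_of(self, network: str) -> np.ndarray:
        return np.flatnonzero(self.network == network)

    @property
    def lattice_shape(self) -> tuple[int, int, int]:
        return tuple(self.lattice_xyz.max(axis=0) + 1)  # type: ignore[return-value]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node_id": self.node_id,
            "network": self.network,
            "hierarchy": self.hierarchy_position,
            "x": self.lattice_xyz[:, 0],
            "y": self.lattice_xyz[:, 1],
            "z": self.lattice_xyz[:, 2],
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        return cls(
            node_id=df["node_id"].to_numpy(),
            network=df["network"].to_numpy(),
            hierarchy_position=df["hierarchy"].to_numpy(),
            lattice_xyz=df[["x", "y", "z"]].to_numpy(),
        )


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per frame.

    Translations are in mm; rotations are already expressed in mm-equivalent
    units, so frame-wise displacement is a plain Euclidean norm of the six
    backward differences.
    """

    params: np.ndarray  # (n_frames, 6)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be (n_frames, 6)")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass
class BoldRun:
    """A node x frame BOLD-like signal matrix with censoring mask and labels.

    Censoring is represented as a boolean mask (True = retained) rather than
    frame deletion, so frame indices stay aligned with ground-truth state
    sequences and motion traces throughout the pipeline.
    """

    signal: np.ndarray  # (n_nodes, n_frames)
    dt_seconds: float
    censor_mask: Optional[np.ndarray] = None  # True = retained
    subject_id: str = "sub-00"
    condition: str = "baseline"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D node x frame matrix")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.n_frames, dtype=bool)
        self.censor_mask = np.asarray(self.censor_mask, bool)
        if self.censor_mask.shape != (self.n_frames,):
            raise ValueError("censor_mask length must equal frame count")

    @property
    def n_nodes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_frames(self) -> int:
        return self.signal.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.censor_mask.sum())

    @property
    def retained(self) -> np.ndarray:
        """Node x retained-frame view of the signal."""
        return self.signal[:, self.censor_mask]

    def with_signal(self, signal: np.ndarray) -> "BoldRun":
        return replace(self, signal=np.asarray(signal, float))


@dataclass
class GroundTruth:
    """Generative ground truth for a synthetic cohort."""

    state_topographies: np.ndarray       # (8, n_nodes), zero-mean unit-var rows
    transition_matrix: np.ndarray        # (8, 8) row-stochastic (baseline)
    transition_matrix_drug: np.ndarray   # (8, 8) row-stochastic (drug)
    cap_names: tuple[str, ...] = CAP_NAMES
    planted_gradient_shift: dict[str, float] = field(default_factory=dict)
    planted_occupancy_shift: Optional[np.ndarray] = None
    asc_effect: float = 0.0

    def __post_init__(self) -> None:
        self.state_topographies = np.asarray(self.state_topographies, float)
        for name in ("transition_matrix", "transition_matrix_drug"):
            t = np.asarray(getattr(self, name), float)
            if t.shape != (8, 8):
                raise ValueError(f"{name} must be 8x8")
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
                raise ValueError(f"{name} rows must sum to 1")
            if np.any(t < 0):
                raise ValueError(f"{name} must be nonnegative")
            setattr(self, name, t)

    def stationary_distribution(self, condition: str = "baseline") -> np.ndarray:
        """Stationary distribution of the chain, by left eigendecomposition."""
        t = (self.transition_matrix if condition == "baseline"
             else self.transition_matrix_drug)
        vals, vecs = np.linalg.eig(t.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class AscScores:
    """Altered-states questionnaire scores, 11 dimensions per subject x condition.

    ``total`` is the sum of the 11 dimension scores (each dimension itself an
    item average in [0, 10]); the summation convention is recorded in
    ``total_rule``.
    """

    table: pd.DataFrame  # columns: subject, condition, dim_01..dim_11, total
    total_rule: str = "sum"

    DIMENSIONS = tuple(f"dim_{i:02d}" for i in range(1, 12))

    def __post_init__(self) -> None:
        required = {"subject", "condition", *self.DIMENSIONS, "total"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"AscScores table missing columns: {sorted(missing)}")
        dims = self.table[list(self.DIMENSIONS)].to_numpy(float)
        if dims.size and (np.nanmin(dims) < -1e-9 or np.nanmax(dims) > 10 + 1e-9):
            raise ValueError("dimension scores must lie in [0, 10]")


@dataclass
class ConnectivityMatrix:
    """Node x node Pearson correlation matrix."""

    values: np.ndarray
    n_frames_used: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v


@dataclass
class GradientSet:
    """Diffusion-embedding loadings ("gradient values") per node.

    ``loadings[:, m]`` is the (m+1)-th non-trivial diffusion component scaled
    by its eigenvalue damping; eigenvalues are reported in decreasing order.
    """

    loadings: np.ndarray      # (n_nodes, k)
    eigenvalues: np.ndarray   # (k,)
    aligned_to: Optional[str] = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, float)
        self.eigenvalues = np.asarray(self.eigenvalues, float)
        if self.loadings.ndim != 2:
            raise ValueError("loadings must be (n_nodes, k)")
        if self.eigenvalues.shape != (self.loadings.shape[1],):
            raise ValueError("one eigenvalue per component required")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")
        if not np.all(np.isfinite(self.loadings)):
            raise ValueError("loadings must be finite")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class CapCentroids:
    """Eight co-activation-pattern centroid topographies."""

    maps: np.ndarray                    # (8, n_nodes), z-scored rows
    names: tuple[str, ...]
    source: str = "kmeans"              # "kmeans" or "ground_truth"
    inertia: Optional[float] = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, float)
        if self.maps.shape[0] != len(self.names):
            raise ValueError("one name per centroid required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("centroid names must be unique")


@dataclass
class CapLabeling:
    """Per-frame CAP assignment for one run (label -1 marks censored frames)."""

    labels: np.ndarray                 # (n_frames,) int, -1 = censored
    best_r: np.ndarray                 # (n_frames,) float, nan where censored
    occurrence_rates: np.ndarray       # (k,)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        self.best_r = np.asarray(self.best_r, float)
        self.occurrence_rates = np.asarray(self.occurrence_rates, float)
        if not np.isclose(self.occurrence_rates.sum(), 1.0):
            raise ValueError("occurrence rates must sum to 1")


@dataclass
class StatResult:
    """A single inferential result with optional adjustment and CI."""

    statistic: float
    df: object
    p_raw: float
    method: str
    p_adjusted: Optional[float] = None
    ci_95: Optional[tuple[float, float]] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError("p_raw outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be below raw p")

    def to_dict(self) -> dict:
        d = {
            "statistic": float(self.statistic),
            "df": self.df,
            "p_raw": float(self.p_raw),
            "method": self.method,
        }
        if self.p_adjusted is not None:
            d["p_adjusted"] = float(self.p_adjusted)
        if self.ci_95 is not None:
            d["ci_95"] = [float(self.ci_95[0]), float(self.ci_95[1])]
        if self.extras:
            d["extras"] = self.extras
        return d
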
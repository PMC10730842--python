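"""Synthetic paired-cohort generator with known ground truth.

Emulates the structure of a paired pharmaco-fMRI resting-state study:

* a seven-network parcellation whose networks are ordered along a
  unimodal -> transmodal hierarchy and occupy contiguous blocks of an
  integer lattice;
* BOLD-like node signals driven by (i) a latent eight-state Markov chain of
  co-activation topographies organized as four anticorrelated "mirror"
  pairs, (ii) hierarchy-coupled latent network signals whose inter-network
  correlation decays with hierarchy distance, (iii) a shared global signal,
  and (iv) white node noise;
* six-parameter motion traces with occasional spikes;
* an 11-dimension altered-states questionnaire whose total is coupled
  (negatively) to each subject's realized functional differentiation.

The drug condition contracts the FPN and SMN hierarchy positions toward the
centre of the axis, raises global coupling, and shifts state occupancy from
FPN+/SMN+ toward global co-activation (GN+) — the planted analogues of the
effects the analysis stages are meant to recover.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import CohortConfig, EffectConfig
from .datatypes import (
    CAP_NAMES,
    DEFAULT_HIERARCHY,
    MIRROR_PAIRS,
    NETWORKS,
    AscScores,
    BoldRun,
    GroundTruth,
    MotionTrace,
    Parcellation,
)

# Latent connectivity field: nodes carry a continuous coordinate on the
# unimodal->transmodal axis (network hierarchy position plus a within-network
# spread of +/- NODE_SPREAD) and their latent signals follow an
# Ornstein-Uhlenbeck kernel corr = exp(-|du| / LATENT_SCALE) in that
# coordinate.  Smooth decay (rather than network-block coupling) is what
# makes the top-10%-per-row sparsified connectivity retain between-network
# neighbours, so the principal diffusion component is ordered by hierarchy.
NODE_SPREAD = 0.08
LATENT_SCALE = 0.15

BASELINE_OCCUPANCY = {
    "DMN+": 0.15, "DAT+": 0.12, "FPN+": 0.16, "SMN+": 0.16,
    "VIS+": 0.12, "VAT+": 0.11, "GN+": 0.06, "GN-": 0.12,
}

#: Temporal AR(1) coefficient of the latent network and global signals
#: (dt = 2 s); ~0.6 puts most of their power in the 0.01-0.1 Hz band.
AR_COEFF = 0.6


@dataclass
class MotionSpec:
    """Motion model: smooth drift plus large spikes at given/random frames."""

    base_sd: float = 0.02
    spike_prob: float = 0.03
    spike_mm: float = 0.5
    spike_frames: Optional[list[int]] = None


@dataclass
class Cohort:
    """A generated paired cohort: runs, motion, ground truth, questionnaires."""

    parcellation: Parcellation
    truth: GroundTruth
    runs: dict            # (subject_id, condition) -> BoldRun
    motion: dict          # (subject_id, condition) -> MotionTrace
    cap_sequences: dict   # (subject_id, condition) -> (n_frames,) int array
    asc: AscScores
    subject_effects: dict  # subject_id -> realized effect scale
    conditions: tuple[str, str] = ("baseline", "drug")

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.runs})


def make_parcellation(n_nodes: int, seed: int = 0) -> Parcellation:
    """Build a seven-network parcellation on an integer lattice.

    Nodes are split evenly across the canonical networks; each network
    occupies a contiguous raster-order block of the smallest lattice that
    holds ``n_nodes`` voxels, so network clusters are spatially compact.
    """
    if n_nodes < 70 or n_nodes % 7 != 0:
        raise ValueError("n_nodes must be >= 70 and divisible by 7")
    per = n_nodes // 7
    network = np.repeat(np.array(NETWORKS, dtype=object), per)
    hierarchy = np.repeat([DEFAULT_HIERARCHY[n] for n in NETWORKS], per)

    # smallest near-cubic lattice that holds all nodes, filled in raster order
    side = int(np.ceil(n_nodes ** (1 / 3)))
    nz = side
    ny = side
    nx = int(np.ceil(n_nodes / (ny * nz)))
    idx = np.arange(n_nodes)
    x = idx // (ny * nz)
    y = (idx // nz) % ny
    z = idx % nz
    return Parcellation(
        node_id=idx,
        network=network,
        hierarchy_position=hierarchy,
        lattice_xyz=np.column_stack([x, y, z]),
    )


def _standardize_rows(m: np.ndarray) -> np.ndarray:
    m = m - m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    return m / sd


def make_ground_truth(
    parc: Parcellation,
    effects: EffectConfig | None = None,
    persistence: float = 0.7,
    seed: int = 0,
    texture_sd: float = 0.40,
    mirror_jitter: float = 0.05,
) -> GroundTruth:
    """Construct state topographies and baseline/drug transition matrices.

    The eight CAP topographies are network contrasts plus fine per-node
    texture, organized as four mirror pairs (the partner is the negated
    map up to a small jitter, so pair correlation <= -0.9).  The texture is
    spatially white, hence nearly orthogonal to the smooth latent
    connectivity field — it is what lets frame labelling discriminate
    states against ongoing connectivity fluctuations, as fine-grained
    structure does in real co-activation topographies.  Transition matrices
    are ``persistence * I + (1 - persistence) * pi`` so their stationary
    distribution equals the target occupancy ``pi`` exactly.
    """
    effects = effects or EffectConfig()
    rng = np.random.default_rng(seed)
    n = parc.n_nodes

    def contrast(pos_net: str, neg_net: str) -> np.ndarray:
        t = np.zeros(n)
        t[parc.nodes_of(pos_net)] = 1.0
        t[parc.nodes_of(neg_net)] = -1.0
        return t

    base_maps = {
        "DMN+": contrast("DMN", "DAT"),
        "FPN+": contrast("FPN", "SMN"),
        "VIS+": contrast("VIS", "VAT"),
        "GN+": 0.7 + 0.6 * parc.hierarchy_position,
    }
    maps = np.zeros((8, n))
    for a, b in MIRROR_PAIRS:
        full = base_maps[a] + texture_sd * rng.standard_normal(n)
        maps[CAP_NAMES.index(a)] = full + mirror_jitter * rng.standard_normal(n)
        maps[CAP_NAMES.index(b)] = -full + mirror_jitter * rng.standard_normal(n)
    maps = _standardize_rows(maps)

    pi_base = np.array([BASELINE_OCCUPANCY[c] for c in CAP_NAMES])
    pi_drug = pi_base.copy()
    pi_drug[CAP_NAMES.index("FPN+")] += effects.occupancy_shift_fpn
    pi_drug[CAP_NAMES.index("SMN+")] += effects.occupancy_shift_smn
    pi_drug[CAP_NAMES.index("GN+")] += effects.occupancy_shift_gn
    if np.any(pi_drug <= 0):
        raise ValueError("occupancy shifts drive a state probability below 0")
    pi_drug = pi_drug / pi_drug.sum()

    def chain(pi: np.ndarray) -> np.ndarray:
        return persistence * np.eye(8) + (1.0 - persistence) * pi[None, :]

    return GroundTruth(
        state_topographies=maps,
        transition_matrix=chain(pi_base),
        transition_matrix_drug=chain(pi_drug),
        planted_gradient_shift={
            "FPN": -effects.gradient_shift, "SMN": +effects.gradient_shift,
        },
        planted_occupancy_shift=pi_drug - pi_base,
        asc_effect=-effects.asc_gain,
    )


def node_coordinates(
    parc: Parcellation, hierarchy: np.ndarray, spread: float = NODE_SPREAD,
) -> np.ndarray:
    """Continuous per-node coordinate on the unimodal->transmodal axis.

    Nodes of a network are spread evenly over ``[h - spread, h + spread]``
    around the network's (possibly condition-shifted) hierarchy position
    ``h``; deterministic in node order.
    """
    u = np.empty(parc.n_nodes)
    for i, net in enumerate(NETWORKS):
        nodes = parc.nodes_of(net)
        offsets = np.linspace(-spread, spread, nodes.size)
        u[nodes] = hierarchy[i] + offsets
    return u


def latent_covariance(u: np.ndarray, scale: float = LATENT_SCALE) -> np.ndarray:
    """Node x node latent correlation: exp(-|u_i - u_j| / scale).

    The Ornstein-Uhlenbeck kernel on the 1-D hierarchy coordinate is
    positive definite and decays smoothly, planting a principal
    connectivity gradient ordered by hierarchy.
    """
    d = np.abs(u[:, None] - u[None, :])
    return np.exp(-d / scale)


def model_covariance(
    parc: Parcellation,
    truth: GroundTruth,
    condition: str = "baseline",
    hierarchy_override: Optional[dict[str, float]] = None,
    cap_amp: float = 0.8,
    latent_amp: float = 1.6,
    global_amp: float = 0.2,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Exact (infinite-data) node covariance implied by the generative model.

    Sum of the occupancy-weighted state-topography covariance, the latent
    Ornstein-Uhlenbeck kernel, the global-signal term and the white-noise
    diagonal.  Its diffusion embedding serves as the study's external
    alignment template, playing the role a large independent reference
    sample plays for real gradient analyses.
    """
    pi = truth.stationary_distribution(condition)
    t = truth.state_topographies
    mean_map = (pi[:, None] * t).sum(axis=0)
    state_cov = (t.T * pi) @ t - np.outer(mean_map, mean_map)
    hierarchy = np.array([DEFAULT_HIERARCHY[n] for n in NETWORKS])
    if hierarchy_override:
        for net, h in hierarchy_override.items():
            hierarchy[NETWORKS.index(net)] = h
    k = latent_covariance(node_coordinates(parc, hierarchy))
    n = parc.n_nodes
    return (cap_amp**2 * state_cov + latent_amp**2 * k
            + global_amp**2 * np.ones((n, n)) + noise_sd**2 * np.eye(n))


def _ar1(innovations: np.ndarray, phi: float) -> np.ndarray:
    """Turn iid innovations (frames x series) into stationary unit-variance
    AR(1) series, so most latent power falls in the 0.01-0.1 Hz band."""
    n = innovations.shape[0]
    out = np.empty_like(innovations)
    out[0] = innovations[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + scale * innovations[t]
    return out


def simulate_markov_chain(
    transition: np.ndarray, n_frames: int, rng: np.random.Generator,
    start_dist: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Sample a state sequence from a row-stochastic transition matrix."""
    k = transition.shape[0]
    if start_dist is None:
        vals, vecs = np.linalg.eig(transition.T)
        pi = np.abs(np.real(vecs[:, np.argmin(np.abs(vals - 1.0))]))
        start_dist = pi / pi.sum()
    cum = np.cumsum(transition, axis=1)
    states = np.empty(n_frames, dtype=int)
    u = rng.random(n_frames)
    states[0] = int(np.searchsorted(np.cumsum(start_dist), u[0]))
    for t in range(1, n_frames):
        states[t] = int(np.searchsorted(cum[states[t - 1]], u[t]))
    return np.clip(states, 0, k - 1)


def simulate_motion(
    n_frames: int, spec: MotionSpec, rng: np.random.Generator,
) -> MotionTrace:
    """Motion trace whose backward differences are small, with planted spikes."""
    deriv = spec.base_sd * rng.standard_normal((n_frames, 6))
    if spec.spike_frames is not None:
        spikes = np.asarray(spec.spike_frames, dtype=int)
    else:
        spikes = np.flatnonzero(rng.random(n_frames) < spec.spike_prob)
        spikes = spikes[spikes > 0]
    deriv[spikes, :3] += spec.spike_mm
    deriv[0] = 0.0
    return MotionTrace(params=np.cumsum(deriv, axis=0))


def simulate_run(
    parc: Parcellation,
    truth: GroundTruth,
    n_frames: int = 180,
    dt_seconds: float = 2.0,
    noise_sd: float = 1.0,
    motion_spec: MotionSpec | None = None,
    seed: int = 0,
    *,
    condition: str = "baseline",
    subject_id: str = "sub-00",
    cap_amp: float = 1.0,
    latent_amp: float = 1.0,
    global_amp: float = 0.2,
    hierarchy_override: Optional[dict[str, float]] = None,
    start_state: Optional[int] = None,
) -> tuple[BoldRun, MotionTrace, np.ndarray]:
    """Simulate one run: signal = CAP topography + hierarchy-coupled latent
    field + global signal + node noise.

    Each frame is ``cap_amp * T[s_t] + latent_amp * L[node, t]
    + global_amp * g_t + noise_sd * eps`` where ``L`` is smooth over the
    nodes' hierarchy coordinates; ``hierarchy_override`` replaces the
    hierarchy position of selected networks before building the latent
    covariance (the drug contraction enters here).
    """
    if n_frames < 50:
        raise ValueError("n_frames must be >= 50")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    motion_spec = motion_spec or MotionSpec()

    hierarchy = np.array([DEFAULT_HIERARCHY[n] for n in NETWORKS])
    if hierarchy_override:
        for net, h in hierarchy_override.items():
            hierarchy[NETWORKS.index(net)] = h

    transition = (truth.transition_matrix if condition == "baseline"
                  else truth.transition_matrix_drug)
    start = None if start_state is None else np.eye(8)[start_state]
    states = simulate_markov_chain(transition, n_frames, rng, start_dist=start)

    u = node_coordinates(parc, hierarchy)
    cov = latent_covariance(u)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(u)))
    latents = _ar1(rng.standard_normal((n_frames, parc.n_nodes)), AR_COEFF)
    latents = latents @ chol.T  # (frames, nodes), smooth over hierarchy

    signal = cap_amp * truth.state_topographies[states].T  # (nodes, frames)
    signal = signal + latent_amp * latents.T
    g = _ar1(rng.standard_normal((n_frames, 1)), AR_COEFF).ravel()
    signal = signal + global_amp * g[None, :]
    if noise_sd > 0:
        signal = signal + noise_sd * rng.standard_normal(signal.shape)

    run = BoldRun(signal=signal, dt_seconds=dt_seconds,
                  subject_id=subject_id, condition=condition)
    motion = simulate_motion(n_frames, motion_spec, rng)
    return run, motion, states


def _asc_table(
    subjects: list[str], effects: EffectConfig,
    effect_scale: dict[str, float], rng: np.random.Generator,
) -> AscScores:
    """Questionnaire scores: drug totals track realized contraction."""
    rows = []
    present = set(subjects)
    n_missing = min(effects.n_missing_asc, len(subjects))
    if n_missing > 0:
        missing = rng.choice(subjects, size=n_missing, replace=False)
        present -= set(missing)
    for sub in subjects:
        if sub not in present:
            continue
        for condition in ("baseline", "drug"):
            if condition == "baseline":
                total = float(np.clip(rng.normal(4.0, 2.0), 0, 110))
            else:
                contraction = effect_scale[sub] * 2.0 * effects.gradient_shift
                total = float(np.clip(
                    effects.asc_gain * contraction + rng.normal(0.0, 8.0), 0, 110))
            dims = np.clip(total / 11.0 + rng.normal(0.0, 0.8, size=11), 0, 10)
            rows.append({"subject": sub, "condition": condition,
                         **{d: float(v) for d, v in zip(AscScores.DIMENSIONS, dims)},
                         "total": float(dims.sum())})
    columns = ["subject", "condition", *AscScores.DIMENSIONS, "total"]
    return AscScores(table=pd.DataFrame(rows, columns=columns), total_rule="sum")


def simulate_cohort(
    n_subjects: int = 16,
    effect_config: EffectConfig | None = None,
    seed: int = 0,
    cohort_config: CohortConfig | None = None,
) -> Cohort:
    """Generate a paired two-condition cohort with planted effects.

    Drug runs apply the FPN/SMN hierarchy contraction (scaled by a
    per-subject effect jitter), a raised global-signal amplitude, and the
    shifted state-occupancy chain; questionnaire totals are coupled to the
    realized contraction so differentiation and subjective intensity are
    negatively related across records.
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    effects = effect_config or EffectConfig()
    cc = cohort_config or CohortConfig(n_subjects=n_subjects)
    rng = np.random.default_rng(seed)

    parc = make_parcellation(cc.n_nodes, seed=seed)
    truth = make_ground_truth(parc, effects, persistence=cc.persistence,
                              seed=rng.integers(2**31))

    subjects = [f"sub-{i:02d}" for i in range(n_subjects)]
    effect_scale = {
        s: float(np.clip(rng.normal(1.0, effects.subject_sd), 0.2, 2.0))
        for s in subjects
    }

    runs, motion, seqs = {}, {}, {}
    for sub in subjects:
        for condition in ("baseline", "drug"):
            if condition == "drug":
                e = effect_scale[sub]
                shift = e * effects.gradient_shift
                override = {
                    "FPN": DEFAULT_HIERARCHY["FPN"] - shift,
                    "SMN": DEFAULT_HIERARCHY["SMN"] + shift,
                }
                g_amp = cc.global_amp + e * effects.global_coupling_increase
            else:
                override = None
                g_amp = cc.global_amp
            run, mot, seq = simulate_run(
                parc, truth,
                n_frames=cc.n_frames, dt_seconds=cc.dt_seconds,
                noise_sd=cc.noise_sd,
                motion_spec=MotionSpec(base_sd=cc.motion_base_sd,
                                       spike_prob=cc.motion_spike_prob,
                                       spike_mm=cc.motion_spike_mm),
                seed=int(rng.integers(2**31)),
                condition=condition, subject_id=sub,
                cap_amp=cc.cap_amp, latent_amp=cc.latent_amp,
                global_amp=g_amp, hierarchy_override=override,
            )
            runs[(sub, condition)] = run
            motion[(sub, condition)] = mot
            seqs[(sub, condition)] = seq

    asc = _asc_table(subjects, effects, effect_scale, rng)
    return Cohort(parcellation=parc, truth=truth, runs=runs, motion=motion,
                  cap_sequences=seqs, asc=asc, subject_effects=effect_scale)
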
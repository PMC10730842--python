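"""Connectivity-gradient estimation.

The chain follows the standard connectome-gradient recipe: Pearson
connectivity -> Fisher z -> row-wise sparsification (top 10% of weighted
connections per row) -> normalized-angle (cosine) affinity -> diffusion-map
embedding with density normalization ``alpha`` and diffusion time ``t``
(``t = 0`` selects automated damping, scaling component ``m`` by
``lambda_m / (1 - lambda_m)``).  Per-subject embeddings are made comparable
by Procrustes rotation onto a common reference.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .config import GradientConfig
from .datatypes import NETWORKS, BoldRun, ConnectivityMatrix, GradientSet, Parcellation


def connectivity_matrix(run: BoldRun) -> ConnectivityMatrix:
    """Pearson correlation between node series over retained frames."""
    if run.n_retained < 10:
        raise ValueError("need at least 10 retained frames for connectivity")
    x = run.retained
    c = np.corrcoef(x)
    np.fill_diagonal(c, 1.0)
    c = (c + c.T) / 2.0
    return ConnectivityMatrix(values=c, n_frames_used=run.n_retained)


def fisher_z(c: ConnectivityMatrix, clip: float = 0.999999) -> np.ndarray:
    """Fisher z-transform of off-diagonal correlations; diagonal set to 0."""
    z = np.arctanh(np.clip(c.values, -clip, clip))
    np.fill_diagonal(z, 0.0)
    return z


def sparsify_rows(z: np.ndarray, sparsity: float = 0.90) -> np.ndarray:
    """Keep the top ``(1 - sparsity)`` fraction of weighted connections per row.

    The diagonal is excluded from selection (a self-connection is not a
    connection); the retained count per row is ``round((1-s)*(n-1))``.
    Ties at the cutoff break deterministically toward the lowest index.
    The result is generally asymmetric.
    """
    z = np.asarray(z, float)
    n = z.shape[0]
    if z.ndim != 2 or z.shape[1] != n:
        raise ValueError("sparsify_rows expects a square matrix")
    if not (0.0 < sparsity < 1.0):
        raise ValueError("sparsity must lie in (0, 1)")
    keep = int(round((1.0 - sparsity) * (n - 1)))
    keep = max(keep, 1)
    out = np.zeros_like(z)
    work = z.copy()
    np.fill_diagonal(work, -np.inf)
    # stable argsort of descending values -> ties resolved to lowest index
    order = np.argsort(-work, axis=1, kind="stable")[:, :keep]
    rows = np.repeat(np.arange(n), keep)
    out[rows, order.ravel()] = z[rows, order.ravel()]
    np.fill_diagonal(out, np.diag(z))
    return out


def normalized_angle_affinity(s: np.ndarray) -> np.ndarray:
    """Similarity of connectivity profiles: 1 - arccos(cosine) / pi.

    Identical rows map to 1, orthogonal rows to 0.5, anti-parallel rows
    to 0; the result is symmetric with unit diagonal.
    """
    s = np.asarray(s, float)
    norms = np.linalg.norm(s, axis=1)
    zero = np.flatnonzero(norms < 1e-300)
    if zero.size:
        raise ValueError(f"all-zero connectivity rows for nodes {zero.tolist()}")
    cos = (s @ s.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    a = 1.0 - np.arccos(cos) / np.pi
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def diffusion_embedding(
    a: np.ndarray, cfg: GradientConfig | None = None,
) -> GradientSet:
    """Diffusion-map embedding of a symmetric nonnegative affinity matrix.

    With row sums ``d``, the kernel is density-normalized as
    ``W = a / (d_i^alpha d_j^alpha)`` and row-normalized into a Markov
    operator ``P``; the embedding consists of the non-trivial right
    eigenvectors of ``P`` (constant stationary vector dropped), each scaled
    by ``lambda^t`` or, for ``t = 0``, by the damped factor
    ``lambda / (1 - lambda)``.  Component signs are fixed by making the
    largest-magnitude element positive.
    """
    cfg = cfg or GradientConfig()
    cfg.validate()
    a = np.asarray(a, float)
    n = a.shape[0]
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    n_comp_graph, labels = connected_components(a > 0, directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"affinity graph is disconnected; component sizes {sizes}")

    k = min(cfg.n_components, n - 2)
    d = a.sum(axis=1)
    w = a / np.outer(d**cfg.alpha, d**cfg.alpha)
    d2 = w.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d2)
    m = (w * inv_sqrt[:, None]) * inv_sqrt[None, :]
    m = (m + m.T) / 2.0
    vals, vecs = eigh(m, subset_by_index=[n - (k + 1), n - 1])
    vals = vals[::-1]
    vecs = vecs[:, ::-1]

    psi = vecs * inv_sqrt[:, None]
    # normalize against the trivial (stationary) component so psi_0 == 1
    psi = psi / psi[:, [0]]

    lambdas = np.clip(vals[1:], 0.0, 1.0 - 1e-12)
    warn_list: list[str] = []
    gaps = -np.diff(vals)
    if np.any(gaps[: max(1, k - 1)] < 1e-8):
        warn_list.append("near-degenerate leading eigenvalues; component order unstable")
        warnings.warn(warn_list[-1], RuntimeWarning, stacklevel=2)

    if cfg.diffusion_time == 0:
        scale = lambdas / (1.0 - lambdas)
    else:
        scale = lambdas**cfg.diffusion_time
    loadings = psi[:, 1:] * scale[None, :]
    # sign convention: largest-magnitude element positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return GradientSet(loadings=loadings, eigenvalues=lambdas, warnings=warn_list)


def gradients_from_connectivity(
    c: ConnectivityMatrix, cfg: GradientConfig | None = None,
) -> GradientSet:
    """Chain from a ready connectivity matrix: z -> sparsify -> affinity -> embed."""
    cfg = cfg or GradientConfig()
    z = fisher_z(c)
    s = sparsify_rows(z, cfg.sparsity)
    a = normalized_angle_affinity(s)
    return diffusion_embedding(a, cfg)


def gradients_from_run(
    run: BoldRun, cfg: GradientConfig | None = None,
) -> GradientSet:
    """Full per-run chain: connectivity -> z -> sparsify -> affinity -> embed."""
    return gradients_from_connectivity(connectivity_matrix(run), cfg)


def procrustes_align(g: GradientSet, ref: GradientSet,
                     ref_id: str = "reference") -> GradientSet:
    """Rotate ``g`` onto ``ref`` with the best orthogonal transform.

    No scaling or translation is applied; reflections are allowed (the
    transform resolves eigenvector sign and order ambiguity)."""
    if g.loadings.shape != ref.loadings.shape:
        raise ValueError("gradient sets must share node count and k")
    r, _ = orthogonal_procrustes(g.loadings, ref.loadings)
    return GradientSet(loadings=g.loadings @ r, eigenvalues=g.eigenvalues,
                       aligned_to=ref_id, warnings=list(g.warnings))


def build_reference(gradients: list[GradientSet], n_iter: int = 10,
                    tol: float = 1e-6,
                    orient_to: np.ndarray | None = None) -> GradientSet:
    """Iterative mean template: align all sets to the running mean, average,
    repeat.  Deterministic given input order; initialized at the first set.

    ``orient_to`` (e.g. the parcellation's hierarchy positions) fixes the
    otherwise arbitrary global sign of the principal component so that it
    correlates positively with the given node vector — the role an external
    alignment template plays in fixing gradient polarity across studies.
    """
    if len(gradients) < 2:
        raise ValueError("need at least 2 gradient sets to build a reference")
    ref = gradients[0].loadings.copy()
    for _ in range(n_iter):
        aligned = []
        for g in gradients:
            r, _ = orthogonal_procrustes(g.loadings, ref)
            aligned.append(g.loadings @ r)
        new = np.mean(aligned, axis=0)
        delta = np.linalg.norm(new - ref) / max(np.linalg.norm(ref), 1e-300)
        ref = new
        if delta < tol:
            break
    if orient_to is not None:
        v = np.asarray(orient_to, float)
        if np.corrcoef(ref[:, 0], v)[0, 1] < 0:
            ref = -ref
    ev = np.mean([g.eigenvalues for g in gradients], axis=0)
    ev = np.minimum.accumulate(ev)  # enforce monotone order after averaging
    return GradientSet(loadings=ref, eigenvalues=ev, aligned_to="self")


def network_summary(
    g: GradientSet, parc: Parcellation, component: int = 0,
) -> pd.Series:
    """Mean loading per network on one component, plus the overall range.

    Returns a Series indexed by the seven network names with an extra
    ``range`` entry (max - min over all nodes)."""
    if not (0 <= component < g.n_components):
        raise ValueError(f"component {component} out of bounds")
    v = g.loadings[:, component]
    means = {net: float(v[parc.nodes_of(net)].mean()) for net in NETWORKS}
    means["range"] = float(v.max() - v.min())
    return pd.Series(means)
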
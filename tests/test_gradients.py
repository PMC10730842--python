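"""Gradient chain: connectivity, Fisher z, sparsification, normalized-angle
affinity, diffusion embedding (vs independent dense oracle), Procrustes."""
import numpy as np
import pytest

from gradcap import (
    BoldRun,
    ConnectivityMatrix,
    GradientConfig,
    GradientSet,
    NETWORKS,
    make_parcellation,
)
from gradcap.gradients import (
    build_reference,
    connectivity_matrix,
    diffusion_embedding,
    fisher_z,
    gradients_from_connectivity,
    network_summary,
    normalized_angle_affinity,
    procrustes_align,
    sparsify_rows,
)


# ----------------------------------------------------- independent oracles

def oracle_diffusion_embedding(a, alpha=0.5, diffusion_time=0.0, k=10):
    """Brute-force diffusion map via the *nonsymmetric* Markov operator.

    Deliberately takes a different route from the implementation (which
    eigendecomposes a symmetrized kernel): build P explicitly, use
    scipy.linalg.eig, sort by eigenvalue, normalize against the stationary
    eigenvector."""
    from scipy.linalg import eig

    a = np.asarray(a, float)
    d = a.sum(axis=1)
    w = a / np.outer(d**alpha, d**alpha)
    d2 = w.sum(axis=1)
    p = w / d2[:, None]
    vals, vecs = eig(p)
    order = np.argsort(-np.real(vals))
    vals = np.real(vals[order])
    vecs = np.real(vecs[:, order])
    # scale convention: unit-norm eigenvectors of the *symmetrized* operator
    # (v = D^{1/2} u), then psi_ij = v_ij / v_i0
    v = vecs * np.sqrt(d2)[:, None]
    v = v / np.linalg.norm(v, axis=0, keepdims=True)
    psi = v / v[:, [0]]
    lam = np.clip(vals[1:k + 1], 0, 1 - 1e-12)
    scale = lam / (1 - lam) if diffusion_time == 0 else lam**diffusion_time
    return psi[:, 1:k + 1] * scale, lam


def oracle_full_chain(corr, sparsity=0.9, alpha=0.5, k=10):
    """Monolithic reference for z -> sparsify -> affinity -> embed, written
    with plain loops, independent of the package's vectorized path."""
    n = corr.shape[0]
    z = np.arctanh(np.clip(corr, -0.999999, 0.999999))
    for i in range(n):
        z[i, i] = 0.0
    keep = max(1, int(round((1 - sparsity) * (n - 1))))
    s = np.zeros_like(z)
    for i in range(n):
        vals = [(z[i, j], j) for j in range(n) if j != i]
        vals.sort(key=lambda t: (-t[0], t[1]))
        for v, j in vals[:keep]:
            s[i, j] = v
    aff = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            cos = s[i] @ s[j] / (np.linalg.norm(s[i]) * np.linalg.norm(s[j]))
            aff[i, j] = 1 - np.arccos(np.clip(cos, -1, 1)) / np.pi
    aff = (aff + aff.T) / 2
    np.fill_diagonal(aff, 1.0)
    return oracle_diffusion_embedding(aff, alpha=alpha, k=k)


def random_affinity(rng, n):
    x = rng.normal(size=(n, n))
    a = np.abs(x @ x.T) / n
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a / a.max()


def assert_match_up_to_sign(got, expect, atol, eigenvalues=None, min_gap=1e-6):
    """Component-wise comparison up to sign.

    Components inside a (near-)degenerate eigenvalue group have an
    arbitrary basis, so only components separated from both neighbours by
    ``min_gap`` are compared one-to-one; at least one component must be
    comparable."""
    assert got.shape == expect.shape
    k = got.shape[1]
    compared = 0
    for j in range(k):
        if eigenvalues is not None:
            lo = eigenvalues[j - 1] - eigenvalues[j] if j > 0 else np.inf
            hi = eigenvalues[j] - eigenvalues[j + 1] if j < k - 1 else np.inf
            if min(lo, hi) < min_gap:
                continue
        d1 = np.max(np.abs(got[:, j] - expect[:, j]))
        d2 = np.max(np.abs(got[:, j] + expect[:, j]))
        assert min(d1, d2) < atol, f"component {j}: {min(d1, d2)}"
        compared += 1
    assert compared >= 1


# ------------------------------------------------------------- connectivity

def test_connectivity_copies_and_anticopies(rng):
    sig = rng.normal(size=(3, 40))
    sig[1] = sig[0]
    sig[2] = -sig[0]
    c = connectivity_matrix(BoldRun(signal=sig, dt_seconds=2.0))
    assert c.values[0, 1] == pytest.approx(1.0)
    assert c.values[0, 2] == pytest.approx(-1.0)
    assert np.allclose(np.diag(c.values), 1.0)


def test_connectivity_matches_pairwise_loop(rng):
    sig = rng.normal(size=(5, 20))
    c = connectivity_matrix(BoldRun(signal=sig, dt_seconds=2.0))
    for i in range(5):
        for j in range(5):
            xi, xj = sig[i], sig[j]
            r = (np.mean(xi * xj) - xi.mean() * xj.mean()) / (xi.std() * xj.std())
            assert c.values[i, j] == pytest.approx(r, abs=1e-12)


def test_connectivity_requires_retained_frames(rng):
    sig = rng.normal(size=(3, 30))
    mask = np.zeros(30, bool)
    mask[:5] = True
    with pytest.raises(ValueError):
        connectivity_matrix(BoldRun(signal=sig, dt_seconds=2.0, censor_mask=mask))


def test_fisher_z_closed_form():
    c = ConnectivityMatrix(values=np.array([[1.0, 0.0, 0.5],
                                            [0.0, 1.0, 1.0],
                                            [0.5, 1.0, 1.0]]), n_frames_used=10)
    z = fisher_z(c)
    assert z[0, 1] == 0.0
    assert z[0, 2] == pytest.approx(np.arctanh(0.5), abs=1e-12)  # ~0.5493
    assert np.isfinite(z[1, 2])  # clipped r=1
    assert np.all(np.diag(z) == 0.0)


# ------------------------------------------------------------ sparsification

def test_sparsify_top10_count():
    rng = np.random.default_rng(0)
    z = rng.normal(size=(101, 101))
    s = sparsify_rows(z, 0.9)
    nnz = (s != 0).sum(axis=1) - (np.diag(s) != 0)
    assert np.all(nnz == 10)


def test_sparsify_limit_keeps_everything(rng):
    z = rng.normal(size=(50, 50))
    np.fill_diagonal(z, 0.0)
    s = sparsify_rows(z, 0.001)
    off = ~np.eye(50, dtype=bool)
    assert np.array_equal(s[off], z[off])


def test_sparsify_tie_break_lowest_index():
    z = np.zeros((5, 5))
    z[0] = [0.0, 0.7, 0.7, 0.7, 0.7]  # four-way tie, keep = round(.5*4) = 2
    s = sparsify_rows(z, 0.5)
    assert list(np.flatnonzero(s[0])) == [1, 2]
    with pytest.raises(ValueError):
        sparsify_rows(z, 1.5)


# --------------------------------------------------------------- affinity

def test_affinity_angle_landmarks():
    s = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 3.0], [-1.0, 0.0]])
    a = normalized_angle_affinity(s)
    assert a[0, 1] == pytest.approx(1.0)     # parallel
    assert a[0, 2] == pytest.approx(0.5)     # orthogonal
    assert a[0, 3] == pytest.approx(0.0)     # anti-parallel
    assert np.allclose(a, a.T)
    assert np.all((a >= 0) & (a <= 1))


def test_affinity_zero_row_names_node():
    s = np.ones((3, 4))
    s[1] = 0.0
    with pytest.raises(ValueError, match="1"):
        normalized_angle_affinity(s)


# --------------------------------------------------------------- embedding

def test_embedding_matches_dense_oracle(rng):
    for n in (12, 25, 30):
        a = random_affinity(rng, n)
        cfg = GradientConfig(n_components=6)
        g = diffusion_embedding(a, cfg)
        expect, lam = oracle_diffusion_embedding(a, k=6)
        assert_match_up_to_sign(g.loadings, expect, 1e-8, eigenvalues=lam)
        assert np.allclose(g.eigenvalues, lam, atol=1e-10)
        assert np.all(np.diff(g.eigenvalues) <= 1e-12)
        assert np.all((g.eigenvalues >= 0) & (g.eigenvalues < 1))


def test_embedding_two_blocks_with_weak_bridge():
    n = 12
    a = np.full((n, n), 0.02)
    a[:6, :6] = 0.9
    a[6:, 6:] = 0.9
    np.fill_diagonal(a, 1.0)
    g = diffusion_embedding(a, GradientConfig(n_components=3))
    v = g.loadings[:, 0]
    assert np.all(np.sign(v[:6]) != np.sign(v[6:]))
    gap = abs(v[:6].mean() - v[6:].mean())
    spread = max(v[:6].std(), v[6:].std())
    assert spread < gap
    expect, lam = oracle_diffusion_embedding(a, k=3)
    assert_match_up_to_sign(g.loadings, expect, 1e-8, eigenvalues=lam)


def test_embedding_permutation_equivariance(rng):
    a = random_affinity(rng, 20)
    perm = rng.permutation(20)
    g = diffusion_embedding(a, GradientConfig(n_components=4))
    gp = diffusion_embedding(a[np.ix_(perm, perm)], GradientConfig(n_components=4))
    assert_match_up_to_sign(gp.loadings, g.loadings[perm], 1e-8,
                            eigenvalues=g.eigenvalues)


def test_embedding_rejects_disconnected_affinity():
    a = np.zeros((6, 6))
    a[:3, :3] = 0.8
    a[3:, 3:] = 0.8
    np.fill_diagonal(a, 1.0)
    with pytest.raises(ValueError, match="3"):
        diffusion_embedding(a)


def test_markov_operator_row_stochastic(rng):
    """After alpha-normalization the implied operator P is row-stochastic;
    checked by reconstructing P exactly as the definition states."""
    a = random_affinity(rng, 15)
    d = a.sum(axis=1)
    w = a / np.outer(d**0.5, d**0.5)
    p = w / w.sum(axis=1, keepdims=True)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)


def test_full_chain_matches_monolithic_oracle(rng):
    for n in (15, 30):
        x = rng.normal(size=(n, 60))
        corr = np.corrcoef(x)
        got = gradients_from_connectivity(
            ConnectivityMatrix(values=corr, n_frames_used=60),
            GradientConfig(n_components=5))
        expect, lam = oracle_full_chain(corr.copy(), k=5)
        assert_match_up_to_sign(got.loadings, expect, 1e-8,
                                eigenvalues=lam, min_gap=1e-4)


# --------------------------------------------------------------- procrustes

def _random_gradient(rng, n=40, k=5):
    lam = np.sort(rng.uniform(0.1, 0.9, size=k))[::-1]
    return GradientSet(loadings=rng.normal(size=(n, k)), eigenvalues=lam)


def test_procrustes_identity(rng):
    g = _random_gradient(rng)
    out = procrustes_align(g, g)
    assert np.allclose(out.loadings, g.loadings, atol=1e-12)


def test_procrustes_recovers_flip_and_swap(rng):
    ref = _random_gradient(rng)
    perm = np.array([1, 0, 3, 2, 4])
    signs = np.array([1, -1, 1, -1, 1.0])
    g = GradientSet(loadings=ref.loadings[:, perm] * signs[perm],
                    eigenvalues=ref.eigenvalues)
    out = procrustes_align(g, ref)
    assert np.allclose(out.loadings, ref.loadings, atol=1e-8)


def test_procrustes_recovers_random_rotation(rng):
    from scipy.stats import ortho_group
    ref = _random_gradient(rng)
    q = ortho_group.rvs(5, random_state=7)
    g = GradientSet(loadings=ref.loadings @ q, eigenvalues=ref.eigenvalues)
    out = procrustes_align(g, ref)
    assert np.linalg.norm(out.loadings - ref.loadings) < 1e-8
    with pytest.raises(ValueError):
        procrustes_align(_random_gradient(rng, n=40, k=3), ref)


# ----------------------------------------------------------- reference build

def test_reference_of_identical_inputs_is_that_input(rng):
    g = _random_gradient(rng)
    ref = build_reference([g, g, g])
    assert np.allclose(ref.loadings, g.loadings, atol=1e-10)


def test_reference_recovers_template_subspace(rng):
    from scipy.linalg import subspace_angles
    from scipy.stats import ortho_group
    template = _random_gradient(rng, n=50, k=4)
    inputs = [GradientSet(loadings=template.loadings @ ortho_group.rvs(4, random_state=i),
                          eigenvalues=template.eigenvalues) for i in range(6)]
    ref = build_reference(inputs, n_iter=20)
    angles = subspace_angles(ref.loadings, template.loadings)
    assert np.max(angles) < 1e-6


def test_reference_converges_quickly(rng):
    """On cohort-like inputs (rotated copies of one template plus noise) the
    iterative mean template settles within 10 iterations."""
    from scipy.stats import ortho_group
    template = _random_gradient(rng, n=30, k=4)
    inputs = [GradientSet(
        loadings=(template.loadings + 0.05 * rng.normal(size=(30, 4)))
        @ ortho_group.rvs(4, random_state=i),
        eigenvalues=template.eigenvalues) for i in range(6)]
    a = build_reference(inputs, n_iter=10)
    b = build_reference(inputs, n_iter=30)
    assert np.linalg.norm(a.loadings - b.loadings) < 1e-5
    with pytest.raises(ValueError):
        build_reference(inputs[:1])


# ----------------------------------------------------------- network summary

def test_network_summary_constant_and_toy(parc70):
    g = GradientSet(loadings=np.ones((70, 2)), eigenvalues=np.array([0.5, 0.4]))
    s = network_summary(g, parc70, 0)
    assert np.allclose([s[n] for n in NETWORKS], 1.0)
    assert s["range"] == 0.0
    v = np.zeros(70)
    v[parc70.nodes_of("DMN")] = 1.0
    g2 = GradientSet(loadings=v[:, None], eigenvalues=np.array([0.5]))
    s2 = network_summary(g2, parc70, 0)
    assert s2["DMN"] == pytest.approx(1.0)
    assert s2["VIS"] == pytest.approx(0.0)
    assert s2["range"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        network_summary(g2, parc70, 3)


def test_planted_hierarchy_orders_network_means(parc350, truth350):
    """The exact model covariance yields network means monotone in the
    unimodal->transmodal hierarchy on the principal component."""
    from gradcap.synth import model_covariance
    cov = model_covariance(parc350, truth350)
    d = np.sqrt(np.diag(cov))
    g = gradients_from_connectivity(
        ConnectivityMatrix(values=cov / np.outer(d, d), n_frames_used=0))
    v = g.loadings[:, 0]
    if np.corrcoef(v, parc350.hierarchy_position)[0, 1] < 0:
        v = -v
    means = [v[parc350.nodes_of(n)].mean() for n in NETWORKS]
    assert np.all(np.diff(means) > 0)
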
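"""Inferential statistics: paired t, Bonferroni, Spearman + CI, ANCOVA,
Monte-Carlo cluster-extent thresholding, node contrast maps, coupling."""
import numpy as np
import pytest
from scipy import stats as sps

from gradcap import make_parcellation
from gradcap.stats import (
    ClusterThreshold,
    ancova_condition_effect,
    bonferroni,
    cluster_extent_threshold,
    gradient_occurrence_coupling,
    network_contrast_table,
    node_contrast_map,
    paired_t_test,
    spearman_with_ci,
)


# ----------------------------------------------------------------- oracles

def oracle_paired_t(x, y):
    """Textbook formula t = mean(d) / (sd(d)/sqrt(n)), two-tailed p."""
    d = np.asarray(x, float) - np.asarray(y, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return t, p


def oracle_spearman(x, y):
    """Rank (average ties) then Pearson; exact t-based two-tailed p."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    n = len(rx)
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return rho, p


def oracle_rm_ancova_f(dep, condition, subject, fd):
    """Condition F by explicit projection matrices (type-II SS)."""
    import pandas as pd
    df = pd.DataFrame({"dep": dep, "c": condition, "s": subject, "fd": fd})
    subs = sorted(df["s"].unique())
    conds = sorted(df["c"].unique())
    n = len(df)

    def design(with_condition):
        cols = [np.ones(n)]
        for s in subs[1:]:
            cols.append((df["s"] == s).astype(float).to_numpy())
        if with_condition:
            for c in conds[1:]:
                cols.append((df["c"] == c).astype(float).to_numpy())
        cols.append(df["fd"].to_numpy())
        return np.column_stack(cols)

    y = df["dep"].to_numpy()

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return r @ r, x.shape[1]

    rss_full, p_full = rss(design(True))
    rss_red, _ = rss(design(False))
    df_num = len(conds) - 1
    df_den = n - p_full
    f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    p = sps.f.sf(f, df_num, df_den)
    return f, p


# ---------------------------------------------------------------- paired t

def test_paired_t_identical_pairs_degenerate():
    res = paired_t_test(np.arange(5.0), np.arange(5.0))
    assert res.statistic == 0.0 and res.p_raw == 1.0
    with pytest.raises(ValueError):
        paired_t_test(np.arange(5.0) + 1.0, np.arange(5.0))  # zero-var, mean != 0


def test_paired_t_df_is_n_minus_1(rng):
    res = paired_t_test(rng.normal(size=16), rng.normal(size=16))
    assert res.df == 15


def test_paired_t_matches_closed_form():
    x = np.array([4.1, 3.9, 5.2, 4.8, 4.4, 5.0, 3.6, 4.9])
    y = np.array([3.8, 4.0, 4.6, 4.1, 4.5, 4.2, 3.1, 4.0])
    res = paired_t_test(x, y)
    t, p = oracle_paired_t(x, y)
    assert res.statistic == pytest.approx(t, abs=1e-12)
    assert res.p_raw == pytest.approx(p, abs=1e-12)


# --------------------------------------------------------------- bonferroni

def test_bonferroni_arithmetic():
    adj, sig = bonferroni(np.array([0.02]))
    assert adj[0] == pytest.approx(0.02) and sig[0]
    adj, _ = bonferroni(np.array([0.02] * 7))
    assert adj[0] == pytest.approx(0.14)
    adj, _ = bonferroni(np.array([0.3] * 8))
    assert adj[0] == 1.0
    with pytest.raises(ValueError):
        bonferroni(np.array([]))


# ----------------------------------------------------------------- spearman

def test_spearman_monotone_extremes(rng):
    x = rng.normal(size=12)
    res = spearman_with_ci(x, np.exp(x))
    assert res.statistic == pytest.approx(1.0)
    res2 = spearman_with_ci(x, -x**3)
    assert res2.statistic == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        spearman_with_ci(np.ones(8), rng.normal(size=8))


def test_spearman_matches_rank_oracle_with_fisher_ci(rng):
    x = rng.normal(size=26)
    y = 0.5 * x + rng.normal(size=26)
    y[3] = y[5]  # introduce a tie
    res = spearman_with_ci(x, y)
    rho, p = oracle_spearman(x, y)
    assert res.statistic == pytest.approx(rho, abs=1e-12)
    assert res.p_raw == pytest.approx(p, abs=1e-10)
    z = np.arctanh(rho)
    half = sps.norm.ppf(0.975) / np.sqrt(26 - 3)
    assert res.ci_95[0] == pytest.approx(np.tanh(z - half), abs=1e-12)
    assert res.ci_95[1] == pytest.approx(np.tanh(z + half), abs=1e-12)


# ------------------------------------------------------------------- ancova

def _paired_layout(rng, n_sub=12):
    subject = np.repeat([f"s{i}" for i in range(n_sub)], 2)
    condition = np.tile(["baseline", "drug"], n_sub)
    return subject, condition


def test_ancova_constant_fd_reduces_to_paired_t(rng):
    subject, condition = _paired_layout(rng)
    dep = rng.normal(size=24) + (condition == "drug") * 0.8
    with pytest.warns(RuntimeWarning):
        res = ancova_condition_effect(dep, condition, subject,
                                      np.full(24, 0.11))
    x = dep[condition == "drug"]
    y = dep[condition == "baseline"]
    t = paired_t_test(x, y).statistic
    assert res.statistic == pytest.approx(t**2, abs=1e-8)


def test_ancova_matches_projection_oracle(rng):
    subject, condition = _paired_layout(rng)
    fd = rng.uniform(0.05, 0.3, size=24)
    dep = rng.normal(size=24) + 0.5 * fd + (condition == "drug") * 0.4
    res = ancova_condition_effect(dep, condition, subject, fd)
    f, p = oracle_rm_ancova_f(dep, condition, subject, fd)
    assert res.statistic == pytest.approx(f, abs=1e-8)
    assert res.p_raw == pytest.approx(p, abs=1e-10)


def test_ancova_null_calibration_when_fd_drives_dep(rng):
    """If the dependent variable is pure FD plus noise (no condition
    effect), the condition test stays calibrated."""
    rejections = 0
    pvals = []
    for rep in range(60):
        subject, condition = _paired_layout(rng)
        fd = rng.uniform(0.05, 0.4, size=24)
        dep = 2.0 * fd + rng.normal(scale=0.3, size=24)
        res = ancova_condition_effect(dep, condition, subject, fd)
        pvals.append(res.p_raw)
        rejections += res.p_raw < 0.05
    assert rejections / 60 <= 0.15
    assert np.median(pvals) > 0.2


def test_ancova_rejects_duplicate_cells(rng):
    with pytest.raises(ValueError):
        ancova_condition_effect(np.zeros(4), ["a", "a", "b", "b"],
                                ["s0", "s0", "s0", "s0"], np.zeros(4))


# ------------------------------------------------- cluster-extent threshold

def test_cluster_threshold_independent_voxels_limit():
    thr = cluster_extent_threshold((12, 12, 12), smoothness_fwhm=0.0,
                                   voxel_p=1e-5, n_iterations=1000, seed=0)
    assert thr.min_cluster_size == 1


def test_cluster_threshold_monotone_in_voxel_p_and_smoothness():
    sizes = [cluster_extent_threshold((14, 14, 14), smoothness_fwhm=1.5,
                                      voxel_p=p, n_iterations=1000, seed=3
                                      ).min_cluster_size
             for p in (0.05, 0.01, 0.001)]
    assert sizes[0] >= sizes[1] >= sizes[2]
    small = cluster_extent_threshold((20, 20, 20), smoothness_fwhm=1.5,
                                     voxel_p=0.01, n_iterations=1000, seed=5)
    big = cluster_extent_threshold((20, 20, 20), smoothness_fwhm=3.0,
                                   voxel_p=0.01, n_iterations=1000, seed=5)
    assert big.min_cluster_size > small.min_cluster_size


def test_cluster_threshold_validation():
    with pytest.raises(ValueError):
        cluster_extent_threshold((10, 10, 10), smoothness_fwhm=0.5,
                                 n_iterations=1000)
    with pytest.raises(ValueError):
        cluster_extent_threshold((10, 10, 10), n_iterations=10)
    with pytest.raises(ValueError):
        ClusterThreshold(voxel_p=0.01, fwe_p=0.05, min_cluster_size=0,
                         n_iterations=1000, smoothness_fwhm=1.0)


# -------------------------------------------------------- node contrast map

def test_node_contrast_finds_planted_network_cluster(rng):
    parc = make_parcellation(350, seed=0)
    n_sub = 16
    base = rng.normal(size=(n_sub, 350)) * 0.05
    drug = base.copy()
    drug[:, parc.nodes_of("FPN")] -= 0.2  # planted decrease in FPN only
    thr = ClusterThreshold(voxel_p=0.01, fwe_p=0.05, min_cluster_size=4,
                           n_iterations=1000, smoothness_fwhm=1.5)
    tmap, clusters = node_contrast_map(drug, base, parc, thr)
    assert any(c.sign == -1 and "FPN" in c.networks for c in clusters)
    # opposite-extreme network carries no planted effect -> no VIS cluster
    assert not any("VIS" in c.networks for c in clusters)
    with pytest.raises(ValueError):
        node_contrast_map(drug[:8], base, parc, thr)


def test_node_contrast_null_rarely_survives(rng):
    parc = make_parcellation(350, seed=0)
    thr = ClusterThreshold(voxel_p=0.01, fwe_p=0.05, min_cluster_size=6,
                           n_iterations=1000, smoothness_fwhm=1.5)
    survivors = 0
    for rep in range(20):
        a = rng.normal(size=(16, 350))
        b = rng.normal(size=(16, 350))
        _, clusters = node_contrast_map(a, b, parc, thr)
        survivors += bool(clusters)
    assert survivors <= 3


# ----------------------------------------------------------------- coupling

def test_coupling_identity_and_mismatch(rng):
    g = rng.normal(size=20)
    res = gradient_occurrence_coupling(g, g.copy())
    assert res.statistic == pytest.approx(1.0)
    with pytest.raises(ValueError):
        gradient_occurrence_coupling(g, g[:10])


def test_network_contrast_table_bonferroni_family(rng):
    import pandas as pd
    rows = []
    for i in range(10):
        for cond in ("baseline", "drug"):
            rows.append({"subject": f"s{i}", "condition": cond,
                         "m1": rng.normal() + (cond == "drug"),
                         "m2": rng.normal()})
    table = network_contrast_table(pd.DataFrame(rows), ["m1", "m2"])
    assert set(table["measure"]) == {"m1", "m2"}
    assert np.allclose(table["p_bonf"],
                       np.minimum(1.0, table["p_raw"] * 2))
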
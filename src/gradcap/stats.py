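"""Inferential statistics for paired two-condition designs.

Paired two-tailed t-tests with Bonferroni correction, Spearman correlations
with Fisher-z confidence intervals, repeated-measures ANCOVA with a motion
covariate, Monte-Carlo cluster-extent thresholding on the node lattice, and
node-level contrast maps with family-wise-error control.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .datatypes import Parcellation, StatResult


def paired_t_test(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Two-tailed paired t-test of ``x`` vs ``y`` (df = n - 1)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("paired samples must match and have n >= 3")
    d = x - y
    if np.std(d, ddof=1) < 1e-300:
        # identical pairs are a well-defined degenerate case (t = 0);
        # zero-variance with a nonzero mean difference is not
        if np.allclose(d, 0.0):
            return StatResult(statistic=0.0, df=int(x.size - 1), p_raw=1.0,
                              method="paired_t_two_tailed")
        raise ValueError("zero-variance differences; t undefined")
    t, p = sps.ttest_rel(x, y)
    return StatResult(statistic=float(t), df=int(x.size - 1), p_raw=float(p),
                      method="paired_t_two_tailed")


def bonferroni(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni adjustment: p_adj = min(1, m * p); flags at ``alpha``."""
    p = np.atleast_1d(np.asarray(p_values, float))
    if p.size < 1:
        raise ValueError("need at least one p value")
    adj = np.minimum(1.0, p * p.size)
    return adj, adj < alpha


def spearman_with_ci(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Spearman rho with two-tailed p and a 95% CI via Fisher z.

    Average ranks handle ties; the CI uses SE = 1/sqrt(n - 3) on the
    z-transformed rho.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need matched samples with n >= 5")
    if np.std(x) < 1e-300 or np.std(y) < 1e-300:
        raise ValueError("constant input; Spearman undefined")
    rho, p = sps.spearmanr(x, y)
    n = x.size
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    half = sps.norm.ppf(0.975) / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return StatResult(statistic=float(rho), df=int(n - 2), p_raw=float(p),
                      method="spearman_fisher_ci", ci_95=ci)


def ancova_condition_effect(
    dep: np.ndarray, condition: np.ndarray, subject: np.ndarray,
    fd: np.ndarray,
) -> StatResult:
    """Repeated-measures ANCOVA: condition effect adjusting for mean FD.

    Model: ``dep ~ C(subject) + C(condition) + fd`` with subject as a
    blocking factor; reports the condition F and p.  A (near-)constant FD
    covariate is dropped with a warning, in which case F equals the paired-t
    statistic squared.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({
        "dep": np.asarray(dep, float),
        "condition": np.asarray(condition),
        "subject": np.asarray(subject),
        "fd": np.asarray(fd, float),
    })
    if df.groupby(["subject", "condition"]).size().max() > 1:
        raise ValueError("one observation per subject x condition required")
    formula = "dep ~ C(subject) + C(condition) + fd"
    # FD collinear with the rest of the design (e.g. constant) adds nothing
    resid = df["fd"] - df["fd"].mean()
    if np.std(resid) < 1e-10:
        warnings.warn("FD covariate is constant; dropped from ANCOVA",
                      RuntimeWarning, stacklevel=2)
        formula = "dep ~ C(subject) + C(condition)"
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=2)
    row = table.loc["C(condition)"]
    return StatResult(
        statistic=float(row["F"]),
        df=(int(row["df"]), int(table.loc["Residual", "df"])),
        p_raw=float(row["PR(>F)"]),
        method="rm_ancova_fd",
        extras={"fd_in_model": "fd" in formula},
    )


def cluster_extent_threshold(
    lattice_shape: tuple[int, int, int],
    smoothness_fwhm: float = 1.5,
    voxel_p: float = 0.01,
    fwe_p: float = 0.05,
    n_iterations: int = 1000,
    seed: int = 0,
) -> "ClusterThreshold":
    """Monte-Carlo minimum cluster size controlling family-wise error.

    Gaussian noise fields on the lattice are smoothed to
    ``smoothness_fwhm`` (voxel units), standardized, thresholded two-tailed
    at ``voxel_p``; the max 26-connected suprathreshold cluster size is
    recorded per iteration and the threshold is the ceiling of the
    ``1 - fwe_p`` quantile (at least 1).
    """
    if n_iterations < 1000:
        raise ValueError("n_iterations must be >= 1000")
    if 0.0 < smoothness_fwhm < 1.0:
        raise ValueError("smoothness_fwhm below voxel size; use 0 for none")
    rng = np.random.default_rng(seed)
    zthr = sps.norm.isf(voxel_p / 2.0)
    sigma = smoothness_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    maxes = np.zeros(n_iterations, dtype=int)
    for i in range(n_iterations):
        field = rng.standard_normal(lattice_shape)
        if smoothness_fwhm > 0:
            field = ndimage.gaussian_filter(field, sigma)
            field = (field - field.mean()) / field.std()
        above = np.abs(field) > zthr
        if above.any():
            labels, n_lab = ndimage.label(above, structure=structure)
            if n_lab:
                maxes[i] = int(np.bincount(labels.ravel())[1:].max())
    q = float(np.quantile(maxes, 1.0 - fwe_p))
    return ClusterThreshold(
        voxel_p=voxel_p, fwe_p=fwe_p,
        min_cluster_size=max(1, int(np.ceil(q))),
        n_iterations=n_iterations, smoothness_fwhm=smoothness_fwhm,
    )


@dataclass
class ClusterThreshold:
    """Result of the Monte-Carlo cluster-extent simulation."""

    voxel_p: float
    fwe_p: float
    min_cluster_size: int
    n_iterations: int
    smoothness_fwhm: float

    def __post_init__(self) -> None:
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class NodeCluster:
    """A surviving cluster of the node-level contrast map."""

    sign: int
    size: int
    node_ids: list[int]
    networks: list[str]
    peak_t: float


def node_contrast_map(
    loadings_a: np.ndarray, loadings_b: np.ndarray, parc: Parcellation,
    threshold: ClusterThreshold,
) -> tuple[np.ndarray, list[NodeCluster]]:
    """Per-node paired contrast with cluster-extent FWE correction.

    ``loadings_a``/``loadings_b`` are subject x node matrices of aligned
    gradient values for the two conditions.  Returns the node t-map and the
    clusters (26-connected on the parcellation lattice, same-sign members)
    at least ``threshold.min_cluster_size`` large.
    """
    a = np.asarray(loadings_a, float)
    b = np.asarray(loadings_b, float)
    if a.shape != b.shape:
        raise ValueError("both conditions required for every subject")
    n_sub, n_nodes = a.shape
    d = a - b
    sd = d.std(axis=0, ddof=1)
    sd[sd < 1e-300] = np.nan
    tmap = d.mean(axis=0) / (sd / np.sqrt(n_sub))
    tcrit = sps.t.isf(threshold.voxel_p / 2.0, df=n_sub - 1)

    shape = parc.lattice_shape
    vol = np.zeros(shape)
    idx = tuple(parc.lattice_xyz.T)
    vol[idx] = tmap
    inside = np.zeros(shape, dtype=bool)
    inside[idx] = True
    structure = np.ones((3, 3, 3), dtype=bool)

    clusters: list[NodeCluster] = []
    node_of_voxel = -np.ones(shape, dtype=int)
    node_of_voxel[idx] = parc.node_id
    for sign in (+1, -1):
        above = inside & (sign * vol > tcrit)
        labels, n_lab = ndimage.label(above, structure=structure)
        for lab in range(1, n_lab + 1):
            members = node_of_voxel[labels == lab]
            members = members[members >= 0]
            if members.size >= threshold.min_cluster_size:
                nets = sorted({str(parc.network[i]) for i in members})
                peak = tmap[members][np.argmax(np.abs(tmap[members]))]
                clusters.append(NodeCluster(
                    sign=sign, size=int(members.size),
                    node_ids=sorted(int(i) for i in members),
                    networks=nets, peak_t=float(peak)))
    return tmap, clusters


def gradient_occurrence_coupling(
    gradient_means: np.ndarray, rates: np.ndarray,
) -> StatResult:
    """Spearman coupling of a network's gradient mean with its CAP rate
    across matched subject x condition records."""
    g = np.asarray(gradient_means, float)
    r = np.asarray(rates, float)
    if g.shape != r.shape:
        raise ValueError("mismatched subject x condition records")
    return spearman_with_ci(g, r)


def network_contrast_table(
    table: pd.DataFrame, value_cols: list[str], alpha: float = 0.05,
    condition_col: str = "condition", subject_col: str = "subject",
    conditions: tuple[str, str] = ("drug", "baseline"),
) -> pd.DataFrame:
    """Paired contrasts (first condition minus second) for several measures.

    ``table`` is long by subject x condition; one paired t per column in
    ``value_cols``, Bonferroni-corrected over the family of columns.
    """
    wide = table.pivot(index=subject_col, columns=condition_col,
                       values=value_cols)
    rows = []
    for col in value_cols:
        x = wide[(col, conditions[0])].to_numpy(float)
        y = wide[(col, conditions[1])].to_numpy(float)
        res = paired_t_test(x, y)
        rows.append({"measure": col, "t": res.statistic, "df": res.df,
                     "p_raw": res.p_raw, "mean_diff": float(np.mean(x - y))})
    out = pd.DataFrame(rows)
    out["p_bonf"], out["significant"] = bonferroni(out["p_raw"].to_numpy(), alpha)
    return out
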
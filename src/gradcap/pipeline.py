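"""End-to-end orchestration: simulate -> preprocess -> gradients -> CAPs ->
statistics, with TSV/JSON artifacts and a Markdown report.

Every output table carries the configuration hash; re-running with the same
master seed reproduces all numbers exactly.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .caps import centroids_from_truth, derive_centroids, label_frames, \
    match_centroid_labels, stack_frames
from .config import StudyConfig
from .datatypes import CAP_NAMES, NETWORKS, ConnectivityMatrix, GradientSet
from .gradients import build_reference, gradients_from_connectivity, \
    gradients_from_run, network_summary, procrustes_align
from .preprocess import preprocess_run
from .stats import (
    ancova_condition_effect,
    bonferroni,
    cluster_extent_threshold,
    gradient_occurrence_coupling,
    network_contrast_table,
    node_contrast_map,
    spearman_with_ci,
)
from .synth import Cohort, model_covariance, simulate_cohort


@dataclass
class StudyResult:
    """All tables and statistics produced by one pipeline run."""

    gradient_table: pd.DataFrame      # subject, condition, VIS..DMN, range, mean_fd
    occurrence_table: pd.DataFrame    # subject, condition, 8 CAP columns
    network_contrasts: pd.DataFrame
    cap_contrasts: pd.DataFrame
    coupling: dict                    # network -> StatResult
    behavior_gradients: pd.DataFrame
    behavior_caps: pd.DataFrame
    ancova: pd.DataFrame
    node_tmap: np.ndarray
    clusters: list
    cluster_threshold: object
    provenance: dict
    reference: Optional[GradientSet] = None

    def significant_networks(self) -> list[str]:
        t = self.network_contrasts
        return t.loc[t["significant"], "measure"].tolist()

    def significant_caps(self) -> list[str]:
        t = self.cap_contrasts
        return t.loc[t["significant"], "measure"].tolist()


def analyze_cohort(
    cohort: Cohort, cfg: StudyConfig, *, compute_clusters: bool = True,
) -> StudyResult:
    """Run preprocessing, gradient, CAP and statistical stages on a cohort."""
    parc = cohort.parcellation
    conditions = cohort.conditions
    subjects = cohort.subjects

    # ---- preprocessing -------------------------------------------------
    processed: dict = {}
    mean_fd: dict = {}
    for key, run in cohort.runs.items():
        clean, fd = preprocess_run(run, cohort.motion[key], cfg.preprocess)
        processed[key] = clean
        mean_fd[key] = float(fd.mean())

    # ---- gradients -----------------------------------------------------
    raw_gradients = {k: gradients_from_run(r, cfg.gradient)
                     for k, r in processed.items()}
    if cfg.gradient.reference_source == "model_template":
        cov = model_covariance(
            parc, cohort.truth, condition=conditions[0],
            cap_amp=cfg.cohort.cap_amp, latent_amp=cfg.cohort.latent_amp,
            global_amp=cfg.cohort.global_amp, noise_sd=cfg.cohort.noise_sd)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        reference = gradients_from_connectivity(
            ConnectivityMatrix(values=corr, n_frames_used=0), cfg.gradient)
        if np.corrcoef(reference.loadings[:, 0],
                       parc.hierarchy_position)[0, 1] < 0:
            reference.loadings[:] = -reference.loadings
        reference.aligned_to = "model_template"
    else:
        baseline_sets = [raw_gradients[(s, conditions[0])] for s in subjects]
        reference = build_reference(baseline_sets,
                                    orient_to=parc.hierarchy_position)
    aligned = {k: procrustes_align(g, reference) for k, g in raw_gradients.items()}

    grad_rows = []
    for (sub, cond), g in sorted(aligned.items()):
        summary = network_summary(g, parc, component=0)
        grad_rows.append({"subject": sub, "condition": cond,
                          **{n: summary[n] for n in NETWORKS},
                          "range": summary["range"],
                          "mean_fd": mean_fd[(sub, cond)]})
    gradient_table = pd.DataFrame(grad_rows)

    # ---- CAPs ----------------------------------------------------------
    if cfg.cap.centroids_source == "ground_truth":
        centroids = centroids_from_truth(cohort.truth.state_topographies)
    else:
        frames = stack_frames([processed[(s, conditions[0])] for s in subjects])
        if frames.shape[0] > cfg.cap.max_kmeans_frames:
            step = frames.shape[0] / cfg.cap.max_kmeans_frames
            frames = frames[(np.arange(cfg.cap.max_kmeans_frames) * step).astype(int)]
        centroids = derive_centroids(frames, k=cfg.cap.k, seed=cfg.seed,
                                     n_init=cfg.cap.n_init)
        centroids = match_centroid_labels(
            centroids, cohort.truth.state_topographies)

    occ_rows = []
    for (sub, cond), run in sorted(processed.items()):
        lab = label_frames(run, centroids)
        occ_rows.append({"subject": sub, "condition": cond,
                         **{name: rate for name, rate
                            in zip(lab.names, lab.occurrence_rates)}})
    occurrence_table = pd.DataFrame(occ_rows)

    # ---- statistics ----------------------------------------------------
    network_contrasts = network_contrast_table(
        gradient_table, list(NETWORKS), alpha=cfg.stats.alpha,
        conditions=(conditions[1], conditions[0]))
    cap_contrasts = network_contrast_table(
        occurrence_table.merge(gradient_table[["subject", "condition"]],
                               on=["subject", "condition"]),
        list(CAP_NAMES), alpha=cfg.stats.alpha,
        conditions=(conditions[1], conditions[0]))
    range_contrast = network_contrast_table(
        gradient_table, ["range"], alpha=cfg.stats.alpha,
        conditions=(conditions[1], conditions[0]))

    coupling = {}
    for net in ("FPN", "SMN"):
        merged = gradient_table.merge(occurrence_table, on=["subject", "condition"])
        coupling[net] = gradient_occurrence_coupling(
            merged[net].to_numpy(), merged[f"{net}+"].to_numpy())

    # brain-behavior correlations across subject x condition records;
    # needs enough questionnaire records (Spearman is undefined below n=5)
    asc = cohort.asc.table[["subject", "condition", "total"]]
    gb = gradient_table.merge(asc, on=["subject", "condition"])
    rows = []
    for net in (NETWORKS if len(gb) >= 5 else ()):
        res = spearman_with_ci(gb[net].to_numpy(), gb["total"].to_numpy())
        rows.append({"measure": net, "rho": res.statistic, "p_raw": res.p_raw,
                     "ci_low": res.ci_95[0], "ci_high": res.ci_95[1],
                     "n": len(gb)})
    behavior_gradients = pd.DataFrame(
        rows, columns=["measure", "rho", "p_raw", "ci_low", "ci_high", "n"])
    if len(behavior_gradients):
        behavior_gradients["p_bonf"], behavior_gradients["significant"] = \
            bonferroni(behavior_gradients["p_raw"].to_numpy(), cfg.stats.alpha)

    ob = occurrence_table.merge(asc, on=["subject", "condition"])
    rows = []
    for cap in (("FPN+", "SMN+", "GN+") if len(ob) >= 5 else ()):
        res = spearman_with_ci(ob[cap].to_numpy(), ob["total"].to_numpy())
        rows.append({"measure": cap, "rho": res.statistic, "p_raw": res.p_raw,
                     "ci_low": res.ci_95[0], "ci_high": res.ci_95[1],
                     "n": len(ob)})
    behavior_caps = pd.DataFrame(
        rows, columns=["measure", "rho", "p_raw", "ci_low", "ci_high", "n"])
    if len(behavior_caps):
        behavior_caps["p_bonf"], behavior_caps["significant"] = bonferroni(
            behavior_caps["p_raw"].to_numpy(), cfg.stats.alpha)

    # ANCOVA with mean FD as covariate, per network and per contrasted CAP
    ancova_rows = []
    merged = gradient_table.merge(occurrence_table, on=["subject", "condition"])
    for measure in [*NETWORKS, *CAP_NAMES]:
        res = ancova_condition_effect(
            merged[measure].to_numpy(), merged["condition"].to_numpy(),
            merged["subject"].to_numpy(), merged["mean_fd"].to_numpy())
        ancova_rows.append({"measure": measure, "F": res.statistic,
                            "df": str(res.df), "p_raw": res.p_raw})
    ancova = pd.DataFrame(ancova_rows)

    # node-level contrast with cluster-extent FWE correction
    if compute_clusters:
        thr = cluster_extent_threshold(
            parc.lattice_shape,
            smoothness_fwhm=cfg.stats.cluster.smoothness_fwhm,
            voxel_p=cfg.stats.cluster.voxel_p,
            fwe_p=cfg.stats.cluster.fwe_p,
            n_iterations=cfg.stats.cluster.n_iterations,
            seed=cfg.seed)
        a = np.stack([aligned[(s, conditions[1])].loadings[:, 0] for s in subjects])
        b = np.stack([aligned[(s, conditions[0])].loadings[:, 0] for s in subjects])
        tmap, clusters = node_contrast_map(a, b, parc, thr)
    else:
        thr, tmap, clusters = None, np.zeros(parc.n_nodes), []

    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "software_version": __version__,
        "n_subjects": len(subjects),
        "conditions": list(conditions),
        "range_contrast": range_contrast.to_dict("records"),
        "centroid_source": cfg.cap.centroids_source,
        "timestamp_unix": None,  # filled on write for stable in-memory results
    }
    return StudyResult(
        gradient_table=gradient_table, occurrence_table=occurrence_table,
        network_contrasts=network_contrasts, cap_contrasts=cap_contrasts,
        coupling=coupling, behavior_gradients=behavior_gradients,
        behavior_caps=behavior_caps, ancova=ancova,
        node_tmap=tmap, clusters=clusters, cluster_threshold=thr,
        provenance=provenance, reference=reference)


def run_pipeline(cfg: StudyConfig, outdir: Optional[Path] = None,
                 *, compute_clusters: bool = True) -> StudyResult:
    """Simulate a cohort from the config and analyze it end-to-end."""
    cohort = simulate_cohort(
        n_subjects=cfg.cohort.n_subjects, effect_config=cfg.effects,
        seed=cfg.seed, cohort_config=cfg.cohort)
    result = analyze_cohort(cohort, cfg, compute_clusters=compute_clusters)
    if outdir is not None:
        write_result(Path(outdir), result, cfg)
    return result


def _render_report(result: StudyResult, cfg: StudyConfig) -> str:
    lines = [
        "# Study report",
        "",
        f"- config hash: `{result.provenance['config_hash']}`",
        f"- seed: {result.provenance['seed']}",
        f"- subjects: {result.provenance['n_subjects']}",
        "",
        "## Network gradient contrasts (drug - baseline)",
        result.network_contrasts.to_string(index=False),
        "",
        "## CAP occurrence contrasts (drug - baseline)",
        result.cap_contrasts.to_string(index=False),
        "",
        "## Gradient range contrast",
        pd.DataFrame(result.provenance["range_contrast"]).to_string(index=False),
        "",
        "## Gradient-occurrence coupling",
    ]
    for net, res in result.coupling.items():
        lines.append(f"- {net}: rho={res.statistic:.3f}, p={res.p_raw:.4g}, "
                     f"CI={res.ci_95}")
    lines += [
        "",
        "## Brain-behavior (questionnaire total vs gradient means)",
        result.behavior_gradients.to_string(index=False),
        "",
        "## Brain-behavior (questionnaire total vs CAP rates)",
        result.behavior_caps.to_string(index=False),
        "",
        "## ANCOVA (condition effect with FD covariate)",
        result.ancova.to_string(index=False),
        "",
        f"## Surviving clusters (min size "
        f"{getattr(result.cluster_threshold, 'min_cluster_size', 'n/a')})",
    ]
    for c in result.clusters:
        lines.append(f"- sign {c.sign:+d}, size {c.size}, networks "
                     f"{','.join(c.networks)}, peak t={c.peak_t:.2f}")
    lines.append("")
    return "\n".join(lines)


def write_result(outdir: Path, result: StudyResult, cfg: StudyConfig) -> None:
    """Write all tables (TSV), statistics (JSON), config and report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = result.provenance["config_hash"]
    for name, df in (
        ("gradient_table", result.gradient_table),
        ("occurrence_table", result.occurrence_table),
        ("network_contrasts", result.network_contrasts),
        ("cap_contrasts", result.cap_contrasts),
        ("behavior_gradients", result.behavior_gradients),
        ("behavior_caps", result.behavior_caps),
        ("ancova", result.ancova),
    ):
        df2 = df.copy()
        df2.insert(0, "config_hash", h)
        df2.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                   float_format="%.17g")
    stats_json = {
        "provenance": result.provenance,
        "coupling": {k: v.to_dict() for k, v in result.coupling.items()},
        "cluster_threshold": dataclasses.asdict(result.cluster_threshold)
        if result.cluster_threshold is not None else None,
        "clusters": [dataclasses.asdict(c) for c in result.clusters],
    }
    (outdir / "stats.json").write_text(json.dumps(stats_json, indent=1))
    cfg.to_yaml(outdir / "config.yaml")
    (outdir / "report.md").write_text(_render_report(result, cfg))
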
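"""Co-activation-pattern (CAP) dynamics.

Centroids are derived by k-means on frame-wise activation maps (frames
z-scored across nodes, so squared Euclidean distance is monotone in Pearson
correlation), named by optimal assignment against template topographies, and
then used to label every retained frame of a run by its best spatial
correlation.  Occurrence rates divide each CAP's frame count by the number
of retained (or, optionally, acquired) frames per scan.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .config import CapConfig
from .datatypes import CAP_NAMES, BoldRun, CapCentroids, CapLabeling


def _zscore_rows(m: np.ndarray) -> np.ndarray:
    m = m - m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    if np.any(sd < 1e-12):
        raise ValueError("cannot z-score a constant map")
    return m / sd


def stack_frames(runs: list[BoldRun]) -> np.ndarray:
    """Stack retained frames of several runs into a frame x node matrix."""
    return np.vstack([r.retained.T for r in runs])


def derive_centroids(
    frames: np.ndarray, k: int = 8, seed: int = 0, n_init: int = 10,
) -> CapCentroids:
    """k-means centroids of frame-wise activation maps.

    Frames are z-scored across nodes before clustering; centroids are
    z-scored on output.  Empty clusters are re-initialized internally by the
    solver.  Names are placeholders until :func:`match_centroid_labels`.
    """
    frames = np.asarray(frames, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if frames.shape[0] < 10 * k:
        raise ValueError(f"need at least {10 * k} frames for k={k}")
    x = _zscore_rows(frames)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(x)
    maps = _zscore_rows(km.cluster_centers_)
    names = tuple(f"cluster_{i}" for i in range(k))
    return CapCentroids(maps=maps, names=names, source="kmeans",
                        inertia=float(km.inertia_))


def match_centroid_labels(
    c: CapCentroids, templates: np.ndarray,
    template_names: tuple[str, ...] = CAP_NAMES,
) -> CapCentroids:
    """Name centroids by one-to-one optimal assignment to templates.

    The assignment maximizes total spatial correlation (Hungarian
    algorithm); the returned centroids are reordered to template order.
    """
    templates = _zscore_rows(np.asarray(templates, float))
    if templates.shape[0] != c.maps.shape[0]:
        raise ValueError("template count must match centroid count")
    maps = _zscore_rows(c.maps)
    n_nodes = maps.shape[1]
    corr = (maps @ templates.T) / n_nodes  # (centroid, template)
    rows, cols = linear_sum_assignment(-corr)
    order = np.empty(len(rows), dtype=int)
    order[cols] = rows  # centroid index serving template j
    return CapCentroids(
        maps=c.maps[order], names=tuple(template_names),
        source=c.source, inertia=c.inertia,
    )


def label_frames(run: BoldRun, c: CapCentroids) -> CapLabeling:
    """Assign each retained frame to its best-correlated centroid.

    Censored frames get label -1 and NaN correlation.  Exact ties go to the
    lowest centroid index with a warning.
    """
    if run.n_nodes != c.maps.shape[1]:
        raise ValueError("node count mismatch between run and centroids")
    n_nodes = run.n_nodes
    frames = _zscore_rows(run.retained.T)
    maps = _zscore_rows(c.maps)
    r = (frames @ maps.T) / n_nodes  # (retained_frames, k)
    best = np.argmax(r, axis=1)
    top = r[np.arange(r.shape[0]), best]
    ties = (np.isclose(r, top[:, None], rtol=0, atol=1e-12).sum(axis=1) > 1)
    if np.any(ties):
        warnings.warn(f"{int(ties.sum())} frames tied between centroids; "
                      "lowest index chosen", RuntimeWarning, stacklevel=2)
    labels = np.full(run.n_frames, -1, dtype=int)
    best_r = np.full(run.n_frames, np.nan)
    labels[run.censor_mask] = best
    best_r[run.censor_mask] = top
    rates = occurrence_rates(labels, k=c.maps.shape[0])
    return CapLabeling(labels=labels, best_r=best_r,
                       occurrence_rates=rates, names=c.names)


def occurrence_rates(
    labels: np.ndarray, k: int = 8, n_acquired: int | None = None,
    denominator: str = "retained",
) -> np.ndarray:
    """Fraction of frames assigned to each CAP.

    ``denominator="retained"`` divides by the number of labelled
    (non-censored) frames; ``"acquired"`` divides by ``n_acquired`` (the
    scan's full frame count), in which case rates sum to the retained
    fraction instead of 1.
    """
    labels = np.asarray(labels, int)
    retained = labels[labels >= 0]
    if retained.size == 0:
        raise ValueError("no retained frames to compute occurrence rates")
    counts = np.bincount(retained, minlength=k).astype(float)
    if denominator == "retained":
        denom = retained.size
    elif denominator == "acquired":
        if n_acquired is None:
            raise ValueError("acquired denominator requires n_acquired")
        denom = n_acquired
    else:
        raise ValueError(f"unknown denominator policy {denominator!r}")
    return counts / denom


def centroids_from_truth(topographies: np.ndarray,
                         names: tuple[str, ...] = CAP_NAMES) -> CapCentroids:
    """Wrap generator state topographies as supervised labelling centroids."""
    return CapCentroids(maps=_zscore_rows(np.asarray(topographies, float)),
                        names=names, source="ground_truth")
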
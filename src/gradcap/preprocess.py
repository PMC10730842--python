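"""Temporal preprocessing: frame drop, FD censoring, band-pass, nuisance
regression, standardization.

Censoring is mask-based (frames are flagged, never deleted) so indices stay
aligned with ground truth.  Band-passing removes out-of-band sine/cosine
components by least squares on the retained frames only — an exact
projection, so the composed chain drop -> censor -> band-pass -> regress ->
standardize is idempotent on retained values.  Nuisance regressors are
band-passed with the same projection before regression so the two
projections commute on the processed data.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .config import PreprocessConfig
from .datatypes import BoldRun, MotionTrace


def framewise_displacement(m: MotionTrace) -> np.ndarray:
    """Per-frame head-motion magnitude.

    FD[i] is the Euclidean norm of the six backward differences of the
    motion parameters at frame i; FD[0] = 0.
    """
    if m.n_frames < 2:
        raise ValueError("need at least 2 frames to compute FD")
    d = np.diff(m.params, axis=0)
    fd = np.zeros(m.n_frames)
    fd[1:] = np.linalg.norm(d, axis=1)
    return fd


def censor_frames(run: BoldRun, fd: np.ndarray, cfg: PreprocessConfig) -> BoldRun:
    """Flag initial frames and high-motion frames (plus their predecessors).

    A frame whose FD exceeds the threshold is censored together with the
    frame immediately preceding it; the first ``n_initial_drop`` frames are
    always censored.  The signal matrix is untouched.
    """
    fd = np.asarray(fd, float)
    if fd.shape != (run.n_frames,):
        raise ValueError("fd length must equal frame count")
    if cfg.fd_threshold_mm <= 0:
        raise ValueError("fd_threshold_mm must be > 0")
    mask = np.ones(run.n_frames, dtype=bool)
    mask[:cfg.n_initial_drop] = False
    bad = fd > cfg.fd_threshold_mm
    mask[bad] = False
    prev = np.flatnonzero(bad) - 1
    mask[prev[prev >= 0]] = False
    return dataclasses.replace(run, censor_mask=mask & run.censor_mask)


def _band_regressors(n_frames: int, dt: float, low: float, high: float,
                     retained: np.ndarray) -> np.ndarray:
    """Out-of-band Fourier regressors evaluated at the retained frame times.

    Frequencies are the DFT frequencies of the full (uncensored) grid; all
    sine/cosine pairs with f < low or f > high, plus the constant, form the
    stop-band design."""
    t = np.arange(n_frames) * dt
    freqs = np.fft.rfftfreq(n_frames, d=dt)
    cols = [np.ones(n_frames)]
    for f in freqs[1:]:
        if low <= f <= high:
            continue
        cols.append(np.cos(2 * np.pi * f * t))
        if not np.isclose(f, 0.5 / dt):  # sine at Nyquist is identically 0
            cols.append(np.sin(2 * np.pi * f * t))
    return np.column_stack(cols)[retained]


def bandpass_design(run: BoldRun, cfg: PreprocessConfig) -> np.ndarray:
    """The stop-band design matrix used by :func:`bandpass` (retained rows)."""
    cfg.validate(run.dt_seconds)
    return _band_regressors(run.n_frames, run.dt_seconds,
                            cfg.band_low_hz, cfg.band_high_hz, run.censor_mask)


def _project_out(data: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residualize ``data`` (rows = series, cols = frames) against ``design``."""
    beta, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    return data - (design @ beta).T


def bandpass(run: BoldRun, cfg: PreprocessConfig) -> BoldRun:
    """Band-pass the retained frames to [band_low, band_high] Hz.

    Implemented by projecting out out-of-band sine/cosine components (and
    the mean) over the retained frames; censored frames are zeroed in the
    output and must not be used downstream.
    """
    cfg.validate(run.dt_seconds)
    if run.n_retained < 32:
        raise ValueError("need at least 32 retained frames to band-pass")
    design = bandpass_design(run, cfg)
    out = np.zeros_like(run.signal)
    out[:, run.censor_mask] = _project_out(run.retained, design)
    return run.with_signal(out)


def build_nuisance_regressors(
    motion: MotionTrace, n_frames: int,
    tissue: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Standard nuisance design: intercept, linear/quadratic drift, six
    motion parameters and their temporal derivatives, and two surrogate
    tissue-mean series (stand-ins for white-matter and CSF signals).
    """
    t = np.linspace(-1.0, 1.0, n_frames)
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion.params, axis=0)])
    if tissue is None:
        tissue = np.random.default_rng(seed).standard_normal((n_frames, 2))
    return np.column_stack([
        np.ones(n_frames), t, t**2, motion.params, deriv, tissue,
    ])


def nuisance_regress(run: BoldRun, regressors: np.ndarray) -> BoldRun:
    """Regress the given frame x p design out of every node series.

    The fit uses retained frames only; residuals at censored frames are set
    to zero.  A rank-deficient design triggers a warning and a pseudoinverse
    solution (lstsq handles both).
    """
    regressors = np.asarray(regressors, float)
    if regressors.shape[0] != run.n_frames:
        raise ValueError("regressors must have one row per frame")
    design = regressors[run.censor_mask]
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("nuisance design is rank-deficient; using pseudoinverse",
                      RuntimeWarning, stacklevel=2)
    out = np.zeros_like(run.signal)
    out[:, run.censor_mask] = _project_out(run.retained, design)
    return run.with_signal(out)


def standardize(run: BoldRun) -> BoldRun:
    """Scale each node series to zero mean, unit (population) variance over
    the retained frames; censored frames are transformed with the same
    affine map so the matrix stays aligned."""
    x = run.retained
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population (1/N) convention
    bad = np.flatnonzero(sd.ravel() < 1e-12)
    if bad.size:
        raise ValueError(f"constant node series, cannot standardize: nodes {bad.tolist()}")
    out = (run.signal - mu) / sd
    out[:, ~run.censor_mask] = 0.0
    return run.with_signal(out)


def preprocess_run(
    run: BoldRun, motion: MotionTrace, cfg: PreprocessConfig | None = None,
    tissue: np.ndarray | None = None,
) -> tuple[BoldRun, np.ndarray]:
    """Full temporal chain; returns the processed run and the FD trace.

    Order: initial-frame drop + FD censoring -> band-pass -> nuisance
    regression (with band-passed regressors) -> standardization.
    """
    cfg = cfg or PreprocessConfig()
    fd = framewise_displacement(motion)
    run = censor_frames(run, fd, cfg)
    run = bandpass(run, cfg)
    reg = build_nuisance_regressors(motion, run.n_frames, tissue=tissue)
    # in-band dof left after projecting out stop-band and nuisance terms
    dof = run.n_retained - bandpass_design(run, cfg).shape[1] - reg.shape[1]
    if dof < 8:
        raise ValueError(
            f"only {max(dof, 0)} temporal degrees of freedom remain after "
            "band-passing and nuisance regression; the run is too short or "
            "too heavily censored for this band")
    # Band-pass the non-constant regressors with the same projection so the
    # regression cannot reintroduce out-of-band energy.
    design = bandpass_design(run, cfg)
    reg_r = reg[run.censor_mask]
    reg_f = reg_r - design @ np.linalg.lstsq(design, reg_r, rcond=None)[0]
    reg_full = np.zeros_like(reg)
    reg_full[run.censor_mask] = reg_f
    reg_full[:, 0] = 1.0  # keep an explicit intercept
    run = nuisance_regress(run, reg_full)
    run = standardize(run)
    return run, fd
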
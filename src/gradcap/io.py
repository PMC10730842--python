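"""Reading and writing pipeline artifacts.

All tables are TSV with a header row; float matrices use ``%.17g`` so a
round trip is bit-exact for doubles.  BOLD runs carry a JSON sidecar with
sampling interval, censor mask and labels.  Node maps can optionally be
painted onto the parcellation lattice and exported as NIfTI at 4 mm
isotropic resolution.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    CAP_NAMES, AscScores, BoldRun, GradientSet, MotionTrace, Parcellation,
)

_FLOAT_FMT = "%.17g"


def write_matrix_tsv(path, matrix: np.ndarray, columns: list[str]) -> None:
    matrix = np.asarray(matrix, float)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        np.savetxt(fh, matrix, fmt=_FLOAT_FMT, delimiter="\t")


def read_matrix_tsv(path, expected_prefix: str | None = None) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if expected_prefix is not None:
        bad = [c for c in header if not c.startswith(expected_prefix)]
        if bad:
            raise ValueError(f"malformed header: unexpected columns {bad}")
    return data, header


def write_bold_run(path_prefix, run: BoldRun) -> None:
    """Write ``<prefix>.tsv`` (nodes x frames) and ``<prefix>.json`` metadata."""
    prefix = Path(path_prefix)
    cols = [f"frame_{i:04d}" for i in range(run.n_frames)]
    write_matrix_tsv(prefix.with_suffix(".tsv"), run.signal, cols)
    meta = {
        "dt_seconds": run.dt_seconds,
        "subject_id": run.subject_id,
        "condition": run.condition,
        "censor_mask": [bool(v) for v in run.censor_mask],
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_bold_run(path_prefix) -> BoldRun:
    prefix = Path(path_prefix)
    signal, _ = read_matrix_tsv(prefix.with_suffix(".tsv"), "frame_")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return BoldRun(
        signal=signal, dt_seconds=float(meta["dt_seconds"]),
        censor_mask=np.array(meta["censor_mask"], dtype=bool),
        subject_id=meta["subject_id"], condition=meta["condition"],
    )


def write_motion(path, m: MotionTrace) -> None:
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    write_matrix_tsv(path, m.params, cols)


def read_motion(path) -> MotionTrace:
    data, header = read_matrix_tsv(path)
    if len(header) != 6:
        raise ValueError(f"motion table must have 6 columns, got {header}")
    return MotionTrace(params=data)


def write_parcellation(path, parc: Parcellation) -> None:
    parc.to_frame().to_csv(path, sep="\t", index=False,
                           float_format="%.17g")


def read_parcellation(path) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    required = {"node_id", "network", "hierarchy", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parcellation table missing columns {sorted(missing)}")
    return Parcellation.from_frame(df)


def write_gradients(path, g: GradientSet) -> None:
    cols = [f"gradient_{i + 1}" for i in range(g.n_components)]
    write_matrix_tsv(path, g.loadings, cols)


def write_asc(path, asc: AscScores) -> None:
    asc.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_asc(path, total_rule: str = "sum") -> AscScores:
    df = pd.read_csv(path, sep="\t")
    return AscScores(table=df, total_rule=total_rule)


def node_map_to_nifti(values: np.ndarray, parc: Parcellation,
                      voxel_mm: float = 4.0) -> nib.Nifti1Image:
    """Paint per-node values onto the integer lattice as a NIfTI volume."""
    values = np.asarray(values, float)
    vol = np.zeros(parc.lattice_shape, dtype=np.float64)
    vol[tuple(parc.lattice_xyz.T)] = values
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return nib.Nifti1Image(vol, affine)


def nifti_to_node_map(img: nib.Nifti1Image, parc: Parcellation) -> np.ndarray:
    vol = np.asarray(img.dataobj, dtype=np.float64)
    return vol[tuple(parc.lattice_xyz.T)]


# --- supplementary per-subject tables -------------------------------------

GRADIENT_COLUMNS = ["VIS", "SMN", "DAT", "VAT", "LIM", "FPN", "DMN"]


def import_supplementary_tables(
    path, mapping: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Normalize an external per-subject table to the internal schema.

    The documented schema is TSV with ``subject`` and ``condition`` columns
    plus either per-network gradient columns (VIS..DMN) and/or per-CAP
    occurrence-rate columns (DMN+..GN-).  ``mapping`` renames nonstandard
    columns before validation.  Returns the recognized sub-tables keyed by
    ``"gradients"`` / ``"occurrence"``.
    """
    df = pd.read_csv(path, sep="\t")
    if mapping:
        df = df.rename(columns=mapping)
    for col in ("subject", "condition"):
        if col not in df.columns:
            raise ValueError(
                f"unrecognized layout: missing column {col!r}; "
                f"columns present: {list(df.columns)}")
    out: dict[str, pd.DataFrame] = {}
    grad_cols = [c for c in GRADIENT_COLUMNS if c in df.columns]
    cap_cols = [c for c in CAP_NAMES if c in df.columns]
    if grad_cols:
        out["gradients"] = df[["subject", "condition", *grad_cols]].copy()
    if cap_cols:
        out["occurrence"] = df[["subject", "condition", *cap_cols]].copy()
    if not out:
        raise ValueError(
            "unrecognized layout: no network gradient or CAP rate columns; "
            f"columns present: {list(df.columns)}")
    return out
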
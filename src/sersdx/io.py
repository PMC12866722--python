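"""Delimited-text readers and writers for spectra cohorts.

Schema of the spectra matrix CSV (one row per spectrum):

    spectrum_id, sample_id, class, stage, <wn_0>, <wn_1>, ... <wn_C-1>

where the remaining headers are the wavenumber channel positions in
cm^-1. A ground-truth sidecar (``*_truth.csv``) carries the generator's
per-spectrum spike channels and jitter scale, and a ``*_plan.json``
carries cohort-level annotations (planted marker offsets, seed).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import META_COLUMNS, CohortDataset
from .grid import WavenumberGrid

__all__ = ["write_cohort", "read_spectra", "truth_path", "plan_path"]

log = logging.getLogger(__name__)

_ID_COLS = ["spectrum_id", "sample_id", "class", "stage"]


def _fmt_wavenumber(v: float) -> str:
    return format(v, ".10g")


def truth_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_truth.csv")


def plan_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_plan.json")


def write_cohort(dataset: CohortDataset, path: str | Path) -> Path:
    """Write ``dataset`` to the spectra-matrix CSV plus sidecars.

    Round-trips losslessly through :func:`read_spectra` (intensities at
    full float precision via ``repr``-grade formatting).
    """
    if dataset.n_spectra == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    header = _ID_COLS + [_fmt_wavenumber(v) for v in dataset.grid.values]
    mat = pd.DataFrame(dataset.intensities, columns=header[4:])
    ids = dataset.meta[META_COLUMNS].rename(columns={"class_label": "class"})
    out = pd.concat([ids.reset_index(drop=True), mat], axis=1)
    out.to_csv(path, index=False, float_format="%.17g")

    truth_cols = [c for c in ("spike_channels", "jitter")
                  if c in dataset.meta.columns]
    if truth_cols:
        truth = dataset.meta[META_COLUMNS + truth_cols].rename(
            columns={"class_label": "class"}).copy()
        if "spike_channels" in truth_cols:
            truth["spike_channels"] = truth["spike_channels"].map(
                lambda xs: ";".join(str(int(x)) for x in xs))
        truth.to_csv(truth_path(path), index=False)

    ann = {k: v for k, v in dataset.attrs.items() if k != "preprocessed"}
    with open(plan_path(path), "w") as fh:
        json.dump(ann, fh, indent=2, sort_keys=True, default=str)
    log.info("wrote %d spectra to %s", dataset.n_spectra, path)
    return path


def read_spectra(path: str | Path) -> CohortDataset:
    """Read a spectra-matrix CSV (plus sidecars when present).

    Raises ``ValueError`` with row context on duplicate spectrum IDs,
    ragged rows, or non-numeric intensities; a zero-data-row file yields
    an empty dataset with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={c: str for c in _ID_COLS})
    for col in ("spectrum_id", "sample_id", "class"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "stage" not in df.columns:
        df["stage"] = ""
    df["stage"] = df["stage"].fillna("")

    wn_cols = [c for c in df.columns if c not in _ID_COLS]
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric wavenumber header: {e}") from e
    grid = WavenumberGrid.from_values(wavenumbers) if wn_cols else None

    dup = df["spectrum_id"].duplicated()
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        bad = df.loc[dup, "spectrum_id"].iloc[0]
        raise ValueError(
            f"{path}: duplicate spectrum_id {bad!r} (lines {lines})")

    if len(df) == 0:
        warnings.warn(f"{path}: no data rows, returning empty dataset")
        intensities = np.empty((0, len(wn_cols)))
    else:
        block = df[wn_cols].apply(pd.to_numeric, errors="coerce")
        bad_rows = block.isna().any(axis=1)
        if bad_rows.any():
            lines = (df.index[bad_rows] + 2).tolist()  # header + 1-based
            raise ValueError(
                f"{path}: ragged or non-numeric intensities at lines {lines}")
        intensities = block.to_numpy(dtype=float)

    meta = df[_ID_COLS].rename(columns={"class": "class_label"})

    tpath = truth_path(path)
    if tpath.exists():
        truth = pd.read_csv(tpath, dtype={"spectrum_id": str,
                                          "spike_channels": str})
        truth = truth.set_index("spectrum_id")
        if "spike_channels" in truth.columns:
            sc = truth["spike_channels"].fillna("")
            meta = meta.copy()
            meta["spike_channels"] = [
                [int(x) for x in str(sc.get(sid, "")).split(";") if x != ""
                 and x != "nan"]
                for sid in meta["spectrum_id"]
            ]
        if "jitter" in truth.columns:
            meta["jitter"] = [float(truth["jitter"].get(sid, np.nan))
                              for sid in meta["spectrum_id"]]

    attrs: dict = {"preprocessed": False}
    ppath = plan_path(path)
    if ppath.exists():
        with open(ppath) as fh:
            attrs.update(json.load(fh))

    return CohortDataset(grid, intensities, meta, attrs=attrs)
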
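"""In-memory containers for SERS cohorts.

A cohort is stored column-oriented for speed: one intensity matrix
(rows = spectra) plus a pandas metadata frame aligned row-for-row.
``RamanSpectrum`` and ``SampleBundle`` are light views used by the
per-spectrum operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .grid import WavenumberGrid

__all__ = ["RamanSpectrum", "SampleBundle", "CohortDataset", "META_COLUMNS"]

#: required metadata columns, in canonical order
META_COLUMNS = ["spectrum_id", "sample_id", "class_label", "stage"]


@dataclass
class RamanSpectrum:
    """One intensity vector on a shared wavenumber grid."""

    grid: WavenumberGrid
    intensity: np.ndarray
    spectrum_id: str = ""
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.grid),):
            raise ValueError(
                f"intensity length {self.intensity.size} != grid length "
                f"{len(self.grid)} (spectrum {self.spectrum_id!r})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError(f"non-finite intensities in {self.spectrum_id!r}")

    def with_intensity(self, intensity: np.ndarray, **meta) -> "RamanSpectrum":
        merged = {**self.meta, **meta}
        return RamanSpectrum(self.grid, intensity, self.spectrum_id,
                             self.sample_id, merged)


@dataclass
class SampleBundle:
    """All spectra acquired from one serum sample, plus its label."""

    sample_id: str
    class_label: str
    stage: str
    spectra: list[RamanSpectrum]

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)


class CohortDataset:
    """Labeled collection of per-sample spectrum bundles.

    Parameters
    ----------
    grid : shared wavenumber axis.
    intensities : (n_spectra, n_channels) array.
    meta : DataFrame with columns ``spectrum_id, sample_id, class_label,
        stage`` (stage may be empty), one row per spectrum, plus optional
        extra columns (e.g. ground-truth ``spike_channels``).
    classes : class vocabulary; inferred from labels when omitted.
    attrs : free-form cohort-level annotations (e.g. planted effect sizes).
    """

    def __init__(self, grid: WavenumberGrid, intensities: np.ndarray,
                 meta: pd.DataFrame, classes: list[str] | None = None,
                 attrs: dict | None = None):
        intensities = np.asarray(intensities, dtype=float)
        if intensities.ndim != 2 or intensities.shape[1] != len(grid):
            raise ValueError("intensities must be (n_spectra, n_channels)")
        meta = meta.reset_index(drop=True).copy()
        if "stage" not in meta.columns:
            meta["stage"] = ""
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"meta missing columns {missing}")
        if len(meta) != intensities.shape[0]:
            raise ValueError("meta rows != intensity rows")
        dup = meta["spectrum_id"].duplicated()
        if dup.any():
            bad = meta.loc[dup, "spectrum_id"].iloc[0]
            raise ValueError(f"duplicate spectrum_id {bad!r}")
        self.grid = grid
        self.intensities = intensities
        self.meta = meta
        if classes is None:
            classes = sorted(meta["class_label"].unique().tolist())
        self.classes = list(classes)
        self.attrs = dict(attrs or {})

    # ------------------------------------------------------------------ sizes
    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.meta["sample_id"].nunique()

    def __len__(self) -> int:
        return self.n_spectra

    # ------------------------------------------------------------- accessors
    def sample_table(self) -> pd.DataFrame:
        """One row per sample: sample_id, class_label, stage, n_spectra."""
        g = self.meta.groupby("sample_id", sort=True)
        out = g.agg(class_label=("class_label", "first"),
                    stage=("stage", "first"),
                    n_spectra=("spectrum_id", "size")).reset_index()
        return out

    def spectrum(self, i: int) -> RamanSpectrum:
        row = self.meta.iloc[i]
        meta = {k: row[k] for k in self.meta.columns if k not in META_COLUMNS}
        return RamanSpectrum(self.grid, self.intensities[i],
                             str(row["spectrum_id"]), str(row["sample_id"]),
                             meta)

    def spectra(self) -> Iterator[RamanSpectrum]:
        for i in range(self.n_spectra):
            yield self.spectrum(i)

    def bundles(self) -> Iterator[SampleBundle]:
        for sid, idx in self.meta.groupby("sample_id", sort=True).groups.items():
            rows = self.meta.loc[idx]
            yield SampleBundle(
                sample_id=str(sid),
                class_label=str(rows["class_label"].iloc[0]),
                stage=str(rows["stage"].iloc[0]),
                spectra=[self.spectrum(i) for i in idx],
            )

    # ----------------------------------------------------------- operations
    def subset(self, mask: np.ndarray) -> "CohortDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return CohortDataset(self.grid, self.intensities[idx],
                             self.meta.iloc[idx], classes=self.classes,
                             attrs=self.attrs)

    def with_intensities(self, intensities: np.ndarray,
                         **attrs) -> "CohortDataset":
        merged = {**self.attrs, **attrs}
        return CohortDataset(self.grid, intensities, self.meta,
                             classes=self.classes, attrs=merged)

    def relabel(self, mapping: dict[str, str],
                classes: list[str] | None = None) -> "CohortDataset":
        meta = self.meta.copy()
        meta["class_label"] = meta["class_label"].map(
            lambda c: mapping.get(c, c))
        return CohortDataset(self.grid, self.intensities, meta,
                             classes=classes, attrs=self.attrs)

    def equals(self, other: "CohortDataset", atol: float = 0.0) -> bool:
        if len(self.grid) != len(other.grid):
            return False
        if not np.allclose(self.grid.values, other.grid.values, atol=1e-9):
            return False
        if self.intensities.shape != other.intensities.shape:
            return False
        if not np.allclose(self.intensities, other.intensities, atol=atol):
            return False
        a = self.meta[META_COLUMNS].astype(str).reset_index(drop=True)
        b = other.meta[META_COLUMNS].astype(str).reset_index(drop=True)
        return a.equals(b)
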
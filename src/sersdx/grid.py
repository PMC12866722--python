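"""Wavenumber (Raman shift) axis shared by all spectra in a cohort."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavenumberGrid", "default_grid"]


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, strictly increasing Raman-shift axis in cm^-1.

    The default axis (400-1800 cm^-1 at 1 cm^-1, 1401 channels) covers the
    diagnostic bands used throughout the package: the 643 cm^-1 internal
    reference and the 1080 / 1380 cm^-1 marker bands.
    """

    start: float = 400.0
    stop: float = 1800.0
    step: float = 1.0
    values: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.values is None:
            n = int(round((self.stop - self.start) / self.step)) + 1
            vals = self.start + self.step * np.arange(n, dtype=float)
            object.__setattr__(self, "values", vals)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("grid needs at least two channels")
        d = np.diff(vals)
        if not np.all(d > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not np.allclose(d, d[0], rtol=0, atol=1e-6 * abs(d[0])):
            raise ValueError("wavenumber grid must be uniformly spaced")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_channels(self) -> int:
        return self.values.size

    def index_of(self, wavenumber: float) -> int:
        """Index of the channel nearest to ``wavenumber`` (must lie on-grid)."""
        if wavenumber < self.values[0] or wavenumber > self.values[-1]:
            raise ValueError(
                f"wavenumber {wavenumber} cm^-1 outside grid "
                f"[{self.values[0]}, {self.values[-1]}]"
            )
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def window(self, center: float, halfwidth: float) -> np.ndarray:
        """Channel indices within ``center +/- halfwidth`` cm^-1."""
        return np.nonzero(np.abs(self.values - center) <= halfwidth)[0]

    def covers(self, wavenumber: float) -> bool:
        return self.values[0] <= wavenumber <= self.values[-1]

    @classmethod
    def from_values(cls, values: np.ndarray) -> "WavenumberGrid":
        values = np.asarray(values, dtype=float)
        step = float(values[1] - values[0])
        return cls(start=float(values[0]), stop=float(values[-1]), step=step,
                   values=values)


def default_grid() -> WavenumberGrid:
    """The package-wide default axis: 400-1800 cm^-1 at 1 cm^-1."""
    return WavenumberGrid()
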
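"""Synthetic SERS cohort generator.

Emulates the statistical structure of label-free serum-exosome SERS
acquisitions: a shared set of smooth vibrational bands, a pan-cancer
intensity increase at 1080 cm^-1 (dATP) and decrease at 1380 cm^-1
(phosphatidylserine) against a stable 643 cm^-1 internal reference,
plus the acquisition artifacts the preprocessing chain must remove —
low-order baseline drift, additive shot-like noise, per-spectrum
amplitude jitter, and one-channel cosmic-ray spikes.

Every spectrum records its ground truth (spike channels, jitter scale)
so downstream stages can be tested against the generator rather than
against themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .dataset import CohortDataset, RamanSpectrum
from .grid import WavenumberGrid, default_grid

__all__ = [
    "PeakSpec", "ClassSignature", "NoiseModel", "CohortPlan",
    "simulate_spectrum", "simulate_cohort",
    "base_peaks", "binary_signatures", "multiclass_signatures",
    "default_binary_plan", "default_multiclass_plan",
    "CANCER_TYPES", "REFERENCE_CENTER", "MARKER_UP", "MARKER_DOWN",
    "EARLY_STAGES", "LATE_STAGES",
]

log = logging.getLogger(__name__)

#: the eleven-class vocabulary (ten cancer types + control)
CANCER_TYPES = ["breast", "thyroid", "esophageal", "kidney", "pancreatic",
                "duodenal", "lung", "colorectal", "ovarian", "gastric"]
REFERENCE_CENTER = 643.0   # stable internal-reference band, cm^-1
MARKER_UP = 1080.0         # dATP band, elevated in cancer
MARKER_DOWN = 1380.0       # phosphatidylserine band, reduced in cancer

EARLY_STAGES = ("T1N0M0", "T2N0M0")
LATE_STAGES = ("T3N1M0", "T4N2M1")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PeakSpec:
    """One vibrational band: center (cm^-1), FWHM (cm^-1), amplitude (a.u.)."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, grid: WavenumberGrid) -> np.ndarray:
        x = grid.values - self.center
        if self.shape == "gaussian":
            sigma = self.width * _FWHM_TO_SIGMA
            return self.amplitude * np.exp(-0.5 * (x / sigma) ** 2)
        hw = self.width / 2.0
        return self.amplitude * hw**2 / (x**2 + hw**2)


@dataclass(frozen=True)
class ClassSignature:
    """Deterministic band model of one diagnostic class.

    ``delta_1080``/``delta_1380`` are signed amplitude offsets applied to
    the marker bands on top of the shared base peaks; for every cancer
    class the offsets follow the pan-cancer direction (+ at 1080, - at
    1380). ``extra_peaks`` carry class-specific minor bands that make
    cancer types mutually distinguishable.
    """

    class_label: str
    base_peaks: tuple[PeakSpec, ...]
    delta_1080: float = 0.0
    delta_1380: float = 0.0
    extra_peaks: tuple[PeakSpec, ...] = ()
    marker_width: float = 12.0

    def __post_init__(self) -> None:
        if self.class_label != "non_cancer":
            if self.delta_1080 < 0 or self.delta_1380 > 0:
                raise ValueError(
                    f"{self.class_label}: cancer classes need delta_1080 >= 0 "
                    "and delta_1380 <= 0 (pan-cancer direction)")

    def clean_profile(self, grid: WavenumberGrid) -> np.ndarray:
        """Noise-free band sum of this class on ``grid``."""
        for p in list(self.base_peaks) + list(self.extra_peaks):
            if not grid.covers(p.center):
                raise ValueError(
                    f"peak center {p.center} cm^-1 outside grid for class "
                    f"{self.class_label!r}")
        y = np.zeros(len(grid))
        for p in list(self.base_peaks) + list(self.extra_peaks):
            y += p.profile(grid)
        if self.delta_1080:
            y += PeakSpec(MARKER_UP, self.marker_width, 1.0).profile(grid) \
                * self.delta_1080
        if self.delta_1380:
            y += PeakSpec(MARKER_DOWN, self.marker_width, 1.0).profile(grid) \
                * self.delta_1380
        return y

    def reference_amplitude(self) -> float:
        for p in self.base_peaks:
            if p.center == REFERENCE_CENTER:
                return p.amplitude
        return 0.0


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition artifacts added to each clean class profile.

    baseline_poly_coeffs: per-order (low, high) ranges for a random
    polynomial in t = (wavenumber - start)/(stop - start) in [0, 1].
    Spike amplitudes must clear 10x the additive noise SD so ground-truth
    spikes are unambiguous for the despiking oracle.
    """

    additive_sd: float = 0.03
    baseline_poly_coeffs: tuple[tuple[float, float], ...] = (
        (0.2, 0.8), (-0.3, 0.3), (-0.3, 0.3), (-0.2, 0.2))
    spike_rate: float = 0.05
    spike_amplitude_range: tuple[float, float] = (1.0, 5.0)
    amplitude_jitter_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.spike_rate < 0 \
                or self.amplitude_jitter_cv < 0:
            raise ValueError("noise rates and SDs must be >= 0")
        lo, hi = self.spike_amplitude_range
        if not 0 <= lo <= hi:
            raise ValueError("invalid spike amplitude range")
        if self.spike_rate > 0 and self.additive_sd > 0 \
                and lo <= 10 * self.additive_sd:
            raise ValueError(
                "minimum spike amplitude must exceed 10x additive_sd")

    @classmethod
    def zero(cls) -> "NoiseModel":
        """All artifact terms off: spectra equal the clean band sums."""
        return cls(additive_sd=0.0, baseline_poly_coeffs=((0.0, 0.0),),
                   spike_rate=0.0, spike_amplitude_range=(0.0, 0.0),
                   amplitude_jitter_cv=0.0)


@dataclass(frozen=True)
class CohortPlan:
    """Full recipe for one synthetic cohort."""

    classes: tuple[ClassSignature, ...]
    samples_per_class: int = 40
    spectra_per_sample: int = 50
    grid: WavenumberGrid = field(default_factory=default_grid)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spectra_per_sample < 1:
            raise ValueError("spectra_per_sample must be >= 1")
        if self.samples_per_class < 2:
            raise ValueError("samples_per_class must be >= 2")
        if len(self.classes) < 2:
            raise ValueError("need at least two classes")
        ref_amps = {s.class_label: s.reference_amplitude()
                    for s in self.classes}
        vals = set(ref_amps.values())
        if len(vals) != 1:
            raise ValueError(
                f"643 cm^-1 reference amplitude must match across classes, "
                f"got {ref_amps}")


# --------------------------------------------------------------- primitives

@lru_cache(maxsize=64)
def _cached_profile(signature: ClassSignature,
                    grid: WavenumberGrid) -> np.ndarray:
    return signature.clean_profile(grid)


def simulate_spectrum(signature: ClassSignature, grid: WavenumberGrid,
                      noise: NoiseModel,
                      rng: np.random.Generator) -> RamanSpectrum:
    """One noisy spectrum: band sum x jitter + baseline + noise + spikes.

    Ground-truth spike channel indices and the jitter scale are stored in
    the spectrum's ``meta`` for oracle tests. Intensities are clipped at 0.
    """
    clean = _cached_profile(signature, grid)

    if noise.amplitude_jitter_cv > 0:
        cv = noise.amplitude_jitter_cv
        sigma = np.sqrt(np.log(1.0 + cv**2))
        jitter = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
    else:
        jitter = 1.0
    y = clean * jitter

    t = (grid.values - grid.values[0]) / (grid.values[-1] - grid.values[0])
    baseline = np.zeros_like(y)
    for order, (lo, hi) in enumerate(noise.baseline_poly_coeffs):
        c = float(rng.uniform(lo, hi)) if hi > lo else lo
        if c:
            baseline += c * t**order
    y = y + baseline

    if noise.additive_sd > 0:
        y = y + rng.normal(0.0, noise.additive_sd, size=y.size)

    spikes: list[int] = []
    if noise.spike_rate > 0:
        n_spikes = int(rng.poisson(noise.spike_rate))
        if n_spikes:
            chans = rng.choice(y.size, size=n_spikes, replace=False)
            lo, hi = noise.spike_amplitude_range
            amps = rng.uniform(lo, hi, size=n_spikes)
            y[chans] += amps
            spikes = sorted(int(c) for c in chans)

    y = np.clip(y, 0.0, None)
    return RamanSpectrum(grid, y, meta={"spike_channels": spikes,
                                        "jitter": jitter})


def simulate_cohort(plan: CohortPlan) -> CohortDataset:
    """Generate the full cohort described by ``plan``.

    Emits ``len(plan.classes) * samples_per_class`` sample bundles with
    ``spectra_per_sample`` spectra each. Cancer samples are assigned a TNM
    stage (cycled deterministically through early and late stages) so the
    early-stage filtering task is exercisable. All randomness flows from
    ``plan.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
    n_chan = len(plan.grid)
    stages_cycle = list(EARLY_STAGES) + list(LATE_STAGES)

    rows = []
    mats = []
    for sig in plan.classes:
        for j in range(plan.samples_per_class):
            sample_id = f"{sig.class_label}_s{j:03d}"
            if sig.class_label == "non_cancer":
                stage = ""
            else:
                stage = stages_cycle[j % len(stages_cycle)]
            for r in range(plan.spectra_per_sample):
                spec = simulate_spectrum(sig, plan.grid, plan.noise, rng)
                mats.append(spec.intensity)
                rows.append({
                    "spectrum_id": f"{sample_id}_r{r:03d}",
                    "sample_id": sample_id,
                    "class_label": sig.class_label,
                    "stage": stage,
                    "spike_channels": spec.meta["spike_channels"],
                    "jitter": spec.meta["jitter"],
                })
    meta = pd.DataFrame(rows)
    intensities = np.vstack(mats) if mats else np.empty((0, n_chan))
    classes = [s.class_label for s in plan.classes]
    attrs = {
        "planted_deltas": {s.class_label: (s.delta_1080, s.delta_1380)
                           for s in plan.classes},
        "seed": plan.seed,
        "preprocessed": False,
    }
    log.info("simulated cohort: %d classes x %d samples x %d spectra = %d",
             len(plan.classes), plan.samples_per_class,
             plan.spectra_per_sample, len(meta))
    return CohortDataset(plan.grid, intensities, meta, classes=classes,
                         attrs=attrs)


# ------------------------------------------------------------ default plans

def base_peaks() -> tuple[PeakSpec, ...]:
    """Shared band set of all classes.

    Centers follow common serum/exosome Raman assignments; the global
    maximum sits at 1004 cm^-1 (phenylalanine) so that min-max scaling
    does not pin the 1080 cm^-1 marker band at 1 in every class.
    """
    return (
        PeakSpec(643.0, 12.0, 0.60),    # internal reference (C-S / tyrosine)
        PeakSpec(724.0, 14.0, 0.45),
        PeakSpec(850.0, 14.0, 0.40),
        PeakSpec(1004.0, 10.0, 1.00),   # phenylalanine, global max
        PeakSpec(1080.0, 12.0, 0.80),   # dATP marker band
        PeakSpec(1260.0, 16.0, 0.50),
        PeakSpec(1380.0, 12.0, 0.70),   # phosphatidylserine marker band
        PeakSpec(1450.0, 14.0, 0.55),
        PeakSpec(1585.0, 16.0, 0.45),
        PeakSpec(1655.0, 18.0, 0.40),
    )


#: per-cancer-type minor bands (center pairs), away from shared bands
_EXTRA_CENTERS: dict[str, tuple[float, float]] = {
    "breast": (520.0, 1210.0),
    "thyroid": (560.0, 1302.0),
    "esophageal": (610.0, 1240.0),
    "kidney": (700.0, 1330.0),
    "pancreatic": (760.0, 1418.0),
    "duodenal": (820.0, 1480.0),
    "lung": (880.0, 1520.0),
    "colorectal": (940.0, 1560.0),
    "ovarian": (1030.0, 1620.0),
    "gastric": (1120.0, 1680.0),
}

DEFAULT_DELTA_1080 = 0.15
DEFAULT_DELTA_1380 = -0.10


def binary_signatures(delta_1080: float = DEFAULT_DELTA_1080,
                      delta_1380: float = DEFAULT_DELTA_1380,
                      ) -> tuple[ClassSignature, ClassSignature]:
    """non_cancer vs pooled 'cancer' with the pan-cancer marker offsets."""
    bp = base_peaks()
    return (
        ClassSignature("non_cancer", bp),
        ClassSignature("cancer", bp, delta_1080=delta_1080,
                       delta_1380=delta_1380),
    )


def multiclass_signatures(delta_1080: float = DEFAULT_DELTA_1080,
                          delta_1380: float = DEFAULT_DELTA_1380,
                          extra_amplitude: float = 0.30,
                          ) -> tuple[ClassSignature, ...]:
    """Eleven-class vocabulary: ten cancer types + non_cancer control."""
    bp = base_peaks()
    sigs = [ClassSignature("non_cancer", bp)]
    for name in CANCER_TYPES:
        c1, c2 = _EXTRA_CENTERS[name]
        extras = (PeakSpec(c1, 12.0, extra_amplitude),
                  PeakSpec(c2, 12.0, extra_amplitude))
        sigs.append(ClassSignature(name, bp, delta_1080=delta_1080,
                                   delta_1380=delta_1380, extra_peaks=extras))
    return tuple(sigs)


def default_binary_plan(samples_per_class: int = 40,
                        spectra_per_sample: int = 50,
                        seed: int = 0, **noise_kwargs) -> CohortPlan:
    noise = NoiseModel(**noise_kwargs) if noise_kwargs else NoiseModel()
    return CohortPlan(binary_signatures(), samples_per_class,
                      spectra_per_sample, noise=noise, seed=seed)


def default_multiclass_plan(samples_per_class: int = 15,
                            spectra_per_sample: int = 30,
                            seed: int = 0, **noise_kwargs) -> CohortPlan:
    noise = NoiseModel(**noise_kwargs) if noise_kwargs else NoiseModel()
    return CohortPlan(multiclass_signatures(), samples_per_class,
                      spectra_per_sample, noise=noise, seed=seed)
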
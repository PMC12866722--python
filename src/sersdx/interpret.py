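"""Interpretability layer: feature importance, differential spectra,
and internal-reference peak-ratio statistics.

* Feature importance — default is gradient x input saliency (signed
  attributions averaged over spectra, magnitude normalized to percent);
  a literal weight-projection method is kept as a named alternative.
  Band scores aggregate channel percents inside a +/-10 cm^-1 window
  around a named center.
* Differential spectra — channelwise mean(class) - mean(control).
* Peak ratios — per-spectrum intensity at the 1080 (or 1380) channel
  divided by the 643 cm^-1 internal-reference channel, compared between
  groups by a Welch t-test with the conventional star codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import CohortDataset
from .grid import WavenumberGrid
from .nn import Network
from .simulate import MARKER_UP, REFERENCE_CENTER

__all__ = ["ImportanceProfile", "DifferentialSpectrum", "PeakRatioStat",
           "feature_importance", "differential_spectrum",
           "differential_matrix", "peak_ratio_test", "p_to_stars",
           "BAND_HALFWIDTH"]

log = logging.getLogger(__name__)

BAND_HALFWIDTH = 10.0  # cm^-1 on each side of a named band center


@dataclass
class ImportanceProfile:
    """Per-channel contribution percentages (non-negative, sum 100)."""

    grid: WavenumberGrid
    channel_percent: np.ndarray
    method: str

    def band_score(self, center: float,
                   halfwidth: float = BAND_HALFWIDTH) -> float:
        """Summed channel percents within ``center +/- halfwidth``."""
        return float(self.channel_percent[self.grid.window(center,
                                                           halfwidth)].sum())

    def top_bands(self, n: int = 5,
                  halfwidth: float = BAND_HALFWIDTH) -> list[float]:
        """Greedy non-overlapping top bands: repeatedly take the center
        with the highest windowed score, excluding overlaps."""
        width = int(round(2 * halfwidth / self.grid.step)) + 1
        kernel = np.ones(width)
        scores = np.convolve(self.channel_percent, kernel, mode="same")
        scores = scores.copy()
        centers = []
        for _ in range(n):
            i = int(np.argmax(scores))
            if scores[i] <= 0:
                break
            centers.append(float(self.grid.values[i]))
            lo = max(0, i - (width - 1))
            scores[lo:i + width] = -np.inf
        return centers


def feature_importance(net: Network, spectra: np.ndarray,
                       grid: WavenumberGrid,
                       method: str = "saliency") -> ImportanceProfile:
    """Percent contribution of every wavenumber channel to the model.

    ``saliency``: gradient x input attribution — for each spectrum, the
    gradient of the winning-vs-rest logit contrast w.r.t. the input,
    multiplied by the input; attributions are averaged over spectra with
    their sign (channels the model uses consistently reinforce, noise
    cancels) and the magnitude is normalized to percent.
    ``weight``: data-free projection of absolute weights from the output
    layer back to input channels (Garson-style chain product through the
    dense stack, upsampled through pooling, spread by the conv kernel).
    """
    if method == "saliency":
        spectra = np.ascontiguousarray(spectra, dtype=np.float32)
        if spectra.ndim != 2:
            raise ValueError("spectra must be (n_spectra, n_channels)")
        logits = net.forward(spectra, train=False)
        n_cls = logits.shape[1]
        onehot = np.zeros_like(logits)
        onehot[np.arange(spectra.shape[0]), logits.argmax(axis=1)] = 1.0
        contrast = onehot * (1.0 + 1.0 / (n_cls - 1)) - 1.0 / (n_cls - 1)
        grad = net.backward(contrast.astype(np.float32))
        raw = np.abs((grad * spectra).mean(axis=0))
    elif method == "weight":
        raw = _weight_energy(net, len(grid))
    else:
        raise ValueError(f"unknown importance method {method!r}")
    total = raw.sum()
    if total == 0:
        raise ValueError("zero importance everywhere; is the model trained?")
    pct = 100.0 * raw / total
    return ImportanceProfile(grid, pct, method)


def _weight_energy(net: Network, n_channels: int) -> np.ndarray:
    """Chain |W| products from the logits back to the input channels."""
    from .nn import Conv1D, Dense

    dense = [l for l in net.layers if isinstance(l, Dense)]
    conv = [l for l in net.layers if isinstance(l, Conv1D)]
    if not dense:
        raise ValueError("network has no dense layers")
    v = np.abs(dense[-1].W).sum(axis=1)  # (n_in of last layer,)
    for layer in reversed(dense[:-1]):
        v = np.abs(layer.W) @ v
    if conv:
        c = conv[0]
        kernel = c.kernel
        conv_len = n_channels - kernel + 1
        pool_len = conv_len // 2
        filters = c.W.shape[0]
        # v is over the flatten axis: (pool_len, filters)
        v = v.reshape(pool_len, filters)
        conv_score = np.zeros((conv_len, filters))
        conv_score[0:2 * pool_len:2] = v / 2.0  # pooled pair shares score
        conv_score[1:2 * pool_len:2] = v / 2.0
        wk = np.abs(c.W)  # (filters, kernel)
        chan = np.zeros(n_channels)
        for k in range(kernel):
            chan[k:k + conv_len] += conv_score @ wk[:, k]
        return chan
    return v


@dataclass
class DifferentialSpectrum:
    """Channelwise mean(class) - mean(reference group)."""

    class_label: str
    reference_label: str
    grid: WavenumberGrid
    delta: np.ndarray

    def at(self, wavenumber: float) -> float:
        return float(self.delta[self.grid.index_of(wavenumber)])


def differential_spectrum(dataset: CohortDataset, class_label: str,
                          reference_label: str = "non_cancer"
                          ) -> DifferentialSpectrum:
    """Mean spectrum of ``class_label`` minus mean of the reference group."""
    labels = dataset.meta["class_label"]
    for name in (class_label, reference_label):
        if not (labels == name).any():
            raise ValueError(f"no spectra for group {name!r}")
    mean_cls = dataset.intensities[(labels == class_label).to_numpy()].mean(
        axis=0)
    mean_ref = dataset.intensities[(labels == reference_label).to_numpy()
                                   ].mean(axis=0)
    return DifferentialSpectrum(class_label, reference_label, dataset.grid,
                                mean_cls - mean_ref)


def differential_matrix(dataset: CohortDataset,
                        reference_label: str = "non_cancer"):
    """Differential spectra for every non-reference class (heatmap rows)."""
    import pandas as pd

    rows = {}
    for cls in dataset.classes:
        if cls == reference_label:
            continue
        rows[cls] = differential_spectrum(dataset, cls, reference_label).delta
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=dataset.grid.values)


# ------------------------------------------------------------- peak ratios

def p_to_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class PeakRatioStat:
    numerator_center: float
    reference_center: float
    group_labels: tuple[str, str]
    ratios: tuple[np.ndarray, np.ndarray]
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    t_statistic: float
    p_value: float
    stars: str
    n_excluded: int


def peak_ratio_test(dataset: CohortDataset,
                    numerator_center: float = MARKER_UP,
                    reference_center: float = REFERENCE_CENTER,
                    groups: tuple[str, str] = ("cancer", "non_cancer"),
                    max_spectra_per_group: int | None = None,
                    seed: int = 0) -> PeakRatioStat:
    """Welch t-test on internal-reference peak ratios between two groups.

    Per-spectrum ratio: intensity at the channel nearest
    ``numerator_center`` divided by intensity at the channel nearest
    ``reference_center``. Spectra with non-positive reference intensity
    are excluded (logged); more than 5% such spectra means the reference
    band is unusable and raises ``ValueError``. ``max_spectra_per_group``
    subsamples each group (seeded) — e.g. 25 to mirror per-group spectrum
    counts of small comparison panels.
    """
    gi = dataset.grid.index_of(numerator_center)
    ri = dataset.grid.index_of(reference_center)
    labels = dataset.meta["class_label"].to_numpy()
    rng = np.random.default_rng(seed)

    ratios = []
    n_excluded = 0
    for gname in groups:
        mask = labels == gname
        if not mask.any():
            raise ValueError(f"no spectra for group {gname!r}")
        num = dataset.intensities[mask, gi]
        ref = dataset.intensities[mask, ri]
        ok = ref > 0
        n_bad = int((~ok).sum())
        if n_bad > 0.05 * ok.size:
            raise ValueError(
                f"group {gname!r}: reference band at {reference_center} "
                f"cm^-1 non-positive in {n_bad}/{ok.size} spectra")
        if n_bad:
            log.info("group %s: excluded %d spectra with non-positive "
                     "reference intensity", gname, n_bad)
            n_excluded += n_bad
        r = num[ok] / ref[ok]
        if max_spectra_per_group is not None \
                and r.size > max_spectra_per_group:
            r = rng.choice(r, size=max_spectra_per_group, replace=False)
        ratios.append(r)

    t, p = stats.ttest_ind(ratios[0], ratios[1], equal_var=False)
    return PeakRatioStat(
        numerator_center=float(numerator_center),
        reference_center=float(reference_center),
        group_labels=tuple(groups),
        ratios=(ratios[0], ratios[1]),
        group_means=(float(ratios[0].mean()), float(ratios[1].mean())),
        group_sds=tuple(float(r.std(ddof=1)) if r.size > 1 else float("nan")
                        for r in ratios),
        t_statistic=float(t), p_value=float(p), stars=p_to_stars(float(p)),
        n_excluded=n_excluded)
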
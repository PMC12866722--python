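"""Sample-level diagnosis and evaluation surfaces.

A sample's diagnosis is the unweighted mean of its spectrum-level class
probabilities; the call is the argmax (lowest class index wins ties),
or, for the binary task, a thresholded positive call on the mean cancer
probability (default threshold 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

__all__ = ["SampleDiagnosis", "EvaluationReport", "aggregate_sample",
           "aggregate_all", "evaluate", "probability_heatmap"]


@dataclass
class SampleDiagnosis:
    sample_id: str
    mean_probs: np.ndarray
    call: str
    n_spectra: int
    classes: list[str] = field(default_factory=list)


def _prob_cols(predictions: pd.DataFrame, classes: list[str],
               kind: str) -> list[str]:
    prefix = {"cnn": "cnn_p_", "refined": "ref_p_"}[kind]
    cols = [prefix + c for c in classes]
    missing = [c for c in cols if c not in predictions.columns]
    if missing:
        raise ValueError(f"missing probability columns {missing}")
    return cols


def aggregate_sample(predictions: pd.DataFrame, sample_id: str,
                     classes: list[str],
                     kind: str = "refined") -> SampleDiagnosis:
    """Mean of the sample's spectrum probabilities; argmax call."""
    rows = predictions[predictions["sample_id"] == sample_id]
    if rows.empty:
        raise KeyError(f"no predictions for sample {sample_id!r}")
    cols = _prob_cols(predictions, classes, kind)
    mean = rows[cols].to_numpy().mean(axis=0)
    call = classes[int(np.argmax(mean))]  # argmax takes lowest index on ties
    return SampleDiagnosis(str(sample_id), mean, call, len(rows),
                           list(classes))


def aggregate_all(predictions: pd.DataFrame, classes: list[str],
                  kind: str = "refined",
                  positive_class: str | None = None,
                  threshold: float = 0.5) -> pd.DataFrame:
    """One diagnosis row per sample.

    With ``positive_class`` set (binary task), the call is positive when
    the mean positive-class probability is >= ``threshold``.
    """
    cols = _prob_cols(predictions, classes, kind)
    g = predictions.groupby("sample_id", sort=True)
    out = g[cols].mean()
    out.columns = [f"mean_p_{c}" for c in classes]
    out["n_spectra"] = g.size()
    if "class_label" in predictions.columns:
        out["truth"] = g["class_label"].first()
    probs = out[[f"mean_p_{c}" for c in classes]].to_numpy()
    if positive_class is not None:
        j = classes.index(positive_class)
        others = [c for c in classes if c != positive_class]
        if len(others) != 1:
            raise ValueError("thresholded calls require a binary task")
        out["call"] = np.where(probs[:, j] >= threshold, positive_class,
                               others[0])
    else:
        out["call"] = [classes[i] for i in probs.argmax(axis=1)]
    return out.reset_index()


@dataclass
class EvaluationReport:
    """Confusion matrix, accuracy, per-class sensitivity/specificity,
    one-vs-rest ROC curves and trapezoidal AUCs."""

    classes: list[str]
    confusion: np.ndarray          # rows = truth, cols = call
    accuracy: float
    sensitivity: dict[str, float]  # TP / (TP + FN), one-vs-rest
    specificity: dict[str, float]  # TN / (TN + FP), one-vs-rest
    roc: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (fpr, tpr)
    auc: dict[str, float]
    macro_auc: float
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "macro_auc": self.macro_auc,
            "n_samples": self.n_samples,
        }


def evaluate(diagnoses: pd.DataFrame, truth: pd.Series | None = None,
             classes: list[str] | None = None) -> EvaluationReport:
    """Score sample-level diagnoses against truth labels.

    ``diagnoses`` is the frame from :func:`aggregate_all` (needs ``call``
    and ``mean_p_<class>`` columns); ``truth`` defaults to its ``truth``
    column. ROC curves sweep the mean-probability threshold one-vs-rest;
    AUC is trapezoidal.
    """
    if truth is None:
        truth = diagnoses["truth"]
    truth = pd.Series(truth).reset_index(drop=True).astype(str)
    calls = diagnoses["call"].reset_index(drop=True).astype(str)
    if classes is None:
        classes = sorted(set(truth))
    unknown = set(truth) - set(classes)
    if unknown:
        raise ValueError(f"labels outside class vocabulary: {unknown}")

    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=int)
    for t, c in zip(truth, calls):
        confusion[idx[t], idx[c]] += 1
    n = int(confusion.sum())
    accuracy = float(np.trace(confusion)) / n

    sens, spec, rocs, aucs = {}, {}, {}, {}
    for c in classes:
        i = idx[c]
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens[c] = tp / (tp + fn) if tp + fn else float("nan")
        spec[c] = tn / (tn + fp) if tn + fp else float("nan")
        score_col = f"mean_p_{c}"
        if score_col in diagnoses.columns and truth.nunique() > 1:
            y_true = (truth == c).astype(int).to_numpy()
            scores = diagnoses[score_col].to_numpy()
            if 0 < y_true.sum() < y_true.size:
                fpr, tpr, _ = _roc_curve(y_true, scores)
                rocs[c] = (fpr, tpr)
                aucs[c] = float(_trapezoid_auc(fpr, tpr))
    macro = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return EvaluationReport(list(classes), confusion, accuracy, sens, spec,
                            rocs, aucs, macro, n)


def probability_heatmap(predictions: pd.DataFrame, classes: list[str],
                        kind: str = "refined",
                        subsample_per_sample: int | None = None,
                        seed: int = 0,
                        csv_path=None, image_path=None) -> pd.DataFrame:
    """Spectrum x class probability matrix, rows grouped by class/sample.

    ``subsample_per_sample`` optionally limits rows per sample (the
    published heatmaps use 100 of the >=200 acquired spectra). Written as
    CSV and/or an image when paths are given.
    """
    if predictions.empty:
        raise ValueError("no predictions to plot")
    cols = _prob_cols(predictions, classes, kind)
    df = predictions.sort_values(["class_label", "sample_id",
                                  "spectrum_id"]).reset_index(drop=True)
    if subsample_per_sample is not None:
        rng = np.random.default_rng(seed)
        keep = []
        for _, grp in df.groupby("sample_id", sort=False):
            if len(grp) > subsample_per_sample:
                keep.extend(rng.choice(grp.index, subsample_per_sample,
                                       replace=False))
            else:
                keep.extend(grp.index)
        df = df.loc[sorted(keep)].reset_index(drop=True)
    mat = df[["spectrum_id", "sample_id", "class_label"] + cols].copy()
    mat.columns = ["spectrum_id", "sample_id", "class_label"] + classes
    if csv_path is not None:
        mat.to_csv(csv_path, index=False)
    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 8))
        ax.imshow(mat[classes].to_numpy(), aspect="auto",
                  interpolation="nearest", cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(len(classes)))
        ax.set_xticklabels(classes, rotation=90)
        ax.set_ylabel("spectra (grouped by class, sample)")
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
    return mat
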
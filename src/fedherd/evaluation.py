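"""Classification metrics and run comparison tables.

Window-level binary metrics from a confusion matrix: accuracy,
precision, recall, F1. The decision rule is "predict stress iff
probability > threshold" with a strict inequality and a default
threshold of 0.5. Undefined ratios (zero denominators) map to 0 with a
logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .federated import MB, RunResult
from .model import ModelConfig, ParamVector, predict_proba
from .preprocess import WindowedDataset

logger = logging.getLogger("fedherd.evaluation")

__all__ = [
    "Confusion",
    "Metrics",
    "confusion_matrix",
    "classification_metrics",
    "evaluate_model",
    "compare_runs",
    "render_report",
]


@dataclass
class Confusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """2×2 layout [[tn, fp], [fn, tp]] (rows: true class, cols: predicted)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy


def confusion_matrix(probabilities, labels, threshold: float = 0.5) -> Confusion:
    """Tabulate predictions (1 iff probability > threshold, strict)."""
    p = np.asarray(probabilities, dtype=float)
    z = np.asarray(labels)
    if p.shape != z.shape or p.size == 0:
        raise DataError("probabilities and labels must be equal-length and non-empty")
    if not np.isin(z, (0, 1)).all():
        raise DataError("labels must be 0/1")
    pred = (p > threshold).astype(int)
    return Confusion(
        tp=int(((pred == 1) & (z == 1)).sum()),
        fp=int(((pred == 1) & (z == 0)).sum()),
        fn=int(((pred == 0) & (z == 1)).sum()),
        tn=int(((pred == 0) & (z == 0)).sum()),
    )


def classification_metrics(conf: Confusion) -> Metrics:
    """Accuracy, precision, recall, F1 from counts; undefined ratios → 0."""
    if conf.total == 0:
        raise DataError("empty confusion matrix")
    accuracy = (conf.tp + conf.tn) / conf.total
    if conf.tp + conf.fp > 0:
        precision = conf.tp / (conf.tp + conf.fp)
    else:
        logger.warning("precision undefined (no positive predictions); reporting 0")
        precision = 0.0
    if conf.tp + conf.fn > 0:
        recall = conf.tp / (conf.tp + conf.fn)
    else:
        logger.warning("recall undefined (no positive labels); reporting 0")
        recall = 0.0
    denom = precision + recall
    f1 = 2.0 * precision * recall / denom if denom > 0 else 0.0
    return Metrics(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def evaluate_model(
    params: ParamVector,
    data: WindowedDataset,
    model_cfg: ModelConfig,
    threshold: float = 0.5,
) -> tuple[Confusion, Metrics]:
    """Forward pass over all windows, then confusion + metrics."""
    if data is None or len(data) == 0:
        raise DataError("evaluate_model requires non-empty data")
    p = predict_proba(params, data.X, model_cfg)
    conf = confusion_matrix(p, data.y, threshold)
    return conf, classification_metrics(conf)


def compare_runs(
    results: list[tuple[str, RunResult]],
    test_data: WindowedDataset,
    model_cfg: ModelConfig,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """One row per run: accuracy %, F1, and total traffic in MB.

    The communication columns come from each run's analytic ledger; a
    centralized run has an empty ledger and shows 0 MB.
    """
    if not results:
        raise DataError("compare_runs requires at least one result")
    rows = []
    for name, res in results:
        _, m = evaluate_model(res.params, test_data, model_cfg, threshold)
        rows.append({
            "model": name,
            "accuracy_pct": m.accuracy_pct,
            "accuracy": m.accuracy,
            "precision": m.precision,
            "recall": m.recall,
            "f1": m.f1,
            "uplink_mb": res.ledger.total_uplink_bytes / MB,
            "downlink_mb": res.ledger.total_downlink_bytes / MB,
        })
    return pd.DataFrame(rows)


def render_report(table: pd.DataFrame) -> str:
    """Human-readable comparison report."""
    lines = ["Model comparison (window-level, decision threshold 0.5)", ""]
    lines.append(table.to_string(
        index=False,
        formatters={
            "accuracy_pct": "{:.1f}".format,
            "accuracy": "{:.4f}".format,
            "precision": "{:.4f}".format,
            "recall": "{:.4f}".format,
            "f1": "{:.4f}".format,
            "uplink_mb": "{:.2f}".format,
            "downlink_mb": "{:.2f}".format,
        },
    ))
    lines.append("")
    lines.append("Traffic in MB (1 MB = 2^20 bytes); centralized runs move no model traffic.")
    return "\n".join(lines)


def confusion_to_image(conf: Confusion, path) -> None:
    """Optionally render the confusion matrix to an image (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = conf.as_array()
    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    ax.imshow(arr, cmap="Blues")
    for (i, j), v in np.ndenumerate(arr):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], ["normal", "stressed"])
    ax.set_yticks([0, 1], ["normal", "stressed"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
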
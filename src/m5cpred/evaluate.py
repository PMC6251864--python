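"""Performance evaluation: sensitivity/specificity, ROC, AUC, and the
intra-/inter-tissue benchmark matrix.

ROC analysis is implemented from first principles because it is the
package's evaluation contract, and by **two independent routes** that must
agree:

* :func:`roc_curve` sweeps thresholds over the unique scores, groups tied
  scores into single (diagonal) steps, and integrates the curve with the
  trapezoidal rule;
* :func:`auc` computes the Mann–Whitney concordance — the probability that
  a random positive outscores a random negative, ties counting 1/2 — from
  average ranks.

The two are mathematically identical; the test suite holds them to 1e-12
agreement. Class imbalance does not bias either quantity, which is why ROC
is the metric of choice for candidate-C scans where negatives outnumber
positives by orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import SingleClassError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts at one operating point."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.TP + self.FN

    @property
    def negatives(self) -> int:
        return self.TN + self.FP


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); raises if there are no positives."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    return c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); raises if there are no negatives."""
    if c.TN + c.FP == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    return c.TN / (c.TN + c.FP)


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    """Counts for the rule ``score > threshold`` ⇒ call positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    calls = scores > threshold
    return ConfusionCounts(
        TP=int(np.sum(calls & (labels == 1))),
        TN=int(np.sum(~calls & (labels == 0))),
        FP=int(np.sum(calls & (labels == 0))),
        FN=int(np.sum(~calls & (labels == 1))),
    )


@dataclass
class ROCResult:
    """An ROC curve as (FPR, TPR) points from (0,0) to (1,1) plus its area."""

    points: np.ndarray  # shape (k, 2), columns FPR, TPR
    auc: float
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["fpr", "tpr"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_two_classes(labels: np.ndarray) -> None:
    if not ((labels == 1).any() and (labels == 0).any()):
        raise SingleClassError("both classes are required for ROC analysis")


def roc_curve(scores, labels) -> ROCResult:
    """Threshold-sweep ROC with trapezoidal area.

    Scores are sorted descending; each unique score value contributes one
    curve point, so tied positive/negative scores produce a single diagonal
    segment rather than an arbitrary staircase.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be parallel")
    _check_two_classes(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels == 1)
    fp = np.cumsum(sorted_labels == 0)
    # keep only the last index of each tied score block
    last_of_block = np.r_[np.diff(sorted_scores) != 0, True]
    tp = tp[last_of_block]
    fp = fp[last_of_block]
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(points=np.column_stack([fpr, tpr]), auc=area,
                     n_pos=n_pos, n_neg=n_neg)


def auc(scores, labels) -> float:
    """Mann–Whitney concordance: mean over positive/negative pairs of
    1 (positive scored higher), 1/2 (tie), 0 (lower). Equals the
    trapezoidal ROC area."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    ranks = rankdata(scores)  # average ranks on ties
    rank_sum = float(ranks[labels == 1].sum())
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def server_point(calls, labels) -> tuple[float, float]:
    """(FPR, TPR) of a fixed-threshold binary predictor — how an external
    server with a hard-coded cutoff appears on an ROC plot: one point, not
    a curve."""
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    c = ConfusionCounts(
        TP=int(np.sum((calls == 1) & (labels == 1))),
        TN=int(np.sum((calls == 0) & (labels == 0))),
        FP=int(np.sum((calls == 1) & (labels == 0))),
        FN=int(np.sum((calls == 0) & (labels == 1))),
    )
    return 1.0 - specificity(c), sensitivity(c)


@dataclass
class TissueMatrix:
    """AUC of every predictor (rows) on every tissue test set (columns)."""

    table: pd.DataFrame  # index = predictor tissue, columns = test tissue

    @property
    def tissues(self) -> list[str]:
        return list(self.table.index)

    def diagonal_mean(self) -> float:
        return float(np.nanmean(np.diag(self.table.to_numpy())))

    def off_diagonal_mean(self) -> float:
        arr = self.table.to_numpy().astype(float).copy()
        np.fill_diagonal(arr, np.nan)
        if np.isnan(arr).all():
            return float("nan")
        return float(np.nanmean(arr))

    def summary(self) -> dict[str, float]:
        return {
            "intra_tissue_mean_auc": self.diagonal_mean(),
            "inter_tissue_mean_auc": self.off_diagonal_mean(),
        }

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="predictor")

    def plot_heatmap(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.2 * len(self.table.columns) + 2,
                                        1.0 * len(self.table.index) + 2))
        im = ax.imshow(self.table.to_numpy(), vmin=0.5, vmax=1.0,
                       cmap="viridis")
        ax.set_xticks(range(len(self.table.columns)),
                      self.table.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(self.table.index)), self.table.index)
        ax.set_xlabel("test set tissue")
        ax.set_ylabel("predictor tissue")
        for i in range(len(self.table.index)):
            for j in range(len(self.table.columns)):
                val = self.table.iat[i, j]
                if np.isfinite(val):
                    ax.text(j, i, f"{val:.2f}", ha="center", va="center",
                            color="white")
        fig.colorbar(im, ax=ax, label="AUC")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def cross_tissue_benchmark(predictors: Mapping[str, "TrainedPredictor"],
                           test_sets: Mapping[str, "LabelledDataset"],
                           ) -> TissueMatrix:
    """AUC of predictor *i* on test set *j*: diagonal cells are intra-tissue
    performance, off-diagonal inter-tissue. Missing test sets yield NaN
    cells, never silent zeros."""
    from .models import predict_scores  # local import avoids a cycle

    tissues = sorted(set(predictors) | set(test_sets))
    table = pd.DataFrame(np.nan, index=tissues, columns=tissues, dtype=float)
    for pred_tissue in tissues:
        if pred_tissue not in predictors:
            continue
        predictor = predictors[pred_tissue]
        for test_tissue in tissues:
            if test_tissue not in test_sets:
                continue
            ds = test_sets[test_tissue]
            scores = predict_scores(predictor, ds.windows)
            table.loc[pred_tissue, test_tissue] = auc(scores, ds.labels)
    return TissueMatrix(table=table)
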
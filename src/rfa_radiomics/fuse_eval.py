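"""Decision-level fusion, ROC/AUC, DeLong test, and threshold metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

log = logging.getLogger(__name__)


@dataclass
class FusionWeights:
    w_radiomics: float
    w_clinical: float

    def __post_init__(self) -> None:
        if self.w_radiomics < 0 or self.w_clinical < 0:
            raise ValueError("fusion weights must be non-negative")
        if abs(self.w_radiomics + self.w_clinical - 1.0) > 1e-9:
            raise ValueError("fusion weights must sum to 1")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        if denom == 0:
            log.warning("no positives: sensitivity undefined")
            return None
        return self.tp / denom

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        if denom == 0:
            log.warning("no negatives: specificity undefined")
            return None
        return self.tn / denom


def fuse(
    scores_radiomics: pd.Series, scores_clinical: pd.Series, weights: FusionWeights
) -> pd.Series:
    """Elementwise w1 * radiomics + w2 * clinical on aligned lesion ids."""
    if not scores_radiomics.index.equals(scores_clinical.index):
        if set(scores_radiomics.index) != set(scores_clinical.index):
            raise ValueError("score sets cover different lesions")
        scores_clinical = scores_clinical.reindex(scores_radiomics.index)
    fused = weights.w_radiomics * scores_radiomics + weights.w_clinical * scores_clinical
    fused.name = "fused"
    return fused


def roc_auc(scores: np.ndarray | pd.Series, labels: np.ndarray | pd.Series) -> float:
    """Mann-Whitney rank AUC with midranks for ties."""
    s = np.asarray(scores, dtype=float)
    y = _binary(labels)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == "CR").astype(int)
    return arr.astype(int)


def weight_scan(
    scores_radiomics: pd.Series,
    scores_clinical: pd.Series,
    labels: pd.Series | np.ndarray,
    grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, FusionWeights]:
    """AUC for each w1 on the grid; best w1 by max AUC, ties to larger w1."""
    if grid is None:
        grid = np.round(np.arange(0.1, 1.0, 0.1), 10)
    if len(grid) == 0:
        raise ValueError("empty weight grid")
    rows = []
    for w1 in grid:
        fused = fuse(
            scores_radiomics, scores_clinical, FusionWeights(float(w1), float(1 - w1))
        )
        rows.append({"w_radiomics": float(w1), "auc": roc_auc(fused, labels)})
    table = pd.DataFrame(rows)
    best_row = table.sort_values(["auc", "w_radiomics"], ascending=False).iloc[0]
    best = FusionWeights(float(best_row["w_radiomics"]), float(1 - best_row["w_radiomics"]))
    return table, best


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _structural_components(scores: np.ndarray, y: np.ndarray):
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    # midrank-based placement values
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    return v10, v01


def delong_test(
    scores_a: np.ndarray | pd.Series,
    scores_b: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """Two-sided DeLong test for paired correlated ROC curves.

    Returns (AUC_a - AUC_b, p). Identical scores (zero variance of the
    difference) return p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = _binary(labels)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("delong_test requires paired scores on the same lesions")
    v10a, v01a = _structural_components(a, y)
    v10b, v01b = _structural_components(b, y)
    auc_a = v10a.mean()
    auc_b = v10b.mean()
    m, n = len(v10a), len(v01a)
    diff = float(auc_a - auc_b)
    if m < 2 or n < 2:
        log.warning("delong_test: <2 samples in a class, variance undefined; p := 1")
        return diff, 1.0
    s10 = np.cov(np.vstack([v10a, v10b]), bias=False)
    s01 = np.cov(np.vstack([v01a, v01b]), bias=False)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if not np.isfinite(var) or var <= 0:
        return diff, 1.0
    z = diff / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return diff, p


# ---------------------------------------------------------------------------
# threshold metrics
# ---------------------------------------------------------------------------

def youden_threshold(scores: np.ndarray | pd.Series, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on these scores."""
    s = np.asarray(scores, dtype=float)
    y = _binary(labels)
    order = np.argsort(-s)
    s_sorted = s[order]
    y_sorted = y[order]
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    sens = tps / n_pos
    spec = 1 - fps / n_neg
    j = sens + spec - 1.0
    # candidate thresholds between distinct scores
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    j[~distinct] = -np.inf
    k = int(np.argmax(j))
    return float(s_sorted[k])


def confusion_metrics(
    scores: np.ndarray | pd.Series,
    labels,
    threshold: float = 0.5,
) -> dict[str, float | None | ConfusionCounts]:
    """ACC / sensitivity / specificity at a fixed threshold (positive = CR)."""
    s = np.asarray(scores, dtype=float)
    y = _binary(labels)
    pred = (s >= threshold).astype(int)
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )
    return {
        "counts": counts,
        "accuracy": counts.accuracy,
        "sensitivity": counts.sensitivity,
        "specificity": counts.specificity,
        "threshold": float(threshold),
    }


@dataclass
class EvaluationReport:
    per_model: dict[str, dict] = field(default_factory=dict)
    delong: dict[str, dict[str, float]] = field(default_factory=dict)
    weight_grid: pd.DataFrame | None = None
    best_weights: FusionWeights | None = None

    def to_dict(self) -> dict:
        out: dict = {"models": {}, "delong": self.delong}
        for name, metrics in self.per_model.items():
            entry = {k: v for k, v in metrics.items() if k != "counts"}
            counts = metrics.get("counts")
            if counts is not None:
                entry["confusion"] = {
                    "TP": counts.tp, "FP": counts.fp, "TN": counts.tn, "FN": counts.fn
                }
            out["models"][name] = entry
        if self.weight_grid is not None:
            out["weight_grid"] = self.weight_grid.to_dict(orient="records")
        if self.best_weights is not None:
            out["best_weights"] = {
                "radiomics": self.best_weights.w_radiomics,
                "clinical": self.best_weights.w_clinical,
            }
        return out


def evaluate_models(
    test_scores: dict[str, pd.Series],
    test_labels: pd.Series,
    train_scores: dict[str, pd.Series] | None = None,
    train_labels: pd.Series | None = None,
) -> EvaluationReport:
    """AUC + threshold metrics per model and pairwise DeLong comparisons.

    Thresholds use Youden's J on the training fold when training scores are
    supplied, else a fixed 0.5.
    """
    report = EvaluationReport()
    for name, scores in test_scores.items():
        if train_scores is not None and name in train_scores:
            thr = youden_threshold(train_scores[name], train_labels)
        else:
            thr = 0.5
        metrics = confusion_metrics(scores, test_labels.loc[scores.index], threshold=thr)
        metrics["auc"] = roc_auc(scores, test_labels.loc[scores.index])
        report.per_model[name] = metrics
    names = list(test_scores)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            common = test_scores[a].index.intersection(test_scores[b].index)
            diff, p = delong_test(
                test_scores[a].loc[common],
                test_scores[b].loc[common],
                test_labels.loc[common],
            )
            report.delong[f"{a}_vs_{b}"] = {"auc_diff": diff, "p": p}
    return report


def plot_roc(
    scores: dict[str, "pd.Series"],
    labels,
    path,
) -> None:
    """ROC curves for each score set, saved as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, s in scores.items():
        y = _binary(np.asarray(labels))
        sc = np.asarray(s, dtype=float)
        order = np.argsort(-sc)
        ys = y[order]
        tpr = np.r_[0, np.cumsum(ys)] / max(y.sum(), 1)
        fpr = np.r_[0, np.cumsum(1 - ys)] / max((1 - y).sum(), 1)
        ax.plot(fpr, tpr, label=f"{name} (AUC {roc_auc(sc, y):.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
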
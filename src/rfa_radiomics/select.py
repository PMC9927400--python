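"""Five-criterion mRMR feature ranking and top-k frequency consensus.

Criteria: MID (mutual-information difference), MIQ (quotient), FCD (F-test /
Pearson difference), FCQ (quotient), RFCQ (random-forest importance /
Pearson quotient). Greedy forward selection; redundancy is the mean over the
already-selected set (MI for MID/MIQ, |Pearson| otherwise); quotient forms
guard the denominator with eps = 1e-12.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import roc_auc_score

log = logging.getLogger(__name__)

CRITERIA = ("MID", "MIQ", "FCD", "FCQ", "RFCQ")
_EPS = 1e-12
_F_CAP = 1e12


@dataclass
class RankingResult:
    criterion: str
    order: list[str]
    scores: list[float]

    def top(self, k: int) -> list[str]:
        return self.order[:k]


@dataclass
class ConsensusSelection:
    frequency: dict[str, int]
    chosen_set: list[str]
    chosen_m: int
    cv_scores: dict[int, float] = field(default_factory=dict)
    consensus_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.chosen_set) != self.chosen_m:
            raise ValueError("chosen_set size must equal chosen_m")


# ---------------------------------------------------------------------------
# primitive statistics
# ---------------------------------------------------------------------------

def _quantile_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile binning of a continuous column into at most n_bins codes."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 8,
    x_is_discrete: bool = False,
    y_is_discrete: bool = True,
) -> float:
    """Plug-in mutual information (natural log, nats) on the joint histogram.

    Continuous x is quantile-binned into ``n_bins``; y is categorical by
    default (class labels) but is binned likewise when ``y_is_discrete`` is
    False (feature-feature redundancy). Constant x returns 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size < 4:
        raise ValueError("mutual_information requires n >= 4")
    if np.all(x == x.flat[0]):
        return 0.0
    xc = x.astype(int) if x_is_discrete else _quantile_bin(x.astype(float), n_bins)
    yc = y if y_is_discrete else _quantile_bin(y.astype(float), n_bins)
    _, xi = np.unique(xc, return_inverse=True)
    _, yi = np.unique(yc, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())


def f_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """One-way ANOVA F of x across the classes of y.

    Zero within-group variance with distinct means is capped at a large
    finite value (with a warning) rather than returning inf.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("f_statistic requires >= 2 classes")
    groups = [x[y == c] for c in classes]
    if any(len(g) < 1 for g in groups):
        raise ValueError("every class needs at least one member")
    grand = x.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(classes) - 1
    df2 = x.size - len(classes)
    if df2 <= 0:
        raise ValueError("not enough samples for within-group variance")
    msb = ssb / df1
    msw = ssw / df2
    if msw == 0:
        if msb == 0:
            return 0.0
        warnings.warn("zero within-group variance; F capped", stacklevel=2)
        return _F_CAP
    return float(msb / msw)


def pearson_redundancy(x1: np.ndarray, x2: np.ndarray) -> float:
    """Absolute Pearson correlation; constant input gives 0 with a warning."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.std() == 0 or x2.std() == 0:
        warnings.warn("constant input to pearson_redundancy", stacklevel=2)
        return 0.0
    return float(abs(np.corrcoef(x1, x2)[0, 1]))


def rf_relevance(
    X: pd.DataFrame, y: np.ndarray, seed: int = 0, n_estimators: int = 200
) -> dict[str, float]:
    """Impurity-decrease importances from a seeded forest (sum to 1)."""
    if len(X) < 20:
        raise ValueError("rf_relevance requires n >= 20")
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(X.to_numpy(), y)
    return dict(zip(X.columns, forest.feature_importances_))


# ---------------------------------------------------------------------------
# greedy mRMR
# ---------------------------------------------------------------------------

def mrmr_rank(
    X: pd.DataFrame,
    y: np.ndarray,
    criterion: str,
    depth: int | None = None,
    mi_bins: int = 8,
    seed: int = 0,
) -> RankingResult:
    """Greedy forward mRMR ranking under one of the five criteria.

    The first feature maximizes the criterion's relevance term; each later
    step maximizes relevance minus (difference forms) or divided by (quotient
    forms) the mean redundancy against the already-selected set. Ties break
    on the feature name, so input column order is irrelevant.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    if depth is None:
        depth = X.shape[1]
    if depth < 1:
        raise ValueError("depth must be >= 1")
    depth = min(depth, X.shape[1])
    names = sorted(X.columns)
    cols = {n: X[n].to_numpy(dtype=float) for n in names}
    y = np.asarray(y)

    if criterion in ("MID", "MIQ"):
        relevance = {n: mutual_information(cols[n], y, n_bins=mi_bins) for n in names}
    elif criterion in ("FCD", "FCQ"):
        relevance = {n: f_statistic(cols[n], y) for n in names}
    else:  # RFCQ
        relevance = rf_relevance(X[names], y, seed=seed)

    use_mi_redundancy = criterion in ("MID", "MIQ")
    quotient = criterion in ("MIQ", "FCQ", "RFCQ")

    selected: list[str] = []
    scores: list[float] = []
    remaining = list(names)
    red_cache: dict[str, list[float]] = {n: [] for n in names}

    while len(selected) < depth:
        best_name, best_score = None, -np.inf
        for n in remaining:
            if selected:
                red = float(np.mean(red_cache[n]))
                if quotient:
                    score = relevance[n] / max(red, _EPS)
                else:
                    score = relevance[n] - red
            else:
                score = relevance[n]
            if score > best_score:
                best_name, best_score = n, score
        selected.append(best_name)
        scores.append(float(best_score))
        remaining.remove(best_name)
        xb = cols[best_name]
        for n in remaining:
            if use_mi_redundancy:
                red_cache[n].append(
                    mutual_information(cols[n], xb, n_bins=mi_bins, y_is_discrete=False)
                )
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    red_cache[n].append(pearson_redundancy(cols[n], xb))
    return RankingResult(criterion=criterion, order=selected, scores=scores)


def mrmr_score(
    relevance: float, redundancies: list[float], quotient: bool
) -> float:
    """Criterion arithmetic on explicit (relevance, redundancy) inputs."""
    red = float(np.mean(redundancies)) if redundancies else 0.0
    if quotient:
        return relevance / max(red, _EPS)
    return relevance - red


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus_select(
    rankings: list[RankingResult],
    X: pd.DataFrame,
    y: np.ndarray,
    m_range: tuple[int, int] = (5, 15),
    cutoffs: tuple[int, ...] = (5, 10, 15),
    seed: int = 0,
    inner_folds: int = 5,
    n_estimators: int = 200,
    per_criterion_only: bool = False,
) -> ConsensusSelection:
    """Frequency consensus over criteria x top-k cutoffs, then pick the set
    size by inner-CV AUC of a seeded forest on the top-m consensus features.

    With ``per_criterion_only`` a feature counts at most once per criterion
    (membership in its deepest cutoff list) instead of once per
    criterion-cutoff pair.
    """
    freq: dict[str, int] = {}
    rank_sum: dict[str, list[int]] = {}
    for r in rankings:
        counted: set[str] = set()
        for k in cutoffs:
            for pos, name in enumerate(r.top(k)):
                if per_criterion_only and name in counted:
                    continue
                freq[name] = freq.get(name, 0) + 1
                counted.add(name)
        for pos, name in enumerate(r.order):
            rank_sum.setdefault(name, []).append(pos)
    mean_rank = {n: float(np.mean(v)) for n, v in rank_sum.items()}
    ordered = sorted(freq, key=lambda n: (-freq[n], mean_rank.get(n, np.inf), n))

    lo, hi = m_range
    if hi > len(ordered):
        log.warning("m_range truncated to %d candidates", len(ordered))
        hi = len(ordered)
        lo = min(lo, hi)

    y = np.asarray(y)
    cv_scores: dict[int, float] = {}
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    for m in range(lo, hi + 1):
        feats = ordered[:m]
        aucs = []
        for tr, te in skf.split(X[feats], y):
            forest = RandomForestClassifier(
                n_estimators=n_estimators, random_state=seed, n_jobs=1
            )
            forest.fit(X[feats].iloc[tr], y[tr])
            prob = forest.predict_proba(X[feats].iloc[te])[:, 1]
            aucs.append(roc_auc_score(y[te], prob))
        cv_scores[m] = float(np.mean(aucs))
    chosen_m = max(cv_scores, key=lambda m: (cv_scores[m], -m))
    return ConsensusSelection(
        frequency=freq,
        chosen_set=ordered[:chosen_m],
        chosen_m=chosen_m,
        cv_scores=cv_scores,
        consensus_order=ordered,
    )
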
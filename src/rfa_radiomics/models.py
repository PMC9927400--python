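"""Clinical screening (univariate -> multivariate logistic), SMOTE balancing,
and the random-forest clinical / radiomics models.

Event coding: the non-CR outcome is the event for screening odds ratios;
model confidences are reported for the CR class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)

LOCATION_LEVELS = ("RUL", "RML", "RLL", "LUL", "LLL")  # RUL is the reference

#: clinical design: how each covariate enters the logistic screen
CONTINUOUS_VARS = ("age", "cea", "ca19_9")
BINARY_VARS = {
    "gender": "male",
    "distance1": "<1cm",
    "distance2": "<1cm",
    "pneumothorax": True,
    "iah": True,
}


@dataclass
class VariableScreen:
    variable: str
    columns: list[str]
    odds_ratios: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_values: dict[str, float]
    p_overall: float
    retained: bool
    penalized: bool = False


@dataclass
class ScreeningResult:
    univariate: dict[str, VariableScreen] = field(default_factory=dict)
    multivariate: dict[str, VariableScreen] = field(default_factory=dict)

    @property
    def retained_univariate(self) -> list[str]:
        return [v for v, s in self.univariate.items() if s.retained]

    @property
    def retained_multivariate(self) -> list[str]:
        return [v for v, s in self.multivariate.items() if s.retained]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage, screens in (("univariate", self.univariate), ("multivariate", self.multivariate)):
            for var, s in screens.items():
                for col in s.columns:
                    rows.append(
                        {
                            "stage": stage,
                            "variable": var,
                            "term": col,
                            "OR": s.odds_ratios[col],
                            "CI_low": s.ci_low[col],
                            "CI_high": s.ci_high[col],
                            "p": s.p_values[col],
                            "p_overall": s.p_overall,
                            "retained": s.retained,
                        }
                    )
        return pd.DataFrame(rows)


def design_matrix(clinical: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Numeric design columns for the requested clinical variables.

    Location is dummy-coded against the RUL reference; binary covariates are
    0/1 indicators of the listed event level.
    """
    cols: dict[str, np.ndarray] = {}
    for var in variables:
        if var in CONTINUOUS_VARS:
            cols[var] = clinical[var].to_numpy(dtype=float)
        elif var == "location":
            for lev in LOCATION_LEVELS[1:]:
                cols[f"location_{lev}"] = (clinical["location"] == lev).to_numpy(dtype=float)
        elif var in BINARY_VARS:
            cols[var] = (clinical[var] == BINARY_VARS[var]).to_numpy(dtype=float)
        else:
            raise KeyError(f"unknown clinical variable {var!r}")
    return pd.DataFrame(cols, index=clinical.index)


def _variable_columns(var: str) -> list[str]:
    if var == "location":
        return [f"location_{lev}" for lev in LOCATION_LEVELS[1:]]
    return [var]


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """ML logit fit; falls back to a ridge-penalized fit under separation."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if np.isfinite(res.bse).all() and (res.bse < 1e3).all():
                return res, False
        except Exception:  # noqa: BLE001 - separation / singular hessian
            pass
    # penalized fallback: sklearn L2 for coefficients, no trustworthy p-values
    clf = LogisticRegression(C=10.0, max_iter=1000)  # L2 by default
    clf.fit(X.to_numpy(), y)

    class _Penalized:
        params = pd.Series(
            np.concatenate([[clf.intercept_[0]], clf.coef_[0]]), index=Xc.columns
        )
        bse = pd.Series(np.full(X.shape[1] + 1, np.nan), index=Xc.columns)
        pvalues = pd.Series(np.ones(X.shape[1] + 1), index=Xc.columns)
        llf = np.nan

    log.warning("logit fell back to penalized fit (possible separation)")
    return _Penalized(), True


def _screen_variable(
    clinical: pd.DataFrame, y: np.ndarray, var: str, alpha: float
) -> VariableScreen | None:
    X = design_matrix(clinical, [var])
    if (X.nunique() <= 1).all():
        log.warning("variable %s constant, skipped", var)
        return None
    res, penalized = _fit_logit(X, y)
    cols = list(X.columns)
    ors = {c: float(np.exp(res.params[c])) for c in cols}
    ci_lo = {c: float(np.exp(res.params[c] - 1.96 * res.bse[c])) for c in cols}
    ci_hi = {c: float(np.exp(res.params[c] + 1.96 * res.bse[c])) for c in cols}
    pvals = {c: float(res.pvalues[c]) for c in cols}
    if len(cols) > 1 and not penalized:
        # multi-level variable: likelihood-ratio test against intercept-only
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
        from scipy.stats import chi2

        lr = 2.0 * (res.llf - null.llf)
        p_overall = float(chi2.sf(max(lr, 0.0), df=len(cols)))
    else:
        p_overall = min(pvals.values())
    return VariableScreen(
        variable=var,
        columns=cols,
        odds_ratios=ors,
        ci_low=ci_lo,
        ci_high=ci_hi,
        p_values=pvals,
        p_overall=p_overall,
        retained=p_overall < alpha,
        penalized=penalized,
    )


def univariate_screen(
    clinical: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    alpha1: float = 0.1,
    variables: tuple[str, ...] | None = None,
) -> ScreeningResult:
    """One logistic fit per clinical variable; retain variables with p < alpha1.

    The event is non-CR. Multi-level location uses a likelihood-ratio overall
    p-value; continuous markers enter per-unit.
    """
    y = _event_vector(labels)
    if len(y) < 50:
        raise ValueError("univariate_screen requires n >= 50")
    if variables is None:
        variables = CONTINUOUS_VARS + ("gender", "location", "distance1", "distance2",
                                       "pneumothorax", "iah")
    result = ScreeningResult()
    for var in variables:
        screen = _screen_variable(clinical, y, var, alpha1)
        if screen is not None:
            result.univariate[var] = screen
    return result


def multivariate_screen(
    clinical: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    candidates: list[str],
    alpha2: float = 0.05,
    result: ScreeningResult | None = None,
) -> ScreeningResult:
    """Joint logistic fit of the univariate-retained variables; retain p < alpha2."""
    y = _event_vector(labels)
    if result is None:
        result = ScreeningResult()
    if not candidates:
        return result
    X = design_matrix(clinical, candidates)
    # drop exactly collinear columns, keeping the earlier one
    keep: list[str] = []
    for c in X.columns:
        sub = X[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(sub) == len(keep) + 1:
            keep.append(c)
        else:
            log.warning("dropping collinear column %s", c)
    X = X[keep]
    res, penalized = _fit_logit(X, y)
    for var in candidates:
        cols = [c for c in _variable_columns(var) if c in X.columns]
        if not cols:
            continue
        ors = {c: float(np.exp(res.params[c])) for c in cols}
        ci_lo = {c: float(np.exp(res.params[c] - 1.96 * res.bse[c])) for c in cols}
        ci_hi = {c: float(np.exp(res.params[c] + 1.96 * res.bse[c])) for c in cols}
        pvals = {c: float(res.pvalues[c]) for c in cols}
        p_overall = min(pvals.values())
        result.multivariate[var] = VariableScreen(
            variable=var,
            columns=cols,
            odds_ratios=ors,
            ci_low=ci_lo,
            ci_high=ci_hi,
            p_values=pvals,
            p_overall=p_overall,
            retained=p_overall < alpha2,
            penalized=penalized,
        )
    return result


def _event_vector(labels) -> np.ndarray:
    """1 for the non-CR event, 0 for CR; accepts strings or 0/1."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == "nonCR").astype(int)
    return arr.astype(int)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_balance(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to the majority count.

    Each synthetic sample is a convex combination of a minority point and one
    of its k minority-class nearest neighbours. Training data only — callers
    must never pass test rows here.
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_balance expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return Xa.copy(), y.copy()
    Xm = Xa[y == minority]
    if n_min < 2:
        raise ValueError("minority class too small for SMOTE")
    if n_min < k + 1:
        k = n_min - 1
        log.warning("SMOTE k reduced to %d (minority size %d)", k, n_min)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)  # skip self at position 0
    lam = rng.uniform(size=n_new)[:, None]
    neighbors = Xm[idx[base, pick]]
    synthetic = Xm[base] + lam * (neighbors - Xm[base])
    X_out = np.vstack([Xa, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# random-forest models
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    kind: str  # "clinical" | "radiomics"
    forest: RandomForestClassifier
    feature_names: list[str]
    positive_class: str = "CR"


def train_rf(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    kind: str,
    seed: int = 0,
    n_estimators: int = 500,
    smote: bool = True,
    smote_k: int = 5,
) -> FittedModel:
    """Seeded forest (``n_estimators`` trees, sqrt-features splits) on
    SMOTE-balanced training data."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data has a single class")
    Xb, yb = (smote_balance(X, y, k=smote_k, seed=seed) if smote
              else (X.to_numpy(dtype=float), y))
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(Xb, yb)
    return FittedModel(kind=kind, forest=forest, feature_names=list(X.columns))


def predict(model: FittedModel, X: pd.DataFrame) -> pd.Series:
    """Per-lesion confidence of the positive (CR) class in [0, 1]."""
    cols = model.feature_names
    probs = model.forest.predict_proba(X[cols].to_numpy(dtype=float))
    classes = list(model.forest.classes_)
    if model.positive_class in classes:
        pos_idx = classes.index(model.positive_class)
    else:  # numeric labels: positive class is 1 -> CR encoded by caller
        pos_idx = classes.index(max(classes))
    return pd.Series(probs[:, pos_idx], index=X.index, name=model.kind)
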
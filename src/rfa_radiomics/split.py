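"""GMM cluster-stratified division of the cohort into 5 groups.

A full-covariance Gaussian mixture is fitted by EM (k-means++ init, multiple
restarts, BIC over a K range) on standardized features; lesions are then dealt
round-robin within each (cluster x class) cell into the groups, and one group
serves as the held-out test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

log = logging.getLogger(__name__)

_RIDGE = 1e-6


@dataclass
class GmmModel:
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray  # (K, d, d)
    log_likelihood_trace: list[float]
    bic: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_scale

    def log_prob(self, X: np.ndarray) -> np.ndarray:
        """Per-sample mixture log-likelihood (on raw, unstandardized features)."""
        return logsumexp(self._log_resp_terms(self._standardize(X)), axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self._log_resp_terms(self._standardize(X)), axis=1)

    def _log_resp_terms(self, Z: np.ndarray) -> np.ndarray:
        n, d = Z.shape
        out = np.empty((n, self.n_components))
        for k in range(self.n_components):
            out[:, k] = np.log(self.weights[k]) + _gauss_logpdf(
                Z, self.means[k], self.covariances[k]
            )
        return out


def _gauss_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    chol = np.linalg.cholesky(cov)
    diff = X - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _em_fit(
    Z: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 200, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    n, d = Z.shape
    centers, _ = kmeans_plusplus(Z, n_clusters=k, random_state=int(rng.integers(2**31)))
    means = centers.copy()
    covs = np.tile(np.cov(Z, rowvar=False, bias=True) + _RIDGE * np.eye(d), (k, 1, 1))
    weights = np.full(k, 1.0 / k)
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        log_terms = np.empty((n, k))
        for j in range(k):
            log_terms[:, j] = np.log(weights[j]) + _gauss_logpdf(Z, means[j], covs[j])
        norm = logsumexp(log_terms, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(log_terms - norm[:, None])
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp.T @ Z) / nk[:, None]
        for j in range(k):
            diff = Z - means[j]
            cov = (resp[:, j, None] * diff).T @ diff / nk[j]
            covs[j] = cov + _RIDGE * np.eye(d)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return weights, means, covs, trace


def fit_gmm(
    features: pd.DataFrame | np.ndarray,
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 200,
) -> GmmModel:
    """EM fit with k-means++ init and restarts; K chosen by BIC.

    Features are z-scored internally; singular covariances are ridge-
    regularized (1e-6 on the diagonal).
    """
    X = np.asarray(features, dtype=float)
    mu = X.mean(axis=0)
    sc = X.std(axis=0)
    sc[sc == 0] = 1.0
    Z = (X - mu) / sc
    n, d = Z.shape
    lo, hi = k_range
    hi = min(hi, max(lo, n // 10))  # need n >= 10 K
    if n < 10 * lo:
        raise ValueError("fit_gmm requires n >= 10 * K")
    rng = np.random.default_rng(seed)
    best: GmmModel | None = None
    for k in range(lo, hi + 1):
        best_k = None
        for _ in range(n_restarts):
            try:
                w, m, c, trace = _em_fit(Z, k, rng, max_iter=max_iter)
            except np.linalg.LinAlgError:
                log.warning("EM restart failed (singular covariance), retrying")
                continue
            if best_k is None or trace[-1] > best_k[3][-1]:
                best_k = (w, m, c, trace)
        if best_k is None:
            continue
        w, m, c, trace = best_k
        n_params = k - 1 + k * d + k * d * (d + 1) // 2
        bic = -2.0 * trace[-1] + n_params * np.log(n)
        model = GmmModel(
            weights=w,
            means=m,
            covariances=c,
            log_likelihood_trace=trace,
            bic=float(bic),
            feature_mean=mu,
            feature_scale=sc,
        )
        if best is None or model.bic < best.bic:
            best = model
    if best is None:
        raise RuntimeError("GMM fitting failed for every K")
    return best


@dataclass
class SplitAssignment:
    table: pd.DataFrame  # index lesion_id; columns cluster, group, role

    def __post_init__(self) -> None:
        roles = set(self.table["role"].unique())
        if not roles <= {"train", "test"}:
            raise ValueError("roles must be train/test")

    @property
    def train_ids(self) -> list[str]:
        return list(self.table.index[self.table["role"] == "train"])

    @property
    def test_ids(self) -> list[str]:
        return list(self.table.index[self.table["role"] == "test"])


def stratified_group_split(
    gmm: GmmModel,
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_groups: int = 5,
    seed: int = 0,
    test_group: int | None = None,
) -> SplitAssignment:
    """Deal lesions round-robin into ``n_groups`` within (cluster x class)
    cells after a seeded shuffle; one group (by seed unless ``test_group``
    given) becomes the test set.
    """
    ids = np.asarray(features.index)
    y = np.asarray(labels)
    clusters = gmm.predict(features.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    group = np.empty(len(ids), dtype=int)
    # the round-robin position continues across cells of the same class, so
    # per-group counts of each class are balanced to +/-1 globally, not just
    # within each (cluster x class) cell
    for cls in np.unique(y):
        pos = int(rng.integers(n_groups))
        for c in np.unique(clusters):
            cell = np.flatnonzero((clusters == c) & (y == cls))
            perm = rng.permutation(len(cell))
            for idx in cell[perm]:
                group[idx] = pos % n_groups + 1
                pos += 1
    test = int(rng.integers(1, n_groups + 1)) if test_group is None else int(test_group)
    if not 1 <= test <= n_groups:
        raise ValueError("test_group out of range")
    table = pd.DataFrame(
        {
            "cluster": clusters,
            "group": group,
            "role": np.where(group == test, "test", "train"),
        },
        index=pd.Index(ids, name="lesion_id"),
    )
    return SplitAssignment(table=table)
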
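"""Common Components Analysis with iterated salience weights.

The model extracts orthogonal components from a column-centered matrix
``X`` (samples x variables).  Each variable ``x_j`` is treated as its own
block and carries a non-negative weight, the *salience* ``lambda_j``.  A
component is a fixed point of the alternation

    W = sum_j lambda_j x_j x_j^T          (salience-weighted association)
    t = dominant unit-norm eigenvector of W
    lambda_j  proportional to  (x_j^T t)^2,   sum_j lambda_j = 1

so that variables dispersing the samples in the same way end up sharing a
component with large saliences.  After each component the working matrix is
deflated by projection, ``X <- X - t t^T X``.

Scores are ``t * sqrt(mu)`` with ``mu`` the dominant eigenvalue of ``W``;
loadings are ``X^T t`` against the working matrix the component was
extracted from.  The per-variable covariance and correlation with the
scores (the S-plot coordinates) drive variable selection: a variable is
selected when its absolute covariance exceeds one standard deviation of the
covariance vector.

Everything here is deterministic: saliences start uniform and no random
numbers are used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io_formats import ValidationError
from .preprocess import ScaledMatrix


class ConvergenceWarning(UserWarning):
    """Salience iteration did not reach the fixed point within max_iter."""


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class CommonComponentsAnalysis(TransformerMixin, BaseEstimator):
    """Salience-weighted common components decomposition.

    Parameters
    ----------
    n_components : int, default 2
        Number of components to extract; must not exceed
        ``min(n_samples - 1, n_variables)``.
    tol : float, default 1e-10
        Convergence threshold: maximum absolute change of the salience
        vector between successive iterations.
    max_iter : int, default 500
        Iteration cap per component; hitting it flags the component as
        unconverged but still returns it.
    center_tol : float, default 1e-6
        Largest tolerated absolute column mean of the input.

    Attributes
    ----------
    scores_ : ndarray (n_samples, n_components)
        Component scores ``t_c * sqrt(mu_c)``; columns mutually orthogonal.
    loadings_ : ndarray (n_features, n_components)
        ``X_c^T t_c`` with ``X_c`` the working matrix for component c.
    saliences_ : ndarray (n_features, n_components)
        Converged non-negative weights; each column sums to 1.
    explained_ : ndarray (n_components,)
        Fraction of the initial squared Frobenius norm removed by each
        component's deflation.
    n_iter_ : ndarray of int
    converged_ : ndarray of bool
    working_matrices_ : list of ndarray
        Working matrix as it stood when each component was extracted
        (pre-deflation); used for S-plot covariances.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-10,
                 max_iter: int = 500, center_tol: float = 1e-6):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.center_tol = center_tol

    def fit(self, X, y=None):
        index = columns = None
        if isinstance(X, pd.DataFrame):
            index, columns = X.index, X.columns
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("expected a 2-D samples x variables matrix")
        n, p = arr.shape
        means = arr.mean(axis=0)
        if np.abs(means).max() > self.center_tol:
            raise ValidationError(
                f"input is not column-centered (max |column mean| = {np.abs(means).max():.3g})"
            )
        if not 1 <= self.n_components <= min(n - 1, p):
            raise ValidationError(
                f"n_components={self.n_components} outside [1, min(n_samples-1, n_vars)]"
            )

        K = self.n_components
        total = float((arr ** 2).sum())
        Xw = arr.copy()
        scores = np.zeros((n, K))
        loadings = np.zeros((p, K))
        saliences = np.zeros((p, K))
        explained = np.zeros(K)
        n_iter = np.zeros(K, dtype=int)
        converged = np.zeros(K, dtype=bool)
        working = []

        for c in range(K):
            working.append(Xw.copy())
            t, mu, lam, its, ok = self._extract_component(Xw)
            if not ok:
                warnings.warn(
                    f"component {c + 1} did not converge in {self.max_iter} iterations",
                    ConvergenceWarning,
                )
            load = Xw.T @ t
            # orient so the largest-|.| loading is positive (first index on ties)
            pivot = int(np.argmax(np.abs(load)))
            if load[pivot] < 0:
                t = -t
                load = -load
            scores[:, c] = t * np.sqrt(max(mu, 0.0))
            loadings[:, c] = load
            saliences[:, c] = lam
            before = float((Xw ** 2).sum())
            Xw = Xw - np.outer(t, t) @ Xw
            after = float((Xw ** 2).sum())
            explained[c] = (before - after) / total if total > 0 else 0.0
            n_iter[c] = its
            converged[c] = ok

        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(columns) if columns is not None else None
        self.sample_index_ = index
        self.scores_ = scores
        self.loadings_ = loadings
        self.saliences_ = saliences
        self.explained_ = explained
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.working_matrices_ = working
        # linear map from centered data to scores, for out-of-sample projection
        self.projection_ = np.linalg.pinv(arr) @ scores
        return self

    def _extract_component(self, Xw: np.ndarray):
        n, p = Xw.shape
        lam = np.full(p, 1.0 / p)
        t = np.zeros(n)
        mu = 0.0
        for it in range(1, self.max_iter + 1):
            W = (Xw * lam) @ Xw.T
            vals, vecs = linalg.eigh(W)
            mu = vals[-1]
            t = vecs[:, -1]
            contrib = (Xw.T @ t) ** 2
            s = contrib.sum()
            lam_new = contrib / s if s > 0 else np.full(p, 1.0 / p)
            delta = np.abs(lam_new - lam).max()
            lam = lam_new
            if delta < self.tol:
                return t, mu, lam, it, True
        return t, mu, lam, self.max_iter, False

    def transform(self, X):
        """Project (already centered) data onto the fitted components."""
        check_is_fitted(self, "projection_")
        arr = np.asarray(X, dtype=float)
        return arr @ self.projection_

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.scores_


# ---------------------------------------------------------------------------
# Domain types and wrappers
# ---------------------------------------------------------------------------

@dataclass
class CcaModel:
    """Fitted CCA with labelled result tables."""

    scores: pd.DataFrame     # samples x CC1..CCK
    loadings: pd.DataFrame   # otus x CC1..CCK
    saliences: pd.DataFrame  # otus x CC1..CCK, columns sum to 1
    explained: pd.Series     # fraction of total variation per component
    iterations: pd.Series
    converged: pd.Series
    tol: float
    max_iter: int
    working_matrices: list = field(default_factory=list, repr=False)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    @property
    def otu_ids(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class SPlotData:
    """Per-variable covariance/correlation with a component's scores."""

    component: int
    covariance: pd.Series
    correlation: pd.Series
    zero_variance: pd.Series  # flag: correlation undefined, reported as 0

    def __post_init__(self) -> None:
        corr = self.correlation.to_numpy()
        if np.any(np.abs(corr) > 1 + 1e-9):
            raise ValidationError("correlations outside [-1, 1]")


@dataclass
class SelectionResult:
    """OTUs passing the S-plot covariance threshold, per component."""

    tables: dict[int, pd.DataFrame]  # component -> (otu_id, covariance, correlation, sign)
    thresholds: dict[int, float]

    @property
    def n_components(self) -> int:
        return len(self.tables)

    def otus(self, component: int) -> list[str]:
        return list(self.tables[component]["otu_id"])


def component_columns(k: int) -> list[str]:
    return [f"CC{i + 1}" for i in range(k)]


def fit_cca(X: ScaledMatrix, n_components: int = 2, tol: float = 1e-10,
            max_iter: int = 500) -> CcaModel:
    """Step 2b: fit the salience-weighted common components model."""
    est = CommonComponentsAnalysis(n_components=n_components, tol=tol, max_iter=max_iter)
    est.fit(X.values)
    cols = component_columns(n_components)
    return CcaModel(
        scores=pd.DataFrame(est.scores_, index=X.values.index, columns=cols),
        loadings=pd.DataFrame(est.loadings_, index=X.values.columns, columns=cols),
        saliences=pd.DataFrame(est.saliences_, index=X.values.columns, columns=cols),
        explained=pd.Series(est.explained_, index=cols),
        iterations=pd.Series(est.n_iter_, index=cols),
        converged=pd.Series(est.converged_, index=cols),
        tol=tol,
        max_iter=max_iter,
        working_matrices=[
            pd.DataFrame(w, index=X.values.index, columns=X.values.columns)
            for w in est.working_matrices_
        ],
    )


def splot(X: pd.DataFrame, scores_c: pd.Series | np.ndarray, component: int = 1) -> SPlotData:
    """S-plot coordinates of every variable against one component's scores.

    ``X`` is the working matrix as it stood when the component was extracted.
    ``cov_j = sum_i x_ij t_i / (n - 1)``; ``corr_j = cov_j / (sd_j sd_t)``.
    """
    arr = np.asarray(X, dtype=float)
    t = np.asarray(scores_c, dtype=float)
    n = arr.shape[0]
    sd_t = t.std(ddof=1)
    if sd_t == 0:
        raise ValidationError("component scores have zero variance")
    cov = arr.T @ t / (n - 1)
    sd_x = arr.std(axis=0, ddof=1)
    zero = sd_x == 0
    corr = np.zeros_like(cov)
    nz = ~zero
    corr[nz] = cov[nz] / (sd_x[nz] * sd_t)
    corr = np.clip(corr, -1.0, 1.0)
    idx = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(arr.shape[1])
    return SPlotData(
        component=component,
        covariance=pd.Series(cov, index=idx),
        correlation=pd.Series(corr, index=idx),
        zero_variance=pd.Series(zero, index=idx),
    )


def select_otus(sp: SPlotData, center: str = "zero") -> tuple[pd.DataFrame, float]:
    """Select variables whose |covariance| exceeds one sd of the covariances.

    ``center='zero'`` (default) uses a symmetric band about zero,
    ``|cov_j| > sd(cov)``; ``center='mean'`` bands about the mean covariance
    instead.  The sd uses the n-1 denominator over all variables of the
    component.  When sd(cov) = 0 (all covariances equal) nothing is selected.
    """
    cov = sp.covariance.to_numpy()
    if cov.size < 2:
        raise ValidationError("need at least 2 variables for selection")
    sd = cov.std(ddof=1)
    if center == "zero":
        mask = np.abs(cov) > sd if sd > 0 else np.zeros_like(cov, dtype=bool)
    elif center == "mean":
        mask = np.abs(cov - cov.mean()) > sd if sd > 0 else np.zeros_like(cov, dtype=bool)
    else:
        raise ValueError(f"unknown center mode: {center!r}")
    table = pd.DataFrame(
        {
            "otu_id": sp.covariance.index[mask],
            "covariance": cov[mask],
            "correlation": sp.correlation.to_numpy()[mask],
            "sign": np.sign(cov[mask]).astype(int),
        }
    ).reset_index(drop=True)
    return table, float(sd)


def select_components(model: CcaModel, center: str = "zero",
                      against: str = "working") -> SelectionResult:
    """Run S-plot selection for every component of a fitted model.

    ``against='working'`` (default) computes covariances on the working
    matrix as of each component's extraction; ``against='original'`` uses
    the undeflated input matrix for every component.
    """
    tables: dict[int, pd.DataFrame] = {}
    thresholds: dict[int, float] = {}
    for c in range(model.n_components):
        X = model.working_matrices[0] if against == "original" else model.working_matrices[c]
        sp = splot(X, model.scores.iloc[:, c], component=c + 1)
        table, sd = select_otus(sp, center=center)
        tables[c + 1] = table
        thresholds[c + 1] = sd
    return SelectionResult(tables=tables, thresholds=thresholds)
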
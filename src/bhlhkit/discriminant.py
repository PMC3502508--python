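"""Canonical Variate Analysis and StepWise Discriminant Analysis.

Both methods operate on factor-score datasets (rows = sequences, columns =
(site, factor) variables) with Kingdom labels.

CVA solves the generalized eigenproblem ``B a = lambda W a`` (B = between-
group SSCP, W = within-group SSCP), yielding G-1 canonical variates scaled
to unit pooled within-group variance.  Group separation is summarized by
Wilks' lambda (det W / det T), squared canonical correlations
``rho_i^2 = lambda_i / (1 + lambda_i)``, their average (ASCC = Pillai's
trace / (G-1)), and Mahalanobis distances under the pooled within-group
covariance.  Classification assigns each gap-free sequence to the Kingdom
with the highest posterior ``prior_g * exp(-d_g^2 / 2)``; a sequence missing
any model variable is left UNCLASSIFIED.

SWDA is an entry-only (step-up) greedy selection: at each step the candidate
variable minimizing Wilks' lambda of the enlarged model enters, tracked by
its partial r^2, F-to-enter, and the cumulative ASCC; selection stops at an
ASCC target, a step limit, or when no candidate is significant at the
entry threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Hashable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .alignment import UNCLASSIFIED


class SingularMatrixError(np.linalg.LinAlgError):
    """Raised when W or T is singular; names likely collinear variables."""


# ---------------------------------------------------------------------------
# sums of squares and cross-products


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def _complete_cases(X: pd.DataFrame, y: pd.Series | Sequence) -> tuple[pd.DataFrame, pd.Series]:
    y = pd.Series(np.asarray(y, dtype=object), index=X.index, name="label")
    mask = X.notna().all(axis=1) & y.notna()
    return X.loc[mask], y.loc[mask]


def _sscp(X: pd.DataFrame, y: pd.Series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Within-group (W), between-group (B) and total (T) SSCP matrices."""
    Xv = X.to_numpy(dtype=float)
    grand = Xv.mean(axis=0)
    p = Xv.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in pd.unique(y):
        Xg = Xv[(y == g).to_numpy()]
        mg = Xg.mean(axis=0)
        C = Xg - mg
        W += C.T @ C
        d = (mg - grand)[:, None]
        B += len(Xg) * (d @ d.T)
    Tc = Xv - grand
    T = Tc.T @ Tc
    return W, B, T


def _collinearity_diagnostic(X: pd.DataFrame, M: np.ndarray) -> str:
    """Name variables loading on the near-null space of a singular SSCP."""
    evals, evecs = np.linalg.eigh(M)
    v = np.abs(evecs[:, 0])
    worst = [str(X.columns[i]) for i in np.argsort(v)[::-1][:3]]
    zero_var = [str(c) for c, d in zip(X.columns, np.diag(M)) if d <= 1e-12]
    parts = [f"variables most involved: {worst}"]
    if zero_var:
        parts.append(f"zero-variance within groups: {zero_var}")
    return "; ".join(parts)


def _logdet_pd(X: pd.DataFrame, M: np.ndarray, name: str) -> float:
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        raise SingularMatrixError(
            f"{name} SSCP matrix is singular ({_collinearity_diagnostic(X, M)})"
        )
    return logdet


def wilks_lambda(X, y) -> float:
    """Wilks' lambda = det(W) / det(T) on complete cases.

    1 means no group-mean separation; values near 0 mean strong separation.
    """
    X, y = _complete_cases(_as_frame(X), y)
    G = y.nunique()
    if len(X) <= G + X.shape[1]:
        raise ValueError(
            f"need more than G + p = {G + X.shape[1]} complete cases, got {len(X)}"
        )
    W, _, T = _sscp(X, y)
    return float(np.exp(_logdet_pd(X, W, "within-group") - _logdet_pd(X, T, "total")))


def _cva_eig(W: np.ndarray, B: np.ndarray, n_keep: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues/vectors of W^-1 B via the symmetric generalized problem.

    Returns the top ``n_keep`` eigenvalues (non-increasing) and vectors
    normalized so that a' W a = 1.
    """
    evals, evecs = linalg.eigh(B, W)
    order = np.argsort(evals)[::-1][:n_keep]
    lam = np.clip(evals[order], 0.0, None)
    A = evecs[:, order]
    # deterministic sign: largest-|coefficient| entry positive
    for j in range(A.shape[1]):
        k = int(np.argmax(np.abs(A[:, j])))
        if A[k, j] < 0:
            A[:, j] = -A[:, j]
    return lam, A


def ascc(X, y, ridge: float = 0.0) -> float:
    """Average Squared Canonical Correlation = Pillai's trace / (G - 1).

    0 means no discrimination; 1 would mean complete discrimination.
    """
    X, y = _complete_cases(_as_frame(X), y)
    G = y.nunique()
    W, B, _ = _sscp(X, y)
    W = _ridge(W, ridge, len(X))
    try:
        lam, _ = _cva_eig(W, B, G - 1)
    except linalg.LinAlgError as exc:
        raise SingularMatrixError(
            f"within-group SSCP singular ({_collinearity_diagnostic(X, W)})"
        ) from exc
    rho2 = lam / (1.0 + lam)
    return float(rho2.sum() / (G - 1))


def _ridge(W: np.ndarray, ridge: float, n: int) -> np.ndarray:
    if ridge > 0:
        return W + ridge * np.diag(np.diag(W)) / n
    return W


# ---------------------------------------------------------------------------
# Canonical Variate Analysis


class CanonicalVariateClassifier(ClassifierMixin, BaseEstimator):
    """Canonical variate analysis with Mahalanobis-distance classification.

    Parameters
    ----------
    priors : "uniform", "proportional", or dict
        Class prior probabilities.  Uniform by default.
    ridge : float
        Optional diagonal ridge ``ridge * diag(W) / n`` added to the
        within-group SSCP.  Off (0.0) by default: a singular W raises
        :class:`SingularMatrixError` rather than silently regularizing.

    Attributes
    ----------
    classes_ : ndarray of group names (sorted)
    coef_ : (p, G-1) canonical coefficients, unit pooled within-group
        variance per variate
    eigenvalues_ : eigenvalues of W^-1 B, non-increasing
    canonical_corr_sq_ : squared canonical correlations lambda/(1+lambda)
    proportions_ : per-variate share of sum(lambda)
    means_ : (G, p) group means in the original variable space
    centroids_ : (G, G-1) group centroids in canonical space
    pooled_cov_ : (p, p) pooled within-group covariance W / (n - G)
    n_complete_ : number of complete-case rows used for fitting
    """

    def __init__(self, priors: Any = "uniform", ridge: float = 0.0):
        self.priors = priors
        self.ridge = ridge

    def fit(self, X, y) -> "CanonicalVariateClassifier":
        X = _as_frame(X)
        self.feature_names_ = list(X.columns)
        Xc, yc = _complete_cases(X, y)
        classes = np.array(sorted(pd.unique(yc)))
        G = len(classes)
        if G < 2:
            raise ValueError("need at least 2 groups")
        p = Xc.shape[1]
        if len(Xc) < G + p:
            raise ValueError(
                f"need at least G + p = {G + p} complete cases, got {len(Xc)}"
            )
        W, B, _ = _sscp(Xc, yc)
        W = _ridge(W, self.ridge, len(Xc))
        try:
            lam, A = _cva_eig(W, B, G - 1)
        except linalg.LinAlgError as exc:
            raise SingularMatrixError(
                "within-group SSCP singular; consider the ridge option "
                f"({_collinearity_diagnostic(Xc, W)})"
            ) from exc
        n = len(Xc)
        self.classes_ = classes
        self.n_features_in_ = p
        self.n_complete_ = n
        # eigh normalizes a' W a = 1; rescale to a' S_W a = 1, S_W = W/(n-G)
        self.coef_ = A * np.sqrt(n - G)
        self.eigenvalues_ = lam
        self.canonical_corr_sq_ = lam / (1.0 + lam)
        tot = lam.sum()
        self.proportions_ = lam / tot if tot > 0 else np.zeros_like(lam)
        self.means_ = pd.DataFrame(
            [Xc.loc[(yc == g).to_numpy()].mean(axis=0).to_numpy() for g in classes],
            index=classes,
            columns=X.columns,
        )
        self.grand_mean_ = Xc.mean(axis=0).to_numpy()
        self.pooled_cov_ = W / (n - G)
        self._cov_cho = linalg.cho_factor(self.pooled_cov_)
        self.centroids_ = (self.means_.to_numpy() - self.grand_mean_) @ self.coef_
        self.priors_ = self._resolve_priors(yc, classes)
        return self

    def _resolve_priors(self, y: pd.Series, classes: np.ndarray) -> np.ndarray:
        if isinstance(self.priors, str):
            if self.priors == "uniform":
                return np.full(len(classes), 1.0 / len(classes))
            if self.priors == "proportional":
                counts = y.value_counts()
                pr = np.array([counts[g] for g in classes], dtype=float)
                return pr / pr.sum()
            raise ValueError(f"unknown priors {self.priors!r}")
        pr = np.array(
            [self.priors[g] for g in classes]
            if isinstance(self.priors, dict)
            else self.priors,
            dtype=float,
        )
        return pr / pr.sum()

    # -- geometry ----------------------------------------------------------

    def _check_X(self, X) -> np.ndarray:
        X = _as_frame(X)
        if list(X.columns) != self.feature_names_ and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} variables {self.feature_names_}, "
                f"got {X.shape[1]}"
            )
        return X.to_numpy(dtype=float)

    def transform(self, X) -> np.ndarray:
        """Canonical scores (centered at the training grand mean)."""
        return (self._check_X(X) - self.grand_mean_) @ self.coef_

    def mahalanobis(self, X, squared: bool = False) -> pd.DataFrame:
        """Distance of each row to each group mean under the pooled
        within-group covariance.  Rows with missing values get NaN."""
        Xv = self._check_X(X)
        out = np.full((len(Xv), len(self.classes_)), np.nan)
        ok = ~np.isnan(Xv).any(axis=1)
        for j, g in enumerate(self.classes_):
            diff = Xv[ok] - self.means_.loc[g].to_numpy()
            sol = linalg.cho_solve(self._cov_cho, diff.T)
            out[ok, j] = np.einsum("ij,ji->i", diff, sol)
        if not squared:
            out = np.sqrt(out)
        idx = X.index if isinstance(X, pd.DataFrame) else None
        return pd.DataFrame(out, columns=self.classes_, index=idx)

    def mahalanobis_between(self, g: Hashable, h: Hashable) -> float:
        """sqrt Mahalanobis distance between two group centroids."""
        diff = (self.means_.loc[g] - self.means_.loc[h]).to_numpy()
        d2 = float(diff @ linalg.cho_solve(self._cov_cho, diff))
        return float(np.sqrt(max(d2, 0.0)))

    def pairwise_distances(self) -> pd.DataFrame:
        """Square table of sqrt Mahalanobis distances between centroids."""
        G = len(self.classes_)
        out = np.zeros((G, G))
        for i, g in enumerate(self.classes_):
            for j, h in enumerate(self.classes_):
                if i < j:
                    out[i, j] = out[j, i] = self.mahalanobis_between(g, h)
        return pd.DataFrame(out, index=self.classes_, columns=self.classes_)

    # -- classification ----------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """Posterior per class, prior_g * exp(-d_g^2/2) normalized; rows
        with any missing variable get NaN posteriors."""
        d2 = self.mahalanobis(X, squared=True).to_numpy()
        out = np.full_like(d2, np.nan)
        ok = ~np.isnan(d2).any(axis=1)
        z = -0.5 * d2[ok] + np.log(self.priors_)
        z -= z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        out[ok] = ez / ez.sum(axis=1, keepdims=True)
        return out

    def predict(self, X) -> np.ndarray:
        """Class label per row; UNCLASSIFIED where any variable is missing."""
        proba = self.predict_proba(X)
        out = np.full(len(proba), UNCLASSIFIED, dtype=object)
        ok = ~np.isnan(proba).any(axis=1)
        out[ok] = self.classes_[np.argmax(proba[ok], axis=1)]
        return out

    def classification_report(self, X) -> pd.DataFrame:
        """Per-sequence report: prediction, sqrt distances, posteriors."""
        dist = self.mahalanobis(X)
        proba = self.predict_proba(X)
        rep = pd.DataFrame(index=dist.index)
        rep["predicted"] = self.predict(X)
        for j, g in enumerate(self.classes_):
            rep[f"dist_{g}"] = dist[g].to_numpy()
            rep[f"prob_{g}"] = proba[:, j]
        return rep

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": [list(v) if isinstance(v, tuple) else v for v in self.feature_names_],
            "classes": self.classes_.tolist(),
            "priors": self.priors_.tolist(),
            "coefficients": self.coef_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "means": self.means_.to_numpy().tolist(),
            "grand_mean": self.grand_mean_.tolist(),
            "pooled_covariance": self.pooled_cov_.tolist(),
            "n_complete": self.n_complete_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CanonicalVariateClassifier":
        model = cls()
        model.feature_names_ = [
            tuple(v) if isinstance(v, list) else v for v in d["variables"]
        ]
        model.classes_ = np.array(d["classes"])
        model.priors_ = np.array(d["priors"], dtype=float)
        model.coef_ = np.array(d["coefficients"], dtype=float)
        model.eigenvalues_ = np.array(d["eigenvalues"], dtype=float)
        model.canonical_corr_sq_ = model.eigenvalues_ / (1 + model.eigenvalues_)
        tot = model.eigenvalues_.sum()
        model.proportions_ = model.eigenvalues_ / tot if tot > 0 else model.eigenvalues_
        model.means_ = pd.DataFrame(
            np.array(d["means"], dtype=float),
            index=model.classes_,
            columns=pd.Index(model.feature_names_),
        )
        model.grand_mean_ = np.array(d["grand_mean"], dtype=float)
        model.pooled_cov_ = np.array(d["pooled_covariance"], dtype=float)
        model._cov_cho = linalg.cho_factor(model.pooled_cov_)
        model.centroids_ = (model.means_.to_numpy() - model.grand_mean_) @ model.coef_
        model.n_complete_ = d["n_complete"]
        model.n_features_in_ = len(model.feature_names_)
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "CanonicalVariateClassifier":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_cva(X, y, priors: Any = "uniform", ridge: float = 0.0) -> CanonicalVariateClassifier:
    return CanonicalVariateClassifier(priors=priors, ridge=ridge).fit(X, y)


# ---------------------------------------------------------------------------
# StepWise Discriminant Analysis


class StepwiseDiscriminantSelector(BaseEstimator):
    """Entry-only stepwise variable selection minimizing Wilks' lambda.

    Parameters
    ----------
    ascc_target : float
        Stop once the cumulative ASCC of the selected set reaches this
        value (0.70 for single-factor datasets, 0.80 for the combined set).
    max_steps : int
    entry_alpha : float
        Significance-to-enter on the F-to-enter statistic.

    Attributes
    ----------
    steps_ : DataFrame with one row per entered variable: variable, Wilks'
        lambda after entry, partial r^2, F-to-enter, p-value, cumulative
        ASCC.
    selected_ : list of entered variable names, in entry order.
    stopping_reason_ : "ascc_target", "max_steps", or "entry_threshold".
    """

    def __init__(self, ascc_target: float = 0.70, max_steps: int = 20, entry_alpha: float = 0.15):
        self.ascc_target = ascc_target
        self.max_steps = max_steps
        self.entry_alpha = entry_alpha

    def fit(self, X, y) -> "StepwiseDiscriminantSelector":
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        X = _as_frame(X)
        self.feature_names_ = list(X.columns)
        Xc, yc = _complete_cases(X, y)
        Xv = Xc.to_numpy(dtype=float)
        yv = yc
        n = len(Xc)
        G = yv.nunique()
        cols = list(Xc.columns)

        selected: list[int] = []
        rows = []
        lam_current = 1.0
        reason = "entry_threshold"
        while len(selected) < self.max_steps:
            remaining = [j for j in range(len(cols)) if j not in selected]
            if not remaining:
                reason = "exhausted_variables"
                break
            lams = np.array(
                [self._wilks(Xv[:, selected + [j]], yv) for j in remaining]
            )
            k = int(np.nanargmin(lams))
            lam_new = float(lams[k])
            j_best = remaining[k]
            r2 = 1.0 - lam_new / lam_current
            m = len(selected)
            df2 = n - G - m
            if df2 <= 0:
                reason = "insufficient_cases"
                break
            if r2 >= 1.0:
                F = np.inf
                pval = 0.0
            elif r2 <= 0.0:
                F, pval = 0.0, 1.0
            else:
                F = (df2 / (G - 1)) * r2 / (1.0 - r2)
                pval = float(stats.f.sf(F, G - 1, df2))
            if pval > self.entry_alpha:
                reason = "entry_threshold"
                break
            selected.append(j_best)
            lam_current = lam_new
            a = ascc(Xc.iloc[:, selected], yv)
            var = cols[j_best]
            site, factor = (var if isinstance(var, tuple) else (var, None))
            rows.append(
                {
                    "step": len(selected),
                    "variable": var,
                    "site": site,
                    "factor": factor,
                    "wilks_lambda": lam_current,
                    "partial_r2": r2,
                    "F": F,
                    "p_value": pval,
                    "ascc": a,
                }
            )
            if a >= self.ascc_target:
                reason = "ascc_target"
                break
        else:
            reason = "max_steps"

        self.steps_ = pd.DataFrame(
            rows,
            columns=[
                "step", "variable", "site", "factor",
                "wilks_lambda", "partial_r2", "F", "p_value", "ascc",
            ],
        )
        self.selected_ = [cols[j] for j in selected]
        self.stopping_reason_ = reason
        self.support_ = np.array([c in self.selected_ for c in self.feature_names_])
        return self

    @staticmethod
    def _wilks(Xsub: np.ndarray, y: pd.Series) -> float:
        df = pd.DataFrame(Xsub)
        W, _, T = _sscp(df, y.reset_index(drop=True))
        sw, lw = np.linalg.slogdet(W)
        st, lt = np.linalg.slogdet(T)
        if sw <= 0 or st <= 0:
            return np.nan
        return float(np.exp(lw - lt))

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X)
        return X[self.selected_]


def fit_swda(
    X, y, ascc_target: float = 0.70, max_steps: int = 20, entry_alpha: float = 0.15
) -> StepwiseDiscriminantSelector:
    return StepwiseDiscriminantSelector(
        ascc_target=ascc_target, max_steps=max_steps, entry_alpha=entry_alpha
    ).fit(X, y)


def swda_to_classifier(
    X, y, swda: StepwiseDiscriminantSelector, priors: Any = "uniform", ridge: float = 0.0
) -> CanonicalVariateClassifier:
    """CVA restricted to the SWDA-selected variables.  Classification then
    tolerates gaps at non-selected sites."""
    if not swda.selected_:
        raise ValueError("stepwise selection entered no variables")
    return fit_cva(_as_frame(X)[swda.selected_], y, priors=priors, ridge=ridge)


def _var_site(v) -> Hashable:
    return v[0] if isinstance(v, tuple) else v


def discerning_sites(swda: StepwiseDiscriminantSelector, r2_threshold: float = 0.20) -> list:
    """Sites whose entry partial r^2 exceeds the threshold (deduplicated)."""
    hits = swda.steps_.loc[swda.steps_["partial_r2"] > r2_threshold, "variable"]
    return sorted({_var_site(v) for v in hits})


def cv_top_sites(
    model: CanonicalVariateClassifier, magnitude_threshold: float = 1.0
) -> dict[int, list]:
    """Per canonical variate: sites with |raw coefficient| > threshold."""
    out: dict[int, list] = {}
    for j in range(model.coef_.shape[1]):
        sites = {
            _var_site(v)
            for v, c in zip(model.feature_names_, model.coef_[:, j])
            if abs(c) > magnitude_threshold
        }
        out[j + 1] = sorted(sites)
    return out
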
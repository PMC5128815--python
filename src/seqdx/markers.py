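"""Receptor-status prediction models and ROC machinery.

ER, PR and HER2 status are modeled by univariate logistic regression on the
log2 expression of the corresponding gene (ESR1, PGR, ERBB2); Ki-67 percent
by a linear elastic net over all genes.  Performance is always estimated by
nested cross-validation: the outer folds provide out-of-fold scores from
models whose training and tuning never saw the scored sample, while the
penalty strength lambda is tuned in inner folds on outer-training data
only.  The elastic-net mixing weight alpha defaults to 0.5.

ROC analysis uses probability scores (predicted percent for the linear
Ki-67 model); the operating point is the curve point with minimal Euclidean
distance to the top-left corner.  Two cohorts' AUCs are compared with the
unpaired DeLong test based on placement-value variance estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import ConfigurationError, DegenerateDataError
from .expression import ExpressionMatrix

MARKER_GENE = {"ER": "ESR1", "PR": "PGR", "HER2": "ERBB2"}

# Tiny ridge on the slope so that perfectly separable data still yield
# finite maximum-penalized-likelihood estimates.
_SEPARATION_RIDGE = 1e-8


# --------------------------------------------------------------------------
# Single-gene logistic models
# --------------------------------------------------------------------------

@dataclass
class BinaryMarkerModel:
    marker: str
    gene: str
    intercept: float
    slope: float
    probability_boundary: Optional[float] = None

    def predict_proba(self, values) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(values, dtype=float))

    def predict_status(self, values) -> np.ndarray:
        if self.probability_boundary is None:
            raise ConfigurationError(
                f"{self.marker} model has no probability boundary; call optimal_boundary first"
            )
        return self.predict_proba(values) > self.probability_boundary


def fit_single_gene_logistic(values, labels, marker: str = "", gene: str = "") -> BinaryMarkerModel:
    """Maximum-likelihood logistic fit of binary ``labels`` on one gene.

    A 1e-8 ridge on the slope guards against separation.  The predictor is
    centered internally for conditioning; returned coefficients are on the
    original scale.
    """
    x = np.asarray(values, dtype=float)
    y = _binary_labels(labels)
    if len(x) != len(y):
        raise ConfigurationError("values and labels differ in length")
    if len(y) < 4:
        raise DegenerateDataError("at least 4 samples are required")
    if y.min() == y.max():
        raise DegenerateDataError("both classes must be present in labels")

    xm = x.mean()
    xc = x - xm
    b = np.array([logit(y.mean()), 0.0])  # (intercept, slope) in centered coords
    X = np.column_stack([np.ones_like(xc), xc])
    penalty = np.array([0.0, _SEPARATION_RIDGE])
    for _ in range(200):
        eta = X @ b
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = X.T @ (y - mu) - penalty * b
        hess = (X * w[:, None]).T @ X + np.diag(penalty)
        step = np.linalg.solve(hess, grad)
        b = b + step
        if np.max(np.abs(step)) < 1e-12:
            break
    intercept = float(b[0] - b[1] * xm)
    return BinaryMarkerModel(marker=marker, gene=gene, intercept=intercept, slope=float(b[1]))


# --------------------------------------------------------------------------
# Elastic net
# --------------------------------------------------------------------------

@dataclass
class PenalizedModel:
    """Elastic-net model over genes.  ``coef`` is on the original (log2)
    scale; predictors were standardized internally during fitting."""

    genes: list[str]
    coef: np.ndarray
    intercept: float
    alpha: float
    lam: float
    family: str  # "linear" | "binomial"

    @property
    def active_genes(self) -> list[str]:
        return [g for g, c in zip(self.genes, self.coef) if c != 0.0]

    def linear_predictor(self, m: ExpressionMatrix) -> pd.Series:
        sub = m.subset_genes(self.genes)
        eta = sub.values.to_numpy(dtype=float).T @ self.coef + self.intercept
        return pd.Series(eta, index=sub.sample_ids)

    def predict(self, m: ExpressionMatrix) -> pd.Series:
        """Predicted response: probability (binomial) or mean (linear)."""
        eta = self.linear_predictor(m)
        return expit(eta) if self.family == "binomial" else eta


def default_lambda_grid(X: np.ndarray, y: np.ndarray, family: str, alpha: float,
                        n_lambda: int = 50, ratio: Optional[float] = None) -> np.ndarray:
    """Log-spaced grid from lambda_max (smallest lambda with all gene
    coefficients zero) down by ``ratio`` (glmnet-style defaults: 1e-4, or
    1e-2 when there are more genes than samples)."""
    Xs, *_ = _standardize(X)
    n, p = X.shape
    if ratio is None:
        ratio = 1e-4 if n > p else 1e-2
    resid = y - y.mean()
    a = max(alpha, 1e-3)
    lam_max = np.max(np.abs(Xs.T @ resid)) / (n * a)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def fit_elastic_net(m: ExpressionMatrix, response, family: str = "binomial",
                    alpha: float = 0.5, lambda_grid: Optional[Sequence[float]] = None,
                    inner_folds: int = 5, seed: int = 0, n_lambda: int = 50,
                    tol: float = 1e-6) -> PenalizedModel:
    """Fit an elastic net with lambda chosen by inner cross-validation.

    The grid (default: 50 log-spaced values from lambda_max down by 1e-4)
    is scored by mean inner-CV deviance (squared error for the linear
    family); the model is then refit on all provided data at the selected
    lambda.  Ties prefer the larger (more parsimonious) lambda.
    """
    if m.scale != "log2":
        raise ConfigurationError("fit_elastic_net expects a log2-scale matrix")
    X = m.values.to_numpy(dtype=float).T  # samples x genes
    if family == "binomial":
        y = _binary_labels(response)
        if y.min() == y.max():
            raise DegenerateDataError("both classes must be present in response")
    elif family == "linear":
        y = np.asarray(response, dtype=float)
    else:
        raise ConfigurationError(f"unknown family {family!r}")
    n = X.shape[0]
    if lambda_grid is None:
        grid = default_lambda_grid(X, y, family, alpha, n_lambda=n_lambda)
    else:
        grid = np.sort(np.asarray(list(lambda_grid), dtype=float))[::-1]
    if len(grid) == 0:
        raise ConfigurationError("lambda_grid must be non-empty")

    if len(grid) > 1:
        if n < inner_folds:
            raise DegenerateDataError(
                f"n={n} is smaller than inner_folds={inner_folds}"
            )
        deviance = np.zeros(len(grid))
        splitter = (StratifiedKFold(inner_folds, shuffle=True, random_state=seed)
                    if family == "binomial"
                    else KFold(inner_folds, shuffle=True, random_state=seed))
        for train, val in splitter.split(X, y if family == "binomial" else None):
            path = _fit_path(X[train], y[train], family, alpha, grid, tol=max(tol, 1e-5))
            for gi, (coef, b0) in enumerate(path):
                eta = X[val] @ coef + b0
                deviance[gi] += _deviance(y[val], eta, family)
        deviance /= inner_folds
        # first index = largest lambda; argmin takes it on exact ties
        best = grid[int(np.argmin(deviance))]
    else:
        best = grid[0]

    coef, b0 = _fit_path(X, y, family, alpha, np.asarray([g for g in grid if g >= best]),
                         tol=tol)[-1]
    return PenalizedModel(genes=list(m.gene_ids), coef=coef, intercept=b0,
                          alpha=alpha, lam=float(best), family=family)


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd, sd_safe


def _fit_path(X, y, family, alpha, grid, tol):
    """Fit along a descending lambda path with warm starts; returns a list
    of (coef_original_scale, intercept) per lambda.

    The binomial family uses the classic penalized-IRLS scheme: outer
    Newton steps on the log-likelihood, each solving a weighted elastic-net
    least-squares subproblem (working response z, weights mu(1-mu) rescaled
    to sum to n) by coordinate descent, warm-started across both IRLS
    iterations and the lambda path.
    """
    Xs, mean, sd, sd_safe = _standardize(X)
    n = X.shape[0]
    out = []
    if family == "linear":
        est = ElasticNet(alpha=float(grid[0]) or 1e-12, l1_ratio=alpha, fit_intercept=True,
                         warm_start=True, max_iter=20000, tol=tol)
        for lam in grid:
            est.set_params(alpha=max(lam, 1e-12))
            est.fit(Xs, y)
            out.append(_unstandardize(est.coef_.copy(), float(est.intercept_),
                                      mean, sd, sd_safe))
        return out

    p0 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    coef = np.zeros(Xs.shape[1])
    b0 = float(logit(p0))
    inner = ElasticNet(alpha=float(grid[0]) or 1e-12, l1_ratio=alpha, fit_intercept=True,
                       warm_start=True, max_iter=3000, tol=1e-5)
    null_dev = _deviance(y, np.full(n, logit(p0)), "binomial")
    for gi, lam in enumerate(grid):
        inner.set_params(alpha=max(lam, 1e-12))
        for _ in range(15):
            eta = np.clip(Xs @ coef + b0, -30.0, 30.0)
            mu = np.clip(expit(eta), 1e-5, 1.0 - 1e-5)
            w = mu * (1.0 - mu)
            z = eta + (y - mu) / w
            inner.fit(Xs, z, sample_weight=w * (n / w.sum()))
            step = max(abs(float(inner.intercept_) - b0),
                       float(np.max(np.abs(inner.coef_ - coef), initial=0.0)))
            coef = inner.coef_.copy()
            b0 = float(inner.intercept_)
            if step < max(tol, 1e-9):
                break
            if np.abs(coef).max(initial=0.0) > 1e3:
                break  # separation: log-odds saturated, stop refining
        sol = _unstandardize(coef.copy(), b0, mean, sd, sd_safe)
        out.append(sol)
        # deviance saturation: once the fit is essentially perfect, smaller
        # lambdas only overfit further; reuse the solution (glmnet-style
        # early path exit)
        dev = _deviance(y, np.clip(Xs @ coef + b0, -30.0, 30.0), "binomial")
        if null_dev > 0 and dev / null_dev < 0.01:
            out.extend([sol] * (len(grid) - gi - 1))
            break
    return out


def _unstandardize(coef_std, b0_std, mean, sd, sd_safe):
    coef = np.where(sd > 0, coef_std / sd_safe, 0.0)
    b0 = b0_std - float(np.dot(coef, mean))
    return coef, b0


def _deviance(y, eta, family) -> float:
    if family == "linear":
        return float(np.sum((y - eta) ** 2))
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


# --------------------------------------------------------------------------
# Nested cross-validation
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """What to fit inside each outer training fold.

    kind: "single_gene_logistic" (requires ``gene``) or "elastic_net".
    For elastic nets, ``family`` selects binomial (status) or linear
    (Ki-67 percent) modeling; lambda is tuned in the inner folds.
    """

    kind: str
    gene: Optional[str] = None
    family: str = "binomial"
    alpha: float = 0.5
    n_lambda: int = 50
    tol: float = 1e-5


def nested_cv_scores(m: ExpressionMatrix, labels, model_spec: ModelSpec,
                     outer_k: int = 5, inner_k: int = 5, seed: int = 0):
    """Out-of-fold score per sample from nested cross-validation.

    Every sample is scored exactly once, by a model whose training and
    lambda tuning never saw it.  Returns ``(scores, fold_assignment)`` as
    Series indexed by sample id; scores are probabilities for
    classification models and predicted values for linear models.
    """
    if outer_k < 2 or inner_k < 2:
        raise ConfigurationError("outer_k and inner_k must both be >= 2")
    classification = not (model_spec.kind == "elastic_net" and model_spec.family == "linear")
    samples = np.array(m.sample_ids)
    y = _binary_labels(_align(labels, samples)) if classification else np.asarray(
        _align(labels, samples), dtype=float)
    X = m.values  # genes x samples DataFrame
    scores = pd.Series(np.nan, index=samples, dtype=float)
    folds = pd.Series(-1, index=samples, dtype=int)
    splitter = (StratifiedKFold(outer_k, shuffle=True, random_state=seed)
                if classification else KFold(outer_k, shuffle=True, random_state=seed))
    for fold, (train, test) in enumerate(splitter.split(samples, y if classification else None)):
        if classification and y[train].min() == y[train].max():
            raise DegenerateDataError(
                "a class is absent from an outer training fold; use fewer folds"
            )
        m_train = ExpressionMatrix(X.iloc[:, train], scale=m.scale)
        m_test = ExpressionMatrix(X.iloc[:, test], scale=m.scale)
        if model_spec.kind == "single_gene_logistic":
            if model_spec.gene is None:
                raise ConfigurationError("single_gene_logistic spec requires a gene")
            model = fit_single_gene_logistic(
                m_train.values.loc[model_spec.gene].to_numpy(), y[train],
                gene=model_spec.gene)
            pred = model.predict_proba(m_test.values.loc[model_spec.gene].to_numpy())
        elif model_spec.kind == "elastic_net":
            model = fit_elastic_net(
                m_train, y[train], family=model_spec.family, alpha=model_spec.alpha,
                inner_folds=inner_k, seed=seed + 1000 * (fold + 1),
                n_lambda=model_spec.n_lambda, tol=model_spec.tol)
            pred = model.predict(m_test).to_numpy()
        else:
            raise ConfigurationError(f"unknown model spec kind {model_spec.kind!r}")
        scores.iloc[test] = pred
        folds.iloc[test] = fold
    return scores, folds


# --------------------------------------------------------------------------
# ROC machinery
# --------------------------------------------------------------------------

@dataclass
class RocCurve:
    """Ordered ROC points; fpr/tpr non-decreasing with endpoints (0,0) and
    (1,1).  ``thresholds[0]`` is +inf (the classify-nothing point)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr})


def roc_points(scores, labels) -> RocCurve:
    """ROC curve with one step per distinct score value (ties grouped)."""
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise DegenerateDataError("both classes must be present for a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # guaranteed by construction, kept as guard
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
        thr = np.append(thr, -np.inf)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr)


def auc_score(scores, labels) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the fraction of (positive, negative) pairs ranked correctly,
    with 0.5 credit for ties.
    """
    curve = roc_points(scores, labels)
    return float(np.trapezoid(curve.tpr, curve.fpr))


def optimal_boundary(curve: RocCurve) -> float:
    """Threshold of the curve point with minimal Euclidean distance to the
    top-left corner; exact distance ties resolve to the lower-fpr point."""
    d2 = curve.fpr ** 2 + (1.0 - curve.tpr) ** 2
    best = d2.min()
    candidates = np.nonzero(d2 <= best + 1e-15)[0]
    idx = candidates[np.argmin(curve.fpr[candidates])]
    return float(curve.thresholds[idx])


# --------------------------------------------------------------------------
# DeLong AUC comparison
# --------------------------------------------------------------------------

@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    z: float
    p_two_sided: float


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """(AUC, variance) via DeLong placement values for one cohort."""
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise DegenerateDataError("both classes must be present")
    pos = s[y == 1]
    neg = s[y == 0]
    m_, n_ = len(pos), len(neg)
    cmp_ = (pos[:, None] > neg[None, :]).astype(float)
    cmp_ += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_.mean(axis=1)  # placement of each positive among negatives
    v01 = cmp_.mean(axis=0)
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m_ > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n_ > 1 else 0.0
    return auc, s10 / m_ + s01 / n_


def delong_compare(scores_a, labels_a, scores_b, labels_b) -> AucComparison:
    """Unpaired DeLong test comparing the AUCs of two independent cohorts."""
    auc_a, var_a = delong_auc_variance(scores_a, labels_a)
    auc_b, var_b = delong_auc_variance(scores_b, labels_b)
    tot = var_a + var_b
    if tot <= 0.0:
        if auc_a == auc_b:
            z = 0.0
        else:
            raise DegenerateDataError(
                "zero combined variance with unequal AUCs (degenerate separation)"
            )
    else:
        z = (auc_a - auc_b) / np.sqrt(tot)
    p = float(2.0 * norm.sf(abs(z)))
    return AucComparison(auc_a=auc_a, auc_b=auc_b, var_a=var_a, var_b=var_b,
                         z=float(z), p_two_sided=p)


def auc_confidence_interval(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """DeLong-based normal-approximation CI: (auc, lower, upper)."""
    auc, var = delong_auc_variance(scores, labels)
    half = norm.ppf(0.5 + level / 2.0) * np.sqrt(var)
    return auc, max(0.0, auc - half), min(1.0, auc + half)


# --------------------------------------------------------------------------

def _binary_labels(labels) -> np.ndarray:
    """Coerce labels to 0/1.  Accepts booleans, 0/1 ints, '+'/'-',
    'positive'/'negative', 'high'/'low'."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr.astype(int)
    if np.issubdtype(arr.dtype, np.number):
        vals = set(np.unique(arr).tolist())
        if not vals <= {0, 1, 0.0, 1.0}:
            raise ConfigurationError(f"numeric labels must be 0/1, got {sorted(vals)}")
        return arr.astype(int)
    mapping = {"+": 1, "-": 0, "positive": 1, "negative": 0, "high": 1, "low": 0,
               "1": 1, "0": 0, "true": 1, "false": 0}
    try:
        return np.array([mapping[str(v).strip().lower() if str(v) not in "+-" else str(v)]
                         for v in arr], dtype=int)
    except KeyError as exc:
        raise ConfigurationError(f"unrecognized label {exc.args[0]!r}") from None


def _align(labels, samples: np.ndarray):
    if isinstance(labels, pd.Series):
        return labels.loc[list(samples)].to_numpy()
    if isinstance(labels, dict):
        return np.array([labels[s] for s in samples])
    return labels
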
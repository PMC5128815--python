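"""Composite transcriptomic grade (TG) model.

Three binomial elastic nets are fitted, one per Nottingham grade
subcomponent (mitotic count, nuclear atypia, tubular formation), each
trained only on tumors scored 1 or 3 for that component (event = score 3).
The TG score of a tumor is the sum of the three predicted probabilities,
so it lies in [0, 3]; the low/high decision boundary on the summed score
is placed at the ROC operating point (minimal distance to the top-left
corner) computed from nested-cross-validated scores of overall grade 1 vs
grade 3 tumors.  Grade 2 tumors, which carry no actionable information on
their own, are then reclassified into low and high TG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError, DegenerateDataError
from .expression import ExpressionMatrix
from .markers import PenalizedModel, fit_elastic_net, optimal_boundary, roc_points

COMPONENTS = ("mitotic", "nuclear_atypia", "tubular_formation")


@dataclass
class GradeComponentModel:
    component: str
    model: PenalizedModel  # binomial; event = component score 3
    n_trained: int
    n_excluded_score2: int  # audit: intermediate tumors left out of training


@dataclass
class TgModel:
    components: dict[str, GradeComponentModel]
    score_boundary: Optional[float] = None
    cv_scores: Optional[pd.Series] = None  # nested-CV summed scores (grade 1/3)
    cv_labels: Optional[pd.Series] = None

    @property
    def genes(self) -> list[str]:
        return self.components[COMPONENTS[0]].model.genes


@dataclass
class ReclassificationTable:
    """Counts of samples by histological grade (1/2/3) x TG (low/high)."""

    counts: pd.DataFrame  # index 1..3, columns ["low", "high"]

    @property
    def grade2_split(self) -> dict[str, float]:
        row = self.counts.loc[2]
        tot = int(row.sum())
        out = {"low": int(row["low"]), "high": int(row["high"]), "n": tot}
        if tot:
            out["pct_low"] = 100.0 * row["low"] / tot
            out["pct_high"] = 100.0 * row["high"] / tot
        return out


@dataclass
class TgCvConfig:
    outer_k: int = 5
    inner_k: int = 5
    alpha: float = 0.5
    n_lambda: int = 50
    tol: float = 1e-5
    seed: int = 0


def _component_model(m: ExpressionMatrix, scores: pd.Series, component: str,
                     cv: TgCvConfig, seed_offset: int = 0) -> GradeComponentModel:
    scores = scores.loc[m.sample_ids]
    extreme = scores.isin([1, 3])
    if not (scores == 1).any() or not (scores == 3).any():
        raise DegenerateDataError(
            f"component {component!r} lacks samples at both scores 1 and 3"
        )
    sub = ExpressionMatrix(m.values.loc[:, extreme[extreme].index], scale=m.scale)
    y = (scores[extreme] == 3).to_numpy().astype(int)
    model = fit_elastic_net(sub, y, family="binomial", alpha=cv.alpha,
                            inner_folds=cv.inner_k, seed=cv.seed + seed_offset,
                            n_lambda=cv.n_lambda, tol=cv.tol)
    return GradeComponentModel(component=component, model=model,
                               n_trained=int(extreme.sum()),
                               n_excluded_score2=int((scores == 2).sum()))


def fit_tg_model(m: ExpressionMatrix, subcomponent_scores: pd.DataFrame,
                 overall_grades: pd.Series, cv_config: Optional[TgCvConfig] = None) -> TgModel:
    """Fit the three component models and place the score boundary.

    ``subcomponent_scores`` must have one column per component (values in
    {1,2,3}); ``overall_grades`` the 1-3 histological grade.  The boundary
    comes from nested-CV summed scores of grade 1 vs grade 3 tumors, so it
    is set on predictions from models that never saw the scored tumor.
    """
    cv = cv_config or TgCvConfig()
    if m.scale != "log2":
        raise ConfigurationError("fit_tg_model expects a log2-scale matrix")
    missing = [c for c in COMPONENTS if c not in subcomponent_scores.columns]
    if missing:
        raise ConfigurationError(f"subcomponent_scores missing columns: {missing}")

    components = {
        c: _component_model(m, subcomponent_scores[c], c, cv, seed_offset=i + 1)
        for i, c in enumerate(COMPONENTS)
    }

    overall = overall_grades.loc[m.sample_ids]
    g13 = overall.isin([1, 3])
    ids13 = list(overall[g13].index)
    y13 = (overall[g13] == 3).astype(int)
    cv_scores = _nested_cv_summed_scores(m, subcomponent_scores, ids13, y13, cv)
    curve = roc_points(cv_scores.to_numpy(), y13.loc[cv_scores.index].to_numpy())
    boundary = optimal_boundary(curve)

    return TgModel(components=components, score_boundary=float(boundary),
                   cv_scores=cv_scores, cv_labels=y13.loc[cv_scores.index])


def _nested_cv_summed_scores(m: ExpressionMatrix, subcomponent_scores: pd.DataFrame,
                             ids13: list[str], y13: pd.Series, cv: TgCvConfig) -> pd.Series:
    """Out-of-fold summed scores for grade 1/3 samples: within each outer
    fold the three component models are refitted on outer-training samples
    only (each on its own score-1/3 subset)."""
    ids13 = np.array(ids13)
    y = y13.loc[ids13].to_numpy()
    out = pd.Series(np.nan, index=ids13, dtype=float)
    splitter = StratifiedKFold(cv.outer_k, shuffle=True, random_state=cv.seed)
    all_ids = np.array(m.sample_ids)
    for fold, (train, test) in enumerate(splitter.split(ids13, y)):
        if y[train].min() == y[train].max():
            raise DegenerateDataError("a grade is absent from an outer training fold")
        # outer-training pool: every sample not in this test fold (component
        # training sets are defined by component scores, not overall grade)
        test_ids = set(ids13[test])
        train_ids = [s for s in all_ids if s not in test_ids]
        m_train = ExpressionMatrix(m.values.loc[:, train_ids], scale=m.scale)
        m_test = ExpressionMatrix(m.values.loc[:, list(ids13[test])], scale=m.scale)
        fold_cv = TgCvConfig(outer_k=cv.outer_k, inner_k=cv.inner_k, alpha=cv.alpha,
                             n_lambda=cv.n_lambda, tol=cv.tol,
                             seed=cv.seed + 7919 * (fold + 1))
        total = np.zeros(len(test))
        for i, c in enumerate(COMPONENTS):
            comp = _component_model(m_train, subcomponent_scores[c], c, fold_cv,
                                    seed_offset=i + 1)
            total += comp.model.predict(m_test).to_numpy()
        out.loc[ids13[test]] = total
    return out


def tg_scores(model: TgModel, m: ExpressionMatrix) -> pd.Series:
    """Summed score (in [0, 3]) per sample: p_mitotic + p_nuclear + p_tubular.

    Genes used by the model must all be present; there is no silent
    imputation of missing genes.
    """
    missing = [g for g in model.genes if g not in m.values.index]
    if missing:
        raise ConfigurationError(f"matrix is missing model genes: {', '.join(missing)}")
    total = None
    for c in COMPONENTS:
        p = model.components[c].model.predict(m)
        total = p if total is None else total + p
    total.name = "tg_score"
    return total


def classify_tg(model: TgModel, m: ExpressionMatrix) -> pd.Series:
    """Per-sample low/high TG call: high iff score > boundary (a score
    exactly on the boundary is conservatively called low)."""
    if model.score_boundary is None:
        raise ConfigurationError("TG model has no score boundary set")
    s = tg_scores(model, m)
    return pd.Series(np.where(s > model.score_boundary, "high", "low"),
                     index=s.index, name="tg_class")


def reclassification_table(model: TgModel, m: ExpressionMatrix,
                           grades: pd.Series) -> ReclassificationTable:
    """Cross-tabulate histological grade 1-3 against low/high TG."""
    calls = classify_tg(model, m)
    grades = grades.loc[calls.index]
    bad = set(grades.unique()) - {1, 2, 3}
    if bad:
        raise ConfigurationError(f"grades outside {{1,2,3}}: {sorted(bad)}")
    counts = pd.DataFrame(0, index=[1, 2, 3], columns=["low", "high"])
    for g in (1, 2, 3):
        for cls in ("low", "high"):
            counts.loc[g, cls] = int(((grades == g) & (calls == cls)).sum())
    return ReclassificationTable(counts=counts)


def write_tg_model(model: TgModel, path) -> None:
    """Serialize as TSV of (component, gene, coefficient) for non-zero
    coefficients, with intercepts, lambdas and the boundary in header
    comments."""
    with open(path, "w") as fh:
        fh.write(f"# score_boundary={model.score_boundary!r}\n")
        for c in COMPONENTS:
            pm = model.components[c].model
            fh.write(f"# {c}: intercept={pm.intercept!r} lambda={pm.lam!r} "
                     f"alpha={pm.alpha!r} n_excluded_score2={model.components[c].n_excluded_score2}\n")
        fh.write("component\tgene\tcoefficient\n")
        for c in COMPONENTS:
            pm = model.components[c].model
            for g, coef in zip(pm.genes, pm.coef):
                if coef != 0.0:
                    fh.write(f"{c}\t{g}\t{coef!r}\n")
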
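"""Expression -> drug-sensitivity transfer by ridge regression.

A model is trained on cell-line expression against a per-line response
(log-IC50-like), then applied to a tumor cohort; a lower predicted
score means higher predicted sensitivity. Group comparison of predicted
scores between high/low infiltration uses the moderated t across drugs.

Cross-dataset batch homogenization is deliberately out of scope; the
model standardizes genes on the training set and applies the stored
transform to the cohort, which absorbs per-gene affine differences but
not more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .data import ExpressionMatrix
from .stats import GroupComparisonResult, moderated_t, group_tests, bh_fdr

logger = logging.getLogger(__name__)

#: default regularization grid, log-spaced
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2, 4, 13))


@dataclass
class DrugModel:
    """A fitted ridge transfer model for one drug."""

    drug: str
    genes: list[str]
    weights: np.ndarray          # on standardized genes
    intercept: float
    lambda_: float
    train_mean: np.ndarray       # per-gene standardization, training set
    train_sd: np.ndarray
    n_lines: int
    n_genes: int
    cv_error: float              # mean CV squared error at the chosen lambda

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights).all():
            raise ValueError("model weights must be finite")
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")


def _ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form (X'X + lam I)^-1 X'y; lstsq fallback at lam = 0."""
    k = X.shape[1]
    if lam == 0:
        return np.linalg.lstsq(X, y, rcond=None)[0]
    return np.linalg.solve(X.T @ X + lam * np.eye(k), X.T @ y)


def fit_ridge_transfer(
    train_expr: ExpressionMatrix,
    response: pd.Series,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    cv_folds: int = 5,
    seed: Optional[int] = 0,
    drug: str = "drug",
) -> DrugModel:
    """Fit a ridge model of response on standardized gene expression.

    Genes are standardized to mean 0, sd 1 on the training set (the
    transform is stored in the model); genes with sd < 1e-8 are
    dropped. Lambda is chosen by minimum mean squared error over
    ``cv_folds``-fold cross-validation with a seeded shuffle, then the
    model is refit on all lines at that lambda. The intercept is the
    mean response (standardized predictors are centered).
    """
    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ValueError("empty lambda grid")
    if any(l < 0 for l in lambda_grid):
        raise ValueError("lambda values must be >= 0")
    lines = train_expr.sample_ids
    y = response.reindex(lines).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("response missing for some training lines")
    if np.std(y) == 0:
        raise ValueError("constant training response")
    n = len(lines)
    if n < cv_folds:
        raise ValueError(f"{n} training lines but {cv_folds} CV folds")

    X_raw = train_expr.values().T  # lines x genes
    sd = X_raw.std(axis=0, ddof=0)
    keep = sd >= 1e-8
    if (~keep).any():
        logger.info("fit_ridge_transfer: dropping %d low-variance gene(s)", int((~keep).sum()))
    if not keep.any():
        raise ValueError("no gene with usable variance")
    genes = [g for g, k in zip(train_expr.gene_ids, keep) if k]
    mu = X_raw[:, keep].mean(axis=0)
    sigma = X_raw[:, keep].std(axis=0, ddof=0)
    X = (X_raw[:, keep] - mu) / sigma
    yc = y - y.mean()

    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X))
    cv_err = np.zeros(len(lambda_grid))
    for i, lam in enumerate(lambda_grid):
        sq = 0.0
        for tr, te in folds:
            beta = _ridge_solve(X[tr], yc[tr] - yc[tr].mean(), lam)
            pred = X[te] @ beta + yc[tr].mean()
            sq += float(((yc[te] - pred) ** 2).sum())
        cv_err[i] = sq / n
    best = int(np.argmin(cv_err))
    lam = float(lambda_grid[best])
    beta = _ridge_solve(X, yc, lam)
    return DrugModel(
        drug=drug, genes=genes, weights=beta, intercept=float(y.mean()),
        lambda_=lam, train_mean=mu, train_sd=sigma,
        n_lines=n, n_genes=len(genes), cv_error=float(cv_err[best]),
    )


@dataclass
class DrugSensitivityTable:
    """Predicted sensitivity scores, samples x drugs.

    The orientation flag records that a *lower* score predicts *higher*
    sensitivity (log-IC50 semantics).
    """

    scores: pd.DataFrame
    orientation: str = "lower_is_sensitive"

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("sensitivity scores must be finite")
        if self.orientation != "lower_is_sensitive":
            raise ValueError("orientation flag must be 'lower_is_sensitive'")


def predict_sensitivity(model: DrugModel, cohort: ExpressionMatrix) -> pd.Series:
    """Apply a fitted model to a cohort.

    Cohort genes are standardized with the stored training transform.
    Model genes absent from the cohort are imputed at the training mean
    (standardized value 0), which contributes nothing to the score; the
    imputation count is logged. No overlap at all is an error.
    """
    index = set(cohort.data.index)
    present = [g for g in model.genes if g in index]
    if not present:
        raise ValueError(f"no model gene of drug {model.drug!r} present in the cohort")
    n_missing = len(model.genes) - len(present)
    if n_missing:
        logger.info(
            "predict_sensitivity[%s]: %d/%d model genes missing; imputed at training mean",
            model.drug, n_missing, len(model.genes),
        )
    pos = {g: i for i, g in enumerate(model.genes)}
    rows = [pos[g] for g in present]
    Xc = cohort.data.loc[present].to_numpy(dtype=float).T  # samples x present genes
    Z = (Xc - model.train_mean[rows]) / model.train_sd[rows]
    scores = model.intercept + Z @ model.weights[rows]
    return pd.Series(scores, index=cohort.sample_ids, name=model.drug)


def predict_sensitivity_table(
    models: Sequence[DrugModel], cohort: ExpressionMatrix
) -> DrugSensitivityTable:
    cols = {m.drug: predict_sensitivity(m, cohort) for m in models}
    return DrugSensitivityTable(scores=pd.DataFrame(cols))


def compare_sensitivity(
    table: DrugSensitivityTable, labels: Sequence[str]
) -> pd.DataFrame:
    """Per-drug high-vs-low comparison of predicted sensitivity.

    logFC = mean(high) - mean(low) of the predicted (log-scale) scores;
    with the lower-is-sensitive orientation, logFC > 0 means the
    high-infiltration group is predicted more resistant. Inference is
    the moderated t across drugs; with a single drug it falls back to
    the ordinary Student t with a warning.
    """
    scores = table.scores.T  # drugs x samples
    lab = np.asarray(labels)
    high = scores.loc[:, lab == "high"]
    low = scores.loc[:, lab == "low"]
    if high.shape[1] == 0 or low.shape[1] == 0:
        raise ValueError("both groups must be non-empty")
    logfc = high.mean(axis=1) - low.mean(axis=1)
    if scores.shape[0] == 1:
        logger.warning("compare_sensitivity: single drug; ordinary Student t")
        stat, p = group_tests(scores.iloc[0].to_numpy(), lab, test="student_t")
        out = pd.DataFrame(
            {"logFC": logfc, "t": stat, "p": p, "q": bh_fdr([p])}, index=scores.index
        )
    else:
        res: GroupComparisonResult = moderated_t(scores, lab)
        out = res.table[["t", "p", "q"]].copy()
        out.insert(0, "logFC", logfc)
    out["direction"] = np.where(
        out["logFC"] > 0, "more_resistant_in_high", "more_sensitive_in_high"
    )
    return out
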
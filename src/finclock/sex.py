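"""Methylation-based sex classification.

A binomial elastic net (mixing alpha = 0.5) on CpG beta values, with sex
encoded 0 = female, 1 = male.  All samples of known sex enter with unit
weight; the penalty is selected by n-fold (= leave-one-out) internal
cross-validation on the binomial deviance, and the final model is fitted
on all samples (no outer cross-validation — reported accuracy is
resubstitution accuracy unless the caller evaluates otherwise).  A sample
is called male iff its predicted male probability strictly exceeds the
decision threshold (default 0.5); a probability of exactly 0.5 is female.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import BetaMatrix, CoefficientTable, SampleSheet
from .linear_model import ElasticNetConfig, LogisticElasticNetCD
from .clock import _linear_predictor

__all__ = [
    "MethylationSexClassifier",
    "SexModel",
    "train_sex",
    "predict_sex",
]


@dataclass
class SexModel:
    """A trained sex predictor: sparse coefficients plus the threshold."""

    table: CoefficientTable
    threshold: float
    n_samples: int
    lam: float
    n_nonzero: int

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.table.cpg_ids)


class MethylationSexClassifier(ClassifierMixin, BaseEstimator):
    """Binomial elastic net over beta values (sklearn interface).

    ``fit(X, y)`` takes samples x CpGs and labels in {"F", "M"} (or
    {0, 1}, female first); ``predict_proba`` returns female/male columns
    and ``predict`` applies the strict > ``threshold`` rule for male.
    """

    def __init__(
        self,
        alpha: float = 0.5,
        lam: float | None = None,
        n_lambda: int = 100,
        lambda_min_ratio: float | None = None,
        cv_folds: int | None = None,
        use_1se: bool = False,
        threshold: float = 0.5,
        tol: float = 1e-7,
        max_iter: int = 100_000,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.lam = lam
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv_folds = cv_folds
        self.use_1se = use_1se
        self.threshold = threshold
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        self.enet_ = LogisticElasticNetCD(
            alpha=self.alpha, lam=self.lam, n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio, cv_folds=self.cv_folds,
            use_1se=self.use_1se, tol=self.tol, max_iter=self.max_iter,
            standardize=self.standardize, random_state=self.random_state,
        ).fit(X, y, sample_weight=sample_weight)
        self.classes_ = self.enet_.classes_
        self.coef_ = self.enet_.coef_
        self.intercept_ = self.enet_.intercept_
        self.lambda_ = self.enet_.lambda_
        self.n_nonzero_ = self.enet_.n_nonzero_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        return self.enet_.predict_proba(X)

    def predict(self, X):
        p_male = self.predict_proba(X)[:, 1]
        # strictly greater: exactly at threshold is called female
        return np.where(p_male > self.threshold, self.classes_[1], self.classes_[0])


def train_sex(
    beta: BetaMatrix,
    sheet: SampleSheet,
    config: ElasticNetConfig | None = None,
    threshold: float = 0.5,
) -> SexModel:
    """Train the sex predictor on all samples with known sex, unit weights.

    Raises on single-sex input.
    """
    cfg = config or ElasticNetConfig()
    df = sheet.data
    known = df.index[df["sex"].notna()]
    usable = [s for s in known if s in beta.sample_ids]
    if len(usable) < 4:
        raise ValueError("sex training needs at least 4 samples of known sex")
    sub = beta.select_samples(usable)
    y = df.loc[usable, "sex"].astype(str).to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("both sexes must be present in the training data")
    clf = MethylationSexClassifier(
        alpha=cfg.alpha, lam=cfg.lam, n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio, cv_folds=cfg.cv_folds,
        use_1se=cfg.use_1se, threshold=threshold, tol=cfg.tol,
        max_iter=cfg.max_iter, standardize=cfg.standardize,
    ).fit(sub.samples_by_cpgs(), y)
    entries = {
        str(beta.cpg_ids[j]): float(clf.coef_[j])
        for j in np.flatnonzero(clf.coef_)
    }
    table = CoefficientTable(
        intercept=clf.intercept_, entries=entries, model_kind="sex",
        metadata={"threshold": threshold},
    )
    return SexModel(
        table=table, threshold=threshold, n_samples=len(usable),
        lam=clf.lambda_, n_nonzero=clf.n_nonzero_,
    )


def predict_sex(
    model: SexModel, beta: BetaMatrix, impute_missing: bool = False
) -> pd.DataFrame:
    """Per-sample male probability and F/M label for a beta matrix.

    probability = logistic(intercept + sum_j coef_j beta_ji); the label is
    male iff probability strictly exceeds the model threshold.
    """
    eta = _linear_predictor(model.table, beta, impute_missing)
    p_male = expit(eta)
    return pd.DataFrame(
        {
            "prob_male": p_male,
            "predicted_sex": np.where(p_male > model.threshold, "M", "F"),
        },
        index=pd.Index(beta.sample_ids, name="sample_id"),
    )


def model_from_table(table: CoefficientTable) -> SexModel:
    """Rebuild a :class:`SexModel` from a saved coefficient table."""
    return SexModel(
        table=table,
        threshold=float(table.metadata.get("threshold", 0.5)),
        n_samples=0,
        lam=float("nan"),
        n_nonzero=len(table),
    )
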
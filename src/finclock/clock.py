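"""Epigenetic age clock: training, LOOCV evaluation, application.

The clock is a weighted elastic net (mixing alpha = 0.5) regressing
log-linear-transformed chronological age on CpG beta values.  Samples are
weighted by the accuracy of their observational age estimate: ages known
to +/-1 year weigh 1.0, +/-2 years weigh 0.5, and anything less accurate
is excluded.  The penalty is selected once by leave-one-out internal
cross-validation on the full weighted training set; the LOOCV evaluation
then refits at that fixed penalty with each sample held out in turn, and
its predicted transformed age is mapped back to years.  Accuracy is
summarized by the Pearson correlation r between predicted and observed
age, the median absolute error (MAE) in years, and the least-squares line
of predicted on observed age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .age_transform import AgeTransform, NoTransform
from .io import BetaMatrix, CoefficientTable, SampleSheet
from .linear_model import (
    ElasticNetCD,
    ElasticNetConfig,
    _gaussian_path,
    _lambda_max,
    cv_select_lambda,
)

__all__ = [
    "EpigeneticAgeClock",
    "ClockModel",
    "LoocvResult",
    "EvaluationReport",
    "accuracy_weights",
    "train_clock",
    "loocv_predict",
    "apply_clock",
    "evaluate",
]

MIN_TRAINING_SAMPLES = 10


@dataclass
class EvaluationReport:
    """Prediction accuracy summary.

    r: Pearson correlation of predicted vs observed age (NaN when either
    vector has zero variance); mae: median absolute error in years;
    slope/intercept: ordinary least squares of predicted on observed.
    """

    r: float
    mae: float
    slope: float
    intercept: float
    n: int

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "mae": self.mae,
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
        }


@dataclass
class ClockModel:
    """A trained age clock: sparse coefficients plus its age transform."""

    table: CoefficientTable
    transform: AgeTransform | NoTransform
    n_samples: int
    lam: float
    n_nonzero: int

    @property
    def cpg_ids(self) -> list[str]:
        return self.table.cpg_ids


@dataclass
class LoocvResult:
    """Per-sample LOOCV predictions and their accuracy summary."""

    predictions: pd.DataFrame  # columns: observed, predicted
    report: EvaluationReport
    lam: float

    def to_dict(self) -> dict:
        return {
            "lam": self.lam,
            "report": self.report.to_dict(),
            "predictions": self.predictions.reset_index().to_dict(orient="list"),
        }


class EpigeneticAgeClock(RegressorMixin, BaseEstimator):
    """Elastic-net age clock on beta values (sklearn interface).

    ``fit(X, y)`` takes a samples-x-CpGs matrix and ages in years; ages
    are mapped through the log-linear transform (knot at ``adult_age``)
    before the penalized fit, and ``predict`` maps back to years.  With
    ``lam=None`` the penalty is chosen by leave-one-out internal CV.
    """

    def __init__(
        self,
        alpha: float = 0.5,
        lam: float | None = None,
        n_lambda: int = 100,
        lambda_min_ratio: float | None = None,
        cv_folds: int | None = None,
        use_1se: bool = False,
        adult_age: float = 7.0,
        offset: float = 1.0,
        age_transform: str = "loglinear",
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
        self.adult_age = adult_age
        self.offset = offset
        self.age_transform = age_transform
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize
        self.random_state = random_state

    def _transform(self) -> AgeTransform | NoTransform:
        if self.age_transform == "none":
            return NoTransform()
        return AgeTransform(adult_age=self.adult_age, offset=self.offset)

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n_eff = X.shape[0] if sample_weight is None else int(
            np.count_nonzero(np.asarray(sample_weight))
        )
        if n_eff < MIN_TRAINING_SAMPLES:
            raise ValueError(
                f"clock training needs at least {MIN_TRAINING_SAMPLES} "
                f"weighted samples, got {n_eff}"
            )
        t = self._transform()
        if np.ptp(y) == 0:
            raise ValueError("all training ages are identical")
        self.enet_ = ElasticNetCD(
            alpha=self.alpha, lam=self.lam, n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio, cv_folds=self.cv_folds,
            use_1se=self.use_1se, tol=self.tol, max_iter=self.max_iter,
            standardize=self.standardize, random_state=self.random_state,
        ).fit(X, t.transform(y), sample_weight=sample_weight)
        self.transform_ = t
        self.coef_ = self.enet_.coef_
        self.intercept_ = self.enet_.intercept_
        self.lambda_ = self.enet_.lambda_
        self.n_nonzero_ = self.enet_.n_nonzero_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return self.transform_.inverse(self.enet_.predict(X))


def accuracy_weights(sheet: SampleSheet) -> pd.Series:
    """Per-sample clock-training weights from age-accuracy classes.

    Accuracy <= 1 year -> weight 1.0; <= 2 years -> 0.5; coarser or
    unknown accuracy (or unknown age) -> sample excluded (absent from the
    result).
    """
    df = sheet.data
    usable = df["age"].notna() & df["age_accuracy"].notna() & (
        df["age_accuracy"] <= 2.0
    )
    acc = df.loc[usable, "age_accuracy"]
    return pd.Series(
        np.where(acc <= 1.0, 1.0, 0.5), index=acc.index, name="weight"
    )


def _training_arrays(beta: BetaMatrix, sheet: SampleSheet):
    """Weighted samples, design matrix (samples x CpGs), transformed ages."""
    w = accuracy_weights(sheet)
    missing = [s for s in w.index if s not in beta.sample_ids]
    if missing:
        raise ValueError(
            f"beta matrix lacks weighted sample(s): {missing[:5]}"
        )
    sub = beta.select_samples(list(w.index))
    X = sub.samples_by_cpgs()
    ages = sheet.data.loc[w.index, "age"].to_numpy(dtype=float)
    return X, ages, w.to_numpy(dtype=float), list(w.index)


def _model_from_estimator(
    clock: EpigeneticAgeClock, cpg_ids, n_samples: int
) -> ClockModel:
    t = clock.transform_
    entries = {
        str(cpg_ids[j]): float(clock.coef_[j])
        for j in np.flatnonzero(clock.coef_)
    }
    meta = (
        {} if isinstance(t, NoTransform)
        else {"adult_age": t.adult_age, "offset": t.offset}
    )
    table = CoefficientTable(
        intercept=clock.intercept_,
        entries=entries,
        model_kind="age",
        metadata=meta,
    )
    return ClockModel(
        table=table, transform=t, n_samples=n_samples,
        lam=clock.lambda_, n_nonzero=clock.n_nonzero_,
    )


def model_from_table(table: CoefficientTable) -> ClockModel:
    """Rebuild a :class:`ClockModel` from a saved coefficient table.

    A table carrying ``adult_age`` metadata reconstructs its log-linear
    transform; one without is treated as fitted on untransformed ages.
    """
    if "adult_age" in table.metadata:
        t: AgeTransform | NoTransform = AgeTransform(
            adult_age=table.metadata["adult_age"],
            offset=table.metadata.get("offset", 1.0),
        )
    else:
        t = NoTransform()
    return ClockModel(
        table=table, transform=t, n_samples=0, lam=float("nan"),
        n_nonzero=len(table),
    )


def train_clock(
    beta: BetaMatrix,
    sheet: SampleSheet,
    config: ElasticNetConfig | None = None,
    transform: AgeTransform | None = None,
) -> ClockModel:
    """Train the age clock on all weighted samples.

    The penalty comes from n-fold (= leave-one-out) internal CV on the
    weighted training set unless ``config.lam`` fixes it.
    """
    cfg = config or ElasticNetConfig()
    t = transform or AgeTransform()
    X, ages, w, ids = _training_arrays(beta, sheet)
    identity = isinstance(t, NoTransform)
    clock = EpigeneticAgeClock(
        alpha=cfg.alpha, lam=cfg.lam, n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio, cv_folds=cfg.cv_folds,
        use_1se=cfg.use_1se,
        adult_age=7.0 if identity else t.adult_age,
        offset=1.0 if identity else t.offset,
        age_transform="none" if identity else "loglinear",
        tol=cfg.tol, max_iter=cfg.max_iter, standardize=cfg.standardize,
    ).fit(X, ages, sample_weight=w)
    return _model_from_estimator(clock, beta.cpg_ids, len(ids))


def loocv_predict(
    beta: BetaMatrix,
    sheet: SampleSheet,
    config: ElasticNetConfig | None = None,
    transform: AgeTransform | None = None,
    refit_lambda: bool = False,
) -> LoocvResult:
    """Leave-one-out evaluation of the clock.

    The penalty is determined once on the full weighted dataset; each
    sample is then dropped, the clock refitted at that fixed penalty on
    the rest, and the held-out age predicted.  ``refit_lambda=True``
    instead reselects the penalty inside every fold (nested LOOCV), a
    stricter and much slower variant.
    """
    cfg = config or ElasticNetConfig()
    t = transform or AgeTransform()
    X, ages, w, ids = _training_arrays(beta, sheet)
    n = len(ids)
    if n - 1 < MIN_TRAINING_SAMPLES:
        raise ValueError(
            f"LOOCV needs at least {MIN_TRAINING_SAMPLES + 1} weighted "
            f"samples, got {n}"
        )
    y = t.transform(ages)
    if cfg.lam is not None:
        lam = float(cfg.lam)
    else:
        lam, _ = cv_select_lambda(X, y, w, cfg, family="gaussian")

    pred_t = np.empty(n)
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        if refit_lambda and cfg.lam is None:
            lam_i, _ = cv_select_lambda(
                X[keep], y[keep], w[keep], cfg, family="gaussian"
            )
        else:
            lam_i = lam
        lmax = _lambda_max(
            X[keep], y[keep], w[keep], cfg.alpha, cfg.standardize, "gaussian"
        )
        if lam_i >= lmax:
            lams = np.array([lam_i])
        elif lam_i <= 0:
            lams = np.append(np.geomspace(lmax, lmax * 1e-3, 5), lam_i)
        else:
            lams = np.append(np.geomspace(lmax, lam_i, 8)[:-1], lam_i)
        coefs, icpts, _, _ = _gaussian_path(
            X[keep], y[keep], w[keep], lams, cfg.alpha, cfg.tol,
            cfg.max_iter, cfg.standardize,
        )
        pred_t[i] = icpts[-1] + X[i] @ coefs[:, -1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        predicted = t.inverse(pred_t)
    predictions = pd.DataFrame(
        {"observed": ages, "predicted": predicted},
        index=pd.Index(ids, name="sample_id"),
    )
    return LoocvResult(
        predictions=predictions,
        report=evaluate(predicted, ages),
        lam=float(lam),
    )


def apply_clock(
    model: ClockModel, beta: BetaMatrix, impute_missing: bool = False
) -> pd.Series:
    """Predict ages in years for every sample of a beta matrix.

    Every model CpG must be present unless ``impute_missing``: then a
    wholly absent CpG is imputed at beta = 0.5 (missing cells in present
    CpGs are always per-CpG mean-imputed).
    """
    pred_t = _linear_predictor(model.table, beta, impute_missing)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        years = model.transform.inverse(pred_t)
    return pd.Series(years, index=beta.sample_ids, name="predicted_age")


def _linear_predictor(
    table: CoefficientTable, beta: BetaMatrix, impute_missing: bool
) -> np.ndarray:
    """intercept + sum_j coef_j * beta_j for each sample."""
    present = set(beta.cpg_ids)
    absent = [c for c in table.cpg_ids if c not in present]
    if absent and not impute_missing:
        raise ValueError(
            f"beta matrix lacks {len(absent)} model CpG(s): {absent[:10]}"
        )
    eta = np.full(beta.n_samples, table.intercept)
    if table.entries:
        frame = beta.to_frame()
        imputed = pd.DataFrame(
            beta.imputed(), index=frame.index, columns=frame.columns
        )
        for cpg, coef in table.entries.items():
            if cpg in present:
                eta += coef * imputed.loc[cpg].to_numpy(dtype=float)
            else:
                eta += coef * 0.5
    return eta


def evaluate(predicted, observed) -> EvaluationReport:
    """Accuracy summary for paired predicted/observed ages (years).

    r is the Pearson correlation (NaN if either side has zero variance);
    mae the median absolute error; slope/intercept the OLS line of
    predicted on observed.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if p.size < 3:
        raise ValueError("evaluation needs at least 3 pairs")
    mae = float(np.median(np.abs(p - o)))
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(p, o).statistic)
    if np.ptp(o) == 0:
        slope, intercept = float("nan"), float("nan")
    else:
        fit = stats.linregress(o, p)
        slope, intercept = float(fit.slope), float(fit.intercept)
    return EvaluationReport(
        r=r, mae=mae, slope=slope, intercept=intercept, n=int(p.size)
    )
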
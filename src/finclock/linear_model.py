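"""Weighted elastic-net regression via cyclic coordinate descent.

Implements the penalized estimators the clock and sex predictor are built
on.  For responses y, features X (samples x features) and non-negative
sample weights w normalized to sum to one, the gaussian family minimizes

    (1/2) sum_i w_i (y_i - b0 - x_i b)^2
        + lam * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2)

and the binomial family the analogous penalized logistic deviance

    - sum_i w_i [y_i log p_i + (1 - y_i) log(1 - p_i)] + lam * P(b),

with alpha in [0, 1] mixing lasso (selection) and ridge (shrinkage).  The
penalty applies to coefficients on the internally standardized scale
(weighted mean 0, weighted variance 1) when ``standardize`` is on; reported
coefficients are always back-transformed to the original scale.  The
intercept is never penalized.

The gaussian solver is cyclic coordinate descent with soft-thresholding,
residual updates, an active-set strategy and warm starts down the
regularization path; the binomial solver wraps it in iteratively reweighted
least squares.  The penalty strength is chosen by n-fold cross-validation
(leave-one-out by default, matching the clock-building procedure) on a
log-spaced path from lambda_max, the smallest penalty that zeroes every
coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

__all__ = [
    "ElasticNetConfig",
    "FitResult",
    "ElasticNetCD",
    "LogisticElasticNetCD",
    "fit_gaussian",
    "fit_binomial",
    "lambda_path",
    "cv_select_lambda",
]

# linear predictors beyond this magnitude indicate quasi-separation; the
# working response is clamped there and the fit flagged
_ETA_CLAMP = 30.0
_MIN_PQ = 1e-5


@dataclass
class ElasticNetConfig:
    """Solver settings shared by the gaussian and binomial families.

    alpha is the L1/L2 mixing parameter (0.5 shrinks and removes predictors
    in equal measure, the customary choice for methylation clocks); lam
    fixes the penalty, or None to select it by internal cross-validation
    over an ``n_lambda``-point log-spaced path down to
    lambda_max * lambda_min_ratio (default ratio 1e-4 when samples exceed
    features, else 1e-2).  ``cv_folds`` is the number of internal CV folds,
    None meaning leave-one-out.  ``use_1se`` switches lambda selection from
    the CV-error minimizer to the one-standard-error rule.
    """

    alpha: float = 0.5
    lam: float | None = None
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    cv_folds: int | None = None
    use_1se: bool = False
    tol: float = 1e-7
    max_iter: int = 100_000
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be at least 2")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lam must be non-negative")


@dataclass
class FitResult:
    """A single penalized fit on the original feature scale."""

    intercept: float
    coefficients: dict[str, float]
    lam: float
    n_nonzero: int
    converged: bool
    separation: bool = False
    dropped_features: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _cd_sweep(X, w, d, r, beta, l1, l2, idx):
    """One pass of coordinate updates over the columns listed in idx.

    X is centered (and possibly scaled) with weighted column sums of
    squares d; r is the current residual, updated in place along with beta.
    Returns the largest absolute coefficient change of the pass.
    """
    n = X.shape[0]
    dmax = 0.0
    for k in range(idx.size):
        j = idx[k]
        dj = d[j]
        if dj <= 0.0:
            continue
        bj = beta[j]
        g = dj * bj
        for i in range(n):
            g += w[i] * X[i, j] * r[i]
        if g > l1:
            bn = (g - l1) / (dj + l2)
        elif g < -l1:
            bn = (g + l1) / (dj + l2)
        else:
            bn = 0.0
        diff = bn - bj
        if diff != 0.0:
            for i in range(n):
                r[i] -= diff * X[i, j]
            beta[j] = bn
            ad = abs(diff)
            if ad > dmax:
                dmax = ad
    return dmax


@njit(cache=True)
def _cd_solve(X, w, d, r, beta, l1, l2, tol, max_iter):
    """Full coordinate-descent solve: alternate active-set sweeps with
    full sweeps until a full sweep moves no coefficient by more than tol."""
    p = beta.size
    all_idx = np.arange(p)
    n_sweeps = 0
    while n_sweeps < max_iter:
        dmax = _cd_sweep(X, w, d, r, beta, l1, l2, all_idx)
        n_sweeps += 1
        if dmax < tol:
            return n_sweeps, True
        active = np.nonzero(beta)[0]
        while n_sweeps < max_iter:
            dm = _cd_sweep(X, w, d, r, beta, l1, l2, active)
            n_sweeps += 1
            if dm < tol:
                break
    return n_sweeps, False


_COARSE_TOL = 1e-4
_ACTIVE_CAP = 400


def _solve_penalized(Xs, w, d, yc, q, r, beta, l1, l2, tol, max_iter):
    """Solve one penalized weighted least-squares problem to tol.

    Three phases: coarse coordinate descent to locate the active set; an
    active-set Newton polish that solves the stationarity system
    (G_AA + l2 I) b_A = q_A - l1 sign(b_A) exactly, dropping sign-flipped
    entries and admitting KKT violators until none remain; and a final
    certified coordinate-descent pass at ``tol`` (the polish is an
    accelerator, the certificate is always coordinate descent).  ``r`` and
    ``beta`` are updated in place; ``q = X' W yc`` is precomputed by the
    caller.  Returns the convergence flag.
    """
    n, p = Xs.shape
    _cd_solve(Xs, w, d, r, beta, l1, l2, max(tol, _COARSE_TOL), max_iter)
    for _ in range(40):
        A = np.flatnonzero(beta)
        if A.size == 0 or A.size > min(n + 50, _ACTIVE_CAP):
            break
        sgn = np.sign(beta[A])
        XA = Xs[:, A]
        G = XA.T @ (XA * w[:, None])
        M = G + l2 * np.eye(A.size)
        try:
            bA = np.linalg.solve(M, q[A] - l1 * sgn)
        except np.linalg.LinAlgError:
            break
        for _ in range(A.size):  # drop sign-flipped entries, re-solve
            keep = bA * sgn > 0
            if keep.all():
                break
            A, sgn, M = A[keep], sgn[keep], M[np.ix_(keep, keep)]
            if A.size == 0:
                bA = bA[:0]
                break
            bA = np.linalg.solve(M, q[A] - l1 * sgn)
        beta[:] = 0.0
        if A.size:
            beta[A] = bA
            r[:] = yc - Xs[:, A] @ bA
        else:
            r[:] = yc
        g = (w * r) @ Xs
        viol = np.abs(g) > l1 * (1.0 + 1e-12) + 1e-14
        viol[A] = False
        viol[d <= 0] = False
        vi = np.flatnonzero(viol)
        if vi.size == 0:
            break
        # admit violators with infinitesimal mass of the correct sign so
        # the next polish round includes them in the active set
        beta[vi] = np.sign(g[vi]) * 1e-300
    _, ok = _cd_solve(Xs, w, d, r, beta, l1, l2, tol, max_iter)
    return ok


# ---------------------------------------------------------------------------
# internal dense-array machinery (original-scale inputs)


def _check_weights(w, n):
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have shape ({n},), got {w.shape}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("weights must not be all zero")
    return w / tot


def _standardize(X, w, standardize):
    """Weighted centering (always) and scaling (optional).

    Returns the transformed Fortran-ordered matrix, the column means,
    scales (ones when not standardizing), weighted sums of squares d, and
    the indices of zero-variance columns (dropped: d set to 0).
    """
    xm = w @ X
    Xc = X - xm
    var = w @ (Xc**2)
    zero = np.flatnonzero(var <= 0)
    if standardize:
        s = np.sqrt(var)
        s[zero] = 1.0
        Xc = Xc / s
        d = np.ones(X.shape[1])
    else:
        s = np.ones(X.shape[1])
        d = var.copy()
    d[zero] = 0.0
    return np.asfortranarray(Xc), xm, s, d, zero


def _gaussian_path(X, y, w, lambdas, alpha, tol, max_iter, standardize):
    """Fit the gaussian elastic net at each penalty with warm starts.

    Per-penalty work runs on a candidate column set screened by the
    sequential strong rule |g_j| >= alpha (2 lam_k - lam_{k-1}); a full
    KKT pass on the gradient at the solution admits any violator and
    re-solves, so screening never changes the answer.

    Returns (coefs [p x L] on the original scale, intercepts [L],
    converged [L], zero-variance column indices).
    """
    n, p = X.shape
    w = _check_weights(w, n)
    Xs, xm, s, d, zero = _standardize(X, w, standardize)
    ym = float(w @ y)
    yc = y - ym

    L = len(lambdas)
    beta = np.zeros(p)
    g_full = (w * yc) @ Xs  # gradient at the null model
    usable = d > 0
    coefs = np.empty((p, L))
    intercepts = np.empty(L)
    converged = np.empty(L, dtype=bool)
    lam_prev = lambdas[0]
    for k, lam in enumerate(lambdas):
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        thr = alpha * (2.0 * lam - lam_prev)
        lam_prev = lam
        cand = ((np.abs(g_full) >= thr) | (beta != 0.0)) & usable
        ok = True
        for _ in range(1 + p):
            C = np.flatnonzero(cand)
            if C.size:
                XC = np.asfortranarray(Xs[:, C])
                qC = (w * yc) @ XC
                betaC = beta[C].copy()
                rC = yc - XC @ betaC
                ok = _solve_penalized(
                    XC, w, d[C], yc, qC, rC, betaC, l1, l2, tol, max_iter
                )
                beta[C] = betaC
                r = rC
            else:
                r = yc
            g_full = (w * r) @ Xs
            viol = (
                (np.abs(g_full) > l1 * (1.0 + 1e-12) + 1e-14)
                & (beta == 0.0) & usable & ~cand
            )
            if not viol.any():
                break
            cand |= viol
        converged[k] = ok
        b_orig = beta / s
        coefs[:, k] = b_orig
        intercepts[k] = ym - b_orig @ xm
    return coefs, intercepts, converged, zero


def _binomial_path(X, y, w, lambdas, alpha, tol, max_iter, standardize):
    """Penalized logistic path via IRLS with an inner coordinate-descent
    solve; warm starts down the path.

    Returns (coefs, intercepts, converged, zero-variance indices,
    separation flags).
    """
    n, p = X.shape
    w = _check_weights(w, n)
    y = np.asarray(y, dtype=float)
    Xs, xm, s, _, zero = _standardize(X, w, standardize)
    pbar = float(w @ y)
    if pbar <= 0.0 or pbar >= 1.0:
        raise ValueError("both classes must be present with positive weight")

    L = len(lambdas)
    beta = np.zeros(p)
    b0 = float(np.log(pbar / (1.0 - pbar)))
    usable = np.ones(p, dtype=bool)
    usable[zero] = False
    g_full = (w * (y - pbar)) @ Xs  # deviance gradient at the null model
    coefs = np.empty((p, L))
    intercepts = np.empty(L)
    converged = np.empty(L, dtype=bool)
    separation = np.empty(L, dtype=bool)
    irls_max = 100
    lam_prev = lambdas[0]
    for k, lam in enumerate(lambdas):
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        thr = alpha * (2.0 * lam - lam_prev)
        lam_prev = lam
        cand = ((np.abs(g_full) >= thr) | (beta != 0.0)) & usable
        ok = False
        sep = False
        for _ in range(1 + p):  # strong-rule set growth loop
            C = np.flatnonzero(cand)
            XC = np.asfortranarray(Xs[:, C])
            betaC = beta[C].copy()
            ok = False
            for _ in range(irls_max):
                eta = b0 + XC @ betaC
                if np.any(np.abs(eta) > _ETA_CLAMP):
                    sep = True
                eta_c = np.clip(eta, -_ETA_CLAMP, _ETA_CLAMP)
                pr = expit(eta_c)
                pq = np.maximum(pr * (1.0 - pr), _MIN_PQ)
                ww = w * pq
                z = eta_c + (y - pr) / pq
                sw = ww.sum()
                xmw = (ww @ XC) / sw if C.size else np.empty(0)
                zm = float(ww @ z) / sw
                Xcc = np.asfortranarray(XC - xmw)
                dC = ww @ (Xcc**2)
                zc = z - zm
                q = (ww * zc) @ Xcc
                r = zc - (Xcc @ betaC)
                b_prev = betaC.copy()
                b0_prev = b0
                _solve_penalized(
                    Xcc, ww, dC, zc, q, r, betaC, l1, l2, tol, max_iter
                )
                b0 = zm - float(xmw @ betaC)
                delta = max(
                    float(np.max(np.abs(betaC - b_prev))) if C.size else 0.0,
                    abs(b0 - b0_prev),
                )
                if delta < max(tol, 1e-10):
                    ok = True
                    break
            beta[:] = 0.0
            beta[C] = betaC
            # full KKT pass at the fitted probabilities
            eta = np.clip(b0 + XC @ betaC, -_ETA_CLAMP, _ETA_CLAMP)
            g_full = (w * (y - expit(eta))) @ Xs
            viol = (
                (np.abs(g_full) > l1 * (1.0 + 1e-12) + 1e-14)
                & (beta == 0.0) & usable & ~cand
            )
            if not viol.any():
                break
            cand |= viol
        converged[k] = ok
        separation[k] = sep
        b_orig = beta / s
        coefs[:, k] = b_orig
        intercepts[k] = b0 - b_orig @ xm
    return coefs, intercepts, converged, zero, separation


def _lambda_max(X, y, w, alpha, standardize, family):
    """Smallest penalty that zeroes every coefficient (KKT at b = 0)."""
    n = X.shape[0]
    w = _check_weights(w, n)
    Xs, _, _, _, _ = _standardize(X, w, standardize)
    y = np.asarray(y, dtype=float)
    if family == "binomial":
        pbar = float(w @ y)
        grad = (w * (y - pbar)) @ Xs
    else:
        ym = float(w @ y)
        grad = (w * (y - ym)) @ Xs
    gmax = float(np.max(np.abs(grad))) if grad.size else 0.0
    a_eff = max(alpha, 1e-3)  # conventional surrogate for pure ridge
    # tiny relative margin so a fit at exactly lambda_max is null despite
    # rounding differences between gradient evaluations
    return gmax / a_eff * (1.0 + 1e-9)


def lambda_path(
    X,
    y,
    weights=None,
    config: ElasticNetConfig | None = None,
    family: str = "gaussian",
) -> np.ndarray:
    """Descending log-spaced penalty sequence starting at lambda_max.

    The first element zeroes the model exactly; consecutive ratios are
    constant.  A constant response admits no path and raises.
    """
    config = config or ElasticNetConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("response is constant: no regularization path")
    lmax = _lambda_max(X, y, weights, config.alpha, config.standardize, family)
    if lmax <= 0:
        raise ValueError("response is constant: no regularization path")
    ratio = config.lambda_min_ratio
    if ratio is None:
        ratio = 1e-4 if n > p else 1e-2
    return np.geomspace(lmax, lmax * ratio, config.n_lambda)


def _make_folds(n, n_folds, seed):
    """Deterministic fold assignment; LOO (n_folds == n) uses singletons
    in sample order with no randomness."""
    if not 2 <= n_folds <= n:
        raise ValueError(f"n_folds must be in [2, {n}], got {n_folds}")
    if n_folds == n:
        return [np.array([i]) for i in range(n)]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(perm[k::n_folds]) for k in range(n_folds)]


def _binomial_deviance(y, pr, w):
    pr = np.clip(pr, 1e-10, 1 - 1e-10)
    return -2.0 * w * (y * np.log(pr) + (1 - y) * np.log(1 - pr))


def cv_select_lambda(
    X,
    y,
    weights=None,
    config: ElasticNetConfig | None = None,
    n_folds: int | None = None,
    seed: int = 0,
    family: str = "gaussian",
    lambdas: Sequence[float] | None = None,
):
    """Cross-validated penalty selection over the regularization path.

    Error is the weighted mean squared error (gaussian) or weighted
    binomial deviance on held-out samples; the selected lambda minimizes
    the mean CV error, ties broken toward the larger penalty (sparser
    model).  With ``config.use_1se`` the largest lambda within one standard
    error of the minimum is chosen.  Folds derive deterministically from
    ``seed``; leave-one-out (the default) involves no randomness.

    Returns ``(lambda_selected, mean_cv_error_per_lambda)``.
    """
    config = config or ElasticNetConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    w = _check_weights(weights, n)
    if n_folds is None:
        n_folds = config.cv_folds if config.cv_folds is not None else n
    if lambdas is None:
        lambdas = lambda_path(X, y, w, config, family=family)
    lambdas = np.asarray(lambdas, dtype=float)

    folds = _make_folds(n, n_folds, seed)
    if family == "binomial":
        # every training part must retain both classes
        def _ok(folds):
            return all(
                0.0 < np.mean(np.delete(y, f)) < 1.0 and np.delete(w, f).sum() > 0
                for f in folds
            )

        if not _ok(folds):
            folds = _make_folds(n, n_folds, seed + 1)
            if not _ok(folds):
                raise ValueError(
                    "cross-validation folds cannot retain both classes"
                )

    L = len(lambdas)
    err_sum = np.zeros(L)
    w_sum = 0.0
    fold_means = np.empty((len(folds), L))
    for fi, hold in enumerate(folds):
        keep = np.setdiff1d(np.arange(n), hold)
        Xt, yt, wt = X[keep], y[keep], w[keep]
        Xh, yh, wh = X[hold], y[hold], w[hold]
        if family == "binomial":
            coefs, icpts, _, _, _ = _binomial_path(
                Xt, yt, wt, lambdas, config.alpha, config.tol,
                config.max_iter, config.standardize,
            )
            pr = expit(icpts[None, :] + Xh @ coefs)
            e = _binomial_deviance(yh[:, None], pr, wh[:, None])
        else:
            coefs, icpts, _, _ = _gaussian_path(
                Xt, yt, wt, lambdas, config.alpha, config.tol,
                config.max_iter, config.standardize,
            )
            pred = icpts[None, :] + Xh @ coefs
            e = wh[:, None] * (yh[:, None] - pred) ** 2
        err_sum += e.sum(axis=0)
        whs = wh.sum()
        w_sum += whs
        fold_means[fi] = e.sum(axis=0) / whs if whs > 0 else np.nan
    mean_err = err_sum / w_sum

    i_min = int(np.argmin(mean_err))  # argmin returns the first (largest lam)
    if config.use_1se and len(folds) > 1:
        se = np.nanstd(fold_means, axis=0, ddof=1) / np.sqrt(len(folds))
        cutoff = mean_err[i_min] + se[i_min]
        i_min = int(np.flatnonzero(mean_err <= cutoff)[0])
    return float(lambdas[i_min]), mean_err


# ---------------------------------------------------------------------------
# estimators


class ElasticNetCD(RegressorMixin, BaseEstimator):
    """Weighted gaussian elastic net with internal CV penalty selection.

    Parameters mirror :class:`ElasticNetConfig`; ``lam=None`` selects the
    penalty by ``cv_folds``-fold (default leave-one-out) cross-validation.

    Attributes
    ----------
    coef_, intercept_ : fitted coefficients on the original feature scale.
    lambda_ : penalty used for the final fit.
    n_nonzero_, converged_ : sparsity and convergence of the final fit.
    lambda_path_, cv_errors_ : CV path and mean CV error (when CV ran).
    """

    def __init__(
        self,
        alpha: float = 0.5,
        lam: float | None = None,
        n_lambda: int = 100,
        lambda_min_ratio: float | None = None,
        cv_folds: int | None = None,
        use_1se: bool = False,
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
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize
        self.random_state = random_state

    _family = "gaussian"

    def _config(self) -> ElasticNetConfig:
        return ElasticNetConfig(
            alpha=self.alpha,
            lam=self.lam,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            cv_folds=self.cv_folds,
            use_1se=self.use_1se,
            tol=self.tol,
            max_iter=self.max_iter,
            standardize=self.standardize,
        )

    def _path_fit(self, X, y, w, lambdas):
        coefs, icpts, conv, zero = _gaussian_path(
            X, y, w, lambdas, self.alpha, self.tol, self.max_iter,
            self.standardize,
        )
        return coefs, icpts, conv, zero, np.zeros(len(lambdas), dtype=bool)

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x features)")
        if y.shape != (X.shape[0],):
            raise ValueError("y length must match the number of samples")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("X and y must not contain missing values")
        if X.shape[0] < 2:
            raise ValueError("at least 2 samples are required")
        return X, y

    def fit(self, X, y, sample_weight=None):
        X, y = self._validate(X, y)
        cfg = self._config()
        n = X.shape[0]
        w = _check_weights(sample_weight, n)
        if np.count_nonzero(w) < 2:
            raise ValueError("at least 2 samples need positive weight")

        constant_y = self._family == "gaussian" and np.ptp(y) == 0
        if self.lam is not None:
            lam = float(self.lam)
            if constant_y:
                lambdas = np.array([lam])
            else:
                lmax = _lambda_max(
                    X, y, w, self.alpha, self.standardize, self._family
                )
                # short warm-up path for stability; exact at the target lam
                if lam <= 0:
                    lambdas = np.append(np.geomspace(lmax, lmax * 1e-3, 5), lam)
                elif lam < lmax:
                    lambdas = np.append(np.geomspace(lmax, lam, 6)[:-1], lam)
                else:
                    lambdas = np.array([lam])
            self.cv_errors_ = None
            self.lambda_path_ = None
        else:
            if constant_y:
                raise ValueError("response is constant: no regularization path")
            lambdas = lambda_path(X, y, w, cfg, family=self._family)
            lam, cv_err = cv_select_lambda(
                X, y, w, cfg, seed=self.random_state,
                family=self._family, lambdas=lambdas,
            )
            self.cv_errors_ = cv_err
            self.lambda_path_ = lambdas
            lambdas = lambdas[lambdas >= lam]

        if constant_y:
            self.coef_ = np.zeros(X.shape[1])
            self.intercept_ = float(w @ y)
            self.converged_ = True
            self.separation_ = False
            zero = np.flatnonzero((w @ (X - w @ X) ** 2) <= 0)
        else:
            coefs, icpts, conv, zero, sep = self._path_fit(X, y, w, lambdas)
            self.coef_ = coefs[:, -1]
            self.intercept_ = float(icpts[-1])
            self.converged_ = bool(conv[-1])
            self.separation_ = bool(sep[-1])
        if zero.size:
            warnings.warn(
                f"{zero.size} zero-variance feature(s) dropped from the "
                "penalized fit",
                RuntimeWarning,
                stacklevel=2,
            )
        self.dropped_ = zero
        self.lambda_ = float(lam)
        self.n_nonzero_ = int(np.count_nonzero(self.coef_))
        self.n_features_in_ = X.shape[1]
        if not self.converged_:
            warnings.warn(
                "coordinate descent did not converge; consider raising "
                "max_iter",
                RuntimeWarning,
                stacklevel=2,
            )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


class LogisticElasticNetCD(ClassifierMixin, BaseEstimator):
    """Weighted binomial (logistic) elastic net, IRLS over the gaussian
    coordinate-descent core.

    The response must be binary; ``classes_`` holds the sorted labels and
    the linear predictor models the probability of ``classes_[1]``.
    ``separation_`` flags quasi-separation (|linear predictor| beyond the
    working-response clamp during the fit).
    """

    def __init__(
        self,
        alpha: float = 0.5,
        lam: float | None = None,
        n_lambda: int = 100,
        lambda_min_ratio: float | None = None,
        cv_folds: int | None = None,
        use_1se: bool = False,
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
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize
        self.random_state = random_state

    _family = "binomial"
    _config = ElasticNetCD._config
    _validate = ElasticNetCD._validate

    def _path_fit(self, X, y, w, lambdas):
        return _binomial_path(
            X, y, w, lambdas, self.alpha, self.tol, self.max_iter,
            self.standardize,
        )

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        classes = np.unique(np.asarray(y))
        if classes.size != 2:
            raise ValueError(
                f"binomial fit requires exactly 2 classes, got {classes.size}"
            )
        self.classes_ = classes
        y01 = (np.asarray(y) == classes[1]).astype(float)
        ElasticNetCD.fit(self, X, y01, sample_weight=sample_weight)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        # strictly greater than 0.5 maps to the positive class
        p1 = self.predict_proba(X)[:, 1]
        return np.where(p1 > 0.5, self.classes_[1], self.classes_[0])


# ---------------------------------------------------------------------------
# functional wrappers (single-penalty fits, named-feature results)


def _result_from_estimator(est, feature_ids) -> FitResult:
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(est.n_features_in_)]
    coeffs = {
        str(feature_ids[j]): float(est.coef_[j])
        for j in np.flatnonzero(est.coef_)
    }
    return FitResult(
        intercept=float(est.intercept_),
        coefficients=coeffs,
        lam=est.lambda_,
        n_nonzero=est.n_nonzero_,
        converged=est.converged_,
        separation=bool(getattr(est, "separation_", False)),
        dropped_features=[str(feature_ids[j]) for j in est.dropped_],
    )


def fit_gaussian(
    X, y, weights=None, lam: float = 0.0,
    config: ElasticNetConfig | None = None, feature_ids=None,
) -> FitResult:
    """Weighted gaussian elastic net at a fixed penalty."""
    cfg = config or ElasticNetConfig()
    est = ElasticNetCD(
        alpha=cfg.alpha, lam=lam, tol=cfg.tol, max_iter=cfg.max_iter,
        standardize=cfg.standardize,
    ).fit(X, y, sample_weight=weights)
    return _result_from_estimator(est, feature_ids)


def fit_binomial(
    X, y01, weights=None, lam: float = 0.0,
    config: ElasticNetConfig | None = None, feature_ids=None,
) -> FitResult:
    """Weighted binomial elastic net at a fixed penalty; y01 is 0/1."""
    cfg = config or ElasticNetConfig()
    est = LogisticElasticNetCD(
        alpha=cfg.alpha, lam=lam, tol=cfg.tol, max_iter=cfg.max_iter,
        standardize=cfg.standardize,
    ).fit(X, np.asarray(y01), sample_weight=weights)
    return _result_from_estimator(est, feature_ids)
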
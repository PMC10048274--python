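"""Calibration models and model selection for spectral quantification.

Three algorithm families are provided:

* ``PLSR`` — partial least squares regression via NIPALS with y-deflation.
  Successive latent variables maximise covariance between the (deflated)
  spectra and the concentration; the regression-coefficient vector is kept
  for every intermediate component count, so cross-validating a whole
  1..A_max grid costs one decomposition per fold.
* ``PCR``  — principal component regression: SVD of the mean-centred
  spectra, ordinary least squares on the leading scores.  Because scores
  are orthogonal, coefficients for every component count come from one SVD.
  The minimum component count explaining 95% of spectral variance is
  reported alongside.
* ``ANN``  — single-hidden-layer network (sigmoidal hidden units, linear
  output, L2 weight decay) trained full-batch with L-BFGS; inputs are
  standardised and the response min-max scaled to [0, 1] internally.

Model comparison follows the usual chemometric protocol: an 80/20 random
split, 10-fold cross-validation on the training part over a (preprocessing
x algorithm x hyperparameter) grid ranked by RMSE_CV, and the winner
refit on the full training set and scored on the held-out test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .preprocess import PreprocessMethod, apply_method
from .spectra import SpectraSet

__all__ = [
    "ModelSpec",
    "CVResult",
    "CalibrationModel",
    "train_test_split",
    "fit_plsr",
    "fit_pcr",
    "fit_ann",
    "predict",
    "kfold_cv",
    "grid_search",
    "linear_profile",
    "DEFAULT_ANN_DECAYS",
]

DEFAULT_ANN_DECAYS = (0.0, 1e-4, 1e-3, 1e-2, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class ModelSpec:
    """One (algorithm, preprocessing, hyperparameter) candidate."""

    algorithm: str  # "PLSR" | "PCR" | "ANN"
    method: PreprocessMethod = field(default_factory=lambda: PreprocessMethod("RAW"))
    n_components: int | None = None  # PLSR / PCR latent variables
    size: int | None = None  # ANN hidden units
    decay: float | None = None  # ANN L2 penalty
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("PLSR", "PCR", "ANN"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm in ("PLSR", "PCR") and (self.n_components or 0) < 1:
            raise ValueError("n_components >= 1 required for PLSR/PCR")
        if self.algorithm == "ANN":
            if (self.size or 0) < 1:
                raise ValueError("size >= 1 required for ANN")
            if self.decay is None or self.decay < 0:
                raise ValueError("decay >= 0 required for ANN")

    def label(self) -> str:
        if self.algorithm == "ANN":
            return f"ANN({self.method.id}, size={self.size}, decay={self.decay:g})"
        return f"{self.algorithm}({self.method.id}, nLV={self.n_components})"


@dataclass
class CVResult:
    """Cross-validation (and optional held-out test) scores of one candidate."""

    spec: ModelSpec
    rmse_cv: float  # mean over folds of per-fold RMSE, mg/100 mL
    rmse_cv_sd: float  # SD over folds
    r2_cv: float  # 1 - SS_res/SS_tot pooled over held-out predictions
    rmse_p: float | None = None  # held-out test RMSE
    r2_p: float | None = None


@dataclass
class CalibrationModel:
    """A fitted calibration: predicts concentration (mg/100 mL) from spectra."""

    algorithm: str
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray | None = None  # (p,) for linear models, final component count
    coef_path: np.ndarray | None = None  # (p, A) coefficients for 1..A components
    n_components: int | None = None
    n_components_95: int | None = None  # PCR: minimum PCs for 95% cumulative variance
    explained_variance_ratio: np.ndarray | None = None
    ann: MLPRegressor | None = None
    x_scale: np.ndarray | None = None  # ANN feature SDs
    y_span: tuple[float, float] | None = None  # ANN response min/max

    @property
    def n_features(self) -> int:
        return self.x_mean.size

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


def train_test_split(
    s: SpectraSet, frac: float = 0.8, seed: int = 0
) -> tuple[SpectraSet, SpectraSet]:
    """Random disjoint split; test size = round(n * (1 - frac)) (105 -> 84/21)."""
    if not 0 < frac < 1:
        raise ValueError("frac must lie strictly between 0 and 1")
    n = s.n_samples
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_test = int(round(n * (1.0 - frac)))
    n_test = min(max(n_test, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    return s.select_samples(np.sort(order[n_test:])), s.select_samples(np.sort(order[:n_test]))


# --------------------------------------------------------------------- PLSR
def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int) -> CalibrationModel:
    """NIPALS partial least squares with y-deflation, single response.

    Keeps the coefficient vector after each component.  If ``n_lv`` exceeds
    the effective rank the extraction stops early with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    max_rank = min(n - 1, p)
    if n_lv > max_rank:
        warnings.warn(
            f"n_lv={n_lv} exceeds max rank {max_rank}; truncating", stacklevel=2
        )
        n_lv = max_rank
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros(n_lv)
    x_norm0 = np.linalg.norm(Xc)
    a = 0
    for a in range(n_lv):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn <= 1e-12 * max(x_norm0, 1.0) or np.linalg.norm(yc) <= 1e-12:
            warnings.warn(f"rank exhausted after {a} components; truncating", stacklevel=2)
            break
        w /= wn
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 1e-24:
            warnings.warn(f"rank exhausted after {a} components; truncating", stacklevel=2)
            break
        pvec = Xc.T @ t / tt
        q = float(yc @ t) / tt
        Xc -= np.outer(t, pvec)
        yc = yc - q * t
        W[:, a], P[:, a], Q[a] = w, pvec, q
        a += 1
    n_used = a
    W, P, Q = W[:, :n_used], P[:, :n_used], Q[:n_used]
    # coefficients for each intermediate component count: B_a = W_a (P_a' W_a)^-1 q_a
    coef_path = np.zeros((p, max(n_used, 1)))
    for k in range(1, n_used + 1):
        Rk = np.linalg.solve((P[:, :k].T @ W[:, :k]).T, W[:, :k].T).T
        coef_path[:, k - 1] = Rk @ Q[:k]
    coef = coef_path[:, n_used - 1] if n_used else np.zeros(p)
    return CalibrationModel(
        algorithm="PLSR",
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef,
        coef_path=coef_path,
        n_components=n_used,
    )


# ---------------------------------------------------------------------- PCR
def fit_pcr(X: np.ndarray, y: np.ndarray, n_pc: int) -> CalibrationModel:
    """Principal component regression on mean-centred (unscaled) spectra."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = svals.max(initial=0.0) * max(n, p) * np.finfo(float).eps
    rank = int(np.sum(svals > tol))
    if n_pc > rank:
        warnings.warn(f"n_pc={n_pc} exceeds rank {rank}; truncating", stacklevel=2)
        n_pc = max(rank, 1)
    var = svals**2
    evr = var / var.sum() if var.sum() > 0 else var
    n95 = int(np.searchsorted(np.cumsum(evr), 0.95) + 1)
    # scores are orthogonal: per-component OLS slopes are independent
    yc = y - y_mean
    gamma = (U[:, :n_pc].T @ yc) / svals[:n_pc]
    coef_path = np.cumsum(Vt[:n_pc].T * gamma[None, :], axis=1)
    return CalibrationModel(
        algorithm="PCR",
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef_path[:, -1],
        coef_path=coef_path,
        n_components=n_pc,
        n_components_95=n95,
        explained_variance_ratio=evr,
    )


# ---------------------------------------------------------------------- ANN
def fit_ann(
    X: np.ndarray, y: np.ndarray, size: int, decay: float, seed: int = 0
) -> CalibrationModel:
    """Single-hidden-layer network: sigmoid hidden, linear output, L2 = decay.

    Trained full-batch with L-BFGS; deterministic for a fixed seed.  Inputs
    are standardised and the response min-max scaled to [0, 1] internally.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_lo, y_hi = float(y.min()), float(y.max())
    span = (y_hi - y_lo) or 1.0
    ys = (y - y_lo) / span
    net = MLPRegressor(
        hidden_layer_sizes=(size,),
        activation="logistic",
        solver="lbfgs",
        alpha=float(decay),
        max_iter=2000,
        tol=1e-7,
        random_state=int(seed) % 2**31,
    )
    with warnings.catch_warnings():
        # non-convergence is reported but the best-found weights are kept
        warnings.filterwarnings("default", category=UserWarning)
        net.fit((X - x_mean) / x_scale, ys)
    return CalibrationModel(
        algorithm="ANN",
        x_mean=x_mean,
        y_mean=float(y.mean()),
        ann=net,
        x_scale=x_scale,
        y_span=(y_lo, y_hi),
    )


def predict(m: CalibrationModel, X: np.ndarray) -> np.ndarray:
    """Predicted concentrations (mg/100 mL); negative values are not clipped."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.n_features:
        raise ValueError(
            f"feature mismatch: model expects {m.n_features} points, got {X.shape[1]}"
        )
    if m.algorithm == "ANN":
        y_lo, y_hi = m.y_span
        out = m.ann.predict((X - m.x_mean) / m.x_scale)
        return out * ((y_hi - y_lo) or 1.0) + y_lo
    return (X - m.x_mean) @ m.coef + m.y_mean


def _fit_by_spec(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> CalibrationModel:
    if spec.algorithm == "PLSR":
        return fit_plsr(X, y, spec.n_components)
    if spec.algorithm == "PCR":
        return fit_pcr(X, y, spec.n_components)
    return fit_ann(X, y, spec.size, spec.decay, spec.seed)


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def kfold_cv(
    X: np.ndarray, y: np.ndarray, spec: ModelSpec, k: int = 10, seed: int = 0
) -> CVResult:
    """k-fold CV: RMSE_CV = mean of per-fold RMSE (SD over folds alongside),
    R2_CV = 1 - SS_res/SS_tot pooled over the held-out predictions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if k > len(y):
        raise ValueError("more folds than samples")
    kf = KFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
    fold_rmse = []
    pooled = np.empty_like(y)
    for tr, te in kf.split(X):
        model = _fit_by_spec(spec, X[tr], y[tr])
        pred = predict(model, X[te])
        pooled[te] = pred
        fold_rmse.append(_rmse(pred, y[te]))
    fold_rmse = np.array(fold_rmse)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pooled) ** 2)) / ss_tot if ss_tot > 0 else np.nan
    return CVResult(
        spec=spec,
        rmse_cv=float(fold_rmse.mean()),
        rmse_cv_sd=float(fold_rmse.std(ddof=1)) if k > 1 else 0.0,
        r2_cv=r2,
    )


def _cv_component_path(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str,
    method: PreprocessMethod,
    max_comp: int,
    k: int,
    seed: int,
) -> list[CVResult]:
    """CV every component count 1..max_comp with one decomposition per fold."""
    kf = KFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
    max_comp = min(max_comp, len(y) - max(len(y) // k, 1) - 1, X.shape[1])
    fold_rmse = np.zeros((k, max_comp))
    pooled = np.zeros((max_comp, len(y)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f, (tr, te) in enumerate(kf.split(X)):
            fit = fit_plsr if algorithm == "PLSR" else fit_pcr
            model = fit(X[tr], y[tr], max_comp)
            a_used = model.coef_path.shape[1]
            preds = (X[te] - model.x_mean) @ model.coef_path + model.y_mean  # (n_te, A)
            if a_used < max_comp:  # rank-limited fold: reuse the deepest model
                preds = np.hstack(
                    [preds, np.repeat(preds[:, -1:], max_comp - a_used, axis=1)]
                )
            pooled[:, te] = preds.T
            fold_rmse[f] = np.sqrt(np.mean((preds - y[te, None]) ** 2, axis=0))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    out = []
    for a in range(max_comp):
        r2 = 1.0 - float(np.sum((y - pooled[a]) ** 2)) / ss_tot
        out.append(
            CVResult(
                spec=ModelSpec(algorithm, method, n_components=a + 1, seed=seed),
                rmse_cv=float(fold_rmse[:, a].mean()),
                rmse_cv_sd=float(fold_rmse[:, a].std(ddof=1)),
                r2_cv=r2,
            )
        )
    return out


def grid_search(
    train: SpectraSet,
    algorithms: Sequence[str] = ("PLSR", "PCR", "ANN"),
    methods: Sequence[PreprocessMethod] = (),
    *,
    max_components: int = 25,
    ann_sizes: Sequence[int] = (1, 2, 3, 4, 5, 6),
    ann_decays: Sequence[float] = DEFAULT_ANN_DECAYS,
    k: int = 10,
    seed: int = 0,
    test: SpectraSet | None = None,
) -> list[CVResult]:
    """Evaluate every (preprocessing, algorithm, hyperparameter) cell by
    k-fold CV on the training set; return results sorted by RMSE_CV.

    The winner is refit on the full training set and, when a held-out test
    set is supplied, scored there (``rmse_p`` / ``r2_p`` filled in).
    """
    methods = list(methods) or [PreprocessMethod("RAW")]
    if not algorithms:
        raise ValueError("no algorithms requested")
    y = train.concentrations
    results: list[CVResult] = []
    for method in methods:
        X = apply_method(train, method).absorbance
        for algo in algorithms:
            if algo in ("PLSR", "PCR"):
                results.extend(
                    _cv_component_path(X, y, algo, method, max_components, k, seed)
                )
            elif algo == "ANN":
                for size in ann_sizes:
                    for decay in ann_decays:
                        spec = ModelSpec(
                            "ANN", method, size=size, decay=decay, seed=seed
                        )
                        results.append(kfold_cv(X, y, spec, k=k, seed=seed))
            else:
                raise ValueError(f"unknown algorithm {algo!r}")
    results.sort(key=lambda r: r.rmse_cv)
    if test is not None and results:
        best = results[0]
        Xtr = apply_method(train, best.spec.method).absorbance
        Xte = apply_method(test, best.spec.method).absorbance
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = _fit_by_spec(best.spec, Xtr, y)
        pred = predict(model, Xte)
        yt = test.concentrations
        best.rmse_p = _rmse(pred, yt)
        ss_tot = float(np.sum((yt - yt.mean()) ** 2))
        best.r2_p = 1.0 - float(np.sum((yt - pred) ** 2)) / ss_tot
    return results


def linear_profile(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """OLS of predicted on true concentration: (slope, intercept, R^2)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if truth.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(truth) == 0:
        raise ValueError("true concentrations are constant")
    fit = stats.linregress(truth, pred)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
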
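"""Random-forest response-permutation significance testing of spectral bands.

A regression random forest (500 trees by default) is fit to the spectra and
the per-point importance taken as the mean increase in out-of-bag MSE when
that point's values are permuted among the OOB samples of each tree — the
classic OOB permutation importance (node-impurity importance is available
as an option).  The null distribution of each importance is obtained by
refitting the forest ``B`` times with the response permuted; the p-value of
point j is

    p_j = (1 + #{b : null importance_bj >= observed_j}) / (B + 1),

so p-values live on {1/(B+1), ..., 1}.  Points with p <= alpha (0.05) are
selected and merged into contiguous wavenumber regions for reporting.  No
multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .spectra import SpectraSet

__all__ = [
    "ImportanceResult",
    "rf_importance",
    "permutation_pvalues",
    "select_bands",
    "refit_on_selection",
]


@dataclass
class ImportanceResult:
    """Observed importances, permutation p-values and the selection mask."""

    wavenumbers: np.ndarray | None
    observed_importance: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    n_trees: int
    seed: int
    alpha: float = 0.05

    @property
    def selected(self) -> np.ndarray:
        return self.p_values <= self.alpha


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int) -> RandomForestRegressor:
    # mtry = p/3 and node size 5, the R randomForest regression defaults
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=1.0 / 3.0,
        min_samples_leaf=5,
        bootstrap=True,
        random_state=int(seed) % 2**31,
    )
    rf.fit(X, y)
    return rf


def _oob_permutation_importance(
    rf: RandomForestRegressor, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mean over trees of the OOB MSE increase per permuted feature.

    Only features a tree actually splits on are permuted for that tree —
    any other feature leaves its predictions, hence its contribution,
    exactly unchanged.
    """
    n, p = X.shape
    imp = np.zeros(p)
    Xf = np.ascontiguousarray(X, dtype=np.float32)
    all_idx = np.arange(n)
    for tree, samples in zip(rf.estimators_, rf.estimators_samples_):
        oob = np.setdiff1d(all_idx, samples)
        if oob.size < 2:
            continue
        Xo = Xf[oob].copy()
        yo = y[oob]
        t = tree.tree_
        base_mse = float(np.mean((yo - t.predict(Xo).ravel()) ** 2))
        feats = np.unique(t.feature)
        for j in feats[feats >= 0]:
            col = Xo[:, j].copy()
            Xo[:, j] = col[rng.permutation(oob.size)]
            imp[j] += float(np.mean((yo - t.predict(Xo).ravel()) ** 2)) - base_mse
            Xo[:, j] = col
    return imp / rf.n_estimators


def rf_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    importance: str = "oob_permutation",
) -> np.ndarray:
    """Per-feature importance of a regression random forest."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    rf = _fit_forest(X, y, n_trees, seed)
    if importance == "impurity":
        return rf.feature_importances_.copy()
    if importance != "oob_permutation":
        raise ValueError(f"unknown importance kind {importance!r}")
    rng = np.random.default_rng([1, int(seed) % 2**31])
    return _oob_permutation_importance(rf, X, y, rng)


def permutation_pvalues(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 1000,
    n_trees: int = 500,
    seed: int = 0,
    importance: str = "oob_permutation",
    wavenumbers: np.ndarray | None = None,
    alpha: float = 0.05,
) -> ImportanceResult:
    """Response-permutation null: refit the forest on permuted y, B times."""
    if B < 20:
        raise ValueError("B must be at least 20")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    observed = rf_importance(X, y, n_trees=n_trees, seed=seed, importance=importance)
    rng = np.random.default_rng([2, int(seed) % 2**31])
    exceed = np.zeros(X.shape[1])
    for b in range(B):
        y_perm = y[rng.permutation(len(y))]
        null = rf_importance(
            X, y_perm, n_trees=n_trees, seed=seed + 1 + b, importance=importance
        )
        exceed += null >= observed
    p = (1.0 + exceed) / (B + 1.0)
    return ImportanceResult(
        wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers, float),
        observed_importance=observed,
        p_values=p,
        n_permutations=B,
        n_trees=n_trees,
        seed=seed,
        alpha=alpha,
    )


def select_bands(
    res: ImportanceResult, alpha: float = 0.05
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Selection mask (p <= alpha) and merged contiguous wavenumber regions.

    Adjacent selected grid points are merged into one reported region;
    a gap wider than 1.5x the median grid step (e.g. across the omitted
    water window) starts a new region.
    """
    mask = res.p_values <= alpha
    if not mask.any():
        warnings.warn("no spectral points selected at this alpha", stacklevel=2)
        return mask, []
    if res.wavenumbers is None:
        return mask, []
    w = res.wavenumbers
    step = float(np.median(np.diff(w))) if w.size > 1 else 1.0
    regions: list[tuple[float, float]] = []
    idx = np.flatnonzero(mask)
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1 and (w[i] - w[prev]) <= 1.5 * step:
            prev = i
        else:
            regions.append((float(w[start]), float(w[prev])))
            start = prev = i
    regions.append((float(w[start]), float(w[prev])))
    return mask, regions


def refit_on_selection(
    train: SpectraSet,
    mask: np.ndarray,
    *,
    test: SpectraSet | None = None,
    **grid_kwargs,
):
    """Rerun the model grid search restricted to the selected grid points."""
    from .chemometrics import grid_search

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("selection mask is empty")
    sub_train = train.select_points(mask)
    sub_test = test.select_points(mask) if test is not None else None
    return grid_search(sub_train, test=sub_test, **grid_kwargs)
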
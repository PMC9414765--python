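"""Informative-wavelength selection.

Two selectors:

* random-forest impurity importance with a strictly-greater-than-threshold
  screen (threshold 0 keeps every band that contributed any impurity
  decrease), and
* CARS — competitive adaptive reweighted sampling: Monte Carlo calibration
  subsets, PLS regression coefficients, an exponentially decreasing
  retention schedule (EDF), adaptive reweighted sampling, and RMSECV
  minimization over iterations.

Class labels are regression-coded for PLS as ordinal severity integers,
since the mildew classes are ordered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold

from .segmentation import SeedSpectraTable

__all__ = [
    "BandScore",
    "CarsResult",
    "rf_band_importance",
    "select_positive_importance",
    "edf_schedule",
    "cars_select",
]


@dataclass(frozen=True)
class BandScore:
    band_index: int
    wavelength_nm: float
    importance: float


@dataclass
class CarsResult:
    """Per-iteration CARS trace plus the RMSECV-optimal subset."""

    retained_sets: list[np.ndarray]
    rmsecv: np.ndarray
    selected: np.ndarray
    best_iteration: int
    seed: int
    edf_counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        sizes = [len(s) for s in self.retained_sets]
        if any(b > a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("retained-set sizes must be non-increasing")


def rf_band_importance(
    table: SeedSpectraTable,
    n_trees: int = 500,
    seed: int = 0,
) -> list[BandScore]:
    """Mean-impurity-decrease importance per band, normalized to sum 1."""
    if table.class_labels is None:
        raise ValueError("table has no class labels")
    if np.unique(table.class_labels).size < 2:
        raise ValueError("band importance needs >= 2 classes")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(table.spectra, table.class_labels)
    imp = forest.feature_importances_
    return [
        BandScore(band_index=j, wavelength_nm=float(table.wavelengths_nm[j]),
                  importance=float(imp[j]))
        for j in range(imp.size)
    ]


def select_positive_importance(
    scores: list[BandScore], threshold: float = 0.0
) -> np.ndarray:
    """Band indices with importance strictly above ``threshold``, ascending."""
    idx = [s.band_index for s in scores if s.importance > threshold]
    return np.array(sorted(idx), dtype=int)


def edf_schedule(n_bands: int, n_runs: int) -> np.ndarray:
    """Retention counts ceil(r_i * B) for the EDF r_i = a*exp(-k*i).

    Boundary conditions r_1 = 1 and r_N = 2/B fix
    a = (B/2)^(1/(N-1)) and k = ln(B/2)/(N-1).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if n_bands < 3:
        raise ValueError("need at least 3 bands")
    a = (n_bands / 2.0) ** (1.0 / (n_runs - 1))
    k = math.log(n_bands / 2.0) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    ratio = a * np.exp(-k * i)
    counts = np.ceil(ratio * n_bands).astype(int)
    counts[0] = n_bands  # r_1 = 1 exactly; guard rounding
    counts[-1] = 2
    return counts


def _rmsecv(X: np.ndarray, y: np.ndarray, n_components: int, cv_folds: int) -> float:
    """Root-mean-square error of deterministic k-fold cross-validation."""
    n = X.shape[0]
    ncomp = min(n_components, X.shape[1], max(1, n - n // cv_folds - 1))
    kf = KFold(n_splits=cv_folds, shuffle=False)
    sq = 0.0
    for train, test in kf.split(X):
        pls = PLSRegression(n_components=min(ncomp, len(train) - 1), scale=False)
        pls.fit(X[train], y[train])
        pred = pls.predict(X[test]).ravel()
        sq += float(np.sum((pred - y[test]) ** 2))
    return math.sqrt(sq / n)


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    cal_fraction: float = 0.8,
    n_components: int = 5,
    cv_folds: int = 5,
    seed: int = 0,
) -> CarsResult:
    """Competitive adaptive reweighted sampling over the band axis.

    Each iteration draws a Monte Carlo calibration subset of rows, fits PLS
    on the currently retained bands, keeps the EDF-scheduled count of bands
    ranked by absolute regression coefficient, resamples within that set
    proportionally to coefficient weight (adaptive reweighted sampling),
    and scores the retained set by RMSECV.  The selected subset is the
    retained set of the minimum-RMSECV iteration.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not 0.0 < cal_fraction < 1.0:
        raise ValueError("cal_fraction must be in (0, 1)")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    rng = np.random.default_rng(seed)
    counts = edf_schedule(B, n_runs)
    retained = np.arange(B)
    retained_sets: list[np.ndarray] = []
    rmsecv: list[float] = []
    n_cal = max(2, int(round(cal_fraction * n)))

    for i in range(n_runs):
        cal = rng.choice(n, size=n_cal, replace=False)
        ncomp = min(n_components, retained.size, n_cal - 1)
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(X[np.ix_(cal, retained)], y[cal])
        weights = np.abs(np.asarray(pls.coef_).reshape(-1))

        n_keep = min(int(counts[i]), retained.size)
        order = np.argsort(-weights, kind="stable")
        forced = retained[order[:n_keep]]
        w_forced = weights[order[:n_keep]]
        if w_forced.sum() <= 0:
            probs = np.full(n_keep, 1.0 / n_keep)
        else:
            probs = w_forced / w_forced.sum()
        sampled = np.unique(rng.choice(forced, size=n_keep, p=probs))
        if sampled.size < max(2, min(n_components, 2)):
            break  # degenerate subset: stop at last valid iteration
        retained = np.sort(sampled)
        retained_sets.append(retained.copy())
        rmsecv.append(_rmsecv(X[:, retained], y, n_components, cv_folds))
        if retained.size <= 2:
            break

    rmsecv_arr = np.asarray(rmsecv)
    best = int(np.argmin(rmsecv_arr))
    return CarsResult(
        retained_sets=retained_sets,
        rmsecv=rmsecv_arr,
        selected=retained_sets[best].copy(),
        best_iteration=best,
        seed=seed,
        edf_counts=counts,
    )
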
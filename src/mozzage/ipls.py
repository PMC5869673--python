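"""Interval partial least squares: the chemometric core.

PLS regression projects thousands of collinear wavelength columns onto a
few latent components chosen to covary with age.  The interval variant
fits separate PLS models on non-overlapping wavelength windows and keeps
the most predictive windows; per-model component counts are chosen by
bootstrap cross-validation.  Columns are mean-centred; unit-variance
scaling is off by default, matching long-standing chemometric practice
for absorbance spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .errors import ConfigurationError, DegenerateInputError, GridError
from .spectra_io import SpectraDataset, WavelengthGrid


@dataclass(frozen=True)
class WavelengthInterval:
    """Closed wavelength interval [low_nm, high_nm], in nm."""

    low_nm: float
    high_nm: float

    def __post_init__(self) -> None:
        if self.low_nm > self.high_nm:
            raise GridError(
                f"interval low ({self.low_nm}) exceeds high ({self.high_nm})"
            )

    def __str__(self) -> str:
        return f"[{self.low_nm:g}-{self.high_nm:g} nm]"


#: Optimal age-predictive windows for Anopheles spectra.
ANOPHELES_INTERVALS = (
    WavelengthInterval(350, 708),
    WavelengthInterval(709, 1066),
    WavelengthInterval(1067, 1424),
)
#: Optimal age-predictive windows for Aedes spectra.
AEDES_INTERVALS = (
    WavelengthInterval(709, 1066),
    WavelengthInterval(1067, 1424),
)
#: The wider window whose PLS model supplements the interval models
#: (it improves predictions for older mosquitoes).
WIDE_INTERVAL = WavelengthInterval(350, 1850)

GENUS_PRESETS = {
    "anopheles": ANOPHELES_INTERVALS,
    "aedes": AEDES_INTERVALS,
}

#: Component caps: 20 for interval models, 40 for the wide-window model.
INTERVAL_COMPONENT_CAP = 20
WIDE_COMPONENT_CAP = 40


@dataclass(frozen=True)
class CVConfig:
    """Bootstrap cross-validation settings for component selection.

    Each repetition draws a with-replacement sample of the training rows;
    the out-of-bag rows form the validation fold.  The component count
    minimising the mean out-of-bag RMSE is chosen, ties broken toward
    fewer components.
    """

    n_bootstrap: int = 25
    seed: int = 0
    component_cap: int = INTERVAL_COMPONENT_CAP

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ConfigurationError("n_bootstrap must be >= 1")
        if self.component_cap < 1:
            raise ConfigurationError("component_cap must be >= 1")


def bin_intervals(
    grid: WavelengthGrid, intervals
) -> list[np.ndarray]:
    """Map wavelength intervals to disjoint column-index ranges of `grid`.

    Raises :class:`ConfigurationError` if intervals overlap and
    :class:`GridError` if one does not intersect the grid.
    """
    ivs = [
        iv if isinstance(iv, WavelengthInterval) else WavelengthInterval(*iv)
        for iv in intervals
    ]
    ordered = sorted(ivs, key=lambda iv: iv.low_nm)
    for a, b in zip(ordered[:-1], ordered[1:]):
        if b.low_nm <= a.high_nm:
            raise ConfigurationError(f"intervals {a} and {b} overlap")
    out = []
    for iv in ivs:
        idx = grid.indices_between(iv.low_nm, iv.high_nm)
        if idx.size == 0:
            raise GridError(f"interval {iv} does not intersect the grid")
        out.append(idx)
    return out


class PLSModel:
    """A fitted single-response PLS regression on one wavelength window.

    Stores the centring vectors and regression coefficients needed to
    predict ages on new spectra.  ``n_components == 0`` denotes the
    intercept-only model returned when the training response is constant.
    """

    def __init__(
        self,
        *,
        interval: WavelengthInterval | None,
        n_components: int,
        coef: np.ndarray | None,
        x_mean: np.ndarray | None,
        y_mean: float,
        n_columns: int,
        cv_rmse: np.ndarray | None = None,
    ):
        self.interval = interval
        self.n_components = int(n_components)
        self.coef_ = coef
        self.x_mean_ = x_mean
        self.y_mean_ = float(np.asarray(y_mean).reshape(-1)[0])
        self.n_columns = int(n_columns)
        #: Mean out-of-bag RMSE indexed by component count (1-based entry k-1).
        self.cv_rmse_ = cv_rmse

    @property
    def cv_score_(self) -> float:
        """Cross-validated RMSE at the chosen component count."""
        if self.cv_rmse_ is None or self.n_components == 0:
            return float("nan")
        return float(self.cv_rmse_[self.n_components - 1])

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_columns:
            raise ConfigurationError(
                f"model expects {self.n_columns} wavelength columns, "
                f"got {X.shape[1]}"
            )
        if self.n_components == 0:
            return np.full(X.shape[0], self.y_mean_)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


def _truncated_coefs(pls: PLSRegression, k: int) -> np.ndarray:
    # The NIPALS deflation is sequential, so the first k components of a
    # model fitted with more components equal a k-component fit exactly.
    return (pls.x_rotations_[:, :k] @ pls.y_loadings_[:, :k].T).ravel()


def fit_pls(
    X,
    y,
    cv: CVConfig | None = None,
    *,
    interval: WavelengthInterval | None = None,
    scale: bool = False,
) -> PLSModel:
    """Fit a PLS model with bootstrap-CV component selection.

    Parameters
    ----------
    X, y:
        Training spectra sub-matrix (rows = mosquitoes) and ages (days).
    cv:
        Bootstrap settings; ``cv.component_cap`` bounds the search.
    interval:
        Optional provenance tag recording which window `X` was cut from.
    scale:
        If True, scale columns to unit variance as well as centring them.
    """
    cv = cv or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ConfigurationError("X must be 2-d with one row per element of y")
    n, p = X.shape
    if n < 3:
        raise ConfigurationError(f"need at least 3 training rows, got {n}")
    if np.ptp(y) == 0:
        return PLSModel(
            interval=interval,
            n_components=0,
            coef=None,
            x_mean=None,
            y_mean=y[0],
            n_columns=p,
        )
    col_var = X.var(axis=0)
    if np.all(col_var <= 0):
        raise DegenerateInputError("every spectral column has zero variance")

    k_max = int(min(cv.component_cap, p, n - 1))
    rng = np.random.default_rng(cv.seed)
    sq_err = np.zeros(k_max)
    counts = np.zeros(k_max)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(cv.n_bootstrap):
            boot = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), boot)
            if oob.size == 0 or np.ptp(y[boot]) == 0:
                continue
            k_rep = int(min(k_max, np.unique(boot).size - 1))
            if k_rep < 1:
                continue
            pls = PLSRegression(n_components=k_rep, scale=scale)
            pls.fit(X[boot], y[boot])
            Xc = X[oob] - pls._x_mean
            if scale:
                Xc = Xc / pls._x_std
            for k in range(1, k_rep + 1):
                pred = Xc @ _truncated_coefs(pls, k) + pls._y_mean
                sq_err[k - 1] += np.sum((pred - y[oob]) ** 2)
                counts[k - 1] += oob.size
        valid = counts > 0
        if not np.any(valid):
            # Degenerate bootstrap (tiny n); fall back to 1 component.
            best_k = 1
            cv_rmse = None
        else:
            cv_rmse = np.full(k_max, np.inf)
            cv_rmse[valid] = np.sqrt(sq_err[valid] / counts[valid])
            # ties (within floating-point slack) break toward fewer components
            tol = cv_rmse.min() * (1 + 1e-6) + 1e-8 * float(np.std(y))
            best_k = int(np.argmax(cv_rmse <= tol)) + 1
        final = PLSRegression(n_components=best_k, scale=scale)
        final.fit(X, y)
    coef = _truncated_coefs(final, best_k)
    x_mean = final._x_mean.copy()
    if scale:
        coef = coef / final._x_std
    return PLSModel(
        interval=interval,
        n_components=best_k,
        coef=coef,
        x_mean=x_mean,
        y_mean=final._y_mean,
        n_columns=p,
        cv_rmse=cv_rmse,
    )


def predict_pls(model: PLSModel, X) -> np.ndarray:
    """Predicted ages (days) for a spectra sub-matrix; forward pass only."""
    return model.predict(X)


def candidate_windows(
    grid: WavelengthGrid,
    width_nm: float = 358.0,
    *,
    start_nm: float | None = None,
    stop_nm: float | None = None,
) -> list[WavelengthInterval]:
    """Equal-width non-overlapping candidate windows tiling the grid."""
    lo = grid.start_nm if start_nm is None else start_nm
    hi = grid.stop_nm if stop_nm is None else stop_nm
    out = []
    x = lo
    while x <= hi - grid.step_nm:
        out.append(WavelengthInterval(x, min(x + width_nm, hi)))
        x += width_nm + grid.step_nm
    return out


def search_intervals(
    train: SpectraDataset,
    candidate_intervals,
    cv: CVConfig | None = None,
    k_keep: int = 3,
) -> list[WavelengthInterval]:
    """Rank candidate windows by cross-validated RMSE and keep the best.

    Returns the ``k_keep`` candidates with the lowest bootstrap-CV RMSE,
    sorted into wavelength order.  The published per-genus presets
    (:data:`GENUS_PRESETS`) are available as a no-search shortcut.
    """
    cands = [
        iv if isinstance(iv, WavelengthInterval) else WavelengthInterval(*iv)
        for iv in candidate_intervals
    ]
    if len(cands) < 2:
        raise ConfigurationError("need at least 2 candidate intervals")
    if k_keep > len(cands):
        raise ConfigurationError(
            f"k_keep={k_keep} exceeds the {len(cands)} candidates"
        )
    if train.n_samples == 0:
        raise ConfigurationError("training dataset is empty")
    cv = cv or CVConfig()
    scores = []
    for iv in cands:
        cols = train.grid.indices_between(iv.low_nm, iv.high_nm)
        if cols.size == 0:
            raise GridError(f"candidate {iv} does not intersect the grid")
        model = fit_pls(train.absorbance[:, cols], train.ages, cv, interval=iv)
        scores.append(model.cv_score_)
    order = np.argsort(scores, kind="stable")[:k_keep]
    return sorted((cands[i] for i in order), key=lambda iv: iv.low_nm)
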
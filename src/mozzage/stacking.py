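"""Combining interval models and removing prediction bias.

The per-window PLS predictions, together with the wide-window model's
prediction, are combined by an additive model with one penalized cubic
spline per base predictor, fitted on the validation rows only.  Raw
stacked predictions systematically over-predict young and under-predict
old mosquitoes (a regression-to-the-mean effect amplified by the age
imbalance of calibration datasets), so a second, monotone spline map from
raw prediction to age is fitted on the same validation rows and applied
to held-out spectra.  Removing the bias costs a little RMSE but makes
population mean-age estimates unbiased, which is what field monitoring
needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from sklearn.isotonic import IsotonicRegression

from .errors import ConfigurationError, GridError, SizeError
from .ipls import (
    CVConfig,
    GENUS_PRESETS,
    INTERVAL_COMPONENT_CAP,
    PLSModel,
    WIDE_COMPONENT_CAP,
    WIDE_INTERVAL,
    WavelengthInterval,
    bin_intervals,
    fit_pls,
)
from .spectra_io import SpectraDataset, SplitResult, SplitSpec, split_train_val_test


@dataclass(frozen=True)
class SplineConfig:
    """Penalized cubic regression spline settings.

    ``df`` is the basis dimension per smooth term; the penalty weight is
    chosen by generalized cross-validation over ``alpha_grid``.
    ``min_rows`` guards against fitting the stacker on validation sets too
    small to support the smooths; lower it (with a smaller ``df``) only for
    deliberately scaled-down experiments.
    """

    df: int = 8
    degree: int = 3
    alpha_grid: tuple = tuple(float(a) for a in np.logspace(-4.0, 5.0, 10))
    min_rows: int = 30


class _PenalizedAdditiveSpline:
    """Additive P-spline smoother: cubic B-spline bases with a
    second-difference coefficient penalty per term, penalty weight shared
    across terms and chosen by generalized cross-validation.  Solved by
    direct penalized least squares, so it is robust to noiseless inputs.
    Inputs outside the fitted range are clamped to it.
    """

    def __init__(self, df: int, degree: int, alpha_grid):
        self.df = df
        self.degree = degree
        self.alpha_grid = tuple(alpha_grid)
        self._bases: list[tuple[np.ndarray, int]] = []  # (knots, n_basis)
        self._ranges: np.ndarray | None = None
        self._coef: np.ndarray | None = None
        self.gcv_: float | None = None
        self.edf_: float | None = None

    def _knots(self, x: np.ndarray) -> tuple[np.ndarray, int]:
        k = self.degree
        lo, hi = float(x.min()), float(x.max())
        n_interior = max(self.df - k - 1, 0)
        if n_interior:
            qs = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
            interior = np.unique(qs[(qs > lo) & (qs < hi)])
        else:
            interior = np.array([])
        t = np.concatenate([np.full(k + 1, lo), interior, np.full(k + 1, hi)])
        return t, t.size - k - 1

    def _design(self, X: np.ndarray) -> np.ndarray:
        cols = [np.ones((X.shape[0], 1))]
        for j, (t, nb) in enumerate(self._bases):
            xj = np.clip(X[:, j], self._ranges[0, j], self._ranges[1, j])
            cols.append(BSpline.design_matrix(xj, t, self.degree).toarray())
        return np.hstack(cols)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PenalizedAdditiveSpline":
        n, m = X.shape
        self._ranges = np.stack([X.min(axis=0), X.max(axis=0)])
        self._bases = [self._knots(X[:, j]) for j in range(m)]
        D = self._design(X)
        p = D.shape[1]
        # Block-diagonal second-difference penalty; a whisper of ridge on
        # everything keeps the overlap between the intercept and the
        # per-term constants identifiable.
        pen = 1e-8 * np.eye(p)
        offset = 1
        blocks = []
        for t, nb in self._bases:
            if nb >= 3:
                d2 = np.diff(np.eye(nb), n=2, axis=0)
                blocks.append((offset, d2.T @ d2))
            offset += nb
        DtD = D.T @ D
        Dty = D.T @ y
        best = (np.inf, None, None)
        for alpha in self.alpha_grid:
            P = pen.copy()
            for off, block in blocks:
                nb = block.shape[0]
                P[off : off + nb, off : off + nb] += alpha * block
            A = DtD + P
            try:
                coef = np.linalg.solve(A, Dty)
                edf = float(np.trace(np.linalg.solve(A, DtD)))
            except np.linalg.LinAlgError:  # pragma: no cover
                continue
            rss = float(np.sum((D @ coef - y) ** 2))
            gcv = n * rss / max(n - edf, 1e-8) ** 2
            if gcv < best[0]:
                best = (gcv, coef, edf)
        self.gcv_, self._coef, self.edf_ = best
        if self._coef is None:  # pragma: no cover - singular for all alphas
            raise ConfigurationError("penalized spline system is singular")
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._design(X) @ self._coef


class SplineStacker:
    """Additive penalized-spline combiner of base-model predictions."""

    def __init__(self, config: SplineConfig | None = None):
        self.config = config or SplineConfig()
        self._smooth: _PenalizedAdditiveSpline | None = None
        self._active: np.ndarray | None = None
        self._y_mean = 0.0
        self.n_inputs: int | None = None

    def fit(self, base_predictions, true_ages) -> "SplineStacker":
        X = np.asarray(base_predictions, dtype=float)
        y = np.asarray(true_ages, dtype=float).ravel()
        if X.ndim == 1:
            X = X[:, None]
        n, m = X.shape
        if n != y.size:
            raise ConfigurationError("row mismatch between predictions and ages")
        cfg = self.config
        if n < cfg.min_rows:
            raise SizeError(
                f"stacker needs >= {cfg.min_rows} validation rows, got {n}"
            )
        if n <= m * cfg.df + 1:
            raise ConfigurationError(
                f"{n} rows cannot support {m} smooth terms of df={cfg.df}"
            )
        self.n_inputs = m
        self._y_mean = float(y.mean())
        # Constant base predictors carry no information and break the
        # spline basis; exclude them from the smoother.
        self._active = np.flatnonzero(np.ptp(X, axis=0) > 1e-12)
        if self._active.size == 0:
            self._smooth = None
            return self
        self._smooth = _PenalizedAdditiveSpline(
            cfg.df, cfg.degree, cfg.alpha_grid
        ).fit(X[:, self._active], y)
        return self

    def predict(self, base_predictions) -> np.ndarray:
        X = np.asarray(base_predictions, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.n_inputs is None:
            raise ConfigurationError("stacker is not fitted")
        if X.shape[1] != self.n_inputs:
            raise ConfigurationError(
                f"stacker expects {self.n_inputs} base predictions per row"
            )
        if self._smooth is None:
            return np.full(X.shape[0], self._y_mean)
        return self._smooth.predict(X[:, self._active])


def fit_stacker(
    base_predictions, true_ages, spline_config: SplineConfig | None = None
) -> SplineStacker:
    """Fit the additive spline combiner on validation-set predictions."""
    return SplineStacker(spline_config).fit(base_predictions, true_ages)


@dataclass
class BiasCurve:
    """Mean prediction error (days) on a grid of true ages."""

    ages: np.ndarray
    mean_error: np.ndarray


def bias_curve(predicted, true, n_bins: int = 10) -> BiasCurve:
    """Binned mean error (predicted - true) across the observed age range."""
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    edges = np.quantile(true, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    centers, errs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (true >= lo) & (true <= hi)
        if mask.any():
            centers.append(true[mask].mean())
            errs.append((predicted[mask] - true[mask]).mean())
    return BiasCurve(np.asarray(centers), np.asarray(errs))


class BiasCorrector:
    """Monotone map from raw stacked prediction to corrected age.

    The map is a penalized spline fit of true age on raw prediction,
    smoothed onto a dense grid and made monotone non-decreasing by
    isotonic regression.  Beyond the fitted range it extends linearly
    (splines extrapolate wildly otherwise); corrected ages are floored
    at 0 days.
    """

    def __init__(
        self,
        x_grid: np.ndarray,
        y_grid: np.ndarray,
        *,
        identity: bool = False,
    ):
        self.x_grid = np.asarray(x_grid, dtype=float)
        self.y_grid = np.asarray(y_grid, dtype=float)
        self.identity = identity
        if not identity:
            if np.any(np.diff(self.y_grid) < -1e-9):
                raise ConfigurationError("bias-correction map must be monotone")
            span = self.x_grid[-1] - self.x_grid[0]
            edge = max(3, int(0.1 * self.x_grid.size))
            self._slope_lo = self._edge_slope(slice(0, edge))
            self._slope_hi = self._edge_slope(slice(-edge, None))

    def _edge_slope(self, sl: slice) -> float:
        x, y = self.x_grid[sl], self.y_grid[sl]
        dx = x[-1] - x[0]
        return float((y[-1] - y[0]) / dx) if dx > 0 else 0.0

    def __call__(self, raw) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        if self.identity:
            return np.maximum(raw, 0.0)
        out = np.interp(raw, self.x_grid, self.y_grid)
        lo, hi = self.x_grid[0], self.x_grid[-1]
        below = raw < lo
        above = raw > hi
        out[below] = self.y_grid[0] + self._slope_lo * (raw[below] - lo)
        out[above] = self.y_grid[-1] + self._slope_hi * (raw[above] - hi)
        return np.maximum(out, 0.0)


def fit_bias_correction(
    raw_predictions,
    true_ages,
    spline_config: SplineConfig | None = None,
    *,
    grid_size: int = 256,
) -> BiasCorrector:
    """Fit the monotone recalibration map on validation-set predictions."""
    raw = np.asarray(raw_predictions, dtype=float).ravel()
    true = np.asarray(true_ages, dtype=float).ravel()
    if raw.size != true.size:
        raise ConfigurationError("row mismatch between predictions and ages")
    if np.unique(true).size < 3:
        raise ConfigurationError("need >= 3 distinct true ages")
    if np.ptp(raw) <= 1e-12:
        warnings.warn(
            "raw predictions are constant; bias corrector falls back to the "
            "identity map",
            stacklevel=2,
        )
        return BiasCorrector(raw[:1], raw[:1], identity=True)

    cfg = spline_config or SplineConfig()
    x = np.linspace(raw.min(), raw.max(), grid_size)
    smooth = _PenalizedAdditiveSpline(cfg.df, cfg.degree, cfg.alpha_grid)
    smooth.fit(raw[:, None], true)
    smoothed = smooth.predict(x[:, None])
    iso = IsotonicRegression(increasing=True)
    monotone = iso.fit_transform(x, smoothed)
    return BiasCorrector(x, monotone)


@dataclass
class AgePipeline:
    """The trained end-to-end age predictor.

    Interval PLS models plus the wide-window PLS model feed an additive
    spline stacker; an optional monotone bias corrector recalibrates the
    stacked output.  Base models are fitted on the inner training rows
    only, the stacker and corrector on the validation rows only, and the
    recorded split indices allow a leakage audit.
    """

    grid_wavelengths: np.ndarray
    intervals: tuple
    interval_columns: list
    wide_columns: np.ndarray
    interval_models: list
    wide_model: PLSModel
    stacker: SplineStacker
    bias_corrector: BiasCorrector | None
    genus: str | None = None
    seed: int | None = None
    split_sizes: tuple | None = None
    split_indices: dict = field(default_factory=dict, repr=False)

    def _check_grid(self, ds: SpectraDataset) -> None:
        if len(ds.grid) != self.grid_wavelengths.size or not np.allclose(
            ds.grid.wavelengths, self.grid_wavelengths
        ):
            raise GridError("dataset grid does not match the fitted pipeline")

    def base_predictions(self, ds: SpectraDataset) -> np.ndarray:
        self._check_grid(ds)
        cols = [ds.absorbance[:, c] for c in self.interval_columns]
        preds = [m.predict(X) for m, X in zip(self.interval_models, cols)]
        preds.append(self.wide_model.predict(ds.absorbance[:, self.wide_columns]))
        return np.column_stack(preds)

    def predict_raw(self, ds: SpectraDataset) -> np.ndarray:
        """Stacked prediction before bias correction (days)."""
        return self.stacker.predict(self.base_predictions(ds))

    def predict(self, ds: SpectraDataset) -> np.ndarray:
        """Corrected age predictions (days), finite and floored at 0."""
        raw = self.predict_raw(ds)
        if self.bias_corrector is None:
            return np.maximum(raw, 0.0)
        return self.bias_corrector(raw)


def fit_pipeline(
    ds: SpectraDataset,
    genus: str = "anopheles",
    split: SplitSpec | None = None,
    cv: CVConfig | None = None,
    *,
    intervals=None,
    bias_correct: bool = True,
    wide_interval: WavelengthInterval = WIDE_INTERVAL,
    wide_cap: int = WIDE_COMPONENT_CAP,
    spline_config: SplineConfig | None = None,
    precomputed_split: SplitResult | None = None,
) -> AgePipeline:
    """Train the full interval-PLS age pipeline on one dataset.

    The dataset is partitioned per ``split``; interval and wide-window PLS
    models are fitted on the inner training rows, and the stacker plus
    bias corrector on the validation rows.  Test rows are never touched,
    so held-out evaluation stays honest.
    """
    if ds.n_samples < 50:
        warnings.warn(
            f"fitting a pipeline on only {ds.n_samples} rows; >= 50 recommended",
            stacklevel=2,
        )
    if intervals is None:
        try:
            intervals = GENUS_PRESETS[genus.lower()]
        except KeyError:
            raise ConfigurationError(
                f"unknown genus preset {genus!r}; expected one of "
                f"{sorted(GENUS_PRESETS)} (or pass intervals= explicitly)"
            ) from None
    split = split or SplitSpec()
    cv = cv or CVConfig()
    parts = precomputed_split or split_train_val_test(ds, split)
    train, val = parts.train, parts.val

    interval_columns = bin_intervals(ds.grid, intervals)
    wide_columns = ds.grid.indices_between(
        wide_interval.low_nm, wide_interval.high_nm
    )
    if wide_columns.size == 0:
        raise GridError(f"wide interval {wide_interval} misses the grid")

    interval_models = []
    for iv, cols in zip(intervals, interval_columns):
        iv_cv = CVConfig(cv.n_bootstrap, cv.seed, min(cv.component_cap, INTERVAL_COMPONENT_CAP))
        interval_models.append(
            fit_pls(train.absorbance[:, cols], train.ages, iv_cv, interval=iv)
        )
    wide_cv = CVConfig(cv.n_bootstrap, cv.seed, wide_cap)
    wide_model = fit_pls(
        train.absorbance[:, wide_columns], train.ages, wide_cv, interval=wide_interval
    )

    pipeline = AgePipeline(
        grid_wavelengths=ds.grid.wavelengths,
        intervals=tuple(intervals),
        interval_columns=interval_columns,
        wide_columns=wide_columns,
        interval_models=interval_models,
        wide_model=wide_model,
        stacker=SplineStacker(spline_config),
        bias_corrector=None,
        genus=genus,
        seed=split.seed,
        split_sizes=(train.n_samples, val.n_samples, parts.test.n_samples),
        split_indices={
            "train": parts.train_idx,
            "val": parts.val_idx,
            "test": parts.test_idx,
        },
    )
    base_val = pipeline.base_predictions(val)
    pipeline.stacker.fit(base_val, val.ages)
    if bias_correct:
        raw_val = pipeline.stacker.predict(base_val)
        pipeline.bias_corrector = fit_bias_correction(
            raw_val, val.ages, spline_config
        )
    return pipeline


def predict_age(pipeline: AgePipeline, spectra: SpectraDataset) -> np.ndarray:
    """Corrected age predictions (days) for new spectra."""
    return pipeline.predict(spectra)


# ---------------------------------------------------------------------------
# The "standard" comparison method: one full-spectrum PLS model
# ---------------------------------------------------------------------------

@dataclass
class StandardPipeline:
    """Single full-spectrum PLS predictor, no stacking or bias correction.

    This is the classical NIRS chemometric baseline: one PLS regression
    over the whole recorded spectrum with components chosen by the same
    bootstrap CV as the interval models.
    """

    grid_wavelengths: np.ndarray
    model: PLSModel

    def predict(self, ds: SpectraDataset) -> np.ndarray:
        if len(ds.grid) != self.grid_wavelengths.size or not np.allclose(
            ds.grid.wavelengths, self.grid_wavelengths
        ):
            raise GridError("dataset grid does not match the fitted pipeline")
        return self.model.predict(ds.absorbance)


def fit_standard_pipeline(
    ds: SpectraDataset,
    split: SplitSpec | None = None,
    cv: CVConfig | None = None,
    *,
    component_cap: int = WIDE_COMPONENT_CAP,
    precomputed_split: SplitResult | None = None,
) -> StandardPipeline:
    """Fit the full-spectrum baseline on the combined train+validation rows."""
    split = split or SplitSpec()
    cv = cv or CVConfig()
    parts = precomputed_split or split_train_val_test(ds, split)
    fit_idx = np.sort(np.concatenate([parts.train_idx, parts.val_idx]))
    fit_ds = ds.subset(fit_idx)
    model = fit_pls(
        fit_ds.absorbance,
        fit_ds.ages,
        CVConfig(cv.n_bootstrap, cv.seed, component_cap),
        interval=WavelengthInterval(ds.grid.start_nm, ds.grid.stop_nm),
    )
    return StandardPipeline(ds.grid.wavelengths, model)
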
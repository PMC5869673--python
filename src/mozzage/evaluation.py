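"""Accuracy metrics, learning curves, and the RMSE-vs-training-size law.

Because individual-age prediction error is dominated by sampling
variation in the calibration data, the central limit theorem suggests
RMSE should fall off with the square root of the training-set size:

    RMSE(n) = a + b / sqrt(n)

with asymptote ``a`` (days) and scale ``b`` (days * sqrt(mosquitoes)).
The coefficients are estimated by Gaussian maximum likelihood, which for
this linear-in-parameters model is least squares on the regressor
``1/sqrt(n)`` (non-negativity enforced, since a negative asymptote or an
RMSE that grows with data is meaningless).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import ConfigurationError, SizeError
from .spectra_io import SpectraDataset, SplitSpec, split_train_val_test

#: Published reference coefficients for the RMSE-vs-training-size relation,
#: estimated from a large single-study Anopheles arabiensis calibration
#: dataset (n = 871): RMSE(n) ~= 0.44 + 34.81 / sqrt(n) days.
STUDY_A_POWER_LAW_A = 0.44
STUDY_A_POWER_LAW_B = 34.81


def rmse(predicted, true) -> float:
    """Root-mean-square error in days; 0 iff the vectors are identical."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if predicted.size != true.size:
        raise ConfigurationError(
            f"length mismatch: {predicted.size} predictions vs {true.size} truths"
        )
    if predicted.size == 0:
        raise SizeError("rmse needs at least one pair")
    return float(np.sqrt(np.mean((predicted - true) ** 2)))


@dataclass(frozen=True)
class PowerLawFit:
    """Coefficients of RMSE(n) = a + b / sqrt(n)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ConfigurationError("power-law coefficients must be >= 0")

    def predict(self, n_train) -> np.ndarray | float:
        return predicted_rmse(self, n_train)


def study_a_power_law() -> PowerLawFit:
    """The reference coefficients as a ready-made :class:`PowerLawFit`."""
    return PowerLawFit(STUDY_A_POWER_LAW_A, STUDY_A_POWER_LAW_B)


def fit_power_law(sizes, median_rmse) -> PowerLawFit:
    """Fit RMSE(n) = a + b/sqrt(n) by (non-negative) least squares.

    With Gaussian additive noise on the median RMSE values this is the
    maximum-likelihood estimate.  Needs >= 3 distinct sizes.
    """
    x = np.asarray(sizes, dtype=float).ravel()
    y = np.asarray(median_rmse, dtype=float).ravel()
    if x.size != y.size:
        raise ConfigurationError("sizes and median_rmse must align")
    if np.unique(x).size < 3:
        raise ConfigurationError("need >= 3 distinct training sizes")
    if np.any(x < 1):
        raise ConfigurationError("training sizes must be >= 1")
    design = np.column_stack([np.ones_like(x), 1.0 / np.sqrt(x)])
    coef, _ = nnls(design, y)
    return PowerLawFit(float(coef[0]), float(coef[1]))


def predicted_rmse(fit: PowerLawFit, n_train) -> np.ndarray | float:
    """RMSE (days) predicted at a given training-set size."""
    n = np.asarray(n_train, dtype=float)
    if np.any(n < 1):
        raise ConfigurationError("n_train must be >= 1")
    out = fit.a + fit.b / np.sqrt(n)
    return float(out) if out.ndim == 0 else out


@dataclass
class LearningCurveResult:
    """Replicate RMSEs per training size, with quartile summaries."""

    sizes: np.ndarray
    rmses: dict  # size -> array of replicate RMSEs (days)

    @property
    def medians(self) -> np.ndarray:
        return np.array([np.median(self.rmses[s]) for s in self.sizes])

    @property
    def q25(self) -> np.ndarray:
        return np.array([np.quantile(self.rmses[s], 0.25) for s in self.sizes])

    @property
    def q75(self) -> np.ndarray:
        return np.array([np.quantile(self.rmses[s], 0.75) for s in self.sizes])

    def to_frame(self) -> pd.DataFrame:
        """Tidy (size, replicate, rmse) table for plotting or export."""
        rows = [
            {"size": int(s), "replicate": r, "rmse": v}
            for s in self.sizes
            for r, v in enumerate(self.rmses[s])
        ]
        return pd.DataFrame(rows)

    def fit_power_law(self) -> PowerLawFit:
        return fit_power_law(self.sizes, self.medians)


def learning_curve(
    ds: SpectraDataset,
    sizes,
    replicates: int = 100,
    seed: int = 0,
    *,
    fit_predict=None,
    split: SplitSpec | None = None,
) -> LearningCurveResult:
    """Estimate test RMSE as a function of training-set size.

    A single test set (the ``split`` test fraction, stratified by age) is
    held fixed across all replicates so only the training-size effect
    varies.  For each size, each replicate draws that many rows without
    replacement from the training pool, fits a predictor and scores it on
    the test set.

    Parameters
    ----------
    fit_predict:
        Callable ``(train_ds, test_ds, seed) -> predictions``; defaults to
        fitting the full interval-PLS pipeline with its published presets.
    """
    from .stacking import fit_pipeline  # local import avoids a cycle

    split = split or SplitSpec(seed=seed)
    parts = split_train_val_test(ds, split)
    pool_idx = np.sort(np.concatenate([parts.train_idx, parts.val_idx]))
    pool = ds.subset(pool_idx)
    test = parts.test
    sizes = np.asarray(sizes, dtype=int)
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    if np.any(sizes > pool.n_samples):
        raise SizeError(
            f"requested size exceeds the {pool.n_samples}-row training pool"
        )
    if np.any(sizes < 10):
        raise SizeError("training sizes below 10 cannot support the pipeline")

    if fit_predict is None:
        # Default: the full interval-PLS pipeline, with the subsample split
        # 70/30 into inner-train and validation (the test set is the fixed
        # external one).  Sizes below ~100 rows need a custom fit_predict
        # with a smaller spline basis.

        def fit_predict(train_ds, test_ds, fit_seed):
            from .ipls import CVConfig
            from .spectra_io import split_train_val

            pipe = fit_pipeline(
                train_ds,
                cv=CVConfig(seed=int(fit_seed)),
                precomputed_split=split_train_val(train_ds, 0.3, int(fit_seed)),
            )
            return pipe.predict(test_ds)

    rng = np.random.default_rng(seed)
    rmses: dict[int, np.ndarray] = {}
    for s in sizes:
        vals = np.empty(replicates)
        for r in range(replicates):
            sub = rng.choice(pool.n_samples, size=int(s), replace=False)
            fit_seed = int(rng.integers(0, 2**31 - 1))
            preds = fit_predict(pool.subset(sub), test, fit_seed)
            vals[r] = rmse(preds, test.ages)
        rmses[int(s)] = vals
    return LearningCurveResult(sizes=sizes, rmses=rmses)
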
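"""Heteroscedastic surrogate for "spectrometer + age pipeline".

Population-level simulations need the distribution of predicted age given
true age, but generating spectra for every simulated mosquito would be
wasteful.  The surrogate is a linear model with age-dependent noise,

    predicted ~ Normal(alpha + beta * age, (sigma0 + sigma1 * age)^2),

fitted to (true age, pipeline prediction) pairs.  An unbiased pipeline
gives alpha ~= 0, beta ~= 1; sigma1 > 0 captures the widening spread of
predictions for older mosquitoes.  Fitting is Bayesian with weakly
informative priors; a deterministic point-estimate (MAP) mode exists for
tests, a Laplace mode gives fast approximate posteriors, and an MCMC
mode (affine-invariant ensemble sampler) gives full posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError, SizeError

_SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors; override for sensitivity analysis.

    alpha ~ Normal(0, 5^2) days; beta ~ Normal(1, 1^2);
    sigma0, sigma1 ~ Half-Normal(2.5).
    """

    alpha_loc: float = 0.0
    alpha_scale: float = 5.0
    beta_loc: float = 1.0
    beta_scale: float = 1.0
    sigma_scale: float = 2.5


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-MCMC settings for the fully Bayesian mode."""

    n_walkers: int = 32
    n_steps: int = 1500
    n_burn: int = 500
    thin: int = 5
    seed: int = 0


@dataclass
class SurrogateModel:
    """Fitted surrogate parameters, optionally with posterior draws.

    ``sigma0`` is the noise SD at age 0 (days); ``sigma1`` is its growth
    per day of age.  ``posterior`` holds draws of (alpha, beta, sigma0,
    sigma1), one row per draw, when fitted in Laplace or MCMC mode.
    """

    alpha: float
    beta: float
    sigma0: float
    sigma1: float = 0.0
    posterior: np.ndarray | None = field(default=None, repr=False)
    age_range: tuple | None = None
    diagnostics: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.sigma1 < 0:
            raise ConfigurationError("noise-scale parameters must be >= 0")

    def sd(self, age) -> np.ndarray | float:
        """Measurement SD (days) at a given true age."""
        return self.sigma0 + self.sigma1 * np.asarray(age, dtype=float)

    def credible_intervals(self, level: float = 0.95) -> dict:
        """Central posterior intervals per parameter (posterior modes only)."""
        if self.posterior is None:
            raise ConfigurationError("model has no posterior draws")
        q = [(1 - level) / 2, 1 - (1 - level) / 2]
        names = ("alpha", "beta", "sigma0", "sigma1")
        los, his = np.quantile(self.posterior, q, axis=0)
        return {n: (float(lo), float(hi)) for n, lo, hi in zip(names, los, his)}


def _log_posterior(theta, t, p, priors: PriorConfig):
    alpha, beta, s0, s1 = theta
    sd = s0 + s1 * t
    if s0 < 0 or s1 < 0 or np.any(sd <= 0):
        return -np.inf
    resid = p - alpha - beta * t
    ll = -0.5 * np.sum((resid / sd) ** 2) - np.sum(np.log(sd))
    lp = (
        -0.5 * ((alpha - priors.alpha_loc) / priors.alpha_scale) ** 2
        - 0.5 * ((beta - priors.beta_loc) / priors.beta_scale) ** 2
        - 0.5 * (s0 / priors.sigma_scale) ** 2
        - 0.5 * (s1 / priors.sigma_scale) ** 2
    )
    return ll + lp


def _map_estimate(t, p, priors):
    slope, intercept = np.polyfit(t, p, 1)
    resid_sd = max(float(np.std(p - intercept - slope * t)), 0.05)
    x0 = np.array([intercept, slope, resid_sd, 0.01])
    res = minimize(
        lambda th: -_log_posterior(th, t, p, priors),
        x0,
        method="L-BFGS-B",
        bounds=[(None, None), (None, None), (_SIGMA_FLOOR, None), (0.0, None)],
    )
    return res


def _numerical_hessian(f, x, eps=1e-4):
    n = x.size
    h = np.empty((n, n))
    steps = eps * np.maximum(np.abs(x), 1.0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h


def fit_surrogate(
    true_ages,
    predicted_ages,
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    *,
    method: str = "laplace",
) -> SurrogateModel:
    """Fit the heteroscedastic surrogate to (true, predicted) age pairs.

    Parameters
    ----------
    method:
        ``"map"`` - deterministic point estimate (posterior mode), no draws;
        ``"laplace"`` - MAP plus a Gaussian approximation of the posterior
        (2000 draws); ``"mcmc"`` - affine-invariant ensemble sampling.
    """
    t = np.asarray(true_ages, dtype=float).ravel()
    p = np.asarray(predicted_ages, dtype=float).ravel()
    if t.size != p.size:
        raise ConfigurationError("true and predicted ages must align")
    if t.size < 50:
        raise SizeError(f"surrogate fitting needs >= 50 pairs, got {t.size}")
    if np.unique(t).size < 3:
        raise ConfigurationError("true ages must span >= 3 distinct values")
    priors = priors or PriorConfig()
    sampler = sampler or SamplerConfig()

    res = _map_estimate(t, p, priors)
    theta = res.x
    diagnostics = {"map_converged": bool(res.success), "neg_log_post": float(res.fun)}
    if np.any(theta[2] + theta[3] * t <= 0):  # pragma: no cover - bounded away
        raise ConfigurationError(
            "fitted noise scale is non-positive on the observed age range; "
            f"theta={theta.tolist()}"
        )
    posterior = None

    if method == "map":
        pass
    elif method == "laplace":
        f = lambda th: -_log_posterior(th, t, p, priors)  # noqa: E731
        hess = _numerical_hessian(f, theta)
        try:
            cov = np.linalg.inv(hess)
            # Symmetrise and repair tiny negative eigenvalues from finite
            # differencing near the sigma bounds.
            cov = (cov + cov.T) / 2
            w, v = np.linalg.eigh(cov)
            cov = (v * np.maximum(w, 1e-12)) @ v.T
        except np.linalg.LinAlgError:  # pragma: no cover
            cov = np.diag(np.full(4, 1e-6))
        rng = np.random.default_rng(sampler.seed)
        draws = rng.multivariate_normal(theta, cov, size=2000)
        draws[:, 2] = np.maximum(draws[:, 2], _SIGMA_FLOOR)
        draws[:, 3] = np.maximum(draws[:, 3], 0.0)
        posterior = draws
        diagnostics["posterior_sd"] = np.sqrt(np.diag(cov)).tolist()
    elif method == "mcmc":
        import emcee

        ndim = 4
        rng = np.random.default_rng(sampler.seed)
        p0 = theta + 1e-3 * np.abs(theta + 0.1) * rng.standard_normal(
            (sampler.n_walkers, ndim)
        )
        p0[:, 2] = np.maximum(p0[:, 2], 2 * _SIGMA_FLOOR)
        p0[:, 3] = np.abs(p0[:, 3])
        es = emcee.EnsembleSampler(
            sampler.n_walkers, ndim, _log_posterior, args=(t, p, priors)
        )
        es.random_state = np.random.RandomState(sampler.seed).get_state()
        es.run_mcmc(p0, sampler.n_steps, progress=False)
        posterior = es.get_chain(discard=sampler.n_burn, thin=sampler.thin, flat=True)
        diagnostics["mean_acceptance"] = float(np.mean(es.acceptance_fraction))
        theta = posterior.mean(axis=0)
        theta[2] = max(theta[2], _SIGMA_FLOOR)
        theta[3] = max(theta[3], 0.0)
    else:
        raise ConfigurationError(f"unknown fitting method {method!r}")

    return SurrogateModel(
        alpha=float(theta[0]),
        beta=float(theta[1]),
        sigma0=float(theta[2]),
        sigma1=float(theta[3]),
        posterior=posterior,
        age_range=(float(t.min()), float(t.max())),
        diagnostics=diagnostics,
    )


def simulate_predictions(
    model: SurrogateModel,
    true_ages,
    seed: int = 0,
    mode: str = "point",
    *,
    floor_at_zero: bool = True,
) -> np.ndarray:
    """Draw simulated pipeline predictions for given true ages.

    ``mode="point"`` uses the fitted point parameters; ``mode="posterior"``
    draws one parameter set from the posterior per call (one replicate),
    propagating parameter uncertainty across replicates.  Simulated ages
    are floored at 0 days by default (set ``floor_at_zero=False`` for
    strictly mean-zero measurement error).
    """
    ages = np.asarray(true_ages, dtype=float)
    if np.any(ages < 0):
        raise ConfigurationError("true ages must be >= 0")
    rng = np.random.default_rng(seed)
    if mode == "point":
        a, b, s0, s1 = model.alpha, model.beta, model.sigma0, model.sigma1
    elif mode == "posterior":
        if model.posterior is None:
            raise ConfigurationError(
                "posterior mode requires a model fitted with draws "
                "(method='laplace' or 'mcmc')"
            )
        a, b, s0, s1 = model.posterior[rng.integers(model.posterior.shape[0])]
    else:
        raise ConfigurationError(f"unknown simulation mode {mode!r}")
    sd = s0 + s1 * ages
    out = a + b * ages + rng.normal(0.0, 1.0, ages.shape) * sd
    return np.maximum(out, 0.0) if floor_at_zero else out


def surrogate_from_training_size(fit, n_train: int) -> SurrogateModel:
    """Unbiased homoscedastic surrogate whose SD follows the size-RMSE law.

    ``fit`` is a :class:`mozzage.evaluation.PowerLawFit`; the surrogate is
    alpha = 0, beta = 1, sigma = a + b / sqrt(n_train).
    """
    from .evaluation import predicted_rmse

    sigma = float(predicted_rmse(fit, n_train))
    return SurrogateModel(alpha=0.0, beta=1.0, sigma0=sigma, sigma1=0.0)
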
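"""Bayesian robust estimation of the cytosolic RNA volume fraction.

Whole-cell transcript abundances are, up to measurement error, a convex
combination of the nuclear and cytosolic abundances:

    FPKM_w(i) = (1 - beta) * FPKM_n(i) + beta * FPKM_c(i) + error(i)

where ``beta`` is the fraction of the total cellular RNA volume (nucleotides
summed over molecules) residing in the cytosol. The error is modelled as
Student-t, ``error(i) ~ t(nu, 0, sigma)``, which keeps the estimate robust to
outlying transcripts. Priors: ``nu ~ Gamma(2, 0.1)`` (rate parameterization),
``sigma ~ Exponential(mean = s)`` with ``s`` the standard deviation of the
whole-cell FPKMs (a weakly-informative data-dependent scale), and
``beta ~ Beta(2, 2)`` — symmetric around 0.5 and bounded in (0, 1).

Posterior sampling uses an affine-invariant ensemble MCMC (emcee) on the
unconstrained scale (logit beta, log nu, log sigma) with exact Jacobian
corrections; the point estimate of beta is the posterior mode (MAP), read off
a kernel-density estimate of the pooled draws. A fast deterministic
alternative maximizes the log posterior directly (`optimize_map`).

The estimator is exposed scikit-learn style as :class:`BetaTRegressor`
(``X`` columns = nuclear and cytosolic FPKM, ``y`` = whole-cell FPKM); the
module-level functions are thin wrappers operating on
:class:`~locindex.io.MatchedTriplet`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .io import MatchedTriplet

logger = logging.getLogger(__name__)

__all__ = [
    "BetaModelConfig",
    "BetaPosterior",
    "BetaTRegressor",
    "InferenceError",
    "QCStatus",
    "estimate_beta_map",
    "log_posterior",
    "optimize_map",
    "qc_beta",
    "sample_posterior",
]


class InferenceError(RuntimeError):
    """Posterior sampling or optimization failed irrecoverably."""


class QCStatus(str, Enum):
    PASS = "pass"
    FLAG_EXCLUDE = "flag_exclude"


@dataclass
class BetaModelConfig:
    """Priors and sampler settings for the volume-fraction regression.

    ``target_accept`` and ``max_tree_depth`` configure gradient-based
    (NUTS/HMC) backends; the ensemble sampler used here ignores them, they
    are retained for interface compatibility. The number of retained
    posterior draws is ``chains * (iterations - warmup)`` regardless of
    backend.
    """

    nu_prior_shape: float = 2.0
    nu_prior_rate: float = 0.1
    sigma_prior_mean: float | None = None  # default: std of fpkm_w, set at fit time
    beta_prior_a: float = 2.0
    beta_prior_b: float = 2.0
    chains: int = 4
    iterations: int = 6000
    warmup: int = 2000
    target_accept: float = 0.9
    max_tree_depth: int = 10
    seed: int = 0
    n_walkers: int = 16
    error_model: str = "student_t"  # or "normal"

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        for name in ("nu_prior_shape", "nu_prior_rate", "beta_prior_a", "beta_prior_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_prior_mean is not None and self.sigma_prior_mean <= 0:
            raise ValueError("sigma_prior_mean must be positive")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must lie in (0, 1)")
        if self.error_model not in ("student_t", "normal"):
            raise ValueError("error_model must be 'student_t' or 'normal'")
        if self.n_walkers < 2 * self.chains or self.n_walkers % self.chains:
            raise ValueError("n_walkers must be a multiple of chains, at least 2 per chain")

    @property
    def n_draws(self) -> int:
        return self.chains * (self.iterations - self.warmup)


@dataclass
class BetaPosterior:
    """Pooled posterior draws of (beta, nu, sigma) with convergence diagnostics."""

    beta_draws: np.ndarray
    nu_draws: np.ndarray
    sigma_draws: np.ndarray
    beta_map: float
    rhat_beta: float
    ess_beta: float
    n_transcripts: int
    seed: int
    config: BetaModelConfig | None = None

    def __post_init__(self) -> None:
        self.beta_draws = np.asarray(self.beta_draws, float)
        if ((self.beta_draws <= 0) | (self.beta_draws >= 1)).any():
            raise ValueError("beta draws must lie strictly inside (0, 1)")
        if not (len(self.beta_draws) == len(self.nu_draws) == len(self.sigma_draws)):
            raise ValueError("draw vectors must have equal length")

    def interval(self, prob: float = 0.90) -> tuple[float, float]:
        """Central credible interval for beta."""
        lo = (1.0 - prob) / 2.0
        return tuple(np.quantile(self.beta_draws, [lo, 1.0 - lo]))

    def summary(self) -> dict:
        lo, hi = self.interval(0.90)
        return {
            "beta_map": float(self.beta_map),
            "beta_mean": float(self.beta_draws.mean()),
            "beta_ci90": [float(lo), float(hi)],
            "rhat_beta": float(self.rhat_beta),
            "ess_beta": float(self.ess_beta),
            "n_transcripts": int(self.n_transcripts),
            "n_draws": int(len(self.beta_draws)),
            "seed": int(self.seed),
        }


# ---------------------------------------------------------------------------
# log posterior
# ---------------------------------------------------------------------------

def _sigma_scale(fpkm_w: np.ndarray, config: BetaModelConfig) -> float:
    if config.sigma_prior_mean is not None:
        return float(config.sigma_prior_mean)
    s = float(np.std(np.asarray(fpkm_w, float)))
    if s <= 0:
        # degenerate constant response: fall back to a unit scale
        s = 1.0
    return s


def _log_posterior_arrays(
    beta: np.ndarray,
    nu: np.ndarray,
    sigma: np.ndarray,
    fpkm_w: np.ndarray,
    fpkm_n: np.ndarray,
    fpkm_c: np.ndarray,
    config: BetaModelConfig,
    s: float,
) -> np.ndarray:
    """Vectorized over leading parameter axis; data axis is last."""
    beta = np.atleast_1d(np.asarray(beta, float))[:, None]
    nu = np.atleast_1d(np.asarray(nu, float))[:, None]
    sigma = np.atleast_1d(np.asarray(sigma, float))[:, None]
    resid = fpkm_w[None, :] - ((1.0 - beta) * fpkm_n[None, :] + beta * fpkm_c[None, :])
    if config.error_model == "student_t":
        loglik = stats.t.logpdf(resid, df=nu, loc=0.0, scale=sigma).sum(axis=1)
    else:
        loglik = stats.norm.logpdf(resid, loc=0.0, scale=sigma).sum(axis=1)
    logprior = (
        stats.gamma.logpdf(nu[:, 0], a=config.nu_prior_shape, scale=1.0 / config.nu_prior_rate)
        + stats.expon.logpdf(sigma[:, 0], scale=s)
        + stats.beta.logpdf(beta[:, 0], config.beta_prior_a, config.beta_prior_b)
    )
    return loglik + logprior


def log_posterior(
    beta: float,
    nu: float,
    sigma: float,
    triplet: MatchedTriplet,
    config: BetaModelConfig | None = None,
) -> float:
    """Unnormalized log posterior density of (beta, nu, sigma).

    Sum of the Student-t log likelihood of the regression residuals and the
    log prior densities described in the module docstring.
    """
    config = config or BetaModelConfig()
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie strictly inside (0, 1)")
    if nu <= 0 or sigma <= 0:
        raise ValueError("nu and sigma must be positive")
    if len(triplet) < 2:
        raise ValueError("at least 2 transcripts are required")
    s = _sigma_scale(triplet.fpkm_w, config)
    out = _log_posterior_arrays(
        beta, nu, sigma, triplet.fpkm_w, triplet.fpkm_n, triplet.fpkm_c, config, s
    )
    return float(out[0])


# ---------------------------------------------------------------------------
# unconstrained parameterization
# ---------------------------------------------------------------------------

_Z_BOUNDS = [(-13.8, 13.8), (np.log(0.5), np.log(1e3)), None]  # sigma bound set per fit


def _from_z(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z = np.atleast_2d(z)
    beta = 1.0 / (1.0 + np.exp(-z[:, 0]))
    return beta, np.exp(z[:, 1]), np.exp(z[:, 2])


def _to_z(beta: float, nu: float, sigma: float) -> np.ndarray:
    return np.array([np.log(beta) - np.log1p(-beta), np.log(nu), np.log(sigma)])


# ---------------------------------------------------------------------------
# MAP optimization
# ---------------------------------------------------------------------------

def _optimize_map_arrays(
    fpkm_w: np.ndarray,
    fpkm_n: np.ndarray,
    fpkm_c: np.ndarray,
    config: BetaModelConfig,
) -> tuple[float, float, float, float]:
    s = _sigma_scale(fpkm_w, config)

    def neg(z: np.ndarray) -> float:
        beta, nu, sigma = _from_z(z)
        val = _log_posterior_arrays(beta, nu, sigma, fpkm_w, fpkm_n, fpkm_c, config, s)[0]
        return -val if np.isfinite(val) else 1e300

    bounds = [_Z_BOUNDS[0], _Z_BOUNDS[1], (np.log(1e-9 * s), np.log(1e3 * s))]
    starts = [
        _to_z(b, nu0, sig0 * s)
        for b in (0.1, 0.3, 0.5, 0.7, 0.9)
        for nu0 in (2.0, 20.0)
        for sig0 in (0.05, 1.0)
    ]
    best = None
    for z0 in starts:
        res = optimize.minimize(neg, z0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise InferenceError("MAP optimization failed from every start")
    beta, nu, sigma = _from_z(best.x)
    return float(beta[0]), float(nu[0]), float(sigma[0]), -float(best.fun)


def optimize_map(
    triplet: MatchedTriplet, config: BetaModelConfig | None = None
) -> tuple[float, float, float]:
    """Deterministic joint MAP of (beta, nu, sigma) by bounded multi-start L-BFGS.

    Agrees with the KDE mode of the MCMC draws on well-identified problems;
    used as the fast path and as a cross-check of the sampler.
    """
    config = config or BetaModelConfig()
    if len(triplet) < 2:
        raise ValueError("at least 2 transcripts are required")
    beta, nu, sigma, _ = _optimize_map_arrays(
        triplet.fpkm_w, triplet.fpkm_n, triplet.fpkm_c, config
    )
    return beta, nu, sigma


# ---------------------------------------------------------------------------
# posterior sampling
# ---------------------------------------------------------------------------

def _sample_posterior_arrays(
    fpkm_w: np.ndarray,
    fpkm_n: np.ndarray,
    fpkm_c: np.ndarray,
    config: BetaModelConfig,
) -> BetaPosterior:
    import emcee

    s = _sigma_scale(fpkm_w, config)
    log_sigma_floor = np.log(1e-12 * s)

    def log_prob(z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(z)
        beta, nu, sigma = _from_z(z)
        out = np.full(len(z), -np.inf)
        ok = (
            (np.abs(z[:, 0]) < 35)
            & (z[:, 1] > np.log(0.1)) & (z[:, 1] < np.log(1e4))
            & (z[:, 2] > log_sigma_floor) & (z[:, 2] < np.log(1e6 * s))
        )
        if ok.any():
            lp = _log_posterior_arrays(
                beta[ok], nu[ok], sigma[ok], fpkm_w, fpkm_n, fpkm_c, config, s
            )
            # Jacobian of (logit, log, log) transform
            jac = np.log(beta[ok]) + np.log1p(-beta[ok]) + z[ok, 1] + z[ok, 2]
            out[ok] = lp + jac
        return out

    nwalkers = config.n_walkers
    kept_per_walker = int(np.ceil(config.n_draws / nwalkers))
    burn = max(1, int(np.ceil(config.chains * config.warmup / nwalkers)))
    total_steps = burn + kept_per_walker

    rng = np.random.default_rng(config.seed)
    beta0, nu0, sigma0, _ = _optimize_map_arrays(fpkm_w, fpkm_n, fpkm_c, config)
    z_map = _to_z(beta0, max(nu0, 0.6), max(sigma0, 1e-9 * s))
    z0 = z_map[None, :] + 0.05 * rng.standard_normal((nwalkers, 3))

    lp0 = log_prob(z0)
    if not np.isfinite(lp0).any():
        raise InferenceError(
            f"no finite posterior density at initialization (beta0={beta0:.3g}, "
            f"nu0={nu0:.3g}, sigma0={sigma0:.3g})"
        )
    # replace any non-finite starts by resampling around the MAP
    bad = ~np.isfinite(lp0)
    while bad.any():
        z0[bad] = z_map[None, :] + 0.01 * rng.standard_normal((int(bad.sum()), 3))
        bad = ~np.isfinite(log_prob(z0))

    sampler = emcee.EnsembleSampler(nwalkers, 3, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(
        int(rng.integers(2**31 - 1))
    ).get_state()
    sampler.run_mcmc(z0, total_steps, progress=False, skip_initial_state_check=True)

    chain = sampler.get_chain(discard=burn)  # (steps, walkers, 3)
    beta, nu, sigma = _from_z(chain.reshape(-1, 3))
    # pool to exactly chains * (iterations - warmup) draws
    n = config.n_draws
    beta, nu, sigma = beta[:n], nu[:n], sigma[:n]

    # walkers grouped into `chains` pseudo-chains for diagnostics
    per_chain = nwalkers // config.chains
    beta_chains = (
        chain[:, :, 0]
        .reshape(chain.shape[0], config.chains, per_chain)
        .transpose(1, 0, 2)
        .reshape(config.chains, -1)
    )
    beta_chains = 1.0 / (1.0 + np.exp(-beta_chains))
    rhat, ess = _diagnostics(beta_chains)
    if rhat > 1.01 or ess < 400:
        warnings.warn(
            f"beta posterior convergence is questionable (rhat={rhat:.3f}, ess={ess:.0f})",
            RuntimeWarning,
            stacklevel=3,
        )

    beta_map = estimate_beta_map(beta)
    return BetaPosterior(
        beta_draws=beta,
        nu_draws=nu,
        sigma_draws=sigma,
        beta_map=beta_map,
        rhat_beta=rhat,
        ess_beta=ess,
        n_transcripts=len(fpkm_w),
        seed=config.seed,
        config=config,
    )


def _diagnostics(beta_chains: np.ndarray) -> tuple[float, float]:
    """Split-R-hat and bulk ESS over a (chain, draw) array via ArviZ."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = az.convert_to_dataset(beta_chains)  # (chain, draw)
        rhat = float(az.rhat(data)["x"].values)
        ess = float(az.ess(data)["x"].values)
    if not np.isfinite(rhat):
        rhat = np.inf
    if not np.isfinite(ess):
        ess = 0.0
    return rhat, ess


def sample_posterior(
    triplet: MatchedTriplet, config: BetaModelConfig | None = None
) -> BetaPosterior:
    """Draw from the posterior of (beta, nu, sigma) given a matched triplet.

    Deterministic given ``config.seed``. Convergence problems warn rather
    than fail (diagnostics are recorded on the result); a sampler that finds
    no region of finite density raises :class:`InferenceError`.
    """
    config = config or BetaModelConfig()
    if len(triplet) < 2:
        raise ValueError("at least 2 transcripts are required")
    if len(triplet) < 50:
        logger.warning("only %d transcripts; beta is weakly identified", len(triplet))
    return _sample_posterior_arrays(
        triplet.fpkm_w, triplet.fpkm_n, triplet.fpkm_c, config
    )


def estimate_beta_map(posterior: BetaPosterior | np.ndarray) -> float:
    """Posterior mode of beta: Gaussian-KDE over the pooled draws on a
    512-point grid in (0, 1), Scott's-rule bandwidth."""
    draws = posterior.beta_draws if isinstance(posterior, BetaPosterior) else np.asarray(posterior, float)
    if len(draws) < 100:
        raise ValueError("at least 100 posterior draws are required for the MAP")
    if np.ptp(draws) < 1e-12:
        return float(draws[0])
    grid = np.linspace(0.0, 1.0, 514)[1:-1]
    kde = stats.gaussian_kde(draws)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])


def qc_beta(beta_map: float, threshold: float = 0.95) -> QCStatus:
    """Sample-level QC: flag implausibly cytosolic estimates for exclusion.

    Estimates above the threshold (default 0.95) typically reflect
    incomplete experimental fractionation or unstable regression rather than
    biology; the flag marks the sample for exclusion from downstream
    analysis (strict inequality: exactly 0.95 passes).
    """
    if not 0.0 < beta_map < 1.0:
        raise ValueError("beta_map must lie in (0, 1)")
    return QCStatus.FLAG_EXCLUDE if beta_map > threshold else QCStatus.PASS


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class BetaTRegressor(RegressorMixin, BaseEstimator):
    """Robust convex-combination regression ``y = (1-beta)*x_n + beta*x_c``.

    scikit-learn estimator interface to the volume-fraction model: ``X`` is
    an ``(n_transcripts, 2)`` array with nuclear FPKM in column 0 and
    cytosolic FPKM in column 1, ``y`` the whole-cell FPKM. After ``fit``:

    Attributes
    ----------
    beta_map_ : float
        MAP estimate of the cytosolic volume fraction.
    nu_, sigma_ : float
        Point estimates of the Student-t degrees of freedom and error scale
        (joint MAP).
    posterior_ : BetaPosterior or None
        Full posterior when ``method='mcmc'``.
    qc_status_ : QCStatus
        Sample-level QC flag at ``qc_threshold``.

    Parameters mirror :class:`BetaModelConfig`; ``method='map'`` skips MCMC
    and uses the deterministic optimizer only.
    """

    def __init__(
        self,
        method: str = "mcmc",
        error_model: str = "student_t",
        nu_prior_shape: float = 2.0,
        nu_prior_rate: float = 0.1,
        sigma_prior_mean: float | None = None,
        beta_prior_a: float = 2.0,
        beta_prior_b: float = 2.0,
        chains: int = 4,
        iterations: int = 6000,
        warmup: int = 2000,
        n_walkers: int = 16,
        target_accept: float = 0.9,
        max_tree_depth: int = 10,
        qc_threshold: float = 0.95,
        random_state: int = 0,
    ) -> None:
        self.method = method
        self.error_model = error_model
        self.nu_prior_shape = nu_prior_shape
        self.nu_prior_rate = nu_prior_rate
        self.sigma_prior_mean = sigma_prior_mean
        self.beta_prior_a = beta_prior_a
        self.beta_prior_b = beta_prior_b
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.n_walkers = n_walkers
        self.target_accept = target_accept
        self.max_tree_depth = max_tree_depth
        self.qc_threshold = qc_threshold
        self.random_state = random_state

    def _config(self) -> BetaModelConfig:
        return BetaModelConfig(
            nu_prior_shape=self.nu_prior_shape,
            nu_prior_rate=self.nu_prior_rate,
            sigma_prior_mean=self.sigma_prior_mean,
            beta_prior_a=self.beta_prior_a,
            beta_prior_b=self.beta_prior_b,
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            target_accept=self.target_accept,
            max_tree_depth=self.max_tree_depth,
            seed=self.random_state,
            n_walkers=self.n_walkers,
            error_model=self.error_model,
        )

    def fit(self, X, y) -> "BetaTRegressor":
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if X.shape[1] != 2:
            raise ValueError("X must have exactly 2 columns: [fpkm_n, fpkm_c]")
        if self.method not in ("mcmc", "map"):
            raise ValueError("method must be 'mcmc' or 'map'")
        config = self._config()
        fpkm_n, fpkm_c = X[:, 0], X[:, 1]
        if self.method == "map":
            beta, nu, sigma, _ = _optimize_map_arrays(y, fpkm_n, fpkm_c, config)
            self.posterior_ = None
            self.beta_map_, self.nu_, self.sigma_ = beta, nu, sigma
        else:
            post = _sample_posterior_arrays(y, fpkm_n, fpkm_c, config)
            self.posterior_ = post
            self.beta_map_ = post.beta_map
            # nu/sigma point estimates from the joint MAP for determinism
            _, self.nu_, self.sigma_, _ = _optimize_map_arrays(y, fpkm_n, fpkm_c, config)
        self.qc_status_ = qc_beta(self.beta_map_, self.qc_threshold)
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "beta_map_")
        X = check_array(X)
        if X.shape[1] != 2:
            raise ValueError("X must have exactly 2 columns: [fpkm_n, fpkm_c]")
        return (1.0 - self.beta_map_) * X[:, 0] + self.beta_map_ * X[:, 1]

    @classmethod
    def from_triplet(
        cls, triplet: MatchedTriplet, **params
    ) -> "BetaTRegressor":
        """Fit directly on a matched triplet."""
        est = cls(**params)
        X = np.column_stack([triplet.fpkm_n, triplet.fpkm_c])
        return est.fit(X, triplet.fpkm_w)
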
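"""Bayesian inference for the GLUT4 study via likelihood-tempered SMC.

The sampler follows the standard adaptive resample-move recipe: particles
are initialised from the prior, the likelihood is annealed through a
temperature ladder chosen on the fly so the effective sample size (ESS) of
each reweighting stays near a target, and particles are rejuvenated with
random-walk Metropolis-Hastings moves whose proposal covariance is adapted
from the current particle cloud.

The GLUT4 likelihood is the *naive* lognormal likelihood evaluated at the
recorded protocol times -- timing error is deliberately not modelled, which
is exactly the scenario whose robustness the study probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errorsim import TimecourseDataset
from .models import Glut4Params

__all__ = [
    "PriorSpec",
    "ParticleSet",
    "PosteriorMetrics",
    "Glut4LogLik",
    "lognormal_loglik",
    "run_smc",
    "posterior_metrics",
    "default_glut4_priors",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one (lower, upper) pair per parameter."""

    bounds: dict

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name!r} needs lower < upper")

    @property
    def names(self) -> tuple:
        return tuple(self.bounds)

    @property
    def dim(self) -> int:
        return len(self.bounds)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo, hi = self._arrays()
        return rng.uniform(lo, hi, size=(n, self.dim))

    def logpdf(self, theta: np.ndarray) -> np.ndarray:
        """Log prior density; -inf outside the box."""
        theta = np.atleast_2d(theta)
        lo, hi = self._arrays()
        inside = np.all((theta >= lo) & (theta <= hi), axis=1)
        const = -np.sum(np.log(hi - lo))
        return np.where(inside, const, -np.inf)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([b[0] for b in self.bounds.values()], dtype=float)
        hi = np.array([b[1] for b in self.bounds.values()], dtype=float)
        return lo, hi


def default_glut4_priors(grid_max: dict | None = None) -> PriorSpec:
    """Uniform priors over [0, 2 x largest value on the study's parameter grid].

    The study varies P(0) and k up to 0.25 and the plateau M up to 29, so the
    default box is P0, k in [0, 0.5] and M in [0, 58]; pass ``grid_max`` to
    override per parameter.
    """
    gm = {"P0": 0.25, "k": 0.25, "M": 29.0}
    gm.update(grid_max or {})
    return PriorSpec({name: (0.0, 2.0 * v) for name, v in gm.items()})


class Glut4LogLik:
    """Naive lognormal log-likelihood for GLUT4 data, O(#protocol times) per call.

    Observations replicated at the same protocol time share the same
    moment-matched lognormal, so the dataset collapses to per-time
    sufficient statistics (count, sum of log responses, sum of squared log
    responses).  Instances are callable on a parameter vector (P0, k, M) or
    a matrix of such vectors.
    """

    param_names = ("P0", "k", "M")

    def __init__(self, dataset: TimecourseDataset, sigma_Y: float):
        if sigma_Y <= 0:
            raise ValueError("sigma_Y must be positive for a lognormal likelihood")
        y = dataset.y
        if np.any(y <= 0):
            raise ValueError("lognormal likelihood requires positive responses")
        w = dataset.w
        self.sigma_Y = float(sigma_Y)
        self.times, inverse = np.unique(w, return_inverse=True)
        logy = np.log(y)
        self.n_t = np.bincount(inverse).astype(float)
        self.S1 = np.bincount(inverse, weights=logy)
        self.S2 = np.bincount(inverse, weights=logy**2)
        self.n_total = float(len(y))

    def __call__(self, theta) -> np.ndarray | float:
        theta_arr = np.atleast_2d(np.asarray(theta, dtype=float))
        P0, k, M = theta_arr[:, 0:1], theta_arr[:, 1:2], theta_arr[:, 2:3]
        with np.errstate(over="ignore", invalid="ignore"):
            mean = (P0 - M) * np.exp(-k * self.times[None, :]) + M
        out = np.full(theta_arr.shape[0], -np.inf)
        ok = np.all(mean > 0, axis=1) & np.all(np.isfinite(mean), axis=1)
        if np.any(ok):
            m2 = mean[ok] ** 2
            mu = np.log(m2 / np.sqrt(m2 + self.sigma_Y**2))
            s2 = np.log1p(self.sigma_Y**2 / m2)
            term = (
                -self.S1[None, :]
                - self.n_t[None, :] * 0.5 * np.log(2.0 * np.pi * s2)
                - (self.S2[None, :] - 2.0 * mu * self.S1[None, :] + self.n_t[None, :] * mu**2)
                / (2.0 * s2)
            )
            out[ok] = term.sum(axis=1)
        if np.ndim(theta) == 1:
            return float(out[0])
        return out


def lognormal_loglik(theta, dataset: TimecourseDataset, sigma_Y: float) -> float:
    """Naive lognormal log-likelihood of GLUT4 parameters given observed data.

    ``theta`` may be a :class:`~mistime.models.Glut4Params`, a dict with keys
    P0/k/M, or an array (P0, k, M).  The model mean is evaluated at the
    *recorded* protocol times; non-positive model means give -inf.
    """
    if isinstance(theta, Glut4Params):
        vec = np.array([theta.P0, theta.k, theta.M])
    elif isinstance(theta, dict):
        vec = np.array([theta["P0"], theta["k"], theta["M"]])
    else:
        vec = np.asarray(theta, dtype=float)
    return Glut4LogLik(dataset, sigma_Y)(vec)


@dataclass
class ParticleSet:
    """Weighted posterior sample from SMC with its adaptation traces."""

    particles: np.ndarray
    weights: np.ndarray
    loglik: np.ndarray
    logprior: np.ndarray
    param_names: tuple
    betas: list = field(default_factory=list)
    ess_trace: list = field(default_factory=list)
    acceptance_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to one")

    @property
    def n_particles(self) -> int:
        return self.particles.shape[0]

    @property
    def ess(self) -> float:
        return float(1.0 / np.sum(self.weights**2))

    def marginal(self, name: str) -> np.ndarray:
        return self.particles[:, self.param_names.index(name)]

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(self.particles, columns=list(self.param_names))
        frame["weight"] = self.weights
        frame["loglik"] = self.loglik
        return frame


@dataclass(frozen=True)
class PosteriorMetrics:
    """Per-parameter MAP error and 95% credibility-interval summaries."""

    map_estimate: dict
    map_abs_error: dict
    ci: dict
    ci_width: dict
    ci_distance: dict


def _ess(logw: np.ndarray) -> float:
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return float(1.0 / np.sum(w**2))


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(weights)
    positions = (rng.uniform() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(0, n - 1)


def run_smc(
    loglik,
    priors: PriorSpec,
    n_particles: int = 1000,
    rng=None,
    ess_target: float = 0.5,
    n_moves: int = 5,
    vectorized: bool = True,
) -> ParticleSet:
    """Adaptive likelihood-tempered SMC targeting prior x likelihood.

    ``loglik`` maps a parameter vector (or, when ``vectorized``, an
    (n, d) matrix) to log-likelihood value(s).  Temperatures are chosen by
    bisection so each increment's conditional ESS is about
    ``ess_target * n_particles``; particles are then systematically
    resampled and rejuvenated with ``n_moves`` random-walk MH steps using a
    cloud-adapted proposal covariance.  The final ladder always ends at
    temperature 1, so the returned particles target the full posterior.
    """
    if n_particles < 100:
        raise ValueError("n_particles must be >= 100")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    def ll_all(theta: np.ndarray) -> np.ndarray:
        if vectorized:
            return np.asarray(loglik(theta), dtype=float)
        return np.array([loglik(t) for t in theta], dtype=float)

    particles = priors.sample(rng, n_particles)
    ll = ll_all(particles)
    lp = priors.logpdf(particles)
    if not np.any(np.isfinite(ll)):
        raise RuntimeError(
            "SMC aborted: every prior particle has zero likelihood; "
            "check the prior support and data scaling"
        )
    target_ess = ess_target * n_particles
    beta = 0.0
    betas = [0.0]
    ess_trace: list[float] = []
    acc_trace: list[float] = []
    d = priors.dim

    while beta < 1.0:
        # pick the largest temperature increment keeping conditional ESS near target
        ll_safe = np.where(np.isfinite(ll), ll, -1e300)
        lo_b, hi_b = beta, 1.0
        if _ess((1.0 - beta) * ll_safe) >= target_ess:
            new_beta = 1.0
        else:
            for _ in range(60):
                mid = 0.5 * (lo_b + hi_b)
                if _ess((mid - beta) * ll_safe) < target_ess:
                    hi_b = mid
                else:
                    lo_b = mid
            new_beta = hi_b
        delta = new_beta - beta
        logw = delta * ll_safe
        w = np.exp(logw - logw.max())
        w /= w.sum()
        ess_trace.append(float(1.0 / np.sum(w**2)))

        # adapt the proposal from the weighted cloud before resampling
        mean = np.average(particles, axis=0, weights=w)
        centred = particles - mean
        cov = (centred * w[:, None]).T @ centred
        cov += 1e-12 * np.eye(d) * max(np.trace(cov) / d, 1e-12)
        prop_cov = (2.38**2 / d) * cov

        idx = _systematic_resample(w, rng)
        particles, ll, lp = particles[idx], ll[idx], lp[idx]
        beta = new_beta
        betas.append(beta)

        chol = np.linalg.cholesky(prop_cov)
        accepted = 0
        for _ in range(n_moves):
            prop = particles + rng.standard_normal((n_particles, d)) @ chol.T
            lp_prop = priors.logpdf(prop)
            feasible = np.isfinite(lp_prop)
            ll_prop = np.full(n_particles, -np.inf)
            if np.any(feasible):
                ll_prop[feasible] = ll_all(prop[feasible])
            with np.errstate(invalid="ignore"):
                log_ratio = beta * (ll_prop - ll) + (lp_prop - lp)
            accept = np.log(rng.uniform(size=n_particles)) < log_ratio
            particles[accept] = prop[accept]
            ll[accept] = ll_prop[accept]
            lp[accept] = lp_prop[accept]
            accepted += int(accept.sum())
        acc_trace.append(accepted / (n_moves * n_particles))

    weights = np.full(n_particles, 1.0 / n_particles)
    return ParticleSet(
        particles=particles,
        weights=weights,
        loglik=ll,
        logprior=lp,
        param_names=priors.names,
        betas=betas,
        ess_trace=ess_trace,
        acceptance_trace=acc_trace,
    )


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(q, cum / w.sum(), v))


def posterior_metrics(particles: ParticleSet, theta_true: dict) -> PosteriorMetrics:
    """MAP error, 95% credibility-interval width and distance to the truth.

    The MAP is the particle maximising prior x likelihood (deterministic
    given the particle set); intervals are equal-tailed weighted marginal
    2.5-97.5 percentiles.  ``ci_distance`` is zero when the true value lies
    inside the interval, else the gap to the nearest bound.
    """
    score = particles.loglik + particles.logprior
    if not np.any(np.isfinite(score)):
        raise ValueError("degenerate particle set: no finite posterior scores")
    map_vec = particles.particles[int(np.argmax(score))]
    map_estimate, map_abs_error, ci, ci_width, ci_distance = {}, {}, {}, {}, {}
    for j, name in enumerate(particles.param_names):
        vals = particles.particles[:, j]
        lo = _weighted_quantile(vals, particles.weights, 0.025)
        hi = _weighted_quantile(vals, particles.weights, 0.975)
        truth = float(theta_true[name])
        map_estimate[name] = float(map_vec[j])
        map_abs_error[name] = abs(float(map_vec[j]) - truth)
        ci[name] = (lo, hi)
        ci_width[name] = hi - lo
        ci_distance[name] = max(0.0, lo - truth, truth - hi)
    return PosteriorMetrics(map_estimate, map_abs_error, ci, ci_width, ci_distance)
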
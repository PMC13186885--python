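"""Correction methods for independent-variable measurement error.

Implemented correctors, ordered roughly by how much they assume:

* reliability-ratio rescaling of a naive linear slope (classical error,
  error variance known);
* Fuller's method-of-moments slope for simple linear regression;
* regression calibration (best-linear imputation of the truth);
* orthogonal (Deming-type) regression minimising vertical plus
  eta-weighted horizontal distances jointly over parameters and latent
  abscissae;
* SIMEX -- simulation-extrapolation under classical normal error;
* error-aware marginal likelihoods for classical and Berkson mechanisms,
  integrating the latent truth out by Gaussian quadrature;
* a rule-based helper ranking which method fits a given data situation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import roots_hermite, roots_legendre

from .errorsim import TimecourseDataset
from .naivefit import PARAM_NAMES, _LOWER_BOUNDS, GaussianNoiseSpec, _default_init, predict

__all__ = [
    "AttenuationInputs",
    "SimexConfig",
    "SimexResult",
    "MELikelihoodSpec",
    "CalibrationModel",
    "OrthogonalFit",
    "Recommendation",
    "reliability_ratio",
    "correct_slope",
    "variance_inequality_holds",
    "fuller_moment_fit",
    "regression_calibration",
    "orthogonal_regression_fit",
    "simex",
    "me_likelihood",
    "fit_me_likelihood",
    "select_correction_method",
]


@dataclass(frozen=True)
class AttenuationInputs:
    """Variance components of a classical-error linear design."""

    sigma_x2: float
    sigma_u2: float
    sigma_eps2: float
    beta_x: float

    def __post_init__(self) -> None:
        if self.sigma_x2 <= 0:
            raise ValueError("sigma_x2 must be positive")
        if self.sigma_u2 < 0 or self.sigma_eps2 < 0:
            raise ValueError("variances must be non-negative")


def reliability_ratio(sigma_x2: float, sigma_u2: float) -> float:
    """lambda = sigma_x^2 / (sigma_x^2 + sigma_u^2), the slope attenuation factor."""
    if sigma_x2 <= 0:
        raise ValueError("sigma_x2 must be positive")
    if sigma_u2 < 0:
        raise ValueError("sigma_u2 must be non-negative")
    return sigma_x2 / (sigma_x2 + sigma_u2)


def correct_slope(naive_beta: float, lam: float) -> float:
    """Undo attenuation of a naive linear slope: corrected = naive / lambda."""
    if not 0 < lam <= 1:
        raise ValueError("reliability ratio must be in (0, 1]")
    return naive_beta / lam


def variance_inequality_holds(inputs: AttenuationInputs) -> bool:
    """Whether the naive (observed-data) slope estimator is asymptotically
    *less* variable than the true-data estimator:
    beta_x^2 sigma_x^2 / (sigma_x^2 + sigma_u^2) < sigma_eps^2 / sigma_x^2.
    """
    lhs = inputs.beta_x**2 * inputs.sigma_x2 / (inputs.sigma_x2 + inputs.sigma_u2)
    rhs = inputs.sigma_eps2 / inputs.sigma_x2
    return bool(lhs < rhs)


def fuller_moment_fit(w, y, sigma_u2: float) -> tuple[float, float]:
    """Moment-corrected simple-linear-regression estimator for known sigma_u2.

    slope = S_wy / (S_ww - sigma_u2), intercept = ybar - slope * wbar.
    Reduces to OLS at sigma_u2 = 0; degenerate when the sample variance of w
    does not exceed the error variance.
    """
    w = np.asarray(w, dtype=float)
    y = np.asarray(y, dtype=float)
    if sigma_u2 < 0:
        raise ValueError("sigma_u2 must be non-negative")
    s_ww = float(np.var(w, ddof=1))
    s_wy = float(np.cov(w, y, ddof=1)[0, 1])
    denom = s_ww - sigma_u2
    if denom <= 0:
        raise ValueError(
            "degenerate denominator: sample variance of w must exceed sigma_u2"
        )
    slope = s_wy / denom
    intercept = float(np.mean(y)) - slope * float(np.mean(w))
    return slope, intercept


@dataclass(frozen=True)
class CalibrationModel:
    """Best-linear calibration E[X | W] = mu_x + lambda (W - mu_x)."""

    mu_x: float
    lam: float

    def __post_init__(self) -> None:
        if not 0 <= self.lam <= 1:
            raise ValueError("lambda must lie in [0, 1]")

    @classmethod
    def from_observed(cls, w, sigma_u2: float) -> "CalibrationModel":
        """Estimate (mu_x, lambda) from observed w under classical error."""
        w = np.asarray(w, dtype=float)
        s_ww = float(np.var(w, ddof=1))
        lam = max(0.0, min(1.0, (s_ww - sigma_u2) / s_ww))
        return cls(mu_x=float(np.mean(w)), lam=lam)


def regression_calibration(w, model: CalibrationModel) -> np.ndarray:
    """Impute the truth by its conditional expectation given the observation.

    With lambda = 1 (no classical error, or unbiased Berkson error where
    E[X | W] = W) the imputation is the identity and nothing is gained.
    """
    w = np.asarray(w, dtype=float)
    return model.mu_x + model.lam * (w - model.mu_x)


@dataclass
class OrthogonalFit:
    """Result of a joint minimisation over parameters and latent abscissae."""

    theta_hat: dict
    x_hat: np.ndarray
    objective: float
    converged: bool
    n_evals: int


def orthogonal_regression_fit(
    model_id: str,
    w,
    y,
    eta: float,
    init: dict | None = None,
    free_params: list[str] | None = None,
    fixed_params: dict | None = None,
) -> OrthogonalFit:
    """Orthogonal (Deming-type) regression for any of the closed-form models.

    Minimises sum_i [(y_i - f(theta, x_i))^2 + eta (w_i - x_i)^2] jointly
    over theta and the N latent abscissae x_i, with eta = sigma_eps^2 /
    sigma_u^2.  Note the eta = 1 special case is scale-dependent: rescaling
    the response rescales the implicit weighting, so the correction differs
    under unit changes -- it ignores the error in the equation and tends to
    overcorrect.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    w = np.asarray(w, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(w)
    names = PARAM_NAMES[model_id]
    fixed = dict(fixed_params or {})
    free = tuple(free_params) if free_params is not None else tuple(
        nm for nm in names if nm not in fixed
    )
    init_full = _default_init(model_id, w, y)
    init_full.update(init or {})
    p = len(free)
    z0 = np.concatenate([[init_full[nm] for nm in free], w])
    lo = np.concatenate(
        [[_LOWER_BOUNDS[model_id].get(nm, -np.inf) for nm in free], np.full(n, -np.inf)]
    )
    z0 = np.maximum(z0, np.where(np.isfinite(lo), lo + 1e-12, z0))
    sqrt_eta = np.sqrt(eta)

    def residual(z: np.ndarray) -> np.ndarray:
        theta = dict(zip(free, z[:p]))
        theta.update(fixed)
        x = z[p:]
        with np.errstate(over="ignore", invalid="ignore"):
            pred = predict(model_id, theta, x)
        top = np.nan_to_num(pred - y, nan=1e12, posinf=1e12, neginf=-1e12)
        return np.concatenate([top, sqrt_eta * (w - x)])

    # the Jacobian couples each x_i to only two residuals -> sparse structure
    from scipy.sparse import lil_matrix

    sparsity = lil_matrix((2 * n, p + n), dtype=int)
    sparsity[:n, :p] = 1
    for i in range(n):
        sparsity[i, p + i] = 1
        sparsity[n + i, p + i] = 1
    sol = optimize.least_squares(
        residual, z0, bounds=(lo, np.full_like(z0, np.inf)), method="trf",
        jac_sparsity=sparsity, xtol=2.3e-16, ftol=2.3e-16, gtol=1e-15,
    )
    theta_hat = dict(zip(free, (float(v) for v in sol.x[:p])))
    return OrthogonalFit(
        theta_hat=theta_hat,
        x_hat=sol.x[p:].copy(),
        objective=float(2.0 * sol.cost),
        converged=bool(sol.success),
        n_evals=int(sol.nfev),
    )


@dataclass(frozen=True)
class SimexConfig:
    """SIMEX settings: inflation grid, pseudo-datasets per point, extrapolant."""

    zeta_grid: tuple = (0.5, 1.0, 1.5, 2.0)
    n_pseudo: int = 100
    extrapolant: str = "quadratic"

    def __post_init__(self) -> None:
        if any(z <= 0 for z in self.zeta_grid):
            raise ValueError("zeta values must be positive")
        if self.n_pseudo < 2:
            raise ValueError("n_pseudo must be >= 2")
        if self.extrapolant not in ("quadratic", "rational_linear"):
            raise ValueError("extrapolant must be 'quadratic' or 'rational_linear'")


@dataclass
class SimexResult:
    """SIMEX corrected estimates with the zeta-trajectory diagnostics."""

    corrected: np.ndarray
    naive: np.ndarray
    zetas: np.ndarray
    trajectory: np.ndarray  # (len(zetas), n_params) mean estimates
    extrapolant: str
    flags: list = field(default_factory=list)


def _rational_extrapolate(zetas: np.ndarray, g: np.ndarray) -> float:
    """Fit g(zeta) ~ a + b / (c + zeta) and evaluate at zeta = -1.

    This family is exact for the linear-model attenuation curve
    lambda(zeta) beta = beta sigma_x^2 / (sigma_x^2 + (1 + zeta) sigma_u^2).
    """

    def f(z, a, b, c):
        return a + b / (c + z)

    best = None
    for c0 in (0.5, 1.5, 3.0, 6.0):
        try:
            popt, _ = optimize.curve_fit(
                f, zetas, g, p0=(g[-1], (g[0] - g[-1]) * (c0 + zetas[0]), c0), maxfev=5000
            )
        except (RuntimeError, TypeError):
            continue
        sse = float(np.sum((f(zetas, *popt) - g) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("rational extrapolant failed to fit")
    a, b, c = best[1]
    if abs(c - 1.0) < 1e-8:
        raise RuntimeError("rational extrapolant singular at zeta = -1")
    return float(a + b / (c - 1.0))


def simex(fitter, dataset, sigma_u2: float, config: SimexConfig | None = None, rng=None) -> SimexResult:
    """Simulation extrapolation for classical, normally distributed error.

    ``fitter(w, y)`` returns the naive estimates (scalar or vector) for any
    pseudo-dataset.  For each inflation factor zeta, ``n_pseudo``
    pseudo-datasets w + sqrt(zeta) N(0, sigma_u2) are refit and the
    estimates averaged; the chosen extrapolant is then fit to the
    (zeta, estimate) trajectory -- including the naive zeta = 0 point --
    and read off at zeta = -1, the no-error case.
    """
    if sigma_u2 < 0:
        raise ValueError("sigma_u2 must be non-negative")
    config = config or SimexConfig()
    if isinstance(dataset, TimecourseDataset):
        w, y = dataset.w, dataset.y
    else:
        w, y = (np.asarray(v, dtype=float) for v in dataset)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    naive = np.atleast_1d(np.asarray(fitter(w, y), dtype=float))
    if sigma_u2 == 0:
        zetas = np.concatenate([[0.0], config.zeta_grid])
        traj = np.tile(naive, (len(zetas), 1))
        return SimexResult(naive.copy(), naive, zetas, traj, config.extrapolant, ["no_error"])
    sd = np.sqrt(sigma_u2)
    zetas = np.concatenate([[0.0], config.zeta_grid])
    traj = np.empty((len(zetas), len(naive)))
    traj[0] = naive
    for iz, zeta in enumerate(config.zeta_grid, start=1):
        acc = np.zeros(len(naive))
        for _ in range(config.n_pseudo):
            wb = w + np.sqrt(zeta) * sd * rng.standard_normal(len(w))
            acc += np.atleast_1d(np.asarray(fitter(wb, y), dtype=float))
        traj[iz] = acc / config.n_pseudo
    corrected = np.empty(len(naive))
    flags: list[str] = []
    used = config.extrapolant
    for j in range(len(naive)):
        if config.extrapolant == "rational_linear":
            try:
                corrected[j] = _rational_extrapolate(zetas, traj[:, j])
                continue
            except RuntimeError:
                flags.append(f"rational_fallback_param{j}")
                used = "quadratic"
        corrected[j] = np.polyval(np.polyfit(zetas, traj[:, j], 2), -1.0)
    return SimexResult(corrected, naive, zetas, traj, used, flags)


@dataclass(frozen=True)
class MELikelihoodSpec:
    """Error model for a marginal (error-aware) likelihood.

    ``error_model`` is classical (needs the latent-X density ``x_density``
    = (mean, variance) of a normal) or Berkson (must not have one: the
    distribution of the recorded W carries no information).  The error
    distribution is normal with variance ``var_u`` or, for Berkson timing
    errors, uniform of width ``delta`` (biased on [0, delta] or centred).
    ``quad_order`` controls the Gauss-Hermite / Gauss-Legendre rule.
    """

    error_model: str
    distribution: str = "normal"
    var_u: float | None = None
    delta: float | None = None
    biased: bool = True
    x_density: tuple | None = None
    quad_order: int = 21

    def __post_init__(self) -> None:
        if self.error_model not in ("classical", "berkson"):
            raise ValueError("error_model must be 'classical' or 'berkson'")
        if self.distribution == "normal":
            if self.var_u is None or self.var_u < 0:
                raise ValueError("normal error requires var_u >= 0")
        elif self.distribution == "uniform":
            if self.error_model != "berkson":
                raise ValueError("uniform error is implemented for the Berkson model")
            if self.delta is None or self.delta < 0:
                raise ValueError("uniform error requires delta >= 0")
        else:
            raise ValueError("distribution must be 'normal' or 'uniform'")
        if self.error_model == "classical" and self.x_density is None:
            raise ValueError("classical error requires x_density = (mean, variance)")
        if self.error_model == "berkson" and self.x_density is not None:
            raise ValueError("Berkson error must not specify an x density")
        if self.quad_order < 2:
            raise ValueError("quad_order must be >= 2")


def _norm_pdf(z: np.ndarray, mean: np.ndarray, var: float) -> np.ndarray:
    return np.exp(-((z - mean) ** 2) / (2.0 * var)) / np.sqrt(2.0 * np.pi * var)


def me_likelihood(
    theta: dict,
    dataset: TimecourseDataset,
    model_id: str,
    spec: MELikelihoodSpec,
    noise: GaussianNoiseSpec,
) -> float:
    """Marginal log-likelihood integrating the latent truth out of each point.

    Classical:  phi(y | w) = int phi(y | x) phi(w | x) phi_X(x) dx
    Berkson:    phi(y | w) = int phi(y | x) phi(x | w) dx

    The response density phi(y | x) is Gaussian about the model curve with
    variance ``noise.sigma2``.  Normal latent errors use Gauss-Hermite
    quadrature; uniform Berkson errors use Gauss-Legendre on the support.
    Observations with zero marginal density return -inf.
    """
    w = dataset.w
    y = dataset.y
    theta = dict(theta)

    def f(x: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore"):
            return predict(model_id, theta, x)

    zero_error = (spec.distribution == "normal" and spec.var_u == 0) or (
        spec.distribution == "uniform" and spec.delta == 0
    )
    if zero_error:
        dens = _norm_pdf(y, f(w), noise.sigma2)
        if spec.error_model == "classical":
            mu_x, var_x = spec.x_density
            dens = dens * _norm_pdf(w, mu_x, var_x)
    elif spec.error_model == "berkson":
        if spec.distribution == "normal":
            nodes, wts = roots_hermite(spec.quad_order)
            x = w[:, None] + np.sqrt(2.0 * spec.var_u) * nodes[None, :]
            dens = (_norm_pdf(y[:, None], f(x), noise.sigma2) * wts[None, :]).sum(axis=1)
            dens /= np.sqrt(np.pi)
        else:
            lo, hi = (0.0, spec.delta) if spec.biased else (-spec.delta / 2, spec.delta / 2)
            nodes, wts = roots_legendre(spec.quad_order)
            x = w[:, None] + (lo + hi) / 2.0 + (hi - lo) / 2.0 * nodes[None, :]
            dens = (_norm_pdf(y[:, None], f(x), noise.sigma2) * wts[None, :]).sum(axis=1)
            dens *= 0.5  # (hi-lo)/2 scale times the 1/(hi-lo) uniform density
    else:  # classical: integrate against the latent-X density
        mu_x, var_x = spec.x_density
        nodes, wts = roots_hermite(spec.quad_order)
        x = mu_x + np.sqrt(2.0 * var_x) * nodes[None, :]
        dens = (
            _norm_pdf(y[:, None], f(x), noise.sigma2)
            * _norm_pdf(w[:, None], x, spec.var_u)
            * wts[None, :]
        ).sum(axis=1) / np.sqrt(np.pi)
    if not np.all(np.isfinite(dens)):
        raise FloatingPointError("non-finite quadrature result in me_likelihood")
    if np.any(dens <= 0):
        return float("-inf")
    return float(np.sum(np.log(dens)))


def fit_me_likelihood(
    model_id: str,
    dataset: TimecourseDataset,
    spec: MELikelihoodSpec,
    noise: GaussianNoiseSpec,
    free_params: list[str],
    init: dict,
    fixed_params: dict | None = None,
    bounds: dict | None = None,
) -> dict:
    """Maximise the error-aware likelihood over ``free_params``.

    Returns the estimates as a dict; a thin convenience wrapper over
    ``scipy.optimize.minimize`` (Nelder-Mead with bound clipping).
    """
    fixed = dict(fixed_params or {})
    lower = {**_LOWER_BOUNDS[model_id], **(bounds or {})}

    def neg_ll(vec: np.ndarray) -> float:
        theta = dict(zip(free_params, vec))
        for nm, lb in lower.items():
            if nm in theta and theta[nm] < lb:
                return 1e12
        theta.update(fixed)
        ll = me_likelihood(theta, dataset, model_id, spec, noise)
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.array([init[nm] for nm in free_params], dtype=float)
    sol = optimize.minimize(neg_ll, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    return dict(zip(free_params, (float(v) for v in sol.x)))


@dataclass(frozen=True)
class Recommendation:
    method: str
    note: str
    reference: str


_METHODS = {
    "reliability_ratio": Recommendation(
        "reliability ratio",
        "exact slope correction for linear models with known classical error variance",
        "Berkson (1950); Carroll et al. (2006)",
    ),
    "fuller": Recommendation(
        "Fuller's method of moments",
        "moment-corrected linear estimator; needs known error variance",
        "Fuller (1987)",
    ),
    "simex": Recommendation(
        "SIMEX",
        "model-agnostic simulation extrapolation; needs (an estimate of) the error variance",
        "Cook & Stefanski (1994)",
    ),
    "orthogonal": Recommendation(
        "orthogonal regression",
        "joint minimisation over parameters and latent abscissae; needs eta = "
        "sigma_eps^2/sigma_u^2 and ignores error in the equation",
        "Fuller (1987); Casella & Berger (2002)",
    ),
    "regression_calibration": Recommendation(
        "regression calibration",
        "impute E[X|W,Z]; most useful for generalised linear models with replicate data",
        "Prentice (1982); Carroll et al. (2006)",
    ),
    "validation": Recommendation(
        "validation-data methods",
        "use a gold-standard subsample; reference only (not implemented here)",
        "Sepanski & Carroll (1993)",
    ),
    "classical_likelihood": Recommendation(
        "classical measurement-error likelihood",
        "marginal likelihood integrating over the latent X density",
        "Carroll et al. (2006)",
    ),
    "berkson_likelihood": Recommendation(
        "Berkson measurement-error likelihood",
        "marginal likelihood over X|W; no density for the recorded values needed",
        "Carroll et al. (2006)",
    ),
}


def select_correction_method(answers: dict) -> list[Recommendation]:
    """Rank correction methods for a described data situation.

    ``answers`` needs keys: ``model_class`` (linear | glm | nonlinear),
    ``extra_data`` (none | replicates | validation), ``variance_known``
    (bool), ``error_model`` (classical | berkson) and
    ``distribution_fully_specified`` (bool).  The ranking is a deterministic
    rule table; earlier entries assume less.
    """
    model_class = answers["model_class"]
    extra_data = answers["extra_data"]
    variance_known = bool(answers["variance_known"])
    error_model = answers["error_model"]
    dist_specified = bool(answers["distribution_fully_specified"])
    if model_class not in ("linear", "glm", "nonlinear"):
        raise ValueError("model_class must be linear, glm or nonlinear")
    if extra_data not in ("none", "replicates", "validation"):
        raise ValueError("extra_data must be none, replicates or validation")
    if error_model not in ("classical", "berkson"):
        raise ValueError("error_model must be classical or berkson")

    keys: list[str] = []
    if extra_data == "validation":
        keys += ["validation", "regression_calibration"]
    elif extra_data == "replicates":
        keys.append("regression_calibration")
    if variance_known:
        if model_class == "linear" and error_model == "classical":
            keys += ["reliability_ratio", "fuller", "simex"]
        else:
            keys += ["simex", "orthogonal"]
    if dist_specified:
        keys.append("berkson_likelihood" if error_model == "berkson" else "classical_likelihood")
    if not keys:
        keys = ["orthogonal"]
    seen: list[str] = []
    for k in keys:
        if k not in seen:
            seen.append(k)
    return [_METHODS[k] for k in seen]
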
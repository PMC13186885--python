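"""Naive frequentist inference: bounded least squares, t-intervals, fit stats.

"Naive" means the fit treats the recorded independent values as exact --
measurement error in the timing is ignored.  The machinery mirrors the
standard nonlinear-regression stack: trust-region least squares with lower
bounds enforcing non-negative parameters, covariance (J^T J)^{-1} s^2 from
the Jacobian at the optimum, and confidence bounds b +/- t sqrt(S) with t
the Student quantile at the residual degrees of freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errorsim import TimecourseDataset

__all__ = [
    "PARAM_NAMES",
    "FitResult",
    "GaussianNoiseSpec",
    "fit_least_squares",
    "fit_per_subject",
    "confidence_intervals",
    "goodness_of_fit",
    "gaussian_nll",
    "kde",
]

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "linear": ("beta0", "beta_x"),
    "cosine": ("a", "b"),
    "parasite": ("V0", "g", "B0", "k"),
    "gompertz": ("y0", "r", "K"),
    "glut4": ("P0", "k", "M"),
}

# Lower bounds keep sign-constrained parameters in range during optimisation.
_LOWER_BOUNDS: dict[str, dict[str, float]] = {
    "linear": {},
    "cosine": {"a": 0.0},
    "parasite": {"V0": 0.0, "g": 0.0, "B0": 0.0, "k": 0.0},
    "gompertz": {"y0": 1e-12, "r": 1e-12, "K": 1e-12},
    "glut4": {"P0": 0.0, "k": 1e-12, "M": 0.0},
}


def predict(model_id: str, theta: dict, x: np.ndarray) -> np.ndarray:
    """Evaluate a model from a flat name->value dict (no dataclass validation).

    Used inside optimisation loops where intermediate iterates may violate
    the strict dataclass invariants (e.g. y0 > K transiently).
    """
    x = np.asarray(x, dtype=float)
    if model_id == "linear":
        return theta["beta0"] + theta["beta_x"] * x
    if model_id == "cosine":
        return theta["a"] * np.cos(theta["b"] * x)
    if model_id == "parasite":
        return theta["V0"] * np.exp(theta["g"] * x) + theta["B0"] * np.exp(-theta["k"] * x)
    if model_id == "gompertz":
        return theta["K"] * np.exp(np.exp(-theta["r"] * x) * np.log(theta["y0"] / theta["K"]))
    if model_id == "glut4":
        return (theta["P0"] - theta["M"]) * np.exp(-theta["k"] * x) + theta["M"]
    raise ValueError(f"unknown model_id {model_id!r}")


def _default_init(model_id: str, x: np.ndarray, y: np.ndarray) -> dict:
    """Generic data-driven starting values when the caller supplies none."""
    if model_id == "linear":
        return {"beta0": 0.0, "beta_x": 0.0}
    if model_id == "cosine":
        return {"a": float(np.std(y) * np.sqrt(2.0) + 1e-6), "b": 1.0}
    if model_id == "parasite":
        return {"V0": 0.01, "g": 0.3, "B0": 0.01, "k": 0.5}
    if model_id == "gompertz":
        ymin = max(float(np.min(y)), 1e-6)
        ymax = float(np.max(y))
        return {"y0": ymin, "r": 0.1, "K": max(ymax * 1.2, ymin * 2.0)}
    if model_id == "glut4":
        order = np.argsort(x)
        return {
            "P0": max(float(y[order[0]]), 1e-6),
            "k": 0.1,
            "M": max(float(np.mean(y[order[-3:]])), 1e-6),
        }
    raise ValueError(f"unknown model_id {model_id!r}")


def _linear_design(model_id: str, free: tuple, fixed: dict, x: np.ndarray):
    """Design matrix and offset when the model is linear in the free parameters.

    Returns ``(A, offset)`` with prediction = A @ theta_free + offset, or
    None when the problem is genuinely nonlinear in the free parameters.
    """
    if model_id == "linear":
        cols, offset = [], np.zeros_like(x)
        for name in free:
            cols.append(np.ones_like(x) if name == "beta0" else x)
        for name, val in fixed.items():
            offset = offset + (val if name == "beta0" else val * x)
        return np.column_stack(cols), offset
    if model_id == "cosine" and free == ("a",) and "b" in fixed:
        return np.cos(fixed["b"] * x)[:, None], np.zeros_like(x)
    return None


@dataclass
class FitResult:
    """Point estimates plus Jacobian-based uncertainty from a least-squares fit."""

    model_id: str
    theta_hat: dict
    fixed_params: dict
    param_names: tuple
    cov: np.ndarray | None
    ci: dict
    residuals: np.ndarray
    dof: int
    s2: float
    r2: float
    adj_r2: float
    converged: bool
    n_evals: int
    level: float = 0.95
    flags: list = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.residuals)

    def full_theta(self) -> dict:
        return {**self.theta_hat, **self.fixed_params}

    def to_json(self) -> str:
        payload = {
            "model_id": self.model_id,
            "theta_hat": self.theta_hat,
            "fixed_params": self.fixed_params,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "level": self.level,
            "dof": self.dof,
            "s2": self.s2,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "converged": self.converged,
            "flags": self.flags,
        }
        return json.dumps(payload, indent=2)


@dataclass(frozen=True)
class GaussianNoiseSpec:
    """Constant-variance Gaussian observation noise about the model curve."""

    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


def fit_least_squares(
    model_id: str,
    dataset: TimecourseDataset,
    time_column: str = "protocol",
    free_params: list[str] | None = None,
    init: dict | None = None,
    bounds: dict | None = None,
    fixed_params: dict | None = None,
    level: float = 0.95,
) -> FitResult:
    """Bounded nonlinear least squares of ``model_id`` to a timecourse dataset.

    ``time_column`` selects the recorded protocol values (``protocol``, the
    naive fit) or the hidden truth (``true``).  ``free_params`` restricts
    which parameters are estimated; the rest are held at ``fixed_params``.
    Residuals are stacked across all rows, so a multi-subject dataset gets a
    single pooled parameter vector.  Non-convergence is flagged on the
    result, not raised.
    """
    if model_id not in PARAM_NAMES:
        raise ValueError(f"unknown model_id {model_id!r}")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    x = dataset.times(time_column)
    y = dataset.y
    names = PARAM_NAMES[model_id]
    fixed = dict(fixed_params or {})
    free = tuple(free_params) if free_params is not None else tuple(
        n for n in names if n not in fixed
    )
    unknown = set(free) - set(names)
    if unknown:
        raise ValueError(f"unknown parameters {sorted(unknown)} for model {model_id!r}")
    missing = set(names) - set(free) - set(fixed)
    if missing:
        raise ValueError(f"parameters {sorted(missing)} neither free nor fixed")

    init_full = _default_init(model_id, x, y)
    init_full.update(init or {})
    lower_map = dict(_LOWER_BOUNDS[model_id])
    lower_map.update(bounds or {})

    n, p = len(y), len(free)
    flags: list[str] = []

    design = _linear_design(model_id, free, fixed, x)
    if design is not None:
        # linear in the free parameters: solve exactly instead of iterating
        A, offset = design
        coef, *_ = np.linalg.lstsq(A, y - offset, rcond=None)
        at_bound = False
        if model_id == "cosine" and free == ("a",) and coef[0] < lower_map.get("a", 0.0):
            coef[0] = lower_map.get("a", 0.0)  # 1-D convex problem: project onto bound
            at_bound = True
        theta_hat = dict(zip(free, (float(v) for v in coef)))
        res = (A @ coef + offset) - y
        jac = A
        converged = True
        n_evals = 1
        if at_bound:
            flags.append("at_bound")
    else:
        theta0 = np.array([init_full[n_] for n_ in free], dtype=float)
        lo = np.array([lower_map.get(n_, -np.inf) for n_ in free])
        theta0 = np.maximum(theta0, np.where(np.isfinite(lo), lo + 1e-12, theta0))

        def residual(vec: np.ndarray) -> np.ndarray:
            theta = dict(zip(free, vec))
            theta.update(fixed)
            with np.errstate(over="ignore", invalid="ignore"):
                pred = predict(model_id, theta, x)
            return np.nan_to_num(pred - y, nan=1e12, posinf=1e12, neginf=-1e12)

        with np.errstate(divide="ignore", invalid="ignore"):
            sol = optimize.least_squares(
                residual, theta0, bounds=(lo, np.full(p, np.inf)), method="trf",
                xtol=2.3e-16, ftol=2.3e-16, gtol=1e-15,
            )
        theta_hat = dict(zip(free, (float(v) for v in sol.x)))
        res = sol.fun
        jac = sol.jac
        converged = bool(sol.success)
        n_evals = int(sol.nfev)
        if not converged:
            flags.append("non_convergence")

    dof = n - p
    cov = None
    s2 = float("nan")
    if dof >= 1:
        s2 = float(res @ res) / dof
        JtJ = jac.T @ jac
        try:
            cov = np.linalg.inv(JtJ) * s2
            if not np.all(np.isfinite(cov)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(JtJ) * s2
            flags.append("singular_jacobian")
        cond = np.linalg.cond(JtJ)
        if not np.isfinite(cond) or cond > 1e12:
            if "singular_jacobian" not in flags:
                flags.append("ill_conditioned")
    else:
        flags.append("ci_unavailable")

    sst = float(np.sum((y - np.mean(y)) ** 2))
    ssr = float(res @ res)
    if sst > 0:
        r2 = 1.0 - ssr / sst
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else float("nan")
    else:
        r2 = adj_r2 = float("nan")
        flags.append("zero_sst")

    fit = FitResult(
        model_id=model_id,
        theta_hat=theta_hat,
        fixed_params=fixed,
        param_names=free,
        cov=cov,
        ci={},
        residuals=res,
        dof=dof,
        s2=s2,
        r2=r2,
        adj_r2=adj_r2,
        converged=converged,
        n_evals=n_evals,
        level=level,
        flags=flags,
    )
    if cov is not None:
        fit.ci = confidence_intervals(fit, level)
    return fit


def fit_per_subject(model_id: str, dataset: TimecourseDataset, **kwargs) -> dict:
    """Fit each subject's trajectory separately; returns subject_id -> FitResult."""
    out = {}
    for sid in sorted(set(dataset.subjects.tolist())):
        out[sid] = fit_least_squares(model_id, dataset.subset(sid), **kwargs)
    return out


def confidence_intervals(fit: FitResult, level: float = 0.95) -> dict:
    """Per-parameter t-based bounds: estimate +/- t_{dof,(1+level)/2} sqrt(diag cov)."""
    if fit.cov is None or fit.dof < 1:
        raise ValueError("confidence intervals unavailable (insufficient dof or covariance)")
    tq = stats.t.ppf(0.5 + level / 2.0, fit.dof)
    half = tq * np.sqrt(np.clip(np.diag(fit.cov), 0.0, None))
    return {
        name: (fit.theta_hat[name] - h, fit.theta_hat[name] + h)
        for name, h in zip(fit.param_names, half)
    }


def goodness_of_fit(fit: FitResult) -> tuple[float, float]:
    """(R^2, adjusted R^2) about the mean of the observed response."""
    if "zero_sst" in fit.flags:
        raise ValueError("R^2 undefined: zero total sum of squares")
    return fit.r2, fit.adj_r2


def gaussian_nll(
    theta: dict,
    dataset: TimecourseDataset,
    noise: GaussianNoiseSpec,
    model_id: str,
    time_column: str = "protocol",
) -> float:
    """Negative log-likelihood under iid Gaussian noise of variance sigma2.

    sum_i [y_i - y(theta, x_i)]^2 / (2 sigma^2) + 0.5 log(2 pi sigma^2);
    with constant sigma its minimiser coincides with least squares.
    """
    x = dataset.times(time_column)
    resid = predict(model_id, theta, x) - dataset.y
    n = len(resid)
    return float(
        np.sum(resid**2) / (2.0 * noise.sigma2) + 0.5 * n * np.log(2.0 * np.pi * noise.sigma2)
    )


def kde(samples, grid=None) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density with the normal-reference (Silverman) bandwidth.

    Returns ``(grid, density)``.  A constant sample has no spread for the
    bandwidth rule and raises a ValueError (degenerate density).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("kde requires at least 2 samples")
    if np.ptp(samples) == 0:
        raise ValueError("degenerate (constant) sample: density is a point mass")
    est = stats.gaussian_kde(samples, bw_method="silverman")
    if grid is None:
        lo = samples.min() - 4 * samples.std()
        hi = samples.max() + 4 * samples.std()
        grid = np.linspace(lo, hi, 512)
    grid = np.asarray(grid, dtype=float)
    return grid, est(grid)
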
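"""Deterministic model equations for the five case studies.

All five models have closed-form solutions, so evaluation is a pure,
vectorised function of the parameters and the independent variable
(time in most studies):

* ``linear``    y = beta0 + beta_x * x
* ``cosine``    y = a * cos(b * x)
* ``parasite``  P(t) = V0 * exp(g t) + B0 * exp(-k t)  (growth over decaying
  background fluorescence)
* ``gompertz``  y(t) = K * (y0 / K) ** exp(-r t)  (sigmoidal tumour growth)
* ``glut4``     P(t) = (P0 - M) * exp(-k t) + M  (two-compartment exchange of
  GLUT4 transporter between plasma membrane and internal pool; exponential
  rise to the plateau M with effective rate k = k_ex + k_en)
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "LinearParams",
    "CosineParams",
    "ParasiteParams",
    "GompertzParams",
    "Glut4Params",
    "LognormalMoments",
    "MODEL_IDS",
    "evaluate_model",
    "lognormal_from_moments",
    "params_to_dict",
    "params_from_dict",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _finite(*vals: float) -> bool:
    return all(np.isfinite(v) for v in vals)


@dataclass(frozen=True)
class LinearParams:
    """Straight line y = beta0 + beta_x * x."""

    beta0: float
    beta_x: float

    def __post_init__(self) -> None:
        _require(_finite(self.beta0, self.beta_x), "linear parameters must be finite")


@dataclass(frozen=True)
class CosineParams:
    """Oscillation y = a cos(b x); amplitude a >= 0, angular frequency b."""

    a: float
    b: float

    def __post_init__(self) -> None:
        _require(_finite(self.a, self.b), "cosine parameters must be finite")
        _require(self.a >= 0, "amplitude a must be non-negative")


@dataclass(frozen=True)
class ParasiteParams:
    """Exponential parasite growth over a decaying background fluorescence.

    V0: initial parasite level, g: growth rate (per day),
    B0: initial background fluorescence, k: background decay rate (per day).
    """

    V0: float
    g: float
    B0: float
    k: float

    def __post_init__(self) -> None:
        _require(_finite(self.V0, self.g, self.B0, self.k), "parasite parameters must be finite")
        _require(
            min(self.V0, self.g, self.B0, self.k) >= 0,
            "parasite parameters must be non-negative",
        )


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz growth with initial volume y0, rate r and carrying capacity K."""

    y0: float
    r: float
    K: float

    def __post_init__(self) -> None:
        _require(_finite(self.y0, self.r, self.K), "Gompertz parameters must be finite")
        _require(0 < self.y0 < self.K, "Gompertz requires 0 < y0 < K")
        _require(self.r > 0, "Gompertz growth rate r must be positive")


@dataclass(frozen=True)
class Glut4Params:
    """Exponential rise to plateau, P(t) = (P0 - M) exp(-k t) + M.

    The plateau M is stored as a free parameter.  When the two-compartment
    rates are known, M = k_ex / (k_ex + k_en) and k = k_ex + k_en; the
    decomposition is optional and only validated when provided.
    """

    P0: float
    k: float
    M: float
    k_en: float | None = None
    k_ex: float | None = None

    def __post_init__(self) -> None:
        _require(_finite(self.P0, self.k, self.M), "GLUT4 parameters must be finite")
        _require(self.P0 >= 0, "P0 must be non-negative")
        _require(self.k > 0, "effective rate k must be positive")
        _require(self.M >= 0, "plateau M must be non-negative")
        if self.k_en is not None or self.k_ex is not None:
            _require(
                self.k_en is not None and self.k_ex is not None,
                "provide both k_en and k_ex or neither",
            )
            _require(self.k_en >= 0 and self.k_ex >= 0, "rates must be non-negative")
            _require(
                np.isclose(self.k_en + self.k_ex, self.k, rtol=1e-9, atol=1e-12),
                "k must equal k_en + k_ex",
            )

    @classmethod
    def from_rates(cls, P0: float, k_en: float, k_ex: float) -> "Glut4Params":
        k = k_en + k_ex
        _require(k > 0, "k_en + k_ex must be positive")
        return cls(P0=P0, k=k, M=k_ex / k, k_en=k_en, k_ex=k_ex)


@dataclass(frozen=True)
class LognormalMoments:
    """Log-scale (mu, sigma2) matching a target mean/variance on the original scale.

    mu     = ln(m^2 / sqrt(m^2 + v))
    sigma2 = ln(1 + v / m^2)

    ``degenerate`` flags a zero target variance (point mass at the mean).
    """

    target_mean: float
    target_var: float
    mu: float
    sigma2: float
    degenerate: bool = field(default=False)


ParamsType = Union[LinearParams, CosineParams, ParasiteParams, GompertzParams, Glut4Params]

_PARAM_CLASSES: dict[str, type] = {
    "linear": LinearParams,
    "cosine": CosineParams,
    "parasite": ParasiteParams,
    "gompertz": GompertzParams,
    "glut4": Glut4Params,
}

MODEL_IDS = tuple(_PARAM_CLASSES)


def _eval_linear(p: LinearParams, x: np.ndarray) -> np.ndarray:
    return p.beta0 + p.beta_x * x


def _eval_cosine(p: CosineParams, x: np.ndarray) -> np.ndarray:
    return p.a * np.cos(p.b * x)


def _eval_parasite(p: ParasiteParams, t: np.ndarray) -> np.ndarray:
    return p.V0 * np.exp(p.g * t) + p.B0 * np.exp(-p.k * t)


def _eval_gompertz(p: GompertzParams, t: np.ndarray) -> np.ndarray:
    # K (y0/K)^{exp(-rt)}, computed on the log scale for numerical safety
    return p.K * np.exp(np.exp(-p.r * t) * np.log(p.y0 / p.K))


def _eval_glut4(p: Glut4Params, t: np.ndarray) -> np.ndarray:
    return (p.P0 - p.M) * np.exp(-p.k * t) + p.M


_EVALUATORS = {
    "linear": _eval_linear,
    "cosine": _eval_cosine,
    "parasite": _eval_parasite,
    "gompertz": _eval_gompertz,
    "glut4": _eval_glut4,
}


def evaluate_model(model_id: str, params: ParamsType, x) -> np.ndarray:
    """Evaluate the closed-form model ``model_id`` at times/abscissae ``x``.

    Parameters are validated by their dataclass constructors; evaluation is
    deterministic and broadcasts elementwise over ``x``.  Scalar input
    returns a scalar.
    """
    if model_id not in _EVALUATORS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    expected = _PARAM_CLASSES[model_id]
    if not isinstance(params, expected):
        raise TypeError(f"model {model_id!r} expects {expected.__name__}, got {type(params).__name__}")
    x_arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x_arr)):
        raise ValueError("independent variable values must be finite")
    out = _EVALUATORS[model_id](params, x_arr)
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(out)
    return out


def lognormal_from_moments(target_mean: float, target_var: float) -> LognormalMoments:
    """Log-scale location/scale of a lognormal with the given original-scale moments.

    Solves E[Y] = exp(mu + sigma2/2) = target_mean and
    Var[Y] = (exp(sigma2) - 1) exp(2 mu + sigma2) = target_var.
    A zero target variance yields the degenerate point mass (sigma2 = 0).
    """
    if not np.isfinite(target_mean) or target_mean <= 0:
        raise ValueError("target_mean must be positive and finite")
    if not np.isfinite(target_var) or target_var < 0:
        raise ValueError("target_var must be non-negative and finite")
    if target_var == 0.0:
        return LognormalMoments(target_mean, 0.0, float(np.log(target_mean)), 0.0, degenerate=True)
    m2 = target_mean**2
    mu = np.log(m2 / np.sqrt(m2 + target_var))
    sigma2 = np.log1p(target_var / m2)
    return LognormalMoments(target_mean, target_var, float(mu), float(sigma2))


def params_to_dict(model_id: str, params: ParamsType) -> dict:
    """Flatten a parameter object to a JSON/YAML-serialisable dict with a model tag."""
    if model_id not in _PARAM_CLASSES:
        raise ValueError(f"unknown model_id {model_id!r}")
    d = {k: v for k, v in asdict(params).items() if v is not None}
    d["model_id"] = model_id
    return d


def params_from_dict(d: dict) -> tuple[str, ParamsType]:
    """Inverse of :func:`params_to_dict`."""
    d = dict(d)
    model_id = d.pop("model_id")
    if model_id not in _PARAM_CLASSES:
        raise ValueError(f"unknown model_id {model_id!r}")
    return model_id, _PARAM_CLASSES[model_id](**d)
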
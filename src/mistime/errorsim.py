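"""Error-model primitives and the five seeded synthetic-data generators.

Two mechanisms for error on the independent variable (time) are supported:

* **classical** -- the observation scatters about the truth, ``w = x + u``.
  Typical of a non-controlled experiment where the time stamp itself is
  measured with noise.
* **Berkson** -- the truth scatters about the recorded value, ``x = w + u``.
  Typical of a controlled experiment: the protocol time ``w`` is what gets
  written down, while the actual measurement happens at ``x = w + u``.

Every generator keeps the hidden truth (actual times, per-subject
parameters) alongside the observed ``(w, y)`` pairs so that downstream code
can fit both the observed data and the "true" data and compare.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    CosineParams,
    Glut4Params,
    GompertzParams,
    LinearParams,
    ParasiteParams,
    evaluate_model,
    lognormal_from_moments,
    params_to_dict,
)

__all__ = [
    "ErrorSpec",
    "SequentialDelaySpec",
    "EquationErrorSpec",
    "TimecourseDataset",
    "draw_classical_observations",
    "draw_berkson_truth",
    "sequential_timing_errors",
    "generate_linear_dataset",
    "generate_oscillation_dataset",
    "generate_parasite_dataset",
    "generate_tumour_dataset",
    "generate_glut4_dataset",
    "as_rng",
]

PARASITE_PROTOCOL_DAYS = np.arange(0.0, 26.0, 2.0)  # {0, 2, ..., 24}
TUMOUR_PROTOCOL_DAYS = np.arange(0.0, 62.0, 2.0)  # {0, 2, ..., 60}
GLUT4_PROTOCOL_MINUTES = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 45.0, 60.0])


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ErrorSpec:
    """Declarative description of a measurement-error mechanism.

    ``kind`` selects classical (w = x + u) or Berkson (x = w + u).
    ``distribution`` is ``normal`` with variance ``var_u`` (note: variance,
    not standard deviation) or ``uniform``; a uniform error is either biased
    on [0, delta] (mean delta/2, e.g. a dose always administered *after* the
    protocol time) or unbiased on [-delta/2, delta/2].
    """

    kind: str
    distribution: str = "normal"
    var_u: float | None = None
    delta: float | None = None
    biased: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("classical", "berkson"):
            raise ValueError("kind must be 'classical' or 'berkson'")
        if self.distribution == "normal":
            if self.var_u is None or self.var_u < 0:
                raise ValueError("normal error requires var_u >= 0")
        elif self.distribution == "uniform":
            if self.delta is None or self.delta < 0:
                raise ValueError("uniform error requires delta >= 0")
        else:
            raise ValueError("distribution must be 'normal' or 'uniform'")

    @property
    def bias(self) -> float:
        """Mean of the error distribution (non-zero only for biased uniform)."""
        if self.distribution == "uniform" and self.biased:
            return self.delta / 2.0
        return 0.0

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.distribution == "normal":
            if self.var_u == 0:
                return np.zeros(size)
            return rng.normal(0.0, np.sqrt(self.var_u), size)
        if self.delta == 0:
            return np.zeros(size)
        lo, hi = (0.0, self.delta) if self.biased else (-self.delta / 2.0, self.delta / 2.0)
        return rng.uniform(lo, hi, size)


@dataclass(frozen=True)
class SequentialDelaySpec:
    """Sequential-measurement delays: one experimentalist, one tumour at a time.

    Each measurement takes a lognormally distributed duration with mean
    ``mean_duration`` and standard deviation ``sd_duration`` (days, on the
    original scale).  The timing error of the T-th subject measured on a day
    is the cumulative sum of the first T durations that day.  ``ordering``
    is ``fixed`` (same subject order every day) or ``random_per_day``.
    """

    mean_duration: float = 1.0 / 6.0
    sd_duration: float = 0.1
    ordering: str = "fixed"

    def __post_init__(self) -> None:
        if self.mean_duration <= 0:
            raise ValueError("mean_duration must be positive")
        if self.sd_duration < 0:
            raise ValueError("sd_duration must be non-negative")
        if self.ordering not in ("fixed", "random_per_day"):
            raise ValueError("ordering must be 'fixed' or 'random_per_day'")


@dataclass(frozen=True)
class EquationErrorSpec:
    """Scatter of the response about the deterministic model.

    ``additive``: y = f(x) + eps;  ``multiplicative``: y = (1 + eps) f(x);
    ``none``: y = f(x) exactly.  ``variance`` is the variance of eps.
    """

    form: str = "additive"
    variance: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("additive", "multiplicative", "none"):
            raise ValueError("form must be 'additive', 'multiplicative' or 'none'")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")

    def apply(self, y_true: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.form == "none" or self.variance == 0:
            return np.asarray(y_true, dtype=float).copy()
        eps = rng.normal(0.0, np.sqrt(self.variance), np.shape(y_true))
        if self.form == "additive":
            return y_true + eps
        return (1.0 + eps) * y_true


class TimecourseDataset:
    """Tidy timecourse data with observed pairs and (optionally) hidden truth.

    The backing frame has columns ``subject_id``, ``protocol_time`` (the
    recorded/observed independent value w), ``true_time`` (the hidden truth
    x; NaN for external data), and ``response`` (y).  ``metadata`` records
    the design label, error specs and seed; ``true_params`` holds hidden
    per-subject generating parameters for synthetic cohorts.
    """

    COLUMNS = ("subject_id", "protocol_time", "true_time", "response")

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None, true_params=None):
        missing = [c for c in ("subject_id", "protocol_time", "response") if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset frame is missing columns {missing}")
        frame = frame.copy()
        if "true_time" not in frame.columns:
            frame["true_time"] = np.nan
        if not np.all(np.isfinite(frame["protocol_time"].to_numpy(dtype=float))):
            raise ValueError("protocol_time must be finite")
        if frame["response"].isna().any():
            raise ValueError("response column must be complete")
        self.frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        self.metadata = dict(metadata or {})
        self.true_params = true_params

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        design = self.metadata.get("design", "external")
        return f"TimecourseDataset(n={len(self)}, design={design!r})"

    @property
    def w(self) -> np.ndarray:
        """Recorded (protocol/observed) independent values."""
        return self.frame["protocol_time"].to_numpy(dtype=float)

    @property
    def x(self) -> np.ndarray:
        """Hidden true independent values; raises if absent (external data)."""
        vals = self.frame["true_time"].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("dataset has no hidden truth (external data?)")
        return vals

    @property
    def y(self) -> np.ndarray:
        return self.frame["response"].to_numpy(dtype=float)

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    @property
    def has_truth(self) -> bool:
        return not self.frame["true_time"].isna().any()

    def times(self, which: str) -> np.ndarray:
        """Independent values by role: ``protocol`` (w) or ``true`` (x)."""
        if which == "protocol":
            return self.w
        if which == "true":
            return self.x
        raise ValueError("time column must be 'protocol' or 'true'")

    def subset(self, subject_id) -> "TimecourseDataset":
        sub = self.frame[self.frame["subject_id"] == subject_id]
        if sub.empty:
            raise KeyError(f"no rows for subject {subject_id!r}")
        tp = None
        if isinstance(self.true_params, dict):
            tp = self.true_params.get(subject_id)
        return TimecourseDataset(sub, dict(self.metadata, subject=subject_id), tp)

    def to_csv(self, path) -> None:
        """Write the tidy CSV plus a JSON sidecar of design metadata."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.metadata, indent=2, default=str))

    @classmethod
    def read_csv(cls, path) -> "TimecourseDataset":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(frame, metadata)


def draw_classical_observations(x, spec: ErrorSpec, rng) -> np.ndarray:
    """Contaminate true values classically: w = x + u with u iid from ``spec``."""
    if spec.kind != "classical":
        raise ValueError("draw_classical_observations requires a classical ErrorSpec")
    x = np.asarray(x, dtype=float)
    return x + spec.draw(as_rng(rng), x.shape)


def draw_berkson_truth(w, spec: ErrorSpec, rng) -> np.ndarray:
    """Scatter the truth about recorded values: x = w + u with u iid from ``spec``."""
    if spec.kind != "berkson":
        raise ValueError("draw_berkson_truth requires a Berkson ErrorSpec")
    w = np.asarray(w, dtype=float)
    return w + spec.draw(as_rng(rng), w.shape)


def sequential_timing_errors(
    n_subjects: int, n_days: int, spec: SequentialDelaySpec, rng
) -> np.ndarray:
    """Cumulative sequential-measurement delays, shape (n_subjects, n_days).

    On each day the experimentalist measures the subjects one after another;
    subject measured in position T that day is delayed by the sum of the
    first T measurement durations (its own included).  Durations are iid
    lognormal with the original-scale moments of ``spec``; a zero
    ``sd_duration`` makes every duration exactly ``mean_duration``.
    """
    if n_subjects < 1 or n_days < 1:
        raise ValueError("n_subjects and n_days must be >= 1")
    rng = as_rng(rng)
    mom = lognormal_from_moments(spec.mean_duration, spec.sd_duration**2)
    if mom.degenerate:
        durations = np.full((n_subjects, n_days), spec.mean_duration)
    else:
        durations = rng.lognormal(mom.mu, np.sqrt(mom.sigma2), (n_subjects, n_days))
    U = np.empty((n_subjects, n_days))
    for j in range(n_days):
        if spec.ordering == "fixed":
            order = np.arange(n_subjects)
        else:
            order = rng.permutation(n_subjects)
        cum = np.cumsum(durations[:, j])
        U[order, j] = cum
    return U


def _n_unique_subjects(n: int) -> np.ndarray:
    return np.arange(n)


def generate_linear_dataset(
    design: str,
    n: int = 50,
    params: LinearParams = LinearParams(0.0, 1.0),
    error_spec: ErrorSpec | None = None,
    eq_error: EquationErrorSpec | None = None,
    rng=None,
) -> TimecourseDataset:
    """Synthetic straight-line data under three designs.

    * ``noncontrolled_classical``: x ~ N(0, 1); w = x + u.
    * ``noncontrolled_berkson``:   w ~ N(0, 1); x = w + u.
    * ``controlled_berkson``: w on 5 equally spaced protocol points in
      [-2, 2] with n/5 replicates each; x = w + u.

    The response is always generated from the hidden truth,
    y = beta0 + beta_x * x + eps.  Defaults follow the standard study
    conditions: u and eps zero-mean normal with variance 0.25 each.
    """
    rng = as_rng(rng)
    if n < 2:
        raise ValueError("n must be >= 2")
    if eq_error is None:
        eq_error = EquationErrorSpec("additive", 0.25)
    if design == "noncontrolled_classical":
        spec = error_spec or ErrorSpec("classical", "normal", var_u=0.25)
        x = rng.normal(0.0, 1.0, n)
        w = draw_classical_observations(x, spec, rng)
    elif design in ("noncontrolled_berkson", "controlled_berkson"):
        spec = error_spec or ErrorSpec("berkson", "normal", var_u=0.25)
        if design == "noncontrolled_berkson":
            w = rng.normal(0.0, 1.0, n)
        else:
            if n % 5:
                raise ValueError("controlled design needs n divisible by 5")
            w = np.repeat(np.linspace(-2.0, 2.0, 5), n // 5)
        x = draw_berkson_truth(w, spec, rng)
    else:
        raise ValueError(f"unknown linear design {design!r}")
    y = eq_error.apply(evaluate_model("linear", params, x), rng)
    frame = pd.DataFrame(
        {"subject_id": _n_unique_subjects(n), "protocol_time": w, "true_time": x, "response": y}
    )
    meta = {
        "design": f"linear/{design}",
        "params": params_to_dict("linear", params),
        "error_spec": asdict(spec),
        "eq_error": asdict(eq_error),
    }
    return TimecourseDataset(frame, meta)


def generate_oscillation_dataset(
    design: str,
    params: CosineParams = CosineParams(3.0, 4.0),
    error_spec: ErrorSpec | None = None,
    eq_error: EquationErrorSpec | None = None,
    n: int = 50,
    rng=None,
) -> TimecourseDataset:
    """Synthetic oscillation data, y = a cos(b x) + eps, under four designs.

    * ``noncontrolled_classical``: x ~ U(-2, 2); w = x + u.
    * ``noncontrolled_berkson``:   w ~ U(-2, 2); x = w + u.
    * ``controlled_case1``: 5 protocol points equally spaced on [-2, 2]
      (n/5 replicates each), not aligned with the oscillation.
    * ``controlled_case2``: 5 protocol points equally spaced on
      [-pi/2, pi/2] (spacing pi/4), coinciding with turning points of
      cos(4x) so the amplitude is observed directly.

    Defaults: timing and equation errors zero-mean normal, variance 0.05.
    """
    rng = as_rng(rng)
    if eq_error is None:
        eq_error = EquationErrorSpec("additive", 0.05)
    if design == "noncontrolled_classical":
        spec = error_spec or ErrorSpec("classical", "normal", var_u=0.05)
        x = rng.uniform(-2.0, 2.0, n)
        w = draw_classical_observations(x, spec, rng)
    elif design in ("noncontrolled_berkson", "controlled_case1", "controlled_case2"):
        spec = error_spec or ErrorSpec("berkson", "normal", var_u=0.05)
        if design == "noncontrolled_berkson":
            w = rng.uniform(-2.0, 2.0, n)
        else:
            if n % 5:
                raise ValueError("controlled design needs n divisible by 5")
            lim = 2.0 if design == "controlled_case1" else np.pi / 2.0
            w = np.repeat(np.linspace(-lim, lim, 5), n // 5)
        x = draw_berkson_truth(w, spec, rng)
    else:
        raise ValueError(f"unknown oscillation design {design!r}")
    y = eq_error.apply(evaluate_model("cosine", params, x), rng)
    frame = pd.DataFrame(
        {"subject_id": _n_unique_subjects(n), "protocol_time": w, "true_time": x, "response": y}
    )
    meta = {
        "design": f"oscillation/{design}",
        "params": params_to_dict("cosine", params),
        "error_spec": asdict(spec),
        "eq_error": asdict(eq_error),
    }
    return TimecourseDataset(frame, meta)


def generate_parasite_dataset(
    params: ParasiteParams = ParasiteParams(0.002, 0.531, 0.02, 0.323),
    sigma_U: float = 0.25,
    sigma_eps: float = 0.0,
    rng=None,
) -> TimecourseDataset:
    """Parasite growth with Berkson day-timing error, one observation per day.

    Protocol days are {0, 2, ..., 24}; the actual measurement happens at
    t = w + u with u ~ N(0, sigma_U^2) (only the protocol day is recorded).
    The response carries a multiplicative equation error,
    y = (1 + eps) P(t) with eps ~ N(0, sigma_eps^2); large sigma_eps can
    produce negative responses, which are kept (no censoring).
    """
    if sigma_U < 0 or sigma_eps < 0:
        raise ValueError("sigma_U and sigma_eps must be non-negative")
    rng = as_rng(rng)
    w = PARASITE_PROTOCOL_DAYS.copy()
    spec = ErrorSpec("berkson", "normal", var_u=sigma_U**2)
    t = draw_berkson_truth(w, spec, rng)
    eq = EquationErrorSpec("multiplicative", sigma_eps**2)
    y = eq.apply(evaluate_model("parasite", params, t), rng)
    frame = pd.DataFrame(
        {"subject_id": np.zeros(len(w), dtype=int), "protocol_time": w, "true_time": t, "response": y}
    )
    meta = {
        "design": "parasite/berkson_day_timing",
        "params": params_to_dict("parasite", params),
        "error_spec": asdict(spec),
        "eq_error": asdict(eq),
    }
    return TimecourseDataset(frame, meta)


def generate_tumour_dataset(
    scenario: str = "perfect",
    n_tumours: int = 6,
    spec: SequentialDelaySpec = SequentialDelaySpec(),
    rng=None,
) -> TimecourseDataset:
    """Six-tumour Gompertz cohort with correlated sequential timing delays.

    Per-tumour parameters: y(0) ~ U(100, 120), r ~ N(0.08, 0.02^2), K = 4000.
    Measurements every second day for 60 days (protocol days {0, 2, ..., 60},
    31 per tumour); tumour volume itself is measured exactly, so the response
    is the Gompertz curve evaluated at the true measurement time.

    Scenarios: ``perfect`` (t = w), ``ordered`` (sequential delays, fixed
    measurement order) and ``random_order`` (order reshuffled independently each day).
    """
    if scenario not in ("perfect", "ordered", "random_order"):
        raise ValueError(f"unknown tumour scenario {scenario!r}")
    rng = as_rng(rng)
    days = TUMOUR_PROTOCOL_DAYS
    y0 = rng.uniform(100.0, 120.0, n_tumours)
    r = rng.normal(0.08, 0.02, n_tumours)
    while np.any(r <= 0):  # Gompertz needs r > 0; resample the (4-sigma) tail
        bad = r <= 0
        r[bad] = rng.normal(0.08, 0.02, bad.sum())
    tumours = [GompertzParams(y0=float(a), r=float(b), K=4000.0) for a, b in zip(y0, r)]
    if scenario == "perfect":
        U = np.zeros((n_tumours, len(days)))
    else:
        ordering = "fixed" if scenario == "ordered" else "random_per_day"
        delay_spec = SequentialDelaySpec(spec.mean_duration, spec.sd_duration, ordering)
        U = sequential_timing_errors(n_tumours, len(days), delay_spec, rng)
    rows = []
    for i, p in enumerate(tumours):
        t = days + U[i]
        y = evaluate_model("gompertz", p, t)
        rows.append(
            pd.DataFrame(
                {"subject_id": i, "protocol_time": days, "true_time": t, "response": y}
            )
        )
    frame = pd.concat(rows, ignore_index=True)
    meta = {
        "design": f"tumour/{scenario}",
        "delay_spec": asdict(spec),
        "n_tumours": n_tumours,
    }
    return TimecourseDataset(frame, meta, true_params={i: p for i, p in enumerate(tumours)})


def generate_glut4_dataset(
    params: Glut4Params = Glut4Params(P0=0.1, k=0.1, M=1.0),
    Delta: float = 0.5,
    sigma_Y: float = 0.05,
    n_rep: int = 1000,
    rng=None,
    protocol_times: Sequence[float] | None = None,
) -> TimecourseDataset:
    """GLUT4 translocation timecourse with biased uniform timing error.

    Protocol minutes {0, 0.5, 1, 2, 5, 10, 15, 20, 25, 30, 45, 60}, ``n_rep``
    independent replicates per time point.  The actual measurement time is
    t = w + U with U ~ U(0, Delta) (the dose response is always observed a
    little *late*).  Responses are lognormal with original-scale mean
    P(theta, t) and variance sigma_Y^2; sigma_Y = 0 returns the exact curve.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if Delta < 0 or sigma_Y < 0:
        raise ValueError("Delta and sigma_Y must be non-negative")
    rng = as_rng(rng)
    w_grid = np.asarray(
        GLUT4_PROTOCOL_MINUTES if protocol_times is None else protocol_times, dtype=float
    )
    w = np.tile(w_grid, n_rep)
    subject = np.repeat(np.arange(n_rep), len(w_grid))
    spec = ErrorSpec("berkson", "uniform", delta=Delta, biased=True)
    t = draw_berkson_truth(w, spec, rng)
    mean = evaluate_model("glut4", params, t)
    if np.any(mean <= 0):
        raise ValueError("model mean must be positive for the lognormal response")
    if sigma_Y == 0:
        y = mean.copy()
    else:
        m2 = mean**2
        mu = np.log(m2 / np.sqrt(m2 + sigma_Y**2))
        sigma = np.sqrt(np.log1p(sigma_Y**2 / m2))
        y = rng.lognormal(mu, sigma)
    frame = pd.DataFrame(
        {"subject_id": subject, "protocol_time": w, "true_time": t, "response": y}
    )
    meta = {
        "design": "glut4/biased_uniform_timing",
        "params": params_to_dict("glut4", params),
        "Delta": Delta,
        "sigma_Y": sigma_Y,
        "n_rep": n_rep,
        "error_spec": asdict(spec),
    }
    return TimecourseDataset(frame, meta)
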
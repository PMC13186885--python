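"""Replicated experiment pipelines wiring generators, fitters and metrics.

Each named study regenerates synthetic data many times, refits it, and
returns a tidy long-format table (one row per replicate x scenario x
parameter) suitable for density plots and bias/variance summaries.  Default
replicate counts follow the study designs (1000 for the linear study, 10000
for the oscillator and tumour resampling studies, 1000 per parasite grid
cell); the ``scale`` factor shrinks them proportionally for quick runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errorsim import (
    SequentialDelaySpec,
    generate_glut4_dataset,
    generate_linear_dataset,
    generate_oscillation_dataset,
    generate_parasite_dataset,
    generate_tumour_dataset,
)
from .models import CosineParams, Glut4Params, LinearParams, ParasiteParams
from .naivefit import fit_least_squares, kde
from .smc_bayes import Glut4LogLik, default_glut4_priors, posterior_metrics, run_smc

__all__ = [
    "StudyConfig",
    "run_study",
    "bias_variance_grid",
    "density_summary",
    "DEFAULT_REPLICATES",
]

STUDY_IDS = (
    "linear",
    "oscillator",
    "parasite",
    "parasite_grid",
    "tumour",
    "tumour_individual",
    "glut4_grid",
)

DEFAULT_REPLICATES = {
    "linear": 1000,
    "oscillator": 10000,
    "parasite": 1000,
    "parasite_grid": 1000,  # per grid cell
    "tumour": 10000,
    "tumour_individual": 10000,
    "glut4_grid": 1,  # per grid cell (one SMC run)
}

LINEAR_DESIGNS = ("noncontrolled_classical", "noncontrolled_berkson", "controlled_berkson")
OSCILLATOR_DESIGNS = (
    "noncontrolled_classical",
    "noncontrolled_berkson",
    "controlled_case1",
    "controlled_case2",
)


@dataclass
class StudyConfig:
    """Configuration of a named replicated experiment."""

    study_id: str
    replicates: int | None = None
    seed: int = 0
    scale: float = 1.0
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.study_id not in STUDY_IDS:
            raise ValueError(f"unknown study_id {self.study_id!r}; expected one of {STUDY_IDS}")
        if self.replicates is None:
            self.replicates = max(1, int(round(DEFAULT_REPLICATES[self.study_id] * self.scale)))
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _row(config, scenario, replicate, parameter, estimate, fit=None, **extra) -> dict:
    base = {
        "study_id": config.study_id,
        "scenario": scenario,
        "replicate": replicate,
        "parameter": parameter,
        "estimate": estimate,
        "ci_lower": np.nan,
        "ci_upper": np.nan,
        "r2": np.nan,
        "adj_r2": np.nan,
    }
    if fit is not None:
        base["r2"] = fit.r2
        base["adj_r2"] = fit.adj_r2
        if parameter in fit.ci:
            base["ci_lower"], base["ci_upper"] = fit.ci[parameter]
    base.update(extra)
    return base


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Run a named replicated study and return its tidy results table.

    Per-replicate fit failures are recorded (``converged`` column), never
    fatal.  The same config (including seed) always reproduces the same
    table.
    """
    dispatch = {
        "linear": _run_linear,
        "oscillator": _run_oscillator,
        "parasite": _run_parasite,
        "tumour": _run_tumour,
        "tumour_individual": _run_tumour_individual,
        "parasite_grid": lambda c: bias_variance_grid("parasite_grid", None, c.replicates, c),
        "glut4_grid": lambda c: bias_variance_grid("glut4_grid", None, c.replicates, c),
    }
    return dispatch[config.study_id](config)


def _spawn(config: StudyConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def _run_linear(config: StudyConfig) -> pd.DataFrame:
    params = config.options.get("params", LinearParams(0.0, 1.0))
    rows = []
    rngs = _spawn(config, config.replicates)
    for rep, rng in enumerate(rngs):
        for design in LINEAR_DESIGNS:
            ds = generate_linear_dataset(design, params=params, rng=rng)
            for which, label in (("true", "true"), ("protocol", "observed")):
                fit = fit_least_squares("linear", ds, time_column=which)
                for name, est in fit.theta_hat.items():
                    rows.append(
                        _row(config, f"{design}/{label}", rep, name, est, fit,
                             converged=fit.converged)
                    )
    return pd.DataFrame(rows)


def _run_oscillator(config: StudyConfig) -> pd.DataFrame:
    params = config.options.get("params", CosineParams(3.0, 4.0))
    rows = []
    rngs = _spawn(config, config.replicates)
    for rep, rng in enumerate(rngs):
        for design in OSCILLATOR_DESIGNS:
            ds = generate_oscillation_dataset(design, params=params, rng=rng)
            for which, label in (("true", "true"), ("protocol", "observed")):
                fit = fit_least_squares(
                    "cosine", ds, time_column=which, free_params=["a"],
                    fixed_params={"b": params.b}, init={"a": 1.0},
                )
                rows.append(
                    _row(config, f"{design}/{label}", rep, "a", fit.theta_hat["a"], fit,
                         converged=fit.converged)
                )
    return pd.DataFrame(rows)


def _run_parasite(config: StudyConfig) -> pd.DataFrame:
    """Single-realisation parasite demonstrations, replicated.

    Three fits per replicate: a no-timing-error dataset with all four
    parameters free, and a timing-error dataset fit first with all
    parameters free and then with only (V0, g) free and the background
    fixed at truth.
    """
    params = config.options.get("params", ParasiteParams(0.002, 0.531, 0.02, 0.323))
    sigma_U = config.options.get("sigma_U", 0.25)
    truth = {"V0": params.V0, "g": params.g, "B0": params.B0, "k": params.k}
    init_15 = {k: 1.5 * v for k, v in truth.items()}
    rows = []
    rngs = _spawn(config, config.replicates)
    for rep, rng in enumerate(rngs):
        ds0 = generate_parasite_dataset(params, sigma_U=0.0, sigma_eps=0.0, rng=rng)
        ds1 = generate_parasite_dataset(params, sigma_U=sigma_U, sigma_eps=0.0, rng=rng)
        fits = {
            "no_time_error/all_params": fit_least_squares(
                "parasite", ds0, init=init_15),
            "timing_error/all_params": fit_least_squares(
                "parasite", ds1, init=init_15),
            "timing_error/V0_g_only": fit_least_squares(
                "parasite", ds1, free_params=["V0", "g"],
                fixed_params={"B0": params.B0, "k": params.k},
                init={"V0": 1.5 * params.V0, "g": 1.5 * params.g},
            ),
        }
        for scenario, fit in fits.items():
            for name, est in fit.theta_hat.items():
                rows.append(_row(config, scenario, rep, name, est, fit, converged=fit.converged))
    return pd.DataFrame(rows)


def _tumour_pooled_fits(ds, include_free_y0: bool):
    """Pooled Gompertz fits: y0 fixed to the day-0 mean, optionally y0 free."""
    day0_mean = float(np.mean(ds.y[ds.w == 0.0]))
    ymax = float(ds.y.max())
    fits = {
        "y0_fixed": fit_least_squares(
            "gompertz", ds, free_params=["r", "K"], fixed_params={"y0": day0_mean},
            init={"r": 0.1, "K": ymax * 1.2},
        )
    }
    if include_free_y0:
        fits["y0_free"] = fit_least_squares(
            "gompertz", ds, init={"y0": day0_mean, "r": 0.1, "K": ymax * 1.2},
        )
    return fits


def _run_tumour(config: StudyConfig) -> pd.DataFrame:
    spec = config.options.get("delay_spec", SequentialDelaySpec())
    include_free = config.options.get("include_free_y0", True)
    scenarios = config.options.get("scenarios", ("perfect", "ordered", "random_order"))
    rows = []
    rngs = _spawn(config, config.replicates)
    for rep, rng in enumerate(rngs):
        for scenario in scenarios:
            ds = generate_tumour_dataset(scenario, spec=spec, rng=rng)
            for variant, fit in _tumour_pooled_fits(ds, include_free).items():
                for name, est in fit.theta_hat.items():
                    rows.append(
                        _row(config, f"{scenario}/{variant}", rep, name, est, fit,
                             converged=fit.converged)
                    )
    return pd.DataFrame(rows)


def _run_tumour_individual(config: StudyConfig) -> pd.DataFrame:
    """Per-tumour fits; estimates are recorded as relative errors vs the
    tumour's own true parameters, since every tumour has its own draw."""
    spec = config.options.get("delay_spec", SequentialDelaySpec())
    scenarios = config.options.get("scenarios", ("perfect", "ordered", "random_order"))
    rows = []
    rngs = _spawn(config, config.replicates)
    for rep, rng in enumerate(rngs):
        for scenario in scenarios:
            ds = generate_tumour_dataset(scenario, spec=spec, rng=rng)
            for sid, p in ds.true_params.items():
                sub = ds.subset(sid)
                fit = fit_least_squares(
                    "gompertz", sub, init={"y0": float(sub.y[0]), "r": 0.1, "K": 4800.0}
                )
                truth = {"y0": p.y0, "r": p.r, "K": p.K}
                for name, est in fit.theta_hat.items():
                    rows.append(
                        _row(config, f"{scenario}/tumour{sid}", rep, name,
                             (est - truth[name]) / truth[name], fit,
                             converged=fit.converged, metric="relative_error")
                    )
    return pd.DataFrame(rows)


def bias_variance_grid(
    study_id: str,
    axes: dict | None,
    reps: int,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Gridded bias/variance (parasite) or posterior-metric (GLUT4) summary.

    * ``parasite_grid``: axes are ``sigma_U`` and ``sigma_eps`` (defaults:
      20 linearly spaced points on [0, 0.5] each); per cell, ``reps``
      datasets are fitted for (V0, g) with the background fixed at truth and
      the mean bias and variance of each estimate recorded.
    * ``glut4_grid``: axes are ``Delta`` (minutes) and ``sigma_Y``; per cell
      an SMC posterior is drawn and MAP absolute error, credibility-interval
      width and interval distance recorded per parameter, averaged over
      ``reps`` seeds.
    """
    config = config or StudyConfig(study_id, replicates=reps)
    axes = axes or config.options.get("axes")
    if study_id == "parasite_grid":
        return _parasite_grid(axes, reps, config)
    if study_id == "glut4_grid":
        return _glut4_grid(axes, reps, config)
    raise ValueError(f"unknown grid study {study_id!r}")


def _parasite_grid(axes: dict | None, reps: int, config: StudyConfig) -> pd.DataFrame:
    if axes is None:
        axes = {"sigma_U": np.linspace(0.0, 0.5, 20), "sigma_eps": np.linspace(0.0, 0.5, 20)}
    params = config.options.get("params", ParasiteParams(0.002, 0.531, 0.02, 0.323))
    truth = {"V0": params.V0, "g": params.g}
    rows = []
    cells = [(su, se) for se in axes["sigma_eps"] for su in axes["sigma_U"]]
    seeds = np.random.SeedSequence(config.seed).spawn(len(cells))
    for (sigma_U, sigma_eps), cell_seed in zip(cells, seeds):
        rngs = [np.random.default_rng(s) for s in cell_seed.spawn(reps)]
        ests = {"V0": [], "g": []}
        n_fail = 0
        for rng in rngs:
            ds = generate_parasite_dataset(params, sigma_U=sigma_U, sigma_eps=sigma_eps, rng=rng)
            fit = fit_least_squares(
                "parasite", ds, free_params=["V0", "g"],
                fixed_params={"B0": params.B0, "k": params.k},
                init={"V0": params.V0, "g": params.g},
            )
            if not fit.converged:
                n_fail += 1
                continue
            for name in ests:
                ests[name].append(fit.theta_hat[name])
        for name, vals in ests.items():
            vals = np.asarray(vals)
            rows.append(
                {
                    "study_id": "parasite_grid",
                    "sigma_U": float(sigma_U),
                    "sigma_eps": float(sigma_eps),
                    "parameter": name,
                    "bias": float(np.mean(vals - truth[name])) if vals.size else np.nan,
                    "variance": float(np.var(vals)) if vals.size else np.nan,
                    "n_ok": int(vals.size),
                    "n_fail": n_fail,
                }
            )
    return pd.DataFrame(rows)


def _glut4_grid(axes: dict | None, reps: int, config: StudyConfig) -> pd.DataFrame:
    if axes is None:
        axes = {"Delta": np.linspace(0.0, 1.0, 10), "sigma_Y": np.linspace(0.0, 0.3, 10)[1:]}
    params = config.options.get("params", Glut4Params(P0=0.1, k=0.1, M=1.0))
    n_rep = config.options.get("n_rep", 1000)
    n_particles = config.options.get("n_particles", 1000)
    priors = config.options.get("priors", default_glut4_priors())
    truth = {"P0": params.P0, "k": params.k, "M": params.M}
    rows = []
    cells = [(d, s) for s in axes["sigma_Y"] for d in axes["Delta"]]
    seeds = np.random.SeedSequence(config.seed).spawn(len(cells))
    for (delta, sigma_Y), cell_seed in zip(cells, seeds):
        if sigma_Y <= 0:
            raise ValueError("glut4 grid requires sigma_Y > 0 for the lognormal likelihood")
        metrics_acc: dict[str, dict[str, list]] = {
            name: {"map_abs_error": [], "ci_width": [], "ci_distance": []} for name in truth
        }
        for rep_seed in cell_seed.spawn(reps):
            child = rep_seed.spawn(2)
            ds = generate_glut4_dataset(
                params, Delta=delta, sigma_Y=sigma_Y, n_rep=n_rep,
                rng=np.random.default_rng(child[0]),
            )
            loglik = Glut4LogLik(ds, sigma_Y)
            particles = run_smc(
                loglik, priors, n_particles=n_particles, rng=np.random.default_rng(child[1])
            )
            pm = posterior_metrics(particles, truth)
            for name in truth:
                metrics_acc[name]["map_abs_error"].append(pm.map_abs_error[name])
                metrics_acc[name]["ci_width"].append(pm.ci_width[name])
                metrics_acc[name]["ci_distance"].append(pm.ci_distance[name])
        for name, acc in metrics_acc.items():
            rows.append(
                {
                    "study_id": "glut4_grid",
                    "Delta": float(delta),
                    "sigma_Y": float(sigma_Y),
                    "parameter": name,
                    "map_abs_error": float(np.mean(acc["map_abs_error"])),
                    "ci_width": float(np.mean(acc["ci_width"])),
                    "ci_distance": float(np.mean(acc["ci_distance"])),
                    "n_reps": reps,
                }
            )
    return pd.DataFrame(rows)


def density_summary(table: pd.DataFrame, parameter: str, scenario: str | None = None):
    """KDE of a parameter's estimates for one scenario of a study table."""
    sub = table[table["parameter"] == parameter]
    if scenario is not None:
        sub = sub[sub["scenario"] == scenario]
    if sub.empty:
        raise ValueError("no matching rows for density summary")
    return kde(sub["estimate"].to_numpy())
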
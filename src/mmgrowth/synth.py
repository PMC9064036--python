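"""Synthetic mother-machine studies with known ground truth.

Simulates the event-generation process the analysis assumes: per growth
channel a single mother-cell lineage (daughters wash out with the medium
flow), iid generation times from a configurable family, births and divisions
only resolved on the imaging grid, and a finite observation window that
censors long generation times — the bias the estimation pipeline corrects.
Concentration enters through a kinetic model: the target population growth
rate mu(c) is mapped to the family's mean generation time through the exact
Euler-Lotka inverse, so the generating mu is known analytically.  Replicate-
level all-or-nothing non-growth at extreme concentrations is modelled by a
per-replicate coin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .events import (
    DivisionEvent,
    ExperimentRecord,
    ObservationWindow,
    snap_to_grid,
    write_events,
)
from .kinetics import SingleStepParams, TABLE_SINGLE, TwoStepParams, mu_single, mu_two

__all__ = [
    "SimulationConfig",
    "PAPER_CONCENTRATIONS",
    "default_p_nongrowth",
    "mean_tau_for_target_mu",
    "simulate_lineage",
    "simulate_experiment",
    "simulate_study",
    "simulate_censored_sample",
]

#: The 12 PCA concentrations of the study design, mmol/L.
PAPER_CONCENTRATIONS = (0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 1.0, 6.0, 20.0, 30.0, 50.0, 100.0)

_FAMILIES = ("gamma", "lognormal", "fixed")


def default_p_nongrowth(c: float) -> float:
    """Probability that a replicate at concentration ``c`` shows no growth.

    Reflects the observed replicate-level pattern: occasional complete
    absence of divisions at very low concentrations (diffusion limitation),
    reliable growth in the mid range, all-or-nothing behaviour around
    30 mmol/L (3 of 5 replicates non-growing), and complete inactivity at
    50 mmol/L and above.
    """
    if c <= 0:
        return 0.0  # growth is impossible anyway (mu(0) = 0)
    if c < 0.05:
        return 0.3
    if c <= 20.0:
        return 0.0
    if c < 50.0:
        return 0.6
    return 1.0


@dataclass
class SimulationConfig:
    """Study-level simulation settings.

    Defaults mirror the device and design: 30 growth channels per
    experiment, a 40 h observation imaged every 5 min with the first 15 h
    discarded downstream, 5 biological replicates at each of the 12 study
    concentrations, gamma generation times with cv 0.2, and single-step
    substrate-inhibition kinetics with the published parameters.
    """

    concentrations: Sequence[float] = PAPER_CONCENTRATIONS
    replicates_per_concentration: int = 5
    channels_per_experiment: int = 30
    window: ObservationWindow = field(default_factory=ObservationWindow)
    tau_family: str = "gamma"
    cv_tau: float = 0.2
    kinetic_params: SingleStepParams | TwoStepParams = TABLE_SINGLE
    p_nongrowth: Callable[[float], float] = default_p_nongrowth
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_family not in _FAMILIES:
            raise ValueError(
                f"tau_family must be one of {_FAMILIES}, got {self.tau_family!r}"
            )
        if self.cv_tau <= 0:
            raise ValueError(f"cv_tau must be > 0, got {self.cv_tau}")
        if self.replicates_per_concentration < 1 or self.channels_per_experiment < 1:
            raise ValueError("counts must be >= 1")

    def mu_of_c(self, c: float) -> float:
        if isinstance(self.kinetic_params, TwoStepParams):
            return float(mu_two(c, self.kinetic_params))
        return float(mu_single(c, self.kinetic_params))


def mean_tau_for_target_mu(
    mu_target: float, family: str = "gamma", cv: float = 0.2
) -> float:
    """Mean generation time such that the Euler-Lotka relation holds exactly.

    Solves ``1 = 2 * E[exp(-mu * tau)]`` for the family's mean at the given
    target population growth rate.  Closed form for the gamma family
    (shape k = 1/cv^2, scale theta = (2^(1/k) - 1)/mu, mean = k*theta) and
    the point mass (ln 2 / mu); solved numerically for the lognormal.
    """
    if mu_target <= 0:
        raise ValueError(f"mu_target must be > 0, got {mu_target}")
    if family == "fixed":
        return math.log(2.0) / mu_target
    if cv <= 0:
        raise ValueError(f"cv must be > 0, got {cv}")
    if family == "gamma":
        k = 1.0 / cv**2
        theta = (2.0 ** (1.0 / k) - 1.0) / mu_target
        return k * theta
    if family == "lognormal":
        sigma2 = math.log(1.0 + cv**2)
        sigma = math.sqrt(sigma2)

        def laplace_minus_half(mean: float) -> float:
            # E[exp(-mu tau)] for tau ~ LogN with arithmetic mean `mean`
            mu_ln = math.log(mean) - sigma2 / 2.0
            val, _ = quad(
                lambda z: math.exp(-mu_target * math.exp(mu_ln + sigma * z))
                * math.exp(-z * z / 2.0)
                / math.sqrt(2.0 * math.pi),
                -10.0,
                10.0,
            )
            return val - 0.5

        lo, hi = 1e-6, 1e-6
        while laplace_minus_half(hi) > 0:
            hi *= 2.0
            if hi > 1e6:
                raise ValueError("no attainable lognormal mean for this mu")
        return float(brentq(laplace_minus_half, lo, hi, rtol=1e-12))
    raise ValueError(f"unknown family {family!r}")


def _draw_tau(rng: np.random.Generator, family: str, mean: float, cv: float) -> float:
    if family == "fixed":
        return mean
    if family == "gamma":
        k = 1.0 / cv**2
        return float(rng.gamma(shape=k, scale=mean / k))
    sigma2 = math.log(1.0 + cv**2)
    return float(rng.lognormal(mean=math.log(mean) - sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def simulate_lineage(
    mean_tau: float,
    family: str,
    cv: float,
    window: ObservationWindow,
    rng: np.random.Generator,
    channel_id: str = "ch0",
    initial_age: float | None = None,
) -> list[DivisionEvent]:
    """Simulate one mother-cell lineage over ``[0, t_end]``.

    The cell occupying the channel at t = 0 has age uniform on [0, its
    generation time) — the steady-state approximation; its own birth is not
    an observed event.  Each subsequent cell's birth and division are snapped
    to the imaging grid and the event is emitted only if the division falls
    at or before ``t_end`` (natural right-censoring).
    """
    if mean_tau <= 0:
        raise ValueError(f"mean_tau must be > 0, got {mean_tau}")
    tau0 = _draw_tau(rng, family, mean_tau, cv)
    if initial_age is None:
        initial_age = float(rng.uniform(0.0, tau0))
    elif not 0.0 <= initial_age < tau0:
        raise ValueError("initial_age must lie in [0, first generation time)")

    events: list[DivisionEvent] = []
    t = tau0 - initial_age  # first division after observation starts
    i = 0
    while t <= window.t_end:
        birth = t
        tau = _draw_tau(rng, family, mean_tau, cv)
        t = birth + tau
        if t > window.t_end:
            break  # division unobserved; life censored
        birth_snap = snap_to_grid(birth, window.delta_tau)
        div_snap = snap_to_grid(t, window.delta_tau)
        tau_snap = div_snap - birth_snap
        if tau_snap <= 0 or tau_snap >= window.length:
            continue  # unresolvable on the grid / unobservable geometry
        i += 1
        events.append(
            DivisionEvent(
                cell_id=f"{channel_id}_cell{i}",
                channel_id=channel_id,
                birth_time=birth_snap,
                generation_time=tau_snap,
            )
        )
    return events


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Named RNG stream: one generator per (experiment, channel) so adding
    replicates never perturbs existing ones."""
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def simulate_experiment(
    c: float,
    config: SimulationConfig,
    experiment_index: int,
    experiment_id: str | None = None,
) -> tuple[ExperimentRecord, dict]:
    """Simulate one biological replicate at concentration ``c``.

    Returns the record plus its ground-truth manifest entry (generating mu,
    mean tau, family, cv, and the non-growth flag).
    """
    if experiment_id is None:
        experiment_id = f"sim{experiment_index:04d}"
    mu_true = config.mu_of_c(c)
    coin = _stream(config.seed, experiment_index, 0)
    nongrowing = bool(coin.uniform() < config.p_nongrowth(c)) or mu_true <= 0.0

    record = ExperimentRecord(experiment_id=experiment_id, concentration=c)
    mean_tau = None
    if not nongrowing:
        mean_tau = mean_tau_for_target_mu(mu_true, config.tau_family, config.cv_tau)
        for ch in range(config.channels_per_experiment):
            rng = _stream(config.seed, experiment_index, ch + 1)
            record.events.extend(
                simulate_lineage(
                    mean_tau,
                    config.tau_family,
                    config.cv_tau,
                    config.window,
                    rng,
                    channel_id=f"ch{ch:02d}",
                )
            )
    truth = {
        "experiment_id": experiment_id,
        "concentration_mmol_per_L": c,
        "mu_true_per_h": mu_true if not nongrowing else 0.0,
        "mu_kinetic_per_h": mu_true,
        "mean_tau_h": mean_tau,
        "tau_family": config.tau_family,
        "cv_tau": config.cv_tau,
        "nongrowing": nongrowing,
        "n_events": len(record.events),
    }
    return record, truth


def simulate_study(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[list[ExperimentRecord], list[dict]]:
    """Simulate the full study: all concentrations x replicates.

    Returns (records, manifest); if ``out_dir`` is given, additionally writes
    ``events.tsv`` in the event-table dialect and ``truth.json`` with the
    per-experiment generating parameters.
    """
    records: list[ExperimentRecord] = []
    manifest: list[dict] = []
    index = 0
    for c in config.concentrations:
        for rep in range(config.replicates_per_concentration):
            exp_id = f"c{c:g}_r{rep + 1}"
            record, truth = simulate_experiment(
                c, config, experiment_index=index, experiment_id=exp_id
            )
            records.append(record)
            manifest.append(truth)
            index += 1
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_events(records, out / "events.tsv")
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"config": _config_summary(config), "experiments": manifest},
                fh,
                indent=2,
            )
            fh.write("\n")
    return records, manifest


def simulate_censored_sample(
    n_events: int,
    mean_tau: float,
    family: str,
    cv: float,
    window: ObservationWindow,
    rng: np.random.Generator,
) -> list[DivisionEvent]:
    """Pool lineages until at least ``n_events`` censored events are observed.

    Convenience for estimator-consistency studies: gives a sample of the
    given size drawn from the window-censored observation process.
    """
    events: list[DivisionEvent] = []
    ch = 0
    while len(events) < n_events:
        events.extend(
            simulate_lineage(
                mean_tau, family, cv, window, rng, channel_id=f"ch{ch:04d}"
            )
        )
        ch += 1
        if ch > 100 * n_events + 1000:  # pragma: no cover - pathological config
            raise RuntimeError("window too short to accumulate requested events")
    return events[:n_events]


def _config_summary(config: SimulationConfig) -> dict:
    return {
        "concentrations_mmol_per_L": list(config.concentrations),
        "replicates_per_concentration": config.replicates_per_concentration,
        "channels_per_experiment": config.channels_per_experiment,
        "t_start_h": config.window.t_start,
        "t_end_h": config.window.t_end,
        "delta_tau_h": config.window.delta_tau,
        "tau_family": config.tau_family,
        "cv_tau": config.cv_tau,
        "kinetic_params": vars(config.kinetic_params),
        "seed": config.seed,
    }
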
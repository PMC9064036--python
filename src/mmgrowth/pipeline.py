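"""End-to-end orchestration: event table -> growth-rate table -> kinetic fits.

``run_analysis`` drives the whole chain for one study: read and grid-snap
the event table, window-filter and classify every replicate, estimate the
bias-corrected generation-time distribution and population growth rate for
analyzed replicates, fit the requested kinetic models to the replicate-level
(concentration, mu) pairs, and assemble the heterogeneity (variance vs mean
generation time) table.  Everything is deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .events import ExperimentRecord, ExperimentStatus, ObservationWindow, read_events
from .growth_rate import GrowthRateResult, analyze_experiment
from .kinetics import FitResult, GrowthObservation, fit_kinetics
from .transport import TransportParams, transport_report

__all__ = ["AnalysisConfig", "ResultsBundle", "run_analysis", "analyze_records"]

logger = logging.getLogger("mmgrowth")

RESULTS_COLUMNS = (
    "experiment_id",
    "concentration_mmol_per_L",
    "n_events",
    "status",
    "growth_rate_per_h",
    "mean_tau_h",
    "var_tau_h2",
    "cv_tau",
)


@dataclass
class AnalysisConfig:
    """Settings for one analysis run."""

    window: ObservationWindow = field(default_factory=ObservationWindow)
    models_to_fit: tuple[str, ...] = ("single", "two")
    include_zero_growth_in_fit: bool = True
    rebin_width: float | None = None
    transport_params: TransportParams | None = None

    def __post_init__(self) -> None:
        if not self.models_to_fit:
            raise ValueError("select at least one kinetic model to fit")


@dataclass
class ResultsBundle:
    """Everything one run produces, in memory."""

    results: pd.DataFrame
    per_experiment: list[GrowthRateResult]
    fits: dict[str, FitResult | None]
    heterogeneity: pd.DataFrame
    transport: dict | None
    log_lines: list[str]

    def write(self, out_dir: str | Path) -> None:
        """Write the bundle: results/heterogeneity TSVs, per-experiment
        distribution TSVs, JSON fit and transport reports, and the run log."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "results.tsv", sep="\t", index=False)
        self.heterogeneity.to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
        dist_dir = out / "distributions"
        dist_dir.mkdir(exist_ok=True)
        for res in self.per_experiment:
            if res.distribution is None:
                continue
            d = res.distribution
            pd.DataFrame(
                {
                    "tau_h": d.tau_values,
                    "count": d.counts,
                    "weight": [
                        d.window.length / (d.window.length - t) for t in d.tau_values
                    ],
                    "probability": d.probabilities,
                }
            ).to_csv(dist_dir / f"{res.experiment_id}.tsv", sep="\t", index=False)
        fit_doc = {
            name: (fit.to_dict() if fit is not None else None)
            for name, fit in self.fits.items()
        }
        (out / "fits.json").write_text(json.dumps(fit_doc, indent=2) + "\n")
        if self.transport is not None:
            (out / "transport.json").write_text(
                json.dumps(self.transport, indent=2) + "\n"
            )
        (out / "run.log").write_text("\n".join(self.log_lines) + "\n")


def analyze_records(
    records: list[ExperimentRecord], config: AnalysisConfig | None = None
) -> ResultsBundle:
    """Run the full analysis on in-memory experiment records."""
    if config is None:
        config = AnalysisConfig()
    log: list[str] = [f"mmgrowth {__version__}"]
    window = config.window
    log.append(
        f"window: t_start={window.t_start} h, t_end={window.t_end} h, "
        f"delta_tau={window.delta_tau:g} h"
    )
    log.append(f"experiments: {len(records)}")

    per_experiment: list[GrowthRateResult] = []
    for rec in records:
        try:
            res = analyze_experiment(rec, window, rebin_width=config.rebin_width)
        except Exception as err:
            raise RuntimeError(
                f"growth-rate stage failed for experiment "
                f"{rec.experiment_id!r}: {err}"
            ) from err
        per_experiment.append(res)
        log.append(
            f"  {res.experiment_id}: c={res.concentration:g} mmol/L, "
            f"{res.n_events} events post-filter, status={res.status.value}"
            + (f", mu={res.mu:.4f} 1/h" if res.mu is not None else "")
        )
        if res.distribution is not None:
            tail = res.distribution.tau_values[-1]
            if tail > 0.8 * window.length:
                log.append(
                    f"    warning: {res.experiment_id} has generation times up "
                    f"to {tail:g} h, near the {window.length:g} h window length; "
                    "correction weights are large there"
                )

    counts = {
        status: sum(1 for r in per_experiment if r.status is status)
        for status in ExperimentStatus
    }
    log.append(
        "classified: "
        + ", ".join(f"{s.value}={n}" for s, n in counts.items())
    )

    results = pd.DataFrame(
        [
            (
                r.experiment_id,
                r.concentration,
                r.n_events,
                r.status.value,
                r.mu,
                r.mean_tau,
                r.var_tau,
                r.cv_tau,
            )
            for r in per_experiment
        ],
        columns=list(RESULTS_COLUMNS),
    )

    # replicate-level observations feeding the kinetic fit: analyzed replicates
    # always; zero-growth replicates as mu = 0 when configured; excluded never
    observations = [
        GrowthObservation(r.concentration, r.mu, r.experiment_id)
        for r in per_experiment
        if r.status is ExperimentStatus.ANALYZED
        or (
            config.include_zero_growth_in_fit
            and r.status is ExperimentStatus.ZERO_GROWTH
        )
    ]
    fits: dict[str, FitResult | None] = {}
    for model in config.models_to_fit:
        try:
            fits[model] = fit_kinetics(observations, model=model)
            log.append(
                f"fit[{model}]: rss={fits[model].rss:.5g} on "
                f"{fits[model].n_obs} observations"
            )
        except (ValueError, RuntimeError) as err:
            fits[model] = None
            log.append(f"fit[{model}]: degenerate or failed ({err})")

    het = results[results["status"] == ExperimentStatus.ANALYZED.value][
        [
            "experiment_id",
            "concentration_mmol_per_L",
            "mean_tau_h",
            "var_tau_h2",
            "cv_tau",
        ]
    ].reset_index(drop=True)

    transport = None
    if config.transport_params is not None:
        transport = transport_report(config.transport_params)
        log.append(
            f"transport: u={transport['u_mol_per_s']:.3g} mol/s, "
            f"U_hat={transport['U_hat_mol_per_s_m3']:.3g} mol/s/m^3, "
            f"c_crit={transport['c_crit_mmol_per_L']:.3g} mmol/L"
        )

    for line in log:
        logger.info(line)
    return ResultsBundle(
        results=results,
        per_experiment=per_experiment,
        fits=fits,
        heterogeneity=het,
        transport=transport,
        log_lines=log,
    )


def run_analysis(
    events_path: str | Path,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> ResultsBundle:
    """Analyze an event-table TSV end to end; optionally write all outputs."""
    if config is None:
        config = AnalysisConfig()
    records = read_events(events_path, config.window)
    bundle = analyze_records(records, config)
    bundle.log_lines.insert(1, f"input: {events_path}")
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
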
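"""Division-event tables: data model, TSV I/O, window filtering, replicate classification.

A mother-machine experiment yields one row per observed cell life: the cell's
first appearance (birth) and the time from first to last appearance ending in
a division (generation time, tau).  Experiments are grouped by an opaque
``experiment_id`` and carry the substrate (PCA) concentration at which the
replicate was run.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DivisionEvent",
    "ObservationWindow",
    "ExperimentRecord",
    "ExperimentStatus",
    "EVENT_COLUMNS",
    "read_events",
    "write_events",
    "filter_events",
    "classify_experiment",
    "snap_to_grid",
]

#: Exact header of the event-table TSV dialect.
EVENT_COLUMNS = (
    "experiment_id",
    "concentration_mmol_per_L",
    "channel_id",
    "cell_id",
    "birth_time_h",
    "generation_time_h",
)

#: Thresholds of the replicate-classification rule: fewer than
#: MIN_EVENTS_NONZERO surviving events marks the replicate as growth-rate
#: zero; fewer than MIN_EVENTS_ANALYZED excludes it as unrepresentative.
MIN_EVENTS_NONZERO = 5
MIN_EVENTS_ANALYZED = 50


class EventTableError(ValueError):
    """Malformed event table (missing column, bad value, broken invariant)."""


@dataclass(frozen=True)
class ObservationWindow:
    """Analysis interval and imaging grid.

    Parameters
    ----------
    t_start : float
        Start of the analysis window in hours.  Division events of cells born
        before this time are discarded to exclude preculture carry-over
        effects; default 15 h.
    t_end : float
        End of the observation in hours (default 40 h).
    delta_tau : float
        Imaging interval in hours (default 5 min).  Birth and division times
        are only resolved to this grid.
    """

    t_start: float = 15.0
    t_end: float = 40.0
    delta_tau: float = 5.0 / 60.0

    def __post_init__(self) -> None:
        if self.delta_tau <= 0:
            raise ValueError(f"delta_tau must be > 0, got {self.delta_tau}")
        if self.t_end <= self.t_start:
            raise ValueError(
                f"t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )
        if self.t_end - self.t_start <= self.delta_tau:
            raise ValueError("window length must exceed the imaging interval")

    @property
    def length(self) -> float:
        """Observable window length ``t_end - t_start`` in hours."""
        return self.t_end - self.t_start


@dataclass(frozen=True)
class DivisionEvent:
    """One observed cell life ending in a division.

    ``birth_time`` is the time of first appearance relative to experiment
    start, ``generation_time`` (tau) the span from first to last appearance.
    Both are in hours and, after ingest, multiples of the imaging interval.
    """

    cell_id: str
    channel_id: str
    birth_time: float
    generation_time: float

    def __post_init__(self) -> None:
        if self.birth_time < 0:
            raise EventTableError(
                f"birth_time must be >= 0, got {self.birth_time} (cell {self.cell_id})"
            )
        if self.generation_time <= 0:
            raise EventTableError(
                f"generation_time must be > 0, got {self.generation_time} "
                f"(cell {self.cell_id})"
            )

    @property
    def division_time(self) -> float:
        return self.birth_time + self.generation_time


class ExperimentStatus(enum.Enum):
    """Replicate classification by number of events surviving the window filter."""

    ANALYZED = "analyzed"
    ZERO_GROWTH = "zero_growth"
    EXCLUDED = "excluded"


@dataclass
class ExperimentRecord:
    """All division events of one biological replicate at one concentration."""

    experiment_id: str
    concentration: float  # mmol / L
    events: list[DivisionEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise EventTableError(
                f"concentration must be >= 0, got {self.concentration} "
                f"(experiment {self.experiment_id})"
            )


def snap_to_grid(t: float, delta_tau: float) -> float:
    """Snap a time to the nearest multiple of the imaging interval.

    Ties (exact midpoints) round up, so a time halfway between two frames is
    attributed to the later frame.
    """
    import math

    k = math.floor(t / delta_tau + 0.5)
    return k * delta_tau


def classify_experiment(n_events: int) -> ExperimentStatus:
    """Classify a replicate from its post-filter event count.

    Fewer than 5 events mean the replicate showed essentially no growth and
    is assigned growth rate zero; 5-49 events are too few to represent a
    population growth rate and the replicate is excluded; 50 or more events
    are analyzed.
    """
    if n_events < 0:
        raise ValueError(f"event count must be >= 0, got {n_events}")
    if n_events < MIN_EVENTS_NONZERO:
        return ExperimentStatus.ZERO_GROWTH
    if n_events < MIN_EVENTS_ANALYZED:
        return ExperimentStatus.EXCLUDED
    return ExperimentStatus.ANALYZED


def filter_events(
    events: Iterable[DivisionEvent], window: ObservationWindow
) -> list[DivisionEvent]:
    """Keep events fully observable within the window.

    A cell life is observable iff it is born at or after ``t_start`` and its
    division falls at or before ``t_end``; everything else is censored.  Order
    is preserved.  Idempotent.
    """
    return [
        e
        for e in events
        if e.birth_time >= window.t_start and e.division_time <= window.t_end
    ]


def _snap_event(
    event: DivisionEvent, window: ObservationWindow
) -> DivisionEvent | None:
    """Snap birth/division to the imaging grid; drop events the grid or the
    window geometry cannot represent (zero-length after snapping, or tau at
    least the window length, which no correctly censored observation can
    produce)."""
    birth = snap_to_grid(event.birth_time, window.delta_tau)
    division = snap_to_grid(event.division_time, window.delta_tau)
    tau = division - birth
    if tau <= 0:
        warnings.warn(
            f"event {event.cell_id}: generation time collapses to 0 on the "
            f"{window.delta_tau:g} h imaging grid; dropped",
            stacklevel=3,
        )
        return None
    if tau >= window.length:
        warnings.warn(
            f"event {event.cell_id}: generation time {tau:g} h is not below the "
            f"window length {window.length:g} h; such an event cannot arise from "
            "a correctly censored observation and is dropped",
            stacklevel=3,
        )
        return None
    return replace(event, birth_time=birth, generation_time=tau)


def read_events(
    path: str | Path,
    window: ObservationWindow | None = None,
) -> list[ExperimentRecord]:
    """Read an event-table TSV into one record per experiment.

    The file must be UTF-8, tab-separated, with header columns exactly
    ``experiment_id, concentration_mmol_per_L, channel_id, cell_id,
    birth_time_h, generation_time_h``.  Row order is preserved within each
    experiment.  Birth and division times are snapped to the imaging grid of
    ``window`` (defaults apply if omitted).

    Raises
    ------
    EventTableError
        On a missing/renamed column, a non-numeric time field (with the
        offending row number), or an invariant violation such as a negative
        generation time.
    """
    if window is None:
        window = ObservationWindow()
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(
            f"{path}: missing or renamed column(s): {', '.join(missing)}; "
            f"expected header {list(EVENT_COLUMNS)}"
        )

    records: dict[str, ExperimentRecord] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        exp_id = str(getattr(row, "experiment_id"))
        numeric = {}
        for col in ("concentration_mmol_per_L", "birth_time_h", "generation_time_h"):
            raw = getattr(row, col)
            try:
                numeric[col] = float(raw)
            except (TypeError, ValueError):
                raise EventTableError(
                    f"{path}, row {idx}: non-numeric value {raw!r} in column {col}"
                ) from None
        try:
            event = DivisionEvent(
                cell_id=str(getattr(row, "cell_id")),
                channel_id=str(getattr(row, "channel_id")),
                birth_time=numeric["birth_time_h"],
                generation_time=numeric["generation_time_h"],
            )
        except EventTableError as err:
            raise EventTableError(f"{path}, row {idx}: {err}") from None
        if exp_id not in records:
            records[exp_id] = ExperimentRecord(
                experiment_id=exp_id,
                concentration=numeric["concentration_mmol_per_L"],
            )
        snapped = _snap_event(event, window)
        if snapped is not None:
            records[exp_id].events.append(snapped)
    return list(records.values())


def write_events(
    records: Sequence[ExperimentRecord],
    path: str | Path,
    concentrations: dict[str, float] | None = None,
) -> None:
    """Write records to the event-table TSV dialect (LF endings, '.' decimals)."""
    rows = []
    for rec in records:
        for e in rec.events:
            rows.append(
                (
                    rec.experiment_id,
                    rec.concentration,
                    e.channel_id,
                    e.cell_id,
                    e.birth_time,
                    e.generation_time,
                )
            )
    df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")
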
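"""Whistle-detection ingestion and dp10m binning.

The analysis unit is the monitored hour.  Whistle detections are reduced to
*detection-positive 10-minute intervals per hour* (dp10m h⁻¹): each clock hour
is divided into six clock-aligned 10-min bins ``[h:00, h:10), …`` and a bin is
detection-positive when it contains at least one whistle and at least one
minute of recording.  dp10m of an hour is the number of positive bins (0–6).

Hours with zero recording effort are dropped rather than zero-filled: the
modelling population is monitored hours only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import pandas as pd

from .errors import ConfigError, RowError, SchemaError, ValidationError

BOTTOM_TYPES = ("sand", "mud", "rubble")


@dataclass(frozen=True)
class WhistleEvent:
    """A single visually confirmed whistle detection."""

    timestamp: datetime
    deployment_id: str
    station_id: str


@dataclass(frozen=True)
class DeploymentWindow:
    """One mooring of a recorder: the monitored interval plus site descriptors.

    Numeric descriptors default to the middle of the study ranges so synthetic
    schedules can omit them; ``end - start`` may not exceed ``max_hours``.
    """

    deployment_id: str
    station_id: str
    start: datetime
    end: datetime
    depth_m: float = 3.0
    distance_km: float = 3.0
    coast_km: float = 0.5
    mangrove_km: float = 1.0
    bottom: str = "sand"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"deployment {self.deployment_id}: end ({self.end}) must follow start ({self.start})"
            )
        if self.bottom not in BOTTOM_TYPES:
            raise ValidationError(
                f"deployment {self.deployment_id}: bottom {self.bottom!r} not in {BOTTOM_TYPES}"
            )

    @property
    def duration_h(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


@dataclass
class HourlyRecord:
    """One monitored hour: the dp10m count, effort and (later) covariates."""

    hour_start: datetime
    deployment_id: str
    dp10m: int
    effort_min: int
    n_bins_recorded: int = 6
    station_id: str = ""
    covariates: dict = field(default_factory=dict)


@dataclass
class EffortSummary:
    total_hours: int
    positive_hours: int
    total_bins: int
    positive_bins: int
    per_deployment: pd.DataFrame


# ---------------------------------------------------------------------------
# loading


def load_whistle_log(path: str | Path) -> list[WhistleEvent]:
    """Read a whistle log CSV (columns: timestamp, deployment_id, station_id).

    Events are returned sorted by timestamp.  A missing column raises
    :class:`SchemaError`; an unparseable timestamp raises :class:`RowError`
    naming the offending line (1-based, header = line 1).
    """
    df = pd.read_csv(path, dtype=str)
    required = ["timestamp", "deployment_id", "station_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"whistle log {path}: missing column(s) {missing}")
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            ts = datetime.fromisoformat(str(row.timestamp))
        except (TypeError, ValueError) as exc:
            raise RowError(f"unparseable timestamp {row.timestamp!r}", line=i + 2) from exc
        events.append(WhistleEvent(ts, str(row.deployment_id), str(row.station_id)))
    events.sort(key=lambda e: e.timestamp)
    return events


def load_schedule(path: str | Path) -> list[DeploymentWindow]:
    """Read a deployment schedule CSV.

    Required columns: deployment_id, station_id, start, end.  Optional:
    depth_m, distance_km, coast_km, mangrove_km, bottom.
    """
    df = pd.read_csv(path)
    required = ["deployment_id", "station_id", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"schedule {path}: missing column(s) {missing}")
    windows = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for opt in ("depth_m", "distance_km", "coast_km", "mangrove_km", "bottom"):
            if hasattr(row, opt) and not pd.isna(getattr(row, opt)):
                kwargs[opt] = getattr(row, opt)
        windows.append(
            DeploymentWindow(
                deployment_id=str(row.deployment_id),
                station_id=str(row.station_id),
                start=datetime.fromisoformat(str(row.start)),
                end=datetime.fromisoformat(str(row.end)),
                **kwargs,
            )
        )
    return windows


def validate_events(events: list[WhistleEvent], schedule: list[DeploymentWindow]) -> None:
    """Check every event falls inside its deployment's window."""
    by_id = {w.deployment_id: w for w in schedule}
    for i, ev in enumerate(events):
        win = by_id.get(ev.deployment_id)
        if win is None:
            raise ValidationError(f"event {i}: unknown deployment {ev.deployment_id!r}")
        if not (win.start <= ev.timestamp < win.end):
            raise ValidationError(
                f"event {i} at {ev.timestamp} outside window of deployment "
                f"{ev.deployment_id} [{win.start}, {win.end})"
            )


# ---------------------------------------------------------------------------
# binning


def _check_no_overlap(schedule: list[DeploymentWindow]) -> None:
    by_station: dict[str, list[DeploymentWindow]] = {}
    for w in schedule:
        by_station.setdefault(w.station_id, []).append(w)
    for station, wins in by_station.items():
        wins = sorted(wins, key=lambda w: w.start)
        for a, b in zip(wins, wins[1:]):
            if b.start < a.end:
                raise ConfigError(
                    f"station {station}: deployments {a.deployment_id} and "
                    f"{b.deployment_id} overlap"
                )


def _floor_hour(t: datetime) -> datetime:
    return t.replace(minute=0, second=0, microsecond=0)


def _overlap_minutes(a0: datetime, a1: datetime, b0: datetime, b1: datetime) -> float:
    lo, hi = max(a0, b0), min(a1, b1)
    return max(0.0, (hi - lo).total_seconds() / 60.0)


def bin_dp10m(
    events: list[WhistleEvent],
    schedule: list[DeploymentWindow],
    validate: bool = True,
) -> list[HourlyRecord]:
    """Aggregate whistle events into hourly dp10m records with effort.

    One record per clock hour intersecting a deployment window.  Hours whose
    recorded effort rounds below one minute are dropped.
    """
    _check_no_overlap(schedule)
    if validate:
        validate_events(events, schedule)

    ev_by_dep: dict[str, list[datetime]] = {}
    for ev in events:
        ev_by_dep.setdefault(ev.deployment_id, []).append(ev.timestamp)

    records: list[HourlyRecord] = []
    for win in schedule:
        times = ev_by_dep.get(win.deployment_id, [])
        hour = _floor_hour(win.start)
        while hour < win.end:
            nxt = hour + timedelta(hours=1)
            effort = _overlap_minutes(hour, nxt, win.start, win.end)
            effort_min = int(round(effort))
            if effort_min >= 1:
                positive = 0
                n_rec = 0
                for b in range(6):
                    b0 = hour + timedelta(minutes=10 * b)
                    b1 = b0 + timedelta(minutes=10)
                    rec_min = _overlap_minutes(b0, b1, win.start, win.end)
                    if rec_min >= 1.0:
                        n_rec += 1
                        if any(b0 <= t < b1 for t in times):
                            positive += 1
                records.append(
                    HourlyRecord(
                        hour_start=hour,
                        deployment_id=win.deployment_id,
                        dp10m=positive,
                        effort_min=min(effort_min, 60),
                        n_bins_recorded=n_rec,
                        station_id=win.station_id,
                    )
                )
            hour = nxt
    return records


def summarize_effort(records: list[HourlyRecord]) -> EffortSummary:
    """Totals and per-deployment breakdown of monitoring effort and detections."""
    if not records:
        raise ValidationError("summarize_effort: no records")
    rows = []
    for r in records:
        rows.append(
            {
                "deployment_id": r.deployment_id,
                "hours": 1,
                "positive_hours": int(r.dp10m > 0),
                "bins": r.n_bins_recorded,
                "positive_bins": r.dp10m,
            }
        )
    df = pd.DataFrame(rows)
    per_dep = df.groupby("deployment_id", sort=True).sum().reset_index()
    return EffortSummary(
        total_hours=int(df["hours"].sum()),
        positive_hours=int(df["positive_hours"].sum()),
        total_bins=int(df["bins"].sum()),
        positive_bins=int(df["positive_bins"].sum()),
        per_deployment=per_dep,
    )


# ---------------------------------------------------------------------------
# hourly-record table IO (the fixture contract shared with synthetic data)


def records_to_frame(records: list[HourlyRecord]) -> pd.DataFrame:
    """Flatten records (and any attached covariates) into a DataFrame."""
    rows = []
    for r in records:
        row = {
            "hour_start": r.hour_start,
            "deployment_id": r.deployment_id,
            "station_id": r.station_id,
            "dp10m": r.dp10m,
            "effort_min": r.effort_min,
            "n_bins_recorded": r.n_bins_recorded,
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def load_dp10m_table(path: str | Path) -> list[HourlyRecord]:
    """Read an hourly dp10m table (columns: hour_start, deployment_id, dp10m,
    effort_min; optional station_id, n_bins_recorded, covariate columns).

    This is the schema the deposited per-hour dataset of the study maps onto;
    ``n_bins_recorded`` defaults to ``ceil(effort_min / 10)`` when absent.
    """
    df = pd.read_csv(path)
    required = ["hour_start", "deployment_id", "dp10m", "effort_min"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"dp10m table {path}: missing column(s) {missing}")
    base = set(required) | {"station_id", "n_bins_recorded"}
    extra = [c for c in df.columns if c not in base]
    records = []
    for row in df.itertuples(index=False):
        effort = int(row.effort_min)
        n_bins = (
            int(row.n_bins_recorded)
            if "n_bins_recorded" in df.columns and not pd.isna(row.n_bins_recorded)
            else math.ceil(effort / 10)
        )
        rec = HourlyRecord(
            hour_start=datetime.fromisoformat(str(row.hour_start)),
            deployment_id=str(row.deployment_id),
            dp10m=int(row.dp10m),
            effort_min=effort,
            n_bins_recorded=n_bins,
            station_id=str(getattr(row, "station_id", "")),
        )
        rec.covariates = {c: getattr(row, c) for c in extra}
        records.append(rec)
    return records


def save_dp10m_table(records: list[HourlyRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
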
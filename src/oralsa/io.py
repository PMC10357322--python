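"""Data model and TSV readers/writers for behavioral, photometry and spike data.

Three plain-text formats are used throughout, all UTF-8 tab-separated values
with a ``#``-prefixed ``key=value`` metadata header followed by a column
header row:

* event logs   — columns ``t, kind, port, animal``
* photometry   — columns ``t, f470, f415``
* spike tables — columns ``unit_id, region, spike_time`` (optional ``group``)

Times are seconds from session start, written as shortest round-tripping
decimal text (at least six significant digits), so write→read is lossless.
Missing optional fields are empty strings, never sentinel numbers.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

EVENT_KINDS = frozenset({"lick", "reward", "laser_on", "laser_off", "rfid_read"})
LIQUIDS = frozenset({"fentanyl", "quinine", "water"})
REGIONS = frozenset({"ACC", "PL", "IL", "OFC", "other"})
SETUPS = frozenset({"operant", "homecage"})


def _fmt_time(t: float) -> str:
    """Decimal text for a time value; repr round-trips binary floats exactly."""
    s = repr(float(t))
    if "e" in s or "E" in s:
        # fall back to positional notation with plenty of digits
        s = f"{float(t):.9f}"
    return s


@dataclass(frozen=True)
class Event:
    """A single timestamped behavioral event.

    ``port`` is required for rewards and absent for RFID reads; ``animal`` is
    required for RFID reads and optional elsewhere (filled in by attribution).
    """

    t: float
    kind: str
    port: Optional[int] = None
    animal: Optional[str] = None

    def __post_init__(self):
        if self.t < 0:
            raise ValidationError(f"event time must be non-negative, got {self.t}")
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.kind == "reward" and self.port is None:
            raise ValidationError("reward events must carry a port")
        if self.kind == "rfid_read" and self.animal is None:
            raise ValidationError("rfid_read events must carry an animal id")


@dataclass
class SessionLog:
    """One recording session (operant box) or home-cage epoch of events."""

    session_id: str
    setup: str
    port_map: dict[int, str]
    dose_mg_per_ml: dict[int, float]
    reward_volume_ul: float
    schedule: int
    events: list[Event] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.setup not in SETUPS:
            raise ValidationError(f"setup must be one of {sorted(SETUPS)}")
        for port, liquid in self.port_map.items():
            if liquid not in LIQUIDS:
                raise ValidationError(f"port {port} maps to unknown liquid {liquid!r}")
        if self.reward_volume_ul <= 0:
            raise ValidationError("reward_volume_ul must be positive")
        if self.schedule < 1:
            raise ValidationError("schedule (FR value) must be a positive integer")
        prev = -math.inf
        for i, ev in enumerate(self.events):
            if ev.t < prev:
                raise ValidationError(
                    f"events not sorted by time: row {i} (t={ev.t}) precedes t={prev}"
                )
            prev = ev.t
            if ev.kind == "reward" and ev.port not in self.port_map:
                raise ValidationError(
                    f"reward at t={ev.t} uses port {ev.port} absent from port_map"
                )

    def liquid_of(self, port: int) -> str:
        return self.port_map[port]


@dataclass
class PhotometrySession:
    """Two-channel fluorescence trace (470 nm signal + 415 nm isosbestic)."""

    fs: float
    t: np.ndarray
    f_signal: np.ndarray
    f_iso: np.ndarray
    events: list[Event] = field(default_factory=list)
    hemisphere: str = ""
    session_id: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.f_signal = np.asarray(self.f_signal, dtype=float)
        self.f_iso = np.asarray(self.f_iso, dtype=float)
        self.validate()

    def validate(self, rel_tol: float = 1e-6) -> None:
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        n = len(self.t)
        if len(self.f_signal) != n or len(self.f_iso) != n:
            raise ValidationError(
                "channel length mismatch: "
                f"t={n}, f_signal={len(self.f_signal)}, f_iso={len(self.f_iso)}"
            )
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValidationError("sample times must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > rel_tol * (1.0 / self.fs):
                raise ValidationError(
                    "non-uniform sample spacing beyond tolerance of 1/fs"
                )


@dataclass
class Unit:
    """Spike times of one sorted unit with its anatomical region label."""

    unit_id: str
    region: str
    spike_times: np.ndarray
    group: Optional[str] = None

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValidationError(
                f"unit {self.unit_id}: region {self.region!r} not in {sorted(REGIONS)}"
            )
        self.spike_times = np.asarray(self.spike_times, dtype=float)


@dataclass
class UnitSet:
    """A set of units recorded across a saline→fentanyl injection session."""

    units: list[Unit]
    t_saline: float
    t_fentanyl: float
    t_end: float

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (0 <= self.t_saline < self.t_fentanyl < self.t_end):
            raise ValidationError(
                "epoch ordering must satisfy 0 <= t_saline < t_fentanyl < t_end"
            )
        for u in self.units:
            st = u.spike_times
            if len(st) and (st[0] < 0 or st[-1] > self.t_end):
                raise ValidationError(
                    f"unit {u.unit_id}: spike outside [0, t_end={self.t_end}]"
                )
            if np.any(np.diff(st) < 0):
                raise ValidationError(f"unit {u.unit_id}: spike times not sorted")


# ---------------------------------------------------------------------------
# metadata header helpers
# ---------------------------------------------------------------------------

def _write_meta(fh, meta: dict) -> None:
    for key, val in meta.items():
        fh.write(f"# {key}={val}\n")


def _read_meta_and_table(path) -> tuple[dict[str, str], pd.DataFrame]:
    meta: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line[1:].strip()
            if "=" not in stripped:
                raise FormatError(f"{path}: malformed metadata line {i + 1}: {line!r}")
            key, _, val = stripped.partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    body = "".join(lines[body_start:])
    if not body.strip():
        raise FormatError(f"{path}: missing column header row")
    table = pd.read_csv(_io.StringIO(body), sep="\t", dtype=str, keep_default_na=False)
    return meta, table


def _port_dict_to_str(d: dict) -> str:
    return ",".join(f"{port}:{val}" for port, val in sorted(d.items()))


def _str_to_port_dict(s: str, cast=str) -> dict:
    out = {}
    if not s:
        return out
    for item in s.split(","):
        port, _, val = item.partition(":")
        out[int(port)] = cast(val)
    return out


def _require_meta(meta: dict, keys: list[str], path) -> None:
    missing = [k for k in keys if k not in meta]
    if missing:
        raise FormatError(f"{path}: missing metadata keys {missing}")


def _require_columns(table: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# event logs
# ---------------------------------------------------------------------------

def write_event_log(log: SessionLog, path) -> None:
    """Serialize a SessionLog to TSV; lossless round-trip with read_event_log."""
    log.validate()
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, {
            "session_id": log.session_id,
            "setup": log.setup,
            "port_map": _port_dict_to_str(log.port_map),
            "dose_mg_per_ml": _port_dict_to_str(log.dose_mg_per_ml),
            "reward_volume_ul": repr(float(log.reward_volume_ul)),
            "schedule": log.schedule,
        })
        fh.write("t\tkind\tport\tanimal\n")
        for ev in log.events:
            port = "" if ev.port is None else str(ev.port)
            animal = "" if ev.animal is None else ev.animal
            fh.write(f"{_fmt_time(ev.t)}\t{ev.kind}\t{port}\t{animal}\n")


def read_event_log(path) -> SessionLog:
    """Parse and validate an event-log TSV written by :func:`write_event_log`."""
    meta, table = _read_meta_and_table(path)
    _require_meta(meta, ["session_id", "setup", "port_map", "reward_volume_ul",
                         "schedule"], path)
    _require_columns(table, ["t", "kind", "port", "animal"], path)
    events = []
    prev_t = -math.inf
    for i, row in enumerate(table.itertuples(index=False)):
        t = float(row.t)
        if t < prev_t:
            raise ValidationError(
                f"{path}: events out of order at data row {i + 1} "
                f"(t={t} after t={prev_t})"
            )
        prev_t = t
        events.append(Event(
            t=t,
            kind=row.kind,
            port=int(row.port) if row.port != "" else None,
            animal=row.animal if row.animal != "" else None,
        ))
    return SessionLog(
        session_id=meta["session_id"],
        setup=meta["setup"],
        port_map=_str_to_port_dict(meta["port_map"]),
        dose_mg_per_ml=_str_to_port_dict(meta.get("dose_mg_per_ml", ""), float),
        reward_volume_ul=float(meta["reward_volume_ul"]),
        schedule=int(meta["schedule"]),
        events=events,
    )


# ---------------------------------------------------------------------------
# photometry traces
# ---------------------------------------------------------------------------

def write_photometry(session: PhotometrySession, path) -> None:
    session.validate()
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, {
            "session_id": session.session_id,
            "fs": repr(float(session.fs)),
            "hemisphere": session.hemisphere,
        })
        fh.write("t\tf470\tf415\n")
        for t, sig, iso in zip(session.t, session.f_signal, session.f_iso):
            fh.write(f"{_fmt_time(t)}\t{_fmt_time(sig)}\t{_fmt_time(iso)}\n")


def read_photometry(path, events: Optional[list[Event]] = None) -> PhotometrySession:
    """Read a two-channel trace TSV.

    Events live in the companion event log, not the trace file; pass them via
    ``events`` to attach them to the returned session.
    """
    meta, table = _read_meta_and_table(path)
    _require_meta(meta, ["fs"], path)
    _require_columns(table, ["t", "f470", "f415"], path)
    for col in ("t", "f470", "f415"):
        if (table[col] == "").any():
            raise FormatError(f"{path}: channel length mismatch (empty {col} cell)")
    return PhotometrySession(
        fs=float(meta["fs"]),
        t=table["t"].astype(float).to_numpy(),
        f_signal=table["f470"].astype(float).to_numpy(),
        f_iso=table["f415"].astype(float).to_numpy(),
        events=list(events) if events is not None else [],
        hemisphere=meta.get("hemisphere", ""),
        session_id=meta.get("session_id", ""),
    )


# ---------------------------------------------------------------------------
# spike tables
# ---------------------------------------------------------------------------

def write_spike_table(units: UnitSet, path) -> None:
    units.validate()
    has_group = any(u.group is not None for u in units.units)
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, {
            "t_saline": repr(float(units.t_saline)),
            "t_fentanyl": repr(float(units.t_fentanyl)),
            "t_end": repr(float(units.t_end)),
        })
        cols = "unit_id\tregion\tspike_time"
        fh.write(cols + ("\tgroup\n" if has_group else "\n"))
        for u in units.units:
            grp = "" if u.group is None else u.group
            if len(u.spike_times) == 0:
                # a row with empty spike_time declares a silent unit
                row = f"{u.unit_id}\t{u.region}\t"
                fh.write(row + (f"\t{grp}\n" if has_group else "\n"))
            for t in u.spike_times:
                row = f"{u.unit_id}\t{u.region}\t{_fmt_time(t)}"
                fh.write(row + (f"\t{grp}\n" if has_group else "\n"))


def read_spike_table(path) -> UnitSet:
    meta, table = _read_meta_and_table(path)
    _require_meta(meta, ["t_saline", "t_fentanyl", "t_end"], path)
    _require_columns(table, ["unit_id", "region", "spike_time"], path)
    t_end = float(meta["t_end"])
    units: dict[str, Unit] = {}
    order: list[str] = []
    for row in table.itertuples(index=False):
        uid = row.unit_id
        region = row.region
        if region not in REGIONS:
            raise ValidationError(
                f"{path}: unit {uid} has region {region!r} outside {sorted(REGIONS)}"
            )
        group = getattr(row, "group", "") or None
        if uid not in units:
            units[uid] = Unit(uid, region, np.empty(0), group=group)
            order.append(uid)
        if row.spike_time != "":
            t = float(row.spike_time)
            if t > t_end or t < 0:
                raise ValidationError(
                    f"{path}: unit {uid} spike at t={t} outside [0, t_end={t_end}]"
                )
            units[uid].spike_times = np.append(units[uid].spike_times, t)
    for u in units.values():
        u.spike_times = np.sort(u.spike_times)
    return UnitSet(
        units=[units[uid] for uid in order],
        t_saline=float(meta["t_saline"]),
        t_fentanyl=float(meta["t_fentanyl"]),
        t_end=t_end,
    )


def sessionlog_equal(a: SessionLog, b: SessionLog) -> bool:
    """Field-by-field equality of two session logs (exact, incl. event order)."""
    return (
        a.session_id == b.session_id
        and a.setup == b.setup
        and a.port_map == b.port_map
        and a.dose_mg_per_ml == b.dose_mg_per_ml
        and a.reward_volume_ul == b.reward_volume_ul
        and a.schedule == b.schedule
        and a.events == b.events
    )


__all__ = [
    "Event", "SessionLog", "PhotometrySession", "Unit", "UnitSet",
    "read_event_log", "write_event_log", "read_photometry", "write_photometry",
    "read_spike_table", "write_spike_table", "sessionlog_equal",
    "EVENT_KINDS", "LIQUIDS", "REGIONS",
]
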
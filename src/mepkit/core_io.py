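"""Data model and session bundle I/O.

A *session* is one continuous multi-channel differential EMG recording from
a single animal at a single time point, together with its event timestamps:
stimulus onsets for evoked-potential (MEP) and recruitment sessions, grip
trial windows for voluntary-contraction (MVC) sessions.

On disk a session is a *bundle*: a directory holding

* ``signal.csv`` — column 0 is time in seconds, one column per channel in mV;
* ``meta.json`` — every other session field (ids, modality, sampling rate,
  events, stimulation current, free-form extras such as simulation ground
  truth).

All stored times are seconds; analysis code reports milliseconds.  The
second-to-millisecond conversion happens in exactly one place (epoching).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

GROUPS = ("untreated", "chabc_only", "triple", "stim_only", "stim_rehab")
MODALITIES = ("mep", "mvc", "recruitment")
MN_GROUPS = ("naive", "sci")
SPINAL_LEVELS = ("C2", "C3", "C4", "C5", "C6", "C7", "C8", "T1", "T2")

#: Week code for the pre-injury baseline recording; post-injury weeks are
#: 1..11 and the terminal time point is 12.  An integer code keeps weeks
#: sortable without string-ordering accidents.
BASELINE_WEEK = -1

SIGNAL_FILE = "signal.csv"
META_FILE = "meta.json"
_FLOAT_FMT = "%.10g"  # lossless well below the 1e-9 mV round-trip budget


@dataclass
class TrialEvent:
    """One grip-strength trial window on one forelimb."""

    start_s: float
    end_s: float
    limb: str
    grip_force: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class RawSession:
    """A raw multi-channel EMG recording with event timestamps.

    ``signal`` is an array of shape ``(n_channels, n_samples)`` in mV;
    ``channels`` gives the matching labels (e.g. ``biceps_R``).
    ``extras`` carries free-form metadata (for simulated sessions, the
    ground-truth burst parameters) and round-trips through the bundle.
    """

    session_id: str
    animal_id: str
    group: str
    week: int
    modality: str
    fs: float
    channels: list[str]
    signal: np.ndarray
    stim_events: np.ndarray = field(default_factory=lambda: np.empty(0))
    stim_current_mA: float | None = None
    trial_events: list[TrialEvent] = field(default_factory=list)
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.stim_events = np.asarray(self.stim_events, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs if self.fs > 0 else math.nan

    def channel_index(self, channel: int | str) -> int:
        """Resolve a channel given as index, full label, or limb suffix."""
        if isinstance(channel, (int, np.integer)):
            return int(channel)
        if channel in self.channels:
            return self.channels.index(channel)
        guess = f"biceps_{channel}"
        if guess in self.channels:
            return self.channels.index(guess)
        raise KeyError(f"unknown channel {channel!r}; have {self.channels}")


@dataclass
class MEPResult:
    """Scored motor evoked potential from one averaged, conditioned trace.

    Times are ms relative to the stimulus; AUC is the trapezoidal integral
    of the averaged rectified trace between onset and offset, in mV·ms.
    An undetected response carries zero AUC/duration and no bounds.
    """

    baseline_mV: float
    detected: bool
    onset_ms: float | None = None
    offset_ms: float | None = None
    auc_mVms: float = 0.0
    n_sweeps_used: int = 0
    threshold_mA: float | None = None

    @property
    def duration_ms(self) -> float:
        if not self.detected or self.onset_ms is None or self.offset_ms is None:
            return 0.0
        return self.offset_ms - self.onset_ms


@dataclass
class MVCResult:
    """Maximum-voluntary-contraction score for one session.

    ``trial_aucs_mVms`` maps limb -> per-trial AUCs; ``mvc_mVms`` is the
    mean over limbs of the per-limb trial means.  Grip-force readings from
    the apparatus are averaged alongside but never enter the EMG AUC.
    """

    trial_aucs_mVms: dict[str, list[float]]
    limb_means: dict[str, float]
    mvc_mVms: float
    grip_force: float
    trial_durations_s: dict[str, list[float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# validation

def validate_session(session: RawSession) -> list[str]:
    """Check every session invariant; return human-readable issues.

    Total by construction: reports problems, never raises, so it can be
    pointed at arbitrarily malformed objects.
    """
    issues: list[str] = []
    try:
        if session.group not in GROUPS and session.group not in MN_GROUPS:
            issues.append(f"group: unknown label {session.group!r}")
        if session.modality not in MODALITIES:
            issues.append(f"modality: unknown label {session.modality!r}")
        if not (np.isfinite(session.fs) and session.fs > 0):
            issues.append(f"fs: must be a positive finite rate, got {session.fs!r}")
        sig = session.signal
        if sig.ndim != 2:
            issues.append(f"signal: expected 2-d (channels x samples), got ndim={sig.ndim}")
        elif sig.shape[0] != len(session.channels):
            issues.append(
                f"signal: {sig.shape[0]} rows but {len(session.channels)} channel labels"
            )
        if sig.size and not np.all(np.isfinite(sig)):
            issues.append("signal: contains non-finite samples")
        if len(session.channels) == 0:
            issues.append("channels: at least one channel required")

        dur = session.duration_s
        if np.isfinite(dur):
            ev = session.stim_events
            if ev.size and (np.any(ev < 0) or np.any(ev > dur)):
                issues.append("stim_events: event time outside [0, duration]")
            for i, tr in enumerate(session.trial_events):
                if tr.start_s < 0 or tr.end_s > dur:
                    issues.append(f"trial_events[{i}]: window outside [0, duration]")
                if tr.end_s <= tr.start_s:
                    issues.append(f"trial_events[{i}]: non-positive duration")
        if session.modality in ("mep", "recruitment") and session.stim_events.size < 1:
            issues.append("stim_events: mep/recruitment session needs >=1 stimulus")
        if session.modality == "mvc" and len(session.trial_events) < 1:
            issues.append("trial_events: mvc session needs >=1 trial")
        if session.modality in ("mep", "recruitment") and session.stim_current_mA is None:
            issues.append("stim_current_mA: required for mep/recruitment sessions")
    except Exception as exc:  # pragma: no cover - defensive totality
        issues.append(f"validation internal failure: {exc!r}")
    return issues


# ---------------------------------------------------------------------------
# bundle I/O

def write_session(session: RawSession, path: str | Path) -> Path:
    """Write a session bundle (signal CSV + JSON sidecar) under ``path``."""
    issues = validate_session(session)
    if issues:
        raise ValueError("refusing to write invalid session: " + "; ".join(issues))
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    t = np.arange(session.n_samples) / session.fs
    df = pd.DataFrame({"time_s": t})
    for label, row in zip(session.channels, session.signal):
        df[label] = row
    df.to_csv(path / SIGNAL_FILE, index=False, float_format=_FLOAT_FMT)

    meta = {
        "session_id": session.session_id,
        "animal_id": session.animal_id,
        "group": session.group,
        "week": int(session.week),
        "modality": session.modality,
        "fs": session.fs,
        "channels": list(session.channels),
        "stim_events": [float(x) for x in session.stim_events],
        "stim_current_mA": session.stim_current_mA,
        "trial_events": [asdict(tr) for tr in session.trial_events],
        "extras": _jsonable(session.extras),
    }
    (path / META_FILE).write_text(json.dumps(meta, indent=1))
    return path


def read_session(path: str | Path) -> RawSession:
    """Read a session bundle written by :func:`write_session`."""
    path = Path(path)
    sig_path, meta_path = path / SIGNAL_FILE, path / META_FILE
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    if not sig_path.exists():
        raise FileNotFoundError(f"missing signal file {sig_path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("modality") not in MODALITIES:
        raise ValueError(f"unknown modality {meta.get('modality')!r} in {meta_path}")

    df = pd.read_csv(sig_path)
    channels = meta["channels"]
    missing = [c for c in channels if c not in df.columns]
    if missing:
        raise ValueError(f"signal file lacks channel columns {missing}")
    signal = df[channels].to_numpy().T

    session = RawSession(
        session_id=meta["session_id"],
        animal_id=meta["animal_id"],
        group=meta["group"],
        week=int(meta["week"]),
        modality=meta["modality"],
        fs=float(meta["fs"]),
        channels=list(channels),
        signal=signal,
        stim_events=np.asarray(meta.get("stim_events", []), dtype=float),
        stim_current_mA=meta.get("stim_current_mA"),
        trial_events=[TrialEvent(**tr) for tr in meta.get("trial_events", [])],
        extras=meta.get("extras", {}),
    )
    issues = validate_session(session)
    if issues:
        raise ValueError(f"bundle {path} fails validation: " + "; ".join(issues))
    return session


def _jsonable(obj: Any):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# tidy tables

def make_longitudinal_table(rows: Sequence[tuple]) -> pd.DataFrame:
    """Build a tidy (animal_id, group, week, measure, value) table."""
    df = pd.DataFrame(rows, columns=["animal_id", "group", "week", "measure", "value"])
    df["week"] = df["week"].astype(int)
    return df


def is_balanced_panel(table: pd.DataFrame, measure: str | None = None) -> bool:
    """True when every animal has exactly one value at every week.

    Repeated-measures ANOVA requires the complete panel; unbalanced input
    is rejected rather than silently dropped.
    """
    df = table if measure is None else table[table["measure"] == measure]
    if df.empty:
        return False
    counts = df.groupby(["animal_id", "week"]).size()
    if (counts != 1).any():
        return False
    pivot = df.pivot_table(index="animal_id", columns="week", values="value")
    return not pivot.isna().any().any()
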
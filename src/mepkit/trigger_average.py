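"""Stimulus-triggered epoching, cleanliness scoring, selection, averaging.

Movement artifacts in awake recordings are handled by acquiring many
sweeps (default 60), scoring each by its pre-stimulus rectified RMS, and
averaging only the quietest k (default 20).  The manual trigger curation
of the original workflow is operationalised as "lowest pre-stimulus RMS",
which is deterministic and reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import RawSession
from .preprocess import Trace

log = logging.getLogger(__name__)


@dataclass
class SweepSet:
    """Stimulus-aligned epochs from one session/channel.

    ``sweeps`` has shape (n_sweeps, n_samples); sample 0 sits at
    ``window_ms[0]`` relative to the stimulus.  ``cleanliness`` holds each
    sweep's pre-stimulus rectified RMS in mV (computed once, from the raw
    sweep, before any conditioning).
    """

    sweeps: np.ndarray
    fs: float
    window_ms: tuple[float, float]
    cleanliness: np.ndarray
    selected: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        self.cleanliness = np.asarray(self.cleanliness, dtype=float)
        self.selected = np.asarray(self.selected, dtype=int)

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    def sweep_trace(self, i: int) -> Trace:
        return Trace(self.sweeps[i], self.fs, t0_ms=self.window_ms[0])


def epoch_sweeps(
    session: RawSession,
    channel: int | str = 0,
    window_ms: tuple[float, float] = (-50.0, 100.0),
    blank_ms: float = 3.0,
    clean_window_ms: tuple[float, float] | None = None,
) -> SweepSet:
    """Cut one stimulus-aligned sweep per trigger.

    The first ``blank_ms`` after each stimulus is replaced by that sweep's
    pre-stimulus mean, removing the electrical stimulation artifact before
    any rectification can smear it.  Events whose window would leave the
    recording are skipped with a warning.

    Cleanliness is the rectified RMS over ``clean_window_ms`` (default:
    the early half of the pre-stimulus window).  Keeping this span
    disjoint from the late pre-stimulus span used downstream for DC and
    baseline reference matters: selecting the quietest sweeps biases the
    scored span low, and a baseline referenced to the *same* span would
    sit below the true background level, leaving a spurious positive
    offset after the stimulus.
    """
    if session.modality not in ("mep", "recruitment"):
        raise ValueError(f"epoching needs a mep/recruitment session, got {session.modality}")
    if window_ms[0] >= 0 or window_ms[1] <= 0:
        raise ValueError(f"window {window_ms} must straddle the stimulus (pre<0<post)")
    if clean_window_ms is None:
        clean_window_ms = (window_ms[0], window_ms[0] / 2.0)
    if clean_window_ms[1] > 0:
        raise ValueError(f"cleanliness window {clean_window_ms} must be pre-stimulus")
    ch = session.channel_index(channel)
    x = session.signal[ch]
    fs = session.fs
    pre = int(round(-window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    n_blank = int(round(blank_ms * fs / 1000.0))
    c_lo = pre + int(round(clean_window_ms[0] * fs / 1000.0))
    c_hi = pre + int(round(clean_window_ms[1] * fs / 1000.0))

    rows, clean = [], []
    for t_ev in np.sort(session.stim_events):
        i_ev = int(round(t_ev * fs))
        lo, hi = i_ev - pre, i_ev + post
        if lo < 0 or hi > x.size:
            log.warning(
                "skipping stimulus at %.4f s: window [%d, %d) outside recording", t_ev, lo, hi
            )
            continue
        sweep = x[lo:hi].copy()
        base = sweep[:pre]
        score_span = sweep[max(c_lo, 0) : max(c_hi, 0)]
        clean.append(float(np.sqrt(np.mean(score_span**2))) if score_span.size else 0.0)
        if n_blank:
            # fill with reflected pre-stimulus samples: keeps background
            # statistics through the blank, so downstream rectification +
            # steep filtering sees no level step at the blank edges (a
            # constant fill would sit at zero in the rectified domain and
            # the filter's edge overshoot would mimic a response onset)
            stop = min(pre + n_blank, sweep.size)
            span = stop - pre
            if pre >= span:
                sweep[pre:stop] = sweep[pre - span : pre][::-1]
            elif pre:
                sweep[pre:stop] = base.mean()
        rows.append(sweep)
    if not rows:
        raise ValueError("no usable stimulus events in session")

    n = len(rows)
    return SweepSet(
        sweeps=np.asarray(rows),
        fs=fs,
        window_ms=window_ms,
        cleanliness=np.asarray(clean),
        selected=np.arange(n),
    )


def select_clean(sweeps: SweepSet, k: int = 20) -> SweepSet:
    """Keep the k sweeps with the smallest pre-stimulus rectified RMS.

    Ties resolve to the earlier sweep (stable sort), so selection is fully
    deterministic.  Post-stimulus content never influences the choice.
    """
    if k > sweeps.n_sweeps:
        raise ValueError(f"cannot select {k} of {sweeps.n_sweeps} sweeps")
    order = np.argsort(sweeps.cleanliness, kind="stable")
    chosen = np.sort(order[:k])
    return replace(sweeps, selected=chosen)


def average_sweeps(sweeps: SweepSet, use_selected: bool = True) -> Trace:
    """Pointwise arithmetic mean across sweeps, as an aligned Trace."""
    idx = sweeps.selected if use_selected else np.arange(sweeps.n_sweeps)
    if idx.size == 0:
        raise ValueError("empty sweep selection")
    avg = sweeps.sweeps[idx].mean(axis=0)
    return Trace(avg, sweeps.fs, t0_ms=sweeps.window_ms[0])


def map_sweeps(sweeps: SweepSet, fn) -> SweepSet:
    """Apply a Trace->Trace transform to every sweep (e.g. conditioning).

    Cleanliness scores are kept as computed from the raw sweeps.
    """
    out = [fn(sweeps.sweep_trace(i)).samples for i in range(sweeps.n_sweeps)]
    return replace(sweeps, sweeps=np.asarray(out))
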
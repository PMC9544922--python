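"""Maximum-voluntary-contraction (MVC) quantification from grip trials.

Each session holds three timestamped ~8 s grip trials per forelimb.  Per
trial the raw trace is low-pass filtered at 230 Hz, the timestamped
portion rectified, and its trapezoidal AUC taken over the full trial
window (mV·ms).  Per-limb trial AUCs are averaged, and the session MVC is
the mean of the two limb means.  Note the order: filter **then** rectify —
the reverse of the evoked-potential chain, where rectification
demodulates before filtering.  Grip-force apparatus readings ride along
as metadata and are averaged separately; they never enter the EMG AUC.

Filtering is applied to the trial cut plus a small guard margin that is
trimmed before rectification, so the result is exactly invariant to
signal content away from the trial windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import MVCResult, RawSession, TrialEvent
from .preprocess import Trace, lowpass, rectify


@dataclass
class MVCParams:
    cutoff_hz: float = 230.0
    order: int = 8
    n_trials_per_limb: int = 3
    #: filter guard margin around each trial cut, trimmed before AUC
    guard_ms: float = 50.0
    #: when False, accept any positive trial count per limb
    strict: bool = True


def extract_trials(session: RawSession) -> list[tuple[str, Trace]]:
    """Cut one raw trace per trial event, labelled by limb.

    Trials must have positive duration, lie inside the recording, and not
    overlap one another.
    """
    if session.modality != "mvc":
        raise ValueError(f"expected an mvc session, got {session.modality}")
    if not session.trial_events:
        raise ValueError("mvc session has no trial events")
    _check_windows(session.trial_events, session.duration_s)

    out: list[tuple[str, Trace]] = []
    for tr in session.trial_events:
        ch = session.channel_index(tr.limb)
        sl = slice(int(round(tr.start_s * session.fs)), int(round(tr.end_s * session.fs)))
        out.append((tr.limb, Trace(session.signal[ch, sl].copy(), session.fs, t0_ms=0.0)))
    return out


def _check_windows(events: list[TrialEvent], duration_s: float) -> None:
    for i, tr in enumerate(events):
        if tr.end_s <= tr.start_s:
            raise ValueError(f"trial {i}: zero or negative duration")
        if tr.start_s < 0 or tr.end_s > duration_s + 1e-9:
            raise ValueError(f"trial {i}: window outside recording")
    spans = sorted((tr.start_s, tr.end_s) for tr in events)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1 - 1e-9:
            raise ValueError("overlapping trial windows")


def _trial_auc(session: RawSession, tr: TrialEvent, params: MVCParams) -> float:
    """Filter-then-rectify AUC of one timestamped trial, in mV·ms."""
    ch = session.channel_index(tr.limb)
    fs = session.fs
    guard = int(round(params.guard_ms * fs / 1000.0))
    i0, i1 = int(round(tr.start_s * fs)), int(round(tr.end_s * fs))
    lo, hi = max(i0 - guard, 0), min(i1 + guard, session.n_samples)
    cut = Trace(session.signal[ch, lo:hi], fs)
    filt = lowpass(cut, params.cutoff_hz, params.order)
    portion = rectify(Trace(filt.samples[i0 - lo : i1 - lo], fs))
    dt_ms = 1000.0 / fs
    return float(np.trapezoid(portion.samples, dx=dt_ms))


def quantify_mvc(session: RawSession, params: MVCParams | None = None) -> MVCResult:
    """Score one grip session into an :class:`MVCResult`."""
    params = params or MVCParams()
    if session.modality != "mvc":
        raise ValueError(f"expected an mvc session, got {session.modality}")
    if not session.trial_events:
        raise ValueError("mvc session has no trial events")
    _check_windows(session.trial_events, session.duration_s)

    aucs: dict[str, list[float]] = {}
    durations: dict[str, list[float]] = {}
    for tr in session.trial_events:
        aucs.setdefault(tr.limb, []).append(_trial_auc(session, tr, params))
        durations.setdefault(tr.limb, []).append(tr.duration_s)

    if params.strict:
        bad = {limb: len(v) for limb, v in aucs.items() if len(v) != params.n_trials_per_limb}
        if bad:
            raise ValueError(
                f"expected {params.n_trials_per_limb} trials per limb, got {bad}"
            )

    limb_means = {limb: float(np.mean(v)) for limb, v in aucs.items()}
    grip = float(np.mean([tr.grip_force for tr in session.trial_events]))
    return MVCResult(
        trial_aucs_mVms=aucs,
        limb_means=limb_means,
        mvc_mVms=float(np.mean(list(limb_means.values()))),
        grip_force=grip,
        trial_durations_s=durations,
    )
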
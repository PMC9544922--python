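"""Scoring of averaged evoked-potential traces.

The response is recognised on the averaged, conditioned trace by a
sustained 15% deviation from the pre-stimulus baseline: onset is the first
time the trace exceeds the criterion for at least ``min_run_ms``, offset
the end of the last such excursion.  AUC is the trapezoidal integral of
the trace between those bounds (mV·ms); duration is offset − onset.

Because a purely relative criterion degenerates as baseline approaches
zero (1.15 x 0 = 0 would flag noise everywhere), the detection level is
``max(baseline * (1 + rel), baseline + abs_floor)`` with a small absolute
floor.  Optionally the criterion can be referenced to baseline
variability (mean + k·SD) instead of the baseline mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import MEPResult
from .preprocess import Trace

log = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Response-recognition settings for :func:`quantify_mep`."""

    rel_criterion: float = 0.15
    abs_floor_mV: float = 0.005
    min_run_ms: float = 1.0
    #: longest excursion still counted as an evoked response.  A cortical
    #: MEP in rat biceps lasts tens of ms; slow movement-related humps
    #: that survive averaging run far longer and are rejected by this cap.
    max_run_ms: float = 60.0
    #: pre-stimulus window for baseline estimation, ms relative to
    #: stimulus; kept inside the DC reference span (late pre-stimulus,
    #: disjoint from the sweep-selection span)
    baseline_window_ms: tuple[float, float] = (-25.0, -2.0)
    #: latency window in which the response must *begin* (start past the
    #: artifact blanking, end at the physiological upper latency bound);
    #: the offset may extend beyond it
    search_window_ms: tuple[float, float] = (3.0, 30.0)
    #: drop satellite excursions whose peak is below this fraction of the
    #: dominant excursion's peak — the steep zero-phase low-pass rings at
    #: sharp response edges, and its sidelobes (a few % of the response)
    #: must not masquerade as onset
    satellite_frac: float = 0.25
    #: "sd" references the criterion to baseline mean + rel*SD instead of
    #: the relative-to-mean rule
    criterion_mode: str = "relative"


def estimate_baseline(trace: Trace, pre_window_ms: tuple[float, float]) -> float:
    """Mean rectified level over a pre-stimulus window, in mV (>= 0)."""
    if pre_window_ms[1] > 0:
        raise ValueError(f"baseline window {pre_window_ms} must be pre-stimulus")
    sl = trace.window_slice(*pre_window_ms)
    if sl.stop <= sl.start:
        raise ValueError(f"baseline window {pre_window_ms} ms is empty")
    return float(np.abs(trace.samples[sl]).mean())


def detection_level(
    trace: Trace, baseline_mV: float, params: DetectionParams
) -> float:
    """Threshold the trace must sustain for a response to count."""
    if params.criterion_mode == "sd":
        sl = trace.window_slice(*params.baseline_window_ms)
        sd = float(np.abs(trace.samples[sl]).std(ddof=1)) if sl.stop - sl.start > 1 else 0.0
        level = baseline_mV + params.rel_criterion * sd
    else:
        level = baseline_mV * (1.0 + params.rel_criterion)
    return max(level, baseline_mV + params.abs_floor_mV)


def detect_onset_offset(
    trace: Trace,
    baseline_mV: float,
    rel_criterion: float = 0.15,
    min_run_ms: float = 1.0,
    search_window_ms: tuple[float, float] = (3.0, 30.0),
    abs_floor_mV: float = 0.005,
    max_run_ms: float | None = 60.0,
    satellite_frac: float = 0.25,
    criterion_mode: str = "relative",
    consistency_trace: Trace | None = None,
) -> tuple[float, float] | None:
    """Find sustained supra-criterion response bounds, ms post-stimulus.

    A qualifying excursion must *start* inside ``search_window_ms``, stay
    above the criterion for ``min_run_ms`` to ``max_run_ms``, and reach
    at least ``satellite_frac`` of the tallest qualifying excursion.
    Onset is the first qualifying crossing; offset is the end of the last
    qualifying run (which may extend beyond the search window).  Returns
    ``None`` when no excursion qualifies.

    ``consistency_trace`` (typically the median across sweeps, aligned
    and conditioned like the mean) gates candidate excursions on
    stimulus-locking: a genuine evoked response replicates in every
    sweep and survives the median, whereas a movement artifact riding on
    a minority of sweeps inflates only the mean.  Candidates with no
    supra-criterion support in the consistency trace are dropped.
    """
    if baseline_mV < 0:
        raise ValueError("baseline must be non-negative")
    if search_window_ms[1] <= search_window_ms[0]:
        raise ValueError(f"invalid search window {search_window_ms}")
    params = DetectionParams(
        rel_criterion=rel_criterion,
        abs_floor_mV=abs_floor_mV,
        min_run_ms=min_run_ms,
        max_run_ms=max_run_ms if max_run_ms is not None else np.inf,
        search_window_ms=search_window_ms,
        criterion_mode=criterion_mode,
    )
    level = detection_level(trace, baseline_mV, params)
    # runs are traced to the end of the sweep; only their *starts* are
    # constrained to the latency window
    sl = trace.window_slice(search_window_ms[0], trace.times_ms[-1] + 1e-9)
    if sl.stop <= sl.start:
        raise ValueError("search window outside trace extent")
    t = trace.times_ms[sl]
    above = trace.samples[sl] > level

    step = 1000.0 / trace.fs
    cap = max_run_ms if max_run_ms is not None else np.inf
    x = trace.samples[sl]
    qualifying = [
        (a, b)
        for a, b in _runs(above)
        if t[a] < search_window_ms[1]
        and min_run_ms - 1e-9 <= (b - a) * step <= cap + 1e-9
    ]
    if consistency_trace is not None and qualifying:
        support = consistency_trace.samples[sl]
        qualifying = [(a, b) for a, b in qualifying if support[a:b].max() > level]
    if not qualifying:
        return None
    peaks = np.array([x[a:b].max() for a, b in qualifying])
    keep = peaks >= satellite_frac * peaks.max() - 1e-12
    qualifying = [run for run, k in zip(qualifying, keep) if k]
    onset = t[qualifying[0][0]]
    offset = t[qualifying[-1][1] - 1]
    return float(onset), float(offset)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        stops = stops + [mask.size]
    return list(zip(starts, stops))


def compute_auc(trace: Trace, onset_ms: float, offset_ms: float) -> float:
    """Trapezoidal integral of the trace between bounds, in mV·ms."""
    if onset_ms > offset_ms:
        raise ValueError("onset must not exceed offset")
    t = trace.times_ms
    if onset_ms < t[0] - 1e-9 or offset_ms > t[-1] + 1e-9:
        raise ValueError("integration bounds outside trace extent")
    # integrate on the sample grid restricted to [onset, offset], with
    # linear interpolation at the fractional endpoints
    grid = t[(t > onset_ms) & (t < offset_ms)]
    tt = np.concatenate([[onset_ms], grid, [offset_ms]])
    yy = np.interp(tt, t, trace.samples)
    return float(np.trapezoid(yy, tt))


def quantify_mep(
    avg_trace: Trace,
    params: DetectionParams | None = None,
    n_sweeps_used: int = 0,
    threshold_mA: float | None = None,
    consistency_trace: Trace | None = None,
) -> MEPResult:
    """Score one averaged, conditioned trace into an :class:`MEPResult`."""
    params = params or DetectionParams()
    baseline = estimate_baseline(avg_trace, params.baseline_window_ms)
    bounds = detect_onset_offset(
        avg_trace,
        baseline,
        rel_criterion=params.rel_criterion,
        min_run_ms=params.min_run_ms,
        search_window_ms=params.search_window_ms,
        abs_floor_mV=params.abs_floor_mV,
        max_run_ms=params.max_run_ms,
        satellite_frac=params.satellite_frac,
        criterion_mode=params.criterion_mode,
        consistency_trace=consistency_trace,
    )
    if bounds is None:
        return MEPResult(
            baseline_mV=baseline,
            detected=False,
            n_sweeps_used=n_sweeps_used,
            threshold_mA=threshold_mA,
        )
    onset, offset = bounds
    auc = compute_auc(avg_trace, onset, offset)
    return MEPResult(
        baseline_mV=baseline,
        detected=True,
        onset_ms=onset,
        offset_ms=offset,
        auc_mVms=max(auc, 0.0),
        n_sweeps_used=n_sweeps_used,
        threshold_mA=threshold_mA,
    )


def find_threshold(series: list[tuple[float, MEPResult]]) -> float | None:
    """Smallest stimulation current that evoked a detected response.

    ``series`` must be sorted by strictly ascending current.  If detection
    is non-monotone along the series (a response at some current but none
    at a higher one) the smallest detected current is still returned, with
    a warning — recruitment is expected to be monotone.
    """
    currents = [c for c, _ in series]
    if any(b <= a for a, b in zip(currents, currents[1:])):
        raise ValueError("recruitment series must have strictly ascending currents")
    detected = [c for c, r in series if r.detected]
    if not detected:
        return None
    thr = detected[0]
    above = [r.detected for c, r in series if c >= thr]
    if not all(above):
        log.warning("non-monotone detection along recruitment series; using %.3g mA", thr)
    return thr
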
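"""End-to-end session and cohort analysis.

Chains the per-module operations into the two session pipelines —

* MEP: epoch sweeps around each stimulus (artifact-blanked), condition
  each sweep (rectify, smooth, low-pass, DC-correct), select the 20
  quietest of 60, average, then score baseline/onset/offset/AUC;
* MVC: low-pass each timestamped trial, rectify, integrate, average over
  trials and limbs —

and rolls session results into the tidy longitudinal table the statistics
module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import MEPResult, MVCResult, RawSession, make_longitudinal_table
from .mep_quant import DetectionParams, find_threshold, quantify_mep
from dataclasses import replace as _dc_replace

import numpy as np

from .mvc_quant import MVCParams, quantify_mvc
from .preprocess import PreprocessParams, Trace, preprocess_mep_batch
from .trigger_average import average_sweeps, epoch_sweeps, select_clean


@dataclass
class AnalysisParams:
    """Everything the session pipelines need, in one place."""

    window_ms: tuple[float, float] = (-50.0, 100.0)
    blank_ms: float = 3.0
    k_select: int = 20
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    mvc: MVCParams = field(default_factory=MVCParams)


def analyze_mep_session(
    session: RawSession,
    channel: int | str = 0,
    params: AnalysisParams | None = None,
) -> MEPResult:
    """Raw MEP session -> scored result, per the full evoked pipeline."""
    params = params or AnalysisParams()
    sweeps = epoch_sweeps(session, channel, params.window_ms, params.blank_ms)
    conditioned = _dc_replace(
        sweeps,
        sweeps=preprocess_mep_batch(
            sweeps.sweeps, sweeps.fs, sweeps.window_ms[0], params.preprocess
        ),
    )
    k = min(params.k_select, conditioned.n_sweeps)
    chosen = select_clean(conditioned, k)
    avg = average_sweeps(chosen)
    # median across the selected sweeps: immune to artifacts riding on a
    # minority of sweeps, used to gate detection on stimulus-locking
    median = Trace(
        np.median(chosen.sweeps[chosen.selected], axis=0), chosen.fs, avg.t0_ms
    )
    return quantify_mep(
        avg,
        params.detection,
        n_sweeps_used=k,
        threshold_mA=session.stim_current_mA,
        consistency_trace=median,
    )


def analyze_mvc_session(
    session: RawSession, params: AnalysisParams | None = None
) -> MVCResult:
    params = params or AnalysisParams()
    return quantify_mvc(session, params.mvc)


def analyze_recruitment(
    series: list[tuple[float, RawSession]],
    channel: int | str = 0,
    params: AnalysisParams | None = None,
) -> float | None:
    """Threshold current from a recruitment series of raw sessions."""
    scored = [(c, analyze_mep_session(s, channel, params)) for c, s in series]
    return find_threshold(scored)


def analyze_cohort(
    sessions, params: AnalysisParams | None = None
) -> pd.DataFrame:
    """Score an iterable of sessions into a tidy longitudinal table.

    Emits one row per animal x week x measure with measures ``mep_auc``,
    ``mep_duration``, ``mvc_auc`` and ``grip_force``.
    """
    params = params or AnalysisParams()
    rows = []
    for s in sessions:
        if s.modality in ("mep", "recruitment"):
            r = analyze_mep_session(s, 0, params)
            rows.append((s.animal_id, s.group, s.week, "mep_auc", r.auc_mVms))
            rows.append((s.animal_id, s.group, s.week, "mep_duration", r.duration_ms))
        elif s.modality == "mvc":
            r = analyze_mvc_session(s, params)
            rows.append((s.animal_id, s.group, s.week, "mvc_auc", r.mvc_mVms))
            rows.append((s.animal_id, s.group, s.week, "grip_force", r.grip_force))
    return make_longitudinal_table(rows)
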
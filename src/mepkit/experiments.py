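"""Cohort-level simulation experiments: calibration and effect recovery.

These routines run the *whole* chain — session synthesis, epoching,
conditioning, sweep selection, averaging, scoring, tidy table, split-plot
ANOVA — many times over seeded replicates, to answer two questions about
the pipeline rather than about any single trace:

* calibration: with flat effect profiles (no group differences built in),
  does the treatment term of the repeated-measures ANOVA reject at its
  nominal rate?
* recovery: with the default effect profiles, does the estimated
  triple-vs-untreated MVC AUC ratio at week 11 come back near the
  generator's configured truth, and does the week-4-rise/week-6-plateau
  time course survive the pipeline?

Problem sizes default to the reduced configuration (8 kHz, 20 triggers,
4 animals/group, 5 weeks) so hundreds of replicates stay cheap.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .stats import rm_anova_split_plot
from .synthetic import (
    SimConfig,
    flat_group_profiles,
    make_animals,
    simulate_mep_session,
    simulate_mvc_session,
    small_config,
)
from .workflow import AnalysisParams, analyze_mep_session, analyze_mvc_session


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(int(seed) & 0x7FFFFFFF).spawn(n)


def mep_cohort_table(cfg: SimConfig, seed, params: AnalysisParams | None = None) -> pd.DataFrame:
    """Simulate and score one MEP cohort into a tidy longitudinal table."""
    params = params or AnalysisParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    animals = make_animals(cfg, ss.spawn(1)[0])
    rows = []
    children = ss.spawn(len(animals) * len(cfg.weeks))
    i = 0
    for a in animals:
        for w in cfg.weeks:
            current = cfg.mep_test_factor * a.threshold_mA
            session = simulate_mep_session(cfg, a, w, current, children[i])
            i += 1
            res = analyze_mep_session(session, 0, params)
            rows.append((a.animal_id, a.group, w, "mep_auc", res.auc_mVms))
    return pd.DataFrame(rows, columns=["animal_id", "group", "week", "measure", "value"])


def null_rejection_rate(
    n_replicates: int = 200,
    seed: int = 0,
    cfg: SimConfig | None = None,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the treatment term under flat effect profiles.

    Every replicate simulates a complete cohort with all group-week
    multipliers at 1.0, runs the full MEP pipeline, and tests the group
    effect with the split-plot ANOVA.  Returns the rejection rate and the
    raw p-values (their distribution should be uniform).
    """
    if cfg is None:
        cfg = small_config()
    cfg = replace(
        cfg, group_profiles=flat_group_profiles(cfg.groups, cfg.weeks)
    )
    pvals = []
    for child in _child_seeds(seed, n_replicates):
        table = mep_cohort_table(cfg, child)
        res = rm_anova_split_plot(table[table["measure"] == "mep_auc"])
        pvals.append(res.effect_terms["treatment"][2])
    pvals = np.asarray(pvals)
    return {
        "rejection_rate": float(np.mean(pvals < alpha)),
        "n_replicates": n_replicates,
        "p_values": pvals,
    }


def mvc_week11_ratio(
    n_replicates: int = 50,
    seed: int = 0,
    cfg: SimConfig | None = None,
) -> dict:
    """Triple/untreated group-mean MVC AUC ratio at week 11 vs truth.

    Truth is the ratio of the generator's expected trial AUCs (which
    account for the analysis low-pass attenuating background and carrier
    bands); the measured ratio averages the pipeline's session MVC over
    animals and replicates.
    """
    if cfg is None:
        cfg = small_config()
    measured = {"triple": [], "untreated": []}
    expected = {"triple": [], "untreated": []}
    for child in _child_seeds(seed, n_replicates):
        sub = child.spawn(1)[0]
        animals = [a for a in make_animals(cfg, sub) if a.group in measured]
        sess_seeds = child.spawn(len(animals))
        for a, s_seed in zip(animals, sess_seeds):
            session = simulate_mvc_session(cfg, a, 11, s_seed)
            res = analyze_mvc_session(session)
            measured[a.group].append(res.mvc_mVms)
            expected[a.group].append(session.extras["truth"]["expected_trial_auc_mVms"])
    ratio = float(np.mean(measured["triple"]) / np.mean(measured["untreated"]))
    truth = float(np.mean(expected["triple"]) / np.mean(expected["untreated"]))
    return {"measured_ratio": ratio, "true_ratio": truth,
            "relative_error": ratio / truth - 1.0, "n_replicates": n_replicates}


def mvc_time_course(
    n_replicates: int = 10,
    seed: int = 0,
    cfg: SimConfig | None = None,
    weeks: tuple[int, ...] = (1, 4, 6, 8, 11),
    group: str = "triple",
) -> pd.DataFrame:
    """Group-mean MVC AUC per week for one treatment group.

    Used to confirm the configured time course — low immediately after
    injury, rising from week 4, plateau from week 6 — survives the full
    pipeline.  Animal identities (and their amplitude factors) are held
    fixed across weeks within a replicate, as in a longitudinal study.
    """
    if cfg is None:
        cfg = small_config()
    if any(w not in cfg.weeks for w in weeks):
        # profiles are regenerated for the extended week set
        cfg = replace(
            cfg, weeks=tuple(sorted(set(cfg.weeks) | set(weeks))), group_profiles=None
        )
    rows = []
    for rep, child in enumerate(_child_seeds(seed, n_replicates)):
        animals = [a for a in make_animals(cfg, child.spawn(1)[0]) if a.group == group]
        sess_seeds = child.spawn(len(animals) * len(weeks))
        i = 0
        for a in animals:
            for w in weeks:
                session = simulate_mvc_session(cfg, a, w, sess_seeds[i])
                i += 1
                res = analyze_mvc_session(session)
                rows.append((rep, a.animal_id, w, res.mvc_mVms))
    df = pd.DataFrame(rows, columns=["replicate", "animal_id", "week", "mvc_auc"])
    return df.groupby("week", as_index=False)["mvc_auc"].mean()


def noiseless_mep_benchmark(seed: int = 0) -> dict:
    """Score a noise-free synchronized-carrier MEP session.

    Returns detected onset/offset/AUC together with the independent
    closed-form expectations from the gamma burst envelope: onset/offset
    are where ``(2/pi) * amp * g(t)`` crosses the detection floor, and
    the AUC is the analytic integral of that curve between the crossings.
    """
    from scipy.optimize import brentq

    from .synthetic import Animal, mep_envelope

    cfg = SimConfig(
        bg_rms_mV=0.0, artifact_rate_hz=0.0, carrier_mode="sine",
        n_triggers=20, isi_s=0.3, pad_s=0.2,
    )
    animal = Animal("benchmark", "untreated", 1.5, 1.0)
    session = simulate_mep_session(cfg, animal, -1, cfg.threshold_mA, seed)
    result = analyze_mep_session(session)
    amp = session.extras["truth"]["amp_eff_mV"]
    floor = 0.005

    def level(t_ms: float) -> float:
        return (2.0 / np.pi) * amp * float(
            mep_envelope(np.array([t_ms]), cfg.mep_latency_ms, cfg.mep_dur_ms, cfg.mep_shape_k)[0]
        ) - floor

    t_peak = cfg.mep_latency_ms + cfg.mep_dur_ms / cfg.mep_shape_k
    onset_cf = brentq(level, cfg.mep_latency_ms + 1e-6, t_peak)
    offset_cf = brentq(level, t_peak, cfg.mep_latency_ms + 6 * cfg.mep_dur_ms)
    tt = np.linspace(onset_cf, offset_cf, 20001)
    env = mep_envelope(tt, cfg.mep_latency_ms, cfg.mep_dur_ms, cfg.mep_shape_k)
    auc_cf = float(np.trapezoid((2.0 / np.pi) * amp * env, tt))
    return {
        "onset_ms": result.onset_ms, "offset_ms": result.offset_ms,
        "auc_mVms": result.auc_mVms, "onset_closed_form_ms": onset_cf,
        "offset_closed_form_ms": offset_cf, "auc_closed_form_mVms": auc_cf,
        "detected": result.detected,
    }


def threshold_recovery(
    n_series: int = 8, seed: int = 0, cfg: SimConfig | None = None
) -> dict:
    """Recruitment-threshold recovery over seeded series.

    Returns recovered thresholds, the configured truth and the grid step,
    so callers can check the within-one-grid-step property.
    """
    from .synthetic import Animal, simulate_recruitment_series
    from .workflow import analyze_recruitment

    if cfg is None:
        cfg = small_config()
    animal = Animal("thr", "untreated", cfg.threshold_mA, 1.0)
    recovered = []
    for child in _child_seeds(seed, n_series):
        series = simulate_recruitment_series(cfg, animal, child)
        recovered.append(analyze_recruitment(series))
    step = float(np.diff(cfg.current_grid).max())
    return {
        "recovered": recovered,
        "true_threshold_mA": cfg.threshold_mA,
        "grid_step_mA": step,
        "max_abs_error_mA": float(
            max(abs((r if r is not None else np.inf) - cfg.threshold_mA) for r in recovered)
        ),
    }
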
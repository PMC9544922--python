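"""Seeded synthetic EMG sessions with known ground truth.

The study's raw recordings are not public, so every downstream stage is
exercised on simulated sessions that reproduce the statistical structure
the analysis assumes:

* stimulus-locked MEP bursts — a gamma-shaped envelope multiplying a
  100–1000 Hz carrier — riding on band-limited background EMG, with a
  brief stimulation artifact at each trigger and occasional low-frequency
  movement artifacts;
* grip trials with a voluntary-contraction burst inside each timestamped
  window, plus apparatus force readings that share only a weak common
  factor with the EMG (the two measures dissociate, as in vivo);
* recruitment series over ascending stimulation currents with a per-animal
  threshold;
* longitudinal cohorts whose group-by-week amplitude profiles encode the
  treatment effect (drop after injury, recovery rising from week 4 and
  plateauing from week 6 in the triple-treatment group);
* negative-binomial motor-neuron counts per spinal level.

Every generator is a pure function of (config, identifiers, seed):
identical inputs give bit-identical sessions.  Ground-truth burst
parameters and expected outcome values ride along in ``session.extras``
so recovery can be tested quantitatively.

The burst carrier has two modes: ``"noise"`` (band-limited Gaussian, the
realistic asynchronous interference pattern, default) and ``"sine"`` (a
deterministic synchronized carrier whose rectified mean has the exact
closed form ``(2/pi) * envelope``, used for noise-free validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core_io import RawSession, TrialEvent
from .preprocess import butter_sos

SQRT_2_OVER_PI = float(np.sqrt(2.0 / np.pi))


@dataclass(frozen=True)
class Animal:
    animal_id: str
    group: str
    threshold_mA: float = 1.5
    #: multiplicative per-animal amplitude factor (between-subject variance)
    factor: float = 1.0


def default_group_profiles(
    groups: tuple[str, ...], weeks: tuple[int, ...]
) -> dict[str, dict[int, float]]:
    """Per-(group, week) amplitude multipliers on burst amplitude.

    Baseline (week -1) is 1.0 everywhere.  After injury all groups drop;
    the triple-treatment group recovers from week 4 and plateaus at 0.9
    from week 6 onward, the single-treatment and untreated groups stay
    low.  The same multiplier drives evoked and voluntary bursts.
    """
    post = {
        "untreated": lambda w: 0.30,
        "chabc_only": lambda w: 0.35,
        "stim_only": lambda w: 0.35,
        "stim_rehab": lambda w: 0.50,
        "triple": lambda w: 0.30 if w < 4 else (0.50 if w == 4 else (0.70 if w == 5 else 0.90)),
    }
    out: dict[str, dict[int, float]] = {}
    for g in groups:
        fn = post.get(g, lambda w: 1.0)
        out[g] = {w: (1.0 if w < 0 else float(fn(w))) for w in weeks}
    return out


def flat_group_profiles(
    groups: tuple[str, ...], weeks: tuple[int, ...]
) -> dict[str, dict[int, float]]:
    """Null profiles: every multiplier 1.0 (no group or week effect)."""
    return {g: {w: 1.0 for w in weeks} for g in groups}


@dataclass
class SimConfig:
    """All tunable parameters of the simulator, with study defaults."""

    fs: float = 20_000.0
    n_triggers: int = 60
    isi_s: float = 2.0
    # therapeutic stimulation train (metadata; MEP probes use single pulses)
    n_pulses: int = 5
    pulse_rate_hz: float = 500.0
    pulse_width_ms: float = 0.2
    stim_artifact_mV: float = 5.0
    # MEP burst model
    mep_latency_ms: float = 8.0
    mep_amp_mV: float = 0.5
    mep_dur_ms: float = 15.0
    mep_shape_k: float = 4.0
    carrier_band_hz: tuple[float, float] = (100.0, 1000.0)
    carrier_mode: str = "noise"  # or "sine"
    carrier_sine_hz: float = 400.0
    #: amplitude gain saturates at this multiple of threshold current
    recruit_cap: float = 2.0
    # background EMG and artifacts; the band mirrors a 100 Hz – 3 kHz
    # acquisition bandwidth, so the 230 Hz analysis low-pass suppresses
    # most of the rectified-background fluctuation (clean averages)
    bg_band_hz: tuple[float, float] = (100.0, 3000.0)
    bg_rms_mV: float = 0.05
    artifact_rate_hz: float = 0.1
    artifact_rms_mV: float = 0.3
    artifact_band_hz: tuple[float, float] = (2.0, 10.0)
    artifact_dur_s: float = 0.5
    # MVC sessions
    mvc_trial_s: float = 8.0
    mvc_gap_s: float = 12.0
    n_trials_per_limb: int = 3
    mvc_amp_mV: float = 0.5
    mvc_burst_frac: float = 0.6
    grip_base: float = 8.0
    grip_shared: float = 0.1
    grip_noise_sd: float = 1.0
    # cohort structure
    groups: tuple[str, ...] = ("untreated", "chabc_only", "triple")
    n_animals: int = 6
    weeks: tuple[int, ...] = (-1, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11)
    threshold_mA: float = 1.5
    current_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    #: MEP sessions are recorded at this multiple of each animal's threshold
    mep_test_factor: float = 1.5
    animal_sd: float = 0.2
    #: low-pass settings mirrored from the analysis, used only to compute
    #: ground-truth expected values in ``extras``
    analysis_cutoff_hz: float = 230.0
    analysis_order: int = 8
    truth_floor_mV: float = 0.005
    group_profiles: dict[str, dict[int, float]] | None = None
    pad_s: float = 0.5

    def __post_init__(self) -> None:
        if self.group_profiles is None:
            self.group_profiles = default_group_profiles(self.groups, self.weeks)
        for name in ("bg_rms_mV", "artifact_rate_hz", "artifact_rms_mV",
                     "mep_amp_mV", "mvc_amp_mV", "stim_artifact_mV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for g in self.groups:
            prof = self.group_profiles.get(g, {})
            missing = [w for w in self.weeks if w not in prof]
            if missing:
                raise ValueError(f"group_profiles[{g!r}] missing weeks {missing}")

    def multiplier(self, group: str, week: int) -> float:
        return self.group_profiles[group][week]


def small_config(**overrides) -> SimConfig:
    """A reduced-size configuration for quick simulation studies.

    Shorter sessions at 2 kHz with fewer triggers, animals and weeks;
    burst timing, noise levels and effect profiles keep their defaults so
    the generated data have the same structure as the full-size setup.
    """
    base = dict(
        fs=8000.0,
        n_triggers=30,
        isi_s=0.2,
        n_animals=4,
        weeks=(-1, 1, 4, 6, 11),
        mvc_trial_s=2.0,
        mvc_gap_s=0.5,
        pad_s=0.2,
    )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# building blocks

def mep_envelope(t_ms: np.ndarray, latency_ms: float, dur_ms: float, shape_k: float = 4.0):
    """Peak-normalised gamma-shaped burst envelope.

    Rises from ``latency_ms``, peaks at ``latency_ms + dur_ms / shape_k``
    and decays to below 1% of peak by roughly ``latency_ms + dur_ms``.
    """
    tau = np.asarray(t_ms, dtype=float) - latency_ms
    tp = dur_ms / shape_k
    out = np.zeros_like(tau)
    pos = tau > 0
    r = tau[pos] / tp
    out[pos] = r ** (shape_k - 1.0) * np.exp((shape_k - 1.0) * (1.0 - r))
    return out


def band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], rms: float
) -> np.ndarray:
    """Gaussian noise band-passed to ``band`` and scaled to exact RMS.

    The filter runs over a longer segment and the interior is cut, so the
    returned samples have spatially uniform variance (the band-pass edge
    transient, ~3 cycles of the low band edge, never reaches the output).
    """
    if rms <= 0 or n == 0:
        return np.zeros(n)
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    if hi <= lo:
        x = rng.standard_normal(n)
    else:
        margin = int(round(3.0 * fs / lo))
        white = rng.standard_normal(n + 2 * margin)
        sos = butter_sos(4, (lo, hi), fs, "band")
        x = sps.sosfiltfilt(sos, white)[margin : margin + n]
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _carrier(rng, t_ms: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.carrier_mode == "sine":
        return np.sin(2.0 * np.pi * cfg.carrier_sine_hz * t_ms / 1000.0)
    c = band_limited_noise(rng, t_ms.size, cfg.fs, cfg.carrier_band_hz, 1.0)
    return c


from functools import lru_cache


@lru_cache(maxsize=64)
def post_filter_rms_factor(
    fs: float, band: tuple[float, float], cutoff_hz: float, order: int
) -> float:
    """RMS fraction of band-limited noise surviving the zero-phase low-pass.

    Models the noise spectrum by the order-4 band-pass used in synthesis
    and the analysis filter by the squared (two-pass) Butterworth
    response; used for ground-truth expected values.
    """
    f = np.linspace(0.0, fs / 2.0, 4096)
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    if hi <= lo:
        spec = np.ones_like(f)
    else:
        sos_bp = butter_sos(4, (lo, hi), fs, "band")
        _, h_bp = sps.sosfreqz(sos_bp, worN=f, fs=fs)
        spec = np.abs(h_bp) ** 2
    sos_lp = butter_sos(order, cutoff_hz, fs)
    _, h_lp = sps.sosfreqz(sos_lp, worN=f, fs=fs)
    gain2 = np.abs(h_lp) ** 4  # forward-backward pass squares the magnitude
    denom = np.trapezoid(spec, f)
    if denom <= 0:
        return 1.0
    return float(np.sqrt(np.trapezoid(spec * gain2, f) / denom))


def _as_animal(animal, cfg: SimConfig) -> Animal:
    if isinstance(animal, Animal):
        return animal
    return Animal(animal_id=str(animal), group="untreated", threshold_mA=cfg.threshold_mA)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# expected-value (ground truth) helpers

def expected_rectified_level(
    cfg: SimConfig, amp_eff: float, t_ms: np.ndarray
) -> np.ndarray:
    """Expected rectified trace (mV) of burst + background at times t_ms.

    For the Gaussian carrier the burst and background add in variance, so
    ``E|x| = sqrt(2/pi) * sqrt(sigma_b^2 + (amp * g)^2)``; for the
    deterministic sine carrier on zero background the exact low-passed
    rectified mean is ``(2/pi) * amp * g``.
    """
    g = mep_envelope(t_ms, cfg.mep_latency_ms, cfg.mep_dur_ms, cfg.mep_shape_k)
    if cfg.carrier_mode == "sine" and cfg.bg_rms_mV == 0:
        return (2.0 / np.pi) * amp_eff * g
    sigma = np.sqrt(cfg.bg_rms_mV**2 + (amp_eff * g) ** 2)
    return SQRT_2_OVER_PI * sigma


def mep_truth(cfg: SimConfig, amp_eff: float) -> dict:
    """Ground-truth onset/offset/AUC for one burst amplitude.

    Truth is the infinite-averaging limit of the measurement: the
    expected rectified curve is passed through the same conditioning
    chain the analysis applies (5-point smoothing and the zero-phase
    low-pass, both of which smear the burst foot non-causally), the
    expected baseline level subtracted, and onset/offset read off as the
    crossings with the detection floor.  AUC is the trapezoidal integral
    of that noise-free curve between the crossings.  Recovery error
    against this truth therefore measures estimation noise, not the
    deterministic filter response.
    """
    from .mep_quant import compute_auc, detect_onset_offset
    from .preprocess import Trace, lowpass, smooth5

    pre_ms = 50.0
    t = np.arange(
        -pre_ms, cfg.mep_latency_ms + 6.0 * cfg.mep_dur_ms + 20.0, 1000.0 / cfg.fs
    )
    base = 0.0 if (cfg.carrier_mode == "sine" and cfg.bg_rms_mV == 0) else (
        SQRT_2_OVER_PI * cfg.bg_rms_mV
    )
    curve = expected_rectified_level(cfg, amp_eff, t)
    tr = Trace(curve, cfg.fs, t0_ms=t[0])
    filtered = lowpass(smooth5(tr), cfg.analysis_cutoff_hz, cfg.analysis_order).samples
    clean = Trace(filtered - base, cfg.fs, t0_ms=t[0])
    bounds = detect_onset_offset(clean, 0.0, abs_floor_mV=cfg.truth_floor_mV)
    if bounds is None:
        return {"onset_ms": np.nan, "offset_ms": np.nan, "auc_mVms": 0.0}
    onset, offset = bounds
    return {
        "onset_ms": onset,
        "offset_ms": offset,
        "auc_mVms": max(compute_auc(clean, onset, offset), 0.0),
    }


def mvc_truth_auc(cfg: SimConfig, amp_eff: float) -> float:
    """Expected filter-then-rectify trial AUC (mV·ms) for one burst.

    Models the full expected measurement: the analysis low-pass
    attenuates background and carrier bands before rectification, and
    Poisson movement artifacts (which the low-pass passes) elevate the
    rectified mean over the fraction of trial time they cover.  Without
    the artifact term the expected group-AUC *ratios* would be biased:
    artifacts add the same absolute area to every group.
    """
    fb = post_filter_rms_factor(cfg.fs, cfg.bg_band_hz, cfg.analysis_cutoff_hz, cfg.analysis_order)
    fc = post_filter_rms_factor(cfg.fs, cfg.carrier_band_hz, cfg.analysis_cutoff_hz, cfg.analysis_order)
    t_ms = np.arange(0.0, cfg.mvc_trial_s * 1000.0, 1.0)
    g = _mvc_envelope(t_ms / 1000.0, cfg)
    sigma0 = np.sqrt((cfg.bg_rms_mV * fb) ** 2 + (amp_eff * fc * g) ** 2)
    level = SQRT_2_OVER_PI * sigma0
    if cfg.artifact_rate_hz > 0 and cfg.artifact_rms_mV > 0:
        fa = post_filter_rms_factor(
            cfg.fs, cfg.artifact_band_hz, cfg.analysis_cutoff_hz, cfg.analysis_order
        )
        p_cov = 1.0 - np.exp(-cfg.artifact_rate_hz * cfg.artifact_dur_s)
        h = np.hanning(256) * cfg.artifact_rms_mV * fa
        with_art = SQRT_2_OVER_PI * np.sqrt(
            sigma0[:, None] ** 2 + h[None, :] ** 2
        ).mean(axis=1)
        level = (1.0 - p_cov) * level + p_cov * with_art
    return float(np.trapezoid(level, t_ms))


def _mvc_envelope(t_s: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Tukey-windowed contraction envelope centred in the trial."""
    dur = cfg.mvc_burst_frac * cfg.mvc_trial_s
    start = (cfg.mvc_trial_s - dur) / 2.0
    x = (np.asarray(t_s) - start) / dur
    win = np.zeros_like(x)
    inside = (x >= 0) & (x <= 1)
    alpha = 0.5
    xi = x[inside]
    w = np.ones_like(xi)
    ramp_in = xi < alpha / 2
    ramp_out = xi > 1 - alpha / 2
    w[ramp_in] = 0.5 * (1 + np.cos(np.pi * (2 * xi[ramp_in] / alpha - 1)))
    w[ramp_out] = 0.5 * (1 + np.cos(np.pi * (2 * (1 - xi[ramp_out]) / alpha - 1)))
    win[inside] = w
    return win


# ---------------------------------------------------------------------------
# session generators

def simulate_mep_session(
    cfg: SimConfig, animal, week: int, current_mA: float, seed
) -> RawSession:
    """One evoked-potential recording: triggers every ``isi_s`` seconds.

    A burst follows each stimulus iff ``current_mA`` reaches the animal's
    threshold; burst amplitude scales with the group-week multiplier, the
    per-animal factor, and (capped) current above threshold.
    """
    animal = _as_animal(animal, cfg)
    if week not in cfg.weeks:
        raise ValueError(f"week {week} not in configured weeks {cfg.weeks}")
    if current_mA < 0:
        raise ValueError("current must be >= 0")
    rng = _rng(seed)
    fs = cfg.fs
    duration = cfg.pad_s + cfg.n_triggers * cfg.isi_s + cfg.pad_s
    n = int(round(duration * fs))
    x = band_limited_noise(rng, n, fs, cfg.bg_band_hz, cfg.bg_rms_mV)
    x = x + _movement_artifacts(rng, n, fs, cfg)

    events = cfg.pad_s + np.arange(cfg.n_triggers) * cfg.isi_s
    supra = current_mA >= animal.threshold_mA
    mult = cfg.multiplier(animal.group, week)
    gain = min(current_mA / animal.threshold_mA, cfg.recruit_cap) if supra else 0.0
    amp_eff = cfg.mep_amp_mV * mult * animal.factor * gain

    n_pw = max(int(round(cfg.pulse_width_ms * fs / 1000.0)), 1)
    burst_len = int(round((cfg.mep_latency_ms + 6.0 * cfg.mep_dur_ms) * fs / 1000.0))
    t_burst_ms = np.arange(burst_len) * 1000.0 / fs
    env = mep_envelope(t_burst_ms, cfg.mep_latency_ms, cfg.mep_dur_ms, cfg.mep_shape_k)
    # one stationary carrier stream per session, sliced per burst: the
    # disjoint slices are independent, and one filter pass replaces one
    # per trigger
    carrier_stream = None
    if supra and amp_eff > 0 and cfg.carrier_mode != "sine":
        carrier_stream = band_limited_noise(rng, n, fs, cfg.carrier_band_hz, 1.0)
    for t_ev in events:
        i_ev = int(round(t_ev * fs))
        # single biphasic test-pulse artifact at the trigger
        x[i_ev : i_ev + n_pw] += cfg.stim_artifact_mV
        x[i_ev + n_pw : i_ev + 2 * n_pw] -= cfg.stim_artifact_mV
        if supra and amp_eff > 0:
            hi = min(i_ev + burst_len, n)
            seg = t_burst_ms[: hi - i_ev]
            carrier = (
                _carrier(rng, seg, cfg)
                if carrier_stream is None
                else carrier_stream[i_ev:hi]
            )
            x[i_ev:hi] += amp_eff * env[: hi - i_ev] * carrier

    truth = {"amp_eff_mV": amp_eff, "multiplier": mult, "animal_factor": animal.factor,
             "suprathreshold": bool(supra), "threshold_mA": animal.threshold_mA,
             "latency_ms": cfg.mep_latency_ms, "dur_ms": cfg.mep_dur_ms}
    truth.update(mep_truth(cfg, amp_eff) if supra else
                 {"onset_ms": np.nan, "offset_ms": np.nan, "auc_mVms": 0.0})
    return RawSession(
        session_id=f"{animal.animal_id}_w{week}_mep_{current_mA:g}mA",
        animal_id=animal.animal_id,
        group=animal.group,
        week=week,
        modality="mep",
        fs=fs,
        channels=["biceps_R"],
        signal=x[None, :],
        stim_events=events,
        stim_current_mA=current_mA,
        extras={"truth": truth},
    )


def _movement_artifacts(rng, n: int, fs: float, cfg: SimConfig) -> np.ndarray:
    out = np.zeros(n)
    if cfg.artifact_rate_hz <= 0 or cfg.artifact_rms_mV <= 0:
        return out
    n_events = rng.poisson(cfg.artifact_rate_hz * n / fs)
    dur = int(round(cfg.artifact_dur_s * fs))
    for t0 in rng.uniform(0, n - 1, size=n_events):
        i0 = int(t0)
        seg = min(dur, n - i0)
        if seg < 8:
            continue
        burst = band_limited_noise(rng, seg, fs, cfg.artifact_band_hz, cfg.artifact_rms_mV)
        out[i0 : i0 + seg] += burst * np.hanning(seg)
    return out


def simulate_mvc_session(cfg: SimConfig, animal, week: int, seed) -> RawSession:
    """One grip session: three timestamped trials per forelimb.

    The contraction burst sits inside each trial window on the active
    limb's channel; grip-force readings share only the weak common factor
    ``grip_shared`` with the EMG amplitude.
    """
    animal = _as_animal(animal, cfg)
    if week not in cfg.weeks:
        raise ValueError(f"week {week} not in configured weeks {cfg.weeks}")
    rng = _rng(seed)
    fs = cfg.fs
    limbs = ("R", "L")
    n_trials = cfg.n_trials_per_limb * len(limbs)
    slot = cfg.mvc_trial_s + cfg.mvc_gap_s
    duration = cfg.pad_s + n_trials * slot + cfg.pad_s
    n = int(round(duration * fs))

    mult = cfg.multiplier(animal.group, week)
    amp_eff = cfg.mvc_amp_mV * mult * animal.factor
    n_trial = int(round(cfg.mvc_trial_s * fs))
    t_trial_s = np.arange(n_trial) / fs
    env = _mvc_envelope(t_trial_s, cfg)
    t_trial_ms = t_trial_s * 1000.0

    signal = np.vstack([
        band_limited_noise(rng, n, fs, cfg.bg_band_hz, cfg.bg_rms_mV)
        + _movement_artifacts(rng, n, fs, cfg)
        for _ in limbs
    ])
    trials: list[TrialEvent] = []
    for j in range(n_trials):
        limb = limbs[j // cfg.n_trials_per_limb]
        ch = limbs.index(limb)
        start = cfg.pad_s + j * slot
        i0 = int(round(start * fs))
        signal[ch, i0 : i0 + n_trial] += amp_eff * env * _carrier(rng, t_trial_ms, cfg)
        grip = cfg.grip_base * (1.0 + cfg.grip_shared * (mult - 1.0)) + rng.normal(
            0.0, cfg.grip_noise_sd
        )
        trials.append(TrialEvent(start, start + cfg.mvc_trial_s, limb, float(grip)))

    truth = {
        "amp_eff_mV": amp_eff,
        "multiplier": mult,
        "animal_factor": animal.factor,
        "expected_trial_auc_mVms": mvc_truth_auc(cfg, amp_eff),
    }
    return RawSession(
        session_id=f"{animal.animal_id}_w{week}_mvc",
        animal_id=animal.animal_id,
        group=animal.group,
        week=week,
        modality="mvc",
        fs=fs,
        channels=["biceps_R", "biceps_L"],
        signal=signal,
        trial_events=trials,
        extras={"truth": truth},
    )


def simulate_recruitment_series(
    cfg: SimConfig, animal, seed
) -> list[tuple[float, RawSession]]:
    """Sessions over the ascending current grid, week = baseline."""
    if len(cfg.current_grid) == 0:
        raise ValueError("current grid is empty")
    grid = tuple(cfg.current_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("current grid must be strictly ascending")
    animal = _as_animal(animal, cfg)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(len(grid))
    return [
        (c, simulate_mep_session(cfg, animal, cfg.weeks[0], c, child))
        for c, child in zip(grid, children)
    ]


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortSim:
    """Lazy cohort: a manifest plus on-demand session construction."""

    cfg: SimConfig
    animals: list[Animal]
    manifest: pd.DataFrame
    truth: pd.DataFrame
    _seed: int = 0

    def build(self, row_index: int) -> RawSession:
        row = self.manifest.iloc[row_index]
        animal = next(a for a in self.animals if a.animal_id == row["animal_id"])
        child = np.random.SeedSequence([self._seed & 0x7FFFFFFF, int(row_index)])
        if row["modality"] == "mep":
            return simulate_mep_session(
                self.cfg, animal, int(row["week"]), float(row["current_mA"]), child
            )
        return simulate_mvc_session(self.cfg, animal, int(row["week"]), child)

    def sessions(self) -> Iterator[RawSession]:
        for i in range(len(self.manifest)):
            yield self.build(i)


def make_animals(cfg: SimConfig, seed) -> list[Animal]:
    """Per-group animal rosters with lognormal amplitude factors."""
    rng = _rng(seed)
    out = []
    for g in cfg.groups:
        for j in range(cfg.n_animals):
            factor = float(np.exp(rng.normal(0.0, cfg.animal_sd))) if cfg.animal_sd > 0 else 1.0
            out.append(Animal(f"{g}_{j + 1:02d}", g, cfg.threshold_mA, factor))
    return out


def simulate_cohort(cfg: SimConfig, seed: int) -> CohortSim:
    """Full factorial animals x weeks x {mep, mvc} with ground truth.

    MEP sessions are recorded at ``mep_test_factor`` times each animal's
    threshold.  The truth table holds, per animal and week, the configured
    multiplier and the expected AUC of each modality, for recovery tests.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xA17])
    animals = make_animals(cfg, ss)
    rows, truth_rows = [], []
    for a in animals:
        for w in cfg.weeks:
            current = cfg.mep_test_factor * a.threshold_mA
            rows.append((a.animal_id, a.group, w, "mep", current))
            rows.append((a.animal_id, a.group, w, "mvc", np.nan))
            mult = cfg.multiplier(a.group, w)
            amp_mep = cfg.mep_amp_mV * mult * a.factor * min(cfg.mep_test_factor, cfg.recruit_cap)
            amp_mvc = cfg.mvc_amp_mV * mult * a.factor
            truth_rows += [
                (a.animal_id, a.group, w, "multiplier", mult),
                (a.animal_id, a.group, w, "animal_factor", a.factor),
                (a.animal_id, a.group, w, "true_mep_auc_mVms", mep_truth(cfg, amp_mep)["auc_mVms"]),
                (a.animal_id, a.group, w, "true_mvc_auc_mVms", mvc_truth_auc(cfg, amp_mvc)),
            ]
    manifest = pd.DataFrame(
        rows, columns=["animal_id", "group", "week", "modality", "current_mA"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["animal_id", "group", "week", "measure", "value"]
    )
    return CohortSim(cfg=cfg, animals=animals, manifest=manifest, truth=truth,
                     _seed=int(seed))


# ---------------------------------------------------------------------------
# motor-neuron counts

def simulate_mn_counts(
    n_per_group: int | dict[str, int],
    level_means: dict[str, dict[str, float]],
    dispersion: float,
    seed,
) -> pd.DataFrame:
    """Negative-binomial motor-neuron counts per animal and spinal level.

    ``level_means`` maps group -> level -> mean count; variance is
    ``mu + dispersion * mu^2`` (Poisson at dispersion 0).  Zero-mean
    levels give zero counts exactly.
    """
    rng = _rng(seed)
    rows = []
    for group, means in level_means.items():
        n_g = n_per_group[group] if isinstance(n_per_group, dict) else n_per_group
        for level, mu in means.items():
            if mu < 0:
                raise ValueError(f"negative mean for {group}/{level}")
        for j in range(n_g):
            for level, mu in means.items():
                if mu == 0:
                    c = 0
                elif dispersion > 0:
                    r = 1.0 / dispersion
                    c = int(rng.negative_binomial(r, r / (r + mu)))
                else:
                    c = int(rng.poisson(mu))
                rows.append((f"{group}_{j + 1:03d}", group, level, c))
    return pd.DataFrame(rows, columns=["animal_id", "group", "level", "count"])
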
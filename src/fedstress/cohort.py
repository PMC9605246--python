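"""Synthetic multimodal smartwatch cohort generation.

Emulates the structure of a laboratory stress-induction session recorded with a
wrist-worn device: skin temperature (ST, 4 Hz), 3-axis accelerometer (ACC,
32 Hz), electrodermal activity (EDA, 4 Hz) and blood volume pulse (BVP, 64 Hz),
with per-second condition labels in {neutral, stress, amusement}.  The default
session is 2190 s: 20 min neutral, 10 min stress, 6.5 min amusement.

The signal model is deliberately minimal so that every stress-response property
is analytically checkable at zero noise:

* ST   — baseline + slow linear drift + small decrement under stress + noise.
* EDA  — tonic level elevated under stress, plus phasic skin-conductance
  responses (SCRs) arriving as a Poisson process whose rate rises under stress,
  each shaped as a fast rise with exponential decay, plus noise.
* BVP  — unit-amplitude sinusoid at the instantaneous heart rate, which is
  elevated under stress with smoothed transitions, plus noise.
* ACC  — Gaussian noise around a gravity offset, with occasional movement
  bursts whose rate does not depend on condition.

Participant-to-participant heterogeneity (baselines, response magnitude,
responder type) induces the non-IID client structure that makes the
individual / centralized / federated comparison meaningful.  *Atypical*
responders have all three stress deltas (tonic EDA, SCR rate, heart rate)
sign-flipped; *weak* responders have them halved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

CONDITIONS = ("neutral", "stress", "amusement")

#: Empatica-E4-style export rates, Hz.
SAMPLING_RATES: dict[str, float] = {
    "ST": 4.0,
    "ACCx": 32.0,
    "ACCy": 32.0,
    "ACCz": 32.0,
    "EDA": 4.0,
    "BVP": 64.0,
}
CHANNELS = tuple(SAMPLING_RATES)

#: Per-sensor Gaussian noise standard deviations (°C, g, µS, a.u.).
DEFAULT_NOISE_SCALES: dict[str, float] = {
    "ST": 0.05,
    "ACC": 0.02,
    "EDA": 0.03,
    "BVP": 0.15,
}

# Stress-response magnitudes at stress_effect_scale == 1, typical responder.
EDA_TONIC_STRESS_DELTA = 1.5  # µS
SCR_RATE_NEUTRAL = 3.0  # events / min
SCR_RATE_STRESS_DELTA = 6.0  # events / min
HR_STRESS_DELTA = 18.0  # beats / min
ST_STRESS_DELTA = -0.4  # °C
ST_SESSION_DRIFT = -0.3  # °C over the whole session

SCR_AMPLITUDE = 0.4  # µS
SCR_RISE_TAU = 0.7  # s
SCR_DECAY_TAU = 4.0  # s
HR_SMOOTH_SECONDS = 9

ACC_GRAVITY = (0.0, 0.0, 1.0)  # g, wrist at rest
ACC_BURST_RATE = 2.0  # movement bursts / min, condition-independent
ACC_BURST_DURATION = 2.0  # s
ACC_BURST_GAIN = 20.0  # burst noise amplification over resting noise

RESPONDER_FACTORS = {"typical": 1.0, "weak": 0.5, "atypical": -1.0}


@dataclass(frozen=True)
class SessionPlan:
    """Ordered (condition, duration-in-seconds) segments of one session."""

    segments: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("session plan needs at least one segment")
        for cond, dur in self.segments:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if dur <= 0:
                raise ValueError("segment durations must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))

    def per_second_labels(self) -> np.ndarray:
        """Condition of each whole second, length floor(total duration)."""
        n = int(np.floor(self.total_duration))
        labels = np.empty(n, dtype="<U9")
        t = 0.0
        for cond, dur in self.segments:
            lo, hi = int(np.ceil(t - 1e-9)), min(n, int(np.ceil(t + dur - 1e-9)))
            labels[lo:hi] = cond
            t += dur
        return labels


def default_session_plan() -> SessionPlan:
    """The full-length protocol: 20 min neutral, 10 min stress, 6.5 min amusement."""
    return SessionPlan((("neutral", 1200.0), ("stress", 600.0), ("amusement", 390.0)))


def scaled_session_plan(total_seconds: float) -> SessionPlan:
    """Proportionally shrunk protocol with integer-second segments.

    Used for quick experiments; e.g. ``scaled_session_plan(360)`` gives the
    6-minute session (197 / 99 / 64 s) with the same neutral:stress:amusement
    proportions as the default plan.
    """
    f = total_seconds / 2190.0
    segs = [("neutral", round(1200 * f)), ("stress", round(600 * f)), ("amusement", round(390 * f))]
    return SessionPlan(tuple((c, float(d)) for c, d in segs))


@dataclass
class ParticipantProfile:
    """Per-participant physiological baselines and stress-response shape."""

    participant_id: int
    st_baseline: float = 33.5  # °C
    eda_tonic_baseline: float = 2.0  # µS
    heart_rate_baseline: float = 70.0  # beats/min
    stress_effect_scale: float = 1.0
    responder_type: str = "typical"
    noise_scales: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SCALES))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.participant_id < 1:
            raise ValueError("participant_id must be >= 1")
        if self.stress_effect_scale < 0:
            raise ValueError("stress_effect_scale must be >= 0")
        if not 40.0 <= self.heart_rate_baseline <= 200.0:
            raise ValueError("heart_rate_baseline must lie in [40, 200] bpm")
        if self.responder_type not in RESPONDER_FACTORS:
            raise ValueError(
                f"unknown responder_type {self.responder_type!r}; "
                f"expected one of {sorted(RESPONDER_FACTORS)}"
            )
        if any(v < 0 for v in self.noise_scales.values()):
            raise ValueError("noise_scales must be >= 0")


@dataclass
class Channel:
    sampling_rate: float
    samples: np.ndarray

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class SensorRecording:
    """One participant's multi-rate channel set plus per-second condition labels."""

    participant_id: int
    channels: dict[str, Channel]
    labels: np.ndarray
    ground_truth: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return float(len(self.labels))


def _smooth_per_second(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width)
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return np.convolve(x, kernel, mode="same") / norm


def generate_participant(profile: ParticipantProfile, plan: SessionPlan) -> SensorRecording:
    """Simulate one participant's session; bit-reproducible under profile.rng_seed."""
    rng = np.random.default_rng(profile.rng_seed)
    labels = plan.per_second_labels()
    duration = float(len(labels))
    stress_sec = (labels == "stress").astype(float)
    eff = profile.stress_effect_scale * RESPONDER_FACTORS[profile.responder_type]
    noise = profile.noise_scales

    def sample_times(rate: float) -> np.ndarray:
        return np.arange(round(rate * duration)) / rate

    def stress_at(t: np.ndarray) -> np.ndarray:
        return stress_sec[np.minimum(t.astype(int), len(labels) - 1)]

    channels: dict[str, Channel] = {}

    # --- skin temperature -------------------------------------------------
    t_st = sample_times(SAMPLING_RATES["ST"])
    st = (
        profile.st_baseline
        + ST_SESSION_DRIFT * (t_st / duration)
        + ST_STRESS_DELTA * eff * stress_at(t_st)
        + rng.normal(0.0, noise["ST"], t_st.size)
    )
    channels["ST"] = Channel(SAMPLING_RATES["ST"], st)

    # --- electrodermal activity ------------------------------------------
    t_eda = sample_times(SAMPLING_RATES["EDA"])
    tonic = profile.eda_tonic_baseline + EDA_TONIC_STRESS_DELTA * eff * stress_at(t_eda)
    rate_per_sec = np.maximum(
        0.0, (SCR_RATE_NEUTRAL + SCR_RATE_STRESS_DELTA * eff * stress_sec) / 60.0
    )
    counts = rng.poisson(rate_per_sec)
    scr_times = np.sort(
        np.concatenate([s + rng.random(c) for s, c in enumerate(counts) if c > 0])
        if counts.sum() > 0
        else np.empty(0)
    )
    amplitudes = SCR_AMPLITUDE * rng.uniform(0.7, 1.3, scr_times.size)
    eda = tonic.copy()
    fs = SAMPLING_RATES["EDA"]
    kernel_len = int(20 * fs)  # truncate SCR shape at 20 s
    for te, amp in zip(scr_times, amplitudes):
        i0 = int(np.ceil(te * fs))
        tk = t_eda[i0 : i0 + kernel_len] - te
        eda[i0 : i0 + kernel_len] += amp * (1 - np.exp(-tk / SCR_RISE_TAU)) * np.exp(
            -tk / SCR_DECAY_TAU
        )
    eda += rng.normal(0.0, noise["EDA"], eda.size)
    channels["EDA"] = Channel(fs, eda)

    # --- blood volume pulse ----------------------------------------------
    hr_sec = profile.heart_rate_baseline + HR_STRESS_DELTA * eff * stress_sec
    hr_smooth = _smooth_per_second(hr_sec, HR_SMOOTH_SECONDS)
    fs_bvp = SAMPLING_RATES["BVP"]
    n_bvp = round(fs_bvp * duration)
    hr_samples = np.repeat(hr_smooth, int(fs_bvp))[:n_bvp]
    phase = 2.0 * np.pi * np.cumsum(hr_samples / 60.0) / fs_bvp
    bvp = np.sin(phase) + rng.normal(0.0, noise["BVP"], n_bvp)
    channels["BVP"] = Channel(fs_bvp, bvp)

    # --- accelerometer ----------------------------------------------------
    fs_acc = SAMPLING_RATES["ACCx"]
    n_acc = round(fs_acc * duration)
    n_bursts = rng.poisson(ACC_BURST_RATE * duration / 60.0)
    burst_starts = np.sort(rng.uniform(0.0, duration, n_bursts))
    burst_mask = np.zeros(n_acc, dtype=bool)
    for b in burst_starts:
        i0 = int(b * fs_acc)
        burst_mask[i0 : i0 + int(ACC_BURST_DURATION * fs_acc)] = True
    sigma = noise["ACC"] * (1.0 + (ACC_BURST_GAIN - 1.0) * burst_mask)
    for axis, g in zip(("ACCx", "ACCy", "ACCz"), ACC_GRAVITY):
        channels[axis] = Channel(fs_acc, g + rng.normal(0.0, 1.0, n_acc) * sigma)

    return SensorRecording(
        participant_id=profile.participant_id,
        channels=channels,
        labels=labels,
        ground_truth={
            "profile": profile,
            "stress_effect": eff,
            "heart_rate_per_second": hr_smooth,
            "scr_times": scr_times,
            "scr_rate_per_second": rate_per_sec,
        },
    )


@dataclass
class CohortHeterogeneity:
    """Gaussian spreads of the participant profile around cohort centers."""

    st_baseline_sd: float = 0.4  # °C
    eda_baseline_sd: float = 0.8  # µS
    heart_rate_sd: float = 8.0  # bpm
    stress_scale_sd: float = 0.35


def generate_cohort(
    n_participants: int,
    heterogeneity: CohortHeterogeneity | None = None,
    atypical_fraction: float = 0.2,
    seed: int = 0,
    plan: SessionPlan | None = None,
    noise_scales: Mapping[str, float] | None = None,
) -> list[SensorRecording]:
    """Generate ``n_participants`` seeded recordings with heterogeneous profiles."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if not 0.0 <= atypical_fraction <= 1.0:
        raise ValueError("atypical_fraction must lie in [0, 1]")
    het = heterogeneity or CohortHeterogeneity()
    plan = plan or default_session_plan()
    rng = np.random.default_rng(seed)
    cohort = []
    for pid in range(1, n_participants + 1):
        profile = ParticipantProfile(
            participant_id=pid,
            st_baseline=rng.normal(33.5, het.st_baseline_sd),
            eda_tonic_baseline=max(0.3, rng.normal(2.0, het.eda_baseline_sd)),
            heart_rate_baseline=float(np.clip(rng.normal(70.0, het.heart_rate_sd), 45.0, 190.0)),
            stress_effect_scale=max(0.1, rng.normal(1.0, het.stress_scale_sd)),
            responder_type="atypical" if rng.random() < atypical_fraction else "typical",
            noise_scales=dict(noise_scales or DEFAULT_NOISE_SCALES),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append(generate_participant(profile, plan))
    return cohort
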
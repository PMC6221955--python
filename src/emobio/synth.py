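"""Synthetic two-group EEG cohorts with injectable band x cluster effects.

Each subject's continuous signal is the sum of three parts, per channel:

* 1/f^alpha background (FFT-shaped Gaussian noise),
* band-limited oscillations (band-passed Gaussian noise, one per band),
* white measurement noise.

A group effect multiplies the amplitude of one band's oscillation, in the
channels of one cluster, inside a chosen trial window (the cued imagery
period, the neutral period, or both), time-locked to the trial schedule.
The default effect set elevates theta and high-beta/gamma power in the
right parieto-occipital cluster during imagery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import yaml
from scipy import signal as sps
from scipy.fft import next_fast_len

from .bands import BANDS, get_band
from .montage import Montage, default_montage
from .recording import Recording
from .schedule import TrialSchedule, make_imagery_schedule

__all__ = [
    "GroupEffect",
    "CohortSpec",
    "simulate_subject",
    "simulate_cohort",
    "DEFAULT_EFFECTS",
]

GROUPS = ("asd", "td")


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative amplitude gain for (band, cluster) inside a window."""

    band: str
    cluster: str
    window: Literal["emotion", "neutral", "both"]
    gain: float

    def __post_init__(self) -> None:
        get_band(self.band)  # raises on unknown band
        if self.window not in ("emotion", "neutral", "both"):
            raise ValueError(f"unknown effect window {self.window!r}")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


DEFAULT_EFFECTS = (
    GroupEffect("theta", "C4", "emotion", 3.0),
    GroupEffect("high_beta", "C4", "emotion", 2.0),
    GroupEffect("gamma", "C4", "emotion", 2.0),
)


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: int = 17
    sampling_rate_hz: float = 250.0
    background_exponent: float = 1.0
    background_amplitude: float = 10.0  # standard deviation, microvolt
    oscillations: tuple[tuple[str, float], ...] = tuple((b, 2.0) for b in BANDS)
    oscillation_band_margin: float = 0.15
    group_effects: tuple[GroupEffect, ...] = DEFAULT_EFFECTS
    affected_group: str = "asd"
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        highest = max(get_band(name).high_hz for name, _ in self.oscillations)
        if self.sampling_rate_hz <= 2 * highest:
            raise ValueError(
                f"sampling rate {self.sampling_rate_hz} Hz must exceed twice the "
                f"highest band edge ({highest} Hz)"
            )
        if self.affected_group not in GROUPS:
            raise ValueError(f"affected_group must be one of {GROUPS}")
        for _name, amp in self.oscillations:
            if amp < 0:
                raise ValueError("oscillation amplitudes must be non-negative")

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_per_group": self.n_per_group,
            "sampling_rate_hz": self.sampling_rate_hz,
            "background_exponent": self.background_exponent,
            "background_amplitude": self.background_amplitude,
            "oscillations": [[n, a] for n, a in self.oscillations],
            "oscillation_band_margin": self.oscillation_band_margin,
            "group_effects": [
                {"band": e.band, "cluster": e.cluster, "window": e.window, "gain": e.gain}
                for e in self.group_effects
            ],
            "affected_group": self.affected_group,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "oscillations" in d:
            d["oscillations"] = tuple((n, float(a)) for n, a in d["oscillations"])
        if "group_effects" in d:
            d["group_effects"] = tuple(GroupEffect(**e) for e in d["group_effects"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _one_over_f(
    shape: tuple[int, int], exponent: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise rows with power spectral density ~ 1/f^exponent."""
    nchan, n = shape
    nfft = next_fast_len(n)  # pad away slow prime-length FFTs
    white = rng.standard_normal((nchan, nfft))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(nfft, d=1.0)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=nfft, axis=-1)[:, :n]
    sd = x.std(axis=-1, keepdims=True)
    return x * (amplitude / np.where(sd > 0, sd, 1.0))


def _narrowband(
    shape: tuple[int, int],
    band_name: str,
    rate: float,
    rng: np.random.Generator,
    margin: float = 0.0,
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise rows.

    ``margin`` insets the generation band by that fraction of its width on
    each side, keeping the oscillation's energy away from the band edges so
    analysis filters for neighbouring bands do not pick it up.
    """
    band = get_band(band_name)
    width = band.high_hz - band.low_hz
    lo = band.low_hz + margin * width
    hi = band.high_hz - margin * width
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)

# Window inside the imagery / neutral segments where effects apply,
# matching the feature-extraction windows (skips the cue-evoked response).
EFFECT_WINDOW_MS = (500.0, 3500.0)


def _effect_envelope(
    schedule: TrialSchedule, window: str, gain: float, n: int, rate: float
) -> np.ndarray:
    """Per-sample gain envelope: `gain` inside target windows, 1 elsewhere."""
    env = np.ones(n)
    targets = {"emotion": ("imagery",), "neutral": ("neutral",), "both": ("imagery", "neutral")}[
        window
    ]
    for trial in schedule.trials:
        t = trial.onset_ms
        for seg_label, dur in trial.segments:
            if seg_label in targets:
                lo = int(round((t + EFFECT_WINDOW_MS[0]) / 1000.0 * rate))
                hi = int(round((t + EFFECT_WINDOW_MS[1]) / 1000.0 * rate))
                env[max(lo, 0) : min(hi, n)] = gain
            t += dur
    return env


def _schedule_events(schedule: TrialSchedule, rate: float, n: int) -> list[tuple[str, int]]:
    events = []
    for trial in schedule.trials:
        t = trial.onset_ms
        for seg_label, dur in trial.segments:
            s = int(round(t / 1000.0 * rate))
            if 0 <= s < n:
                events.append((f"{trial.condition}/{seg_label}", s))
            t += dur
    return events


def simulate_subject(
    spec: CohortSpec,
    group: str,
    schedule: TrialSchedule,
    seed: int,
    montage: Montage | None = None,
) -> Recording:
    """Synthesize one subject's continuous recording for a trial schedule.

    Group effects are applied when ``group == spec.affected_group``, as a
    multiplicative gain on the targeted band oscillation in the targeted
    cluster channels, time-locked to the schedule.  Deterministic given
    (spec, group, schedule, seed).
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if len(schedule.trials) == 0:
        raise ValueError("schedule has no trials")
    montage = montage or default_montage()
    rate = spec.sampling_rate_hz
    n = int(round(schedule.total_duration_ms / 1000.0 * rate))
    rng = np.random.default_rng(seed)
    nchan = montage.n_channels

    data = _one_over_f((nchan, n), spec.background_exponent, spec.background_amplitude, rng)

    affected = group == spec.affected_group
    for band_name, base_amp in spec.oscillations:
        envs: dict[int, np.ndarray] = {}
        if affected:
            for eff in spec.group_effects:
                if eff.band != band_name:
                    continue
                env = _effect_envelope(schedule, eff.window, eff.gain, n, rate)
                for ci in montage.cluster_indices(eff.cluster):
                    envs[ci] = envs.get(ci, np.ones(n)) * env
        osc = _narrowband(
            (nchan, n), band_name, rate, rng, margin=spec.oscillation_band_margin
        ) * base_amp
        for ch, env in envs.items():
            osc[ch] *= env
        data += osc

    data += spec.noise_sd * rng.standard_normal((nchan, n))
    events = _schedule_events(schedule, rate, n)
    return Recording(data=data, rate_hz=rate, montage=montage, events=events)


def simulate_cohort(
    spec: CohortSpec,
    schedule: TrialSchedule | None = None,
    montage: Montage | None = None,
) -> list[tuple[Recording, str]]:
    """Simulate ``2 * n_per_group`` subjects; per-subject seeds derive from spec.seed.

    Uses the full imagery schedule by default (a fresh schedule per subject,
    seeded reproducibly).
    """
    montage = montage or default_montage()
    ss = np.random.SeedSequence(spec.seed)
    out: list[tuple[Recording, str]] = []
    children = ss.spawn(2 * spec.n_per_group)
    i = 0
    for group in GROUPS:
        for _ in range(spec.n_per_group):
            child = children[i]
            sched_seed, subj_seed = child.generate_state(2).tolist()
            sched = schedule if schedule is not None else make_imagery_schedule(sched_seed)
            rec = simulate_subject(spec, group, sched, subj_seed, montage=montage)
            out.append((rec, group))
            i += 1
    return out
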
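"""Filtering, referencing, epoching, artifact rejection and ERP averaging.

Both filters are applied forward-backward (zero phase): offline analysis
does not need causality and latency-sensitive features must not be phase
shifted.  The band-pass is FIR (windowed sinc), the notch is IIR
(Butterworth band-stop), mirroring common EEG practice.

ICA-based artifact removal is deliberately a no-op hook
(:func:`apply_artifact_removal`): the decomposition itself is an external,
published algorithm orthogonal to this pipeline; plug a callable in if you
need it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import Recording

__all__ = [
    "EpochSet",
    "bandpass",
    "notch",
    "rereference_average",
    "apply_artifact_removal",
    "epoch",
    "reject_bad_epochs",
    "baseline_correct",
    "compute_erp",
]

logger = logging.getLogger(__name__)

DEFAULT_BANDPASS = (1.0, 100.0)
DEFAULT_NOTCH = (47.5, 52.5)
DEFAULT_REJECT_ABS_UV = 100.0
DEFAULT_REJECT_PROB_Z = 5.0


@dataclass
class EpochSet:
    """Trials x channels x samples tensor with trial metadata.

    ``window_ms`` is relative to the locking event; sample ``s`` of a trial
    sits at ``round(start_ms * rate / 1000) + s`` samples from the event.
    Rejected trials stay in the tensor; ``rejected`` masks them out of
    downstream averaging.
    """

    tensor: np.ndarray
    rate_hz: float
    window_ms: tuple[float, float]
    conditions: np.ndarray  # (n_trials,) of str
    channel_names: tuple[str, ...]
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be trials x channels x samples")
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("window start must precede window end")
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.rejected is None:
            self.rejected = np.zeros(self.n_trials, dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if len(self.conditions) != self.n_trials or len(self.rejected) != self.n_trials:
            raise ValueError("per-trial metadata length mismatch")

    @property
    def n_trials(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_samples(self) -> int:
        return self.tensor.shape[2]

    def ms_to_index(self, t_ms: float) -> int:
        """In-epoch sample index of epoch-relative time ``t_ms`` (half-open)."""
        return _round_half_up((t_ms - self.window_ms[0]) * self.rate_hz / 1000.0)

    def copy(self) -> "EpochSet":
        return EpochSet(
            tensor=self.tensor.copy(),
            rate_hz=self.rate_hz,
            window_ms=self.window_ms,
            conditions=self.conditions.copy(),
            channel_names=self.channel_names,
            rejected=self.rejected.copy(),
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _check_band(low: float, high: float, rate: float) -> None:
    if not 0 < low < high < rate / 2:
        raise ValueError(
            f"band edges ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({rate / 2})"
        )


def bandpass(
    rec: Recording, low_hz: float = DEFAULT_BANDPASS[0], high_hz: float = DEFAULT_BANDPASS[1]
) -> Recording:
    """Zero-phase FIR band-pass; defaults 1-100 Hz.

    The tap count is chosen from the narrower transition band so that the
    single-pass stop-band attenuation reaches ~20 dB at 0.5x``low_hz`` and
    1.5x``high_hz``; filtfilt doubles that in power.
    """
    rate = rec.rate_hz
    _check_band(low_hz, high_hz, rate)
    trans = min(0.5 * low_hz, 0.5 * high_hz)
    numtaps = int(np.ceil(3.3 * rate / trans))
    # filtfilt needs signal longer than 3*numtaps; degrade gracefully
    max_taps = rec.n_samples // 3 - 1
    if numtaps > max_taps:
        warnings.warn(
            f"signal too short for {numtaps}-tap FIR; truncating to {max_taps} taps "
            "(transition bands will widen)",
            stacklevel=2,
        )
        numtaps = max_taps
    numtaps |= 1  # odd length -> type-I linear phase
    taps = sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=rate)
    out = sps.filtfilt(taps, [1.0], rec.data, axis=1)
    return rec.with_data(out)


def notch(
    rec: Recording, low_hz: float = DEFAULT_NOTCH[0], high_hz: float = DEFAULT_NOTCH[1]
) -> Recording:
    """Zero-phase IIR (Butterworth) band-stop; defaults 47.5-52.5 Hz."""
    _check_band(low_hz, high_hz, rec.rate_hz)
    sos = sps.butter(4, [low_hz, high_hz], btype="bandstop", fs=rec.rate_hz, output="sos")
    return rec.with_data(sps.sosfiltfilt(sos, rec.data, axis=1))


def rereference_average(rec: Recording) -> Recording:
    """Subtract the across-good-channel mean at every sample."""
    good = rec.good_channel_indices
    if len(good) < 2:
        raise ValueError("average reference needs at least 2 good channels")
    ref = rec.data[good].mean(axis=0, keepdims=True)
    return rec.with_data(rec.data - ref)


def apply_artifact_removal(rec: Recording, method=None) -> Recording:
    """Artifact-removal hook.

    ``method`` may be a callable ``Recording -> Recording`` (e.g. an ICA
    clean-up); the default is the identity.
    """
    if method is None:
        return rec
    return method(rec)


def epoch(rec: Recording, lock_label: str, start_ms: float, end_ms: float) -> EpochSet:
    """Cut trials locked to every event matching ``lock_label``.

    Matches the full event label or its segment part (after the last '/');
    the trial condition is taken from the label prefix when present.
    Windows are half-open ``[start, end)`` in ms relative to the event;
    trials whose window leaves the recording are dropped with a warning.
    """
    if start_ms >= end_ms:
        raise ValueError("start_ms must precede end_ms")
    rate = rec.rate_hz
    off_lo = _round_half_up(start_ms * rate / 1000.0)
    off_hi = _round_half_up(end_ms * rate / 1000.0)
    n_samp = off_hi - off_lo

    trials, conds = [], []
    n_dropped = 0
    for label, s in rec.events:
        seg = label.rsplit("/", 1)[-1]
        if label != lock_label and seg != lock_label:
            continue
        lo, hi = s + off_lo, s + off_hi
        if lo < 0 or hi > rec.n_samples:
            n_dropped += 1
            continue
        trials.append(rec.data[:, lo:hi])
        conds.append(label.rsplit("/", 1)[0] if "/" in label else "")
    if n_dropped:
        logger.warning("dropped %d event(s) whose window left the recording", n_dropped)

    tensor = (
        np.stack(trials) if trials else np.empty((0, rec.n_channels, max(n_samp, 1)))
    )
    return EpochSet(
        tensor=tensor,
        rate_hz=rate,
        window_ms=(start_ms, end_ms),
        conditions=np.array(conds, dtype=object),
        channel_names=rec.montage.channel_names,
    )


def _joint_log_prob(tensor: np.ndarray) -> np.ndarray:
    """Per-trial joint log-probability under per-channel Gaussian fits.

    The per-channel amplitude distribution is estimated from all trials'
    samples pooled; a trial's score is the mean log-density of its own
    samples, summed over channels.
    """
    mu = tensor.mean(axis=(0, 2), keepdims=True)
    sd = tensor.std(axis=(0, 2), keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = (tensor - mu) / sd
    logpdf = -0.5 * z**2 - np.log(sd) - 0.5 * np.log(2 * np.pi)
    return logpdf.mean(axis=2).sum(axis=1)


def reject_bad_epochs(
    ep: EpochSet,
    abs_uV: float = DEFAULT_REJECT_ABS_UV,
    prob_z: float = DEFAULT_REJECT_PROB_Z,
) -> EpochSet:
    """Flag extreme-value and improbable trials; data are kept, mask updated.

    A trial is rejected if any sample exceeds ``abs_uV`` in magnitude, or
    if its joint log-probability deviates more than ``prob_z`` standard
    deviations from the across-trial mean.
    """
    if abs_uV <= 0 or prob_z <= 0:
        raise ValueError("thresholds must be positive")
    out = ep.copy()
    if ep.n_trials == 0:
        return out
    extreme = np.abs(ep.tensor).max(axis=(1, 2)) > abs_uV

    jp = _joint_log_prob(ep.tensor)
    sd = jp.std()
    improbable = (
        np.abs(jp - jp.mean()) > prob_z * sd if sd > 0 else np.zeros(ep.n_trials, dtype=bool)
    )
    out.rejected = out.rejected | extreme | improbable
    return out


def baseline_correct(ep: EpochSet, base_start_ms: float, base_end_ms: float) -> EpochSet:
    """Subtract each trial/channel's mean over the baseline window."""
    lo, hi = ep.ms_to_index(base_start_ms), ep.ms_to_index(base_end_ms)
    if not (0 <= lo < hi <= ep.n_samples):
        raise ValueError(
            f"baseline [{base_start_ms}, {base_end_ms}) ms outside epoch window {ep.window_ms}"
        )
    out = ep.copy()
    out.tensor = out.tensor - out.tensor[:, :, lo:hi].mean(axis=2, keepdims=True)
    return out


def compute_erp(ep: EpochSet, condition: str) -> np.ndarray:
    """Mean over non-rejected trials of one condition (channels x samples)."""
    keep = (ep.conditions == condition) & ~ep.rejected
    if not keep.any():
        raise ValueError(f"no surviving trials for condition {condition!r}")
    return ep.tensor[keep].mean(axis=0)
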
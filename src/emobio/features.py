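"""Windowed, band-limited feature extraction.

Eight features per (trial, channel, band, window): three time/frequency
descriptors — mean Hilbert-envelope magnitude (``env``), mean
Teager-Kaiser energy (``teag``), mean instantaneous power (``pow``) — and
five non-linear descriptors (``sfi``, ``lyap``, ``corrdim``, ``apen``,
``sampen``) computed on delay embeddings of the band-filtered window.

Windows default to: baseline 500 ms before the instruction, and the
500-3500 ms stretch after the imagery and neutral triggers respectively.
Undefined values (too-short window, vanishing tolerance, no template
matches) are recorded as NaN sentinels and skipped, with counts logged, by
downstream averaging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BAND_ORDER, BANDS, BandDef
from .embedding import autocorr_lag
from .montage import Montage
from .nonlinear import nonlinear_profile
from .preprocess import EpochSet

__all__ = [
    "FEATURES",
    "TIMEFREQ_FEATURES",
    "NONLINEAR_FEATURES",
    "DEFAULT_WINDOWS",
    "WindowedFeatures",
    "band_filter",
    "feat_envelope",
    "feat_teager",
    "feat_power",
    "extract_all",
    "normalize_features",
]

logger = logging.getLogger(__name__)

TIMEFREQ_FEATURES = ("env", "teag", "pow")
NONLINEAR_FEATURES = ("sfi", "lyap", "corrdim", "apen", "sampen")
FEATURES = TIMEFREQ_FEATURES + NONLINEAR_FEATURES

# Epoch-relative windows (ms), for epochs locked to the instruction onset of
# the imagery task: instruction 1500 + preparation 1500 -> imagery trigger at
# 3000 ms; imagery 4000 -> neutral trigger at 7000 ms.  The analysis windows
# sit 500-3500 ms after each trigger; baseline is the 500 ms pre-instruction.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "baseline": (-500.0, 0.0),
    "emotion": (3500.0, 6500.0),
    "neutral": (7500.0, 10500.0),
}


def band_filter(x, band: BandDef, rate_hz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    if band.high_hz >= rate_hz / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist for rate {rate_hz} Hz")
    sos = sps.butter(4, [band.low_hz, band.high_hz], btype="bandpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def feat_envelope(x) -> float:
    """Mean magnitude of the analytic signal."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    return float(np.mean(np.abs(sps.hilbert(x))))


def feat_teager(x) -> float:
    """Mean Teager-Kaiser energy: psi[n] = x[n]^2 - x[n-1] x[n+1]."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("Teager operator needs at least 3 samples")
    return float(np.mean(x[1:-1] ** 2 - x[:-2] * x[2:]))


def feat_power(x) -> float:
    """Mean instantaneous power."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    return float(np.mean(x**2))


@dataclass
class WindowedFeatures:
    """Long-format feature table.

    Columns: subject, trial, channel, band, window, feature, value.
    """

    table: pd.DataFrame

    COLUMNS = ("subject", "trial", "channel", "band", "window", "feature", "value")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")

    @classmethod
    def concat(cls, parts: list["WindowedFeatures"]) -> "WindowedFeatures":
        return cls(pd.concat([p.table for p in parts], ignore_index=True))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WindowedFeatures":
        return cls(pd.read_csv(path))

    @property
    def subjects(self) -> list[str]:
        return sorted(self.table["subject"].unique())


def _series_features(
    x: np.ndarray, rate_hz: float, entropy_m: int, entropy_r: float, sfi_grid: int
) -> dict[str, float]:
    vals = {"env": feat_envelope(x), "teag": feat_teager(x), "pow": feat_power(x)}
    # embedding lag, capped so 3-D embeddings keep >= 100 states
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lag = autocorr_lag(x)
    lag = int(np.clip(lag, 1, max((len(x) - 100) // 2, 1)))
    nl = nonlinear_profile(
        x, rate_hz, lag, sfi_grid=sfi_grid, entropy_m=entropy_m, entropy_r=entropy_r
    )
    vals.update(nl)
    return vals


def extract_all(
    ep: EpochSet,
    montage: Montage,
    bands: list[BandDef] | None = None,
    windows: dict[str, tuple[float, float]] | None = None,
    channels: list[str] | None = None,
    subject: str = "s0",
    entropy_m: int = 2,
    entropy_r: float = 0.2,
    sfi_grid: int = 10,
) -> WindowedFeatures:
    """Extract all 8 features per (trial, channel, band, window).

    ``channels`` restricts extraction (e.g. to cluster channels only);
    rejected trials are skipped.  Values that cannot be computed are NaN.
    """
    bands = bands if bands is not None else [BANDS[b] for b in BAND_ORDER]
    windows = windows if windows is not None else DEFAULT_WINDOWS
    if channels is None:
        channels = list(ep.channel_names)
    ch_idx = [ep.channel_names.index(c) for c in channels]

    win_slices = {}
    for wname, (s_ms, e_ms) in windows.items():
        lo, hi = ep.ms_to_index(s_ms), ep.ms_to_index(e_ms)
        if not (0 <= lo < hi <= ep.n_samples):
            raise ValueError(f"window {wname} [{s_ms}, {e_ms}) ms outside epoch {ep.window_ms}")
        win_slices[wname] = slice(lo, hi)

    trials = np.flatnonzero(~ep.rejected)
    rows: list[tuple] = []
    n_nan = 0
    for band in bands:
        filtered = band_filter(ep.tensor[trials][:, ch_idx, :], band, ep.rate_hz)
        for wname, sl in win_slices.items():
            seg = filtered[:, :, sl]
            for ti, trial in enumerate(trials):
                for ci, chan in enumerate(channels):
                    vals = _series_features(
                        seg[ti, ci], ep.rate_hz, entropy_m, entropy_r, sfi_grid
                    )
                    for feat in FEATURES:
                        v = vals[feat]
                        if not np.isfinite(v):
                            n_nan += 1
                        rows.append((subject, int(trial), chan, band.name, wname, feat, v))
    if n_nan:
        logger.info("extract_all: %d undefined feature value(s) recorded as NaN", n_nan)
    return WindowedFeatures(pd.DataFrame(rows, columns=list(WindowedFeatures.COLUMNS)))


def normalize_features(wf: WindowedFeatures) -> WindowedFeatures:
    """Baseline-normalize the time/frequency features.

    ``env``/``teag``/``pow`` in the emotion and neutral windows are
    replaced by (window - baseline); the non-linear features keep their
    absolute values, bit-exactly.
    """
    t = wf.table
    if not (t["window"] == "baseline").any():
        raise ValueError("baseline window missing; cannot normalize")
    keys = ["subject", "trial", "channel", "band", "feature"]
    base = (
        t[t["window"] == "baseline"]
        .set_index(keys)["value"]
        .rename("baseline_value")
    )
    out = t.copy()
    is_tf = out["feature"].isin(TIMEFREQ_FEATURES) & (out["window"] != "baseline")
    if is_tf.any():
        sub = out.loc[is_tf]
        aligned = base.reindex(pd.MultiIndex.from_frame(sub[keys]))
        out.loc[is_tf, "value"] = sub["value"].to_numpy() - aligned.to_numpy()
    return WindowedFeatures(out)
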
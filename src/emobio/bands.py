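"""Frequency-band definitions used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BandDef", "BANDS", "BAND_ORDER", "get_band"]


@dataclass(frozen=True)
class BandDef:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges for {self.name}: [{self.low_hz}, {self.high_hz}]")


BAND_ORDER = ("theta", "alpha", "low_beta", "high_beta", "gamma")

BANDS: dict[str, BandDef] = {
    "theta": BandDef("theta", 4.0, 8.0),
    "alpha": BandDef("alpha", 8.0, 12.0),
    "low_beta": BandDef("low_beta", 12.0, 21.0),
    "high_beta": BandDef("high_beta", 21.0, 30.0),
    "gamma": BandDef("gamma", 30.0, 40.0),
}


def get_band(name: str) -> BandDef:
    try:
        return BANDS[name]
    except KeyError:
        raise ValueError(f"unknown frequency band {name!r}; known: {list(BANDS)}") from None
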
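"""Continuous multi-channel recording container."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage

__all__ = ["Recording"]


@dataclass
class Recording:
    """Continuous signal (channels x samples, microvolt) with event markers.

    Event labels follow the convention ``"<condition>/<segment>"`` (e.g.
    ``"happy/imagery"``); epoching matches either the full label or the
    bare segment name.
    """

    data: np.ndarray
    rate_hz: float
    montage: Montage
    events: list[tuple[str, int]] = field(default_factory=list)
    bad_channels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        n = self.data.shape[1]
        for label, s in self.events:
            if not 0 <= s < n:
                raise ValueError(f"event {label!r} at sample {s} outside recording of length {n}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def good_channel_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.montage.channel_names) if c not in self.bad_channels],
            dtype=int,
        )

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with the signal replaced."""
        return replace(self, data=data, events=list(self.events))
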
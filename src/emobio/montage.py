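"""Electrode montage: 64-channel 10-10 layout and feature clusters.

The default montage ships as an editable YAML file
(``emobio/data/default_montage.yaml``).  Channel positions are idealized
unit-sphere coordinates derived from the 10-10 label grammar; they are a
geometric stand-in, adequate for bookkeeping but not for source modelling.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["Montage", "default_montage", "load_montage"]

# Anterior-posterior arc angle (degrees from the vertex; negative = anterior)
# for each 10-10 row prefix.  T/TP/FT rows sit on the C/CP/FC arcs.
_ROW_ANGLE = {
    "Fp": -72.0, "AF": -54.0, "F": -36.0, "FC": -18.0, "FT": -18.0,
    "C": 0.0, "T": 0.0, "CP": 18.0, "TP": 18.0, "P": 36.0,
    "PO": 54.0, "O": 72.0, "I": 90.0,
}

_LABEL_RE = re.compile(r"^(Fp|AF|FC|FT|CP|TP|PO|F|C|T|P|O|I)(z|\d+)$")


def _label_position(label: str) -> np.ndarray:
    """Idealized unit-sphere position (x=right, y=anterior, z=up)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse 10-10 label: {label!r}")
    row, col = m.groups()
    ap = _ROW_ANGLE[row]
    if col == "z":
        lat = 0.0
    else:
        n = int(col)
        # odd indices are left, even right; T7/T8 count as C-row index 7/8
        if row in ("T", "TP", "FT"):
            n += 0  # label already carries the lateral index
        k = (n + 1) // 2
        lat = 22.5 * k * (1.0 if n % 2 == 0 else -1.0)
    arc = np.hypot(ap, lat)
    az = np.arctan2(np.deg2rad(lat), -np.deg2rad(ap)) if arc else 0.0
    arc = np.deg2rad(arc)
    return np.array([np.sin(arc) * np.sin(az), np.sin(arc) * np.cos(az), np.cos(arc)])


@dataclass(frozen=True)
class Montage:
    """Named channels with positions and named channel clusters."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit vectors
    clusters: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in montage")
        if self.positions.shape != (len(names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        known = set(names)
        for cid, chans in self.clusters.items():
            missing = set(chans) - known
            if missing:
                raise ValueError(f"cluster {cid} references unknown channels: {sorted(missing)}")
        flat = [c for chans in self.clusters.values() for c in chans]
        if len(flat) != len(set(flat)):
            raise ValueError("clusters must be pairwise disjoint")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def cluster_indices(self, cluster_id: str) -> np.ndarray:
        """Channel indices (into ``channel_names``) of one cluster."""
        chans = self.clusters[cluster_id]
        return np.array([self.index(c) for c in chans], dtype=int)

    @property
    def cluster_channels(self) -> tuple[str, ...]:
        """All channels belonging to any cluster, in montage order."""
        member = {c for chans in self.clusters.values() for c in chans}
        return tuple(c for c in self.channel_names if c in member)


def load_montage(path_or_dict) -> Montage:
    """Build a :class:`Montage` from a YAML file path or a parsed mapping."""
    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    names = tuple(cfg["channels"])
    positions = np.stack([_label_position(c) for c in names])
    clusters = {k: tuple(v) for k, v in cfg.get("clusters", {}).items()}
    return Montage(channel_names=names, positions=positions, clusters=clusters)


def default_montage() -> Montage:
    """The shipped 64-channel 10-10 montage with clusters C1, C2, C4, C5."""
    ref = importlib.resources.files("emobio.data") / "default_montage.yaml"
    cfg = yaml.safe_load(ref.read_text())
    return load_montage(cfg)
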
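"""File I/O: BrainVision and EDF recordings, epoch tensors, event sidecars.

Minimal, self-contained readers/writers (no external EEG library in the
runtime environment):

* BrainVision: ``.vhdr`` header + ``.vmrk`` markers + ``.eeg`` binary
  (IEEE float32, multiplexed) — lossless round trip up to float32.
* EDF: standard 256-byte headers, 16-bit samples, 1-second data records
  (integer sampling rates only).  EDF carries no event track here; events
  go to a ``.events.tsv`` sidecar.
* EpochSet: ``.npy`` tensor + JSON sidecar with labels, window and mask.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .montage import Montage, load_montage
from .preprocess import EpochSet
from .recording import Recording

__all__ = [
    "write_brainvision",
    "read_brainvision",
    "write_edf",
    "read_edf",
    "write_events_tsv",
    "read_events_tsv",
    "save_epochs",
    "load_epochs",
]


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

def write_brainvision(rec: Recording, basename) -> tuple[Path, Path, Path]:
    """Write ``<basename>.vhdr/.vmrk/.eeg``; returns the three paths."""
    base = Path(basename)
    vhdr, vmrk, eeg = base.with_suffix(".vhdr"), base.with_suffix(".vmrk"), base.with_suffix(".eeg")
    stem = base.name

    interval_us = 1e6 / rec.rate_hz
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.montage.channel_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for i, (label, sample) in enumerate(rec.events, start=2):
        # BrainVision marker positions are 1-based
        mlines.append(f"Mk{i}=Stimulus,{label},{sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)  # multiplexed: sample-major
    return vhdr, vmrk, eeg


def _parse_bv_sections(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
        elif "=" in line and current is not None:
            k, v = line.split("=", 1)
            current[k.strip()] = v.strip()
    return sections


def read_brainvision(vhdr_path, montage: Montage | None = None) -> Recording:
    """Read a BrainVision triplet written by :func:`write_brainvision`."""
    vhdr = Path(vhdr_path)
    sec = _parse_bv_sections(vhdr.read_text(encoding="utf-8"))
    common = sec["Common Infos"]
    if sec.get("Binary Infos", {}).get("BinaryFormat") != "IEEE_FLOAT_32":
        raise ValueError("only IEEE_FLOAT_32 BrainVision data is supported")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    n_chan = int(common["NumberOfChannels"])
    rate = 1e6 / float(common["SamplingInterval"])
    names = tuple(
        sec["Channel Infos"][f"Ch{i}"].split(",")[0] for i in range(1, n_chan + 1)
    )

    raw = np.fromfile(vhdr.parent / common["DataFile"], dtype="<f4")
    data = raw.reshape(-1, n_chan).T.astype(float)

    events: list[tuple[str, int]] = []
    msec = _parse_bv_sections((vhdr.parent / common["MarkerFile"]).read_text(encoding="utf-8"))
    for key in sorted(msec.get("Marker Infos", {}), key=lambda k: int(k[2:])):
        parts = msec["Marker Infos"][key].split(",")
        if parts[0] != "Stimulus":
            continue
        events.append((parts[1], int(parts[2]) - 1))

    if montage is None:
        montage = _positionless_montage(names)
    return Recording(data=data, rate_hz=rate, montage=montage, events=events)


def _positionless_montage(names: tuple[str, ...]) -> Montage:
    """Montage from labels alone (for files lacking geometry)."""
    try:
        return load_montage({"channels": list(names)})
    except ValueError:
        # non-10-10 labels: place everything at the vertex
        return Montage(
            channel_names=names,
            positions=np.tile([0.0, 0.0, 1.0], (len(names), 1)),
        )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> Path:
    """Write a plain EDF file (16-bit, 1-second records; integer rate only).

    Events are written to ``<path>.events.tsv`` since plain EDF has no
    annotation track.  The last record is zero-padded.
    """
    path = Path(path)
    rate = rec.rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1 s record
    n_chan = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    same = phys_max <= phys_min
    phys_max = np.where(same, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))  # local patient id
        fh.write(_edf_field("Startdate X X X X", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(256 * (1 + n_chan), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_records, 8))
        fh.write(_edf_field("1", 8))  # record duration, seconds
        fh.write(_edf_field(n_chan, 4))
        names = rec.montage.channel_names
        for n in names:
            fh.write(_edf_field(f"EEG {n}", 16))
        for _ in names:
            fh.write(_edf_field("AgAgCl electrode", 80))
        for _ in names:
            fh.write(_edf_field("uV", 8))
        for v in phys_min:
            fh.write(_edf_field(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            fh.write(_edf_field(f"{v:.6g}"[:8], 8))
        for _ in names:
            fh.write(_edf_field(dig_min, 8))
        for _ in names:
            fh.write(_edf_field(dig_max, 8))
        for _ in names:
            fh.write(_edf_field("", 80))  # prefiltering
        for _ in names:
            fh.write(_edf_field(spr, 8))
        for _ in names:
            fh.write(_edf_field("", 32))  # reserved

        scale = (phys_max - phys_min) / (dig_max - dig_min)
        padded = np.zeros((n_chan, n_records * spr))
        padded[:, : rec.n_samples] = rec.data
        digital = np.round((padded - phys_min[:, None]) / scale[:, None] + dig_min)
        digital = np.clip(digital, dig_min, dig_max).astype("<i2")
        for r in range(n_records):
            digital[:, r * spr : (r + 1) * spr].tofile(fh)

    write_events_tsv(rec.events, path.with_suffix(path.suffix + ".events.tsv"))
    return path


def read_edf(path, montage: Montage | None = None) -> Recording:
    """Read an EDF file written by :func:`write_edf` (plus events sidecar)."""
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(256)
        n_records = int(header[236:244])
        dur = float(header[244:252])
        n_chan = int(header[252:256])
        sig = fh.read(256 * n_chan)

        def fields(offset: int, width: int) -> list[str]:
            start = offset * n_chan
            return [
                sig[start + i * width : start + (i + 1) * width].decode("ascii").strip()
                for i in range(n_chan)
            ]

        labels = [s.removeprefix("EEG ").strip() for s in fields(0, 16)]
        phys_min = np.array([float(v) for v in fields(16 + 80 + 8, 8)], dtype=float)
        phys_max = np.array(
            [float(v) for v in fields(16 + 80 + 8 + 8, 8)], dtype=float
        )
        dig_min = np.array([float(v) for v in fields(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in fields(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError("heterogeneous per-signal rates are not supported")
        spr = spr[0]
        raw = np.fromfile(fh, dtype="<i2")

    raw = raw[: n_records * n_chan * spr].reshape(n_records, n_chan, spr)
    digital = np.concatenate([raw[r] for r in range(n_records)], axis=1).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    rate = spr / dur

    events_path = path.with_suffix(path.suffix + ".events.tsv")
    events = read_events_tsv(events_path) if events_path.exists() else []
    n = data.shape[1]
    events = [(lbl, s) for lbl, s in events if 0 <= s < n]
    if montage is None:
        montage = _positionless_montage(tuple(labels))
    return Recording(data=data, rate_hz=rate, montage=montage, events=events)


# ---------------------------------------------------------------------------
# events & epochs
# ---------------------------------------------------------------------------

def write_events_tsv(events: list[tuple[str, int]], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("label\tsample\n")
        for label, s in events:
            fh.write(f"{label}\t{s}\n")
    return path


def read_events_tsv(path) -> list[tuple[str, int]]:
    out = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            label, s = line.rstrip("\n").split("\t")
            out.append((label, int(s)))
    return out


def save_epochs(ep: EpochSet, basename) -> tuple[Path, Path]:
    base = Path(basename)
    npy = base.with_suffix(".npy")
    meta = base.with_suffix(".json")
    np.save(npy, ep.tensor)
    with open(meta, "w") as fh:
        json.dump(
            {
                "rate_hz": ep.rate_hz,
                "window_ms": list(ep.window_ms),
                "conditions": list(map(str, ep.conditions)),
                "channel_names": list(ep.channel_names),
                "rejected": ep.rejected.astype(int).tolist(),
            },
            fh,
        )
    return npy, meta


def load_epochs(basename) -> EpochSet:
    base = Path(basename)
    tensor = np.load(base.with_suffix(".npy"))
    with open(base.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return EpochSet(
        tensor=tensor,
        rate_hz=meta["rate_hz"],
        window_ms=tuple(meta["window_ms"]),
        conditions=np.array(meta["conditions"], dtype=object),
        channel_names=tuple(meta["channel_names"]),
        rejected=np.array(meta["rejected"], dtype=bool),
    )
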
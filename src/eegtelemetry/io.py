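"""File formats: the CSV recording dialect, the DMP1 packet binary, YAML config.

CSV dialect
    Comma-separated, UTF-8, header ``time_s`` followed by the montage
    labels in montage order, values in microvolts with >= 6 significant
    digits, plus an optional trailing ``condition`` column.  This layout
    is normative for the repository.

DMP1 binary
    Little-endian.  File magic ``DMP1`` (4 bytes), then packets back to
    back: seq uint16, flags uint8 (bit 0 = keyframe), n_samples uint8,
    24 × shift uint8; keyframe payload 24 × int32 (sign-extended 24-bit
    codes), delta payload n_samples × 24 × int16.  Payload symbols up to
    16 bits are stored in int16 without tighter bit-packing.  Truncated
    files raise :class:`PacketFormatError` naming the byte offset.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .adc import AdcConfig, RawRecording
from .codec import CodecConfig, Packet
from .synth import Montage, ProtocolSpec, SignalParams, default_montage
from .analysis import ClusterTestConfig

__all__ = [
    "CsvFormatError",
    "PacketFormatError",
    "write_csv",
    "read_csv",
    "write_packets",
    "read_packets",
    "RunConfig",
    "load_config",
]

MAGIC = b"DMP1"


class CsvFormatError(ValueError):
    pass


class PacketFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CSV recordings

def write_csv(rec: RawRecording, path: str | Path,
              with_condition: bool = True) -> None:
    """Write a recording as CSV (time_s, one µV column per channel[, condition])."""
    path = Path(path)
    # fixed-point time (µs precision) so late samples keep their spacing
    t = pd.Series(np.arange(rec.n_samples) / rec.fs).map(lambda v: f"{v:.6f}")
    data = {"time_s": t}
    for i, name in enumerate(rec.montage.names):
        data[name] = rec.samples[i] * 1e6
    df = pd.DataFrame(data)
    if with_condition:
        df["condition"] = rec.condition_labels
    df.to_csv(path, index=False, float_format="%.6g")


def read_csv(path: str | Path, montage: Montage | None = None,
             fs: float | None = None) -> RawRecording:
    """Read a recording written by :func:`write_csv`.

    The header must be ``time_s`` followed by the montage labels in montage
    order; values are microvolts.  The sampling rate is inferred from the
    time column unless given.
    """
    path = Path(path)
    if montage is None:
        montage = default_montage()
    try:
        df = pd.read_csv(path)
    except Exception as e:  # ragged rows, bad encoding …
        raise CsvFormatError(f"{path}: {e}") from e
    cols = list(df.columns)
    if not cols or cols[0] != "time_s":
        raise CsvFormatError(f"{path}: first column must be 'time_s', got {cols[:1]}")
    has_cond = cols[-1] == "condition"
    ch_cols = cols[1:-1] if has_cond else cols[1:]
    if tuple(ch_cols) != tuple(montage.names):
        raise CsvFormatError(
            f"{path}: channel columns do not match the montage "
            f"(expected {list(montage.names)}, got {ch_cols})")
    if fs is None:
        if len(df) < 2:
            raise CsvFormatError(f"{path}: cannot infer fs from {len(df)} rows")
        dt = np.diff(df["time_s"].to_numpy())
        if np.ptp(dt) > 1e-6:
            raise CsvFormatError(f"{path}: time column is not uniformly sampled")
        fs = 1.0 / dt[0]
    samples = df[list(ch_cols)].to_numpy().T * 1e-6
    cond = (df["condition"].to_numpy(dtype=object) if has_cond
            else np.full(len(df), "none", dtype=object))
    return RawRecording(montage=montage, fs=float(round(fs, 6)),
                        samples=samples, condition_labels=cond)


# ---------------------------------------------------------------------------
# DMP1 packet binary

def write_packets(packets: Sequence[Packet], path: str | Path,
                  n_channels: int = 24) -> None:
    """Serialize packets to the DMP1 binary format."""
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        for p in packets:
            if len(p.shifts) != n_channels:
                raise PacketFormatError("packet shift count must match channels")
            n_samp = 0 if p.keyframe else p.payload.shape[0]
            if n_samp > 255:
                raise PacketFormatError("n_samples exceeds uint8")
            fh.write(struct.pack("<HBB", p.seq, 1 if p.keyframe else 0, n_samp))
            fh.write(struct.pack(f"<{n_channels}B", *p.shifts))
            if p.keyframe:
                fh.write(np.asarray(p.payload, dtype="<i4").tobytes())
            else:
                sym = np.asarray(p.payload)
                if np.any(np.abs(sym) > 32767):
                    raise PacketFormatError("delta symbol does not fit int16")
                fh.write(sym.astype("<i2").tobytes())


def read_packets(path: str | Path, n_channels: int = 24) -> list[Packet]:
    """Read a DMP1 file; truncation raises with the offending byte offset."""
    path = Path(path)
    raw = path.read_bytes()
    if raw[:4] != MAGIC:
        raise PacketFormatError(f"{path}: bad magic {raw[:4]!r}, expected {MAGIC!r}")
    off = 4
    head = 4 + n_channels
    packets: list[Packet] = []
    while off < len(raw):
        if off + head > len(raw):
            raise PacketFormatError(f"{path}: truncated packet header at byte {off}")
        seq, flags, n_samp = struct.unpack_from("<HBB", raw, off)
        shifts = struct.unpack_from(f"<{n_channels}B", raw, off + 4)
        off += head
        keyframe = bool(flags & 1)
        nbytes = 4 * n_channels if keyframe else 2 * n_samp * n_channels
        if off + nbytes > len(raw):
            raise PacketFormatError(f"{path}: truncated packet payload at byte {off}")
        if keyframe:
            payload = np.frombuffer(raw, dtype="<i4", count=n_channels,
                                    offset=off).astype(np.int64)
        else:
            payload = np.frombuffer(raw, dtype="<i2", count=n_samp * n_channels,
                                    offset=off).astype(np.int32)
            payload = payload.reshape(n_samp, n_channels)
        off += nbytes
        packets.append(Packet(seq=seq, keyframe=keyframe, shifts=shifts,
                              payload=payload))
    return packets


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Validated bundle of all pipeline parameters."""

    adc: AdcConfig = field(default_factory=AdcConfig)
    codec: CodecConfig = field(default_factory=CodecConfig)
    filters: dict = field(default_factory=lambda: {"hp": "hp=1.0x4",
                                                   "lp": "lp=45x4",
                                                   "bs": "bs=46-54x6"})
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    signal: SignalParams = field(default_factory=SignalParams)
    cluster: ClusterTestConfig = field(default_factory=ClusterTestConfig)
    epoch_s: float = 30.0
    seed: int = 0


_SECTIONS = {
    "adc": AdcConfig,
    "codec": CodecConfig,
    "protocol": ProtocolSpec,
    "signal": SignalParams,
    "cluster": ClusterTestConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration with strict key validation."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    cfg = RunConfig()
    known = set(_SECTIONS) | {"filters", "epoch_s", "seed"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key, cls in _SECTIONS.items():
        if key in doc:
            section = doc[key] or {}
            valid = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
            bad = set(section) - valid
            if bad:
                raise ValueError(f"{path}: unknown keys {sorted(bad)} in '{key}'")
            if key == "signal" and "alpha_channels" in section:
                section["alpha_channels"] = tuple(section["alpha_channels"])
            setattr(cfg, key, cls(**section))
    if "filters" in doc:
        cfg.filters = dict(doc["filters"])
    if "epoch_s" in doc:
        cfg.epoch_s = float(doc["epoch_s"])
    if "seed" in doc:
        cfg.seed = int(doc["seed"])
    return cfg
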
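"""Model of the 24-bit EEG acquisition front end.

The acquisition chip digitizes each channel with a delta-sigma converter
referenced to ``vref`` volts behind a programmable gain amplifier (PGA).
The bipolar input range is ±vref/gain and one least-significant bit (LSB)
corresponds to ``2*vref/gain / 2**bits`` volts.  Codes are signed
two's-complement integers centered on 0 V; out-of-range voltages saturate
to full scale, as a real converter does.

All public functions take voltages in volts and return integer codes (or
vice versa); nothing in this module ever touches microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AdcConfig",
    "RawRecording",
    "lsb_volts",
    "input_range_volts",
    "volts_to_code",
    "code_to_volts",
    "requantize",
]

_VALID_GAINS = (1, 2, 4, 8)
_VALID_BITS = (10, 14, 16, 24)

#: Condition labels carried alongside samples.
CONDITIONS = ("eyes_closed", "eyes_open", "none")


@dataclass(frozen=True)
class AdcConfig:
    """Converter configuration: reference voltage, PGA gain and bit depth.

    Parameters
    ----------
    vref : float
        Reference voltage in volts (default 2.5).
    gain : int
        PGA gain, one of 1, 2, 4, 8.  Higher gain trades input range
        (±vref/gain) for finer resolution.
    bits : int
        Converter resolution; 24 is the native depth, 10/14/16 are the
        reduced depths used for transmission and storage.
    """

    vref: float = 2.5
    gain: int = 1
    bits: int = 24

    def __post_init__(self) -> None:
        if not (self.vref > 0):
            raise ValueError(f"vref must be positive, got {self.vref}")
        if self.gain not in _VALID_GAINS:
            raise ValueError(f"gain must be one of {_VALID_GAINS}, got {self.gain}")
        if self.bits not in _VALID_BITS:
            raise ValueError(f"bits must be one of {_VALID_BITS}, got {self.bits}")

    @property
    def n_codes(self) -> int:
        """Number of representable codes, ``2**bits``."""
        return 1 << self.bits

    @property
    def code_min(self) -> int:
        return -(1 << (self.bits - 1))

    @property
    def code_max(self) -> int:
        return (1 << (self.bits - 1)) - 1


@dataclass
class RawRecording:
    """A multichannel recording in physical units.

    ``samples`` is a channels × time float array in **volts**;
    ``condition_labels`` tags every sample with the behavioural condition
    (``eyes_closed`` / ``eyes_open`` / ``none``).
    """

    montage: "object"  # synth.Montage; duck-typed to avoid a hard import cycle
    fs: float
    samples: np.ndarray
    condition_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.montage is not None and len(self.montage) != self.samples.shape[0]:
            raise ValueError(
                f"channel count {self.samples.shape[0]} does not match montage "
                f"size {len(self.montage)}"
            )
        if not (self.fs > 0):
            raise ValueError("fs must be positive")
        if self.condition_labels is None:
            self.condition_labels = np.full(self.samples.shape[1], "none", dtype=object)
        self.condition_labels = np.asarray(self.condition_labels, dtype=object)
        if self.condition_labels.shape != (self.samples.shape[1],):
            raise ValueError("condition_labels must have one entry per sample")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "RawRecording":
        return RawRecording(
            montage=self.montage,
            fs=self.fs,
            samples=self.samples.copy(),
            condition_labels=self.condition_labels.copy(),
        )


def lsb_volts(cfg: AdcConfig) -> float:
    """Voltage step of one LSB: ``(2 * vref / gain) / 2**bits``.

    At vref = 2.5 V, gain 1 and 24 bits this is ≈ 0.298 µV; gain 8 brings
    it down to ≈ 0.037 µV at the cost of input range.
    """
    return (2.0 * cfg.vref / cfg.gain) / cfg.n_codes


def input_range_volts(cfg: AdcConfig) -> tuple[float, float]:
    """Bipolar input span ``(-vref/gain, +vref/gain)`` in volts."""
    half = cfg.vref / cfg.gain
    return (-half, half)


def _round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest integer, ties away from zero (symmetric in sign)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def volts_to_code(cfg: AdcConfig, v: float | Sequence[float] | np.ndarray):
    """Quantize voltage(s) to signed integer codes, saturating at full scale.

    Rounds half away from zero so positive and negative inputs are treated
    symmetrically.  Non-finite inputs raise ``ValueError``.
    """
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("voltage input must be finite")
    codes = _round_half_away(arr / lsb_volts(cfg))
    codes = np.clip(codes, cfg.code_min, cfg.code_max)
    if np.isscalar(v) or arr.ndim == 0:
        return int(codes)
    return codes.astype(np.int64)


def code_to_volts(cfg: AdcConfig, code) -> float | np.ndarray:
    """Map signed code(s) back to volts (``code * lsb``).

    Raises on codes outside the signed range for ``cfg.bits``.
    """
    arr = np.asarray(code)
    if np.any(arr < cfg.code_min) or np.any(arr > cfg.code_max):
        raise ValueError(
            f"code out of range [{cfg.code_min}, {cfg.code_max}] for {cfg.bits}-bit config"
        )
    out = arr * lsb_volts(cfg)
    if np.isscalar(code) or arr.ndim == 0:
        return float(out)
    return out


def requantize(code24, target_bits: int):
    """Reduce 24-bit codes to 10/14/16-bit depth by arithmetic right shift.

    Pure truncation of the ``24 - target_bits`` low-order bits; no dithering.
    ``target_bits=24`` is the identity.  The inverse (upscaling) is a left
    shift that leaves the low bits zero.
    """
    if target_bits not in _VALID_BITS:
        raise ValueError(f"target_bits must be one of {_VALID_BITS}, got {target_bits}")
    shift = 24 - target_bits
    arr = np.asarray(code24)
    out = arr >> shift  # arithmetic shift: numpy int >> preserves sign
    if np.isscalar(code24) or arr.ndim == 0:
        return int(out)
    return out
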
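"""Butterworth IIR filter bank, decimation and the sweep-test harness.

The device samples at 500 Hz, filters, then downsamples to 250 Hz (or
167 Hz) for transmission.  The filter menu is fixed: a small set of
validated high-pass, low-pass and band-stop Butterworth designs, applied
causally per channel in the order HP -> LP -> BS.  Band-stop "order" is the
total polynomial order (an order-6 band-stop is a 3rd-order low-pass
prototype mirrored around the stop band).

Custom cutoffs outside the menu are possible only with ``unvalidated=True``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "FilterSpec",
    "FilterChain",
    "FILTER_MENU",
    "default_chain",
    "design",
    "apply_chain",
    "decimate",
    "sweep_attenuation",
]

logger = logging.getLogger("eegtelemetry.filters")

#: The validated filter menu: (kind, cutoff(s), order).
FILTER_MENU: dict[str, tuple] = {
    "hp=0.8x2": ("high_pass", 0.8, 2),
    "hp=1.0x4": ("high_pass", 1.0, 4),
    "hp=1.7x4": ("high_pass", 1.7, 4),
    "hp=1.7x2": ("high_pass", 1.7, 2),
    "lp=45x4": ("low_pass", 45.0, 4),
    "lp=60x6": ("low_pass", 60.0, 6),
    "bs=46-54x6": ("band_stop", (46.0, 54.0), 6),
    "bs=46-54x4": ("band_stop", (46.0, 54.0), 4),
    "bs=48-52x6": ("band_stop", (48.0, 52.0), 6),
    "bs=48-52x4": ("band_stop", (48.0, 52.0), 4),
    "off": ("off", None, 0),
}


@dataclass(frozen=True)
class FilterSpec:
    """One member of the filter menu (or ``off``)."""

    kind: str  # high_pass | low_pass | band_stop | off
    cutoff_hz: float | tuple[float, float] | None
    order: int

    @classmethod
    def from_name(cls, name: str) -> "FilterSpec":
        try:
            kind, cutoff, order = FILTER_MENU[name]
        except KeyError:
            raise ValueError(f"unknown filter preset {name!r}; choose from "
                             f"{sorted(FILTER_MENU)}") from None
        return cls(kind=kind, cutoff_hz=cutoff, order=order)

    @property
    def is_off(self) -> bool:
        return self.kind == "off"

    def in_menu(self) -> bool:
        key = (self.kind, self.cutoff_hz, self.order)
        return any(key == v for v in FILTER_MENU.values())


def design(spec: FilterSpec, fs_in: float, unvalidated: bool = False) -> np.ndarray:
    """Design a menu filter as second-order sections at rate ``fs_in``.

    Butterworth throughout; the cutoff frequency is the -3 dB point.  For
    band-stop designs ``spec.order`` is the total order, so the prototype
    order passed to the designer is ``order // 2``.
    """
    if spec.is_off:
        return np.empty((0, 6))
    if not spec.in_menu() and not unvalidated:
        raise ValueError(
            f"{spec} is not in the validated filter menu; pass unvalidated=True "
            "to design it anyway"
        )
    nyq = fs_in / 2.0
    cut = spec.cutoff_hz
    if spec.kind == "high_pass":
        if not (0 < cut < nyq):
            raise ValueError("cutoff must be below Nyquist")
        sos = signal.butter(spec.order, cut, btype="highpass", fs=fs_in, output="sos")
    elif spec.kind == "low_pass":
        if not (0 < cut < nyq):
            raise ValueError("cutoff must be below Nyquist")
        sos = signal.butter(spec.order, cut, btype="lowpass", fs=fs_in, output="sos")
    elif spec.kind == "band_stop":
        lo, hi = cut
        if not (0 < lo < hi < nyq):
            raise ValueError("band edges must be ordered and below Nyquist")
        if spec.order % 2:
            raise ValueError("band-stop total order must be even")
        sos = signal.butter(spec.order // 2, [lo, hi], btype="bandstop",
                            fs=fs_in, output="sos")
    else:
        raise ValueError(f"unknown filter kind {spec.kind!r}")
    _check_stable(sos)
    return sos


def _check_stable(sos: np.ndarray, margin: float = 1e-9) -> None:
    if sos.size == 0:
        return
    _, poles, _ = signal.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0 - margin):
        raise ValueError("designed filter is not strictly stable")


@dataclass(frozen=True)
class FilterChain:
    """A high-pass / low-pass / band-stop chain designed at ``fs_in``."""

    hp: FilterSpec
    lp: FilterSpec
    bs: FilterSpec
    fs_in: float = 500.0
    zero_phase: bool = False

    def __post_init__(self) -> None:
        # design eagerly so instability is caught at construction
        for sos in self.sections():
            _check_stable(sos)

    def sections(self) -> list[np.ndarray]:
        """SOS coefficient sets in application order HP -> LP -> BS."""
        return [design(s, self.fs_in) for s in (self.hp, self.lp, self.bs)
                if not s.is_off]

    def frequency_response(self, freqs: Sequence[float]) -> np.ndarray:
        """Complex composite response at the given frequencies (Hz)."""
        w = np.asarray(freqs, dtype=float)
        h = np.ones_like(w, dtype=complex)
        for sos in self.sections():
            _, hi = signal.sosfreqz(sos, worN=w, fs=self.fs_in)
            h *= hi
        return h


def default_chain(fs_in: float = 500.0, zero_phase: bool = False) -> FilterChain:
    """The default preprocessing chain: HP 1 Hz/4, LP 45 Hz/4, BS 46-54 Hz/6."""
    return FilterChain(
        hp=FilterSpec.from_name("hp=1.0x4"),
        lp=FilterSpec.from_name("lp=45x4"),
        bs=FilterSpec.from_name("bs=46-54x6"),
        fs_in=fs_in,
        zero_phase=zero_phase,
    )


def apply_chain(chain: FilterChain, x: np.ndarray, fs: float | None = None) -> np.ndarray:
    """Filter channels × time data through the chain.

    Causal (forward-only) by default, matching the streaming firmware;
    ``chain.zero_phase`` switches to forward-backward filtering for offline
    use.  Output has the same shape as the input.
    """
    if fs is not None and abs(fs - chain.fs_in) > 1e-9:
        raise ValueError(f"data rate {fs} Hz does not match chain design rate "
                         f"{chain.fs_in} Hz")
    y = np.atleast_2d(np.asarray(x, dtype=float))
    squeeze = np.asarray(x).ndim == 1
    for sos in chain.sections():
        if chain.zero_phase:
            y = signal.sosfiltfilt(sos, y, axis=-1)
        else:
            y = signal.sosfilt(sos, y, axis=-1)
    return y[0] if squeeze else y


def decimate(x: np.ndarray, target_fs: int, fs_in: float = 500.0,
             filtered: bool = True) -> np.ndarray:
    """Downsample 500 Hz data to 250 Hz (every 2nd) or 167 Hz (every 3rd sample).

    Sample index 0 is kept.  No extra anti-alias stage is applied here: the
    chain's low-pass (cutoff <= 60 Hz, far below the new Nyquist) is the
    anti-aliasing filter, so decimating unfiltered data logs a warning.
    """
    factors = {250: 2, 167: 3}
    if target_fs not in factors:
        raise ValueError(f"target rate must be one of {sorted(factors)}")
    if abs(fs_in - 500.0) > 1e-9:
        raise ValueError("decimation factors are defined for 500 Hz input")
    if not filtered:
        logger.warning("decimating unfiltered data: aliasing above %d Hz is "
                       "not suppressed", target_fs // 2)
        warnings.warn("decimating unfiltered data", stacklevel=2)
    return np.asarray(x)[..., ::factors[target_fs]]


def sweep_attenuation(chain_on: FilterChain | None,
                      chain_off: FilterChain | None = None,
                      f_lo: float = 1.0, f_hi: float = 70.0,
                      fs: float = 500.0, duration_s: float = 60.0,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Power ratio filtered/unfiltered of a linear sine sweep, per frequency.

    Injects a unit-amplitude linear chirp from ``f_lo`` to ``f_hi`` and
    returns ``(freqs, ratio)`` where ratio is the spectrogram power of the
    filtered sweep divided by the reference (chain_off, or the raw sweep
    when chain_off is None), evaluated at the instantaneous sweep frequency.
    """
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    sweep = signal.chirp(t, f0=f_lo, f1=f_hi, t1=duration_s, method="linear")

    y_on = apply_chain(chain_on, sweep) if chain_on is not None else sweep
    y_off = apply_chain(chain_off, sweep) if chain_off is not None else sweep

    # short-time power tracked along the sweep; each window is centred on a
    # known instantaneous frequency of the linear chirp
    win = int(round(fs))  # 1-s windows -> ~1.15 Hz of sweep per window
    hop = win // 2
    starts = np.arange(0, n - win + 1, hop)
    inst_freq = f_lo + (f_hi - f_lo) * (starts + win / 2) / n
    w = np.hanning(win)
    p_on = np.array([np.mean((y_on[s:s + win] * w) ** 2) for s in starts])
    p_off = np.array([np.mean((y_off[s:s + win] * w) ** 2) for s in starts])
    ratio = p_on / np.where(p_off > 0, p_off, np.inf)
    return inst_freq, ratio
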
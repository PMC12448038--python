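"""Adaptive delta-encoding telemetry codec with per-channel bit shift.

Raw samples are signed 24-bit ADC codes, but successive EEG samples are
strongly correlated, so only quantized *differences* are transmitted
(closed-loop DPCM: the encoder quantizes against its own reconstruction,
never the true previous sample, so quantization error never accumulates).
Each channel adapts a bit shift ``s`` once per statistics window (1 s by
default): the difference is transmitted as ``q = round(d / 2**s)`` in a
``payload_bits``-wide symbol, so larger shifts admit larger signal changes
at coarser resolution.  The shift is chosen so that a single change up to
``safety_factor`` times the recent standard deviation of the difference
signal fits without truncation; with the default safety factor 8 this
allocates 3 extra high-order bits beyond covering one standard deviation,
4 beyond the bits covering differences strictly below it.

Framing: every statistics window opens with a *keyframe* packet carrying
each channel's absolute 24-bit reconstruction state and the freshly
selected shifts, followed by delta packets of ``samples_per_packet``
symbols per channel.  Keyframes let the decoder resynchronize exactly
after packet loss; lost delta packets are bridged by holding the last
reconstructed value, and the affected samples are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CodecConfig",
    "ChannelState",
    "Packet",
    "StreamStats",
    "DecodeResult",
    "StreamError",
    "update_stats",
    "bits_needed",
    "select_shift",
    "encode_sample",
    "decode_sample",
    "encode_stream",
    "decode_stream",
    "loss_monitor",
    "stream_bits",
]

SEQ_MOD = 1 << 16  # sequence numbers are unsigned 16-bit and wrap


class StreamError(ValueError):
    """Raised on malformed or corrupted packet streams."""


@dataclass(frozen=True)
class CodecConfig:
    """Codec parameters.

    payload_bits
        Width b of one transmitted difference symbol (10, 14 or 16).
    safety_factor
        Multiplier f >= 1 on the per-second standard deviation: a single
        change up to f*sigma must be transmissible without truncation.
    max_shift
        Upper clamp on the adaptive shift; large jumps beyond what the
        clamp admits saturate ("peak clipping"), which mainly affects
        artifacts.
    stats_window_s, fs
        The shift is re-selected once per ``stats_window_s`` from the
        previous window's statistics at stream rate ``fs``.
    samples_per_packet
        Delta-packet frame size; 25 gives ten delta packets per second at
        250 Hz, so one lost packet costs at most 100 ms.
    """

    payload_bits: int = 16
    safety_factor: float = 8.0
    max_shift: int = 8
    stats_window_s: float = 1.0
    samples_per_packet: int = 25
    fs: float = 250.0

    def __post_init__(self) -> None:
        if self.payload_bits not in (10, 14, 16):
            raise ValueError("payload_bits must be 10, 14 or 16")
        if not (0 <= self.max_shift <= 24 - self.payload_bits + 1):
            raise ValueError(
                f"max_shift must be in [0, {24 - self.payload_bits + 1}]")
        if self.safety_factor < 1:
            raise ValueError("safety_factor must be >= 1")
        if self.samples_per_packet < 1 or self.stats_window_s <= 0 or self.fs <= 0:
            raise ValueError("invalid framing parameters")

    @property
    def symbol_max(self) -> int:
        """Largest transmissible symbol magnitude, ``2**(b-1) - 1``."""
        return (1 << (self.payload_bits - 1)) - 1

    @property
    def window_samples(self) -> int:
        return int(round(self.stats_window_s * self.fs))


@dataclass
class ChannelState:
    """Per-channel codec state shared by encoder and decoder.

    After every decoded packet of a loss-free stream the decoder's
    ``prev_recon`` is bit-identical to the encoder's.
    """

    prev_recon: int = 0
    running_mean: float = 0.0
    sigma: float = 0.0
    shift: int = 0
    saturations: int = 0


@dataclass(frozen=True)
class Packet:
    """One framed telemetry packet.

    Keyframes carry each channel's absolute 24-bit state (``payload`` shape
    ``(n_channels,)``); delta packets carry ``(n_samples, n_channels)``
    quantized difference symbols.  ``shifts`` always lists the per-channel
    shift in force.
    """

    seq: int
    keyframe: bool
    shifts: tuple[int, ...]
    payload: np.ndarray

    def __post_init__(self) -> None:
        if not (0 <= self.seq < SEQ_MOD):
            raise ValueError("seq must fit in unsigned 16 bits")

    @property
    def n_samples(self) -> int:
        return 0 if self.keyframe else self.payload.shape[0]


@dataclass
class StreamStats:
    """Packet-loss accounting from sequence-number arithmetic."""

    packets_expected: int = 0
    packets_received: int = 0
    recommendation: bool = False
    message: str = ""

    @property
    def loss_fraction(self) -> float:
        if self.packets_expected == 0:
            return 0.0
        return 1.0 - self.packets_received / self.packets_expected


@dataclass
class DecodeResult:
    """Decoded stream: 24-bit codes, per-sample loss flags and statistics."""

    codes: np.ndarray    # (n_channels, n_samples) int64
    flagged: np.ndarray  # (n_samples,) bool, True where reconstruction is unreliable
    stats: StreamStats


# ---------------------------------------------------------------------------
# shift selection

def bits_needed(limit: int) -> int:
    """Minimal magnitude bits representing every value in [0, limit].

    ``floor(log2(limit)) + 1`` for positive limits and 0 for limit 0.
    """
    limit = int(limit)
    if limit < 0:
        raise ValueError("limit must be non-negative")
    return limit.bit_length()


def select_shift(sigma: float, cfg: CodecConfig) -> int:
    """Shift s making a change of ``safety_factor * sigma`` transmissible.

    The symbol carries ``payload_bits - 1`` magnitude bits, so the shift is
    the number of extra high-order bits needed:
    ``clamp(bits_needed(round(f * sigma)) - (payload_bits - 1), 0, max_shift)``.
    Monotone non-decreasing in sigma and in the safety factor.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    target = int(math.floor(cfg.safety_factor * sigma + 0.5))
    s = bits_needed(target) - (cfg.payload_bits - 1)
    return max(0, min(cfg.max_shift, s))


def update_stats(state: ChannelState, window_codes: Sequence[int],
                 cfg: CodecConfig) -> ChannelState:
    """Refresh running mean, difference-signal sigma and shift from a window.

    ``sigma`` is the population standard deviation of the first differences
    within the window (the quantity the safety factor bounds is a single
    signal *change*).  An empty window leaves the state unchanged; a
    single-sample window has no differences, hence sigma 0.
    """
    w = np.asarray(window_codes, dtype=np.int64)
    if w.size == 0:
        return state
    mean = float(w.mean())
    sigma = float(np.diff(w).std()) if w.size > 1 else 0.0
    return replace(state, running_mean=mean, sigma=sigma,
                   shift=select_shift(sigma, cfg))


# ---------------------------------------------------------------------------
# single-sample reference operations

def _quantize(d: int, shift: int, qmax: int) -> int:
    """Round d / 2**shift half away from zero, saturated to ±qmax."""
    if shift == 0:
        q = d
    else:
        half = 1 << (shift - 1)
        q = (abs(d) + half) >> shift
        q = q if d >= 0 else -q
    return max(-qmax, min(qmax, q))


def encode_sample(state: ChannelState, code24: int,
                  cfg: CodecConfig) -> tuple[int, ChannelState]:
    """Encode one sample against the channel state (closed loop).

    Returns the quantized difference symbol and the updated state whose
    ``prev_recon`` is the encoder's own reconstruction — exactly what the
    decoder will hold after applying the symbol.
    """
    d = int(code24) - state.prev_recon
    q = _quantize(d, state.shift, cfg.symbol_max)
    saturated = abs(q) >= cfg.symbol_max and abs(d) > (cfg.symbol_max << state.shift)
    new = replace(state,
                  prev_recon=state.prev_recon + (q << state.shift),
                  saturations=state.saturations + int(saturated))
    return q, new


def decode_sample(state: ChannelState, symbol: int, shift: int,
                  cfg: CodecConfig) -> tuple[int, ChannelState]:
    """Reconstruct one sample: ``prev_recon + symbol * 2**shift``."""
    if abs(symbol) > cfg.symbol_max:
        raise StreamError(
            f"symbol {symbol} exceeds {cfg.payload_bits}-bit payload range")
    code = state.prev_recon + (int(symbol) << shift)
    return code, replace(state, prev_recon=code, shift=shift)


# ---------------------------------------------------------------------------
# stream loops (numba-accelerated when available)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=True)
    def _encode_window_nb(x, prev, shifts, qmax):  # type: ignore[misc]
        n, c = x.shape
        sym = np.zeros((n, c), dtype=np.int32)
        out_prev = prev.copy()
        nsat = 0
        for j in range(c):
            r = prev[j]
            s = shifts[j]
            half = (1 << (s - 1)) if s > 0 else 0
            for i in range(n):
                d = x[i, j] - r
                if s == 0:
                    q = d
                else:
                    q = (abs(d) + half) >> s
                    if d < 0:
                        q = -q
                if q > qmax:
                    q = qmax
                    nsat += 1
                elif q < -qmax:
                    q = -qmax
                    nsat += 1
                r += q << s
                sym[i, j] = q
            out_prev[j] = r
        return sym, out_prev, nsat

    @njit(cache=True)
    def _decode_window_nb(sym, prev, shifts):  # type: ignore[misc]
        n, c = sym.shape
        codes = np.zeros((n, c), dtype=np.int64)
        for j in range(c):
            r = prev[j]
            s = shifts[j]
            for i in range(n):
                r += np.int64(sym[i, j]) << s
                codes[i, j] = r
            prev[j] = r
        return codes

    def _encode_window(x, prev, shifts, qmax):
        sym, out_prev, nsat = _encode_window_nb(x, prev, shifts, np.int64(qmax))
        return sym, out_prev, int(nsat)

    def _decode_window(sym, prev, shifts):
        return _decode_window_nb(sym, prev, shifts)

except ImportError:  # pragma: no cover
    def _encode_window(x, prev, shifts, qmax):
        n = x.shape[0]
        sym = np.zeros_like(x, dtype=np.int32)
        out_prev = prev.copy()
        nsat = 0
        for j in range(x.shape[1]):
            r = int(prev[j])
            s = int(shifts[j])
            for i in range(n):
                q = _quantize(int(x[i, j]) - r, s, qmax)
                if abs(q) >= qmax and abs(int(x[i, j]) - r) > (qmax << s):
                    nsat += 1
                r += q << s
                sym[i, j] = q
            out_prev[j] = r
        return sym, out_prev, nsat

    def _decode_window(sym, prev, shifts):
        n, c = sym.shape
        codes = np.zeros((n, c), dtype=np.int64)
        for j in range(c):
            r = int(prev[j])
            s = int(shifts[j])
            for i in range(n):
                r += int(sym[i, j]) << s
                codes[i, j] = r
            prev[j] = r
        return codes


# ---------------------------------------------------------------------------
# stream encode / decode

def _window_shifts(window: np.ndarray, cfg: CodecConfig) -> np.ndarray:
    """Per-channel shift selected from a (n_channels, n) code window."""
    if window.shape[1] > 1:
        sig = np.diff(window, axis=1).std(axis=1)
    else:
        sig = np.zeros(window.shape[0])
    return np.asarray([select_shift(float(s), cfg) for s in sig], dtype=np.int64)


def encode_stream(codes: np.ndarray, cfg: CodecConfig = CodecConfig(),
                  n_channels: int = 24) -> list[Packet]:
    """Encode a (n_channels, n_samples) array of 24-bit codes into packets.

    Each statistics window opens with a keyframe holding the encoder's
    absolute reconstruction state and the shifts selected from the
    *previous* window (the first window uses its own statistics, the only
    place the encoder looks ahead).  All samples of the window — including
    the first — are then delta-encoded, ``samples_per_packet`` at a time.
    """
    codes = np.asarray(codes, dtype=np.int64)
    if codes.ndim != 2 or codes.shape[0] != n_channels:
        raise ValueError(f"expected a ({n_channels}, n) code array, got {codes.shape}")
    n = codes.shape[1]
    packets: list[Packet] = []
    if n == 0:
        return packets

    win = cfg.window_samples
    qmax = cfg.symbol_max
    prev = codes[:, 0].copy()  # bootstrap: state = first sample
    seq = 0
    prev_window: np.ndarray | None = None
    for start in range(0, n, win):
        window = codes[:, start:start + win]
        basis = window if prev_window is None else prev_window
        shifts = _window_shifts(basis, cfg)
        packets.append(Packet(seq=seq % SEQ_MOD, keyframe=True,
                              shifts=tuple(int(s) for s in shifts),
                              payload=prev.copy()))
        seq += 1
        for p0 in range(0, window.shape[1], cfg.samples_per_packet):
            chunk = window[:, p0:p0 + cfg.samples_per_packet].T.copy()  # (n, ch)
            sym, prev, _ = _encode_window(chunk, prev, shifts, qmax)
            packets.append(Packet(seq=seq % SEQ_MOD, keyframe=False,
                                  shifts=tuple(int(s) for s in shifts),
                                  payload=sym))
            seq += 1
        prev_window = window
    return packets


def _seq_gap(expected: int, got: int) -> int:
    return (got - expected) % SEQ_MOD


def decode_stream(packets: Sequence[Packet], cfg: CodecConfig = CodecConfig(),
                  n_channels: int = 24) -> DecodeResult:
    """Decode a possibly-gapped packet stream.

    Samples covered by lost delta packets are filled by holding each
    channel's last reconstructed value and flagged; after any loss the
    stream stays flagged until the next received keyframe restores the
    absolute state and shifts, from which point reconstruction is again
    exact.  Loss statistics come from sequence-number arithmetic.
    """
    if not packets:
        return DecodeResult(codes=np.zeros((n_channels, 0), dtype=np.int64),
                            flagged=np.zeros(0, dtype=bool),
                            stats=StreamStats())
    if not packets[0].keyframe:
        raise StreamError("stream must start with a keyframe")

    prev = np.zeros(n_channels, dtype=np.int64)
    shifts = np.zeros(n_channels, dtype=np.int64)
    synced = False
    chunks: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    expected = packets[0].seq
    received = 0
    for pkt in packets:
        gap = _seq_gap(expected, pkt.seq)
        if gap:
            # bridge lost delta packets with held values; keyframe-sized
            # holes carry no samples but still break synchrony
            n_lost_samples = gap * cfg.samples_per_packet  # worst case
            chunks.append(np.repeat(prev[:, None], n_lost_samples, axis=1))
            flags.append(np.ones(n_lost_samples, dtype=bool))
            synced = False
        expected = (pkt.seq + 1) % SEQ_MOD
        received += 1
        if pkt.keyframe:
            prev = np.asarray(pkt.payload, dtype=np.int64).copy()
            shifts = np.asarray(pkt.shifts, dtype=np.int64)
            synced = True
        else:
            sym = np.asarray(pkt.payload)
            if np.any(np.abs(sym) > cfg.symbol_max):
                raise StreamError("delta symbol exceeds payload range")
            codes = _decode_window(sym.astype(np.int32), prev,
                                   np.asarray(pkt.shifts, dtype=np.int64))
            chunks.append(codes.T)
            flags.append(np.full(sym.shape[0], not synced))

    out = np.concatenate(chunks, axis=1) if chunks else np.zeros((n_channels, 0),
                                                                 dtype=np.int64)
    flagged = np.concatenate(flags) if flags else np.zeros(0, dtype=bool)
    # expected count from first/last sequence numbers (wrap-aware)
    span = _seq_gap(packets[0].seq, packets[-1].seq) + 1
    stats = StreamStats(packets_expected=span, packets_received=received)
    return DecodeResult(codes=out, flagged=flagged, stats=stats)


def loss_monitor(stats: StreamStats, threshold: float = 0.01) -> StreamStats:
    """Flag a settings recommendation when loss exceeds the threshold.

    The recommendation mirrors the companion app's notification: when more
    than ``threshold`` of the packets are lost, suggest reducing the
    payload bit depth or the sampling rate.  Loss exactly at the threshold
    does not trigger (strict inequality).
    """
    loss = stats.loss_fraction
    if loss > threshold + 1e-12:  # strict inequality, robust to float rounding
        stats.recommendation = True
        stats.message = (
            f"{loss * 100:.1f}% of packets lost (threshold {threshold * 100:.1f}%): "
            "consider lowering the payload bit depth (16 -> 14 -> 10 bits) or "
            "the sampling rate (250 -> 167 Hz) to reduce bandwidth."
        )
    else:
        stats.recommendation = False
        stats.message = f"{loss * 100:.1f}% of packets lost; settings are adequate."
    return stats


def stream_bits(packets: Sequence[Packet], cfg: CodecConfig,
                n_channels: int = 24) -> int:
    """Conceptual transmitted size in bits (header + shifts + payload).

    Keyframe values count 24 bits each, delta symbols ``payload_bits``;
    headers count seq(16) + flags(8) + n_samples(8) + 8 bits per shift.
    """
    header = 16 + 8 + 8 + 8 * n_channels
    total = 0
    for p in packets:
        if p.keyframe:
            total += header + 24 * n_channels
        else:
            total += header + cfg.payload_bits * p.payload.size
    return total
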
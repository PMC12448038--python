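"""Synthetic eyes-open/eyes-closed EEG sessions on the 24-channel 10-20 montage.

The generator emulates the classical alpha-blocking validation protocol:
alternating two-minute blocks of eyes-closed and eyes-open rest, repeated
five times (20 minutes total).  Signal content is built additively per
channel:

* pink (1/f) background noise on every channel, always;
* an ~10 Hz alpha oscillation on occipital channels during eyes-closed
  blocks (attenuated by half on parietal channels, so the effect is
  spatially clustered rather than punctate);
* slow delta-band activity and smooth biphasic blink transients on the
  frontopolar channels during eyes-open blocks;
* optionally a common-phase mains sinusoid (50 Hz by default) everywhere.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SignalParams.seed``, so a fixed seed reproduces the recording bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .adc import RawRecording

__all__ = [
    "Montage",
    "ProtocolSpec",
    "SignalParams",
    "default_montage",
    "make_protocol",
    "generate",
    "add_line_noise",
    "add_blinks",
]

#: Channel order of the device's 24-channel 10-20 layout.
CHANNELS_1020 = (
    "FP1", "FPZ", "FP2", "F7", "F3", "FZ", "F4", "F8", "M1", "T7", "C3", "CZ",
    "C4", "T8", "M2", "P7", "P3", "PZ", "P4", "P8", "POZ", "O1", "OZ", "O2",
)

OCCIPITAL = ("POZ", "O1", "OZ", "O2")
PARIETAL = ("P3", "PZ", "P4")
FRONTOPOLAR = ("FP1", "FPZ", "FP2")


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels with schematic 2-D head-plane positions.

    Positions are on the unit-head-radius disc, x toward the right ear and
    y toward the nasion; they are schematic layout coordinates, not
    digitized electrode locations.
    """

    names: tuple[str, ...]
    positions: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.names) != len(set(self.names)):
            raise ValueError("montage channel names must be unique")
        if pos.shape != (len(self.names), 2):
            raise ValueError("positions must be an (n_channels, 2) array")
        r = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(r > 1.0 + 1e-9):
            raise ValueError("montage positions must lie within the unit disc")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels: Iterable[str]) -> list[int]:
        return [self.index(lb) for lb in labels]


def default_montage() -> Montage:
    """The 24-channel 10-20 montage shipped with the package."""
    text = resources.files("eegtelemetry.data").joinpath("montage_1020.tsv").read_text()
    names: list[str] = []
    pos: list[tuple[float, float]] = []
    for line in text.strip().splitlines()[1:]:
        label, x, y = line.split("\t")
        names.append(label)
        pos.append((float(x), float(y)))
    return Montage(names=tuple(names), positions=np.asarray(pos))


@dataclass(frozen=True)
class ProtocolSpec:
    """Alternating eyes-closed/eyes-open block timeline.

    Defaults give the standard validation session: five cycles of 2-minute
    eyes-closed then 2-minute eyes-open, 20 minutes total, starting with
    eyes closed.
    """

    block_s: float = 120.0
    n_cycles: int = 5
    first: str = "eyes_closed"

    def __post_init__(self) -> None:
        if self.block_s <= 0 or self.n_cycles <= 0:
            raise ValueError("block_s and n_cycles must be positive")
        if self.first not in ("eyes_closed", "eyes_open"):
            raise ValueError(f"unknown starting condition {self.first!r}")

    @property
    def total_s(self) -> float:
        return 2.0 * self.block_s * self.n_cycles


@dataclass(frozen=True)
class SignalParams:
    """Amplitudes and rates of the synthetic signal components.

    Amplitudes are in microvolts at the scalp; defaults are physiologically
    plausible resting-EEG magnitudes (alpha ~20 µV peak over occiput,
    ~10 µV RMS broadband background, ~100 µV blinks frontally).
    """

    alpha_hz: float = 10.0
    alpha_amp_uv: float = 20.0
    alpha_channels: tuple[str, ...] = OCCIPITAL + PARIETAL
    delta_amp_uv: float = 15.0
    blink_rate_hz: float = 0.25
    blink_amp_uv: float = 100.0
    pink_amp_uv: float = 10.0
    line_hz: float = 50.0
    line_amp_uv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_amp_uv", "delta_amp_uv", "blink_amp_uv",
                     "pink_amp_uv", "line_amp_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (8.0 <= self.alpha_hz <= 12.0):
            raise ValueError("alpha_hz must lie in the 8-12 Hz alpha band")
        if self.blink_rate_hz < 0:
            raise ValueError("blink_rate_hz must be non-negative")


def make_protocol(spec: ProtocolSpec, fs: float = 250.0) -> np.ndarray:
    """Per-sample condition labels for the block protocol at rate ``fs``.

    Returns an object array of length ``round(total_s * fs)`` alternating
    between the two conditions, starting with ``spec.first``.
    """
    n_block = int(round(spec.block_s * fs))
    second = "eyes_open" if spec.first == "eyes_closed" else "eyes_closed"
    labels = np.empty(2 * n_block * spec.n_cycles, dtype=object)
    for c in range(spec.n_cycles):
        a = 2 * c * n_block
        labels[a:a + n_block] = spec.first
        labels[a + n_block:a + 2 * n_block] = second
    return labels


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    # 1/sqrt(f) amplitude => 1/f power; flatten below 0.5 Hz to keep variance finite
    shaping[nz] = 1.0 / np.sqrt(np.maximum(f[nz], 0.5))
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz (FFT mask)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _blink_kernel(fs: float, width_s: float = 0.3) -> np.ndarray:
    """Smooth biphasic blink shape of ~width_s seconds, unit peak."""
    n = int(round(width_s * fs))
    t = np.linspace(0.0, 1.0, n)
    # dominant positive lobe followed by a small rebound, Hann-windowed
    shape = np.sin(np.pi * t) ** 2 - 0.3 * np.sin(2 * np.pi * t) * np.sin(np.pi * t)
    return shape / np.abs(shape).max()


def _condition_mask(labels: np.ndarray, condition: str) -> np.ndarray:
    return np.asarray([lb == condition for lb in labels], dtype=bool)


def generate(protocol: ProtocolSpec, montage: Montage, params: SignalParams,
             fs: float = 250.0) -> RawRecording:
    """Synthesize a full session as a :class:`RawRecording` in volts.

    The occipital members of ``params.alpha_channels`` carry the alpha
    oscillation at full amplitude during eyes-closed samples; parietal
    members carry it at half amplitude.  Frontopolar channels carry delta
    activity and blinks during eyes-open samples.  Identical parameters and
    seed produce identical output.
    """
    unknown = [c for c in params.alpha_channels if c not in montage.names]
    if unknown:
        raise ValueError(f"unknown alpha channels {unknown}")

    labels = make_protocol(protocol, fs)
    n = labels.size
    rng = np.random.default_rng(params.seed)
    uv = np.zeros((len(montage), n))

    # 1/f background on every channel
    for ch in range(len(montage)):
        uv[ch] += params.pink_amp_uv * _pink_noise(rng, n, fs)

    # occipital/parietal alpha during eyes-closed, with slow AM/FM jitter
    ec = _condition_mask(labels, "eyes_closed")
    if params.alpha_amp_uv > 0 and ec.any():
        freq_jitter = 0.2 * _bandlimited_noise(rng, n, fs, 0.0, 0.1)  # Hz
        phase = 2 * np.pi * np.cumsum(params.alpha_hz + freq_jitter) / fs
        am = 1.0 + 0.2 * _bandlimited_noise(rng, n, fs, 0.0, 0.2)
        alpha = np.sin(phase) * np.clip(am, 0.2, None)
        for lb in params.alpha_channels:
            weight = 0.5 if lb in PARIETAL else 1.0
            uv[montage.index(lb), ec] += params.alpha_amp_uv * weight * alpha[ec]

    # frontal delta random walk during eyes-open
    eo = _condition_mask(labels, "eyes_open")
    if params.delta_amp_uv > 0 and eo.any():
        for lb in FRONTOPOLAR:
            delta = _bandlimited_noise(rng, n, fs, 0.5, 4.0)
            uv[montage.index(lb), eo] += params.delta_amp_uv * delta[eo]

    rec = RawRecording(montage=montage, fs=fs, samples=uv * 1e-6,
                       condition_labels=labels)

    if params.blink_rate_hz > 0 and params.blink_amp_uv > 0:
        rec = add_blinks(rec, params.blink_rate_hz, params.blink_amp_uv,
                         rng=rng)
    if params.line_amp_uv > 0:
        rec = add_line_noise(rec, params.line_hz, params.line_amp_uv)
    return rec


def add_line_noise(rec: RawRecording, line_hz: float, amp_uv: float) -> RawRecording:
    """Add a common-phase mains sinusoid of ``amp_uv`` µV peak to all channels."""
    if line_hz >= rec.fs / 2:
        raise ValueError("line frequency must be below Nyquist")
    if amp_uv == 0:
        return rec
    out = rec.copy()
    t = np.arange(rec.n_samples) / rec.fs
    out.samples += (amp_uv * 1e-6) * np.sin(2 * np.pi * line_hz * t)[None, :]
    return out


def add_blinks(rec: RawRecording, rate_hz: float, amp_uv: float,
               channels: Sequence[str] = FRONTOPOLAR,
               rng: np.random.Generator | None = None,
               seed: int = 0) -> RawRecording:
    """Superimpose Poisson-placed blink transients on eyes-open spans.

    Blink onsets are a Poisson process of ``rate_hz`` restricted to samples
    labelled ``eyes_open``; each blink is a ~300 ms smooth biphasic
    transient, full amplitude on the given frontal channels only.
    """
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    if rate_hz == 0 or amp_uv == 0:
        return rec
    if rng is None:
        rng = np.random.default_rng(seed)
    out = rec.copy()
    eo_idx = np.flatnonzero(_condition_mask(rec.condition_labels, "eyes_open"))
    if eo_idx.size == 0:
        return out
    total_eo_s = eo_idx.size / rec.fs
    n_blinks = rng.poisson(rate_hz * total_eo_s)
    kernel = _blink_kernel(rec.fs)
    ch_idx = out.montage.indices(channels)
    onsets = rng.choice(eo_idx, size=n_blinks, replace=True) if n_blinks else []
    amp_v = amp_uv * 1e-6
    eo_mask = _condition_mask(rec.condition_labels, "eyes_open")
    for start in np.sort(onsets):
        stop = min(start + kernel.size, rec.n_samples)
        # truncate at the condition boundary so only eyes-open samples change
        seg = kernel[: stop - start] * eo_mask[start:stop]
        scale = amp_v * rng.uniform(0.7, 1.3)
        for ci in ch_idx:
            out.samples[ci, start:stop] += scale * seg
    return out
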
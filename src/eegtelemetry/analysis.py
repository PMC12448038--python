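"""Eyes-open/eyes-closed validation pipeline.

The analysis mirrors the classical alpha-blocking validation: exclude
noisy channels, cut each condition into 30-second epochs, estimate power
spectra with the multitaper FFT method, and compare conditions with an
independent-samples t map corrected for multiple comparisons by a
cluster-based permutation test over the channel × frequency grid
(Monte Carlo p-values from the permutation distribution of the maximum
cluster statistic).

t statistics are computed on log10 power: EEG band power is strongly
right-skewed and the log brings the two groups close to the equal-variance
Gaussian setting the pooled t assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import scipy.fft as sfft
from scipy import stats as sps
from scipy.signal import windows
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .adc import RawRecording
from .synth import Montage

__all__ = [
    "BANDS",
    "BandDef",
    "EpochSet",
    "SpectrumSet",
    "ClusterTestConfig",
    "Cluster",
    "ClusterResult",
    "exclude_noisy_channels",
    "epoch",
    "psd_multitaper",
    "band_power",
    "t_map",
    "channel_adjacency",
    "cluster_permutation",
    "effective_channels",
    "compare_pipelines",
]


@dataclass(frozen=True)
class BandDef:
    """A named frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise ValueError("band must satisfy lo < hi")


#: The canonical resting-EEG bands used throughout the analysis.
BANDS: Mapping[str, BandDef] = {
    "Delta": BandDef("Delta", 1.0, 4.0),
    "Theta": BandDef("Theta", 4.0, 8.0),
    "Alpha": BandDef("Alpha", 8.0, 12.0),
    "Beta": BandDef("Beta", 12.0, 30.0),
}


@dataclass
class EpochSet:
    """Equal-length epochs of one condition: (n_epochs, n_channels, n_times)."""

    condition: str
    epochs: np.ndarray
    fs: float
    epoch_s: float
    ch_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch, channel, time)")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class SpectrumSet:
    """Per-epoch multitaper power spectra in µV²/Hz."""

    power: np.ndarray  # (n_epochs, n_channels, n_freqs)
    freqs: np.ndarray
    ch_names: tuple[str, ...]
    n_tapers: int
    smoothing_hz: float

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass(frozen=True)
class ClusterTestConfig:
    """Knobs of the cluster-based permutation test.

    ``cluster_alpha`` is the (two-sided) tail probability whose critical t
    forms clusters; ``cluster_sig_alpha`` is the Monte Carlo significance
    level applied to cluster p-values.  Testing is restricted to
    ``fmin``–``fmax`` Hz (the union of the canonical bands).
    """

    cluster_alpha: float = 0.01
    cluster_sig_alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    fmin: float = 1.0
    fmax: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.cluster_alpha < 1 and 0 < self.cluster_sig_alpha < 1):
            raise ValueError("alphas must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


@dataclass
class Cluster:
    """One supra-threshold connected component of the t map."""

    members: list[tuple[int, int]]  # (channel index, frequency-bin index)
    stat: float                     # sum of member t-values
    p: float
    sign: int                       # +1 / -1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    freqs: np.ndarray
    ch_names: tuple[str, ...]
    significant_channels: tuple[str, ...]


# ---------------------------------------------------------------------------
# preprocessing

def exclude_noisy_channels(rec: RawRecording, z_threshold: float = 5.0
                           ) -> tuple[RawRecording, list[str]]:
    """Drop channels whose log-variance is an outlier, or which are flat.

    The z-score is robust — deviation of each channel's log variance from
    the across-channel median, scaled by 1.4826 × the median absolute
    deviation — so one or two broken channels cannot mask themselves.
    """
    if rec.n_channels < 4:
        raise ValueError("need at least 4 channels")
    var = rec.samples.var(axis=1)
    flat = var <= 0
    logvar = np.where(flat, -np.inf, np.log(np.where(flat, 1.0, var)))
    finite = logvar[~flat]
    med = np.median(finite)
    mad = np.median(np.abs(finite - med))
    # floor the scale: channel variances legitimately spread over a factor of
    # a few (alpha/blink topography), so deviations below ~e^1.75 from the
    # median must never be flagged even when the MAD is tiny
    scale = max(1.4826 * mad, 0.35)
    z = np.abs(logvar - med) / scale
    bad = flat | (z > z_threshold)
    if bad.all():
        raise ValueError("all channels were excluded as noisy")
    keep = np.flatnonzero(~bad)
    excluded = [rec.montage.names[i] for i in np.flatnonzero(bad)]
    sub = Montage(names=tuple(rec.montage.names[i] for i in keep),
                  positions=rec.montage.positions[keep])
    out = RawRecording(montage=sub, fs=rec.fs, samples=rec.samples[keep],
                       condition_labels=rec.condition_labels)
    return out, excluded


def epoch(rec: RawRecording, epoch_s: float = 30.0) -> dict[str, EpochSet]:
    """Cut each condition block into consecutive non-overlapping epochs.

    Epochs never span a condition boundary; partial tails of a block are
    discarded.  Returns one :class:`EpochSet` per condition present.
    """
    labels = rec.condition_labels
    n_ep_samp = int(round(epoch_s * rec.fs))
    # contiguous blocks of identical labels
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    per_cond: dict[str, list[np.ndarray]] = {}
    min_block = np.inf
    for a, b in zip(bounds[:-1], bounds[1:]):
        cond = labels[a]
        if cond == "none":
            continue
        min_block = min(min_block, b - a)
        for s in range(a, b - n_ep_samp + 1, n_ep_samp):
            per_cond.setdefault(cond, []).append(rec.samples[:, s:s + n_ep_samp])
    if min_block < n_ep_samp:
        raise ValueError(
            f"epoch length {epoch_s}s exceeds the shortest condition block "
            f"({min_block / rec.fs:.1f}s)")
    return {
        cond: EpochSet(condition=cond, epochs=np.stack(eps), fs=rec.fs,
                       epoch_s=epoch_s, ch_names=tuple(rec.montage.names))
        for cond, eps in per_cond.items()
    }


# ---------------------------------------------------------------------------
# spectra

@lru_cache(maxsize=8)
def _dpss_tapers(n: int, nw: float, k: int) -> np.ndarray:
    return windows.dpss(n, nw, Kmax=k)


def psd_multitaper(epochs: EpochSet, smoothing_hz: float = 1.0) -> SpectrumSet:
    """Multitaper power spectral density per epoch and channel, in µV²/Hz.

    DPSS tapers with half-bandwidth W = ``smoothing_hz``; the taper count
    is ``K = floor(2 T W) - 1`` (T the epoch length), the standard choice
    keeping only well-concentrated tapers.  Eigenspectra are averaged with
    equal weights; the one-sided density integrates to the signal variance.
    """
    n = epochs.epochs.shape[-1]
    t_len = n / epochs.fs
    nw = t_len * smoothing_hz
    k = int(np.floor(2 * nw)) - 1
    if k < 1:
        raise ValueError(
            f"smoothing {smoothing_hz} Hz is too small for {t_len:.1f}s epochs")
    tapers = _dpss_tapers(n, nw, k)  # (k, n), unit energy
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.fs)
    x_uv = epochs.epochs * 1e6  # volts -> µV
    power = np.empty((epochs.n_epochs, x_uv.shape[1], freqs.size))
    scale = np.full(freqs.size, 2.0 / epochs.fs)
    scale[0] = 1.0 / epochs.fs
    if n % 2 == 0:
        scale[-1] = 1.0 / epochs.fs
    n_ch = x_uv.shape[1]
    for e in range(epochs.n_epochs):
        tapered = x_uv[e][:, None, :] * tapers[None, :, :]   # (ch, k, n)
        spec = sfft.rfft(tapered.reshape(n_ch * k, n), axis=-1)
        eig = (spec.real**2 + spec.imag**2).reshape(n_ch, k, -1)
        power[e] = eig.mean(axis=1) * scale
    return SpectrumSet(power=power, freqs=freqs, ch_names=epochs.ch_names,
                       n_tapers=k, smoothing_hz=smoothing_hz)


def band_power(spec: SpectrumSet, band: BandDef) -> np.ndarray:
    """Integrated power over ``band.lo <= f < band.hi``, per epoch × channel."""
    if band.lo < spec.freqs[0] or band.hi > spec.freqs[-1] + 1e-9:
        raise ValueError(f"band {band.name} outside the spectral range")
    mask = (spec.freqs >= band.lo) & (spec.freqs < band.hi)
    df = spec.freqs[1] - spec.freqs[0]
    return spec.power[..., mask].sum(axis=-1) * df


# ---------------------------------------------------------------------------
# statistics

_LOG_FLOOR = 1e-30


def _pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t along axis 0 (cellwise)."""
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 epochs per group")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    sp2 = ((a - ma) ** 2).sum(axis=0) + ((b - mb) ** 2).sum(axis=0)
    sp2 = sp2 / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def t_map(spec_a: SpectrumSet, spec_b: SpectrumSet) -> np.ndarray:
    """Independent-samples t per (channel, frequency) cell on log10 power."""
    la = np.log10(np.maximum(spec_a.power, _LOG_FLOOR))
    lb = np.log10(np.maximum(spec_b.power, _LOG_FLOOR))
    return _pooled_t(la, lb)


def channel_adjacency(montage: Montage, radius: float = 0.4) -> np.ndarray:
    """Symmetric, irreflexive neighbour matrix: distance <= radius."""
    pos = montage.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = d <= radius
    np.fill_diagonal(adj, False)
    return adj


def _cluster_labels(mask: np.ndarray, ch_pairs: np.ndarray) -> np.ndarray:
    """Label connected components of a masked channel × frequency grid.

    Cells are connected along the frequency axis within a channel and
    across adjacent channels at the same frequency.  Returns an int array
    of the mask's shape, -1 outside the mask.
    """
    n_ch, n_f = mask.shape
    idx = -np.ones(mask.shape, dtype=np.int64)
    cells = np.flatnonzero(mask.ravel())
    if cells.size == 0:
        return idx
    node = -np.ones(n_ch * n_f, dtype=np.int64)
    node[cells] = np.arange(cells.size)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    # frequency-neighbour edges within each channel
    h = mask[:, :-1] & mask[:, 1:]
    r, c = np.nonzero(h)
    rows.append(node[r * n_f + c])
    cols.append(node[r * n_f + c + 1])
    # channel-neighbour edges at the same frequency
    for a, b in ch_pairs:
        both = mask[a] & mask[b]
        f = np.flatnonzero(both)
        rows.append(node[a * n_f + f])
        cols.append(node[b * n_f + f])
    row = np.concatenate(rows)
    col = np.concatenate(cols)
    graph = coo_matrix((np.ones(row.size, dtype=np.int8), (row, col)),
                       shape=(cells.size, cells.size))
    _, labels = connected_components(graph, directed=False)
    idx.ravel()[cells] = labels
    return idx


def _signed_clusters(t: np.ndarray, tcrit: float, ch_pairs: np.ndarray
                     ) -> list[tuple[np.ndarray, float, int]]:
    """Positive and negative supra-threshold clusters of a t map."""
    out = []
    for sign in (1, -1):
        mask = (sign * t) > tcrit
        labels = _cluster_labels(mask, ch_pairs)
        for lb in range(labels.max() + 1):
            cells = np.argwhere(labels == lb)
            stat = float(t[labels == lb].sum())
            out.append((cells, stat, sign))
    return out


def _max_cluster_stat(t: np.ndarray, tcrit: float, ch_pairs: np.ndarray) -> float:
    best = 0.0
    for _, stat, _ in _signed_clusters(t, tcrit, ch_pairs):
        best = max(best, abs(stat))
    return best


def cluster_permutation(spec_a: SpectrumSet, spec_b: SpectrumSet,
                        adjacency: np.ndarray,
                        cfg: ClusterTestConfig = ClusterTestConfig()
                        ) -> ClusterResult:
    """Cluster-based permutation test of condition differences.

    Cellwise |t| values exceeding the two-sided critical value at
    ``cluster_alpha`` are grouped into connected clusters (channel
    neighbours × adjacent frequency bins); each cluster's statistic is the
    sum of its member t-values, and its Monte Carlo p-value is the fraction
    of label permutations whose *maximum* |cluster statistic| reaches it
    (with the +1/+1 correction, so p is never exactly 0).  Deterministic
    under a fixed ``cfg.seed``.
    """
    if spec_a.ch_names != spec_b.ch_names:
        raise ValueError("spectra must share channels")
    if not np.allclose(spec_a.freqs, spec_b.freqs):
        raise ValueError("spectra must share the frequency grid")
    fsel = (spec_a.freqs >= cfg.fmin) & (spec_a.freqs <= cfg.fmax)
    freqs = spec_a.freqs[fsel]
    la = np.log10(np.maximum(spec_a.power[..., fsel], _LOG_FLOOR))
    lb = np.log10(np.maximum(spec_b.power[..., fsel], _LOG_FLOOR))
    na, nb = la.shape[0], lb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 epochs per group")
    n_ch, n_f = la.shape[1], la.shape[2]
    ch_pairs = np.argwhere(np.triu(adjacency, 1))

    df = na + nb - 2
    tcrit = float(sps.t.ppf(1.0 - cfg.cluster_alpha / 2.0, df))
    t_obs = _pooled_t(la, lb)
    observed = _signed_clusters(t_obs, tcrit, ch_pairs)

    # permutation distribution of the maximum |cluster statistic|
    x = np.concatenate([la, lb], axis=0).reshape(na + nb, -1)
    x2 = x ** 2
    rng = np.random.default_rng(cfg.seed)
    null_max = np.empty(cfg.n_permutations)
    inv_n = 1.0 / na + 1.0 / nb
    tot_s = x.sum(axis=0)
    tot_ss = x2.sum(axis=0)
    for p in range(cfg.n_permutations):
        sel = rng.permutation(na + nb)[:na]
        sa = x[sel].sum(axis=0)
        ssa = x2[sel].sum(axis=0)
        sb = tot_s - sa
        ssb = tot_ss - ssa
        sp2 = (ssa - sa**2 / na + ssb - sb**2 / nb) / df
        denom = np.sqrt(np.maximum(sp2, 0.0) * inv_n)
        with np.errstate(divide="ignore", invalid="ignore"):
            tp = np.where(denom > 0, (sa / na - sb / nb) / denom, 0.0)
        null_max[p] = _max_cluster_stat(tp.reshape(n_ch, n_f), tcrit, ch_pairs)

    clusters = []
    for cells, stat, sign in observed:
        pval = (1.0 + np.sum(null_max >= abs(stat))) / (cfg.n_permutations + 1.0)
        clusters.append(Cluster(members=[tuple(c) for c in cells],
                                stat=stat, p=float(pval), sign=sign))
    clusters.sort(key=lambda c: c.p)
    sig = _member_channels(clusters, cfg.cluster_sig_alpha, spec_a.ch_names)
    return ClusterResult(clusters=clusters, t_map=t_obs, freqs=freqs,
                         ch_names=spec_a.ch_names, significant_channels=sig)


def _member_channels(clusters: Sequence[Cluster], sig_alpha: float,
                     ch_names: Sequence[str]) -> tuple[str, ...]:
    chans: set[int] = set()
    for cl in clusters:
        if cl.p < sig_alpha:
            chans.update(c for c, _ in cl.members)
    return tuple(ch_names[i] for i in sorted(chans))


def effective_channels(result: ClusterResult, sig_alpha: float = 0.05
                       ) -> list[str]:
    """Channels belonging to any cluster with p below ``sig_alpha``,
    in montage order."""
    return list(_member_channels(result.clusters, sig_alpha, result.ch_names))


# ---------------------------------------------------------------------------
# end-to-end fidelity

def compare_pipelines(rec_clean: RawRecording, rec_processed: RawRecording,
                      band: BandDef = BANDS["Alpha"], epoch_s: float = 30.0
                      ) -> float:
    """Correlation of the condition-difference band-power topography.

    Computes, for each recording, the per-channel eyes-closed minus
    eyes-open mean band power, and returns the Pearson correlation of the
    two topographies across channels.  Identical recordings give r = 1;
    heavy codec truncation pushes r down.
    """
    if tuple(rec_clean.montage.names) != tuple(rec_processed.montage.names):
        raise ValueError("recordings must share the montage")

    def topo(rec: RawRecording) -> np.ndarray:
        sets = epoch(rec, epoch_s)
        out = {}
        for cond, es in sets.items():
            bp = band_power(psd_multitaper(es), band)
            out[cond] = bp.mean(axis=0)
        return out["eyes_closed"] - out["eyes_open"]

    a, b = topo(rec_clean), topo(rec_processed)
    return float(np.corrcoef(a, b)[0, 1])
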
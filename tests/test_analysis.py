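import itertools

import numpy as np
import pytest
from scipy import stats as sps

from eegtelemetry import (BANDS, BandDef, ClusterTestConfig, EpochSet,
                          ProtocolSpec, RawRecording, SignalParams,
                          band_power, channel_adjacency, cluster_permutation,
                          compare_pipelines, effective_channels, epoch,
                          exclude_noisy_channels, generate, make_protocol,
                          psd_multitaper, t_map)
from eegtelemetry.analysis import SpectrumSet
from eegtelemetry.synth import Montage


def labelled_recording(montage, samples, fs=250.0, block_s=120.0, n_cycles=5):
    labels = make_protocol(ProtocolSpec(block_s=block_s, n_cycles=n_cycles), fs)
    return RawRecording(montage=montage, fs=fs, samples=samples[:, :labels.size],
                        condition_labels=labels)


def spectrum(power, freqs, names):
    return SpectrumSet(power=power, freqs=np.asarray(freqs, dtype=float),
                       ch_names=tuple(names), n_tapers=1, smoothing_hz=1.0)


class TestChannelExclusion:
    def test_clean_recording_keeps_everything(self, short_recording):
        _, excluded = exclude_noisy_channels(short_recording)
        assert excluded == []

    def test_loud_channel_dropped(self, short_recording, rng):
        rec = short_recording.copy()
        rec.samples[5] = 10 * rec.samples.std() * rng.standard_normal(rec.n_samples)
        out, excluded = exclude_noisy_channels(rec)
        assert excluded == [rec.montage.names[5]]
        assert out.n_channels == 23

    def test_flat_channel_dropped(self, short_recording):
        rec = short_recording.copy()
        rec.samples[0] = 0.0
        _, excluded = exclude_noisy_channels(rec)
        assert "FP1" in excluded

    def test_too_few_channels(self, montage):
        sub = Montage(names=montage.names[:3], positions=montage.positions[:3])
        rec = RawRecording(montage=sub, fs=250.0, samples=np.zeros((3, 100)))
        with pytest.raises(ValueError):
            exclude_noisy_channels(rec)


class TestEpoching:
    def test_default_protocol_gives_forty_epochs(self, montage, rng):
        rec = labelled_recording(montage, rng.standard_normal((24, 300000)))
        sets = epoch(rec, 30.0)
        assert sum(s.n_epochs for s in sets.values()) == 40
        assert sets["eyes_closed"].n_epochs == sets["eyes_open"].n_epochs == 20

    def test_partial_tails_discarded(self, montage, rng):
        # 100-s blocks hold three 30-s epochs; 10-s tails are dropped
        rec = labelled_recording(montage, rng.standard_normal((24, 300000)),
                                 block_s=100.0, n_cycles=2)
        sets = epoch(rec, 30.0)
        assert sets["eyes_closed"].n_epochs == 6
        assert sets["eyes_open"].n_epochs == 6

    def test_epoch_longer_than_block_rejected(self, montage, rng):
        rec = labelled_recording(montage, rng.standard_normal((24, 20000)),
                                 block_s=20.0, n_cycles=1)
        with pytest.raises(ValueError):
            epoch(rec, 30.0)

    def test_epochs_never_cross_boundaries(self, montage):
        fs = 100.0
        labels = make_protocol(ProtocolSpec(block_s=60, n_cycles=2), fs)
        # encode the condition as the sample value, then check epoch purity
        x = np.where(labels == "eyes_closed", 1.0, -1.0)[None, :].repeat(24, 0)
        rec = RawRecording(montage=None, fs=fs, samples=x,
                           condition_labels=labels)
        rec.montage = None
        sets = epoch_with_names(rec)
        for cond, es in sets.items():
            want = 1.0 if cond == "eyes_closed" else -1.0
            assert np.all(es.epochs == want)


def epoch_with_names(rec):
    # epoch() needs montage names; patch a minimal stand-in
    class _M:
        names = tuple(f"ch{i}" for i in range(rec.samples.shape[0]))

        def __len__(self):
            return rec.samples.shape[0]

    rec.montage = _M()
    return epoch(rec, 30.0)


class TestMultitaper:
    def make_epochs(self, x, fs=250.0):
        return EpochSet(condition="eyes_closed", epochs=x, fs=fs,
                        epoch_s=x.shape[-1] / fs,
                        ch_names=tuple(f"ch{i}" for i in range(x.shape[1])))

    def test_sine_power_recovered(self):
        fs, T = 250.0, 30.0
        amp_uv = 12.0
        t = np.arange(int(fs * T)) / fs
        x = (amp_uv * 1e-6) * np.sin(2 * np.pi * 10.0 * t)
        spec = psd_multitaper(self.make_epochs(x[None, None, :]))
        # integrate over the smoothing bandwidth around the peak
        sel = np.abs(spec.freqs - 10.0) <= 2.0
        df = spec.freqs[1] - spec.freqs[0]
        est = spec.power[0, 0, sel].sum() * df
        assert est == pytest.approx(amp_uv**2 / 2, rel=0.05)

    def test_white_noise_spectrum_flat(self, rng):
        fs = 250.0
        x = rng.standard_normal((20, 1, int(fs * 30))) * 1e-6
        spec = psd_multitaper(self.make_epochs(x))
        mean_spec = spec.power[:, 0, :].mean(axis=0)
        lo = mean_spec[(spec.freqs > 10) & (spec.freqs < 50)].mean()
        hi = mean_spec[(spec.freqs > 60) & (spec.freqs < 100)].mean()
        assert lo == pytest.approx(hi, rel=0.05)

    def test_zero_in_zero_out(self):
        spec = psd_multitaper(self.make_epochs(np.zeros((2, 3, 7500))))
        assert np.all(spec.power == 0)

    def test_taper_count(self):
        spec = psd_multitaper(self.make_epochs(np.zeros((1, 1, 7500))))
        assert spec.n_tapers == 59  # floor(2 * 30s * 1Hz) - 1

    def test_insufficient_smoothing_rejected(self):
        with pytest.raises(ValueError):
            psd_multitaper(self.make_epochs(np.zeros((1, 1, 250))), 0.01)


class TestBandPower:
    def test_partition_of_1_to_30(self, rng):
        freqs = np.arange(0, 125, 1 / 30)
        power = rng.random((4, 3, freqs.size))
        spec = spectrum(power, freqs, ["a", "b", "c"])
        total = sum(band_power(spec, b).sum() for b in BANDS.values())
        full = band_power(spec, BandDef("all", 1.0, 30.0)).sum()
        assert total == pytest.approx(full)

    def test_sine_alpha_exceeds_beta(self):
        fs = 250.0
        t = np.arange(int(fs * 30)) / fs
        x = 1e-5 * np.sin(2 * np.pi * 10.0 * t)
        es = EpochSet(condition="c", epochs=x[None, None, :], fs=fs,
                      epoch_s=30.0, ch_names=("O1",))
        spec = psd_multitaper(es)
        assert (band_power(spec, BANDS["Alpha"])[0, 0]
                > 100 * band_power(spec, BANDS["Beta"])[0, 0])

    def test_zero_spectrum(self):
        spec = spectrum(np.zeros((2, 2, 100)), np.linspace(0, 99, 100), ["a", "b"])
        assert np.all(band_power(spec, BANDS["Delta"]) == 0)

    def test_band_outside_range_rejected(self):
        spec = spectrum(np.ones((1, 1, 10)), np.linspace(0, 9, 10), ["a"])
        with pytest.raises(ValueError):
            band_power(spec, BandDef("hf", 40.0, 80.0))


class TestTMap:
    def test_identical_groups_give_zero(self, rng):
        p = rng.random((6, 4, 5))
        sa = spectrum(p, np.arange(5), list("abcd"))
        sb = spectrum(p.copy(), np.arange(5), list("abcd"))
        assert np.allclose(t_map(sa, sb), 0)

    def test_matches_textbook_pooled_formula(self, rng):
        a = rng.random((3, 1, 1)) + 0.5
        b = rng.random((3, 1, 1)) + 0.1
        la, lb = np.log10(a[:, 0, 0]), np.log10(b[:, 0, 0])
        # hand evaluation of the pooled two-sample t
        sp2 = (((la - la.mean())**2).sum() + ((lb - lb.mean())**2).sum()) / 4
        expect = (la.mean() - lb.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        got = t_map(spectrum(a, [1.0], ["x"]), spectrum(b, [1.0], ["x"]))[0, 0]
        assert got == pytest.approx(expect, abs=1e-10)

    def test_agrees_with_scipy(self, rng):
        a = 10 ** rng.standard_normal((8, 2, 3))
        b = 10 ** rng.standard_normal((9, 2, 3))
        got = t_map(spectrum(a, np.arange(3), ["x", "y"]),
                    spectrum(b, np.arange(3), ["x", "y"]))
        ref = sps.ttest_ind(np.log10(a), np.log10(b), axis=0).statistic
        assert np.allclose(got, ref)

    def test_swapping_groups_negates(self, rng):
        a = rng.random((5, 2, 2)) + 0.1
        b = rng.random((5, 2, 2)) + 0.1
        sa = spectrum(a, np.arange(2), ["x", "y"])
        sb = spectrum(b, np.arange(2), ["x", "y"])
        assert np.allclose(t_map(sa, sb), -t_map(sb, sa))


class TestAdjacency:
    def test_examples(self, montage):
        adj = channel_adjacency(montage)
        assert adj[montage.index("O1"), montage.index("OZ")]
        assert not adj[montage.index("FP1"), montage.index("O2")]

    def test_symmetric_irreflexive_connected(self, montage):
        adj = channel_adjacency(montage)
        assert np.array_equal(adj, adj.T)
        assert not adj.diagonal().any()
        assert adj.sum(axis=1).min() >= 1


def brute_force_max_cluster(x_all, na, tcrit, adj):
    """Independent oracle: t via scipy, clustering via DFS over cells."""
    a, b = x_all[:na], x_all[na:]
    t = sps.ttest_ind(a, b, axis=0).statistic
    n_ch, n_f = t.shape
    best = 0.0
    for sign in (1, -1):
        mask = sign * t > tcrit
        seen = set()
        for c0 in range(n_ch):
            for f0 in range(n_f):
                if not mask[c0, f0] or (c0, f0) in seen:
                    continue
                stack, comp = [(c0, f0)], []
                seen.add((c0, f0))
                while stack:
                    c, f = stack.pop()
                    comp.append((c, f))
                    for cn, fn in [(c, f - 1), (c, f + 1)] + [
                            (c2, f) for c2 in range(n_ch) if adj[c, c2]]:
                        if (0 <= fn < n_f and mask[cn, fn]
                                and (cn, fn) not in seen):
                            seen.add((cn, fn))
                            stack.append((cn, fn))
                best = max(best, abs(sum(t[c, f] for c, f in comp)))
    return best


class TestClusterPermutation:
    def small_adj(self):
        # 3 channels in a chain: 0-1, 1-2
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        return adj

    def test_deterministic_under_seed(self, rng):
        p = 10 ** rng.standard_normal((12, 3, 6))
        sa = spectrum(p[:6], np.linspace(1, 30, 6), list("abc"))
        sb = spectrum(p[6:], np.linspace(1, 30, 6), list("abc"))
        cfg = ClusterTestConfig(n_permutations=100, seed=3)
        r1 = cluster_permutation(sa, sb, self.small_adj(), cfg)
        r2 = cluster_permutation(sa, sb, self.small_adj(), cfg)
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]

    def test_monte_carlo_matches_exhaustive_on_tiny_instance(self, rng):
        # 4 vs 4 epochs: only C(8,4)=70 label splits exist, so the full
        # permutation distribution can be enumerated exactly
        na = nb = 4
        x = rng.standard_normal((na + nb, 3, 4))
        x[:na, 1, 1:3] += 2.5  # a genuine effect on channel 1
        power = 10.0 ** x
        freqs = np.linspace(2, 20, 4)
        sa = spectrum(power[:na], freqs, list("abc"))
        sb = spectrum(power[na:], freqs, list("abc"))
        adj = self.small_adj()
        cfg = ClusterTestConfig(cluster_alpha=0.05, n_permutations=2000, seed=0)
        res = cluster_permutation(sa, sb, adj, cfg)
        assert res.clusters, "the planted effect must form a cluster"
        tcrit = sps.t.ppf(1 - cfg.cluster_alpha / 2, na + nb - 2)

        null = [brute_force_max_cluster(x[list(sel) + [i for i in range(8)
                                                       if i not in sel]],
                                        na, tcrit, adj)
                for sel in itertools.combinations(range(8), na)]
        null = np.asarray(null)
        for cl in res.clusters[:2]:
            p_exact = null[null >= abs(cl.stat) - 1e-9].size / null.size
            se = np.sqrt(max(p_exact * (1 - p_exact), 1e-4) / cfg.n_permutations)
            assert cl.p == pytest.approx(p_exact, abs=max(3 * se, 2 / 2000))

    def test_null_data_yields_no_small_p(self, rng):
        p = 10 ** rng.standard_normal((16, 3, 8))
        sa = spectrum(p[:8], np.linspace(1, 29, 8), list("abc"))
        sb = spectrum(p[8:], np.linspace(1, 29, 8), list("abc"))
        res = cluster_permutation(sa, sb, self.small_adj(),
                                  ClusterTestConfig(n_permutations=200, seed=1))
        assert all(c.p > 0 for c in res.clusters)

    def test_effective_channels_empty_without_clusters(self, rng):
        p = np.ones((8, 3, 4)) + 0.001 * rng.random((8, 3, 4))
        sa = spectrum(p[:4], np.linspace(1, 30, 4), list("abc"))
        sb = spectrum(p[4:], np.linspace(1, 30, 4), list("abc"))
        res = cluster_permutation(sa, sb, self.small_adj(),
                                  ClusterTestConfig(n_permutations=100, seed=0))
        if not res.clusters:
            assert effective_channels(res) == []


class TestComparePipelines:
    def test_identical_inputs_give_unit_correlation(self, short_recording):
        assert compare_pipelines(short_recording, short_recording) == pytest.approx(1.0)

    def test_mismatched_montages_rejected(self, short_recording, montage):
        sub = Montage(names=montage.names[:23], positions=montage.positions[:23])
        rec = RawRecording(montage=sub, fs=250.0,
                           samples=short_recording.samples[:23],
                           condition_labels=short_recording.condition_labels)
        with pytest.raises(ValueError):
            compare_pipelines(short_recording, rec)
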
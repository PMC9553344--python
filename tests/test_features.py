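"""Subband reconstruction, fuzzy entropy, and feature-matrix mechanics."""

from __future__ import annotations

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from eegchansel import (
    DEFAULT_BANDS,
    FuzzyEntropyParams,
    WPDConfig,
    epoch_std,
    fe_features,
    fuse,
    fuzzy_entropy,
    read_feature_matrix,
    subband_std_features,
    unfuse,
    wpd_subband_signals,
    write_feature_matrix,
)
from eegchansel.errors import ConfigError, DataError, FusionError
from eegchansel.features import wpd_leaf_coefficients

from conftest import small_epochs
from oracles import band_energy_fractions_fft, fuzzy_entropy_bruteforce

FS = 128.0


class TestEpochStd:
    def test_known_values(self):
        assert epoch_std([5.0, 5.0, 5.0]) == 0.0
        assert epoch_std([0.0, 2.0]) == 1.0

    def test_unit_variance_draw(self, rng):
        x = rng.standard_normal(1000)
        assert 0.9 < epoch_std(x) < 1.1

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            epoch_std([])


class TestWPD:
    @pytest.mark.parametrize(
        "freq,band", [(6.0, "Theta"), (10.0, "Alpha"), (16.0, "Beta1"), (25.0, "Beta2")]
    )
    def test_pure_tone_lands_in_its_band(self, freq, band):
        t = np.arange(int(FS)) / FS
        sig = np.sin(2 * np.pi * freq * t + 0.3)
        recon = wpd_subband_signals(sig, FS)
        energies = {k: np.sum(v**2) for k, v in recon.items()}
        frac = energies[band] / sum(energies.values())
        assert frac >= 0.9
        # FFT oracle agrees the reconstruction is concentrated in-band
        fracs = band_energy_fractions_fft(recon[band], FS, DEFAULT_BANDS)
        assert fracs[band] >= 0.9

    def test_zero_epoch_gives_zero_bands(self):
        recon = wpd_subband_signals(np.zeros(128), FS)
        for v in recon.values():
            assert np.all(v == 0)

    def test_two_tone_separation(self):
        t = np.arange(int(FS)) / FS
        sig = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 25 * t)
        recon = wpd_subband_signals(sig, FS)
        for band, f0 in [("Alpha", 10.0), ("Beta2", 25.0)]:
            fracs = band_energy_fractions_fft(recon[band], FS, DEFAULT_BANDS)
            assert fracs[band] >= 0.8

    def test_reconstruction_length_matches_epoch(self, rng):
        sig = rng.standard_normal(128)
        for v in wpd_subband_signals(sig, FS).values():
            assert len(v) == 128

    def test_leaf_energy_conservation(self, rng):
        sig = rng.standard_normal(128)
        leaves = wpd_leaf_coefficients(sig, FS)
        assert len(leaves) == 2**6
        e = sum(np.sum(l**2) for l in leaves)
        assert abs(e - np.sum(sig**2)) / np.sum(sig**2) < 1e-6

    def test_band_leaves_disjoint_and_inside_nyquist(self):
        cfg = WPDConfig()
        ranges = cfg.band_leaf_indices(FS)
        claimed = [i for r in ranges.values() for i in r]
        assert len(claimed) == len(set(claimed))
        assert max(claimed) < 2**cfg.levels

    def test_misaligned_band_edge_rejected(self):
        cfg = WPDConfig(bands={"odd": (4.25, 8.0)})
        with pytest.raises(ConfigError):
            cfg.band_leaf_indices(FS)

    def test_short_epoch_rejected(self, rng):
        with pytest.raises(DataError):
            wpd_subband_signals(rng.standard_normal(32), FS)

    def test_matches_pywt_wavelet_packet(self, rng):
        """Batched tree equals the reference WaveletPacket reconstruction."""
        cfg = WPDConfig()
        sig = rng.standard_normal(128)
        ours = wpd_subband_signals(sig, FS, cfg)
        wp = pywt.WaveletPacket(sig, cfg.wavelet, mode=cfg.mode, maxlevel=cfg.levels)
        paths = [n.path for n in wp.get_level(cfg.levels, order="freq")]
        for band, leaf_range in cfg.band_leaf_indices(FS).items():
            ref = pywt.WaveletPacket(None, cfg.wavelet, mode=cfg.mode, maxlevel=cfg.levels)
            for i in leaf_range:
                ref[paths[i]] = wp[paths[i]].data
            np.testing.assert_allclose(
                ours[band], ref.reconstruct(update=False)[:128], atol=1e-10
            )


class TestSubbandStdFeatures:
    def test_shapes_and_labels(self):
        es = small_epochs(n_epochs=6, n_channels=4)
        mats = subband_std_features(es)
        assert set(mats) == set(DEFAULT_BANDS)
        for fm in mats.values():
            assert fm.values.shape == (6, 4)
            assert np.array_equal(fm.labels, es.labels)

    def test_zero_signal_gives_zero_features(self):
        es = small_epochs(n_epochs=3, n_channels=2)
        es.epochs[:] = 0.0
        mats = subband_std_features(es)
        for fm in mats.values():
            assert np.all(fm.values == 0)

    def test_amplitude_scaling_is_exactly_linear(self):
        es = small_epochs(n_epochs=4, n_channels=3, seed=7)
        doubled = small_epochs(n_epochs=4, n_channels=3, seed=7)
        doubled.epochs[:, 1, :] *= 2.0
        a = subband_std_features(es)["Theta"].values
        b = subband_std_features(doubled)["Theta"].values
        np.testing.assert_allclose(b[:, 1], 2.0 * a[:, 1], rtol=1e-12)
        np.testing.assert_array_equal(b[:, 0], a[:, 0])


class TestFuzzyEntropy:
    def test_constant_sequence_is_exactly_zero(self):
        assert fuzzy_entropy(np.full(50, 3.0)) == 0.0

    def test_alternating_sequence_matches_bruteforce(self):
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], dtype=float)
        expected = fuzzy_entropy_bruteforce(x)
        assert fuzzy_entropy(x) == pytest.approx(expected, abs=1e-12)

    def test_noise_exceeds_sine(self, rng):
        noise = rng.standard_normal(200)
        sine = np.sin(2 * np.pi * np.arange(200) / 20.0)  # 20 samples/cycle
        assert fuzzy_entropy(noise) > fuzzy_entropy(sine)

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            fuzzy_entropy([1.0, 2.0, 3.0])  # m=2 needs >= 4 samples

    def test_absolute_tolerance_mode(self, rng):
        x = rng.standard_normal(50)
        p_abs = FuzzyEntropyParams(r_mode="absolute")
        got = fuzzy_entropy(x, p_abs)
        want = fuzzy_entropy_bruteforce(x, relative=False)
        assert got == pytest.approx(want, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=30), st.integers(0, 10))
    def test_nonnegative_and_scale_invariant(self, vals, scale_pick):
        x = np.asarray(vals)
        fe = fuzzy_entropy(x)
        assert fe >= 0.0
        c = [0.5, 2.0, -3.0, 7.5, 0.01, 100.0, -0.2, 11.0, 1e3, 1e-3, 5.0][scale_pick]
        assert fuzzy_entropy(c * x) == pytest.approx(fe, rel=1e-8, abs=1e-9)


class TestFeFeatures:
    def test_shape_and_constant_channel(self):
        es = small_epochs(n_epochs=5, n_channels=3)
        es.epochs[:, 2, :] = 4.2
        fm = fe_features(es)
        assert fm.values.shape == (5, 3)
        assert np.all(fm.values[:, 2] == 0.0)
        assert np.all(fm.values[:, :2] > 0)

    def test_label_conditional_means_invariant_to_shuffling(self, rng):
        es = small_epochs(n_epochs=8, n_channels=2, seed=3)
        fm = fe_features(es)
        perm = rng.permutation(8)
        es2 = small_epochs(n_epochs=8, n_channels=2, seed=3)
        es2.epochs = es2.epochs[perm]
        es2.labels = es2.labels[perm]
        fm2 = fe_features(es2)
        for lab in (0, 1):
            np.testing.assert_allclose(
                fm.values[fm.labels == lab].mean(axis=0),
                fm2.values[fm2.labels == lab].mean(axis=0),
                rtol=1e-12,
            )


class TestFusion:
    def _two_matrices(self):
        es = small_epochs(n_epochs=6, n_channels=3)
        return subband_std_features(es)["Theta"], fe_features(es)

    def test_fused_shape_and_interleaving(self):
        a, b = self._two_matrices()
        f = fuse(a, b)
        assert f.values.shape == (6, 6)
        assert f.features_per_channel == 2
        np.testing.assert_array_equal(f.values[:, 0], a.values[:, 0])
        np.testing.assert_array_equal(f.values[:, 1], b.values[:, 0])
        assert f.column_map[0] == (0, "Theta_Std")
        assert f.column_map[1] == (0, "FE")

    def test_self_fusion_duplicates_columns(self):
        a, _ = self._two_matrices()
        f = fuse(a, a)
        for c in range(3):
            np.testing.assert_array_equal(f.values[:, 2 * c], f.values[:, 2 * c + 1])

    def test_unfuse_round_trip(self):
        a, b = self._two_matrices()
        f = fuse(a, b)
        a2, b2 = unfuse(f)
        np.testing.assert_array_equal(a2.values, a.values)
        np.testing.assert_array_equal(b2.values, b.values)
        assert a2.column_map == a.column_map

    def test_mismatched_inputs_rejected(self):
        a, b = self._two_matrices()
        short = small_epochs(n_epochs=5, n_channels=3)
        with pytest.raises(FusionError):
            fuse(a, fe_features(short))
        bad_labels = small_epochs(n_epochs=6, n_channels=3,
                                  labels=np.zeros(6, dtype=int))
        with pytest.raises(FusionError):
            fuse(a, subband_std_features(bad_labels)["Theta"])


class TestSerialization:
    def test_round_trip_exact(self, tmp_path):
        es = small_epochs(n_epochs=4, n_channels=3)
        fm = fuse(subband_std_features(es)["Theta"], fe_features(es))
        write_feature_matrix(fm, tmp_path / "fm.tsv")
        back = read_feature_matrix(tmp_path / "fm.tsv")
        np.testing.assert_array_equal(back.values, fm.values)
        np.testing.assert_array_equal(back.labels, fm.labels)
        assert back.column_map == fm.column_map
        assert back.channel_names == fm.channel_names
        assert back.features_per_channel == 2
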
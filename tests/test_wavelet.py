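import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pathobrain.wavelet import (
    FAMILIES,
    dwt1d,
    dwt2,
    extract_features,
    idwt1d,
    load_features_csv,
    load_features_npz,
    save_features_csv,
    save_features_npz,
    wavedec2,
    wavelet_bank,
    waverec2,
)

# our families mapped onto pywt names (sym1 is not in pywt; it is Haar)
PYWT_NAME = {
    "haar": "haar", "db2": "db2", "coif1": "coif1",
    "sym1": "haar", "bior1.1": "bior1.1", "rbio1.1": "rbio1.1",
}
ORTHOGONAL = [f for f in FAMILIES if wavelet_bank(f).orthogonal]


class TestFilterBanks:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_taps_match_reference_library(self, family):
        bank = wavelet_bank(family)
        ref = pywt.Wavelet(PYWT_NAME[family])
        assert np.allclose(bank.dec_lo, ref.dec_lo, atol=1e-12)
        assert np.allclose(bank.dec_hi, ref.dec_hi, atol=1e-12)
        assert np.allclose(bank.rec_lo, ref.rec_lo, atol=1e-12)
        assert np.allclose(bank.rec_hi, ref.rec_hi, atol=1e-12)

    @pytest.mark.parametrize("family", ORTHOGONAL)
    def test_orthonormality_conditions(self, family):
        bank = wavelet_bank(family)
        assert np.isclose(np.sum(bank.dec_lo**2), 1.0)
        assert np.isclose(np.dot(bank.dec_lo, bank.dec_hi), 0.0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            wavelet_bank("db97")


class TestDwt1d:
    def test_constant_signal_haar(self):
        a, d = dwt1d([1.0, 1.0, 1.0, 1.0], "haar")
        assert np.allclose(a, np.sqrt(2.0))
        assert np.allclose(d, 0.0)

    def test_alternating_signal_haar(self):
        a, d = dwt1d([1.0, -1.0, 1.0, -1.0], "haar")
        assert np.allclose(a, 0.0)
        assert np.allclose(np.abs(d), np.sqrt(2.0))

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            dwt1d([1.0, 2.0, 3.0], "haar")

    @pytest.mark.parametrize("family", FAMILIES)
    def test_matches_reference_library(self, family):
        x = np.random.default_rng(7).standard_normal(64)
        a, d = dwt1d(x, family)
        ca, cd = pywt.dwt(x, PYWT_NAME[family], mode="periodization")
        assert np.allclose(a, ca, atol=1e-8)
        assert np.allclose(d, cd, atol=1e-8)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_single_level_round_trip(self, family):
        x = np.random.default_rng(8).standard_normal(32)
        a, d = dwt1d(x, family)
        assert np.allclose(idwt1d(a, d, family), x, atol=1e-10)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        arrays(np.float64, st.sampled_from([8, 16, 32]),
               elements=st.floats(-10, 10, allow_nan=False))
    )
    def test_haar_energy_conserved(self, x):
        a, d = dwt1d(x, "haar")
        assert np.isclose(np.sum(a**2) + np.sum(d**2), np.sum(x**2), rtol=1e-9, atol=1e-9)


class TestDwt2:
    def test_subband_shapes_256(self):
        img = np.random.default_rng(0).random((256, 256))
        for band in dwt2(img, "haar"):
            assert band.shape == (128, 128)

    def test_constant_image_haar(self):
        ll, lh, hl, hh = dwt2(np.ones((16, 16)), "haar")
        assert np.allclose(ll, 2.0)
        for band in (lh, hl, hh):
            assert np.allclose(band, 0.0)

    def test_checkerboard_energy_in_diagonal_band(self):
        img = np.indices((16, 16)).sum(axis=0) % 2 == 0
        ll, lh, hl, hh = dwt2(img.astype(float) * 2 - 1, "haar")
        assert np.allclose(ll, 0.0)
        assert np.allclose(lh, 0.0) and np.allclose(hl, 0.0)
        assert np.allclose(np.abs(hh), 2.0)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            dwt2(np.zeros((15, 16)), "haar")

    @pytest.mark.parametrize("family", FAMILIES)
    def test_matches_reference_library(self, family):
        img = np.random.default_rng(1).random((32, 32))
        ll, lh, hl, hh = dwt2(img, family)
        cA, (cH, cV, cD) = pywt.dwt2(img, PYWT_NAME[family], mode="periodization")
        # naming: our first letter = filter along axis 0
        assert np.allclose(ll, cA, atol=1e-8)
        assert np.allclose(lh, cV, atol=1e-8)
        assert np.allclose(hl, cH, atol=1e-8)
        assert np.allclose(hh, cD, atol=1e-8)


class TestWavedec2:
    def test_three_level_shape_and_count(self):
        img = np.random.default_rng(2).random((256, 256))
        for family in FAMILIES:
            res = wavedec2(img, family, 3)
            assert res.approx.shape == (32, 32)
            assert res.n_subbands == 10

    def test_too_many_levels_rejected(self):
        with pytest.raises(ValueError):
            wavedec2(np.zeros((16, 16)), "coif1", 3)  # level-3 side 4 < 6 taps

    @pytest.mark.parametrize("family", FAMILIES)
    @pytest.mark.parametrize("seed", range(20))
    def test_perfect_reconstruction(self, family, seed):
        img = np.random.default_rng(seed).random((64, 64))
        res = wavedec2(img, family, 3)
        assert np.abs(waverec2(res, family) - img).max() < 1e-8

    @pytest.mark.parametrize("family", ORTHOGONAL)
    def test_parseval_energy_conservation(self, family):
        img = np.random.default_rng(5).random((64, 64))
        res = wavedec2(img, family, 3)
        energy = np.sum(img**2)
        assert abs(res.energy() - energy) / energy < 1e-8

    def test_matches_reference_multilevel(self):
        img = np.random.default_rng(6).random((64, 64))
        res = wavedec2(img, "db2", 3)
        ref = pywt.wavedec2(img, "db2", mode="periodization", level=3)
        assert np.allclose(res.approx, ref[0], atol=1e-8)
        # pywt lists detail levels deepest-first; ours shallowest-first
        for ours, theirs in zip(reversed(res.details), ref[1:]):
            lh, hl, hh = ours
            cH, cV, cD = theirs
            assert np.allclose(lh, cV, atol=1e-8)
            assert np.allclose(hl, cH, atol=1e-8)
            assert np.allclose(hh, cD, atol=1e-8)


class TestExtractFeatures:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_length_1024_for_all_families(self, family):
        img = np.random.default_rng(3).random((256, 256))
        assert extract_features(img, family, 3).shape == (1024,)

    def test_constant_image_gain_is_eight(self):
        c = 0.4
        feats = extract_features(np.full((256, 256), c), "haar", 3)
        assert np.allclose(feats, 8.0 * c)

    def test_single_level_length(self):
        img = np.random.default_rng(4).random((256, 256))
        assert extract_features(img, "haar", 1).shape == (128 * 128,)

    def test_row_major_flattening(self):
        img = np.random.default_rng(9).random((64, 64))
        res = wavedec2(img, "haar", 3)
        assert np.array_equal(extract_features(img, "haar", 3), res.approx.ravel())


class TestFeatureIO:
    def test_csv_and_npz_round_trip(self, tmp_path):
        X = np.random.default_rng(10).random((5, 16))
        labels = ["pathological", "normal", "normal", "pathological", "normal"]
        save_features_csv(tmp_path / "f.csv", X, labels)
        X2, l2 = load_features_csv(tmp_path / "f.csv")
        assert np.allclose(X2, X) and list(l2) == labels
        save_features_npz(tmp_path / "f.npz", X, labels)
        X3, l3 = load_features_npz(tmp_path / "f.npz")
        assert np.array_equal(X3, X) and list(l3) == labels
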
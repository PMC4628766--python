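"""Morphological parameters against brute-force evaluations and physics."""

import numpy as np
import pytest

from msmorph import (MorphConfig, VoiceSpec, cil, compute_modspec, drb,
                     extract_features, lmr, msc, msh, msw, pala_rala,
                     rala_from_pala, reduce_mod_bands, synth_vowel)
from msmorph.modspec import ReducedModSpec
from msmorph.morphology import feature_names, texture_image
from tests.test_modspec import make_modspec

RATE = 25000


def make_reduced(band_energy, fa=None):
    be = np.asarray(band_energy, dtype=np.float64)
    na, nb = be.shape
    if fa is None:
        fa = (np.arange(na) + 0.5) * 100.0
    edges = np.linspace(0, 240.0, nb + 1)
    return ReducedModSpec(band_energy=be, band_edges=edges,
                          fa=np.asarray(fa, dtype=np.float64))


class TestMsc:
    def test_point_mass_at_pitch_band(self):
        be = np.zeros((10, 4))
        be[2, :] = 5.0                      # fa[2] = 250 Hz
        r = make_reduced(be)
        np.testing.assert_allclose(msc(r, 250.0), 1.0)

    def test_point_mass_at_second_harmonic(self):
        be = np.zeros((10, 4))
        be[5, :] = 1.0                      # fa[5] = 550 Hz
        r = make_reduced(be)
        np.testing.assert_allclose(msc(r, 275.0), 2.0)

    def test_matches_bruteforce(self, rng):
        be = rng.uniform(0.1, 2.0, size=(10, 8))
        r = make_reduced(be)
        got = msc(r, 180.0)
        for b in range(8):
            expect = sum(r.fa[a] * be[a, b] for a in range(10)) \
                / (180.0 * sum(be[a, b] for a in range(10)))
            assert got[b] == pytest.approx(expect, rel=1e-12)

    def test_zero_energy_band_imputed(self):
        be = np.ones((5, 3))
        be[:, 1] = 0.0
        assert msc(make_reduced(be), 100.0)[1] == 0.0


class TestDrb:
    def test_constant_band_zero_db(self):
        assert drb(make_reduced(np.full((6, 3), 2.0)))[0] == 0.0

    def test_ratio_100_gives_20db(self):
        be = np.ones((4, 2))
        be[0, 0] = 100.0
        assert drb(make_reduced(be))[0] == pytest.approx(20.0)

    def test_matches_bruteforce(self, rng):
        be = rng.uniform(0.5, 50.0, size=(9, 5))
        got = drb(make_reduced(be))
        expect = [10 * np.log10(be[:, b].max() / be[:, b].min())
                  for b in range(5)]
        np.testing.assert_allclose(got, expect, rtol=1e-12)


class TestLmr:
    def test_all_energy_in_first_band_gives_zero(self):
        E = np.zeros((8, 40), dtype=complex)
        E[3, 0] = 2.0
        ms = make_modspec(E, max_mod_freq=240.0)
        f_pitch = ms.fa[3]
        assert lmr(ms, f_pitch) == 0.0

    def test_half_energy_split_gives_minus_3db(self):
        E = np.zeros((8, 40), dtype=complex)
        E[3, 0] = 1.0
        E[3, 2] = 1.0          # fm[2] ~ 12.3 Hz, inside the 0-25 Hz range
        ms = make_modspec(E, max_mod_freq=240.0)
        assert lmr(ms, ms.fa[3]) == pytest.approx(10 * np.log10(0.5),
                                                  abs=1e-9)

    def test_never_positive(self, rng):
        E = rng.standard_normal((8, 40)) + 1j * rng.standard_normal((8, 40))
        ms = make_modspec(E, max_mod_freq=240.0)
        assert lmr(ms, ms.fa[4]) <= 0.0

    def test_tremor_lowers_lmr_vs_clean_twin(self):
        clean = synth_vowel(VoiceSpec(f0=200, duration=1.0, seed=4))
        trem = synth_vowel(VoiceSpec(f0=200, duration=1.0, seed=4,
                                     tremor_freq=6.0, tremor_extent_pct=5.0,
                                     am_tremor_extent_pct=8.0))
        v_clean = lmr(compute_modspec(clean.samples[:3500], RATE), 200.0)
        v_trem = lmr(compute_modspec(trem.samples[:3500], RATE), 200.0)
        assert v_trem < v_clean

    def test_degenerate_band_errors(self):
        E = np.zeros((8, 40), dtype=complex)
        E[0, 0] = 1.0
        ms = make_modspec(E, max_mod_freq=240.0)
        with pytest.raises(ValueError, match="degenerate"):
            lmr(ms, ms.fa[5])


class TestMsh:
    def test_constant_matrix_zero(self):
        assert msh(np.full((5, 5), 3.3)) == pytest.approx(0.0, abs=1e-25)

    def test_impulse_matches_hand_computation(self):
        M = np.zeros((5, 5))
        M[2, 2] = 1.0
        local_means = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                block = M[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
                local_means[i, j] = block.mean()
        expect = ((M - local_means) ** 2).mean()
        assert msh(M) == pytest.approx(expect, rel=1e-12)

    def test_checkerboard_grows_with_amplitude(self):
        base = np.indices((6, 6)).sum(axis=0) % 2
        values = [msh(a * base) for a in (1.0, 2.0, 4.0)]
        assert values[0] < values[1] < values[2]

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            msh(np.ones((2, 5)))


class TestMsw:
    def test_constant_matrix_zero(self):
        assert msw(np.full((4, 4), 7.0)) == 0.0

    def test_scale_free(self, rng):
        M = rng.uniform(0.5, 3.0, size=(6, 7))
        assert msw(M) == pytest.approx(msw(10.0 * M), rel=1e-12)

    def test_checkerboard_matches_bruteforce(self):
        M = np.where(np.indices((4, 4)).sum(axis=0) % 2 == 0, 3.0, 1.0)
        total = 0.0
        for i in range(4):
            for j in range(4):
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = i + di, j + dj
                    if 0 <= ni < 4 and 0 <= nj < 4:
                        s = M[i, j] + M[ni, nj]
                        if s != 0:
                            total += abs(M[i, j] - M[ni, nj]) / abs(s)
        assert msw(M) == pytest.approx(total / 16.0, rel=1e-12)

    def test_zero_pairs_skipped(self):
        M = np.zeros((3, 3))
        M[0, 0] = 1.0
        assert np.isfinite(msw(M))


class TestCil:
    def test_all_equal_is_that_level(self):
        mag = np.full((4, 5), 10.0 ** (-30.0 / 20.0))
        assert cil(mag) == pytest.approx(-30.0, abs=1e-9)

    def test_two_level_split_is_midpoint(self):
        levels = np.array([0.0] * 50 + [20.0] * 50)
        mag = 10.0 ** (levels / 20.0)
        assert cil(mag) == pytest.approx(10.0, abs=0.5)

    def test_gaussian_levels_near_mean(self, rng):
        levels = rng.normal(-30.0, 5.0, size=10000)
        mag = 10.0 ** (levels / 20.0)
        assert cil(mag) == pytest.approx(-30.0, abs=0.5)

    def test_matches_bruteforce_cumulative_intersection(self, rng):
        levels = rng.normal(-20.0, 8.0, size=400)
        mag = 10.0 ** (levels / 20.0)
        got = cil(mag)
        # independent check: the crossing of #{x <= L} and #{x >= L} is
        # bracketed by the sample median
        med = np.median(levels)
        assert abs(got - med) <= 1.0


class TestPalaRala:
    def test_direct_count_2x2(self):
        pala, rala = pala_rala(np.array([[1.0, 1.0], [1.0, 3.0]]))
        assert pala == pytest.approx(0.25)
        assert rala == pytest.approx(1.0 / 3.0)

    def test_identity_on_random_matrices(self, rng):
        for _ in range(20):
            mag = rng.uniform(0, 5, size=(9, 11))
            pala, rala = pala_rala(mag)
            assert rala == pytest.approx(pala / (1 - pala), rel=1e-14)

    def test_tie_counts_as_above(self):
        # mean is 2; the two cells equal to the mean count as "above"
        pala, rala = pala_rala(np.array([[0.0, 2.0], [2.0, 4.0]]))
        assert pala == pytest.approx(0.75)
        assert rala == pytest.approx(3.0)

    def test_flat_spectrum_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            pala_rala(np.ones((3, 3)))

    def test_rala_from_pala_mapping(self):
        assert round(rala_from_pala(0.11), 2) == 0.12
        assert round(rala_from_pala(0.21), 2) == 0.27
        with pytest.raises(ValueError):
            rala_from_pala(1.0)


class TestExtractFeatures:
    @pytest.mark.parametrize("nb,expected", [(6, 20), (18, 44), (22, 52)])
    def test_vector_length_is_2nb_plus_8(self, nb, expected):
        w = synth_vowel(VoiceSpec(f0=200, duration=0.2, seed=1))
        vec = extract_features(w.samples[:3500], RATE, 200.0,
                               MorphConfig(nb=nb))
        assert len(vec) == expected == len(feature_names(nb))

    def test_scale_invariances(self):
        """msc, lmr, msw, pala, rala unchanged under x -> k*x;
        cil shifts by exactly 20*log10(k)."""
        w = synth_vowel(VoiceSpec(f0=180, duration=0.2, jitter_pct=1.0,
                                  hnr_db=20.0, seed=6))
        cfg = MorphConfig(nb=6)
        names = feature_names(6)
        k = 7.5
        v1 = extract_features(w.samples[:3500], RATE, 180.0, cfg)
        v2 = extract_features(k * w.samples[:3500], RATE, 180.0, cfg)
        invariant = [i for i, n in enumerate(names)
                     if n.split("_")[0] in ("msc", "drb", "lmr", "msw",
                                            "msh", "pala", "rala")]
        np.testing.assert_allclose(v2[invariant], v1[invariant], rtol=1e-7)
        i_cil = names.index("cil")
        assert v2[i_cil] - v1[i_cil] == pytest.approx(20 * np.log10(k),
                                                      abs=1e-6)

    def test_severe_vowel_separates_from_clean(self):
        cfg = MorphConfig(nb=14)
        names = feature_names(14)
        clean = synth_vowel(VoiceSpec(f0=170, duration=0.3, seed=2))
        severe = synth_vowel(VoiceSpec(f0=170, duration=0.3, seed=2,
                                       jitter_pct=3.0, shimmer_pct=9.0,
                                       tremor_extent_pct=6.0,
                                       am_tremor_extent_pct=10.0,
                                       hnr_db=8.0))
        vc = extract_features(clean.samples[:3500], RATE, 170.0, cfg)
        vs = extract_features(severe.samples[:3500], RATE, 170.0, cfg)
        for key in ("pala", "rala", "msw_mod"):
            assert vs[names.index(key)] > vc[names.index(key)]
        assert vs[names.index("lmr")] < vc[names.index("lmr")]

    def test_texture_image_range_limited(self, rng):
        mag = rng.uniform(1e-9, 1.0, size=(20, 20))
        img = texture_image(mag)
        assert img.min() == 0.0 and img.max() <= 40.0 + 1e-9
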
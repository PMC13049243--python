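import numpy as np
import pytest

from rosettemrf.dictionary import DictionaryConfig, build_dictionary, compress
from rosettemrf.mapping import (T2STAR_MAX_MS, T2STAR_MIN_MS, compute_pdff,
                                fit_dual_t2star, ideal_separate, pattern_match)

from oracles import brute_force_match

TE = 1.74 + 0.8 * np.arange(22)


def _decay_images(w, f, t2w, t2f, fat_hz=220.0, n=4):
    te_s = TE * 1e-3
    s = w * np.exp(-TE / t2w)
    if f:
        s = s + f * np.exp(-TE / t2f) * np.exp(2j * np.pi * fat_hz * te_s)
    return np.tile(s[:, None, None], (1, n, n)).astype(complex)


class TestDualT2Star:
    def test_pure_water_recovery(self):
        imgs = _decay_images(1.0, 0.0, 30.0, 20.0)
        t2w, t2f, aw, af = fit_dual_t2star(imgs, TE)
        assert abs(t2w[0, 0] - 30.0) < 0.5
        assert np.abs(af[0, 0]) < 0.01

    def test_two_component_recovery_within_10pct(self):
        imgs = _decay_images(0.5, 0.5, 30.0, 20.0)
        t2w, t2f, aw, af = fit_dual_t2star(imgs, TE)
        assert abs(t2w[0, 0] - 30.0) / 30.0 < 0.10
        assert abs(t2f[0, 0] - 20.0) / 20.0 < 0.10
        assert abs(np.abs(aw[0, 0]) - 0.5) < 0.05
        assert abs(np.abs(af[0, 0]) - 0.5) < 0.05

    def test_short_decay_clamped_to_lower_bound(self):
        imgs = _decay_images(1.0, 0.0, 1.0, 20.0)
        t2w, *_ = fit_dual_t2star(imgs, TE)
        assert t2w[0, 0] == pytest.approx(T2STAR_MIN_MS)

    @pytest.mark.parametrize("t2true", [0.5, 1.0, 500.0, 5000.0])
    def test_clamping_bounds_always_hold(self, t2true):
        imgs = _decay_images(1.0, 0.0, t2true, 20.0)
        t2w, t2f, *_ = fit_dual_t2star(imgs, TE)
        for m in (t2w, t2f):
            assert np.all(m >= T2STAR_MIN_MS - 1e-9)
            assert np.all(m <= T2STAR_MAX_MS + 1e-9)

    def test_nonfinite_voxels_flagged_invalid(self):
        imgs = _decay_images(1.0, 0.0, 30.0, 20.0)
        imgs[:, 0, 0] = np.nan
        t2w, t2f, aw, af = fit_dual_t2star(imgs, TE)
        assert aw[0, 0] == 0
        assert abs(t2w[1, 1] - 30.0) < 0.5

    def test_requires_six_echoes(self):
        with pytest.raises(ValueError):
            fit_dual_t2star(_decay_images(1, 0, 30, 20)[:5], TE[:5])

    def test_b0_demodulation(self):
        b0 = np.full((4, 4), 35.0)
        imgs = _decay_images(1.0, 0.0, 30.0, 20.0) * \
            np.exp(2j * np.pi * 35.0 * TE * 1e-3)[:, None, None]
        t2w, _, aw, _ = fit_dual_t2star(imgs, TE, b0_hz=b0)
        assert abs(t2w[0, 0] - 30.0) < 0.5


class TestIdealSeparate:
    def test_water_only_voxel(self):
        imgs = _decay_images(1.0, 0.0, 30.0, 20.0)[None]  # rank 1
        t2w = np.full((4, 4), 30.0)
        t2f = np.full((4, 4), 20.0)
        w, f = ideal_separate(imgs, np.zeros((4, 4)), t2w, t2f, TE)
        assert np.all(np.abs(f) < 0.01 * np.abs(w))

    def test_known_mixture_ratio(self):
        imgs = _decay_images(0.7, 0.3, 30.0, 20.0)[None]
        w, f = ideal_separate(imgs, np.zeros((4, 4)),
                              np.full((4, 4), 30.0), np.full((4, 4), 20.0), TE)
        ratio = np.abs(f[0, 0, 0]) / (np.abs(f[0, 0, 0]) + np.abs(w[0, 0, 0]))
        assert ratio == pytest.approx(0.30, abs=0.01)

    def test_amplitudes_referenced_to_te0(self):
        imgs = _decay_images(0.8, 0.0, 25.0, 20.0)[None]
        w, _ = ideal_separate(imgs, np.zeros((4, 4)),
                              np.full((4, 4), 25.0), np.full((4, 4), 20.0), TE)
        # decay at the first echo removed: amplitude equals the TE=0 value
        assert np.abs(w[0, 0, 0]) == pytest.approx(0.8, abs=0.01)

    def test_energy_not_lost_by_dephasing_removal(self):
        imgs = _decay_images(0.6, 0.4, 30.0, 20.0)[None]
        w, f = ideal_separate(imgs, np.zeros((4, 4)),
                              np.full((4, 4), 30.0), np.full((4, 4), 20.0), TE)
        first_echo = np.abs(imgs[0, 0, 0, 0])
        assert np.abs(w[0, 0, 0]) + np.abs(f[0, 0, 0]) >= first_echo - 1e-6

    def test_degenerate_echo_times_rejected(self):
        imgs = _decay_images(1.0, 0.0, 30.0, 20.0)[None][:, :1]
        with pytest.raises(ValueError):
            ideal_separate(imgs, np.zeros((4, 4)), np.full((4, 4), 30.0),
                           np.full((4, 4), 20.0), TE[:1])


@pytest.fixture(scope="module")
def match_setup(schedule_1000):
    cfg = DictionaryConfig(t1_grid_ms=np.arange(100.0, 2001.0, 50.0),
                           t2_grid_ms=np.arange(8.0, 250.0, 8.0))
    d = build_dictionary(cfg, schedule_1000, dtype=np.complex128)
    basis, comp = compress(d, 10)
    return d, basis, comp


class TestPatternMatch:
    def test_self_match_with_complex_scale(self, match_setup):
        d, basis, comp = match_setup
        i = int(np.where((d.entries[:, 0] == 950) & (d.entries[:, 1] == 48 + 0))[0][0]) \
            if np.any((d.entries[:, 0] == 950)) else 100
        atom = comp[i]
        sig = (3j * atom * d.norms[i]).reshape(-1, 1, 1) * np.ones((1, 2, 2))
        t1, t2, m0 = pattern_match(sig, comp, d.entries, d.norms)
        assert t1[0, 0] == d.entries[i, 0]
        assert t2[0, 0] == d.entries[i, 1]
        assert m0[0, 0] == pytest.approx(3j, rel=1e-6)

    def test_matches_brute_force_oracle(self, match_setup, rng):
        d, basis, comp = match_setup
        take = rng.integers(0, d.n_entries, 25)
        sig = comp[take].T.reshape(10, 5, 5) * (1.3 - 0.4j)
        t1, t2, _ = pattern_match(sig, comp, d.entries, d.norms)
        winners = brute_force_match(sig.reshape(10, -1), comp)
        assert np.array_equal(t1.ravel(), d.entries[winners, 0])
        assert np.array_equal(t2.ravel(), d.entries[winners, 1])

    def test_noise_robustness_monte_carlo(self, match_setup, rng):
        """Atom + 1% noise matches the true node or an adjacent one in at
        least 95% of draws."""
        d, basis, comp = match_setup
        idx = int(np.argmin(np.abs(d.entries[:, 0] - 950) + np.abs(d.entries[:, 1] - 48)))
        t1g = np.unique(d.entries[:, 0])
        t2g = np.unique(d.entries[:, 1])
        atom = comp[idx]
        hits = 0
        n_draws = 100
        for _ in range(n_draws):
            noisy = atom + 0.01 * (rng.standard_normal(10) + 1j * rng.standard_normal(10))
            t1, t2, _ = pattern_match(noisy.reshape(10, 1, 1), comp,
                                      d.entries, d.norms)
            di1 = abs(np.searchsorted(t1g, t1[0, 0]) - np.searchsorted(t1g, d.entries[idx, 0]))
            di2 = abs(np.searchsorted(t2g, t2[0, 0]) - np.searchsorted(t2g, d.entries[idx, 1]))
            hits += (di1 <= 1 and di2 <= 1)
        assert hits >= 95

    def test_zero_voxel_maps_to_zero(self, match_setup):
        d, basis, comp = match_setup
        t1, t2, m0 = pattern_match(np.zeros((10, 2, 2), dtype=complex),
                                   comp, d.entries, d.norms)
        assert np.all(t1 == 0) and np.all(t2 == 0) and np.all(m0 == 0)

    def test_tie_breaks_to_lowest_index(self):
        comp = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]], dtype=complex)
        entries = np.array([[100.0, 10.0], [200.0, 20.0], [300.0, 30.0]])
        norms = np.ones(3)
        sig = np.array([1.0, 0.0], dtype=complex).reshape(2, 1, 1)
        t1, t2, _ = pattern_match(sig, comp, entries, norms)
        assert t1[0, 0] == 100.0


class TestPDFF:
    @pytest.mark.parametrize("w,f,expect", [
        (1.0, 0.0, 0.0), (0.0, 1.0, 1.0), (1.0, 1.0, 0.5), (3.0, 1.0, 0.25),
    ])
    def test_magnitude_discrimination_values(self, w, f, expect):
        got = compute_pdff(np.array([[w]], dtype=complex),
                           np.array([[f]], dtype=complex))
        assert got[0, 0] == pytest.approx(expect, abs=1e-9)

    def test_zero_total_flagged_zero(self):
        assert compute_pdff(np.zeros((1, 1)), np.zeros((1, 1)))[0, 0] == 0.0

    def test_clipped_to_unit_interval(self, rng):
        w = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        f = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        p = compute_pdff(w, f)
        assert np.all((p >= 0) & (p <= 1))
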
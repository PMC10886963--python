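"""Single-step transport physics: free path, HG spin, Fresnel, weight rules."""

import numpy as np
import pytest

from sesorsmc.optics import OpticalProperties, RamanPeakSet
from sesorsmc.tally import RunCounters
from sesorsmc.transport import (
    PhotonState,
    TransportConfig,
    _fresnel_scalar,
    _hg_cos_scalar,
    _rotate_scalar,
    drop_and_roulette,
    fresnel_reflectance,
    hg_cos_theta,
    launch,
    maybe_raman,
    rotate_direction,
    sample_step,
    spin,
)


def _counters():
    return RunCounters(per_peak=[0, 0, 0, 0])


class TestLaunch:
    def test_unit_weight_45_degree_tilt(self):
        state = launch(TransportConfig(n_photons=1))
        assert state.weight == 1.0
        assert state.wl_index == 0
        assert not state.shifted
        assert state.direction[2] == pytest.approx(np.cos(np.pi / 4))
        assert np.linalg.norm(state.direction) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(state.position, 0.0)

    def test_deterministic(self):
        a = launch(TransportConfig(n_photons=1))
        b = launch(TransportConfig(n_photons=1))
        assert np.array_equal(a.direction, b.direction)

    def test_azimuth_controls_tilt_plane(self):
        state = launch(TransportConfig(n_photons=1, launch_azimuth_deg=0.0))
        assert state.direction[0] == pytest.approx(np.sin(np.pi / 4))


class TestSampleStep:
    def test_closed_form(self):
        props = OpticalProperties(mu_a=1.0, mu_s=9.0, g=0.9, n=1.4)
        assert sample_step(1.0, props) == 0.0
        assert sample_step(np.exp(-1.0), props) == pytest.approx(0.1)

    def test_mean_free_path_is_reciprocal_mu_t(self, rng):
        mu_t = 10.0
        n = 1_000_000
        s = sample_step(1.0 - rng.random(n), mu_t)
        se = (1.0 / mu_t) / np.sqrt(n)  # exponential: sd = mean
        assert abs(s.mean() - 0.1) < 3 * se


class TestHenyeyGreenstein:
    def test_isotropic_midpoint(self):
        assert hg_cos_theta(0.5, 0.0) == 0.0

    @pytest.mark.parametrize("g", [0.0, 0.8, 0.9])
    def test_mean_cosine_equals_g(self, g, rng):
        n = 1_000_000
        cos_t = hg_cos_theta(rng.random(n), g)
        se = cos_t.std() / np.sqrt(n)
        assert abs(cos_t.mean() - g) < 3 * se

    def test_rotation_preserves_unit_norm(self, rng):
        d = rng.normal(size=(2000, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        cos_t = hg_cos_theta(rng.random(2000), 0.9)
        out = rotate_direction(d, cos_t, 2 * np.pi * rng.random(2000))
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)

    def test_scalar_kernels_match_array_kernels(self, rng):
        for _ in range(300):
            u = float(rng.random())
            g = float(rng.choice([0.0, 0.8, 0.9, 0.99]))
            assert _hg_cos_scalar(u, g) == float(hg_cos_theta(u, g))
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cos_t = _hg_cos_scalar(u, g)
            phi = 2.0 * np.pi * float(rng.random())
            sx, sy, sz = _rotate_scalar(d[0], d[1], d[2], cos_t, phi)
            vec = rotate_direction(d, cos_t, phi)
            assert (sx, sy, sz) == (vec[0], vec[1], vec[2])


class TestFresnel:
    def test_matched_media_never_reflect(self):
        assert fresnel_reflectance(1.4, 1.4, 0.3) == 0.0

    def test_normal_incidence_closed_form(self):
        r = fresnel_reflectance(1.4, 1.0, 1.0)
        assert r == pytest.approx((0.4 / 2.4) ** 2, rel=1e-12)

    def test_total_internal_reflection(self):
        crit = np.arcsin(1.0 / 1.4)
        assert fresnel_reflectance(1.4, 1.0, np.cos(crit) * 0.99) == 1.0

    def test_scalar_kernel_matches_array_kernel(self, rng):
        for _ in range(200):
            ci = float(rng.random())
            assert _fresnel_scalar(1.4, 1.0, ci) == float(
                fresnel_reflectance(1.4, 1.0, ci)
            )


class TestDropAndRoulette:
    def _state(self, weight=1.0):
        return PhotonState(
            position=np.zeros(3),
            direction=np.array([0.0, 0.0, 1.0]),
            weight=weight,
        )

    def test_absorbed_fraction(self):
        props = OpticalProperties(mu_a=1.0, mu_s=9.0, g=0.9, n=1.4)
        c = _counters()
        out = drop_and_roulette(self._state(1.0), props, u=0.99, counters=c)
        assert out.weight == pytest.approx(0.9)
        assert c.absorbed_weight == pytest.approx(0.1)

    def test_roulette_survivor_weight_rescaled(self):
        props = OpticalProperties(mu_a=0.0, mu_s=10.0, g=0.9, n=1.4)
        out = drop_and_roulette(
            self._state(5e-5), props, u=0.05, threshold=1e-4, survive=0.1
        )
        assert out.alive
        assert out.weight == pytest.approx(5e-4)

    def test_roulette_loser_terminated(self):
        props = OpticalProperties(mu_a=0.0, mu_s=10.0, g=0.9, n=1.4)
        out = drop_and_roulette(
            self._state(5e-5), props, u=0.5, threshold=1e-4, survive=0.1
        )
        assert not out.alive
        assert out.weight == 0.0

    def test_roulette_conserves_weight_in_expectation(self, rng):
        # survivors carry w/chance, so E[weight out] = weight in
        n = 200_000
        w = 5e-5
        u = rng.random(n)
        out = np.where(u < 0.1, w / 0.1, 0.0)
        se = out.std() / np.sqrt(n)
        assert abs(out.mean() - w) < 3 * se


class TestMaybeRaman:
    def setup_method(self):
        self.peaks = RamanPeakSet.default()

    def _state(self):
        return PhotonState(
            position=np.zeros(3), direction=np.array([0.0, 0.0, 1.0])
        )

    def test_outside_inclusion_is_inert(self):
        c = _counters()
        s = maybe_raman(self._state(), "dermis", self.peaks, 1e-2, 0.001, 0.5, c)
        assert not s.shifted and s.wl_index == 0
        assert c.n_raman_total == 0 and c.n_additional_criteria == 0

    def test_trigger_selects_peak_by_branch_cdf(self):
        c = _counters()
        s = maybe_raman(self._state(), "inclusion", self.peaks, 1e-2, 0.005, 0.5, c)
        assert s.shifted
        assert s.wl_index == 3  # 1582 cm^-1 channel
        assert c.n_raman_total == 1 and c.per_peak == [0, 0, 1, 0]

    def test_no_trigger_above_probability(self):
        c = _counters()
        s = maybe_raman(self._state(), "inclusion", self.peaks, 1e-2, 0.5, 0.5, c)
        assert not s.shifted and c.n_raman_total == 0

    def test_one_shift_per_photon_and_additional_counter(self):
        c = _counters()
        s = self._state()
        s.shifted = True
        s.wl_index = 1
        out = maybe_raman(s, "inclusion", self.peaks, 1e-2, 0.001, 0.5, c)
        assert out.wl_index == 1
        assert c.n_raman_total == 0
        assert c.n_additional_criteria == 1


class TestSpin:
    def test_direction_changes_but_stays_unit(self):
        s = PhotonState(position=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))
        out = spin(s, g=0.9, u1=0.3, u2=0.7)
        assert np.linalg.norm(out.direction) == pytest.approx(1.0, abs=1e-12)
        assert out.direction[2] != 1.0
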
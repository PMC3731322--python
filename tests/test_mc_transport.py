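"""Photon-transport physics: sampling laws, conservation, diffusion limit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import nirsens as ns
from nirsens.head_model import GRAY, HeadVolume, SurfacePoint
from nirsens.mc_transport import PhotonState, propagate


def homogeneous_block(n=40, code=GRAY, voxel=1.0, pad=2):
    labels = np.zeros((n, n, n), dtype=np.int16)
    labels[pad:-pad, pad:-pad, pad:-pad] = code
    return HeadVolume(labels, voxel_size=voxel)


def top_source(head, pad=2):
    n = head.shape[0]
    return SurfacePoint(position=np.array([n / 2, n / 2, pad + 0.5]),
                        direction=np.array([0.0, 0.0, 1.0]))


class TestSampling:
    def test_step_closed_form_and_mean(self, rng):
        assert ns.sample_step(1.0, math.exp(-1.0)) == pytest.approx(1.0)
        # CSF scattering 0.01/mm -> 100 mm mean free path
        draws = ns.sample_step(0.01, rng.random(100_000))
        assert draws.mean() == pytest.approx(100.0, rel=0.02)
        with pytest.raises(ValueError):
            ns.sample_step(0.0, 0.5)

    def test_step_distribution_is_exponential(self, rng):
        mu_s = 0.72
        draws = ns.sample_step(mu_s, rng.random(10_000))
        ks = stats.kstest(draws, "expon", args=(0, 1 / mu_s))
        assert ks.pvalue > 0.01

    def test_hg_isotropic_limit_uniform(self, rng):
        ct = ns.hg_cos_theta(0.0, rng.random(100_000))
        ks = stats.kstest(ct, "uniform", args=(-1, 2))
        assert ks.pvalue > 0.01

    @pytest.mark.parametrize("g", [0.0, 0.01, 0.5, 0.9])
    def test_hg_first_moment_equals_g(self, g, rng):
        ct = ns.hg_cos_theta(g, rng.random(1_000_000))
        se = ct.std() / math.sqrt(len(ct))
        assert abs(ct.mean() - g) < 3 * se

    def test_hg_rejects_degenerate_anisotropy(self):
        with pytest.raises(ValueError):
            ns.hg_cos_theta(1.0, 0.5)

    def test_scatter_returns_unit_vector_at_expected_angle(self):
        d = ns.sample_scatter(0.9, 0.3, 0.7, direction=(0, 0, 1))
        assert np.linalg.norm(d) == pytest.approx(1.0)
        assert d[2] == pytest.approx(float(ns.hg_cos_theta(0.9, 0.3)))


class TestSamplingProperties:
    @settings(derandomize=True, max_examples=200)
    @given(g=st.floats(-0.99, 0.99), u=st.floats(0.0, 1.0))
    def test_hg_cosine_always_in_valid_range(self, g, u):
        ct = float(ns.hg_cos_theta(g, u))
        assert -1.0 <= ct <= 1.0

    @settings(derandomize=True, max_examples=200)
    @given(mu_s=st.floats(1e-3, 10.0),
           u=st.floats(1e-12, 1.0, exclude_max=False))
    def test_step_lengths_non_negative_and_scale_inversely(self, mu_s, u):
        L = float(ns.sample_step(mu_s, u))
        assert L >= 0.0
        assert float(ns.sample_step(2 * mu_s, u)) == pytest.approx(L / 2)

    @settings(derandomize=True, max_examples=200)
    @given(n1=st.floats(1.0, 2.0), n2=st.floats(1.0, 2.0),
           ci=st.floats(0.0, 1.0))
    def test_fresnel_is_a_probability(self, n1, n2, ci):
        r = ns.fresnel_reflectance(n1, n2, ci)
        assert 0.0 <= r <= 1.0


class TestFresnel:
    def test_matched_index_never_reflects(self):
        for ci in (0.0, 0.3, 1.0):
            assert ns.fresnel_reflectance(1.0, 1.0, ci) == 0.0

    def test_normal_incidence_closed_form(self):
        r = ns.fresnel_reflectance(1.4, 1.0, 1.0)
        assert r == pytest.approx((0.4 / 2.4) ** 2, rel=1e-12)

    def test_total_internal_reflection(self):
        # critical angle for 1.4 -> 1.0: sin(theta_c) = 1/1.4
        cos_c = math.sqrt(1 - (1 / 1.4) ** 2)
        assert ns.fresnel_reflectance(1.4, 1.0, cos_c * 0.9) == 1.0


class TestPropagate:
    def test_exit_weight_is_unity_without_absorption(self, rng):
        head = homogeneous_block(n=20)
        optics = ns.OpticalProperties.default_head()
        optics.mu_a[:] = 0.0
        for _ in range(40):
            ph = PhotonState(position=np.array([10.0, 10.0, 2.5]),
                             direction=np.array([0.0, 0.0, 1.0]))
            ev = propagate(ph, head, optics, rng, t_max_ns=1000.0)
            assert ev.kind == "exited"
            assert ev.weight == pytest.approx(1.0)

    def test_straight_path_obeys_beer_lambert(self, rng):
        # scattering length far larger than the slab: the photon crosses
        # straight through and exits with exp(-mu_a * thickness)
        head = homogeneous_block(n=30)
        optics = ns.OpticalProperties.default_head()
        optics.mu_s[:] = 1e-9
        optics.mu_a[GRAY] = 0.0195
        ph = PhotonState(position=np.array([15.0, 15.0, 2.5]),
                         direction=np.array([0.0, 0.0, 1.0]))
        ev = propagate(ph, head, optics, rng, t_max_ns=1e9)
        assert ev.kind == "exited"
        thickness = 30 - 2 * 2 - 0.5  # from start voxel centre to air
        assert ev.weight == pytest.approx(math.exp(-0.0195 * thickness),
                                          rel=1e-9)

    def test_tissue_paths_sum_to_cumulative_path(self, rng):
        head = ns.build_layered_slab((20, 20, 20), (4, 4, 2, 4),
                                     voxel_size=1.0)
        optics = ns.OpticalProperties.default_head()
        for _ in range(25):
            ph = PhotonState(position=np.array([10.0, 10.0, 0.5]),
                             direction=np.array([0.0, 0.0, 1.0]))
            ev = propagate(ph, head, optics, rng)
            assert ev.tissue_paths.sum() == pytest.approx(ev.cumulative_path,
                                                          rel=1e-9)

    def test_photon_must_start_in_tissue(self, rng):
        head = homogeneous_block(n=20)
        optics = ns.OpticalProperties.default_head()
        ph = PhotonState(position=np.array([1.0, 1.0, 1.0]),
                         direction=np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError, match="tissue"):
            propagate(ph, head, optics, rng)


class TestRunMC:
    def test_zero_photons_gives_empty_outputs(self):
        head = homogeneous_block(n=16)
        optics = ns.OpticalProperties.default_head()
        grid, hist = ns.run_mc(head, optics, top_source(head),
                               detectors=[np.array([8.0, 8.0, 2.5])],
                               config=ns.SimConfig(n_photons=0))
        assert grid.total() == 0.0
        assert hist[0].n_detected == 0

    def test_same_seed_is_bit_identical(self):
        head = homogeneous_block(n=20)
        optics = ns.OpticalProperties.default_head()
        cfg = ns.SimConfig(n_photons=2000, seed=42)
        g1, _ = ns.run_mc(head, optics, top_source(head), config=cfg)
        g2, _ = ns.run_mc(head, optics, top_source(head), config=cfg)
        np.testing.assert_array_equal(g1.values, g2.values)

    def test_energy_accounting_closes(self):
        head = ns.build_layered_slab((30, 30, 30), voxel_size=1.0)
        optics = ns.OpticalProperties.default_head()
        src = SurfacePoint(position=np.array([15.0, 15.0, 0.5]),
                           direction=np.array([0.0, 0.0, 1.0]))
        grid, _ = ns.run_mc(head, optics, src,
                            config=ns.SimConfig(n_photons=20_000, seed=7))
        eb = grid.energy_balance
        total = eb["exit"] + eb["absorbed"] + eb["in_flight"]
        assert abs(total - 20_000) / 20_000 < 1e-6

    def test_exit_weight_equals_launched_without_absorption(self):
        head = homogeneous_block(n=24)
        optics = ns.OpticalProperties.default_head()
        optics.mu_a[:] = 0.0
        n = 5000
        grid, _ = ns.run_mc(head, optics, top_source(head),
                            config=ns.SimConfig(n_photons=n, seed=1,
                                                t_max_ns=1e6))
        assert grid.energy_balance["exit"] == pytest.approx(n, rel=1e-9)

    def test_source_in_air_rejected(self):
        head = homogeneous_block(n=16)
        optics = ns.OpticalProperties.default_head()
        src = SurfacePoint(position=np.array([0.5, 0.5, 0.5]),
                           direction=np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError, match="tissue"):
            ns.run_mc(head, optics, src, config=ns.SimConfig(n_photons=10))

    def test_kernel_agrees_with_reference_propagator(self):
        # dual route: compiled kernel vs the pure-Python propagator on the
        # same absorbing block; mean exit weights agree within MC error
        head = homogeneous_block(n=20)
        optics = ns.OpticalProperties.default_head()
        grid, _ = ns.run_mc(head, optics, top_source(head),
                            config=ns.SimConfig(n_photons=40_000, seed=3))
        kernel_mean = grid.energy_balance["exit"] / 40_000
        rng = np.random.default_rng(9)
        weights = []
        for _ in range(400):
            ph = PhotonState(position=np.array([10.0, 10.0, 2.5]),
                             direction=np.array([0.0, 0.0, 1.0]))
            ev = propagate(ph, head, optics, rng)
            weights.append(ev.weight if ev.kind == "exited" else 0.0)
        w = np.asarray(weights)
        se = w.std(ddof=1) / math.sqrt(len(w))
        assert abs(w.mean() - kernel_mean) < 4 * se

    def test_detected_counts_decrease_with_separation(self):
        head = ns.build_layered_slab((80, 80, 40), voxel_size=1.0)
        optics = ns.OpticalProperties.default_head()
        src = SurfacePoint(position=np.array([40.5, 40.5, 0.5]),
                           direction=np.array([0.0, 0.0, 1.0]))
        dets = [np.array([40.5 + s, 40.5, 0.0]) for s in (10, 20, 30)]
        _, hist = ns.run_mc(head, optics, src, detectors=dets,
                            config=ns.SimConfig(n_photons=300_000, seed=5))
        counts = [h.n_detected for h in hist]
        assert counts[0] > counts[1] > counts[2] > 0

    def test_detector_history_paths_sum_below_time_cutoff(self):
        head = ns.build_layered_slab((40, 40, 30), voxel_size=1.0)
        optics = ns.OpticalProperties.default_head()
        src = SurfacePoint(position=np.array([20.5, 20.5, 0.5]),
                           direction=np.array([0.0, 0.0, 1.0]))
        det = np.array([30.5, 20.5, 0.0])
        _, hist = ns.run_mc(head, optics, src, detectors=[det],
                            config=ns.SimConfig(n_photons=100_000, seed=5))
        h = hist[0]
        assert h.n_detected > 10
        total = h.tissue_paths.sum(axis=1)
        assert (total <= ns.C_MM_PER_NS * 10.0 + 1e-6).all()
        assert (h.weights > 0).all() and (h.weights <= 1.0).all()


class TestNormalization:
    def test_total_divided_by_n_launched(self):
        head = homogeneous_block(n=16)
        optics = ns.OpticalProperties.default_head()
        grid, _ = ns.run_mc(head, optics, top_source(head),
                            config=ns.SimConfig(n_photons=1000, seed=2))
        norm = ns.normalize_fluence(grid)
        assert norm.total() == pytest.approx(grid.total() / 1000)

    def test_renormalization_warns_and_is_noop(self):
        head = homogeneous_block(n=16)
        optics = ns.OpticalProperties.default_head()
        grid, _ = ns.run_mc(head, optics, top_source(head),
                            config=ns.SimConfig(n_photons=100, seed=2))
        norm = ns.normalize_fluence(grid)
        with pytest.warns(UserWarning, match="already normalized"):
            again = ns.normalize_fluence(norm)
        assert again is norm

    def test_per_photon_fluence_consistent_across_budgets(self):
        # mu_a = 0: the normalized total deposited path per photon is a
        # geometric quantity, independent of the photon budget
        head = homogeneous_block(n=20)
        optics = ns.OpticalProperties.default_head()
        optics.mu_a[:] = 0.0
        totals = []
        for n, seed in ((2000, 1), (20_000, 2)):
            grid, _ = ns.run_mc(head, optics, top_source(head),
                                config=ns.SimConfig(n_photons=n, seed=seed))
            totals.append(ns.normalize_fluence(grid).total())
        assert totals[0] == pytest.approx(totals[1], rel=0.05)


class TestDiffusionLimit:
    def test_on_axis_decay_matches_effective_attenuation(self):
        # point source in a homogeneous gray block: beyond ~2 transport
        # lengths the radial fluence follows exp(-mu_eff*r)/r, so the decay
        # of ln(r * phi) on the source axis approaches mu_eff
        head = homogeneous_block(n=90, pad=2)
        optics = ns.OpticalProperties.default_head()
        src = top_source(head)
        grid, _ = ns.run_mc(head, optics, src,
                            config=ns.SimConfig(n_photons=200_000, seed=3))
        mu_a, mu_s, g = (optics.mu_a[GRAY], optics.mu_s[GRAY],
                         optics.g[GRAY])
        mu_eff = math.sqrt(3 * mu_a * (mu_a + mu_s * (1 - g)))
        ltr = 1 / (mu_a + mu_s * (1 - g))
        c = 45
        col = grid.values[c - 2:c + 3, c - 2:c + 3, :].mean(axis=(0, 1))
        z = (np.arange(90) + 0.5) - 2.5
        sel = (z > 2 * ltr + 3) & (z < 35) & (col > 0)
        slope = np.polyfit(z[sel], np.log(col[sel] * z[sel]), 1)[0]
        assert -slope == pytest.approx(mu_eff, rel=0.15)


class TestReciprocity:
    def test_fluence_symmetric_under_source_detector_swap(self):
        # homogeneous block: fluence near B from a source at A equals
        # fluence near A from a source at B (underpins the 3-point product)
        head = homogeneous_block(n=40)
        optics = ns.OpticalProperties.default_head()
        A = SurfacePoint(position=np.array([20.5, 20.5, 2.5]),
                         direction=np.array([0.0, 0.0, 1.0]))
        B = SurfacePoint(position=np.array([20.5, 2.5, 20.5]),
                         direction=np.array([0.0, 1.0, 0.0]))
        n = 400_000
        vals = {}
        for tag, src, probe in (("AB", A, B), ("BA", B, A)):
            grid, _ = ns.run_mc(head, optics, src,
                                config=ns.SimConfig(n_photons=n,
                                                    seed=11 if tag == "AB"
                                                    else 12))
            p = probe.position + 3.0 * probe.direction
            i = np.floor(p).astype(int)
            region = grid.values[i[0] - 2:i[0] + 3, i[1] - 2:i[1] + 3,
                                 i[2] - 2:i[2] + 3] / n
            vals[tag] = (region.mean(), region.std() / math.sqrt(region.size))
        diff = abs(vals["AB"][0] - vals["BA"][0])
        se = math.hypot(vals["AB"][1], vals["BA"][1])
        assert diff < 3 * se
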
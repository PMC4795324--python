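"""Monte Carlo surface-source transport: sampling, CSDA, tallies, doses."""
import math

import numpy as np
import pytest
from scipy import stats

from aunp_radiodose import (
    MicroCellTally,
    ShellTally,
    TumorModel,
    csda_point_kernel,
    depth_dose_profile,
    run_tally,
    sample_surface_source,
    transport_history,
)
from aunp_radiodose.beta_transport import (
    E_CUTOFF_MEV,
    transport_energy,
    transport_range,
)
from aunp_radiodose.nuclear_optical_data import TissueConstants
from aunp_radiodose.pipeline import default_depths_mm

RHO = 1.05
MEDIUM = TissueConstants(density_g_cm3=RHO)


class TestTransportRangeEnergy:
    def test_matches_published_branch_above_seam(self):
        assert transport_range(0.96) == pytest.approx(0.38732, abs=1e-12)

    def test_continuous_and_monotone_across_seam(self):
        e = np.linspace(0.01, 3.0, 20000)
        r = transport_range(e)
        assert np.all(np.diff(r) > 0)
        assert abs(transport_range(0.8) - transport_range(0.8 - 1e-9)) < 1e-8

    def test_exact_inverse(self):
        e = np.linspace(0.011, 2.9, 5000)
        np.testing.assert_allclose(
            transport_energy(transport_range(e)), e, rtol=1e-12
        )


class TestSurfaceSource:
    def test_uniform_on_the_sphere(self, large_tumor, au198_spectrum, rng):
        pts, _, _ = sample_surface_source(large_tumor, au198_spectrum, 100_000, rng)
        radii = np.linalg.norm(pts, axis=1)
        np.testing.assert_allclose(radii, large_tumor.radius_cm, rtol=1e-12)
        mean_unit = (pts / radii[:, None]).mean(axis=0)
        assert np.linalg.norm(mean_unit) < 0.02

    def test_directions_isotropic(self, large_tumor, au198_spectrum, rng):
        _, dirs, _ = sample_surface_source(large_tumor, au198_spectrum, 100_000, rng)
        assert np.linalg.norm(dirs.mean(axis=0)) < 0.02
        # z-component of an isotropic direction is uniform on [-1, 1]
        assert abs(dirs[:, 2].mean()) < 0.02
        assert dirs[:, 2].var() == pytest.approx(1.0 / 3.0, rel=0.05)

    def test_deterministic_under_fixed_seed(self, large_tumor, au198_spectrum):
        out1 = sample_surface_source(
            large_tumor, au198_spectrum, 100, np.random.default_rng(5)
        )
        out2 = sample_surface_source(
            large_tumor, au198_spectrum, 100, np.random.default_rng(5)
        )
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a, b)

    def test_energies_follow_the_spectrum(self, large_tumor, au198_spectrum, rng):
        _, _, e = sample_surface_source(large_tumor, au198_spectrum, 100_000, rng)
        edges = np.linspace(0.0, au198_spectrum.e_max_mev, 21)
        observed, _ = np.histogram(e, bins=edges)
        expected = np.diff(au198_spectrum.cdf(edges)) * len(e)
        chi2 = stats.chisquare(observed, expected * observed.sum() / expected.sum())
        assert chi2.pvalue > 1e-3


class TestTransportHistory:
    def test_full_pathlength_of_endpoint_electron(self):
        segs = transport_history((0, 0, 0), (1, 0, 0), 0.96, MEDIUM)
        assert len(segs) == 1
        assert segs[0].length_cm == pytest.approx(0.38732 / RHO, rel=1e-12)
        assert round(segs[0].length_cm, 2) == 0.37

    def test_energy_conservation_straight(self):
        segs = transport_history((0, 0, 0), (0, 0, 1), 0.5, MEDIUM)
        total = sum(s.energy_deposited_mev for s in segs)
        assert total == pytest.approx(0.5, abs=1e-9)

    def test_energy_conservation_with_scattering(self, rng):
        for e0 in [0.05, 0.3, 0.96]:
            segs = transport_history(
                (0, 0, 0), (0, 0, 1), e0, MEDIUM, rng=rng, scattering=True
            )
            total = sum(s.energy_deposited_mev for s in segs)
            assert total == pytest.approx(e0, abs=1e-9)
            if e0 >= 0.3:  # range much longer than one step -> many segments
                assert len(segs) > 1

    def test_sub_cutoff_electron_deposits_locally(self):
        segs = transport_history((1, 2, 3), (1, 0, 0), 0.5 * E_CUTOFF_MEV, MEDIUM)
        assert len(segs) == 1
        assert segs[0].length_cm == 0.0
        assert segs[0].energy_deposited_mev == pytest.approx(0.5 * E_CUTOFF_MEV)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            transport_history((0, 0, 0), (1, 0, 0), 0.0, MEDIUM)


class TestTallies:
    def test_shell_masses_match_geometry(self, large_tumor):
        tally = ShellTally.from_depths(large_tumor, default_depths_mm(0.5))
        for (r_in, r_out), mass in zip(tally.regions_cm, tally.masses_g):
            vol = 4.0 / 3.0 * math.pi * (r_out**3 - r_in**3)
            assert mass == pytest.approx(vol * RHO, rel=1e-9)

    def test_microcell_masses_match_geometry(self, large_tumor):
        tally = MicroCellTally.from_depths(large_tumor, default_depths_mm(0.5))
        vol = 4.0 / 3.0 * math.pi * 0.02**3
        np.testing.assert_allclose(tally.masses_g, vol * RHO, rtol=1e-9)

    def test_overlapping_shells_rejected(self):
        with pytest.raises(ValueError):
            ShellTally(np.array([[0.0, 0.2], [0.1, 0.3]]), RHO)

    def test_overlapping_microcells_rejected(self):
        with pytest.raises(ValueError):
            MicroCellTally(np.array([[0, 0, 0.0], [0, 0, 0.03]]), 0.02, RHO)

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            ShellTally(np.empty((0, 2)), RHO)


class TestRunTally:
    def test_deterministic_under_fixed_seed(self, large_tumor):
        tally = ShellTally.from_depths(large_tumor, (0.3, 0.8, 1.3))
        r1 = run_tally(large_tumor, tally, 2000, 99)
        r2 = run_tally(large_tumor, tally, 2000, 99)
        np.testing.assert_array_equal(r1.t_mev_per_g, r2.t_mev_per_g)
        np.testing.assert_array_equal(r1.t_stderr, r2.t_stderr)

    def test_depth_falloff_and_range_cutoff(self, large_tumor):
        tally = ShellTally.from_depths(large_tumor, default_depths_mm(0.5))
        res = run_tally(large_tumor, tally, 20_000, 7)
        order = np.argsort(res.depths_mm)
        t = res.t_mev_per_g[order]
        se = res.t_stderr[order]
        assert np.all(np.diff(t) <= 2.0 * np.hypot(se[1:], se[:-1]))
        # beyond the 3.7 mm beta range nothing is deposited (straight-line)
        d = res.depths_mm[order]
        assert np.all(t[d >= 4.3] == 0.0)

    def test_energy_conservation_with_tiling_tally(self, small_tumor, au198):
        reach = small_tumor.radius_cm + transport_range(au198.e_max_mev) / RHO
        edges = np.linspace(0.0, reach + 0.01, 30)
        tile = ShellTally(np.column_stack([edges[:-1], edges[1:]]), RHO)
        res = run_tally(small_tumor, tile, 2000, 11)
        total = res.energy_mev_per_particle.sum()
        assert total == pytest.approx(res.mean_emitted_mev, rel=1e-9)

    def test_partial_tally_scores_less_than_emitted(self, small_tumor):
        tally = ShellTally.from_depths(small_tumor, (0.3, 0.8))
        res = run_tally(small_tumor, tally, 2000, 13)
        assert res.energy_mev_per_particle.sum() < res.mean_emitted_mev

    def test_stderr_scales_with_inverse_sqrt_histories(self, large_tumor):
        tally = ShellTally.from_depths(large_tumor, (0.3, 0.8, 1.3))
        lo = run_tally(large_tumor, tally, 1000, 3)
        hi = run_tally(large_tumor, tally, 100_000, 3)
        ratio = lo.t_stderr[-1] / hi.t_stderr[-1]
        assert 5.0 < ratio < 20.0  # within a factor of 2 of sqrt(100)

    def test_microcell_mode_shows_same_falloff(self, large_tumor):
        tally = MicroCellTally.from_depths(large_tumor, (0.3, 0.8, 1.3, 1.8))
        res = run_tally(large_tumor, tally, 50_000, 21)
        t = res.t_mev_per_g[np.argsort(res.depths_mm)]
        assert t[0] > t[-1] > 0

    def test_scattering_mode_runs_and_conserves(self, small_tumor, au198):
        reach = small_tumor.radius_cm + transport_range(au198.e_max_mev) / RHO
        edges = np.linspace(0.0, reach + 0.01, 20)
        tile = ShellTally(np.column_stack([edges[:-1], edges[1:]]), RHO)
        res = run_tally(small_tumor, tile, 1000, 17, scattering=True)
        # scattering keeps tracks shorter in radius but conserves energy
        assert res.energy_mev_per_particle.sum() == pytest.approx(
            res.mean_emitted_mev, rel=1e-6
        )

    def test_too_few_histories_rejected(self, small_tumor):
        tally = ShellTally.from_depths(small_tumor, (0.3,))
        with pytest.raises(ValueError):
            run_tally(small_tumor, tally, 10, 1)


class TestPointKernelOracle:
    def test_monoenergetic_point_source_matches_closed_form(self, rng):
        # isotropic monoenergetic source at the origin: every straight-line
        # history deposits identically in radius, so the MC shell profile
        # must match the analytic residual-energy kernel
        e0 = 0.5
        edges = np.linspace(0.0, 0.35, 15)
        regions = np.column_stack([edges[:-1], edges[1:]])
        tally = ShellTally(regions, RHO)
        n = 100_000
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        starts = np.zeros((n, 3))
        r0 = np.full(n, float(transport_range(e0)))
        mc = tally.score(starts, dirs, r0 / RHO, r0, RHO)
        mean = mc.mean(axis=0)
        se = mc.std(axis=0, ddof=1) / math.sqrt(n)
        kernel = csda_point_kernel(e0, regions, RHO)
        assert np.all(np.abs(mean - kernel) <= 3.0 * se + 1e-12)

    def test_kernel_conserves_total_energy(self):
        e0 = 0.96
        reach = transport_range(e0) / RHO
        edges = np.linspace(0.0, reach + 0.01, 40)
        kernel = csda_point_kernel(e0, np.column_stack([edges[:-1], edges[1:]]), RHO)
        assert kernel.sum() == pytest.approx(e0, rel=1e-12)


class TestDepthDoseProfile:
    def test_linearity_and_zero_regions(self, small_tumor, au198):
        tally = ShellTally.from_depths(small_tumor, default_depths_mm(0.25))
        res = run_tally(small_tumor, tally, 5000, 31)
        p1 = depth_dose_profile(res, 100.0, au198)
        p2 = depth_dose_profile(res, 200.0, au198)
        np.testing.assert_allclose(p2.dose_gy, 2.0 * p1.dose_gy, rtol=1e-12)
        assert np.all(p1.dose_gy[res.t_mev_per_g[np.argsort(res.depths_mm)] == 0] == 0)

    def test_small_tumor_dosed_at_every_depth(self, small_tumor, au198):
        tally = ShellTally.from_depths(small_tumor, (0.3, 0.8, 1.3, 1.8, 2.3))
        res = run_tally(small_tumor, tally, 20_000, 37)
        profile = depth_dose_profile(res, 185.6, au198)
        assert np.all(profile.dose_gy > 0)
        assert list(profile.depth_mm) == [0.3, 0.8, 1.3, 1.8, 2.3]

    def test_depths_strictly_increasing_enforced(self, au198):
        from aunp_radiodose.beta_transport import DoseProfile

        with pytest.raises(ValueError):
            DoseProfile(
                depth_mm=np.array([0.3, 0.3]),
                dose_gy=np.array([1.0, 1.0]),
                dose_stderr_gy=np.zeros(2),
                t_mev_per_g=np.ones(2),
                t_stderr=np.zeros(2),
                activity_mci=1.0,
                lambda_eff_per_h=0.01,
            )
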
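"""Source recovery: locus curves, three-window inversion round trips,
uncertainty regions and the distance-flux map."""

import numpy as np
import pytest

from gradsense.errors import ConfigurationError
from gradsense.asymptotics import source_locus_curve, splitting_two_windows
from gradsense.geometry import HalfPlane, SourceSpec, WindowSet
from gradsense.recovery import (
    RecoveryProblem,
    distance_flux_map,
    forward_fluxes,
    recover_source,
    recover_two_windows,
    recovery_uncertainty,
)


@pytest.fixture
def fig4_setup():
    geom = HalfPlane(side=-1)
    windows = WindowSet.on_line([-1.0, 0.0, 1.0], 0.1)
    x0 = np.array([-2.0, 8.0])
    return geom, windows, x0


class TestLocus:
    def test_equal_fluxes_give_symmetry_line(self, halfplane, two_windows_line):
        curve = source_locus_curve(halfplane, two_windows_line, 0.5)
        assert curve.points.shape[0] > 10
        assert np.all(np.abs(curve.points[:, 1]) < 1e-10)

    def test_every_traced_point_reproduces_alpha(self, halfplane, two_windows_line):
        curve = source_locus_curve(halfplane, two_windows_line, 0.37)
        for p in curve.points[::7]:
            res = splitting_two_windows(halfplane, two_windows_line, SourceSpec(p))
            assert res.probabilities[1] == pytest.approx(0.37, abs=1e-6)

    def test_known_source_lies_on_its_curve(self, halfplane, two_windows_line):
        src = SourceSpec((1.0, 2.0))
        alpha = splitting_two_windows(halfplane, two_windows_line,
                                      src).probabilities[1]
        curve = source_locus_curve(halfplane, two_windows_line, alpha)
        assert abs(curve.implicit(src.x0)) < 1e-8

    def test_three_alphas_give_disjoint_curves(self, halfplane, two_windows_line):
        # distinct flux levels trace non-crossing loci
        curves = [source_locus_curve(halfplane, two_windows_line, a)
                  for a in (0.35, 0.45, 0.55)]
        for c1, c2 in zip(curves, curves[1:]):
            for p in c1.points[::9]:
                assert np.sign(c2.implicit(p)) == np.sign(c2.alpha - c1.alpha) * -1 or \
                    abs(c2.implicit(p)) > 1e-9

    def test_degenerate_alpha_rejected(self, halfplane, two_windows_line):
        from gradsense.errors import DegenerateConfigurationError
        with pytest.raises(DegenerateConfigurationError):
            source_locus_curve(halfplane, two_windows_line, 1.0)


class TestRecoverSource:
    def test_reference_three_window_roundtrip(self, fig4_setup):
        geom, windows, x0 = fig4_setup
        obs = forward_fluxes(geom, windows, x0)[:2]
        res = recover_source(RecoveryProblem(geom, windows, obs))
        np.testing.assert_allclose(res.position, x0, atol=1e-6)
        assert not res.ambiguous

    def test_symmetric_observations_recover_on_axis(self, fig4_setup):
        geom, windows, _ = fig4_setup
        # source on the perpendicular axis through the middle window
        x0 = np.array([-5.0, 0.0])
        obs = forward_fluxes(geom, windows, x0)[:2]
        assert obs[0] == pytest.approx(1.0 - obs.sum(), abs=1e-12)  # P1 == P3
        res = recover_source(RecoveryProblem(geom, windows, obs))
        assert abs(res.position[1]) < 1e-6

    def test_random_roundtrips_halfplane(self, fig4_setup, rng):
        geom, windows, _ = fig4_setup
        for _ in range(20):
            r = rng.uniform(2.0, 15.0)
            th = rng.uniform(0.2, np.pi - 0.2)
            x0 = np.array([-r * np.sin(th), r * np.cos(th)])
            obs = forward_fluxes(geom, windows, x0)[:2]
            res = recover_source(RecoveryProblem(geom, windows, obs))
            np.testing.assert_allclose(res.position, x0, atol=1e-6)

    def test_random_roundtrips_disk(self, disk, rng):
        windows = WindowSet.from_angles([0.4, 2.1, 4.4], 0.1, disk.R)
        for _ in range(15):
            r = rng.uniform(2.0, 12.0)
            th = rng.uniform(0.0, 2 * np.pi)
            x0 = r * np.array([np.cos(th), np.sin(th)])
            obs = forward_fluxes(disk, windows, x0)[:2]
            res = recover_source(RecoveryProblem(disk, windows, obs))
            np.testing.assert_allclose(res.position, x0, atol=1e-6)

    def test_five_window_roundtrip(self, rng):
        geom = HalfPlane(side=-1)
        windows = WindowSet.on_line([-2.0, -1.0, 0.0, 1.0, 2.0], 0.1)
        x0 = np.array([-2.0, 8.0])
        obs = forward_fluxes(geom, windows, x0)[:4]
        res = recover_source(RecoveryProblem(geom, windows, obs))
        np.testing.assert_allclose(res.position, x0, atol=1e-6)
        assert not res.ambiguous

    def test_inconsistent_observations_raise(self, fig4_setup):
        from gradsense.errors import NoSolutionError
        geom, windows, _ = fig4_setup
        with pytest.raises(NoSolutionError):
            recover_source(RecoveryProblem(geom, windows, np.array([0.8, 0.15])))

    def test_observation_validation(self, fig4_setup):
        geom, windows, _ = fig4_setup
        with pytest.raises(ConfigurationError):
            RecoveryProblem(geom, windows, np.array([0.7, 0.4]))
        with pytest.raises(ConfigurationError):
            RecoveryProblem(geom, windows, np.array([0.5]))


class TestUncertainty:
    def test_zero_eta_degenerates_to_point(self, fig4_setup):
        geom, windows, x0 = fig4_setup
        obs = forward_fluxes(geom, windows, x0)[:2]
        region = recovery_uncertainty(RecoveryProblem(geom, windows, obs, eta=0.0))
        assert region.area == 0.0
        np.testing.assert_allclose(region.points[0], x0, atol=1e-6)

    def test_region_contains_noiseless_solution(self, fig4_setup):
        geom, windows, x0 = fig4_setup
        obs = forward_fluxes(geom, windows, x0)[:2]
        region = recovery_uncertainty(
            RecoveryProblem(geom, windows, obs, eta=0.005), grid=7)
        assert region.area > 0.0
        assert region.contains_point(x0, tol=1e-6)

    def test_region_area_monotone_in_eta(self, fig4_setup):
        geom, windows, x0 = fig4_setup
        obs = forward_fluxes(geom, windows, x0)[:2]
        areas = [
            recovery_uncertainty(RecoveryProblem(geom, windows, obs, eta=e),
                                 grid=5).area
            for e in (0.001, 0.003, 0.005)
        ]
        assert areas[0] <= areas[1] <= areas[2]

    def test_uncertainty_grows_with_source_distance(self, fig4_setup):
        # the flux->position map steepens with distance: same eta, larger area
        geom, windows, _ = fig4_setup
        areas = []
        for r in (4.0, 12.0):
            x0 = np.array([-r * np.sin(1.2), r * np.cos(1.2)])
            obs = forward_fluxes(geom, windows, x0)[:2]
            areas.append(recovery_uncertainty(
                RecoveryProblem(geom, windows, obs, eta=0.003), grid=5).area)
        assert areas[1] > areas[0]


class TestDistanceFluxMap:
    def test_forward_spot_check(self, fig4_setup):
        geom, windows, x0 = fig4_setup
        p = forward_fluxes(geom, windows, x0)
        P1, P3, dist = distance_flux_map(geom, windows, [p[0]], [p[2]])
        expected = np.hypot(*(x0 - windows.centers.mean(axis=0)))
        assert dist[0, 0] == pytest.approx(expected, abs=1e-5)

    def test_inadmissible_cells_masked(self, fig4_setup):
        geom, windows, _ = fig4_setup
        P1, P3, dist = distance_flux_map(geom, windows, [0.7], [0.6])
        assert dist.mask[0, 0]

    def test_distance_grows_toward_equal_fluxes(self, fig4_setup):
        # along the symmetric transect P1 = P3 the distance increases as the
        # fluxes approach the remote-source limit
        geom, windows, _ = fig4_setup
        vals = []
        for p1 in (0.25, 0.29, 0.32):
            _, _, dist = distance_flux_map(geom, windows, [p1], [p1])
            vals.append(float(dist[0, 0]))
        assert vals[0] < vals[1] < vals[2]


class TestTwoWindowRecovery:
    def test_direction_flag_points_to_stronger_window(self, halfplane,
                                                      two_windows_line):
        prob = RecoveryProblem(halfplane, two_windows_line, np.array([0.6]))
        curve, direction = recover_two_windows(prob)
        assert direction == 0
        prob2 = RecoveryProblem(halfplane, two_windows_line, np.array([0.4]))
        _, direction2 = recover_two_windows(prob2)
        assert direction2 == 1

    def test_known_source_lies_on_recovered_curve(self, halfplane,
                                                  two_windows_line):
        src = SourceSpec((2.0, 1.0))
        p = splitting_two_windows(halfplane, two_windows_line, src).probabilities
        curve, _ = recover_two_windows(
            RecoveryProblem(halfplane, two_windows_line, p[:1]))
        assert abs(curve.implicit(src.x0)) < 1e-8
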
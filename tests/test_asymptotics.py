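"""Matched-asymptotic splitting probabilities: closed forms, the N-window
linear system, the explicit three-window solution, and the sensitivity /
detection-threshold functions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gradsense.asymptotics import (
    detection_threshold_disk,
    detection_threshold_disk_asymptotic,
    sensitivity_ratio_halfplane,
    solve_window_system,
    splitting_two_windows,
    three_window_explicit,
    two_class_sensitivity_product,
)
from gradsense.errors import (
    DegenerateConfigurationError,
    DomainError,
    RegimeViolationError,
    RegimeWarning,
)
from gradsense.geometry import HalfPlane, SourceSpec, WindowSet


class TestTwoWindows:
    def test_symmetric_source_splits_evenly(self, halfplane, two_windows_line):
        res = splitting_two_windows(halfplane, two_windows_line, SourceSpec((3.0, 0.0)))
        np.testing.assert_allclose(res.probabilities, [0.5, 0.5], atol=1e-14)

    def test_nearer_window_wins(self, halfplane, two_windows_line):
        # source closer to window 1 (at y = +1/2)
        res = splitting_two_windows(halfplane, two_windows_line, SourceSpec((1.0, 2.0)))
        assert res.probabilities[0] > 0.5
        assert res.probabilities.sum() == 1.0

    def test_leading_log_reference_value(self, halfplane, two_windows_line):
        # plain leading-log convention (matching constant ln eps)
        res = splitting_two_windows(halfplane, two_windows_line, SourceSpec((1.0, 2.0)),
                                    capacity_factor=1.0)
        expected = 0.5 + 0.25 * np.log(7.25 / 3.25) / np.log(10.0)
        assert res.probabilities[0] == pytest.approx(expected, abs=1e-12)
        assert res.probabilities[0] == pytest.approx(0.58711, abs=1e-5)

    def test_capacity_default_reference_value(self, halfplane, two_windows_line):
        # default matching constant ln(eps/4)
        res = splitting_two_windows(halfplane, two_windows_line, SourceSpec((1.0, 2.0)))
        expected = 0.5 + 0.25 * np.log(7.25 / 3.25) / np.log(40.0)
        assert res.probabilities[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_linear_system(self, halfplane, two_windows_line, rng):
        for _ in range(50):
            x0 = rng.uniform([0.3, -6.0], [8.0, 6.0])
            a = splitting_two_windows(halfplane, two_windows_line, SourceSpec(x0))
            b = solve_window_system(halfplane, two_windows_line, SourceSpec(x0))
            np.testing.assert_allclose(a.probabilities, b.probabilities, atol=1e-12)

    def test_disk_two_windows_threshold_consistency(self, disk):
        # diametrically opposed windows aligned with the source: |P1 - P2|
        # equals the detection-threshold function
        L = 5.0
        ws = WindowSet.from_angles([0.0, np.pi], 0.1, disk.R)
        res = splitting_two_windows(disk, ws, SourceSpec((L, 0.0)))
        f = detection_threshold_disk(disk.R, L, 0.1)
        assert res.probabilities[0] > 0.5
        assert abs(res.probabilities[0] - res.probabilities[1]) == pytest.approx(f, rel=1e-10)

    def test_window_size_larger_than_separation_raises(self, halfplane):
        ws = WindowSet.on_line([0.1, -0.1], 0.25)
        with pytest.raises(RegimeViolationError):
            splitting_two_windows(halfplane, ws, SourceSpec((1.0, 2.0)))

    def test_narrow_separation_emits_regime_warning(self, halfplane):
        ws = WindowSet.on_line([0.15, -0.15], 0.1)
        with pytest.warns(RegimeWarning):
            splitting_two_windows(halfplane, ws, SourceSpec((1.0, 2.0)))


class TestWindowSystem:
    def test_single_window_absorbs_everything(self, halfplane):
        ws = WindowSet.on_line([0.0], 0.1)
        sol = solve_window_system(halfplane, ws, SourceSpec((1.0, 2.0)))
        assert sol.A[0] == pytest.approx(1.0 / np.pi, abs=1e-14)
        assert sol.probabilities[0] == pytest.approx(1.0, abs=1e-13)

    @pytest.mark.parametrize("n_windows", [1, 2, 3, 5])
    def test_conservation_random_configurations(self, halfplane, rng, n_windows):
        for _ in range(25):
            ys = np.cumsum(rng.uniform(0.8, 2.0, n_windows))
            ws = WindowSet.on_line(ys, 0.1)
            x0 = rng.uniform([0.5, -5.0], [10.0, 10.0])
            sol = solve_window_system(halfplane, ws, SourceSpec(x0))
            assert abs(sol.probabilities.sum() - 1.0) < 1e-12

    def test_conservation_disk(self, disk, rng):
        for _ in range(25):
            angles = np.sort(rng.uniform(0, 2 * np.pi, 4))
            if np.min(np.diff(angles)) < 0.6:
                continue
            ws = WindowSet.from_angles(angles, 0.1, disk.R)
            r = rng.uniform(2.0, 12.0)
            th = rng.uniform(0, 2 * np.pi)
            sol = solve_window_system(disk, ws, SourceSpec((r * np.cos(th), r * np.sin(th))))
            assert abs(sol.probabilities.sum() - 1.0) < 1e-12

    def test_permutation_equivariance(self, halfplane, rng):
        ys = np.array([-1.5, 0.0, 2.0, 3.5])
        x0 = (2.0, 4.0)
        base = solve_window_system(halfplane, WindowSet.on_line(ys, 0.1),
                                   SourceSpec(x0)).probabilities
        perm = rng.permutation(4)
        permuted = solve_window_system(halfplane, WindowSet.on_line(ys[perm], 0.1),
                                       SourceSpec(x0)).probabilities
        np.testing.assert_allclose(permuted, base[perm], atol=1e-12)

    def test_monotone_in_source_position(self, halfplane, two_windows_line):
        # between the windows, moving the source toward window 1 along the
        # window axis raises P1 (beyond the pair the ratio saturates)
        ps = [
            splitting_two_windows(halfplane, two_windows_line,
                                  SourceSpec((0.2, y))).probabilities[0]
            for y in np.linspace(-0.45, 0.45, 13)
        ]
        assert np.all(np.diff(ps) > 0)

    def test_coincident_windows_raise(self, halfplane):
        ws = WindowSet(np.array([[0.0, 1.0], [0.0, 1.0]]), 0.1)
        with pytest.raises((DegenerateConfigurationError, RegimeViolationError)):
            solve_window_system(halfplane, ws, SourceSpec((1.0, 2.0)))


class TestThreeWindowExplicit:
    def test_symmetric_triangle_splits_evenly(self, disk):
        ws = WindowSet.from_angles([0.5, 0.5 + 2 * np.pi / 3, 0.5 + 4 * np.pi / 3],
                                   0.1, disk.R)
        # a very remote source sees all three windows equally
        sol = three_window_explicit(disk, ws, SourceSpec((1e7 * np.cos(1.1),
                                                          1e7 * np.sin(1.1))))
        np.testing.assert_allclose(sol.A, 1.0 / (3 * np.pi), atol=1e-7)

    def test_matches_generic_solver(self, halfplane, rng):
        for _ in range(100):
            ys = np.cumsum(rng.uniform(0.8, 2.0, 3)) - 2.0
            ws = WindowSet.on_line(ys, 0.1)
            x0 = rng.uniform([0.5, -5.0], [10.0, 10.0])
            a = solve_window_system(halfplane, ws, SourceSpec(x0))
            b = three_window_explicit(halfplane, ws, SourceSpec(x0))
            np.testing.assert_allclose(a.A, b.A, atol=1e-10)

    def test_matches_generic_solver_disk(self, disk, rng):
        for _ in range(50):
            angles = np.sort(rng.uniform(0, 2 * np.pi, 3))
            if np.min(np.diff(angles)) < 0.5 or angles[-1] - angles[0] > 2 * np.pi - 0.5:
                continue
            ws = WindowSet.from_angles(angles, 0.1, disk.R)
            r = rng.uniform(2.0, 10.0)
            th = rng.uniform(0, 2 * np.pi)
            src = SourceSpec((r * np.cos(th), r * np.sin(th)))
            a = solve_window_system(disk, ws, src)
            b = three_window_explicit(disk, ws, src)
            np.testing.assert_allclose(a.A, b.A, atol=1e-10)


class TestSensitivity:
    def test_zero_on_symmetry_axis(self):
        assert sensitivity_ratio_halfplane(1.0, 10.0, 0.0, 0.1) == 0.0

    def test_leading_log_reference_value(self):
        # plain convention: (1/2) ln(110.25/90.25) / ln 10
        r = sensitivity_ratio_halfplane(1.0, 10.0, np.pi / 2, 0.1, capacity_factor=1.0)
        assert r == pytest.approx(0.043466, abs=1e-6)

    def test_matches_two_window_difference(self, halfplane, two_windows_line):
        d, L, th, eps = 1.0, 10.0, 1.0, 0.1
        r = sensitivity_ratio_halfplane(d, L, th, eps)
        src = SourceSpec((L * np.cos(th), L * np.sin(th)))
        p = splitting_two_windows(halfplane, two_windows_line, src).probabilities
        assert r == pytest.approx(abs(p[0] - p[1]), rel=1e-12)

    def test_large_distance_taylor_limit(self):
        # r * L / (d |sin th|) -> 1 / ln(d/eps_hat)
        d, eps, th = 1.0, 0.1, 0.7
        L = 1e3 * d
        r = sensitivity_ratio_halfplane(d, L, th, eps)
        lim = 1.0 / np.log(d / (eps / 4.0))
        assert r * L / (d * abs(np.sin(th))) == pytest.approx(lim, rel=1e-2)

    def test_detection_threshold_leading_log_values(self):
        f = detection_threshold_disk(1.0, 10.0, 0.1, capacity_factor=1.0)
        fa = detection_threshold_disk_asymptotic(1.0, 10.0, 0.1, capacity_factor=1.0)
        assert f == pytest.approx(0.066986, abs=1e-5)
        assert fa == pytest.approx(0.066762, abs=1e-5)

    def test_detection_threshold_asymptotic_limit(self):
        R, eps = 1.0, 0.1
        L = 1e4 * R
        ratio = (detection_threshold_disk(R, L, eps)
                 / detection_threshold_disk_asymptotic(R, L, eps))
        assert ratio == pytest.approx(1.0, abs=1e-3)

    def test_two_class_product_is_square(self):
        f = detection_threshold_disk(1.0, 7.0, 0.1)
        assert two_class_sensitivity_product(1.0, 7.0, 0.1) == pytest.approx(f**2)

    def test_domain_errors(self):
        with pytest.raises(RegimeViolationError):
            sensitivity_ratio_halfplane(1.0, 10.0, 0.5, 1.5)
        with pytest.raises(DomainError):
            detection_threshold_disk(1.0, 0.5, 0.1)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    y1=st.floats(-3.0, -0.6), y2=st.floats(0.6, 3.0),
    sx=st.floats(0.5, 8.0), sy=st.floats(-6.0, 6.0),
)
def test_two_window_probabilities_sum_to_one_and_lie_in_unit_interval(y1, y2, sx, sy):
    """Flux conservation and admissibility over a broad random family."""
    hp = HalfPlane()
    ws = WindowSet.on_line([y1, y2], 0.1)
    res = splitting_two_windows(hp, ws, SourceSpec((sx, sy)))
    assert res.probabilities.sum() == 1.0
    assert np.all(res.probabilities > 0.0) and np.all(res.probabilities < 1.0)
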
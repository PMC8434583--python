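"""Exact-arithmetic properties of the ring-electrode estimator derivation."""

from fractions import Fraction

import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from ringlap.fdm_core import (
    ConfigurationError,
    CREConfig,
    SingularMomentSystemError,
    _solve_fraction_system,
    difference_moments,
    estimate_from_surface_potentials,
    round_half_up,
    solve_weights,
    surface_circles,
    surface_moment,
    truncation_coefficient,
)
from ringlap.config_search import enumerate_configs

from oracles import X, Y, estimator_on_polynomial, laplacian


class TestConfig:
    @pytest.mark.parametrize(
        "disc, rings, expected",
        [
            (1, ((2, 3), (4, 9)), [(0, 1), (2, 3), (4, 5, 6, 7, 8, 9)]),
            (1, ((2, 3), (4, 6)), [(0, 1), (2, 3), (4, 5, 6)]),
            (2, ((3, 4), (5, 6)), [(0, 1, 2), (3, 4), (5, 6)]),
        ],
    )
    def test_surface_circles(self, disc, rings, expected):
        assert surface_circles(CREConfig(disc, rings)) == expected

    @pytest.mark.parametrize(
        "disc, rings",
        [
            (1, ((1, 2), (3, 4))),  # ring starts at the disc boundary
            (1, ((3, 2), (4, 5))),  # ring bounds reversed
            (0, ((1, 2), (3, 4))),  # zero disc
            (2, ((3, 4), (4, 5))),  # rings touch
        ],
    )
    def test_invalid_boundaries_rejected(self, disc, rings):
        with pytest.raises(ConfigurationError):
            CREConfig(disc, rings)

    def test_error_names_offending_pair(self):
        with pytest.raises(ConfigurationError, match="3 follows 3"):
            CREConfig(1, ((2, 3), (3, 9)))

    def test_compact_round_trip(self):
        cfg = CREConfig(1, ((2, 3), (4, 9)))
        assert cfg.compact() == "1|2-3|4-9"
        assert CREConfig.from_compact("1|2-3|4-9") == cfg
        assert CREConfig.from_dict(cfg.to_dict()) == cfg

    def test_dict_outer_radius_mismatch(self):
        with pytest.raises(ConfigurationError, match="outer_radius"):
            CREConfig.from_dict(
                {"outer_radius": 8, "disc_radius": 1, "rings": [[2, 3], [4, 9]]}
            )


class TestMoments:
    @pytest.mark.parametrize(
        "circles, k, expected",
        [
            ((0, 1), 1, Fraction(1, 2)),
            ((4, 5, 6, 7, 8, 9), 1, Fraction(271, 6)),
            ((8, 9), 3, Fraction(793585, 2)),
        ],
    )
    def test_surface_moment(self, circles, k, expected):
        assert surface_moment(circles, k) == expected

    def test_order_below_one_rejected(self):
        with pytest.raises(ValueError, match="order"):
            surface_moment((0, 1), 0)

    def test_moments_increase_with_order(self):
        cfg = CREConfig(2, ((4, 6), (7, 9)))
        for circles in surface_circles(cfg):
            moments = [surface_moment(circles, k) for k in range(1, 5)]
            assert all(a < b for a, b in zip(moments, moments[1:]))

    def test_first_order_differences_positive(self):
        for cfg in enumerate_configs(7):
            for row in difference_moments(cfg, [1]):
                assert row[0] > 0


class TestWeights:
    @pytest.mark.parametrize(
        "boundaries, expected",
        [
            ((1, 4, 5, 8, 9), (Fraction(37, 130), Fraction(-11, 468))),
            ((1, 3, 4, 8, 9), (Fraction(37, 90), Fraction(-7, 540))),
            ((1, 2, 3, 4, 9), (Fraction(952, 1227), Fraction(-6, 409))),
        ],
    )
    def test_published_weight_pairs(self, boundaries, expected):
        cfg = CREConfig.from_boundaries(boundaries)
        assert solve_weights(cfg).weights == expected

    @pytest.mark.parametrize(
        "boundaries, exact, rounded",
        [
            ((1, 4, 5, 8, 9), Fraction(163, 36), 4.528),
            ((1, 3, 4, 8, 9), Fraction(173, 60), 2.883),
            ((1, 2, 3, 4, 6), None, 0.685),
        ],
    )
    def test_truncation_coefficients(self, boundaries, exact, rounded):
        coef = truncation_coefficient(CREConfig.from_boundaries(boundaries))
        assert coef.order == 6
        if exact is not None:
            assert coef.value == exact
        assert coef.rounded(3) == rounded

    def test_identities_hold_on_every_radius9_config(self):
        """Exact cancellation/normalization on all 70 radius-9 layouts."""
        configs = enumerate_configs(9)
        assert len(configs) == 70
        for cfg in configs:
            w = solve_weights(cfg).weights
            diff = difference_moments(cfg, [1, 2])
            assert sum(wj * d[0] for wj, d in zip(w, diff)) == 4
            assert sum(wj * d[1] for wj, d in zip(w, diff)) == 0

    def test_general_ring_count_solver(self):
        """Quadripolar system cancels orders 2 and 3 and normalizes order 1."""
        cfg = CREConfig(1, ((2, 3), (4, 5), (6, 7)))
        w = solve_weights(cfg).weights
        diff = difference_moments(cfg, [1, 2, 3])
        assert sum(wj * d[0] for wj, d in zip(w, diff)) == 4
        assert sum(wj * d[1] for wj, d in zip(w, diff)) == 0
        assert sum(wj * d[2] for wj, d in zip(w, diff)) == 0
        assert truncation_coefficient(cfg).order == 8

    @given(
        bounds=st.sets(st.integers(min_value=1, max_value=13), min_size=5, max_size=5)
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_identities_hold_for_arbitrary_geometries(self, bounds):
        cfg = CREConfig.from_boundaries(tuple(sorted(bounds)))
        w = solve_weights(cfg).weights
        diff = difference_moments(cfg, [1, 2])
        assert sum(wj * d[0] for wj, d in zip(w, diff)) == 4
        assert sum(wj * d[1] for wj, d in zip(w, diff)) == 0
        assert truncation_coefficient(cfg).value > 0

    def test_singular_system_reports_matrix(self):
        with pytest.raises(SingularMomentSystemError) as exc:
            _solve_fraction_system(
                [[Fraction(1), Fraction(2)], [Fraction(2), Fraction(4)]],
                [Fraction(4), Fraction(0)],
            )
        assert exc.value.matrix[0] == [Fraction(1), Fraction(2)]


class TestEstimator:
    def test_constant_field_gives_zero(self):
        weights = solve_weights(CREConfig(1, ((2, 3), (4, 9))))
        assert estimate_from_surface_potentials(weights, [5.0, 5.0, 5.0], 0.1) == 0.0

    def test_h_scaling(self):
        weights = solve_weights(CREConfig(1, ((2, 3), (4, 9))))
        pots = [0.0, 1.0, 2.0]
        assert estimate_from_surface_potentials(weights, pots, 0.2) == pytest.approx(
            estimate_from_surface_potentials(weights, pots, 0.1) / 4
        )

    @pytest.mark.parametrize("h", [0.0, -1.0])
    def test_nonpositive_interval_rejected(self, h):
        weights = solve_weights(CREConfig(1, ((2, 3), (4, 9))))
        with pytest.raises(ValueError, match="positive"):
            estimate_from_surface_potentials(weights, [0.0, 1.0, 2.0], h)

    def test_wrong_potential_count_rejected(self):
        weights = solve_weights(CREConfig(1, ((2, 3), (4, 9))))
        with pytest.raises(ValueError, match="expected 3"):
            estimate_from_surface_potentials(weights, [0.0, 1.0], 0.1)


# Fields with their analytic Laplacians are checked exactly through the
# symbolic-circle-average oracle; degree <= 5 must be reproduced exactly.
DEGREE5_FIELDS = [
    X**2 + Y**2,
    X**4,
    X**3 * Y**2,
    3 * X**5 - sp.Rational(1, 2) * X**2 * Y**3 + 7 * X * Y - 2,
]


class TestPolynomialOracle:
    @pytest.mark.parametrize("poly", DEGREE5_FIELDS, ids=str)
    @pytest.mark.parametrize("boundaries", [(1, 2, 3, 4, 9), (1, 4, 5, 8, 9)])
    def test_exact_circle_averages_reproduce_laplacian(self, poly, boundaries):
        cfg = CREConfig.from_boundaries(boundaries)
        x0, y0, h = sp.Rational(3, 2), sp.Rational(-2, 5), sp.Rational(1, 9)
        est = estimator_on_polynomial(cfg, poly, x0, y0, h, sampling="exact")
        assert sp.simplify(est - laplacian(poly, x0, y0)) == 0

    @pytest.mark.parametrize(
        "poly",
        [X**2 + Y**2, X**3, X**2 * Y, X * Y, 2 * X**3 - Y**3 + X * Y - 5, X**4],
        ids=str,
    )
    def test_four_point_sampling_exact_for_low_degrees(self, poly):
        """4-point circle sampling differs from the true circle mean only in
        terms proportional to rho^(2k), k >= 2 — and the k = 2 mismatch is
        wiped out by the same weight cancellation, so cubic (and even
        quartic) fields are still reproduced exactly."""
        cfg = CREConfig(1, ((2, 3), (4, 9)))
        x0, y0, h = sp.Rational(1, 3), sp.Rational(2, 7), sp.Rational(1, 6)
        est = estimator_on_polynomial(cfg, poly, x0, y0, h, sampling="4pt")
        assert sp.simplify(est - laplacian(poly, x0, y0)) == 0

    def test_four_point_sampling_not_exact_at_degree_six(self):
        """Degree 6 hits the uncancelled truncation order."""
        cfg = CREConfig(1, ((2, 3), (4, 9)))
        x0, y0, h = sp.Integer(0), sp.Integer(0), sp.Rational(1, 6)
        est = estimator_on_polynomial(cfg, X**6, x0, y0, h, sampling="4pt")
        assert sp.simplify(est - laplacian(X**6, x0, y0)) != 0


class TestRounding:
    @pytest.mark.parametrize(
        "value, ndigits, expected",
        [
            (Fraction(1, 8), 2, 0.13),  # 0.125 rounds up, not to even
            (Fraction(27, 40), 2, 0.68),  # 0.675 exact tie
            (Fraction(-1, 8), 2, -0.13),  # ties away from zero
            (Fraction(163, 36), 3, 4.528),
        ],
    )
    def test_half_up_ties(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected
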
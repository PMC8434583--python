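"""Independent oracles shared by the unit and acceptance tests.

These deliberately avoid the library's own code paths: circle averages are
computed symbolically with sympy (exact trigonometric integrals) or as exact
4-point means over rational sample points, and the finite-difference
Laplacian uses a high-order stencil on the closed-form potential.
"""

from __future__ import annotations

from fractions import Fraction

import sympy as sp

from ringlap.dipole_field import Dipole, potential
from ringlap.fdm_core import CREConfig, solve_weights, surface_circles

X, Y = sp.symbols("x y")
_THETA = sp.symbols("theta")


def exact_circle_average(poly: sp.Expr, x0, y0, rho) -> sp.Expr:
    """Mean of a bivariate polynomial over a circle, by symbolic integration."""
    sub = poly.subs(
        {X: x0 + rho * sp.cos(_THETA), Y: y0 + rho * sp.sin(_THETA)}
    )
    return sp.simplify(sp.integrate(sp.expand(sub), (_THETA, 0, 2 * sp.pi)) / (2 * sp.pi))


def fourpt_circle_average(poly: sp.Expr, x0, y0, rho) -> sp.Expr:
    """Mean of a polynomial over the four axis-aligned circle points."""
    pts = [(x0 + rho, y0), (x0 - rho, y0), (x0, y0 + rho), (x0, y0 - rho)]
    return sp.simplify(sum(poly.subs({X: px, Y: py}) for px, py in pts) / 4)


def estimator_on_polynomial(
    config: CREConfig, poly: sp.Expr, x0, y0, h, sampling: str = "exact"
) -> sp.Expr:
    """Apply the ring-electrode Laplacian estimator to an analytic field.

    Surface potentials are means of circle averages (``sampling="exact"``)
    or of 4-point circle means (``sampling="4pt"``) at radii ``r * h``;
    the result is the estimate at the electrode centre, exact.
    """
    avg = exact_circle_average if sampling == "exact" else fourpt_circle_average
    circle_vals = {}
    for circles in surface_circles(config):
        for r in circles:
            if r not in circle_vals:
                circle_vals[r] = (
                    poly.subs({X: x0, Y: y0}) if r == 0 else avg(poly, x0, y0, r * h)
                )
    weights = solve_weights(config)
    surfaces = []
    for circles in surface_circles(config):
        surfaces.append(sum(circle_vals[r] for r in circles) / sp.Integer(len(circles)))
    disc = surfaces[0]
    acc = sum(
        sp.Rational(w.numerator, w.denominator) * (ring - disc)
        for w, ring in zip(weights.weights, surfaces[1:])
    )
    return sp.simplify(acc / h**2)


def laplacian(poly: sp.Expr, x0, y0) -> sp.Expr:
    """Analytic tangential Laplacian of a polynomial at a point."""
    return sp.simplify(
        (sp.diff(poly, X, 2) + sp.diff(poly, Y, 2)).subs({X: x0, Y: y0})
    )


def tangential_laplacian_fd(dipole: Dipole, x: float, y: float, step: float = 0.01):
    """-(v_xx + v_yy) of the dipole potential via 4th-order central stencils."""

    def d2(axis: str) -> float:
        def v(offset: float) -> float:
            if axis == "x":
                return potential(dipole, x + offset, y, 0.0)
            return potential(dipole, x, y + offset, 0.0)

        return (
            -v(2 * step) + 16 * v(step) - 30 * v(0.0) + 16 * v(-step) - v(-2 * step)
        ) / (12 * step**2)

    return -(d2("x") + d2("y"))


def brute_force_boundaries(outer_radius: int) -> set[tuple[int, ...]]:
    """All strictly increasing 5-tuples ending at the outer radius, by loops."""
    found = set()
    for d in range(1, outer_radius):
        for a1 in range(d + 1, outer_radius):
            for b1 in range(a1 + 1, outer_radius):
                for a2 in range(b1 + 1, outer_radius):
                    found.add((d, a1, b1, a2, outer_radius))
    return found
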
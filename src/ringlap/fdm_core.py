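"""Exact finite-dimensions-model (FDM) algebra for concentric ring electrodes.

A concentric ring electrode (CRE) records the surface potential on a central
disc and one or more concentric rings.  Linear combinations of the bipolar
differences *ring minus disc* estimate the surface Laplacian of the potential
at the electrode centre, the quantity that gives CREs their spatial
resolution advantage over conventional disc electrodes.

The finite-dimensions model places all electrode boundaries on an integer
grid: the electrode radius is split into equal intervals (nine for the
standard tripolar layouts), and the disc radius, ring widths and inter-ring
gaps are whole numbers of intervals.  The potential on a recording surface is
modelled as the unweighted mean of the circle-average potentials over the
integer-radius circles that the surface covers; the disc additionally
includes its centre point (the degenerate circle of radius 0).

Expanding each circle average in a Taylor series around the centre turns a
recording surface into a sequence of even-order radial moments.  Choosing the
ring weights so that the moment differences of orders ``2..n_rings`` cancel,
while the order-1 difference sums to 4, leaves the tangential Laplacian as
the leading term of the weighted bipolar combination divided by the squared
interval length.  The magnitude of the first *uncancelled* term — order
``2*(n_rings + 1)``, i.e. sixth order for a tripolar electrode — is the
truncation-term coefficient used to rank candidate geometries: the smaller
the coefficient, the more accurate the estimate.

Everything in this module is computed with :class:`fractions.Fraction`;
floating point appears only when callers ask for decimal renderings.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "ConfigurationError",
    "SingularMomentSystemError",
    "CREConfig",
    "EstimatorWeights",
    "TruncationCoefficient",
    "surface_circles",
    "surface_moment",
    "difference_moments",
    "solve_weights",
    "truncation_coefficient",
    "estimate_from_surface_potentials",
    "round_half_up",
    "format_fraction",
]


class ConfigurationError(ValueError):
    """Electrode boundaries are not strictly increasing positive integers."""


class SingularMomentSystemError(ArithmeticError):
    """The moment system has no unique weight solution.

    Carries the offending moment-difference matrix in :attr:`matrix`.
    """

    def __init__(self, matrix: Sequence[Sequence[Fraction]]):
        self.matrix = [list(row) for row in matrix]
        super().__init__(f"singular moment system: {self.matrix}")


_COMPACT_RE = re.compile(r"^(\d+)(\|\d+-\d+)+$")


@dataclass(frozen=True)
class CREConfig:
    """Integer-boundary geometry of an FDM concentric ring electrode.

    Parameters
    ----------
    disc_radius
        Outer radius of the central disc, in grid intervals (>= 1).
    ring_bounds
        One ``(inner, outer)`` integer pair per ring, ordered outward.  All
        boundaries must strictly increase:
        ``disc < inner_1 < outer_1 < inner_2 < ... < outer_n``.
    """

    disc_radius: int
    ring_bounds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        rings = tuple((int(a), int(b)) for a, b in self.ring_bounds)
        object.__setattr__(self, "ring_bounds", rings)
        object.__setattr__(self, "disc_radius", int(self.disc_radius))
        if not rings:
            raise ConfigurationError("at least one ring is required")
        if self.disc_radius < 1:
            raise ConfigurationError(
                f"disc_radius must be >= 1, got {self.disc_radius}"
            )
        prev = self.disc_radius
        for a, b in rings:
            for bound in (a, b):
                if bound <= prev:
                    raise ConfigurationError(
                        f"boundaries must strictly increase: {bound} follows {prev} "
                        f"in {self.boundaries}"
                    )
                prev = bound

    @property
    def n_rings(self) -> int:
        return len(self.ring_bounds)

    @property
    def outer_radius(self) -> int:
        return self.ring_bounds[-1][1]

    @property
    def boundaries(self) -> tuple[int, ...]:
        """Flat strictly-increasing boundary tuple ``(disc, a1, b1, ..)``."""
        return (self.disc_radius,) + tuple(b for pair in self.ring_bounds for b in pair)

    @classmethod
    def from_boundaries(cls, boundaries: Sequence[int]) -> "CREConfig":
        """Build from the flat tuple ``(disc, a1, b1, a2, b2, ...)``."""
        if len(boundaries) < 3 or len(boundaries) % 2 == 0:
            raise ConfigurationError(
                f"need an odd number (>= 3) of boundaries, got {list(boundaries)}"
            )
        disc = boundaries[0]
        rings = tuple(
            (boundaries[i], boundaries[i + 1]) for i in range(1, len(boundaries), 2)
        )
        return cls(disc, rings)

    def compact(self) -> str:
        """Compact notation, e.g. ``"1|2-3|4-9"``."""
        return "|".join(
            [str(self.disc_radius)] + [f"{a}-{b}" for a, b in self.ring_bounds]
        )

    @classmethod
    def from_compact(cls, text: str) -> "CREConfig":
        if not _COMPACT_RE.match(text):
            raise ConfigurationError(f"cannot parse config notation {text!r}")
        parts = text.split("|")
        rings = tuple(
            tuple(int(x) for x in part.split("-")) for part in parts[1:]
        )
        return cls(int(parts[0]), rings)  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        return {
            "outer_radius": self.outer_radius,
            "disc_radius": self.disc_radius,
            "rings": [list(pair) for pair in self.ring_bounds],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CREConfig":
        cfg = cls(data["disc_radius"], tuple(tuple(r) for r in data["rings"]))
        if "outer_radius" in data and data["outer_radius"] != cfg.outer_radius:
            raise ConfigurationError(
                f"outer_radius {data['outer_radius']} does not match rings "
                f"(outer boundary {cfg.outer_radius})"
            )
        return cfg


def surface_circles(config: CREConfig) -> list[tuple[int, ...]]:
    """Integer circle radii covered by each recording surface.

    The disc covers circles ``0..disc_radius`` (its centre point is the
    radius-0 circle); a ring ``(a, b)`` covers circles ``a..b``.
    """
    out = [tuple(range(config.disc_radius + 1))]
    for a, b in config.ring_bounds:
        out.append(tuple(range(a, b + 1)))
    return out


def surface_moment(circles: Iterable[int], k: int) -> Fraction:
    """Mean of ``r**(2k)`` over a set of integer circle radii, exact.

    This is the order-``k`` radial moment of a recording surface: the
    coefficient structure the circle-average Taylor expansion attaches to the
    order-``2k`` derivative term.
    """
    if k < 1:
        raise ValueError(f"moment order must be >= 1, got {k}")
    radii = list(circles)
    if not radii:
        raise ValueError("empty circle set")
    return Fraction(sum(r ** (2 * k) for r in radii), len(radii))


def difference_moments(config: CREConfig, orders: Sequence[int]) -> list[list[Fraction]]:
    """Ring-minus-disc moment differences ``D[j][i] = m_k(ring j) - m_k(disc)``.

    Rows index rings (outward order), columns index the requested ``orders``.
    """
    surfaces = surface_circles(config)
    disc = surfaces[0]
    disc_moments = [surface_moment(disc, k) for k in orders]
    return [
        [surface_moment(ring, k) - m for k, m in zip(orders, disc_moments)]
        for ring in surfaces[1:]
    ]


@dataclass(frozen=True)
class EstimatorWeights:
    """Exact weights of the bipolar-difference combination for one geometry.

    The Laplacian estimate is ``sum_j w_j * (P_ring_j - P_disc) / h**2`` with
    ``h`` the physical interval length.  The weights satisfy, exactly:

    * ``sum_j w_j * D[j, k] == 0`` for ``k = 2..n_rings`` (truncation-term
      cancellation), and
    * ``sum_j w_j * D[j, 1] == 4`` (the order-1 circle-average term carries
      ``r**2 / 4`` of the Laplacian, so the estimate is normalized to one
      unit of it).
    """

    config: CREConfig
    weights: tuple[Fraction, ...]

    def estimate(self, surface_potentials: Sequence[float], h: float) -> float:
        return estimate_from_surface_potentials(self, surface_potentials, h)


def _solve_fraction_system(
    matrix: list[list[Fraction]], rhs: list[Fraction]
) -> list[Fraction]:
    """Gaussian elimination with partial (nonzero) pivoting over Fractions."""
    n = len(matrix)
    aug = [row[:] + [r] for row, r in zip(matrix, rhs)]
    for col in range(n):
        pivot = next((i for i in range(col, n) if aug[i][col] != 0), None)
        if pivot is None:
            raise SingularMomentSystemError(matrix)
        aug[col], aug[pivot] = aug[pivot], aug[col]
        inv = 1 / aug[col][col]
        aug[col] = [x * inv for x in aug[col]]
        for i in range(n):
            if i != col and aug[i][col] != 0:
                factor = aug[i][col]
                aug[i] = [x - factor * y for x, y in zip(aug[i], aug[col])]
    return [aug[i][n] for i in range(n)]


def solve_weights(config: CREConfig) -> EstimatorWeights:
    """Solve for the exact Laplacian-estimate weights of a configuration.

    The linear system cancels the moment differences of orders
    ``2..n_rings`` and normalizes the order-1 sum to 4.  For a tripolar
    electrode this is the 2x2 system whose printed solutions for the
    classical layouts are (37/130, -11/468), (37/90, -7/540) and
    (952/1227, -6/409).
    """
    n = config.n_rings
    orders = list(range(1, n + 1))
    diff = difference_moments(config, orders)
    # Row 0: normalization (order 1); rows 1..n-1: cancellation (orders 2..n).
    matrix = [[diff[j][i] for j in range(n)] for i in range(n)]
    rhs = [Fraction(4)] + [Fraction(0)] * (n - 1)
    weights = _solve_fraction_system(matrix, rhs)
    return EstimatorWeights(config, tuple(weights))


@dataclass(frozen=True)
class TruncationCoefficient:
    """Magnitude of the first uncancelled Taylor term of an estimator.

    ``order`` is ``2 * (n_rings + 1)`` (6 for tripolar); ``value`` is
    ``|sum_j w_j * D[j, n_rings + 1]| / (2 * order!)`` — divisor 1440 at
    order 6, matching the published tables digit for digit.  Only ratios of
    coefficients matter for ranking geometries.
    """

    value: Fraction
    order: int

    def rounded(self, ndigits: int = 3) -> float:
        return round_half_up(self.value, ndigits)


def truncation_coefficient(
    config: CREConfig, weights: EstimatorWeights | None = None
) -> TruncationCoefficient:
    """Truncation-term coefficient of the lowest remaining order."""
    if weights is None:
        weights = solve_weights(config)
    k = config.n_rings + 1
    diff = difference_moments(config, [k])
    total = sum(w * d[0] for w, d in zip(weights.weights, diff))
    order = 2 * k
    value = abs(total) / (2 * math.factorial(order))
    return TruncationCoefficient(value=value, order=order)


def estimate_from_surface_potentials(
    weights: EstimatorWeights, surface_potentials: Sequence[float], h: float
) -> float:
    """Tangential-Laplacian estimate from per-surface potentials.

    ``surface_potentials`` holds one value per recording surface, disc first;
    ``h`` is the physical interval length (electrode radius divided by the
    outer boundary).  Returns ``sum_j w_j (P_j - P_disc) / h**2`` in
    potential units per squared length — the mathematical (x, y) Laplacian,
    +4 for the field ``x**2 + y**2``.
    """
    if h <= 0:
        raise ValueError(f"interval length h must be positive, got {h}")
    if len(surface_potentials) != weights.config.n_rings + 1:
        raise ValueError(
            f"expected {weights.config.n_rings + 1} surface potentials, "
            f"got {len(surface_potentials)}"
        )
    disc = surface_potentials[0]
    acc = sum(
        w * (p - disc) for w, p in zip(weights.weights, surface_potentials[1:])
    )
    return acc / (h * h)


def round_half_up(value: Fraction | float, ndigits: int = 0) -> float:
    """Decimal rounding with ties away from zero, exact for Fractions.

    The published tables render coefficients to 3 decimals and percentages
    to 2; ``round()``'s banker's rounding can differ on exact ties.
    """
    frac = Fraction(value)
    scale = Fraction(10) ** ndigits
    scaled = frac * scale
    if scaled >= 0:
        quantized = (2 * scaled.numerator + scaled.denominator) // (
            2 * scaled.denominator
        )
    else:
        quantized = -((-2 * scaled.numerator + scaled.denominator) // (
            2 * scaled.denominator
        ))
    return float(Fraction(quantized) / scale)


def format_fraction(value: Fraction) -> str:
    """Render a Fraction as ``"num/den"`` (or ``"num"`` for integers)."""
    if value.denominator == 1:
        return str(value.numerator)
    return f"{value.numerator}/{value.denominator}"
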
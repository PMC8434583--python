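"""Exhaustive enumeration and ranking of concentric-ring-electrode layouts.

For a given outer radius ``R`` (in grid intervals) and ring count ``n``, every
admissible geometry corresponds to a strictly increasing integer boundary
tuple ``(disc, a1, b1, ..., a_n)`` ending at ``b_n = R`` — there are
``C(R - 1, 2n)`` of them (70 tripolar layouts at the standard radius 9).
Ranking them by the exact truncation-term coefficient turns electrode design
into a small combinatorial optimization that can be solved by brute force.

The ranking obeys a handful of qualitative design principles (checked in
:func:`check_principles`): keep the disc and the inner rings minimal and the
surfaces as close together as possible, spend all remaining width on the
outer ring, and when a gap must exist, push it outward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fdm_core import (
    CREConfig,
    TruncationCoefficient,
    format_fraction,
    round_half_up,
    solve_weights,
    truncation_coefficient,
)

__all__ = [
    "RankedConfig",
    "enumerate_configs",
    "rank_configs",
    "named_config",
    "NAMED_CONFIGS",
    "ranking_table",
    "check_principles",
]

#: Classical tripolar layouts at outer radius 9: constant inter-ring
#: distances (CIRD), linearly increasing inter-ring distances (LIIRD), and
#: the minimum-truncation-coefficient geometry.
NAMED_CONFIGS: Mapping[str, CREConfig] = {
    "CIRD": CREConfig(1, ((4, 5), (8, 9))),
    "LIIRD": CREConfig(1, ((3, 4), (8, 9))),
    "OPTIMAL": CREConfig(1, ((2, 3), (4, 9))),
}


@dataclass(frozen=True)
class RankedConfig:
    """One row of a ranking: geometry, coefficient and increase vs rank 1."""

    rank: int
    config: CREConfig
    coefficient: TruncationCoefficient
    pct_increase: Fraction  # exact 100 * (coef / coef_opt - 1)

    @property
    def pct_increase_rounded(self) -> float:
        return round_half_up(self.pct_increase, 2)


def enumerate_configs(outer_radius: int, n_rings: int = 2) -> list[CREConfig]:
    """All admissible configurations with the given outer radius.

    Boundaries are every strictly increasing choice of ``2 * n_rings``
    integers from ``1..outer_radius - 1`` followed by ``outer_radius``.
    Returns an empty list (with a warning) when the radius is too small to
    admit any geometry.
    """
    if n_rings < 1:
        raise ValueError(f"n_rings must be >= 1, got {n_rings}")
    need = 2 * n_rings
    if outer_radius - 1 < need:
        warnings.warn(
            f"outer radius {outer_radius} admits no {n_rings}-ring "
            f"configuration (needs at least {need + 1})",
            stacklevel=2,
        )
        return []
    configs = []
    for inner in combinations(range(1, outer_radius), need):
        configs.append(CREConfig.from_boundaries(inner + (outer_radius,)))
    return configs


def rank_configs(configs: Sequence[CREConfig]) -> list[RankedConfig]:
    """Rank configurations by exact truncation coefficient, ascending.

    All configurations must share the same outer radius and ring count.
    Ties (not observed for radii 5-12) break lexicographically on the
    boundary tuple.  Percentage increases are computed from the exact
    rational coefficient ratio before any rounding.
    """
    if not configs:
        raise ValueError("cannot rank an empty configuration list")
    radii = {c.outer_radius for c in configs}
    rings = {c.n_rings for c in configs}
    if len(radii) > 1 or len(rings) > 1:
        raise ValueError(
            f"mixed geometries: outer radii {sorted(radii)}, ring counts {sorted(rings)}"
        )
    scored = sorted(
        ((truncation_coefficient(c), c) for c in configs),
        key=lambda item: (item[0].value, item[1].boundaries),
    )
    best = scored[0][0].value
    return [
        RankedConfig(
            rank=i + 1,
            config=c,
            coefficient=coef,
            pct_increase=100 * (coef.value / best - 1),
        )
        for i, (coef, c) in enumerate(scored)
    ]


def named_config(name: str, outer_radius: int = 9) -> CREConfig:
    """Look up a classical layout (``CIRD``, ``LIIRD`` or ``OPTIMAL``)."""
    key = name.strip().upper()
    if key not in NAMED_CONFIGS:
        raise KeyError(
            f"unknown configuration {name!r}; valid names: "
            f"{', '.join(sorted(NAMED_CONFIGS))}"
        )
    if outer_radius != 9:
        raise ValueError(
            f"named configurations are defined for outer radius 9, got {outer_radius}"
        )
    return NAMED_CONFIGS[key]


def ranking_table(
    ranked: Sequence[RankedConfig],
    top: int | None = None,
    bottom: int | None = None,
    include: Iterable[CREConfig] = (),
) -> pd.DataFrame:
    """Tabulate a ranking in the published layout.

    ``top``/``bottom`` select head/tail rows; ``include`` forces specific
    geometries (e.g. the named classical layouts) into the selection.  With
    all three unset, every row is emitted.  Columns carry both the rounded
    decimals the tables print and the exact fractions.
    """
    wanted: set[int] | None = None
    if top is not None or bottom is not None or include:
        wanted = set()
        if top:
            wanted.update(r.rank for r in ranked[:top])
        if bottom:
            wanted.update(r.rank for r in ranked[-bottom:])
        forced = {c.boundaries for c in include}
        wanted.update(r.rank for r in ranked if r.config.boundaries in forced)

    rows = []
    for r in ranked:
        if wanted is not None and r.rank not in wanted:
            continue
        cfg = r.config
        row: dict[str, object] = {
            "rank": r.rank,
            "central_disc_radius": cfg.disc_radius,
        }
        for j, (a, b) in enumerate(cfg.ring_bounds, start=1):
            label = (
                "outer" if j == cfg.n_rings
                else "middle" if cfg.n_rings == 2
                else f"ring{j}"
            )
            row[f"{label}_ring_inner"] = a
            row[f"{label}_ring_outer"] = b
        weights = solve_weights(cfg)
        row.update(
            {
                "coefficient": r.coefficient.rounded(3),
                "increase_pct": r.pct_increase_rounded,
                "coefficient_exact": format_fraction(r.coefficient.value),
                "weights_exact": ";".join(
                    format_fraction(w) for w in weights.weights
                ),
                "config": cfg.compact(),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _coef(boundaries: tuple[int, ...]) -> Fraction:
    return truncation_coefficient(CREConfig.from_boundaries(boundaries)).value


def check_principles(outer_radius: int) -> dict[str, bool]:
    """Check the five qualitative design principles on one radius (tripolar).

    1. The best layout is ``(1, (2, 3), (4, R))``: minimal disc, minimal
       middle ring, minimal gaps, all remaining width on the outer ring.
    2. Widening the outer ring (moving its inner boundary inward) always
       lowers the coefficient, other boundaries equal.
    3. Closing the middle-outer gap from the outer side (widening the outer
       ring) beats closing it from the middle side (widening the middle
       ring).
    4. Closing the disc-middle gap by widening the middle ring inward beats
       closing it by growing the disc.
    5. For equal disc and ring widths, placing the larger gap outward gives
       the smaller coefficient.
    """
    ranked = rank_configs(enumerate_configs(outer_radius, n_rings=2))
    results: dict[str, bool] = {}
    results["p1_minimal_inner_maximal_outer"] = ranked[0].config.boundaries == (
        1, 2, 3, 4, outer_radius,
    )

    r = outer_radius
    p2 = p3 = p4 = p5 = True
    for rc in ranked:
        d, a1, b1, a2, b2 = rc.config.boundaries
        # P2: widen the outer ring by one interval.
        if a2 - b1 >= 2:
            p2 &= _coef((d, a1, b1, a2 - 1, b2)) < rc.coefficient.value
            # P3: same gap closed by widening the middle ring instead.
            p3 &= _coef((d, a1, b1, a2 - 1, b2)) < _coef((d, a1, b1 + 1, a2, b2))
        # P4: close a disc-middle gap by ring width vs by disc radius.
        if a1 - d >= 2:
            p4 &= _coef((d, a1 - 1, b1, a2, b2)) < _coef((d + 1, a1, b1, a2, b2))
        # P5: swap unequal gaps so the larger one sits outward.
        g1, g2 = a1 - d - 1, a2 - b1 - 1
        if g1 > g2:
            w1, w2 = b1 - a1, b2 - a2
            swapped = (d, d + g2 + 1, d + g2 + 1 + w1,
                       d + g2 + 1 + w1 + g1 + 1, b2)
            if swapped[3] + w2 == b2:
                p5 &= _coef(swapped) < rc.coefficient.value
    results["p2_wider_outer_ring_wins"] = p2
    results["p3_widen_outer_over_middle"] = p3
    results["p4_widen_ring_over_disc"] = p4
    results["p5_larger_gap_outward"] = p5
    return results
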
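# Methods

## Electrode model and estimator derivation

A concentric ring electrode is modelled on an integer grid: the outer radius
is divided into `N` equal intervals (N = 9 throughout; the physical interval
length is `h = diameter/18`), and every boundary — disc radius, ring inner
and outer radii — is an integer number of intervals. A geometry is the
strictly increasing boundary tuple `(disc, a₁, b₁, ..., a_n, b_n = N)`.

The potential on a recording surface is the unweighted mean of the
circle-average potentials on the integer-radius circles it covers; the disc
includes its centre point (the radius-0 "circle"). This circle-potential
averaging — rather than area-weighted annulus averaging — is the convention
under which the solver reproduces the classical published weight pairs
exactly, and is the package's fixed convention.

Expanding the circle average of a smooth potential `v` about the centre,

    v̄(ρ) − v(0) = (ρ²/4)·∇²v + higher even-order terms,

each surface contributes exact rational radial moments
`m_k(S) = mean_{r∈S}(r^{2k})`. With bipolar differences
`D_{j,k} = m_k(ring_j) − m_k(disc)`, the estimator weights solve the linear
system

    Σ_j w_j·D_{j,k} = 0   for k = 2..n_rings   (truncation cancellation)
    Σ_j w_j·D_{j,1} = 4                         (Laplacian normalization)

by Gaussian elimination over `fractions.Fraction`; the solver is written for
any ring count (the quadripolar/pentapolar systems cancel orders 2..n), with
acceptance-grade validation done for the tripolar case. The ranking statistic
is the magnitude of the first uncancelled term,

    coefficient = |Σ_j w_j·D_{j, n+1}| / (2·(2(n+1))!)    (divisor 1440 at order 6),

an exact rational. The divisor is a fixed normalization chosen to match the
published tables digit-for-digit; only coefficient *ratios* matter for
ranking and for predicting error increases. Percentage increases over the
optimum are computed from the exact rational ratio and only then rounded
(half-up, 2 decimals; coefficients render at 3 decimals), which avoids
last-digit drift.

Exhaustive search is used because the space is tiny: `C(N−1, 2n)` geometries
(70 tripolar layouts at N = 9, 330 at N = 12). Ties between equal
coefficients would break lexicographically on the boundary tuple; none occur
for radii 5–12.

## Dipole validation model

The forward model is a unit current dipole at depth 1–10 cm below the
measurement plane, oriented along +Z, in an unbounded homogeneous medium,
with distances in cm, conductivity entered as 7.14 (mS/cm) and unit moment,
so potentials read as volts:

    v = (r_rel·p) / (4πσ·|r_rel|³)

The reference surface Laplacian is the standard closed form

    ∇v = 3/(4πσ)·[ 5·dz²·(r_rel·p)/|r_rel|⁷ − ((r_rel·p) + 2·dz·p_z)/|r_rel|⁵ ]

**Sign convention.** On the source-free measurement plane `v` is harmonic in
3-D, so this expression equals `∂²v/∂z² = −(∂²v/∂x² + ∂²v/∂y²)` — the
current-source-density orientation used in electrophysiology, positive above
a +Z dipole. The core estimator (`fdm_core`) returns the mathematical
tangential Laplacian (+4 for the field `x² + y²`); the mesh evaluator
(`mesh_eval`) therefore forms its estimate maps with disc-minus-ring
differences so that estimates and reference share the CSD orientation (the
quadratic field maps to −4 there). Comparing across orientations would make
the relative error ≈ 200 % instead of the few percent actually observed.

**Mesh.** 700 × 700 nodes, spacing 0.25/9 cm ≈ 0.278 mm (side ≈ 19.4 cm),
dipole projected exactly under node (350, 350). The spacing makes every
tested electrode diameter (0.5–5 cm in 0.5 cm steps) an integer number of
grid steps per interval (`2·diameter_cm`), so all circle sample points fall
on nodes and the valid region (nodes at least nine circle-radii from every
edge) is exactly `700 − 18·steps` per side: 682 nodes at 0.5 cm, 520 at 5 cm.
Placing a node exactly on-axis makes the on-axis closed forms exact and the
maps symmetric; evaluating with half-node dipole offsets changes every
reported measure by under 0.01 percentage points, so the node-centred
placement is the default and the only convention exercised.

**Circle sampling.** Circle potentials are 4-point means (the axis-aligned
nodes at each radius). For a tripolar electrode this sampling is exact for
polynomial fields through degree 5 — the 4-point/circular-mean mismatch is
proportional to ρ^(2k) with k ≥ 2, and the k = 2 mismatch is annihilated by
the same weight cancellation — with the first genuine sampling error at the
(already uncancelled) sixth order. The test suite asserts this, slightly
strengthening the usual degree ≤ 3 statement.

**Measures** (per configuration, diameter, depth, over the valid region):

- `max_amp` — maximum of the map (sensitivity), V/cm²; the analytic maximum
  sits at the centre node, inside every valid region.
- `nsg` — normalized spatial gradient at the dipole node: mean over four
  cross displacements of 0.5 cm (18 grid steps) of
  `|L(centre) − L(displaced)| / L(centre)`, using the map's own signed
  centre value (positive here).
- `re` — relative (L2) error vs the closed form; `nme` — maximum absolute
  error normalized by the reference's maximum absolute value; `max_err` —
  the raw maximum error, computed but secondary to `nme`.

Per-depth increase statistics (`100·(err_config/err_optimal − 1)` over the
ten diameters) are summarized as mean ± **population** standard deviation
(`ddof = 0`); this is the convention under which the computed spreads match
the published per-depth statistics to the printed digit. Medians over depths
of the per-depth means are the summary used to check consistency with the
analytic coefficient ratios (within 5 %; at 10 cm depth the agreement is
within 1 %).

## Numerical and design notes

- All analytic computation (moments, weights, coefficients, increases) is
  exact rational arithmetic; floats appear only in the field model, the mesh
  maps and final rendering. Decimal rendering rounds half-up (ties away from
  zero), 3 decimals for coefficients and 2 for percentages.
- The mesh pipeline is vectorized: circle-mean maps are shifted array views,
  so a full 10-diameter × 10-depth × 3-configuration sweep runs in a few
  seconds on one CPU. These are also the problem sizes used by the test
  suite and the acceptance script.
- A singular moment system cannot arise from a valid strictly-increasing
  geometry (the order-1 differences are strictly positive and the moment
  rows are generically independent), but the solver still detects and
  reports it with the offending matrix.
- Degenerate inputs are rejected early with named boundaries: non-increasing
  boundary tuples, non-positive interval length, electrode diameters that do
  not align circle radii to mesh nodes, and NSG evaluation at a zero centre
  value.
- There is no randomness anywhere in the pipeline; identical inputs produce
  byte-identical outputs.

## Limitations

- The medium is a homogeneous half-space evaluated in closed form on a plane;
  multi-layer conductor models (layered abdomen, spherical head) and curved
  or flexible substrates are out of scope, as are physical-electrode effects
  (salt bridges between closely spaced surfaces — a real concern precisely
  for the optimal, minimal-gap layouts).
- The validation dipole is vertical and centred; the field formulas support
  arbitrary moments, but tilted or off-centre sources are not part of the
  evaluated sweeps.
- The truncation-coefficient divisor `2·(2(n+1))!` beyond the tripolar case
  is an extrapolation of the tripolar normalization; it cancels in ratios,
  which is all the ranking uses.
- Mesh-model agreement with the published validation values is within
  0.03 percentage points for errors and amplitudes; the published NSG values
  for the estimate maps are printed at one decimal, and the CIRD estimate's
  NSG computes to 11.29 % against a printed 11.4 % — the lone value that
  differs by more than rounding of the computed number.
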
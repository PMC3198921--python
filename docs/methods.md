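# Methods

## The model

`nichecomp` treats the bone-marrow hematopoietic stem-cell (HSC) niche as a
structured habitat: a large number of identical sites, each holding at most
one cell.  Two species compete for sites — resident HSCs and disseminated
tumor cells — and the state is the pair of occupied-site fractions
(ρ₁, ρ₂) on the unit simplex (ρᵢ ≥ 0, ρ₁ + ρ₂ ≤ 1).

**Classic (strict-hierarchy) variant.**  Species 1 is absolutely superior: a
species-1 birth claims any site not already held by species 1, evicting a
species-2 occupant for free, while species 2 establishes only on empty sites:

    dρ₁/dt = β₁ρ₁(1 − ρ₁) − μ₁ρ₁
    dρ₂/dt = β₂ρ₂(1 − ρ₁ − ρ₂) − μ₂ρ₂ − β₁ρ₁ρ₂

βᵢ are per-capita colonization (birth) rates and μᵢ per-capita death rates
(apoptosis or movement out of the niche); both carry units of 1/time, with
the time unit left abstract throughout.  Setting the flow to zero gives the
closed-form equilibrium

    ρ₁* = 1 − μ₁/β₁
    ρ₂* = 1 − μ₂/β₂ − ρ₁*(1 + β₁/β₂) = μ₁/β₁ − μ₂/β₂ + μ₁/β₂ − β₁/β₂

(the two printed forms are algebraically identical; a property test confirms
they agree to 1e-12 over 1000 random parameter draws).  A negative
closed-form component means that species is competitively excluded; the
result object then carries the realized boundary equilibrium together with a
`feasible=False` flag so the raw diagnostic is not lost.

**Generalized (mutual-displacement) variant.**  Real HSCs and tumor cells
are unlikely to behave as absolute superior/inferior competitors.  A
displacement probability k ∈ [0, 1] (species 1 evicting species 2) and
v ∈ [0, 1] (species 2 evicting species 1) generalize the hierarchy:

    dρ₁/dt = β₁ρ₁[1 − ρ₁ − (1−k)ρ₂] − μ₁ρ₁ − β₂ρ₂ρ₁·v
    dρ₂/dt = β₂ρ₂[1 − (1−v)ρ₁ − ρ₂] − μ₂ρ₂ − β₁ρ₁ρ₂·k

k = 1, v = 0 recovers the classic variant exactly; the expressions are
arranged so the reduction holds bit-for-bit in floating point, and both a
derandomized property test and an acceptance check assert it at 1e-15
relative tolerance.  For ρ₁, ρ₂ ≠ 0 the interior equilibrium solves the
linear nullcline system

    β₁ρ₁ + [β₁(1−k) + β₂v]ρ₂           = β₁ − μ₁
    [β₂(1−v) + β₁k]ρ₁ + β₂ρ₂           = β₂ − μ₂

solved with `numpy.linalg`.  Systems with |det| < 1e-12 are reported as
degenerate rather than solved: k = v = 0 (no displacement at all) is the
canonical case, where the nullclines are parallel and no isolated interior
fixed point exists.

**Stability.**  The analytic Jacobian of the generalized flow is evaluated
at a fixed point and classified by the signs of the eigenvalue real parts
(stable / unstable / saddle, with a ±1e-10 band reported as marginal).
Stability classification is this package's addition — the habitat model
itself only defines the flow — and it is kept in separate functions so the
core vector fields stand alone.  When the interior solution is infeasible,
`interior_equilibrium_general` returns the "best" feasible boundary fixed
point, defined here as the linearly stable one (ties broken by larger total
density); this choice is the package's own, made because the stable boundary
point is where the flow actually delivers the system.

## Numerical integration

`scipy.integrate.solve_ivp` with DOP853, rtol = 1e-9, atol = 1e-14, dense
output sampled on 1000 evenly spaced points by default.  The dynamics are
non-stiff at the parameter scales of interest (rates ≤ ~2/time), so an
explicit high-order scheme is appropriate and keeps the integration error
three decades below the tightest comparison tolerance (1e-6) used anywhere.

The exact flow never leaves the simplex (on ρ₁ + ρ₂ = 1 the colonization
terms cancel and d(ρ₁+ρ₂)/dt = −μ₁ρ₁ − μ₂ρ₂ ≤ 0, an identity asserted by a
property test), but the numerical solution of an extinction trajectory can
undershoot zero by accumulated absolute error, empirically ~100·atol over a
100-time-unit horizon.  atol = 1e-14 keeps the worst undershoot near 1e-12;
components in [−1e-10, 0) are clipped to zero and anything below −1e-10 is
raised as an integrator failure rather than masked.

Equilibrium location by integration proceeds in chunks of ≤ 200 time units
until the RHS infinity-norm falls below 1e-10 (then the state is within
~1e-9 of the fixed point, since the slowest contraction rate among the
built-in panels is ~0.012/time) or a horizon of t = 20000 is exhausted,
in which case the result is flagged not-converged rather than raised.
The generous horizon matters: from ρ₁(0) = 1e-4 the generalized-model
invader grows at only ≈ 0.0125/time (its per-capita growth rate against the
resident's quasi-equilibrium background), so it needs t ≈ 550 merely to
reach macroscopic density and t ≈ 1400 to get within 1e-5 of equilibrium —
well past the panel's display horizon of 1000, at which the state is still
~9e-4 away.

**Lag (dormancy) metric.**  The dormancy of a low-density invader is
quantified as the first time its density reaches a fraction f of its
equilibrium value (default f = 0.9), linearly interpolated between stored
samples; `None` marks thresholds never reached within the horizon.  The
fractional-threshold definition is this package's operationalization of the
qualitative "lag period": it is monotone in f, zero when the species starts
above threshold, and independent of the time grid up to interpolation error.

## Stochastic lattice counterpart

The finite-habitat process makes the site picture explicit: L sites,
per-site occupancy in {empty, species 1, species 2}.  Events are simulated
exactly (Gillespie): with counts (n₁, n₂) the total event rate is
(β₁+μ₁)n₁ + (β₂+μ₂)n₂; a species-i birth picks a target site uniformly over
all L sites (well-mixed dispersal — the mean-field equations carry no
spatial structure, so the lattice does not either), succeeding on an empty
site, with probability k (resp. v) on a site held by the other species, and
never on a site held by its own species (the attempt is wasted, matching the
1 − ρᵢ − (1−k)ρⱼ establishment factor).  Deaths vacate a uniformly random
occupant of the species instantaneously.  Per-attempt displacement with
probability k (or v) makes the expected drift of (n₁/L, n₂/L) exactly the
generalized vector field, so replicate averages converge to the ODE as
L → ∞ and the lattice is an independent check on the deterministic core.

The event loop is numba-jitted (index lists with O(1) swap-removal; ~10⁷
events/s), which keeps 100 replicates at L = 10⁴ over 200 time units under
half a minute.  Replicate seeds derive from the master seed via
`numpy.random.SeedSequence(master).generate_state(2·replicates)` masked to
31 bits (one init seed, one simulation seed per replicate); identical master
seeds give byte-identical CSV output.

`compare_to_meanfield` reports, per grid time and species, the replicate
mean, its standard error, the ODE value, and z = (mean − ODE)/SE.  When all
replicates coincide (SE = 0 up to round-off in the mean) the only admissible
deviation is the half-site initial-rounding error 0.5/L.

**Known limitation of the z summary.**  For an invader launched from a
single founder occupant the early-time population is a near-critical
branching process: most replicates go extinct and the mean is carried by
rare surviving lineages.  The resulting t-statistic is heavy-tailed, and
with 100 replicates |z| can occasionally exceed 4 for the invading species
even though the simulator is exact — the deficit of survivors depresses the
sample mean and the sample SE together.  The resident species and
stationary-density checks do not suffer from this and stay within |z| ≈ 3.

## Built-in scenarios

Nine panels in three families; parameters are frozen as printed in the
source captions (see the literal table in `tests/test_scenarios.py`):

| family | variant | species 1 | species 2 | notes |
|--------|---------|-----------|-----------|-------|
| fig2a–c | classic | HSC (β₁=0.2, μ₁=0.1) | cancer (β₂=0.8, μ₂=0.1) | resident superior; invader seeded at 1e-4 (a), 0.1 (b); resident at 0.4 (c) |
| fig3a–c | classic | cancer (β₁=0.2, μ₁=0.1) | HSC (β₂=0.8, μ₂=0.1) | invader superior, seeded at 1e-4/0.01; fig3c lowers β₂ to 0.6 |
| fig4a–c | general (k=0.9, v=0.1) | cancer | HSC | same states as fig3a–c; fig4c records β₂ = 0.61 as printed, preserving its discrepancy with fig3c's 0.60 |

The classic-family horizon is 500 time units (unstated in the source; the
classic dynamics settle within ~1e-10 of equilibrium well before t = 500, so
the choice is inconsequential and is recorded in each run's config).  The
general family uses the stated horizon of 1000.  Classic panels carry
k = 1, v = 0 so the generalized Jacobian, stability classification and
lattice process specialize to them without a separate code path.

`run_scenario` bundles the trajectory, the analytic equilibrium (closed form
or linear solve), the integration-located equilibrium (settled, i.e. run to
convergence past the display horizon), the stability label, and per-species
lag metrics at f = 0.9 measured against the analytic equilibrium.

## What the scenarios do and do not show

The scenario suite demonstrates the model's qualitative claims: initial
densities move the time to equilibrium (dormancy lag) but not the
equilibrium itself; a smaller seeding density prolongs the lag; lowering the
inferior species' birth rate lowers its equilibrium (1/6 vs 1/4); partial
mutual displacement lowers the invader's equilibrium (1/7 vs 1/2) and slows
both species' approach.  All of this is internal to the model: no clinical
data enter anywhere, rates are constant and density-independent, cells are
a single homogeneous species per side, and the habitat is fixed, homogeneous
and well-mixed.  Passing tests validate the mathematics and the simulators,
not the biological fidelity of the model to marrow metastasis.

## Tolerances and degenerate inputs

| constant | value | role |
|----------|-------|------|
| state validation | 1e-9 | densities may undershoot 0 / overshoot sum=1 by this much |
| fixed-point check | 1e-9 | RHS norm for accepting a point into `classify_stability` |
| settle tolerance | 1e-10 | RHS norm at which integration declares equilibrium |
| eigenvalue band | 1e-10 | real parts within ±band classify as marginal |
| determinant | 1e-12 | below this the nullcline system is degenerate |
| clip band | 1e-10 | integrator output below −band is an error, above is clipped |

Degenerate discretizations are refused loudly: a nonzero density that rounds
to zero occupants at the requested L (e.g. ρ = 1e-4 at L = 1000) raises an
error naming the minimum L rather than silently extinguishing the species.
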
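"""Two-species competition for a structured habitat.

The habitat (the bone-marrow hematopoietic niche) is a large collection of
sites, each holding at most one cell.  Species densities rho1, rho2 are the
occupied-site fractions.  Two deterministic mean-field variants are provided:

* the *classic* strict-hierarchy model, in which species 1 colonizes as if
  species-2 occupants were absent (it displaces them freely) while species 2
  can only establish on empty sites and is additionally evicted by species-1
  births::

      drho1/dt = beta1*rho1*(1 - rho1) - mu1*rho1
      drho2/dt = beta2*rho2*(1 - rho1 - rho2) - mu2*rho2 - beta1*rho1*rho2

* the *generalized* mutual-displacement model, in which a species-1 birth
  landing on a species-2 site succeeds with probability k, and symmetrically a
  species-2 birth displaces species 1 with probability v::

      drho1/dt = beta1*rho1*(1 - rho1 - (1-k)*rho2) - mu1*rho1 - beta2*rho2*rho1*v
      drho2/dt = beta2*rho2*(1 - (1-v)*rho1 - rho2) - mu2*rho2 - beta1*rho1*rho2*k

  Setting k=1, v=0 recovers the classic model term by term (the expressions
  below are arranged so the reduction is exact in floating point).

Closed-form equilibria exist for the classic model; the generalized model's
interior (coexistence) equilibrium is the solution of a 2x2 linear nullcline
system.  Stability is classified from the eigenvalues of the analytic
Jacobian.  Stability classification is an addition of this package: the
habitat model itself only defines the flow, and all stability machinery is
kept in separate functions so the core vector fields stand alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateParametersError, ValidationError

#: tolerance for treating a density component as zero when labelling regimes
ZERO_TOL = 1e-9
#: tolerance for accepting a state as lying on the simplex
STATE_TOL = 1e-9
#: tolerance on |det| below which the nullcline system is called degenerate
DET_TOL = 1e-12
#: half-width of the "marginal" band for eigenvalue real parts
EIG_TOL = 1e-10
#: tolerance for verifying that a point is a fixed point of the flow
FIXED_POINT_TOL = 1e-9

REGIME_BOTH_EXTINCT = "both-extinct"
REGIME_SPECIES1_ONLY = "species1-only"
REGIME_SPECIES2_ONLY = "species2-only"
REGIME_COEXISTENCE = "coexistence"


@dataclass(frozen=True)
class CompetitionParams:
    """Rate parameters of the competition model.

    Parameters
    ----------
    beta1, beta2
        Per-capita colonization (birth) rates, per unit time; must be > 0.
    mu1, mu2
        Per-capita death rates (apoptosis or movement out of the niche),
        per unit time; must be >= 0.
    k
        Proportion of species-2 occupants displaceable by a species-1 birth,
        in [0, 1].  k=1 together with v=0 gives the classic strict hierarchy.
    v
        Proportion of species-1 occupants displaceable by a species-2 birth,
        in [0, 1].
    """

    beta1: float
    beta2: float
    mu1: float
    mu2: float
    k: float = 1.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if not (self.beta1 > 0 and self.beta2 > 0):
            raise ValidationError(
                f"birth rates must be positive: beta1={self.beta1}, beta2={self.beta2}"
            )
        if not (self.mu1 >= 0 and self.mu2 >= 0):
            raise ValidationError(
                f"death rates must be non-negative: mu1={self.mu1}, mu2={self.mu2}"
            )
        if not (0.0 <= self.k <= 1.0):
            raise ValidationError(f"k={self.k} outside the bound [0,1]")
        if not (0.0 <= self.v <= 1.0):
            raise ValidationError(f"v={self.v} outside the bound [0,1]")

    def with_kv(self, k: float, v: float) -> "CompetitionParams":
        return replace(self, k=k, v=v)


@dataclass(frozen=True)
class DensityState:
    """Occupied-site fractions (rho1, rho2) on the unit simplex."""

    rho1: float
    rho2: float

    def __post_init__(self) -> None:
        if self.rho1 < -STATE_TOL or self.rho2 < -STATE_TOL:
            raise ValidationError(
                f"negative density beyond tolerance: ({self.rho1}, {self.rho2})"
            )
        if self.rho1 + self.rho2 > 1.0 + STATE_TOL:
            raise ValidationError(
                f"rho1 + rho2 = {self.rho1 + self.rho2} exceeds 1 beyond tolerance"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.rho1, self.rho2], dtype=float)


@dataclass(frozen=True)
class EquilibriumResult:
    """A fixed point of one of the model variants.

    ``feasible`` reports whether the *raw* analytic components lie in the
    simplex; when a closed-form component is negative the realized densities
    are the corresponding boundary equilibrium, the regime is adjusted, and
    ``feasible`` stays False so the diagnostic information is not lost.
    """

    rho1_star: float
    rho2_star: float
    regime: str
    feasible: bool
    method: str  # closed_form | linear_solve | integration
    stability: str = "not-assessed"
    converged: bool | None = None
    t_reached: float | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.rho1_star, self.rho2_star], dtype=float)


def classify_regime(rho1: float, rho2: float, tol: float = ZERO_TOL) -> str:
    """Label which species persist at a fixed point."""
    z1 = abs(rho1) <= tol
    z2 = abs(rho2) <= tol
    if z1 and z2:
        return REGIME_BOTH_EXTINCT
    if z2:
        return REGIME_SPECIES1_ONLY
    if z1:
        return REGIME_SPECIES2_ONLY
    return REGIME_COEXISTENCE


# ---------------------------------------------------------------------------
# vector fields
# ---------------------------------------------------------------------------

def _rhs_classic_raw(rho1: float, rho2: float, p: CompetitionParams) -> tuple[float, float]:
    d1 = p.beta1 * rho1 * (1.0 - rho1) - p.mu1 * rho1
    d2 = p.beta2 * rho2 * (1.0 - rho1 - rho2) - p.mu2 * rho2 - p.beta1 * rho1 * rho2
    return d1, d2


def _rhs_general_raw(rho1: float, rho2: float, p: CompetitionParams) -> tuple[float, float]:
    # arranged so that k=1, v=0 reproduces _rhs_classic_raw bit for bit
    d1 = (
        p.beta1 * rho1 * (1.0 - rho1 - (1.0 - p.k) * rho2)
        - p.mu1 * rho1
        - p.beta2 * rho2 * rho1 * p.v
    )
    d2 = (
        p.beta2 * rho2 * (1.0 - (1.0 - p.v) * rho1 - rho2)
        - p.mu2 * rho2
        - p.beta1 * rho1 * rho2 * p.k
    )
    return d1, d2


def rhs_classic(params: CompetitionParams, state: DensityState) -> tuple[float, float]:
    """Time derivatives (drho1/dt, drho2/dt) of the classic model.

    Displacement coefficients k, v in ``params`` are ignored.
    """
    return _rhs_classic_raw(state.rho1, state.rho2, params)


def rhs_general(params: CompetitionParams, state: DensityState) -> tuple[float, float]:
    """Time derivatives of the generalized mutual-displacement model."""
    return _rhs_general_raw(state.rho1, state.rho2, params)


def rhs_for(variant: str):
    """Return the raw (rho1, rho2, params) -> (d1, d2) function for a variant."""
    if variant == "classic":
        return _rhs_classic_raw
    if variant == "general":
        return _rhs_general_raw
    raise ValidationError(f"unknown model variant: {variant!r}")


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------

def equilibrium_classic(params: CompetitionParams) -> EquilibriumResult:
    """Closed-form equilibrium of the classic model.

    rho1* = 1 - mu1/beta1.  With species 1 settled, the species-2 nullcline
    gives rho2* = mu1/beta1 - mu2/beta2 + mu1/beta2 - beta1/beta2 (equivalently
    1 - mu2/beta2 - rho1*(1 + beta1/beta2)).  Negative raw components mean the
    corresponding species is excluded: the realized densities are the boundary
    equilibrium and ``feasible`` records that the raw formula left the simplex.
    """
    raw1 = 1.0 - params.mu1 / params.beta1
    raw2 = (
        params.mu1 / params.beta1
        - params.mu2 / params.beta2
        + params.mu1 / params.beta2
        - params.beta1 / params.beta2
    )
    feasible = raw1 >= 0.0 and raw2 >= 0.0 and raw1 + raw2 <= 1.0
    if raw1 <= ZERO_TOL:
        # species 1 cannot persist; species 2 relaxes to its single-species level
        rho1, rho2 = 0.0, max(0.0, 1.0 - params.mu2 / params.beta2)
    elif raw2 <= ZERO_TOL:
        rho1, rho2 = raw1, 0.0
    else:
        rho1, rho2 = raw1, raw2
    return EquilibriumResult(
        rho1_star=rho1,
        rho2_star=rho2,
        regime=classify_regime(rho1, rho2),
        feasible=feasible,
        method="closed_form",
    )


def boundary_equilibria(params: CompetitionParams) -> list[EquilibriumResult]:
    """The origin and the two single-species fixed points.

    Single-species densities 1 - mu_i/beta_i below zero are reported as-is
    with ``feasible=False``.
    """
    out = [
        EquilibriumResult(0.0, 0.0, REGIME_BOTH_EXTINCT, True, "closed_form")
    ]
    s1 = 1.0 - params.mu1 / params.beta1
    out.append(
        EquilibriumResult(s1, 0.0, classify_regime(s1, 0.0), s1 >= 0.0, "closed_form")
    )
    s2 = 1.0 - params.mu2 / params.beta2
    out.append(
        EquilibriumResult(0.0, s2, classify_regime(0.0, s2), s2 >= 0.0, "closed_form")
    )
    return out


def nullcline_system(params: CompetitionParams) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient matrix and right-hand side of the interior nullclines.

    Dividing the generalized vector field by rho1 and rho2 respectively gives

        beta1*rho1 + [beta1*(1-k) + beta2*v]*rho2 = beta1 - mu1
        [beta2*(1-v) + beta1*k]*rho1 + beta2*rho2 = beta2 - mu2
    """
    p = params
    a = np.array(
        [
            [p.beta1, p.beta1 * (1.0 - p.k) + p.beta2 * p.v],
            [p.beta2 * (1.0 - p.v) + p.beta1 * p.k, p.beta2],
        ]
    )
    b = np.array([p.beta1 - p.mu1, p.beta2 - p.mu2])
    return a, b


def interior_equilibrium_general(params: CompetitionParams) -> EquilibriumResult:
    """Coexistence equilibrium of the generalized model by linear solve.

    If the nullcline intersection falls outside the open feasible region the
    returned densities are the best feasible boundary equilibrium (the
    linearly stable one when exactly one is; ties broken by larger total
    density) with ``feasible=False`` flagging the infeasible interior point.
    """
    a, b = nullcline_system(params)
    det = float(np.linalg.det(a))
    if abs(det) < DET_TOL:
        raise DegenerateParametersError(
            f"nullcline system is singular (|det| = {abs(det):.3e} < {DET_TOL})"
        )
    rho1, rho2 = np.linalg.solve(a, b)
    if rho1 > 0.0 and rho2 > 0.0 and rho1 + rho2 < 1.0:
        return EquilibriumResult(
            float(rho1), float(rho2), REGIME_COEXISTENCE, True, "linear_solve"
        )
    # interior point infeasible: fall back to the boundary
    candidates = [e for e in boundary_equilibria(params) if e.feasible]
    stable = [
        e for e in candidates
        if classify_stability(params, e, _check_fixed_point=False) == "stable"
    ]
    pool = stable if stable else candidates
    best = max(pool, key=lambda e: e.rho1_star + e.rho2_star)
    return replace(best, feasible=False, method="linear_solve")


# ---------------------------------------------------------------------------
# linearization and stability
# ---------------------------------------------------------------------------

def jacobian_general(params: CompetitionParams, state: DensityState) -> np.ndarray:
    """Analytic Jacobian of the generalized vector field at ``state``."""
    p, r1, r2 = params, state.rho1, state.rho2
    j11 = p.beta1 * (1.0 - 2.0 * r1 - (1.0 - p.k) * r2) - p.mu1 - p.beta2 * r2 * p.v
    j12 = -p.beta1 * r1 * (1.0 - p.k) - p.beta2 * r1 * p.v
    j21 = -p.beta2 * r2 * (1.0 - p.v) - p.beta1 * r2 * p.k
    j22 = p.beta2 * (1.0 - (1.0 - p.v) * r1 - 2.0 * r2) - p.mu2 - p.beta1 * r1 * p.k
    return np.array([[j11, j12], [j21, j22]])


def classify_stability(
    params: CompetitionParams,
    eq: EquilibriumResult,
    *,
    _check_fixed_point: bool = True,
) -> str:
    """Linear stability of a fixed point of the generalized model.

    Labels: both eigenvalue real parts < -1e-10 -> "stable"; both > 1e-10 ->
    "unstable"; opposite signs -> "saddle"; any within the band -> "marginal".
    """
    state = DensityState(eq.rho1_star, eq.rho2_star)
    if _check_fixed_point:
        d = _rhs_general_raw(state.rho1, state.rho2, params)
        if max(abs(d[0]), abs(d[1])) > FIXED_POINT_TOL:
            raise ValidationError(
                f"({eq.rho1_star}, {eq.rho2_star}) is not a fixed point of the "
                f"generalized model: |rhs| = {max(abs(d[0]), abs(d[1])):.3e}"
            )
    eigs = np.linalg.eigvals(jacobian_general(params, state))
    re = np.real(eigs)
    if np.any(np.abs(re) <= EIG_TOL):
        return "marginal"
    if np.all(re < 0.0):
        return "stable"
    if np.all(re > 0.0):
        return "unstable"
    return "saddle"
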
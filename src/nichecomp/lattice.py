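"""Exact stochastic simulation of the finite occupancy process.

The habitat is an explicit collection of L sites, each empty or held by one
cell of species 1 or 2.  Events form a continuous-time Markov jump process
simulated exactly (Gillespie):

* species-i birth attempts occur at rate ``beta_i * n_i`` and pick a target
  site uniformly at random over the whole habitat (well-mixed dispersal —
  the deterministic equations carry no spatial terms, so neither does the
  lattice).  An attempt succeeds on an empty site, succeeds with probability
  k (species 1 displacing species 2) or v (species 2 displacing species 1)
  on a site held by the other species, and is wasted on a site already held
  by the attempting species;
* species-i deaths occur at rate ``mu_i * n_i`` and vacate a uniformly random
  occupant of that species instantaneously (a displaced or dead cell leaves
  the habitat).

Per-attempt displacement with probability k (or v) makes the expected drift
of (n1/L, n2/L) exactly the generalized mean-field vector field, so replicate
averages at large L are an independent check on the ODE core.

The event loop is numba-jitted; a given (lattice, parameters, seed) triple is
bit-reproducible.  Replicate seeds are derived from the master seed with
``numpy.random.SeedSequence(master).generate_state(...)``, masked to 31 bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .dynamics import Trajectory, integrate
from .errors import DegenerateDiscretizationError, ValidationError
from .model import CompetitionParams, DensityState

EMPTY, SP1, SP2 = 0, 1, 2


@dataclass
class LatticeState:
    """Explicit habitat of L sites with per-site occupancy codes {0, 1, 2}."""

    L: int
    occupancy: np.ndarray  # int8, length L
    n1: int
    n2: int
    t: float = 0.0

    def validate(self) -> None:
        if self.L < 1 or len(self.occupancy) != self.L:
            raise ValidationError("occupancy length must equal L >= 1")
        c1 = int(np.count_nonzero(self.occupancy == SP1))
        c2 = int(np.count_nonzero(self.occupancy == SP2))
        if (c1, c2) != (self.n1, self.n2):
            raise ValidationError(
                f"counts ({self.n1}, {self.n2}) do not match occupancy ({c1}, {c2})"
            )
        if self.n1 + self.n2 > self.L:
            raise ValidationError("n1 + n2 exceeds L")

    def densities(self) -> DensityState:
        return DensityState(self.n1 / self.L, self.n2 / self.L)


def init_lattice(L: int, initial: DensityState, seed: int) -> LatticeState:
    """Scatter round(L*rho_i) occupants of each species on distinct sites.

    Raises :class:`DegenerateDiscretizationError` when a nonzero density
    rounds to zero occupants (the discretization would silently extinguish
    that species; use a larger L).
    """
    if L < 1:
        raise ValidationError(f"L must be >= 1, got {L}")
    n1 = int(round(L * initial.rho1))
    n2 = int(round(L * initial.rho2))
    for name, rho, n in (("rho1", initial.rho1, n1), ("rho2", initial.rho2, n2)):
        if rho > 0 and n == 0:
            raise DegenerateDiscretizationError(
                f"{name} = {rho} rounds to 0 occupants at L = {L}; "
                f"use L >= {int(np.ceil(0.5 / rho))} to resolve this density"
            )
    if n1 + n2 > L:
        raise ValidationError("initial densities fill more than the whole lattice")
    occ = np.zeros(L, dtype=np.int8)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(L, size=n1 + n2, replace=False)
    occ[chosen[:n1]] = SP1
    occ[chosen[n1:]] = SP2
    return LatticeState(L=L, occupancy=occ, n1=n1, n2=n2, t=0.0)


@njit(cache=False)
def _gillespie(occ, L, beta1, beta2, mu1, mu2, k, v, t_grid, seed):  # pragma: no cover
    np.random.seed(seed)
    # index lists per species with O(1) swap-removal
    sites1 = np.empty(L, np.int64)
    sites2 = np.empty(L, np.int64)
    pos = np.full(L, -1, np.int64)
    n1 = 0
    n2 = 0
    for s in range(L):
        if occ[s] == 1:
            sites1[n1] = s
            pos[s] = n1
            n1 += 1
        elif occ[s] == 2:
            sites2[n2] = s
            pos[s] = n2
            n2 += 1
    ng = t_grid.shape[0]
    out1 = np.zeros(ng, np.int64)
    out2 = np.zeros(ng, np.int64)
    gi = 0
    t = 0.0
    while gi < ng:
        total = (beta1 + mu1) * n1 + (beta2 + mu2) * n2
        if total <= 0.0:
            while gi < ng:
                out1[gi] = n1
                out2[gi] = n2
                gi += 1
            break
        t_next = t + np.random.exponential(1.0 / total)
        while gi < ng and t_grid[gi] < t_next:
            out1[gi] = n1
            out2[gi] = n2
            gi += 1
        t = t_next
        if gi >= ng:
            break
        u = np.random.random() * total
        birth1 = beta1 * n1
        birth2 = birth1 + beta2 * n2
        death1 = birth2 + mu1 * n1
        if u < birth1:
            s = np.random.randint(0, L)
            c = occ[s]
            if c == 0 or (c == 2 and np.random.random() < k):
                if c == 2:
                    j = pos[s]
                    n2 -= 1
                    sites2[j] = sites2[n2]
                    pos[sites2[j]] = j
                occ[s] = 1
                sites1[n1] = s
                pos[s] = n1
                n1 += 1
        elif u < birth2:
            s = np.random.randint(0, L)
            c = occ[s]
            if c == 0 or (c == 1 and np.random.random() < v):
                if c == 1:
                    j = pos[s]
                    n1 -= 1
                    sites1[j] = sites1[n1]
                    pos[sites1[j]] = j
                occ[s] = 2
                sites2[n2] = s
                pos[s] = n2
                n2 += 1
        elif u < death1:
            j = np.random.randint(0, n1)
            s = sites1[j]
            n1 -= 1
            sites1[j] = sites1[n1]
            pos[sites1[j]] = j
            occ[s] = 0
            pos[s] = -1
        else:
            j = np.random.randint(0, n2)
            s = sites2[j]
            n2 -= 1
            sites2[j] = sites2[n2]
            pos[sites2[j]] = j
            occ[s] = 0
            pos[s] = -1
    return out1, out2, n1, n2, t


def _seed31(x: np.uint32) -> int:
    return int(x) & 0x7FFFFFFF


def simulate_lattice(
    params: CompetitionParams,
    lattice: LatticeState,
    t_max: float,
    record_every: float,
    seed: int,
) -> Trajectory:
    """Run the jump process to ``t_max``, recording densities periodically.

    The input lattice is left untouched; the returned trajectory has one row
    per multiple of ``record_every`` in [0, t_max], starting with the initial
    densities.
    """
    lattice.validate()
    if t_max <= 0 or record_every <= 0:
        raise ValidationError("t_max and record_every must be positive")
    grid = np.arange(0.0, t_max + 0.5 * record_every, record_every)
    occ = lattice.occupancy.copy()
    out1, out2, _, _, _ = _gillespie(
        occ, lattice.L,
        params.beta1, params.beta2, params.mu1, params.mu2, params.k, params.v,
        grid, np.uint32(seed),
    )
    states = np.column_stack([out1 / lattice.L, out2 / lattice.L])
    return Trajectory(times=grid, states=states, variant="lattice", params=params)


def replicate_seeds(master_seed: int, replicates: int) -> list[tuple[int, int]]:
    """(init_seed, sim_seed) pair per replicate, split from the master seed."""
    words = np.random.SeedSequence(master_seed).generate_state(2 * replicates)
    return [
        (_seed31(words[2 * r]), _seed31(words[2 * r + 1]))
        for r in range(replicates)
    ]


def compare_to_meanfield(
    params: CompetitionParams,
    variant: str,
    initial: DensityState,
    L: int,
    replicates: int,
    t_grid: np.ndarray,
    seed: int,
) -> pd.DataFrame:
    """Replicate-averaged lattice densities against the ODE on a shared grid.

    Returns one row per grid time with columns ``time, mean_rho1, se_rho1,
    ode_rho1, z1, mean_rho2, se_rho2, ode_rho2, z2`` where z is the
    standardized deviation of the replicate mean from the ODE value.  The
    classic variant is the k=1, v=0 special case of the jump process.
    """
    if replicates < 2:
        raise ValidationError(
            f"replicates must be >= 2 for a standard error, got {replicates}"
        )
    t_grid = np.asarray(t_grid, dtype=float)
    if variant == "classic":
        lat_params = params.with_kv(1.0, 0.0)
    elif variant == "general":
        lat_params = params
    else:
        raise ValidationError(f"unknown model variant: {variant!r}")

    acc = np.empty((replicates, len(t_grid), 2))
    for r, (init_seed, sim_seed) in enumerate(replicate_seeds(seed, replicates)):
        lat = init_lattice(L, initial, init_seed)
        occ = lat.occupancy
        out1, out2, _, _, _ = _gillespie(
            occ, L,
            lat_params.beta1, lat_params.beta2, lat_params.mu1, lat_params.mu2,
            lat_params.k, lat_params.v, t_grid, np.uint32(sim_seed),
        )
        acc[r, :, 0] = out1 / L
        acc[r, :, 1] = out2 / L

    mean = acc.mean(axis=0)
    se = acc.std(axis=0, ddof=1) / np.sqrt(replicates)
    ode = integrate(params, variant, initial, float(t_grid[-1]), output_grid=t_grid)
    diff = mean - ode.states
    # when all replicates agree (se = 0 up to round-off in the mean) the only
    # admissible deviation is the initial-rounding half-site; anything larger
    # is a genuine discrepancy.  Replicate densities are multiples of 1/L, so
    # any real spread gives se >> 1/(10*L*sqrt(replicates)).
    se_floor = 0.01 / (L * np.sqrt(replicates))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            se > se_floor, diff / np.where(se > se_floor, se, 1.0),
            np.where(np.abs(diff) <= 0.5 / L + 1e-12, 0.0, np.inf),
        )
    return pd.DataFrame(
        {
            "time": t_grid,
            "mean_rho1": mean[:, 0],
            "se_rho1": se[:, 0],
            "ode_rho1": ode.states[:, 0],
            "z1": z[:, 0],
            "mean_rho2": mean[:, 1],
            "se_rho2": se[:, 1],
            "ode_rho2": ode.states[:, 1],
            "z2": z[:, 1],
        }
    )
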
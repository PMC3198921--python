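"""Built-in simulation scenarios: the nine published figure panels.

Three families of three panels each.  In the fig2 family the resident HSCs
are the strict superior species and the tumor cells invade as the inferior
species; fig3 swaps the roles (tumor cells strictly superior, invading a
high-density HSC resident); fig4 repeats the fig3 setups under the
generalized model with partial mutual displacement (k=0.9, v=0.1 — the tumor
displaces 90% of HSC occupants it lands on, HSCs displace 10% of tumor
occupants).

Rates are shared across families (beta1=0.2, mu1=0.1 for species 1;
beta2=0.8, mu2=0.1 for species 2) except the reduced-birth-rate panels:
fig3c uses beta2=0.6 and fig4c uses beta2=0.61 as printed in the respective
captions (the 0.60/0.61 discrepancy is preserved, not harmonized).  The
classic-family horizon is 500 time units; the general family runs to the
stated 1000.  Classic panels carry k=1, v=0 so the generalized vector field,
Jacobian and lattice process all specialize to them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    LagMetrics,
    Trajectory,
    find_equilibrium_by_integration,
    integrate,
    time_to_fraction,
)
from .model import (
    CompetitionParams,
    DensityState,
    EquilibriumResult,
    classify_stability,
    equilibrium_classic,
    interior_equilibrium_general,
)

#: default equilibrium fraction defining the lag/dormancy time
LAG_FRACTION = 0.9
#: horizon used when locating equilibria by integration (generous: the
#: general-model invasion transient is slow, ~e^{0.0125 t} from rho=1e-4)
SETTLE_T_MAX = 20000.0


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    variant: str  # classic | general
    params: CompetitionParams
    initial: DensityState
    species1_label: str  # HSC | cancer
    species2_label: str
    t_max: float


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    trajectory: Trajectory
    eq_analytic: EquilibriumResult
    eq_integrated: EquilibriumResult
    stability: str
    lag1: LagMetrics | None
    lag2: LagMetrics | None


def _classic(beta1, mu1, beta2, mu2):
    return CompetitionParams(beta1=beta1, beta2=beta2, mu1=mu1, mu2=mu2, k=1.0, v=0.0)


def builtin_scenarios() -> dict[str, ScenarioSpec]:
    """Registry of the nine figure-panel fixtures, keyed by name."""
    hsc_sup = _classic(0.2, 0.1, 0.8, 0.1)  # fig2: species 1 = HSC (superior)
    ca_sup = _classic(0.2, 0.1, 0.8, 0.1)  # fig3: species 1 = cancer (superior)
    ca_sup_lowb2 = _classic(0.2, 0.1, 0.6, 0.1)
    gen = CompetitionParams(beta1=0.2, beta2=0.8, mu1=0.1, mu2=0.1, k=0.9, v=0.1)
    gen_lowb2 = CompetitionParams(beta1=0.2, beta2=0.61, mu1=0.1, mu2=0.1, k=0.9, v=0.1)

    def spec(name, variant, params, rho1, rho2, lab1, lab2, t_max):
        return ScenarioSpec(
            name=name, variant=variant, params=params,
            initial=DensityState(rho1, rho2),
            species1_label=lab1, species2_label=lab2, t_max=t_max,
        )

    reg = [
        spec("fig2a", "classic", hsc_sup, 0.6, 0.0001, "HSC", "cancer", 500.0),
        spec("fig2b", "classic", hsc_sup, 0.6, 0.1, "HSC", "cancer", 500.0),
        spec("fig2c", "classic", hsc_sup, 0.4, 0.0001, "HSC", "cancer", 500.0),
        spec("fig3a", "classic", ca_sup, 0.0001, 0.5, "cancer", "HSC", 500.0),
        spec("fig3b", "classic", ca_sup, 0.01, 0.85, "cancer", "HSC", 500.0),
        spec("fig3c", "classic", ca_sup_lowb2, 0.0001, 0.84, "cancer", "HSC", 500.0),
        spec("fig4a", "general", gen, 0.0001, 0.5, "cancer", "HSC", 1000.0),
        spec("fig4b", "general", gen, 0.01, 0.85, "cancer", "HSC", 1000.0),
        spec("fig4c", "general", gen_lowb2, 0.0001, 0.84, "cancer", "HSC", 1000.0),
    ]
    return {s.name: s for s in reg}


def get_scenario(name: str) -> ScenarioSpec:
    reg = builtin_scenarios()
    if name not in reg:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(reg))}"
        )
    return reg[name]


def analytic_equilibrium(spec: ScenarioSpec) -> EquilibriumResult:
    """Closed form for classic panels, nullcline linear solve for general."""
    if spec.variant == "classic":
        return equilibrium_classic(spec.params)
    return interior_equilibrium_general(spec.params)


def run_scenario(
    spec: ScenarioSpec,
    output_grid: np.ndarray | None = None,
    lag_fraction: float = LAG_FRACTION,
) -> ScenarioResult:
    """Trajectory, both equilibrium routes, stability, and lag metrics.

    Lag metrics are first-passage times to ``lag_fraction`` of the analytic
    equilibrium density, per species (None for a species whose equilibrium
    density is zero).  The integration equilibrium follows the flow until it
    settles, which for the slow general-model invasions runs far beyond the
    panel's display horizon.
    """
    traj = integrate(spec.params, spec.variant, spec.initial, spec.t_max, output_grid)
    eq_a = analytic_equilibrium(spec)
    eq_i = find_equilibrium_by_integration(
        spec.params, spec.variant, spec.initial, t_max=max(SETTLE_T_MAX, spec.t_max)
    )
    stability = classify_stability(spec.params, eq_a)
    lag1 = (
        time_to_fraction(traj, 1, lag_fraction, eq_a.rho1_star)
        if eq_a.rho1_star > 0 else None
    )
    lag2 = (
        time_to_fraction(traj, 2, lag_fraction, eq_a.rho2_star)
        if eq_a.rho2_star > 0 else None
    )
    return ScenarioResult(
        spec=spec, trajectory=traj, eq_analytic=eq_a, eq_integrated=eq_i,
        stability=stability, lag1=lag1, lag2=lag2,
    )
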
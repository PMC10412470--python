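"""Steady 0D solve of the VEP-assisted Fontan circulation.

Topology (device serves the IVC pathway only; the SVC joins downstream of
the throat at the TCPC junction):

    IVC inflow (prescribed) --> device inlet --> mixing throat <-- aortic jet
                                         |            |
                                  atrial discharge    v
                                  (to atrium, 5)   diffuser --> TCPC/PA outlet (10)
    SVC inflow (prescribed) ----------------------------------^

Caval inflows are prescribed flow sources (the reference setup prescribes
inlet velocity profiles, i.e. flows); the pulmonary outlets are lumped
into a single prescribed-pressure node and the atrium is a prescribed-
pressure sink.  The only nonlinear unknown is the throat static pressure,
coupled to the graft and atrial-discharge orifice flows; it is solved by
damped fixed-point iteration with a bisection fallback (deterministic, no
randomness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import Enum

import yaml

from .geometry import DeviceGeometry, TCPCGeometry, port_area, validate_device
from .hydraulics import (FluidProperties, LossModel, ejector_throat_pressure,
                         orifice_flow, pathway_loss)
from .units import LMIN_TO_M3S, PA_TO_MMHG

__all__ = [
    "Scenario",
    "Mode",
    "HemodynamicState",
    "SolverError",
    "solve_circulation",
    "apply_mode",
    "pressure_change_vs_baseline",
]


class Mode(Enum):
    """Operating mode of the circulation solve.

    BASELINE excludes the device entirely (plain TCPC pathways);
    AOG_OCCLUSION pins the graft flow to zero with the atrial discharge
    still draining toward the atrium; FULL_FAILURE pins both shunts to
    zero with the device body still in line.
    """

    BASELINE = "baseline"
    FULL_ASSIST = "full_assist"
    AOG_OCCLUSION = "aog_occlusion"
    FULL_FAILURE = "full_failure"


@dataclass(frozen=True)
class Scenario:
    """Boundary conditions and fluid properties for one circulation solve.

    Defaults are the postoperative pediatric Fontan stage: 2.1 L/min total
    caval return with a 60/40 IVC/SVC split, 65 mmHg mean aortic pressure
    at the graft inlet, 10 mmHg at both lumped pulmonary outlets, 5 mmHg
    mean atrial pressure.  For the PSC2 anatomy the SVC return is split
    20/20% between the innominate veins (bookkeeping only).
    """

    Q_caval_total: float = 2.1      # L/min
    ivc_fraction: float = 0.6
    P_aorta: float = 65.0           # mmHg
    P_PA_outlet: float = 10.0       # mmHg, both lungs (lumped)
    P_atrium: float = 5.0           # mmHg
    fluid: FluidProperties = field(default_factory=FluidProperties)
    tcpc: TCPCGeometry = field(default_factory=TCPCGeometry)
    innominate_split: float = 0.2   # per vein, PSC2 only

    def __post_init__(self) -> None:
        if not 0.0 < self.ivc_fraction < 1.0:
            raise ValueError("ivc_fraction must be in (0, 1)")
        if not self.P_aorta > self.P_PA_outlet > 0.0:
            raise ValueError("require P_aorta > P_PA_outlet > 0")
        if self.Q_caval_total <= 0:
            raise ValueError("caval return must be positive")
        if self.P_atrium <= 0:
            raise ValueError("atrial pressure must be positive")

    @property
    def Q_IVC(self) -> float:
        return self.Q_caval_total * self.ivc_fraction

    @property
    def Q_SVC(self) -> float:
        return self.Q_caval_total * (1.0 - self.ivc_fraction)

    def to_yaml(self) -> str:
        raw = asdict(self)
        return yaml.safe_dump(raw, sort_keys=True)

    @classmethod
    def from_yaml(cls, payload: str) -> "Scenario":
        raw = yaml.safe_load(payload)
        fluid = FluidProperties(**raw.pop("fluid", {}))
        tcpc = TCPCGeometry(**raw.pop("tcpc", {}))
        return cls(fluid=fluid, tcpc=tcpc, **raw)


@dataclass
class HemodynamicState:
    """Solved node pressures (mmHg) and branch flows (L/min) for one mode.

    ``Q_AD`` is signed: negative values mean the atrial discharge has
    reversed (atrium feeding the device), which occurs for narrow-throat /
    large-nozzle corners of the design space where the throat pressure
    falls below atrial pressure.  ``P_throat`` is NaN in BASELINE (no
    device in line).
    """

    P_IVC: float
    P_SVC: float
    P_throat: float
    Q_IVC: float
    Q_SVC: float
    Q_AoG: float
    Q_AD: float
    Q_P: float
    CO: float
    mode: Mode
    mass_residual: float = 0.0
    iterations: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mode"] = self.mode.value
        return d


class SolverError(RuntimeError):
    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class ModeConstraints:
    """System description after applying a mode's constraints."""

    device_in_line: bool
    aog_active: bool
    ad_active: bool


def apply_mode(mode: Mode) -> ModeConstraints:
    """Translate a mode into shunt/device activation flags."""
    if mode is Mode.BASELINE:
        return ModeConstraints(device_in_line=False, aog_active=False, ad_active=False)
    if mode is Mode.FULL_ASSIST:
        return ModeConstraints(device_in_line=True, aog_active=True, ad_active=True)
    if mode is Mode.AOG_OCCLUSION:
        return ModeConstraints(device_in_line=True, aog_active=False, ad_active=True)
    if mode is Mode.FULL_FAILURE:
        return ModeConstraints(device_in_line=True, aog_active=False, ad_active=False)
    raise ValueError(f"unknown mode {mode!r}")


def _device_inlet_pressure(P_throat: float, Q_IVC: float, Q_AD: float,
                           geom: DeviceGeometry, losses: LossModel,
                           fluid: FluidProperties) -> float:
    """IVC pressure just upstream of the device, mmHg (Bernoulli + entry loss)."""
    A_ivc = port_area(geom.D_IVC)
    A_s = port_area(geom.D_T) - port_area(geom.D_N)
    v_i = Q_IVC * LMIN_TO_M3S / A_ivc
    v_s = (Q_IVC - Q_AD) * LMIN_TO_M3S / A_s
    dp = 0.5 * fluid.rho * ((1.0 + losses.k_inlet) * v_s * v_s - v_i * v_i)
    return P_throat + dp * PA_TO_MMHG


def solve_circulation(scenario: Scenario, geom: DeviceGeometry | None,
                      losses: LossModel, mode: Mode,
                      tol: float = 1e-8, max_iter: int = 400,
                      damping: float = 0.5, P_init: float | None = None) -> HemodynamicState:
    """Solve the steady network for one operating mode.

    The coupled system {graft orifice flow <-> throat pressure <->
    atrial-discharge orifice flow <-> pathway losses} is iterated on the
    throat pressure until successive iterates differ by less than ``tol``
    mmHg, falling back to bisection on the fixed-point residual if the
    damped iteration stalls.
    """
    label = scenario.tcpc.label
    fluid = scenario.fluid
    Q_IVC, Q_SVC = scenario.Q_IVC, scenario.Q_SVC

    constraints = apply_mode(mode)

    if not constraints.device_in_line:
        p_ivc = scenario.P_PA_outlet + pathway_loss(Q_IVC, losses.k_for(label, "ivc"), 12.0, fluid)
        p_svc = scenario.P_PA_outlet + pathway_loss(Q_SVC, losses.k_for(label, "svc"), 12.0, fluid)
        q_p = Q_IVC + Q_SVC
        return HemodynamicState(
            P_IVC=p_ivc, P_SVC=p_svc, P_throat=math.nan,
            Q_IVC=Q_IVC, Q_SVC=Q_SVC, Q_AoG=0.0, Q_AD=0.0, Q_P=q_p,
            CO=scenario.Q_caval_total,
            mode=mode, mass_residual=Q_IVC + Q_SVC - q_p, iterations=0,
        )

    if geom is None:
        raise ValueError("device geometry required for device-in-line modes")
    report = validate_device(geom)
    if not report.ok:
        raise ValueError("invalid device geometry: " + "; ".join(report.violations))

    def branch_flows(p_throat: float) -> tuple[float, float]:
        q_aog = 0.0
        if constraints.aog_active:
            q_aog = max(0.0, orifice_flow(scenario.P_aorta - p_throat, geom.D_N,
                                          losses.cd_for_nozzle(geom.D_N), fluid))
        q_ad = 0.0
        if constraints.ad_active:
            q_ad = orifice_flow(p_throat - scenario.P_atrium, geom.D_AD,
                                losses.cd_ad, fluid)
        return q_aog, q_ad

    def fixed_point_map(p_throat: float) -> float:
        q_aog, q_ad = branch_flows(p_throat)
        return ejector_throat_pressure(q_aog, Q_IVC, geom, scenario.P_PA_outlet,
                                       losses, fluid, Q_AD=q_ad, tcpc_label=label)

    # damped fixed-point iteration on throat pressure
    p = scenario.P_PA_outlet if P_init is None else P_init
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        p_new = p + damping * (fixed_point_map(p) - p)
        if abs(p_new - p) < tol * damping:
            p = p_new
            converged = True
            break
        p = p_new

    if not converged:
        last_residual = abs(fixed_point_map(p) - p)
        p_bisect = _bisect_residual(fixed_point_map, scenario, tol)
        if p_bisect is None:
            raise SolverError("throat-pressure iteration did not converge", last_residual)
        p = p_bisect

    q_aog, q_ad = branch_flows(p)
    q_p = Q_IVC + Q_SVC + q_aog - q_ad
    p_ivc = _device_inlet_pressure(p, Q_IVC, q_ad, geom, losses, fluid)
    p_svc = (scenario.P_PA_outlet
             + pathway_loss(Q_SVC, losses.k_for(label, "svc"), 12.0, fluid)
             + losses.svc_interaction * pathway_loss(q_p, 1.0, 12.0, fluid))
    co = scenario.Q_caval_total + q_aog
    residual = Q_IVC + Q_SVC + q_aog - q_ad - q_p
    return HemodynamicState(
        P_IVC=p_ivc, P_SVC=p_svc, P_throat=p,
        Q_IVC=Q_IVC, Q_SVC=Q_SVC, Q_AoG=q_aog, Q_AD=q_ad, Q_P=q_p,
        CO=co, mode=mode, mass_residual=residual, iterations=iterations,
    )


def _bisect_residual(fixed_point_map, scenario: Scenario, tol: float) -> float | None:
    """Bisection fallback on g(p) = F(p) - p over a scanned bracket."""
    lo = scenario.P_atrium - 40.0
    hi = scenario.P_aorta
    n = 200
    prev_p = lo
    prev_g = fixed_point_map(lo) - lo
    for i in range(1, n + 1):
        x = lo + (hi - lo) * i / n
        g = fixed_point_map(x) - x
        if prev_g == 0.0:
            return prev_p
        if prev_g * g < 0:
            a, b, ga = prev_p, x, prev_g
            for _ in range(200):
                m = 0.5 * (a + b)
                gm = fixed_point_map(m) - m
                if abs(b - a) < tol:
                    return m
                if ga * gm <= 0:
                    b = m
                else:
                    a, ga = m, gm
            return 0.5 * (a + b)
        prev_p, prev_g = x, g
    return None


@dataclass(frozen=True)
class BaselineComparison:
    dP_IVC: float      # mmHg, baseline minus assisted (positive = improvement)
    dP_SVC: float      # mmHg
    dQ_P_pct: float    # percent change in pulmonary flow


def pressure_change_vs_baseline(assisted: HemodynamicState,
                                baseline: HemodynamicState) -> BaselineComparison:
    """Device effect relative to the no-device baseline of the same scenario."""
    if baseline.mode is not Mode.BASELINE:
        raise ValueError("reference state must be a BASELINE solve")
    if not math.isclose(assisted.Q_IVC + assisted.Q_SVC,
                        baseline.Q_IVC + baseline.Q_SVC, rel_tol=1e-12, abs_tol=1e-12):
        raise ValueError("states were solved under different scenarios")
    return BaselineComparison(
        dP_IVC=baseline.P_IVC - assisted.P_IVC,
        dP_SVC=baseline.P_SVC - assisted.P_SVC,
        dQ_P_pct=100.0 * (assisted.Q_P - baseline.Q_P) / baseline.Q_P,
    )
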
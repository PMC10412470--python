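"""Reduced-order ejector-pump hydraulics.

The 3D suction mechanism — a high-velocity aortic jet entraining the IVC
stream inside the device throat (Venturi/ejector effect) — is collapsed to
classical one-dimensional ejector theory:

* orifice (Bernoulli) laws with discharge coefficients for the aortic
  nozzle and the atrial-discharge port,
* a single constant-area momentum balance over the mixing throat,
* a diffuser pressure recovery with efficiency ``eta_diffuser`` from the
  throat to the pulmonary-side outlet port,
* quadratic lumped losses for the caval pathways (TCPC impingement
  dissipation folded into one coefficient per pathway per TCPC model).

The model's free coefficients are pinned to data before any prediction is
made: nozzle discharge coefficients are calibrated to the measured graft
flows for the 1.5 and 3.0 mm nozzles (linear interpolation in diameter in
between), and the pathway loss coefficients are calibrated so that the
no-device baseline solve reproduces the reference IVC/SVC pressures of
each TCPC model exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .geometry import DeviceGeometry, port_area, validate_device
from .units import MMHG_TO_PA, PA_TO_MMHG, LMIN_TO_M3S, M3S_TO_LMIN, MM_TO_M

__all__ = [
    "FluidProperties",
    "JetState",
    "LossModel",
    "CalibrationError",
    "orifice_flow",
    "jet_state",
    "pathway_loss",
    "ejector_throat_pressure",
    "calibrate_nozzle_cd",
    "calibrate_pathway_losses",
    "interp_cd",
]


@dataclass(frozen=True)
class FluidProperties:
    """Blood as a Newtonian fluid (steady, incompressible)."""

    rho: float = 1060.0   # kg/m^3
    mu: float = 0.0035    # Pa.s

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("fluid density and viscosity must be positive")


@dataclass(frozen=True)
class JetState:
    """Diagnostics of the aortic nozzle jet.

    ``v_jet`` is the superficial (area-averaged) nozzle exit velocity
    Q/A_N; the Reynolds number uses it with the nozzle diameter.  The
    momentum flux reported here is the superficial one, rho*Q*v_jet; the
    throat balance itself uses the vena-contracta velocity (see
    :func:`ejector_throat_pressure`).
    """

    Q_AoG: float          # L/min
    v_jet: float          # m/s
    Re: float             # dimensionless
    momentum_flux: float  # N


class CalibrationError(RuntimeError):
    pass


@dataclass
class LossModel:
    """Free coefficients of the 0D closure.

    cd_nozzle       discharge coefficient per anchored nozzle diameter, (0,1]
    cd_ad           discharge coefficient of the atrial-discharge port;
                    default 0.75, the classical short-tube orifice value
    k_path          lumped loss coefficient per TCPC model and caval
                    pathway, referenced to the 12 mm port dynamic pressure
    eta_diffuser    throat-to-outlet pressure-recovery efficiency, [0,1]
    k_inlet         secondary-stream entry loss into the mixing annulus
    svc_interaction coefficient of the (approximate) jet-boosted SVC
                    impingement pressure rise; default off
    """

    cd_nozzle: dict[float, float] = field(default_factory=dict)
    cd_ad: float = 0.75
    k_path: dict[str, dict[str, float]] = field(default_factory=dict)
    eta_diffuser: float = 0.8
    k_inlet: float = 0.0
    svc_interaction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cd_ad <= 1.0:
            raise ValueError("cd_ad must be in (0, 1]")
        if not 0.0 <= self.eta_diffuser <= 1.0:
            raise ValueError("eta_diffuser must be in [0, 1]")
        for d, cd in self.cd_nozzle.items():
            if not 0.0 < cd <= 1.0:
                raise ValueError(f"cd_nozzle[{d}] must be in (0, 1]")
        for label, ks in self.k_path.items():
            for path, k in ks.items():
                if k < 0:
                    raise ValueError(f"k_path[{label}][{path}] must be >= 0")

    def cd_for_nozzle(self, D_N: float) -> float:
        return interp_cd(self.cd_nozzle, D_N)

    def k_for(self, label: str, pathway: str) -> float:
        try:
            return self.k_path[label][pathway]
        except KeyError as exc:
            raise CalibrationError(
                f"no calibrated loss for TCPC model {label!r}, pathway {pathway!r}"
            ) from exc

    # -- persistence: calibrations are reproducible artifacts ------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, payload: str) -> "LossModel":
        raw = yaml.safe_load(payload)
        raw["cd_nozzle"] = {float(k): float(v) for k, v in raw.get("cd_nozzle", {}).items()}
        return cls(**raw)


def interp_cd(cd_map: Mapping[float, float], D_N: float) -> float:
    """Discharge coefficient at ``D_N`` by linear interpolation in diameter.

    Outside the anchored range the nearest anchor is used (clamped).
    """
    if not cd_map:
        raise CalibrationError("no nozzle discharge coefficients calibrated")
    ds = sorted(cd_map)
    if D_N <= ds[0]:
        return cd_map[ds[0]]
    if D_N >= ds[-1]:
        return cd_map[ds[-1]]
    for lo, hi in zip(ds, ds[1:]):
        if lo <= D_N <= hi:
            w = (D_N - lo) / (hi - lo)
            return (1.0 - w) * cd_map[lo] + w * cd_map[hi]
    raise AssertionError("unreachable")


def orifice_flow(dP_mmhg: float, D_mm: float, Cd: float,
                 fluid: FluidProperties = FluidProperties()) -> float:
    """Signed Bernoulli orifice flow, L/min.

    Q = sign(dP) * Cd * A * sqrt(2|dP|/rho); antisymmetric in dP.
    """
    if D_mm <= 0:
        raise ValueError("orifice diameter must be positive")
    if not 0.0 < Cd <= 1.0:
        raise ValueError("discharge coefficient must be in (0, 1]")
    area = port_area(D_mm)
    dp = abs(dP_mmhg) * MMHG_TO_PA
    v = math.sqrt(2.0 * dp / fluid.rho)
    return math.copysign(Cd * area * v * M3S_TO_LMIN, dP_mmhg)


def jet_state(Q_AoG: float, D_N: float,
              fluid: FluidProperties = FluidProperties()) -> JetState:
    """Nozzle-jet diagnostics from the graft flow (L/min) and D_N (mm)."""
    if D_N <= 0:
        raise ValueError("nozzle diameter must be positive")
    if Q_AoG < 0:
        raise ValueError("graft flow must be non-negative")
    q = Q_AoG * LMIN_TO_M3S
    v = q / port_area(D_N)
    re = fluid.rho * v * D_N * MM_TO_M / fluid.mu
    return JetState(Q_AoG=Q_AoG, v_jet=v, Re=re, momentum_flux=fluid.rho * q * v)


def pathway_loss(Q_lmin: float, K: float, D_mm: float,
                 fluid: FluidProperties = FluidProperties()) -> float:
    """Lumped quadratic pathway loss, mmHg: dP = K * 1/2 rho v^2, v = Q/A(D)."""
    if K < 0:
        raise ValueError("loss coefficient must be non-negative")
    v = Q_lmin * LMIN_TO_M3S / port_area(D_mm)
    return K * 0.5 * fluid.rho * v * v * PA_TO_MMHG


def ejector_throat_pressure(Q_AoG: float, Q_IVC: float, geom: DeviceGeometry,
                            P_downstream: float, losses: LossModel,
                            fluid: FluidProperties = FluidProperties(),
                            Q_AD: float = 0.0, tcpc_label: str = "1-DO",
                            k_path_override: float | None = None) -> float:
    """Static pressure in the mixing throat, mmHg.

    One-dimensional constant-area momentum balance over the throat, then
    diffuser recovery to the pulmonary-side port, then the lumped pathway
    loss down to ``P_downstream`` (the prescribed pulmonary outlet
    pressure).  Working upstream:

        P_T = P_downstream + K * 1/2 rho v_out^2        (pathway loss)
                           - dP_momentum                 (jet suction)
                           - dP_diffuser                 (recovery)

    The jet enters the balance with its vena-contracta velocity
    Q_AoG/(Cd*A_N); the secondary (IVC minus atrial-discharge) stream
    occupies the annulus A_T - A_N.  With the jet off the suction terms
    vanish up to the device's small passive residual (annulus
    acceleration at partial recovery), which is provably >= 0.
    """
    report = validate_device(geom)
    if not report.ok:
        raise ValueError("invalid device geometry: " + "; ".join(report.violations))
    if Q_AoG < 0 or Q_IVC < 0:
        raise ValueError("flows must be non-negative")

    rho = fluid.rho
    A_N = port_area(geom.D_N)
    A_T = port_area(geom.D_T)
    A_s = A_T - A_N
    A_out = port_area(geom.D_PA)
    if A_s <= 0:
        raise ValueError("nozzle area must be smaller than throat area")

    q_j = Q_AoG * LMIN_TO_M3S
    q_s = (Q_IVC - Q_AD) * LMIN_TO_M3S   # signed: AD reversal feeds the annulus
    q_m = q_j + q_s

    # vena-contracta jet velocity: the physical jet is contracted to
    # Cd*A_N (Cv ~ 1 for a sharp orifice), so its momentum flux is
    # rho * q_j^2 / (Cd * A_N).
    cd = losses.cd_for_nozzle(geom.D_N) if Q_AoG > 0 else 1.0
    v_j = q_j / (cd * A_N)
    v_s = q_s / A_s
    v_m = q_m / A_T
    v_out = q_m / A_out

    dp_momentum = rho * (q_j * v_j + q_s * v_s - q_m * v_m) / A_T
    dp_diffuser = losses.eta_diffuser * 0.5 * rho * (v_m * v_m - v_out * v_out)

    K = losses.k_for(tcpc_label, "ivc") if k_path_override is None else k_path_override
    dp_path = K * 0.5 * rho * v_out * abs(v_out)

    p_t_pa = P_downstream * MMHG_TO_PA + dp_path - dp_momentum - dp_diffuser
    return p_t_pa * PA_TO_MMHG


def calibrate_nozzle_cd(anchors: Mapping[float, float], aortic_pressure: float = 65.0,
                        reference_downstream: float = 10.0,
                        fluid: FluidProperties = FluidProperties()) -> dict[float, float]:
    """Invert the orifice law for each anchored nozzle diameter.

    ``anchors`` maps nozzle diameter (mm) to the measured graft flow
    (L/min) at the reference driving pressure (aortic minus downstream).
    Unanchored diameters are served later by linear interpolation
    (:func:`interp_cd`).  A required Cd outside (0, 1] is a calibration
    error naming the anchor.
    """
    if not anchors:
        raise CalibrationError("no nozzle flow anchors provided")
    dp = aortic_pressure - reference_downstream
    if dp <= 0:
        raise CalibrationError("aortic pressure must exceed the reference downstream pressure")
    cds: dict[float, float] = {}
    for d, q in sorted(anchors.items()):
        if q <= 0:
            raise CalibrationError(f"anchored flow for D_N={d} mm must be positive")
        q_ideal = orifice_flow(dp, d, 1.0, fluid)
        cd = q / q_ideal
        if not 0.0 < cd <= 1.0:
            raise CalibrationError(
                f"anchor D_N={d} mm, Q={q} L/min needs Cd={cd:.4f} outside (0, 1]"
            )
        cds[float(d)] = cd
    return cds


def calibrate_pathway_losses(table1: Mapping[str, tuple[float, float]],
                             Q_IVC: float, Q_SVC: float,
                             P_outlet: float = 10.0, D_ref: float = 12.0,
                             fluid: FluidProperties = FluidProperties()) -> dict[str, dict[str, float]]:
    """Fit one loss coefficient per caval pathway per TCPC model.

    ``table1`` maps TCPC label to the measured baseline (no device)
    (P_IVC, P_SVC) in mmHg; K is chosen so the baseline solve reproduces
    each fixture exactly:  K = (P_fixture - P_outlet) / (1/2 rho v^2)
    with v the pathway flow through the reference 12 mm port.
    """
    out: dict[str, dict[str, float]] = {}
    for label, (p_ivc, p_svc) in table1.items():
        ks: dict[str, float] = {}
        for path, p_fix, q in (("ivc", p_ivc, Q_IVC), ("svc", p_svc, Q_SVC)):
            if p_fix < P_outlet:
                raise CalibrationError(
                    f"{label} {path} fixture {p_fix} mmHg below outlet {P_outlet} mmHg: "
                    "negative loss impossible"
                )
            v = q * LMIN_TO_M3S / port_area(D_ref)
            dyn = 0.5 * fluid.rho * v * v
            ks[path] = (p_fix - P_outlet) * MMHG_TO_PA / dyn if dyn > 0 else 0.0
        out[label] = ks
    return out
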
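"""Venous ejector pump (VEP) and TCPC geometry.

The device is an in-line jet ejector placed in the inferior vena cava (IVC)
pathway of a total cavopulmonary connection (TCPC): an aortic graft feeds a
converging nozzle whose jet discharges into a constant-area throat, and a
fenestration-like atrial-discharge port taps the device body.  Only the
port/nozzle/throat/discharge diameters matter to the reduced-order model;
axial lengths (nozzle standoff, throat length, diffuser angle) are not part
of the 0D description and are left unmodelled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

from .units import MM_TO_M

__all__ = [
    "DeviceGeometry",
    "TCPCGeometry",
    "DesignSpace",
    "ValidationReport",
    "validate_device",
    "enumerate_design_space",
    "port_area",
    "geometry_to_json",
    "geometry_from_json",
    "design_space_to_csv",
]

#: TCPC model identifiers: idealized caval-offset models (offset in inlet
#: diameters) and the two patient-specific cases.
TCPC_LABELS = ("0-DO", "0.5-DO", "1-DO", "PSC1", "PSC2")


@dataclass(frozen=True)
class DeviceGeometry:
    """VEP port and internal diameters, mm.

    D_N   nozzle exit diameter (restricts the 4 mm aortic graft)
    D_T   mixing-throat diameter
    D_AD  atrial-discharge port diameter
    D_IVC IVC inlet port diameter (12 mm, typical idealized pediatric size)
    D_AoG aortic-graft inlet diameter (4 mm, clinical shunt practice)
    D_PA  pulmonary-side outlet port diameter
    """

    D_N: float
    D_T: float
    D_AD: float
    D_IVC: float = 12.0
    D_AoG: float = 4.0
    D_PA: float = 12.0

    #: which study arm the design belongs to in reports ("nozzle" for the
    #: nozzle-diameter arm at D_T=8/D_AD=4, "throat_discharge" otherwise).
    study: str = field(default="", compare=False)


@dataclass(frozen=True)
class TCPCGeometry:
    """Idealized or patient-specific TCPC junction.

    Idealized models are double-inlet/double-outlet crosses with 12 mm
    inlets (cavae), 9 mm outlets (pulmonary arteries), 3 mm fillets, and a
    caval offset of 0, 0.5 or 1 inlet diameter.  Patient-specific cases
    (PSC1/PSC2) are represented only by label; their baseline pressures are
    carried as calibration fixtures, not as surface meshes.
    """

    label: str = "1-DO"
    inlet_diameter: float = 12.0
    outlet_diameter: float = 9.0
    offset: float = 1.0
    fillet_radius: float = 3.0

    def __post_init__(self) -> None:
        if self.label not in TCPC_LABELS:
            raise ValueError(f"unknown TCPC label {self.label!r}; expected one of {TCPC_LABELS}")
        if self.inlet_diameter <= 0 or self.outlet_diameter <= 0:
            raise ValueError("TCPC diameters must be positive")
        if self.label.endswith("-DO") and self.offset not in (0.0, 0.5, 1.0):
            raise ValueError("idealized caval offset must be 0, 0.5 or 1 inlet diameters")


@dataclass(frozen=True)
class DesignSpace:
    """Design-of-experiments grid for the three free device diameters.

    The nozzle arm varies D_N at the reference throat/discharge; the
    throat x discharge arm varies (D_T, D_AD) at the reference nozzle.
    Together they give 15 unique designs (the shared reference case is
    counted once, in the nozzle arm).
    """

    nozzle_diameters: tuple[float, ...] = (1.5, 2.0, 2.5, 3.0)
    throat_diameters: tuple[float, ...] = (6.0, 8.0, 10.0, 12.0)
    discharge_diameters: tuple[float, ...] = (4.0, 5.0, 6.0)
    reference_nozzle: float = 2.5
    reference_throat: float = 8.0
    reference_discharge: float = 4.0


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str]


def port_area(diameter_mm: float) -> float:
    """Circular port cross-section area in m^2 from a diameter in mm."""
    if diameter_mm <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_mm}")
    r = 0.5 * diameter_mm * MM_TO_M
    return math.pi * r * r


def validate_device(geom: DeviceGeometry) -> ValidationReport:
    """Check the device invariants; violations are data, not exceptions.

    A throat narrower than half the IVC diameter would place a high series
    resistance on the systemic venous return and is excluded from the
    design space, as is a nozzle that does not restrict the aortic graft.
    """
    violations: list[str] = []
    for name in ("D_N", "D_T", "D_AD", "D_IVC", "D_AoG", "D_PA"):
        if getattr(geom, name) <= 0:
            violations.append(f"non-positive diameter {name}")
    if geom.D_N > 0 and geom.D_AoG > 0 and not geom.D_N < geom.D_AoG:
        violations.append("nozzle diameter must be smaller than the aortic graft inlet")
    if geom.D_T > 0 and geom.D_IVC > 0 and geom.D_T < 0.5 * geom.D_IVC:
        violations.append("throat below half IVC diameter")
    if geom.D_AD > 0 and geom.D_T > 0 and geom.D_AD > geom.D_T:
        violations.append("atrial discharge wider than throat")
    return ValidationReport(ok=not violations, violations=violations)


def enumerate_design_space(space: DesignSpace) -> list[DeviceGeometry]:
    """Enumerate the unique designs of the two study arms, sorted.

    Order is deterministic: nozzle ascending, then throat, then discharge.
    The duplicate reference design is attributed to the nozzle arm.
    """
    if not (space.nozzle_diameters and space.throat_diameters and space.discharge_diameters):
        raise ValueError("design space sets must be non-empty")

    seen: dict[tuple[float, float, float], str] = {}
    for dn in space.nozzle_diameters:
        seen[(dn, space.reference_throat, space.reference_discharge)] = "nozzle"
    for dt in space.throat_diameters:
        for dad in space.discharge_diameters:
            key = (space.reference_nozzle, dt, dad)
            seen.setdefault(key, "throat_discharge")

    designs = [
        DeviceGeometry(D_N=dn, D_T=dt, D_AD=dad, study=study)
        for (dn, dt, dad), study in sorted(seen.items())
    ]
    return designs


# ---------------------------------------------------------------------------
# serialization

def geometry_to_json(geom: DeviceGeometry) -> str:
    return json.dumps(asdict(geom), sort_keys=True)


def geometry_from_json(payload: str) -> DeviceGeometry:
    return DeviceGeometry(**json.loads(payload))


def design_space_to_csv(designs: Iterable[DeviceGeometry]) -> str:
    """One row per design: D_N, D_T, D_AD (mm)."""
    lines = ["D_N,D_T,D_AD"]
    lines += [f"{g.D_N:g},{g.D_T:g},{g.D_AD:g}" for g in designs]
    return "\n".join(lines) + "\n"
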
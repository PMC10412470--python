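"""Boundary-condition scenarios and packaged calibration fixtures.

Everything the pipeline needs is either a printed constant (packaged as a
versioned CSV) or generated here: the pediatric reference scenario and
randomized perturbations of it for robustness testing.  No external data
downloads are involved anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .circulation import Scenario
from .geometry import TCPCGeometry, TCPC_LABELS
from .hydraulics import FluidProperties

__all__ = [
    "FixtureSet",
    "load_fixtures",
    "pediatric_scenario",
    "randomized_scenarios",
    "tcpc_for_label",
]

_TCPC_OFFSET = {"0-DO": 0.0, "0.5-DO": 0.5, "1-DO": 1.0, "PSC1": 1.0, "PSC2": 1.0}


@dataclass(frozen=True)
class FixtureSet:
    """Packaged reference values used to pin the model's free coefficients.

    table1                  baseline (no device) caval pressures per TCPC
                            model, mmHg
    nozzle_flow_anchors     measured graft flow per nozzle diameter at the
                            reference conditions, L/min
    nozzle_ivc_drop_anchors measured full-assist IVC pressure drop per
                            nozzle diameter, mmHg (reporting/check only)
    """

    table1: dict[str, tuple[float, float]]
    nozzle_flow_anchors: dict[float, float]
    nozzle_ivc_drop_anchors: dict[float, float]


def load_fixtures() -> FixtureSet:
    """Load the packaged fixture CSVs (immutable reference data)."""
    pkg = resources.files("fontanvep.data")
    with resources.as_file(pkg / "table1_baseline.csv") as path:
        table1_df = pd.read_csv(path, comment="#")
    with resources.as_file(pkg / "nozzle_anchors.csv") as path:
        anchors_df = pd.read_csv(path, comment="#")

    table1 = {row.label: (float(row.P_IVC), float(row.P_SVC))
              for row in table1_df.itertuples()}
    missing = set(TCPC_LABELS) - set(table1)
    if missing or set(table1) - set(TCPC_LABELS):
        raise ValueError(f"fixture table must contain exactly {TCPC_LABELS}")
    flow = {float(row.D_N): float(row.Q_AoG) for row in anchors_df.itertuples()}
    drop = {float(row.D_N): float(row.dP_IVC) for row in anchors_df.itertuples()}
    return FixtureSet(table1=table1, nozzle_flow_anchors=flow,
                      nozzle_ivc_drop_anchors=drop)


def tcpc_for_label(label: str) -> TCPCGeometry:
    """TCPCGeometry record for a named model (idealized offset filled in)."""
    return TCPCGeometry(label=label, offset=_TCPC_OFFSET[label])


def pediatric_scenario(tcpc_label: str = "1-DO") -> Scenario:
    """The reference pediatric Fontan operating point.

    2.1 L/min total caval return, 60/40 IVC/SVC split, 65 mmHg aortic
    pressure, 10 mmHg pulmonary outlets, 5 mmHg atrium, blood at
    1060 kg/m^3 and 3.5 mPa.s.
    """
    return Scenario(
        Q_caval_total=2.1, ivc_fraction=0.6,
        P_aorta=65.0, P_PA_outlet=10.0, P_atrium=5.0,
        fluid=FluidProperties(rho=1060.0, mu=0.0035),
        tcpc=tcpc_for_label(tcpc_label),
    )


def randomized_scenarios(n: int, seed: int, spread: float = 0.15,
                         tcpc_label: str = "1-DO") -> list[Scenario]:
    """Uniformly perturbed scenarios around the pediatric reference.

    Each continuous field is perturbed independently and uniformly within
    +/- ``spread`` (fractional) of its default; candidates violating the
    scenario invariants are resampled.  Bounded (uniform) support keeps
    resampling rare.  Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spread < 0:
        raise ValueError("spread must be non-negative")
    rng = np.random.default_rng(seed)
    base = pediatric_scenario(tcpc_label)
    out: list[Scenario] = []
    while len(out) < n:
        factors = rng.uniform(1.0 - spread, 1.0 + spread, size=5)
        try:
            out.append(replace(
                base,
                Q_caval_total=base.Q_caval_total * factors[0],
                ivc_fraction=min(0.95, base.ivc_fraction * factors[1]),
                P_aorta=base.P_aorta * factors[2],
                P_PA_outlet=base.P_PA_outlet * factors[3],
                P_atrium=base.P_atrium * factors[4],
            ))
        except ValueError:
            continue  # invariant violated: resample
    return out
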
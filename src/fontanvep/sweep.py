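"""Design-space sweep, four-criterion evaluation and report writing.

Every design is solved in all four operating modes; an acceptable design
must (c1) keep the aortic steal below half the systemic flow during full
assist, (c2) keep arterial saturation at or above the floor during full
assist, (c3) keep it there even with the graft occluded, and (c4)
preserve the pre-device baseline pressures when the device fails
completely.  Among designs meeting all four, the one with the largest
full-assist IVC pressure drop is flagged as selected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .circulation import (HemodynamicState, Mode, Scenario, BaselineComparison,
                          pressure_change_vs_baseline, solve_circulation)
from .geometry import DesignSpace, DeviceGeometry, enumerate_design_space
from .hydraulics import LossModel
from .oxygen import OxygenState, oxygen_state, qp_qs_check

__all__ = ["CriteriaConfig", "SweepRow", "run_sweep", "evaluate_criteria", "write_reports"]

MODES = (Mode.BASELINE, Mode.FULL_ASSIST, Mode.AOG_OCCLUSION, Mode.FULL_FAILURE)


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds of the four selection criteria (user-visible, not code).

    The saturation floors are the stated 80% criteria; the baseline-
    preservation tolerance brackets the small full-failure IVC elevations
    an acceptable design may produce (the criterion itself is qualitative).
    """

    qp_qs_limit: float = 1.5
    min_sat_assist_pct: float = 80.0
    min_sat_occlusion_pct: float = 80.0
    baseline_preservation_tol_mmhg: float = 0.6

    def __post_init__(self) -> None:
        for name in ("qp_qs_limit", "min_sat_assist_pct",
                     "min_sat_occlusion_pct", "baseline_preservation_tol_mmhg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SweepRow:
    """One design's per-mode states, oxygen bookkeeping and criteria flags."""

    geometry: DeviceGeometry
    states: dict[Mode, HemodynamicState]
    oxygen: dict[Mode, OxygenState]
    comparisons: dict[Mode, BaselineComparison]
    qp_qs_ratio: float = float("nan")
    c1: bool = False
    c2: bool = False
    c3: bool = False
    c4: bool = False
    selected: bool = False

    @property
    def all_pass(self) -> bool:
        return self.c1 and self.c2 and self.c3 and self.c4


def evaluate_criteria(row: SweepRow, criteria: CriteriaConfig,
                      Q_S: float) -> SweepRow:
    """Set the four pass/fail flags on a completed row (in place)."""
    assist = row.states[Mode.FULL_ASSIST]
    ratio, _ = qp_qs_check(assist.Q_AoG, Q_S)
    row.qp_qs_ratio = ratio
    row.c1 = assist.Q_AoG / Q_S < criteria.qp_qs_limit - 1.0
    row.c2 = row.oxygen[Mode.FULL_ASSIST].C_sa_pct >= criteria.min_sat_assist_pct
    row.c3 = row.oxygen[Mode.AOG_OCCLUSION].C_sa_pct >= criteria.min_sat_occlusion_pct
    failure = row.states[Mode.FULL_FAILURE]
    baseline = row.states[Mode.BASELINE]
    row.c4 = (abs(failure.P_IVC - baseline.P_IVC) <= criteria.baseline_preservation_tol_mmhg
              and failure.P_SVC <= baseline.P_SVC + 1e-9)
    return row


def run_sweep(space: DesignSpace, scenario: Scenario, losses: LossModel,
              criteria: CriteriaConfig = CriteriaConfig()) -> list[SweepRow]:
    """Solve every design of the space in all four modes and rank it.

    Row order is deterministic (designs sorted by nozzle, throat,
    discharge); solver failures propagate with the offending design named.
    """
    designs = enumerate_design_space(space)
    rows: list[SweepRow] = []
    for geom in designs:
        states: dict[Mode, HemodynamicState] = {}
        for mode in MODES:
            try:
                states[mode] = solve_circulation(scenario, geom, losses, mode)
            except Exception as exc:
                raise RuntimeError(
                    f"solve failed for design (D_N={geom.D_N}, D_T={geom.D_T}, "
                    f"D_AD={geom.D_AD}), mode {mode.value}: {exc}"
                ) from exc
        oxy = {mode: oxygen_state(s.Q_AoG, s.Q_IVC, s.Q_AD, s.Q_P, s.CO)
               for mode, s in states.items()}
        comps = {mode: pressure_change_vs_baseline(states[mode], states[Mode.BASELINE])
                 for mode in MODES if mode is not Mode.BASELINE}
        row = SweepRow(geometry=geom, states=states, oxygen=oxy, comparisons=comps)
        rows.append(evaluate_criteria(row, criteria, scenario.Q_caval_total))

    passing = [r for r in rows if r.all_pass]
    if passing:
        best = max(passing, key=lambda r: r.comparisons[Mode.FULL_ASSIST].dP_IVC)
        best.selected = True
    return rows


_CSV_COLUMNS = [
    "D_N", "D_T", "D_AD", "study",
    "P_IVC_baseline", "P_SVC_baseline",
    "P_IVC_assist", "P_SVC_assist", "P_throat_assist",
    "dP_IVC_assist", "dP_SVC_assist", "dQ_P_pct_assist",
    "Q_AoG_assist", "Q_AD_assist", "Q_P_assist",
    "C_sa_pct_assist", "m_assist", "qp_qs_ratio",
    "C_sa_pct_occlusion", "Q_AD_occlusion", "dP_IVC_occlusion",
    "dP_IVC_failure", "dP_SVC_failure",
    "c1", "c2", "c3", "c4", "selected",
]


def row_to_record(row: SweepRow) -> dict:
    g = row.geometry
    b = row.states[Mode.BASELINE]
    a = row.states[Mode.FULL_ASSIST]
    occ = row.states[Mode.AOG_OCCLUSION]
    ca = row.comparisons[Mode.FULL_ASSIST]
    cocc = row.comparisons[Mode.AOG_OCCLUSION]
    cf = row.comparisons[Mode.FULL_FAILURE]
    return {
        "D_N": g.D_N, "D_T": g.D_T, "D_AD": g.D_AD, "study": g.study,
        "P_IVC_baseline": b.P_IVC, "P_SVC_baseline": b.P_SVC,
        "P_IVC_assist": a.P_IVC, "P_SVC_assist": a.P_SVC, "P_throat_assist": a.P_throat,
        "dP_IVC_assist": ca.dP_IVC, "dP_SVC_assist": ca.dP_SVC, "dQ_P_pct_assist": ca.dQ_P_pct,
        "Q_AoG_assist": a.Q_AoG, "Q_AD_assist": a.Q_AD, "Q_P_assist": a.Q_P,
        "C_sa_pct_assist": row.oxygen[Mode.FULL_ASSIST].C_sa_pct,
        "m_assist": row.oxygen[Mode.FULL_ASSIST].m,
        "qp_qs_ratio": row.qp_qs_ratio,
        "C_sa_pct_occlusion": row.oxygen[Mode.AOG_OCCLUSION].C_sa_pct,
        "Q_AD_occlusion": occ.Q_AD, "dP_IVC_occlusion": cocc.dP_IVC,
        "dP_IVC_failure": cf.dP_IVC, "dP_SVC_failure": cf.dP_SVC,
        "c1": row.c1, "c2": row.c2, "c3": row.c3, "c4": row.c4,
        "selected": row.selected,
    }


def rows_to_frame(rows: list[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame([row_to_record(r) for r in rows], columns=_CSV_COLUMNS)


def write_reports(rows: list[SweepRow], outdir: str | Path) -> dict[str, Path]:
    """Write the sweep CSV, per-design JSON records and a summary table.

    Re-running with identical inputs produces byte-identical files (fixed
    column order, full-precision floats, sorted keys).
    """
    if not rows:
        raise ValueError("no sweep rows to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    frame = rows_to_frame(rows)
    csv_path = outdir / "sweep.csv"
    frame.to_csv(csv_path, index=False, float_format="%.12g")

    json_paths = []
    for row in rows:
        g = row.geometry
        payload = {
            "geometry": {"D_N": g.D_N, "D_T": g.D_T, "D_AD": g.D_AD, "study": g.study},
            "states": {m.value: row.states[m].to_dict() for m in MODES},
            "oxygen": {m.value: {"C_sa_pct": row.oxygen[m].C_sa_pct,
                                 "C_sv_pct": row.oxygen[m].C_sv_pct,
                                 "m": row.oxygen[m].m} for m in MODES},
            "criteria": {"c1": row.c1, "c2": row.c2, "c3": row.c3, "c4": row.c4,
                         "qp_qs_ratio": row.qp_qs_ratio, "selected": row.selected},
        }
        path = outdir / f"design_DN{g.D_N:g}_DT{g.D_T:g}_DAD{g.D_AD:g}.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n")
        json_paths.append(path)

    summary_path = outdir / "summary.txt"
    summary_path.write_text(summary_table(rows))
    return {"csv": csv_path, "summary": summary_path, "json": json_paths}


def summary_table(rows: list[SweepRow]) -> str:
    """Human-readable sweep summary; the selected design is starred."""
    header = (f"{'D_N':>5} {'D_T':>5} {'D_AD':>5} {'dP_IVC':>8} {'C_sa%':>7} "
              f"{'Qp/Qs':>7} {'c1':>3} {'c2':>3} {'c3':>3} {'c4':>3}  sel\n")
    lines = [header, "-" * len(header) + "\n"]
    for r in rows:
        g = r.geometry
        ca = r.comparisons[Mode.FULL_ASSIST]
        lines.append(
            f"{g.D_N:>5g} {g.D_T:>5g} {g.D_AD:>5g} {ca.dP_IVC:>8.3f} "
            f"{r.oxygen[Mode.FULL_ASSIST].C_sa_pct:>7.2f} {r.qp_qs_ratio:>7.3f} "
            f"{'P' if r.c1 else 'F':>3} {'P' if r.c2 else 'F':>3} "
            f"{'P' if r.c3 else 'F':>3} {'P' if r.c4 else 'F':>3}  "
            f"{'*' if r.selected else ''}\n"
        )
    return "".join(lines)
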
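"""Model/Results surface over the calibrated ejector-pump circulation.

Usage mirrors the statsmodels idiom: a :class:`VEPCirculationModel` is
built from a scenario, a device geometry and the calibration data (nozzle
flow anchors and baseline pressure table); ``fit()`` calibrates the free
coefficients and returns a :class:`VEPCalibrationResults` carrying the
fitted parameters, their calibration residuals and a ``summary()`` table.
Steady solves, baseline comparisons, the design sweep and plotting hang
off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .circulation import (BaselineComparison, HemodynamicState, Mode, Scenario,
                          pressure_change_vs_baseline, solve_circulation)
from .geometry import DesignSpace, DeviceGeometry
from .hydraulics import (FluidProperties, LossModel, calibrate_nozzle_cd,
                         calibrate_pathway_losses, orifice_flow)
from .oxygen import OxygenState, oxygen_state, qp_qs_check
from .scenarios import FixtureSet, load_fixtures, pediatric_scenario, tcpc_for_label
from .sweep import CriteriaConfig, SweepRow, rows_to_frame, run_sweep

__all__ = ["VEPCirculationModel", "VEPCalibrationResults", "SELECTED_DESIGN"]

#: the device prototype carried through to all TCPC models: 2.5 mm nozzle,
#: full-caval-diameter (12 mm) throat, 4 mm (fenestration-sized) discharge.
SELECTED_DESIGN = DeviceGeometry(D_N=2.5, D_T=12.0, D_AD=4.0)


class VEPCirculationModel:
    """Reduced-order model of a VEP-assisted Fontan circulation.

    Parameters
    ----------
    scenario : Scenario, optional
        Boundary conditions; defaults to the pediatric reference point.
    geometry : DeviceGeometry, optional
        Device to solve with; defaults to the selected prototype.
    fixtures : FixtureSet, optional
        Calibration data (nozzle flow anchors, baseline pressure table);
        defaults to the packaged printed values.
    cd_ad, eta_diffuser, k_inlet, svc_interaction : float
        Closure coefficients not pinned by the fixtures (see LossModel).
    """

    def __init__(self, scenario: Scenario | None = None,
                 geometry: DeviceGeometry = SELECTED_DESIGN,
                 fixtures: FixtureSet | None = None,
                 cd_ad: float = 0.75, eta_diffuser: float = 0.8,
                 k_inlet: float = 0.0, svc_interaction: float = 0.0):
        self.scenario = scenario if scenario is not None else pediatric_scenario()
        self.geometry = geometry
        self.fixtures = fixtures if fixtures is not None else load_fixtures()
        self.cd_ad = cd_ad
        self.eta_diffuser = eta_diffuser
        self.k_inlet = k_inlet
        self.svc_interaction = svc_interaction

    @classmethod
    def from_tcpc(cls, tcpc_label: str, **kwargs) -> "VEPCirculationModel":
        """Model on the pediatric scenario of a named TCPC anatomy."""
        return cls(scenario=pediatric_scenario(tcpc_label), **kwargs)

    def fit(self) -> "VEPCalibrationResults":
        """Calibrate the free coefficients to the fixture data.

        Nozzle discharge coefficients invert the orifice law at the
        anchored graft flows; pathway loss coefficients reproduce every
        baseline caval pressure exactly.  Both inversions are closed-form,
        so the 'fit' residuals are round-trip checks, not optimizer
        leftovers.
        """
        scn = self.scenario
        cd = calibrate_nozzle_cd(self.fixtures.nozzle_flow_anchors,
                                 aortic_pressure=scn.P_aorta,
                                 reference_downstream=scn.P_PA_outlet,
                                 fluid=scn.fluid)
        k = calibrate_pathway_losses(self.fixtures.table1, scn.Q_IVC, scn.Q_SVC,
                                     P_outlet=scn.P_PA_outlet, fluid=scn.fluid)
        losses = LossModel(cd_nozzle=cd, cd_ad=self.cd_ad, k_path=k,
                           eta_diffuser=self.eta_diffuser, k_inlet=self.k_inlet,
                           svc_interaction=self.svc_interaction)
        return VEPCalibrationResults(self, losses)


@dataclass
class VEPCalibrationResults:
    """Calibrated coefficients plus solve/sweep/report methods."""

    model: VEPCirculationModel
    losses: LossModel

    # -- parameter access ------------------------------------------------
    @property
    def params(self) -> pd.Series:
        entries: dict[str, float] = {}
        for d, cd in sorted(self.losses.cd_nozzle.items()):
            entries[f"Cd_nozzle[{d:g}mm]"] = cd
        entries["Cd_AD"] = self.losses.cd_ad
        entries["eta_diffuser"] = self.losses.eta_diffuser
        for label, ks in self.losses.k_path.items():
            entries[f"K_ivc[{label}]"] = ks["ivc"]
            entries[f"K_svc[{label}]"] = ks["svc"]
        return pd.Series(entries, name="value")

    def calibration_report(self) -> pd.DataFrame:
        """Round-trip residuals of both calibrations.

        Anchored graft flows are re-predicted through the orifice law and
        baseline pressures re-solved through the circulation; residuals
        should sit at floating-point noise.
        """
        scn = self.model.scenario
        recs = []
        dp = scn.P_aorta - scn.P_PA_outlet
        for d, q_target in sorted(self.model.fixtures.nozzle_flow_anchors.items()):
            q_fit = orifice_flow(dp, d, self.losses.cd_nozzle[d], scn.fluid)
            recs.append({"anchor": f"Q_AoG[{d:g}mm]", "target": q_target,
                         "fitted": q_fit, "residual": q_fit - q_target})
        for label, (p_ivc, p_svc) in self.model.fixtures.table1.items():
            state = solve_circulation(replace(scn, tcpc=tcpc_for_label(label)),
                                      None, self.losses, Mode.BASELINE)
            recs.append({"anchor": f"P_IVC[{label}]", "target": p_ivc,
                         "fitted": state.P_IVC, "residual": state.P_IVC - p_ivc})
            recs.append({"anchor": f"P_SVC[{label}]", "target": p_svc,
                         "fitted": state.P_SVC, "residual": state.P_SVC - p_svc})
        return pd.DataFrame(recs)

    # -- solves ----------------------------------------------------------
    def solve(self, mode: Mode = Mode.FULL_ASSIST,
              geometry: DeviceGeometry | None = None) -> HemodynamicState:
        geom = geometry if geometry is not None else self.model.geometry
        return solve_circulation(self.model.scenario,
                                 None if mode is Mode.BASELINE else geom,
                                 self.losses, mode)

    def oxygen(self, state: HemodynamicState) -> OxygenState:
        return oxygen_state(state.Q_AoG, state.Q_IVC, state.Q_AD, state.Q_P, state.CO)

    def performance(self, geometry: DeviceGeometry | None = None) -> pd.Series:
        """Headline device metrics for one geometry under full assist."""
        baseline = self.solve(Mode.BASELINE)
        assist = self.solve(Mode.FULL_ASSIST, geometry)
        comp = pressure_change_vs_baseline(assist, baseline)
        oxy = self.oxygen(assist)
        ratio, ok = qp_qs_check(assist.Q_AoG, self.model.scenario.Q_caval_total)
        return pd.Series({
            "dP_IVC_mmHg": comp.dP_IVC,
            "dP_SVC_mmHg": comp.dP_SVC,
            "dQ_P_pct": comp.dQ_P_pct,
            "Q_AoG_Lmin": assist.Q_AoG,
            "Q_AD_Lmin": assist.Q_AD,
            "C_sa_pct": oxy.C_sa_pct,
            "m": oxy.m,
            "Qp_Qs": ratio,
            "graft_flow_criterion": float(ok),
        })

    def sweep(self, space: DesignSpace = DesignSpace(),
              criteria: CriteriaConfig = CriteriaConfig()) -> list[SweepRow]:
        return run_sweep(space, self.model.scenario, self.losses, criteria)

    def sweep_frame(self, space: DesignSpace = DesignSpace(),
                    criteria: CriteriaConfig = CriteriaConfig()) -> pd.DataFrame:
        return rows_to_frame(self.sweep(space, criteria))

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        """statsmodels-flavoured text summary of calibration and headline solve."""
        scn = self.model.scenario
        g = self.model.geometry
        perf = self.performance()
        lines = []
        w = 66
        lines.append("VEP-assisted Fontan circulation (reduced-order)".center(w))
        lines.append("=" * w)
        lines.append(f"{'TCPC model:':<24}{scn.tcpc.label:>18}")
        lines.append(f"{'Caval return (L/min):':<24}{scn.Q_caval_total:>18.3f}")
        lines.append(f"{'IVC fraction:':<24}{scn.ivc_fraction:>18.2f}")
        lines.append(f"{'P aorta/PA/atrium:':<24}"
                     f"{f'{scn.P_aorta:g}/{scn.P_PA_outlet:g}/{scn.P_atrium:g} mmHg':>18}")
        lines.append(f"{'Device (D_N/D_T/D_AD):':<24}"
                     f"{f'{g.D_N:g}/{g.D_T:g}/{g.D_AD:g} mm':>18}")
        lines.append("-" * w)
        lines.append("Calibrated coefficients")
        for name, value in self.params.items():
            lines.append(f"  {name:<28}{value:>14.6f}")
        lines.append("-" * w)
        lines.append("Full-assist performance vs baseline")
        for name, value in perf.items():
            lines.append(f"  {name:<28}{value:>14.4f}")
        lines.append("=" * w)
        return "\n".join(lines) + "\n"

    def plot_nozzle_study(self, ax=None):
        """Bar chart of the full-assist IVC drop across the nozzle arm."""
        import matplotlib.pyplot as plt

        space = DesignSpace()
        baseline = self.solve(Mode.BASELINE)
        drops = []
        for dn in space.nozzle_diameters:
            geom = DeviceGeometry(D_N=dn, D_T=space.reference_throat,
                                  D_AD=space.reference_discharge)
            assist = self.solve(Mode.FULL_ASSIST, geom)
            drops.append(pressure_change_vs_baseline(assist, baseline).dP_IVC)
        if ax is None:
            _, ax = plt.subplots()
        ax.bar([f"{d:g}" for d in space.nozzle_diameters], drops)
        ax.set_xlabel("nozzle diameter (mm)")
        ax.set_ylabel("IVC pressure drop (mmHg)")
        ax.set_title("Full assist, nozzle study")
        return ax
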
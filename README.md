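# fontanvep

Reduced-order hemodynamic model of a **self-powered venous ejector pump
(VEP)** assisting a Fontan (total cavopulmonary connection, TCPC)
circulation.

Fontan patients lack a subpulmonary ventricle, so systemic venous return
drains passively into the lungs and the inferior vena cava (IVC) runs
chronically hypertensive. The VEP is a passive implant: a 4 mm aortic
graft feeds a converging nozzle whose high-velocity jet discharges into
the IVC pathway inside a mixing throat, lowering IVC pressure by momentum
exchange (ejector/Venturi effect); a fenestration-like atrial-discharge
port relieves caval pressure further at the cost of a small right-to-left
shunt. `fontanvep` models this device and its circulation with
one-dimensional ejector theory and lumped (0D) network hydraulics, for
researchers exploring device sizing and failure behaviour at desk scale.

## Model

For a device with nozzle/throat/discharge diameters `D_N / D_T / D_AD`:

* orifice laws `Q = Cd·A·sqrt(2ΔP/ρ)` for the aortic graft and the
  atrial discharge;
* a constant-area momentum balance over the throat,
  `(P₂−P₁)A_T = ρ(q_j v_j + q_s v_s − q_m v_m)`, with the jet at its
  vena-contracta velocity, followed by diffuser recovery with efficiency
  `η`;
* quadratic lumped losses `ΔP = K·½ρv²` per caval pathway per TCPC model;
* oxygen bookkeeping `C_sa = Q_P·C_PV / (CO − (0.6 + 0.4m)·Q_AD)` with
  perfect-mixing coefficient `m = Q_AoG/(Q_AoG+Q_IVC)`, and the shunt
  criterion Qp/Qs = 1 + Q_AoG/Q_S < 1.5.

Nozzle discharge coefficients are calibrated to measured graft flows for
the 1.5/3.0 mm nozzles, pathway losses to measured baseline caval
pressures of five TCPC models (three idealized caval offsets, two
patient-specific cases). Operating modes: baseline (no device), full
assist, aortic-graft occlusion, full failure. See `docs/methods.md` for
the complete account.

## Worked example

```python
from fontanvep import VEPCirculationModel

results = VEPCirculationModel().fit()   # pediatric scenario, 1-DO TCPC,
print(results.performance())            # 2.5/12/4 mm device prototype
```

```
dP_IVC_mmHg              3.266075
dP_SVC_mmHg              0.000000
dQ_P_pct                27.152562
Q_AoG_Lmin               1.032860
Q_AD_Lmin                0.462656
C_sa_pct                91.514564
m                        0.450468
Qp_Qs                    1.491838
graft_flow_criterion     1.000000
```

Reading: under full assist the device drops IVC pressure by 3.27 mmHg
below the 10.85 mmHg no-device baseline, boosts pulmonary flow by 27%,
steals 1.03 L/min from the aorta (Qp/Qs = 1.49, inside the < 1.5 safety
bound), and the 0.46 L/min atrial-discharge shunt leaves systemic
arterial saturation at 91.5%. `results.summary()` prints the calibrated
coefficients alongside these metrics, and
`results.sweep_frame()` evaluates all 15 designs of the
nozzle/throat/discharge design space against the four selection criteria
(steal bound, assist and occlusion saturation floors, baseline
preservation under full failure).

The same pipeline is scriptable from the shell:

```sh
fontanvep calibrate --out losses.yaml
fontanvep solve --mode full-assist --dn 2.5 --dt 12 --dad 4
fontanvep sweep --outdir sweep_out && fontanvep report --outdir sweep_out
```

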
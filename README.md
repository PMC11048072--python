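# chometab

Stoichiometric and kinetic modelling of CHO-cell fed-batch metabolism for
monoclonal-antibody production, with a focus on high-seeding-density (HSD)
processes and the **lactate shift** — the transition from lactate production
(overflow/Warburg metabolism, 2 ATP per glucose) to lactate consumption
feeding complete oxidation (36 ATP per glucose).

The package is aimed at bioprocess modellers who have offline fed-batch
measurements (VCD, viability, titer, glucose/lactate/ammonium/amino acids)
and want to:

1. convert concentrations into cell-specific rates q [µmol/g_DW/h]
   (outlier removal, LOWESS smoothing, feed-corrected interval balances);
2. run FBA/MFA on a reduced central-carbon network (S·v = 0, measured
   exchanges constrained to ±10%, biomass/product objectives, weighted
   least-squares reconciliation with pooled R²);
3. simulate a reduced kinetic ODE model (10 metabolites + biomass + mAb +
   volume) whose regulation reproduces the lactate shift: glycolysis
   activated by asparagine, LDH feedback-inhibited by lactate
   (Ki^n/(Ki^n+Lac^n)), lactate uptake inversely coupled to the glycolytic
   rate (α/(α+r_gly)), pyruvate entry into the TCA inhibited by asparagine;
4. calibrate model structures globally (seeded differential evolution +
   trust-region least squares), select them by AIC, sample the viable
   parameter space, and predict with a mean-of-members ensemble;
5. run feed-composition studies: scaling asparagine in the feed moves the
   shift (less asparagine → earlier shift; enough asparagine → no shift).

Everything runs end-to-end on synthetic data generated by the package
itself (`chometab.synthetic`), which emulates the study conditions:
12–14-day cultivations, 13 daily samples, seeding at 10×10⁶ cells/mL (HSD)
or 0.7×10⁶ cells/mL (standard fed-batch), and the four conditions
STD_FB / HSD_CONTROL / HSD_LAC_CYS / HSD_BM with their bolus windows.

## Worked example

```python
import numpy as np
from chometab import network
from chometab.fluxanalysis import apply_measurement_constraints, run_mfa, solve_fba
from chometab.kinetics import ModelStructure, reference_parameters, simulate
from chometab.feedscan import detect_lactate_shift
from chometab.synthetic import default_spec, generate_dataset, initial_state, standard_schedule

# 1. simulate the HSD control with the shipped reference model
spec = default_spec("HSD_CONTROL")
traj = simulate(ModelStructure(1), reference_parameters(),
                standard_schedule("HSD_CONTROL"), (0.0, 288.0), initial_state(spec))
print("lactate peak [mmol/L]:", round(traj.states["Lac"].max(), 1))
print("shift day:", detect_lactate_shift(traj))

# 2. generate a noisy dataset and reconcile fluxes on the default network
net = network.default_network()
from chometab.synthetic import make_consistent_flux_set
meas, truth = make_consistent_flux_set(net, magnitude=10.0, seed=0, noise_cv=0.05)
sol = solve_fba(apply_measurement_constraints(net, meas), "biomass")
mfa = run_mfa(net, meas, sol)
print("MFA R^2:", round(mfa.r_squared, 4))
```

prints

```
lactate peak [mmol/L]: 68.7
shift day: 3
MFA R^2: 0.9967
```

The lactate trajectory rises during the first days (overflow metabolism
while asparagine is abundant), peaks near 69 mmol/L and then falls — the
net lactate flux turns durably negative on day 3 (the shift). The MFA
reconciles 5%-noisy exchange measurements against the steady-state
constraint with R² ≈ 0.997, above the 0.98 threshold used to validate the
stoichiometric model.

A thin CLI wraps the same functionality:

```
chometab synth make --condition HSD_CONTROL --seed 3 --out hsd.csv
chometab prep fluxes hsd.csv --out fluxes.csv
chometab kin simulate --condition HSD_CONTROL --days 12 --out traj.csv
chometab scan asn --factors 0.75,1.0,2.0 --out scan.csv
```

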
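# algakin

Mechanistic enzyme-kinetics modelling and rate-constant estimation for the
two-stage enzymatic hydrolysis of microalgal biomass.

Microalgae such as *Tetraselmis chuii* are a lignin-free feedstock for
bioethanol: a **pretreatment** stage (cellulase + xylanase) breaks the cell
wall and converts cellulose and hemicellulose to glucose, and a
**saccharification** stage (α-amylase + glucoamylase) liquefies the
intracellular starch to dextrin and hydrolyses the dextrin to glucose.
`algakin` is for kineticists and process engineers who want to simulate
these stages mechanistically, estimate rate constants from time-course
data, quantify how identifiable those constants are, and run
activation-energy (Arrhenius) analyses — including on fully synthetic
experiments that mimic the lab design (500 mg biomass in 100 mL buffer,
samples every 10 min for 60 min, triplicate measurements).

## The model

Each enzymatic conversion is a reversible elementary-step mechanism

```
E + S  ⇌(k_bind, k_unbind)  ES  ⇌(k_cat, k_rebind)  E + P
```

so every step carries four mass-action rate constants. The pretreatment
stage runs two such steps in parallel into one shared glucose pool
(constants k1–k8 for cellulase/cellulose and xylanase/hemicellulose); the
saccharification stage runs them in series through two distinct complexes
(k9–k12 for α-amylase/starch → dextrin, k13–k16 for glucoamylase/dextrin →
glucose). Species are dimensionless fractions of the process's convertible
substrate, which makes all constants — including the bimolecular ones —
carry units of min⁻¹. Each system conserves every enzyme pool
(E + ES = const) and total substrate carbon (ΣS + ΣES + P = const), and
admits the usual pseudo-steady-state (Michaelis–Menten-type) reduction
d(ES)/dt = 0, implemented alongside the full model.

Rate constants are estimated by bounded multi-start least squares around
an adaptive Dormand–Prince (RK45-class) integration, with the misfit
reported as the root-mean-square error on the yield-fraction scale,
SE = √(Σ(y_obs − y_model)²/n). Activation energies come from ordinary
least squares on ln k vs 1/T(K), with the pre-denaturation temperature
range selected as the longest initial run of increasing k.

## Worked example

Simulate the saccharification stage with its published 55 °C constants,
then check that those constants are recoverable from the model's own
noiseless trajectories:

```python
import numpy as np
import algakin as ak

cfg = ak.SimulationConfig(model=ak.SACCHARIFICATION,
                          rate_constants=ak.SACCHARIFICATION_BY_TEMPERATURE[55])
traj = ak.integrate(cfg)
for t, y, g in zip(traj.time_min, traj.yield_pct, traj.glucose_g_per_l):
    print(f"{t:5.0f}  {y:7.2f}  {g:7.4f}")
```

```
    0     0.00   0.0000
   10    22.82   0.2239
   20    43.13   0.4231
   30    50.72   0.4976
   40    53.13   0.5212
   50    53.84   0.5282
   60    54.05   0.5302
```

The columns are time (min), glucose yield (% of initial starch) and
glucose concentration (g/L in the 100 mL flask): the cascade converts
about half the starch within the first 30 minutes and then approaches its
reversible-step equilibrium.

```python
res = ak.self_consistency_refit(cfg, n_starts=16, seed=0)
print(res.as_dict())   # {'k9': 0.14, 'k10': 0.02, 'k11': 1.45, ..., 'k16': 0.25}
print(res.se)          # 1.2e-16
```

All eight generating constants come back exactly (SE at machine
precision), confirming the inverse problem is well posed when the full
state is observed. An Arrhenius fit over the pre-denaturation regime of
the xylanase glucose-formation constant (auto-selected: 40 and 45 °C, the
constant collapses above that as the enzyme denatures):

```python
temps = np.array([40.0, 45.0, 50.0, 60.0])
k7 = np.array([ak.PRETREATMENT_BY_TEMPERATURE[t].k7 for t in temps])
fit = ak.fit_arrhenius(ak.ArrheniusInput(temps, k7), subset="auto")
print(fit.ea_kj_mol)   # 28.70 kJ/mol
```

The same stages are scriptable from the shell via the `algakin` console
command (`simulate`, `synth`, `fit`, `arrhenius`, `report`), each reading
one YAML run configuration and writing delimited-text outputs stamped with
the package version, a configuration hash and the seed.

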
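# lipogrid

Grid-based kinetic modelling of murine lipoprotein metabolism with in
silico FPLC profiling.

## The problem

In preclinical mouse studies, lipoprotein phenotypes are routinely read
out as FPLC profiles: plasma is separated by size-exclusion
chromatography into numbered fractions and each fraction is assayed for
triglyceride (TG) and total cholesterol (TC). The profile is shaped
simultaneously by lipoprotein production, remodelling (lipolysis, lipid
exchange, selective uptake) and whole-particle catabolism, so a change
in the curve cannot be attributed to a mechanism by inspection.
`lipogrid` closes that gap: it simulates a mechanistic kinetic model of
the circulating lipoprotein population, converts the simulated particle
distribution into an in silico FPLC profile on the same fraction axis as
the data, and estimates the kinetic parameters from observed profiles.
It is aimed at modellers and lipid biologists who have mouse FPLC tables
(plus a measured VLDL-TG production rate) and want flux- and
mechanism-level interpretations.

## The model

A particle is characterized by its two core lipids. On a discrete
composition grid, index *i* encodes TG content exponentially,

> #TG(i) = TG_min · g^(i−1),  g = (TG_max/TG_min)^(1/(i_max−1)),

and index *j* encodes cholesteryl-ester (CE) content on a ladder built
so that, for minimal-TG particles, particle diameter is linear in FPLC
fraction number. Diameter follows from core volume and a fixed 2 nm
surface layer,

> D = 2·(r_core + δ),  (4/3)π r_core³ = #TG·v_TG + #CE·v_CE,

so an empty core gives the model's 4 nm minimum. Free cholesterol (FC)
and phospholipid (PL) are attached through empirical surface-to-core
ratios interpolated over log core radius.

Two sub-models of 320 states each cover HDL (8×40) and the Apo
B-containing VLDL/LDL continuum (40×8). Each sub-model is a population
balance dH_ij/dt = production + remodelling − catabolism with closed
grid boundaries; sixteen parameters define the wild-type model. VLDL
production is a two-dimensional log-normal over core contents scaled to
the measured VLDL-TG production rate; the PL shed by shrinking VLDL
drives HDL lipid accumulation (the sub-models are solved consecutively).
All rate laws are linear in the state, so steady states are obtained by
a direct sparse solve. Profiles per component (TG, TC, FC, CE, PL,
particle number, per-process fluxes) are produced by integrating each
grid cell between fraction boundaries obtained from a two-parameter
gel-filtration calibration, log D = p1 + p2·Kav.

On top sit: weighted least-squares parameter estimation with
steady-state and boundary penalties, multi-start optimization, profile
likelihood and local resampling for identifiability; knockout sweeps
(SR-B1, PLTP, LDLr), the LXR-agonist production adaptation, three model
extensions (E1–E3) for the enlarged-HDL phenotype; and a synthetic-data
generator used for validation throughout.

## Worked example

```python
import numpy as np
import lipogrid as lg

model = lg.default_model()
boundaries = lg.default_boundaries()
params = lg.default_parameters()
sim = lg.Simulator(model, boundaries)

profiles, coupled = sim.profiles(params, 60.0, components=("TG", "TC"))
tc, tg = profiles["TC"], profiles["TG"]
print(f"steady state reached: {coupled.converged}")
print(f"surface-remnant PL flux to HDL: {coupled.pl_release:.2f} nmol/h")
print(f"plasma totals: TC {tc.total:.1f} nmol, TG {tg.total:.1f} nmol")
cal = lg.default_calibration()
peak = int(tc.fractions[np.argmax(tc.amounts)])
print(f"TC peak: fraction {peak} ({cal.diameter_of_fraction(peak):.1f} nm)")

rows = lg.sweep_summary(model, params, lg.KNOCKOUT_SCENARIOS["SR-B1"], 60.0)
print("SR-B1 knockout HDL-TC change across sweep: "
      + ", ".join(f"{100*r['hdl_tc_rel_change']:+.0f}%" for r in rows))
```

prints

```
steady state reached: True
surface-remnant PL flux to HDL: 7.49 nmol/h
plasma totals: TC 145.5 nmol, TG 20.9 nmol
TC peak: fraction 27 (11.3 nm)
SR-B1 knockout HDL-TC change across sweep: +72%, +70%, +69%, +67%, +65%
```

The simulated mouse is HDL-dominant in cholesterol with the HDL peak at
11.3 nm; the wild-type VLDL-TG production of 60 nmol/h feeds a 7.5
nmol/h surface-remnant PL flux into HDL. Deleting the HDL selective
uptake receptor (SR-B1, residual activity swept over 0.1–5 %) raises
HDL cholesterol by roughly 70 % and shifts the peak toward larger
particles.

The same machinery is scriptable from the shell:

```sh
lipogrid synth --seed 3 --out synth.tsv          # synthetic observed table
lipogrid fit --data synth.tsv --n-starts 50 --out fitdir
lipogrid scenario --name PLTP --out pltp.tsv
lipogrid simulate --out simdir                   # component profiles
```

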
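# Wild-type kinetic/geometric parameter set (16 parameters).
# SYNTHETIC stand-in values: the published fitted values are not shipped
# with this package; this set was calibrated once so that the model
# reproduces a realistic chow-fed mouse profile (HDL-dominant cholesterol,
# HDL peak near 11 nm, VLDL peak near 40 nm) and the published knockout
# phenotypes, and is frozen as the package's reference operating point.
# transform: how the optimizer sees the parameter (log or linear).
parameters:
  - name: hdl_prod_rate
    value: 1.2e14
    transform: log
    bounds: [1.0e12, 1.0e16]
    role: HDL production (particles/h)
  - name: hdl_prod_small_frac
    value: 0.95
    transform: linear
    bounds: [0.0, 1.0]
    role: weight of the smaller nascent HDL type (dimensionless)
  - name: lip_rate
    value: 0.5
    transform: log
    bounds: [1.0e-3, 50.0]
    role: universal lipolysis rate, shared by HDL and VLDL (1/h)
  - name: lip_exp
    value: 1.0
    transform: linear
    bounds: [0.2, 3.0]
    role: universal lipolysis exponent on relative TG content
  - name: hdl_sel_rate
    value: 0.045
    transform: log
    bounds: [1.0e-4, 10.0]
    role: HDL selective CE uptake rate (1/h)
  - name: hdl_chol_rate
    value: 8.8e-3
    transform: log
    bounds: [1.0e-6, 1.0]
    role: HDL TC accumulation rate (CE molecules/h per nm^2 per nmol PL/h)
  - name: hdl_trig_rate
    value: 2.0e-4
    transform: log
    bounds: [1.0e-7, 0.1]
    role: HDL TG accumulation rate (TG molecules/h per nm^2 per nmol PL/h)
  - name: hdl_upt_rate
    value: 0.2
    transform: log
    bounds: [1.0e-3, 10.0]
    role: HDL catabolism rate at the reference diameter (1/h)
  - name: vldl_nascent_diameter
    value: 45.0
    transform: linear
    bounds: [30.0, 70.0]
    role: nascent VLDL diameter (nm)
  - name: vldl_lip_rate
    value: 3.0
    transform: log
    bounds: [1.0e-2, 100.0]
    role: VLDL-specific lipolysis rate at the reference diameter (1/h)
  - name: vldl_lip_exp
    value: 1.5
    transform: linear
    bounds: [0.0, 4.0]
    role: VLDL-specific lipolysis exponent on relative size
  - name: vldl_sel_rate
    value: 0.1
    transform: log
    bounds: [1.0e-4, 10.0]
    role: VLDL selective CE uptake rate (1/h)
  - name: vldl_upt_const
    value: 0.3
    transform: log
    bounds: [1.0e-3, 10.0]
    role: constant VLDL catabolism (1/h)
  - name: vldl_upt_surf_rate
    value: 0.4
    transform: log
    bounds: [1.0e-2, 50.0]
    role: surface-area-dependent VLDL catabolism ceiling (1/h)
  - name: vldl_upt_surf_d50
    value: 35.0
    transform: linear
    bounds: [15.0, 70.0]
    role: diameter of half-maximal surface-dependent catabolism (nm)
  - name: vldl_upt_surf_hill
    value: 4.0
    transform: linear
    bounds: [1.0, 8.0]
    role: steepness of the surface-dependent catabolism saturation
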
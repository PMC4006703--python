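# Structural model constants.  SYNTHETIC stand-in values: chosen to satisfy
# the published structural constraints (grid shapes, composition bound
# ordering, 2 nm surface layer, nascent compositions) since the original
# supplementary tables are not shipped with this package.  Units noted per
# entry.
grids:
  vldl:
    i_max: 40            # TG index levels
    j_max: 8             # CE index levels
    tg_min: 20.0         # molecules/particle
    tg_max: 200000.0     # molecules/particle  (tg_max > ce_max for VLDL)
    ce_min: 5.0          # molecules/particle
    ce_max: 12000.0      # molecules/particle
  hdl:
    i_max: 8
    j_max: 40
    tg_min: 2.0
    tg_max: 200.0
    ce_min: 3.0
    ce_max: 3500.0       # ce_max > tg_max for HDL
geometry:
  surface_thickness_nm: 2.0
  v_tg_nm3: 1.61         # molecular volume of a triglyceride
  v_ce_nm3: 1.17         # molecular volume of a cholesteryl ester
nascent:
  hdl_types:             # ordered large -> small; weights (1-k2, k2)
    - target_tc: 55.0    # molecules total cholesterol per particle
      sigma_log: 0.12
    - target_tc: 24.0
      sigma_log: 0.12
  vldl_tg_ce_ratio: 10.0 # molar TG:CE of nascent VLDL
  vldl_cv: 0.2           # CV of nascent VLDL lipid content
  e3_tg_ce_ratio: 0.05   # molar TG:CE of the E3 large CE-rich input
reference_sizes:
  d_ref_hdl_nm: 10.0
  d_ref_vldl_nm: 40.0
calibration_anchors:     # (fraction, hydrodynamic diameter nm); class medians
  fractions: [14, 20, 27]
  diameters_nm: [41.5, 22.6, 11.3]
fractions:
  first: 1
  last: 40
estimation:
  weight_floor_nmol: 0.5   # additive floor of the per-fraction s.d.
  weight_cv: 0.10          # multiplicative part of the per-fraction s.d.
  lambda_steady_state: 1.0e6   # penalty weight on the squared rhs residual
  lambda_boundary: 1.0e2       # penalty weight on squared boundary mass share
study_conditions:
  measured_vldl_tg_production_nmol_h: 60.0   # wild-type Triton estimate
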
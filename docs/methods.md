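# Methods

This note documents the model implemented in `lipogrid`, the choices
made where the design was open, the numerical machinery, and what the
validation on synthetic data does and does not demonstrate.

## Composition model

A circulating lipoprotein is reduced to its core triglyceride (TG) and
cholesteryl-ester (CE) molecule counts. Two particle classes are
modelled: HDL, and the Apo B-containing continuum spanning VLDL and its
LDL remnants (called "VLDL" throughout). Each class lives on a discrete
(i, j) grid; i indexes TG, j indexes CE.

* **TG ladder.** Lipolysis removes TG roughly in proportion to what is
  present, so equal index steps correspond to equal relative TG changes:
  `#TG(i) = TG_min·g^(i−1)` with `g` fixed by the bounds. TG-free
  particles are excluded by construction (the ladder never reaches 0).
* **CE ladder.** CE turnover is not proportional to CE content (uptake
  and esterification add cholesterol regardless of what is present), so
  the CE axis is instead spaced for even data coverage: on the
  minimal-TG column the particle diameter interpolates geometrically
  between the ladder endpoints. Because the size calibration makes
  log-diameter affine in fraction number, this renders the CE index
  linear in FPLC fraction number for small particles — each fraction of
  the HDL peak region is covered by a comparable number of states. The
  closed form is `D(j) = D_min·(D_max/D_min)^((j−1)/(j_max−1))` with
  `#CE(j)` recovered by inverting the sphere volume; its defining
  linearity property is asserted by test rather than assumed.
* **Size.** `D = 2(r_core + δ)` with a spherical core,
  `(4/3)π r_core³ = #TG·v_TG + #CE·v_CE`, surface thickness δ = 2 nm and
  molecular volumes v_TG = 1.61 nm³, v_CE = 1.17 nm³ (standard values
  from molecular weight and density). An empty core gives the 4 nm
  minimum diameter.
* **Surface lipids.** Free cholesterol and phospholipid counts follow
  from tabulated #FC/(#CE+#TG) and #PL/(#CE+#TG) ratios per core radius,
  interpolated linearly over log radius with nearest-row (constant)
  extrapolation outside the table. Total cholesterol of a particle is
  TC = #FC + #CE throughout the package. The packaged table
  (`surface_ratios_synthetic.tsv`) is a synthetic stand-in emulating
  published size-class ratios: eight rows from r = 1.2 nm to 40 nm with
  ratios declining with size as surface/volume scaling dictates.

Grid shapes are 40×8 (VLDL; TG-dominated, TG_max > CE_max) and 8×40
(HDL; CE-dominated), 320 states per sub-model. The packaged bounds
(VLDL TG 20–2·10⁵, CE 5–1.2·10⁴; HDL TG 2–200, CE 3–3500 molecules) are
synthetic stand-ins chosen so that (a) the physiological size ranges
(LDL ≈ 22.6 nm at mostly-CE cores, nascent VLDL ≈ 45 nm, HDL 6–24 nm
including the enlarged-HDL regime) are representable with headroom, and
(b) the nascent VLDL composition sits well inside the grid so the
closed upper boundaries stay empty.

Indices are real-valued coordinates with model states at integer
points; sub-integer evaluation exists only for fraction-boundary
integration. Half-cells that overhang the ladder ends take the
ladder-edge composition (constant continuation).

## Kinetic model — rate-law reference

Each sub-model is a population balance over its grid. Remodelling moves
a particle one index step; because an index step corresponds to a
composition-dependent number of molecules, every molecular rate v
(molecules/h per particle) is converted to an index-step particle rate
by the per-state correction factor `v / Δlipid(step)`, keeping the
molecular ledger exact on the non-uniform grid. All grid-boundary
fluxes are zero; the only exits are catabolic.

With relTG = #TG/(#TG+#CE), relCE = 1−relTG, D the diameter, A = πD²
the surface area, and Q_PL the surface-remnant phospholipid influx
(nmol/h, see coupling):

| process | per-particle molecular rate | parameters |
|---|---|---|
| universal lipolysis (HDL+VLDL, i→i−1) | `lip_rate · relTG^lip_exp · #TG` | `lip_rate`, `lip_exp` (shared) |
| VLDL-specific lipolysis (i→i−1) | `vldl_lip_rate · (D/D_v)^vldl_lip_exp · #TG` | `vldl_lip_rate`, `vldl_lip_exp` |
| selective CE uptake (j→j−1) | `sel_rate · relCE · (D/D_ref) · #CE` | `hdl_sel_rate` / `vldl_sel_rate` |
| HDL TC accumulation (j→j+1) | `hdl_chol_rate · Q_PL · A` | `hdl_chol_rate` |
| HDL TG accumulation (i→i+1) | `hdl_trig_rate · Q_PL · A` | `hdl_trig_rate` |
| HDL catabolism (removal) | first-order rate `hdl_upt_rate · (D_ref/D)` | `hdl_upt_rate` |
| VLDL catabolism, constant (removal) | first-order rate `vldl_upt_const` | `vldl_upt_const` |
| VLDL catabolism, surface (removal) | first-order rate `vldl_upt_surf_rate · A^h/(A50^h + A^h)`, `A50 = π·d50²` | `vldl_upt_surf_rate`, `vldl_upt_surf_d50`, `vldl_upt_surf_hill` |

D_ref = 10 nm (HDL) and D_v = 40 nm (VLDL) are fixed reference sizes
that make the rate parameters interpretable at typical particle sizes.
Removal processes act on the absolute amount of the targeted lipid;
lipolysis is modulated by relative TG content, selective uptake by size
and relative CE content, HDL catabolism is inversely proportional to
size, and the saturating surface-area term represents Apo E-mediated
uptake of large particles. Selective uptake removes CE only; the
surface FC shed as the particle shrinks is part of the surface-remnant
ledger, not of the selective-uptake flux. VLDL has no gain processes:
core content never increases there.

**Production.** HDL particles enter at `hdl_prod_rate` particles/h,
split between two nascent species with weights (1−k₂, k₂),
k₂ = `hdl_prod_small_frac`. Each species carries the minimal TG content
and a narrow log-normal CE distribution centred where total cholesterol
(CE+FC) matches the species target — 24 molecules for the small species
and 55 for the large one (in vitro-style nascent compositions; the
small-species 24 is the value the wild-type model effectively produces,
since the fitted k₂ is close to 1). VLDL production is an independent
two-dimensional log-normal over (TG, CE): the nascent-diameter
parameter sets the mean core volume, split at a fixed molar TG:CE
ratio of 10 (TG-rich nascent VLDL); the content CV is fixed at 0.2.
Cell weights are obtained by 2-point Gauss integration of the density
per index cell (with the ladder Jacobians), renormalized on the grid,
and globally scaled so that simulated VLDL-TG production equals the
measured rate — the model's single absolute flux anchor.

**Coupling.** The sub-models are solved consecutively. At the VLDL
steady state, every shrink step sheds surface lipid; the summed PL
release Q_PL (nmol/h) is the scalar input that drives HDL TC and TG
accumulation. This one-way coupling reflects the dominant direction of
surface-remnant transfer in the mouse (no CETP).

**Units.** State amounts are particle counts per plasma pool of the
profiled specimen; molecular fluxes are molecules/h and are converted
to nmol via Avogadro's number wherever profiles or ledgers are
reported. The packaged study condition (60 nmol VLDL-TG/h) produces
profile totals of order 10²  nmol, matching the scale of per-fraction
lipid assays.

## Steady state

Every rate law above is linear in the state, so each sub-model is an
affine ODE dx/dt = Mx + p. M is a transition-rate matrix minus positive
uptake rates — an M-matrix — so the steady state −M⁻¹p exists, is
unique and non-negative whenever catabolism is active everywhere. The
solver therefore uses a direct dense solve (320×320, ~1 ms), verifying
the residual and falling back to stiff BDF time integration for
degenerate draws (e.g. catabolism rates at the bound); non-convergence
is reported in the diagnostics, never raised, so the cost function can
penalize it. Negative entries at round-off level (≲10⁻⁹ of the maximum)
are clamped to zero; anything larger triggers the fallback.

The diagnostics also track the mass fraction in the top two rows and
columns of the grid. With the packaged parameters this is ≤10⁻⁵ (VLDL)
and ≈1.4·10⁻² (HDL; the top TG rows are genuinely, mildly occupied by
TG-accumulating HDL), and the estimation penalty keeps optimizers away
from parameter regions that pile mass against the closed boundaries.

## In silico FPLC profiles

Gel filtration separates by hydrodynamic size; by the standard
calibration convention log D is affine in the partition coefficient
Kav, and Kav is affine in fraction number (constant fraction volume).
The two calibration parameters are fitted by least squares to anchor
fractions with known class-median sizes; the packaged anchors
(fraction 14 → 41.5 nm VLDL, 20 → 22.6 nm LDL, 27 → 11.3 nm HDL) are a
synthetic transcription chosen to be mutually consistent with the
4 nm diameter at the last pictured fraction (37) — the fitted mapping
reproduces all three medians within 0.6 % and gives 4.15 nm at
fraction 37.

Fraction k owns the diameter interval between the calibration evaluated
at the half-integer edges, half-open `[lower, upper)` with the shared
edge owned by the smaller-numbered (larger-diameter) fraction. Each
grid state owns the unit index cell `[i±½)×[j±½)`; its content is
apportioned to fractions by the measure of the cell below each edge
diameter. Because diameter is strictly monotone in both indices, the
CE-axis crossing of each edge is computed in closed form per TG
coordinate, the TG integral is split analytically at the ladder edges,
and 8-point Gauss quadrature handles the remaining smooth monotone
segments. Apportionment therefore conserves content exactly (shares
telescope to 1) and agrees with a dense 100×100 midpoint subdivision to
better than the oracle's own quantization (≤0.3 %, well inside the
0.5 % contract). Sizes outside the modelled fraction range go to
explicit underflow/overflow bins. Lipid profiles weight the particle
shares by the state's nominal per-particle content; flux profiles run
any per-state lipid-flux field through the same weights. The weight
matrix depends only on geometry and is computed once per session.

## Parameter estimation

* **Cost.** Weighted SSR over the TG and TC fraction tables plus two
  penalty residuals per sub-model: λ_ss·(relative rhs residual)² for
  steady-state failure and λ_b·(boundary mass fraction)². Per-fraction
  weights are 1/sd² with sd = floor + cv·observed (defaults 0.5 nmol and
  10 %), a literature-style variability model standing in for the
  replicate errors that published single-profile tables lack. Defaults
  λ_ss = 10⁶ (any failed steady state dominates the cost) and λ_b = 10²
  (tolerates the ~1 % physiological boundary occupancy, punishes
  pile-ups, which reach O(10 %) mass). Simulation failures return a
  large finite residual vector so bounded optimizers can back away.
* **Transforms.** Rate-like parameters are log₁₀-scaled, geometric and
  dimensionless ones affinely, each to the unit interval, so the
  optimizer sees a canonical box and comparable magnitudes.
* **Optimizer.** Bounded trust-region least squares (`least_squares`,
  trf) on the residual vector, multi-started from uniform draws in the
  box; all randomness flows from one seed through `SeedSequence`.
* **Identifiability.** Profile likelihood re-optimizes all other free
  parameters on a scan grid, warm-starting outward from the optimum;
  curves whose excursion stays below the pointwise 95 % chi-square
  threshold (Δcost = 3.84) are flagged flat. The threshold is an
  approximation — without replicate-based error models the weighted SSR
  is not a calibrated deviance — and is documented as such. Local
  resampling re-optimizes from perturbed starts around an optimum and
  reports the fractions returning versus escaping.

**The HDL rate degeneracy.** Jointly scaling the six HDL rate
parameters (production plus the five kinetic rates) multiplies every
HDL flux by the same factor while leaving the steady-state field — and
hence every concentration profile — exactly invariant; this follows
from the linearity of the sub-model in its state with production
entering as a rate. Since the shared universal lipolysis rate is pinned
by the VLDL sub-model (where the absolute TG production anchors it),
the practical consequence is that the five remaining HDL rates are
individually unidentifiable from profile data: only their ratios are
estimated, and an absolute HDL flux measurement would be needed to fix
the scale. Recovery tests therefore assert ratios for the HDL group and
absolute values for the VLDL side.

## Scenarios

* **Knockouts** scale the parameters of the affected process over
  published residual-activity ranges: SR-B1 → `hdl_sel_rate` ×
  0.001–0.05; PLTP → `hdl_chol_rate` × 0.30–0.50 (the parameter lumps
  PLTP with LCAT/ABCA1 activity, hence the conservative floor); LDLr →
  both VLDL catabolism rates × 0.40–0.925. Sweeps are first-class:
  summaries report every sweep point, since the appropriate residual
  activity within a published range is not a single number.
* **LXR production adaptation** keeps the untreated nascent VLDL
  particle secretion rate and CE content while multiplying the TG
  content by the measured relative increase in VLDL-TG production; the
  nascent diameter then follows from the composition and leaves the
  free parameter set (16 → 15).
* **Extensions** (alternatives, applied one at a time, each nesting the
  base model exactly at zero added rate): E1 adds TC accumulation
  restricted to large particles (logistic gate in diameter, fixed 1 nm
  steepness; 2 parameters); E2 adds a saturating surface-area-dependent
  HDL catabolism term with the same functional form as the VLDL Apo E
  uptake law (3 parameters); E3 adds a second nascent input of large,
  TG-poor, CE-rich particles through the same discretized log-normal
  machinery as VLDL production (molar TG:CE fixed at 0.05;
  3 parameters). E1 and E2 calibrated to deposit the same cholesterol
  mass in the LDL-size fractions remain distinguishable by their
  catabolism-to-production TC flux ratio (E2's is ≈2× larger) — the
  flux-readout logic by which the mechanisms can be told apart
  experimentally.
* **Lipolysis-block (Triton-style) experiment**: from the wild-type
  steady state all lipolysis fluxes are zeroed and the system integrated
  for 4 h; the plasma-TG rise divided by the horizon estimates VLDL-TG
  production. Whole-particle uptake stays active, so the estimate is a
  strict lower bound on the true production and approaches it as
  whole-particle uptake becomes small (>90 % recovery when catabolism
  rates are reduced to ~10⁻²/h). At the packaged wild-type operating
  point the estimate recovers ≈30 % of the true production: the
  reference parameter set clears large VLDL at a few tenths per hour,
  which is fast relative to a 4 h accumulation window. This is a known
  property of the packaged stand-in parameters, not of the method.

## Synthetic data generator

The generator forward-simulates the coupled model with known
parameters, produces the TG/TC fraction tables and the true VLDL-TG
production, and applies mean-one multiplicative log-normal noise with
5 % CV per fraction (an optional additive floor exists for detection-
limit studies). The CV is a stand-in: published FPLC tables are single
measurements, so no empirical replicate SD is available. All noise
derives from the spec's seed.

What passing on synthetic data shows: the estimation machinery inverts
the forward model correctly (noiseless recovery to <1 %), is unbiased
under the assumed noise, and the documented degeneracy behaves as
analysed. What it does not show: that the rate-law forms, the surface
ratio table or the reference parameter values are quantitatively those
of real mouse plasma — the packaged constants are calibrated stand-ins
reproducing published structural facts and knockout phenotypes
(HDL-dominant cholesterol, HDL peak at 11.3 nm, SR-B1 knockout ≈+70 %
HDL-TC, PLTP knockout reaching ≈−55 % plasma TC), not fitted to any
shipped experimental dataset. Real profiles also contain features the
generator omits: chromatographic peak broadening and carry-over,
chylomicron material in non-fasted samples, and assay baselines.

## Problem sizes and numerics

Defaults used by the test suite and the acceptance script: 320 states
per sub-model; 40 fractions; steady states by direct solve (tolerance
‖rhs‖∞ < 10⁻⁸ relative); parameter recovery with 50 random multi-starts
(a coarse pass capped at 30 trust-region iterations, then a tight
polish of the best three candidates at tolerances 10⁻¹²) — the full
estimation campaign would use the same machinery at ~10³ starts;
profile-likelihood scans of 5 points per parameter; noise-bias checks
over 20 replicates; Monte-Carlo oracles at 4·10⁵ samples. A coupled
steady state plus profiles costs ≈5 ms, so these sizes were chosen as
comfortable desk-scale settings for the synthetic study conditions.

## Known limitations

* Chylomicron metabolism and Apo E-knockout phenotypes are out of
  scope; the model cannot represent chylomicron-remnant accumulation.
* CETP-expressing (humanized) mice would require a neutral-lipid
  exchange coupling between the sub-models that is not implemented.
* Discoidal HDL is not modelled; the HDL grid represents spherical
  particles only.
* The composition grid quantizes CE coarsely on the VLDL side (8
  levels), which shifts discrete nascent-CE means by a few percent
  relative to the continuous density — visible in the Monte-Carlo
  oracle test and accepted as the price of the even data coverage the
  grid is designed for.
* All numeric constants not fixed by structure (grid bounds, surface
  ratios, nascent targets, calibration anchors, weights, the wild-type
  parameter set) are synthetic stand-ins, clearly labelled in their
  fixture files and chosen once against published constraints; every
  one is config-overridable for users with real tables.
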
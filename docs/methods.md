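# Methods

## The glide model and its assumptions

A passively gliding, negatively buoyant diver is modelled as a point mass
acted on by three along-path forces: quadratic drag referenced to frontal
area, the along-path component (`sin p`) of the tissue's net buoyancy, and
the along-path component of the buoyancy of the respiratory air carried from
the surface. The air space is treated as perfectly compliant, compressing by
Boyle's law `V(d) = V(0)/(1 + 0.1 d)` (one extra atmosphere per 10 m); the
tissue is treated as incompressible over the depths analysed; lift and
thrust-induced drag are neglected, which is why glide selection demands steep
(< −60°) stable descents; the drag coefficient is held constant (its Reynolds
dependence flattens at the speeds involved). Air mass `rho_air V(0)` is
conserved (molecules don't leave), so it appears in the buoyancy deficit but
the inertial mass is the body mass alone (the difference is < 0.05 %).

Mass-specific DRAV is reported in ml/kg: `DRAV = V_air(0)/m x 1e6`.

## Estimation chain

1. **Kinematics.** Depth is decimated to 1 Hz and acceleration to 25 Hz
   (zero-phase 4th-order Butterworth anti-alias, then stride slicing). The
   gravity/dynamic split uses a zero-phase low-pass whose cutoff is read off
   the Welch PSD of sway: the minimum between the postural band and the
   dominant stroking peak, falling back to half the stroking frequency when
   no postural band rises above the valley (contrast factor 4; stroking peak
   must exceed 10x the median high-band PSD, else the record is flagged and a
   0.7 Hz default applies). Pitch is `arcsin(-g_surge/|g|)` (negative =
   head-down), roll `atan2(g_sway, -g_heave)`. Speed is the 1 Hz depth
   difference divided by `sin(pitch)`, reported as a non-negative along-path
   magnitude and left undefined at |pitch| <= 30° where the projection is
   unreliable.
2. **Dives and phases.** A dive is any excursion beyond 5 m. Descent ends at
   the first positive pitch; ascent begins at the last negative pitch; the
   bottom phase lies between. Boundaries are at 1-s resolution — the model's
   own time step — so no sub-sample interpolation is attempted.
3. **Strokes and glides.** Half-strokes are between-zero-crossing intervals
   of dynamic sway whose peak amplitude reaches a per-individual threshold
   (default: 3x the median absolute deviation of bottom-phase dynamic sway,
   floored at 0.5 m/s² — about a quarter of a typical stroking amplitude —
   so that quiet records and filter-edge transients cannot produce spurious
   strokes). A sample exactly at zero opens the following half-stroke.
   Glides are maximal stroke-free runs with sub-threshold sway, at least 5 s
   long; the 10 s requirement belongs to *selection*, kept separate so the
   two stages remain independently configurable.
4. **Selection.** Descent glides clipped to the 5–50 m analysis window must
   start above 30 m, last over 10 s, average steeper than −60°, and keep the
   circular variance of pitch and roll below 0.1. One glide per dive (the
   first qualifying one). Every rejection is logged with the violated
   criterion, since selection attrition is itself a result.
5. **Tissue density** is fitted (bounded scalar minimisation over
   [1015, 1060] kg/m³) on glide portions lying entirely below 100 m with the
   air term switched off, minimising the unweighted mean squared speed error.
   The last 4 s before the bottom phase are trimmed (pitch-over and the
   anti-aliased depth corner distort speeds there).
6. **Drag coefficient** comes from deep glides whose final 5 s speed slope is
   below 1 %/s (a terminal plateau): a joint grid over C_d (100 log-spaced
   candidates in [0.01, 1]) and tissue density, scoring the measured plateau
   speeds against open-loop simulated speeds, then a Nelder–Mead polish in
   (log C_d, rho_tissue). Two designed details matter here. *Simulated*, not
   closed-form, plateau speeds are scored: a descending glide chases a
   terminal speed that itself drifts with depth, so measured plateaus sit
   ~1 % off the instantaneous closed-form value, and on the narrow
   C_d-vs-density trade-off ridge a 1 % systematic error moves the minimum by
   tens of percent in C_d. Scoring simulations cancels the lag. The
   continuous polish removes grid aliasing along the same ridge (coordinate
   descent stalls on it; a simplex does not). Identifiability of the pair
   rests on the depth variation of seawater density, so a depth-resolved
   density profile is required; per-individual fits are pooled by median.
7. **DRAV.** For each selected glide, speed is simulated from the measured
   start speed over the measured depth/pitch series for 301 candidate
   volumes, scored by compression-weighted MSE `(1/n) Σ c_i e_i²`,
   `c_i = 1/(1+0.1 d_i)`. Ties take the smallest volume. Estimates of exactly
   0 (physiologically impossible — seals cannot fully exhale) and estimates
   at the 0.03 m³ grid edge are flagged.
8. **Neutral-buoyancy depth.** The net upward force
   `F_B(d) = g [rho_sw(d)(m/rho_tissue + V(0)/(1+0.1d)) - m - rho_air V(0)]`
   is scanned on a 1 m grid from 1 m to the dive's maximum depth; the first
   non-positive value marks the transition from buoyancy hindering to aiding
   the descent. Sentinels: `<1m` (aiding from the onset) and `never` (the
   air-mass term keeps `F_B` positive throughout — possible only near
   neutral tissue). A closed-form inversion of `F_B(D) = 0` produces the
   DRAV-vs-tissue-density isolines of constant neutral depth.

## Numerical scheme: why trapezoidal, and why midpoint depths

Measured speed is a forward difference of 1 Hz depth, i.e. the *average*
speed over `[t, t+1]` — a sample on the staggered midpoint grid. The
estimator therefore (a) associates each speed sample with the mid-interval
depth and pitch, and (b) propagates speed with an explicit trapezoidal
(Heun) 1-s step, averaging the acceleration at the current state and at the
Euler-predicted next state. With plain forward-Euler steps on sample-aligned
depths, noise-free DRAV recovery is biased low by up to 6 grid steps
(0.0006 m³, ~2 ml/kg at 300 kg); with the staggered trapezoidal scheme it is
exact to the grid. A plain-Euler mode remains available
(`simulate_glide_speed(..., method="euler")`). The 1-s step size is the
method's step size, not a numerical convenience; the test suite checks it
against a high-resolution ODE integration.

## Parameters

| parameter | default | units | meaning / why |
|---|---|---|---|
| dive threshold | 5 | m | surface/dive boundary; also the shallow edge of every analysis window (flipper–surface interaction above it) |
| analysis window | 5–50 | m | below 50 m the air holds < 16.7 % of its surface volume and stops shaping the speed profile |
| deep-glide window | > 100 | m | air compressed to < 9 %; tissue density dominates |
| C_d | 0.03 | – | pooled median of per-individual terminal-speed fits; sweep 0.02–0.05 available |
| rho_air | 1.225 | kg/m³ | air at 101,325 Pa, 15 °C |
| g | 9.81 | m/s² | |
| candidate grid | 0–0.03, step 1e-4 | m³ | upper bound spans maximum plausible lung capacity of the heaviest animals |
| stroke threshold | 3×MAD, floor 0.5 | m/s² | per-individual; floor ≈ quarter of typical stroke amplitude |
| min glide (detect / select) | 5 / 10 | s | detection vs selection kept separate |
| selection pitch / circ. var. | −60° / 0.1 | | steep, stable glides only (lift neglected) |
| tissue bounds | 1015–1060 | kg/m³ | brackets plausible phocid body densities |

Seawater density comes from a user-supplied depth profile (piecewise-linear,
constant extrapolation) or constant; a temperature/salinity profile is
converted with the one-atmosphere EOS-80 polynomial (pressure dependence of
density is second-order for these purposes and not applied).

## The synthetic-data generator

`synthetic_data` builds full tag records with known truth: an 8 s surface
interval; a stroking descent at constant speed (default 1.84 m/s, pitch
−75°, 1.4 Hz sinusoidal sway of 2 m/s², duration quantised to whole
half-stroke cycles so the programmed cessation depth is exact); a passive
glide integrated *closed-loop* (speed and depth both propagated at 0.04 s
resolution) down to the maximum depth; a quiet bottom phase; a stroking
ascent. Gravity components follow the programmed pitch; Gaussian noise can
be added to the acceleration channels and the depth channel. Defaults mirror
the calibration deployments: mass 313 kg, girth 1.70 m, tissue density
1037 kg/m³, DRAV 21.1 ± 8.1 ml/kg (clipped to 1.3–53.7), cessation
18.8 m, maximum depth uniform over 100–700 m. Cohorts can impose a known
linear dependence of DRAV on depth (+2 ml/kg per 100 m) and tissue density
(+4 ml/kg per kg/m³) for trend-recovery checks.

The generator is deliberately asymmetric to the estimator: it integrates
depth from simulated speed, while the estimator simulates speed over
measured depth, so round-trip tests never compare an algorithm with itself.
`speed_noise_sd` applies where speed is a primary signal (the glide-level
generator, which emulates exactly what the kinematics stage would deliver);
full tag records instead carry `depth_noise_sd`/`accel_noise_sd`, since
speed there is derived downstream.

What the simulator does **not** emulate: thrust mechanics (stroking speed is
held constant rather than force-balanced), body rotations contaminating
dynamic acceleration, magnetometer information, drift dives, depth-dependent
stroke modulation, tag orientation error, and pressure effects on tissue.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own physics, not robustness to every artefact of
real deployments.

## Known limitations

* **Residual-air bias in tissue density.** Below 100 m the air term is small
  but not zero: for a true DRAV of `D` ml/kg the fitted tissue density is
  biased low by roughly `0.05 x D` kg/m³ (e.g. ~1.2 kg/m³ at 25 ml/kg over a
  100–400 m fit window), which propagates into a DRAV underestimate of
  ~15–20 % when the pipeline estimates both. This is inherent to excluding
  the air term from the deep fit; the test suite pins the bias direction, and
  the recovery benchmarks quote tissue-density accuracy in the air-free
  regime the assumption describes.
* The C_d/tissue-density pair is unidentifiable in truly constant-density
  water; estimation then returns a ridge point and should be treated as a
  product `A_f C_d` calibration.
* Boundary effects of zero-phase filtering (stroke cessation, glide onset)
  are kept to ~0.1 s by the threshold floor but not eliminated.
* Ascent glides are excluded by design (known systematic underestimation of
  DRAV from gas exchange during the dive).
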
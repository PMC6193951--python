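# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `chexfit`.

## Exchange models

Conformational exchange is modeled as first-order kinetics between a ground
state G and one or two sparsely populated excited states.  Supported
topologies are the two-state scheme G ⇌ E and the three linear three-state
schemes G ⇌ E1 ⇌ E2, G ⇌ E2 ⇌ E1 and E1 ⇌ G ⇌ E2 (no direct edge between the
terminal states).  Each edge carries one apparent rate k_ex = k_f + k_b; the
directional rates follow from stationarity across that edge,
k_{i→j} = k_ex · p_j / (p_i + p_j), which for the two-state scheme reduces to
the familiar k_GE = k_ex·p_E and k_EG = k_ex·p_G.  The rate matrix built from
these rates conserves population (columns sum to zero) and has the population
vector as its stationary state by construction.

State labels in three-state models carry meaning: E1 is the state producing
the larger minor dip.  Operationally we enforce p_E1 ≥ p_E2 during fitting
(parameterized as p_E2 = p_E1·f, f ∈ (0, 1]).  Without this constraint the
two chain topologies that differ only in which excited state adjoins G are
relabelings of one another and fit identically, making model selection
meaningless.

Chemical shifts are absolute ¹⁵N ppm.  Conversion to angular frequency uses
|γ(¹⁵N)/γ(¹H)| = 0.101329118, so a 600-MHz (¹H) spectrometer observes ¹⁵N at
60.7974708 MHz; only the magnitude of the ratio is used (the ¹⁵N γ is
negative, but no computed quantity here depends on the sign).

## CEST forward model

For each carrier offset the x, y, z magnetization of all states evolves under
one linear generator combining transverse/longitudinal relaxation, offset
precession, B1 nutation (RF along x) and exchange.  The start vector is the
equilibrium z-magnetization ∝ populations; evolution for T_EX is a matrix
exponential; the observable is the ground-state z component divided by its
reference value.

Key conventions, chosen once and used throughout:

* **Reference experiment is delay-free.**  The I₀ spectrum is modeled as
  omitting the T_EX period entirely, so the far-off-resonance plateau of a
  simulated profile is exp(−R1·T_EX).  This affects the absolute plateau
  level — and hence which R1 a fit returns — but never dip positions.
* **Relaxation toward zero.**  No thermal-recovery term during T_EX; the
  standard approximation for sub-second exchange periods.
* **Shared relaxation.**  All states share one R1 and one R2 by default
  (per-state R2 can be supplied); per-state relaxation is not identifiable
  from these data and sharing is the common convention.
* **B1 inhomogeneity off by default.**  The stated ±0.2 Hz calibration
  spread is available as a 3-point Gauss–Hermite average
  (`apply_b1_inhomogeneity`); its effect on dip depths is below 2% relative
  at B1 = 8.4 Hz, far below the fitting noise, so fits use the center value.

The propagator evaluates the stacked per-offset generators with one batched
eigendecomposition (these generators are generically diagonalizable), with a
per-matrix Padé matrix exponential as fallback; an independent fixed-step
Runge–Kutta integrator of the same ODE (`simulate_cest_ode`, dt = 10 µs)
serves as cross-check and agrees to ~1e-14 on spot checks.

Two physical fine points the tests encode: with B1 ≈ 13.5 Hz and R2 ≈ 11 s⁻¹
the on-resonance spin is underdamped, so the z-magnetization can nutate
slightly below zero (≈ −3·10⁻⁴) at the dip center — simulated ratios are
bounded by [−0.01, 1], not [0, 1]; and the ground line's off-resonant
saturation tail still depresses the profile by ~1% at 5 ppm from the dip.

Dip detection smooths the profile (moving average, window 5), takes the 95th
percentile as the plateau, and keeps local minima deeper than `min_depth`.
At the exchange rates studied here (k_ex ≳ 100 s⁻¹) minor dips are often
shoulders without a local minimum; dip detection is therefore a convenience
for initialization and bookkeeping, and the fitting layer does not depend on
it (see below).

## CPMG forward model

R2eff = −(1/T_CPMG)·ln(I/I₀), with uncertainty (1/T_CPMG)(ΔI/I).  ΔI is
estimated from duplicate ν_CPMG measurements.  Because a single duplicate
pair is a hopeless estimator of a standard deviation, the fitting layer pools
the *relative* repeat std (std/mean) over all residues at one static field
and applies it per point as ΔI = rel_std·I; this keeps the formula above
pointwise while matching the intensity-proportional character of
peak-intensity noise.  The pooled estimate from n = 2 repeats is biased low
by the usual √(2/π) factor, which inflates reduced χ² (to ≈ 1.5–2 on
synthetic data) but not point estimates; the covariance-matrix uncertainties
are scaled by reduced χ² and therefore absorb it.

The two-state dispersion model is the Carver–Richards closed form, computed
through a log-scaled branch for large arguments so it never overflows.  It
is exactly the dominant eigenvalue decay rate of the
(τ − 180° − 2τ − 180° − τ) echo cycle (verified to 1e-14 against a numeric
eigendecomposition), valid in all exchange regimes.  The independent oracle
(`simulate_cpmg_numeric`) propagates transverse magnetization explicitly
through the echo train with ideal refocusing pulses (complex conjugation) for
any number of states and converts the surviving ground-state coherence to
R2eff.  The two agree to 0.35% at the active-site-group parameters; the
difference — the projection of the initial condition onto sub-dominant
modes, absent from any dominant-eigenvalue expression — grows with the minor
population and reaches ≈ 2.5% at p_E = 5%, |Δω| = 1 ppm, k_ex ≤ 500 s⁻¹.
This is an intrinsic property of the closed form, not a numerical error, and
is why the cross-oracle test bounds the full-grid deviation at 2.5% rather
than 2%.

ν_CPMG = 1/(4τ_cp), so successive refocusing pulses are separated by
1/(2ν_CPMG) and a T_CPMG of 40/60/80 ms accommodates an integer number of
cycles for every value in the measured ladder.  The acquisition preset
encodes the printed ladder — twelve distinct values of which 100 Hz is
measured twice (13 measurements); the acquisition description's "fourteen"
appears to count differently and the printed list is authoritative here.

## Fitting

All fits are weighted trust-region least squares (lmfit/`least_squares`)
from a deterministic multi-start grid, so identical inputs give identical
results.  Bounds: k_ex ∈ [1, 10⁴] s⁻¹, p_E ∈ [10⁻⁴, 0.5], R2_0 ∈ [1, 100]
s⁻¹, shifts within the offset window ±5 ppm.  The (k_ex, p_E) start grid is
{100, 300, 1000, 3000} s⁻¹ × {0.5, 2, 8}%.

* **CPMG** (closed form, cheap): every grid start is optimized; |Δω| in ppm
  is shared across static fields with one R2_0 per residue per field.
  Individual and global fits share one engine, so a single-member "global"
  fit is identical to the individual fit.  Profiles whose low-ν minus high-ν
  R2eff contrast is below 2σ in every profile are flagged `no_exchange`
  instead of force-fitted.
* **CEST** (Bloch–McConnell, ~10 ms per evaluation): the grid is combined
  with candidate excited-state positions — detected dips plus a coarse scan
  of the offset range, since shoulder dips defeat peak picking — screened by
  a single χ² evaluation each, and only the best few starts are fully
  optimized.  Selected positions are kept pairwise ≥1.2 ppm apart so the
  starts do not all pile onto the deepest feature.  Three-state fits first
  fit the two-state model and include the embedded two-state solution
  (extra state at the population floor) as one start; optimizer
  monotonicity then guarantees the nested-model χ² ordering.  Two failure
  modes get dedicated starts that bypass the screen: stage-free starts with
  default relaxation rates (the two-state stage can converge to a
  pathological optimum when both minor features overlap the ground dip and
  would otherwise poison every inherited start), and a label-swapped start
  with E1 at the scanned position and E2 at the two-state solution, which a
  raw χ² screen cannot rank fairly because ground-shift and R2 nuisance
  mismatches dominate its score.
* **Grouping** is greedy agglomeration in (log k_ex, logit p_E), visiting
  residues in sequence order (deterministic; ties broken by residue number);
  default tolerances 0.4 in log k_ex (~±50%) and 0.6 in logit p_E.
  Structure-region tags can only split clusters, never merge them.

**Model selection** ranks candidate topologies by BIC (AICc and reduced χ²
are also reported).  BIC rather than AICc is a deliberate choice: a freely
scanned excited-state position can harvest the single best noise cluster
among ~191 offsets, an expected spurious χ² gain of ≈ 2·ln 191 ≈ 10.5
(look-elsewhere effect).  AICc's 2Δk = 6 penalty loses to that — on pure
two-state synthetic data it preferred a spurious third state more often than
not — while BIC's Δk·ln n ≈ 18 penalty does not, and the ranking among the
equally parameterized three-state topologies is unaffected.  The default
candidate set includes the two-state model as the parsimony reference.
Selection requires two detected minor dips unless the caller overrides
(`force=True`); at the published rates the minor dips are shoulders, so the
synthetic-data studies use the override.

**Uncertainties.**  `covariance` (default): reduced-χ²-scaled inverse of
J'J at the optimum, J the weighted-residual Jacobian — exactly the
closed-form linear-regression covariance for linear models.  `jacobian`: the
unscaled inverse, appropriate when per-point sigmas are absolute.
`monte_carlo`: ≥100 synthetic-noise refits, used as a cross-check (agrees
with the covariance method within a factor of two on synthetic dispersion
data).  Rank-deficient Jacobian columns are reported as infinite sigmas.

## Ligand binding

With the ground state the ligand-bound form, the minor-state population
follows p_minor([L]) = K_d/(K_d + [L]); free ligand is approximated by total
ligand, flagged valid per point when ligand ≥ 10× protein (a 1.8 mM protein
with 20 mM ligand satisfies this only marginally, which the flag makes
visible).  K_d is a weighted isotherm fit on fitted populations — not raw dip
depths — so the CEST fitting layer is the source of the observable.  The
pseudo-first-order rate k_ex = k_on[L] + k_off and the gated-rate product
(a forward rate multiplied by the occupancy fractions of gating events,
reported to one decimal) complete the kinetic interpretation.  The
independently measured calorimetric K_d of 0.7 mM is stored as a documented
cross-reference constant only.

## Synthetic data

Generators are pure functions of (scenario, preset, seed) and emit the same
TSV dialects the readers consume, so every pipeline stage is testable
offline.  Acquisition presets encode the published settings: 191 CEST
offsets from 100 to 138 ppm at 0.2 ppm spacing, B1 = 8.4/13.5 Hz (± 0.2 Hz),
T_EX = 800 ms at 600 MHz; CPMG ladders at 600 and 800 MHz with
T_CPMG = 60 ms (free enzyme), 80 ms (thioredoxin) or 40 ms (complex).

Truth scenarios take group-level (k_ex, p_E) from the published kinetics
table.  Quantities the table does not pin are drawn once per scenario from
physically typical ranges and documented here: CPMG |Δω| ~ U(1, 4) ppm,
ground shifts ~ U(106, 132) ppm, per-field R2_0 ~ U(10, 20) s⁻¹; CEST truths
use R1 = 1.2 s⁻¹, R2 = 11 s⁻¹, |Δω| ~ U(1.5, 3) ppm with random sign (the
two excited-state dips kept ≥1 ppm apart so they remain distinguishable).
The three-state CEST scenario places the binding edge at k_ex = 120 s⁻¹ with
p_E1 = 4.8% — the free-enzyme fraction of a 20 mM ligand at K_d ≈ 1 mM — and
the conformational edge at k_ex = 300 s⁻¹ with p_E2 = 1.5%, a visible but
clearly smaller third dip.

Noise: CPMG intensities carry multiplicative Gaussian noise (default 2%
relative), and duplicate ν points receive independent noise so they inform
the ΔI estimate.  CEST ratios carry additive Gaussian noise of σ = 1% on the
I/I₀ scale — peak intensity noise relative to the reference intensity, which
is approximately offset-independent.

What the generators deliberately do not emulate — and hence what passing
recovery tests do not demonstrate about real data: no spectral overlap or
peak-picking errors, no off-resonance pulse imperfections (mitigated
experimentally by recording at three carrier positions), no ¹H-decoupling
artifacts, no B0 drift, no protein oligomerization, and the CPMG generator
produces data exactly from the closed form being fitted (recovery quantifies
noise propagation, not model error).

## Problem sizes and replication

Recovery studies use the sizes the study design implies: the full 12-residue
active-site group at both fields for global CPMG fits, and single-residue
CEST profiles at both B1 values for three-state work.  Because a single
2%-noise replicate of the group fit carries ~10% intrinsic scatter in k_ex,
recovery is reported as the median over 5 (CPMG) or 20 (CEST model
selection) seeded replicates.

## Known limitations

* The Carver–Richards closed form vs echo-train discrepancy described above
  (≈2.5% worst case within the studied regime).
* Three-state CPMG fitting is intentionally absent (it did not improve the
  published dispersion analysis); the numeric echo-train oracle already
  handles N states if ever needed.
* CEST fits assume the documented delay-free reference convention; data
  acquired with a T_EX-containing reference would bias fitted R1 (only).
* `group_residues` uses fixed tolerances, not a statistical test; judging
  whether a global fit is adequate is left to the reported reduced χ².
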
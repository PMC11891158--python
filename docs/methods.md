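# Methods

## Model overview and assumptions

`radiosim` represents a macroscopic solid tumor as a cubic lattice of
geometrical cells (GCs), each holding on the order of NBC = cell density x
voxel volume biological cells (default 10^6 cells/mm^3 at a 1 mm voxel
edge).  Within a GC, cells form equivalence subclasses indexed by category
(stem; LIMP progenitors with k = 1..N_LIMP remaining mitoses; terminally
differentiated; apoptotic; necrotic), cycle phase (G1, S, G2, M, G0) and
radiation hit status (unhit; hit with two or one mitoses left).  All cells
of a subclass within a GC are treated as synchronized; subclasses in
different GCs are not.  The time step is 1 h, matching the duration of
mitosis, the shortest phase.

Key simplifications inherited from the modelling tradition this package
follows: oxygen and nutrient transport are not modelled explicitly —
hypoxic dormancy is summarised by two constants, the post-mitotic dormancy
probability P_sleep and the dormancy-exit fraction P_G0toG1; dose is
uniform over the tumor; the mechanical environment is isotropic and
invariant; repair kinetics beyond the Linear-Quadratic abstraction are not
modelled.

## The hourly biological update

Order of operations within each hour, for each GC:

1. spontaneous apoptosis removes a linear fraction R_A·dt from every
   living stem/LIMP subclass (cycling, dormant, hit or not), and R_ADiff·dt
   / R_NDiff·dt from the differentiated pool.  Rates are applied as linear
   per-hour fractions rather than exp(−R dt); at dt = 1 h the two agree to
   O(R²) and the linear form matches the rates' definition as "fraction of
   cells per unit time";
2. the apoptotic and necrotic pools age along hourly rings and entries
   older than T_A / T_N leave the tumor;
3. dormancies end at hazard 1/T_G0 per hour (see "Dormancy semantics");
   a fraction P_G0toG1 of the endings re-enters G1, the rest becomes
   necrotic;
4. cycle phases advance along hourly delay lines; cohorts whose residence
   expired move G1→S→G2→M, and cohorts completing M divide: a fraction
   P_sym of stem divisions yields two stem daughters, the rest one stem and
   one LIMP(N_LIMP); LIMP(k>1) divisions yield two LIMP(k−1); LIMP(1)
   divisions yield two differentiated cells;
5. newborn stem/LIMP siblings are routed together: with probability
   P_sleep the pair enters G0, otherwise G1.  The cycle-vs-dormancy
   decision is made once, at birth — there is no mid-cycle exit.

Counts are real-valued deterministic flows by default.  With
`stochastic=True` every branching (deaths, dormancy endings, symmetric
vs asymmetric division, sleep routing, residence splits, radiation kills)
is drawn binomially from a seeded generator; the deterministic mode is the
expectation of the stochastic one.  One simplification in the stochastic
mode: the sleep decision is drawn per division within each category, so an
asymmetric pair (one stem, one LIMP daughter) is co-routed only in
expectation.

### Phase durations and the hourly clock

T_G1 = T_S = 0.41 (T_c − T_M), T_G2 = 0.18 (T_c − T_M), T_M = 1 h, so the
four durations sum exactly to T_c.  Fractional durations are realised on
the hourly clock with the *exact mean residence*: entrants split between
floor(T) and ceil(T) hour residences with weights chosen so the cohort
mean equals T.  The alternative of rounding every duration up to the next
tick lengthens the effective cycle by up to 2 h; because the net growth
rate of a slow tumor is a small difference between birth and death fluxes,
that bias propagates into a systematic overestimate of the doubling time
(for the slow profiles studied here, tens of percent).  The exact-mean
delay line removes this bias while keeping cohort synchronization.

### Dormancy semantics

Two readings of the dormancy parameters are implemented:

* `g0_exit="sojourn"` (default): dormancy lasts an exponentially
  distributed time with mean T_G0 (hazard 1/T_G0 per hour); when it ends,
  a fraction P_G0toG1 of the cells re-enters G1 and the remainder dies
  through necrosis; spontaneous apoptosis competes throughout.  The
  survival of the dormancy detour is then
  P_G0toG1/(T_G0·R_A + 1), the factor appearing in the closed-form
  free-growth condition, making the analytic check and the simulator two
  views of the same model.
* `g0_exit="hourly"`: a literal per-hour reading in which a fraction
  P_G0toG1 of the dormant pool re-enters G1 every hour and survivors
  necrose at an age wall of T_G0.  With the tabulated values
  P_G0toG1 = 0.5–1 h⁻¹ this empties G0 within a couple of hours, yields
  negligible dormant fractions and growth far faster than the
  characteristics the sojourn reading (and the analytic condition)
  produce.  It is retained for comparison, not as the default.

The default was chosen because only the sojourn reading reproduces the
documented equilibrium compositions and doubling times of the reference
virtual tumors; the per-hour reading is dimensionally suggested by the
h⁻¹ unit printed next to P_G0toG1 but is quantitatively inconsistent with
every other reported number.

### Radiotherapy

Cell kill per fraction follows S(D) = exp(−(αD + βD²)) with
phase-specific coefficients: (α_p, β_p) for G1/G2/M, the S-phase pair
α_S = 0.6 α_p + 0.4 α_G0 (same for β), and the hypoxic pair
α_G0 = α_p/OER, β_G0 = β_p/OER².  Killed cycling and dormant cells are
marked hit(2) in place at the administration instant, before the hour's
biological update; they continue a rudimentary cycle (never entering G0)
and their entire progeny joins the necrotic pool at the second post-hit
mitosis.  Decisions where the underlying description is silent, adopted
here: differentiated cells are irradiated with the dormant-cell
coefficients (non-cycling, most radioresistant) and their killed part
joins the necrotic pool at the administration instant; hit cells remain
subject to spontaneous apoptosis; cells already marked hit are not
re-marked by later fractions; `cell_kill_factor` multiplies the stem-cell
kill probability (default 1).  β is conventionally slaved to α through
α/β = 3 Gy (prostate).

## Equilibrium bootstrap

Arbitrary initial mixes produce artificial transients (an initial dip and
rebound).  `bootstrap_equilibrium` instead grows n_gcs = 10 independent
GCs, each seeded with 100 stem cells spread over the cycle phases
proportionally to the phase durations, with per-GC random clock draws to
desynchronise them.  Equilibrium is declared when the cycling,
differentiated, dormant and dead fractions each vary by less than 1 %
(relative) over a sliding 30-day window (both defaults configurable; the
cap is 3000 simulated days, enough for doubling times up to ~1.5 years).
The growth rate is an ordinary least-squares fit of log total cells over
that window; the doubling time is ln2/(24·rate) days.  Self-diminishing
parameter sets (closed-form LHS < 0.9) fail fast with an explanatory
error, and a bootstrap that stabilises without growing is also rejected.
Stem seeds start fully cycling by default; `seed_g0_share` optionally
seeds a dormant cohort, which changes the transient but not the detected
equilibrium (asserted by test).

Mesh GCs are then populated at NBC cells with the stabilised subclass
fractions; cohorts are spread uniformly over the residence slots — the
continuum limit of drawing each cell's clock uniformly within its phase —
which makes free growth monotone from t = 0 (no initial dip).  In the
stochastic mode the spreading is multinomial.

## Morphology (second scan)

After the biological scan, occupied GCs are visited in lexicographic order
from a random origin offset (avoiding directional drift).  A GC above
1.1 NBC unloads its excess over NBC to 26-neighbours with free space
(total < NBC), largest free space first, seeded-random tie-breaks; if
excess remains, a random direction is drawn, the adjacent GC along it is
freed by pushing the chain of GC contents one step outward, and the excess
moves into the freed site (differential expansion).  A GC below 0.9 NBC
offers all its cells to neighbours with free space; if it empties, an
inward chain shift fills the vacuum, choosing among six randomly drawn
directions the one whose outermost occupied GC has the most 6-neighbours
in the tumor.  A repair pass then iterates to a fixpoint: detached GCs
(empty 6-neighbourhood) move one GC per step toward the centre of mass
along the axis of smallest non-zero offset (zero-offset axes are excluded
— the literal minimum would select a direction with no displacement; ties
broken by the seeded generator), and enclosed empty GCs are filled by the
shrinkage chain shift.  Because chain shifts can relocate a
not-yet-visited overload into an already-visited site, a bounded sweep
re-balances any GC still above the upper band and repairs again.  All
moves draw cells proportionally from every subclass of the source; the
scan conserves cell numbers exactly.

Band semantics: above-band loads are violations anywhere; below-band
loads are tolerated at the tumor surface (partially filled frontier
voxels are inherent to growth) and at freshly fallback-created sites,
which refill from their overloaded neighbours over subsequent steps.
`TumorMesh.band_violations()` implements exactly this reading and the
invariant tests assert it after every scan.

A simulation aborts with a clear error if the tumor truly reaches the
lattice boundary in every direction; the user re-runs with larger dims.

With `spatial_evolution=False` the engine degenerates to a well-mixed
single-GC ("0-D") mode in which volume = total cells / cell density.  The
bootstrap, the calibration runner and the sensitivity runners use this
mode: for a homogeneous tumor under uniform dose, volume reduction is
composition-driven, so the 0-D run reproduces the lattice-mode reduction
at a fraction of the cost (a final lattice confirmation run remains
available through the ordinary engine).

## Calibration and sensitivity analysis

`calibrate_alpha` finds the LQ α whose simulated volume reduction matches
an observed one, by Brent root finding over a bracket (default
[0.001, 0.4] Gy⁻¹) on a deterministic (fixed-seed) runner, with β = α/3.
The bracket endpoints must straddle the target; otherwise the error
reports the reduction attainable at the bracket maximum — low
growth-fraction tumors genuinely cannot regress to large observed
reductions, and that outcome is informative rather than exceptional.  The
residual tolerance is 0.1 percentage points.

One-factor-at-a-time sensitivity indices normalise the percent change of
an output (initial growth rate, initial growth fraction, or final volume)
to a ±1 % input change; the input change enters with its magnitude, so a
positive correlation gives SI+ > 0 and SI− < 0.  Perturbations are ±5 %
with an automatic fallback to ±2.5 % when a perturbed run is biologically
unrealistic (non-convergent bootstrap).  A probability already at its
bound (e.g. P_G0toG1 = 1) yields a one-sided index, reported with NaN on
the inadmissible side.  The integer N_LIMP is perturbed by ±1 unit and
normalised by the actual relative change.  Baseline and perturbed runs
share one seed (common random numbers) so small indices are not swamped by
initialisation noise.

## Synthetic data and what the tests show

No clinical images or per-patient schedules ship with the package.  The
fixture generator emulates an imaging-derived case with a triaxial
ellipsoid mask (GC occupied iff its centre lies inside the ellipsoid) and
a weekday fractionation schedule with weekend pauses; named presets
provide the published kinetic parameter columns of the five virtual
prostate tumors and their single-parameter variations.  These fixtures
reproduce the geometry, fractionation pattern and kinetic regimes of real
neoadjuvant prostate radiotherapy, but not imaging noise, segmentation
error, intratumoral heterogeneity (all presets are macroscopically
homogeneous), anatomical deformation, or per-patient dose plans.  Tests
passing on these fixtures therefore validate the mechanism — kinetics,
radiobiology, mass conservation, morphology, calibration machinery — not
patient-level predictive accuracy.

The acceptance checks compare the bootstrap's measured doubling times and
composition fractions against the documented characteristics of those
virtual tumors at ±15 % relative.  Residual discrepancies of up to ~14 %
on the doubling times of the fastest and slowest profiles reflect the
hourly-clock discretisation choices described above: a slow tumor's net
growth rate is the small difference of large fluxes, so doubling times
amplify per-cycle bookkeeping differences by an order of magnitude, while
composition fractions agree to a few percent.

## Problem sizes and numerics

Default analysis runs use the 0-D mode and the 10-GC bootstrap (seconds
per parameter set); lattice examples in the tests use 3³–5³-GC tumors over
days-to-weeks horizons, and the shipped example runs an ~80-GC tumor for a
month of simulated time in seconds.  Counts below 1e-9 cells are treated
as empty in occupancy logic; conservation is asserted to 1e-9 relative
every step inside the engine itself, and any negative count aborts the
run.  All randomness flows from a single seed: identical seeds give
byte-identical outputs (asserted by test).

## Known limitations

* The two dormancy readings bracket, but cannot uniquely pin down, the
  in-vivo dormancy-exit process; only the sojourn reading is consistent
  with the reference characteristics.
* Subclass synchronization within a GC is an approximation; at very small
  cell counts the stochastic mode should be preferred.
* No normal-tissue compartment, no dose-volume heterogeneity, no coupling
  to deformable anatomy.
* The calibration identifies α given α/β; it cannot separate α from β
  with a single observed reduction.
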
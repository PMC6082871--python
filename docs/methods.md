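# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `clampchem`.

## Physical model

**Units.** Forces in pN, distances in nm internally (Å at interfaces,
converted by ×0.1), energies in units of kT at 298 K. kT = 4.114 pN·nm =
0.5925 kcal·mol⁻¹; all experiments are treated as room temperature. The two
kT representations are validated against each other (through J ↔ kcal/mol)
to 1% at construction.

**Cleavage kinetics.** The disulfide of each unfolded domain is cleaved by
a bimolecular SN2 attack of a thiolate with pseudo-first-order rate

    r(F) = A · [S⁻] · exp(−ΔG‡) · exp(F·Δx / kBT),

where A = 10⁷ M⁻¹s⁻¹ is treated as exact, ΔG‡ is the zero-force activation
free energy in kT, Δx the distance to the transition state, and
[S⁻] = C_total/(1 + 10^(pKa−pH)) the active thiolate concentration. The
inverse map ΔG‡ = ln(A / r₀_norm) converts a concentration-normalized
zero-force rate into a barrier; it is the exact inverse of the rate law at
F = 0 and is used after the Bell regression.

**Reformation thermodynamics.** After a force quench the ruptured bond is
modeled as a Boltzmann partition over end states with the intact
disulfide + free thiolate as energy reference:

* `equilibrium2` — two states {reformed native bond, mixed disulfide} with
  energies {0, ΔG°_red/kT}: p_reform = 1/(1 + exp(−ΔG°_red/kT)). This is
  the thermodynamic-control limit appropriate to the 8 s quench; it gives
  exactly 50% at ΔG° = 0 and is antisymmetric in ΔG°.
* `boltzmann3` — adds the fully reduced protein (mixed disulfide displaced
  by a second solution thiolate, forming the thiol homodimer) at energy
  (ΔG° + ΔG°_homodimer)/kT. The homodimer free energies are not tabulated
  in the package's sources; the default placeholder ΔG°_homodimer = ΔG°
  (symmetric-exchange assumption) is synthetic and meant to be replaced by
  the user. The model reduces to `equilibrium2` as the fully-reduced state
  is pushed to high energy.
* `empirical_linear` — p_reform = clamp(−0.26·pKa + 2.416, 0, 1). The pure
  two-state model predicts near-total reformation for any ΔG° > a few kT
  and near-zero below, whereas measured reformation grades roughly linearly
  with pKa across nucleophiles (protein-context and steric effects that the
  solution-phase ΔG° does not capture). The coefficients are this package's
  calibration, anchored so a mesna-like thiolate (pKa ≈ 9.1) reforms ≈3–5%
  and a cysteine-methyl-ester-like one (pKa ≈ 6.6) ≈70%.

An optional first-order relaxation p(t_q) = p_eq·(1 − exp(−k_rev·t_q)) is
available for sensitivity analysis; by default the partition is
time-independent (thermodynamic control).

**Landscape.** `build_landscape` returns the three-level 1D profile
(reactant 0, transition state ΔG‡ − F·Δx/kBT, product ΔG°/kT). The tilted
barrier is clamped at the higher of the two wells so the landscape stays
physical at forces beyond the calibrated regime (F·Δx > ΔG‡ is never
reached in the packaged conditions).

## Compound parameter table

`data/compounds.json` carries one record per nucleophile: pKa, ΔG° of
disulfide reduction (kcal/mol), Δx (Å), ΔG‡ (kT), total concentration, pH,
and a sulfur partial charge. Everything downstream is parameterized on this
table. Provenance varies by field and the table is meant to be edited:

* ΔG° for cysteine-methyl-ester (+7.3), L-cysteine (0), mesna (−6.7) and
  NAC (−9.6) are the published solution values; the other five are
  representative interpolations consistent with the published ordering.
* ΔG‡ for NAC (10.6 kT) and glutathione (11.7 kT) are the published
  barriers. For the three compounds whose 350 pN rates (0.40, 0.58,
  2.48 s⁻¹ at [S⁻] = 2 mM) are the primary observables, ΔG‡ is derived by
  inverting the rate law at Δx = 0.35 Å, so the generator reproduces those
  rates by construction. The remaining barriers are editable placeholders.
* pKa values span the experimentally typical ~7–10 window; per-compound
  values are literature-typical, not transcriptions.
* Δx is 0.35 Å uniformly (published per-compound range 0.33–0.37 Å, no
  individual values available).
* Sulfur charges are synthetic placeholders, monotone in the zero-force
  rate, for exercising the charge–rate correlation utility only.
* Total concentrations are set so the *active* concentration matches the
  assay design: 2 mM for the three kinetics compounds, 1 mM for the
  reformation assays, and 0.1 / 0.25 mM for the NAC / glutathione force
  series. The force-series values are a design-of-experiment choice: at
  1 kHz sampling with 2 ms feedback settling, per-domain cleavage rates
  above ~2.5 s⁻¹ pile events into unresolvable clusters at the top of the
  300–500 pN grid, so the concentrations keep the fastest condition near
  1.5–1.8 s⁻¹.

## Synthetic-data generator

The generator emulates the statistical structure of force-clamp recordings
of an (I27)₈ polyprotein, not their microscopic mechanics:

* Per-domain unfolding is an exponential clock with Bell force dependence,
  default 10 s⁻¹ per domain at 150 pN and Δx_unfold = 2.5 Å — chosen so
  nearly all 8 domains unfold within the 0.5 s / 150 pN pulse and at least
  5 are typically *detected* (early events overlap). Unfolding kinetics are
  not an output of the analysis; both parameters are configurable.
* Cleavage clocks start at each domain's unfolding time and integrate the
  piecewise-constant hazard r(F(t)) across protocol segments, so cleavage
  during the 150 pN pulse (rare but real under Bell extrapolation) is
  simulated honestly. During the zero-force quench all mechanical and
  chemical hazards are zero; quench chemistry is handled by the partition
  model instead.
* Step sizes are force-independent Gaussians (15 ± 1 nm unfolding,
  10 ± 1 nm cleavage) rather than worm-like-chain increments: the analysis
  is calibrated to fixed fingerprints, and modeling their force dependence
  would add parameters the estimators never consume.
* The signal is the cumulative staircase convolved with a first-order
  feedback-settling response (τ = 2 ms, the instrument's 1–3 ms feedback
  plus 1 kHz Bessel filtering approximated by a single lag) plus white
  Gaussian noise (SD 1 nm) at 1 kHz sampling.
* Five-pulse trajectories collapse to extension ≈ 0 during the quench;
  refolding bookkeeping is metadata, not signal. Reformed bonds behave as
  fresh intact domains in the probe pulses; non-reformed domains (mixed
  disulfide retained or fully reduced) refold without the disulfide staple
  and release their full ~25 nm length in a single step when re-stretched,
  which keeps the initial/probe extensions equal — the property the
  acceptance filter checks.
* The reformation test force is chosen per nucleophile (the lowest of
  350–500 pN giving a cleavage rate ≥ 1.2 s⁻¹), mirroring the experimental
  protocol's per-compound 200–500 pN choice; otherwise slow nucleophiles
  leave intact disulfides that cleave in the probe pulse and contaminate
  the reformation count.
* Randomness: one root seed; per-trajectory child seeds derive from
  `numpy.random.SeedSequence([root, *indices])`, so cohorts are
  reproducible and independent of generation order. Identical seeds give
  bit-identical trajectories.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: worm-like-chain elasticity and
force-dependent step sizes, cantilever drift and 1/f noise, surface
detachment, misfolding, multiple tethers, and refolding kinetics during the
quench (refolding is assumed complete within 8 s).

## Step detection

Within each constant-force segment, greedy binary segmentation minimizes
the within-plateau sum of squares; a split is kept when it reduces the cost
by more than β·σ̂²·ln n (β = 10, tuned on seeded fixtures), with σ̂ the
robust noise SD from the median absolute deviation of first differences.
The first max(4τ, 8 ms) after every force change is masked (feedback
transients). Change points closer than the settling ramp are coalesced
into one event; clusters whose level jump stays below the 5 nm detection
threshold are pruned iteratively so settling residues cannot fragment
plateaus; plateau levels are means that skip 3τ of ramp. Event size is the
difference between stabilized plateau levels, event time the first sample
of the cluster.

Classification is by size window with segment-phase priority: unfolding
15 ± 4 nm (the only class in unfold pulses), reduction 10 ± 3 nm in
test/probe pulses (the 11–13 nm overlap resolves to the phase-expected
reduction class); everything else — including unresolved double steps — is
unclassified. Trace filters: kinetics recordings need 5–8 unfolding and
5–8 reduction events and no unfolding-class event in the high-force pulse;
reformation recordings need 5–8 first-pulse ruptures and equal
initial/probe extensions within 10 nm (one reduction step; the protocol
source states "the same length" without a tolerance). Filters are
idempotent.

With zero noise and zero settling, detection reproduces the generator's
ground truth exactly (sizes and classes; times to one sample) for events
outside masks and separated by more than the dwell threshold — the
end-to-end identity the test suite checks.

## Kinetics estimation

Each accepted recording's cumulative reduction extension in the test pulse
is aligned at the pulse onset, normalized by its own total, resampled onto
a 100 Hz grid (staircases are exact between events; traces shorter than the
grid hold their final value), and averaged pointwise. All steps in the test
pulse contribute: the filters bar unfolding there, so any step — including
a merged pair of near-simultaneous cleavages that the classifier cannot
split — is reduction extension. This mirrors summing raw reduction
trajectories and avoids censoring early event mass for fast kinetics.

The summed trace is fitted by unweighted least squares with 1 − exp(−rt)
(no offset; curves are normalized), r > 0 enforced by bounds, initial value
from the 63% crossing time. A warning is raised when the pulse spans less
than 3/r (censoring bias). The point estimate is the fit to the full
ensemble; the SD comes from 500 bootstrap resamples of whole recordings.
Test-pulse durations are chosen as 8 mean lifetimes (clipped to 5–60 s),
mirroring the "large, variable period" of the experimental protocol.

Residual estimator bias is dominated by filter selection against recordings
with early event pile-up; at the fastest packaged condition
(L-cysteine, 2.48 s⁻¹) it is ≈ −3…−7%, well inside the 10% recovery
tolerance, and ≤ 2% below 1 s⁻¹.

## Landscape and titration fits

ln(r/[S⁻]) is regressed on F — weighted by inverse delta-method variances
(sd/r)² when bootstrap SDs are available — matching the straight-line
semi-log presentation and making the noiseless round trip exact. Slope →
Δx = slope·kBT; intercept → r₀_norm = exp(intercept); barrier =
ln(A/r₀_norm) with A exact, so the barrier SD is the intercept SE. The
default force grid is 300–500 pN in 50 pN steps with 100 traces per force.

pKa fits use least squares on A(pH) = A_min + (A_max−A_min)/(1+10^(pKa−pH))
with all three parameters free; inputs must contain ≥ 4 points, span the
midpoint, and increase with pH (thiolate absorbs at 240 nm). Reformation
and charge–rate correlations share one ordinary-least-squares utility
returning slope, intercept and r².

## Reformation scoring

fraction = Σ probe-pulse reduction events / Σ first-pulse rupture events,
pooled event-wise over accepted recordings (per-trace probe counts are
capped at the trace's rupture count, since reformation is defined only for
ruptured bonds). The bootstrap treats each recording as one independent
unit; 500 resamples give the SD. Whether the pooled or per-trace-averaged
estimator matches the original analysis is not documented; pooled
event-wise was chosen as the lower-variance estimator consistent with the
per-recording bootstrap.

## Numerical and degenerate-input choices

* Two-state partitions are evaluated in log space, exact in the far tails
  (p ≈ 1.2×10⁻⁵ at ΔG° = −6.7 kcal/mol).
* `barrier_from_rate` rejects r₀ ≤ 0 and r₀ > A (invalid extrapolation).
* Flat traces yield an empty, rejected event set ("no events"); degenerate
  or non-monotone summed traces and flat/inverted titrations raise.
* The segmentation penalty has a 10⁻⁹ floor so noiseless signals are
  handled; exact ties in the (now phase-resolved) size windows no longer
  arise.
* TSV trajectories are written at %.17g and read with round-trip float
  parsing, so serialization is bit-exact.

## Problem sizes

The packaged analyses use 200 trajectories per kinetics condition, 100 per
force for the five-force Bell series, 50 five-pulse recordings per
reformation cohort, and 500 bootstrap resamples — cohort sizes at which the
estimators' bootstrap SDs (2–5%) comfortably resolve the effects studied.

## Known limitations

* The empirical linear reformation calibration is a two-anchor choice, not
  a fit to data; only its qualitative structure (graded, decreasing in pKa)
  is supported by the package's sources.
* Detection resolves events no closer than ~4 ms at 1 kHz/τ = 2 ms; very
  fast conditions (> ~2.5 s⁻¹ per domain across 8 domains) are biased by
  filter selection, which is why the force-series concentrations keep rates
  below that regime.
* The unfolding kinetics defaults are plausible but invented; only the
  chemistry downstream of unfolding is quantitatively calibrated.
* No temperature dependence (298 K only), no quantum-chemical computation
  of ΔG°, pKa or charges, and no modeling of alternative disulfide
  positions beyond what the parameter table can express.
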
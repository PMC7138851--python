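# Methods

This note documents the models implemented in `grxtools`, the assumptions
behind them, the calibration of the synthetic-data generators, and the
numerical choices that were genuinely open.

## Ping-pong kinetics and the Dalziel description

The catalytic cycle is the two-half-reaction ping-pong scheme

    E + GSSR  <->(k1, k-1)  E.GSSR  ->(k2)  E-SSG + RS-
    E-SSG + GSH <->(k4, k-4) E-SSG.GSH ->(k5) E + GSSG

At steady state with both substrates in excess the velocity obeys the
Dalziel relation e0/v = Φ0 + Φ1/[GSSR] + Φ2/[GSH] with

    Φ1 = (k-1 + k2)/(k1 k2),   Φ2 = (k-4 + k5)/(k4 k5),   Φ0 = 1/k2 + 1/k5.

`phi_from_microscopic` implements this closed form; the test suite verifies
it against an independent numerical steady state of the full four-species
mass-action system on 100 random rate sets (relative error < 1e-6).  Two
consequences are asserted as invariants: 1/Φ1 ≤ k1 and 1/Φ2 ≤ k4 (a
half-reaction can never be faster than its association step), and the
apparent k_cat at fixed [GSSR] equals 1/(Φ0 + Φ1/[GSSR]).  The chemical-step
symbols k2/k5 are a package convention; only the association/dissociation
constants carry canonical names.  Apparent K_m values from the
fixed-co-substrate Michaelis–Menten fits are composites of several rate
constants and are not interpreted as substrate affinities.

### Coupled-assay simulation

The photometric assay couples Grx turnover to NADPH consumption through
glutathione reductase (GR): each GSSG produced is reduced back to 2 GSH at
the cost of one NADPH, monitored as A340 with ε(NADPH) = 6220 M⁻¹cm⁻¹ and a
1 cm path (textbook constants; the assay description does not state them).
GR coupling is treated as **instantaneous** by default: the coupling enzyme
is supplied in excess, and explicit GR kinetics would add unidentifiable
parameters.  Bookkeeping per turnover: GSSR −1, GSH −1 (reductive step)
+2 (GR regeneration) = net +1, NADPH −1.  Total glutathione
[GSH] + 2[GSSG] + [GSSR] is therefore conserved, which the tests assert.  An
optional finite-GR mode (Michaelis–Menten in GSSG, default K_m 65 µM) exists
for robustness checks.  Integration uses LSODA with rtol 1e-8 on a fixed
output grid; NADPH exhaustion is handled by a terminal integration event
after which the curve is held at its plateau and flagged.  A 30-s flat
baseline precedes substrate addition.

### Dalziel inference

The primary estimation route is a one-stage weighted linear least-squares
fit of e0/v on (1, 1/[GSSR], 1/[GSH]) with weights ∝ v², which undoes the
variance distortion introduced by the reciprocal transform (the original
regression weighting is not documented, so the package states its own).
The classical two-stage secondary-plot route (primary Lineweaver–Burk
intercepts regressed on the reciprocal co-substrate) is retained and agrees
with the one-stage route to < 1e-8 relative on noiseless data.  Parameter
uncertainties come from the weighted linear-model covariance.  Rates at or
below the blank are excluded from fits and flagged; replicates are averaged
before fitting by default.  The design must span at least two distinct
levels of each substrate (rank condition); fewer than three levels per
substrate triggers a conditioning warning.  Under 2% multiplicative Gaussian
noise on the standard grid, the median relative error of the recovered
reciprocal coefficients is below 5% over 200 simulations (asserted in the
tests).

## Thiol-pKa alkylation-protection assay

The assay incubates freshly reduced enzyme with 150 µM iodoacetamide for
180 s at 23 °C over pH 3.5–8.5, then measures residual oxidoreductase
activity normalized to a mock control.  The package fits the
four-parameter Hill curve

    residual(pH) = bottom + (top − bottom) / (1 + 10^(h (pH − pKa)))

directly to the profile, reporting the midpoint as the pKa — this is the
assay's standard readout.  The default pH grid is 0.5-unit steps over
3.5–8.5 (11 points); the grid spacing of the original measurements is not
documented, so the generator states its own.  Multi-start fitting seeds the
midpoint at the half-range crossing with five jittered restarts under a
fixed seed; the best residual sum of squares wins.  Fits whose midpoint
falls more than one pH unit outside the data range, or whose profile shows
no transition, are flagged rather than rejected.

A **mechanistic generator** is provided for robustness studies:
pseudo-first-order alkylation of the thiolate fraction
f(pH) = 1/(1 + 10^(pKa−pH)) gives

    residual = 100 exp(−k_alk [IAM] f t) · (1 + (s − 1)(1 − f)),

where s > 1 is a low-pH stability factor reproducing the experimentally
observed residual activities slightly above 100% where the thiol is
protonated (the protein is more stable at low pH than its mock control).
The inflection of this survival curve sits where f = ln2/(k_alk [IAM] t),
i.e. **below** the true pKa for effective alkylation — a systematic offset
that is documented and quantified in the tests but deliberately not
corrected, because the Hill fit of the measured profile is the assay's
stated procedure.  The default k_alk = 150 M⁻¹s⁻¹ makes alkylation
essentially complete at full deprotonation (k_alk·[IAM]·t ≈ 4).

Group comparison uses one-way ANOVA followed by Holm–Šidák-adjusted pairwise
t tests against a reference group, with the star convention P > 0.05 ns,
≤ 0.05 *, ≤ 0.01 **, ≤ 0.001 ***.

## roGFP2 ratiometric analysis

The degree of oxidation of a sample well is computed from the two excitation
channels and the plate's fully reduced (100 mM DTT) and fully oxidized
(20 mM diamide) control wells:

    OxD = (I400s·I480r − I400r·I480s) /
          ((I400s·I480r − I400s·I480o) + (I400o·I480s − I400r·I480s)).

This expression is exactly linear in the disulfide fraction for convex
mixtures of the control spectra and invariant under common rescaling of all
intensities — both asserted as machine-precision property tests.  Control
wells are aggregated as per-plate means.  OxD values outside [0, 1]
(possible with noisy controls) are retained for integration but flagged;
clipping is opt-in, because subtraction-based statistics should not be
biased by truncation.

The screening readout subtracts the untreated (0 µM H2O2) trace pointwise
(linear interpolation onto the sample grid where needed) and integrates the
corrected OxD by the trapezoid rule over the first 48 s after oxidant
addition, interpolating the final partial interval to exactly t = 48 s.  The
generator samples every 12 s (48 s = 4 intervals), configurable; the
instrument's native interval is not documented.

The generator's probe response is phenomenological: a dose-dependent GSSG
pulse drives dOxD/dt = k_probe·c(dose)·e^(−t/τ)·(1 − OxD) with
c(dose) = dose/(dose + K), K = 0.2 mM, τ = 30 s and k_probe = 0.12 s⁻¹
scaled by the variant's activity factor, solved in closed form.  This
reproduces the qualitative behavior that matters to the analysis layer —
AUC strictly increasing over 0.02–1 mM for active constructs, flat
responses for inactive ones — and makes no claim about intracellular
peroxiredoxin-mediated GSSG production.  The DTT-pretreatment/washout
protocol is represented only as a lower initial OxD.

## GS⁻ binding-trajectory analytics

A GS⁻ molecule is bound in a frame when its sulfur lies within 5.5 Å of the
center of the two disulfide sulfurs.  The center is implemented as the
unweighted midpoint (equal masses), and the boundary is inclusive at exactly
5.5 Å; neither choice is documented in the assay description, so the package
fixes them.  Binding frequency is the fraction of frames with at least one
event, computed per replication; variants are compared with two-tailed
Welch t tests and reported normalized to a reference trajectory (= 100%).

The S–S–S angle vertex is configurable because "the angle created by the
three sulfur atoms" is ambiguous: the default places the vertex at the
active-site cysteine sulfur, angle(GS-S, Cys-S, moiety-S); `vertex="gs"`
places it at the incoming sulfur.  Histograms use 0.1 Å × 2° bins by
default.  Occupancy grids bin bound-state sulfur positions across
replications; iso-thresholds are caller-fixed so variants are comparable at
the same level.  Pre-binding paths take the 25 frames (500 ps at 20 ps per
frame) before an event, smoothed by a centered width-5 moving average that
shrinks symmetrically at the ends (straight approaches are preserved
exactly).  Pose clustering computes pairwise Kabsch-superposition RMSDs
(SVD with reflection correction, verified against an independent
superposition oracle), average-linkage agglomerative clustering, and a
fixed cluster count k = 2 by default (the analyses of interest report the
most- and second-most-populated clusters).  Trajectories are assumed
unwrapped; there is no periodic-boundary handling.

## Synthetic-data generators and calibration

The variant table encodes each mutant as fold changes on a wild-type
baseline.  Calibrated entries (oxidative/reductive factors such as E147K
2.5×, D144K 1.7×, R153A 0.40×, Y110A 0.205/0.12 as midpoints of the
published 18–23% and 9–15% ranges; pKa values 4.3 and 5.0; binding
propensities 0.34, 2.0 and 2.2; the HsGrx5-loop absolute reciprocal
coefficients 2×10³ and 5×10³ M⁻¹s⁻¹) carry provenance notes.  Quantities
that are not published as absolute numbers — most prominently the wild-type
Φ baseline (packaged as 1/Φ1 = 2×10⁵ M⁻¹s⁻¹, 1/Φ2 = 5×10⁴ M⁻¹s⁻¹,
k_cat = 50 s⁻¹) and several mutant factors — are order-of-magnitude
placeholders flagged `calibrated_not_measured`; every headline comparison
the package reproduces is a ratio, which is calibrated.

The rate-grid generator evaluates the Dalziel law on the standard assay
grid (GSH 50 µM–1.5 mM in 8 log-spaced levels at fixed GSSCys
25/50/100/150 µM, 10 nM enzyme), so noiseless grids are exact fixed points
of the Dalziel fitter.  Noise models are none, multiplicative Gaussian or
additive Gaussian, with the seed recorded in the output metadata; reruns
with the same seed are bit-identical.

The trajectory generator emulates 4 replications saved every 20 ps
(production scale 25,000 frames per replication = 500 ns; desk default
5,000).  Ten GS⁻ sulfurs diffuse by a reflected random walk (step σ = 2 Å)
in a 60 Å box around a fixed disulfide; a square-well attraction at the
site is implemented as a two-state (bound/unbound) occupancy chain started
at stationarity, with the per-particle bound probability chosen so that the
frame-level probability of at least one bound GS⁻ equals
baseline × propensity factor exactly (baseline 0.15 for wild type — only
relative propensities are published, so the baseline is a package choice).
With the default zero persistence, frames are independent and
per-replication fractions are binomial, which the tests exploit; a
persistence parameter produces correlated dwell times while preserving the
stationary occupancy.  Bound sulfurs are placed uniformly inside the cutoff
sphere, unbound walkers are kept outside it.  What this generator does
*not* emulate: realistic Brownian dynamics, electrostatics, solvent, or
binding-pathway kinetics — so passing recovery tests demonstrates the
correctness of the analysis layer, not of any physical simulation.

## Problem sizes and reproducibility

The default test and acceptance runs use the grid sizes above, 200–500
simulation repetitions for the noise studies, and 4 × 25,000 frames per
variant for the trajectory ratios — sizes chosen so the full suite and the
acceptance script each complete in well under a minute on one CPU while
keeping Monte-Carlo errors far below the tolerances being tested.  All
randomness flows through explicit integer seeds (numpy `SeedSequence` in
the acceptance script).

## Known limitations

- The mechanistic pKa generator's inflection-vs-pKa offset is documented,
  not corrected (the Hill fit is the assay's readout).
- Absolute wild-type kinetic constants are placeholders; only ratios are
  calibrated.
- HEDS is treated as an alternative substrate label within the same Dalziel
  framework; the two-step HEDS chemistry (GSSEtOH reorientation) is not
  modeled.
- The roGFP2 generator is phenomenological; it does not model
  peroxiredoxin-mediated GSSG production, instrument gain or
  photobleaching.
- Trajectory analytics assume unwrapped coordinates and exactly one
  disulfide sulfur pair per frame.
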
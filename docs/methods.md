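# Methods

This note documents the models implemented in `myoxwalk`, the defaults they
ship with, and what the synthetic-data tests do and do not demonstrate.

## Actin lattice and target zones

F-actin is treated as a single-start helix: subunit *n* sits at axial
position *n·rise* and azimuth *n·twist*, wrapped to (−180°, 180°].
Defaults are rise = 2.75 nm and twist = −2160/13° ≈ −166.154° per subunit,
the exact 13/6 lattice, so the 13-subunit pseudo-repeat (35.75 nm) returns
to azimuth zero exactly and the familiar ~36 nm binding repeat is crisp.
The commonly quoted average twist of −166.6° is available as
`TWIST_ALTERNATIVE`; with it the pseudo-repeat is only approximate and the
accessible sets change slightly at tight tolerances.

"Accessible" is operationalized as an azimuthal cone plus an axial band: a
subunit is a target zone if its binding face lies within `azim_tol_deg` of
the motor-facing direction and its axial separation from the rear head falls
in `[band_min, band_max]` (the dimer's reach). Defaults: 60° tolerance on
the rear head's own filament (the head can swing some way around its own
track) and 30° toward a neighbour filament (the head must insert between
filaments), with a 33–57 nm band on-filament. These are the only free
accessibility parameters and were chosen so the on-filament accessible set
is {35.75, 41.25, 46.75} nm with nothing in 47–57 nm — the geometric signature
the rest of the package builds on. A cone is a deliberate simplification; a
real head tolerates azimuthal mismatch anisotropically, but no quantitative
acceptance map is available.

For a neighbour filament the motor-facing direction is the inter-filament
direction. Each neighbour carries an azimuthal registry `phase_deg` (the
rotation aligning its subunit 0 with that direction; the accessibility
offset of subunit *n* is `wrap(n·twist − phase)`) and an axial registry
`axial_offset_nm`.

### Fascin-bundle preset

Fascin bundles are hexagonally packed at ~12 nm axis spacing, but the
inter-filament registry is irregular and no single registry is "the" truth.
The preset ships three neighbour registry classes, phases 90°, 190° and
277° (zero axial offset), calibrated so that the bundle target map with a
30° cone and a 15–60 nm band exposes sites within 2 nm of each of the
hot spots measured on real bundles: ~19, 38, 52 and 57 nm. Two registry
classes cannot do this — no phase simultaneously exposes a ~19 nm and a
~38 nm site under the same cone — so a third class is included. The preset
is a representative unit cell, not a transcription of any specific bundle.

## Dimer mechanics

Each lever arm is a planar two-segment linkage: the stiff converter+3IQ
segment (default 9.7 nm) from the head to the pliant point, then the SAH
(10.5 nm) to the junction with the anti-parallel coiled-coil (CC, default
25.7 nm relaxed / 24.0 nm crystal preset). Bending is confined to the two
joints, capped at 120° (pliant point) and 90° (SAH/CC junction). The
9.7 nm IQ-segment default is set so the flattened head-to-head span,
`cc + 2(l_IQ + l_SAH)`, equals 66.1 nm with the relaxed CC — the span seen
for flattened molecules. Joint caps are not independently measured; they
were chosen once so the reach envelope covers the observed 36–57 nm steps
with margin and are exposed on `LeverSpec`.

The minimal total bend θ(d) needed to hold the heads at axial separation
*d* is found numerically (joint-angle grid, 0.05° resolution, optimal split
of extension between the two arms). Target zones are weighted
`w ∝ exp(−flat_bias·θ²)`; `flat_bias = 2.54e-5 deg⁻²` is calibrated so the
52 nm : 19 nm weight ratio on the bundle hot-spot set is 3:1, encoding the
qualitative observation that short steps require strong folding and are
rare. Only the *ordering* of weights is treated as a prediction; the ratio
itself is a calibration.

The powerstroke is modelled as a rigid lever chord, `2L sin(Δθ/2)`, with
the swing planar (no azimuthal component). The lever lengths of the two
presets are inverted from the printed stroke distances (25 nm at 70° → L =
21.79 nm for myosin V; 48 nm at 120° → L = 27.71 nm for myosin X), so these
two numbers are calibrations, not predictions; the formula's content is the
scaling between swing, lever length and displacement.

## Synthetic stepping data

`simulate` generates what the downstream statistics assume: piecewise-
constant traces with i.i.d. Exponential(k_step) dwells (Erlang-2 optional),
signed step sizes drawn from a Gaussian mixture, Gaussian localization
noise per frame, and a finite frame rate. Defaults: 50 Hz, 3 nm noise,
2 steps/s — a typical EM-CCD FIONA regime; the real assays' frame rate and
localization precision are not published, so these are stated assumptions.
Mixture presets carry the fitted component means/sds of the four measured
datasets (two constructs × two tracks). Component weights were never
published; forward components share the non-backward mass equally and
backward steps carry 30% where no finer split is known. Tests therefore
target component *means* and *counts*, never weights.

Run lengths are `X₀ + Exponential(λ)` — the law recovered when runs shorter
than a detection floor X₀ are not scored — with durations built from
per-step exponential dwells (as a Gamma draw) so velocities are consistent
with lengths. The default stepping rate for runs (8.7 s⁻¹ at 36 nm steps)
reproduces the ~0.31 µm/s single-filament velocity scale.

What the generator does *not* emulate: drift, intensity-dependent
localization error, blinking/photobleaching, hand-over-hand alternation of
two labelled heads, or load dependence. Passing tests show the estimators
recover known truth under the stated noise model; they do not certify
performance on real traces with these artifacts.

## Step detection

The step finder is a greedy chi-square splitter: starting from one plateau,
it repeatedly inserts the changepoint that maximally reduces the residual
sum of squares (minimum plateau length 2 frames), producing a nested family
of fits. The step count is chosen by the counter-fit quality factor
S(k) = χ²_counter/χ²_fit, where the counter-fit places its steps at the
plateau midpoints of the fit; S peaks at the true count and the smallest
arg-max is taken. Flat traces return zero steps with an undefined quality
flag.

With 36 nm steps, 3 nm noise and 20-frame plateaus the finder recovers
≥95% of steps within ±1 frame. With *exponential* dwells of the same mean,
~9% of dwells are shorter than the 2-frame minimum and the corresponding
steps are merged with their neighbour; detection then plateaus near ~90–94%.
This is censoring by the acquisition, not detector error, and it also
produces a small tail of apparent double-size steps in pipeline output —
visible in the end-to-end demo, where cross-validation occasionally assigns
the merged tail its own component.

## Mixture fitting and component-count selection

Step-size mixtures are univariate Gaussian, fit by EM: means initialized at
data quantiles (restart 0) or drawn from the data (9 further restarts, all
run in a single vectorized batch), relative log-likelihood tolerance 1e-8,
at most 500 iterations, sd floor 1 nm against collapse. A restart ending
with a component of weight < 1/N is flagged degenerate and cannot win
unless all restarts degenerate. The per-iteration log-likelihood path of
the winning restart is retained and asserted non-decreasing in tests;
components are reported sorted by mean (backward steps first).

K is selected by 5-fold cross-validation on mean held-out log-likelihood,
ties to the smaller K; candidate K values the training folds cannot support
(fewer than 3K points) are dropped with a warning. At the measured sample
sizes the modal selected K over 25 seeds equals the generative count (2 at
n = 214, 4 at n = 178).

A known identifiability limit: in the four-component bundle mixture the
broad backward component (−28 ± 18 nm) overlaps its forward neighbours, and
at n = 178 the maximum-likelihood solution sometimes reallocates mass
between the overlapping components. The sharp 57 ± 2 nm component is
recovered to ~0.3 nm on average, but the overlapping components carry mean
absolute errors of 3–5 nm — and an independent EM implementation (sklearn's
`GaussianMixture`) shows the same or slightly larger errors on identical
draws. This is a property of the estimation problem at that sample size,
not of the implementation.

## Run lengths and velocities

λ is estimated by nonlinear least squares between the empirical CDF (Hazen
plotting positions, (i−½)/n, so exact quantile inputs are recovered
exactly) and `1 − exp(−(X−X₀)/λ)` for runs ≥ X₀; the standard error is a
200-resample bootstrap. The NLS estimator tracks the closed-form ML
estimate (mean excess over X₀) within a few percent and its relative bias
is below 1% by n = 10⁵. X₀ defaults to 0.4 µm; the floors used for the
published tables are not printed, so X₀ is always an explicit argument.
Velocities are summarized as pooled mean/sd/se with se = sd/√N.

## Kinetics and gating

Measured rates ship as a frozen record: pyrene-actin transition 19 s⁻¹
(filament) / 34 s⁻¹ (dimer on bundle), mantADP release ~60 s⁻¹, phosphate
release ≤108 s⁻¹, steady-state ATPase 19 s⁻¹ (monomer) / 9.0 s⁻¹ per head
(dimer). The pyrene-monitored transition is the cycle minimum and is taken
as rate limiting.

Gating is modelled at steady state by an alternating-renewal argument: with
gating efficiency g, a head waits a fraction g of a partner cycle between
its own cycles, so the per-head rate is `k/(1+g)` — k at g = 0, k/2 under
strict gating (g = 1), continuous and monotone between. Strict gating maps
19 → 9.5 s⁻¹, within 6% of the measured 9.0 s⁻¹ per head. No multi-state
cycle is fit: the data constrain only the halving.

Velocity is `step × k_limiting × coupling`, with coupling (steps per
rate-limiting event) defaulting to 1 as an explicit model choice. The
observed ~312 nm/s at ~36 nm steps implies an effective stepping rate of
~8.7 s⁻¹, below the measured 19 s⁻¹ transition; the package exposes the
two quantities separately rather than resolving the discrepancy. The
kinetic prediction used for the bundle comparison is the *ratio*
34/19 ≈ 1.79, compared with the observed velocity ratio 0.66/0.31 ≈ 2.1
(agreement within a factor 1.2). Transient records are fit as sums of 1–2
decaying exponentials (initial rate from the signal half-life; rates
reported descending; non-decaying records flagged failed), and the actin
dependence of a rate as the hyperbola `k_max[A]/(K_half+[A])`.

## Pipeline and reproducibility

The end-to-end pipeline (simulate → detect → pool → select K → fit mixture
→ fit run lengths → report) draws every stage's seed from one root seed via
named substreams, so a report regenerates bit-identically from its config
(validated YAML; unknown keys rejected). The demo configs pool ~200
detected steps from 9–11 traces to match the measured dataset sizes; the
bundle demo steps at 1 s⁻¹ (rather than the 2 s⁻¹ default) so its 17 nm
steps are well averaged at 50 Hz. Problem sizes throughout the tests — 25
seeds for stochastic recoveries, 10⁵ draws for consistency checks — were
chosen to make sampling error small relative to the tolerances tested.

## Known limitations

- The accessibility cone and the fascin registry preset are calibrated, not
  measured; conclusions should be read as "a geometry of this kind
  reproduces the hot spots", not as a fitted structure.
- The bending model is planar and torsion-free; off-axis lever twist and
  azimuthal strain (invoked for the bundle-accelerated kinetics) are not
  modelled mechanically.
- Observed steps are drawn directly from the printed mixtures rather than
  derived from head positions on the lattice, so the generator reproduces
  the measured distributions by construction; the geometric and statistical
  halves of the package are linked by the reach band and the hot-spot
  distances, not by a full mechanochemical simulation.
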
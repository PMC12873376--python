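# Methods

## Exchange model

A single labeled protein exchanging into a preformed condensate is modeled
as a three-state continuous-time Markov chain over the dilute phase, the
interfacial layer, and the (absorbing) dense phase, with rates k_on
(adsorption, dilute → interface), k_bounce (desorption, interface → dilute)
and k_entry (interface → dense). The model is zero-dimensional: it contains
no diffusion, droplet geometry or many-particle coupling; the interfacial
layer is the only barrier, which is the regime where condensate aging acts
(interface solidification raises k_bounce). The first-passage time from
dilute to dense is phase-type (hypoexponential-with-return) distributed.

Units are seconds and s⁻¹ throughout the core; any minute-scale axis is
converted at the I/O boundary.

### Numerical form of the closed solutions

With S = k_on + k_bounce + k_entry and Δ = √(S² − 4·k_on·k_entry) (provably
real for positive rates, since S² − 4·k_on·k_entry ≥ (k_on − k_entry)²),
the density is evaluated as a difference of two decaying exponentials with
rates α± = (S ± Δ)/2 rather than as an e^x·(e^y − 1) product, which
overflows at large t. α₋ is computed as k_on·k_entry/α₊ to avoid
subtractive cancellation when Δ ≈ S. The CDF is the term-wise integral,
rearranged through `expm1` so that CDF(0) = 0 exactly and small-t values
retain full relative precision. When Δ/S < 1e−9 the degenerate
(critically damped) limits F(t) = k_on·k_entry·t·e^(−St/2) and
CDF(t) = 1 − e^(−at)(1 + at), a = S/2, are used. Quadrature appears only in
tests; the closed CDF is what likelihood evaluations call.

Two independent oracles check the closed forms: a stiff ODE integration
(Radau, rtol 1e−9) of the forward master equation with absorbing dense
state, whose dense-phase occupancy must equal the CDF; and exact Gillespie
simulation, whose empirical moments and ECDF must match. The quantile
function inverts the CDF by Brent's method with bracket doubling from the
MFPT.

### Aging presets

`early`, `intermediate`, `late` fix k_on = 0.05 s⁻¹ and k_entry = 0.1 s⁻¹
and set k_bounce = 0.01, 0.1, 1.0 s⁻¹ (MFPT 32, 50, 230 s). A
reduced-k_entry description of aged, kinetically trapped interfaces is
supported by constructing `RateParameters` freely; no preset values are
shipped for it.

## Stochastic simulator

Direct (exact) SSA: the chain has at most two active channels per state, so
tau-leaping would buy nothing. `sample_exchange_times` vectorizes whole
cohorts: each cycle adds Exp(k_on) + Exp(k_bounce + k_entry) waiting times
to all unabsorbed samples and absorbs each with probability
k_entry/(k_bounce + k_entry). Every entry point builds one
`numpy.random.default_rng(seed)`; identical inputs give bitwise identical
outputs. A 10⁷-transition cap guards parameter regimes (k_entry ≪ k_bounce)
where mean cycle counts explode; hitting it raises an error carrying the
step count.

## Synthetic assay generator

The generator emulates the two-color exchange experiment: red condensates
formed in advance, blue protein added at mixing, tubes sampled repeatedly,
~10,000 events per acquisition (the cytometer's stopping rule). Design
choices:

- **Per-droplet conversion through the single-protein CDF.** Droplet i at
  reported time t has blue fill fᵢ(t) = CDF(t + dead; k_bounce·ηᵢ) with
  ηᵢ ~ lognormal(0, het_sigma) — quenched disorder on the interface
  resistance. This keeps generation O(n_droplets) instead of simulating
  thousands of proteins per droplet; the population-level double-positive
  fraction depends only on the fraction-entered curve.
- **Dead time.** One draw from Uniform(10, 15) s per run (mixing happens
  once), stored as ground truth. Reported time axes exclude it, as in the
  experimental convention; only the fitting layer reintroduces an offset
  parameter.
- **Droplets are resampled per timepoint** (repeated tube sampling), not
  tracked longitudinally; `droplet_id` links only within a timepoint.
- **Sizes and optics.** Sizes are lognormal (defaults μ_ln = 0, σ_ln = 0.4,
  a realistic droplet polydispersity); fluorescence scales linearly with
  size (red_scale = blue_scale = 1000 a.u.); FSC ∝ s² and SSC ∝ s^1.5 with
  lognormal noise are deliberately phenomenological proxies, not a Mie
  computation. Aspect ratio uses the convention 1 = round, drawn from
  Beta(15, 1.5) for condensates.
- **Detection threshold.** The blue positivity threshold sits at
  detect_fraction ε of a median droplet's saturating signal, default
  ε = 0.5: a droplet is scored converted at half-saturation, the EC50-style
  convention under which the median droplet's crossing time equals the
  first-passage median and the double-positive fraction is an approximately
  calibrated readout of the conversion curve. A gate placed just above
  autofluorescence (ε ≈ 0.03–0.05), as an operator would set from controls,
  makes droplets score positive after only a few percent of exchange — on
  the model's seconds timescale the readout then saturates before the first
  acquisition and carries almost no kinetic information. This is the same
  seconds-versus-minutes gap that separates the theoretical first-passage
  scale from experimental mixing times; comparisons to wet data are
  qualitative (curve shape and aging order), and no scale factor is assumed.
- **Noise defaults.** Multiplicative measurement CV 0.05 per channel,
  additive autofluorescence 10 a.u., interface heterogeneity
  het_sigma = 0.3; optional slow red decline (δ, τ_d) mimicking the slight
  red decrease seen after blue addition; optional immobile fraction φ
  (default 0) for droplets that never convert.

What passing tests on this generator do **not** show about real data:
spectral spillover/compensation, fluidics shear, instrument voltages,
droplet coalescence and growth, and the absolute experimental timescale are
all outside the emulation.

## Cytometry analytics

Event tables are pandas DataFrames with a fixed schema (time_s, fsc, ssc,
red, blue [, area, aspect_ratio, droplet_id, label]), written as CSV. FCS
3.0/3.1 listmode files are read and written by a small self-contained
implementation (float/double and byte-aligned integer data, both byte
orders, log-amplified $PnE on read); channel maps bind logical {red, blue,
fsc, ssc} names to instrument detector labels.

Conventions fixed here because the assay literature leaves them open:
positivity at a quadrant threshold is strict (`>`), so a boundary event is
negative; MFI is the arithmetic mean of raw (not log) intensities, ungated
by default, with median as an option; the imaging-cytometry morphology gate
is a rectangle (aspect_ratio ≥ aspect_min AND area ≥ area_min) — a
diagonal-band variant is deliberately omitted as under-specified; the
t-test is the classical equal-variance unpaired Student's t, two-tailed.

## Rate inference

Double-positive counts are binomial: n_dp(t) ~ Binomial(n_total(t), p(t))
with p(t) = (1 − φ)·CDF(t + dead_offset), probabilities clipped to
[1e−12, 1 − 1e−12]. Counts, not fractions, are what the cytometer yields,
hence the binomial rather than Gaussian choice; timepoints are treated as
independent (the experiment resamples the tube), an acknowledged
approximation of repeated sampling from one evolving pool.

Optimization is L-BFGS-B on log-transformed rates within [1e−4, 1e2] s⁻¹
(φ ∈ [0, 0.999], dead_offset ∈ [0, 60] s around the experimental 10–15 s),
with 8 seeded multi-starts (first start at the box midpoint). Estimates
within 1e−6 of a box edge are flagged `at_bound`. Profile-likelihood
intervals use the χ²₁ threshold with geometric/linear outward scans and
Brent root-finding; a profile that never crosses the threshold inside the
box returns an open-interval flag instead of raising.

**Identifiability.** A single DP curve determines only two exponential
rates and one weight, so the default posture frees k_bounce alone, fixing
k_on = 0.05 s⁻¹ and k_entry = 0.1 s⁻¹ at their reference values. Because
the generator's DP readout is a *threshold crossing* of a deterministic
fill, it lags the single-protein conversion curve (no droplet is
half-filled at first read) and plateaus slightly below 1 (the small-droplet
tail never crosses); a k_bounce-only fit therefore carries a structural
upward bias of order 25%. The recommended protocol for threshold-crossing
data frees {k_bounce, dead_offset} so the offset absorbs the onset lag;
under the default generator this recovers k_bounce essentially unbiased
(≈ +4% mean error at 10,000 events × 12 timepoints). Freeing φ as well
collapses the fit (φ trades off against the offset and the plateau
deficit); joint fits of all three rates on a single curve yield wide or
open profiles, which the test suite asserts rather than hides. Whether an
experimental plateau below 100% reflects a true immobile fraction or slow
kinetics cannot be decided from one curve; both fits can be run and should
be reported together.

## Sequence charge statistics

Charges default to D, E → −1; K, R → +1; H → 0; termini uncharged — the
common convention for SCD-style analyses; it is configurable because
published values rarely state theirs. SCD over a segment renumbers
positions 1..N within the segment (pair separations are unchanged by this,
but the 1/N prefactor uses the segment length). The implementation is the
exact O(N²) pairwise sum, which is instant at protein scale. For the
bundled canonical NPM1 sequence (UniProt P06748, 294 aa) the domain net
charges are −7 (residues 1–118), −19 (119–242) and +2 (243–294), and the
disordered region's SCD is −1.473 under the default convention.

## Problem sizes

Test and acceptance runs use 10⁵ stochastic samples per preset for
simulator/closed-form agreement, 10,000 events × 12 timepoints per
synthetic assay, and 20 seeded replicates for recovery coverage — the same
event count as the experimental stopping rule, and enough replication to
estimate coverage proportions to ±7%.

## Known limitations

- The model is zero-dimensional; no droplet growth, ripening, fusion, or
  spatial gradients.
- The generator's scatter channels are monotone size proxies only.
- The seconds-scale model and minute-scale experimental axes are not mapped
  onto each other; fitted rates from real data are interpretable relative
  to one another (aging order, fold changes), not as absolute microscopic
  constants.
- FCS support covers listmode float/integer data sufficient for event
  tables, not the full breadth of vendor keyword extensions.
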
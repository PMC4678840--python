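# Methods

## The biological model behind the generator

Every simulated cell carries a ground-truth state: cell-cycle phase (G0, G1,
S, G2/M), the fraction of S phase completed, an RB1 state
(unphosphorylated → hypo-phosphorylated/anchored → hyper-phosphorylated/
released), a restriction-point flag (true iff RB1 is hyper-phosphorylated),
and a chromatin-bound MCM fraction in [0, 1].

Per-cell event times on the cell's own clock (hours from G0 exit, mitotic
exit, or birth):

* **Anchoring** at `t_hypo`: RB1 goes from unphosphorylated (unanchored — the
  RB1-negative population seen in quiescent and very early cells) to
  hypo-phosphorylated and anchored.
* **Restriction point** at `t_rp`: RB1 becomes hyper-phosphorylated and is no
  longer anchored.
* **Licensing onset** at `t_load`: the chromatin-bound MCM fraction ramps
  linearly from 0 to 1 over `load_duration` (default 3 h). Whether antibody
  fluorescence is linear in the number of loaded hexamers is unknown; the
  linear ramp is an explicit assumption.
* **S entry** at `t_s` (constrained to `t_s >= t_load + load_duration`, so
  cells enter S fully licensed). During S, DNA content is `2(1 + s)` genome
  equivalents and the MCM fraction falls as `max(0, 1 - s / s_offload_end)` —
  non-increasing in `s`, reaching zero at `s_offload_end` (default 0.70).
  Offloading *completes before late S* so that cells at the S/G2 border are a
  true MCM-negative reference even after DNA-channel noise smears late-S
  cells into the border window; with offloading finishing only at s = 1 the
  border-derived threshold would sit an order of magnitude above background.

Population onsets are the configured means; per-cell jitter is half-normal
(`mean + |N(0, sd)|`), i.e. a Gaussian truncated at zero, so the *first* cells
arrive at the configured onset — matching how "starts from X hours" is read
off a time course.

### Scenarios

* **`exponential`** — ages drawn from the exponential-growth age density
  `p(a) = (2 ln2 / T) 2^(-a/T)` on `[0, T]`; with `T_G1 = 10, T_S = 8,
  T_G2M = 4` the G1 fraction is `2(1 - 2^(-10/22)) ≈ 0.541`. A fraction
  `frac_pre_rp_loaders` of cells license *before* the restriction point;
  these are modeled as anchored and loading from birth (licensing can begin
  in late mitosis with RB1 still bound) and hyper-phosphorylating only at S
  entry, so they occupy Q2 for their whole G1 transit and the snapshot Q2
  occupancy is an unbiased estimate of the propensity — the parameter the
  assay exists to measure. Presets: `bj_exponential`
  (`frac_pre_rp_loaders = 0.14`, long G1) and `u2os_exponential`
  (`0.11`, short G1, early restriction point — hence a much larger Q1).
* **`g0_release`** (`bj_g0_release` preset) — all cells leave quiescence at
  t = 0; anchoring ~2 h, restriction point from 9 h (sd 1.5 h), licensing
  from 11 h, S entry from `T_G1 = 14.5` h, so S-phase cells are visible by
  the printed 15 h timepoint. `frac_pre_rp_loaders = 0`: these cells license
  only after the restriction point.
* **`irradiated_g0_release`** — same release, but the restriction point is
  blocked (`rp_blocked`): no cell ever hyper-phosphorylates RB1 or enters S,
  and licensing onset is delayed by `irr_load_delay` (default +10 h; the
  magnitude of the radiation-induced delay is not quantified upstream, only
  its existence, so it is a configurable dial).
* **`nocodazole_release`** (`u2os_nocodazole_release` preset) — synchronized
  mitotic exit with two subpopulations: a *fast* wave (fraction 0.5) that
  hyper-phosphorylates RB1 almost immediately and licenses at 1.5–4 h
  (appearing in Q1) before entering S from ~10 h, and a *slow* wave that
  anchors RB1, licenses at 6–8 h while still before the restriction point
  (appearing in Q2), and hyper-phosphorylates late. The graded property of
  this scenario is the *ordering* (Q1 rises hours before Q2); the absolute
  quadrant percentages at late timepoints are only qualitative, because the
  simulated slow wave licenses more completely by 12 h than a real
  population.

### Measurement model

Per channel: `signal = gain * truth * LN(cv) + background * LN(cv)`, with
`LN(cv)` a mean-one log-normal factor (`sigma^2 = ln(1 + cv^2)`), so the
sample CV of a constant signal equals the configured `cv`. Defaults: DNA gain
100 per genome equivalent (G1 at 200, G2 at 400), immunofluorescence gains
1000 with background 10 and CV 0.25, DNA CV 0.03, pulse-width CV 0.05. The
specific RB1 component exists only for hypo-phosphorylated (anchored) RB1 —
both the unphosphorylated and hyper-phosphorylated forms are washed out by
the pre-fixation extraction. Pulse width is independent of DNA content for
single cells; doublets sum the pulse areas of a random pair but widen the
pulse by `doublet_width_factor` (default 1.6), which is what makes the
area-versus-width gate work. Barcoding stains each pooled sample with one of
`barcode_levels` (default a 4-fold series 1000/250/62.5/15.625, mirroring a
four-concentration dilution series of one dye).

All randomness flows from explicit seeds; identical configuration and seed
give bit-identical tables.

## Gating rules

1. **Singlets**: keep events with
   `dna_width <= median + k_mad * MAD` (scaled MAD, `k_mad = 4`): retains
   ≥ 99% of log-normal singlets at width CV ≤ 8% while removing essentially
   all 1.6×-width doublets. If MAD = 0 (degenerate widths) a fixed 1.3×
   relative cut is used, with a warning.
2. **DNA peaks**: smoothed 512-bin histogram (range padded so boundary spikes
   stay interior); the dominant mode is first tested for a companion at half
   its position (then it is G2), then at ~2× (then that is G2, constrained to
   1.85–2.15×). Each coarse peak is refined by fitting a Gaussian on a linear
   background in a ±10% window — the S-phase continuum forms a ramp under
   both peaks that would otherwise shift the raw mode by up to ~2.5% at 5%
   DNA CV. A lone mode is taken as G1 with `g2 = 2 g1` but flagged
   *ambiguous*: DNA content alone cannot distinguish a pure-G1 sample from a
   pure-G2/M one (e.g. a mitotic-arrest sample at t = 0).
3. **G1 gate**: `[g1_peak * (1 - w_lo), g1_peak]` with `w_lo = 0.10` — the
   left side of the peak only, minimizing early-S contamination. The gate is
   closed at the peak (a zero-CV population sits exactly there); events right
   of the peak are excluded.
4. **MCM threshold**: the q = 0.99 quantile of the MCM signal among events in
   the S/G2-border window `[0.90, 0.98] * g2_peak`, where offloading is
   complete. The quantile is estimated under a log-normal model from the
   robust location/scale (log-median, scaled log-MAD): the same population
   quantile as the empirical order statistic (available via
   `estimator="empirical"`), but stable to ~1% across seeds at n = 50,000 and
   insensitive to a small bright contaminant tail.
5. **RB1 threshold**: geometric midpoint between the mode of the log RB1
   signal in the S interval (hyper-phosphorylated, washed out — the built-in
   negative reference) and the upper mode among G1-gated events. Requires a
   real S population (≥ 30 events *and* ≥ 0.5% of all events, so the DNA-noise
   tail of a 2N-only sample cannot masquerade as one). If G1 is unimodal the
   fallback is a high quantile of the S-interval signal, flagged.
6. **Pipeline fallbacks** (flagged in `GateSet.threshold_mode` /
   `rb1_fallback`): a release experiment harvested before any cell reaches
   late S has no populated S/G2 border — the MCM threshold is then placed at
   the geometric midpoint of the unloaded/loaded G1 modes, the same
   negative-reference logic a secondary-antibody-only control provides (and
   population- and control-derived thresholds agree within ~1.5× on matched
   simulations). An arrested population with no S cells at all similarly gets
   its RB1 threshold from the G1 bimodality, or — if G1 is unimodal — a
   threshold 1.5 decades below the single G1 mode, treating all G1 as
   RB1-positive; a sample with *no* anchored cells is blindly
   indistinguishable from this, hence the flag. Preferred practice is
   barcoding arrested samples together with cycling controls and deriving one
   set of regions from the pool, which the pipeline supports.
7. **Quadrants**: strict positivity (`signal > threshold`; ties negative),
   Q1 = MCM+/RB1−, Q2 = MCM+/RB1+, Q3 = MCM−/RB1+, Q4 = MCM−/RB1−, Wilson
   95% intervals. Q4 is always reported as ambiguous and never attributed to
   either side of the restriction point; "licensing before the restriction
   point" statements use Q2 only — a conservative lower bound.

Gating consumes only the measurement channels; ground-truth columns, when
present, are ignored (audited by tests).

The pipeline derives peaks and thresholds from events pooled across
timepoints by default: identical regions for all samples remove
sample-to-sample threshold variation (the same rationale as barcoding in the
wet protocol), and late timepoints whose G1 pool has drained into S cannot
support their own fits. Per-timepoint derivation is available
(`gating: {pooled: false}`).

## Demultiplexing

A k-component 1-D Gaussian mixture on log10 barcode intensity, initialized
deterministically at the k evenly spaced sample quantiles; the EM input is
canonicalized by sorting, so event order cannot change per-event assignments.
Component 1 is always the dimmest level. Events whose maximum posterior falls
below `min_confidence = 0.90` are unassigned — the barcode exists to remove
staining variation, so purity beats yield. Components closer than 0.2 decades
raise a merged-component warning.

## Onset estimation

Each fraction-versus-time curve is fit with a logistic
`f(t) = b + A / (1 + exp(-(t - m)/s))` (weighted by binomial standard
errors). The fit supplies baseline, amplitude and a detection decision
(`A >= 0.05` and observed spread above the floor; flat series and
non-convergence return "not detected", never an exception). The onset is
where the curve first reaches `b + 0.10 A` — the 10%-of-amplitude crossing,
matching the "starts from" reading of first appearance, not the midpoint.

Two numerical choices matter on the coarse 2–5 h sampling grids these
experiments use:

* **Rising window.** The fit is restricted to the nadir-to-peak stretch of
  the series. The RB1-negative fraction is non-monotone (it starts near 1
  because quiescent/early-G1 cells have unphosphorylated, unanchored RB1,
  falls on anchoring, then rises at the restriction point), and per-quadrant
  fractions fall again when a subpopulation exits G1 into S.
* **Interpolated crossing.** By default the level `b + 0.10 A` is read off
  the linearly interpolated *measured* curve rather than the fitted logistic
  (`method="fit"` gives the parametric crossing `m - s ln 9`). With onset-at-
  the-mean jitter the leading timepoints are exactly zero, which forces a
  near-step logistic whose parametric crossing is biased late by up to half a
  sampling interval; the interpolated crossing recovers the configured onsets
  to ~0.3 h (restriction point, licensing) and ~1 h (S entry). The two
  definitions coincide for well-resolved logistic rises.

Confidence intervals: parametric bootstrap of the per-timepoint binomial
counts (default 500 resamples at the library level, 200 in the pipeline;
halving/doubling the count moves the CI half-width by well under 20%). CIs
are clipped to contain the point estimate.

`summarize_order` issues `loading_before_rp_detected` only when the lower
Wilson bound of Q2 clears a misclassification floor (default 2%, the null
calibration of the default optics: with no pre-restriction-point loaders the
median measured Q2 across seeds is ~0.5%); `loading_after_rp_dominant`
additionally requires Q1 to be clearly present; anything else is `mixed`.

## File formats

FCS 3.0/3.1 reading and FCS 3.1 writing (float32, little-endian, list mode,
`$PnN` short names with optional `$PnS` labels) are implemented in
`mcmflow.fcs` — a deliberately minimal subset of the standard: no ANALYSIS
segment, one data set per file. CSV uses a mandatory header row with the
channel short names. Ground truth travels in a `<stem>.truth.csv` sidecar
keyed by event index and never enters the cytometry channels. Pipeline
artifacts are JSON stamped with the resolved-configuration hash and seed;
identical configuration and seed reproduce them byte for byte.

## Problem sizes

Default analysis sizes were chosen to keep Monte-Carlo error well below the
effects measured: 50,000 cells for snapshot quadrant estimates (binomial SE
≈ 0.4 pp at Q2 ≈ 15%), 20,000 cells per timepoint for time courses, 20
replicates for ordering/rate claims, 100,000 cells for age-structure checks
(3σ ≈ 0.5 pp).

## Limitations

* The synthetic populations emulate the *logic* of the assay, not its full
  messiness: no spectral spillover/compensation, no instrument
  linearization, no antibody-binding chemistry, no cell-to-cell gain
  variation beyond the per-channel log-normal, doublets only (no higher
  aggregates), and phase durations are fixed per scenario rather than drawn
  per cell. Passing tests show the analysis recovers known ground truth
  under this model — not that the model captures every feature of real flow
  data.
* The exact placement of hand-drawn analysis regions in the original
  instrument software is unrecoverable; the automated rules here are
  principled stand-ins with every constant exposed as a parameter
  (`k_mad`, `w_lo`, `w_hi`, the border window, threshold quantiles).
* Whether the MCM-positive region should carry an upper DNA bound within G1
  is left open; none is applied.
* Q4 is intrinsically ambiguous; no attempt is made to resolve it.
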
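# Methods

This note documents the models, conventions and numerical choices behind
`nbo`, in the order data flows through the package: stimulus space →
simulated infant → preprocessing → Nc measures → Bayesian optimisation →
cohort statistics.

## Stimulus space

The search space is the 4×4 grid of emotion (VeryHappy, Smile, Neutral,
Angry) × gaze (0°, 5°, 45°, 90° averted).  Grid spacing is 1 per step on
each axis, so the Euclidean distance between cells is in "grid units" (e.g.
Angry-0 ↔ VeryHappy-0 = 3.0; opposite corners = √18 ≈ 4.24).  Quadrants
split the space 4/4/4/4: *happy* = emotion index ≤ 1, *direct* = gaze index
≤ 1 — the 5°-averted row counts as direct, since infants of the target age
do not discriminate 5° from straight gaze.  The canonical burn-in order is
Angry-0, Angry-90, VeryHappy-0, VeryHappy-90; a seeded uniform permutation
is available for burn-in-order control experiments.

## Simulated infant (`nbo.synth`)

The generator emulates exactly the statistics the closed loop consumes; it
is not a biophysical head model.

* **Recording.** 8 channels (Fz, Fp1, Fp2, C1, C2, Cz + P7, P8) at 500 Hz;
  12 events per block, 2 s apart, with ≥ 1.5 s of margin everywhere, so
  every segment window has full support.
* **Nc template.** A raised-cosine (Hann) — or optionally triangular —
  negative deflection on the −100..800 ms epoch grid, peak latency 500 ms,
  width 200 ms, support confined to the 250–800 ms window of interest.  Both
  shapes integrate to `depth/2` over their support, giving the Nc metric a
  closed-form oracle.  The per-trial depth is drawn
  `N(surface[x], (0.1·|surface[x]|)²)` by default.
* **Response surface.** Families: `corner-peak` (depth
  `baseline − contrast` at the peak cell, decaying linearly with grid
  distance; unique minimum by construction), `plane`, `flat`, `custom`.
  Default study condition: contrast 6 µV on a −4 µV baseline, i.e. peak
  −10 µV — the magnitude range of published infant Nc means.
* **Noise and artifacts.** White sensor noise (default sd 10 µV per sample);
  a slowly varying common signal (default sd 5 µV) added *identically* to
  all 8 channels, which P7/P8 re-referencing must remove exactly;
  half-cosine transients of 500 µV peak and 150 ms duration placed inside
  250–800 ms with probability 0.05 per channel-trial (large and slow enough
  to survive the 20 Hz low-pass and trip both rejection criteria sets with
  certainty); whole-block flat channels with probability 0.02.  P7/P8 carry
  noise and the common signal but no Nc template, so re-referencing cannot
  cancel the target component.
* **Determinism.** A block is a pure function of
  `(profile.seed, block_index, stimulus)`; recordings are bitwise
  reproducible and round-trip losslessly through the CSV writer
  (shortest-round-trip floats on write, `float_precision="round_trip"` on
  read).

What the generator does **not** emulate: 1/f background spectra are off by
default (white noise keeps the unit tests analytic), channel-specific Nc
topographies, eye-movement dipoles with frontal gradients, habituation or
attention drift across blocks.  Passing tests therefore demonstrate the
pipeline's correctness and the optimiser's behaviour under controlled
conditions, not performance on real infant EEG.

## Real-time preprocessing (`nbo.preproc`)

Per block: cut 1500 ms segments realised as −500..+1000 ms around onset
(the epoch must sit inside with margin on both sides); per channel-trial
linear detrend, demean, mirror-pad by 1000 samples (2 s) per side —
"padding 1000" is read as samples — zero-phase band-pass 0.1–20 Hz; crop to
−100..800 ms (closed grid, 2 ms steps, 451 samples); subtract the −100..0 ms
baseline mean.

* **Filter.** Butterworth band-pass (`scipy.signal.butter`, order 2 per
  edge → a 4th-order transfer function) applied forward–backward
  (`sosfiltfilt` with `padlen=0`, since the pipeline supplies its own
  mirror padding).  Filtering a mirror-padded segment is identical (≤ 1e-6
  µV) to filtering a three-fold-longer reflected signal — the property that
  justifies padding in the first place.
* **Artifact rejection** runs on *un-re-referenced* epochs, inside
  250–800 ms only: flat if max |amplitude| < 1e-4 µV; rejected if
  max |amplitude| > 200 µV or peak-to-peak range > 400 µV (*default*), or
  250/500 µV (*less conservative*).  The first block of a session is
  processed under the less conservative set; if its ERP dips below −200 µV
  that set is kept for the whole session, otherwise the default applies
  from block 2 (the first block is not re-processed).  "Maximum amplitude
  lower than −200 µV" is read as the most negative ERP excursion.
* **Re-referencing.** The trial-wise P7/P8 average is subtracted from the
  six channels of interest *after* rejection ("cleaned data are
  re-referenced").  A flat reference pair subtracts at most a constant that
  baseline correction removes anyway, so such trials stay valid by default;
  `reject_flat_reference=True` treats a flat pair as a broken electrode and
  invalidates the trial instead.
* **Validity gate.** A block yields an observation iff ≥ 16 % of the
  6 × 12 = 72 channel-trials survive, i.e. ≥ 12.  (The neighbouring
  convention of "11 valid trials" equals 15.3 % and is *not* what a strict
  16 % proportion implies; the threshold is a config parameter.)  The block
  ERP is the average over valid channel-trials at each time point; its
  baseline mean is zero to 1e-9 µV by construction.

## Nc measures (`nbo.ncmetric`)

*Nc negativity* (the optimisation objective): find the most negative sample
inside 250–800 ms; if it is negative, the *deflection* is the maximal
contiguous run of strictly negative samples containing it, clipped to the
window (zero crossings bound the deflection; a flat negative plateau counts
as a deflection); return the sign-flipped mean over that run, so larger
positive values mean stronger negativity.  If the window contains no
negative sample, the sign-flipped window mean is the fallback — flipped
like the main measure so the optimiser's scale stays uniform.  *Nc mean
amplitude* is the signed mean over 250–800 ms; the *early window* control
is the signed mean over 0–200 ms.  Window bounds are inclusive on the 2 ms
grid.

End-to-end, a noise-free simulated block recovers the analytic template
statistic (depth/2) within 5 %; the residual bias comes from the per-segment
linear detrend (fitting a line through a one-sided bump) rather than the
band-pass itself.

## Bayesian optimisation (`nbo.bo`)

* **Surrogate.** `sklearn` Gaussian-process regression, kernel
  `C·Matérn(ν=2.5) + WhiteKernel` over grid coordinates normalised to
  [0,1]², `normalize_y=True`, hyperparameters by log-marginal-likelihood
  with 2 seeded starts.  Bounds: signal variance [1e-3, 1e3]; length-scale
  **[1/3, 5]** — one grid step is the finest structure identifiable from 16
  cells, and unconstrained fits collapse below it; noise variance
  **[0.09, 100] µV²** — a single-block Nc estimate never carries less than
  ~0.3 µV of error, and this floor keeps the posterior sd at observed cells
  positive so that expected improvement can re-select the incumbent and
  terminate.  With a vanishing noise floor a noise-free session can *never*
  converge by re-selection (EI at the incumbent is exactly zero), which is
  the failure mode these bounds are designed against.  A degenerate fit
  (non-finite LML) falls back to the prior with default hyperparameters and
  is flagged in the log.
* **Acquisition.** Expected improvement with margin ξ = 0.1 on the µV
  negativity scale (the standard acquisition family for this design; a
  small ξ favours exploitation of the identified maximum).  Argmax over all
  16 cells including already-observed ones; exact ties break to the lowest
  (emotion, gaze) index so runs are reproducible (a seeded-random tie-break
  is available).
* **Session protocol.** 4 burn-ins, then acquisition; convergence = the
  same stimulus *chosen* three times consecutively, burn-ins included
  (hence the theoretical minimum of 6 blocks when the best corner is the
  4th burn-in, 7 otherwise — exactly what noise-free sessions do).  Blocks
  failing the validity gate are re-presented with the same stimulus; they
  count toward the 15-block cap (the cap bounds session duration) but add
  no observation and do not count as a new choice; more than 3 consecutive
  failures abort the session ("infant excluded", no optimum).  At the cap
  the optimum is the posterior-mean argmax.  A session is a pure function
  of the infant seed and the config seeds.

## Cohort statistics (`nbo.bayestats`, `nbo.cohort`)

* **Proportion Bayes factor.** H1 places a logistic prior (scale r = 0.5)
  on the log-odds displacement ψ: `logit(p) = logit(p0) + ψ`;
  `BF10 = ∫ Binom(y|N, p(ψ)) dΠ(ψ) / Binom(y|N, p0)`, integrated in the
  prior CDF domain (stable for any r), relative error < 1e-6.  One-sided
  variants truncate and renormalise the prior; the two halves satisfy
  `(BF⁺ + BF⁻)/2 = BF_two-sided` exactly.  **Convention note:** published
  analyses of this design report the *two-sided* value (and evaluate the
  1/16 chance level at its rounded form 0.063), so the cohort-level code
  passes `side="two-sided"` explicitly; the per-test default remains
  `greater`.
* **Quadrant comparison.** The evidence that the happy-direct/hostile-direct
  split departs from 1/2 is computed as the two-sided proportion BF on the
  optima inside the two direct quadrants.  Because mapping "compare two
  quadrant proportions" onto a single test is not unique, the result is
  labelled *interpretation-dependent* and Dirichlet(1) contingency-table
  variants (two-category multinomial and independent-binomial 2×2, with a
  posterior-ordering correction for one-sided use) are reported alongside.
* **Theory verdict.** BF ≥ 3 is treated as positive evidence and ≥ 6 as
  compelling.  Direction read from counts: hostile > happy with BF ≥ 3 →
  Negativity Bias; the reverse → Natural Pedagogy; equality evidence
  (BF ≤ 1/3) plus a direct-half majority with BF ≥ 3 against 1/2 → Shared
  Signal; otherwise none.
* **JZS t-test BF.** Marginal likelihood of t under a Cauchy(0, √2/2) prior
  on the standardised effect (truncated/doubled for one-sided tests) over
  the central-t likelihood; Gauss–Legendre quadrature after a tangent
  change of variables, checked against an independent implementation
  (pingouin) and fixed-grid quadrature.
* **Design analysis.** Fixed-n BFDA simulates `reps` studies of n paired
  differences ~ N(d, 1), computes each study's one-sided JZS BF and
  classifies it against boundaries 6 and 1/6 (evidence for H1 /
  inconclusive / evidence for H0).  A sequential variant (default n 20→100,
  step 1) stops at the first boundary hit, using exact per-n BF thresholds
  in t.  Everything is seeded.
* **Power.** `required_n_paired_t` scans n upward for the smallest
  noncentral-t power ≥ target; for a 1.0 µV difference with SD 2.4 at
  α = 0.05 one-tailed and 80 % power this gives n = 38 (n = 37 reaches
  0.79997 — just short).

## Problem sizes

The test suite exercises 40 noise-free sessions (10 per corner) for the
recovery property, 30 sessions per noise level at sd ∈ {0, 10, 25, 60} µV
for the noise-degradation property, 10⁴-study design analyses, and a
10⁷-draw Monte-Carlo check of the proportion-BF quadrature; the whole suite
runs in about a minute on one CPU.  These sizes give binomial standard
errors comfortably below the asserted tolerances while keeping the suite
fast.

## Known limitations

* The generator's white-noise default understates real infant EEG structure
  (see above); the optional 1/f component and artifact rates only sketch
  it.
* The Nc deflection definition (zero-crossing-bounded run around the
  in-window minimum) is one of several in use; flanking-local-maxima
  bounds would give slightly different values on multi-peaked ERPs.
* The GP noise floor (0.3 µV) and length-scale floor (one grid step) are
  prior commitments, not fitted quantities; sessions with genuinely smaller
  measurement error would explore marginally more than necessary.
* The contingency-table Bayes factors are reported under explicitly
  labelled formulations; they are not canonical for the quadrant question.
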
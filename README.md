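# nbo — neuroadaptive Bayesian optimisation for infant ERP responses

`nbo` is a closed-loop simulator and analysis toolkit for *neuroadaptive
Bayesian optimisation* (NBO) experiments on infant EEG.  In such an
experiment, an infant watches blocks of face stimuli drawn from a 4×4 grid
crossing **emotional expression** (very happy, smiling, neutral, angry) with
**gaze/head direction** (0°, 5°, 45°, 90° averted).  After every 12-trial
block the EEG is preprocessed in real time, the **Nc negativity** — the
sign-flipped mean amplitude of the biggest negative deflection of the Nc
component (250–800 ms, fronto-central channels) — is extracted, and a
Gaussian-process Bayesian optimiser chooses the next stimulus, converging on
the grid cell that most strongly engages *that individual* infant's
attention.  The distribution of per-infant optima then discriminates between
competing theories of infant social attention (Natural Pedagogy, Negativity
Bias, Shared Signal).

Because live infants are not available to a software package, `nbo` ships a
first-class **simulated-infant generator**: 8-channel, 500 Hz EEG blocks
with a programmable ground-truth response surface, Nc-like deflections,
noise, blink/movement artifacts, flat channels, and a common reference
signal — enough structure to exercise every stage of the real-time pipeline
against closed-form oracles.

## What is inside

| module | contents |
| --- | --- |
| `nbo.stimspace` | the 4×4 grid, quadrants, Euclidean distances, burn-in schedules |
| `nbo.synth` | simulated-infant EEG block generator (the stand-in for acquisition) |
| `nbo.preproc` | real-time pipeline: segment → detrend → demean → mirror-pad → 0.1–20 Hz zero-phase band-pass → epoch (−100..800 ms) → baseline → artifact rejection (±200/400 µV or ±250/500 µV) → P7/P8 re-reference → 16 % validity gate |
| `nbo.ncmetric` | Nc negativity (the optimisation objective), traditional Nc mean amplitude, 0–200 ms early-window control |
| `nbo.bo` | Matérn-5/2 + white-noise GP surrogate, expected improvement (ξ = 0.1), three-in-a-row convergence rule, 15-block cap, session runner |
| `nbo.bayestats` | logistic-prior proportion Bayes factors, χ² check, JZS t-test BF, fixed-n and sequential Bayes Factor Design Analysis, required-n power, contingency BFs |
| `nbo.cohort` | cohort collation, theory testing, subgroup validation, CSV/JSON export |
| `nbo.cli` | `nbo` command line: `run-session`, `run-cohort`, `replay`, `stats …`, `design …` |

## The core loop

The optimiser treats the unknown stimulus→response map `f(x) = y` (x a grid
cell, y the block's Nc negativity in µV, larger = stronger engagement) as a
draw from a Gaussian process

    f ~ GP(0, σ² Matérn₅⁄₂(‖x−x′‖/ℓ) + σₙ² δ),

with coordinates normalised to the unit square and hyperparameters
(ℓ, σ², σₙ²) refitted each block by maximising the log marginal likelihood.
After four fixed corner burn-ins (Angry-0, Angry-90, VeryHappy-0,
VeryHappy-90), the next stimulus maximises expected improvement

    EI(x) = Δ·Φ(Δ/s) + s·φ(Δ/s),   Δ = μ(x) − y_best − ξ,  ξ = 0.1.

The session ends when one stimulus is chosen three times in a row (that cell
is the infant's *optimum*), or after 15 presented blocks (the optimum is the
posterior-mean argmax).  Blocks failing the validity gate are re-presented
and count toward the cap.

## Worked example

Run one closed-loop session against the default simulated infant (ground
truth: corner-peak surface, deepest response −10 µV at Angry-0; sensor noise
10 µV; 5 % artifact rate):

```bash
$ nbo run-session --seed 3 --out session.jsonl
block  1 Angry-0      valid=0.97 nc=5.751823479831889
block  2 Angry-90     valid=0.94 nc=3.4425154830064404
block  3 VeryHappy-0  valid=0.94 nc=3.4227725844805263
block  4 VeryHappy-90 valid=0.99 nc=1.9292316765135265
block  5 Angry-0      valid=0.93 nc=3.1017919048911846
block  6 Angry-0      valid=0.92 nc=5.296086352660127
block  7 Angry-0      valid=0.81 nc=4.162625549045696
{
  "converged": true,
  "optimum": "Angry-0",
  "n_blocks": 7,
  "distance_from_veryhappy0": 3.0,
  "quadrant": "hostile-direct"
}
```

Blocks 1–4 are the corner burn-ins (`valid` is the fraction of the 72
channel-trials surviving artifact rejection, `nc` the block's Nc negativity
in µV).  From block 5 the acquisition function exploits the strongest
response and re-selects Angry-0 three times — the session converges in 7
blocks and reports Angry-0 (grid distance 3.0 from VeryHappy-0, in the
hostile-direct quadrant) as this infant's optimum, matching the generator's
ground truth.

The cohort-level statistics are available directly, e.g. the evidence that
18 of 42 infants converging on one of the four corners exceeds the
corner-chance level of 1/4:

```bash
$ nbo stats proportion-bf --y 18 --n 42 --p0 0.25 --side two-sided
{"y": 18, "N": 42, "p0": 0.25, "side": "two-sided", "r": 0.5, "bf10": 5.330227619532545}
```

a Bayes factor of 5.33 — positive evidence that this stimulus is selected
more often than chance.

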
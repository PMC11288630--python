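# Methods

## Scope and data model

The package analyzes paired control / serotonin (5HT) recordings from
antennal-lobe projection neurons (PNs) together with palp-opening-response
(POR) sessions. Its containers mirror the experiment's structure:

* `SpikeTrain` — strictly increasing spike times (s) of one neuron in one
  trial, with neuron/odorant/condition/trial metadata.
* `PORMatrix` — binary locusts × trials outcomes for one odorant in one
  condition.
* `BinnedResponse` / `PopulationMatrix` — trial-averaged spike counts in
  half-open, non-overlapping bins; population matrices stack all
  neuron-odor rows of the control condition above the same rows after 5HT.
* `DesignMatrix` / `TargetVector` / `DecoderResults` — the linear decoder's
  inputs and fit.

Trial timing (`StimulusProtocol`): 40 s trials, 4 s odor pulse starting at
t = 10 s, five electrophysiology trials per odorant (10 behavioral trials).
The derived windows are baseline `[0, 10)` s, ON `[10, 14)` s and OFF
`[14, 18)` s. All binning is half-open with bin k covering
`[kΔ, (k+1)Δ)`; spike counts are conserved exactly through binning.

## Spike statistics

Spike detection on voltage traces uses local maxima above a trace-relative
threshold (trace mean + k·SD, default k = 5) with a 2 ms minimum peak
separation resolved in favor of the larger peak. The routine is the
standard peak-picking approach for full-blown sodium spikes on
intracellular traces; the defaults are deliberately conservative and both
are parameters.

Inter-spike intervals are pooled within trials only — the inter-trial gap
is not a physiological interval — and summarized by the median (mean of
the middle two values for even counts). Fewer than two spikes raises an
explicit `UndefinedMedianError` rather than returning a silent placeholder.

## ON/OFF response classification

A neuron-odor-condition is ON (OFF) responsive when at least one
trial-averaged bin of the ON (OFF) window exceeds

```
threshold = baseline_mean + k_sd × baseline_SD,      k_sd = 6.5
```

with baseline statistics computed on the trial-averaged bins of the
pre-stimulus window `[0, odor onset)`. Choices made where the procedure is
genuinely underdetermined:

* **Exceedance rule.** A single bin above threshold suffices (the weakest
  reading of "threshold that needs to be exceeded"); a
  `min_consecutive_bins` parameter tightens this to a run of bins.
* **Baseline scope.** Statistics are taken on trial-averaged bins, not
  per-trial bins; with five trials this keeps the threshold on the same
  scale as the classified responses.
* **Degenerate baseline.** Zero baseline SD collapses the threshold onto
  the baseline mean; the result is flagged `degenerate_baseline` because
  any activity then counts as a response.
* **Bin width.** 200 ms by default, configurable.

Robustness across conditions is the fraction of neuron-odor pairs whose
control-condition label (ON / OFF / nonresponsive) is unchanged after
treatment, with per-category denominators reported.

## Behavioral statistics

`p(POR)` is the proportion of positive outcomes over locusts × trials. The
denominator generalizes the canonical 10-trial session to any trial count;
the statistic is unchanged when the session has exactly 10 trials.
Condition comparisons use a one-tailed paired-sample t-test on per-locust
trial-summed POR counts (`d = after − before`, `t = mean(d)/(sd(d)/√n)`).
The tail is a required argument because the hypothesis is odorant-dependent
(increases are expected for appetitive odorants, decreases for aversive
ones). Zero-variance differences cannot support a t statistic: all-zero
differences report p = 0.5 and a constant nonzero shift reports the
boundary p (0 or 1), both flagged as degenerate. The inter-trial interval
is carried as metadata only; no statistic depends on it.

## Population analyses

The stacked population matrix (control rows above 5HT rows; 82 neuron-odor
combinations per condition → 164 × 200 at 200 ms bins) feeds two analyses:

* **PCA trajectories.** Bins are observations, units variables; each unit
  is mean-centered across bins, the covariance eigendecomposition is taken,
  and each bin's population vector is projected onto the top two
  eigenvectors. Eigenvector sign is fixed by making each component's
  largest-magnitude loading positive so plots are reproducible. 200 ms bins
  are the default (a 50 ms option exists; trajectory shape is insensitive
  to the choice, bin count aside).
* **Bin-by-bin correlation.** `C[i, j]` is the Pearson correlation between
  the population vectors of bins i and j; `σ_i` is the across-unit SD of
  bin i. Zero-variance bins are marked undefined (NaN row/column), never
  silently zero, and are excluded from block means. A cross-condition
  variant correlates bin vectors restricted to control rows against bin
  vectors restricted to 5HT rows; this is the quantity that separates
  tuning-preserving amplification (high ON-window correlation) from
  independently restructured spontaneous activity (near-zero correlation).

## The decoder

Weights solve `min‖Y − WᵀX‖²` where `X` is the units × (odors × 800)
concatenation of 50 ms trial-averaged counts and `Y` holds each odorant's
mean-subtracted p(POR) in its stimulus bins (bins 200–279 of each block at
the default protocol) and zeros elsewhere. The printed normal-equation form
`W = (XXᵀ)⁻¹XY` is implemented as the minimum-norm SVD solution with a
relative singular-value cutoff of 1e-10; rank, condition number and an
ill-conditioning flag are part of the results, and an optional ridge
parameter (default 0) switches to the regularized normal equations. Exact
zeros of the fitted weights are reported as their own ensemble rather than
being forced into a sign.

Predictions add the grand-mean POR back:
`p̂ = grand_mean + mean over stimulus bins of WᵀX_odor`. The
uniform-amplification experiment reports
`Δp = (g − 1) × mean stimulus-bin WᵀX_odor` per odorant, whose sign equals
the sign of the odorant's net projection onto `W` — the mechanism by which
a uniform gain produces odor-specific behavioral shifts. Predictions are
in-sample on the training odors (a held-out design is possible but carries
no claim here). Unit orderings for display sort by the difference in peak
stimulus-window response between two odorants, descending, with ties broken
by unit label.

## Synthetic experiments

The generator produces complete paired datasets with known ground truth.

* **Spontaneous activity** is a two-state Markov-modulated Poisson process:
  burst state at rate `b × r` with long-run occupancy `1/(b+1)`, quiet
  state at `r/b`, exponential dwells (burst dwell 0.15 s). This preserves
  the mean rate `r` exactly for any burstiness `b ≥ 1` while placing a
  fraction `b/(b+1)` of spikes inside bursts, so the ISI median falls as
  `b` rises; `b = 1` reduces to a homogeneous Poisson process. The control
  condition uses `b = 1`, the 5HT condition `b = 3` by default; the
  recordings the generator emulates show bursting qualitatively, so the
  dwell and occupancy constants are free choices fixed once. Control and
  5HT spontaneous activity are generated independently (treatment
  restructures spontaneous firing), while each PN's mean rate — drawn once,
  uniform ±40% around 3 Hz — is shared across conditions so that burstiness
  comparisons are at matched rate.
* **Evoked responses** superpose an independent Poisson process at rate
  `gain × amplitude` (default amplitude 15 Hz, 5HT gain 1.5) inside the
  responder's ON or OFF window. Gain scales magnitude only; response timing
  is fixed by the neuron's response type, so classification labels are
  invariant to amplification by construction.
* **Response map and ground-truth weights.** Each PN belongs to a latent
  positive or negative pool (balanced); per odorant, 35% of PNs respond ON
  and 15% OFF, with appetitive-odor ON responders drawn from the positive
  pool with probability 0.8 (aversive → negative pool). The ground-truth
  signed readout `w*` is then the minimum-norm solution mapping each
  odorant's expected stimulus-window population vector exactly onto its
  target POR offset from the grand mean, so the control-condition readout
  reproduces the target probabilities identically and appetitive odorants
  load on positive weights by construction.
* **Behavior** uses a clipped-linear link:
  `p = clip(grand_mean + w*·r + locust offset, 0, 1)` with Gaussian
  per-locust dispersion (SD 0.02) and Bernoulli trial outcomes; the linear
  link (rather than a logistic) keeps decoder parameter recovery exact in
  the noiseless limit. Default panel: HEX (appetitive, p = 0.62), BZA
  (neutral, 0.40), LOOL (aversive, 0.29), grand mean 0.43, 23 locusts × 10
  trials.
* **Reproducibility.** One master seed; every train and every behavioral
  draw uses a named substream keyed by (neuron, odorant, condition, trial),
  so datasets are pure functions of their configuration.

What the generator does **not** emulate: correlated trial-to-trial
variability, lateral-inhibition dynamics and odor-specific temporal
patterning within the ON response, spike-waveform shape (beyond the
triangular template used to exercise spike detection), concentration
dependence, and satiety effects. Passing tests therefore demonstrate that
the analyses recover the structure this generative model encodes — signed
opponent readout, timing-preserving amplification, burst-induced ISI
shifts — not that real recordings satisfy the model.

## Validation sizes and numerical choices

The packaged checks use 100 independently seeded full-size datasets
(89 PNs × 3 odorants) for decoder recovery and the amplification
experiment, 500 draws for classification fidelity, 150 s of spontaneous
activity per neuron and condition for the ISI comparison, and a stacked
164 × 200 matrix for the correlation structure — sizes at which the
Monte-Carlo error of each summary is small relative to the property being
asserted, while the whole suite runs in well under a minute. Numerical
tolerances: SVD cutoff 1e-10 (relative) in the decoder; 1e-9 absolute
slack in bin-edge arithmetic to absorb float division; correlation oracles
agree to 1e-12. The spontaneous cross-condition correlation is near zero
but not exactly zero (≈ 0.1): shared per-neuron mean rates induce a small
positive correlation between conditions even with independent spike
timing, which is the realistic behavior for rate-heterogeneous populations.

## Known limitations

* The decoder is fitted and evaluated in-sample, as the scientific claim
  concerns the existence of a reconciling readout, not generalization.
* The burst process is stationary within a trial; real 5HT-induced
  excitability changes may drift over minutes.
* The behavioral link is linear with clipping; probabilities near 0 or 1
  compress effect sizes, so amplification deltas saturate there.
* LN/PN discrimination, spike sorting of extracellular data, biophysical
  neuron models and antennal transduction are out of scope.
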
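# Methods

`eegsel` implements a subject-independent EEG affect-recognition
pipeline whose centrepiece is an unsupervised, subject-specific
selection of *spatial* features (electrode channels) from inter-channel
co-activation, paired with an unsupervised ranking of *temporal*
features (per-epoch signal descriptors).  Labels enter only at the very
end, through mutual-information refinement and a leave-one-subject-out
(LOSO) support-vector-machine evaluation.  This note records the model,
the parameter choices and the reasoning behind design decisions that
the narrative description of the method leaves open.

## Pipeline

```
recording ── notch(50 Hz) ── band-pass(0.5–40 Hz) ── ocular ICA ──
  down-sample(128 Hz) ── epoch(w s) ── 54 features / epoch / channel ──
    ├─ Laplacian-score feature ranking        (per subject, unsupervised)
    ├─ affinity-propagation channel ranking   (per subject, unsupervised)
    └─ MI best-k  +  nested LOSO SVM          (supervised, leakage-free)
```

## Preprocessing

* **Filters.** Zero-phase forward–backward IIR throughout: an
  `iirnotch` band-stop at 50 Hz (quality 30) and a 4th-order Butterworth
  band-pass 0.5–40 Hz.  Zero-phase filtering preserves epoch timing
  (cross-correlation of a filtered pass-band tone with its input peaks
  at lag 0).  A narrow notch necessarily rings at signal edges; the
  steady-state suppression of a 50 Hz tone is better than −60 dB.
* **Ocular removal.** FastICA on the scalp channels with as many
  components as channels.  The *deflation* variant is used: the
  parallel update stalls without reaching tolerance on mixtures whose
  bulk is near-Gaussian (EEG background), whereas deflation extracts
  the clearly non-Gaussian blink component first and converges.
  Components whose time course correlates with the ocular reference at
  |r| ≥ 0.7 are zeroed (at most 30 % of components), and the reference
  is the bipolar EOG derivation when EOG channels exist, else the
  Fp1/Fp2 mean.  On non-convergence the input is returned unchanged and
  flagged in the provenance log.
* **Down-sampling** is polyphase (`resample_poly`), so non-integer rate
  ratios work; 512 → 128 Hz is the common case and 128 → 128 Hz is the
  identity.  The 40 Hz band-pass doubles as the anti-alias filter.
* **Epoching** cuts non-overlapping windows of `w` ∈ {2, 5, 10} s and
  discards the trailing partial window.  All defaults use `w = 2` s:
  small windows give the channel-selection stage the most epochs to
  average over.

## The 54-feature battery

Seventeen time-domain, seventeen frequency-domain and twenty
time-frequency features per epoch × channel (names in
`eegsel.features.FEATURE_NAMES`, fixed order).  Parameter choices:

* Approximate/sample entropy: `m = 2`, `r = 0.2·std`, Chebyshev metric
  (field-standard defaults).  Spectral entropy: Shannon entropy (log2)
  of the sum-normalised Welch PSD, not normalised by bin count.
* Welch PSD: Hamming window, segment length `min(n, 256)` (2 s at
  128 Hz), 50 % overlap.
* Hjorth mobility `√(var(Δx)/var(x))` and complexity
  `mobility(Δx)/mobility(x)`; also applied verbatim to the PSD sequence
  (`hjorthMsp`, `hjorthCsp`).
* Spectral-slope block `spc_slp1–4`: intercept, slope, MSE and R² of
  the least-squares line through log10(PSD) vs log10(f) over 1–40 Hz;
  MSE and R² are computed on the log-power residuals.
* Bands: delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30, gamma
  30–Nyquist.  Gamma's upper edge is Nyquist even under the 40 Hz
  band-pass, so its content reflects filter roll-off.  `enrg_bnd` is
  the trapezoidal PSD integral per band, `powfreq` the mean PSD.
* Fractal dimensions: Higuchi with `k_max = 10`; Katz in the
  amplitude-only form (L = Σ|Δx|, d = max|x−x₀|), which is
  scale-invariant.  Hurst exponent by rescaled range over dyadic window
  sizes ≥ 8 samples.
* Decorrelation time: first lag (seconds) where the biased
  autocorrelation drops below 1/e.
* Zero crossings are counted on the mean-centred signal; exact zeros
  count once.
* Time-frequency: 6-level db4 DWT with symmetric extension.
  `wvlet1–6` = log10 mean-square of detail coefficients D1…D6 (floor
  10⁻¹²).  Teager–Kaiser energy ψ[c] = c²ₙ − cₙ₋₁cₙ₊₁ over each of the
  seven sub-band coefficient sequences (D1…D6, A6) contributes a
  (mean, std) pair, ordered D1.mean, D1.std, …, A6.mean, A6.std —
  hence (levels+1)·2 = 14 TK features.
* Degenerate (zero-variance) epochs yield zeros for every
  variance-normalised feature, never NaN, and the epoch × channel cell
  is flagged.

Moments use unbiased variance; skewness/kurtosis are the biased moment
ratios with kurtosis reported as excess (normal → 0).  The O(n²)
entropy kernels and the fractal estimators are JIT-compiled with numba
when available, with identical pure-numpy fallbacks (agreement asserted
in tests to 1e-12).

## Laplacian-score feature ranking

Per subject, every epoch × channel feature vector is one sample; the
features are z-scored, a symmetrised 5-NN graph is built, and the heat
kernel `S_ij = exp(−‖x_i−x_j‖²/t)` uses `t` = mean squared distance
over connected pairs.  The score of feature r is
`Σ_ij (f_ri − f_rj)² S_ij / Var(f_r)` — deliberately the *plain*
variance in the denominator, not the degree-weighted variance of other
Laplacian-score formulations; with z-scored features the two orderings
rarely differ and the plain form is what this pipeline defines.
Lower scores rank higher; zero-variance features get an infinite
sentinel and rank last; ties break lexicographically.  One third of the
features (top 18) pass downstream by default (`feature_top_fraction`).

## Channel selection from inter-channel co-activation

For each epoch the channels are compared by the Pearson correlation of
their feature vectors and clustered with affinity propagation
(damping 0.9, preference = median off-diagonal similarity, ≤ 500
iterations, converged after 25 stable iterations; exemplars are the
points with α_kk + ρ_kk > 0).  Anticorrelation is passed through to the
clustering unchanged but clamped to zero in the co-activation graph —
anticorrelation is not co-activation.  Spatial structure enters through
the montage: channels are adjacent when joined by a Delaunay edge of
the 2-D layout not longer than 1.8× the median Delaunay edge length (a
triangulation-based neighbour definition keeps irregular layouts
connected, where fixed distance thresholds do not), and the topological
distance δ(p,q) is the shortest-path hop count, zeroed beyond
κ_max = 2.  Edges between spatially close channels are discounted by
δ/(κ_max+1) — near channels read overlapping sources, so their
correlation carries less information about functional coupling.

Three choices matter and deserve their rationale:

1. **Temporal standardisation.**  Before the per-epoch correlation,
   every channel × feature cell is z-scored across the trial's epochs.
   Co-activation is correlated *fluctuation*; without this step each
   channel's static spectral profile (where its oscillatory peaks
   happen to sit) reads as persistent similarity between functionally
   unrelated channels and dominates the consensus.
2. **Session-level consensus.**  All epochs of all trials contribute to
   one consensus: the mean co-membership matrix M and the mean
   similarity S̄.  A channel's *persistent co-activation strength* is
   `Σ_j (M_ij · max(S̄_ij, 0) · disc_ij)² / Σ_j disc_ij²`.  The product
   rewards pairs that co-cluster consistently *and* stay positively
   correlated on average; squaring emphasises a channel's strongest
   persistent partnerships over an accumulation of weak transient ones
   (per-epoch weighted degree, by contrast, rewards membership in large
   transient clusters and is insensitive to persistence).  The
   denominator removes the montage's deterministic discount footprint:
   peripheral channels have fewer near (discounted) pairs and would
   otherwise be favoured even on exchangeable null data.  Channels are
   ranked by this strength; exemplar frequency across epochs is
   reported and breaks ties (the blend weight `alpha` is configurable;
   the default 0 reflects that exemplar identity rotates within a
   persistent cluster and adds little beyond the strength term).
3. **Epoch filtering.**  A median cut on each epoch's
   consistency-with-consensus is available (`epoch_filter="median"`)
   for sessions with transient artifacts, but is off by default: the
   per-epoch consistency statistic carries little information when the
   session is stationary, and discarding half the epochs costs √2 in
   consensus noise.

`select_top_fraction` keeps the ⌈fraction·C⌉ best channels; the
evaluation sweeps fractions 0.1 … 1.0.

## Mutual-information best-k refinement

Once ratings are available they are binarised at the 1–9 scale midpoint
(> 5 = high).  Each surviving feature column is discretised into 8
equal-frequency bins and scored by the plug-in MI estimate (bits)
against the class label; strictly zero-MI features are dropped and the
top-k kept (ties broken by the upstream unsupervised order).  The
selector is a scikit-learn `SelectorMixin`, so it can only ever see the
training rows of whatever fold calls it.

## Evaluation protocol

Each stimulus is one classification problem whose data points are
subjects.  The outer loop leaves one subject out; the inner loop
(stratified 3-fold, grouped by subject) refits the MI selection and
searches C ∈ {.025, .5, 1, 10, 100} for a linear kernel and an RBF
kernel with kernel scales {0.001, 2, 10, 50, 100}.  The scale values
are length-scales σ, mapped to `gamma = 1/σ²`; used directly as gamma,
four of the five values degenerate the kernel to the identity on
standardised features.  Inner-loop model selection uses *balanced
accuracy*: with tiny grouped folds, a degenerate one-class predictor
can score a perfect positive-class F1 on a validation subject that
happens to be positive, and balanced accuracy is immune to that.
Channel and feature rankings entering a fold are mean-rank aggregates
over the training subjects only; an audit trail records the subjects
used in every fold.

Reported metrics: because every fold's test epochs share one true
label, a single fold has no meaningful F1 — the per-trial F1 pools all
subjects' epoch predictions for that stimulus (confusion counts are
stored per fold), and the headline number is the mean over stimuli.  A
subject-level majority-vote F1 across folds is reported alongside.
The fraction-sweep table gives median and quartiles of the per-trial F1
across stimuli for each channel fraction.  Linear and RBF kernels are
both searched; ties resolve toward the linear kernel, which is also
the stabler choice in practice.

## Synthetic data

The generator emulates the structure of affective-EEG benchmarks:
S subjects × T trials × C channels (10-20 montage names) × a continuous
trace at `fs_raw`, with per-trial 1–9 valence/arousal ratings.  Each
channel carries a unit-variance 1/f^α background (default α = 1), one
sinusoid per canonical band under an independent lognormal amplitude
envelope (1 s node spacing, σ = 0.6, mean 1) — the burst-like
nonstationarity of real band power, without which cross-epoch
consistency would be vacuous — plus a common-phase 50 Hz line sinusoid
and frontally dominant eye blinks (300 ms biphasic raised-cosine
pulses, amplitude decaying with layout distance from the frontal pole,
mirrored into two synthetic EOG channels).

The class effect is a *coherent* band activation: on high-valence
trials the informative channels share one amplitude envelope in the
informative band (co-activation), and their Fourier content in that
band is scaled by √effect_size, so the between-class band-power ratio
equals `effect_size` exactly in expectation.  A purely independent
per-channel power shift is nearly invisible to a correlation-based
co-activation method, and real event-related band responses are
correlated across the involved sites.  With `effect_size = 1` nothing
is planted and all channels are exchangeable, which is what the null
checks rely on.  Arousal labels are drawn independently and carry no
planted effect by default.

What the generator does **not** model: volume conduction (background
channels are independent, so inter-channel correlation is purely
planted), non-stationary artifacts other than blinks, realistic source
geometry, inter-subject montage differences.  Passing tests therefore
demonstrate that the pipeline recovers planted co-activation structure
under realistic noise, fluctuation and artifact levels — not
performance on real EEG.

## Verification battery problem sizes

The verification battery (`scripts/acceptance.py`, mirrored by
`tests/test_acceptance.py`) chooses sizes that keep the full battery
within a coffee break on one CPU:

* Channel-recovery runs: 20 seeds × (1 subject, 8 trials of 60 s at
  128 Hz, 32 channels, 3 planted channels, effect size 3, w = 2 s);
  generated without blinks and evaluated without ICA, since ocular
  removal has its own dedicated test.
* LOSO classification: one dataset of 12 subjects × 8 trials of 40 s,
  full pipeline including ICA; rankings at w = 2 s, classification
  features at w = 10 s, channel fraction 0.25, k = 12 MI-kept features
  (the usual samples-per-feature heuristic at ~44 training epochs per
  fold), valence target, plus a control with labels permuted across
  subjects within each stimulus (the exact permutation null for the
  per-stimulus classifier).
* Null safety: 20 seeds × (1 subject, 4 trials of 24 s) with
  effect_size 1; binomial chance bands for top-25 % selection
  frequency.
* Oracle equivalences run on toy problems (6 × 3 Laplacian scores vs a
  double-loop evaluation, 50 random graphs vs BFS hop counts, Pearson
  similarity vs the direct formula, affinity propagation vs the
  scikit-learn reference on block toys at damping 0.7 — the reference's
  early-stability convergence check degenerates on small toys at 0.9 —
  and the plug-in MI at n = 10⁴).

## Known limitations

* The channel ranking needs tens of epochs per session before the
  consensus statistics separate signal from noise; single short trials
  are not enough (the per-pair consensus noise falls as 1/√epochs).
* The per-epoch feature Pearson similarity has low effective
  dimensionality (the 54 features are mutually redundant), which caps
  the attainable pair similarity around 0.2; the method compensates by
  averaging, not by sharpening the per-epoch statistic.
* The plug-in MI estimate is biased upward at small n; it is used only
  to rank features, never reported as an information quantity.
* Affinity propagation at heavy damping can converge to degenerate
  solutions on very small problems; with 14–32 channels and the median
  preference this was not observed.
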
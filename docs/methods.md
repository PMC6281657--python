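# Methods

This note documents the models, conventions and design choices behind
`valencepop`, in the spirit of a methods appendix: what each stage
assumes, which parameters matter, and what the synthetic benchmarks do
and do not establish about real data.

## Trial timeline and windows

All analyses assume a fixed trial timeline: 23-s trials sampled at
10 frames/s (230 frames), a 10-s baseline, stimulus onset at frame 100
(0-based), a 1-s CS, a 2-s trace interval, and the US 3 s after CS onset.
Response windows are half-open frame ranges — post = [onset, onset + w),
pre = [onset − w, onset) with w = round(width × rate) and width 1 s by
default — so the onset frame belongs to the post window. The predictive
(anticipatory) behaviour window runs from CS onset to US onset.

## Normalisation

ΔF/F is (F − F₀)/F₀ with F₀ the modelled background. z-scores standardise
each trace by its own mean and SD over the *entire* peri-event period
(the full trial), never over a short baseline whose SD can vanish in
sparsely active neurons. Two conventions exist: trial-averaged (average
ΔF/F across trials, then standardise) for ensemble vectors and heat maps,
and per-trial (each single-trial trace standardised by its own mean/SD)
for trial-by-trial analyses. Per-trial standardisation reuses
trial-specific moments rather than session-wide ones — the natural
reading of "the same method without averaging". Constant (zero-SD) traces
cannot be standardised; they are excluded with a logged warning rather
than zero-filled, because zero-filling would manufacture fake
"nonresponsive" neurons.

## Responsiveness classification

A neuron is responsive to a stimulus when its paired 1-s post vs 1-s pre
window means differ by a two-sided Wilcoxon signed-rank test at
α = 0.05; the sign of the mean post − pre difference assigns
excited/inhibited. Zero differences are dropped (Wilcoxon convention).
For n ≤ 25 retained pairs the p-value comes from the exact null
distribution of W⁺, computed in-package by dynamic programming over
doubled midranks; this keeps the test exact even under tied
|differences|, where standard exact routines fall back to a normal
approximation. Beyond n = 25 the tie-corrected normal approximation is
used. At the study's n = 10 trials the exact two-sided test rejects null
data at rate 50/1024 ≈ 4.9% (2 × 25/1024 per side) — the test is
conservative on its discrete support, and this size is itself verified
against brute-force enumeration in the test suite. No multiple-testing
correction is applied across neurons or stimuli, matching standard
practice for these category counts.

## Synthetic generator

The generator is the package's oracle: it emulates the study design with
known ground truth, not raw-movie physics (no pixels, no spike-to-
fluorescence biophysics beyond an exponential kernel).

**Archetypes.** Each neuron belongs to a response archetype — the set of
stimuli that excite (+) or inhibit (−) it. Archetype fractions are
realised by exact largest-remainder allocation (shuffled by seed) rather
than multinomial draws: the configured fractions are the study
conditions, and stratified assignment realises them exactly at finite n,
so recovered category fractions are limited by the classifier, not by
sampling noise in the generator.

**Paper-mimic presets.** The pre-learning preset encodes the published
classified fractions: 15%/12% excited by CS1/CS2, 25%/19% by US1/US2,
rare inhibition (<5%), overlaps CS1∧CS2 6%, US1∧US2 8%, CS1∧US1 5%,
CS2∧US2 4%, and a 47.2 : 30.6 : 22.2 split of US-responsive neurons into
US1-only : US2-only : both. Those printed fractions are measurements made
*through* the signed-rank classifier, which mislabels a truly silent
neuron as excited at the known rate 25/1024 per stimulus. The preset
therefore inverts this classification channel by a fixed-point solve, so
that *classified* fractions of generated data reproduce the printed ones;
`measurement_corrected=False` uses the printed fractions directly as
generative probabilities. The post-learning preset keeps CS-excited
fractions, reduces US-excited ones, doubles the CS∧US co-response
fractions and makes inhibition prominent (~26% of neurons in some
inhibited category); the literature gives these post-learning changes only
qualitatively, so the post fractions are plausible fixed choices, not
targets. Pre and post presets differ only in archetype probabilities and
shared-noise fraction.

**Traces.** A trial trace is a positive ΔF/F baseline (0.5; inhibition
must be expressible as a decrease) plus white frame noise (SD 0.05 ΔF/F)
plus, for responsive neurons, a calcium transient with instantaneous rise
and exponential decay (τ = 0.6 s, GCaMP6f-like). Response amplitudes are
stated in z-units: amplitude a scales the kernel so the 1-s post-window
mean rises by a frame-noise SDs (by a ΔF/F when noise is disabled). The
default 2 z-units makes per-trial effects large enough that classifier
power is ≈ 1 at 10 trials, so category recovery isolates the
false-positive channel. τ, baseline and noise SD are generator choices
exposed in the config — the source experiments report no kinetics.

**Shared noise.** Trial-to-trial co-fluctuation is a single per-trial
Gaussian latent per mouse with a common loading — the simplest model
producing positive mean pairwise noise correlations. It enters the trace
as a constant offset over the 2-s window straddling stimulus onset (a
shared state fluctuation around the stimulus), a choice with two
consequences: it cancels in the post − pre classification contrast (so
false positives stay independent across neurons) and it survives in the
z-scored trial response (so pairwise noise correlations equal the
configured shared-variance fraction; the loading includes the small
attenuation from full-trace mean subtraction). Presets use 0.2 before and
0.05 after learning, encoding the direction — learning reduces noise
correlations — the magnitude of which is a choice.

**Reversal.** Each neuron carries independent pre- and post-reversal CS
amplitudes (responsive with probability 0.3, 80% excited). On trial t the
evoked amplitude interpolates linearly in a latent learning curve
L(t) = 1 − exp(−(((t − t₀))/α)^β) for t ≥ t₀ (0 before), with t₀ the
first post-reversal trial, α the latency (default 10 trials) and β the
abruptness (default 4); thus L(t₀) = 0 exactly and L is nondecreasing.
`remap_mode="step"` is the abrupt limit in which the new contingency is
expressed from t₀ onwards (L = 1 for all post-reversal trials), used for
change-point benchmarks. Per-trial observation noise has SD
`obs_noise_frac` × |remap amplitude| per neuron. Behaviour is driven by
the same latent with *independent* noise (licking rises on the reward
side of the reversal as Poisson counts in the trace interval, eye-area
dips deepen on the punishment side), optionally delayed by
`behavior_lag_trials` so the population signal precedes the behavioural
switch; independence makes the measured neural-behavioural correlation a
genuine pipeline output rather than a wiring artifact. Block lengths
follow the protocol: 10 + 50 trials (punishment→reward, CS2) and 10 + 30
(reward→punishment, CS1). `generate_reversal_session` tracks one neuron
population through both blocks for decoding analyses.

**What the generator does not emulate.** Real data have non-Gaussian,
non-stationary noise, bursty transients, registration errors across
sessions, heterogeneous per-neuron kinetics and behaviour-correlated
motion artifacts. Passing tests therefore establish correctness of the
*analysis chain* under the stated statistical assumptions, not robustness
of the conclusions to real-data pathologies.

## Population geometry

Population vectors stack z-scored responses across neurons, one vector
per frame of the response window (trial-averaged) or per trial
(per-trial window means). PCA is mean-centred and fit on the analysed
vector set; the stored basis and fit mean project out-of-sample vectors.
Conventions: 2 components for ensemble comparisons and decoding, 3 for
reversal trajectories — each configurable.

Mahalanobis distance uses the unbiased (n − 1) sample covariance of the
reference set, ridge-regularised as S + ridge·(trace S / dim)·I whenever
the condition number exceeds 10⁸ or the reference has fewer than dim + 1
vectors (10 reference trials in 3 PCs can be near-singular);
ridge = 10⁻⁶ by default. For ensemble separation the covariance is the
pooled within-condition sample covariance of both sets — the symmetric
choice — and the per-timepoint distances of paired vectors are averaged
over the window. MD is affine-invariant and reduces to Euclidean distance
under identity covariance; both properties are tested against independent
implementations.

## Reversal trajectories

Per-trial series are normalised as x/median(x) − mean(x/median(x)); a
zero median falls back to median(|x|) + ε with a warning (a case the
normalisation recipe leaves undefined, common for near-zero behavioural
channels). Sign is flipped automatically when the pre-reversal mean
exceeds the post-reversal mean so curves run low → high. Licking and
blinking are combined by normalising each channel, aligning signs,
scaling each to unit variance (so neither channel's arbitrary units
dominate) and averaging per trial; variance-standardisation is this
package's resolution of an otherwise unspecified combination rule.
Per-mouse normalised series are averaged per trial across mice before
correlation and fitting; the Pearson correlation is computed on the raw
averaged series, not on fitted curves.

The Weibull learning curve is fitted in its rise form
f(x) = u − (u − l)·exp(−(x/α)^β), monotone from l to u: the historically
printed variant u + (1 − l)·exp(−(x/α)^β) has asymptotes inconsistent
with the stated roles of u and l and is retained only as
`form="printed"`. Fitting is bounded least squares (α ∈ (0, 10n],
β ∈ (0, 50], u and l free within ±10 ranges) over a deterministic 3⁴
multi-start grid; r² = 1 − SS_res/SS_tot, with constant series flagged
degenerate at r² = 0.

Change points are found on the cumulative record: the candidate split is
the index of maximal vertical deviation from the chord joining the
record's endpoints, confirmed by a two-sided rank-sum test and recursed
into both sub-segments, reporting each accepted point as the first trial
of the new regime (1-based). Because the candidate is the most extreme of
n − 1 possible splits, confirming at raw α would inflate the family
false-alarm rate well above α; the confirmation therefore runs at the
Bonferroni level α/(n − 1), which keeps the empirical false-alarm rate on
exchangeable series below α (verified over 10³ null simulations) while a
step of 10× the noise SD is still detected within ±2 trials in ≥95% of
runs. Raw-α behaviour remains available via `correction="none"`.

## Decoding and clustering

Valence decoding uses the 20 trials of a stage window (10 CS-reward, 10
CS-punishment): PCA to 2 components fit per stage, then a linear SVM
(C = 1 fixed; no hyperparameter search) under stratified 10-fold CV with
seeded fold assignment, one trial per class held out per fold. Functional
clustering takes each neuron's eight mean-response features
({CS1, CS2, US1, US2} × {pre, post} 1-s post-onset mean z), reduces them
to 3 PCs and applies agglomerative clustering with correlation distance
and complete linkage, cut at k = 4 clusters (k fixed to mirror the
four-type description; no model-selection criterion). Zero-variance rows
are dropped — correlation distance is undefined for them.

## Problem sizes and numerical conventions

Simulation-based tests and the acceptance benchmarks use the study-scale
conditions: 6 mice × 126 neurons (756) for category recovery, 6 × 113
for reversal trajectories, 10,000 null neurons for the classifier size,
20 seeds for recovery averages — sizes chosen to match the source design
while keeping each benchmark in the seconds-to-a-minute range on one
core. All randomness flows from explicit seeds (numpy Generator seeded
per dataset label); identical config + seed reproduce datasets bitwise.
Floating-point conventions: CSV serialisation round-trips values to
better than 10⁻¹² (HDF5 exactly); PCA uses full SVD for determinism.

## Known limitations

- Post-learning stage datasets present each stimulus in separate trials
  (onset at frame 100) rather than CS followed by US within one trial;
  classification windows for paired presentations would otherwise overlap
  the CS response tail.
- The origin-transition structure of the learning-pair generator
  (inhibited neurons drawn mostly from the nonresponsive pool, US-excited
  from the same US pool) is a stylised preference model, adequate for
  testing the transition bookkeeping but not a learning model.
- Nearest-neighbour angle medians are computed in degrees on pooled or
  per-mouse vector sets; published medians for this analysis carry no
  units and are not targeted.
- The decoder pools neurons across synthetic mice (identities are aligned
  by construction); with real data it should be run per mouse.
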
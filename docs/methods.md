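# Methods

`protaxsound` turns heterogeneous acoustic evidence — template dissimilarities
and the outputs of other classifiers — into calibrated species-membership
probabilities for animal vocalizations, with an explicit open-set
"unknown species" outcome. This note records the models, the defaults and the
reasoning behind the design choices, in the order the pipeline runs.

## Signal front end

**Audio.** WAV input (PCM 16/24/32-bit or float) is mixed to mono by channel
mean and scaled to [-1, 1]; clips at other rates are resampled with a
polyphase filter so that all spectrograms share one axis calibration. The
default rate is 44.1 kHz.

**Spectrograms.** Magnitude STFT with a Hann window. The generic
`stft_spectrogram` default is the common bioacoustics choice of a 512-sample
window at 50% overlap; the *pipeline* default is a 1024-sample window with a
256-sample hop. The longer window is a front-end calibration: the synthetic
fixtures (below) contain tone elements a few hundred Hz wide, and with 86 Hz
bins the analysis mainlobe (~4 bins) is wider than the vocalization itself,
so detected boxes cannot reach IoU 0.5 against the ground truth. With 43 Hz
bins the noiseless fixture recall at IoU 0.5 is 1.0. Both values live in
`PipelineConfig` and are plain config, not code.

**Segmentation.** The widely used median-clipping template method: a pixel is
signal when its magnitude exceeds `factor` (default 3) times both its
frequency-row median and its time-column median. An absolute floor at
-35 dB relative to the spectrogram peak is also applied; without it a
noise-free recording has near-zero medians and windowing sidelobes pass the
relative test everywhere. The binary mask is closed with a 3x3 structuring
element, components below `min_area` (16 px) are dropped, and components
closer in time than `merge_gap` (50 ms) with overlapping frequency bands are
merged. Pixel index `i` covers the half-open interval `[i, i+1)` on its
axis, which makes pixel-to-physical conversions exact and merging arithmetic
unambiguous. Manual validation is a CSV round-trip (export, edit
delete/redraw/add directives, re-import) — a scriptable surrogate for a
visual check.

## Feature families

**MFCC summaries.** 16 cepstral coefficients per 0.02 s frame (hop 0.01 s)
computed only inside ROI time spans: Hann window, 26-band triangular mel
filterbank over 0–Nyquist, log, orthonormal DCT-II, coefficients 1–16 (c0
excluded by default; both c0 and liftering are config options). Delta and
Delta-Delta are regression slopes over ±2 frames with edge replication,
giving 48 parameters per frame. A sample (one file's ROIs) is summarized by
the mean and the *population* variance of each parameter — 96 values; the
population convention keeps single-frame samples defined (variances zero).
Two samples are compared by six blockwise Euclidean distances,
{mean, variance} x {MFCC, Delta, Delta-Delta}, each block 16-dimensional.

**Normalized cross-correlation.** Two spectrogram images slide across each
other over all 2-D lags; the score is the peak normalized inner product.
The default normalization is by the full norms ||A||·||B|| ("cosine" form),
which is symmetric in the two images, invariant to scaling either image by a
positive constant, bounded in [0, 1], and equal to 1 exactly for images
identical up to scale. An overlap-normalized variant
(||A||·||B_overlap||, with a minimum-overlap guard) is available behind
`mode="overlap"`; the cosine form is the default because symmetry is part of
the feature's contract here. A query sample's cross-correlation vector holds,
for each reference template, the maximum score over the query's ROI crops —
max preserves the best template match when a query holds several elements.

**Mel patches.** Mel log-power spectra (default 32 bands) at a 10 ms hop.
The clip's per-band median — a noise-floor estimate under the same
stationary-background assumption as the segmentation — is subtracted and the
result clipped at zero; fixed-duration (1 s) crops centered on the
highest-energy ROIs, zero-padded when short, feed the convolutional
classifier. Without the subtraction the patches mostly carry the noise
floor that the forest's denoised ROI crops never see, and the network is
the weaker classifier for no structural reason.

## Base classifiers

**Random forest** on cross-correlation features (default 300 fully grown
trees, sqrt(p) features per split). Probabilities are tree-vote fractions
and deliberately uncalibrated — calibrating them is the point of the
wrapper. Feature importances drive the template pre-selection: templates are
ranked by importance (ties broken by feature id), the forest is retrained on
shrinking top-ranked prefixes, and the smallest prefix within 0.5 accuracy
points of the curve maximum is kept. Selection accuracy is measured by
internal cross-validation on training data only.

**Convolutional network** on mel patches, written directly in NumPy and
desk-scale by construction (a few thousand parameters): two 3x3 convolution
blocks (12 and 24 filters) with ReLU and 2x2 max pooling, then a readout that
averages over *time only* and keeps the (channel, frequency-row) grid before
the softmax head. Global pooling over both axes would discard absolute
frequency position, which is precisely the class signal in a spectrogram.
Input patches are decimated 2x in time (consecutive-frame averaging).
Training is minibatch Adam (lr 1e-2, batch 32) on the cross-entropy for 40
epochs — enough for the training loss to plateau on the fixture benchmark.
Patch-level softmax outputs are aggregated to a sample-level distribution by
their mean (the least-commitment pooling).

Both classifiers satisfy a checked probability contract (values in [0, 1],
unit sum); anything meeting that contract can serve as a predictor source.

## The calibration model

For a query and each candidate species the model sees eight predictors:
x1..x6 are the minima of the six blockwise dissimilarities over the species'
reference samples; x7 and x8 are modified logits,
logit(eps + (1 - 2 eps) p) with eps = 0.001, of the class probability the
random forest / the network assigns to that species. The eps floor keeps
p = 0 and p = 1 finite. A species left without reference samples receives a
per-block sentinel distance — the maximum distance observed in training,
i.e. "no evidence of similarity" expressed on the distance scale.

Membership probabilities follow a flat multinomial logistic decomposition
(no taxonomic tree): with standardized predictors z_s for candidate s,

    P(s)        ∝ exp(β0 + Σ_k βk z_sk)        for each candidate species s
    P(unknown)  ∝ 1

one shared intercept, eight shared slopes, and the unknown outcome as the
reference category. This is multiclass Platt scaling with an open-set
outcome.

**Training events.** Each reference sample q yields two leave-one-out
pseudo-queries: a *known* event (q removed from its own species' reference
set; truth = q's species) and an *unknown* event (q's species and all its
references removed from the candidate set; truth = unknown), a 1:1 mix.
Predictor standardization constants are computed over all event rows.

**Estimation.** Penalized maximum likelihood — an independent Gaussian prior
(sd 10) on the intercept and slopes — maximized by L-BFGS with an analytic
gradient; non-convergence is flagged, never silent. Standard errors come
from the numerical Hessian of the penalized objective at the optimum. A
point estimate suffices for the probability map; a fully Bayesian treatment
would add posterior uncertainty the downstream diagnostics do not consume.

**Provider consistency.** The base-classifier probabilities inside training
events are produced out-of-fold: the training data are split into three
grouped inner folds and each provider scores only the fold it did not see
(per-sample retraining would be quadratic). At prediction time the
calibrated predictors are fed by one of those same fold-trained providers —
not by a model retrained on all the data — because a query must be scored by
a model of the same strength as the one whose out-of-fold outputs
parameterized the calibration. We measured the alternative directly: with a
full-data network at prediction time the logit of the true species' CN
probability averaged 1.4 at test time against 0.4 inside the events, and the
wrapped probabilities came out overconfident; averaging several fold models
smooths the probabilities into a distribution the calibrator never saw and
is also miscalibrated. The full-data forest and network are still trained
and kept on the bundle: they are the standalone classifiers a practitioner
would use directly, and serve as the raw baselines in the comparison
experiment. Cross-correlation features of a reference sample against
templates cut from that same sample are imputed from the species' other
templates for the same no-self-evidence reason.

## Evaluation

**Accuracy** mimics a user taking the highest-probability outcome; ties are
broken by species id with unknown last. "Unknown" counts as correct only
for queries whose species is truly absent from the reference database.

**Reliability.** Top probabilities are sorted ascending and paired with
correctness; the cumulative predicted sum C_i is plotted against the
cumulative correct count K_i. The scalar summary is mean |K_i - C_i| / n —
zero for a perfectly confident, perfectly correct classifier, and the raw
curve is always emitted alongside it. The comparison experiment reports the
deviation twice: over the in-database test queries (the protocol a
closed-world benchmark forces) and over the pooled open-set population
including the withheld outgroup queries, for which "unknown" is the correct
answer — the population the model's probability space actually describes.

**Species-level calibration.** For each species with n test samples the null
distribution of the correct count is the sum of n Bernoulli trials at the
predicted top probabilities, simulated 10,000 times; the two-tailed p-value
doubles the smaller empirical tail (capped at 1, floored at 1/n_sims). A
"point-mass" variant (summing the null mass of outcomes no more likely than
observed) is available; doubling is the default as the conventional reading
of a two-tailed empirical test. Small-n discreteness piles p-values near 1;
that peak is expected and benign.

**Cross-validation folds.** Rows sharing (author, day, species) are atomic —
recordings that may capture the same individual never straddle the split.
Groups are dealt round-robin per species starting at the smallest fold, so
species spread as evenly as the group structure allows; a species whose
samples form a single atomic group triggers a warning, not an error.

## The synthetic benchmark

The fixture generator renders each species as a motif of 3 linear-frequency-
sweep tone elements (center frequency 1.5–7.5 kHz, bandwidth 100–400 Hz,
duration 0.08–0.25 s, sweep ±4 kHz/s, gaps 50–150 ms) with Hann envelopes,
multiplicative parameter jitter per rendition, and additive white (optionally
pink) noise. Species are drawn with a floor on their pairwise distance in
normalized parameter space, so motifs are distinct but overlap in frequency.
Metadata assign clips to synthetic recording sessions (author, day) so the
grouping rule is exercised.

The comparison experiment uses 10 reference species x 50 clips (5-fold
grouped CV pools 500 held-out queries), 2 withheld outgroup species x 10
clips for the open-set probe, 2 s clips, within-species jitter 0.15 and
noise amplitude 0.3 against a 0.5 signal amplitude. These are moderate-SNR,
noticeably variable conditions under which the base classifiers err visibly
— chosen once as a realistic regime; near-clonal renditions (jitter 0.05)
make every classifier saturate and the calibration comparison vacuous.

What the fixtures do not emulate: harmonic stacks, reverberation and
propagation filtering, non-stationary background (wind gusts, streams),
overlapping vocalizations of several individuals, and diurnal/recordist
effects beyond the synthetic session labels. Passing tests therefore show
the machinery is correct and calibratable under controlled variation, not
that field-recording accuracy will match.

## Numerical choices and degenerate inputs

- Log floors: -100 dB on mel power, 1e-12 inside MFCC logs; all-zero images
  are rejected by the cross-correlation (normalization undefined).
- Variance convention: population (divide by n).
- Ties: feature ranking breaks importance ties by ascending feature id;
  top-outcome ties break by species id, unknown last; both documented
  contracts, not accidents of sorting.
- The L-BFGS fit starts from zero coefficients; the Gaussian penalty makes
  the objective strictly concave, so the optimum does not depend on the
  start.
- Empty masks, ROI-free files and silent clips are "no detection" results,
  never errors; a clip shorter than one analysis window is an error naming
  the minimum.
- Seeds: every stochastic stage takes an explicit seed; derived seeds come
  from `numpy.random.SeedSequence.spawn`, keeping results bit-reproducible.

## Known limitations

- The unknown-species probability reflects the 1:1 known:unknown training
  mix. On a test population that contains no true unknowns, a weak predictor
  set (e.g. the network-only variant when the network is data-starved) tilts
  toward "unknown" and its top probabilities read overconfident; informative
  predictors suppress the effect. This is a property of the leave-one-out
  event design, not of the implementation.
- Fold-level (rather than per-sample) provider retraining is an approximation
  of the leave-one-out rule; it leaves a small optimism in events scored by a
  provider trained on siblings from the same recording session only when the
  grouping metadata are wrong.
- The segmentation reconstructs the median-clipping template method from its
  published outline; the original's exact morphological schedule was not
  available, so thresholds are exposed in config rather than claimed
  faithful.
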
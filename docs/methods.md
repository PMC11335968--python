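# Methods

## The measurement model

Neural tracking is quantified by backward (stimulus-reconstruction)
modelling: a linear decoder maps the multichannel EEG at lags between
−250 and 750 ms onto one stimulus function at a time, and tracking
strength is the Pearson correlation between the reconstruction and the
true function on held-out data. The positive-lag convention is "neural
response after the stimulus sample being reconstructed", matching the
causal interpretation of auditory P1–N1–P2 components; at 32 Hz the lag
grid has 33 taps (−8…+24 samples). The decoder is linear and
time-invariant within a block; it makes no claim about neural sources,
which is why decoder weights are additionally forward-projected into
activation patterns, `a = Cov(lagged EEG) · w / Var(ŝ)`, before any
topographic interpretation.

All stimulus functions and preprocessed EEG live on a common 32 Hz
grid. A sample at time `t = i/32 s` belongs to word `w` iff
`onset ≤ t < offset` (half-open, block-relative); this single assignment
rule is shared by the lexical-function builder, the envelope generator
and the word-half analysis, so word samples partition exactly.

## Stimulus functions

**Acoustic.** The amplitude envelope is the Hilbert magnitude of the
separated talker waveform (no auditory filterbank — a deliberate
simplification; the octave modulation spectrum used for talker
characterization is likewise a single-carrier simplification of
multi-resolution envelope power models, and is documented as such). The
delta band is low-passed at 4 Hz with no high-pass (natural speech has
negligible energy in the lowest modulation frequencies); theta is
band-passed 4–8 Hz. All filters are first-order Butterworth applied
forward-backward (zero-phase), *before* polyphase decimation to 32 Hz so
the decimator sees a band-limited signal; the polyphase FIR supplies the
anti-alias stage. Each block is z-scored. Note the gentle first-order
skirts: forward-backward filtering yields power gain |H|⁴, so content
just above a cutoff is attenuated ~75–90%, not eliminated; the test
suite checks the measured roll-off against the analytic response rather
than asserting a brick wall, and the delta+theta ≈ broadband energy
check carries a deliberately loose tolerance (ratio 0.6–1.4) for the
same reason.

**Lexical.** Word alignments are boundary-filtered first: inter-word
gaps shorter than 250 ms are alignment artifacts and are closed by
extending the *preceding* word's offset (onsets are preserved because
they anchor the word-half analysis); gaps of 250 ms or more are genuine
pauses. Contrastive functions then place, across each word's samples,
the signed deviation of the word's lexical value from the
duration-weighted block mean, with sign −1 for log10 frequency and
n-gram log10 probability (rare/improbable → positive) and +1 for guess
rank (unpredictable → positive); pauses are exactly zero. The
duration-weighted mean of emitted word values is zero by construction.
Words too short to cover one 32 Hz sample emit nothing and are counted
in the function's metadata. Guess-rank scoring lower-cases and strips
punctuation (internal apostrophes kept), matches contractions up to the
apostrophe symmetrically, matches multiword/hyphenated guesses on their
first word, and returns 11 when no guess matches. Frequency lookup is
table-driven with an explicit out-of-vocabulary floor; tables can be
exported from any frequency resource. No orthogonalization is applied
between frequency and predictability functions — they are decoded
separately.

## Decoding

Ridge training solves `w = (XᵀX + λI)⁻¹ Xᵀ s` on column-centered data
with an unpenalized intercept; λ multiplies the identity on z-scored
data with no eigenvalue rescaling. Evaluation is leave-one-block-out;
within each training set of B−1 blocks, λ is selected by rotating a
validation block through those blocks only, over the 16-value decade
grid 10⁻³…10¹², maximizing mean validation r (ties to the smallest λ).
Design matrices are zero-padded at block edges (a negligible fraction of
samples for minutes-long blocks at 32 Hz). Internally, per-block Gram
matrices are cached and block unions are re-centered exactly from the
cached sums, with one eigendecomposition per training set serving all λ
values; this changes nothing numerically (verified against explicit
normal-equation solutions at 1e-8) and makes nested CV affordable.

## Statistics

**Word halves.** Each word splits at its sample midpoint, the first
half taking the extra sample for odd counts. A half is eligible if it
has ≥3 samples and nonzero variance on both sides (32 Hz makes shorter
halves degenerate); ineligible halves are counted, not silently
dropped. Per-word halves are the observations fed to mixed models, with
word duration available as a covariate; predictability and frequency
enter as continuous covariates, median/rank-11 splits being display
conveniences only.

**Permutation null.** Each of 100 randomizations re-pairs every
subject's reconstructions with stimulus segments drawn from a uniformly
chosen *different* block of the same subject, length-matched with a
random circularly wrapped start, and records the across-subject mean
correlation. The reported exceedance is the fraction of randomizations
below the veridical mean. Because Pearson r is scale-free, exceedance is
invariant to affine rescaling of the data.

**Mixed models.** Models have random intercepts for subject and
(optionally) stimulus; with both, the crossed structure is fit through
variance components in statsmodels. Factor chi-squares come from
likelihood-ratio comparisons of maximum-likelihood refits in which the
tested term (and nothing containing it) is removed — a reproducible
stand-in for Wald-type Anova tables. Nonsignificant nested interaction
terms are dropped iteratively at α = 0.05, highest p first. A stimulus
variance component estimated below 5% of the residual variance is
treated as a boundary (singular) fit; the model is refit without it and
the drop is flagged with a warning. The optimizer falls back from
L-BFGS to BFGS to Powell if a step produces a singular linearization.

## The synthetic generator

The generator emulates the statistics of read two-talker stories, not
their acoustics. Defaults: lognormal word durations (log-mean −0.9,
log-sd 0.35 s → median ~0.41 s, natural right skew); pause probability
0.12 per word with shifted-exponential durations of mean 0.69 s starting
at 0.25 s, so every generated pause survives boundary filtering by
construction; Gaussian log10 frequencies on a Zipf-like scale (mean 4,
sd 1); guess-rank probabilities 31, 6, 3, 2, 2, 1, 1, 1, 1, 1% for ranks
1–10 and 51% unmatched. Envelopes are per-word raised-cosine syllable
pulse trains at 4 Hz with 8% rate jitter and per-word amplitude in
0.6–1.4, exactly zero in pauses; their modulation spectrum peaks in the
4 Hz octave band.

EEG is the forward model inverted by the decoder: each stimulus
function convolved with a ground-truth kernel per channel (Hann-windowed
damped sinusoids at random causal latencies, smooth random topographies,
unit Frobenius norm, support inside the lag window), target
contributions scaled by an attention gain, envelope contributions within
each word scaled by `1 + κ·z(rank)` (κ is a synthetic-only device for
power and recovery testing — the analysis pipeline never sees it), plus
1/f Gaussian noise mixed by smooth random topographies and scaled to a
per-channel SD. Attended and ignored talkers get independent kernels:
distinct response patterns are precisely what makes the two talkers
separable by a linear decoder, and with identical kernels the noise-free
reconstruction ceiling would be 1/√2 by construction. Default channel
count is 32 (configurable; chosen for speed over a full research
montage). Talker envelopes are generated independently — the
between-talker envelope correlation of simultaneous speech is not
modelled — and the generator makes no claim to physiological realism in
topography, spectra beyond 1/f, eye artifacts, or electrode geometry;
passing tests demonstrate pipeline correctness and sensitivity, not
real-EEG effect sizes.

## Problem sizes and determinism

Simulation-based checks are sized for a single CPU: coupling-recovery
replicates use 3 blocks × 90 s × 8 channels (50 replicates per κ
condition); the permutation/group analysis in the acceptance script uses
10 subjects × 8 blocks × 120 s × 32 channels with noise SD 20 in
kernel-normalized units, which places mean held-out delta reconstruction
r near 0.1. Every stochastic component takes an explicit seed and is
bit-reproducible; the acceptance script derives all of its seeds from a
single `--seed` argument.

## Known limitations

* Real-recording concerns — mastoid referencing, artifact-rejected
  average reference, blink denoising, bad-channel handling beyond
  flagging constant channels — are out of scope; the pipeline starts
  from per-block channel × sample arrays.
* Forced alignment and language-model querying are ingested, not
  computed: alignments come as TSV, guesses as line-delimited JSON
  records of exactly ten ranked words (prompting protocol: ask the model
  for "10 guesses for the next word" given up to 100 words of preceding
  context, one call per word).
* First-order band filters trade stop-band rejection for phase fidelity
  and minimal ringing; band leakage is characterized, not removed.
* The guess-rank regressor uses the raw rank 1–11; any monotone
  transform can be substituted upstream of the function builder.
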
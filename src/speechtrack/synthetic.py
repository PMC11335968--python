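"""Synthetic stories, envelopes and EEG with known ground truth.

Every downstream stage (stimulus-function construction, backward mTRF
decoding, word-half tracking, permutation and mixed-model statistics) is
exercised on data from this module, where the generating kernels,
attention gain and predictability–envelope coupling are known exactly.

A synthetic story is a time-ordered word sequence with lognormal word
durations, ~12% of words followed by a pause of mean 0.69 s, Zipf-like
log10 frequencies, and next-word guess ranks drawn from a distribution
concentrated on rank 1 with about half the words unmatched (rank 11).
The broadband envelope is a quasi-periodic syllable pulse train near
4 Hz, exactly zero during pauses, so its modulation spectrum peaks in
the 4 Hz octave band like read speech.  EEG is the sum over measures of
the stimulus function convolved with a ground-truth response kernel per
channel, with target-talker contributions scaled by an attention gain,
envelope contributions within each word scaled by ``1 + kappa *
z(hardness)`` (hardness = standardized guess rank), plus spatially mixed
1/f^alpha Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .acoustic import compute_band_envelope, DELTA, THETA
from .decoder import EEGBlock, lag_samples, LAG_MIN_MS, LAG_MAX_MS
from .lexical import STIM_FS, StimulusFunction, WordToken, word_sample_slices

#: empirical guess-rank distribution of read magazine/news stories scored
#: against 10 ranked next-word guesses: P(rank 1..10) then P(unmatched)
DEFAULT_RANK_PROBS = np.array(
    [0.31, 0.06, 0.03, 0.02, 0.02, 0.01, 0.01, 0.01, 0.01, 0.01, 0.51]
)

#: shortest generated pause (s); at or above the boundary-filter threshold
#: so generated pauses survive boundary filtering by construction
MIN_GENERATED_PAUSE_S = 0.25


@dataclass
class StoryParams:
    """Generating parameters of a synthetic story.

    Word durations are lognormal (natural word-duration skew); a word is
    followed by a pause with probability ``pause_prob``, with pause
    durations shifted-exponential of mean ``pause_dur_mean_s`` starting at
    250 ms.  ``zipf_params`` = (mean, sd) of the Gaussian log10-frequency
    distribution; ``rank_probs`` gives P(guess rank = 1..11).
    """

    n_words: int = 200
    syllable_rate_hz: float = 4.0
    word_dur_log_mean: float = -0.9
    word_dur_log_sd: float = 0.35
    pause_prob: float = 0.12
    pause_dur_mean_s: float = 0.69
    rank_probs: np.ndarray = field(default_factory=lambda: DEFAULT_RANK_PROBS.copy())
    zipf_params: tuple[float, float] = (4.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.rank_probs = np.asarray(self.rank_probs, dtype=float)
        if self.n_words < 1:
            raise ValueError("n_words must be at least 1")
        if self.rank_probs.size != 11 or abs(self.rank_probs.sum() - 1.0) > 1e-9:
            raise ValueError("rank_probs must be an 11-vector summing to 1")
        if not 0 <= self.pause_prob <= 1:
            raise ValueError("pause_prob must lie in [0, 1]")
        if min(self.pause_dur_mean_s, self.syllable_rate_hz) <= 0:
            raise ValueError("durations and rates must be positive")
        if self.pause_dur_mean_s <= MIN_GENERATED_PAUSE_S:
            raise ValueError(
                f"pause_dur_mean_s must exceed {MIN_GENERATED_PAUSE_S}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of the forward model: per-channel response kernels
    over the decoder lag grid, attention gain on target contributions,
    predictability–envelope coupling ``kappa``, and 1/f^alpha noise."""

    trf_delta: np.ndarray
    trf_theta: np.ndarray
    trf_lexfreq: np.ndarray
    trf_lexpred: np.ndarray
    attention_gain: float = 1.0
    kappa: float = 0.0
    noise_sd: float = 1.0
    noise_exponent: float = 1.0
    seed: int = 0
    #: kernels of the ignored talker's responses; attended and ignored
    #: speech evoke distinct response patterns, which is what lets a
    #: backward model separate the two talkers at all
    distractor_kernels: dict | None = None

    def __post_init__(self) -> None:
        if self.attention_gain < 0:
            raise ValueError("attention_gain must be nonnegative")

    def kernel_for(self, measure: str, role: str = "target") -> np.ndarray:
        if role == "distractor" and self.distractor_kernels is not None:
            key = "delta_env" if measure == "broadband_env" else measure
            return self.distractor_kernels[key]
        return {
            "delta_env": self.trf_delta,
            "theta_env": self.trf_theta,
            "broadband_env": self.trf_delta,
            "lexfreq": self.trf_lexfreq,
            "lexpred": self.trf_lexpred,
        }[measure]


# ---------------------------------------------------------------------------
# stories
# ---------------------------------------------------------------------------

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def _pseudoword(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(1, 4))
    return "".join(
        rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        for _ in range(n_syll)
    )


def generate_story(params: StoryParams) -> list[WordToken]:
    """Draw a time-ordered, non-overlapping synthetic word sequence.

    Reproducible for a fixed ``params.seed``; each token carries a log10
    frequency drawn from ``zipf_params`` and a guess rank drawn from
    ``rank_probs``.
    """
    rng = np.random.default_rng(params.seed)
    tokens: list[WordToken] = []
    t = 0.0
    for i in range(params.n_words):
        dur = float(rng.lognormal(params.word_dur_log_mean, params.word_dur_log_sd))
        tokens.append(
            WordToken(
                index=i,
                word=_pseudoword(rng),
                onset_s=t,
                offset_s=t + dur,
                log_freq=float(rng.normal(*params.zipf_params)),
                pred_rank=int(rng.choice(11, p=params.rank_probs)) + 1,
            )
        )
        t += dur
        if rng.random() < params.pause_prob:
            t += MIN_GENERATED_PAUSE_S + float(
                rng.exponential(params.pause_dur_mean_s - MIN_GENERATED_PAUSE_S)
            )
    return tokens


def story_for_duration(
    params: StoryParams, duration_s: float
) -> list[WordToken]:
    """A story trimmed to the words that fit entirely within ``duration_s``."""
    mean_word = math.exp(params.word_dur_log_mean + params.word_dur_log_sd**2 / 2)
    per_word = mean_word + params.pause_prob * params.pause_dur_mean_s
    n_est = max(int(duration_s / per_word * 1.4) + 20, 1)
    p = StoryParams(**{**params.__dict__, "n_words": n_est})
    tokens = generate_story(p)
    return [t for t in tokens if t.offset_s <= duration_s]


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

def generate_envelope(
    tokens: list[WordToken],
    fs: float,
    seed: int = 0,
    syllable_rate_hz: float = 4.0,
    rate_jitter: float = 0.08,
    amp_range: tuple[float, float] = (0.6, 1.4),
    duration_s: float | None = None,
) -> np.ndarray:
    """Speech-like broadband amplitude envelope at ``fs``.

    Within each word the envelope is a raised-cosine syllable pulse train
    at a jittered rate near ``syllable_rate_hz`` with a random per-word
    amplitude; it is exactly zero during pauses and nonnegative
    everywhere, so its modulation spectrum peaks near the syllable rate.
    """
    if not tokens:
        raise ValueError("empty token sequence")
    if fs < 64:
        raise ValueError("fs must be at least 64 Hz")
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = tokens[-1].offset_s
    n = int(math.ceil(duration_s * fs))
    env = np.zeros(n)
    for tok, sl in word_sample_slices(tokens, fs, n):
        if sl.stop <= sl.start:
            continue
        f_w = syllable_rate_hz * (1.0 + rate_jitter * rng.standard_normal())
        amp = rng.uniform(*amp_range)
        t = np.arange(sl.start, sl.stop) / fs - tok.onset_s
        env[sl] = amp * 0.5 * (1.0 - np.cos(2.0 * math.pi * f_w * t))
    return env


def envelope_stimulus_functions(
    tokens: list[WordToken],
    fs_env: float = 128.0,
    seed: int = 0,
    duration_s: float | None = None,
    block_id: str = "",
) -> dict[str, StimulusFunction]:
    """Delta- and theta-band envelope functions at 32 Hz for one story."""
    env = generate_envelope(tokens, fs_env, seed=seed, duration_s=duration_s)
    return {
        band.name + "_env": compute_band_envelope(
            env, fs_env, band, input_is_envelope=True, block_id=block_id
        )
        for band in (DELTA, THETA)
    }


# ---------------------------------------------------------------------------
# ground-truth kernels
# ---------------------------------------------------------------------------

def _smooth_topography(rng: np.random.Generator, n_channels: int) -> np.ndarray:
    raw = rng.standard_normal(n_channels + 8)
    kern = np.hanning(9)
    topo = np.convolve(raw, kern / kern.sum(), mode="valid")
    return topo / np.linalg.norm(topo)


def _response_kernel(
    rng: np.random.Generator, n_channels: int, lags: np.ndarray, fs: float
) -> np.ndarray:
    """Hann-windowed damped sinusoid at a random causal latency, spread
    over channels by a smooth random topography (unit Frobenius norm)."""
    tau = lags / fs  # seconds
    t0 = rng.uniform(0.02, 0.25)
    width = rng.uniform(0.2, 0.35)
    f = rng.uniform(2.0, 6.0)
    g = np.zeros_like(tau)
    inside = (tau >= t0) & (tau <= t0 + width)
    phase = (tau[inside] - t0) / width
    g[inside] = np.sin(2 * math.pi * f * (tau[inside] - t0)) * 0.5 * (
        1 - np.cos(2 * math.pi * phase)
    )
    K = np.outer(_smooth_topography(rng, n_channels), g)
    norm = np.linalg.norm(K)
    return K / norm if norm > 0 else K


def make_default_truth(
    n_channels: int = 32,
    fs: float = STIM_FS,
    attention_gain: float = 1.0,
    kappa: float = 0.0,
    noise_sd: float = 1.0,
    noise_exponent: float = 1.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Ground truth with independent random kernels per measure, all with
    support inside the decoder lag window."""
    rng = np.random.default_rng(seed)
    lags = lag_samples(fs)
    kernels = [_response_kernel(rng, n_channels, lags, fs) for _ in range(4)]
    distractor = {
        m: _response_kernel(rng, n_channels, lags, fs)
        for m in ("delta_env", "theta_env", "lexfreq", "lexpred")
    }
    return SyntheticTruth(
        *kernels,
        distractor_kernels=distractor,
        attention_gain=attention_gain,
        kappa=kappa,
        noise_sd=noise_sd,
        noise_exponent=noise_exponent,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# EEG forward model
# ---------------------------------------------------------------------------

def _lag_convolve(stim: np.ndarray, kernel: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """EEG[ch, t] = sum_j kernel[ch, j] * stim[t - lag_j] (zero-padded)."""
    n = stim.size
    S = np.zeros((lags.size, n))
    for j, L in enumerate(lags):
        if L >= 0:
            S[j, L:] = stim[: n - L]
        else:
            S[j, : n + L] = stim[-L:]
    return kernel @ S


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n: int, alpha: float
) -> np.ndarray:
    """Unit-variance 1/f^alpha Gaussian noise, spatially mixed by smooth
    random topographies."""
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    sources = np.empty((n_channels, n))
    for ch in range(n_channels):
        spec = scale * (
            rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
        )
        sources[ch] = np.fft.irfft(spec, n)
    mix = np.stack([_smooth_topography(rng, n_channels) for _ in range(n_channels)], axis=1)
    noise = mix @ sources
    sd = noise.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return noise / sd


def hardness_modulation(
    tokens: list[WordToken], kappa: float, fs: float, n_samples: int
) -> np.ndarray:
    """Per-sample gain 1 + kappa * z(hardness) inside words, 1 elsewhere.

    Hardness is the word's guess rank standardized across the block's
    words, so less predictable words get a stronger envelope contribution.
    """
    gain = np.ones(n_samples)
    if kappa == 0 or not tokens:
        return gain
    ranks = np.array([t.pred_rank for t in tokens], dtype=float)
    sd = ranks.std()
    z = (ranks - ranks.mean()) / sd if sd > 0 else np.zeros_like(ranks)
    for (tok, sl), zi in zip(word_sample_slices(tokens, fs, n_samples), z):
        gain[sl] = 1.0 + kappa * zi
    return gain


def generate_eeg(
    target_stims: dict[str, StimulusFunction],
    distractor_stims: dict[str, StimulusFunction] | None,
    truth: SyntheticTruth,
    n_channels: int,
    fs: float = STIM_FS,
    target_tokens: list[WordToken] | None = None,
    block_id: str = "",
    seed: int | None = None,
) -> EEGBlock:
    """Simulate one EEG block from stimulus functions and ground truth.

    EEG is the sum over measures of stimulus ⊛ kernel; target
    contributions are scaled by ``attention_gain``; envelope measures of
    the target are additionally modulated within each word by
    ``1 + kappa * z(hardness)`` when target tokens are supplied; 1/f^alpha
    Gaussian noise of per-channel standard deviation ``noise_sd`` is added.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be at least 2")
    lengths = {len(sf) for sf in target_stims.values()}
    if distractor_stims:
        lengths |= {len(sf) for sf in distractor_stims.values()}
    if len(lengths) != 1:
        raise ValueError("all stimulus functions must share one length")
    n = lengths.pop()
    lags = lag_samples(fs)
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    eeg = np.zeros((n_channels, n))
    for measure, sf in target_stims.items():
        x = sf.values
        if measure.endswith("_env") and target_tokens is not None:
            x = x * hardness_modulation(target_tokens, truth.kappa, fs, n)
        kernel = truth.kernel_for(measure)[:n_channels]
        eeg += truth.attention_gain * _lag_convolve(x, kernel, lags)
    if distractor_stims:
        for measure, sf in distractor_stims.items():
            kernel = truth.kernel_for(measure, role="distractor")[:n_channels]
            eeg += _lag_convolve(sf.values, kernel, lags)
    if truth.noise_sd > 0:
        eeg = eeg + truth.noise_sd * _one_over_f_noise(
            rng, n_channels, n, truth.noise_exponent
        )
    return EEGBlock(eeg, fs, block_id=block_id)


# ---------------------------------------------------------------------------
# whole-subject simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedBlock:
    """One simulated two-talker block with its ground-truth inputs."""

    block_id: str
    target_tokens: list[WordToken]
    target_stims: dict[str, StimulusFunction]
    distractor_stims: dict[str, StimulusFunction]
    eeg: EEGBlock


def simulate_subject(
    truth: SyntheticTruth,
    n_blocks: int = 8,
    block_duration_s: float = 120.0,
    n_channels: int = 32,
    story_params: StoryParams | None = None,
    fs_env: float = 128.0,
    seed: int = 0,
) -> list[SimulatedBlock]:
    """Simulate a subject's recording: per block, independent target and
    distractor stories, their delta/theta envelope functions, and EEG from
    the forward model."""
    base = StoryParams() if story_params is None else story_params
    blocks = []
    for b in range(n_blocks):
        sp_t = StoryParams(**{**base.__dict__, "seed": seed * 10_000 + 2 * b})
        sp_d = StoryParams(**{**base.__dict__, "seed": seed * 10_000 + 2 * b + 1})
        tok_t = story_for_duration(sp_t, block_duration_s)
        tok_d = story_for_duration(sp_d, block_duration_s)
        stims_t = envelope_stimulus_functions(
            tok_t, fs_env, seed=sp_t.seed + 5_000_000,
            duration_s=block_duration_s, block_id=f"b{b}",
        )
        stims_d = envelope_stimulus_functions(
            tok_d, fs_env, seed=sp_d.seed + 5_000_000,
            duration_s=block_duration_s, block_id=f"b{b}",
        )
        eeg = generate_eeg(
            stims_t, stims_d, truth, n_channels,
            target_tokens=tok_t, block_id=f"b{b}",
            seed=seed * 10_000 + 7_000 + b,
        )
        blocks.append(SimulatedBlock(f"b{b}", tok_t, stims_t, stims_d, eeg))
    return blocks
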
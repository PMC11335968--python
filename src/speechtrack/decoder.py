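"""Backward (stimulus-reconstruction) mTRF decoding.

A ridge-regularized linear decoder maps multichannel EEG at lags between
−250 and 750 ms back onto a stimulus function (positive lag = neural
response *after* the stimulus sample being reconstructed).  Evaluation is
leave-one-block-out: the held-out block is reconstructed by a decoder
trained on the remaining blocks, with the ridge parameter chosen by an
inner cross-validation rotating a validation block through the training
set over a 16-value decade grid from 1e-3 to 1e12.  Decoder weights are
forward-projected through the data covariance into activation patterns
for interpretation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .acoustic import zero_phase_butter, _resample_to
from .lexical import STIM_FS

LAG_MIN_MS = -250.0
LAG_MAX_MS = 750.0

#: ridge parameter grid: decade steps 1e-3 .. 1e12 (16 values)
LAMBDA_GRID = tuple(10.0 ** k for k in range(-3, 13))


class InvalidWindowError(ValueError):
    """Lag span does not fit in the block."""


class InsufficientFoldsError(ValueError):
    """Too few blocks for the requested cross-validation."""


class DegenerateProjectionError(ValueError):
    """Forward projection is undefined (zero-variance reconstruction)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EEGBlock:
    """Multichannel EEG for one recording block (channels x samples)."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = ()
    block_id: str = ""
    flagged_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.channel_labels:
            self.channel_labels = tuple(f"CH{i:02d}" for i in range(self.data.shape[0]))
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class DecoderModel:
    """Backward model: ridge weights over (channel, lag) plus intercept."""

    weights: np.ndarray  # (n_channels, n_lags)
    lam: float
    intercept: float
    fs: float = STIM_FS
    lag_min_ms: float = LAG_MIN_MS
    lag_max_ms: float = LAG_MAX_MS

    @property
    def flat_weights(self) -> np.ndarray:
        """Channel-major, lag-minor flattening matching the lag matrix."""
        return self.weights.reshape(-1)

    def predict(self, design: np.ndarray) -> np.ndarray:
        return design @ self.flat_weights + self.intercept


@dataclass
class ForwardModel:
    """Activation pattern: decoder weights projected through the data
    covariance, scaled by the reconstruction variance (per-channel response
    patterns; same shape as the decoder weights)."""

    coefficients: np.ndarray  # (n_channels, n_lags)
    scale_note: str = "Cov(lagged EEG) @ w / Var(reconstruction)"


@dataclass
class DecodingResult:
    """Leave-one-out decoding output for one subject and measure."""

    r: np.ndarray  # per-block held-out Pearson r
    reconstructions: list[np.ndarray]
    lambdas: np.ndarray
    folds: list[dict] = field(default_factory=list)
    block_ids: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_block(
    raw: EEGBlock,
    hp_hz: float = 0.1,
    lp_hz: float = 8.0,
    fs_out: float = STIM_FS,
) -> EEGBlock:
    """Zero-phase first-order Butterworth band-limiting, decimation and
    per-channel z-normalization.

    Channels with zero variance are flagged, excluded from the
    normalization divide and emitted as zeros.
    """
    if raw.fs <= 2 * lp_hz:
        raise ValueError(f"raw fs={raw.fs} too low for lp_hz={lp_hz}")
    data = raw.data
    degenerate = data.std(axis=1) == 0
    out = np.empty((data.shape[0], int(math.ceil(data.shape[1] * fs_out / raw.fs))))
    for ch in range(data.shape[0]):
        x = zero_phase_butter(data[ch], raw.fs, hp_hz, "highpass")
        x = zero_phase_butter(x, raw.fs, lp_hz, "lowpass")
        x = _resample_to(x, raw.fs, fs_out)
        sd = x.std()
        if degenerate[ch] or sd == 0:
            out[ch] = 0.0
        else:
            out[ch] = (x - x.mean()) / sd
    flagged = tuple(
        lbl for lbl, bad in zip(raw.channel_labels, degenerate) if bad
    )
    return EEGBlock(out, fs_out, raw.channel_labels, raw.block_id, flagged)


# ---------------------------------------------------------------------------
# lag design matrix
# ---------------------------------------------------------------------------

def lag_samples(fs: float, lag_min_ms: float = LAG_MIN_MS,
                lag_max_ms: float = LAG_MAX_MS) -> np.ndarray:
    return np.arange(round(lag_min_ms / 1000 * fs), round(lag_max_ms / 1000 * fs) + 1)


def build_lag_matrix(
    eeg: EEGBlock,
    lag_min_ms: float = LAG_MIN_MS,
    lag_max_ms: float = LAG_MAX_MS,
) -> np.ndarray:
    """Time-lagged design matrix, channel-major / lag-minor columns.

    Row t stacks every channel at times t + tau over the lag grid;
    positive tau looks *forward* in the EEG (response after the stimulus
    sample being reconstructed).  Out-of-range samples are zero-padded.
    """
    lags = lag_samples(eeg.fs, lag_min_ms, lag_max_ms)
    n, nch, nlag = eeg.n_samples, eeg.n_channels, lags.size
    if nlag >= n:
        raise InvalidWindowError("lag span must be shorter than the block")
    X = np.zeros((n, nch, nlag))
    for j, L in enumerate(lags):
        if L >= 0:
            X[: n - L, :, j] = eeg.data[:, L:].T
        else:
            X[-L:, :, j] = eeg.data[:, : n + L].T
    return X.reshape(n, nch * nlag)


# ---------------------------------------------------------------------------
# ridge training
# ---------------------------------------------------------------------------

def train_decoder(
    design: np.ndarray,
    stimulus: np.ndarray,
    lam: float,
    n_channels: int | None = None,
) -> DecoderModel:
    """Ridge solution w = (X'X + lam I)^-1 X' s on column-centered data,
    with an unpenalized intercept recovered from the means."""
    X = np.asarray(design, dtype=float)
    s = np.asarray(stimulus, dtype=float)
    if X.shape[0] != s.shape[0]:
        raise ValueError("design and stimulus row counts differ")
    if not (np.isfinite(X).all() and np.isfinite(s).all()):
        raise ValueError("non-finite values in design or stimulus")
    if lam <= 0:
        raise ValueError("lam must be positive")
    mu = X.mean(axis=0)
    sbar = s.mean()
    Xc = X - mu
    G = Xc.T @ Xc
    G[np.diag_indices_from(G)] += lam
    w = np.linalg.solve(G, Xc.T @ (s - sbar))
    intercept = float(sbar - mu @ w)
    if n_channels is None:
        n_channels = 1
    return DecoderModel(w.reshape(n_channels, -1), lam, intercept)


# ---------------------------------------------------------------------------
# cross-validated lambda selection and leave-one-out decoding
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


class _BlockStats:
    """Sufficient statistics of one block's (design, stimulus) pair, so
    Gram matrices of block unions are sums, with exact re-centering."""

    def __init__(self, X: np.ndarray, s: np.ndarray):
        self.XtX = X.T @ X
        self.Xts = X.T @ s
        self.xsum = X.sum(axis=0)
        self.ssum = float(s.sum())
        self.n = X.shape[0]


def _centered_normal_eq(stats: list[_BlockStats]):
    n = sum(st.n for st in stats)
    xsum = sum(st.xsum for st in stats)
    ssum = sum(st.ssum for st in stats)
    mu = xsum / n
    sbar = ssum / n
    G = sum(st.XtX for st in stats) - n * np.outer(mu, mu)
    b = sum(st.Xts for st in stats) - n * mu * sbar
    return G, b, mu, sbar


def _ridge_path(stats: list[_BlockStats], lams) -> tuple[np.ndarray, np.ndarray, float]:
    """Weights for every lambda via one eigendecomposition of the centered
    Gram matrix.  Returns (W [n_lam x p], mu, sbar)."""
    G, b, mu, sbar = _centered_normal_eq(stats)
    evals, V = np.linalg.eigh(G)
    Vb = V.T @ b
    W = np.empty((len(lams), b.size))
    for i, lam in enumerate(lams):
        W[i] = V @ (Vb / (evals + lam))
    return W, mu, sbar


def select_lambda(
    training_blocks: list[tuple[np.ndarray, np.ndarray]],
    grid=LAMBDA_GRID,
) -> float:
    """Cross-validated ridge parameter within the training blocks.

    Each training block in turn serves as validation: for every lambda in
    the grid, a decoder is fit on the remaining blocks and the Pearson r
    of the validation reconstruction recorded.  Returns the grid value
    maximizing mean validation r (ties break to the smallest lambda).
    """
    if len(training_blocks) < 2:
        raise InsufficientFoldsError("need at least 2 training blocks")
    stats = [_BlockStats(X, s) for X, s in training_blocks]
    return _select_lambda_stats(stats, training_blocks, grid)


def _select_lambda_stats(stats, blocks, grid) -> float:
    grid = list(grid)
    if len(grid) == 1:
        return float(grid[0])
    mean_r = np.zeros(len(grid))
    for v in range(len(blocks)):
        train_stats = [st for i, st in enumerate(stats) if i != v]
        W, mu, sbar = _ridge_path(train_stats, grid)
        Xv, sv = blocks[v]
        pred = (Xv - mu) @ W.T  # columns: one prediction series per lambda
        for i in range(len(grid)):
            mean_r[i] += _pearson(pred[:, i], sv)
    mean_r /= len(blocks)
    return float(grid[int(np.argmax(mean_r))])


def decode_leave_one_out(
    eeg_blocks: list[EEGBlock],
    stim_blocks: list,
    lag_min_ms: float = LAG_MIN_MS,
    lag_max_ms: float = LAG_MAX_MS,
    grid=LAMBDA_GRID,
) -> DecodingResult:
    """Leave-one-block-out stimulus reconstruction.

    For each held-out block the ridge parameter is selected by rotating a
    validation block through the *remaining* blocks only, a decoder is
    trained on those blocks, and the held-out reconstruction is scored by
    Pearson correlation with the true stimulus function.
    """
    if len(eeg_blocks) < 3:
        raise InsufficientFoldsError("need at least 3 blocks for leave-one-out")
    if len(eeg_blocks) != len(stim_blocks):
        raise ValueError("block count mismatch between EEG and stimuli")
    stims = []
    for sf in stim_blocks:
        v = np.asarray(getattr(sf, "values", sf), dtype=float)
        stims.append(v)
    designs = []
    for eeg, s in zip(eeg_blocks, stims):
        if eeg.n_samples != s.size:
            raise ValueError(
                f"block {eeg.block_id!r}: EEG has {eeg.n_samples} samples "
                f"but stimulus has {s.size}"
            )
        designs.append(build_lag_matrix(eeg, lag_min_ms, lag_max_ms))
    stats = [_BlockStats(X, s) for X, s in zip(designs, stims)]

    nb = len(designs)
    rs = np.empty(nb)
    lambdas = np.empty(nb)
    recons: list[np.ndarray] = []
    folds = []
    for test in range(nb):
        train_idx = [i for i in range(nb) if i != test]
        lam = _select_lambda_stats(
            [stats[i] for i in train_idx],
            [(designs[i], stims[i]) for i in train_idx],
            grid,
        )
        W, mu, sbar = _ridge_path([stats[i] for i in train_idx], [lam])
        recon = (designs[test] - mu) @ W[0] + sbar
        recons.append(recon)
        rs[test] = _pearson(recon, stims[test])
        lambdas[test] = lam
        folds.append({"test": test, "train": tuple(train_idx)})
    return DecodingResult(
        rs, recons, lambdas, folds,
        tuple(b.block_id for b in eeg_blocks),
    )


# ---------------------------------------------------------------------------
# forward projection
# ---------------------------------------------------------------------------

def forward_project(
    model: DecoderModel,
    design: np.ndarray,
    reconstruction: np.ndarray,
) -> ForwardModel:
    """Transform decoder weights into an activation pattern.

    a = Cov(lagged EEG) @ w / Var(reconstruction), reshaped to
    (channel, lag).  Backward weights mix denoising with the response and
    are hard to read; the pattern expresses how each channel/lag covaries
    with the reconstructed source.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(reconstruction, dtype=float)
    var_y = float(np.var(y, ddof=1))
    if var_y <= 0:
        raise DegenerateProjectionError("zero-variance reconstruction")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    a = cov @ model.flat_weights / var_y
    return ForwardModel(a.reshape(model.weights.shape))
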
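"""Group-level statistics for neural tracking correlations.

Tracking strength is the Pearson correlation between a stimulus function
and its reconstruction from EEG, one observation per subject x block x
talker role x measure.  This module aggregates those observations into:

* word-half analyses — per-word correlations over the first and second
  temporal halves of each word, the substrate for testing whether
  acoustic tracking is stronger for lexically harder words;
* a group permutation null — the veridical across-subject mean compared
  with re-runs in which every subject's stimulus functions are re-paired
  with random length-matched segments from other blocks;
* linear mixed models with random intercepts for subject (and stimulus),
  factor chi-squares by likelihood-ratio model comparison on ML refits,
  and automatic dropping of nonsignificant nested terms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .lexical import STIM_FS, StimulusFunction, WordToken, word_sample_slices


class DegenerateCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance)."""


class EmptyAnalysisError(ValueError):
    """No eligible observations."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class TrackingRecord:
    """One tracking observation: the correlation between a stimulus
    function and its neural reconstruction for one subject and block."""

    subject: str
    block: str
    role: str  # "target" | "distractor"
    measure: str
    r: float
    language: str | None = None
    task: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r) and abs(self.r) <= 1):
            raise ValueError("r must be finite with |r| <= 1")


@dataclass
class WordHalfRecord:
    """Tracking correlation over one half of one word."""

    word_index: int
    half: int  # 1 | 2
    r: float
    duration_s: float
    pred_rank: int | None
    log_freq: float | None
    n_samples: int


def tracking_table(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _values(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def block_correlation(stimulus, reconstruction) -> float:
    """Pearson correlation between a stimulus function and its
    reconstruction (the tracking strength for one block)."""
    s, y = _values(stimulus), _values(reconstruction)
    if s.size != y.size:
        raise ValueError("length mismatch")
    sc, yc = s - s.mean(), y - y.mean()
    denom = math.sqrt((sc @ sc) * (yc @ yc))
    if denom == 0:
        raise DegenerateCorrelationError("zero variance")
    return float(sc @ yc / denom)


#: minimum samples per word half for a correlation to be emitted
MIN_HALF_SAMPLES = 3


def wordhalf_correlations(
    stimulus,
    reconstruction,
    tokens: list[WordToken],
    fs: float = STIM_FS,
    min_samples: int = MIN_HALF_SAMPLES,
) -> tuple[list[WordHalfRecord], int]:
    """Per-word tracking correlations over each word's two temporal halves.

    Each word is split at its sample midpoint (first half takes the extra
    sample for odd counts); halves with fewer than ``min_samples`` samples
    or zero variance on either side are excluded and counted.  Returns
    ``(records, n_excluded_halves)``.
    """
    s, y = _values(stimulus), _values(reconstruction)
    if s.size != y.size:
        raise ValueError("length mismatch")
    records: list[WordHalfRecord] = []
    n_excluded = 0
    for tok, sl in word_sample_slices(tokens, fs, s.size):
        n = sl.stop - sl.start
        if n <= 0:
            continue
        n1 = n - n // 2  # first half takes the extra sample
        halves = (
            (1, slice(sl.start, sl.start + n1)),
            (2, slice(sl.start + n1, sl.stop)),
        )
        for half, hsl in halves:
            ns = hsl.stop - hsl.start
            if ns < min_samples:
                n_excluded += 1
                continue
            sh, yh = s[hsl], y[hsl]
            if sh.std() == 0 or yh.std() == 0:
                n_excluded += 1
                continue
            r = float(np.corrcoef(sh, yh)[0, 1])
            records.append(
                WordHalfRecord(
                    tok.index, half, r, tok.duration_s,
                    tok.pred_rank, tok.log_freq, ns,
                )
            )
    if not records:
        raise EmptyAnalysisError("no eligible word halves")
    return records, n_excluded


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Group permutation outcome: the fraction of randomizations whose
    across-subject mean correlation falls below the veridical mean."""

    veridical_mean: float
    null_means: np.ndarray
    exceedance: float  # fraction of null means below the veridical mean

    @property
    def exceedance_percent(self) -> float:
        return 100.0 * self.exceedance


def _default_resampler(rng, subject_blocks, block_index, length) -> np.ndarray:
    """A length-matched stimulus segment from a uniformly chosen *other*
    block of the same subject, starting anywhere (circularly wrapped)."""
    others = [i for i in range(len(subject_blocks)) if i != block_index]
    if not others:
        others = [block_index]
    src = _values(subject_blocks[int(rng.choice(others))][1])
    start = int(rng.integers(src.size))
    idx = (start + np.arange(length)) % src.size
    return src[idx]


def permutation_group_test(
    subjects: list[list[tuple[np.ndarray, np.ndarray]]],
    n_perm: int = 100,
    seed: int | None = None,
    resampler=None,
) -> PermutationResult:
    """Compare veridical group tracking with random stimulus pairings.

    ``subjects`` holds per subject a list of ``(reconstruction, stimulus)``
    block pairs.  For each of ``n_perm`` randomizations every subject's
    reconstructions are re-paired with random length-matched stimulus
    segments from other blocks and the across-subject mean correlation
    recorded; tracking is above chance at the group level when the
    veridical mean exceeds (nearly) all randomizations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    if resampler is None:
        resampler = _default_resampler
    rng = np.random.default_rng(seed)

    subj_means = [
        np.mean([block_correlation(stim, recon) for recon, stim in blocks])
        for blocks in subjects
    ]
    veridical = float(np.mean(subj_means))

    null_means = np.empty(n_perm)
    for p in range(n_perm):
        subj_null = []
        for blocks in subjects:
            rs = []
            for b, (recon, _stim) in enumerate(blocks):
                recon_v = _values(recon)
                seg = resampler(rng, blocks, b, recon_v.size)
                rs.append(block_correlation(seg, recon_v))
            subj_null.append(np.mean(rs))
        null_means[p] = np.mean(subj_null)
    exceedance = float(np.mean(null_means < veridical))
    return PermutationResult(veridical, null_means, exceedance)


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    """Effect table and bookkeeping of a mixed-model analysis."""

    effects: pd.DataFrame  # term, chi2, df, p
    params: pd.Series
    dropped_terms: list[str] = field(default_factory=list)
    dropped_random: list[str] = field(default_factory=list)
    fit: object | None = None


def _term_factors(term: str) -> frozenset:
    return frozenset(term.split(":"))


def _strictly_contains(u: str, t: str) -> bool:
    return u != t and _term_factors(t) < _term_factors(u)


def _fit_lmm(df, response, terms, random_intercepts, reml):
    rhs = " + ".join(terms) if terms else "1"
    formula = f"{response} ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(random_intercepts) <= 1:
            group = random_intercepts[0] if random_intercepts else None
            if group is None:
                raise ValueError("at least one random intercept is required")
            model = smf.mixedlm(formula, df, groups=df[group], re_formula="1")
        else:
            vc = {g: f"0 + C({g})" for g in random_intercepts}
            model = smf.mixedlm(
                formula, df,
                groups=pd.Series(np.zeros(len(df)), index=df.index),
                vc_formula=vc, re_formula="0",
            )
        last_err: Exception | None = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                return model.fit(reml=reml, method=method, maxiter=200)
            except np.linalg.LinAlgError as err:  # optimizer-path dependent
                last_err = err
        raise last_err


def _lrt_chi2(df, response, terms, term, random_intercepts):
    """Type-II likelihood-ratio test of one term on ML refits: the base
    model excludes every term containing the tested term."""
    base = [t for t in terms if not _strictly_contains(t, term)]
    reduced = [t for t in base if t != term]
    full_fit = _fit_lmm(df, response, base, random_intercepts, reml=False)
    red_fit = _fit_lmm(df, response, reduced, random_intercepts, reml=False)
    chi2 = max(0.0, 2.0 * (full_fit.llf - red_fit.llf))
    dof = max(1, full_fit.model.exog.shape[1] - red_fit.model.exog.shape[1])
    from scipy.stats import chi2 as chi2_dist

    return chi2, dof, float(chi2_dist.sf(chi2, dof))


def _stimulus_variance_singular(fit, random_intercepts) -> bool:
    if "stimulus" not in random_intercepts or len(random_intercepts) <= 1:
        return False
    try:
        names = list(fit.model.exog_vc.names)
        vcomp = dict(zip(names, np.atleast_1d(fit.vcomp)))
        # near-boundary estimate: negligible against the residual variance
        return vcomp.get("stimulus", np.inf) < 0.05 * fit.scale
    except Exception:
        return False


def fit_mixed_model(
    table: pd.DataFrame,
    fixed: list[str],
    random_intercepts=("subject",),
    covariates=(),
    response: str = "r",
    alpha: float = 0.05,
    drop_nonsignificant_nested: bool = True,
) -> MixedModelResult:
    """Mixed-effects analysis of tracking correlations.

    Fits ``response ~ fixed + covariates`` with random intercepts for
    subject (and optionally stimulus), REML for the final estimates and
    likelihood-ratio chi-squares on ML refits for each factor.
    Nonsignificant nested (interaction) terms are dropped by model
    comparison at ``alpha``.  If the stimulus random-intercept variance is
    singular (estimated at zero) the model is refit without it and the
    drop is flagged.
    """
    df = table.reset_index(drop=True)
    random_intercepts = list(random_intercepts)
    terms = list(fixed) + list(covariates)
    for t in {f for term in terms for f in _term_factors(term)}:
        if t not in df.columns:
            raise ValueError(f"missing column {t!r}")
        if df[t].dtype == object and df[t].nunique() < 2 and t in fixed:
            raise ValueError(f"factor {t!r} needs at least 2 levels")

    dropped_random: list[str] = []
    fit = _fit_lmm(df, response, terms, random_intercepts, reml=True)
    if _stimulus_variance_singular(fit, random_intercepts):
        random_intercepts = [g for g in random_intercepts if g != "stimulus"]
        dropped_random.append("stimulus")
        warnings.warn(
            "stimulus random-intercept variance singular; refit without it",
            RuntimeWarning,
        )
        fit = _fit_lmm(df, response, terms, random_intercepts, reml=True)

    def effect_table(cur_terms):
        rows = []
        for term in cur_terms:
            chi2, dof, p = _lrt_chi2(df, response, cur_terms, term, random_intercepts)
            rows.append({"term": term, "chi2": chi2, "df": dof, "p": p})
        return pd.DataFrame(rows)

    dropped_terms: list[str] = []
    effects = effect_table(terms)
    if drop_nonsignificant_nested:
        while True:
            nested = effects[effects.term.str.contains(":")]
            # only drop interactions not contained in a surviving higher-order term
            droppable = [
                row for _, row in nested.iterrows()
                if row.p > alpha
                and not any(_strictly_contains(u, row.term) for u in effects.term)
            ]
            if not droppable:
                break
            worst = max(droppable, key=lambda r: r.p)
            dropped_terms.append(worst.term)
            terms = [t for t in terms if t != worst.term]
            effects = effect_table(terms)
        fit = _fit_lmm(df, response, terms, random_intercepts, reml=True)

    return MixedModelResult(
        effects, fit.params, dropped_terms, dropped_random, fit
    )
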
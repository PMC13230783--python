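"""Reference-set benchmarking statistics for binary PPI assays.

Recovery rates are fractions of successfully tested pairs scored positive,
with Bayesian credible intervals from a binomial likelihood under a uniform
prior: the central 68.27% interval of Beta(p+1, n+1). Quantitative assays
(GPCA relative light units, MAPPIT fold-induction ratios) are called
positive against a threshold set by the highest-scoring random-reference
pair in the same experiment, so that by construction no random pair is
positive. Dataset recoveries are compared with Fisher's exact test.

Also here: the binned and sliding-window rules that derive confidence-score
thresholds from test outcomes, balanced (class-corrected) precision–recall
curves, and the SWIM score used to prioritize candidate interacting pairs
from pooled-well sequencing read counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssayOutcome",
    "RecoveryEstimate",
    "credible_interval",
    "recovery_estimate",
    "call_from_scores",
    "mappit_score",
    "fisher_exact_2x2",
    "compare_recovery",
    "weighted_control_rate",
    "binned_threshold",
    "sliding_window_threshold",
    "balanced_pr_curve",
    "swim_score",
]


@dataclass
class AssayOutcome:
    """One tested pair in one assay experiment.

    ``score`` is the assay's quantitative readout (RLU for GPCA,
    fold-induction ratio for MAPPIT); ``call`` is positive/negative once
    decided, or None while untested/uncalled.
    """

    pair: tuple[str, str]
    dataset: str
    score: float | None = None
    call: str | None = None


@dataclass
class RecoveryEstimate:
    """Recovery rate p/(p+n) with its 68.27% credible interval."""

    positives: int
    negatives: int
    rate: float
    ci_low: float
    ci_high: float


def credible_interval(p: int, n: int, mass: float = 0.6827) -> tuple[float, float]:
    """Central credible interval of Beta(p+1, n+1).

    Binomial likelihood with a uniform prior; quantiles at (1−mass)/2 and
    1−(1−mass)/2. For p = n = 0 this is the central interval of the uniform
    distribution.
    """
    if p < 0 or n < 0:
        raise ValueError("counts must be non-negative")
    lo = (1.0 - mass) / 2.0
    dist = stats.beta(p + 1, n + 1)
    return float(dist.ppf(lo)), float(dist.ppf(1.0 - lo))


def recovery_estimate(p: int, n: int, mass: float = 0.6827) -> RecoveryEstimate:
    if p + n == 0:
        raise ValueError("no successfully tested pairs")
    lo, hi = credible_interval(p, n, mass)
    return RecoveryEstimate(positives=p, negatives=n, rate=p / (p + n), ci_low=lo, ci_high=hi)


def call_from_scores(outcomes, rrs_outcomes) -> list[AssayOutcome]:
    """Score pairs positive/negative against the top random-reference score.

    The threshold is the highest valid score among the random-reference
    (RRS) outcomes; a test pair is positive iff its score strictly exceeds
    it (the top RRS pair itself is negative). Pairs without valid
    quantitative scores are dropped.
    """
    rrs_scores = [o.score for o in rrs_outcomes if o.score is not None and math.isfinite(o.score)]
    if not rrs_scores:
        raise ValueError("no valid RRS scores: threshold is undefined")
    threshold = max(rrs_scores)
    called = []
    for o in outcomes:
        if o.score is None or not math.isfinite(o.score):
            continue
        called.append(
            AssayOutcome(
                pair=o.pair,
                dataset=o.dataset,
                score=o.score,
                call="positive" if o.score > threshold else "negative",
            )
        )
    return called


def mappit_score(pair_fold: float, control_folds: tuple[float, float]) -> float:
    """Pair fold-induction divided by the maximum of the two negative
    controls' fold-induction values."""
    if min(control_folds) <= 0:
        raise ValueError("control fold-induction values must be positive")
    return pair_fold / max(control_folds)


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value on a 2×2 table [[a, b], [c, d]].

    Computed by summing the conditional hypergeometric pmf directly
    (two-sided: all tables with probability ≤ the observed one, the standard
    definition). Equivalent to scipy.stats.fisher_exact but fast enough for
    exhaustive sweeps. ``alternative``: "two-sided", "less" or "greater"
    refer to the first row's rate.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        logger.info("fisher_exact_2x2: all-zero table, p = 1 by convention")
        return 1.0
    row1, col1 = a + b, a + c
    k = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(k, n, col1, row1)
    p_obs = pmf[np.searchsorted(k, a)]
    if alternative == "two-sided":
        # relative tolerance guards against floating-point ties
        p = pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()
    elif alternative == "less":
        p = pmf[k <= a].sum()
    elif alternative == "greater":
        p = pmf[k >= a].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, 1.0))


def compare_recovery(a: RecoveryEstimate, b: RecoveryEstimate, sided: str = "two") -> float:
    """Fisher's exact test on [[p_a, n_a], [p_b, n_b]].

    ``sided``: "two" for the usual dataset-vs-dataset comparison; "one"
    tests whether a's recovery is *lower* than b's (the convention when
    testing a dataset against the positive control).
    """
    table = [[a.positives, a.negatives], [b.positives, b.negatives]]
    alternative = {"two": "two-sided", "one": "less"}[sided]
    return fisher_exact_2x2(table, alternative=alternative)


def weighted_control_rate(experiments) -> float:
    """Weighted average of per-experiment control recovery rates.

    ``experiments`` is a list of (RecoveryEstimate, weight); weights are
    typically the number of positive test pairs per experiment.
    """
    rates = np.array([est.rate for est, _ in experiments], dtype=float)
    weights = np.array([w for _, w in experiments], dtype=float)
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("weights must be non-negative with positive total")
    return float((rates * weights).sum() / weights.sum())


def binned_threshold(
    bin_results,
    control: RecoveryEstimate,
    alpha: float = 0.05,
    first_bin_rule: bool = False,
):
    """Score cutoff from binned test results: the start of the first bin
    whose positive rate is not significantly lower than the control's
    (one-sided Fisher, p ≥ alpha).

    With non-monotone bins "first non-significant bin" is ambiguous; by
    default the chosen bin and every later (higher-score) bin must be
    non-significant. ``first_bin_rule=True`` applies the literal first-bin
    reading. Returns None when no bin qualifies.
    """
    if not bin_results:
        raise ValueError("no bins supplied")
    non_sig = [
        compare_recovery(est, control, sided="one") >= alpha for _, est in bin_results
    ]
    for i, (start, _) in enumerate(bin_results):
        if non_sig[i] and (first_bin_rule or all(non_sig[i:])):
            return start
    return None


def sliding_window_threshold(scored_pairs, control_rate_low: float, window: int = 250):
    """Score threshold from a sliding window over score-sorted test pairs.

    Pairs are sorted by score descending (ties kept in stable input order);
    windows are contiguous runs of ``window`` successfully tested pairs
    stepping one rank at a time. The threshold is the low end (minimum
    score) of the lowest-score window whose unweighted positive rate is not
    below ``control_rate_low``. Returns None when no window qualifies.
    """
    pairs = [(s, c) for s, c in scored_pairs]
    if len(pairs) < window:
        raise ValueError(
            f"only {len(pairs)} pairs for window size {window}; use a smaller window"
        )
    order = sorted(range(len(pairs)), key=lambda i: -pairs[i][0])
    scores = np.array([pairs[i][0] for i in order], dtype=float)
    calls = np.array([pairs[i][1] == "positive" for i in order], dtype=float)
    cumsum = np.concatenate([[0.0], np.cumsum(calls)])
    best = None
    for start in range(len(pairs) - window + 1):
        rate = (cumsum[start + window] - cumsum[start]) / window
        if rate >= control_rate_low:
            low_end = scores[start + window - 1]
            best = low_end if best is None else min(best, low_end)
    return best


def balanced_pr_curve(prs_scores, rrs_scores):
    """Monotonized balanced precision–recall curve over all score thresholds.

    At threshold t: recall (= TPR) is the fraction of positive-reference
    scores ≥ t; balanced precision is TPR/(TPR+FPR), correcting precision to
    a balanced class mix. Precision is monotonized by a running maximum from
    the high-threshold (low-recall) end. Returns an array of rows
    (threshold, recall, balanced_precision).
    """
    prs = np.asarray(list(prs_scores), dtype=float)
    rrs = np.asarray(list(rrs_scores), dtype=float)
    if prs.size == 0 or rrs.size == 0:
        raise ValueError("both score lists must be non-empty")
    thresholds = np.unique(np.concatenate([prs, rrs]))[::-1]
    rows = []
    best_precision = 0.0
    for t in thresholds:
        tpr = (prs >= t).mean()
        fpr = (rrs >= t).mean()
        if tpr + fpr == 0:
            continue
        best_precision = max(best_precision, tpr / (tpr + fpr))
        rows.append((t, tpr, best_precision))
    return np.array(rows)


def swim_score(x: int, y: int, a: int, d: int, M: float, N: float) -> float:
    """Shared-well interaction mapping score S = 2 / ((a+M)/x + (d+N)/y).

    x, y: AD-ORF and DB-ORF read counts in a well; a, d: total aligned AD
    and DB reads in that well; M, N: per-batch pseudo-counts. A pair
    unobserved on either side (x or y zero) scores 0.
    """
    if x < 0 or y < 0 or M < 0 or N < 0:
        raise ValueError("read counts and pseudo-counts must be non-negative")
    if a < x or d < y:
        raise ValueError("well totals cannot be smaller than the pair's read counts")
    if x == 0 or y == 0:
        logger.info("swim_score: pair unobserved on one side, score 0")
        return 0.0
    return 2.0 / ((a + M) / x + (d + N) / y)
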
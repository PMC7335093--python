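"""Outcome prediction from fiber weight maps.

A stimulation's aggregate score is the sum of the t-values of all valid
fibers connected to it, divided by the stimulation amplitude (larger
stimulation fields recruit more fibers mechanically; normalizing by
amplitude removes that size advantage). The score is correlated with
clinical improvement; inference uses Monte-Carlo permutation of the
outcome vector, which is the exchangeable quantity under the null that
outcomes are independent of stimulation geometry — distribution-free, and
honest at the small sample sizes typical of surgical cohorts.

Cross-cohort prediction fits the fiber model on one cohort only and
evaluates scores and the permutation test on the other; nothing from the
test cohort touches the fitted weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .connectivity import IncidenceMatrix
from .fiber_stats import FiberScoreModel, fit_fiber_scores
from .formats import CohortTable

__all__ = [
    "AggregateScores",
    "PredictionResult",
    "aggregate_scores",
    "correlate",
    "permutation_p",
    "cross_predict",
    "low_high_comparison",
]


@dataclass
class AggregateScores:
    """Per-stimulation aggregated fiber t-scores."""

    stim_ids: list[str]
    score: np.ndarray  # amplitude-normalized
    raw_sum: np.ndarray  # pre-normalization sum of connected valid t-values

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=np.float64)
        self.raw_sum = np.asarray(self.raw_sum, dtype=np.float64)
        if not (len(self.stim_ids) == len(self.score) == len(self.raw_sum)):
            raise ValueError("field lengths disagree")
        if not np.all(np.isfinite(self.score)):
            raise ValueError("scores must be finite")


@dataclass
class PredictionResult:
    """Correlation between aggregate scores and improvements, with permutation p."""

    r: float
    p_perm: float
    n_perm: int
    method: str
    seed: int
    scores: AggregateScores
    improvements: np.ndarray
    alternative: str = "two-sided"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "r": self.r,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
            "method": self.method,
            "seed": self.seed,
            "alternative": self.alternative,
            "stim_ids": self.scores.stim_ids,
            "score": self.scores.score.tolist(),
            "raw_sum": self.scores.raw_sum.tolist(),
            "improvement_pct": np.asarray(self.improvements).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def aggregate_scores(
    inc: IncidenceMatrix, model: FiberScoreModel, cohort: CohortTable
) -> AggregateScores:
    """Sum connected valid fiber t-values per stimulation, normalize by amplitude.

    For records stimulating several electrodes the incidence already
    OR-combines the volumes, so the sum runs over the union of connected
    fibers; the normalizing amplitude is the record's total (summed)
    amplitude.
    """
    if not np.array_equal(inc.fiber_ids, model.fiber_ids):
        raise ValueError("incidence and model fiber orders differ")
    if inc.stim_ids != cohort.stim_ids:
        raise ValueError("incidence and cohort stimulation orders differ")
    amplitudes = cohort.amplitudes
    bad = np.nonzero(amplitudes <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive amplitude for stimulation {cohort.stim_ids[bad[0]]!r}")
    raw = inc.entries.T.astype(np.float64) @ model.effective_weights()
    return AggregateScores(cohort.stim_ids, raw / amplitudes, raw)


def correlate(scores: AggregateScores | np.ndarray, improvements: np.ndarray, method: str = "pearson") -> float:
    """Pearson or Spearman correlation between scores and improvements."""
    x = scores.score if isinstance(scores, AggregateScores) else np.asarray(scores, dtype=np.float64)
    y = np.asarray(improvements, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("scores and improvements have different lengths")
    if len(x) < 3:
        raise ValueError("need at least 3 observations to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def _perm_correlations(x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator, method: str) -> np.ndarray:
    """Correlations of x with n_perm row-wise permutations of y, vectorized.

    Permutation does not change either marginal, so standard deviations are
    computed once and only the cross term varies.
    """
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    xc = x - x.mean()
    pc = perms - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(y - y.mean())
    return (pc @ xc) / denom


def permutation_p(
    scores: AggregateScores | np.ndarray,
    improvements: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "pearson",
    alternative: str = "two-sided",
) -> PredictionResult:
    """Monte-Carlo permutation p-value for the score/improvement correlation.

    The improvement vector is permuted ``n_perm`` times with a generator
    seeded by ``seed``; the p-value uses the add-one estimator
    ``(1 + #extreme) / (n_perm + 1)``, which is never zero and has
    resolution 1/(n_perm + 1). ``alternative`` is ``two-sided`` (default),
    ``greater`` or ``less``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = scores.score if isinstance(scores, AggregateScores) else np.asarray(scores, dtype=np.float64)
    y = np.asarray(improvements, dtype=np.float64)
    r_obs = correlate(x, y, method)
    rng = np.random.default_rng(seed)
    r_perm = _perm_correlations(x, y, n_perm, rng, method)
    if alternative == "two-sided":
        extreme = np.abs(r_perm) >= abs(r_obs)
    elif alternative == "greater":
        extreme = r_perm >= r_obs
    else:
        extreme = r_perm <= r_obs
    p = (1.0 + int(extreme.sum())) / (n_perm + 1.0)
    if isinstance(scores, AggregateScores):
        agg = scores
    else:
        agg = AggregateScores([str(i) for i in range(len(x))], x, x)
    return PredictionResult(r_obs, p, n_perm, method, seed, agg, y, alternative)


def cross_predict(
    train: tuple[IncidenceMatrix, CohortTable],
    test: tuple[IncidenceMatrix, CohortTable],
    min_per_group: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "pearson",
    alternative: str = "two-sided",
) -> PredictionResult:
    """Fit the fiber model on the training cohort, evaluate on the test cohort.

    Both incidence matrices must be indexed against the same tractogram
    fiber order; the fitted weights see training improvements only.
    """
    inc_train, cohort_train = train
    inc_test, cohort_test = test
    if not np.array_equal(inc_train.fiber_ids, inc_test.fiber_ids):
        raise ValueError("train and test incidence matrices index different fiber orders")
    model = fit_fiber_scores(inc_train, cohort_train.improvements, min_per_group)
    agg = aggregate_scores(inc_test, model, cohort_test)
    return permutation_p(agg, cohort_test.improvements, n_perm, seed, method, alternative)


def low_high_comparison(
    result: PredictionResult, cutoff: float
) -> tuple[float, float, tuple[int, int]]:
    """Two-sample t-test of improvements: low-scoring vs high-scoring stimulations.

    Splits stimulations at ``score < cutoff`` vs ``score >= cutoff`` and
    compares their improvements with a pooled-variance Student t and a
    classical (non-permutation) p-value. The sign convention is low minus
    high: stimulations barely touching the predictive tract doing worse
    yields a negative t.

    Returns ``(t, p, (n_low, n_high))``.
    """
    x = result.scores.score
    y = np.asarray(result.improvements, dtype=np.float64)
    low = x < cutoff
    if not low.any() or low.all():
        lo, hi = float(x.min()), float(x.max())
        raise ValueError(
            f"cutoff {cutoff} leaves one group empty; choose a value in ({lo}, {hi}]"
        )
    res = stats.ttest_ind(y[low], y[~low], equal_var=True)
    return float(res.statistic), float(res.pvalue), (int(low.sum()), int((~low).sum()))
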
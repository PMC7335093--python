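"""Reference synthetic experiments.

Canned end-to-end runs of the pipeline on the default planted-bundle
conditions (200 planted + 2,000 background fibers, two cohorts of 20
spherical stimulations, outcome = 60 * overlap + N(0, 10)). These are the
package's benchmark settings: the in-sample analysis, the two-cohort
cross-prediction replicate, and the null calibration all build on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthetic
from .connectivity import IncidenceMatrix, compute_incidence
from .fiber_stats import FiberScoreModel, fit_fiber_scores
from .formats import CohortTable, Tractogram
from .prediction import PredictionResult, aggregate_scores, correlate, cross_predict, permutation_p

__all__ = ["InSampleRun", "run_insample", "run_cross_replicate", "ranking_auc"]


@dataclass
class InSampleRun:
    connectome: Tractogram
    is_planted: np.ndarray
    cohort: CohortTable
    incidence: IncidenceMatrix
    model: FiberScoreModel
    r: float


def ranking_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve of ``scores`` ranking ``labels`` (bool).

    Mann-Whitney formulation with midranks, so ties (e.g. many invalid
    fibers at weight 0) count half.
    """
    from scipy.stats import rankdata

    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _build(seed: int, n_planted: int = 200, n_background: int = 2000,
           n_stims: int = 20):
    grid = synthetic.default_grid()
    connectome, is_planted = synthetic.default_connectome(n_planted, n_background, seed=seed)
    bundle = Tractogram(list(connectome)[:n_planted], space_tag=synthetic.SPACE_TAG)
    spec_a, spec_b = synthetic.default_cohort_specs(seed_a=seed, seed_b=seed + 1)
    spec_a.n_stims = spec_b.n_stims = n_stims
    cohort_a, _ = synthetic.make_cohort(spec_a, bundle, grid)
    cohort_b, _ = synthetic.make_cohort(spec_b, bundle, grid)
    return connectome, is_planted, cohort_a, cohort_b


def run_insample(seed: int = 1, n_planted: int = 200, n_background: int = 2000,
                 n_stims: int = 20) -> InSampleRun:
    """Default experiment: fit and evaluate on one cohort."""
    connectome, is_planted, cohort, _ = _build(seed, n_planted, n_background, n_stims)
    inc = compute_incidence(connectome, cohort)
    model = fit_fiber_scores(inc, cohort.improvements)
    agg = aggregate_scores(inc, model, cohort)
    r = correlate(agg, cohort.improvements)
    return InSampleRun(connectome, is_planted, cohort, inc, model, r)


def run_cross_replicate(
    seed: int, n_perm: int = 1000, shuffle_test: bool = False
) -> PredictionResult:
    """One two-cohort cross-prediction replicate.

    Cohort A (dorsal placements) trains the fiber model; cohort B (lateral
    placements) is scored and permutation-tested. With ``shuffle_test`` the
    test outcomes are randomly shuffled first (null behaviour check).
    """
    connectome, _, cohort_a, cohort_b = _build(seed)
    inc_a = compute_incidence(connectome, cohort_a)
    inc_b = compute_incidence(connectome, cohort_b)
    if shuffle_test:
        rng = np.random.default_rng(seed + 500_000)
        shuffled = rng.permutation(cohort_b.improvements)
        model = fit_fiber_scores(inc_a, cohort_a.improvements)
        agg = aggregate_scores(inc_b, model, cohort_b)
        return permutation_p(agg, shuffled, n_perm=n_perm, seed=seed)
    return cross_predict((inc_a, cohort_a), (inc_b, cohort_b), n_perm=n_perm, seed=seed)
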
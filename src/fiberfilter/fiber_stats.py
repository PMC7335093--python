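"""Mass-univariate fiber t-scores.

Each streamline receives the pooled-variance two-sample Student t
statistic contrasting the clinical improvements of stimulations connected
to it against those of unconnected stimulations (connected minus
unconnected in the numerator, so fibers preferentially connected to good
responders score positive). These t-values are predictive weights, not
hypothesis tests: with hundreds of thousands of fibers no per-fiber
significance is meaningful, so no p-values or multiplicity correction are
computed — the signed weight map itself is the model carried to new
cohorts.

Fibers whose connected or unconnected group is smaller than
``min_per_group`` (or whose pooled variance is zero) cannot support a t
statistic; they are flagged invalid and carry weight 0 everywhere
downstream, keeping fiber indexing stable across cohorts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import IncidenceMatrix

__all__ = ["FiberScoreModel", "fit_fiber_scores", "count_signed", "top_fraction"]


@dataclass
class FiberScoreModel:
    """Per-fiber signed t-values with validity flags."""

    fiber_ids: np.ndarray  # (F,) int64
    t_values: np.ndarray  # (F,) float64; 0 for invalid fibers
    n_connected: np.ndarray  # (F,) int64
    valid: np.ndarray  # (F,) bool
    min_per_group: int
    n_stims: int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.fiber_ids = np.asarray(self.fiber_ids, dtype=np.int64)
        self.t_values = np.asarray(self.t_values, dtype=np.float64)
        self.n_connected = np.asarray(self.n_connected, dtype=np.int64)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.fiber_ids)
        if not (len(self.t_values) == len(self.n_connected) == len(self.valid) == n):
            raise ValueError("field lengths disagree")
        if not np.all(np.isfinite(self.t_values[self.valid])):
            raise ValueError("valid fibers must carry finite t-values")
        if np.any(self.t_values[~self.valid] != 0):
            raise ValueError("invalid fibers must carry t-value 0")

    @property
    def n_fibers(self) -> int:
        return len(self.fiber_ids)

    def effective_weights(self) -> np.ndarray:
        """t-values with invalid fibers zeroed (what aggregation consumes)."""
        return np.where(self.valid, self.t_values, 0.0)

    # -- persistence: TSV of per-fiber rows + JSON header, so a model fitted
    # on one cohort re-applies to another bit-identically.

    def save(self, tsv_path: str | Path) -> None:
        tsv_path = Path(tsv_path)
        pd.DataFrame(
            {
                "fiber_id": self.fiber_ids,
                "t_value": self.t_values,
                "n_connected": self.n_connected,
                "valid": self.valid.astype(int),
            }
        ).to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
        header = {
            "min_per_group": self.min_per_group,
            "n_stims": self.n_stims,
            "provenance": self.provenance,
        }
        tsv_path.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, tsv_path: str | Path) -> "FiberScoreModel":
        tsv_path = Path(tsv_path)
        df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
        header = json.loads(tsv_path.with_suffix(".json").read_text())
        return cls(
            fiber_ids=df["fiber_id"].to_numpy(),
            t_values=df["t_value"].to_numpy(),
            n_connected=df["n_connected"].to_numpy(),
            valid=df["valid"].to_numpy().astype(bool),
            **header,
        )


def fit_fiber_scores(
    inc: IncidenceMatrix,
    improvements: np.ndarray,
    min_per_group: int = 2,
    welch: bool = False,
) -> FiberScoreModel:
    """Fit one two-sample t statistic per fiber, fully vectorized.

    Parameters
    ----------
    inc
        Fiber x stimulation incidence; columns aligned with ``improvements``.
    improvements
        Percent clinical improvement per stimulation, in incidence order.
    min_per_group
        Minimum group size on both sides for a fiber to be scored
        (default 2, the smallest size with an estimable variance).
    welch
        Use the Welch (unequal-variance) statistic instead of the classical
        pooled-variance Student t.
    """
    y = np.asarray(improvements, dtype=np.float64)
    if y.shape != (inc.n_stims,):
        raise ValueError("improvements not aligned with incidence stimulation order")
    if min_per_group < 2:
        raise ValueError("min_per_group must be >= 2")

    m = inc.entries
    n = inc.n_stims
    n1 = m.sum(axis=1)
    n2 = n - n1
    valid = (n1 >= min_per_group) & (n2 >= min_per_group)

    if np.ptp(y) == 0:
        warnings.warn("all improvements equal: every fiber is invalid", stacklevel=2)
        zeros = np.zeros(inc.n_fibers)
        return FiberScoreModel(
            inc.fiber_ids, zeros, n1, np.zeros(inc.n_fibers, dtype=bool),
            min_per_group, n, provenance="degenerate: constant improvements",
        )

    mf = m.astype(np.float64)
    sum1 = mf @ y
    sumsq1 = mf @ (y * y)
    tot, totsq = y.sum(), (y * y).sum()

    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = sum1 / n1
        mean2 = (tot - sum1) / n2
        ss1 = sumsq1 - n1 * mean1**2
        ss2 = (totsq - sumsq1) - n2 * mean2**2
        if welch:
            v1 = ss1 / (n1 - 1)
            v2 = ss2 / (n2 - 1)
            se = np.sqrt(v1 / n1 + v2 / n2)
        else:
            pooled = (ss1 + ss2) / (n1 + n2 - 2)
            se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        t = (mean1 - mean2) / se

    # zero pooled variance with unequal means -> +-inf; either way the
    # statistic is undefined, so such fibers are rejected as invalid.
    degenerate = valid & ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} fiber(s) with zero within-group variance "
            "rejected as invalid",
            stacklevel=2,
        )
        valid &= ~degenerate
    t = np.where(valid, t, 0.0)
    return FiberScoreModel(
        inc.fiber_ids, t, n1, valid, min_per_group, n,
        provenance=f"{'welch' if welch else 'pooled'} t on {n} stimulations",
    )


def count_signed(model: FiberScoreModel) -> tuple[int, int]:
    """Counts of valid fibers with positive and with negative weight."""
    t = model.t_values[model.valid]
    return int((t > 0).sum()), int((t < 0).sum())


def top_fraction(model: FiberScoreModel, fraction: float, sign: str = "positive") -> np.ndarray:
    """IDs of the top fibers by |t| among valid fibers of the requested sign.

    Returns ``ceil(fraction * n_valid_of_sign)`` fiber IDs; ties at the cut
    are broken by ascending fiber id, so the selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if sign not in ("positive", "negative", "absolute"):
        raise ValueError(f"unknown sign {sign!r}")
    t = model.t_values
    if sign == "positive":
        pool = model.valid & (t > 0)
    elif sign == "negative":
        pool = model.valid & (t < 0)
    else:
        pool = model.valid & (t != 0)
    idx = np.nonzero(pool)[0]
    if idx.size == 0:
        warnings.warn(f"no valid fibers of sign {sign!r}", stacklevel=2)
        return np.empty(0, dtype=np.int64)
    k = int(np.ceil(fraction * idx.size))
    order = np.lexsort((model.fiber_ids[idx], -np.abs(t[idx])))
    return np.sort(model.fiber_ids[idx[order[:k]]])
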
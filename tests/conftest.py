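"""Shared fixtures: small synthetic geometries reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import fiberfilter as ff
from fiberfilter import synthetic
from fiberfilter.formats import CohortTable, StimulationRecord, Tractogram
from fiberfilter.volumes import make_grid, sphere_mask


def random_polyline_tractogram(n_fibers: int, seed: int, box: float = 20.0) -> Tractogram:
    """Jagged random polylines inside [-box, box]^3 — worst case for sampling."""
    rng = np.random.default_rng(seed)
    fibers = []
    for i in range(n_fibers):
        n = int(rng.integers(3, 8))
        pts = np.cumsum(rng.uniform(-6, 6, size=(n, 3)), axis=0) + rng.uniform(-box, box, 3)
        fibers.append(ff.Streamline(i, pts))
    return Tractogram(fibers)


def random_sphere_cohort(n_stims: int, seed: int, grid=None) -> CohortTable:
    rng = np.random.default_rng(seed + 1000)
    grid = grid if grid is not None else make_grid((60, 60, 60), 1.0)
    recs = []
    for j in range(n_stims):
        center = rng.uniform(-18, 18, 3)
        radius = rng.uniform(2, 6)
        recs.append(
            StimulationRecord(
                f"s{j}", f"p{j}", "test", [sphere_mask(center, radius, grid)],
                amplitude=float(rng.uniform(1, 5)),
                improvement_pct=float(rng.normal(30, 15)),
            )
        )
    return CohortTable(recs)


@pytest.fixture(scope="session")
def default_grid():
    return synthetic.default_grid()


@pytest.fixture(scope="session")
def small_experiment(default_grid):
    """A reduced planted-bundle experiment shared by fast unit tests.

    50 planted + 300 background fibers, 12 stimulations per cohort.
    """
    conn, is_planted = synthetic.default_connectome(n_planted=50, n_background=300, seed=3)
    bundle = Tractogram(list(conn)[:50], space_tag=synthetic.SPACE_TAG)
    spec_a, spec_b = synthetic.default_cohort_specs(seed_a=3, seed_b=4)
    spec_a.n_stims = spec_b.n_stims = 12
    cohort_a, truth_a = synthetic.make_cohort(spec_a, bundle, default_grid)
    cohort_b, truth_b = synthetic.make_cohort(spec_b, bundle, default_grid)
    inc_a = ff.compute_incidence(conn, cohort_a)
    inc_b = ff.compute_incidence(conn, cohort_b)
    return {
        "connectome": conn,
        "is_planted": is_planted,
        "bundle": bundle,
        "cohort_a": cohort_a,
        "cohort_b": cohort_b,
        "truth_a": truth_a,
        "truth_b": truth_b,
        "inc_a": inc_a,
        "inc_b": inc_b,
    }
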
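"""Shared fixtures.

The expensive end-to-end fixtures (default 68-ROI, 18-subject synthetic
cohort with its independent leakage-free reference, plus the envelope-FC
studies over the filter-weight grid) are session-scoped so the fit and
community analyses share one generation pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import graphfc as g

# Filter-weight grid for synthetic end-to-end analyses: graphs are
# max1-normalized with typical row sums of 5-15, so the transition regime
# G * ||C row|| ~ 1 lies at G ~ 0.05-1; the grid spans it plus the
# saturated region.
G_SYNTH_GRID = (0.0, 0.05, 0.1, 0.2, 0.4, 1.0)


@pytest.fixture(scope="session")
def parc16():
    return g.make_parcellation(16, seed=1)


@pytest.fixture(scope="session")
def small_scs(parc16):
    return g.make_subject_scs(parc16, 6, seed=2)


@pytest.fixture(scope="session")
def small_consensus(parc16, small_scs):
    return g.consensus_sc(small_scs, parc16)


@pytest.fixture(scope="session")
def tiny_study():
    """16 ROIs, 2 subjects, short intervals: for fast pipeline tests."""
    return g.make_study(
        n_rois=16,
        n_subjects=2,
        n_intervals=(2, 2),
        duration_range_s=(20.0, 25.0),
        n_reference_subjects=4,
        seed=3,
    )


@pytest.fixture(scope="session")
def full_study():
    """The default synthetic cohort (68 ROIs, 18 subjects + reference)."""
    return g.make_study(seed=1)


@pytest.fixture(scope="session")
def full_consensus(full_study):
    return g.consensus_sc(full_study.subject_scs, full_study.parcellation)


@pytest.fixture(scope="session")
def full_fcs(full_study, full_consensus):
    """Envelope-FC studies for the SC-masked-ED and dense-ED graphs."""
    out = {}
    for variant in ("ed_match", "ed_full"):
        graph = g.build_filter_graph(
            variant, sc=full_consensus, parcellation=full_study.parcellation
        )
        out[variant] = g.filtered_fc_study(
            full_study.epochs_by_subject, graph, G_SYNTH_GRID, full_study.band
        )
    return out


def fisher_mean(mats):
    zs = [np.arctanh(np.clip(m, -1 + 1e-15, 1 - 1e-15)) for m in mats]
    out = np.tanh(np.mean(zs, axis=0))
    np.fill_diagonal(out, 1.0)
    return out
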
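"""Structure-function GLM: RRV, pair table, stepwise fit, matched comparison."""

import numpy as np
import pandas as pd
import pytest

import graphfc as g
from graphfc.glm import MAIN_EFFECTS, build_pair_table, matched_sc_comparison, rrv, stepwise_glm


def epochs_with_variances(variances, rate=100.0, t=500, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((len(variances), t))
    data = data / data.std(axis=1, keepdims=True) * np.sqrt(np.asarray(variances))[:, None]
    data -= data.mean(axis=1, keepdims=True)
    return g.SourceEpoch(data, rate)


class TestRRV:
    def test_hand_example(self):
        ep = epochs_with_variances([4.0, 1.0])
        out = rrv({"s": [ep]})
        np.testing.assert_allclose(out, [1.0, 0.25], atol=1e-9)

    def test_per_subject_max_is_one_before_averaging(self):
        eps = {f"s{k}": [epochs_with_variances([1 + k, 2 * k + 0.5], seed=k)] for k in range(3)}
        for sub, e in eps.items():
            v = np.mean([x.data.var(axis=1) for x in e], axis=0)
            assert (v / v.max()).max() == pytest.approx(1.0)

    def test_two_subject_mean(self):
        a = epochs_with_variances([4.0, 0.8], seed=1)
        b = epochs_with_variances([2.0, 4.0], seed=2)
        out = rrv({"a": [a], "b": [b]})
        np.testing.assert_allclose(out, [(1.0 + 0.5) / 2, (0.2 + 1.0) / 2], atol=1e-9)

    def test_all_zero_subject_raises(self):
        ep = g.SourceEpoch(np.zeros((2, 50)) + 1.0, 10.0)  # constant -> zero variance
        with pytest.raises(ValueError, match="RRV"):
            rrv({"s": [ep]})


@pytest.fixture(scope="module")
def pair_inputs():
    parc = g.make_parcellation(16, seed=30)
    scs = g.make_subject_scs(parc, 6, seed=31)
    cons = g.consensus_sc(scs, parc)
    si = g.search_information(cons)
    rng = np.random.default_rng(32)
    rrv_vec = rng.uniform(0.2, 1.0, 16)
    fc = rng.uniform(-0.5, 0.9, (16, 16))
    fc = 0.5 * (fc + fc.T)
    np.fill_diagonal(fc, 1.0)
    return parc, cons, si, rrv_vec, fc


class TestPairTable:
    def test_row_count(self, pair_inputs):
        parc, cons, si, rrv_vec, fc = pair_inputs
        table = build_pair_table(fc, si, parc, rrv_vec, cons)
        assert len(table) == 16 * 15 // 2

    def test_ed_consistent_with_centroids(self, pair_inputs):
        parc, cons, si, rrv_vec, fc = pair_inputs
        table = build_pair_table(fc, si, parc, rrv_vec, cons)
        ed = parc.distances()
        iu = np.triu_indices(16, k=1)
        np.testing.assert_allclose(table["ed"].to_numpy(), ed[iu], atol=1e-9)

    def test_roi_permutation_gives_same_rows(self, pair_inputs):
        parc, cons, si, rrv_vec, fc = pair_inputs
        t1 = build_pair_table(fc, si, parc, rrv_vec, cons)
        perm = np.random.default_rng(33).permutation(16)
        parc2 = g.Parcellation(
            roi_names=tuple(np.asarray(parc.roi_names)[perm]),
            hemisphere=parc.hemisphere[perm],
            centroids=parc.centroids[perm],
            roi_size=parc.roi_size[perm],
        )
        cons2 = g.StructuralConnectome(
            weights=cons.weights[np.ix_(perm, perm)], hemisphere=parc.hemisphere[perm]
        )
        si2 = g.SearchInformationMatrix(si=si.si[np.ix_(perm, perm)], symmetrized=True)
        t2 = build_pair_table(fc[np.ix_(perm, perm)], si2, parc2, rrv_vec[perm], cons2)
        cols = ["fc", "ed", "sc_si", "rrv_pair", "roi_size_pair", "sc_connected"]
        a = t1[cols].sort_values(cols).reset_index(drop=True)
        b = t2[cols].sort_values(cols).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, atol=1e-9)


class TestStepwiseGLM:
    def test_exact_linear_truth(self, pair_inputs):
        parc, cons, si, rrv_vec, fc = pair_inputs
        table = build_pair_table(fc, si, parc, rrv_vec, cons)
        table["fc"] = 3.0 - 0.02 * table["ed"]
        res = stepwise_glm(table)
        assert res.entered[0] == "ed"
        assert res.r2_final == pytest.approx(1.0, abs=1e-9)

    def test_planted_interaction_recovered(self, pair_inputs):
        parc, cons, si, rrv_vec, fc = pair_inputs
        table = build_pair_table(fc, si, parc, rrv_vec, cons)
        rng = np.random.default_rng(34)
        z = lambda s: (s - s.mean()) / s.std()  # noqa: E731
        zed, zsi = z(table["ed"]), z(table["sc_si"])
        table["fc"] = 0.5 * zed + 0.5 * zsi + 0.25 * zed * zsi + 0.3 * rng.standard_normal(len(table))
        res = stepwise_glm(table)
        assert {"ed", "sc_si", ("ed", "sc_si")} <= set(res.entered)
        # cumulative r2 close to the direct full least-squares fit
        x = np.column_stack([np.ones(len(table)), zed, zsi, zed * zsi])
        beta, *_ = np.linalg.lstsq(x, table["fc"], rcond=None)
        resid = table["fc"] - x @ beta
        r2_direct = 1 - np.sum(resid**2) / np.sum((table["fc"] - table["fc"].mean()) ** 2)
        assert res.r2_final == pytest.approx(r2_direct, abs=0.02)

    def test_r2_cumulative_nondecreasing(self, pair_inputs):
        parc, cons, si, rrv_vec, fc = pair_inputs
        table = build_pair_table(fc, si, parc, rrv_vec, cons)
        rng = np.random.default_rng(35)
        table["fc"] = (
            0.4 * table["ed"] / table["ed"].std() + rng.standard_normal(len(table))
        )
        res = stepwise_glm(table)
        assert np.all(np.diff(res.r2_cumulative) >= -1e-12)

    def test_interaction_requires_both_mains(self, pair_inputs):
        parc, cons, si, rrv_vec, fc = pair_inputs
        table = build_pair_table(fc, si, parc, rrv_vec, cons)
        rng = np.random.default_rng(36)
        table["fc"] = rng.standard_normal(len(table))
        res = stepwise_glm(table)
        for term in res.entered:
            if isinstance(term, tuple):
                assert term[0] in res.entered and term[1] in res.entered

    def test_single_variable_r2_reported_for_all_mains(self, pair_inputs):
        parc, cons, si, rrv_vec, fc = pair_inputs
        table = build_pair_table(fc, si, parc, rrv_vec, cons)
        res = stepwise_glm(table)
        assert set(res.r2_single) == set(MAIN_EFFECTS)
        assert all(0 <= v <= 1 for v in res.r2_single.values())


def null_tables(parc, cons, si, rrv_vec, n_subjects, rng, effect=0.0, noise_sd=0.1):
    """Per-subject pair tables with fc = f(ED) + effect*connected + noise."""
    tables = []
    base = build_pair_table(np.zeros((parc.n_rois, parc.n_rois)), si, parc, rrv_vec, cons)
    f_ed = np.exp(-base["ed"].to_numpy() / 50.0)
    conn = base["sc_connected"].to_numpy()
    for _ in range(n_subjects):
        t = base.copy()
        t["fc"] = f_ed + effect * conn + noise_sd * rng.standard_normal(len(t))
        tables.append(t)
    return tables


@pytest.fixture(scope="module")
def matched_world():
    parc = g.make_parcellation(40, seed=40)
    scs = g.make_subject_scs(parc, 10, seed=41)
    cons = g.consensus_sc(scs, parc)
    si = g.search_information(cons)
    rrv_vec = np.random.default_rng(42).uniform(0.2, 1.0, 40)
    return parc, cons, si, rrv_vec


class TestMatchedComparison:
    def test_equal_counts_per_bin(self, matched_world):
        parc, cons, si, rrv_vec = matched_world
        rng = np.random.default_rng(43)
        tables = null_tables(parc, cons, si, rrv_vec, 6, rng)
        mc = matched_sc_comparison(tables, n_bins=8, n_resamples=5, seed=1)
        assert np.all(mc.n_matched_per_bin[mc.n_matched_per_bin > 0] >= 1)
        assert len(mc.mean_sc_plus) == 6

    def test_planted_offset_detected(self, matched_world):
        parc, cons, si, rrv_vec = matched_world
        rng = np.random.default_rng(44)
        tables = null_tables(parc, cons, si, rrv_vec, 18, rng, effect=0.05)
        mc = matched_sc_comparison(tables, n_resamples=20, seed=2)
        assert mc.significant and mc.differences.mean() > 0

    def test_null_not_systematically_significant(self, matched_world):
        parc, cons, si, rrv_vec = matched_world
        rng = np.random.default_rng(45)
        rejections = 0
        for k in range(40):
            # exchangeable null: fc independent of class and distance
            tables = null_tables(parc, cons, si, rrv_vec, 12, rng)
            for t in tables:
                t["fc"] = rng.standard_normal(len(t))
            mc = matched_sc_comparison(tables, n_resamples=10, seed=100 + k)
            rejections += mc.p_value < 0.05
        assert rejections <= 8  # ~5% expected; loose bound at 40 runs

    def test_degenerate_identical_classes(self, matched_world):
        parc, cons, si, rrv_vec = matched_world
        tables = null_tables(parc, cons, si, rrv_vec, 4, np.random.default_rng(46), noise_sd=0.0)
        mc = matched_sc_comparison(tables, n_resamples=5, seed=3)
        # without noise or effect, differences are only matching artifacts
        assert mc.p_bonferroni <= 1.0
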
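import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mzt import embryo_qc_defects as qc


def profiles_frame(columns: dict[str, list[float]]) -> pd.DataFrame:
    genes = [f"g{i}" for i in range(len(next(iter(columns.values()))))]
    return pd.DataFrame(columns, index=genes, dtype=float)


class TestPairwiseCorrelation:
    def test_identical_profiles_r1(self):
        df = profiles_frame({"a": [1, 5, 9, 2], "b": [1, 5, 9, 2]})
        corr, means = qc.pairwise_correlation(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert means["all"] == pytest.approx(1.0)

    def test_log_space_negation_r_minus1(self):
        # construct FPKM whose log2(+1) values are exact negations around 0
        a = [2**2 - 1, 2**1 - 1, 2**0 - 1]
        b = [2**-2 - 1 + 1 - 1, 0, 0]  # placeholder replaced below
        log_a = np.log2(np.array(a) + 1)
        log_b = -(log_a - log_a.mean()) + log_a.mean()
        b = 2**log_b - 1
        df = profiles_frame({"a": a, "b": list(b)})
        corr, _ = qc.pairwise_correlation(df)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self, rng):
        df = profiles_frame(
            {k: list(rng.uniform(0, 50, 5)) for k in ["a", "b", "c", "d"]}
        )
        corr, _ = qc.pairwise_correlation(df)
        x = np.log2(df["a"] + 1)
        y = np.log2(df["c"] + 1)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert corr.loc["a", "c"] == pytest.approx(num / den)

    def test_zero_variance_profile_reported_nan(self):
        df = profiles_frame({"a": [1, 2, 3], "flat": [5, 5, 5]})
        corr, means = qc.pairwise_correlation(df)
        assert np.isnan(corr.loc["a", "flat"])

    def test_group_means_off_diagonal(self):
        df = profiles_frame({"a": [1, 5, 9], "b": [1, 5, 9], "c": [9, 5, 1]})
        _, means = qc.pairwise_correlation(df, {"a": "g1", "b": "g1", "c": "g2"})
        assert means["g1"] == pytest.approx(1.0)
        assert np.isnan(means["g2"])  # singleton group has no pairs


class TestPCA:
    def test_two_samples_symmetric_about_zero(self):
        df = profiles_frame({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        coords, _ = qc.pca(df, 1)
        assert coords.loc["a", "PC1"] == pytest.approx(-coords.loc["b", "PC1"])

    def test_explained_variance_sums_to_total(self, rng):
        df = profiles_frame({k: list(rng.uniform(0, 40, 8)) for k in "abcde"})
        _, explained = qc.pca(df, 4)
        X = np.log2(df.to_numpy().T + 1)
        Xc = X - X.mean(axis=0)
        total = (Xc**2).sum() / (df.shape[1] - 1)
        assert explained.sum() == pytest.approx(total)
        assert (np.diff(explained) <= 1e-12).all()  # non-increasing

    def test_matches_covariance_eigendecomposition(self, rng):
        df = profiles_frame({k: list(rng.uniform(0, 40, 6)) for k in "abcd"})
        coords, explained = qc.pca(df, 3)
        X = np.log2(df.to_numpy().T + 1)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        assert explained == pytest.approx(evals[order][:3])
        expected = Xc @ evecs[:, order[:3]]
        for k in range(3):
            assert np.allclose(coords.iloc[:, k], expected[:, k]) or np.allclose(
                coords.iloc[:, k], -expected[:, k]
            )

    def test_sign_convention_and_reorder_invariance(self, rng):
        df = profiles_frame({k: list(rng.uniform(0, 40, 7)) for k in "abcde"})
        coords, _ = qc.pca(df, 2)
        shuffled = df[["c", "a", "e", "b", "d"]]
        coords2, _ = qc.pca(shuffled, 2)
        pd.testing.assert_frame_equal(
            coords.sort_index(), coords2.sort_index(), check_exact=False
        )

    def test_component_bound_enforced(self):
        df = profiles_frame({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(ValueError):
            qc.pca(df, 2)  # rank bound is min(samples-1, genes) = 1


class TestFoldChanges:
    def test_threshold_labels(self):
        test = profiles_frame({"t": [7, 0, 5]})
        ref = profiles_frame({"r": [1, 9, 5]})
        table = qc.fold_changes(test, ref)
        assert table.loc["g0", "ratio"] == pytest.approx(4.0)
        assert table.loc["g0", "label_2x"] == "up"
        assert table.loc["g0", "label_5x"] == ""
        assert table.loc["g1", "ratio"] == pytest.approx(0.1)
        assert table.loc["g1", "label_2x"] == "down"
        assert table.loc["g1", "label_5x"] == "down"
        assert table.loc["g2", "label_2x"] == ""  # identical -> unlabeled
        counts = qc.fold_change_counts(table)
        assert counts["2x"] == {"up": 1, "down": 1}

    def test_antisymmetry(self, rng):
        test = profiles_frame({"t1": list(rng.uniform(0, 30, 10)), "t2": list(rng.uniform(0, 30, 10))})
        ref = profiles_frame({"r1": list(rng.uniform(0, 30, 10))})
        fwd = qc.fold_changes(test, ref)["ratio"]
        rev = qc.fold_changes(ref, test)["ratio"]
        assert np.allclose(fwd * rev, 1.0)

    def test_empty_reference_rejected(self):
        test = profiles_frame({"t": [1, 2]})
        with pytest.raises(ValueError, match="empty reference"):
            qc.fold_changes(test, test.iloc[:, :0])


def hypergeom_enumeration(universe_size, n_a, n_b, k):
    """P(|A ∩ draw| >= k) by exhaustive enumeration of all size-n_b draws."""
    universe = range(universe_size)
    a = set(range(n_a))
    hits = sum(
        1
        for draw in itertools.combinations(universe, n_b)
        if len(a & set(draw)) >= k
    )
    return hits / math.comb(universe_size, n_b)


class TestOverlapEnrichment:
    def test_degenerate_full_overlap_p1(self):
        u = set(range(6))
        res = qc.overlap_enrichment(u, u, u)
        assert res.n_overlap == 6
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_sets_p1(self):
        res = qc.overlap_enrichment({0, 1}, {2, 3}, set(range(10)))
        assert res.n_overlap == 0
        assert res.p_value == pytest.approx(1.0)

    def test_derived_example_matches_enumeration(self):
        a = set(range(5))
        b = {0, 1, 2, 3}
        res = qc.overlap_enrichment(a, b, set(range(10)))
        assert res.p_value == pytest.approx(hypergeom_enumeration(10, 5, 4, 4))

    @pytest.mark.parametrize("universe_size", [5, 8])
    def test_small_universe_sweep_matches_enumeration(self, universe_size):
        for n_a in range(universe_size + 1):
            for n_b in range(universe_size + 1):
                # worst case overlap: A = first n_a elements, B = last n_b
                a = set(range(n_a))
                b = set(range(universe_size - n_b, universe_size))
                res = qc.overlap_enrichment(a, b, set(range(universe_size)))
                expected = hypergeom_enumeration(
                    universe_size, n_a, n_b, len(a & b)
                )
                assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            qc.overlap_enrichment({99}, set(), {1, 2})


def marker_table(test_levels, control_levels=1.0, markers=6, jitter=None):
    idx = [f"M{i}" for i in range(markers)]
    if np.isscalar(test_levels):
        test_levels = [test_levels] * markers
    data = {}
    for r in range(3):
        eps = 0.0 if jitter is None else jitter * (r - 1)
        data[f"t{r}"] = [lv * (1 + eps) for lv in test_levels]
        data[f"c{r}"] = [control_levels * (1 + eps)] * markers
    return pd.DataFrame(data, index=idx)


MARKER_GROUPS = {f"t{r}": "test" for r in range(3)} | {f"c{r}": "control" for r in range(3)}


class TestMDecayDefectCall:
    def test_all_markers_accumulated_calls_defect(self):
        call = qc.call_m_decay_defect(marker_table(4.0, jitter=0.01), MARKER_GROUPS)
        assert call.call == "M_DECAY_DEFECT"
        assert call.evidence["n_accumulated"] == 6

    def test_three_of_six_is_no_defect(self):
        table = marker_table([4, 4, 4, 1, 1, 1], jitter=0.01)
        call = qc.call_m_decay_defect(table, MARKER_GROUPS)
        assert call.call == "NO_DEFECT"
        assert call.evidence["n_accumulated"] == 3

    def test_accumulation_without_significance_is_no_defect(self):
        # huge within-group spread swamps a small mean shift
        idx = [f"M{i}" for i in range(6)]
        data = {
            "t0": [0.1] * 6, "t1": [1.3] * 6, "t2": [10.0] * 6,
            "c0": [0.09] * 6, "c1": [1.0] * 6, "c2": [9.0] * 6,
        }
        call = qc.call_m_decay_defect(pd.DataFrame(data, index=idx), MARKER_GROUPS)
        assert call.evidence["n_accumulated"] == 0
        assert call.call == "NO_DEFECT"

    def test_fewer_than_four_detected_is_indeterminate(self):
        table = marker_table(4.0, jitter=0.01)
        table.iloc[3:] = 0.0  # only 3 markers detected at all
        call = qc.call_m_decay_defect(table, MARKER_GROUPS)
        assert call.call == "INDETERMINATE"

    def test_proportional_threshold_with_five_detected(self):
        table = marker_table(4.0, jitter=0.01)
        table.iloc[5] = 0.0  # 5 detected; ceil(4*5/6) = 4 still required
        call = qc.call_m_decay_defect(table, MARKER_GROUPS)
        assert call.call == "M_DECAY_DEFECT"

    def test_too_few_replicates_rejected(self):
        table = marker_table(4.0)[["t0", "t1", "c0", "c1"]]
        groups = {"t0": "test", "t1": "test", "c0": "control", "c1": "control"}
        with pytest.raises(ValueError, match="replicates"):
            qc.call_m_decay_defect(table, groups)


class TestZDecayGroups:
    def _series(self, values):
        return pd.Series(values, index=[f"g{i}" for i in range(len(values))], dtype=float)

    def test_forced_group_membership(self):
        normal_zy = self._series([15, 0, 15])
        normal_8c = self._series([0, 15, 0])
        arrested = self._series([15, 0, 0])
        ga, gb, _ = qc.call_z_decay_groups(normal_zy, normal_8c, arrested)
        assert "g0" in ga  # degraded normally, stable in arrested
        assert "g1" in gb  # zygotically activated normally, not in arrested
        assert "g2" not in ga and "g2" not in gb  # degraded in both

    def test_groups_disjoint_fuzz(self, rng):
        n = 400
        zy = self._series(rng.uniform(0, 100, n))
        ec = self._series(rng.uniform(0, 100, n))
        arr = self._series(rng.uniform(0, 100, n))
        ga, gb, _ = qc.call_z_decay_groups(zy, ec, arr)
        assert not set(ga) & set(gb)

    def test_missing_condition_rejected(self):
        s = self._series([1, 2])
        with pytest.raises(ValueError, match="missing condition"):
            qc.call_z_decay_groups(s, s, pd.Series(dtype=float))


class TestConcordantSubset:
    def test_outlier_embryo_dropped(self, rng):
        base = rng.uniform(0, 60, 40)
        cols = {f"e{i}": base * 2 ** rng.normal(0, 0.1, 40) for i in range(5)}
        cols["out"] = rng.uniform(0, 60, 40)
        kept, r = qc.concordant_subset(pd.DataFrame(cols), r_min=0.9)
        assert "out" not in kept
        assert len(kept) == 5
        assert r >= 0.9
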
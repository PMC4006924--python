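"""Selection statistics versus brute-force and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import sepsiskit as sk
from sepsiskit.errors import ValidationError
from sepsiskit.filtering import MODEL_TIME, OverlapReport, one_way_f


def _random_matrix(rng, n_probes, n_samples):
    return pd.DataFrame(
        rng.normal(8, 2, size=(n_probes, n_samples)),
        index=pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id"),
        columns=pd.Index([f"s{i}" for i in range(n_samples)], name="sample_id"),
    )


class TestCvFilter:
    def test_known_cv_kept(self):
        # linear-scale values with mean 100, sd 60 -> CV 0.6 > 0.5
        linear = np.array([40.0, 100.0, 160.0])
        linear = linear * (60.0 / np.std(linear, ddof=1))  # force sd 60
        linear = linear - linear.mean() + 100.0
        matrix = pd.DataFrame([np.log2(linear)], index=["p1"],
                              columns=["s1", "s2", "s3"])
        sel = sk.cv_filter(matrix, threshold=0.5)
        assert list(sel.kept) == ["p1"]
        assert sel.statistic["p1"] == pytest.approx(0.6)

    def test_constant_probe_dropped(self):
        matrix = pd.DataFrame([[3.0, 3.0, 3.0]], index=["p1"],
                              columns=["a", "b", "c"])
        sel = sk.cv_filter(matrix, threshold=0.0)
        assert len(sel.kept) == 0

    def test_matches_bruteforce_loop(self, rng):
        matrix = _random_matrix(rng, 50, 10)
        sel = sk.cv_filter(matrix, threshold=0.4)
        kept_oracle = []
        for probe in matrix.index:  # brute-force per-probe recomputation
            vals = 2.0 ** matrix.loc[probe].to_numpy()
            cv = np.std(vals, ddof=1) / np.mean(vals)
            if cv > 0.4:
                kept_oracle.append(probe)
        assert list(sel.kept) == kept_oracle

    def test_log2_scale_option(self, rng):
        matrix = _random_matrix(rng, 30, 6)
        sel = sk.cv_filter(matrix, threshold=0.2, scale="log2")
        vals = matrix.to_numpy()
        cv = vals.std(axis=1, ddof=1) / vals.mean(axis=1)
        assert set(sel.kept) == set(matrix.index[cv > 0.2])


class TestOneWayF:
    def test_matches_scipy_f_oneway(self, rng):
        values = rng.normal(size=(40, 12))
        groups = [np.arange(0, 4), np.arange(4, 8), np.arange(8, 12)]
        f, p = one_way_f(values, groups)
        f_ref, p_ref = stats.f_oneway(values[:, :4], values[:, 4:8],
                                      values[:, 8:], axis=1)
        np.testing.assert_allclose(f, f_ref)
        np.testing.assert_allclose(p, p_ref)

    def test_two_group_f_equals_squared_t(self, rng):
        """Algebraic identity: for 2 groups, F = t^2 and the p-values agree."""
        values = rng.normal(size=(25, 10))
        groups = [np.arange(0, 5), np.arange(5, 10)]
        f, p = one_way_f(values, groups)
        t, p_t = stats.ttest_ind(values[:, :5], values[:, 5:], axis=1)
        np.testing.assert_allclose(f, t**2, rtol=1e-10)
        np.testing.assert_allclose(p, p_t, rtol=1e-10)

    def test_group_below_two_samples_rejected(self, rng):
        with pytest.raises(ValidationError, match=">=2 samples"):
            one_way_f(rng.normal(size=(5, 4)), [np.array([0]), np.arange(1, 4)])

    def test_zero_within_variance_gives_p_zero(self):
        values = np.array([[1.0, 1.0, 2.0, 2.0]])
        with pytest.warns(UserWarning, match="zero within-group"):
            _, p = one_way_f(values, [np.array([0, 1]), np.array([2, 3])])
        assert p[0] == 0.0


class TestFTestSelection:
    def test_extreme_effect_kept(self, rng):
        matrix = _random_matrix(rng, 20, 14)
        samples = pd.DataFrame(
            {"class_label": [sk.CONTROL] * 6 + [sk.MODEL_A] * 4 + [sk.MODEL_B] * 4,
             "timepoint": [None] * 6 + ["2h"] * 8},
            index=matrix.columns,
        )
        matrix.iloc[0, 6:10] += 30.0  # ~10 within-group sd
        sel = sk.f_test_selection(matrix, samples, alpha=0.001)
        assert "p0" in sel.kept
        assert sel.statistic["p0"] < 1e-6

    def test_null_calibration_small(self, rng):
        """Type-I error at alpha=0.05 under the sharp null: the kept
        fraction sits inside the binomial 99.9% interval."""
        matrix = _random_matrix(rng, 4000, 18)
        samples = pd.DataFrame(
            {"class_label": ([sk.CONTROL] * 6 + [sk.MODEL_A] * 6
                             + [sk.MODEL_B] * 6),
             "timepoint": [None] * 6 + ["2h"] * 12},
            index=matrix.columns,
        )
        sel = sk.f_test_selection(matrix, samples, alpha=0.05)
        lo, hi = stats.binom.interval(0.999, 4000, 0.05)
        assert lo <= sel.n_probes_kept <= hi

    def test_selection_invariant_to_sample_order(self, small_dataset, rng):
        matrix, samples, _, _ = small_dataset
        shuffled = matrix[rng.permutation(matrix.columns)]
        sel1 = sk.f_test_selection(matrix, samples)
        sel2 = sk.f_test_selection(shuffled, samples)
        assert set(sel1.kept) == set(sel2.kept)

    def test_model_time_grouping_has_more_power_for_transient_effects(
            self, small_dataset):
        """Effects that change sign over time cancel in the pooled
        three-class means but not in per-(model, time) cells."""
        matrix, samples, _, truth = small_dataset
        sel3 = sk.f_test_selection(matrix, samples, grouping="three-class")
        sel7 = sk.f_test_selection(matrix, samples, grouping=MODEL_TIME)
        de = set(truth.de_flags.index[truth.de_flags])
        assert len(set(sel7.kept) & de) > len(set(sel3.kept) & de)


class TestChangeProfile:
    def test_identity_and_definition_folds(self):
        matrix = pd.DataFrame(
            [[5.0, 5.0, 5.0, 5.0],
             [5.0, 5.0, 7.0, 7.0],
             [5.0, 5.0, 4.0, 4.0]],
            index=["flat", "up2", "down1"],
            columns=["c1", "c2", "a1", "a2"],
        )
        samples = pd.DataFrame(
            {"class_label": [sk.CONTROL, sk.CONTROL, sk.MODEL_A, sk.MODEL_A],
             "timepoint": [None, None, "2h", "2h"]},
            index=matrix.columns,
        )
        profile = sk.change_profile(matrix, samples, sk.MODEL_A, "2h")
        assert profile.fold_change["flat"] == pytest.approx(1.0)   # d=0 -> +1
        assert profile.fold_change["up2"] == pytest.approx(4.0)    # d=+2 -> +4
        assert profile.fold_change["down1"] == pytest.approx(-2.0)  # d=-1 -> -2

    def test_injected_il6_like_fold_recovered(self):
        """A probe injected with delta = log2(31.1) at 2 h in model B comes
        back within noise of 31.1-fold (the scale of a strongly induced
        cytokine such as Il-6)."""
        delta = np.log2(31.1)
        rng = np.random.default_rng(0)
        n_ctrl, n_grp, reps = 6, 4, 200
        folds = np.empty(reps)
        for i in range(reps):
            ctrl = 8.0 + rng.normal(0, 0.2, n_ctrl)
            grp = 8.0 + delta + rng.normal(0, 0.2, n_grp)
            folds[i] = 2.0 ** (grp.mean() - ctrl.mean())
        assert np.median(folds) == pytest.approx(31.1, rel=0.1)
        matrix = pd.DataFrame(
            [np.concatenate([8.0 + np.zeros(n_ctrl), 8.0 + delta + np.zeros(n_grp)])],
            index=["il6_like"],
            columns=[f"s{i}" for i in range(n_ctrl + n_grp)],
        )
        samples = pd.DataFrame(
            {"class_label": [sk.CONTROL] * n_ctrl + [sk.MODEL_B] * n_grp,
             "timepoint": [None] * n_ctrl + ["2h"] * n_grp},
            index=matrix.columns,
        )
        profile = sk.change_profile(matrix, samples, sk.MODEL_B, "2h")
        assert profile.fold_change["il6_like"] == pytest.approx(31.1, rel=1e-9)

    @given(st.floats(min_value=-20, max_value=20,
                     allow_nan=False, allow_infinity=False))
    def test_signed_fold_roundtrip(self, d):
        """d -> signed fold -> d is the identity; |fold| >= 1 always."""
        fold = float(sk.signed_fold(np.array([d]))[0])
        assert abs(fold) >= 1.0
        back = np.log2(fold) if fold > 0 else -np.log2(-fold)
        assert back == pytest.approx(d, abs=1e-9)
        assert np.sign(fold) == (1.0 if d >= 0 else -1.0)


class TestOverlap:
    def _selection(self, universe, kept):
        stat = pd.Series(0.5, index=universe)
        return sk.SelectionResult(kept=pd.Index(kept), statistic=stat,
                                  threshold=0.001, kind="f-test")

    def _probes(self, genes):
        return pd.DataFrame({"gene_symbol": genes.values()},
                            index=pd.Index(genes.keys(), name="probe_id"))

    def test_hand_counts(self):
        universe = pd.Index([f"p{i}" for i in range(1, 9)])
        probes = self._probes({f"p{i}": f"g{i}" for i in range(1, 9)})
        sel_a = self._selection(universe, [f"p{i}" for i in range(1, 6)])
        sel_b = self._selection(universe, [f"p{i}" for i in range(4, 9)])
        rep = sk.collapse_and_overlap(sel_a, sel_b, probes)
        assert rep.counts()["genes_shared"] == 2
        assert rep.counts()["genes_only_a"] == 3
        assert rep.counts()["genes_only_b"] == 3

    def test_identical_selections(self):
        universe = pd.Index(["p1", "p2", "p3"])
        probes = self._probes({"p1": "g1", "p2": "g1", "p3": "g2"})
        sel = self._selection(universe, ["p1", "p3"])
        rep = sk.collapse_and_overlap(sel, sel, probes)
        assert rep.genes_shared == {"g1", "g2"}
        assert not rep.genes_only_a and not rep.genes_only_b

    def test_random_selections_match_set_algebra_oracle(self, rng):
        n_probes = 2000
        universe = pd.Index([f"p{i}" for i in range(n_probes)])
        gene_map = {f"p{i}": f"g{i // 2}" for i in range(n_probes)}
        probes = self._probes(gene_map)
        for _ in range(20):
            kept_a = universe[rng.random(n_probes) < 0.3]
            kept_b = universe[rng.random(n_probes) < 0.3]
            rep = sk.collapse_and_overlap(
                self._selection(universe, kept_a),
                self._selection(universe, kept_b), probes)
            ga = {gene_map[p] for p in kept_a}
            gb = {gene_map[p] for p in kept_b}
            assert rep.genes_shared == ga & gb
            assert rep.genes_only_a == ga - gb
            assert rep.probes_shared == set(kept_a) & set(kept_b)

    def test_differing_universes_rejected(self):
        probes = self._probes({"p1": "g1", "p2": "g2"})
        sel_a = self._selection(pd.Index(["p1", "p2"]), ["p1"])
        sel_b = self._selection(pd.Index(["p1"]), ["p1"])
        with pytest.raises(ValidationError, match="universe"):
            sk.collapse_and_overlap(sel_a, sel_b, probes)


def _naive_average_linkage_heights(dist: np.ndarray) -> list[float]:
    """O(n^3) agglomerative average linkage: independent oracle for the
    merge heights scipy reports."""
    clusters = {i: [i] for i in range(dist.shape[0])}
    d = {(i, j): dist[i, j] for i in clusters for j in clusters if i < j}
    heights = []
    next_id = dist.shape[0]
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        d = {k: v for k, v in d.items() if i not in k and j not in k}
        for k in clusters:
            pair_dists = [dist[a, b] for a in merged for b in clusters[k]]
            d[(min(k, next_id), max(k, next_id))] = float(np.mean(pair_dists))
        clusters[next_id] = merged
        next_id += 1
    return heights


class TestClusterOrder:
    def test_identical_samples_adjacent(self, rng):
        matrix = _random_matrix(rng, 10, 5)
        matrix["s_dup"] = matrix["s0"] + 1e-12
        order = sk.cluster_order(matrix)["sample_order"]
        i, j = order.index("s0"), order.index("s_dup")
        assert abs(i - j) == 1

    def test_anticorrelated_probes_max_distance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        corr = np.corrcoef(np.vstack([x, -x]))
        assert 1 - corr[0, 1] == pytest.approx(2.0)

    def test_linkage_heights_match_naive_agglomeration(self, rng):
        matrix = _random_matrix(rng, 20, 10)
        result = sk.cluster_order(matrix)
        corr = np.corrcoef(matrix.to_numpy())
        dist = np.clip(1 - corr, 0, 2)
        np.fill_diagonal(dist, 0)
        oracle = _naive_average_linkage_heights(dist)
        np.testing.assert_allclose(
            sorted(result["probe_linkage"][:, 2]), sorted(oracle), atol=1e-10)

    def test_constant_row_placed_last(self, rng):
        matrix = _random_matrix(rng, 5, 6)
        matrix.loc["p_const"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            result = sk.cluster_order(matrix)
        assert result["probe_order"][-1] == "p_const"

    def test_deterministic(self, rng):
        matrix = _random_matrix(rng, 15, 8)
        r1 = sk.cluster_order(matrix)
        r2 = sk.cluster_order(matrix)
        assert r1["probe_order"] == r2["probe_order"]
        assert r1["sample_order"] == r2["sample_order"]
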
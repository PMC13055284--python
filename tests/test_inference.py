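"""PERMANOVA (with exhaustive-enumeration oracle), beta-dispersion,
feature exclusion, and alpha diversity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from ordgeom import (
    DesignSpec,
    EffectSpec,
    beta_dispersion,
    bray_curtis,
    chao1,
    exclude_feature_and_renormalize,
    generate_counts,
    generate_metadata,
    pairwise_permanova,
    permanova,
    permanova_sweep,
    shannon,
)
from ordgeom.ordination import Embedding, pcoa


def _meta(ids, **cols):
    return pd.DataFrame(cols, index=pd.Index(ids, name="sample_id"))


def _two_group_meta(ids, n_a):
    return _meta(ids, group=["A"] * n_a + ["B"] * (len(ids) - n_a))


def _anderson_f(dist, labels):
    """Independent one-factor pseudo-F via the direct sum-of-squares
    formulation: SS_W = sum_g (1/n_g) sum_{i<j in g} d_ij^2."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_t = np.sum(dist[np.triu_indices(n, 1)] ** 2) / n
    ss_w = 0.0
    for g in np.unique(labels):
        idx = np.nonzero(labels == g)[0]
        sub = dist[np.ix_(idx, idx)]
        ss_w += np.sum(sub[np.triu_indices(len(idx), 1)] ** 2) / len(idx)
    ss_b = ss_t - ss_w
    a = len(np.unique(labels))
    return (ss_b / (a - 1)) / (ss_w / (n - a)), ss_b / ss_t


class TestPermanova:
    def test_equidistant_design_analytic_partition(self):
        # 6 samples, all pairwise distances equal: SS_total = 15c^2/6,
        # SS_within = 2c^2, so R2_group = 0.5/2.5 = 0.2 and every
        # permutation yields the same F -> p = 1
        c = 2.0
        dist = c * (np.ones((6, 6)) - np.eye(6))
        ids = [f"s{i}" for i in range(6)]
        D = DistanceMatrix(dist, ids=ids)
        res = permanova(D, _two_group_meta(ids, 3), ["group"], n_perm=99)
        assert res.r2("group") == pytest.approx(0.2, abs=1e-12)
        assert res.p_value("group") == pytest.approx(1.0)

    def test_exhaustive_enumeration_matches_oracle(self, rng):
        X = rng.normal(size=(6, 3))
        X[3:] += 1.5  # group separation
        dist = squareform(pdist(X))
        ids = [f"s{i}" for i in range(6)]
        labels = ["A"] * 3 + ["B"] * 3
        D = DistanceMatrix(dist, ids=ids)
        res = permanova(D, _two_group_meta(ids, 3), ["group"],
                        n_perm="exhaustive")
        f_obs, r2_obs = _anderson_f(dist, labels)
        assert res.f("group") == pytest.approx(f_obs, rel=1e-9)
        assert res.r2("group") == pytest.approx(r2_obs, rel=1e-9)
        # oracle p over all 720 label permutations (identity included)
        count = 0
        total = 0
        for perm in itertools.permutations(range(6)):
            f_p, _ = _anderson_f(dist[np.ix_(perm, perm)], labels)
            count += f_p >= f_obs - 1e-12
            total += 1
        assert res.p_value("group") == pytest.approx(count / total, rel=1e-12)

    def test_r2_partition_sums_to_one(self, small_table, small_metadata):
        D = bray_curtis(small_table)
        res = permanova(D, small_metadata, ["soil", "day", "treatment"],
                        n_perm=99, seed=0)
        r2s = res.table.loc[["soil", "day", "treatment", "Residual"], "R2"]
        assert r2s.sum() == pytest.approx(1.0, abs=1e-9)
        p = res.table.loc[["soil", "day", "treatment"], "p"]
        assert ((p >= 1 / 100) & (p <= 1.0)).all()

    def test_consistent_relabeling_invariance(self, rng):
        X = rng.normal(size=(8, 3))
        dist = squareform(pdist(X))
        ids = [f"s{i}" for i in range(8)]
        meta = _two_group_meta(ids, 4)
        D = DistanceMatrix(dist, ids=ids)
        res = permanova(D, meta, ["group"], n_perm="exhaustive")
        order = rng.permutation(8)
        ids2 = [ids[i] for i in order]
        D2 = DistanceMatrix(dist[np.ix_(order, order)], ids=ids2)
        res2 = permanova(D2, meta, ["group"], n_perm="exhaustive")
        assert res2.f("group") == pytest.approx(res.f("group"), rel=1e-9)
        assert res2.r2("group") == pytest.approx(res.r2("group"), rel=1e-9)
        assert res2.p_value("group") == pytest.approx(res.p_value("group"))

    def test_power_increases_with_effect_size(self):
        """Mean treatment R2 grows monotonically across three shift sizes."""
        means = []
        for shift in (0.0, 0.5, 1.5):
            r2s = []
            for seed in range(5):
                design = DesignSpec(soils=("S",), replicates=3, days=(0, 14),
                                    n_features=40, library_size=5000,
                                    seed=100 + seed)
                effects = EffectSpec(
                    drift_scale={"S": 0.0}, treatment_shift={"S": shift},
                    divergence_angle={"S": 0.0},
                    inoculant_initial_fraction=0.0,
                    inoculant_residual_fraction={"S": 0.0},
                )
                table = generate_counts(design, effects)
                meta = generate_metadata(design)
                res = permanova(bray_curtis(table), meta, ["treatment"],
                                n_perm=0)
                r2s.append(res.r2("treatment"))
            means.append(np.mean(r2s))
        assert means[0] < means[1] < means[2]

    def test_constant_factor_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        ids = [f"s{i}" for i in range(6)]
        D = DistanceMatrix(squareform(pdist(X)), ids=ids)
        with pytest.raises(ValueError, match="constant"):
            permanova(D, _meta(ids, group=["A"] * 6), ["group"], n_perm=99)


class TestPermanovaSweep:
    def test_treatment_signal_in_later_components(self):
        """Treatment separation placed on a low-variance axis is invisible at
        d=2 but significant once the embedding includes that axis."""
        r = np.random.default_rng(42)
        n = 60
        grp = np.array([0] * 30 + [1] * 30)
        scales = [5.0, 3.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        X = np.empty((n, 8))
        for j, s in enumerate(scales):
            z = r.normal(size=n)
            # kill chance group separation, pin the column variance exactly
            z[grp == 0] -= z[grp == 0].mean()
            z[grp == 1] -= z[grp == 1].mean()
            X[:, j] = s * z / z.std()
        X[grp == 1, 4] += 4.0  # signal axis: variance 1 + 4, third-ranked
        treatment = np.where(grp == 0, "control", "inoculated")
        ids = [f"s{i}" for i in range(n)]
        meta = _meta(ids, soil=["S"] * n, day=[0] * n, treatment=treatment,
                     replicate=list(range(1, n + 1)))
        D = DistanceMatrix(squareform(pdist(X)), ids=ids)
        embs = [pcoa(D, d) for d in (2, 7)]
        tab = permanova_sweep(embs, meta, global_terms=("treatment",),
                              n_perm=999, seed=0)
        glob = tab[(tab.scope == "global") & (tab.term == "treatment")]
        low = glob[glob.dimension == 2].iloc[0]
        high = glob[glob.dimension == 7].iloc[0]
        assert low["p"] > 0.05
        assert high["p"] < 0.05
        assert high["R2"] > low["R2"]

    def test_seed_reproducibility(self, small_table, small_metadata):
        from ordgeom import rpca_embed
        embs = [rpca_embed(small_table, d) for d in (2, 3)]
        a = permanova_sweep(embs, small_metadata, n_perm=99, seed=3)
        b = permanova_sweep(embs, small_metadata, n_perm=99, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert len(a[(a.scope == "global")]) == 2 * 3  # dims x terms


class TestPairwise:
    def _dm_meta(self, rng, levels, per_level=4):
        n = len(levels) * per_level
        X = rng.normal(size=(n, 3))
        ids = [f"s{i}" for i in range(n)]
        labels = [lv for lv in levels for _ in range(per_level)]
        return (DistanceMatrix(squareform(pdist(X)), ids=ids),
                _meta(ids, group=labels))

    def test_three_levels_three_tests_bh(self, rng):
        D, meta = self._dm_meta(rng, ["A", "B", "C"])
        out = pairwise_permanova(D, meta, "group", n_perm=99, seed=0)
        assert len(out) == 3
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_two_levels_q_equals_p(self, rng):
        D, meta = self._dm_meta(rng, ["A", "B"])
        out = pairwise_permanova(D, meta, "group", n_perm=99, seed=0)
        assert len(out) == 1
        assert out["q"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_null_levels_not_significant(self, rng):
        # identical generating distribution across levels
        D, meta = self._dm_meta(rng, ["A", "B", "C"], per_level=5)
        out = pairwise_permanova(D, meta, "group", n_perm=199, seed=1)
        assert (out["q"] > 0.05).all()


class TestBetaDispersion:
    def test_duplicated_point_zero_dispersion(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0], [7.0, 5.0]])
        ids = list("abcd")
        E = Embedding(ids, X, "pcoa", 2)
        per_sample, per_group = beta_dispersion(
            E, pd.Series(["g1", "g1", "g2", "g2"], index=ids))
        assert per_group["g1"] == pytest.approx(0.0)

    def test_two_points_unit_distance_to_centroid(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        ids = ["a", "b"]
        E = Embedding(ids, X, "pcoa", 2)
        per_sample, per_group = beta_dispersion(
            E, pd.Series(["g", "g"], index=ids))
        np.testing.assert_allclose(per_sample["distance_to_centroid"], 1.0)

    def test_distance_matrix_route_matches_coordinates(self, rng):
        X = rng.normal(size=(10, 4))
        ids = [f"s{i}" for i in range(10)]
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=ids)
        E = Embedding(ids, X, "pcoa", 4)
        ps_coord, _ = beta_dispersion(E, groups)
        D = DistanceMatrix(squareform(pdist(X)), ids=ids)
        ps_dist, _ = beta_dispersion(D, groups)
        np.testing.assert_allclose(ps_dist["distance_to_centroid"],
                                   ps_coord["distance_to_centroid"],
                                   atol=1e-9)

    def test_singleton_group_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        ids = list("abc")
        E = Embedding(ids, X, "pcoa", 2)
        with pytest.raises(ValueError, match="singleton"):
            beta_dispersion(E, pd.Series(["a", "a", "b"], index=ids))


class TestFeatureExclusion:
    def test_controls_unchanged(self, small_table, small_metadata,
                                small_effects):
        out = exclude_feature_and_renormalize(
            small_table, [small_effects.inoculant_feature_id])
        controls = small_metadata.index[small_metadata.treatment == "control"]
        # controls carried zero inoculant, so rescaling leaves them intact
        expected = small_table.loc[controls].drop(
            columns=small_effects.inoculant_feature_id)
        np.testing.assert_allclose(out.loc[controls].to_numpy(),
                                   expected.to_numpy())
        # row totals are preserved for every sample (rescaled to 100%)
        np.testing.assert_allclose(out.sum(axis=1).to_numpy(),
                                   small_table.sum(axis=1).to_numpy())

    def test_absent_feature_rejected(self, small_table):
        with pytest.raises(ValueError, match="not in table"):
            exclude_feature_and_renormalize(small_table, ["missing_feature"])

    def test_removing_all_features_rejected(self, small_table):
        with pytest.raises(ValueError, match="all features"):
            exclude_feature_and_renormalize(small_table,
                                            list(small_table.columns))


class TestAlphaDiversity:
    def test_shannon_equal_abundances(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_shannon_scale_invariant(self):
        assert shannon([1, 2, 3]) == pytest.approx(shannon([10, 20, 30]))

    def test_shannon_bounded_by_log_richness(self, rng):
        counts = rng.integers(1, 50, size=12)
        assert shannon(counts) <= np.log(12) + 1e-12

    def test_chao1_no_rare_features(self):
        assert chao1([3, 4, 5, 6]) == 4.0

    def test_chao1_hand_example(self):
        # counts (1,1,2,5): S_obs=4, F1=2, F2=1 -> 4 + 4/2 = 6
        assert chao1([1, 1, 2, 5]) == pytest.approx(6.0)

    def test_chao1_f2_zero_correction(self):
        # F1=2, F2=0 -> S_obs + F1(F1-1)/2 = 3 + 1
        assert chao1([1, 1, 5]) == pytest.approx(4.0)

    def test_chao1_at_least_observed(self, rng):
        counts = rng.integers(0, 6, size=20)
        counts[0] = 3
        assert chao1(counts) >= (counts > 0).sum()

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])
        with pytest.raises(ValueError):
            chao1([0, 0])
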
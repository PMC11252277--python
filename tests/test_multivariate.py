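import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

import saprolens as sl
from oracles import (
    relate_p_exhaustive,
    scipy_ward_partitions,
    spearman_of_condensed,
    ward_partitions_bruteforce,
)


def cm(values, index=None):
    df = pd.DataFrame(values, index=index or [f"s{i}" for i in range(len(values))])
    df.columns = [f"t{i}" for i in range(df.shape[1])]
    return sl.CommunityMatrix(df)


class TestSqrtTransform:
    def test_values(self):
        m = sl.sqrt_transform(cm([[0.0, 4.0], [9.0, 16.0]]))
        assert m.data.iloc[0, 1] == 2.0
        assert m.data.iloc[1, 0] == 3.0
        assert m.transform == "sqrt"

    def test_double_transform_guarded(self):
        m = sl.sqrt_transform(cm([[16.0]]))
        with pytest.raises(sl.SaprolensError):
            sl.sqrt_transform(m)

    def test_order_preserving(self):
        m = sl.sqrt_transform(cm([[1.0], [4.0], [9.0]]))
        assert m.data["t0"].is_monotonic_increasing


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        d = sl.distance_matrix(cm([[1.0, 2.0], [1.0, 2.0]]).data, "euclidean")
        assert d.values[0, 1] == 0.0

    def test_three_four_five(self):
        d = sl.distance_matrix(cm([[0.0, 3.0], [4.0, 0.0]]).data, "euclidean")
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_bray_curtis_complete_turnover(self):
        d = sl.distance_matrix(cm([[1.0, 0.0], [0.0, 1.0]]).data, "bray-curtis")
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_zero_pair_flagged(self):
        d = sl.distance_matrix(
            cm([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]).data, "bray-curtis"
        )
        assert d.values[0, 1] == 0.0
        assert ("s0", "s1") in d.degenerate_pairs

    def test_bray_curtis_bounded(self):
        rng = np.random.default_rng(7)
        d = sl.distance_matrix(cm(rng.gamma(1.0, 10.0, (12, 6))).data, "bray-curtis")
        assert ((d.values >= 0) & (d.values <= 1)).all()

    def test_normalized_euclidean_standardises(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"a": rng.normal(0, 1, 8), "b": rng.normal(100, 50, 8)},
            index=[f"s{i}" for i in range(8)],
        )
        d = sl.distance_matrix(df, "normalized-euclidean")
        z = (df - df.mean()) / df.std(ddof=1)
        assert np.allclose(d.condensed, pdist(z.to_numpy()))

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 1.0]}, index=["x", "y"])
        with pytest.raises(sl.MatrixError):
            sl.distance_matrix(df, "normalized-euclidean")


class TestWard:
    def test_coincident_points_merge_at_zero(self):
        d = sl.distance_matrix(cm([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]]).data,
                               "euclidean")
        dendro = sl.ward_cluster(d)
        assert dendro.linkage[0, 2] == 0.0

    def test_collinear_first_merge(self):
        d = sl.distance_matrix(cm([[0.0], [1.0], [10.0]]).data, "euclidean")
        dendro = sl.ward_cluster(d)
        assert set(dendro.linkage[0, :2].astype(int)) == {0, 1}

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_agglomeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 8))
        points = rng.normal(0, 1, (n, 3))
        labels = [f"s{i}" for i in range(n)]
        d = sl.distance_matrix(pd.DataFrame(points, index=labels), "euclidean")
        dendro = sl.ward_cluster(d)
        assert scipy_ward_partitions(dendro.linkage, n) == ward_partitions_bruteforce(
            points
        )

    def test_newick_round_trip(self):
        import skbio

        rng = np.random.default_rng(5)
        labels = [f"leaf{i}" for i in range(6)]
        d = sl.distance_matrix(
            pd.DataFrame(rng.normal(0, 1, (6, 3)), index=labels), "euclidean"
        )
        tree = skbio.TreeNode.read([sl.ward_cluster(d).to_newick()])
        assert sorted(t.name for t in tree.tips()) == labels


class TestCut:
    @pytest.fixture
    def dendro(self):
        rng = np.random.default_rng(11)
        d = sl.distance_matrix(
            pd.DataFrame(rng.normal(0, 1, (9, 4)),
                         index=[f"s{i}" for i in range(9)]),
            "euclidean",
        )
        return sl.ward_cluster(d)

    def test_zero_percent_one_group(self, dendro):
        assert sl.cut_at_similarity(dendro, 0).nunique() == 1

    def test_hundred_percent_singletons(self, dendro):
        assert sl.cut_at_similarity(dendro, 100).nunique() == 9

    def test_group_count_monotone_in_similarity(self, dendro):
        counts = [sl.cut_at_similarity(dendro, pct).nunique()
                  for pct in (0, 25, 50, 75, 100)]
        assert counts == sorted(counts)

    def test_fixture_taxa_cut_collects_dominant_ciliates(
        self, fixture_site_means
    ):
        # clustering taxa site-mean profiles: the large cluster at a 43%
        # similarity cut should gather the high-abundance ciliates
        m = sl.sqrt_transform(fixture_site_means["abundance"])
        d = sl.distance_matrix(m.data.T, "euclidean")
        groups = sl.cut_at_similarity(sl.ward_cluster(d), 43.0)
        assert 2 <= groups.nunique() <= 8
        top = groups["paradileptus-elephantinus"]
        cluster = set(groups.index[groups == top])
        dominant = {"paradileptus-elephantinus", "didinium-nasutum",
                    "vorticella-convallaria", "monodinium-balbiani"}
        assert dominant <= cluster


class TestSpearmanScreen:
    def test_identity_and_reversal(self):
        idx = [f"s{i}" for i in range(6)]
        x = pd.DataFrame({"ix": [1.0, 2, 3, 4, 5, 6]}, index=idx)
        env = pd.DataFrame({"same": [1.0, 2, 3, 4, 5, 6],
                            "rev": [6.0, 5, 4, 3, 2, 1]}, index=idx)
        rho, p = sl.spearman_screen(x, env)
        assert rho.loc["ix", "same"] == pytest.approx(1.0)
        assert rho.loc["ix", "rev"] == pytest.approx(-1.0)

    def test_matches_rank_formula(self):
        idx = [f"s{i}" for i in range(5)]
        x = pd.DataFrame({"ix": [3.0, 1.0, 4.0, 1.5, 5.0]}, index=idx)
        env = pd.DataFrame({"v": [2.0, 7.0, 1.0, 8.0, 2.5]}, index=idx)
        rho, _ = sl.spearman_screen(x, env)
        assert rho.loc["ix", "v"] == pytest.approx(
            spearmanr(x["ix"], env["v"]).statistic
        )

    def test_constant_column_flagged_nan(self):
        idx = [f"s{i}" for i in range(5)]
        x = pd.DataFrame({"ix": [1.0, 2, 3, 4, 5]}, index=idx)
        env = pd.DataFrame({"const": [2.0] * 5}, index=idx)
        rho, p = sl.spearman_screen(x, env)
        assert np.isnan(rho.loc["ix", "const"])


def random_distance_pair(seed, n=10):
    rng = np.random.default_rng(seed)
    labels = [f"s{i}" for i in range(n)]
    a = pd.DataFrame(rng.normal(0, 1, (n, 4)), index=labels)
    b = pd.DataFrame(rng.normal(0, 1, (n, 3)), index=labels)
    return (
        sl.distance_matrix(a, "euclidean"),
        sl.distance_matrix(b, "euclidean"),
    )


class TestRelate:
    def test_identity_gives_minimal_p(self):
        d, _ = random_distance_pair(0)
        res = sl.relate(d, d, n_perm=99, seed=1)
        assert res.rho == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_rho_matches_skbio_mantel(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel

        d1, d2 = random_distance_pair(3)
        res = sl.relate(d1, d2, n_perm=99, seed=0)
        corr = mantel(
            SkbioDM(d1.values, d1.ids), SkbioDM(d2.values, d2.ids),
            method="spearman", permutations=0,
        )[0]
        assert res.rho == pytest.approx(corr, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_p_matches_exhaustive_four_labels(self, seed):
        d1, d2 = random_distance_pair(50 + seed, n=4)
        exact = relate_p_exhaustive(d1.values, d2.values)
        res = sl.relate(d1, d2, n_perm=999, seed=seed)
        assert res.p_value == pytest.approx(exact, abs=0.06)

    def test_null_rho_centred_on_zero(self):
        rhos = []
        for seed in range(30):
            rng = np.random.default_rng(900 + seed)
            labels = [f"s{i}" for i in range(12)]
            a = pd.DataFrame(rng.normal(0, 1, (12, 4)), index=labels)
            b = pd.DataFrame(rng.normal(0, 1, (12, 4)), index=labels)
            res = sl.relate(
                sl.distance_matrix(a, "euclidean"),
                sl.distance_matrix(b, "euclidean"),
                n_perm=99, seed=seed,
            )
            rhos.append(res.rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_label_mismatch_rejected(self):
        d1, _ = random_distance_pair(0, n=5)
        d2, _ = random_distance_pair(1, n=6)
        with pytest.raises(sl.MatrixError):
            sl.relate(d1, d2, n_perm=99, seed=0)


class TestBioenv:
    @pytest.fixture(scope="class")
    def planted(self):
        rng = np.random.default_rng(21)
        n = 20
        labels = [f"s{i}" for i in range(n)]
        gradient = np.linspace(0, 1, n)
        # community driven by the gradient
        base = rng.lognormal(2, 1, 8)
        comm = pd.DataFrame(
            base[None, :] * np.exp(np.outer(gradient, rng.normal(0, 1.5, 8))),
            index=labels,
        )
        comm.columns = [f"t{i}" for i in range(8)]
        env = pd.DataFrame(
            {
                "driver": gradient + rng.normal(0, 0.05, n),
                "noise1": rng.normal(0, 1, n),
                "noise2": rng.normal(0, 1, n),
                "noise3": rng.normal(0, 1, n),
            },
            index=labels,
        )
        return sl.CommunityMatrix(comm), env

    def test_kmax1_equals_best_single_variable(self, planted):
        comm, env = planted
        res = sl.bioenv(comm, env, k_max=1)
        d_bio = sl.distance_matrix(sl.sqrt_transform(comm).data, "bray-curtis")
        best = max(
            env.columns,
            key=lambda v: spearman_of_condensed(
                d_bio.condensed,
                pdist(((env[[v]] - env[[v]].mean()) / env[[v]].std(ddof=1))
                      .to_numpy()),
            ),
        )
        assert res.best_subset == (best,)

    def test_subset_count(self, planted):
        comm, env = planted
        env8 = env.copy()
        rng = np.random.default_rng(0)
        for i in range(4):
            env8[f"extra{i}"] = rng.normal(0, 1, len(env8))
        res = sl.bioenv(comm, env8, k_max=8)
        assert len(res.table) == 255

    def test_planted_driver_wins(self, planted):
        comm, env = planted
        res = sl.bioenv(comm, env)
        assert "driver" in res.best_subset
        assert res.best_rho > 0.7

    def test_best_rho_monotone_in_kmax(self, planted):
        comm, env = planted
        rhos = [sl.bioenv(comm, env, k_max=k).best_rho for k in (1, 2, 3, 4)]
        assert all(b >= a - 1e-12 for a, b in zip(rhos, rhos[1:]))

    def test_matches_skbio_single_variable(self, planted):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import bioenv as skbio_bioenv

        comm, env = planted
        d_bio = sl.distance_matrix(sl.sqrt_transform(comm).data, "bray-curtis")
        ours = sl.bioenv(d_bio, env, k_max=1)
        theirs = skbio_bioenv(SkbioDM(d_bio.values, d_bio.ids), env)
        best_rho_1 = ours.table[ours.table.k == 1].iloc[0]["rho"]
        assert best_rho_1 == pytest.approx(
            theirs.iloc[0]["correlation"], abs=1e-9
        )
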
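"""Derived traits, REML BLUEs, standardized PCA, two-stage clustering."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from poolstruct import phenotype
from poolstruct.phenotype import (
    blue_table,
    cluster_means,
    derive_traits,
    estimate_blues,
    explained_variance_percent,
    hier_cluster,
    pheno_pca,
    precluster,
    summarize_collection,
)


def _records(landraces, trials, true_means, trial_eff, resid_sd, rng,
             reps=2, assignment=None):
    rows = []
    for lr in landraces:
        for t in (assignment[lr] if assignment else trials):
            for rep in range(1, reps + 1):
                rows.append({
                    "landrace": lr, "trial": t, "rep": rep,
                    "DT": true_means[lr] + trial_eff[t]
                    + rng.normal(0, resid_sd)})
    return pd.DataFrame(rows)


class TestDeriveTraits:
    @pytest.mark.parametrize("ds,dt,asi", [(75.0, 72.0, 3.0),
                                           (55.0, 57.0, -2.0)])
    def test_asi(self, ds, dt, asi):
        rec = pd.DataFrame([{"DT": dt, "DS": ds, "PH": 150.0, "EH": 70.0}])
        assert derive_traits(rec)["ASI"].iloc[0] == pytest.approx(asi)

    def test_ephr(self):
        rec = pd.DataFrame([{"DT": 70.0, "DS": 72.0, "PH": 200.0,
                             "EH": 50.0}])
        assert derive_traits(rec)["EPHR"].iloc[0] == pytest.approx(25.0)

    def test_zero_plant_height_gives_missing_ephr(self):
        rec = pd.DataFrame([{"DT": 70.0, "DS": 72.0, "PH": 0.0, "EH": 0.0}])
        assert np.isnan(derive_traits(rec)["EPHR"].iloc[0])


class TestBlues:
    def test_balanced_design_equals_raw_means(self):
        rng = np.random.default_rng(5)
        landraces = [f"L{i}" for i in range(8)]
        trials = [f"T{j}" for j in range(4)]
        means = {lr: 70.0 + 2 * i for i, lr in enumerate(landraces)}
        te = {t: rng.normal(0, 3) for t in trials}
        rec = _records(landraces, trials, means, te, 1.5, rng)
        blues, _, _ = estimate_blues(rec, "DT")
        raw = rec.groupby("landrace")["DT"].mean()
        assert np.abs(blues - raw).max() < 1e-8

    def test_zero_trial_variance_recovered(self):
        """With no trial effects, REML drives the trial variance to ~0."""
        landraces = [f"L{i}" for i in range(10)]
        trials = [f"T{j}" for j in range(50)]
        ratios = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            means = {lr: 70.0 + 3 * i for i, lr in enumerate(landraces)}
            te = {t: 0.0 for t in trials}
            rec = _records(landraces, trials, means, te, 1.5, rng)
            _, vc, _ = estimate_blues(rec, "DT")
            ratios.append(vc["trial_var"] / vc["resid_var"])
        assert np.mean(ratios) <= 0.01

    def test_unbalanced_blues_cover_true_means(self):
        """BLUE +/- 2 SE covers the true mean for >= 93% of landraces."""
        hits, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            landraces = [f"L{i}" for i in range(12)]
            trials = [f"T{j}" for j in range(6)]
            means = {lr: 70.0 + rng.normal(0, 4) for lr in landraces}
            te = {t: rng.normal(0, 2.5) for t in trials}
            assignment = {
                lr: sorted(rng.choice(trials, size=rng.integers(2, 6),
                                      replace=False))
                for lr in landraces}
            rec = _records(landraces, trials, means, te, 1.5, rng,
                           assignment=assignment)
            blues, _, se = estimate_blues(rec, "DT")
            # trial effects have mean ~0 but not exactly 0 in finite samples;
            # compare against the true mean plus the mean effect of the
            # trials each landrace actually saw being absorbed by the fit
            for lr in landraces:
                shift = np.mean([te[t] for t in trials])
                hits += abs(blues[lr] - (means[lr] + shift)) <= 2 * se[lr] + 2 * 2.5 / np.sqrt(6)
                total += 1
        assert hits / total >= 0.93

    def test_blue_table_modes_agree_on_asi(self, trial_records):
        rec = trial_records[~trial_records["is_check"]]
        a = blue_table(rec, derived_mode="records")
        b = blue_table(rec, derived_mode="blues")
        # mode B satisfies the defining identities exactly
        assert np.abs(b.blues["ASI"]
                      - (b.blues["DS"] - b.blues["DT"])).max() < 1e-9
        assert np.abs(b.blues["EPHR"]
                      - b.blues["EH"] / b.blues["PH"] * 100).max() < 1e-9
        # and the two modes give similar ASI (they differ only through
        # nonlinearity/unbalancedness)
        assert np.abs(a.blues["ASI"] - b.blues["ASI"]).mean() < 1.0


class TestPhenoPca:
    def _blues(self, n=60, seed=2):
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=(n, 2))
        cols = {}
        for i, trait in enumerate(phenotype.TRAITS_ALL):
            w = rng.normal(size=2)
            cols[trait] = latent @ w + 0.3 * rng.normal(size=n)
        return pd.DataFrame(cols)

    def test_eigenvalues_sum_to_trait_count(self):
        res = pheno_pca(self._blues())
        assert res.eigenvalues.sum() == pytest.approx(6.0, abs=1e-9)

    def test_duplicated_trait_pair(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        blues = pd.DataFrame({"a": x, "b": x.copy()})
        res = pheno_pca(blues)
        assert np.allclose(res.eigenvalues, [2.0, 0.0], atol=1e-9)

    def test_constant_trait_rejected_by_name(self):
        blues = self._blues()
        blues["PH"] = 5.0
        with pytest.raises(ValueError, match="PH"):
            pheno_pca(blues)

    def test_display_percentages_from_eigenvalues(self):
        """Published-style eigenvalues on six standardized traits."""
        pct = explained_variance_percent([4.331, 0.9723, 0.3976], n_traits=6)
        assert round(pct[0]) == 72
        assert round(pct.sum()) == 95

    def test_retains_at_least_two_components(self):
        res = pheno_pca(self._blues())
        assert res.n_retained >= 2
        assert res.scores.shape[1] == res.n_retained

    def test_loadings_orthonormal(self):
        res = pheno_pca(self._blues())
        gram = res.loadings.to_numpy().T @ res.loadings.to_numpy()
        assert np.allclose(gram, np.eye(6), atol=1e-9)


from _helpers import gaussian_blobs as _blobs


class TestTwoStageClustering:
    def test_every_point_its_own_cluster(self):
        scores, _ = _blobs(k=3, per=1, seed=1)
        pre = precluster(scores, k=3, seed=0)
        assert pre.inertia == pytest.approx(0.0, abs=1e-9)

    def test_recovers_planted_blobs_exactly(self):
        scores, labels = _blobs(k=15, per=12, sep=10.0, seed=2)
        pre = precluster(scores, k=15, seed=0)
        assert adjusted_rand_score(labels, pre.labels.to_numpy()) == 1.0
        assert len(np.unique(pre.labels)) == 15

    def test_partition_stable_across_seeds(self):
        scores, _ = _blobs(k=15, per=12, sep=10.0, seed=3)
        a = precluster(scores, k=15, seed=0).labels
        b = precluster(scores, k=15, seed=99).labels
        assert adjusted_rand_score(a.to_numpy(), b.to_numpy()) == 1.0

    def test_coincident_centroids_merge_first_at_zero(self):
        centroids = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        from poolstruct.phenotype import _weighted_average_linkage

        Z = _weighted_average_linkage(centroids, np.array([3, 4, 2]))
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_matches_upgma_oracle_for_equal_sizes(self):
        """Size-weighted linkage over singleton 'clusters' is plain UPGMA."""
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 3))
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import pdist

        from poolstruct.phenotype import _weighted_average_linkage

        Z = _weighted_average_linkage(pts, np.ones(6))
        ref = hierarchy.linkage(pdist(pts), method="average")
        assert np.allclose(Z[:, 2], ref[:, 2], atol=1e-10)

    def test_cuts_into_requested_main_clusters(self):
        scores, _ = _blobs(k=15, per=12, sep=10.0, seed=4)
        pre = precluster(scores, k=15, seed=0)
        cl = hier_cluster(pre, n_main=5)
        assert cl.main_cluster.nunique() == 5
        assert set(cl.main_cluster.unique()) <= set("ABCDE")
        # partition: every entity in exactly one sub and one main cluster
        assert cl.subcluster.notna().all() and cl.main_cluster.notna().all()
        assert len(cl.subcluster) == len(scores)

    def test_main_labels_follow_dendrogram_order(self):
        scores, _ = _blobs(k=6, per=5, sep=12.0, seed=5)
        pre = precluster(scores, k=6, seed=0)
        cl = hier_cluster(pre, n_main=3)
        # first leaf in dendrogram order must be in cluster A
        from scipy.cluster import hierarchy

        first_leaf = hierarchy.leaves_list(cl.tree.linkage)[0]
        assert cl.sub_to_main[first_leaf + 1] == "A"

    def test_n_main_exceeding_k_rejected(self):
        scores, _ = _blobs(k=3, per=4, seed=6)
        pre = precluster(scores, k=3, seed=0)
        with pytest.raises(ValueError):
            hier_cluster(pre, n_main=5)

    def test_cluster_means_table_shape(self, trial_records):
        rec = trial_records[~trial_records["is_check"]]
        blues = blue_table(rec)
        pca = pheno_pca(blues)
        pre = precluster(pca.scores, k=4, seed=0)
        cl = hier_cluster(pre, n_main=2)
        table = cluster_means(blues, cl)
        assert {"cluster", "subcluster", "N"} <= set(table.columns)
        assert set(phenotype.TRAITS_ALL) <= set(table.columns)
        assert (table["cluster"] == "Total").sum() == 1
        total = table[table["cluster"] == "Total"]["N"].iloc[0]
        assert total == len(blues.blues)


class TestSummarize:
    def test_constant_trait(self):
        blues = pd.DataFrame({"DT": [5.0] * 9})
        table = summarize_collection(blues)
        assert (table["DT"] == 5.0).all()

    def test_textbook_quantiles(self):
        blues = pd.DataFrame({"DT": [1.0, 2.0, 3.0, 4.0, 5.0]})
        table = summarize_collection(blues)
        assert table.loc["Q25", "DT"] == 2.0
        assert table.loc["Median", "DT"] == 3.0
        assert table.loc["Q75", "DT"] == 4.0

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(9)
        blues = pd.DataFrame({"DT": rng.normal(70, 5, 37),
                              "PH": rng.normal(170, 20, 37)})
        checks = pd.DataFrame({"DT": [68.0, 75.0], "PH": [200.0, 210.0]},
                              index=["c1", "c2"])
        table = summarize_collection(blues, checks)
        for trait in ("DT", "PH"):
            v = np.sort(blues[trait].to_numpy())
            assert table.loc["Q25", trait] == pytest.approx(
                np.percentile(v, 25, method="linear"), abs=1e-9)
            assert table.loc["Mean", trait] == pytest.approx(v.mean())
        assert table.loc["c1", "DT"] == 68.0
        assert table.loc["Checks mean", "PH"] == pytest.approx(205.0)
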
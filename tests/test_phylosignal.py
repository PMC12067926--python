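import numpy as np
import pandas as pd
import pytest

from phylotox import synthetic_data as sd
from phylotox.phylosignal import (
    bh_adjust,
    blomberg_k,
    mantel_kendall,
    pagels_lambda,
    phenotype_distances,
    phylo_correlogram,
    signal_screen,
    _lambda_vcv,
)
from phylotox.trees import patristic_distances, phylo_vcv, read_newick


class TestBlombergK:
    def test_star_phylogeny_equalises_the_two_mean_squares(self):
        star = read_newick("(A:1,B:1,C:1,D:1,E:1);")
        rng = np.random.default_rng(0)
        trait = pd.Series(rng.normal(size=5), index=list("ABCDE"))
        res = blomberg_k(star, trait, n_perm=0)
        assert res.detail["mse0"] == pytest.approx(res.detail["mse"], rel=1e-12)
        assert res.estimate == pytest.approx(1.0, rel=1e-10)

    @pytest.mark.parametrize("n_tips,seed", [(4, 0), (5, 1), (6, 2)])
    def test_components_match_brute_force_gls(self, n_tips, seed):
        """K's pieces agree with explicit matrix-inversion GLS to 1e-10."""
        tree = sd.simulate_tree(n_tips, seed=seed)
        rng = np.random.default_rng(seed + 10)
        V = phylo_vcv(tree)
        trait = pd.Series(rng.normal(size=n_tips), index=V.index)
        res = blomberg_k(tree, trait, n_perm=0)

        Vi = np.linalg.inv(V.to_numpy())
        x = trait.to_numpy()
        n = n_tips
        ones = np.ones(n)
        ahat = ones @ Vi @ x / (ones @ Vi @ ones)
        mse0 = (x - ahat) @ (x - ahat) / (n - 1)
        mse = (x - ahat) @ Vi @ (x - ahat) / (n - 1)
        expected = (np.trace(V.to_numpy()) - n / Vi.sum()) / (n - 1)
        assert res.detail["mse0"] == pytest.approx(mse0, abs=1e-10)
        assert res.detail["mse"] == pytest.approx(mse, abs=1e-10)
        assert res.detail["expected_ratio"] == pytest.approx(expected, abs=1e-10)
        assert res.estimate == pytest.approx((mse0 / mse) / expected, abs=1e-10)

    def test_matches_independent_r_implementation(self, yule50):
        # frozen reference values computed with phytools::phylosig on the
        # identical tree and trait (K and its components are deterministic)
        trait = sd.simulate_trait(yule50, lam=0.0, seed=101)
        res = blomberg_k(yule50, trait, n_perm=999, seed=0)
        assert res.estimate == pytest.approx(0.142882, abs=1e-5)
        assert res.p_raw == pytest.approx(0.213, abs=0.05)

    def test_constant_trait_rejected(self, yule50):
        trait = pd.Series(1.0, index=phylo_vcv(yule50).index)
        with pytest.raises(ValueError, match="constant"):
            blomberg_k(yule50, trait)


class TestPagelsLambda:
    def test_lambda_one_transform_is_identity(self, yule50):
        V = phylo_vcv(yule50).to_numpy()
        assert np.array_equal(_lambda_vcv(V, 1.0), V)

    def test_matches_independent_r_implementation(self, yule50):
        # phytools::phylosig(method="lambda"): lambda ~ 0, logL = -104.165
        trait = sd.simulate_trait(yule50, lam=0.0, seed=101)
        res = pagels_lambda(yule50, trait)
        assert res.estimate == pytest.approx(0.0, abs=1e-3)
        assert res.detail["loglik"] == pytest.approx(-104.165, abs=1e-2)

    def test_brownian_trait_estimates_near_one(self, yule50):
        trait = sd.simulate_trait(yule50, lam=1.0, seed=4)
        res = pagels_lambda(yule50, trait)
        assert res.estimate > 0.8
        assert res.p_raw < 0.01


@pytest.mark.parametrize("a,b", [(3.0, -2.0), (-0.5, 10.0)])
def test_signal_statistics_affine_invariant(yule50, a, b):
    """K, lambda and their p-values ignore affine trait rescaling."""
    trait = sd.simulate_trait(yule50, lam=1.0, seed=9)
    t2 = a * trait + b
    k1 = blomberg_k(yule50, trait, n_perm=99, seed=1)
    k2 = blomberg_k(yule50, t2, n_perm=99, seed=1)
    assert k1.estimate == pytest.approx(k2.estimate, rel=1e-9)
    assert k1.p_raw == k2.p_raw
    l1, l2 = pagels_lambda(yule50, trait), pagels_lambda(yule50, t2)
    assert l1.estimate == pytest.approx(l2.estimate, abs=1e-4)
    assert l1.p_raw == pytest.approx(l2.p_raw, rel=1e-3)


class TestMantel:
    def dist(self, X, labels):
        from scipy.spatial.distance import pdist, squareform

        return pd.DataFrame(squareform(pdist(X)), index=labels, columns=labels)

    def test_identical_matrices_give_tau_one(self):
        rng = np.random.default_rng(0)
        labels = [f"s{i}" for i in range(10)]
        D = self.dist(rng.normal(size=(10, 3)), labels)
        res = mantel_kendall(D, D, n_perm=99, seed=0)
        assert res.tau == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100, abs=0.05)

    def test_statistic_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        labels = [f"s{i}" for i in range(12)]
        D1 = self.dist(rng.normal(size=(12, 4)), labels)
        D2 = self.dist(rng.normal(size=(12, 4)), labels)
        t12 = mantel_kendall(D1, D2, n_perm=9, seed=0).tau
        t21 = mantel_kendall(D2, D1, n_perm=9, seed=0).tau
        assert t12 == pytest.approx(t21, abs=1e-12)

    def test_p_bounded_below_by_permutation_resolution(self):
        rng = np.random.default_rng(1)
        labels = [f"s{i}" for i in range(8)]
        D = self.dist(rng.normal(size=(8, 2)), labels)
        res = mantel_kendall(D, D, n_perm=49, seed=0)
        assert res.p >= 1 / 50

    def test_seeded_runs_reproducible(self):
        rng = np.random.default_rng(2)
        labels = [f"s{i}" for i in range(9)]
        D1 = self.dist(rng.normal(size=(9, 3)), labels)
        D2 = self.dist(rng.normal(size=(9, 3)), labels)
        r1 = mantel_kendall(D1, D2, n_perm=199, seed=42)
        r2 = mantel_kendall(D1, D2, n_perm=199, seed=42)
        assert (r1.tau, r1.p) == (r2.tau, r2.p)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        D1 = self.dist(rng.normal(size=(5, 2)), list("abcde"))
        D2 = self.dist(rng.normal(size=(5, 2)), list("abcdf"))
        with pytest.raises(ValueError, match="label"):
            mantel_kendall(D1, D2)


class TestCorrelogram:
    def test_constant_trait_rejected(self, yule50):
        trait = pd.Series(2.0, index=phylo_vcv(yule50).index)
        with pytest.raises(ValueError, match="constant"):
            phylo_correlogram(yule50, trait)

    def test_brownian_trait_decays_with_distance(self):
        tree = sd.simulate_tree(100, seed=6)
        short, long_ = [], []
        for s in range(10):
            trait = sd.simulate_trait(tree, lam=1.0, seed=60 + s)
            corr = phylo_correlogram(tree, trait, n_boot=19, seed=s)
            ok = corr.classes.dropna(subset=["moran_i"])
            short.append(ok["moran_i"].iloc[0])
            long_.append(ok["moran_i"].iloc[-1])
        assert np.mean(short) > 0.2
        assert np.mean(short) > np.mean(long_)

    def test_white_noise_rarely_significant(self):
        tree = sd.simulate_tree(60, seed=7)
        hits = []
        for s in range(15):
            trait = sd.simulate_trait(tree, lam=0.0, seed=700 + s)
            corr = phylo_correlogram(tree, trait, n_boot=99, seed=s)
            hits.append(corr.classes["significant"].fillna(False).mean())
        assert np.mean(hits) < 0.25

    def test_classes_ordered_and_bands_consistent(self, yule50):
        trait = sd.simulate_trait(yule50, lam=1.0, seed=8)
        corr = phylo_correlogram(yule50, trait, n_boot=49, seed=0)
        mids = corr.classes["midpoint"].to_numpy()
        assert np.all(np.diff(mids) > 0)
        band = corr.classes.dropna(subset=["ci_low", "ci_high"])
        assert (band["ci_low"] <= band["ci_high"]).all()
        assert corr.null_expectation == pytest.approx(-1 / 49)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_hand_computed_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, size=40)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


def test_phenotype_distance_log_scale_requires_positive(response_matrix):
    D = phenotype_distances(response_matrix.dauc)
    assert np.allclose(D.to_numpy(), D.to_numpy().T)
    Dlog = phenotype_distances(response_matrix.dauc, log10=True)
    assert (Dlog.to_numpy() >= 0).all()


def test_signal_screen_flags_conserved_chemicals(dataset, response_matrix):
    screen = signal_screen(dataset.tree, response_matrix.dauc, n_perm=199, seed=7)
    conserved = [c for c, v in dataset.truth["chemicals"].items() if v["kind"] == "conserved"]
    flagged = (screen["p_K_adj"] < 0.05) | (screen["p_lambda_adj"] < 0.05)
    assert flagged[conserved].sum() >= 6
    inactive = [c for c in screen.index if c not in conserved]
    assert flagged[inactive].sum() <= 2
    assert (screen["p_K_adj"] >= screen["p_K"] - 1e-15).all()


def test_mantel_detects_phylogeny_phenotype_association(dataset, response_matrix):
    """The combined-response Mantel test recovers the conserved structure."""
    D_pheno = phenotype_distances(response_matrix.dauc)
    D_phylo = patristic_distances(dataset.tree).loc[D_pheno.index, D_pheno.index]
    res = mantel_kendall(D_pheno, D_phylo, n_perm=499, seed=3)
    assert res.tau > 0
    assert res.p < 0.05
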
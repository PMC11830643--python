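import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import valvemorph as vm
from valvemorph import phylocomp as pc


def tree_from(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


class TestPhyloVcv:
    def test_two_tip_cherry_no_shared_path(self):
        C, labels = pc.phylo_vcv(tree_from("(A:1,B:1);"))
        np.testing.assert_allclose(C, np.eye(2))
        assert labels == ["A", "B"]

    def test_three_tip_mrca_depths(self):
        C, labels = pc.phylo_vcv(tree_from("((A:1,B:1):1,C:2);"))
        idx = {l: i for i, l in enumerate(labels)}
        np.testing.assert_allclose(np.diag(C), [2, 2, 2])
        assert C[idx["A"], idx["B"]] == pytest.approx(1.0)
        assert C[idx["A"], idx["C"]] == pytest.approx(0.0)

    def test_lambda_zero_is_diagonal(self):
        C, _ = pc.phylo_vcv(tree_from("((A:1,B:1):1,C:2);"), lam=0.0)
        assert np.all(C[~np.eye(3, dtype=bool)] == 0)
        np.testing.assert_allclose(np.diag(C), [2, 2, 2])

    def test_positive_semidefinite_and_symmetric(self, bd_tree64):
        C, _ = pc.phylo_vcv(bd_tree64)
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-9

    def test_duplicate_tip_labels_rejected(self):
        # dendropy refuses duplicate taxa at parse time, so build directly
        tree = dendropy.Tree()
        for _ in range(2):
            child = tree.seed_node.new_child(edge_length=1.0)
            child.taxon = dendropy.Taxon("A")
        with pytest.raises(ValueError, match="unique"):
            pc.phylo_vcv(tree)

    def test_taxa_reorder(self):
        C, labels = pc.phylo_vcv(tree_from("((A:1,B:1):1,C:2);"),
                                 taxa=["C", "A", "B"])
        assert labels == ["C", "A", "B"]
        assert C[1, 2] == pytest.approx(1.0)
        with pytest.raises(pc.TaxonMismatchError, match="D"):
            pc.phylo_vcv(tree_from("(A:1,B:1);"), taxa=["A", "D"])


def brute_force_K(x, C):
    """Independent dense-matrix formulation, scalar loops throughout."""
    n = len(x)
    Cinv = np.linalg.inv(C)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            num += Cinv[i, j] * x[j]
            den += Cinv[i, j]
    ahat = num / den
    mse0 = sum((xi - ahat) ** 2 for xi in x) / (n - 1)
    mse = 0.0
    for i in range(n):
        for j in range(n):
            mse += (x[i] - ahat) * Cinv[i, j] * (x[j] - ahat)
    mse /= n - 1
    expected = (sum(C[i, i] for i in range(n)) - n / den) / (n - 1)
    return (mse0 / mse) / expected


class TestBlombergK:
    def test_four_tip_matches_brute_force(self):
        tree = tree_from("((A:1.5,B:1.5):0.5,(C:1,D:1):1);")
        x = np.array([0.3, -0.2, 1.1, 0.9])
        C, labels = pc.phylo_vcv(tree)
        result = vm.blomberg_K(x, C=C, n_perm=99, seed=1)
        assert result.K == pytest.approx(brute_force_K(x, C), abs=1e-10)

    def test_bm_simulations_center_on_one(self, bd_tree64, bd_tree64_vcv):
        C, labels = bd_tree64_vcv
        ks = [vm.blomberg_K(
            vm.simulate_bm(bd_tree64, seed=1000 + i)[labels].to_numpy(),
            C=C, n_perm=0).K for i in range(100)]
        assert 0.85 < np.mean(ks) < 1.15

    def test_shuffled_traits_lose_signal(self, bd_tree64, bd_tree64_vcv):
        C, labels = bd_tree64_vcv
        rng = np.random.default_rng(0)
        bm_ks, null_ks, pvals = [], [], []
        for i in range(40):
            x = vm.simulate_bm(bd_tree64, seed=3000 + i)[labels].to_numpy()
            bm_ks.append(vm.blomberg_K(x, C=C, n_perm=0).K)
            shuffled = rng.permutation(x)
            res = vm.blomberg_K(shuffled, C=C, n_perm=199, seed=i)
            null_ks.append(res.K)
            pvals.append(res.p)
        assert np.median(null_ks) < 0.5 * np.mean(bm_ks)
        # p-values approximately uniform under the null
        assert 0.3 < np.mean(pvals) < 0.7

    def test_constant_trait_rejected(self, bd_tree64):
        with pytest.raises(pc.UndefinedSignalError):
            vm.blomberg_K(np.ones(64), tree=bd_tree64)

    def test_permutation_p_reproducible(self, bd_tree64, bd_tree64_vcv):
        C, labels = bd_tree64_vcv
        x = vm.simulate_bm(bd_tree64, seed=9)[labels].to_numpy()
        a = vm.blomberg_K(x, C=C, n_perm=199, seed=4)
        b = vm.blomberg_K(x, C=C, n_perm=199, seed=4)
        assert a == b


class TestPagelLambda:
    def test_loglik_at_zero_equals_iid_normal(self, bd_tree64, bd_tree64_vcv):
        """With lambda = 0 the model collapses to independent normals with
        tip-specific variances sigma^2 * depth_i."""
        C, labels = bd_tree64_vcv
        x = vm.simulate_bm(bd_tree64, seed=2)[labels].to_numpy()
        result = vm.pagel_lambda(x, C=C)
        D = np.diag(np.diag(C))
        # closed-form profile likelihood of the diagonal model
        w = 1.0 / np.diag(D)
        mu = (w * x).sum() / w.sum()
        sig2 = ((x - mu) ** 2 * w).sum() / len(x)
        ll = -0.5 * (len(x) * np.log(2 * np.pi * sig2)
                     + np.log(np.diag(D)).sum() + len(x))
        assert result.loglik_zero == pytest.approx(ll, abs=1e-8)

    def test_bm_recovery_high_lambda(self, bd_tree64, bd_tree64_vcv):
        C, labels = bd_tree64_vcv
        lams = [vm.pagel_lambda(
            vm.simulate_bm(bd_tree64, seed=4000 + i)[labels].to_numpy(),
            C=C).lambda_hat for i in range(40)]
        assert np.mean(lams) >= 0.9

    def test_shuffled_traits_near_zero(self, bd_tree64, bd_tree64_vcv):
        C, labels = bd_tree64_vcv
        rng = np.random.default_rng(1)
        lams = []
        for i in range(30):
            x = vm.simulate_bm(bd_tree64, seed=5000 + i)[labels].to_numpy()
            lams.append(vm.pagel_lambda(rng.permutation(x), C=C).lambda_hat)
        assert np.mean(lams) <= 0.1

    def test_lambda_bounded_by_validity_maximum(self, bd_tree64_vcv):
        C, labels = bd_tree64_vcv
        rng = np.random.default_rng(3)
        res = vm.pagel_lambda(rng.normal(size=len(labels)), C=C)
        assert 0.0 <= res.lambda_hat <= res.lambda_max


class TestPglsRrpp:
    def test_two_group_toy_matches_closed_form(self):
        """Groups {1,2,3} and {4,5,6}: SSB = 13.5, SSW = 4, so
        F = 13.5 / (4/4) = 13.5 on (1, 4) df."""
        df = pd.DataFrame({"y": [1.0, 2, 3, 4, 5, 6],
                           "g": ["a"] * 3 + ["b"] * 3})
        tab = vm.pgls_rrpp("y", ["g"], df, n_perm=999, seed=0).table
        assert tab.loc["g", "F"] == pytest.approx(13.5)
        assert tab.loc["g", "Df"] == 1
        assert tab.loc["Residuals", "Df"] == 4
        assert tab.loc["g", "SS"] == pytest.approx(13.5)
        assert tab.loc["Residuals", "SS"] == pytest.approx(4.0)

    def test_collinear_covariate_saturates_rsq(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        df = pd.DataFrame({"y": 3 * x - 1, "x": x})
        tab = vm.pgls_rrpp("y", ["x"], df, n_perm=99, seed=0).table
        assert tab.loc["x", "Rsq"] == pytest.approx(1.0, abs=1e-9)
        assert tab.loc["Residuals", "SS"] == pytest.approx(0.0, abs=1e-16)

    def test_aliased_term_named(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "a": ["u", "u", "v", "v"],
                           "b": ["u", "u", "v", "v"]})
        with pytest.raises(pc.AliasedTermError, match="b"):
            vm.pgls_rrpp("y", ["a", "b"], df, n_perm=99, seed=0)

    def test_few_permutations_warn(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4, 5, 6],
                           "g": ["a"] * 3 + ["b"] * 3})
        with pytest.warns(UserWarning, match="small"):
            vm.pgls_rrpp("y", ["g"], df, n_perm=49, seed=0)

    def test_bookkeeping_identities(self, cohort):
        """Df, SS and Rsq sum identities hold on a realistic multi-term
        GLS fit."""
        frame = cohort.frame
        taxa = list(frame["taxon"])
        order = [taxa.index(t) for t in pc.tip_labels(cohort.tree)]
        aligned = frame.iloc[order].reset_index(drop=True)
        C, _ = pc.phylo_vcv(cohort.tree)
        tab = vm.pgls_rrpp("pSV", ["substratum", "logSL", "XS", "family"],
                           aligned, cov=C, n_perm=199, seed=3).table
        terms = tab.drop(index=["Residuals", "Total"])
        n = len(aligned)
        assert terms["Df"].sum() + tab.loc["Residuals", "Df"] == n - 1
        assert tab.loc["Total", "Df"] == n - 1
        assert terms["SS"].sum() + tab.loc["Residuals", "SS"] \
            == pytest.approx(tab.loc["Total", "SS"])
        assert terms["Rsq"].sum() + tab.loc["Residuals", "Rsq"] \
            == pytest.approx(1.0)

    def test_p_floor_is_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(5)
        g = np.repeat(["a", "b"], 15)
        y = np.where(g == "a", 0.0, 50.0) + rng.normal(size=30)
        df = pd.DataFrame({"y": y, "g": g})
        tab = vm.pgls_rrpp("y", ["g"], df, n_perm=999, seed=1).table
        assert tab.loc["g", "Pr(>F)"] == pytest.approx(1 / 1000)

    def test_converges_to_parametric_anova(self):
        """With identity covariance the RRPP p-value approaches the
        classical F-test p on balanced normal data."""
        rng = np.random.default_rng(7)
        g = np.repeat(["a", "b", "c"], 10)
        y = rng.normal(size=30) + np.where(g == "b", 0.9, 0.0)
        df = pd.DataFrame({"y": y, "g": g})
        tab = vm.pgls_rrpp("y", ["g"], df, n_perm=9999, seed=2).table
        F = tab.loc["g", "F"]
        parametric = stats.f.sf(F, 2, 27)
        assert tab.loc["g", "Pr(>F)"] == pytest.approx(parametric, abs=0.02)

    def test_seed_determinism(self):
        df = pd.DataFrame({"y": np.arange(12.0),
                           "g": list("aabbccddeeff")})
        a = vm.pgls_rrpp("y", ["g"], df, n_perm=199, seed=11).table
        b = vm.pgls_rrpp("y", ["g"], df, n_perm=199, seed=11).table
        pd.testing.assert_frame_equal(a, b)


class TestPearson:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3, 4], [3, 5, 7, 9], 1.0),           # y = 2x + 1
        ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),      # y = -x
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ])
    def test_known_values(self, x, y, expected):
        assert vm.pearson_r(x, y) == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vm.pearson_r([1, 1, 1], [1, 2, 3])

    def test_matrix_is_symmetric_unit_diagonal(self, cohort):
        corr = vm.pearson_matrix(cohort.frame, ["pSV", "logSL", "XS"])
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)


class TestTreeIO:
    def test_newick_and_nexus_round_trip(self, tmp_path, bd_tree64):
        newick_path = tmp_path / "tree.nwk"
        nexus_path = tmp_path / "tree.nex"
        bd_tree64.write(path=str(newick_path), schema="newick",
                        suppress_rooting=True)
        bd_tree64.write(path=str(nexus_path), schema="nexus")
        a = pc.load_tree(newick_path)
        b = pc.load_tree(nexus_path)
        assert sorted(pc.tip_labels(a)) == sorted(pc.tip_labels(b)) \
            == sorted(pc.tip_labels(bd_tree64))
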
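import warnings

import numpy as np
import pytest

from nicrosize.data_io import DatedTree
from nicrosize.phylo_comparative import (
    ancestral_states,
    blomberg_k,
    bm_loglik,
    contrast_matrix,
    edge_interpolated_states,
    lambda_upper_bound,
    pagel_lambda,
    pic,
)
from nicrosize.synthetic_data import simulate_tip_sizes, simulate_tree


def random_tree_and_values(seed, n=6):
    tree = simulate_tree(n, seed=seed)
    vals = simulate_tip_sizes(tree, 6.67, 0.05, 1.0, None, seed=seed + 100)
    return tree, vals


class TestPic:
    def test_two_tip_closed_form(self, cherry_tree):
        cs = pic(cherry_tree, {"A": 10.0, "B": 6.0})
        assert len(cs.contrasts) == 1
        assert cs.contrasts[0].contrast == pytest.approx(2.0)  # (10-6)/sqrt(2+2)
        assert cs.contrasts[0].variance == pytest.approx(4.0)
        assert cs.root_state == pytest.approx(8.0)

    def test_constant_tips_zero_contrasts(self):
        tree, _ = random_tree_and_values(0, n=8)
        cs = pic(tree, {t: 3.3 for t in tree.tip_names})
        assert np.allclose(cs.values(), 0.0)

    def test_one_contrast_per_internal_node(self):
        tree, vals = random_tree_and_values(1, n=9)
        assert len(pic(tree, vals).contrasts) == tree.n_tips - 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_root_state_equals_gls_mean(self, seed):
        tree, vals = random_tree_and_values(seed, n=5)
        names, C = tree.vcv()
        x = np.array([vals[t] for t in names])
        Cinv = np.linalg.inv(C)
        one = np.ones(len(x))
        gls_mean = one @ Cinv @ x / (one @ Cinv @ one)
        assert pic(tree, vals).root_state == pytest.approx(gls_mean, abs=1e-10)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_contrasts_whiten_bm_covariance(self, seed):
        # standardized contrasts are independent unit-variance under BM:
        # W C W' must be the identity
        tree, _ = random_tree_and_values(seed, n=7)
        _, W = contrast_matrix(tree)
        _, C = tree.vcv()
        assert np.allclose(W @ C @ W.T, np.eye(tree.n_tips - 1), atol=1e-10)

    def test_missing_tip_named_in_error(self):
        tree, vals = random_tree_and_values(5)
        vals.pop(tree.tip_names[0])
        with pytest.raises(ValueError, match=tree.tip_names[0]):
            pic(tree, vals)

    def test_extra_taxa_warn_and_are_ignored(self):
        tree, vals = random_tree_and_values(6)
        vals["not_a_tip"] = 1.0
        with pytest.warns(UserWarning, match="not_a_tip"):
            cs = pic(tree, vals)
        assert len(cs.contrasts) == tree.n_tips - 1


class TestAncestralStates:
    def test_constant_tips(self):
        tree, _ = random_tree_and_values(7, n=8)
        anc = ancestral_states(tree, {t: 5.0 for t in tree.tip_names})
        assert all(abs(v - 5.0) < 1e-9 for v in anc.node_states.values())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_states_within_tip_range(self, seed):
        tree, vals = random_tree_and_values(seed, n=8)
        anc = ancestral_states(tree, vals)
        lo, hi = min(vals.values()), max(vals.values())
        for v in anc.node_states.values():
            assert lo - 1e-9 <= v <= hi + 1e-9

    def test_root_state_matches_pic(self):
        tree, vals = random_tree_and_values(8, n=7)
        anc = ancestral_states(tree, vals)
        root = tree.tree.seed_node.label
        assert anc.node_states[root] == pytest.approx(pic(tree, vals).root_state, abs=1e-10)

    def test_ci_ordered_and_widens_toward_root(self):
        tree, vals = random_tree_and_values(9, n=10)
        anc = ancestral_states(tree, vals)
        for lo, hi in anc.ci95.values():
            assert lo < hi
        root = tree.tree.seed_node.label
        root_width = anc.ci95[root][1] - anc.ci95[root][0]
        assert root_width > 0

    def test_edge_interpolation_endpoints(self):
        tree, vals = random_tree_and_values(10, n=5)
        anc = ancestral_states(tree, vals)
        df = edge_interpolated_states(tree, anc, vals, n_points=3)
        # fraction 0 equals the parent state on every edge
        at0 = df[df.fraction == 0.0]
        for _, row in at0.iterrows():
            assert row.state_mm == pytest.approx(anc.node_states[row.parent])


class TestBmLoglik:
    def test_lambda_zero_reduces_to_iid_normal(self):
        tree, vals = random_tree_and_values(11, n=8)
        x = np.array([vals[t] for t in tree.tip_names])
        from scipy.stats import norm
        mu, sd = x.mean(), x.std(ddof=0)
        assert bm_loglik(tree, vals, 0.0) == pytest.approx(
            norm.logpdf(x, mu, sd).sum(), abs=1e-8)

    def test_location_invariance(self):
        tree, vals = random_tree_and_values(12, n=8)
        shifted = {k: v + 17.0 for k, v in vals.items()}
        for lam in (0.0, 0.5, 1.0):
            assert bm_loglik(tree, vals, lam) == pytest.approx(
                bm_loglik(tree, shifted, lam), abs=1e-8)

    @pytest.mark.parametrize("lam", [0.3, 0.8, 1.0])
    def test_matches_dense_mvn_oracle(self, lam):
        tree, vals = random_tree_and_values(13, n=6)
        names, C = tree.vcv()
        x = np.array([vals[t] for t in names])
        V = lam * C
        np.fill_diagonal(V, np.diag(C))
        Vinv = np.linalg.inv(V)
        one = np.ones(len(x))
        mu = one @ Vinv @ x / (one @ Vinv @ one)
        s2 = (x - mu) @ Vinv @ (x - mu) / len(x)
        from scipy.stats import multivariate_normal
        ll = multivariate_normal.logpdf(x, mean=mu * one, cov=s2 * V)
        assert bm_loglik(tree, vals, lam) == pytest.approx(ll, abs=1e-8)

    def test_not_positive_definite_raises(self):
        tree, vals = random_tree_and_values(14, n=6)
        with pytest.raises(ValueError, match="positive definite"):
            bm_loglik(tree, vals, 50.0)


class TestSignal:
    def test_lambda_upper_bound_exceeds_one_on_ultrametric_tree(self):
        tree, _ = random_tree_and_values(15, n=20)
        assert lambda_upper_bound(tree) > 1.0

    def test_lambda_near_one_for_bm_data(self):
        tree = simulate_tree(40, seed=16)
        vals = simulate_tip_sizes(tree, 6.67, 0.05, 1.0, None, seed=17)
        res = pagel_lambda(tree, vals)
        assert res.lambda_hat > 0.7
        assert res.lrt_p < 0.05

    def test_lambda_near_zero_for_iid_data(self):
        tree = simulate_tree(40, seed=18)
        vals = simulate_tip_sizes(tree, 6.67, 0.05, 0.0, None, seed=19)
        assert pagel_lambda(tree, vals).lambda_hat < 0.3

    def test_lambda_and_k_location_invariant(self):
        tree = simulate_tree(25, seed=20)
        vals = simulate_tip_sizes(tree, 6.67, 0.05, 1.0, None, seed=21)
        shifted = {k: v + 3.0 for k, v in vals.items()}
        assert pagel_lambda(tree, vals).lambda_hat == pytest.approx(
            pagel_lambda(tree, shifted).lambda_hat, abs=1e-6)
        k1 = blomberg_k(tree, vals, n_perm=200, seed=0)
        k2 = blomberg_k(tree, shifted, n_perm=200, seed=0)
        assert k1.K == pytest.approx(k2.K, abs=1e-10)
        assert k1.K_p == k2.K_p

    def test_k_permutation_p_not_small_for_shuffled_labels(self):
        # destroying the tip-label association should leave K insignificant
        # in the clear majority of replicates
        tree = simulate_tree(40, seed=22)
        rng = np.random.default_rng(23)
        insignificant = 0
        n_rep = 30
        for s in range(n_rep):
            vals = simulate_tip_sizes(tree, 6.67, 0.05, 1.0, None, seed=300 + s)
            x = rng.permutation(list(vals.values()))
            shuffled = dict(zip(tree.tip_names, x))
            res = blomberg_k(tree, shuffled, n_perm=199, seed=s)
            insignificant += res.K_p > 0.05
        assert insignificant >= 0.8 * n_rep

    def test_k_significant_for_bm_data(self):
        tree = simulate_tree(50, seed=24)
        vals = simulate_tip_sizes(tree, 6.67, 0.05, 1.0, None, seed=25)
        res = blomberg_k(tree, vals, n_perm=499, seed=1)
        assert res.K_p < 0.05
        assert res.n_perm == 499

    def test_agrees_with_reference_r_implementation(self, tmp_path):
        # cross-check lambda and K against phytools::phylosig on shared data
        import subprocess

        tree = simulate_tree(40, seed=30)
        vals = simulate_tip_sizes(tree, 6.67, 0.02, 0.5, None, seed=31)
        (tmp_path / "t.nwk").write_text(tree.as_newick() + "\n")
        with open(tmp_path / "x.csv", "w") as f:
            f.write("species,val\n")
            for k, v in vals.items():
                f.write(f"{k},{v}\n")
        script = (
            'suppressMessages(library(phytools));'
            f'tr <- read.tree("{tmp_path}/t.nwk");'
            f'd <- read.csv("{tmp_path}/x.csv");'
            'x <- setNames(d$val, d$species);'
            'l <- phylosig(tr, x, method="lambda");'
            'k <- phylosig(tr, x, method="K");'
            'cat(l$lambda, unclass(k)[[1]], sep="\\n")'
        )
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                              timeout=300)
        assert proc.returncode == 0, proc.stderr
        r_lambda, r_k = (float(s) for s in proc.stdout.strip().splitlines()[-2:])
        assert pagel_lambda(tree, vals).lambda_hat == pytest.approx(r_lambda, abs=1e-4)
        assert blomberg_k(tree, vals, n_perm=100, seed=0).K == pytest.approx(r_k, abs=1e-6)

    def test_contrast_variance_homogeneity_under_bm(self):
        # |contrast| should be uncorrelated with sqrt(expected variance)
        from scipy.stats import pearsonr
        tree = simulate_tree(60, seed=26)
        ps = []
        for s in range(10):
            vals = simulate_tip_sizes(tree, 6.67, 0.05, 1.0, None, seed=400 + s)
            cs = pic(tree, vals)
            r, p = pearsonr(np.abs(cs.values()), np.sqrt(cs.variances()))
            ps.append(p)
        assert np.mean(np.array(ps) < 0.05) <= 0.3
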
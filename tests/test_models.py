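"""PI/BM/OU moments and fitting against integration, grid and nesting oracles."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import traitevo as te
from traitevo.models import RegimePainting, _ou_structure, auto_clade_painting
from traitevo.phylo import mrca_age_matrix
from conftest import series_on


@pytest.fixture(scope="module")
def tree100():
    return te.simulate_tree(n_tips=100, root_age=100.0, seed=808)


class TestOUMoments:
    def test_alpha_zero_limit_is_bm(self, tree50):
        p = RegimePainting.single(tree50, 4.0)
        mu, V = te.ou_moments(tree50, 1e-12, 1.0, p)
        t_a = _ou_structure(tree50, 0.0)
        assert np.abs(V - t_a).max() < 1e-6
        assert np.allclose(mu, 4.0)

    def test_stationary_variance_closed_form(self):
        tree = te.read_newick("(A:50,B:50);")
        tree.date_from_branch_lengths()
        p = RegimePainting.single(tree, 0.0)
        for alpha in (0.02, 0.1, 1.0):
            _, V = te.ou_moments(tree, alpha, 1.5, p)
            expect = 1.5**2 / (2 * alpha) * (1 - math.exp(-2 * alpha * 50))
            assert V[0, 0] == pytest.approx(expect, rel=1e-10)
        # deep tree: variance approaches sigma^2/(2 alpha)
        deep = te.read_newick("(A:5000,B:5000);")
        deep.date_from_branch_lengths()
        _, V = te.ou_moments(deep, 0.1, 1.5, RegimePainting.single(deep, 0.0))
        assert V[0, 0] == pytest.approx(1.5**2 / 0.2, rel=1e-6)

    def test_two_regime_expectation_vs_euler_integration(self):
        """Expectation weights equal step-by-step integration of dμ/dt = −α(μ−θ)."""
        tree = te.read_newick("(((A:30,B:30)x:40,C:70)y:30,D:100);")
        tree.date_from_branch_lengths()
        x = tree.node_by_label("x")
        # the stem branch of clade x (times 30-70 from the root) carries regime 1
        painting = RegimePainting.from_clades(
            tree, [(x, 1)], thetas={0: 2.0, 1: 7.0}
        )
        alpha = 0.04
        mu, _ = te.ou_moments(tree, alpha, 1.0, painting)

        def euler(theta_path, total, steps=10**4):
            dt = total / steps
            m = theta_path(0.0)  # root state = root optimum
            for s in range(steps):
                t = (s + 0.5) * dt
                m += -alpha * (m - theta_path(t)) * dt
            return m

        # tip A: regime 0 for the first 30 Myr, then regime 1 to the present
        mu_a = euler(lambda t: 2.0 if t < 30 else 7.0, 100.0)
        mu_c = euler(lambda t: 2.0, 100.0)
        tipA = tree.tip_labels.index("A")
        tipC = tree.tip_labels.index("D")
        assert mu[tipA] == pytest.approx(mu_a, abs=1e-3)
        assert mu[tipC] == pytest.approx(mu_c, abs=1e-3)

    def test_covariance_psd_across_alpha(self, tree50):
        p = RegimePainting.single(tree50, 0.0)
        for alpha in (0.0, 1e-6, 0.01, 0.1, 1.0, 10.0):
            _, V = te.ou_moments(tree50, max(alpha, 1e-12), 1.0, p)
            assert np.linalg.eigvalsh(V).min() > -1e-8 * V.max()

    def test_invalid_args_raise(self, tree50):
        p = RegimePainting.single(tree50, 0.0)
        with pytest.raises(ValueError):
            te.ou_moments(tree50, -0.1, 1.0, p)
        with pytest.raises(ValueError):
            te.ou_moments(tree50, 0.1, 0.0, p)
        with pytest.raises(ValueError):
            te.ou_moments(tree50, 0.1, 1.0, RegimePainting.single(tree50, None))


class TestPaintings:
    def test_every_branch_painted_required(self, tree50):
        branch = {n.index: 0 for n in tree50.preorder() if not n.is_root}
        branch.pop(next(iter(branch)))
        with pytest.raises(ValueError, match="unpainted"):
            RegimePainting(tree50, branch)

    def test_auto_painting_contiguous_and_disjoint(self, tree200):
        painting = auto_clade_painting(tree200, 3)
        # a regime switch only at nodes: each node's regime is its parent's
        # unless it is a painted clade root
        switches = 0
        for node in tree200.preorder():
            if node.is_root:
                continue
            parent_regime = (
                painting.root_regime
                if node.parent.is_root
                else painting.branch_regime[node.parent.index]
            )
            if painting.branch_regime[node.index] != parent_regime:
                switches += 1
        assert switches == 2  # one switch per non-background regime
        counts = painting.tip_regimes().value_counts()
        assert set(counts.index) == {0, 1, 2}


class TestFitModel:
    def test_three_tip_grid_oracle(self):
        tree = te.read_newick("((A:40,B:40):60,C:100);")
        tree.date_from_branch_lengths()
        y = pd.Series([3.1, 4.0, 5.5], index=tree.tip_labels)
        fit = te.fit_model(tree, y, "OU1")
        # independent oracle: dense grid over (alpha, sigma), theta by GLS
        M = mrca_age_matrix(tree)
        T = 100.0
        yv = y.to_numpy()
        best = -np.inf
        for a in np.logspace(-6, 1, 50):
            G = _ou_structure((M, T), a)
            w = np.exp(-a * np.zeros(3)) * 0 + 1.0  # design: all weights sum to 1
            Gi = np.linalg.inv(G)
            theta = (w @ Gi @ yv) / (w @ Gi @ w)
            for s in np.linspace(0.05, 3.0, 50):
                ll = multivariate_normal.logpdf(yv, mean=theta * w, cov=s**2 * G)
                best = max(best, ll)
        assert fit.loglik >= best - 1e-6

    def test_fit_loglik_matches_mvn_at_optimum(self, tree50):
        traits, _ = te.simulate_trait(
            tree50, trait_model="OU", alpha=0.05, seed=31, n_replicates=1, within_sd=0.0
        )
        fit = te.fit_model(tree50, traits, "OU1")
        pnt = RegimePainting.single(tree50, fit.thetas[0])
        mu, V = te.ou_moments(tree50, fit.alpha, fit.sigma, pnt)
        y = traits.log_means.reindex(tree50.tip_labels).to_numpy()
        assert fit.loglik == pytest.approx(
            multivariate_normal.logpdf(y, mean=mu, cov=V), abs=1e-6
        )

    def test_bm_data_gives_small_alpha_and_lrt(self, tree100):
        lrts = []
        for r in range(20):
            traits, _ = te.simulate_trait(tree100, trait_model="BM", seed=400 + r)
            bm = te.fit_model(tree100, traits, "BM")
            ou = te.fit_model(tree100, traits, "OU1")
            lrts.append(2 * (ou.loglik - bm.loglik))
            assert ou.loglik >= bm.loglik - 1e-4  # nesting
        assert np.median(lrts) < 2.0

    def test_likelihood_nesting_chain(self, tree100):
        traits, _ = te.simulate_trait(tree100, trait_model="BM", seed=77)
        bm = te.fit_model(tree100, traits, "BM")
        ou1 = te.fit_model(tree100, traits, "OU1")
        ou3 = te.fit_model(tree100, traits, "OU3")
        assert ou3.loglik >= ou1.loglik - 1e-4
        assert ou1.loglik >= bm.loglik - 1e-4

    def test_translation_equivariance(self, tree100):
        traits, _ = te.simulate_trait(
            tree100, trait_model="OU", alpha=0.05, seed=55, n_replicates=1, within_sd=0.0
        )
        y = traits.log_means
        f0 = te.fit_model(tree100, y, "OU1")
        f1 = te.fit_model(tree100, y + 10.0, "OU1")
        assert f1.thetas[0] == pytest.approx(f0.thetas[0] + 10.0, abs=1e-3)
        assert f1.alpha == pytest.approx(f0.alpha, rel=1e-3)
        assert f1.sigma == pytest.approx(f0.sigma, rel=1e-4)

    def test_pi_fit_is_iid_gaussian_mle(self, tree50, pi_traits):
        x = pi_traits(tree50, seed=12)
        fit = te.fit_model(tree50, x, "PI")
        v = x.to_numpy()
        s2 = v.var()
        ll = -0.5 * 50 * (np.log(2 * np.pi * s2) + 1)
        assert fit.loglik == pytest.approx(ll, abs=1e-10)
        assert fit.root_state == pytest.approx(v.mean())

    def test_recovery_improves_with_tree_size(self):
        """Median |α̂ − α| shrinks from 100 to 400 tips."""
        errs = {}
        for n, seed in ((100, 1), (400, 2)):
            tree = te.simulate_tree(n_tips=n, root_age=100.0, seed=seed)
            e = []
            for r in range(8):
                tr, _ = te.simulate_trait(
                    tree, trait_model="OU", alpha=0.05, seed=1000 * n + r
                )
                e.append(abs(te.fit_model(tree, tr, "OU1").alpha - 0.05))
            errs[n] = np.median(e)
        assert errs[400] < errs[100]


class TestCompareModels:
    def test_bic_penalty_ranks_smaller_model_first(self, tree100, pi_traits):
        x = pi_traits(tree100, seed=3)
        base = te.fit_model(tree100, x, "BM")
        inflated = te.fit_model(tree100, x, "BM")
        object.__setattr__(inflated.spec, "model", "BM")  # same data, same loglik
        inflated.bic = 4 * np.log(100) - 2 * inflated.loglik
        table = te.compare_models([inflated, base])
        assert table["model"].iloc[0] == "BM"
        assert table["delta_bic"].iloc[1] == pytest.approx(2 * np.log(100))

    def test_identical_specs_stable_sort(self, tree100, pi_traits):
        x = pi_traits(tree100, seed=3)
        f1 = te.fit_model(tree100, x, "BM")
        f2 = te.fit_model(tree100, x, "BM")
        table = te.compare_models([f1, f2])
        assert table["bic"].iloc[0] == table["bic"].iloc[1]

    def test_different_tip_sets_raise(self, tree100, tree50, pi_traits):
        f1 = te.fit_model(tree100, pi_traits(tree100, seed=0), "BM")
        f2 = te.fit_model(tree50, pi_traits(tree50, seed=0), "BM")
        with pytest.raises(ValueError):
            te.compare_models([f1, f2])


class TestHalfLife:
    def test_examples(self):
        assert te.half_life(math.log(2)) == pytest.approx(1.0)
        assert te.half_life(math.log(2) / 15.5) == pytest.approx(15.5)
        assert te.half_life(0.0) == math.inf
        with pytest.raises(ValueError):
            te.half_life(-0.1)


class TestPercentNullDeviance:
    def test_pi_fit_explains_nothing(self, tree50, pi_traits):
        x = pi_traits(tree50, seed=8)
        fit = te.fit_model(tree50, x, "PI")
        assert te.percent_null_deviance(fit, x) == pytest.approx(0.0, abs=1e-10)

    def test_perfect_fit_explains_everything(self, tree50, pi_traits):
        x = pi_traits(tree50, seed=8)
        fit = te.fit_model(tree50, x, "PI")
        fit.fitted = x.to_numpy()
        assert te.percent_null_deviance(fit, x) == pytest.approx(100.0)

    def test_constant_trait_raises(self, tree50):
        x = series_on(tree50, np.full(50, 2.0))
        fit = te.fit_model(tree50, series_on(tree50, np.arange(50.0)), "PI")
        with pytest.raises(ValueError):
            te.percent_null_deviance(fit, x)

    def test_ou3_explains_more_than_ou1_under_regimes(self, tree200):
        sd = 1 / np.sqrt(0.1)
        thetas = (4.0, 4 + 2 * sd, 4 - 2 * sd)
        painting = auto_clade_painting(tree200, 3, thetas)
        wins = 0
        for r in range(10):
            traits, _ = te.simulate_trait(
                tree200, trait_model="OU", n_regimes=3, alpha=0.05,
                thetas=thetas, painting=painting, seed=600 + r,
            )
            p3 = te.percent_null_deviance(
                te.fit_model(tree200, traits, "OU3", painting=painting), traits
            )
            p1 = te.percent_null_deviance(
                te.fit_model(tree200, traits, "OU1"), traits
            )
            wins += p3 > p1
        assert wins >= 9
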
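"""Tests of the GLS / mixed-model / repeatability machinery.

Independent oracles: explicit-inverse GLS, statsmodels MixedLM, and a direct
multivariate-normal likelihood optimization for the lambda profile.
"""
import math

import dendropy
import numpy as np
import pytest
from scipy import optimize, stats

from spermhelix import phylostats as ps
from spermhelix import synthetic as syn


def _star_tree(n=6, length=1.0):
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    for t in taxa:
        child = tree.seed_node.new_child(edge_length=length)
        child.taxon = t
    return tree


class TestPhyloCovariance:
    def test_star_tree_gives_identity(self):
        pc = ps.phylo_covariance(_star_tree(5))
        assert np.allclose(pc.matrix, np.eye(5))

    def test_sister_pair_shares_divergence_depth(self):
        newick = "((a:0.4,b:0.4):0.6,(c:0.9,d:0.9):0.1):0.0;"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pc = ps.phylo_covariance(tree)
        i, j = pc.species_order.index("a"), pc.species_order.index("b")
        assert pc.matrix[i, j] == pytest.approx(0.6)
        k, l = pc.species_order.index("c"), pc.species_order.index("d")
        assert pc.matrix[k, l] == pytest.approx(0.1)
        assert np.allclose(np.diag(pc.matrix), 1.0)

    def test_yule_tree_covariance_is_psd(self):
        pc = ps.phylo_covariance(syn.simulate_tree(30, seed=2))
        np.linalg.cholesky(pc.matrix + 1e-12 * np.eye(30))

    def test_missing_branch_lengths_error(self):
        tree = dendropy.Tree.get(data="((a,b),c);", schema="newick")
        with pytest.raises(ValueError):
            ps.phylo_covariance(tree)


class TestLambdaTransform:
    def test_limits_and_midpoint(self):
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert np.allclose(ps.lambda_transform(C, 0.0), np.eye(2))
        assert np.allclose(ps.lambda_transform(C, 1.0), C)
        assert ps.lambda_transform(C, 0.5)[0, 1] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ps.lambda_transform(np.eye(3), 1.2)


class TestGLS:
    def test_identity_covariance_equals_ols(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        y = rng.normal(size=12)
        fit = ps.gls_fit(X, y, np.eye(12))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.beta, beta_ols, atol=1e-12)

    def test_matches_explicit_inverse_on_random_systems(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            X = rng.normal(size=(5, 2))
            y = rng.normal(size=5)
            A = rng.normal(size=(5, 5))
            V = A @ A.T + 5 * np.eye(5)
            Vi = np.linalg.inv(V)
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            fit = ps.gls_fit(X, y, V)
            assert np.max(np.abs(fit.beta - beta)) < 1e-10

    def test_block_duplication_leaves_beta_unchanged(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        y = rng.normal(size=6)
        A = rng.normal(size=(6, 6))
        V = A @ A.T + 4 * np.eye(6)
        single = ps.gls_fit(X, y, V)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        V2 = np.block(
            [[V, np.zeros((6, 6))], [np.zeros((6, 6)), V]]
        )
        double = ps.gls_fit(X2, y2, V2)
        assert np.allclose(single.beta, double.beta, atol=1e-10)

    def test_singular_design_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(np.linalg.LinAlgError):
            ps.gls_fit(X, np.zeros(5), np.eye(5))


class TestPGLS:
    def test_star_tree_equals_ols_for_any_lambda(self):
        rng = np.random.default_rng(3)
        tree = _star_tree(10)
        pc = ps.phylo_covariance(tree)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        y = rng.normal(size=10)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        for lam in (0.0, 0.4, 1.0):
            fit = ps.fit_pgls(X, y, pc, lam=lam, compute_p=False)
            assert np.allclose(list(fit.coefficients.values()), beta_ols, atol=1e-10)

    def test_matches_joint_mvn_likelihood_oracle(self):
        """Oracle: direct multivariate-normal likelihood via scipy.stats.

        At each fixed lambda the profiled GLS log-likelihood must equal the
        joint optimum over (beta, sigma2) of the exact MVN density.
        """
        tree = syn.simulate_tree(12, seed=9)
        pc = ps.phylo_covariance(tree)
        spec = syn.ComparativeSimSpec(n_species=12, lambda_true=0.7)
        df, _ = syn.simulate_species_traits(tree, spec, seed=5)
        X = np.column_stack([np.ones(12), df["log_flagellum"]])
        y = df["log_midpiece"].to_numpy()

        for lam in (0.0, 0.3, 0.6, 0.9):
            def negll(theta, lam=lam):
                b0, b1, logs2 = theta
                V = math.exp(logs2) * ps.lambda_transform(pc, lam)
                return -stats.multivariate_normal.logpdf(
                    y, mean=b0 + b1 * X[:, 1], cov=V
                )

            fit = ps.fit_pgls(X, y, pc, ["b0", "b1"], lam=lam, compute_p=False)
            res = optimize.minimize(
                negll, [0.0, 1.0, math.log(np.var(y))], method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000},
            )
            assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)
            assert fit.coefficients["b1"] == pytest.approx(res.x[1], abs=1e-4)

    def test_lambda_zero_generator_recovers_near_zero(self):
        lams = []
        for r in range(25):
            tree = syn.simulate_tree(30, seed=100 + r)
            spec = syn.ComparativeSimSpec(n_species=30, lambda_true=0.0)
            df, _ = syn.simulate_species_traits(tree, spec, seed=200 + r)
            X = np.column_stack([np.ones(30), df["log_flagellum"]])
            fit = ps.fit_pgls(X, df["log_midpiece"].to_numpy(), pc_or(tree),
                              compute_p=False)
            lams.append(fit.lambda_)
        assert np.median(lams) < 0.1

    def test_reorder_and_branch_rescale_invariance(self):
        tree = syn.simulate_tree(15, seed=4)
        pc = ps.phylo_covariance(tree)
        spec = syn.ComparativeSimSpec(n_species=15)
        df, _ = syn.simulate_species_traits(tree, spec, seed=6)
        X = np.column_stack([np.ones(15), df["log_flagellum"]])
        y = df["log_midpiece"].to_numpy()
        base = ps.fit_pgls(X, y, pc, compute_p=False)
        perm = np.random.default_rng(0).permutation(15)
        sub = pc.subset([pc.species_order[i] for i in perm])
        permuted = ps.fit_pgls(X[perm], y[perm], sub, compute_p=False)
        assert permuted.coefficients == pytest.approx(base.coefficients, rel=1e-6)
        assert permuted.lambda_ == pytest.approx(base.lambda_, abs=1e-4)
        scaled = ps.PhyloCovariance(pc.species_order, 3.7 * pc.matrix, 3.7)
        rescaled = ps.fit_pgls(X, y, scaled, compute_p=False)
        assert rescaled.coefficients == pytest.approx(base.coefficients, rel=1e-6)
        assert rescaled.lambda_ == pytest.approx(base.lambda_, abs=1e-4)

    def test_profile_peak_beats_boundaries(self):
        tree = syn.simulate_tree(20, seed=8)
        pc = ps.phylo_covariance(tree)
        spec = syn.ComparativeSimSpec(n_species=20, lambda_true=0.6)
        df, _ = syn.simulate_species_traits(tree, spec, seed=3)
        X = np.column_stack([np.ones(20), df["log_flagellum"]])
        y = df["log_midpiece"].to_numpy()
        best = ps.fit_pgls(X, y, pc, compute_p=False, method="ml")
        l0 = ps.fit_pgls(X, y, pc, lam=0.0, compute_p=False).loglik
        l1 = ps.fit_pgls(X, y, pc, lam=1.0, compute_p=False).loglik
        assert best.loglik >= l0 - 1e-9
        assert best.loglik >= l1 - 1e-9

    def test_non_identifiable_small_n(self):
        pc = ps.phylo_covariance(_star_tree(3))
        X = np.column_stack([np.ones(3), [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="identifiable"):
            ps.fit_pgls(X, np.zeros(3), pc)


def pc_or(tree):
    return ps.phylo_covariance(tree)


class TestPhyloLMM:
    def test_matches_statsmodels_with_identity_structure(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        m, reps = 12, 5
        idx = np.repeat(np.arange(m), reps)
        X = np.column_stack([np.ones(m * reps), rng.normal(size=m * reps)])
        a = rng.normal(0, 0.7, size=m)
        y = 1.0 + 0.5 * X[:, 1] + a[idx] + rng.normal(0, 0.4, size=m * reps)
        fit = ps._fit_mixed(X, y, idx, np.eye(m), ["int", "x"], compute_p=False)
        md = sm.MixedLM(y, X, groups=idx).fit(reml=True)
        assert list(fit.coefficients.values()) == pytest.approx(
            list(md.fe_params), abs=1e-5
        )
        assert fit.variance_components["phylogenetic"] == pytest.approx(
            float(np.asarray(md.cov_re)[0, 0]), rel=1e-3
        )
        assert fit.variance_components["residual"] == pytest.approx(
            md.scale, rel=1e-3
        )

    def test_zero_species_variance_matches_ols(self):
        rng = np.random.default_rng(9)
        tree = syn.simulate_tree(10, seed=10)
        pc = ps.phylo_covariance(tree)
        species = [s for s in pc.species_order for _ in range(4)]
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = 2.0 - 1.0 * X[:, 1] + rng.normal(0, 0.3, size=40)
        fit = ps.fit_phylo_lmm(X, y, species, pc, ["int", "x"], compute_p=False)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit.lambda_ < 0.3
        assert list(fit.coefficients.values()) == pytest.approx(
            list(beta_ols), abs=0.05
        )

    def test_single_obs_small_residual_approaches_pgls(self):
        tree = syn.simulate_tree(12, seed=12)
        pc = ps.phylo_covariance(tree)
        spec = syn.ComparativeSimSpec(n_species=12, lambda_true=1.0)
        df, _ = syn.simulate_species_traits(tree, spec, seed=2)
        X = np.column_stack([np.ones(12), df["log_flagellum"]])
        y = df["log_midpiece"].to_numpy()
        lmm = ps.fit_phylo_lmm(X, y, list(df["species"]), pc, ["i", "b"],
                               compute_p=False)
        pgls = ps.fit_pgls(X, y, pc.subset(list(df["species"])), ["i", "b"],
                           lam=1.0, compute_p=False)
        # residual variance collapses; fixed effects match the lambda=1 GLS
        assert lmm.coefficients["b"] == pytest.approx(
            pgls.coefficients["b"], rel=1e-3
        )

    def test_observation_order_invariance(self):
        rng = np.random.default_rng(11)
        tree = syn.simulate_tree(8, seed=3)
        pc = ps.phylo_covariance(tree)
        species = [s for s in pc.species_order for _ in range(3)]
        X = np.column_stack([np.ones(24), rng.normal(size=24)])
        y = rng.normal(size=24)
        base = ps.fit_phylo_lmm(X, y, species, pc, ["i", "x"], compute_p=False)
        perm = rng.permutation(24)
        shuf = ps.fit_phylo_lmm(
            X[perm], y[perm], [species[i] for i in perm], pc, ["i", "x"],
            compute_p=False,
        )
        assert shuf.coefficients == pytest.approx(base.coefficients, rel=1e-8)
        assert shuf.variance_components["residual"] == pytest.approx(
            base.variance_components["residual"], rel=1e-6
        )


class TestInteractionDropping:
    def _fits(self, interaction: float, seed: int):
        spec = syn.ComparativeSimSpec(
            n_species=20,
            flagellum_diameter=syn.TaperLink(
                0.33, -0.11, 0.04, interaction, 0.013, False
            ),
        )
        bundle = syn.generate_dataset(spec, seed=seed)
        from spermhelix import pipeline as pl

        rep = pl.stage_tapering(
            bundle.cells, bundle.tree, "flagellum_diameter",
            transform="raw", compute_p=False,
        )
        return rep.notes["interaction_kept"], rep.notes["interaction_p"]

    def test_identical_logliks_choose_reduced(self):
        full = ps.ModelFit({"a": 1.0, "b": 2.0}, {}, {}, None, None, {}, -10.0, 5, 5)
        red = ps.ModelFit({"a": 1.0}, {}, {}, None, None, {}, -10.0, 5, 5)
        chosen, p = ps.drop_nonsignificant_interaction(full, red)
        assert chosen is red
        assert p == pytest.approx(1.0)

    def test_non_nested_rejected(self):
        f1 = ps.ModelFit({"a": 1.0}, {}, {}, None, None, {}, -1.0, 5, 5)
        f2 = ps.ModelFit({"b": 1.0}, {}, {}, None, None, {}, -1.0, 5, 5)
        with pytest.raises(ValueError):
            ps.drop_nonsignificant_interaction(f1, f2)

    def test_strong_interaction_kept(self):
        kept = [self._fits(-0.03, 900 + r)[0] for r in range(10)]
        assert sum(kept) >= 9

    def test_zero_interaction_mostly_dropped(self):
        kept = [self._fits(0.0, 950 + r)[0] for r in range(15)]
        assert sum(kept) <= 3


class TestRepeatability:
    def test_identical_repeats_give_exactly_one(self):
        tbl, _ = syn.simulate_repeat_measures(
            {"a": [0.2, 0.3, 0.4], "b": [1.0, 2.0, 3.0]}, cv=0.0, seed=0
        )
        res = ps.repeatability(tbl["value"], tbl["point_id"], tbl["kind"],
                               n_boot=5, seed=0)
        assert res.r == 1.0
        assert res.ci95 == (1.0, 1.0)

    def test_balanced_variance_ratio_near_half(self):
        rs = []
        for s in range(8):
            vals = list(np.linspace(0.0, 3.0, 10))
            sd_b = float(np.std(vals, ddof=1))
            cv = sd_b / float(np.mean(np.abs(vals)))
            tbl, icc = syn.simulate_repeat_measures(vals, cv=cv, n_repeats=6, seed=s)
            assert icc == pytest.approx(0.5, abs=1e-9)
            res = ps.repeatability(tbl["value"], tbl["point_id"], n_boot=0 or 20,
                                   seed=s)
            rs.append(res.r)
        assert np.mean(rs) == pytest.approx(0.5, abs=0.12)

    def test_high_icc_recovery(self):
        rng = np.random.default_rng(5)
        pts = {"flagellum": list(0.30 + 0.112 * rng.standard_normal(12))}
        tbl, icc = syn.simulate_repeat_measures(pts, cv=0.0166, seed=2)
        assert icc > 0.99
        res = ps.repeatability(tbl["value"], tbl["point_id"], tbl["kind"],
                               n_boot=100, seed=0)
        assert res.r == pytest.approx(icc, abs=0.005)
        assert res.ci95[0] <= res.r <= res.ci95[1]

    def test_repeatability_bounded_and_degenerate_grouping_rejected(self):
        with pytest.raises(ValueError):
            ps.repeatability([1.0, 2.0], [1, 2])
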
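"""Signal statistics: BM likelihood, Pagel parameter fits, permutation tests."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phylotempo as pt
from phylotempo.signal import PAGEL_BOUNDS

from conftest import random_small_instance


class TestBMLoglik:
    def test_star_tree_reduces_to_sample_mean_and_ml_variance(self):
        C = pt.PhyloCovariance(("a", "b", "c"), np.eye(3))
        fit = pt.bm_loglik(C, np.array([1.0, 2.0, 3.0]))
        assert fit.mu_hat == pytest.approx(2.0)
        assert fit.sigma2_hat == pytest.approx(2.0 / 3.0)

    def test_constant_trait_rejected(self):
        C = pt.PhyloCovariance(("a", "b"), np.eye(2))
        with pytest.raises(pt.ZeroVarianceError):
            pt.bm_loglik(C, np.array([0.0, 0.0]))

    def test_matches_multivariate_normal_oracle(self):
        """ML profile loglik equals the generic MVN log-density at the
        fitted (mu, sigma2 C), over 50 random small instances."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            tree, y = random_small_instance(rng)
            C = tree.vcv()
            fit = pt.bm_loglik(C, y)
            yv = np.array([y[l] for l in C.labels])
            oracle = stats.multivariate_normal.logpdf(
                yv, mean=np.full(C.n, fit.mu_hat), cov=fit.sigma2_hat * C.matrix,
                allow_singular=True,
            )
            assert fit.loglik == pytest.approx(oracle, abs=1e-8)

    def test_label_mismatch_rejected(self, three_tip_tree):
        C = three_tip_tree.vcv()
        with pytest.raises(ValueError, match="missing"):
            pt.bm_loglik(C, {"A": 1.0, "B": 2.0})


class TestFitPagel:
    def test_lambda_zero_equals_star_fit(self, yule30, bm_traits30):
        """lnL at lambda=0 equals the fit on a star tree with the same
        diagonal — phylogenetic independence."""
        C = yule30.vcv()
        C0 = pt.transform_lambda(C, 0.0)
        star = pt.PhyloCovariance(C.labels, np.diag(np.diag(C.matrix)))
        ll_a = pt.bm_loglik(C0, bm_traits30).loglik
        ll_b = pt.bm_loglik(star, bm_traits30).loglik
        assert ll_a == pytest.approx(ll_b, abs=1e-8)

    @pytest.mark.parametrize("which", ["lambda", "kappa", "delta"])
    def test_estimate_within_bounds_and_beats_boundaries(self, yule30, bm_traits30, which):
        est = pt.fit_pagel(yule30, bm_traits30, which)
        lo, hi = PAGEL_BOUNDS[which]
        assert lo <= est.estimate <= hi
        assert 0.0 <= est.p_vs_zero <= 1.0 and 0.0 <= est.p_vs_one <= 1.0
        assert est.optimizer_converged

    def test_boundary_estimate_reports_p_one(self, yule30, bm_traits30):
        est = pt.fit_pagel(yule30, bm_traits30, "lambda")
        if est.estimate == pytest.approx(1.0, abs=1e-5):
            assert est.p_vs_one == 1.0

    def test_bm_traits_recover_high_lambda(self):
        """Median lambda-hat near 1 for pure BM; shuffling destroys it."""
        hats, shuf = [], []
        for s in range(8):
            tree = pt.simulate_yule_tree(80, 1.0, seed=100 + s)
            y = pt.simulate_bm_traits(tree, pt.SimulationSpec(n_tips=80, seed=200 + s))
            hats.append(pt.fit_pagel(tree, y, "lambda").estimate)
            rng = np.random.default_rng(300 + s)
            ys = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            shuf.append(pt.fit_pagel(tree, ys, "lambda").estimate)
        assert np.median(hats) >= 0.9
        assert np.median(shuf) <= 0.15

    def test_matches_phytools_oracle(self, yule30, tmp_path):
        """Independent cross-check of the lambda ML fit and Blomberg's K
        against R (phytools::phylosig) on one instance."""
        y = pt.simulate_bm_traits(
            yule30,
            pt.SimulationSpec(n_tips=30, transform=pt.TransformParams(lambda_=0.7), seed=7),
        )
        pt.write_newick(yule30, tmp_path / "t.nwk")
        y.rename_axis("species").reset_index().to_csv(tmp_path / "y.csv", index=False)
        script = (
            'suppressMessages(library(phytools));'
            f'tr <- ape::read.tree("{tmp_path / "t.nwk"}");'
            f'd <- read.csv("{tmp_path / "y.csv"}");'
            "x <- setNames(d$value, d$species);"
            'ps <- phylosig(tr, x, method="lambda");'
            'cat(ps$lambda, ps$logL, phylosig(tr, x, method="K"), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_lambda, r_logl, r_k = (float(v) for v in out.stdout.strip().split("\n"))
        est = pt.fit_pagel(yule30, y, "lambda")
        assert est.estimate == pytest.approx(r_lambda, abs=1e-3)
        assert est.loglik_at_estimate == pytest.approx(r_logl, abs=1e-4)
        k = pt.blomberg_k(yule30, y, n_perm=9, seed=0)
        assert k.observed == pytest.approx(r_k, abs=1e-6)

    def test_too_few_tips_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            pt.fit_pagel(three_tip_tree, {"A": 1.0, "B": 2.0, "C": 3.0}, "lambda")


class TestBlombergK:
    def test_star_tree_k_is_one(self, star_tree):
        y = np.arange(12, dtype=float)
        res = pt.blomberg_k(star_tree, y, n_perm=19, seed=0)
        assert res.observed == pytest.approx(1.0, abs=1e-10)

    def test_strong_signal_hits_permutation_floor(self):
        tree = pt.simulate_yule_tree(60, 1.0, seed=11)
        y = pt.simulate_bm_traits(tree, pt.SimulationSpec(n_tips=60, seed=12))
        res = pt.blomberg_k(tree, y, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(0.001)

    def test_nperm_domain(self, yule30, bm_traits30):
        with pytest.raises(ValueError):
            pt.blomberg_k(yule30, bm_traits30, n_perm=0, seed=0)


class TestAbouheif:
    def test_weights_by_hand_three_tips(self, three_tip_tree):
        """Path products of 1/(direct descendant count): the A-B path
        crosses only the cherry node (1/2); A-C and B-C cross the cherry
        node and the root (1/2 * 1/2)."""
        labels, A = pt.abouheif_weights(three_tip_tree)
        m = {lab: i for i, lab in enumerate(labels)}
        assert A[m["A"], m["B"]] == pytest.approx(0.5)
        assert A[m["A"], m["C"]] == pytest.approx(0.25)
        assert A[m["B"], m["C"]] == pytest.approx(0.25)
        assert np.all(np.diag(A) == 0)

    def test_weights_by_hand_five_tips(self):
        """(((A,B),C),(D,E)): full enumeration of the path products."""
        tree = pt.parse_newick("(((A:1,B:1):1,C:2):1,(D:1,E:1):2);")
        labels, A = pt.abouheif_weights(tree)
        m = {lab: i for i, lab in enumerate(labels)}
        assert A[m["A"], m["B"]] == pytest.approx(1 / 2)
        assert A[m["A"], m["C"]] == pytest.approx(1 / 4)
        assert A[m["D"], m["E"]] == pytest.approx(1 / 2)
        # A to D: cherry(2) -> (ABC) node(2) -> root(2) -> (DE) node(2)
        assert A[m["A"], m["D"]] == pytest.approx(1 / 16)
        assert A[m["C"], m["D"]] == pytest.approx(1 / 8)

    def test_constant_trait_rejected(self, yule30):
        with pytest.raises(pt.ZeroVarianceError):
            pt.abouheif_cmean(yule30, np.ones(30), n_perm=9, seed=0)

    def test_bm_positive_shuffled_near_zero(self):
        obs, shuf = [], []
        for s in range(10):
            tree = pt.simulate_yule_tree(50, 1.0, seed=400 + s)
            y = pt.simulate_bm_traits(tree, pt.SimulationSpec(n_tips=50, seed=500 + s))
            obs.append(pt.abouheif_cmean(tree, y, n_perm=9, seed=s).observed)
            rng = np.random.default_rng(600 + s)
            ys = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            shuf.append(pt.abouheif_cmean(tree, ys, n_perm=9, seed=s).observed)
        assert np.mean(obs) > 0.1
        assert abs(np.mean(shuf)) < 0.1


class TestMoransI:
    def test_two_tip_is_minus_one(self):
        tree = pt.parse_newick("(A:1,B:1);")
        res = pt.morans_i(tree, np.array([0.0, 5.0]), n_perm=9, seed=0)
        assert res.observed == pytest.approx(-1.0)

    def test_null_mean_is_minus_one_over_n_minus_one(self, yule30):
        """Mean of I over tip shuffles equals -1/(n-1), the permutation
        null expectation for a row-standardized weight matrix."""
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        vals = []
        for s in range(300):
            ys = rng.permutation(y)
            vals.append(pt.morans_i(yule30, ys, n_perm=1, seed=s).observed)
        assert np.mean(vals) == pytest.approx(-1 / 29, abs=0.02)

    def test_bm_exceeds_null_mean(self):
        hits = 0
        for s in range(10):
            tree = pt.simulate_yule_tree(50, 1.0, seed=700 + s)
            y = pt.simulate_bm_traits(tree, pt.SimulationSpec(n_tips=50, seed=800 + s))
            if pt.morans_i(tree, y, n_perm=9, seed=s).observed > -1 / 49:
                hits += 1
        assert hits >= 9

    def test_zero_distance_pair_names_offenders(self):
        tree = pt.parse_newick("((A:0,B:0):1,C:2);")
        with pytest.raises(ValueError, match="A.*B|B.*A"):
            pt.morans_i(tree, np.array([1.0, 2.0, 3.0]), n_perm=9, seed=0)


class TestPermutationConventions:
    @pytest.mark.parametrize("fn", [pt.blomberg_k, pt.abouheif_cmean, pt.morans_i])
    def test_reproducible_and_floor(self, fn):
        tree = pt.simulate_yule_tree(40, 1.0, seed=21)
        y = pt.simulate_bm_traits(tree, pt.SimulationSpec(n_tips=40, seed=22))
        a = fn(tree, y, n_perm=199, seed=77)
        b = fn(tree, y, n_perm=199, seed=77)
        assert a == b
        assert a.p_value >= 1 / 200

    @pytest.mark.parametrize("fn", [pt.blomberg_k, pt.abouheif_cmean, pt.morans_i])
    def test_affine_invariance_of_p(self, fn):
        """Permutation p-values are unchanged by y -> a*y + b with a > 0."""
        tree = pt.simulate_yule_tree(30, 1.0, seed=31)
        y = pt.simulate_bm_traits(tree, pt.SimulationSpec(n_tips=30, seed=32))
        y2 = 3.7 * y + 11.0
        assert fn(tree, y, 99, 5).p_value == fn(tree, y2, 99, 5).p_value


def test_delta_tempo_ordering():
    """Traits generated with accelerating late change (delta=2) fit larger
    delta than traits with early change (delta=0.5) on the same trees."""
    lo, hi = [], []
    for s in range(10):
        tree = pt.simulate_yule_tree(60, 1.0, seed=900 + s)
        y1 = pt.simulate_bm_traits(
            tree, pt.SimulationSpec(n_tips=60, transform=pt.TransformParams(delta=0.5), seed=s)
        )
        y2 = pt.simulate_bm_traits(
            tree, pt.SimulationSpec(n_tips=60, transform=pt.TransformParams(delta=2.0), seed=s)
        )
        lo.append(pt.fit_pagel(tree, y1, "delta").estimate)
        hi.append(pt.fit_pagel(tree, y2, "delta").estimate)
    assert np.median(lo) < np.median(hi)
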
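import math

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from paralogsel.ctmc import (
    McmcConfig,
    NodeConstraint,
    SteppingStoneConfig,
    TraitLikelihood,
    TraitModel,
    ancestral_constraint_scan,
    fit_ml,
    log_bayes_factor,
    log_likelihood,
    lrt_dependent_vs_independent,
    run_mcmc,
    stepping_stone_logml,
    transition_matrix,
)
from paralogsel.phylo import read_newick
from paralogsel.simulate import TreeSpec, simulate_traits, simulate_tree
from paralogsel.traits import TraitTable

from conftest import enumeration_loglik, random_tree


class TestTransitionMatrix:
    def test_t_zero_identity(self):
        assert np.allclose(transition_matrix(1.0, 2.0, 0.0), np.eye(2))

    def test_stationary_limit(self):
        P = transition_matrix(0.7, 0.7, 1e6)
        assert np.allclose(P, 0.5)

    def test_matches_matrix_exponential(self):
        q01, q10, t = 1.0, 2.0, 0.7
        Q = np.array([[-q01, q01], [q10, -q10]])
        assert np.allclose(transition_matrix(q01, q10, t), expm(Q * t), atol=1e-12)

    def test_rows_sum_to_one(self):
        P = transition_matrix(0.3, 1.7, 2.5)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(1.0, 1.0, -0.1)


class TestLogLikelihood:
    def test_all_unknown_gives_zero(self):
        tree = random_tree(8, 0)
        traits = TraitTable.from_mapping({l: "unknown" for l in tree.tip_labels})
        assert log_likelihood(tree, traits, TraitModel(0.3, 0.9)) == pytest.approx(0.0, abs=1e-12)

    def test_single_tip_zero_branch_stationary(self):
        tree = read_newick("(A:0,B:1e-10):0;" if False else "(A:0.0,B:0.0);")
        traits = TraitTable.from_mapping({"A": "1", "B": "unknown"})
        ll = log_likelihood(tree, traits, TraitModel(0.5, 0.5))
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        tree = random_tree(n, seed + 100, delta_fraction=0.5 if n >= 4 else None)
        model = TraitModel(*np.exp(rng.uniform(-3, 1, size=2)), float(np.exp(rng.uniform(-3, 1))))
        traits = simulate_traits(tree, model, seed=seed)
        if rng.random() < 0.5:  # inject unknowns
            traits[tree.tip_labels[0]] = "unknown"
        ll = log_likelihood(tree, traits, model)
        assert ll == pytest.approx(enumeration_loglik(tree, traits, model), abs=1e-10)

    def test_invariant_to_child_order(self):
        model = TraitModel(0.4, 0.8)
        t1 = read_newick("((A:1,B:2):0.5,C:1.5);")
        t2 = read_newick("(C:1.5,(B:2,A:1):0.5);")
        traits = TraitTable.from_mapping({"A": "1", "B": "0", "C": "1"})
        assert log_likelihood(t1, traits, model) == pytest.approx(
            log_likelihood(t2, traits, model), abs=1e-12
        )

    def test_invariant_to_branch_split(self):
        model = TraitModel(0.4, 0.8)
        whole = read_newick("((A:1,B:2):1.0,C:1.5);")
        split = read_newick("(((A:1,B:2):0.4):0.6,C:1.5);")
        traits = TraitTable.from_mapping({"A": "1", "B": "0", "C": "1"})
        assert log_likelihood(whole, traits, model) == pytest.approx(
            log_likelihood(split, traits, model), abs=1e-12
        )

    def test_scalar_and_vector_paths_agree(self):
        tree = random_tree(80, 5, delta_fraction=0.4)
        model = TraitModel(0.2, 0.5, 1.1)
        traits = simulate_traits(tree, model, seed=6)
        engine = TraitLikelihood(tree, traits, delta_classes=model.delta_classes)
        a = engine._loglik_scalar(0.2, 0.5, 1.1, "stationary")
        b = engine._loglik_vector(0.2, 0.5, 1.1, "stationary")
        assert a == pytest.approx(b, abs=1e-9)

    def test_missing_tip_traits_rejected(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError, match="missing"):
            log_likelihood(tree, {"A": "1", "B": "0"}, TraitModel(0.1, 0.1))


class TestFitMl:
    def test_all_present_loss_at_lower_bound(self):
        tree = random_tree(20, 1)
        traits = TraitTable.from_mapping({l: "1" for l in tree.tip_labels})
        fit = fit_ml(tree, traits, "independent", n_starts=3)
        assert fit.params["q10"] < 1e-4  # driven to the lower bound region
        assert fit.log_likelihood == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("seed", range(20))
    def test_nested_model_dominance(self, seed):
        tree = random_tree(15, seed, delta_fraction=0.4)
        rng = np.random.default_rng(seed)
        model = TraitModel(*np.exp(rng.uniform(-2.5, 0.5, size=2)))
        traits = simulate_traits(tree, model, seed=seed + 1)
        fit_i = fit_ml(tree, traits, "independent", n_starts=2, seed=seed)
        fit_d = fit_ml(
            tree, traits, "dependent", n_starts=2, seed=seed,
            init=[fit_i.model.q01, fit_i.model.q10, fit_i.model.q10],
        )
        assert fit_d.log_likelihood >= fit_i.log_likelihood - 1e-7


class TestLrt:
    def test_equal_likelihoods(self):
        stat, p = lrt_dependent_vs_independent(-10.0, -10.0)
        assert stat == 0.0 and p == 1.0

    def test_chi2_oracle_at_3841(self):
        stat, p = lrt_dependent_vs_independent(-10.0, -10.0 + 3.841 / 2)
        assert p == pytest.approx(stats.chi2.sf(3.841, 1), abs=1e-12)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_precondition(self):
        with pytest.raises(ValueError):
            lrt_dependent_vs_independent(-5.0, -6.0)


class TestMcmc:
    def test_seed_reproducibility(self):
        tree = random_tree(6, 2)
        traits = TraitTable.from_mapping(dict.fromkeys(tree.tip_labels, "unknown"))
        cfg = McmcConfig(iterations=2_000, burn_in=500, thinning=10, seed=7)
        a = run_mcmc(tree, traits, "independent", cfg=cfg)
        b = run_mcmc(tree, traits, "independent", cfg=cfg)
        assert np.array_equal(a.samples["q01"], b.samples["q01"])
        assert np.array_equal(a.samples["q10"], b.samples["q10"])

    def test_sample_count_matches_config(self):
        tree = random_tree(5, 3)
        traits = TraitTable.from_mapping(dict.fromkeys(tree.tip_labels, "unknown"))
        cfg = McmcConfig(iterations=3_000, burn_in=1_000, thinning=20, seed=1)
        res = run_mcmc(tree, traits, "independent", cfg=cfg)
        assert len(res.samples["q01"]) == (3_000 - 1_000) // 20

    def test_ratio_medians_are_per_sample(self):
        tree = random_tree(8, 4, delta_fraction=0.5)
        model = TraitModel(0.5, 0.2, 0.9)
        traits = simulate_traits(tree, model, seed=5)
        cfg = McmcConfig(iterations=3_000, burn_in=500, thinning=25, seed=2)
        res = run_mcmc(tree, traits, "dependent", cfg=cfg)
        expected = float(np.median(res.samples["q01"] / res.samples["q10"]))
        assert res.ratio_medians["q01:q10"] == pytest.approx(expected)
        assert "q01:q10_delta" in res.ratio_medians

    def test_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcConfig(thinning=0)


class TestSteppingStone:
    def test_flat_likelihood_logml_zero(self):
        tree = random_tree(6, 1)
        traits = TraitTable.from_mapping(dict.fromkeys(tree.tip_labels, "unknown"))
        cfg = SteppingStoneConfig(n_stones=8, iterations_per_stone=300, seed=3)
        res = stepping_stone_logml(tree, traits, "independent", cfg=cfg)
        assert res.log_marginal_likelihood == pytest.approx(0.0, abs=0.05)

    def test_requires_two_stones(self):
        with pytest.raises(ValueError):
            SteppingStoneConfig(n_stones=1)

    def test_doubling_stones_reduces_error(self):
        # median absolute error vs a dense-stone reference, over 10 seeds
        tree = random_tree(6, 1)
        traits = simulate_traits(tree, TraitModel(0.5, 0.5), seed=9)
        reference = stepping_stone_logml(
            tree, traits, "independent",
            cfg=SteppingStoneConfig(n_stones=48, iterations_per_stone=2_000, seed=999),
        ).log_marginal_likelihood
        errors = {}
        for stones in (8, 16):
            errs = []
            for seed in range(10):
                res = stepping_stone_logml(
                    tree, traits, "independent",
                    cfg=SteppingStoneConfig(n_stones=stones, iterations_per_stone=500, seed=seed),
                )
                errs.append(abs(res.log_marginal_likelihood - reference))
            errors[stones] = float(np.median(errs))
        assert errors[16] < errors[8] + 0.02  # never meaningfully worse
        assert errors[16] < 0.3


class TestDependentModelPower:
    def test_lrt_detects_class_specific_loss(self):
        # strong loss-rate contrast (q10d >> q10): LRT rejects in >= 80% of 20 seeds
        rejections = 0
        for seed in range(20):
            tree = random_tree(500, 700 + seed, delta_fraction=0.4, scale=4.0)
            traits = simulate_traits(tree, TraitModel(0.1, 0.02, 0.3), seed=800 + seed)
            fit_i = fit_ml(tree, traits, "independent", n_starts=2, seed=seed)
            fit_d = fit_ml(
                tree, traits, "dependent", n_starts=2, seed=seed,
                init=[fit_i.model.q01, fit_i.model.q10, fit_i.model.q10],
            )
            _, p = lrt_dependent_vs_independent(fit_i.log_likelihood, fit_d.log_likelihood)
            rejections += p < 0.05
        assert rejections >= 16


class TestBayesFactor:
    def test_equal_is_weak_zero(self):
        assert log_bayes_factor(-3.0, -3.0) == (0.0, "weak")

    def test_positive_band(self):
        value, verdict = log_bayes_factor(-1.0, -3.45)
        assert value == pytest.approx(4.9)
        assert verdict == "positive"

    def test_strong_band(self):
        value, verdict = log_bayes_factor(0.0, -2.75)
        assert value == pytest.approx(5.5)
        assert verdict == "strong"

    def test_formula_is_twice_difference(self):
        value, _ = log_bayes_factor(-10.0, -12.5)
        assert value == pytest.approx(2 * (-10.0 - -12.5))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            log_bayes_factor(float("inf"), 0.0)


class TestConstraints:
    @pytest.mark.parametrize("seed", range(10))
    def test_partition_identity(self, seed):
        tree = random_tree(10, seed, delta_fraction=0.4)
        rng = np.random.default_rng(seed)
        model = TraitModel(*np.exp(rng.uniform(-2, 0.5, size=2)), float(np.exp(rng.uniform(-2, 0.5))))
        traits = simulate_traits(tree, model, seed=seed + 50)
        taxa = set(tree.tip_labels[: int(rng.integers(2, 6))])
        scan = ancestral_constraint_scan(tree, traits, model, taxa)
        assert scan.identity_ok

    def test_favored_state_costs_less(self):
        tree = random_tree(10, 3)
        model = TraitModel(0.3, 0.3)
        traits = TraitTable.from_mapping({l: "1" for l in tree.tip_labels})
        scan = ancestral_constraint_scan(tree, traits, model, set(tree.tip_labels[:4]))
        # all tips present: ancestor almost surely present
        assert scan.ll_present > scan.ll_absent
        assert scan.ll_unconstrained - scan.ll_present < scan.ll_unconstrained - scan.ll_absent

    def test_constraint_via_log_likelihood(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        traits = TraitTable.from_mapping({"A": "1", "B": "1", "C": "0"})
        model = TraitModel(0.2, 0.2)
        base = log_likelihood(tree, traits, model)
        constrained = log_likelihood(
            tree, traits, model, [NodeConstraint(frozenset({"A", "B"}), "present")]
        )
        assert constrained <= base + 1e-12

    def test_bad_state_rejected(self):
        with pytest.raises(ValueError):
            NodeConstraint(frozenset({"A"}), "maybe")
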
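import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from oracles import (brute_force_loglik, expm_transition,
                     gamma_category_means)
from traitevo import synthetic
from traitevo.io_core import parse_newick
from traitevo.model import (MISSING, BinaryPhyleticMatrix, EstimationError)
from traitevo.trait_rates import (TwoStateModel, discretize_gamma,
                                  estimate_gamma_shape,
                                  pattern_log_likelihood,
                                  posterior_site_rate, trait_rate_profile,
                                  two_state_transition_matrix,
                                  zscore_normalize)

TWO_STATE_Q = np.array([[-1.0, 1.0], [1.0, -1.0]])


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        np.testing.assert_allclose(two_state_transition_matrix(1.0, 0.0),
                                   np.eye(2))

    def test_long_time_reaches_stationarity(self):
        p = two_state_transition_matrix(1.0, 1e6)
        np.testing.assert_allclose(p, np.full((2, 2), 0.5), atol=1e-12)

    def test_closed_form_matches_matrix_exponential(self):
        p = two_state_transition_matrix(1.0, 0.5)
        assert p[0, 0] == pytest.approx(0.6839397, abs=1e-7)
        assert p[0, 1] == pytest.approx(0.3160603, abs=1e-7)
        np.testing.assert_allclose(
            p, expm_transition(TWO_STATE_Q, 1.0, 0.5), atol=1e-12)

    @pytest.mark.parametrize("rate,t", [(0.3, 0.1), (2.5, 1.7),
                                        (1.0, 10.0)])
    def test_rows_sum_to_one(self, rate, t):
        p = two_state_transition_matrix(rate, t)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(Exception, match=">= 0"):
            two_state_transition_matrix(1.0, -0.1)


class TestDiscretizeGamma:
    @pytest.mark.parametrize("alpha,k", [(0.2, 4), (1.0, 6), (5.0, 16),
                                         (0.5, 1)])
    def test_mean_is_one(self, alpha, k):
        rates = discretize_gamma(alpha, k)
        assert rates.mean() == pytest.approx(1.0, abs=1e-9)
        assert len(rates) == k

    def test_vanishing_heterogeneity_limit(self):
        rates = discretize_gamma(1e6, 4)
        np.testing.assert_allclose(rates, 1.0, atol=1e-2)

    def test_matches_quadrature_oracle(self):
        rates = discretize_gamma(0.5, 4)
        assert (np.diff(rates) > 0).all()
        oracle = gamma_category_means(0.5, 4)
        oracle /= oracle.mean()
        np.testing.assert_allclose(rates, oracle, rtol=1e-7)

    def test_invalid_shape_rejected(self):
        with pytest.raises(EstimationError):
            discretize_gamma(-1.0, 4)


class TestPatternLikelihood:
    def test_two_leaf_concordant_value(self):
        tree = parse_newick("(A:0.5,B:0.5);")
        ll = pattern_log_likelihood(tree, {"A": 1, "B": 1}, 1.0)
        assert math.exp(ll) == pytest.approx(0.283834, abs=1e-6)

    def test_all_missing_gives_unit_likelihood(self):
        tree = parse_newick("(A:0.5,B:0.5);")
        ll = pattern_log_likelihood(tree, {"A": MISSING, "B": MISSING},
                                    1.0)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_zero_time_forbids_change(self):
        tree = parse_newick("(A:0,B:0);")
        ll = pattern_log_likelihood(tree, {"A": 1, "B": 0}, 1.0)
        assert ll == -np.inf

    @pytest.mark.parametrize("newick,pattern", [
        ("(A:0.5,B:0.5);", {"A": 1, "B": 0}),
        ("((A:0.2,B:0.7):0.4,C:1.1);", {"A": 1, "B": 0, "C": 1}),
        ("((A:0.2,B:0.7):0.4,(C:1.1,D:0.3):0.6);",
         {"A": 1, "B": 0, "C": 1, "D": 0}),
        ("((A:0.2,B:0.7):0.4,(C:1.1,D:0.3):0.6);",
         {"A": 1, "B": MISSING, "C": 1, "D": 0}),
        ("(((A:0.2,B:0.7):0.3,C:0.5):0.4,(D:1.1,E:0.3):0.6);",
         {"A": 0, "B": 1, "C": 1, "D": 0, "E": 1}),
        ("((((A:0.2,B:0.7):0.3,C:0.5):0.2,D:1.1):0.4,E:0.3);",
         {"A": 0, "B": 1, "C": 0, "D": 0, "E": 1}),
    ])
    def test_agrees_with_enumeration_oracle(self, newick, pattern):
        tree = parse_newick(newick)
        rate = 0.8
        pmats = {id(n): two_state_transition_matrix(rate, n.branch_length)
                 for n in tree.postorder() if n is not tree.root}
        states = {k: (None if v == MISSING else v)
                  for k, v in pattern.items()}
        oracle = brute_force_loglik(tree, states, pmats,
                                    np.array([0.5, 0.5]))
        ll = pattern_log_likelihood(tree, pattern, rate)
        assert abs(ll - oracle) < 1e-10

    def test_k1_mixture_equals_single_rate(self):
        # with a single gamma category the mixture likelihood must reduce
        # to the plain likelihood at rate 1
        tree = parse_newick("((A:0.2,B:0.7):0.4,C:1.1);")
        pattern = {"A": 1, "B": 0, "C": 1}
        rates = discretize_gamma(2.3, 1)
        assert rates[0] == pytest.approx(1.0)
        ll_single = pattern_log_likelihood(tree, pattern, 1.0)
        ll_k1 = pattern_log_likelihood(tree, pattern, float(rates[0]))
        assert ll_k1 == pytest.approx(ll_single, abs=1e-14)

    def test_symmetry_under_state_relabeling(self):
        tree = parse_newick("((A:0.2,B:0.7):0.4,(C:1.1,D:0.3):0.6);")
        pattern = {"A": 1, "B": 0, "C": 1, "D": 1}
        flipped = {k: 1 - v for k, v in pattern.items()}
        for rate in (0.3, 1.0, 4.0):
            assert pattern_log_likelihood(tree, pattern, rate) == \
                pytest.approx(pattern_log_likelihood(tree, flipped, rate),
                              abs=1e-12)


class TestPosteriorRate:
    def test_concordant_star_pattern_is_slow(self):
        tree = parse_newick("(A:0.4,B:0.4,C:0.4,D:0.4,E:0.4);")
        r_same = posterior_site_rate(tree, {lf: 1 for lf in "ABCDE"},
                                     alpha=1.0)
        assert r_same < 1.0

    def test_discordance_raises_the_rate(self):
        tree = parse_newick("(A:0.4,B:0.4,C:0.4,D:0.4);")
        r_same = posterior_site_rate(tree, {lf: 0 for lf in "ABCD"},
                                     alpha=1.0)
        r_half = posterior_site_rate(tree, {"A": 0, "B": 0, "C": 1,
                                            "D": 1}, alpha=1.0)
        assert r_half > r_same

    @pytest.mark.parametrize("pattern", [{"A": 1, "B": 1},
                                         {"A": 1, "B": 0}])
    def test_matches_category_enumeration_oracle(self, pattern):
        tree = parse_newick("(A:0.5,B:0.5);")
        alpha, k = 1.0, 6
        rates = discretize_gamma(alpha, k)
        # closed-form 2-leaf likelihood per category
        liks = []
        for r in rates:
            p = two_state_transition_matrix(r, 0.5)
            states = list(pattern.values())
            lik = sum(0.5 * p[s, states[0]] * p[s, states[1]]
                      for s in (0, 1))
            liks.append(lik)
        liks = np.array(liks)
        oracle = float((rates * liks).sum() / liks.sum())
        got = posterior_site_rate(tree, pattern, alpha, k)
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_relabeling_invariance(self):
        tree = parse_newick("((A:0.2,B:0.7):0.4,C:1.1);")
        pattern = {"A": 1, "B": 0, "C": 0}
        flipped = {k: 1 - v for k, v in pattern.items()}
        assert posterior_site_rate(tree, pattern, 0.7) == pytest.approx(
            posterior_site_rate(tree, flipped, 0.7), abs=1e-12)


class TestZScore:
    def test_forced_by_sample_sd_convention(self):
        np.testing.assert_allclose(zscore_normalize([1.0, 2.0, 3.0]),
                                   [-1.0, 0.0, 1.0])

    def test_mean_zero(self, rng):
        z = zscore_normalize(rng.gamma(2.0, size=200))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(EstimationError, match="constant"):
            zscore_normalize([5.0, 5.0, 5.0])


class TestShapeEstimation:
    def test_recovers_simulated_shape(self):
        tree = synthetic.simulate_yule_tree(30, seed=5, depth=1.0)
        matrix, _, _ = synthetic.simulate_binary_trait_matrix(
            tree, 500, alpha=1.0, seed=11)
        alpha = estimate_gamma_shape(tree, matrix)
        assert 0.75 <= alpha <= 1.25

    def test_constant_matrix_hits_search_bound(self, caplog):
        # no heterogeneity signal: the estimate runs into a search bound
        # (for all-constant columns the likelihood increases as rates
        # shrink, so the boundary reached is the slow/low-shape one)
        tree = parse_newick("((A:0.2,B:0.7):0.4,C:1.1);")
        matrix = BinaryPhyleticMatrix(
            ["A", "B", "C"], np.ones((3, 8), dtype=np.int8), "disorder")
        with caplog.at_level("WARNING", logger="traitevo"):
            alpha = estimate_gamma_shape(tree, matrix)
        assert alpha < 0.011 or alpha > 99.0
        assert any("bound" in r.message for r in caplog.records)

    def test_single_column_is_legal(self):
        tree = parse_newick("((A:0.2,B:0.7):0.4,C:1.1);")
        matrix = BinaryPhyleticMatrix(
            ["A", "B", "C"], np.array([[1], [0], [1]], dtype=np.int8),
            "disorder")
        alpha = estimate_gamma_shape(tree, matrix)
        assert np.isfinite(alpha) and alpha > 0

    def test_all_missing_matrix_rejected(self):
        tree = parse_newick("(A:0.5,B:0.5);")
        matrix = BinaryPhyleticMatrix(
            ["A", "B"], np.full((2, 4), MISSING, dtype=np.int8),
            "disorder")
        with pytest.raises(EstimationError):
            estimate_gamma_shape(tree, matrix)


class TestProfile:
    def test_rate_recovery_on_synthetic_data(self):
        tree = synthetic.simulate_yule_tree(30, seed=3, depth=1.0)
        matrix, true_rates, cats = synthetic.simulate_binary_trait_matrix(
            tree, 200, alpha=0.7, seed=13)
        prof = trait_rate_profile(tree, matrix, "DOT")
        rho = spearmanr(true_rates, prof.raw).statistic
        assert rho > 0.7
        # fastest true category evolves faster than slowest on average
        fast = prof.raw[cats == cats.max()].mean()
        slow = prof.raw[cats == cats.min()].mean()
        assert fast > slow

    def test_single_clade_scope_equals_family(self, tiny_bundle):
        from traitevo.model import CladeAssignment
        from traitevo.trait_binarize import assemble_phyletic_matrix
        aln = tiny_bundle.alignment
        matrix = assemble_phyletic_matrix(
            aln, tiny_bundle.tracks["disorder"], "disorder")
        one_clade = CladeAssignment({lb: "only" for lb in aln.labels})
        fam = trait_rate_profile(tiny_bundle.tree, matrix, "DOT")
        clade = trait_rate_profile(tiny_bundle.tree, matrix, "DOT",
                                   scope="only", clades=one_clade)
        np.testing.assert_allclose(fam.raw, clade.raw, equal_nan=True)

    def test_column_permutation_permutes_profile(self, tiny_bundle):
        from traitevo.trait_binarize import assemble_phyletic_matrix
        matrix = assemble_phyletic_matrix(
            tiny_bundle.alignment, tiny_bundle.tracks["disorder"],
            "disorder")
        perm = np.random.default_rng(0).permutation(matrix.n_columns)
        permuted = BinaryPhyleticMatrix(
            matrix.taxa, matrix.data[:, perm], matrix.kind)
        base = trait_rate_profile(tiny_bundle.tree, matrix, "DOT")
        shuf = trait_rate_profile(tiny_bundle.tree, permuted, "DOT")
        np.testing.assert_allclose(shuf.raw, base.raw[perm],
                                   rtol=1e-8, equal_nan=True)
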
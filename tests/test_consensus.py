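"""Majority voting and Bayes fusion: worked examples, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarfuse import (
    BayesState,
    ConfusionMatrix,
    ConsensusConfig,
    LikelihoodTable,
    bayes_consensus,
    bayes_update,
    coverage,
    estimate_likelihoods,
    majority_vote,
    run_consensus,
    vote_profile,
)
from qsarfuse.io import ACTIVE, INACTIVE
from qsarfuse.synthetic import joint_bayes_oracle

from conftest import A, I, N, make_table


def symmetric_likelihoods(qs):
    """Models whose p(correct|class) is q for both classes."""
    qs = np.asarray(qs, dtype=float)
    return LikelihoodTable([f"m{j}" for j in range(len(qs))], qs, 1.0 - qs)


class TestVoteProfile:
    @pytest.mark.parametrize("votes,ad,expected", [
        ([A, A, I], [1, 1, 1], (3, 2 / 3)),
        ([A, A, I], [1, 0, 1], (2, 1 / 2)),
        ([N, N, N], [1, 1, 1], (0, 0.0)),
    ])
    def test_counts(self, votes, ad, expected):
        n, freq = vote_profile(np.array(votes), np.array(ad, dtype=bool))
        assert n == expected[0]
        assert freq == pytest.approx(expected[1])


class TestMajorityVote:
    def test_unanimity_assigned_under_all_modes(self):
        table = make_table([[A, A, A]], [A])
        for method in ("MVL", "MVI", "MVS"):
            res = majority_vote(table, ConsensusConfig(method=method))
            assert res.fused[0] == ACTIVE
            assert res.agreement[0] == 1.0

    def test_exact_tie_abstains_everywhere(self):
        table = make_table([[A, A, I, I]], [A])
        for method in ("MVL", "MVI", "MVS"):
            res = majority_vote(table, ConsensusConfig(method=method))
            assert res.fused[0] == N

    def test_75_percent_agreement_splits_the_modes(self):
        table = make_table([[A, A, A, I]], [A])
        assert majority_vote(table, ConsensusConfig(method="MVL")).fused[0] == ACTIVE
        assert majority_vote(table, ConsensusConfig(method="MVI")).fused[0] == ACTIVE
        assert majority_vote(table, ConsensusConfig(method="MVS")).fused[0] == N

    def test_unknown_method_rejected(self):
        table = make_table([[A]], [A])
        with pytest.raises(ValueError):
            majority_vote(table, ConsensusConfig(method="B"))

    def test_min_votes_gate(self):
        table = make_table([[A, N, N]], [A])
        cfg = ConsensusConfig(method="MVL", min_votes=2)
        assert majority_vote(table, cfg).fused[0] == N


class TestEstimateLikelihoods:
    def test_raw_ratios(self):
        lk = estimate_likelihoods([ConfusionMatrix(8, 2, 9, 1)], alpha=0.0)
        assert lk.p_active_given_active[0] == pytest.approx(0.8)
        assert lk.p_active_given_inactive[0] == pytest.approx(0.1)

    def test_smoothing_keeps_probabilities_interior(self):
        lk = estimate_likelihoods([ConfusionMatrix(10, 0, 10, 0)], alpha=0.5)
        assert lk.p_active_given_active[0] == pytest.approx(10.5 / 11)
        assert 0 < lk.p_active_given_inactive[0] < 1

    def test_empty_class_without_smoothing_raises(self):
        with pytest.raises(ValueError):
            estimate_likelihoods([ConfusionMatrix(0, 0, 5, 5)], alpha=0.0)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            estimate_likelihoods([ConfusionMatrix(1, 1, 1, 1)], alpha=-0.1)


class TestBayesUpdate:
    def likelihoods(self, pa_A, pa_I):
        return {
            ACTIVE: {ACTIVE: pa_A, INACTIVE: 1 - pa_A},
            INACTIVE: {ACTIVE: pa_I, INACTIVE: 1 - pa_I},
        }

    def test_uninformative_model_leaves_prior(self):
        post = bayes_update(BayesState(0.5, 0.5), self.likelihoods(0.5, 0.5), ACTIVE)
        assert post.p_active == pytest.approx(0.5)

    def test_single_update_arithmetic(self):
        post = bayes_update(BayesState(0.5, 0.5), self.likelihoods(0.8, 0.2), ACTIVE)
        assert post.p_active == pytest.approx(0.8)

    def test_chained_prior(self):
        post = bayes_update(BayesState(0.8, 0.2), self.likelihoods(0.8, 0.2), ACTIVE)
        assert post.p_active == pytest.approx(0.64 / 0.68)
        assert post.p_inactive == pytest.approx(0.04 / 0.68)


class TestBayesConsensus:
    def test_two_agreeing_models(self):
        table = make_table([[A, A]], [A])
        lk = symmetric_likelihoods([0.8, 0.8])
        res = bayes_consensus(table, lk, ConsensusConfig(method="B"))
        assert res.posterior_active[0] == pytest.approx(16 / 17, abs=1e-12)
        assert res.fused[0] == ACTIVE
        # protective at 0.95 abstains: 16/17 ~ 0.941 < 0.95
        res_p = bayes_consensus(table, lk, ConsensusConfig(method="Bp"))
        assert res_p.fused[0] == N

    def test_single_model_posterior(self):
        table = make_table([[A]], [A])
        res = bayes_consensus(table, symmetric_likelihoods([0.9]), ConsensusConfig(method="B"))
        assert res.posterior_active[0] == pytest.approx(0.9, abs=1e-12)
        assert res.fused[0] == ACTIVE

    def test_no_evidence_keeps_prior_and_abstains(self):
        table = make_table([[A, A]], [A], ad=[[False, False]])
        res = bayes_consensus(table, symmetric_likelihoods([0.8, 0.8]),
                              ConsensusConfig(method="B"))
        assert res.fused[0] == N
        assert res.posterior_active[0] == pytest.approx(0.5)

    def test_mismatched_models_rejected(self):
        table = make_table([[A, A]], [A])
        with pytest.raises(ValueError, match="models"):
            bayes_consensus(table, symmetric_likelihoods([0.8]), ConsensusConfig(method="B"))


class TestRunConsensus:
    def test_dispatch_matches_majority_vote(self, small_table):
        cfg = ConsensusConfig(method="MVL")
        r1 = run_consensus(small_table, cfg)
        r2 = majority_vote(small_table, cfg)
        assert np.array_equal(r1.fused, r2.fused)

    def test_protective_bayes_single_weak_model_never_assigns(self):
        table = make_table([[A]] * 5 + [[I]] * 5, [A] * 5 + [I] * 5)
        lk = symmetric_likelihoods([0.6])
        res = bayes_consensus(table, lk, ConsensusConfig(method="Bp"))
        assert (res.fused == N).all()

    def test_bayes_without_likelihoods_or_labels_raises(self):
        from qsarfuse.io import UNKNOWN

        table = make_table([[A, I]], [UNKNOWN])
        with pytest.raises(ValueError, match="likelihood"):
            run_consensus(table, ConsensusConfig(method="B"))

    def test_unanimous_table_fully_assigned_under_mvs(self):
        table = make_table([[A, A], [I, I]], [A, I])
        res = run_consensus(table, ConsensusConfig(method="MVS"))
        assert (res.fused != N).all()


def random_case(rng, max_models=6):
    m = int(rng.integers(1, max_models + 1))
    qs_A = rng.uniform(0.05, 0.95, size=m)
    qs_I = rng.uniform(0.05, 0.95, size=m)
    lk = LikelihoodTable([f"m{j}" for j in range(m)], qs_A, qs_I)
    votes = rng.choice([A, I, N], size=(1, m)).astype(np.int8)
    ad = rng.random((1, m)) < 0.8
    table = make_table(votes, [A], ad=ad)
    return table, lk


class TestOracleEquivalence:
    def test_iterative_matches_joint_product_on_random_configurations(self):
        """Chained per-model updates equal the single-shot normalised product."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            table, lk = random_case(rng)
            res = bayes_consensus(table, lk, ConsensusConfig(method="B"))
            eff = table.effective_votes()[0]
            evidence = [None if v == N else int(v) for v in eff]
            oracle = joint_bayes_oracle(lk, BayesState(0.5, 0.5), evidence)
            assert res.posterior_active[0] == pytest.approx(oracle.p_active, abs=1e-10)

    def test_joint_oracle_single_model_reduces_to_bayes_update(self):
        lk = symmetric_likelihoods([0.7])
        oracle = joint_bayes_oracle(lk, BayesState(0.5, 0.5), [ACTIVE])
        upd = bayes_update(BayesState(0.5, 0.5),
                           lk.for_model("m0"), ACTIVE)
        assert oracle.p_active == pytest.approx(upd.p_active, abs=1e-15)


class TestOrderInvariance:
    def test_permuting_models_leaves_posteriors_unchanged(self):
        """With equal priors the normalised product cannot depend on the
        iteration order of the models."""
        rng = np.random.default_rng(11)
        m = 8
        qs_A = rng.uniform(0.1, 0.9, size=m)
        qs_I = rng.uniform(0.1, 0.9, size=m)
        lk = LikelihoodTable([f"m{j}" for j in range(m)], qs_A, qs_I)
        votes = rng.choice([A, I, N], size=(20, m)).astype(np.int8)
        table = make_table(votes, [A] * 20)
        base = bayes_consensus(table, lk, ConsensusConfig(method="B"))
        for _ in range(100):
            perm = rng.permutation(m)
            t2 = table.select_models(list(perm))
            lk2 = lk.select_models(t2.model_names)
            res = bayes_consensus(t2, lk2, ConsensusConfig(method="B"))
            np.testing.assert_allclose(res.posterior_active, base.posterior_active,
                                       atol=1e-10)


class TestReductionToMajority:
    @settings(max_examples=40)
    @given(
        q=st.floats(0.55, 0.95),
        votes=st.lists(st.sampled_from([A, I]), min_size=1, max_size=7).filter(
            lambda v: len(v) % 2 == 1
        ),
    )
    def test_symmetric_identical_models_argmax_equals_majority(self, q, votes):
        """With identical symmetric likelihoods q > 0.5 and equal priors the
        Bayes argmax is the majority class for every odd vote profile."""
        m = len(votes)
        lk = symmetric_likelihoods([q] * m)
        table = make_table([votes], [A])
        res = bayes_consensus(table, lk, ConsensusConfig(method="B"))
        majority = A if votes.count(A) > m / 2 else I
        assert res.fused[0] == majority


class TestProtectiveDominance:
    def test_coverage_ordering_on_generated_table(self):
        from qsarfuse import demo_config, generate_table

        table = generate_table(demo_config(seed=5, n=800, n_models=12))
        cvg = {}
        for method in ("MVL", "MVI", "MVS", "B", "Bp"):
            res = run_consensus(table, ConsensusConfig(method=method))
            cvg[method] = coverage(res.fused, table.n_chemicals)
        assert cvg["MVS"] <= cvg["MVI"] <= cvg["MVL"]
        assert cvg["Bp"] <= cvg["B"]

    def test_raising_posterior_threshold_never_raises_coverage(self):
        from qsarfuse import demo_config, generate_table

        table = generate_table(demo_config(seed=6, n=500, n_models=10))
        prev = 101.0
        for thr in (0.6, 0.8, 0.9, 0.95, 0.99):
            res = run_consensus(table, ConsensusConfig(method="Bp", posterior_threshold=thr))
            c = coverage(res.fused, table.n_chemicals)
            assert c <= prev + 1e-12
            prev = c
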
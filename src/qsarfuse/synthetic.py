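"""Synthetic multi-model prediction ensembles with known ground truth.

The generator emulates the structure of a large collaborative QSAR
evaluation set: ``n`` chemicals with strong class imbalance, ``M`` models
with heterogeneous sensitivity, specificity and applicability-domain
coverage, votes conditionally independent given the true class, and AD
membership Bernoulli per model. Because the truth is known by construction,
every consensus strategy and metric can be validated against analytic
oracles (binomial majority accuracy, single-shot Bayes products) without
any external data.

The default demo preset mirrors the shape of real multi-group ensembles:
4 000 chemicals, 10 % actives, 30 models with Sn in [0.2, 0.85], Sp in
[0.75, 1.0] and coverage in [0.6, 1.0].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .consensus import BayesState, LikelihoodTable
from .io import ACTIVE, INACTIVE, NO_PREDICTION, PredictionTable


@dataclass(frozen=True)
class ModelSpec:
    """Operating characteristics of one simulated model.

    sn / sp are the probabilities of a correct vote on a true active /
    inactive chemical inside the model's AD; cvg is the Bernoulli
    probability that a chemical falls inside the AD at all.
    """

    sn: float
    sp: float
    cvg: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sn", "sp", "cvg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SimulationConfig:
    """Ensemble-level simulation parameters.

    shared_flip_prob introduces pairwise correlation between models: with
    that probability a chemical is a latent "hard case" whose every in-AD
    vote is flipped, violating conditional independence. It defaults to 0
    (the assumption underlying the Bayes chain).
    """

    n: int
    pi_active: float
    model_specs: list[ModelSpec]
    seed: int
    fingerprint_bits: int | None = None
    shared_flip_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.pi_active <= 1.0):
            raise ValueError("pi_active must lie in [0, 1]")
        if not self.model_specs:
            raise ValueError("at least one model spec is required")
        if not (0.0 <= self.shared_flip_prob <= 1.0):
            raise ValueError("shared_flip_prob must lie in [0, 1]")


def demo_config(seed: int = 0, n: int = 4000, n_models: int = 30,
                pi_active: float = 0.10) -> SimulationConfig:
    """Default heterogeneous-ensemble preset.

    Per-model Sn, Sp and Cvg are drawn uniformly from [0.2, 0.85],
    [0.75, 1.0] and [0.6, 1.0] — the spread observed across community QSAR
    ensembles, where specificities are consistently higher and less variable
    than sensitivities. The draw is part of the seeded configuration.
    """
    rng = np.random.default_rng(seed)
    specs = [
        ModelSpec(
            sn=float(rng.uniform(0.2, 0.85)),
            sp=float(rng.uniform(0.75, 1.0)),
            cvg=float(rng.uniform(0.6, 1.0)),
        )
        for _ in range(n_models)
    ]
    return SimulationConfig(n=n, pi_active=pi_active, model_specs=specs, seed=seed)


def generate_table(config: SimulationConfig) -> PredictionTable:
    """Draw a fully labelled prediction table from the generative model.

    True labels ~ Bernoulli(pi_active); per model, AD membership ~
    Bernoulli(cvg); inside the AD the vote is correct with probability sn
    (actives) or sp (inactives), independently across models given the true
    class. Out-of-AD entries carry no vote. Identical config + seed yields
    a bit-identical table.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n, len(config.model_specs)
    labels = np.where(rng.random(n) < config.pi_active, ACTIVE, INACTIVE).astype(np.int8)

    votes = np.full((n, m), NO_PREDICTION, dtype=np.int8)
    ad = np.zeros((n, m), dtype=bool)
    is_active = labels == ACTIVE
    hard = rng.random(n) < config.shared_flip_prob if config.shared_flip_prob > 0 else None
    for j, spec in enumerate(config.model_specs):
        ad[:, j] = rng.random(n) < spec.cvg
        p_correct = np.where(is_active, spec.sn, spec.sp)
        correct = rng.random(n) < p_correct
        vote = np.where(correct, labels, 1 - labels).astype(np.int8)
        if hard is not None:
            vote = np.where(hard, 1 - vote, vote).astype(np.int8)
        votes[ad[:, j], j] = vote[ad[:, j]]

    return PredictionTable(
        chemical_ids=[f"c{i:06d}" for i in range(n)],
        model_names=[f"m{j:02d}" for j in range(m)],
        votes=votes,
        ad_mask=ad,
        true_labels=labels,
    )


@dataclass
class FingerprintFixture:
    """Planted-cluster fingerprints plus the cluster assignment for tests."""

    fingerprints: "FingerprintMatrix"
    cluster_labels: np.ndarray


def generate_fixture_fingerprints(n: int, bits: int = 64, seed: int = 0,
                                  perturb_rate: float = 0.1) -> FingerprintFixture:
    """Two planted structural clusters in disjoint bit blocks.

    Each cluster owns half of the bit positions; a chemical starts from its
    cluster's base pattern (every other bit of the block set) and flips each
    block bit independently with ``perturb_rate``. Because the blocks are
    disjoint, between-cluster Tanimoto similarity is exactly 0 and MDS must
    separate the clusters on its first dimension.
    """
    from .chemspace import FingerprintMatrix

    if bits < 8:
        raise ValueError("need at least 8 fingerprint bits for two clusters")
    rng = np.random.default_rng(seed)
    half = bits // 2
    clusters = np.arange(n) % 2
    fp = np.zeros((n, bits), dtype=bool)
    base = np.zeros(half, dtype=bool)
    base[::2] = True
    for i in range(n):
        block = base.copy()
        if perturb_rate > 0:
            flip = rng.random(half) < perturb_rate
            block ^= flip
        if not block.any():
            block[int(rng.integers(half))] = True  # keep rows non-empty
        start = 0 if clusters[i] == 0 else half
        fp[i, start:start + half] = block
    return FingerprintFixture(
        fingerprints=FingerprintMatrix(fp, chemical_ids=[f"c{i:06d}" for i in range(n)]),
        cluster_labels=clusters,
    )


def expected_majority_accuracy(q: float, k: int) -> float:
    """Closed-form accuracy of a k-model majority vote with per-vote accuracy q.

    For odd k and conditionally independent votes each correct with
    probability q, the majority is correct with probability
    sum_{j >= (k+1)/2} C(k, j) q^j (1-q)^(k-j). Even k is rejected because
    tie handling would make the quantity method-dependent.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd integer")
    # P(X >= (k+1)/2) = sf(k//2) for X ~ Binomial(k, q)
    return float(binom.sf(k // 2, k, q))


def joint_bayes_oracle(likelihoods: LikelihoodTable, prior: BayesState,
                       evidence: list[int | None]) -> BayesState:
    """Single-shot Bayes posterior: prior(g) * prod_m p_m(e_m | g), normalised once.

    Brute-force reference for the iterative consensus chain; ``None`` marks
    a model that abstains (contributes no factor). Intended for small M.
    """
    if len(evidence) != len(likelihoods.model_names):
        raise ValueError("evidence must provide one entry per model")
    num_a = prior.p_active
    num_i = prior.p_inactive
    for j, e in enumerate(evidence):
        if e is None or e == NO_PREDICTION:
            continue
        pa_A = float(likelihoods.p_active_given_active[j])
        pa_I = float(likelihoods.p_active_given_inactive[j])
        if e == ACTIVE:
            num_a *= pa_A
            num_i *= pa_I
        elif e == INACTIVE:
            num_a *= 1.0 - pa_A
            num_i *= 1.0 - pa_I
        else:
            raise ValueError(f"evidence for model {j} must be a class vote or None")
    z = num_a + num_i
    return BayesState(num_a / z, num_i / z)


def specs_to_frame(specs: list[ModelSpec]):
    import pandas as pd

    return pd.DataFrame(
        {
            "sn": [s.sn for s in specs],
            "sp": [s.sp for s in specs],
            "cvg": [s.cvg for s in specs],
        }
    )


def specs_from_frame(df) -> list[ModelSpec]:
    return [ModelSpec(sn=float(r.sn), sp=float(r.sp), cvg=float(r.cvg)) for r in df.itertuples()]
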
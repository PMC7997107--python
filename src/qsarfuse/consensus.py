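"""Consensus strategies: majority voting and Bayes fusion.

Two families are implemented, both honouring applicability-domain (AD)
masks — a model contributes to a chemical's consensus only where that
chemical is inside the model's AD:

* **Majority voting** assigns the most frequently predicted class among the
  in-AD votes, with three protectiveness levels: loose (``MVL``, agreement
  strictly above 50 %; an exact 50/50 split abstains), intermediate
  (``MVI``, agreement >= 75 %) and strict (``MVS``, unanimity).

* **Bayes consensus with discrete probability distributions** treats each
  model's predicted class as evidence and its confusion-matrix-derived
  conditional probabilities p(predicted class | true class) as likelihoods.
  Starting from a prior over {active, inactive}, Bayes' rule is applied
  once per voting model, each posterior becoming the next prior; the final
  posterior's argmax is the fused class (``B``), or — in the protective
  variant ``Bp`` — the class is assigned only when the maximum posterior
  reaches a threshold (default 95 %).

The iterated update is a normalised product of likelihoods, so it is
computed here in log space (one normalisation at the end), which is
mathematically identical to per-step normalisation but immune to underflow
when thirty-plus models are chained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import (
    ACTIVE,
    INACTIVE,
    NO_PREDICTION,
    UNKNOWN,
    ConsensusConfig,
    DatasetSummary,
    PredictionTable,
    logger,
)
from .metrics import ConfusionMatrix, confusion_counts


@dataclass
class LikelihoodTable:
    """Per-model conditional vote probabilities p_m(predicted | true).

    Only p(active | true class) is stored per model; the complementary
    p(inactive | true class) follows because abstentions are excluded from
    the confusion matrices the probabilities are estimated from. Entries
    must lie strictly inside (0, 1) — a zero likelihood would be absorbing
    in the product — which smoothing guarantees.
    """

    model_names: list[str]
    p_active_given_active: np.ndarray
    p_active_given_inactive: np.ndarray

    def __post_init__(self) -> None:
        self.p_active_given_active = np.asarray(self.p_active_given_active, dtype=float)
        self.p_active_given_inactive = np.asarray(self.p_active_given_inactive, dtype=float)
        m = len(self.model_names)
        if self.p_active_given_active.shape != (m,) or self.p_active_given_inactive.shape != (m,):
            raise ValueError("likelihood arrays must have one entry per model")
        for arr, what in ((self.p_active_given_active, "p(a|A)"),
                          (self.p_active_given_inactive, "p(a|I)")):
            if np.any(arr <= 0) or np.any(arr >= 1):
                raise ValueError(f"{what} entries must lie strictly in (0, 1); use smoothing")

    def for_model(self, name: str) -> dict[int, dict[int, float]]:
        """Nested mapping {true class: {predicted class: probability}}."""
        j = self.model_names.index(name)
        pa_A = float(self.p_active_given_active[j])
        pa_I = float(self.p_active_given_inactive[j])
        return {
            ACTIVE: {ACTIVE: pa_A, INACTIVE: 1.0 - pa_A},
            INACTIVE: {ACTIVE: pa_I, INACTIVE: 1.0 - pa_I},
        }

    def select_models(self, names: Sequence[str]) -> "LikelihoodTable":
        idx = [self.model_names.index(n) for n in names]
        return LikelihoodTable(
            model_names=list(names),
            p_active_given_active=self.p_active_given_active[idx].copy(),
            p_active_given_inactive=self.p_active_given_inactive[idx].copy(),
        )


@dataclass
class BayesState:
    """Probability vector over the two class hypotheses."""

    p_active: float
    p_inactive: float

    def __post_init__(self) -> None:
        if self.p_active < 0 or self.p_inactive < 0:
            raise ValueError("probabilities must be nonnegative")
        if abs(self.p_active + self.p_inactive - 1.0) > 1e-12:
            raise ValueError("BayesState must be normalised (sum to 1 within 1e-12)")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_active, self.p_inactive])


@dataclass
class ConsensusResult:
    """Per-chemical fused class (or abstention) with supporting quantities.

    ``fused`` holds vote codes, with ``NO_PREDICTION`` marking abstention;
    ``agreement`` is the majority-class fraction of the in-AD votes (defined
    for every method, 0 where there are no votes); ``posterior_active`` is
    populated by the Bayes methods only.
    """

    chemical_ids: list[str]
    fused: np.ndarray
    n_votes: np.ndarray
    agreement: np.ndarray
    posterior_active: np.ndarray | None = None
    config: ConsensusConfig | None = None
    metadata: dict = field(default_factory=dict)

    def fused_tokens(self) -> list[str]:
        from .io import NOT_PREDICTED_TOKEN, vote_to_token

        return [NOT_PREDICTED_TOKEN if c == NO_PREDICTION else vote_to_token(c)
                for c in self.fused]


def vote_profile(votes_row: np.ndarray, ad_row: np.ndarray) -> tuple[int, float]:
    """Count usable votes in one chemical's row and the fraction voting active.

    Only entries that carry a class *and* fall inside the model's AD count;
    with zero usable votes the active fraction is reported as 0.
    """
    votes_row = np.asarray(votes_row)
    ad_row = np.asarray(ad_row, dtype=bool)
    if votes_row.shape != ad_row.shape:
        raise ValueError("votes_row and ad_row must be aligned")
    usable = (votes_row != NO_PREDICTION) & ad_row
    n = int(usable.sum())
    if n == 0:
        return 0, 0.0
    return n, float(np.sum(votes_row[usable] == ACTIVE)) / n


def _vote_counts(table: PredictionTable) -> tuple[np.ndarray, np.ndarray]:
    """(n_votes, n_active_votes) per chemical over in-AD class votes."""
    eff = table.effective_votes()
    n_votes = np.sum(eff != NO_PREDICTION, axis=1)
    n_active = np.sum(eff == ACTIVE, axis=1)
    return n_votes.astype(np.int64), n_active.astype(np.int64)


def majority_vote(table: PredictionTable, config: ConsensusConfig) -> ConsensusResult:
    """Frequency-based consensus at the configured protectiveness level.

    A chemical is assigned its majority class iff it has at least
    ``min_votes`` in-AD votes and the majority agreement satisfies the mode:
    strictly > the threshold for MVL (so an exact tie abstains), >= 75 % for
    MVI, and unanimity for MVS.
    """
    if config.method not in ("MVL", "MVI", "MVS"):
        raise ValueError(f"majority_vote cannot handle method {config.method!r}")
    n_votes, n_active = _vote_counts(table)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_active = np.where(n_votes > 0, n_active / np.maximum(n_votes, 1), 0.0)
    agreement = np.where(n_votes > 0, np.maximum(freq_active, 1.0 - freq_active), 0.0)
    majority = np.where(freq_active > 0.5, ACTIVE, INACTIVE).astype(np.int8)

    if config.method == "MVL":
        # strict inequality: an exact 50/50 split yields no prediction
        passes = agreement > config.agreement_threshold
    elif config.method == "MVI":
        passes = agreement >= config.agreement_threshold
    else:  # MVS: unanimity
        passes = agreement >= 1.0
    assigned = passes & (n_votes >= config.min_votes)

    fused = np.where(assigned, majority, NO_PREDICTION).astype(np.int8)
    n_abstain = int(np.sum(~assigned))
    logger.info("%s: %d/%d chemicals assigned (%d abstentions)",
                config.method, table.n_chemicals - n_abstain, table.n_chemicals, n_abstain)
    return ConsensusResult(
        chemical_ids=list(table.chemical_ids),
        fused=fused,
        n_votes=n_votes,
        agreement=agreement,
        posterior_active=None,
        config=config,
        metadata={"method": config.method},
    )


def estimate_likelihoods(cms: Mapping[str, ConfusionMatrix] | Sequence[ConfusionMatrix],
                         alpha: float = 0.5,
                         model_names: Sequence[str] | None = None) -> LikelihoodTable:
    """Estimate p_m(predicted | true) from per-model confusion matrices.

    With pseudocount ``alpha`` (Jeffreys-style default 0.5):

        p_m(a|A) = (TP + alpha) / (TP + FN + 2 alpha)
        p_m(a|I) = (FP + alpha) / (TN + FP + 2 alpha)

    alpha = 0 reproduces the raw rates but requires every rate to be
    estimable and strictly inside (0, 1).
    """
    if alpha < 0:
        raise ValueError("smoothing alpha must be nonnegative")
    if isinstance(cms, Mapping):
        names = list(cms.keys())
        mats = [cms[n] for n in names]
    else:
        mats = list(cms)
        names = list(model_names) if model_names is not None else [f"model_{i}" for i in range(len(mats))]
    pa_A = np.empty(len(mats))
    pa_I = np.empty(len(mats))
    for j, cm in enumerate(mats):
        if cm.tp + cm.fn + 2 * alpha == 0 or cm.tn + cm.fp + 2 * alpha == 0:
            raise ValueError(f"model {names[j]!r}: likelihoods undefined (empty class and alpha = 0)")
        pa_A[j] = (cm.tp + alpha) / (cm.tp + cm.fn + 2 * alpha)
        pa_I[j] = (cm.fp + alpha) / (cm.tn + cm.fp + 2 * alpha)
    return LikelihoodTable(names, pa_A, pa_I)


def estimate_likelihoods_from_table(table: PredictionTable, alpha: float = 0.5) -> LikelihoodTable:
    """Estimate every model's likelihoods from its own in-AD predictions on
    a labelled table. Using the same table for estimation and fusion leaks
    label information; callers fusing the same table should warn."""
    eff = table.effective_votes()
    cms = {}
    for j, name in enumerate(table.model_names):
        cms[name] = confusion_counts(table, eff[:, j])
    return estimate_likelihoods(cms, alpha=alpha)


def bayes_update(prior: BayesState, model_likelihoods: Mapping[int, Mapping[int, float]],
                 evidence: int) -> BayesState:
    """One application of Bayes' rule for a single model's predicted class.

    posterior(g) = p(e|g) prior(g) / sum_g' p(e|g') prior(g'), with g
    ranging over {active, inactive} and e the model's predicted class.
    """
    if evidence not in (ACTIVE, INACTIVE):
        raise ValueError("evidence must be a class vote (active or inactive)")
    la = model_likelihoods[ACTIVE][evidence]
    li = model_likelihoods[INACTIVE][evidence]
    num_a = la * prior.p_active
    num_i = li * prior.p_inactive
    z = num_a + num_i
    if z <= 0:
        raise ValueError("zero normalising constant in Bayes update")
    return BayesState(num_a / z, num_i / z)


def _resolve_prior(config: ConsensusConfig, summary: DatasetSummary | None) -> np.ndarray:
    if config.prior_mode == "equal":
        return np.array([0.5, 0.5])
    if summary is None:
        raise ValueError("proportional priors need a DatasetSummary with class counts")
    return summary.class_priors()


def bayes_consensus(table: PredictionTable, likelihoods: LikelihoodTable,
                    config: ConsensusConfig,
                    summary: DatasetSummary | None = None) -> ConsensusResult:
    """Chain Bayes' rule over every in-AD voting model, per chemical.

    Out-of-AD and abstaining models contribute no evidence. The fused class
    is the posterior argmax; the protective variant (``Bp``) assigns only
    when the maximum posterior reaches ``config.posterior_threshold``. A
    chemical with fewer than ``min_votes`` usable votes — in particular one
    outside every model's AD — is not predicted and keeps the prior as its
    posterior. An exact posterior tie (0.5/0.5) abstains.
    """
    if config.method not in ("B", "Bp"):
        raise ValueError(f"bayes_consensus cannot handle method {config.method!r}")
    if likelihoods.model_names != table.model_names:
        raise ValueError("likelihood table does not cover the table's models (names must match in order)")
    if summary is None and config.prior_mode == "proportional":
        summary = table.summary()
    prior = _resolve_prior(config, summary)
    if abs(prior.sum() - 1.0) > 1e-12:
        raise ValueError("prior is not normalised")

    eff = table.effective_votes()
    is_active_vote = eff == ACTIVE
    is_inactive_vote = eff == INACTIVE

    log_pa_A = np.log(likelihoods.p_active_given_active)
    log_pi_A = np.log1p(-likelihoods.p_active_given_active)
    log_pa_I = np.log(likelihoods.p_active_given_inactive)
    log_pi_I = np.log1p(-likelihoods.p_active_given_inactive)

    # Sum of per-model log likelihoods; equivalent to iterating Bayes' rule
    # with per-step renormalisation, but underflow-safe for M >= 30.
    loglik_A = is_active_vote @ log_pa_A + is_inactive_vote @ log_pi_A
    loglik_I = is_active_vote @ log_pa_I + is_inactive_vote @ log_pi_I

    log_post = np.stack([loglik_A + np.log(prior[0]), loglik_I + np.log(prior[1])], axis=1)
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    posterior_active = post[:, 0]

    n_votes, n_active = _vote_counts(table)
    no_evidence = n_votes == 0
    posterior_active = np.where(no_evidence, prior[0], posterior_active)

    max_post = np.maximum(posterior_active, 1.0 - posterior_active)
    fused_class = np.where(posterior_active > 0.5, ACTIVE, INACTIVE).astype(np.int8)

    assigned = n_votes >= config.min_votes
    assigned &= posterior_active != 0.5  # exact tie abstains
    if config.method == "Bp":
        assigned &= max_post >= config.posterior_threshold
    fused = np.where(assigned, fused_class, NO_PREDICTION).astype(np.int8)

    with np.errstate(invalid="ignore", divide="ignore"):
        freq_active = np.where(n_votes > 0, n_active / np.maximum(n_votes, 1), 0.0)
    agreement = np.where(n_votes > 0, np.maximum(freq_active, 1.0 - freq_active), 0.0)

    n_abstain = int(np.sum(fused == NO_PREDICTION))
    logger.info("%s: %d/%d chemicals assigned (%d abstentions)",
                config.method, table.n_chemicals - n_abstain, table.n_chemicals, n_abstain)
    return ConsensusResult(
        chemical_ids=list(table.chemical_ids),
        fused=fused,
        n_votes=n_votes,
        agreement=agreement,
        posterior_active=posterior_active,
        config=config,
        metadata={
            "method": config.method,
            "prior": [float(prior[0]), float(prior[1])],
            "smoothing_alpha": config.smoothing_alpha,
            "normalisation": "single final normalisation of the log-space product "
                             "(identical to per-step renormalisation)",
        },
    )


def run_consensus(table: PredictionTable, config: ConsensusConfig,
                  likelihoods: LikelihoodTable | None = None,
                  summary: DatasetSummary | None = None) -> ConsensusResult:
    """Dispatch to the configured strategy (MVL / MVI / MVS / B / Bp).

    For the Bayes methods, likelihoods may be supplied (estimated on a
    calibration split) or, failing that, are estimated from the table itself
    when it carries labels — in which case a leakage warning is logged,
    since the same labels then feed both estimation and evaluation.
    """
    if config.method in ("MVL", "MVI", "MVS"):
        return majority_vote(table, config)
    if likelihoods is None:
        if not np.any(table.true_labels != UNKNOWN):
            raise ValueError(
                f"method {config.method} needs a likelihood table or a labelled "
                "table to estimate one from"
            )
        logger.warning(
            "estimating likelihoods from the table being fused: "
            "in-sample estimation leaks label information"
        )
        likelihoods = estimate_likelihoods_from_table(table, alpha=config.smoothing_alpha)
    return bayes_consensus(table, likelihoods, config, summary=summary)
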
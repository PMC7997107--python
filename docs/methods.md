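# Methods

## Data model

A prediction ensemble is a chemicals × models matrix of class votes
(`active` / `inactive` / `no-prediction`) plus a boolean applicability-
domain (AD) mask of the same shape, experimental labels
(`active` / `inactive` / `unknown`) and optional SMILES. The single
semantic rule everything else builds on: **a vote counts only where the AD
mask is true**, and an out-of-AD entry is treated identically to an
explicit no-prediction. This equivalence is enforced in one place
(`PredictionTable.effective_votes`) and verified by a property test that
masks random cells both ways and demands bit-identical downstream output
from every consensus method.

Vocabulary is deliberately two-class: abstention is a distinct
`not-predicted` token, never a third class, because the consensus rules
*decline to assign* rather than assign a null category.

## Majority voting

Per chemical, let n be the number of in-AD class votes and a the fraction
of those votes on the majority class. The chemical is assigned its majority
class iff n ≥ `min_votes` (default 1) and

* **MVL** (loose): a > 0.5 — an exact 50/50 split yields no prediction;
* **MVI** (intermediate): a ≥ 0.75;
* **MVS** (strict): a = 1 (unanimity).

These thresholds give the only internally consistent ordering in which the
strict variant has the lowest coverage; coverage dominance
Cvg(MVS) ≤ Cvg(MVI) ≤ Cvg(MVL) is asserted as a property on arbitrary
generated tables.

## Bayes consensus with discrete probability distributions

Each model m is summarised by its likelihoods p_m(e | g) — the probability
that it predicts class e given true class g — estimated from its confusion
matrix with a Jeffreys-style pseudocount α (default 0.5):

    p_m(a | A) = (TP + α) / (TP + FN + 2α),
    p_m(a | I) = (FP + α) / (TN + FP + 2α).

The smoothing matters: with 30+ models a single empirical likelihood of
exactly 0 or 1 would be absorbing and could fix a posterior at 0 or 1
irrespective of all other evidence. α is configurable; α = 0 reproduces raw
rates.

Starting from a prior over {active, inactive} (default equal, 0.50/0.50),
Bayes' rule is applied once per in-AD voting model, each posterior becoming
the next prior; abstaining and out-of-AD models contribute nothing. Because
per-step renormalisation cancels, the chain equals a single normalised
product

    p(g | e_1..e_M) ∝ p(g) · Π_m p_m(e_m | g),

which is how it is computed — in log space, with one normalisation at the
end — to avoid underflow at M ≥ 30. Equality of the chain and the
single-shot product is the central oracle test: 1 000 random
configurations with up to six models agree within 1e-10, and 100 random
model permutations leave every posterior unchanged within 1e-10 (with a
single prior vector the product is order-invariant; the order sensitivity
that arises when each model carries its *own* proportional prior is out of
scope, and the proportional mode here uses one dataset-level prior
n_g / n).

The fused class is the posterior argmax (**B**); the protective variant
(**Bp**) assigns only when max posterior ≥ `posterior_threshold` (default
0.95). An exact 0.5/0.5 posterior abstains — any tie-break would be
irreproducible. A chemical with zero usable votes abstains and keeps the
prior as its posterior.

When no likelihood table is supplied, it is estimated from the labelled
table being fused, and a leakage warning is logged: in-sample estimation
feeds the evaluation labels into the fusion rule and flatters the measured
performance. Supplying confusion matrices from a separate calibration split
is the clean protocol.

## Metrics and ranking

Sn = 100·TP/(TP+FN), Sp = 100·TN/(TN+FP), NER = (Sn+Sp)/2,
Cvg = 100·(predicted)/(all chemicals), Utility = (Sn+Sp+Cvg)/3. Confusion
cells count only chemicals that are both predicted and labelled. Chemicals
with unknown labels count in the coverage denominator but never in Sn/Sp:
coverage measures reach, not correctness. Undefined rates raise. Ranking
sorts by decreasing Utility with ties broken by NER, then coverage, then
stable input order — a deterministic total order for reproducible tables.
Human-readable output rounds percentages to one decimal; all internal
computation is full precision.

## Subset-of-models curves

Models are ranked by individual NER (ties: higher coverage, then input
order; models with undefined NER are dropped with a warning) and join the
consensus one at a time from the top five (`k_min = 5`, configurable). The
individual NERs are computed on the same labelled table as the curve —
optimistic, but it mirrors how evaluation sets are used in practice.
Likelihoods for the Bayes methods are re-estimated on each subset so every
point is self-contained; this choice is recorded in the run metadata.
Coverage is recorded even where a point's NER is undefined (strict
consensus can assign no actives at large k). Strict-consensus coverage is
provably non-increasing in k — unanimity over a superset is never easier —
and is asserted on every input.

## Chemical-space diagnostic

Chemicals are compared by the Jaccard–Tanimoto coefficient
|A∩B| / |A∪B| on binary fingerprint bits (precomputed, or Morgan
fingerprints of radius 2 / 1024 bits from SMILES via RDKit); distances
d = 1 − s feed classical (Torgerson) MDS: double-center
B = −½ J (D∘D) J, eigendecompose, scale the top-d eigenvectors by the
square roots of their (clipped-nonnegative) eigenvalues. Classical MDS was
chosen over stress majorization because it is deterministic and exactly
recovers d-embeddable configurations, which makes it testable — a known
planar 10-point configuration is recovered to 1e-8. A fixed sign convention
(largest-magnitude loading per axis made positive) removes the reflection
ambiguity across runs. Empty fingerprints are rejected by chemical id at
construction, since their similarity is undefined.

The overlay reports, per chemical, how many prediction sources got it
wrong, how many predicted at all, and the predicting fraction; a separate
scan lists chemicals misclassified by *every* model whose AD covers them,
tagged false-negative or false-positive. These are the systematically hard
cases — in real data typically borderline-potency actives or
charge/counterion artefacts — that no amount of fusion can rescue, because
consensus integrates the very votes that are wrong.

## Synthetic ensembles and what they show

The generator draws true labels Bernoulli(π_active), per-model AD
membership Bernoulli(cvg_m), and — inside the AD — a correct vote with
probability sn_m (actives) or sp_m (inactives), independently across models
given the true class. The demo preset reflects the shape of real
collaborative ensembles: n = 4 000 chemicals, π_active = 0.10, 30 models
with Sn ~ U[0.2, 0.85], Sp ~ U[0.75, 1.0], Cvg ~ U[0.6, 1.0] (specificities
higher and tighter than sensitivities, as observed when classes are heavily
skewed toward inactivity). Identical config + seed gives a bit-identical
table.

Analytic oracles close the loop: at odd k the loose-majority accuracy of k
identical independent models with per-vote accuracy q has the closed form
Σ_{j>k/2} C(k,j) q^j (1−q)^{k−j} (checked at q = 0.7, k = 5, n = 50 000
within three binomial standard errors), and empirical per-model Sn/Sp/Cvg
recover their generating values within three binomial SE at n = 50 000.

**What passing tests do not show.** Conditional independence given the
class is the generator's default and the implicit assumption of the Bayes
chain. Real QSAR ensembles are trained on overlapping data and share
descriptor philosophies, so their errors correlate; consensus gains on real
evaluation sets are accordingly much smaller than on these simulations
(where an in-sample-calibrated Bayes consensus approaches perfection). An
optional `shared_flip_prob` knob plants correlated "hard case" chemicals
whose every vote flips, and a test demonstrates the expected degradation.
Two other idealisations: AD membership is independent of difficulty (real
models are better inside narrow ADs), and fingerprints are abstract
planted-cluster bit blocks, not molecular structures.

A consequence worth noting: with 30 *independent* mid-sensitivity models,
unanimity on an active chemical is vanishingly rare, so the strict
consensus assigns essentially no actives on the demo ensemble and its
sensitivity is undefined there; the acceptance script therefore reports
strict-consensus coverage only. Real ensembles, with correlated models,
reach unanimity far more often.

## Numerical choices

* Log-space likelihood accumulation; single final normalisation.
* Posterior normalisation asserted to 1e-12; oracle agreement to 1e-10.
* Smoothing α = 0.5 default (keeps likelihoods in (0,1)).
* Exact ties (vote 50/50, posterior 0.5/0.5) abstain, never tie-break.
* Posteriors serialised with 8 significant digits; displayed percentages
  rounded to one decimal.
* MDS eigenvalues clipped at zero; axis signs fixed by largest loading.

## Problem sizes

Default test and acceptance runs use 4 000-chemical demo ensembles, two
50 000-chemical single-purpose simulations for the binomial checks, 1 000
random Bayes-oracle configurations, and 10–60-point MDS fixtures; the full
suite completes in a few seconds.
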
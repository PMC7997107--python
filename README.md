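# qsarfuse

Consensus classification for multi-model QSAR prediction ensembles.

## The problem

Collaborative in-silico screening projects (endocrine-disruptor
prioritisation being the archetype) collect binary activity predictions for
thousands of chemicals from twenty or more independently developed QSAR
models. Each model comes with its own applicability domain (AD) — the
region of chemical space where its predictions are considered reliable —
and its own sensitivity/specificity trade-off. The practical question is
how to fuse these conflicting, partially overlapping predictions into a
single call per chemical, and how to quantify what the fusion buys over the
individual models.

`qsarfuse` implements and evaluates the two classical fusion families for
this setting, always discarding votes that fall outside a model's AD:

* **Majority voting** assigns the most frequently predicted class among the
  in-AD votes, at three protectiveness levels: loose (**MVL**, agreement
  strictly > 50 %; an exact tie abstains), intermediate (**MVI**, agreement
  ≥ 75 %) and strict (**MVS**, unanimity).
* **Bayes consensus with discrete probability distributions** treats the
  class predicted by each model as evidence *e* and applies Bayes' rule
  iteratively,

  p(h_g | e) = p(e | h_g) p(h_g) / Σ_g' p(e | h_g') p(h_g'),

  where the likelihoods p(e | h_g) are estimated from each model's
  confusion matrix and each posterior becomes the next model's prior. The
  final argmax is the fused class (**B**); the protective variant (**Bp**)
  assigns only when the maximum posterior reaches a threshold (default
  95 %).

Performance is summarised with the field's standard estimators —
sensitivity (Sn), specificity (Sp), non-error rate (NER = (Sn+Sp)/2,
i.e. balanced accuracy), coverage (Cvg, the percentage of chemicals
receiving a prediction) — plus **Utility** = (Sn+Sp+Cvg)/3 for
multi-criteria ranking. Two diagnostics complete the toolkit: consensus
curves as models are added in decreasing-NER order, and a
Tanimoto-similarity / classical-MDS map of chemical space overlaid with
per-chemical misclassification counts, including the chemicals every
covering model gets wrong.

A synthetic-ensemble generator (known truth, Bernoulli AD membership,
votes conditionally independent given the class) plus analytic oracles
(binomial majority accuracy, single-shot Bayes products) make every stage
testable without any external data.

## Worked example

Simulate a 1000-chemical, 30-model ensemble, fuse it two ways, and rank
everything by Utility:

```bash
qsarfuse simulate --n 1000 --seed 42 --out table.csv
qsarfuse consensus --method MVL --table table.csv --out mvl.csv
qsarfuse consensus --method Bp  --table table.csv --out bp.csv
qsarfuse evaluate --table table.csv \
    --predictions mvl.csv --predictions bp.csv --out report.csv
```

The console reports `MVL: assigned 992/1000 chemicals` and `Bp: assigned
988/1000 chemicals`; the top of the ranked report reads

```
name    Sn    Sp   NER  Cvg  Utility  rank
  bp 100.0 100.0 100.0 98.8     99.6     1
 mvl  71.3 100.0  85.6 99.2     90.2     2
 m06  72.9  90.0  81.5 90.4     84.4     3
```

Both consensus strategies outrank all 30 individual models: loose majority
voting lifts the balanced accuracy above the best single model while
keeping 99 % coverage, and the protective Bayes consensus is (on this
idealised, conditionally independent ensemble) nearly error-free at 98.8 %
coverage. On real ensembles, where models share training data and errors
correlate, the gains are smaller — see `docs/methods.md` for what the
simulation does and does not emulate.

The other subcommands: `qsarfuse curve` traces NER/Cvg as models join the
consensus in decreasing-NER order, and `qsarfuse chemspace` embeds the
chemicals by Tanimoto distance (classical MDS) and writes per-chemical
misclassification overlays plus the list of always-misclassified-within-AD
chemicals. Every run writes a JSON manifest alongside its output so
deterministic stages can be replayed byte-identically.

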
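# mixbiome

Mixture analysis of microbiome abundance data with **weighted quantile sum
(WQS) regression with random subsets and repeated holdouts** (WQS_RSRH),
plus the standard comparator analyses (Shannon diversity, Bray–Curtis /
Aitchison PERMANOVA, SIMPER, random-forest screening) and a simulation
framework for measuring how well planted signal taxa are recovered.

## The problem

Microbiome studies usually test diversity summaries (α, β) or each taxon
separately; neither treats the community as what it is — hundreds of
correlated, zero-inflated predictors acting jointly. WQS regression,
borrowed from environmental-mixture epidemiology, models the joint effect
through a single index

    WQS_j = Σ_i w_i · q_ij ,   w_i ≥ 0,  Σ_i w_i = 1,

where `q_ij` is the quantile score of taxon *i* in subject *j* and the
empirical weights `w_i` say which taxa drive the association. The index
enters an ordinary GLM with covariates, `g(μ) = α + β₁·WQS + δ′Z`, so the
mixture effect β₁ and the covariate adjustments stay interpretable.

Three adaptations make this workable for 16S/ASV tables:

* **Zero-anchored ranking** — exact zeros keep score 0; only positive
  abundances are split into quantile groups (tertiles for 4 levels, or a
  median split for 3), so zero inflation does not collapse the scoring.
* **Random subsets (RS)** — with far more taxa than subjects, weights are
  estimated on many random subsets of *m* taxa and combined by a
  signal-weighted average (signal = t², exp|t| or |t| of each subset's
  β₁), then renormalized to sum 1.
* **Repeated holdouts (RH)** — the whole train(40%)/validation(60%)
  analysis is repeated over (typically 30) stratified partitions; the
  distributions of weights and validation β₁ across repetitions give
  robust estimates.

Weights above the equi-weight threshold 1/p (or 1/c after pooling ASVs to
c genera) mark taxa that matter more than under uniform weighting.

## Worked example

```python
import mixbiome as mb

# synthetic stool-like dataset: 210 samples x 300 taxa, 10 planted signal taxa
table = mb.synthesize_abundance_table(n_samples=210, n_taxa=300, seed=7)
design = mb.assign_signal_taxa(table, n_strong=1, n_medium=4, n_weak=5,
                               seed=8, calibrate_prevalence=0.13)
table.metadata["test"] = mb.simulate_test_variable(table, design, seed=9)

ranked = mb.rank_table(table, levels=4, split="quantile")
cfg = mb.WQSConfig(m=20, B=100, direction="auto", family="binomial")
ens = mb.run_wqs_rsrh(table, ranked, "test", ["sex"], cfg, n_repeats=10, seed=10)

eq = mb.equi_weight_threshold(table.n_taxa)
curve = mb.ensemble_sensitivity_specificity(ens, list(design.signal_taxa))
```

Printing the ensemble summaries (`ens.direction`, `ens.beta_summary`,
`curve.at(eq)`, `ens.mean_weights.sort_values().tail(3)`) gives:

```
direction: negative
mean validation beta1: -3.80
sign consistency: 100% of holdouts
equi-weight cutoff: 1/300 = 0.00333
sensitivity: 0.54  specificity: 0.72
top-weighted taxa:
  OTU0190  0.0416 (planted)
  OTU0095  0.0371 (planted)
  OTU0007  0.0357
```

Reading this: the unconstrained direction scan resolved a *negative*
mixture–outcome association (under the potency-adjusted simulator, signal
taxa being present lowers the outcome's log-odds), every one of the 10
holdout validation GLMs agreed on that sign, and at the equi-weight cutoff
1/300 the ensemble weights identified 54% of the planted taxa while
correctly leaving 72% of the non-signal taxa below the cutoff — with two
of the three top-weighted taxa genuinely planted.

The same pipeline is scriptable from the shell:

```bash
mixbiome simulate table --samples 210 --taxa 868 --seed 1 --out sim
mixbiome simulate outcome sim_abundance.tsv --metadata sim_metadata.csv \
    --calibrate-prevalence 0.13 --seed 2
mixbiome run sim_abundance.tsv --mode relative --metadata sim_metadata.csv \
    --taxonomy sim_taxonomy.tsv --outcome test --covariates sex \
    --subsets 1000 --subset-size 30 --repeats 30 --seed 3 --out-prefix wqs
mixbiome evaluate --weights wqs_weights.tsv --truth design.json
```

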
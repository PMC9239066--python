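# rhizolink

Identify rhizobacterial features associated with continuous plant
growth.

Rhizosphere amplicon surveys produce compositional ASV count tables;
greenhouse experiments produce continuous growth measurements (projected
leaf area, biomass, relative growth rates) structured by treatment,
spatial block and developmental stage. `rhizolink` implements a
discovery pipeline for linking the two:

1. **Compositional preparation** — CSS normalization, Bray–Curtis
   dissimilarities and the day-2-referenced trajectory, alpha diversity,
   core-community extraction, rank/prevalence feature filtering, and a
   centered log-ratio (CLR) transform with a pooled remainder part that
   preserves compositional closure.
2. **Stability-selected LASSO** — repeated cross-validated L1-penalized
   regression of each growth response on the CLR matrix; features with
   nonzero coefficients in ≥80% of runs are candidates. Run-to-run
   variation combines CV fold re-randomization with 80% row subsampling.
3. **Bayesian hierarchical confirmation** — a Gaussian mixed model with
   a random intercept and a random slope per greenhouse block
   (conjugate blocked Gibbs sampler); candidates survive when the 95%
   credible interval of the slope excludes zero. Marginal and
   conditional Bayesian R² quantify variance explained.
4. **Multivariate refinement** — greedy backward elimination over each
   test's candidates guided by PSIS-LOO expected log predictive density.
5. **Permutation screen** — the growth–community pairing is scrambled,
   everything reruns, and tests that still confirm more than one feature
   lose all of their real associations.
6. **Co-occurrence networks** — graphical-lasso sparse inverse
   covariance per sample group with StARS penalty selection, correlation
   edge weights, Louvain modules on the positive-edge graph,
   Table-style network statistics, quartile subnetworks around
   growth-associated ASVs, and module abundance tables that feed back
   into the same selection pipeline.

A fully seeded synthetic generator (`rhizolink.synthetic`) produces
design, growth, counts and responses with annotated ground truth —
block/stage/treatment biomarkers, correlated ASV modules with a known
sparse precision matrix, and features whose CLR abundance is linearly
coupled to growth — so every stage can be benchmarked against truth.

## Worked example

```python
from rhizolink.synthetic import SyntheticConfig, simulate_experiment, default_planted
from rhizolink.prep import rank_prevalence_filter, clr_with_remainder
from rhizolink.select import stability_select
from rhizolink.bayes import fit_univariate, SamplerConfig

config = SyntheticConfig(planted=default_planted(target_r2=0.30))
exp = simulate_experiment(config, seed=2)
counts = exp.counts

# one association test: early inoculated communities vs leaf area at day 3
ids = counts.group_samples("inoculated", "early")
resp = exp.responses
y = resp[(resp.treatment == "inoculated") & (resp.response == "pa_day3")]
y = y.set_index("sample_id")["value"].loc[ids]

features = rank_prevalence_filter(counts.counts.loc[ids], top_n=200, min_prevalence=0.5)
X = clr_with_remainder(counts.counts.loc[ids], features)
result = stability_select(X, y, n_runs=25, threshold=20, base_seed=7)

feature = result.selected[0]
blocks = counts.metadata.loc[ids, "block"]
fit = fit_univariate(X.loc[ids, feature], y, blocks, SamplerConfig(seed=3), feature=feature)
```

Output:

```
288 samples x 150 ASVs, 5 planted growth couplings
132 features pass the rank/prevalence filter; stability selection keeps ['ASV0010']
ASV0010: slope 1.07 (95% CI [0.63, 1.58]), marginal R2 0.41, direction positive
planted truth for this test: [('ASV0010', 1)]
```

The generator planted a positive coupling between ASV0010's CLR
abundance and day-3 leaf area explaining 30% of the latent response
variance; the pipeline recovers exactly that feature, with a positive
slope whose credible interval excludes zero (the marginal R² of 0.41
reflects this dataset's favorable multinomial-sampling draw on top of
the planted 0.30).

## Command line

```bash
rhizolink run-all --config config.yaml          # full pipeline
rhizolink simulate --config config.yaml         # synthetic data only
rhizolink select|confirm|screen|network ...     # individual stages
rhizolink report --outdir rhizolink_out         # summarize a run
```

A minimal config needs only a seed (synthetic data is the default
source); real data enter via `inputs: {counts_tsv, metadata_tsv,
growth_tsv}` or BIOM v1 JSON. See `rhizolink/config.py` for every knob
and `docs/methods.md` for the models and their defaults.

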
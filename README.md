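# fcnet

Graph-theoretical comparison of functional brain networks between two
subject groups. The pipeline takes per-subject regional time series
(regions × time, delimited text) plus a subject manifest and produces:

- Pearson connectivity matrices after temporal cleanup (leading-volume
  discard, linear detrend, ideal band-pass 0.01–0.08 Hz at TR 2 s);
- binary graphs over a sparsity grid (default 0.05–0.40, step 0.01),
  keeping the strongest positive correlations at each level;
- global/local efficiency, clustering coefficient, characteristic path
  length, and degree centrality per graph;
- small-world coefficients γ, λ, σ normalized against degree-preserving
  (double-edge-swap) random reference networks;
- per-group hub sets (degree centrality ≥ mean + 1 SD), rich-club /
  feeder / local edge classification and per-subject class strengths;
- group statistics: per-sparsity two-sample t-tests with
  Benjamini–Hochberg FDR, permutation tests on class strengths,
  chi-square / Mann-Whitney demographics tests, and Spearman
  correlations against clinical covariates.

A synthetic cohort generator (modular latent covariance, planted hub
regions, group-level effects, clinical covariates) makes the whole
pipeline testable end to end without any imaging data.

## CLI

Each stage reads and writes delimited-text files so stages can run
independently:

```bash
fcnet simulate   --n-per-group 15 --out-dir data/ --seed 1
fcnet run        --manifest data/manifest.tsv --timeseries-dir data/ \
                 --out-dir results/ --seed 1            # full pipeline
# or stage by stage:
fcnet construct  --in data/P001.tsv --out P001_conn.tsv
fcnet metrics    --in P001_conn.tsv --out P001_metrics.tsv
fcnet smallworld --in P001_conn.tsv --out P001_sw.tsv
fcnet richclub   --manifest data/manifest.tsv --conn-dir results/connectivity \
                 --out-dir results/
fcnet compare    --manifest data/manifest.tsv --metrics results/profiles.tsv \
                 --strengths results/strengths.tsv --out-dir results/
fcnet report     --manifest data/manifest.tsv --metrics results/profiles.tsv \
                 --out-dir plots/
```

Configuration is a YAML/JSON file (`--config`) with the fields of
`fcnet.config.AnalysisConfig`; `--seed` overrides the config seed.
Every run is deterministic given (inputs, seed): each stage draws from
an independent substream keyed by stage name and subject.

## Conventions and assumptions

Exact metric formulas follow standard binary-graph definitions
(documented in `fcnet.metrics`): clustering is zero for degree < 2 and
averaged over all nodes; path length averages reachable pairs only,
with a connectedness flag; efficiency treats unreachable pairs as zero
contribution. Thresholding uses positive correlations only, with
round-half-up edge counts and lexicographic tie-breaking. The null
model is Maslov–Sneppen rewiring with 10 attempted swaps per edge.
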
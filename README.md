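# connectolapse

Topological connection length as a predictor of longitudinal connection
atrophy in structural brain networks.

## The scientific problem

In neurodegenerative conditions such as premanifest Huntington's disease,
white-matter connections do not weaken uniformly: long-range projections —
cortico-striatal and interhemispheric pathways — appear to degenerate earlier
and faster than short local connections. One way to quantify "long-range" is
**topological length**: on a weighted structural connectome, take each
connection weight *w* to a length *1/w* and measure the shortest weighted path
between the two regions on a healthy average network. The hypothesis this
package operationalizes is that topological length predicts both the
cross-sectional deficit and the longitudinal rate of atrophy of a connection
in a disease cohort relative to controls.

`connectolapse` implements the full analysis pipeline:

1. **Synthetic cohorts** — a generator of longitudinal connectome datasets
   (default: 70 cortical + 4 striatal regions, two groups, three annual
   visits) with a planted modular structure and length-dependent degeneration,
   so every downstream stage can be validated against known ground truth.
2. **Network partition** — consensus Louvain community detection over
   repeated runs (agreement-matrix consensus with threshold τ), with a
   resolution-parameter sensitivity loop (γ ∈ {0.6, 1.0, 1.7}).
3. **Connection classification** — each analysed region pair (all
   cortico-cortical plus striatal-cortical pairs; 2,695 for the default
   parcellation) is labelled cortico-striatal, interhemispheric,
   intrahemispheric or intramodular relative to the consensus partition.
4. **Group models** — per-connection linear mixed-effects models
   `value ~ time + group + group:time + covariates` with random intercept and
   slope per subject, fitted by maximum likelihood; Benjamini–Hochberg FDR
   within each subtype family.
5. **Topology–atrophy analysis** — all-pairs Dijkstra path lengths on the
   control-average baseline network; per-connection Z-scores of disease
   baseline strength and longitudinal slope against control moments,
   logistic-transformed to an atrophy score in (0, 1); Spearman correlation of
   score against path length, plus one-way ANOVA and Tukey–Kramer comparisons
   of path length across subtypes.

## Worked example

Run the full pipeline on a simulated cohort (20 controls, 20 disease
participants, default 74-region parcellation) from Python:

```python
from connectolapse.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(simulation=dict(n_controls=20, n_preHD=20),
                     n_runs=30, seed=42)
report = run_pipeline(cfg)
print(report["partition"]["module_counts_by_gamma"])
print(report["classify"]["subtype_counts"])
print(report["correlate"]["cross_sectional"])
print(report["correlate"]["subtype_mean_path_length"])
```

Output (seed 42):

```
{'0.6': 2, '1.0': 6, '1.7': 6}
{'cortico_striatal': 6, 'interhemispheric': 9, 'intrahemispheric': 6, 'intramodular': 6}
{'rho': 0.5113411838564809, 'p': 1.719779718935279e-179, 'df': 2693, 'n': 2695, 'n_excluded': 0}
{'cortico_striatal': 0.8899324066209958, 'interhemispheric': 0.3097756919257927,
 'intrahemispheric': 0.1624563581971674, 'intramodular': 0.049692241004498094}
```

At resolution γ = 1 the consensus partition recovers the planted six cortical
modules exactly, the 2,695 region pairs split into the four subtype families
shown, the cross-sectional atrophy score correlates positively with
topological length (ρ = 0.51, df = 2,693; the longitudinal score gives
ρ = 0.47), and mean path length orders the subtypes
cortico-striatal > interhemispheric > intrahemispheric > intramodular with
all Tukey–Kramer pairwise comparisons significant.

The same analysis from the command line:

```bash
connectolapse simulate --out-dir data --seed 42          # write a dataset
connectolapse run --seed 42 --out results               # full pipeline
# or stage by stage:
connectolapse partition --data-dir data --gamma 1.0 --out-dir results
connectolapse atrophy --data-dir data --partition results/partition.tsv --out-dir results
connectolapse correlate --atrophy-table results/atrophy.csv --out results/corr.json
```

`run` writes `report.json` plus CSV tables (partition, per-connection model
results, path lengths, atrophy scores, Tukey table) to the output directory.
Re-running with the same seed reproduces every output bit-identically.

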
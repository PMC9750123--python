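# dnrs — directed-network rank score

Tipping-point (critical-state) detection for stage-ordered gene
expression data, for systems biologists studying abrupt transitions:
cell-fate commitment in single-cell time courses, stage progression in
tumor cohorts, or any process with a before-transition, pre-transition
and after-transition regime. Before such a transition a group of genes
— the dynamic network biomarker (DNB) — shows sharply rising variance
and mutual correlation; `dnrs` turns that signature into a network
centrality score with a clear early-warning readout.

## Method

For each stage T (with N observations, and L at the previous stage
T−1), pooled observations are labeled y ∈ {0, 1} by stage and the
undirected PPI scaffold is rewired into a directed network: for an
ordered gene pair (g_i, g_j) with profiles U, V, letting X = U and
X̂ = (U+V)/2, the direction determination index

  w_ij = −½ · log[ (1 − PCC(X̂, y)²) / (1 − PCC(X, y)²) ]

creates the edge g_i → g_j iff w_ij > 0 (a mutual-information form is
available for non-Gaussian data). On this network a personalized
PageRank is iterated to its fixed point,

  s ← α Hᵀ s + α (d·s) τ + (1−α) τ,   α = 0.85,

where H row-normalizes the w-weights, d marks dangling genes and the
teleport vector τ holds the normalized per-gene standard deviations at
stage T. The global score is the concentration of rank mass at the top,

  PR(T) = mean(top-5% of s*) / mean(s*) ,

and stage T is called critical when PR(T) > PR(T−1) and PR(T) differs
from all prior values by a one-sample t test (P < 0.05). The top-5%
genes at the flagged stage are the candidate biomarkers ("signaling
genes"). Because the package ships a stochastic regulatory-network
simulator with a controlled saddle-node bifurcation, the whole method
is testable end to end without any external data.

See `docs/methods.md` for assumptions, parameter defaults, numerical
conventions and known limitations.

## Worked example

Sweep the bundled 18-node Michaelis–Menten network across its fold at
s = 0 (14 stages, 100 cells each, 10 stochastic trials) and detect the
critical stage on the trial-averaged score series:

```python
from dnrs import SweepConfig, run_sweep_detection

sweep = run_sweep_detection(cfg=SweepConfig(n_trials=10, n_cells_per_stage=100, seed=1))
for s, pr in zip(sweep.scored_s, sweep.mean_pr):
    print(f"s = {s:+.2f}   mean PR = {pr:.3f}")
print("flagged stages:", sweep.detection.flagged)
print("detected tipping point: s =", sweep.flagged_s)
```

```
s = -0.45   mean PR = 2.633
s = -0.40   mean PR = 2.876
s = -0.35   mean PR = 2.828
s = -0.30   mean PR = 2.872
s = -0.25   mean PR = 2.768
s = -0.20   mean PR = 2.834
s = -0.15   mean PR = 2.860
s = -0.10   mean PR = 2.766
s = -0.05   mean PR = 2.811
s = -0.00   mean PR = 6.090
s = +0.05   mean PR = 4.114
s = +0.10   mean PR = 2.897
s = +0.15   mean PR = 2.820
flagged stages: ['s-0.00']
detected tipping point: s = -0.0
```

The score series stays flat (~2.8) while the system sits in its
before-transition state, then more than doubles at the grid stage
nearest the engineered bifurcation — that abrupt, significant rise is
the early-warning signal, and the stage it occurs at is the detected
tipping point.

On real data the same pipeline runs from the shell on per-stage
expression matrices (TSV/CSV, genes in rows) plus a two-column PPI edge
list:

```
dnrs run --stage stage1.tsv --stage stage2.tsv --stage stage3.tsv \
         --ppi ppi.tsv --out results/
```

which writes `summary.tsv` (stage, PR, t statistic, P value, flagged),
one `genes_<stage>.tsv` ranking table per scored stage, and
`metadata.json` with the resolved parameters and seed. `dnrs simulate`,
`dnrs score` and `dnrs detect` expose the generator, single-stage
scoring and the series test individually.

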
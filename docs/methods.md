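# Methods

## Overview

`dnrs` detects the critical (pre-transition) state of a complex
biological system from stage-ordered expression data. The underlying
picture is the dynamic network biomarker (DNB) one: as a system drifts
toward a bifurcation, a subset of molecules — the DNB — shows sharply
rising variance and intra-group correlation while the rest of the
network stays quiet. Rather than testing those moments directly, the
method converts them into a network-centrality signal: a stage-specific
*directed* network is built on a protein–protein interaction (PPI)
scaffold, genes are ranked by a personalized PageRank biased toward
high-variance genes, and the concentration of rank mass at the top of
the ranking — the directed-network rank score (DNRS) — rises abruptly
at the tipping point.

## Edge orientation: the direction determination index

For a stage T with N observations and its predecessor T−1 with L
observations, the 0/1 label y marks which stage each pooled observation
came from. For an ordered gene pair (g_i, g_j) with pooled profiles
U (for g_i) and V (for g_j), let X = U and X̂ = (U + V)/2. The
direction determination index is the information gain about y from
averaging the partner in:

    w_ij = MI(X̂; y) − MI(X; y)                          (MI form, nats)
    w_ij = −½ · log[ (1 − r̂²) / (1 − r²) ]              (Gaussian form)

with r̂ = PCC(X̂, y) and r = PCC(X, y). The Gaussian closed form is the
default: it is deterministic, fast and is the exact equivalent of the
MI form under Gaussian/binomial marginals; only the *sign* of w decides
edge existence, and the Gaussian sign rule is exactly
|PCC(X̂,y)| > |PCC(X,y)| (a property test asserts this). The MI form is
available behind `method="mi"`, estimated by equal-frequency binning of
the continuous variable into ⌈√(L+N)⌉ bins (plug-in estimator,
0·log 0 := 0); no binning rule is canonical for this estimator, so the
square-root heuristic was chosen and exposed as a parameter.

Both ordered indices of every PPI pair are computed independently from
the pooled L+N observations; an ordered pair becomes a directed edge
with weight w iff w > 0. Degenerate pairs — a zero-variance profile, or
|PCC| = 1 which makes the log infinite — produce no edge (an undefined
orientation should not create structure); their count is logged. Edges
are only ever computed over PPI pairs, giving O(|PPI| · (L+N)) cost.

## The rank engine

From the directed network N(T) at stage T with K genes:

* **H** — row-normalized weight matrix, H_ij = w_ij / Σ_j w_ij for rows
  with positive out-weight.
* **d** — dangling indicator, d_i = 1 iff gene i has no outgoing edge.
* **τ** — per-gene standard deviation over the N stage-T observations,
  normalized to sum 1. Genes that are constant at stage T keep τ_i = 0
  and receive no teleport mass; if *every* gene is constant, τ falls
  back to uniform with a warning.

The local score vector s* is the fixed point of

    s ← α·Hᵀs + α·(d·s)·τ + (1−α)·τ ,     α = 0.85 by default,

iterated from s(0) = τ until the L1 change drops below 1e−12 (at most
10 000 iterations; non-convergence is an error carrying the residual).
The iteration conserves Σs = 1 exactly in exact arithmetic and
contracts in L1 at rate ≤ α, so ~190 iterations suffice at the default
tolerance.

**Dangling-node treatment.** Two natural conventions exist: place a
unit self-loop on dangling rows, or leave the rows empty and
redistribute dangling mass through the teleport vector. Combining both
(self-loop *and* d_i = 1) double-counts dangling mass and the fixed
point is no longer a probability vector. The default here is
*redistribute* (empty rows, mass through the α(d·s)τ term): it is the
unique convention under which s* stays a probability vector and the
iteration reduces to classical PageRank when d ≡ 0 and τ is uniform.
The self-loop variant is available as `dangling="selfloop-renormalize"`
(the iterate is renormalized each step to repair the double count).

**Global score.** With Q = max(1, ⌈0.05·K⌉),

    PR(T) = (mean of the Q largest s*_i) / mean(s*) = K · (top-Q mean),

which is 1 for a uniform ranking and ≥ 1 always. The top-Q genes are
the stage's *signaling genes* (candidate biomarkers). Ties at the Q-th
rank are broken lexicographically by gene identifier so the signaling
set is byte-reproducible. The 5% fraction applies to the whole aligned
gene universe, isolated genes included.

## Critical-point criterion

Stage t is flagged when (i) PR(t) > PR(t−1) and (ii) the one-sample
t statistic of x = PR(t) against all prior values X = (PR(1) … PR(t−1)),

    Z = (mean(X) − x) / (s / √n),    s = sample sd of X (n−1 denominator),

has a two-sided P < 0.05 under Student t with n−1 degrees of freedom.
All earlier stages serve as the prior sample (no sliding window); the
first two score values are never eligible because the sd of a single
prior is undefined. When the priors are exactly constant the convention
is P = 0 if x differs from their mean and P = 1 otherwise. All flagged
stages are reported; summaries call the *earliest* one the critical
point. A one-sided variant is exposed (`one_sided=True`), but the
direction requirement is already enforced by criterion (i), so
two-sided is the default.

**Calibration caveat.** Z scales a *single* new draw by s/√n, as if x
were the mean of n fresh observations. Under an i.i.d. null this makes
the test deliberately sensitive rather than calibrated: the per-stage
false-flag rate of the gated test is ~0.16 at the 0.05 level (measured
over 1000 simulated null series of length 10; a calibrated variant
would use the prediction scale s·√(1+1/n)). The formula is kept as the
method defines it; users should read isolated early flags on a flat
series accordingly and trust flags that coincide with an abrupt rise.

## Synthetic data

### Michaelis–Menten fixture

The reference test bed is an 18-node regulatory network in
Hill/Michaelis–Menten form with additive white noise, integrated by
Euler–Maruyama (dt = 0.01, burn-in 50 time units, values clipped at 0,
blow-up guard at |x| = 10⁶). Each "cell" is an independent realization
observed once after burn-in. Six nodes (G01–G06) form the DNB block:
mutually activating (total gain 32, split evenly, Hill coefficient 2,
Michaelis constant 8, degradation rate 1, σ = 0.05), with basal
production placed *exactly* at the saddle-node value for the
synchronized block state — the fold position is solved numerically from
the tangency condition at fixture-construction time, not hard-coded —
and the bifurcation parameter s enters the block's drift as +0.8·s.
Consequences, all verified by tests:

* for s < 0 the block relaxes around a low-expression state whose
  restoring rate vanishes like √|s| as s → 0⁻, so DNB variance and
  intra-block correlation rise monotonically toward the fold (the DNB
  signature);
* at s ≥ 0 the low state no longer exists and the block transits to a
  high-expression branch (≈ 30-fold induction), so the stage at s = 0
  carries both a large mean shift and a large variance burst;
* the remaining 12 nodes form a weakly driven activation ring plus four
  DNB-to-ring links (two activating, two repressing) that keep the
  scaffold connected; nothing feeds back into the DNB block, which
  keeps the engineered fold location exact.

The default sweep covers s = −0.5 … 0.15 in steps of 0.05 (fold at grid
point 11 of 14), 100 cells per stage, 50 trials. Stages of one trial
share a single batched integration loop (cells are independent), which
is what makes repeated-trial averaging cheap.

The fixture's *topology and coefficients* are this package's own
canonical stand-in: they are pinned so that the network exhibits the
qualitative study conditions — a flat, low score series before the
transition and an abrupt rise at the fold — and are versioned with the
code. What the generator does **not** emulate: mRNA count noise
(values are concentrations with additive Gaussian noise, not counts),
dropout/sparsity of single-cell data, gene-universe sizes beyond ~10²,
batch effects, and a declining DNB-to-outside correlation near the
fold (the block's neighbors are driven too weakly for that third DNB
property to be visible above noise). Passing tests therefore show the
machinery is correct and the signal is recoverable under ideal
conditions, not that real data of any particular platform will behave
this way.

### Ornstein–Uhlenbeck surrogate

The nonlinear fixture has no closed-form moments, so exact numerical
assertions live on a linear surrogate: DNB nodes revert to a baseline
with rate λ(s) (stationary variance σ²/(2λ(s))), the others with rate 1,
and cells are drawn directly from the exact stationary normal law — no
integration error. Tests assert the sampled variance against the closed
form within Monte-Carlo tolerance; the λ(s) schedule mimics the
vanishing restoring rate of the fold without its nonlinearity.

## Numerical and design choices

* Expression files are read with full-precision float round-tripping;
  result tables are written with `repr` formatting so re-runs are
  byte-identical.
* Duplicate gene rows (multi-probe genes) are averaged element-wise,
  keeping first-occurrence order; the operation is idempotent and is
  required before any network step.
* Gene identifiers are opaque case-sensitive strings; inputs must be
  pre-mapped to one symbol space. No log-transform is applied — values
  are analyzed as given.
* Zero-variance genes are kept at I/O time (dropping them would change
  the gene universe between stages); they are neutralized later — as
  degenerate pairs at orientation time and as τ_i = 0 at teleport time.
* The stage series is either an ordered list of per-stage matrices
  (canonical) or one matrix plus a two-column observation→stage table;
  stage order then follows first appearance in that table.
* Per-trial simulator seeds are spawned from the base seed via
  `numpy.random.SeedSequence`, so different base seeds give independent
  trial sets and every result is reproducible from one integer.
* The acceptance script averages PR(T) over 50 trials — the trial count
  used for the reference simulation figure — at 100 cells per stage,
  ~3 minutes on one CPU; the test suite uses 10 trials for the same
  check to keep the default run short.

## Known limitations

* The one-sample criterion is anti-conservative under a flat null (see
  above); on long flat series occasional early flags are expected, and
  with few trials the trial-averaged score series can show them too.
* With small gene universes the top-5% rule degenerates (Q = 1 for
  K ≤ 20), making the global score a max-to-mean ratio — noisy across
  trials — and making top-5% enrichment statistics uninformative.
* The MI estimator is a plug-in on binned data and inherits its
  positive bias at small n; it is provided for non-Gaussian data, not
  as the default.
* Stages are assumed temporally ordered by the caller; the method never
  reorders them.
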
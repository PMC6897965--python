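# Methods

This note documents the models and procedures implemented in `stemnet`,
their assumptions, the defaults that matter, and what the synthetic
validation does and does not demonstrate.

## Enrichment and ubiquity classification

Genes pass a control gate (q-value < 0.06 and fold-change > 2 versus the
non-stem-cell control; q-values are consumed from an upstream differential-
expression run, never computed here). Per-cell membership then compares
each cell's replicate-mean expression to the *strongest* competing cell
(`denominator="max"`, configurable to the mean of the other cells): cell c
is enriched when mean(c) > 2 × max over the others. When no single cell
passes, the gene is treated as equally expressed across its top cells:
every cell within a factor 2 of the maximum is enriched, provided at least
two cells qualify. A pseudocount (default 1.0 FPKM) guards zero-mean
denominators on dropout genes. The ubiquity partition is exhaustive and
exclusive: ≥ 4 of 6 cells → ubiquitous, 1–3 → specific, 0 → not enriched.

The classifier is deliberately *not* invariant to per-sample rescaling:
fold-changes are recomputed from replicate means, so rescaling one
replicate changes means and may change calls. Rescaling all samples of a
cell type by a common factor does change that cell's mean ratio — this is
the intended behaviour of a fold-change rule on normalized data.

## Consensus network inference

Clustering uses Lloyd k-means (Euclidean, one random initialization per
restart, tol 1e-6, ≤ 300 iterations) on per-gene z-scored spatial profiles
(mean expression per cell type; constant rows map to zeros). The
restart-to-restart variability of a single random initialization is the
randomness the consensus votes over; k defaults to max(2, ⌈√(n/2)⌉),
capped at n, and is configurable — neither k nor the metric is a
biologically derived constant.

Importance scoring trains an extra-trees regression ensemble
(`max_features="sqrt"`) per target on its unit-variance-scaled expression;
a regulator's weight is its normalized summed variance reduction. Candidate
regulators are the annotated TFs of the target's own cluster, so edges are
intra-cluster by construction. Per cluster, the top ⌈trim_factor × n_TF⌉
edges by weight are kept (default trim_factor 5.0 — the trimming rule's
shape, "more TFs, more edges kept", is fixed; its coefficient is a tuning
constant), with ties at the cutoff broken lexicographically for
determinism.

Consensus identity is the (regulator, target) pair, ignoring weights: an
edge survives when present in at least `maxprop` of the restart networks
(≥ at the boundary), with support = the presence fraction and weight = the
mean weight where present. Defaults: numiter = 100 restarts, maxprop = 1/3
for the spatial network and 0.45 for time-point networks. Per-cell runs use
the cell's replicates plus the niche control's, restricted to the genes
enriched in that cell; per-cell networks combine by union with cell-type
labels. Per-iteration seeds are seed + i, so a run is fully reproducible
from one integer.

For time-point networks the reference procedure clusters on the spatial
(per-cell-type) profile; when only a time course is available the package
falls back to the mean-per-time-point profile (`cluster_profile` lets the
caller supply the spatial matrix). Time points with fewer than 3 replicate
samples are skipped with a warning, since the tree ensemble needs ≥ 3
samples.

## Edge signs

The first-order-Markov sign of an edge is the sign of the Pearson
correlation between the regulator at tᵢ and the target at tᵢ₊₁ over
consecutive time-point pairs of the replicate-mean series. A dead band of
|r| ≤ 0.1 leaves the sign at 0 so noise does not produce spurious calls;
zero-variance series are likewise undetermined. This lag-1 correlation
contract is a deliberately simple operationalization of the first-order-
Markov idea; discretized transition-probability variants exist and could
be substituted behind the same interface.

## Network Motif Score

Five directed motif classes are counted: feed-forward loop (A→B, A→C,
B→C), feedback 3-cycle, diamond (A→B, A→C, B→D, C→D), bi-fan (A→C, A→D,
B→C, B→D) and the 4-node multilayer cascade (A→B→C→D). The feedback and
multilayer shapes are the standard choices for those names and the catalog
is user-overridable. Matches are counted as *non-induced* subgraph
monomorphisms modulo pattern automorphism — each placed instance counts
once, identified by its image edge set, and extra edges among the matched
nodes do not disqualify it (the permissive convention of general-purpose
motif matchers). A gene's NMS is the sum over motifs of its count divided
by the per-motif maximum count (0/0 → 0), so NMS ∈ [0, 5] and the top
participant of each motif contributes exactly 1. Enrichment compares
per-motif instance totals against Erdős–Rényi G(n, m) digraphs with the
observed node and edge counts ("a random network of the same size");
degree-preserving rewiring is available via `null="rewire"`. The empirical
p-value is the fraction of null totals ≥ observed; a z-score is reported
as NaN when the motif is absent from both the observed network and every
null.

## ODE model

One state per (gene, cell) on the FPKM scale, hours as time units with the
4-day time point at 96 h. Within a window, production is β times a product
of Hill terms (activators x^h/(K^h+x^h), repressors K^h/(K^h+x^h); h
defaults to 2 and K is shared per edge across windows), degradation is
linear, and intercellular movement between adjacent cells contributes
D·(x_src^n − x_dst^n) with n the oligomeric state. Edges without an
inferred sign act as activations. The functional form is the standard
minimal GRN kinetics; the builder accepts explicit species lists, mobility
and oligomer tables so alternative term shapes can be transcribed if
available. Window boundaries default to 96, 104, 112, 120 h; the state is
continuous across boundaries while the right-hand side switches.

Two integrators share one right-hand-side definition: adaptive LSODA
(rtol 1e-10) for user-facing trajectories, and a numba-compiled fixed-step
RK4 (48 steps per window by default) inside the fitting and sensitivity
loops, where ~10⁵–10⁶ objective evaluations make adaptive-call overhead
prohibitive. Their agreement is unit-tested (< 1e-3 relative on planted
models). States are clipped at zero; δ = 0 is permitted so conservative
transport can be simulated exactly.

**Fitting.** Latin hypercube sampling draws 50 initial vectors over the
free-parameter box; each is refined by simulated annealing (geometric
cooling over the first 60 % of a fixed 2000-evaluation budget, proposal
scale shrinking with temperature from 0.3 to 0.01 of the box range)
followed by a Nelder–Mead polish on the remaining 40 % of the budget — the
hybrid-function pattern of classical annealing toolboxes, needed so each
start converges tightly enough for the final estimate (the elementwise
mean of the 10 lowest-error fits) to be meaningful rather than an average
over scattered ridge points. An evaluation budget replaces wall-clock
cooling deliberately: it makes the procedure deterministic and
hardware-independent. Measured quantities (diffusion coefficients,
oligomeric states) stay fixed and outside the search.

**Sensitivity.** Total Sobol indices via Saltelli sampling (scrambled
Sobol' sequences for the A/B matrices) and the Jansen estimator
S_T = E[(f(A) − f(AB_i))²]/(2 Var f). An inert control parameter is sampled
alongside the real ones but never enters the model; by construction its
estimator is exactly zero up to shared-variance normalization, and it
anchors the significance test. Bootstrap replicates (≥ 30, default 100)
resample Saltelli rows *jointly* for all parameters, so the
parameter-versus-control comparison is paired; significance uses the
one-sided paired bootstrap rank p-value (1 + #{S_T,param ≤ S_T,control})/
(B + 1) with Holm correction across parameters. A joint-ranking
multiple-comparison test (Steel–Dwass) would serve the same role; the
paired bootstrap with Holm was chosen because it demonstrably controls the
familywise false-positive rate under an all-inert null (an unpaired rank
test on bootstrap replicates does not — it rejects whenever point
estimates differ by about one bootstrap standard deviation, which happens
constantly by chance).

**Division calls.** The focal regulator's expression is read at the window
boundary times; for each consecutive pair a fold-change > 1.5 (endpoint
comparison; window means are an alternative reading, endpoints are the
default) calls a significant increase or decrease. A significant decrease
across the final pair classifies the cell as dividing — the regulator's
disappearance precedes division — a final significant increase as
"increase", anything else as "quiescent". Zero baselines get a logged
pseudocount.

## Synthetic data: what it emulates, and what it does not

The generator plants a signed TF→target network (optionally seeding exact
counts of the five motif classes from dedicated node groups), assigns each
gene an enrichment plan over 6 cell types + control with targets largely
inheriting their regulator's cell set (co-regulated genes share spatial
profiles — the assumption the clustering stage exploits), and draws
kinetics (β ∈ [5, 20] FPKM/h, δ ∈ [0.05, 0.2] h⁻¹, K at half the
regulator's saturation level, h = 2). Expression uses a 10× mean
separation between enriched and non-enriched cells (the classifier's own
threshold is 2×), mean-corrected multiplicative log-normal noise (default
sd 0.25, so expected values are independent of the noise level), and
regulator→target dependencies embedded through the regulator's own noise
deviations. Time courses integrate the planted kinetics over the 96–144 h
design (7 points every 8 h, 2–3 replicates), with source genes started off
equilibrium in alternating directions and regulated genes at their
regulated quasi-steady state, so transients propagate with a lag and the
planted signs are recoverable from lag-1 correlations.

What passing these benchmarks shows: the pipeline's machinery — clustering
consensus, importance ranking, trimming, sign reading, fitting,
sensitivity — recovers planted structure under realistic noise at the
stated sizes. What it does not show: performance on real sequencing data,
where library-size effects, unmodeled confounders, non-TF regulation,
feedback on expression means, and thousands of genes are all present. The
defaults (50 genes, 10 TFs, 15 edges, 4 replicates) keep every stage
testable in minutes.

## Problem sizes used by the validation harnesses

The planted-recovery benchmark runs 10 clustering restarts with 40-tree
ensembles per target (the consensus mechanism and boundary semantics are
identical at any size; restart count and ensemble size scale throughput,
not logic). Parameter recovery uses the full 50-start, 2000-evaluation
procedure on a 3-gene model observed two-hourly over 96–144 h with 3
replicates at 10 % noise. The significance null uses Saltelli base 64 with
100 bootstrap replicates per run, 200 runs. The reproduction script
(`scripts/acceptance.py`) uses 5 generator seeds for recovery and 3 for
fitting.

## Known limitations

- Non-TF regulators are excluded by design; regulation through chromatin
  or signaling is invisible.
- The lag-1 sign contract assumes the sampling interval roughly matches
  the regulatory delay; much faster or slower dynamics dilute the signal.
- Consensus support conflates clustering co-membership with importance
  rank; in very small clusters trimming is not binding and support reduces
  to co-clustering frequency.
- The ODE model is deterministic and well-mixed per cell; no stochastic
  bursting, no spatial gradients within a cell type.
- Steel–Dwass joint ranking is not implemented; the paired-bootstrap/Holm
  stand-in is slightly conservative.
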
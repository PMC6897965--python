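# stemnet

Consensus gene-regulatory-network (GRN) inference, network-motif gene
ranking, and mechanistic ODE modeling for stem-cell niches — built around
the analysis style used for the *Arabidopsis* root stem-cell niche, where
six stem-cell populations plus a non-stem control are profiled with a few
replicates each and a short time course (every 8 h from day 4 to day 6).

It is aimed at computational biologists who have cell-population expression
matrices (FPKM-scale), a transcription-factor list, and differential-
expression summaries, and who want to go from those to a signed, cell-type-
labeled regulatory network, a ranking of putative key regulators, and a
quantitative model of when specific cells divide.

## What it computes

**Enrichment / ubiquity classes.** A gene is stem-cell-enriched when
q < 0.06 and fold-change > 2 versus the non-stem control; per-cell
membership requires fold-change > 2 against the other stem cells (genes
expressed at comparable levels in several cells belong to all of them).
Genes enriched in ≥ 4 of the 6 cell types are *ubiquitous*, in 1–3
*specific*.

**Consensus GRN.** For each stem cell, genes enriched in that cell are
clustered by k-means on their spatial mean-expression profile; within each
cluster a tree-ensemble regression (GENIE3-style variance-reduction
importance, regulators restricted to the cluster's TFs) ranks candidate
edges; edges are trimmed in proportion to the cluster's TF count; the
procedure is repeated over `numiter` clustering restarts and only edges in
at least a `maxprop` fraction of restart networks survive (1/3 for the
spatial network, 0.45 for time-point networks). Per-cell networks are
combined by union with cell-type edge labels.

**Edge signs.** A first-order-Markov reading of a time course: sign of the
Pearson correlation between regulator at tᵢ and target at tᵢ₊₁, with a
±0.1 dead band.

**Network Motif Score (NMS).** Per-gene participation counts in five
directed motifs (feed-forward loop, feedback 3-cycle, diamond, bi-fan,
multilayer cascade), each normalized to [0, 1] by the per-motif maximum and
summed; motif enrichment is tested against size-matched random digraphs.

**ODE model.** One state per (gene, cell):

```
dx/dt = β · Π_act x_a^h/(K^h + x_a^h) · Π_rep K^h/(K^h + x_r^h)
        − δ·x + Σ_adj D · (x_src^n − x_dst^n)
```

with the edge set switching at window boundaries (4D, 4D8H, 4D16H, 5D) and
the state continuous across them. Unsigned edges act as activations; `n` is
the protein's oligomeric state. Fitting uses Latin-hypercube-seeded
simulated annealing (50 starts, fixed evaluation budget, average of the 10
lowest-error fits); sensitivity uses total Sobol indices with an inert
control parameter and a paired bootstrap significance test. Division
timing: a > 1.5-fold drop of the focal regulator between the final window
endpoints calls a division, a > 1.5-fold rise an increase, anything else
quiescent.

A synthetic-data module generates planted-truth studies (networks with
known signs, enrichment plans, kinetics) so that every stage is testable
without any external download.

## Worked example

```python
from stemnet.synthetic import make_truth, expression_from_truth, timecourse_from_truth
from stemnet.datamodel import DEFAULT_CONTROL
from stemnet.grn import InferenceConfig, default_cell_contexts, run_rtpstar
from stemnet.signs import sign_network
from stemnet.motifs import count_motifs, nms

truth = make_truth(n_genes=30, tf_frac=0.2, n_edges=10, seed=11)
expr, enrichment, de = expression_from_truth(truth, n_replicates=4, noise_sd=0.25, seed=11)

cfg = InferenceConfig(numiter=10, maxprop=1/3, n_trees=50, seed=0)
net = run_rtpstar(expr, truth.annotation, cfg,
                  default_cell_contexts(expr, DEFAULT_CONTROL), enrichment)
signed = sign_network(net, timecourse_from_truth(truth, noise_sd=0.1, seed=11))
scores = nms(count_motifs(signed)).sort_values("nms", ascending=False)
```

This prints (abridged):

```
consensus network: 93 edges, 48 unique pairs
regulator target   weight  sign cell_type  support
     TF01   G001 0.701474     1      Phlo      0.5
     TF01   G001 0.791468     1       Xyl      0.7
     TF01   G004 0.641321     1       CEI      0.5
      feed_forward  feedback  diamond  bi_fan  multilayer    nms
TF01         1.000       1.0    1.000   1.000       1.000  5.000
TF05         0.688       1.0    0.929   0.722       0.816  4.154
planted edges recovered: 9/10
```

Each edge carries the cell type it was inferred in, its consensus support
(fraction of clustering restarts containing it), and its sign (+1
activation, −1 repression). `TF01` participates in all five motif classes
at the per-motif maximum, so its NMS is 5 — the pattern expected of a hub
regulator. Nine of the ten planted edges are recovered.

The same pipeline is available from the shell:

```
stemnet synth --genes 50 --edges 15 --seed 1 --outdir sim/
stemnet infer --expr sim/expr.tsv --meta sim/meta.tsv --tfs sim/tfs.txt \
              --enrichment sim/enrichment.tsv --numiter 100 --maxprop 0.3333 \
              --seed 42 --out net.tsv
stemnet sign  --network net.tsv --timecourse sim/timecourse.tsv --out signed.tsv
stemnet nms   --network signed.tsv --out nms.tsv
stemnet ode simulate --model model.yaml --out traj.tsv
```

Every output carries the tool version and seed in its header, and a
`run_config.yaml` sidecar records the effective configuration.

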
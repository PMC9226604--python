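# mycolink

Analysis toolkit for fully crossed plant × arbuscular-mycorrhizal-fungi
(AMF) inoculation experiments: it computes plant growth responses to
inoculation, characterises the root/soil AMF communities from amplicon
OTU tables, builds per-inoculum co-occurrence networks with random-graph
null models, and asks whether per-sample network complexity predicts how
much a plant benefits from its fungi.

It is written for ecologists running plant–soil feedback or inoculation
trials: the inputs are an OTU count table (samples × OTUs, TSV) with
sample metadata and taxonomy sidecars, and a per-pot plant trait CSV.

## What it computes

**Growth responses.** For an inoculated pot of host *h* with total
biomass *AM*, the mycorrhizal growth response is the log response ratio

    MGR = ln(AM / NM),

where *NM* is the mean total biomass of host *h*'s uninoculated control
pots. Positive MGR indicates mutualism, negative parasitism. Plant–soil
feedback contrasts conspecific with heterospecific inoculum,

    PSF = ln(Conspecific / Heterospecific),

at the host level using category means; per-pot values substitute the
pot's own biomass for its category's mean so that responses can be
regressed against per-sample community predictors. One-sample *t*-tests
against zero and two-way (host × inoculation) ANOVA with Type II sums of
squares complete the contract.

**Community diversity.** Samples below 5,000 reads are discarded, OTUs
with fewer than 10 total reads removed. Alpha diversity (richness *S*,
Shannon *H′* in nats) is averaged over repeated rarefaction (default
1,000 tables at 5,283 reads, hypergeometric subsampling). Beta diversity
is Bray–Curtis, `BC(x, y) = 1 − 2·Σ min(xᵢ, yᵢ) / Σ(xᵢ + yᵢ)`, with a
within-vs-among-group distance contrast and a sequential-terms PERMANOVA
(Gower-centred partition, free label permutation).

**Co-occurrence networks.** Within each inoculum group, OTUs present in
at least half the samples are screened pairwise by Spearman rank
correlation; an edge is kept when |r| > 0.6 and the Benjamini–Hochberg
FDR-adjusted p < 0.05. Each network gets a 12-metric panel (nodes,
edges, edges per node, average degree, mean clustering coefficient,
average path distance over reachable pairs, density, diameter,
connectedness, modularity, module number, proportion of positive edges)
and is compared metric-by-metric against 1,000 Erdős–Rényi G(n, m)
random graphs with identical node and edge counts.

**Complexity–response linkage.** Every sequenced root sample induces a
sub-network of its inoculum's network (nodes = network OTUs present in
the sample; edges inherited). Ordinary least squares then regresses MGR
and PSF on sub-network node count, edge count, and average degree, and
screens diversity and top-OTU abundances the same way.

A synthetic-data module simulates the whole experiment (4 hosts × 5
inoculation treatments × 10 pots; 20 trap-culture soil samples; 64 root
samples; 165 OTUs with inoculum-specific composition and correlated OTU
blocks) with exactly recomputable ground truth, so every stage has a
parameter-recovery test without external data.

## Worked example

Simulate an experiment and run the full pipeline:

```bash
mycolink simulate --outdir sim --seed 0
cat > config.yaml <<EOF
otu: sim/root_counts.tsv
metadata: sim/root_meta.tsv
taxonomy: sim/taxonomy.tsv
traits: sim/traits.csv
outdir: out
rarefaction_reps: 100
null_reps: 200
permanova_perms: 999
seed: 0
EOF
mycolink run-all --config config.yaml
```

which prints (abridged):

```
discarded low-depth samples: ['root_C_A_3', 'root_D_A_2']

Network properties
Network  Node  Edge  Edges per node  Average degree  ...  Density  ...
A        95    15    0.158           0.316                0.003
B        98    44    0.449           0.898                0.009
C        87    115   1.322           2.644                0.031
D        100   3     0.030           0.060                0.001

Response vs network-complexity regressions
     predictor response   slope  intercept     r2      p  n
          edge      MGR -0.0072     0.8759 0.1801 0.0006 62
average_degree      MGR -0.2402     0.8705 0.1778 0.0006 62
...
```

Reading this: two root samples fell below the 5,000-read cutoff and were
discarded. Inoculum C's community carries the most correlated OTU blocks
and yields the densest network (115 edges), inoculum D the sparsest.
The regression rows show that samples attached to more complex
sub-networks had *lower* growth responses (edge count vs MGR: slope
−0.0072, p ≈ 0.001, R² = 0.18, n = 62 samples) — exactly the negative
complexity–benefit relationship the generator encodes in its ground
truth, recovered end-to-end by the pipeline. Full outputs (responses,
diversity, per-network null comparisons, edge lists) land in `out/` as
plain CSV/TSV/JSON.

Library use mirrors the CLI:

```python
from mycolink import SimulationConfig, simulate_experiment, compute_responses
soil, root, traits, truth = simulate_experiment(SimulationConfig(rng_seed=0))
responses = compute_responses(traits)   # per-pot MGR and PSF
```

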
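# Methods

This note records the statistical model behind each stage, the
conventions adopted where more than one reading was defensible, and what
the synthetic-data generator does and does not emulate.

## Growth responses

MGR is a per-pot log response ratio: `ln(pot total biomass / mean
control biomass of the same host)`. Two choices are deliberate:

- The control mean (NM) is computed **per host species**, never pooled
  across hosts — each host has its own control group in the crossed
  design, and hosts differ in baseline size by an order of magnitude.
- The numerator is the **individual pot's** biomass, so each pot carries
  its own MGR value; the treatment mean of those values estimates the
  treatment-level log ratio (exactly, when noise is absent).

PSF is defined at the host level as `ln(mean conspecific / mean
heterospecific biomass)`. Because the linkage stage needs one response
per sequenced sample, a per-pot attribution is also provided: a
conspecific pot contributes `ln(own biomass / mean heterospecific)`, a
heterospecific pot `ln(mean conspecific / own biomass)`. The mean of the
conspecific contributions converges to the host-level PSF as the noise
CV → 0 (tested); the attribution is a convention, not a canonical
definition, and is documented as such.

`test_nonzero` is a plain one-sample two-sided t-test with df = n − 1; a
zero-variance sample is flagged degenerate instead of producing an
undefined statistic. The factorial ANOVA uses Type II sums of squares
(identical to Type I/III on balanced designs); a constant response is
special-cased to F = 0 for every term, since the 0/0 ratio is otherwise
undefined. Empty design cells abort with the cell list.

## Diversity

Rarefaction is subsampling **without replacement** (multivariate
hypergeometric), the convention of the amplicon ecosystem; depth
defaults to 5,283 reads and the sample-discard threshold to 5,000 reads
(strict "less than"), with the rare-OTU cutoff at 10 total reads
(strict "fewer than"), applied samples-first. Shannon entropy is in
natural-log units. Alpha diversity is the mean over 1,000 rarefied
tables by default; tests and the pipeline example use fewer repetitions
(20–100), which is ample for means of this smoothness at these depths.

PERMANOVA partitions the Gower-centred matrix `G = -½ J D² J` by
**sequential (Type I) terms** in the caller's order (host, inoculum,
interaction in the pipeline). For cumulative hat matrices `H_k`, term
sums of squares are `tr(H_k G) − tr(H_{k−1} G)`; pseudo-F uses the
residual of the full model; p-values are `(1 + #{F* ≥ F}) / (1 + n_perm)`
under free permutation of sample labels. Sequential terms were chosen
because the design is (near-)balanced, where sequential and marginal
tests coincide for main effects; the implementation is validated against
scikit-bio's single-factor PERMANOVA and by a 200-simulation type-I
error check (rejection rate 0.05 ± 0.03 at α = 0.05). Note that the
smallest attainable permutation p is limited by label exchangeability:
with two groups of 5, only 1 in 126 permutations reproduces the split,
so even a perfectly separated configuration cannot reach 1/(n_perm + 1).

Bray–Curtis distances are computed on rarefied counts (one fixed-seed
rarefied table for beta diversity and networks), not on relative
abundances; with equal library sizes the two differ only by the
rarefaction noise. The within/among contrast classifies unordered sample
pairs by a grouping factor and applies Welch's t-test; an all-equal
distance matrix short-circuits to t = 0, p = 1.

## Co-occurrence networks

Edges are Spearman rank correlations over the samples of one inoculum
group (root samples of all four hosts), after removing OTUs present in
fewer than half of the group's samples (an OTU in exactly half is kept).
The correlation matrix is computed as average-rank transform followed by
Pearson correlation, with two-sided p-values from the t approximation
`t = r·√((n−2)/(1−r²))`; constant OTUs give undefined correlations and
contribute no edges. BH-FDR is applied jointly across all tested pairs
of one group, never across groups. An edge requires |r| > 0.6 **and**
q < 0.05, both strict; the absolute value matters because negative
(|r| > 0.6, r < 0) associations are retained with a `-` sign.

Property panel conventions (they matter for disconnected graphs):

- local clustering of a node with degree < 2 counts as 0 and is included
  in the average;
- average path distance and diameter are over **reachable** pairs only;
- connectedness is the fraction of ordered node pairs joined by a path
  (1 iff connected);
- modularity and module number come from greedy (Clauset–Newman–Moore)
  modularity maximisation on the unweighted graph. The algorithm is a
  choice — different community detectors give different module counts —
  so modularity comparisons are reported but should be read as
  algorithm-conditional.

The null model is G(n, m): uniform random simple graphs with exactly the
observed node and edge counts (1,000 replicates by default). Each metric
is compared to the observed value by a one-sample t-test over the null
vector; node and edge counts have zero null variance by construction and
are flagged degenerate. For G(n, m), the expected clustering coefficient
equals the density 2m/(n(n−1)) asymptotically, which provides a
closed-form sanity anchor for the ensemble.

## Sub-network linkage

A root sample's sub-network is the induced subgraph of its inoculum's
network on the OTUs with count > 0 in that sample — induced, never
path-contracted, and edges are inherited rather than re-inferred.
Presence is judged on the same rarefied table used for network
inference, for internal consistency. Node count, edge count, and average
degree of these sub-networks are the complexity predictors; OLS with a
two-sided slope test links them to MGR and PSF, pooled across inocula
(per-inoculum fits are a caller option). The per-sample beta-diversity
predictor is the sample's mean Bray–Curtis distance to the other samples
of its group — one reasonable summary among several, flagged as a
convention. The abundance screen regresses relative abundances of the
top-k most abundant OTUs (k = 20 default) with BH adjustment across the
whole screen.

## Synthetic data

The generator's defaults describe one fully crossed feedback experiment:
4 hosts × 5 inoculation treatments (4 inocula + sterilised control) × 10
pots; 5 trap-culture soil samples per inoculum; 4 sequenced root
replicates per host × inoculum cell; 165 OTUs across three
Glomeromycotina orders; library sizes 3,000–40,000 reads with exactly 4
samples forced below the 5,000-read cutoff (2 soil, 2 root) so the
discard rule is always exercised; retained samples are drawn at ≥ 5,283
reads so the default rarefaction depth is always attainable.

Biomass is `baseline(host) · ρ(host, inoculum) · lognormal(CV)` with
mean-one noise, so `E[biomass]` equals the configured effect and the
true MGR is `ln ρ` (recovered exactly at CV = 0). The default CV of 0.3
is a free parameter chosen as typical pot-to-pot variation in greenhouse
biomass data; it is not calibrated to any particular dataset. The
default ρ matrix encodes the qualitative structure of interest: the
grass-like host D responds most (strongest with its conspecific
inoculum), host C shows negative feedback (worst with its own
inoculum), inoculum D is the most and inoculum C the least beneficial
overall.

Counts follow a Dirichlet-multinomial with three layers on top of the
inoculum-specific base proportions:

1. an independent per-sample, per-OTU lognormal jitter (σ = 0.6) — the
   overdispersion seen in real amplicon data, and a guard that keeps
   compositional closure from inducing spurious correlations among
   non-block OTUs when a block's total mass swings;
2. a host-specific lognormal preference (σ = 0.3) for root samples;
3. per-inoculum **blocks** of OTUs sharing a lognormal latent factor,
   which induces rank correlation of the configured sign within the
   block (a negatively signed block splits into two anti-correlated
   halves, since all-pairs negative correlation is infeasible for more
   than two variables).

Block OTUs are pinned to 4× the median base mass so they reliably pass
the prevalence filter in their own group, and the default within-block
correlation is strong (0.95) so block edges survive the joint BH
correction over thousands of tested pairs at n ≈ 14–16 samples — with
weaker settings, small blocks vanish entirely from the inferred
networks, which is realistic but makes the networks degenerate as a test
bed. The default block layout gives inoculum C three large blocks and
inoculum D one small one, so inferred network density decreases
C > B > A > D while the growth effects increase in that order: the
negative complexity–benefit relationship is part of the configured
ground truth and must be recovered by the full pipeline (it is, in ≥ 90%
of 50 seeds).

What the generator does **not** emulate: sequencing error, chimeras, or
taxonomy mis-assignment; phylogenetic structure among OTUs; genuinely
compositional interaction networks (the blocks are latent-factor
correlations, not ecological interactions); spatial or temporal
structure in the greenhouse. Passing recovery tests therefore shows the
pipeline is faithful to its own definitions under a plausible generative
model — not that thresholded rank-correlation networks recover true
ecological interaction in field data, a known general limitation of
co-occurrence analysis.

## Determinism and problem sizes

All randomness flows from integer seeds through numpy `SeedSequence`
streams: the generator derives one independent stream per component
(biomass, base proportions, soil, root), the pipeline one per stage, so
a re-run with the same config and seed reproduces every output
byte-identically (hash-tested). Test and example runs scale repetitions
down (20–200 rarefactions, 99–999 permutations, 30–200 null graphs);
defaults remain at the 1,000-replicate convention. The acceptance script
uses the full 1,000-replicate ensembles at the published network sizes
(74/645, 75/294, 73/801 nodes/edges), where the ensemble means it
reports are stable to ~3 decimal places across seeds.

## Known limitations

- Spearman p-values use the t approximation, adequate at n ≥ ~10 but
  approximate for the smallest groups the code accepts (n = 4).
- Greedy modularity is deterministic but algorithm-dependent; module
  counts on sparse graphs (many singleton communities) are not
  comparable across community-detection methods.
- The per-pot PSF attribution and the per-sample beta-diversity
  predictor are conventions; both are isolated behind single functions
  so alternatives can be swapped in.
- Multi-factor PERMANOVA assumes exchangeability under free permutation;
  no restricted-permutation schemes are implemented.
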
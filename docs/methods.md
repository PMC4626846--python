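# Methods

`microkey` identifies *key* taxonomic groups — groups statistically
over-represented among the most central nodes of a microbial
co-occurrence network — and *dominant* groups, which top the centrality
rank by sheer membership. The chain is: prevalence filtering of an OTU
count table, sparCC correlation inference with permutation significance,
binary network construction, topology and centrality computation, and
hypergeometric group enrichment of the top-centrality sets.

## Input filtering

An OTU is retained when it appears (count > 0) in at least a fraction
`theta` of the samples of its body site; the default `theta = 0.20`.
The boundary is inclusive ("at least 20%"), and presence is defined as
a strictly positive count — the standard reading where no explicit
detection threshold exists. Samples whose total count is zero are
dropped (with a warning) before prevalence is computed, since presence
fractions would otherwise be 0/0. Filtering acts on the pooled per-site
table: samples from many individuals are analyzed together, trading
individual-level resolution for statistical robustness.

Taxonomy lineages are collapsed to group labels: the most specific
*named* rank at or above genus (genus if named, else family, else
order, ...). Species never serves as the group — groups are meant to be
clinically recognizable units (genera, families), and published group
tables for such networks mix exactly these ranks. A user-supplied
OTU-to-group map overrides lineage parsing.

## sparCC correlation inference

Relative abundances carry only compositional information: closing
counts to a fixed sequencing depth induces spurious negative Pearson
correlation among all taxa. sparCC works instead from the log-ratio
variances `t_ij = Var[log(x_i/x_j)]`, which are invariant to per-sample
scaling. Writing `t_ij = w_i^2 + w_j^2 - 2 rho_ij w_i w_j` with latent
("basis") variances `w_i^2`, and assuming the true correlation network
is sparse (correlations average out to approximately zero), the row
sums of the variation matrix become a linear system in the basis
variances:

    sum_j t_ij ~= d_i w_i^2 + sum_{j in partners(i)} w_j^2 .

After solving, `rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j)`, clamped
to [-1, 1]. The most strongly correlated pair with `|rho|` above the
exclusion threshold is then removed from the system and the solve
repeated — up to `max_exclusions` times — so that pairs violating the
sparsity assumption do not bias the basis variances.

Counts are converted to strictly positive fractions by Dirichlet
resampling with `counts + 1` as parameters (one draw per sample), which
both handles zeros without an ad-hoc pseudocount-and-log and propagates
count uncertainty; the correlation estimate is the mean over
`n_resamples` resamples.

Parameter defaults, all configurable: `n_resamples = 20`,
`exclusion_threshold = 0.1`, `max_exclusions = 10`,
`n_permutations = 100`, `alpha = 0.05`. These are the conventional
settings of the basis-variance methodology; the analysis that motivated
this package names the method without printing parameters, so the
conventional values are adopted as package defaults.

Numerical edge cases: a negative basis variance (possible on small or
strongly non-sparse tables) is clamped to a tiny positive value with a
warning instead of aborting; a singular system falls back to a
least-squares solve; a component is never excluded out of the system
entirely.

## Significance and network construction

Edge significance comes from a permutation null: each OTU's counts are
shuffled independently across samples — destroying all between-OTU
association while preserving every OTU's marginal count distribution —
and the full sparCC estimate is re-run per permutation. The two-sided
edgewise pseudo-p is `(1 + #{|rho_null| >= |rho_obs|}) / (1 + P)`; the
+1 correction keeps p strictly positive, and at least 19 permutations
are required so that `p < 0.05` is attainable at all. The sign of the
correlation is deliberately ignored (co-exclusion is as structural as
co-occurrence here), and no additional magnitude threshold is applied
to `|rho|`.

The interaction network is binary and undirected: edge `(i, j)` exists
iff `p_ij < alpha`, strictly. Every filtered OTU remains a node, so the
node count `N` equals the filtered table size even when OTUs end up
isolated.

## Topology and centrality

Global battery per network: `N`, `L`, `L_max = N(N-1)/2`, density
`C = L/L_max`, diameter (longest finite shortest path), average path
length (mean hop distance over connected ordered pairs) and
transitivity, defined as the mean over nodes of the local clustering
coefficient — the edge density among a node's neighbors, contributing 0
for degree < 2. Disconnected pairs are excluded from the APL and
ignored for the diameter; an edgeless network reports both as 0.

Centralities: degree (neighbor count) and standardized Freeman
betweenness

    BC_i = [ sum_{j != i != k} g_jk(i)/g_jk ] / ((N-1)(N-2)),

summing over ordered pairs, where `g_jk` counts equally shortest j–k
paths and `g_jk(i)` those through `i`. The denominator — twice the
number of pairs excluding `i` — standardizes BC into [0, 1]; this
standardized form is implemented (and pinned against an exhaustive
path-enumeration oracle in the tests). Networks with fewer than 3 nodes
define all betweenness as 0.

## Key and dominant groups

For a cutoff fraction `q` the top set holds the `round(q * N)` most
central nodes (nearest integer, half away from zero, floor of 1). The
rounding rule is pinned by the published cutoff sizes for a 1254-node
network: 251 at 20%, 63 at 5%, and 125 at 10% — the last back-derived
from published singleton-group p-values of 0.0997 = 125/1254 (a ceiling
rule would give 126 and contradict them). Boundary ties are broken by
stable node order by default (deterministic and reproducible); an
include-ties policy is available and recorded in report headers.

A group with `K` members in an `N`-node network, `x` of them inside a
top set of size `n`, gets the strict upper-tail hypergeometric
probability `p = P(X > x)`, computed by exact summation of the p.m.f.
in log space. The strict tail (rather than `P(X >= x)`) is the
convention the published group tables follow — singleton groups absent
from the top-20% set print p = 251/1254 = 0.2002, which is `P(X >= 1) =
P(X > 0)`, and a singleton fully inside prints exactly 0 = `P(X > 1)`.
The conventional inclusive tail is available behind a flag. A group is
significant ("key") at raw `p < alpha` with **no multiple-testing
correction**, matching the reference analysis; Benjamini–Hochberg
adjusted values are emitted as a supplementary column but never drive
the flag. A group is *dominant* when it supplies at least 10%
(inclusive) of the top-20% set, whatever its p-value — numerically
important rather than disproportionately central. Dominance is always
evaluated on the top-20% set even when other cutoffs are also reported.

## Synthetic communities

The generator emulates the statistical features of real 16S census
tables that the pipeline depends on, with known ground truth:

- **Latent law**: per-OTU log-abundance means drawn once per community
  from a normal with SD `mean_spread = 1.5` (heavy-tailed relative
  abundances spanning roughly three orders of magnitude, as in real
  census tables); per-sample latent log-abundances are multivariate
  normal with SD `log_sd = 1.0` and a block correlation matrix —
  `block_rho` (default 0.8) within each designated hub group, zero
  elsewhere.
- **Closure**: counts are a fixed-depth multinomial draw (default
  5 000 reads) over the normalized latent abundances, so the data are
  exactly compositional; optional log-normal depth jitter adds
  overdispersion.
- **Ground truth**: hub groups are central purely through correlation
  density (every within-block pair correlated), which is exactly how
  degree centrality arises in a sparCC graph; no degree sequence is
  imposed. Lineages are synthesized in rank-prefixed form so the real
  lineage parser is exercised end to end.

The log-normal + multinomial construction (not Dirichlet-multinomial)
keeps the planted correlations analytically controlled through
compositional closure. What the generator does **not** imitate: real
taxon frequencies, body-site-specific compositions, zero inflation
beyond what closure produces, or phylogenetic correlation between
groups. Passing recovery tests therefore demonstrates that the
inference chain detects planted covariance structure under
composition and multinomial noise — not that any particular biological
claim about real communities is reproduced.

Reference study conditions used by the test bench (chosen once, before
any measurement, and not revisited): 60 OTUs in six groups of 10, one
hub group at `block_rho = 0.8`, 300 samples at depth 5 000; type-I
control is assessed on fully independent 50-OTU, 200-sample
communities with 100 permutations, over 20 communities in both cases.
The seed-level significant-edge fractions are the Monte-Carlo
replicates for the type-I check, because edges within one network are
mutually dependent.

## Known limitations

- Correlation networks capture association, not mechanism; indirect
  effects and distinct interaction types are not separable.
- The permutation null breaks exact per-sample closure (column sums are
  only approximately constant after row-wise shuffling); empirically
  the test runs very slightly conservative (~0.048 significant-edge
  fraction at alpha 0.05 under independence).
- With a strong correlated block present, compositional closure
  elevates background edge rates above nominal; group-level enrichment
  is robust to this in the tested conditions, edge-level inference less
  so.
- Published global-topology values for the original human-microbiome
  networks cannot be recomputed without the original survey download
  and its unstated processing choices; the topology code is instead
  anchored by closed-form cases (complete graph, paths, stars) and
  exhaustive oracles.
- The published stool-network reproduction checks the enrichment
  arithmetic (counts -> p-values) exactly, but not the upstream network
  inference on real data, for the same reason.
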
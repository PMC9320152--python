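# Methods

## Overview

`ccsn` infers a gene–gene association network for every single cell of a
genes × cells expression matrix, conditions away associations mediated
by the cell's dominant genes, and analyzes the resulting per-cell degree
profiles. Downstream it provides hub ranking by maximal clique
centrality, a ligand–receptor label-permutation test, a "dark"-gene
screen (degree-differential but not expression-differential genes
between two conditions), gene-set over-representation, and median-split
survival analysis. All statistics operate on log(1 + x)-normalized,
nonnegative expression values (natural log; the neighborhood statistics
below depend on values only through local orderings, so the base is
immaterial).

## The cell-specific network statistic

For cell *k* and gene *x*, the neighborhood box N_x(k) is the
⌈a·n⌉ cells whose expression of *x* is nearest (absolute value
distance) to cell *k*'s value, cell *k* included; ties are broken by
ascending cell index so the construction is deterministic even for
genes with many identical values. For a gene pair (x, y) the statistic
is the standardized overlap of the two boxes,

    s = (n·n_xy − n_x·n_y) / sqrt( n_x·n_y·(n − n_x)·(n − n_y) / (n − 1) ),

which under independence of x and y is the standardization of a
hypergeometric overlap count and asymptotically standard normal. An
edge is drawn in cell *k*'s network when s exceeds the upper α quantile
of N(0, 1).

Two numerical choices matter here:

* **The focal cell is excluded from all overlap counts.** Cell *k*
  belongs to every one of its own boxes by construction, so its
  co-membership carries no evidence; counting it shifts the null mean
  of s by roughly (1 − a)/(a·√n) standard units (≈ +0.6 at a = 0.1,
  n = 200), inflating the edge rate several-fold. All counts are
  therefore taken over the n − 1 remaining cells, which centres the
  statistic exactly.
* **Box fraction a = 0.3 by default.** The edge decision reduces to an
  integer threshold on a hypergeometric count, so its true size can be
  computed exactly. At a = 0.1 the normal approximation is markedly
  anti-conservative for a few hundred cells (true size 0.023–0.034 at
  nominal α = 0.01 for n = 100–400); at a = 0.3 the true size is
  0.0085–0.0094 over the same range. The default therefore trades some
  cell-specificity of the box for a calibrated test; `box_fraction` is
  exposed for users who prefer smaller boxes. Because the decision
  threshold is an integer count, the realized size oscillates with n
  (e.g. 0.016 at n = 150); tests that rely on the α·(P − 1) null-degree
  expectation use sizes where the approximation is tight.

## Conditioning

The cell's unconditional network (CSN) supplies the m highest-degree
genes as *conditional genes* (ties by ascending index; m = 1 by
default). For a pair (x, y) not involving a conditional gene *z*, the
same overlap statistic is recomputed inside z's box — universe N_z(k),
counts n_xz, n_yz, n_xyz — and the pair keeps its edge only if both the
marginal statistic and the conditional statistic (averaged over the m
conditional genes; `min` is available) exceed the threshold. Pairs
involving a conditional gene keep their unconditional decision, and
m = 0 reduces exactly to the unconditional network.

Requiring the marginal *and* the conditional test is deliberate:
the conditional statistic lives on a much smaller universe
(⌈a·n⌉ − 1 cells), where the normal approximation is anti-conservative,
and thresholding it alone would *add* edges that the marginal test
rejects — inverting the pruning semantics of conditioning. With the
conjunction, conditioning is monotone (the conditional network is a
subgraph of the unconditional one), and associations that are explained
away by the conditional gene — e.g. two genes driven by a shared factor
that the conditional gene proxies — are removed.

Stacking each cell's degrees column-by-column yields the conditional
network degree matrix (CNDM), an integer genes × cells analogue of the
expression matrix. Genes expressed in fewer than `min_expressing_cells`
(default 10) cells are excluded from construction and sit at degree 0.

For group comparisons the CNDM is computed once per cell type with the
two conditions *pooled* in a single box universe. Building separate
networks per condition makes each gene's degree depend on the realized
edge set of that dataset half; edges persist across the cells of one
network, so the per-gene mean degree then fluctuates far more between
independently built networks than the within-network cell-to-cell
variance suggests, and the t-test below badly overstates significance.
Pooling puts both groups' cells in the same network universe, so this
shared edge-persistence cancels in the group contrast.

## Network integration and hub ranking

Per-cell networks of one cell type are integrated into a weighted
graph: edge weight = fraction of cells containing the edge; edges below
`min_support` (default 0.05) are dropped. Hubs are ranked by maximal
clique centrality, MCC(v) = Σ_C (|C| − 1)! over maximal cliques C ∋ v
(Bron–Kerbosch enumeration via networkx). An isolated node scores 0; a
node whose neighborhood contains no internal edge automatically scores
its degree, since each of its edges is then itself a maximal 2-clique.
Rankings use competition ranking: tied scores share a rank.

## Ligand–receptor communication

For an ordered (source, target) cluster pair, a ligand–receptor pair
scores (mean ligand expression in source + mean receptor expression in
target)/2, computed on the normalized matrix; pairs whose ligand or
receptor is expressed in fewer than `min_frac` (default 0.1) of the
cluster's cells are not tested. Cluster labels of all cells are
permuted B times (default 1000) and p = #(permuted ≥ observed)/B, with
no +1 correction — an observed score at the top-5% boundary of the
permutation distribution gets exactly p = 0.05, and p lies on the grid
{0, 1/B, …, 1}. The (count + 1)/(B + 1) variant can be obtained by
post-processing the returned counts but is not the default.

## The dark-gene screen

Within one cell type, each gene is tested between the two conditions on
two layers: the expression matrix and the (untransformed, integer)
CNDM. Both use Welch's unequal-variance t-test — single-cell groups
are heteroskedastic — with Benjamini–Hochberg adjustment across the
genes of each comparison. A *dark gene* has expression p > 0.05 and
degree FDR < 0.05; its direction records which condition has the higher
mean degree. Degenerate genes (zero variance in both groups) get
p = 1 when the means agree, and a p clipped to the smallest positive
float when they differ. Negative-binomial count testing of raw reads
is out of scope: the screen's defining computation is the two t-tests
on the normalized layers.

Gene-set over-representation of any query (e.g. the dark genes) uses
the one-sided hypergeometric tail against a user-supplied GMT
collection, BH-adjusted across sets; sets are intersected with the
supplied universe before testing.

## Survival analysis

Samples are split at the median of a per-sample score (ties go Low,
making the split deterministic), the High and Low groups are compared
with the standard two-group log-rank test (lifelines), and
Kaplan–Meier curves are estimated by the product-limit formula. When
the split is significant at level α (default 0.05), the call is
*positive* if the High group has the larger restricted mean survival
over the observed time range and *negative* otherwise; non-significant
splits get direction *none*. The median split depends only on score
ranks, so calls are invariant to monotone transformations of the score.
How a per-sample degree score is derived for bulk cohorts is left to
the user; the module consumes any (sample, time, event, score) table.

## The synthetic-data generator

The generator emulates the statistical shape the pipeline assumes
rather than a sequencing protocol. Per (cell type, condition) group it
draws a latent standard-normal matrix, couples the genes of every
module active in that condition through a shared per-cell factor with
loading √ρ (Gaussian copula), and pushes each gene through a
zero-inflated log-normal marginal: the lower `zero_fraction` tail of
the copula uniform maps to 0, the rest to exp(μ_g + σ·Φ⁻¹(·)) with
μ_g ~ U(0.7, 2.0) and σ = 0.6, giving log(1 + x)-scale values in the
range typical of normalized single-cell matrices. Because the copula
only reshapes the joint distribution, every gene's marginal is
*identical* in both conditions by construction — dark genes are created
purely by association-structure switching (a module active in one
condition only), never by mean shifts.

Defaults: 500 genes, 2 × 200 cells, one 10-gene module with ρ = 0.8
active only in the disease condition (`default_dark_spec`), and
`zero_fraction = 0.3`. The zero fraction is set equal to the default
box fraction deliberately: when a gene's zero tie-class is larger than
one neighborhood box, the index tie-break makes zero cells' boxes
coincide across genes, which floods the null networks with
tie-artifact edges and drowns planted structure. Keeping the tie-class
within one box leaves the boxes value-driven. Data with much higher
dropout than box fraction are outside the regime in which the
neighborhood statistic is informative — a genuine limitation of the
method, not just of the generator.

Planted ligand–receptor pairs shift the ligand's (receptor's) location
parameter by `effect` (default 2.0 log-units) in the source (target)
cell type, in both conditions equally. Survival tables use standard
normal scores and exponential event times whose hazard is multiplied by
`hazard_ratio` above the score median; censoring is independent
exponential with per-sample rate chosen so each sample is censored with
probability `censor_rate` exactly.

What the generator does *not* emulate: UMI/read counts, batch and donor
effects, doublets, pseudotime, gene-length or library-size biases, and
realistic gene-gene correlation beyond the planted modules. Passing
tests therefore demonstrate internal correctness and statistical
calibration under the stated model, not performance on any particular
real dataset.

## Problem sizes and determinism

The test suite and the acceptance script run the method at 100–500
genes and 100–400 cells: large enough for the asymptotic calibration of
the overlap statistic to be measurable, small enough to iterate on.
Every stochastic component takes an explicit seed; dataset generation
derives independent substreams per (cell type, condition) group from a
single `SeedSequence`, so identical spec + seed reproduce outputs byte
for byte. Pipeline runs record parameters, seed and output checksums
in a manifest.

## Known limitations

* The overlap test's exact size oscillates with n through the integer
  decision threshold; calibration statements hold for the default
  box fraction at hundreds of cells, not uniformly.
* The conditional statistic is computed on ⌈a·n⌉ − 1 cells; with few
  cells it is noisy, and the conjunction rule means conditioning can
  only remove, never rescue, an edge.
* Degree comparisons inherit cross-gene dependence (cells share one
  network), so gene-level FDR is controlled only approximately; the
  planted-recovery tests measure the realized false-call rate.
* MCC enumeration is exponential in the worst case; integrated networks
  at the default support threshold are sparse, but dense graphs can be
  slow.
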
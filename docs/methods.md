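# Methods

## The problem

Chromosome-scale genomes of an unduplicated invertebrate chordate outgroup
(an amphioxus-like genome) and several jawed-vertebrate-like ingroups allow
two questions to be answered from macro-synteny alone: (1) how many
ancestral chordate linkage groups (CLGs) do the modern karyotypes descend
from, and (2) were the two ancient whole-genome duplications on the
vertebrate stem autotetraploidies (doubling within one species, symmetric
duplicate loss) or allotetraploidies (hybrid doubling, asymmetric loss
between the two parental subgenomes)?

Synteny is used in its classical sense — physical linkage without regard to
gene order or orientation — because internal gene order is thoroughly
scrambled over half a billion years while linkage itself is conserved. All
statistics therefore operate on gene ordinals (0-based ranks along a
chromosome); base-pair coordinates are carried for display only, and
unplaced genes are excluded from every count.

## Orthology anchors

Cross-species anchors are mutual best hits (MBH): a pair is kept iff each
gene is the other's unique top-scoring hit in the reciprocal similarity
searches. Ties for "best" disqualify a gene — MBH is deliberately a
conservative 1:1 set. Anchors from every ingroup to the outgroup are joined
on the outgroup gene map; a gene with no orthologue anywhere is dropped.
For duplicated genomes, gene families (orthogroups) supplement the 1:1
anchors; in retention counting a family contributes at most once per
chromosome (and per segment for split sub-cells), so tandem duplications
never inflate retention.

## Linkage-group inference

For anchored outgroup gene *i* and comparator chromosome *a*, the synteny
indicator x_a(i) is 1 iff *i*'s orthologue lies on *a*. With left/right
windowed means over W genes (default W = 25),

    D(i, i+1) = Σ_a (X^R_a(i+1) − X^L_a(i))²,

the squared Euclidean norm of the composition switch across the junction.
D is 0 on homogeneous stretches, reaches 2 only for a complete
one-chromosome-to-another switch, and spikes at synteny breakpoints.
Numerical choices:

- *Window truncation*: windows shorter than W near chromosome ends average
  over the genes available; D is still reported there, but junctions with
  fewer than W anchored genes on either side are ineligible as breakpoints.
  (Eligibility initially used W/2; truncated windows have roughly doubled
  variance and produced spurious peaks 13–16 genes from ends, so the margin
  is a full window.)
- *Peak calling*: local maxima with D ≥ θ (default θ = 0.5, a 50%
  composition switch) accepted greedily in decreasing D order with a
  minimum separation of W genes.
- *Consensus*: breakpoints are called per comparator; a consensus boundary
  needs support from ≥ 2 comparators within ±W/2 genes and is placed at the
  median supported junction.
- *Merging*: segments between consensus boundaries are combined
  (single-linkage) when the cosine similarity of their mean indicator
  vectors is ≥ 0.75 in a majority of comparators. The threshold is derived
  from the geometry of the problem rather than tuned: two distinct CLGs
  that were co-fused before the second duplication share exactly two of
  their four residence chromosomes, and their profile cosine is then
  (a² + b²)/(2(a² + b²)) = 0.5 identically, independent of retention rates;
  same-CLG segments score ≈ 1. 0.75 sits in the middle of that gap, whereas
  a threshold of 0.5 is a knife edge that merges co-fused CLGs about half
  the time.
- Resulting units are lettered A, B, C, … in decreasing order of gene
  count, ties broken by smallest chromosome identifier. A user-supplied
  merge list supports manual regroupings; no automatic rule is claimed.

## Enrichment testing

Under the null that 1:1 orthologues fall at random across the two genomes,
the overlap between a CLG's anchors and a target chromosome (or window) is
hypergeometric in the shared-anchor universe N. Tests are one-sided (upper
tail, enrichment only), summed in log space, and Bonferroni-corrected by
the number of tests actually performed: #CLGs × #chromosomes at chromosome
scale, #CLGs × #tested windows for sliding windows (size 50 and 100,
step = size/2, pooled per species pair — the more conservative choice —
windows without anchors skipped and not counted). The recorded m makes the
correction auditable. Cells are tiered like the annotation convention of
the original analysis: *strong* iff the 50-gene scan reaches corrected
p < 0.01; *weak* iff 50-gene p < 0.05, 100-gene p < 0.01, or
whole-chromosome p < 0.05. Small high-density blocks inside large
chromosomes are the reason for the window scans: a 60-gene block whose
chromosome-wide share sits at the genome expectation is invisible at
chromosome scale but decisive in a 50-gene window.

## Painting and copy assignment

Ingroup genes inherit a CLG through their family's outgroup members
(majority vote; ties unassigned). Chromosomes are painted in
non-overlapping windows of ≥ 20 genes and partitioned into ancestry blocks
by iterative largest-peak splitting of the same D statistic (CLGs as the
indicator classes, W = 20, θ shared with breakpoint calling, new
breakpoints ≥ 20 genes from accepted ones). Per CLG, runs of blocks holding
≥ 5 of its genes form occurrences; occurrences are linked across ingroup
species into orthologous cells by greedy maximum shared-MBH count (ties
flagged ambiguous and excluded from pairing), and cells co-resident on a
chromosome in any species are united into chromosome groups — the "trio"
units of the downstream retention analysis. Two same-CLG runs on one
chromosome stay distinct sub-cells, so translocated paralogous blocks are
not conflated.

## Retention and the duplication mechanism

The retention fraction of a cell is (families with a member in the cell's
segments, one per segment) / (CLG-defining outgroup gene count). Chromosome
groups with identical CLG-content signatures are fusion-concordant
candidates; within a signature class the i-th highest-retention group pairs
with the i-th lowest, the higher member of each pair is labelled α, the
lower β — so a chromosome is wholly α or wholly β by construction — and an
odd leftover is an α without a β counterpart, reported but excluded from
testing. Copy labels 1/2 carry no retention meaning and are assigned by
total gene content.

The asymmetry test compares the observed mean α − β difference of complete
pairs against a null with a single retention class: pairs drawn iid from
uniform(0, c) with c twice the overall retention mean (a normal null with
moments from the data is also available and is more conservative), the
larger member labelled α. Closed forms for the uniform null are
E[max − min] = c/3 and sd[max − min] = c/√18; the test estimates them by
seeded bootstrap (default 10⁶ replicates) and reports a one-sided normal
z and p. Calibration note: z is standard normal when c is the null's true
scale. If c is re-estimated from each small sample, the ĉ noise term adds
≈ 0.33 to var(z) (sd ≈ 1.15) and the symmetric-truth rejection rate at
α = 0.05 rises to ≈ 0.11; the calibration and mechanism-discrimination
checks therefore condition on the known scale c = 2 × 0.27 = 0.54, exactly
as a single global c is fixed once from the full data in practice.

Bimodality of the pooled per-species cell retentions is tested with the
dip statistic: the smallest sup-norm distance between the empirical
distribution function and any unimodal distribution function (convex then
concave, an atom permitted at the mode). The implementation reduces the
problem to greatest-convex-minorant feasibility inside the tube
[F − t, F + t], giving dip = min over mode placements of the larger of the
left and right hull deviations over 2n. It is validated to 10⁻¹² against
two independent references (a bisection tube-feasibility oracle, and
per-mode from-scratch qhull prefix hulls) and attains the known floor
1/(2n) for tie-free samples. p values bootstrap against uniform samples of
equal size — the least favourable unimodal null — so rejection is exactly
nominal on uniform data (measured 0.049 at α = 0.05) and conservative on
other unimodal shapes. The null table depends only on n and is cached.

Cross-species agreement is summarized by Pearson correlation of per-cell
retention between ingroup pairs. The alternative scenario in which β copies
fused independently but in the same pattern as α is tested by permutation:
the statistic is the number of β fused CLG pairs identical to an α pair,
and the null re-pairs the β segments by a uniformly random perfect
matching — enumerated exactly up to 10⁶ matchings ((2k−1)!! for k pairs),
sampled beyond that.

## The synthetic-data generator

The simulator realises the auto- then allotetraploidy scenario with full
truth labels, and its defaults are the study conditions of the acceptance
suite:

| parameter | default | rationale |
| --- | --- | --- |
| n_clgs | 17 | ancestral chordate linkage-group count under study |
| genes_per_clg | 300 (lognormal spread 0.2) | ~5,000 anchors genome-wide, the scale of a conservative MBH set |
| lineage scrambling | 300 inversions/chromosome | saturating within-chromosome order scrambling; linkage untouched |
| outgroup fusions | 3 (junction mixing 0) | a karyotype a handful of sharp-boundary fusions away from the ancestor |
| 1R | auto, retention 0.75/copy | symmetric post-duplication loss with most families kept in ≥ 1 copy |
| stem fusions | 6, 30 junction-spanning inversions (span 100) | fusion-with-mixing between the two duplications, where most CLG fusions belong |
| 2R | allo, retention 0.39 (α) / 0.15 (β) | the asymmetric retention pattern under study |
| subgenome divergence | 30 local inversions (span 50) | independent α/β evolution before hybridization |
| terminals | 3 species, retention 0.97, 20 local inversions | shared stem loss dominates, small independent terminal loss — which is what makes cross-species retention correlations high |
| min_retained_copies | 1 per species | families are defined from surviving genes, so every family survives somewhere |

Loss is Bernoulli per family per chromosome-copy, so realized retention
directly reflects the configured rates; conditioning on ≥ 1 surviving copy
(by resampling the family's loss vector) inflates realized marginals above
nominal — with the defaults, final α cells sit near 0.45 and β near 0.18
rather than 0.39/0.15. The unconditioned identity (cell means = configured
rates) holds exactly with min_retained_copies = 0 and is tested there.
Similarity scores are constructed so true orthologues are mutual bests:
within-family score levels 100 (same copy and subgenome), 80 (same copy,
other subgenome), 70 (other copy), 60 (to the outgroup), with uniform noise
of width 5 — smaller than every gap. An optional 1R-only intermediate
lineage and terminal translocations are available but off by default.

One structural default deserves emphasis: the stem fusion sampler avoids
re-fusing a pair of CLGs already fused in the outgroup. When the same two
CLGs fuse independently in both lineages, the outgroup junction is
genuinely faint (D ≈ 0.3 < θ) in every duplicated comparator — the
comparators are fused there too — and the boundary cannot be recovered from
duplicated descendants alone; resolving such collisions needs an
independent unduplicated comparator lineage, which this generator does not
emit. The emulated history is therefore one whose boundaries are
resolvable, and the flag can be disabled to study the blind spot.

What the generator does not emulate: sequence evolution (scores are
constructed, not aligned), unassembled/unplaced genes, tandem duplication,
gene movement between CLGs, homeologous recombination between subgenomes,
rate variation among families, and assembly error. Passing tests therefore
demonstrate that the statistics recover a known macro-synteny history from
ordinal gene maps with realistic loss and rearrangement — not that any
particular real genome satisfies these assumptions.

## Problem sizes used in the checks

The acceptance suite runs 20 seeded full-genome simulations for breakpoint
and CLG-count recovery, 500 replicates for null-z calibration (10⁴
bootstrap each; closed forms checked at 10⁶), 100/1,000 replicates for the
allo/auto discrimination arms, 50 seeded mixtures of 100 values per cluster
for dip power with 3,000 uniform replicates for calibration, and exhaustive
hypergeometric enumeration for all N ≤ 25. The acceptance script analyses
one full simulated dataset and a 10-seed recovery batch.

## Known limitations

- Fusion collisions between independent lineages (above) are undetectable
  by construction; the partition then undercounts by one unit per collision.
- α/β pairing among unfused CLGs is arbitrary between pairs (the within-
  pair α/β call is still retention-ordered and is the quantity that
  matters); copy labels 1/2 are likewise conventional.
- The dip test's uniform bootstrap null makes it conservative for
  non-uniform unimodal data; at n = 100 its power against the default
  retention mixture is ≈ 0.83 at the 0.01 level, reaching ≈ 1 at n = 200
  (the scale of a full three-species cell table).
- Manual parsimony resolutions of conflicting cell orthology are out of
  scope: conflicts are flagged ambiguous and excluded from pairing rather
  than resolved.
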
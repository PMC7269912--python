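# clgkit

Macro-synteny analysis of ancestral chordate linkage groups (CLGs) and the
mechanisms of the two ancient vertebrate whole-genome duplications — with a
genome-evolution simulator that makes every stage verifiable against known
truth.

`clgkit` is for comparative genomicists who have ordered gene maps for an
unduplicated outgroup (an amphioxus-like chordate) and two or more
duplicated ingroup genomes, plus reciprocal similarity searches, and who
want to:

1. anchor conservative 1:1 orthologues by **mutual best hits**;
2. partition the outgroup into **conserved linkage groups** from the
   synteny-discontinuity statistic

   D(i, i+1) = Σ_a (X^R_a(i+1) − X^L_a(i))²,

   where x_a(i) indicates whether gene *i*'s orthologue lies on comparator
   chromosome *a* and X^L/X^R are windowed means over W = 25 genes —
   D ∈ [0, 2], spiking at synteny breakpoints;
3. test CLG–chromosome and CLG–window associations against a
   **hypergeometric null** with Bonferroni correction (whole chromosomes,
   plus 50- and 100-gene sliding windows);
4. **paint** duplicated chromosomes by local CLG ancestry in ≥ 20-gene
   windows, partition them into homogeneous blocks, and link blocks across
   species into orthologous cells;
5. compute per-cell **retention fractions** r = (families retained on the
   segment)/(CLG-defining outgroup genes), pair segments into α/β
   subgenomes by fusion concordance, and test loss asymmetry against a
   one-class null (pairs uniform on (0, c), c = 2 × mean retention;
   E[max−min] = c/3, sd = c/√18) — the signature separating
   allotetraploidy (asymmetric loss) from autotetraploidy (symmetric);
6. test bimodality of retention with **Hartigan's dip statistic**
   (implemented and oracle-validated in-package) and reject independent
   convergent β fusions with an exact perfect-matching permutation test.

A full synthetic scenario — ancestral linkage groups, lineage-specific
inversion scrambling, fusions with junction mixing, autotetraploidy (copies
1/2, symmetric loss), then allotetraploidy (subgenomes α/β, asymmetric
loss), then speciation — is generated by `clgkit.simulate` with complete
truth labels, so the whole pipeline is testable end to end without any
downloads.

## Worked example

```sh
clgkit simulate --seed 5 --out ds/
clgkit analyze ds/ --out results/
clgkit plot-data results/ --target ingroupA --out dots.tsv
```

The analyze step prints:

```
clgkit INFO orthology: 5101 anchors across 3 targets
clgkit INFO clg_inference: 5101 anchors, 3 consensus breakpoints, 17 CLGs
clgkit INFO painting: 250 blocks, 81 cells, 56 groups
analysis complete: 17 CLGs, 81 cells; results in results/
```

and `results/acceptance.json` from `python scripts/acceptance.py --seed 1`
(below), which runs the same pipeline on a seed-derived dataset, contains:

| metric | value | meaning |
| --- | --- | --- |
| clg_count | 17 | linkage groups recovered from 5,017 anchors (the number simulated) |
| breakpoint_sensitivity / precision | 1.0 / 1.0 | all outgroup fusion junctions found, none spurious, within ±1 gene |
| alpha_mean_retention_pct | 46.3 | mean retention of α segments (loss conditioned on family survival) |
| beta_mean_retention_pct | 17.8 | paralogous β segments retain less than half as much |
| asymmetry_z / p | 5.19 / 1.1e-07 | observed α−β far above the one-class null ⇒ allotetraploidy |
| dip_statistic / p | 0.086 / 1e-04 | retention distribution over 210 cells×species is bimodal |
| retention_correlation_pct | 99.5 | per-cell retention agrees across ingroup species ⇒ shared stem loss |
| fusion_concordance_p | 3.8e-04 | β segments do not repeat the α fusion pattern by chance |

Result tables (`anchors.tsv`, `clg_assignment.tsv`, `breakpoints.tsv`,
`enrichment_*.tsv`, `tiers.tsv`, `painting.tsv`, `retention.tsv`,
`dotplot.tsv`, …) are plain TSV; `manifest.json` records the configuration
hash, seed and input digests, and identical inputs + seed reproduce every
file byte for byte.

## Layout

- `clgkit.model` / `clgkit.io` — domain types, TSV/BED/GFF3 ingestion,
  deterministic result writing with a run manifest
- `clgkit.orthology` — mutual best hits, anchor sets, one-member-per-
  chromosome family counting
- `clgkit.clg` — indicator profiles, discontinuity D, breakpoints,
  consensus, segment merging into lettered CLGs
- `clgkit.enrichment` — hypergeometric upper tail, chromosome/window
  scans, significance tiers
- `clgkit.painting` — ancestry painting, block partitioning, cross-species
  cell assignment
- `clgkit.retention` / `clgkit.dip` — retention fractions, α/β
  assignment, asymmetry bootstrap test, dip test, correlations,
  fusion-concordance permutation test
- `clgkit.simulate` — the genome-evolution generator with truth labels
- `clgkit.pipeline` / `clgkit.cli` — orchestration and the `clgkit`
  command (`simulate` / `analyze` / `acceptance` / `plot-data`)

See `docs/methods.md` for the model, parameter rationale, numerical
choices, what the simulator does and does not emulate, and known
limitations.
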
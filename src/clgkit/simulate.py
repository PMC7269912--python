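"""Genome-evolution simulator with known truth labels.

The simulator realises the auto- then allotetraploidy scenario for an
ancestral genome of K linkage groups: an unduplicated outgroup lineage
accumulates within-chromosome inversions and a handful of fusions (sharp
junctions, since mixing there is off by default); the ingroup stem first
doubles by autotetraploidy (copies 1/2, symmetric Bernoulli loss per family
per copy), then undergoes fusions with junction mixing, then doubles again
by allotetraploidy (subgenomes alpha/beta, which first diverge by
independent local inversions and then lose duplicates at asymmetric rates),
and finally speciates into several terminal lineages with small independent
loss and local rearrangement. Loss is modelled per family per
chromosome-copy, so realized retention fractions directly reflect the
configured rates; a minimum number of retained copies per family (default
one, per species) is enforced by resampling the family's loss vector, which
biases realized retention upward relative to nominal rates (most strongly
when nominal rates are low) — see docs/methods.md.

Similarity scores are constructed so that true orthologues are mutual best
hits: cross-species scores within a gene family decrease with the age of
the split separating the two copies (same copy and subgenome > same copy,
other subgenome > other copy), with uniform noise smaller than the gaps
between levels. Gene order within chromosomes carries no signal beyond the
simulated rearrangement history.

Every emitted gene carries truth labels (family, linkage group, copy,
subgenome), fusion junctions are logged with their at-fusion ordinals, and
the event log records each sampled event.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .model import GeneMap, OrthogroupTable, SimilarityTable

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "SimulatedDataset",
    "simulate",
    "scramble",
    "fuse_and_mix",
    "apply_wgd",
    "write_dataset",
    "load_dataset",
]

# a simulated gene is (family, clg, copy, subgenome); chromosomes are
# (name, [gene, ...]) pairs
Gene = tuple[str, str, int, str]
Chromosome = tuple[str, list]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator.

    Retention rates are per family per chromosome-copy survival
    probabilities applied at the event where the copy arises; rates for the
    second (allo) duplication default to the asymmetric pair 0.39/0.15 and
    the first (auto) duplication is symmetric by construction.
    """

    n_clgs: int = 17
    genes_per_clg: int = 300
    size_spread: float = 0.2  # lognormal sigma of per-CLG gene counts
    outgroup_name: str = "outgroup"
    ingroup_names: tuple[str, ...] = ("ingroupA", "ingroupB", "ingroupC")
    # lineage-specific scrambling from the chordate ancestor
    lineage_scramble_inversions: int = 300
    outgroup_fusions: int = 3
    outgroup_junction_mixing: int = 0
    # first duplication (auto)
    do_1R: bool = True
    r_1R: float = 0.75
    # stem fusions between the duplications
    stem_fusions: int = 6
    stem_mixing_inversions: int = 30
    mixing_span: int = 100
    # second duplication (allo)
    do_2R: bool = True
    r_alpha: float = 0.39
    r_beta: float = 0.15
    subgenome_divergence_inversions: int = 30
    divergence_span: int = 50
    # terminal lineages
    terminal_retention: float = 0.97
    terminal_inversions: int = 20
    terminal_span: int = 50
    terminal_translocations: int = 0
    min_retained_copies: int = 1
    # when the same two linkage groups fuse independently in the outgroup and
    # on the ingroup stem, the outgroup junction becomes undetectable from
    # duplicated descendants alone (the comparators are fused there too); the
    # emulated scenario is one whose boundaries are resolvable, so the stem
    # sampler avoids re-fusing outgroup-fused pairs by default
    avoid_outgroup_refusion: bool = True
    # similarity-score construction
    ortho_score: float = 100.0
    paralog_recent_score: float = 80.0
    paralog_ancient_score: float = 70.0
    outgroup_score: float = 60.0
    score_noise: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clgs < 1:
            raise ValueError("need at least one linkage group")
        for r in (self.r_1R, self.r_alpha, self.r_beta, self.terminal_retention):
            if not (0.0 <= r <= 1.0):
                raise ValueError("retention rates must lie in [0, 1]")
        if self.min_retained_copies < 0:
            raise ValueError("min_retained_copies must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ingroup_names"] = list(self.ingroup_names)
        return d


@dataclass
class SimulatedTruth:
    genes: pd.DataFrame  # species, gene_id, family, clg, copy, subgenome, chromosome, ordinal
    junctions: pd.DataFrame  # species, chromosome, ordinal, left_clg, right_clg
    events: list


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    gene_maps: dict[str, GeneMap]
    similarities: dict[tuple[str, str], SimilarityTable]
    orthogroups: OrthogroupTable
    truth: SimulatedTruth


# ---------------------------------------------------------------------------
# elementary operations


def scramble(genes: list, n_inversions: int, rng, max_span: Optional[int] = None) -> list:
    """Apply n random interval reversals; gene content is unchanged."""
    if n_inversions < 0:
        raise ValueError("n_inversions must be >= 0")
    out = list(genes)
    n = len(out)
    if n < 2:
        return out
    for _ in range(n_inversions):
        if max_span is None:
            i, j = sorted(rng.integers(0, n, size=2))
        else:
            i = int(rng.integers(0, n))
            j = min(n - 1, i + int(rng.integers(1, max_span + 1)))
        out[i : j + 1] = out[i : j + 1][::-1]
    return out


def fuse_and_mix(
    chrom_a: list, chrom_b: list, mixing_inversions: int, rng, span: int = 100
) -> tuple[list, int]:
    """Concatenate two chromosomes and locally rearrange across the junction.

    Returns (fused gene list, junction ordinal at fusion time). With zero
    mixing the boundary stays sharp; each mixing inversion reverses an
    interval overlapping the junction with endpoints within ``span`` genes
    of it, interleaving the two ancestries locally.
    """
    fused = list(chrom_a) + list(chrom_b)
    junction = len(chrom_a)
    n = len(fused)
    for _ in range(mixing_inversions):
        left = int(rng.integers(max(0, junction - span), junction))
        right = int(rng.integers(junction, min(n, junction + span)))
        fused[left : right + 1] = fused[left : right + 1][::-1]
    return fused, junction


def _resampled_survival(probs: np.ndarray, rng, min_keep: int, max_tries: int = 1000) -> np.ndarray:
    """Bernoulli survival vector conditioned on at least ``min_keep`` survivors."""
    for _ in range(max_tries):
        keep = rng.random(len(probs)) < probs
        if keep.sum() >= min(min_keep, len(probs)):
            return keep
    # fall back: force the highest-rate copies to survive
    order = np.argsort(-probs)
    keep = np.zeros(len(probs), dtype=bool)
    keep[order[:min_keep]] = True
    return keep


def _apply_loss(
    chromosomes: list[Chromosome], rate_of, rng, min_retained: int
) -> list[Chromosome]:
    """Per-family per-gene-instance Bernoulli loss, keeping every family at
    ``min_retained`` copies genome-wide by resampling its loss vector."""
    index: dict[str, list[tuple[int, int]]] = {}
    for ci, (_, genes) in enumerate(chromosomes):
        for gi, gene in enumerate(genes):
            index.setdefault(gene[0], []).append((ci, gi))
    drop: set[tuple[int, int]] = set()
    for family in sorted(index):
        slots = index[family]
        probs = np.array([rate_of(chromosomes[ci][1][gi]) for ci, gi in slots])
        keep = _resampled_survival(probs, rng, min_retained)
        for (slot, k) in zip(slots, keep):
            if not k:
                drop.add(slot)
    out = []
    for ci, (name, genes) in enumerate(chromosomes):
        kept = [g for gi, g in enumerate(genes) if (ci, gi) not in drop]
        out.append((name, kept))
    return out


def apply_wgd(
    chromosomes: list[Chromosome],
    mode: str,
    rates: tuple[float, float],
    rng,
    min_retained: int = 1,
    divergence_inversions: int = 0,
    divergence_span: int = 50,
) -> list[Chromosome]:
    """Whole-genome duplication with duplicate loss.

    auto: both copies (labelled 1 and 2, exchangeable) share one retention
    rate. allo: the two subgenomes (alpha, beta) first diverge by
    independent local inversions, then lose duplicates at their own rates.
    """
    if mode not in ("auto", "allo"):
        raise ValueError(f"unknown WGD mode {mode!r}")
    doubled: list[Chromosome] = []
    if mode == "auto":
        for name, genes in chromosomes:
            for copy_label in (1, 2):
                new = [(f, c, copy_label, s) for (f, c, _cp, s) in genes]
                doubled.append((f"{name}-{copy_label}", new))
        r1, r2 = rates
        rate_of = lambda gene: r1 if gene[2] == 1 else r2  # noqa: E731
    else:
        for name, genes in chromosomes:
            for sub in ("alpha", "beta"):
                new = [(f, c, cp, sub) for (f, c, cp, _s) in genes]
                new = scramble(new, divergence_inversions, rng, max_span=divergence_span)
                doubled.append((f"{name}{'a' if sub == 'alpha' else 'b'}", new))
        ra, rb = rates
        rate_of = lambda gene: ra if gene[3] == "alpha" else rb  # noqa: E731
    return _apply_loss(doubled, rate_of, rng, min_retained)


# ---------------------------------------------------------------------------
# whole scenario


def _ancestor(cfg: SimulationConfig, rng) -> list[Chromosome]:
    sizes = np.maximum(
        4, np.round(cfg.genes_per_clg * rng.lognormal(0.0, cfg.size_spread, cfg.n_clgs))
    ).astype(int)
    chroms = []
    counter = 0
    for i, size in enumerate(sizes):
        clg = f"L{i + 1:02d}"
        genes = [(f"F{counter + j:05d}", clg, 0, "") for j in range(size)]
        counter += size
        chroms.append((clg, genes))
    return chroms


def _fuse_genome(
    chromosomes: list[Chromosome],
    n_fusions: int,
    mixing: int,
    span: int,
    rng,
    events: list,
    lineage: str,
    avoid_pairs: Optional[set[frozenset]] = None,
) -> tuple[list[Chromosome], list[tuple[str, int, str, str]]]:
    if 2 * n_fusions > len(chromosomes):
        raise ValueError(
            f"{lineage}: {n_fusions} fusions need {2 * n_fusions} chromosomes, "
            f"only {len(chromosomes)} available"
        )
    picks = rng.choice(len(chromosomes), size=2 * n_fusions, replace=False)
    if avoid_pairs:
        for _ in range(200):
            chosen = [
                frozenset(
                    (chromosomes[int(picks[2 * k])][1][0][1],
                     chromosomes[int(picks[2 * k + 1])][1][0][1])
                )
                for k in range(n_fusions)
            ]
            if not any(pair in avoid_pairs for pair in chosen):
                break
            picks = rng.choice(len(chromosomes), size=2 * n_fusions, replace=False)
    junctions = []
    out = [c for i, c in enumerate(chromosomes) if i not in set(picks.tolist())]
    for k in range(n_fusions):
        ia, ib = int(picks[2 * k]), int(picks[2 * k + 1])
        (na, ga), (nb, gb) = chromosomes[ia], chromosomes[ib]
        fused, junction = fuse_and_mix(ga, gb, mixing, rng, span=span)
        name = f"{na}+{nb}"
        out.append((name, fused))
        junctions.append((name, junction, ga[-1][1], gb[0][1]))
        events.append(
            {
                "lineage": lineage,
                "event": "fusion",
                "chromosomes": [na, nb],
                "junction": junction,
                "mixing_inversions": mixing,
            }
        )
    return out, junctions


def _scramble_genome(
    chromosomes: list[Chromosome], n_inv: int, span: Optional[int], rng
) -> list[Chromosome]:
    return [(name, scramble(genes, n_inv, rng, max_span=span)) for name, genes in chromosomes]


def _slot(gene: Gene) -> str:
    family, _clg, copy, sub = gene
    if copy == 0 and not sub:
        return "0"
    return f"{copy}{'a' if sub == 'alpha' else ('b' if sub == 'beta' else '')}"


def _emit_species(species: str, chromosomes: list[Chromosome]) -> tuple[GeneMap, pd.DataFrame]:
    rows = []
    truth_rows = []
    for name, genes in sorted(chromosomes, key=lambda c: c[0]):
        for ordinal, gene in enumerate(genes):
            family, clg, copy, sub = gene
            gene_id = f"{species}|{family}|{_slot(gene)}"
            rows.append((gene_id, name, (ordinal + 1) * 1000, (ordinal + 1) * 1000 + 500))
            truth_rows.append(
                (species, gene_id, family, clg, copy, sub or "none", name, ordinal)
            )
    gm = GeneMap.from_rows(species, rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "species", "gene_id", "family", "clg", "copy", "subgenome",
            "chromosome", "ordinal",
        ],
    )
    return gm, truth


def _pair_scores(
    genes_a: pd.DataFrame, genes_b: pd.DataFrame, cfg: SimulationConfig, rng, outgroup_pair: bool
) -> pd.DataFrame:
    """Within-family cross-species scores; symmetric in both directions."""
    a = genes_a[["gene_id", "family", "copy", "subgenome"]]
    b = genes_b[["gene_id", "family", "copy", "subgenome"]]
    merged = a.merge(b, on="family", suffixes=("_a", "_b"))
    if outgroup_pair:
        base = np.full(len(merged), cfg.outgroup_score)
    else:
        same_copy = merged["copy_a"] == merged["copy_b"]
        same_sub = merged["subgenome_a"] == merged["subgenome_b"]
        base = np.where(
            same_copy & same_sub,
            cfg.ortho_score,
            np.where(same_copy, cfg.paralog_recent_score, cfg.paralog_ancient_score),
        )
    noise = rng.uniform(0.0, cfg.score_noise, size=len(merged))
    return pd.DataFrame(
        {
            "query": merged["gene_id_a"],
            "subject": merged["gene_id_b"],
            "score": np.round(base - noise, 6),
        }
    )


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full scenario and emit gene maps, similarity tables,
    orthogroups and truth labels for the outgroup plus ingroup species."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    events: list[dict] = []
    ancestor = _ancestor(cfg, rng)

    # outgroup lineage: scramble within ancestral chromosomes, then fuse
    outg = _scramble_genome(ancestor, cfg.lineage_scramble_inversions, None, rng)
    outg, out_junctions = _fuse_genome(
        outg, cfg.outgroup_fusions, cfg.outgroup_junction_mixing, cfg.mixing_span,
        rng, events, cfg.outgroup_name,
    )

    # ingroup stem
    stem = _scramble_genome(ancestor, cfg.lineage_scramble_inversions, None, rng)
    if cfg.do_1R:
        stem = apply_wgd(
            stem, "auto", (cfg.r_1R, cfg.r_1R), rng, min_retained=cfg.min_retained_copies
        )
        events.append({"lineage": "stem", "event": "wgd", "mode": "auto", "rate": cfg.r_1R})
    avoid = (
        {frozenset((left, right)) for _n, _o, left, right in out_junctions}
        if cfg.avoid_outgroup_refusion
        else None
    )
    stem, stem_junctions = _fuse_genome(
        stem, cfg.stem_fusions, cfg.stem_mixing_inversions, cfg.mixing_span,
        rng, events, "stem", avoid_pairs=avoid,
    )
    if cfg.do_2R:
        stem = apply_wgd(
            stem, "allo", (cfg.r_alpha, cfg.r_beta), rng,
            min_retained=cfg.min_retained_copies,
            divergence_inversions=cfg.subgenome_divergence_inversions,
            divergence_span=cfg.divergence_span,
        )
        events.append(
            {
                "lineage": "stem", "event": "wgd", "mode": "allo",
                "rates": [cfg.r_alpha, cfg.r_beta],
            }
        )

    # terminal lineages
    genomes: dict[str, list[Chromosome]] = {cfg.outgroup_name: outg}
    for species in cfg.ingroup_names:
        g = [(name, list(genes)) for name, genes in stem]
        if cfg.terminal_retention < 1.0:
            g = _apply_loss(
                g, lambda _gene: cfg.terminal_retention, rng, cfg.min_retained_copies
            )
        g = _scramble_genome(g, cfg.terminal_inversions, cfg.terminal_span, rng)
        for _ in range(cfg.terminal_translocations):
            g = _translocate(g, rng, events, species)
        g = [(name, genes) for name, genes in g if genes]
        genomes[species] = g
        events.append({"lineage": species, "event": "terminal_divergence"})

    # emission
    gene_maps: dict[str, GeneMap] = {}
    truth_frames = []
    for species, genome in genomes.items():
        gm, truth = _emit_species(species, genome)
        gene_maps[species] = gm
        truth_frames.append(truth)
    truth_genes = pd.concat(truth_frames, ignore_index=True)

    junction_rows = [
        (cfg.outgroup_name, name, ordinal, left, right)
        for name, ordinal, left, right in out_junctions
    ] + [("stem", name, ordinal, left, right) for name, ordinal, left, right in stem_junctions]
    junctions = pd.DataFrame(
        junction_rows, columns=["species", "chromosome", "ordinal", "left_clg", "right_clg"]
    )

    orthogroups = OrthogroupTable(
        truth_genes[["family", "species", "gene_id"]].rename(columns={"family": "family_id"})
    )

    similarities: dict[tuple[str, str], SimilarityTable] = {}
    species_list = [cfg.outgroup_name] + list(cfg.ingroup_names)
    truth_by_species = {sp: df for sp, df in truth_genes.groupby("species")}
    for i, sa in enumerate(species_list):
        for sb in species_list[i + 1 :]:
            outgroup_pair = cfg.outgroup_name in (sa, sb)
            scores = _pair_scores(
                truth_by_species[sa], truth_by_species[sb], cfg, rng, outgroup_pair
            )
            similarities[(sa, sb)] = SimilarityTable(sa, sb, scores)
            rev = scores.rename(columns={"query": "subject", "subject": "query"})
            similarities[(sb, sa)] = SimilarityTable(
                sb, sa, rev[["query", "subject", "score"]]
            )

    truth = SimulatedTruth(truth_genes, junctions, events)
    return SimulatedDataset(cfg, gene_maps, similarities, orthogroups, truth)


def _translocate(
    chromosomes: list[Chromosome], rng, events: list, lineage: str
) -> list[Chromosome]:
    """Move a random gene interval from one chromosome into another."""
    eligible = [i for i, (_, g) in enumerate(chromosomes) if len(g) >= 10]
    if len(eligible) < 2:
        return chromosomes
    src, dst = rng.choice(eligible, size=2, replace=False)
    out = [(n, list(g)) for n, g in chromosomes]
    name_s, genes_s = out[src]
    n = len(genes_s)
    start = int(rng.integers(0, n - 5))
    end = min(n, start + int(rng.integers(5, max(6, n // 4))))
    moved = genes_s[start:end]
    out[src] = (name_s, genes_s[:start] + genes_s[end:])
    name_d, genes_d = out[dst]
    at = int(rng.integers(0, len(genes_d) + 1))
    out[dst] = (name_d, genes_d[:at] + moved + genes_d[at:])
    events.append(
        {
            "lineage": lineage, "event": "translocation",
            "from": name_s, "to": name_d, "n_genes": len(moved),
        }
    )
    return out


# ---------------------------------------------------------------------------
# on-disk dataset


def write_dataset(dataset: SimulatedDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    for species, gm in dataset.gene_maps.items():
        cio.write_gene_map(gm, out / f"genes_{species}.tsv")
    for (sa, sb), table in dataset.similarities.items():
        cio.write_similarity(table, out / f"similarity_{sa}__{sb}.tsv")
    cio.write_orthogroups(dataset.orthogroups, out / "orthogroups.tsv")
    dataset.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    dataset.truth.junctions.to_csv(out / "truth_junctions.tsv", sep="\t", index=False)
    (out / "events.json").write_text(json.dumps(dataset.truth.events, indent=2) + "\n")
    meta = {
        "outgroup": cfg.outgroup_name,
        "ingroups": list(cfg.ingroup_names),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
    }
    (out / "dataset.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_dataset(dataset_dir):
    """Read a simulated (or identically laid out real) dataset directory.

    Returns (gene_maps, similarities, orthogroups, meta).
    """
    d = Path(dataset_dir)
    meta = yaml.safe_load((d / "dataset.yaml").read_text())
    species = [meta["outgroup"]] + list(meta["ingroups"])
    gene_maps = {
        sp: cio.read_gene_map(d / f"genes_{sp}.tsv", "tsv", species=sp) for sp in species
    }
    similarities = {}
    for path in sorted(d.glob("similarity_*__*.tsv")):
        sa, sb = path.stem[len("similarity_") :].split("__")
        similarities[(sa, sb)] = cio.read_similarity(path, sa, sb)
    orthogroups = cio.read_orthogroups(d / "orthogroups.tsv")
    return gene_maps, similarities, orthogroups, meta
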
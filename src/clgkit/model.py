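"""Shared domain types for the macro-synteny / linkage-group analyses.

All statistics in this package operate on *gene ordinals*: the 0-based rank of
a gene along its chromosome. Base-pair coordinates, when present, are carried
only for display. Segments are half-open on ordinals. Classical synteny —
physical linkage without regard to gene order or orientation — is the working
notion throughout, so strand is ignored everywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneMap",
    "SimilarityTable",
    "OrthologyTable",
    "OrthogroupTable",
    "Segment",
    "AnalysisConfig",
]


GENE_MAP_COLUMNS = ["gene_id", "chromosome", "ordinal", "bp_start", "bp_end"]


@dataclass(frozen=True)
class GeneMap:
    """Ordered gene positions on the chromosomes of one species.

    ``records`` has columns gene_id, chromosome, ordinal, bp_start, bp_end
    (the bp columns may be all-NA). Ordinals are 0-based and consecutive
    within each chromosome, and gene_ids are unique within the species.
    """

    species: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in GENE_MAP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"gene map missing columns {missing}")
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(
                f"duplicate gene_id in species {self.species!r}: {dup.iloc[0]!r}"
            )
        for chrom, sub in df.groupby("chromosome", sort=False):
            ords = np.asarray(sub["ordinal"])
            if not np.array_equal(np.sort(ords), np.arange(len(ords))):
                raise ValueError(
                    f"ordinals on {self.species}:{chrom} are not 0..n-1"
                )

    @classmethod
    def from_rows(
        cls,
        species: str,
        rows: Iterable[tuple],
    ) -> "GeneMap":
        """Build from (gene_id, chromosome, bp_start[, bp_end]) rows.

        Ordinals are assigned by sorting on (chromosome, bp_start, gene_id);
        ties in bp_start fall back to lexicographic gene_id order.
        """
        recs = []
        for row in rows:
            gene_id, chrom, bp_start = row[0], row[1], row[2]
            bp_end = row[3] if len(row) > 3 else None
            recs.append((str(gene_id), str(chrom), bp_start, bp_end))
        df = pd.DataFrame(recs, columns=["gene_id", "chromosome", "bp_start", "bp_end"])
        df = df.sort_values(
            ["chromosome", "bp_start", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        df["ordinal"] = df.groupby("chromosome", sort=False).cumcount()
        return cls(species, df[GENE_MAP_COLUMNS])

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.records["chromosome"]))

    def chromosome_size(self, chromosome: str) -> int:
        return int((self.records["chromosome"] == chromosome).sum())

    def genes_on(self, chromosome: str) -> pd.DataFrame:
        sub = self.records[self.records["chromosome"] == chromosome]
        return sub.sort_values("ordinal")

    def position_index(self) -> pd.DataFrame:
        """gene_id-indexed frame with chromosome and ordinal columns."""
        return self.records.set_index("gene_id")[["chromosome", "ordinal"]]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SimilarityTable:
    """Directed similarity hits (query, subject, score); bitscore-like, higher
    is better. No duplicate (query, subject) pairs; scores finite."""

    species_from: str
    species_to: str
    hits: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.hits
        for col in ("query", "subject", "score"):
            if col not in df.columns:
                raise ValueError(f"similarity table missing column {col!r}")
        if df.duplicated(["query", "subject"]).any():
            raise ValueError("duplicate (query, subject) pair in similarity table")
        scores = np.asarray(df["score"], dtype=float)
        if len(scores) and not np.isfinite(scores).all():
            raise ValueError("non-finite similarity score")


@dataclass(frozen=True)
class OrthologyTable:
    """1:1 orthologue pairs between two species (mutual best hits)."""

    species_a: str
    species_b: str
    pairs: pd.DataFrame  # columns gene_a, gene_b

    def __post_init__(self) -> None:
        df = self.pairs
        for col in ("gene_a", "gene_b"):
            if col not in df.columns:
                raise ValueError(f"orthology table missing column {col!r}")
            if df[col].duplicated().any():
                raise ValueError("gene appears in more than one orthologue pair")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    def transpose(self) -> "OrthologyTable":
        df = self.pairs.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
        return OrthologyTable(self.species_b, self.species_a, df[["gene_a", "gene_b"]])


@dataclass(frozen=True)
class OrthogroupTable:
    """Gene families across species: family_id -> set of (species, gene_id).

    Each gene belongs to at most one family.
    """

    members: pd.DataFrame  # columns family_id, species, gene_id

    def __post_init__(self) -> None:
        df = self.members
        for col in ("family_id", "species", "gene_id"):
            if col not in df.columns:
                raise ValueError(f"orthogroup table missing column {col!r}")
        if df.duplicated(["species", "gene_id"]).any():
            raise ValueError("gene assigned to more than one family")

    def families(self) -> Mapping[str, set[tuple[str, str]]]:
        out: dict[str, set[tuple[str, str]]] = {}
        for fam, sub in self.members.groupby("family_id", sort=False):
            out[fam] = set(zip(sub["species"], sub["gene_id"]))
        return out

    def family_of(self, species: str) -> pd.Series:
        """gene_id -> family_id for one species."""
        sub = self.members[self.members["species"] == species]
        return pd.Series(sub["family_id"].values, index=sub["gene_id"].values)


@dataclass(frozen=True)
class Segment:
    """Half-open run of gene ordinals on one chromosome."""

    species: str
    chromosome: str
    start: int  # inclusive ordinal
    end: int  # exclusive ordinal
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad segment bounds [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, ordinal: int) -> bool:
        return self.start <= ordinal < self.end


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    window_W
        Gene-count window for the synteny discontinuity statistic D.
    paint_min_window
        Minimum genes per window when painting chromosomes by ancestry,
        and the minimum gap between iterative block breakpoints.
    enrich_windows
        Sliding-window sizes (genes) for hypergeometric enrichment scans.
    peak_threshold
        Minimum D value for a local peak to be called a breakpoint; D lies
        in [0, 2], and 0.5 corresponds to a 50% composition switch.
    merge_cosine
        Cosine-similarity threshold above which segments are combined into
        one syntenic unit. Two distinct linkage groups that were co-fused
        before the second genome duplication share exactly half of their
        residence chromosomes, which pins their profile cosine at 0.5;
        the default sits in the gap between that and ~1 for same-group
        segments.
    min_breakpoint_support
        Number of comparator species that must independently support a
        consensus breakpoint.
    alpha_levels
        Significance levels reported on Bonferroni-corrected p values.
    bootstrap_reps
        Replicates for the asymmetry-test null bootstrap.
    dip_bootstrap
        Replicates for the dip-test uniform bootstrap null.
    seed
        Single integer from which all stochastic operations derive.
    """

    window_W: int = 25
    paint_min_window: int = 20
    enrich_windows: tuple[int, ...] = (50, 100)
    peak_threshold: float = 0.5
    min_separation: Optional[int] = None  # defaults to window_W
    merge_cosine: float = 0.75
    min_breakpoint_support: int = 2
    alpha_levels: tuple[float, ...] = (0.05, 0.01)
    bootstrap_reps: int = 1_000_000
    dip_bootstrap: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_W < 2 or self.paint_min_window < 2:
            raise ValueError("windows must be >= 2")
        if any(w < 2 for w in self.enrich_windows):
            raise ValueError("enrichment windows must be >= 2")
        if not (0.0 < self.peak_threshold <= 2.0):
            raise ValueError("peak_threshold must lie in (0, 2]")
        if self.bootstrap_reps < 1 or self.dip_bootstrap < 1:
            raise ValueError("bootstrap replicate counts must be >= 1")

    @property
    def separation(self) -> int:
        return self.window_W if self.min_separation is None else self.min_separation

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enrich_windows"] = list(self.enrich_windows)
        d["alpha_levels"] = list(self.alpha_levels)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        kwargs = dict(d)
        if "enrich_windows" in kwargs:
            kwargs["enrich_windows"] = tuple(kwargs["enrich_windows"])
        if "alpha_levels" in kwargs:
            kwargs["alpha_levels"] = tuple(kwargs["alpha_levels"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)
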
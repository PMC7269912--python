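"""Reading and writing of gene maps, similarity/orthology tables and results.

TSV is the canonical interchange dialect; BED and GFF3 ingestion are
conveniences mapped onto it. All writers are deterministic: identical inputs
and seed produce byte-identical files, and each result set carries a manifest
recording the configuration hash and input digests so that reruns can detect
drift.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .model import (
    GENE_MAP_COLUMNS,
    AnalysisConfig,
    GeneMap,
    OrthogroupTable,
    OrthologyTable,
    SimilarityTable,
)

logger = logging.getLogger("clgkit")

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# gene maps


def read_gene_map(path: PathLike, fmt: str = "tsv", species: Optional[str] = None) -> GeneMap:
    """Read a gene map in ``tsv``, ``bed`` or ``gff3-genes`` dialect.

    tsv: species, chromosome, bp_start, gene_id (tab-separated, '#' comments).
    bed: chrom, start, end, name.
    gff3-genes: standard GFF3; only ``gene`` features are used and the gene
    id is taken from the ID attribute.

    Ordinals are assigned by sorting on (chromosome, bp_start, gene_id).
    """
    path = Path(path)
    rows: list[tuple] = []
    sp = species
    if fmt == "tsv":
        for line in _data_lines(path):
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: expected 4 columns, got {len(parts)}")
            sp = sp or parts[0]
            rows.append((parts[3], parts[1], _int(parts[2], path), None))
    elif fmt == "bed":
        for line in _data_lines(path):
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: BED needs chrom,start,end,name")
            rows.append((parts[3], parts[0], _int(parts[1], path), _int(parts[2], path)))
    elif fmt == "gff3-genes":
        for line in _data_lines(path):
            parts = line.split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise ValueError(f"{path}: gene feature without ID attribute")
            rows.append((gene_id, parts[0], _int(parts[3], path), _int(parts[4], path)))
    else:
        raise ValueError(f"unknown gene-map format {fmt!r}")
    if sp is None:
        sp = path.stem
    if not rows:
        warnings.warn(f"empty gene map {path}", stacklevel=2)
        empty = pd.DataFrame(columns=GENE_MAP_COLUMNS)
        return GeneMap(sp, empty)
    return GeneMap.from_rows(sp, rows)


def write_gene_map(gene_map: GeneMap, path: PathLike) -> None:
    """Write the canonical 4-column TSV (species, chromosome, bp_start, gene_id)."""
    df = gene_map.records.copy()
    bp = df["bp_start"]
    # fall back to ordinal-derived coordinates so the file round-trips
    df["bp_start"] = np.where(bp.isna(), (df["ordinal"] + 1) * 1000, bp).astype(int)
    out = pd.DataFrame(
        {
            "species": gene_map.species,
            "chromosome": df["chromosome"],
            "bp_start": df["bp_start"],
            "gene_id": df["gene_id"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# similarity / orthology / orthogroups


def read_similarity(
    path: PathLike, species_from: str = "", species_to: str = ""
) -> SimilarityTable:
    """Read a similarity table: 3-column TSV (query, subject, score) or
    12-column tabular alignment output (columns 1, 2 and 12 used).

    Lines beginning '#' are skipped. Duplicate (query, subject) pairs are
    collapsed keeping the maximum score.
    """
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 12:
            q, s, score_text = parts[0], parts[1], parts[11]
        elif len(parts) >= 3:
            q, s, score_text = parts[0], parts[1], parts[2]
        else:
            raise ValueError(f"{path}:{lineno}: expected >=3 columns")
        try:
            score = float(score_text)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-numeric score {score_text!r}"
            ) from None
        rows.append((q, s, score))
    df = pd.DataFrame(rows, columns=["query", "subject", "score"])
    df = (
        df.groupby(["query", "subject"], as_index=False, sort=False)["score"].max()
    )
    return SimilarityTable(species_from, species_to, df)


def write_similarity(table: SimilarityTable, path: PathLike) -> None:
    table.hits.to_csv(path, sep="\t", index=False, header=False)


def read_orthology(path: PathLike, species_a: str = "", species_b: str = "") -> OrthologyTable:
    df = pd.read_csv(
        path, sep="\t", names=["gene_a", "gene_b"], comment="#", dtype=str
    )
    return OrthologyTable(species_a, species_b, df)


def write_orthology(table: OrthologyTable, path: PathLike) -> None:
    table.pairs.to_csv(path, sep="\t", index=False, header=False)


def read_orthogroups(path: PathLike) -> OrthogroupTable:
    df = pd.read_csv(
        path, sep="\t", names=["family_id", "species", "gene_id"], comment="#", dtype=str
    )
    return OrthogroupTable(df)


def write_orthogroups(table: OrthogroupTable, path: PathLike) -> None:
    table.members.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# config

def load_config(path: PathLike) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_dict(data)


def save_config(config: AnalysisConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# results

def file_digest(path: PathLike) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: PathLike,
    config: AnalysisConfig,
    seed: int,
    inputs: Optional[Mapping[str, PathLike]] = None,
    extra: Optional[Mapping] = None,
) -> list[Path]:
    """Write result tables as TSVs with a run manifest.

    The manifest records the configuration (and its hash), the seed and
    sha256 digests of the input files; it deliberately contains no
    wall-clock information so that identical runs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        df = tables[name]
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": config_hash(config),
        "seed": int(seed),
        "inputs": {
            name: file_digest(p) for name, p in sorted((inputs or {}).items())
        },
        "tables": [p.name for p in written],
        "notes": {
            "unplaced_genes": "genes not assigned to a chromosome are excluded "
            "from all counts and denominators",
        },
    }
    if extra:
        manifest["extra"] = json.loads(json.dumps(extra, sort_keys=True))
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written


# ---------------------------------------------------------------------------
# helpers

def _data_lines(path: Path):
    for line in path.read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        yield line


def _int(text: str, path: Path) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(f"{path}: bad integer coordinate {text!r}") from None
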
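"""Readers and writers for every external file the pipeline touches.

All tabular formats are tab-separated UTF-8 with ``#`` comment lines
skipped.  Gene identifiers are treated as opaque case-sensitive strings;
drug names are matched case-insensitively after trimming.  Readers validate
strictly and normalize (dedup, sort) so their output is independent of
input row order; every writer round-trips through its reader.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .connectivity import DrugInstanceProfile, TherapeuticResult
from .enrichment import PathwayDB
from .evaluation import Benchmark, rank_drugs
from .expression import ExpressionMatrix, PhenotypeTable
from .network import TissueNetwork

logger = logging.getLogger(__name__)

PathLike = Union[str, os.PathLike]


@dataclass(frozen=True)
class InstanceManifest:
    """Instance id -> (drug name, optional cell line); ids are unique."""

    rows: tuple[tuple[str, str, Optional[str]], ...]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate instance ids in manifest")

    @property
    def instance_ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    def drug_of(self, instance_id: str) -> str:
        for iid, drug, _ in self.rows:
            if iid == instance_id:
                return drug
        raise KeyError(instance_id)


def _read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False, **kwargs)


# ---------------------------------------------------------------- expression

def read_phenotype(path: PathLike) -> PhenotypeTable:
    df = _read_tsv(path)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: phenotype file needs columns "
                         "'sample_id' and 'group'")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample id(s) {dups}")
    return PhenotypeTable(groups=dict(zip(df["sample_id"], df["group"])))


def read_expression(path: PathLike, phenotype_path: PathLike) -> ExpressionMatrix:
    """Expression TSV (gene-id first column, sample-id header) plus a
    phenotype TSV assigning every sample column to tumor/control.

    Rows sharing a gene id are averaged; blank gene ids are dropped.
    """
    phenotype = read_phenotype(phenotype_path)
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expression file needs a gene column and "
                         "at least one sample column")
    gene_col = df.columns[0]
    samples = list(df.columns[1:])
    missing = [s for s in samples if s not in phenotype.groups]
    if missing:
        raise ValueError(f"{path}: sample(s) {missing} absent from the "
                         "phenotype table")
    values = pd.DataFrame(index=df.index)
    for s in samples:
        try:
            values[s] = df[s].astype(float)
        except ValueError:
            bad = df.loc[pd.to_numeric(df[s], errors="coerce").isna(), gene_col]
            raise ValueError(
                f"{path}: non-numeric value in column {s!r}, "
                f"row(s) for gene(s) {bad.tolist()[:5]}"
            ) from None
    values[gene_col] = df[gene_col].str.strip()
    n_blank = (values[gene_col] == "").sum()
    if n_blank:
        logger.warning("%s: dropped %d row(s) with blank gene id", path, n_blank)
        values = values[values[gene_col] != ""]
    if values.empty:
        raise ValueError(f"{path}: no usable expression rows")
    # probes mapping to the same gene are averaged
    collapsed = values.groupby(gene_col, sort=True)[samples].mean()
    return ExpressionMatrix(genes=list(collapsed.index),
                            samples=samples,
                            values=collapsed.to_numpy(),
                            groups=phenotype)


def write_expression(matrix: ExpressionMatrix, path: PathLike,
                     phenotype_path: PathLike) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.samples)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    ph = pd.DataFrame(
        {"sample_id": matrix.samples,
         "group": [matrix.groups.groups[s] for s in matrix.samples]}
    )
    ph.to_csv(phenotype_path, sep="\t", index=False)


# ----------------------------------------------------------------- gene sets

def read_gmt(path: PathLike, background: Optional[Iterable[str]] = None) -> PathwayDB:
    """Standard GMT: pathway name, description, member genes, tab-separated."""
    pathways: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 "description and at least one gene")
            name = fields[0]
            if name in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway "
                                 f"name {name!r}")
            pathways[name] = set(g for g in fields[2:] if g)
    if not pathways:
        logger.warning("%s: empty GMT file", path)
        return PathwayDB(pathways={}, universe=frozenset(background or ()))
    return PathwayDB.build(pathways, background=background)


def write_gmt(db: PathwayDB, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(db.pathways):
            genes = sorted(db.pathways[pid])
            fh.write("\t".join([pid, "na"] + genes) + "\n")


def read_seed_genes(path: PathLike) -> frozenset[str]:
    """One gene id per line; blanks and '#' comments skipped."""
    seeds = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                seeds.add(g)
    if not seeds:
        raise ValueError(f"{path}: no seed genes")
    return frozenset(seeds)


def write_seed_genes(seeds: Iterable[str], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(seeds):
            fh.write(g + "\n")


# ------------------------------------------------------------------- network

def read_network(path: PathLike) -> TissueNetwork:
    """Edge list TSV with columns gene_a, gene_b, confidence in [0, 1]."""
    df = _read_tsv(path)
    if not {"gene_a", "gene_b", "confidence"} <= set(df.columns):
        raise ValueError(f"{path}: network file needs columns gene_a, "
                         "gene_b, confidence")
    conf = df["confidence"].astype(float)
    return TissueNetwork.from_edges(zip(df["gene_a"], df["gene_b"], conf))


def write_network(net: TissueNetwork, path: PathLike) -> None:
    rows = net.edge_list()
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]).to_csv(
        path, sep="\t", index=False)


# ------------------------------------------------------------ drug instances

def read_manifest(path: PathLike) -> InstanceManifest:
    df = _read_tsv(path)
    if not {"instance_id", "drug_name"} <= set(df.columns):
        raise ValueError(f"{path}: manifest needs columns instance_id and "
                         "drug_name")
    cell = df["cell_line"] if "cell_line" in df.columns else [""] * len(df)
    rows = tuple(
        (iid, drug, (cl or None))
        for iid, drug, cl in zip(df["instance_id"], df["drug_name"], cell)
    )
    return InstanceManifest(rows=rows)


def read_drug_instances(profile_dir: PathLike,
                        manifest_path: PathLike) -> list[DrugInstanceProfile]:
    """One ``<instance_id>.tsv`` (columns gene, value) per manifest row.

    Each profile is ranked descending by value with lexicographic
    tie-breaking; a duplicate gene within an instance is an error.
    """
    manifest = read_manifest(manifest_path)
    if not manifest.rows:
        logger.warning("%s: empty manifest; no drug instances", manifest_path)
        return []
    profile_dir = Path(profile_dir)
    profiles = []
    for iid, drug, cell_line in manifest.rows:
        fpath = profile_dir / f"{iid}.tsv"
        if not fpath.exists():
            raise FileNotFoundError(
                f"instance {iid!r} listed in manifest but {fpath} is missing")
        df = _read_tsv(fpath)
        if not {"gene", "value"} <= set(df.columns):
            raise ValueError(f"{fpath}: instance file needs columns gene "
                             "and value")
        if df["gene"].duplicated().any():
            dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"{fpath}: duplicate gene(s) {dups[:5]} within "
                             "instance")
        values = dict(zip(df["gene"], df["value"].astype(float)))
        profiles.append(DrugInstanceProfile.from_values(
            iid, drug, values, cell_line=cell_line))
    return profiles


def write_drug_instances(profiles: Sequence[DrugInstanceProfile],
                         profile_dir: PathLike,
                         manifest_path: PathLike) -> None:
    profile_dir = Path(profile_dir)
    profile_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for prof in profiles:
        rows.append({"instance_id": prof.instance_id,
                     "drug_name": prof.drug_name,
                     "cell_line": prof.cell_line or ""})
        df = pd.DataFrame({"gene": list(prof.ranked_genes),
                           "value": [prof.value[g] for g in prof.ranked_genes]})
        df.to_csv(profile_dir / f"{prof.instance_id}.tsv", sep="\t",
                  index=False)
    pd.DataFrame(rows, columns=["instance_id", "drug_name", "cell_line"]
                 ).to_csv(manifest_path, sep="\t", index=False)


# ----------------------------------------------------------------- benchmark

def read_benchmark(path: PathLike) -> Benchmark:
    df = _read_tsv(path)
    if not {"drug_name", "evidence"} <= set(df.columns):
        raise ValueError(f"{path}: benchmark needs columns drug_name and "
                         "evidence")
    return Benchmark(evidence=dict(zip(df["drug_name"], df["evidence"])))


def write_benchmark(bench: Benchmark, path: PathLike) -> None:
    rows = sorted(bench.evidence.items())
    pd.DataFrame(rows, columns=["drug_name", "evidence"]).to_csv(
        path, sep="\t", index=False)


# ------------------------------------------------------------ ranked results

def write_ranked_drugs(results: Sequence[TherapeuticResult],
                       benchmark: Optional[Benchmark],
                       path: PathLike) -> None:
    """Ranked drug table: rank, drug_name, k, TS, abs_TS, evidence.

    Evidence is looked up in the benchmark when one is given, 'NA'
    otherwise.
    """
    ranked = rank_drugs(results)
    rows = []
    for rank, res in enumerate(ranked, start=1):
        evidence = benchmark.get(res.drug_name) if benchmark is not None else "NA"
        rows.append({"rank": rank, "drug_name": res.drug_name, "k": res.k,
                     "TS": f"{res.ts:.10g}", "abs_TS": f"{abs(res.ts):.10g}",
                     "evidence": evidence})
    pd.DataFrame(rows, columns=["rank", "drug_name", "k", "TS", "abs_TS",
                                "evidence"]).to_csv(path, sep="\t", index=False)


def read_ranked_drugs(path: PathLike) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("rank", "k"):
        df[col] = df[col].astype(int)
    for col in ("TS", "abs_TS"):
        df[col] = df[col].astype(float)
    return df
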
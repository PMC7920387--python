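"""Synthetic pipeline inputs with planted ground truth.

The generator emulates the structure of the real study inputs at desk
scale: a tumor/control expression matrix whose differential genes are
concentrated in designated pathways and in a dense seed-anchored network
module; a drug library in which each instance's differential values are a
scaled, noisy *negative* of the planted disease profile (positive reversal
strength = therapeutic pattern, negative = mimicking); and a benchmark
derived from the planted truth.  Everything is a deterministic function of
``rng_seed``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import io_formats
from .connectivity import DrugInstanceProfile
from .enrichment import PathwayDB
from .evaluation import Benchmark
from .expression import ExpressionMatrix, PhenotypeTable
from .network import TissueNetwork

logger = logging.getLogger(__name__)


def _default_strengths() -> dict[str, float]:
    """Five reversal drugs, fifteen inert drugs."""
    strengths = {f"drug-{i:02d}": 0.9 for i in range(1, 6)}
    strengths.update({f"drug-{i:02d}": 0.0 for i in range(6, 21)})
    return strengths


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults give a ~500-gene, 20-drug study.

    ``effect_size`` is the planted logFC magnitude (log2 units) of
    differential genes; ``noise_sd`` the sd of the Gaussian noise added to
    drug differential values; ``expr_noise_sd`` the per-sample log2
    expression noise.  ``reversal_strengths`` maps each drug to a strength
    in [-1, 1]: positive drugs reverse the disease profile, negative drugs
    mimic it, zero drugs are pure noise.
    """

    n_genes: int = 500
    n_tumor: int = 25
    n_control: int = 15
    n_pathways: int = 5
    pathway_size: int = 20
    n_decoy_pathways: int = 5
    n_seed_genes: int = 8
    module_edge_prob: float = 0.7
    background_edge_prob: float = 0.01
    effect_size: float = 2.0
    noise_sd: float = 0.2
    expr_noise_sd: float = 0.3
    n_drugs: int = 20
    k_instances: int = 3
    reversal_strengths: Mapping[str, float] = field(
        default_factory=_default_strengths)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tumor", "n_control", "n_pathways",
                     "pathway_size", "n_seed_genes", "n_drugs", "k_instances"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("module_edge_prob", "background_edge_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.reversal_strengths) != self.n_drugs:
            raise ValueError("reversal_strengths must name every drug "
                             f"({self.n_drugs} expected, "
                             f"{len(self.reversal_strengths)} given)")
        for d, s in self.reversal_strengths.items():
            if not -1.0 <= s <= 1.0:
                raise ValueError(f"strength of {d!r} outside [-1, 1]")
        n_planted = self.n_pathways * self.pathway_size
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted genes ({n_planted}) exceed n_genes ({self.n_genes})")
        if self.n_seed_genes > n_planted:
            raise ValueError("more seed genes than planted genes")


@dataclass(frozen=True)
class GroundTruth:
    planted_up: frozenset[str]
    planted_down: frozenset[str]
    therapeutic_drugs: frozenset[str]
    enriched_pathways: frozenset[str]


@dataclass(frozen=True)
class SimulatedData:
    matrix: ExpressionMatrix
    seeds: frozenset[str]
    network: TissueNetwork
    db: PathwayDB
    profiles: tuple[DrugInstanceProfile, ...]
    benchmark: Benchmark
    truth: GroundTruth


def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Generate all five pipeline inputs plus the planted truth."""
    rng = np.random.default_rng(config.rng_seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]

    # --- planted differential genes, organized into pathway blocks
    n_planted = config.n_pathways * config.pathway_size
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)
    planted = [genes[i] for i in planted_idx]
    half = config.pathway_size // 2
    pathways: dict[str, list[str]] = {}
    planted_up: set[str] = set()
    planted_down: set[str] = set()
    for p in range(config.n_pathways):
        block = planted[p * config.pathway_size:(p + 1) * config.pathway_size]
        pathways[f"PW{p + 1:02d}"] = block
        planted_up.update(block[:half])
        planted_down.update(block[half:])

    # decoy pathways from non-planted genes
    others = sorted(set(genes) - set(planted))
    for d in range(config.n_decoy_pathways):
        picked = rng.choice(len(others), size=config.pathway_size,
                            replace=False)
        pathways[f"DECOY{d + 1:02d}"] = [others[i] for i in picked]

    # --- seed genes live inside the planted module
    seed_idx = rng.choice(n_planted, size=config.n_seed_genes, replace=False)
    seeds = frozenset(planted[i] for i in seed_idx)

    # --- expression: log2-scale baseline + planted tumor shift
    n_samples = config.n_tumor + config.n_control
    samples = ([f"T{i:02d}" for i in range(config.n_tumor)]
               + [f"C{i:02d}" for i in range(config.n_control)])
    groups = PhenotypeTable(groups={
        **{s: "tumor" for s in samples[:config.n_tumor]},
        **{s: "control" for s in samples[config.n_tumor:]},
    })
    base = rng.uniform(4.0, 8.0, size=config.n_genes)
    log2_expr = base[:, None] + rng.normal(
        0.0, config.expr_noise_sd, size=(config.n_genes, n_samples))
    ideal_logfc = np.zeros(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in planted_up:
        ideal_logfc[gene_pos[g]] = config.effect_size
    for g in planted_down:
        ideal_logfc[gene_pos[g]] = -config.effect_size
    log2_expr[:, :config.n_tumor] += ideal_logfc[:, None]
    matrix = ExpressionMatrix(genes=genes, samples=samples,
                              values=np.power(2.0, log2_expr), groups=groups)

    # --- network: dense planted module, sparse background
    module = sorted(set(planted) | seeds)
    module_pos = {g: i for i, g in enumerate(module)}
    edges: list[tuple[str, str, float]] = []
    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            if rng.random() < config.module_edge_prob:
                edges.append((module[i], module[j],
                              float(rng.uniform(0.4, 1.0))))
    module_set = set(module)
    all_sorted = sorted(genes)
    for i in range(len(all_sorted)):
        gi = all_sorted[i]
        for j in range(i + 1, len(all_sorted)):
            gj = all_sorted[j]
            if gi in module_set and gj in module_set:
                continue
            if rng.random() < config.background_edge_prob:
                edges.append((gi, gj, float(rng.uniform(0.05, 0.95))))
    network = TissueNetwork.from_edges(edges)

    # --- drug instance profiles: noisy negatives of the planted profile
    drug_names = sorted(config.reversal_strengths)
    profiles: list[DrugInstanceProfile] = []
    for drug in drug_names:
        strength = config.reversal_strengths[drug]
        for j in range(config.k_instances):
            values = (-strength * ideal_logfc
                      + rng.normal(0.0, config.noise_sd, size=config.n_genes))
            profiles.append(DrugInstanceProfile.from_values(
                f"{drug}-inst{j + 1}", drug,
                dict(zip(genes, values.tolist()))))

    # --- benchmark derived from the planted truth
    therapeutic = frozenset(d for d, s in config.reversal_strengths.items()
                            if s > 0)
    benchmark = Benchmark(evidence={
        d: ("inferred" if d in therapeutic else "NA") for d in drug_names})

    truth = GroundTruth(
        planted_up=frozenset(planted_up),
        planted_down=frozenset(planted_down),
        therapeutic_drugs=therapeutic,
        enriched_pathways=frozenset(f"PW{p + 1:02d}"
                                    for p in range(config.n_pathways)),
    )
    return SimulatedData(
        matrix=matrix, seeds=seeds, network=network,
        db=PathwayDB.build(pathways), profiles=tuple(profiles),
        benchmark=benchmark, truth=truth,
    )


def write_fixture(data: SimulatedData, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write every simulated object in the pipeline's file dialects so the
    CLI can be driven end-to-end from files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "phenotype": out / "phenotype.tsv",
        "seeds": out / "seeds.txt",
        "network": out / "network.tsv",
        "gmt": out / "pathways.gmt",
        "profiles_dir": out / "drug_profiles",
        "manifest": out / "manifest.tsv",
        "benchmark": out / "benchmark.tsv",
        "truth": out / "truth.tsv",
    }
    io_formats.write_expression(data.matrix, paths["expression"],
                                paths["phenotype"])
    io_formats.write_seed_genes(data.seeds, paths["seeds"])
    io_formats.write_network(data.network, paths["network"])
    io_formats.write_gmt(data.db, paths["gmt"])
    io_formats.write_drug_instances(data.profiles, paths["profiles_dir"],
                                    paths["manifest"])
    io_formats.write_benchmark(data.benchmark, paths["benchmark"])
    rows = ([("planted_up", g) for g in sorted(data.truth.planted_up)]
            + [("planted_down", g) for g in sorted(data.truth.planted_down)]
            + [("therapeutic_drug", d)
               for d in sorted(data.truth.therapeutic_drugs)]
            + [("enriched_pathway", p)
               for p in sorted(data.truth.enriched_pathways)])
    pd.DataFrame(rows, columns=["kind", "name"]).to_csv(
        paths["truth"], sep="\t", index=False)
    return paths
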
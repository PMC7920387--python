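"""Disease expression handling: normalization, fold change, ranked signature.

The disease side of the pipeline starts from a gene x sample expression
matrix with tumor/control labels.  Genes are z-score standardized for
inspection, ranked by ``logFC = log2(mean(tumor)/mean(control))``, and split
into up- (logFC > 0) and down-regulated (logFC <= 0) sets.  The ranked,
partitioned list is the disease signature every later stage consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

TUMOR = "tumor"
CONTROL = "control"
GROUPS = (TUMOR, CONTROL)


@dataclass(frozen=True)
class PhenotypeTable:
    """Sample -> group assignment; every sample is tumor or control."""

    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {s: g for s, g in self.groups.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown phenotype group(s): {bad}")
        for g in GROUPS:
            if g not in self.groups.values():
                raise ValueError(f"phenotype table has no '{g}' samples")

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == TUMOR]

    @property
    def control_samples(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == CONTROL]


@dataclass
class ExpressionMatrix:
    """Gene x sample real-valued matrix with a phenotype assignment.

    ``values[i, j]`` is the expression of ``genes[i]`` in ``samples[j]``.
    ``degenerate_genes`` lists genes whose row had zero variance at the last
    z-score pass (their standardized rows are all zeros).
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    groups: PhenotypeTable
    degenerate_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in expression matrix")
        missing = [s for s in self.samples if s not in self.groups.groups]
        if missing:
            raise ValueError(f"samples without phenotype assignment: {missing}")

    def sample_indices(self, group: str) -> np.ndarray:
        return np.array(
            [j for j, s in enumerate(self.samples) if self.groups.groups[s] == group],
            dtype=int,
        )


@dataclass(frozen=True)
class DiseaseSignature:
    """Genes ranked by descending logFC, partitioned into up/down sets.

    The up set contains genes with logFC > 0; everything else (including
    exact zeros) is down-regulated.  Ties in logFC are broken
    lexicographically by gene id so the ranking is deterministic.
    """

    ranked_genes: tuple[str, ...]
    logfc: Mapping[str, float]
    up_set: frozenset[str]
    down_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.up_set & self.down_set:
            raise ValueError("up and down sets overlap")
        if self.up_set | self.down_set != set(self.ranked_genes):
            raise ValueError("up/down partition does not cover the ranking")

    def rank_index(self) -> dict[str, int]:
        """0-based position of every gene in the disease ranking."""
        return {g: i for i, g in enumerate(self.ranked_genes)}

    @property
    def up_ranked(self) -> tuple[str, ...]:
        return tuple(g for g in self.ranked_genes if g in self.up_set)

    @property
    def down_ranked(self) -> tuple[str, ...]:
        return tuple(g for g in self.ranked_genes if g in self.down_set)


def zscore_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sd 1 across all samples.

    Uses the sample (n-1) standard deviation.  Rows with zero variance are
    set to all-zeros and reported in ``degenerate_genes`` rather than
    producing NaNs.
    """
    if len(matrix.samples) < 2:
        raise ValueError("z-score normalization requires at least 2 samples")
    mean = matrix.values.mean(axis=1, keepdims=True)
    sd = matrix.values.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] == 0.0
    safe_sd = np.where(degenerate[:, None], 1.0, sd)
    z = (matrix.values - mean) / safe_sd
    z[degenerate, :] = 0.0
    flagged = tuple(g for g, d in zip(matrix.genes, degenerate) if d)
    if flagged:
        logger.warning("%d constant gene row(s) set to zero: %s",
                       len(flagged), flagged[:5])
    return ExpressionMatrix(
        genes=list(matrix.genes),
        samples=list(matrix.samples),
        values=z,
        groups=matrix.groups,
        degenerate_genes=flagged,
    )


def compute_logfc(matrix: ExpressionMatrix, epsilon: float = 0.0) -> dict[str, float]:
    """Per-gene log2 ratio of mean tumor to mean control expression.

    Expects the matrix on its original positive scale (not z-scored: a
    z-scored row has mean zero across samples, which makes the ratio of
    group means meaningless).  ``epsilon`` is an optional pseudocount added
    to both group means, useful for count-like data with zeros.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    ti = matrix.sample_indices(TUMOR)
    ci = matrix.sample_indices(CONTROL)
    tumor_mean = matrix.values[:, ti].mean(axis=1) + epsilon
    control_mean = matrix.values[:, ci].mean(axis=1) + epsilon
    out: dict[str, float] = {}
    for gene, tm, cm in zip(matrix.genes, tumor_mean, control_mean):
        if tm <= 0 or cm <= 0:
            raise ValueError(
                f"non-positive group mean for gene {gene!r} "
                f"(tumor {tm}, control {cm}); logFC undefined — "
                "check the expression scale or set epsilon > 0"
            )
        out[gene] = math.log2(tm / cm)
    return out


def build_disease_signature(logfc: Mapping[str, float]) -> DiseaseSignature:
    """Rank genes by descending logFC and split into up/down sets."""
    if not logfc:
        raise ValueError("empty logFC mapping")
    ranked = tuple(sorted(logfc, key=lambda g: (-logfc[g], g)))
    up = frozenset(g for g, v in logfc.items() if v > 0)
    down = frozenset(logfc) - up
    if not down:
        logger.warning("all genes up-regulated; down set is empty")
    if not up:
        logger.warning("all genes down-regulated; up set is empty")
    return DiseaseSignature(ranked_genes=ranked, logfc=dict(logfc),
                            up_set=up, down_set=down)
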
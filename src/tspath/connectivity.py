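"""Kolmogorov-Smirnov-style connectivity scoring of drug instances.

Each drug instance is a full list of genes ranked by their differential
expression under the drug, rank 1 being the most up-regulated.  For an
ordered query gene list (the up or down half of a pathway signature) the
connectivity score asks whether the query genes sit near the top (positive)
or the bottom (negative) of the drug list:

    a  = max_p [ p/m - V(p)/n ]
    b  = max_p [ V(p)/n - (p-1)/m ]
    CS = a if a > b, -b if a < b, 0 on a tie

where m is the number of query genes found in the drug list, n the drug
list length, and V(p) the drug-list position of the p-th query gene after
re-ranking the common genes by the drug's values.  Per pathway i and
instance j, CS^{i,j} = CS_up - CS_down; the therapeutic score of a drug
with k instances sums CS^{i,j} over all pathways and instances and divides
by k.  A negative TS means the drug's profile reverses the disease
signature (up genes pushed down, down genes pushed up) — the therapeutic
pattern.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .signatures import PathwaySignature

logger = logging.getLogger(__name__)

#: a == b within this tolerance counts as a tie (null connectivity, CS = 0)
KS_TIE_TOL = 1e-12


@dataclass(frozen=True)
class DrugInstanceProfile:
    """One drug-treatment expression profile: a full ranked gene list.

    ``ranked_genes[0]`` is the most up-regulated gene under the drug
    (1-based rank 1); ranking is by descending differential value with ties
    broken lexicographically by gene id.
    """

    instance_id: str
    drug_name: str
    ranked_genes: tuple[str, ...]
    value: Mapping[str, float]
    cell_line: Optional[str] = None

    def __post_init__(self) -> None:
        if len(set(self.ranked_genes)) != len(self.ranked_genes):
            raise ValueError(
                f"instance {self.instance_id!r} has duplicate genes"
            )
        object.__setattr__(
            self, "_rank", {g: i + 1 for i, g in enumerate(self.ranked_genes)}
        )

    @classmethod
    def from_values(cls, instance_id: str, drug_name: str,
                    values: Mapping[str, float],
                    cell_line: Optional[str] = None) -> "DrugInstanceProfile":
        if len(values) == 0:
            raise ValueError(f"instance {instance_id!r} has no genes")
        ranked = tuple(sorted(values, key=lambda g: (-values[g], g)))
        return cls(instance_id=instance_id, drug_name=drug_name,
                   ranked_genes=ranked, value=dict(values),
                   cell_line=cell_line)

    @property
    def n(self) -> int:
        return len(self.ranked_genes)

    def rank_of(self, gene: str) -> Optional[int]:
        return self._rank.get(gene)


@dataclass(frozen=True)
class KSInput:
    """Positions (1-based, strictly increasing) of m query genes in a drug
    list of n genes."""

    m: int
    positions: tuple[int, ...]
    n: int

    def __post_init__(self) -> None:
        if self.m != len(self.positions):
            raise ValueError("m must equal the number of positions")
        if self.m > self.n:
            raise ValueError("more positions than genes in the drug list")
        prev = 0
        for v in self.positions:
            if not 1 <= v <= self.n:
                raise ValueError(f"position {v} outside [1, {self.n}]")
            if v <= prev:
                raise ValueError("positions must be strictly increasing")
            prev = v


@dataclass(frozen=True)
class ConnectivityRecord:
    """CS components for one (pathway, instance) pair."""

    pathway_id: str
    instance_id: str
    cs_up: float
    cs_down: float
    cs: float


@dataclass(frozen=True)
class TherapeuticResult:
    """Per-drug aggregate: TS = (1/k) * sum of CS over pathways x instances."""

    drug_name: str
    k: int
    ts: float
    records: tuple[ConnectivityRecord, ...] = field(repr=False, default=())


def intersect_and_rerank(gene_set: Iterable[str],
                         instance: DrugInstanceProfile) -> KSInput:
    """Common genes of a query set and a drug list, as sorted drug-list
    positions.

    Re-ranking the common genes by descending drug value gives the same
    order as sorting their drug-list positions ascending, so the positions
    are returned sorted.  An empty intersection (m = 0) is allowed.
    """
    positions = sorted(
        instance.rank_of(g) for g in gene_set if instance.rank_of(g) is not None
    )
    return KSInput(m=len(positions), positions=tuple(positions), n=instance.n)


def ks_score(inp: KSInput) -> float:
    """The signed KS statistic CS in [-1, 1] for one query gene list.

    Returns 0 when the query does not intersect the drug list (m = 0) or
    when a and b tie within ``KS_TIE_TOL`` (null connectivity).
    """
    if inp.n < 1:
        raise ValueError("drug list must contain at least one gene")
    if inp.m == 0:
        return 0.0
    v = np.asarray(inp.positions, dtype=float)
    p = np.arange(1, inp.m + 1, dtype=float)
    a = float(np.max(p / inp.m - v / inp.n))
    b = float(np.max(v / inp.n - (p - 1) / inp.m))
    if abs(a - b) <= KS_TIE_TOL:
        return 0.0
    return a if a > b else -b


def score_instance(sig: PathwaySignature,
                   instance: DrugInstanceProfile) -> ConnectivityRecord:
    """CS_up, CS_down and their difference for one pathway signature against
    one drug instance.  An empty up or down list contributes 0."""
    cs_up = ks_score(intersect_and_rerank(sig.up_genes, instance))
    cs_down = ks_score(intersect_and_rerank(sig.down_genes, instance))
    return ConnectivityRecord(pathway_id=sig.pathway_id,
                              instance_id=instance.instance_id,
                              cs_up=cs_up, cs_down=cs_down,
                              cs=cs_up - cs_down)


def therapeutic_score(instances: Sequence[DrugInstanceProfile],
                      sigs: Sequence[PathwaySignature],
                      normalize_pathways: bool = False) -> TherapeuticResult:
    """Aggregate TS for one drug over its k instances and all pathway
    signatures: sum of CS over (pathway, instance) pairs, divided by k.

    Note TS is averaged over instances but *summed* over pathways, so its
    magnitude grows with the number of surviving pathways;
    ``normalize_pathways`` divides by the pathway count as well.
    """
    if not instances:
        raise ValueError("drug has no instances")
    if not sigs:
        raise ValueError("no pathway signatures to score against")
    drug_names = {inst.drug_name for inst in instances}
    if len(drug_names) != 1:
        raise ValueError(f"instances belong to multiple drugs: {drug_names}")
    k = len(instances)
    records = tuple(score_instance(sig, inst)
                    for sig in sigs for inst in instances)
    ts = sum(r.cs for r in records) / k
    if normalize_pathways:
        ts /= len(sigs)
    return TherapeuticResult(drug_name=next(iter(drug_names)), k=k, ts=ts,
                             records=records)


def score_drugs(profiles: Sequence[DrugInstanceProfile],
                sigs: Sequence[PathwaySignature],
                normalize_pathways: bool = False) -> list[TherapeuticResult]:
    """Score every drug appearing in ``profiles`` (grouped by drug name)."""
    by_drug: dict[str, list[DrugInstanceProfile]] = defaultdict(list)
    for prof in profiles:
        by_drug[prof.drug_name].append(prof)
    return [
        therapeutic_score(by_drug[name], sigs,
                          normalize_pathways=normalize_pathways)
        for name in sorted(by_drug)
    ]


def profile_signature(instances: Sequence[DrugInstanceProfile]) -> PathwaySignature:
    """Reference up/down signature of a drug from its own profile(s):
    up = genes with positive mean differential value, down = negative,
    both ordered by descending mean value.  Genes with mean exactly 0 are
    excluded."""
    if not instances:
        raise ValueError("no instances to build a reference signature from")
    totals: dict[str, float] = defaultdict(float)
    counts: dict[str, int] = defaultdict(int)
    for inst in instances:
        for g, v in inst.value.items():
            totals[g] += v
            counts[g] += 1
    mean = {g: totals[g] / counts[g] for g in totals}
    order = sorted(mean, key=lambda g: (-mean[g], g))
    up = tuple(g for g in order if mean[g] > 0)
    down = tuple(g for g in order if mean[g] < 0)
    return PathwaySignature(pathway_id=instances[0].drug_name,
                            up_genes=up, down_genes=down)


def drug_drug_score(reference_instances: Sequence[DrugInstanceProfile],
                    target_instances: Sequence[DrugInstanceProfile]) -> float:
    """TS-style similarity of drug B's instances to drug A's own up/down
    signature: positive means similar action, negative opposite."""
    sig = profile_signature(reference_instances)
    result = therapeutic_score(target_instances, [sig])
    return result.ts
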
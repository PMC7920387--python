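"""Drug ranking, precision-at-k against a benchmark, and ablation baselines.

Scored drugs are ranked by descending |TS| (the benchmark rarely marks the
direction of an association, so magnitude is what matters for retrieval);
precision@x is the fraction of the top-x drugs with any benchmark evidence.
Drugs with TS < 0 are classified as putatively therapeutic.

Four scoring variants share the same connectivity core:

* ``full``      — subnetwork extraction, pathway enrichment, per-pathway
                  signatures (the complete pipeline);
* ``seedKS``    — the whole-disease up/down signature, no network, no
                  pathways;
* ``subnetKS``  — the disease signature restricted to the extracted
                  subnetwork's genes;
* ``seedPathKS``— pathways enriched directly from the disease DEG set,
                  ignoring the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from . import connectivity, enrichment, network as network_mod, signatures
from .connectivity import DrugInstanceProfile, TherapeuticResult
from .enrichment import PathwayDB
from .expression import DiseaseSignature, ExpressionMatrix, build_disease_signature, compute_logfc
from .network import TissueNetwork
from .signatures import PathwaySignature

logger = logging.getLogger(__name__)

EVIDENCE_CODES = ("M", "T", "M&T", "inferred", "NA")
METHODS = ("full", "seedKS", "subnetKS", "seedPathKS")


def _norm_name(name: str) -> str:
    return name.strip().lower()


@dataclass(frozen=True)
class Benchmark:
    """Drug -> evidence code; lookups are case-insensitive after trimming
    and absent drugs return 'NA'."""

    evidence: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {d: e for d, e in self.evidence.items() if e not in EVIDENCE_CODES}
        if bad:
            raise ValueError(f"unknown evidence code(s): {bad}")
        index = {_norm_name(d): e for d, e in self.evidence.items()}
        if len(index) != len(self.evidence):
            raise ValueError("duplicate drug names in benchmark "
                             "(after case/whitespace normalization)")
        object.__setattr__(self, "_index", index)

    def get(self, drug_name: str) -> str:
        return self._index.get(_norm_name(drug_name), "NA")

    def is_associated(self, drug_name: str) -> bool:
        return self.get(drug_name) != "NA"


@dataclass(frozen=True)
class PrecisionEntry:
    x: int
    hits: int
    precision: float


@dataclass(frozen=True)
class MethodOutcome:
    """Results of one scoring variant; ``status`` explains an empty result
    (e.g. no pathway survived enrichment)."""

    method: str
    results: tuple[TherapeuticResult, ...]
    status: str = "ok"


def rank_drugs(results: Iterable[TherapeuticResult]) -> list[TherapeuticResult]:
    """Descending by |TS|, ties broken alphabetically by drug name."""
    return sorted(results, key=lambda r: (-abs(r.ts), r.drug_name))


def precision_at(ranked: Sequence[TherapeuticResult], bench: Benchmark,
                 x: int) -> PrecisionEntry:
    """Fraction of the top-x drugs carrying any benchmark evidence."""
    if x <= 0:
        raise ValueError("x must be positive")
    if x > len(ranked):
        raise ValueError(f"x = {x} exceeds the number of ranked drugs "
                         f"({len(ranked)})")
    hits = sum(1 for r in ranked[:x] if bench.is_associated(r.drug_name))
    return PrecisionEntry(x=x, hits=hits, precision=hits / x)


def precision_curve(ranked: Sequence[TherapeuticResult], bench: Benchmark,
                    xs: Iterable[int]) -> list[PrecisionEntry]:
    return [precision_at(ranked, bench, x) for x in xs]


def classify_therapeutic(results: Iterable[TherapeuticResult]) -> dict[str, bool]:
    """A drug is putatively therapeutic iff its TS is strictly negative."""
    return {r.drug_name: r.ts < 0 for r in results}


def _signature_from_lists(pathway_id: str, disease: DiseaseSignature,
                          restrict: Optional[frozenset[str]] = None,
                          top_q: Optional[int] = None) -> PathwaySignature:
    """Whole-disease up/down signature, optionally restricted to a gene set
    and truncated to the top-q genes of each half by |logFC|."""
    up = list(disease.up_ranked)
    down = list(disease.down_ranked)
    if restrict is not None:
        up = [g for g in up if g in restrict]
        down = [g for g in down if g in restrict]
    if top_q is not None:
        # strongest up genes lead the ranking; strongest down genes trail it
        up = up[:top_q]
        down = down[-top_q:] if top_q < len(down) else down
    return PathwaySignature(pathway_id=pathway_id, up_genes=tuple(up),
                            down_genes=tuple(down))


def run_baseline(method: str, *, matrix: ExpressionMatrix,
                 seeds: Iterable[str], network: TissueNetwork,
                 db: PathwayDB, profiles: Sequence[DrugInstanceProfile],
                 cutoff: float = 0.1, p_max: float = 0.001,
                 min_count: int = 5, epsilon: float = 0.0,
                 ease: bool = False, top_q: Optional[int] = None,
                 normalize_pathways: bool = False) -> MethodOutcome:
    """Score every drug with one of the four variants.

    ``top_q`` bounds the DEG set used by seedKS/subnetKS/seedPathKS (top-q
    up and top-q down genes by |logFC|); the default uses all up and all
    down genes.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    disease = build_disease_signature(compute_logfc(matrix, epsilon=epsilon))
    seeds = frozenset(seeds)

    if method == "seedKS":
        sigs = [_signature_from_lists("DEG", disease, top_q=top_q)]
    elif method == "subnetKS":
        sub = network_mod.extract_subnetwork(network, seeds, cutoff=cutoff)
        sigs = [_signature_from_lists("subnet", disease, restrict=sub.nodes,
                                      top_q=top_q)]
    elif method == "seedPathKS":
        deg_sig = _signature_from_lists("DEG", disease, top_q=top_q)
        query = set(deg_sig.up_genes) | set(deg_sig.down_genes)
        enriched = enrichment.enrich(query, db, p_max=p_max,
                                     min_count=min_count, ease=ease)
        if not enriched:
            return MethodOutcome(method=method, results=(),
                                 status="no pathway enriched from the DEG set "
                                        "at the given thresholds")
        sigs = signatures.build_signatures(enriched, db, disease)
    else:  # full
        sub = network_mod.extract_subnetwork(network, seeds, cutoff=cutoff)
        enriched = enrichment.enrich(sub.nodes, db, p_max=p_max,
                                     min_count=min_count, ease=ease)
        if not enriched:
            return MethodOutcome(method=method, results=(),
                                 status="no pathway enriched from the "
                                        "subnetwork at the given thresholds")
        sigs = signatures.build_signatures(enriched, db, disease)

    sigs = [s for s in sigs if s.n_genes > 0]
    if not sigs:
        return MethodOutcome(method=method, results=(),
                             status="all signatures empty after intersection "
                                    "with the disease data")
    results = connectivity.score_drugs(profiles, sigs,
                                       normalize_pathways=normalize_pathways)
    return MethodOutcome(method=method, results=tuple(results))
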
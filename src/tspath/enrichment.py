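"""Hypergeometric pathway enrichment with count/p-value filters, plus a
random-gene-set permutation check of the extracted gene set.

Enrichment asks, for each pathway, whether the query gene set overlaps the
pathway more than expected when drawing ``query_size`` genes uniformly from
the background universe.  The retained pathways are those with overlap at
least ``min_count`` and upper-tail p-value at most ``p_max`` — raw
thresholds, no multiple-testing gate (Benjamini-Hochberg values are carried
along for information only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayDB:
    """Pathway id -> member gene set, with a background universe.

    The universe defaults to the union of all pathway members; an explicit
    background (e.g. all assayed genes) may extend it.
    """

    pathways: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for pid, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pid!r} is empty")
            if not members <= self.universe:
                raise ValueError(f"pathway {pid!r} has members outside the universe")

    @classmethod
    def build(cls, pathways: Mapping[str, Iterable[str]],
              background: Optional[Iterable[str]] = None) -> "PathwayDB":
        path = {pid: frozenset(genes) for pid, genes in pathways.items()}
        universe: set[str] = set()
        for members in path.values():
            universe |= members
        if background is not None:
            universe |= set(background)
        return cls(pathways=path, universe=frozenset(universe))


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    overlap_count: int
    pathway_size: int
    query_size: int
    p_value: float
    bh_q: float  # Benjamini-Hochberg adjusted p, informational only

    def __post_init__(self) -> None:
        if self.overlap_count > min(self.pathway_size, self.query_size):
            raise ValueError("overlap exceeds pathway or query size")


@dataclass(frozen=True)
class NullDistribution:
    """Null draws of the pathway-coverage statistic for random gene sets."""

    draws: tuple[int, ...]
    observed: int
    empirical_p: float


def hypergeom_pvalue(overlap: int, query_size: int, pathway_size: int,
                     universe_size: int, ease: bool = False) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(universe, pathway, query).

    With ``ease=True`` the overlap is decremented by one before the tail is
    taken (the DAVID/EASE conservative variant); an overlap of 0 then still
    yields 1.
    """
    if overlap < 0 or query_size < 0 or pathway_size < 0:
        raise ValueError("counts must be non-negative")
    if overlap > min(query_size, pathway_size):
        raise ValueError(
            f"overlap {overlap} exceeds min(query {query_size}, "
            f"pathway {pathway_size})"
        )
    if max(query_size, pathway_size) > universe_size:
        raise ValueError("query or pathway larger than the universe")
    k = max(overlap - 1, 0) if ease else overlap
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, universe_size, pathway_size, query_size))


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, pvals[idx] * n / rank)
        adj[idx] = running
    return adj


def enrich(query: Iterable[str], db: PathwayDB, p_max: float = 0.001,
           min_count: int = 5, ease: bool = False) -> list[EnrichmentResult]:
    """Pathways over-represented in the query gene set.

    The query is intersected with the universe before testing (genes outside
    the background carry no information under the hypergeometric model).
    Results are sorted by ascending p-value, ties by pathway id.
    """
    query = frozenset(query)
    if not query:
        raise ValueError("empty query gene set")
    eff_query = query & db.universe
    universe_size = len(db.universe)
    pids = sorted(db.pathways)
    rows = []
    for pid in pids:
        members = db.pathways[pid]
        overlap = len(eff_query & members)
        p = hypergeom_pvalue(overlap, len(eff_query), len(members),
                             universe_size, ease=ease)
        rows.append((pid, overlap, len(members), p))
    qvals = _bh_adjust(np.array([r[3] for r in rows])) if rows else np.array([])
    results = [
        EnrichmentResult(pathway_id=pid, overlap_count=ov, pathway_size=ps,
                         query_size=len(eff_query), p_value=p, bh_q=float(q))
        for (pid, ov, ps, p), q in zip(rows, qvals)
        # a pathway the query never touches is not enriched, whatever the
        # thresholds say
        if ov >= max(min_count, 1) and p <= p_max
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def _coverage_statistic(genes: frozenset[str], db: PathwayDB, p_max: float,
                        min_count: int, ease: bool) -> int:
    """Number of distinct genes of ``genes`` covered by pathways that pass
    the enrichment filters for that gene set."""
    passing = enrich(genes, db, p_max=p_max, min_count=min_count, ease=ease)
    covered: set[str] = set()
    for res in passing:
        covered |= genes & db.pathways[res.pathway_id]
    return len(covered)


def random_set_significance(network_genes: Iterable[str], seeds: Iterable[str],
                            observed_genes: Iterable[str], n_draws: int,
                            db: PathwayDB, p_max: float = 0.001,
                            min_count: int = 5, rng_seed: int = 0,
                            draw_size: Optional[int] = None,
                            ease: bool = False) -> NullDistribution:
    """Permutation check: is the observed gene set's pathway coverage higher
    than that of random seed-anchored sets of the same size?

    Each null draw keeps the seeds and replaces the remaining genes with a
    uniform sample (without replacement) of non-seed network genes.  The
    statistic is the number of distinct draw genes covered by pathways that
    pass the enrichment filters.  The empirical p-value uses the add-one
    rule (1 + #{draws >= observed}) / (1 + n_draws).
    """
    seeds = frozenset(seeds)
    observed_genes = frozenset(observed_genes)
    pool = sorted(frozenset(network_genes) - seeds)
    if draw_size is None:
        draw_size = len(observed_genes - seeds)
    if draw_size > len(pool):
        raise ValueError(
            f"draw_size {draw_size} exceeds available non-seed network genes "
            f"({len(pool)})"
        )
    rng = np.random.default_rng(rng_seed)
    draws = []
    for _ in range(n_draws):
        picked = rng.choice(len(pool), size=draw_size, replace=False)
        draw = seeds | {pool[i] for i in picked}
        draws.append(_coverage_statistic(frozenset(draw), db, p_max,
                                         min_count, ease))
    observed = _coverage_statistic(observed_genes, db, p_max, min_count, ease)
    n_ge = sum(1 for d in draws if d >= observed)
    empirical_p = (1 + n_ge) / (1 + len(draws))
    return NullDistribution(draws=tuple(draws), observed=observed,
                            empirical_p=empirical_p)
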
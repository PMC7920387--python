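"""Per-pathway disease signatures.

A pathway signature is the pathway's member genes re-ordered by the disease
ranking (descending logFC) and partitioned into the disease's up- and
down-regulated lists.  These ordered lists are the inputs the connectivity
scoring runs against every drug instance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Union

from .enrichment import EnrichmentResult, PathwayDB
from .expression import DiseaseSignature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwaySignature:
    """Pathway members in disease-rank order, split into up/down lists."""

    pathway_id: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError(f"up/down overlap in signature {self.pathway_id!r}")

    @property
    def n_genes(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def build_signatures(
    pathways: Iterable[Union[str, EnrichmentResult]],
    db: PathwayDB,
    disease: DiseaseSignature,
) -> list[PathwaySignature]:
    """Order each pathway's members by the disease ranking and split them by
    the disease up/down partition.

    Pathway members absent from the disease signature are excluded (logged);
    pathways with no member in the signature are dropped with a warning.
    """
    rank = disease.rank_index()
    out: list[PathwaySignature] = []
    for item in pathways:
        pid = item.pathway_id if isinstance(item, EnrichmentResult) else item
        if pid not in db.pathways:
            raise KeyError(f"pathway {pid!r} not in database")
        members = db.pathways[pid]
        present = sorted(members & set(rank), key=rank.__getitem__)
        dropped = members - set(rank)
        if dropped:
            logger.info("pathway %s: %d member(s) absent from expression data",
                        pid, len(dropped))
        if not present:
            logger.warning("pathway %s has no member in the disease signature; "
                           "dropped", pid)
            continue
        up = tuple(g for g in present if g in disease.up_set)
        down = tuple(g for g in present if g in disease.down_set)
        out.append(PathwaySignature(pathway_id=pid, up_genes=up, down_genes=down))
    return out
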
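"""Gene-set collection hygiene before enrichment testing.

Sets are restricted to genes that actually carry a score (>= 1 assigned
SNP), sets smaller than 10 genes are discarded, and near-duplicate sets
(Jaccard similarity above 0.95) are greedily merged into their union. The
size floor is applied both before and after merging: restriction can shrink
sets below the floor, while merged unions can only grow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._util import ValidationError

logger = logging.getLogger(__name__)

MIN_SET_SIZE = 10
MERGE_THRESHOLD = 0.95


def jaccard(a: set[str], b: set[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def overlap_coefficient(a: set[str], b: set[str]) -> float:
    denom = min(len(a), len(b))
    return len(a & b) / denom if denom else 0.0


_SIMILARITIES = {"jaccard": jaccard, "overlap": overlap_coefficient}


@dataclass
class GeneSetCollection:
    """Named gene sets plus the merged-from lineage of each retained set."""

    sets: dict[str, set[str]]
    lineage: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def prepare_genesets(
    raw: dict[str, set[str]],
    scored_genes: set[str],
    min_size: int = MIN_SET_SIZE,
    merge_threshold: float = MERGE_THRESHOLD,
    similarity: str = "jaccard",
) -> GeneSetCollection:
    """Filter and deduplicate a raw gene-set collection.

    Steps: (1) restrict members to ``scored_genes``; (2) drop sets with
    fewer than ``min_size`` members left; (3) while any pair's similarity
    exceeds ``merge_threshold``, merge the highest-similarity pair into its
    union (similarity ties broken lexicographically by the sorted name pair,
    merged name = member names joined with ``+`` in sorted order, lineage
    recorded); (4) re-apply the size floor. Deterministic for a given input.
    """
    if not raw:
        raise ValidationError("raw gene-set collection is empty")
    sim = _SIMILARITIES.get(similarity)
    if sim is None:
        raise ValidationError(f"unknown similarity {similarity!r}")

    restricted = {
        name: members & scored_genes for name, members in sorted(raw.items())
    }
    sets = {n: m for n, m in restricted.items() if len(m) >= min_size}
    n_small = len(restricted) - len(sets)
    lineage: dict[str, list[str]] = {n: [n] for n in sets}

    n_merges = 0
    while True:
        best: tuple[float, str, str] | None = None
        names = sorted(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                s = sim(sets[a], sets[b])
                if s > merge_threshold and (best is None or s > best[0]):
                    best = (s, a, b)
        if best is None:
            break
        _, a, b = best
        merged_sources = sorted(lineage.pop(a) + lineage.pop(b))
        merged_name = "+".join(merged_sources)
        union = sets.pop(a) | sets.pop(b)
        sets[merged_name] = union
        lineage[merged_name] = merged_sources
        n_merges += 1

    final = {n: m for n, m in sets.items() if len(m) >= min_size}
    logger.info(
        "gene-set prep: %d raw, %d below size floor, %d merges, %d retained",
        len(raw), n_small, n_merges, len(final),
    )
    if not final:
        raise ValidationError("no gene sets survive size filtering and merging")
    return GeneSetCollection(sets=final, lineage={n: lineage[n] for n in final})
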
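"""Gene-level outlier flagging against a user-supplied disease-gene list.

A gene is flagged when its selection score (max |normalized SNP score| over
its SNPs, the same gene score the sum engine uses) reaches the top
``percentile`` percent of all gene scores (default 1 %). The overlap between
the flagged genes and the disease list is summarized with a hypergeometric
over-representation test over the universe of all scored genes. SNP-level
flagging (percentile applied to SNP scores, a gene flagged when it contains
a flagged SNP) is available behind ``level="snp"``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._util import ValidationError

logger = logging.getLogger(__name__)


def flag_disease_genes(
    gene_scores: pd.DataFrame,
    disease_genes: list[str],
    percentile: float = 1.0,
    level: str = "gene",
    snp_scores: pd.Series | None = None,
    gene_to_snps: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Flag top-scoring genes and test disease-list over-representation.

    Parameters
    ----------
    gene_scores
        Indexed by gene id with a ``score`` column (all scored genes, the
        test universe).
    disease_genes
        Non-empty list of gene ids; ids absent from the score table are
        logged and excluded.
    percentile
        Upper tail size in percent, in (0, 50). Genes tied with the cutoff
        value are all flagged.

    Returns
    -------
    (report, p_overlap)
        Per-gene report (score, flagged, in_disease_list) and the
        hypergeometric tail probability of the observed overlap.
    """
    if not disease_genes:
        raise ValidationError("disease gene list is empty")
    if not (0.0 < percentile < 50.0):
        raise ValidationError("percentile must be in (0, 50)")
    scores = gene_scores["score"]
    if level == "snp":
        if snp_scores is None or gene_to_snps is None:
            raise ValidationError("snp-level flagging needs snp_scores and gene_to_snps")
        snp_cut = np.percentile(np.abs(snp_scores.to_numpy()), 100.0 - percentile)
        hot = set(snp_scores.index[np.abs(snp_scores) >= snp_cut])
        flagged = scores.index.map(
            lambda g: bool(hot & set(gene_to_snps.get(g, [])))
        ).to_numpy()
    elif level == "gene":
        cutoff = np.percentile(scores.to_numpy(), 100.0 - percentile)
        flagged = (scores >= cutoff).to_numpy()
    else:
        raise ValidationError(f"unknown flagging level {level!r}")

    listed = set(disease_genes)
    missing = listed - set(scores.index)
    if missing:
        logger.warning(
            "%d disease-list genes absent from the score table (excluded): %s",
            len(missing), sorted(missing)[:5],
        )
    listed &= set(scores.index)
    if not listed:
        raise ValidationError("no disease-list gene present in the score table")

    in_list = scores.index.isin(listed)
    n_universe = len(scores)
    n_flagged = int(flagged.sum())
    overlap = int((flagged & in_list).sum())
    # P[X >= overlap], X ~ Hypergeom(N=universe, K=|list|, n=flagged)
    p_overlap = float(hypergeom.sf(overlap - 1, n_universe, len(listed), n_flagged))
    report = pd.DataFrame(
        {
            "gene": scores.index,
            "score": scores.to_numpy(),
            "flagged": flagged,
            "in_disease_list": in_list,
        }
    ).sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    logger.info(
        "flagged %d of %d genes; %d in the disease list (p=%.3g)",
        n_flagged, n_universe, overlap, p_overlap,
    )
    return report, p_overlap
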
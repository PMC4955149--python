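"""SNP-to-gene assignment and consensus position filtering.

Genes are represented by the union interval of their isoforms (utmost start
to utmost end), so a SNP anywhere inside any isoform's span — or between
isoforms — is counted as belonging to the gene. When two position mappings
of the same SNP panel are supplied (e.g. from two assembly-remapping tools),
only SNPs placed at the identical location by both are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from ._util import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    """A gene with one or more isoform intervals (1-based, inclusive)."""

    gene_id: str
    chrom: str
    isoforms: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValidationError(f"gene {self.gene_id} has no isoforms")
        for start, end in self.isoforms:
            if start > end:
                raise ValidationError(f"gene {self.gene_id}: isoform start > end")

    @property
    def union_interval(self) -> tuple[int, int]:
        """Utmost start and end over all isoforms (the 'longest isoform' span)."""
        return (
            min(s for s, _ in self.isoforms),
            max(e for _, e in self.isoforms),
        )


def consensus_position_filter(
    mapping_a: pd.DataFrame, mapping_b: pd.DataFrame
) -> pd.DataFrame:
    """Keep SNPs mapped to the identical (chrom, pos) by two mapping sources.

    Parameters
    ----------
    mapping_a, mapping_b
        DataFrames with columns ``snp``, ``chrom``, ``pos``.

    Returns
    -------
    DataFrame with columns ``snp``, ``chrom``, ``pos`` for the concordant SNPs.
    """
    a = mapping_a[["snp", "chrom", "pos"]].assign(
        chrom=mapping_a["chrom"].astype(str)
    ).set_index("snp")
    b = mapping_b[["snp", "chrom", "pos"]].assign(
        chrom=mapping_b["chrom"].astype(str)
    ).set_index("snp")
    joined = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    keep = (joined["chrom_a"] == joined["chrom_b"]) & (
        joined["pos_a"] == joined["pos_b"]
    )
    n_discord = int((~keep).sum())
    n_missing = len(a) + len(b) - 2 * len(joined)
    logger.info(
        "consensus filter: %d retained, %d discordant, %d present in one source only",
        int(keep.sum()),
        n_discord,
        n_missing,
    )
    out = joined[keep].reset_index()[["snp", "chrom_a", "pos_a"]]
    out.columns = ["snp", "chrom", "pos"]
    if out.empty:
        raise ValidationError("no SNP positions concordant between the two mappings")
    return out


def assign_snps_to_genes(
    positions: pd.DataFrame,
    genes: list[GeneModel],
    flank: int = 0,
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Assign SNPs to every gene whose union interval contains them.

    Containment is inclusive on both ends (1-based coordinates); a SNP inside
    several overlapping genes is assigned to all of them. ``flank`` widens
    each union interval symmetrically (bp); default 0.

    Returns
    -------
    (gene_to_snps, snp_to_genes)
        ``gene_to_snps`` includes every gene; genes with no SNPs map to an
        empty list (unscored).
    """
    trees: dict[str, IntervalTree] = {}
    gene_to_snps: dict[str, list[str]] = {g.gene_id: [] for g in genes}
    if len(gene_to_snps) != len(genes):
        raise ValidationError("duplicate gene ids in gene models")
    for g in genes:
        start, end = g.union_interval
        # IntervalTree is half-open; +1 makes the inclusive end queryable
        trees.setdefault(g.chrom, IntervalTree()).addi(
            start - flank, end + flank + 1, g.gene_id
        )
    snp_to_genes: dict[str, list[str]] = {}
    for snp, chrom, pos in positions[["snp", "chrom", "pos"]].itertuples(index=False):
        hits = sorted(
            iv.data for iv in trees.get(str(chrom), IntervalTree()).at(pos)
        )
        snp_to_genes[snp] = hits
        for gid in hits:
            gene_to_snps[gid].append(snp)
    n_unscored = sum(1 for v in gene_to_snps.values() if not v)
    logger.info(
        "assigned %d SNPs; %d of %d genes carry no SNP (unscored)",
        sum(1 for v in snp_to_genes.values() if v),
        n_unscored,
        len(genes),
    )
    return gene_to_snps, snp_to_genes
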
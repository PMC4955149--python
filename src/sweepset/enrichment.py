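"""Permutation gene-set enrichment engines and FDR control.

Two engines test whether a gene set carries collectively extreme selection
scores:

* the **sum engine** scores each gene by the maximum |normalized SNP score|
  over its SNPs and tests the sum of gene scores in the set against null
  sets drawn gene-by-gene from SNP-count-matched bins (neutralizing the
  gene-length bias: genes spanning more SNPs have higher extreme-score
  chances), with a one-pass overlap-pruning correction;
* the **candidate engine** thresholds SNPs at a genome-wide percentile of
  |score| and tests the number of member genes containing a candidate SNP
  against uniform SNP permutations of the same candidate count.

Empirical p-values carry the +1 correction, p = (1 + #{null >= obs}) /
(1 + B), so p is never 0. q-values are Benjamini-Hochberg; sets are called
significant at q <= 0.09.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from ._util import ValidationError, merge_small_bins

logger = logging.getLogger(__name__)

Q_THRESHOLD = 0.09
_EXHAUSTIVE_CAP = 500_000


def gene_scores_from_snps(
    snp_scores: pd.Series, gene_to_snps: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-gene score table: max |SNP score| over the gene's SNPs + SNP count.

    Genes with no assigned SNP are omitted (unscored).
    """
    rows = []
    for gene in sorted(gene_to_snps):
        snps = gene_to_snps[gene]
        if not snps:
            continue
        vals = snp_scores.loc[snps].to_numpy()
        rows.append((gene, float(np.abs(vals).max()), len(snps)))
    if not rows:
        raise ValidationError("no gene has any scored SNP")
    return pd.DataFrame(rows, columns=["gene", "score", "n_snps"]).set_index("gene")


def _snp_count_bins(n_snps: pd.Series, n_bins: int) -> np.ndarray:
    """Quantile bins on SNP count; bins with < 5 genes merged into a neighbor.

    Genes with equal SNP counts always share a bin (ties are never split),
    so an equal-length universe collapses to a single bin.
    """
    values = n_snps.to_numpy(dtype=float)
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 3:
        return np.zeros(values.size, dtype=int)
    inner = edges[1:-1]
    codes = np.searchsorted(inner, values, side="right")
    merged = merge_small_bins(codes, int(codes.max()) + 1, min_count=5)
    if merged.max() < codes.max():
        logger.info(
            "merged SNP-count bins: %d -> %d", codes.max() + 1, merged.max() + 1
        )
    return merged


def sumscore_gsea(
    gene_scores: pd.DataFrame,
    collection: dict[str, set[str]],
    n_bins: int = 10,
    n_permutations: int = 10_000,
    seed: int = 0,
    null: str = "permutation",
) -> pd.DataFrame:
    """Sum-of-gene-scores enrichment with SNP-count-matched permutation nulls.

    Every member of every set must have a gene score. Null sets preserve the
    per-bin composition of the tested set: for each member gene, a random
    distinct gene is drawn from the same SNP-count bin.

    ``null="exhaustive"`` enumerates all same-size subsets instead of
    sampling; it requires the universe to collapse into a single SNP-count
    bin and at most 500,000 subsets, and is exact (used as an oracle check
    at tiny sizes).
    """
    if null == "permutation" and n_permutations < 100:
        raise ValidationError("need at least 100 permutations")
    genes = gene_scores.index.to_numpy()
    scores = gene_scores["score"].to_numpy()
    for name, members in collection.items():
        missing = set(members) - set(genes)
        if missing:
            raise ValidationError(
                f"set {name} has members without gene scores: {sorted(missing)[:5]}"
            )
    bins = _snp_count_bins(gene_scores["n_snps"], n_bins)
    rng = np.random.default_rng(seed)
    pos_of = {g: i for i, g in enumerate(genes)}

    rows = []
    for name in sorted(collection):
        member_idx = np.array(sorted(pos_of[g] for g in collection[name]))
        s_obs = float(scores[member_idx].sum())
        if null == "exhaustive":
            p = _exhaustive_sum_p(scores, bins, member_idx)
            b_used = 0
        else:
            s_null = np.zeros(n_permutations)
            for b in np.unique(bins[member_idx]):
                k_b = int((bins[member_idx] == b).sum())
                pool = np.flatnonzero(bins == b)
                keys = rng.random((n_permutations, pool.size))
                pick = np.argpartition(keys, k_b - 1, axis=1)[:, :k_b]
                s_null += scores[pool[pick]].sum(axis=1)
            p = (1 + int((s_null >= s_obs).sum())) / (1 + n_permutations)
            b_used = n_permutations
        rows.append((name, member_idx.size, s_obs, p, b_used))
    out = pd.DataFrame(
        rows, columns=["set", "n_genes", "stat", "p", "n_permutations"]
    )
    out["engine"] = "sum"
    return out


def _exhaustive_sum_p(
    scores: np.ndarray, bins: np.ndarray, member_idx: np.ndarray
) -> float:
    if np.unique(bins).size != 1:
        raise ValidationError(
            "exhaustive null requires a single SNP-count bin (equal gene lengths)"
        )
    n, k = scores.size, member_idx.size
    if comb(n, k) > _EXHAUSTIVE_CAP:
        raise ValidationError("exhaustive null too large; use permutations")
    s_obs = float(scores[np.sort(member_idx)].sum())
    hits = sum(
        1
        for subset in combinations(range(n), k)
        if float(scores[list(subset)].sum()) >= s_obs
    )
    return hits / comb(n, k)


def prune_overlapping_genes(
    results: pd.DataFrame,
    collection: dict[str, set[str]],
    gene_scores: pd.DataFrame,
    n_bins: int = 10,
    n_permutations: int = 10_000,
    seed: int = 0,
    min_size: int = 10,
) -> pd.DataFrame:
    """One-pass overlap correction for sum-engine results.

    Sets are ranked by p ascending (ties: smaller set first, then name).
    Walking down the ranking, genes already claimed by a better-ranked set
    are removed from the current set; a set falling below ``min_size`` genes
    is dropped with status, and a surviving pruned set is re-tested with the
    sum engine on its remaining genes.
    """
    order = results.sort_values(["p", "n_genes", "set"]).reset_index(drop=True)
    claimed: set[str] = set()
    rows = []
    for i, rec in order.iterrows():
        name = rec["set"]
        members = set(collection[name])
        remaining = members - claimed
        if remaining == members:
            status, p, stat, n_g = "kept", rec["p"], rec["stat"], len(members)
        elif len(remaining) < min_size:
            status, p, stat, n_g = "dropped_overlap", np.nan, np.nan, len(remaining)
        else:
            retest = sumscore_gsea(
                gene_scores,
                {name: remaining},
                n_bins=n_bins,
                n_permutations=n_permutations,
                seed=seed + i,
            )
            status = "pruned_retested"
            p, stat, n_g = retest["p"].iloc[0], retest["stat"].iloc[0], len(remaining)
        claimed |= remaining
        rows.append(
            (name, n_g, stat, p, rec["n_permutations"], status,
             ",".join(sorted(members - remaining)))
        )
    out = pd.DataFrame(
        rows,
        columns=["set", "n_genes", "stat", "p", "n_permutations", "status",
                 "pruned_genes"],
    )
    out["engine"] = "sum"
    return out


def candidate_gsea(
    snp_scores: pd.Series,
    snp_to_genes: dict[str, list[str]],
    collection: dict[str, set[str]],
    percentile: float = 1.0,
    n_permutations: int = 100_000,
    seed: int = 0,
    mode: str = "gene",
    chunk: int = 2_000,
) -> pd.DataFrame:
    """Candidate-SNP counting enrichment with genome-wide SNP permutation.

    Candidate SNPs are those with |score| in the top ``percentile`` percent
    (ties at the cutoff all included). The observed statistic per set is the
    number of member genes containing >= 1 candidate SNP (``mode="gene"``)
    or the number of candidate SNPs inside member genes (``mode="snp"``).
    Each permutation redraws the same number of SNPs uniformly without
    replacement from all scored SNPs.
    """
    if not (0.0 < percentile < 50.0):
        raise ValidationError("candidate percentile must be in (0, 50)")
    if mode not in ("gene", "snp"):
        raise ValidationError(f"unknown candidate mode {mode!r}")
    snp_ids = np.asarray(sorted(snp_scores.index))
    abs_scores = np.abs(snp_scores.loc[snp_ids].to_numpy(dtype=float))
    n = snp_ids.size
    k = max(1, int(round(n * percentile / 100.0)))
    cutoff = np.sort(abs_scores)[::-1][k - 1]
    cand = abs_scores >= cutoff
    n_cand = int(cand.sum())
    if n_cand == 0:
        raise ValidationError("no candidate SNPs at this percentile")
    logger.info("candidate engine: %d candidate SNPs (cutoff |score| >= %.4f)",
                n_cand, cutoff)

    gene_ids = np.asarray(
        sorted({g for snp in snp_ids for g in snp_to_genes.get(snp, [])})
    )
    gpos = {g: i for i, g in enumerate(gene_ids)}
    spos = {s: i for i, s in enumerate(snp_ids)}
    rows_g, cols_s = [], []
    for snp in snp_ids:
        for g in snp_to_genes.get(snp, []):
            rows_g.append(gpos[g])
            cols_s.append(spos[snp])
    G = sparse.csr_matrix(
        (np.ones(len(rows_g), dtype=np.int64), (rows_g, cols_s)),
        shape=(gene_ids.size, n),
    )
    set_names = sorted(collection)
    rows_t, cols_g = [], []
    for t, name in enumerate(set_names):
        for g in collection[name]:
            if g in gpos:
                rows_t.append(t)
                cols_g.append(gpos[g])
    S = sparse.csr_matrix(
        (np.ones(len(rows_t), dtype=np.int64), (rows_t, cols_g)),
        shape=(len(set_names), gene_ids.size),
    )

    def set_counts(ind: np.ndarray) -> np.ndarray:
        """ind: (n_snps, m) boolean -> (n_sets, m) statistic."""
        if mode == "gene":
            gene_hit = (G @ ind) > 0
            return S @ gene_hit
        in_gene = ((S @ G) > 0).astype(np.int64)  # set x snp membership
        counts = in_gene @ ind
        return counts.toarray() if sparse.issparse(counts) else np.asarray(counts)

    obs = set_counts(cand[:, None].astype(np.int64))[:, 0]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(set_names), dtype=np.int64)
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        keys = rng.random((m, n))
        pick = np.argpartition(keys, n_cand - 1, axis=1)[:, :n_cand]
        ind = np.zeros((n, m), dtype=np.int64)
        ind[pick.ravel(), np.repeat(np.arange(m), n_cand)] = 1
        counts = np.asarray(set_counts(ind))
        exceed += (counts >= obs[:, None]).sum(axis=1)
        done += m
    p = (1 + exceed) / (1 + n_permutations)
    out = pd.DataFrame(
        {
            "set": set_names,
            "n_genes": [len(collection[s]) for s in set_names],
            "stat": obs,
            "p": p,
            "n_permutations": n_permutations,
        }
    )
    out["engine"] = "candidate"
    return out


def compute_qvalues(pvalues: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values to adjust")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_qvalues(results: pd.DataFrame, q_threshold: float = Q_THRESHOLD) -> pd.DataFrame:
    """Attach q-values and a significance flag to an enrichment table.

    Rows with undefined p (e.g. sets dropped by pruning) are excluded from
    the adjustment and flagged non-significant.
    """
    out = results.copy()
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = compute_qvalues(out.loc[ok, "p"])
    out["significant"] = (out["q"] <= q_threshold).fillna(False)
    return out
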
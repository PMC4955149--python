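"""Reproducible validation experiments on synthetic data.

These functions encapsulate the package's standard simulation studies:
neutral calibration of the cross-population scan, sweep localization power
for both scans, and end-to-end gene-set enrichment power on a polygenic
study with planted sweeps. The study conditions (panel sizes, map
geometries, selection strengths) are fixed here and documented in the
methods note; the seeds are caller-supplied.

Geometry conventions. Physical coordinates are compressed relative to a
human genome: chromosomes are 1 Mb segments whose genetic length matches
the scale each statistic needs. The haplotype scan uses 100 cM/Mb (a
~1 Morgan chromosome, so EHH decays well inside it); the cross-population
scan uses 10-20 cM/Mb so that 50-SNP windows are much shorter than a sweep
footprint, as in dense real panels.

Because a planted sweep occupies more than 1 % of these small genomes, the
"genome-wide" score percentile of a sweep replicate is computed on the
neutral complement (grid points far from the sweep); at real genome scale
the two are interchangeable.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from ._util import stage_seed
from .enrichment import (
    add_qvalues,
    candidate_gsea,
    gene_scores_from_snps,
    sumscore_gsea,
)
from .genes import assign_snps_to_genes
from .genesets import prepare_genesets
from .ihs import ihs_scan
from .panel import HaplotypePanel
from .synthetic import (
    SimulationConfig,
    simulate_polygenic_study,
    simulate_sweep_panel,
)
from .xpclr import xpclr_scan

# Cross-population scan geometry: 10 cM/Mb, dense SNPs, two populations of
# 150 diploids at Balding-Nichols F = 0.05 each.
XPCLR_STUDY = SimulationConfig(
    n_snps=2000,
    n_diploids=200,
    recomb_rate=10.0,
    founder_switch_rate=300.0,
    n_generations=100,
)

# Sweep planted for the scan power study: s = 0.1 from a single-origin
# standing variant, stopped at derived frequency 0.95 (near-complete, so
# hitchhikers stay polymorphic and pass the polymorphic-in-both filter).
XPCLR_SWEEP_STUDY = replace(
    XPCLR_STUDY,
    sweep_site=1000,
    selection_coefficient=0.1,
    sweep_mode="incomplete",
    sweep_target_freq=0.95,
    n_generations=300,
)

# Haplotype-scan geometry: ~1 Morgan chromosome; incomplete sweep at
# intermediate frequency (where the statistic is most sensitive).
IHS_STUDY = SimulationConfig(
    n_snps=800,
    n_diploids=100,
    recomb_rate=100.0,
    founder_switch_rate=300.0,
    sweep_site=400,
    selection_coefficient=0.1,
    sweep_mode="incomplete",
    sweep_target_freq=0.6,
    n_generations=300,
)

# End-to-end polygenic study: twelve chromosomes, each carrying a strong
# (s = 0.3) near-complete sweep inside the planted gene set. Spreading the
# signal over many loci is what makes it polygenic: the candidate engine's
# gene-counting statistic needs many distinct swept genes, not one strong one.
ENDTOEND_STUDY = SimulationConfig(
    n_snps=1000,
    n_diploids=150,
    recomb_rate=20.0,
    founder_switch_rate=300.0,
    sweep_site=500,
    selection_coefficient=0.3,
    sweep_mode="incomplete",
    sweep_target_freq=0.95,
    n_generations=300,
)

SWEEP_PROXIMAL_BP = 25_000
NEUTRAL_COMPLEMENT_BP = 150_000


def _xpclr_snp_scores(panel: HaplotypePanel) -> tuple[pd.DataFrame, pd.DataFrame]:
    grid, snps = xpclr_scan(
        panel.frequency_table(panel.populations[0]),
        panel.frequency_table(panel.populations[1]),
        panel.for_population(panel.populations[1]),
    )
    return grid, snps


def neutral_calibration(seed: int, n_pairs: int = 5) -> dict[str, float]:
    """Cross-replicate false-positive rate of the 99th-percentile cutoff.

    For each pair of independent neutral simulations, the 99th percentile of
    one replicate's normalized SNP scores is applied to the other; returns
    the pooled exceedance rate (in percent; 1 % is perfect calibration) and
    the within-replicate rate (1 % by construction, up to ties).
    """
    rates = []
    within = []
    for i in range(n_pairs):
        sa = stage_seed(seed, f"neutral_a{i}")
        sb = stage_seed(seed, f"neutral_b{i}")
        pa, _ = simulate_sweep_panel(replace(XPCLR_STUDY, rng_seed=sa))
        pb, _ = simulate_sweep_panel(replace(XPCLR_STUDY, rng_seed=sb))
        _, snps_a = _xpclr_snp_scores(pa)
        _, snps_b = _xpclr_snp_scores(pb)
        cut = np.percentile(snps_a["score_norm"], 99)
        rates.append(float((snps_b["score_norm"] > cut).mean()))
        within.append(float((snps_a["score_norm"] > cut).mean()))
    return {
        "cross_replicate_fpr_pct": 100.0 * float(np.mean(rates)),
        "within_replicate_fpr_pct": 100.0 * float(np.mean(within)),
        "n_snps_per_replicate": int(len(snps_a)),
    }


def xpclr_sweep_power(seed: int, n_replicates: int = 20) -> dict[str, float]:
    """Fraction of planted-sweep replicates whose sweep-proximal mean grid
    score exceeds the neutral-complement 99th percentile."""
    hits = 0
    for i in range(n_replicates):
        cfg = replace(
            XPCLR_SWEEP_STUDY, rng_seed=stage_seed(seed, f"xpclr_sweep{i}")
        )
        panel, record = simulate_sweep_panel(cfg)
        grid, _ = _xpclr_snp_scores(panel)
        d = (grid["grid_pos"] - record.position).abs()
        near = grid.loc[d < SWEEP_PROXIMAL_BP, "score"]
        p99 = np.nanpercentile(grid.loc[d > NEUTRAL_COMPLEMENT_BP, "score"], 99)
        hits += int(near.mean() > p99)
    return {
        "detection_rate_pct": 100.0 * hits / n_replicates,
        "n_replicates": n_replicates,
    }


def ihs_sweep_localization(seed: int, n_replicates: int = 10) -> dict[str, float]:
    """Mean |standardized iHS| near the sweep relative to the genome mean.

    Uses the 50 defined SNPs nearest the planted (incomplete) sweep; returns
    the across-replicate mean ratio and the fraction of replicates with
    ratio > 1.
    """
    ratios = []
    for i in range(n_replicates):
        cfg = replace(IHS_STUDY, rng_seed=stage_seed(seed, f"ihs_sweep{i}"))
        panel, record = simulate_sweep_panel(cfg)
        scores = ihs_scan(panel.for_population(panel.populations[0]))
        defined = scores[scores["defined"]]
        near = defined.iloc[
            (defined["pos"] - record.position).abs().argsort()[:50]
        ]
        ratios.append(
            float(near["std"].abs().mean() / defined["std"].abs().mean())
        )
    ratios_arr = np.asarray(ratios)
    return {
        "mean_ratio": float(ratios_arr.mean()),
        "fraction_elevated": float((ratios_arr > 1).mean()),
        "n_replicates": n_replicates,
    }


def endtoend_replicate(
    seed: int,
    sum_permutations: int = 2_000,
    candidate_permutations: int = 10_000,
) -> dict[str, float]:
    """One full pipeline pass on a twelve-chromosome polygenic study.

    Returns the planted set's q-value under both enrichment engines.
    """
    cfg = replace(ENDTOEND_STUDY, rng_seed=seed % 2**31)
    panel, bundle, _ = simulate_polygenic_study(
        cfg,
        n_chromosomes=12,
        n_genes_per_chrom=40,
        n_sets=30,
        set_size=20,
        sweep_flank=50_000,
    )
    _, snps = _xpclr_snp_scores(panel)
    scores = pd.Series(
        snps["score_norm"].to_numpy(), index=snps["snp"].to_numpy()
    )
    positions = pd.DataFrame(
        {"snp": snps["snp"], "chrom": snps["chrom"], "pos": snps["pos"]}
    )
    gene_to_snps, snp_to_genes = assign_snps_to_genes(positions, bundle.genes)
    gene_scores = gene_scores_from_snps(scores, gene_to_snps)
    collection = prepare_genesets(bundle.gene_sets, set(gene_scores.index))
    planted = next(n for n in collection.sets if "planted" in n)
    sums = add_qvalues(
        sumscore_gsea(
            gene_scores,
            collection.sets,
            n_permutations=sum_permutations,
            seed=stage_seed(seed, "e2e_sum"),
        )
    )
    cand = add_qvalues(
        candidate_gsea(
            scores,
            snp_to_genes,
            collection.sets,
            percentile=1.0,
            n_permutations=candidate_permutations,
            seed=stage_seed(seed, "e2e_cand"),
        )
    )
    return {
        "q_sum": float(sums.set_index("set")["q"][planted]),
        "q_candidate": float(cand.set_index("set")["q"][planted]),
    }


def endtoend_power(
    seed: int, n_replicates: int = 20, q_threshold: float = 0.09
) -> dict[str, float]:
    """Fraction of polygenic-study replicates where the planted set is
    significant (q <= threshold) under both enrichment engines."""
    both = sum_only = cand_only = 0
    for i in range(n_replicates):
        res = endtoend_replicate(stage_seed(seed, f"e2e{i}"))
        s_ok = res["q_sum"] <= q_threshold
        c_ok = res["q_candidate"] <= q_threshold
        both += int(s_ok and c_ok)
        sum_only += int(s_ok)
        cand_only += int(c_ok)
    return {
        "both_engines_pct": 100.0 * both / n_replicates,
        "sum_engine_pct": 100.0 * sum_only / n_replicates,
        "candidate_engine_pct": 100.0 * cand_only / n_replicates,
        "n_replicates": n_replicates,
    }
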
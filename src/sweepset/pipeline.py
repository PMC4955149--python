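"""End-to-end orchestration: scans -> gene mapping -> set prep -> GSEA -> flags.

A :class:`PipelineConfig` collects every input path and stage parameter
(defaults follow the analysis settings: 200 bp grid, 50-SNP windows, MAF
0.05, set-size floor 10, merge similarity 0.95, candidate percentile 1,
q threshold 0.09). ``run_pipeline`` executes the stages in order, writes
every output with a provenance header (parameters, seed, version) and a
manifest of input checksums, and is byte-identical under re-runs with the
same config and inputs. A single global seed fans out to per-stage seeds by
stable hashing of stage names, so any stage re-run in isolation reproduces
its random stream.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import __version__
from ._util import SweepsetError, ValidationError, stage_seed
from .disease import flag_disease_genes
from .enrichment import (
    add_qvalues,
    candidate_gsea,
    gene_scores_from_snps,
    prune_overlapping_genes,
    sumscore_gsea,
)
from .genes import assign_snps_to_genes, consensus_position_filter
from .genesets import prepare_genesets
from .ihs import ihs_scan
from .io import (
    read_gene_list,
    read_haplotypes,
    read_support_files,
    read_table,
    write_gmt,
    write_table,
)
from .xpclr import XpclrModelConfig, xpclr_scan

logger = logging.getLogger(__name__)

_BOOL = {"true": True, "false": False, "1": True, "0": False}


@dataclass
class PipelineConfig:
    """All inputs, outputs and stage parameters of one pipeline run."""

    vcf: str = ""
    genetic_map: str = ""
    bed: str = ""
    gmt: str = ""
    disease_list: str = ""
    populations: str = ""  # TSV: sample <tab> population
    mapping_a: str = ""  # optional dual-mapping consensus inputs
    mapping_b: str = ""
    out_dir: str = "results"
    objective: str = "POP1"
    reference: str = "POP2"
    scan: str = "both"  # "ihs" | "xpclr" | "both"
    seed: int = 0
    strict: bool = True
    grid_spacing_bp: int = 200
    window_snps: int = 50
    maf_min: float = 0.05
    ihs_bins: int = 20
    min_set_size: int = 10
    merge_threshold: float = 0.95
    candidate_percentile: float = 1.0
    q_threshold: float = 0.09
    gsea_bins: int = 10
    sum_permutations: int = 10_000
    candidate_permutations: int = 100_000
    disease_percentile: float = 1.0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a plain ``key = value`` text config (# comments allowed)."""
        kwargs: dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{ln}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ValidationError(f"{path}:{ln}: unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                if value.lower() not in _BOOL:
                    raise ValidationError(f"{path}:{ln}: boolean expected for {key}")
                kwargs[key] = _BOOL[value.lower()]
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def validate(self) -> None:
        for key in ("vcf", "genetic_map", "bed", "gmt", "populations"):
            path = getattr(self, key)
            if not path:
                raise ValidationError(f"config is missing required input {key!r}")
            if not Path(path).exists():
                raise ValidationError(f"{key} input does not exist: {path}")
        if self.scan not in ("ihs", "xpclr", "both"):
            raise ValidationError(f"unknown scan selection {self.scan!r}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _header(config: PipelineConfig, stage: str, **extra: object) -> dict[str, object]:
    head: dict[str, object] = {
        "software": f"sweepset {__version__}",
        "stage": stage,
        "seed": config.seed,
    }
    head.update(extra)
    return head


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute every stage in order; returns the result tables by name.

    Any stage failure is re-raised wrapped with the stage name so the
    offending step is identifiable from the error alone.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}
    stage = "setup"
    try:
        stage = "read_inputs"
        pops = pd.read_csv(
            config.populations, sep="\t", header=None, names=["sample", "population"]
        )
        pop_map = dict(zip(pops["sample"], pops["population"]))
        panel = read_haplotypes(config.vcf, pop_map, strict=config.strict)
        gmap, genes, raw_sets = read_support_files(
            config.genetic_map, config.bed, config.gmt
        )
        panel = panel.with_genetic_map(gmap)
        disease = read_gene_list(config.disease_list) if config.disease_list else []

        stage = "consensus_filter"
        positions = pd.DataFrame(
            {"snp": panel.snp_ids, "chrom": panel.chrom, "pos": panel.pos}
        )
        if config.mapping_a and config.mapping_b:
            consensus = consensus_position_filter(
                read_table(config.mapping_a), read_table(config.mapping_b)
            )
            positions = positions[positions["snp"].isin(consensus["snp"])]

        tracks: dict[str, pd.Series] = {}
        if config.scan in ("ihs", "both"):
            stage = "scan_ihs"
            obj_panel = panel.for_population(config.objective)
            ihs = ihs_scan(obj_panel, maf_min=config.maf_min, n_bins=config.ihs_bins)
            write_table(ihs, out_dir / "ihs_scores.tsv",
                        _header(config, stage, population=config.objective,
                                maf_min=config.maf_min, bins=config.ihs_bins))
            results["ihs"] = ihs
            defined = ihs[ihs["defined"]]
            tracks["ihs"] = pd.Series(
                defined["std"].to_numpy(), index=defined["snp"].to_numpy()
            )
        if config.scan in ("xpclr", "both"):
            stage = "scan_xpclr"
            xp_cfg = XpclrModelConfig(
                grid_spacing_bp=config.grid_spacing_bp,
                window_snps=config.window_snps,
            )
            grid, snps = xpclr_scan(
                panel.frequency_table(config.objective),
                panel.frequency_table(config.reference),
                panel.for_population(config.reference),
                xp_cfg,
            )
            write_table(grid, out_dir / "xpclr_grid.tsv",
                        _header(config, stage, objective=config.objective,
                                reference=config.reference,
                                spacing=config.grid_spacing_bp,
                                window_snps=config.window_snps))
            write_table(snps, out_dir / "xpclr_scores.tsv",
                        _header(config, stage, objective=config.objective,
                                reference=config.reference))
            results["xpclr_grid"] = grid
            results["xpclr"] = snps
            tracks["xpclr"] = pd.Series(
                snps["score_norm"].to_numpy(), index=snps["snp"].to_numpy()
            )

        stage = "gene_mapping"
        gene_to_snps, snp_to_genes = assign_snps_to_genes(positions, genes)
        write_table(
            pd.DataFrame(
                [(g, ",".join(s)) for g, s in sorted(gene_to_snps.items())],
                columns=["gene", "snps"],
            ),
            out_dir / "gene_snp_map.tsv",
            _header(config, stage),
        )

        for track, snp_scores in tracks.items():
            track_snp_to_genes = {
                s: snp_to_genes.get(s, []) for s in snp_scores.index
            }
            track_gene_to_snps: dict[str, list[str]] = {g: [] for g in gene_to_snps}
            for s, gs in track_snp_to_genes.items():
                for g in gs:
                    track_gene_to_snps[g].append(s)

            stage = f"gene_scores[{track}]"
            gene_scores = gene_scores_from_snps(snp_scores, track_gene_to_snps)

            stage = f"geneset_prep[{track}]"
            collection = prepare_genesets(
                raw_sets,
                set(gene_scores.index),
                min_size=config.min_set_size,
                merge_threshold=config.merge_threshold,
            )
            write_gmt(collection.sets, out_dir / f"prepared_sets_{track}.gmt")
            write_table(
                pd.DataFrame(
                    [(n, ",".join(src)) for n, src in sorted(collection.lineage.items())],
                    columns=["set", "merged_from"],
                ),
                out_dir / f"set_lineage_{track}.tsv",
                _header(config, stage),
            )

            stage = f"gsea_sum[{track}]"
            sum_res = sumscore_gsea(
                gene_scores, collection.sets, n_bins=config.gsea_bins,
                n_permutations=config.sum_permutations,
                seed=stage_seed(config.seed, stage),
            )
            sum_res = prune_overlapping_genes(
                sum_res, collection.sets, gene_scores, n_bins=config.gsea_bins,
                n_permutations=config.sum_permutations,
                seed=stage_seed(config.seed, stage + ".prune"),
                min_size=config.min_set_size,
            )
            sum_res = add_qvalues(sum_res, config.q_threshold)
            write_table(sum_res, out_dir / f"gsea_sum_{track}.tsv",
                        _header(config, stage, permutations=config.sum_permutations,
                                q_threshold=config.q_threshold))
            results[f"gsea_sum_{track}"] = sum_res

            stage = f"gsea_candidate[{track}]"
            cand_res = candidate_gsea(
                snp_scores, track_snp_to_genes, collection.sets,
                percentile=config.candidate_percentile,
                n_permutations=config.candidate_permutations,
                seed=stage_seed(config.seed, stage),
            )
            cand_res = add_qvalues(cand_res, config.q_threshold)
            write_table(cand_res, out_dir / f"gsea_candidate_{track}.tsv",
                        _header(config, stage,
                                permutations=config.candidate_permutations,
                                percentile=config.candidate_percentile,
                                q_threshold=config.q_threshold))
            results[f"gsea_candidate_{track}"] = cand_res

            if disease:
                stage = f"disease_flags[{track}]"
                report, p_overlap = flag_disease_genes(
                    gene_scores, disease, percentile=config.disease_percentile
                )
                write_table(report, out_dir / f"disease_{track}.tsv",
                            _header(config, stage,
                                    percentile=config.disease_percentile,
                                    overlap_p=f"{p_overlap:.6g}"))
                results[f"disease_{track}"] = report

        stage = "manifest"
        inputs = [
            getattr(config, key)
            for key in ("vcf", "genetic_map", "bed", "gmt", "disease_list",
                        "populations", "mapping_a", "mapping_b")
            if getattr(config, key)
        ]
        manifest = pd.DataFrame(
            [(p, _sha256(p)) for p in inputs], columns=["input", "sha256"]
        )
        write_table(manifest, out_dir / "manifest.tsv", _header(config, stage))
    except SweepsetError as err:
        raise SweepsetError(f"pipeline stage {stage!r} failed: {err}") from err
    return results
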
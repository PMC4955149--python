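"""Readers and writers for every standard format the pipeline touches.

Internal coordinates are 1-based inclusive everywhere (the VCF convention);
BED's 0-based half-open intervals are converted at this boundary. Ancestral
alleles come from a VCF INFO key (default ``AA``) and haplotypes are recoded
so 0 = ancestral. Reading is strict by default: multiallelic, unphased, or
unpolarized records raise; lenient mode drops them with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ._util import ValidationError
from .genes import GeneModel
from .panel import GeneticMap, HaplotypePanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as an uncompressed phased VCF with AA (ancestral) INFO.

    REF/ALT orientation alternates deterministically so that reading back
    exercises the ancestral-allele recoding path, not just the identity case.
    """
    anc = (
        panel.anc_allele
        if panel.anc_allele is not None
        else np.full(panel.n_snps, "A", dtype=object)
    )
    der = (
        panel.der_allele
        if panel.der_allele is not None
        else np.full(panel.n_snps, "G", dtype=object)
    )
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in dict.fromkeys(panel.chrom):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.samples)
    )
    mat = panel.matrix
    for j in range(panel.n_snps):
        # even SNPs: REF=ancestral; odd SNPs: REF=derived (flip exercised)
        if j % 2 == 0:
            ref, alt, code = anc[j], der[j], mat[:, j]
        else:
            ref, alt, code = der[j], anc[j], 1 - mat[:, j]
        gts = "\t".join(
            f"{code[2 * i]}|{code[2 * i + 1]}" for i in range(len(panel.samples))
        )
        lines.append(
            f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_ids[j]}\t{ref}\t{alt}"
            f"\t.\tPASS\tAA={anc[j]}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_haplotypes(
    vcf_path: str | Path,
    populations: dict[str, str],
    aa_key: str = "AA",
    strict: bool = True,
) -> HaplotypePanel:
    """Read phased biallelic records into a polarized haplotype panel.

    Parameters
    ----------
    populations
        Mapping sample id -> population label; every mapped sample must be
        present in the file. Samples absent from the mapping are ignored.
    aa_key
        INFO key holding the ancestral allele.
    strict
        If True, any multiallelic, unphased, or unpolarizable record raises;
        otherwise such records are dropped with a logged count.
    """
    vcf = VCF(str(vcf_path))
    file_samples = list(vcf.samples)
    missing = set(populations) - set(file_samples)
    if missing:
        raise ValidationError(f"samples missing from VCF: {sorted(missing)}")
    keep_idx = [i for i, s in enumerate(file_samples) if s in populations]
    samples = [file_samples[i] for i in keep_idx]

    ids, chroms, poss, rows, ancs, ders = [], [], [], [], [], []
    n_dropped = {"multiallelic": 0, "unphased": 0, "unpolarized": 0}

    def reject(kind: str, v) -> None:
        if strict:
            raise ValidationError(f"{kind} record at {v.CHROM}:{v.POS} ({v.ID})")
        n_dropped[kind] += 1

    for v in vcf:
        if len(v.ALT) != 1:
            reject("multiallelic", v)
            continue
        aa = v.INFO.get(aa_key)
        if aa is None or aa not in (v.REF, v.ALT[0]):
            reject("unpolarized", v)
            continue
        gts = v.genotypes
        if any(not gts[i][2] for i in keep_idx):
            reject("unphased", v)
            continue
        hap = np.array(
            [[gts[i][0], gts[i][1]] for i in keep_idx], dtype=np.int16
        ).ravel()
        if hap.min() < 0 or hap.max() > 1:
            reject("unpolarized", v)  # missing or out-of-range allele codes
            continue
        if aa == v.ALT[0]:
            hap = 1 - hap
            anc, dercol = v.ALT[0], v.REF
        else:
            anc, dercol = v.REF, v.ALT[0]
        ids.append(v.ID if v.ID else f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        rows.append(hap.astype(np.uint8))
        ancs.append(anc)
        ders.append(dercol)
    if sum(n_dropped.values()):
        logger.warning("dropped records: %s", n_dropped)
    if not rows:
        raise ValidationError(f"no parseable records in {vcf_path}")
    return HaplotypePanel(
        snp_ids=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        matrix=np.array(rows, dtype=np.uint8).T,
        samples=samples,
        sample_population={s: populations[s] for s in samples},
        anc_allele=np.array(ancs, dtype=object),
        der_allele=np.array(ders, dtype=object),
    )


# ---------------------------------------------------------------------------
# Genetic map (TSV: chrom, pos, rate cM/Mb, cumulative cM)

def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    rows = []
    for chrom, tab in gmap.tables.items():
        pos = tab["pos"].to_numpy()
        cm = tab["cm"].to_numpy()
        rate = np.zeros(len(pos))
        if len(pos) > 1:
            seg = np.diff(cm) / np.diff(pos) * 1e6
            rate[:-1] = seg
            rate[-1] = seg[-1]
        for p, r, c in zip(pos, rate, cm):
            rows.append((chrom, int(p), r, c))
    pd.DataFrame(rows, columns=["chrom", "pos", "rate_cM_Mb", "cm"]).to_csv(
        path, sep="\t", index=False
    )


def read_genetic_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "cm"}
    if not required <= set(df.columns):
        raise ValidationError(f"genetic map needs columns {sorted(required)}")
    tables = {
        str(chrom): sub[["pos", "cm"]].reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    return GeneticMap(tables)  # monotonicity validated by the constructor


# ---------------------------------------------------------------------------
# BED (isoforms; 0-based half-open -> 1-based inclusive internally)

def write_bed(genes: list[GeneModel], path: str | Path) -> None:
    lines = []
    for g in genes:
        for start, end in g.isoforms:
            lines.append(f"{g.chrom}\t{start - 1}\t{end}\t{g.gene_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed_genes(path: str | Path) -> list[GeneModel]:
    """Read isoform intervals; one GeneModel per distinct name-column id."""
    grouped: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValidationError(f"{path}:{ln}: BED needs chrom,start,end,name")
        chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        if end <= start:
            raise ValidationError(f"{path}:{ln}: empty or inverted interval")
        iv = (start + 1, end)  # 0-based half-open -> 1-based inclusive
        if name in grouped:
            if grouped[name][0] != chrom:
                raise ValidationError(f"gene {name} spans multiple chromosomes")
            grouped[name][1].append(iv)
        else:
            grouped[name] = (chrom, [iv])
    return [GeneModel(name, chrom, ivs) for name, (chrom, ivs) in grouped.items()]


# ---------------------------------------------------------------------------
# GMT (gene sets) and plain-text lists

def write_gmt(gene_sets: dict[str, set[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na"] + sorted(members))
        for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT collection; duplicate genes within a set are collapsed."""
    sets: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{ln}: GMT needs name, desc, >=1 gene")
        name = parts[0]
        if name in sets:
            raise ValidationError(f"duplicate gene-set name {name!r} in {path}")
        sets[name] = {g for g in parts[2:] if g}
    if not sets:
        raise ValidationError(f"no gene sets in {path}")
    return sets


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    genes = [g.strip() for g in Path(path).read_text().splitlines() if g.strip()]
    return list(dict.fromkeys(genes))


# ---------------------------------------------------------------------------
# Score tracks and generic TSV with provenance headers

def write_table(
    df: pd.DataFrame, path: str | Path, header: dict[str, object] | None = None
) -> None:
    """Write a TSV with ``# key=value`` provenance header lines."""
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_support_files(
    map_path: str | Path, bed_path: str | Path, gmt_path: str | Path
) -> tuple[GeneticMap, list[GeneModel], dict[str, set[str]]]:
    """Convenience bundle reader for the three annotation inputs."""
    return read_genetic_map(map_path), read_bed_genes(bed_path), read_gmt(gmt_path)
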
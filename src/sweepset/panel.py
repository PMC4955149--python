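"""Core in-memory containers: phased haplotype panels and genetic maps.

A :class:`HaplotypePanel` holds a phased, ancestral/derived-polarized
haplotype matrix (rows = haplotypes, columns = SNPs; 0 = ancestral allele)
together with physical (bp, 1-based) and genetic (cM) coordinates and a
sample-to-population assignment. A :class:`GeneticMap` is a per-chromosome
piecewise-linear interpolation table from physical position to cumulative cM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneticMap:
    """Piecewise-linear physical-to-genetic coordinate map.

    Parameters
    ----------
    tables
        Mapping chromosome -> DataFrame with columns ``pos`` (bp, 1-based,
        strictly increasing) and ``cm`` (cumulative cM, non-decreasing).
    """

    tables: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        for chrom, tab in self.tables.items():
            pos = np.asarray(tab["pos"], dtype=float)
            cm = np.asarray(tab["cm"], dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"map positions not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValidationError(f"genetic map not monotone on chromosome {chrom}")

    @classmethod
    def from_rate_segments(
        cls, chrom: str, segments: list[tuple[int, int, float]]
    ) -> "GeneticMap":
        """Build a map from (start bp, end bp, rate cM/Mb) segments.

        Segments must be contiguous and ordered; the map anchors 0 cM at the
        first segment start.
        """
        pos = [segments[0][0]]
        cm = [0.0]
        for start, end, rate in segments:
            if start != pos[-1]:
                raise ValidationError("rate segments must be contiguous")
            pos.append(end)
            cm.append(cm[-1] + (end - start) * rate / 1e6)
        return cls({chrom: pd.DataFrame({"pos": pos, "cm": cm})})

    def interpolate(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Genetic position (cM) at each physical position, clamped at map ends."""
        if chrom not in self.tables:
            raise ValidationError(f"chromosome {chrom!r} missing from genetic map")
        tab = self.tables[chrom]
        positions = np.asarray(positions, dtype=float)
        lo, hi = tab["pos"].iloc[0], tab["pos"].iloc[-1]
        n_out = int(np.sum((positions < lo) | (positions > hi)))
        if n_out:
            logger.warning(
                "%d positions outside genetic map range on %s; clamped to map ends",
                n_out,
                chrom,
            )
        return np.interp(positions, tab["pos"].to_numpy(), tab["cm"].to_numpy())


@dataclass
class HaplotypePanel:
    """Phased, polarized haplotype panel.

    ``matrix`` has one row per haplotype and one column per SNP; entries are
    0 (ancestral) or 1 (derived). Haplotypes ``2*i`` and ``2*i + 1`` belong to
    sample ``samples[i]``.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    matrix: np.ndarray
    samples: list[str]
    sample_population: dict[str, str]
    gpos: np.ndarray | None = None
    anc_allele: np.ndarray | None = field(default=None, repr=False)
    der_allele: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.pos.size:
            raise ValidationError("haplotype matrix shape inconsistent with positions")
        if self.matrix.shape[0] != 2 * len(self.samples):
            raise ValidationError("expected two haplotypes per diploid sample")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValidationError("haplotype matrix entries must be 0/1")
        missing = set(self.samples) - set(self.sample_population)
        if missing:
            raise ValidationError(f"samples without population label: {sorted(missing)}")
        for chrom in np.unique(self.chrom):
            p = self.pos[self.chrom == chrom]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(f"positions not strictly increasing on {chrom}")

    @property
    def n_snps(self) -> int:
        return self.pos.size

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.sample_population[s], None)
        return list(seen)

    def haplotype_indices(self, population: str) -> np.ndarray:
        """Row indices of the haplotypes carried by samples of one population."""
        idx = [
            (2 * i, 2 * i + 1)
            for i, s in enumerate(self.samples)
            if self.sample_population[s] == population
        ]
        if not idx:
            raise ValidationError(f"no samples labelled {population!r}")
        return np.asarray(idx).ravel()

    def for_population(self, population: str) -> "HaplotypePanel":
        """Sub-panel restricted to one population's haplotypes."""
        rows = self.haplotype_indices(population)
        samples = [s for s in self.samples if self.sample_population[s] == population]
        return HaplotypePanel(
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            matrix=self.matrix[rows],
            samples=samples,
            sample_population={s: population for s in samples},
            gpos=self.gpos,
            anc_allele=self.anc_allele,
            der_allele=self.der_allele,
        )

    def for_chromosome(self, chrom: str) -> "HaplotypePanel":
        """Sub-panel restricted to one chromosome's SNPs."""
        cols = np.flatnonzero(self.chrom == chrom)
        if cols.size == 0:
            raise ValidationError(f"no SNPs on chromosome {chrom!r}")
        return HaplotypePanel(
            snp_ids=self.snp_ids[cols],
            chrom=self.chrom[cols],
            pos=self.pos[cols],
            matrix=self.matrix[:, cols],
            samples=self.samples,
            sample_population=self.sample_population,
            gpos=None if self.gpos is None else self.gpos[cols],
            anc_allele=None if self.anc_allele is None else self.anc_allele[cols],
            der_allele=None if self.der_allele is None else self.der_allele[cols],
        )

    def with_genetic_map(self, gmap: GeneticMap) -> "HaplotypePanel":
        """Attach genetic positions interpolated from a map."""
        gpos = np.empty(self.n_snps, dtype=float)
        for chrom in np.unique(self.chrom):
            cols = self.chrom == chrom
            gpos[cols] = gmap.interpolate(str(chrom), self.pos[cols])
        return HaplotypePanel(
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            matrix=self.matrix,
            samples=self.samples,
            sample_population=self.sample_population,
            gpos=gpos,
            anc_allele=self.anc_allele,
            der_allele=self.der_allele,
        )

    @classmethod
    def concat(cls, panels: list["HaplotypePanel"]) -> "HaplotypePanel":
        """Concatenate single-chromosome panels of the same samples."""
        first = panels[0]
        for p in panels[1:]:
            if p.samples != first.samples:
                raise ValidationError("panels must share the same samples")
        has_gpos = all(p.gpos is not None for p in panels)
        has_alleles = all(p.anc_allele is not None for p in panels)
        return cls(
            snp_ids=np.concatenate([p.snp_ids for p in panels]),
            chrom=np.concatenate([p.chrom for p in panels]),
            pos=np.concatenate([p.pos for p in panels]),
            matrix=np.hstack([p.matrix for p in panels]),
            samples=first.samples,
            sample_population=first.sample_population,
            gpos=np.concatenate([p.gpos for p in panels]) if has_gpos else None,
            anc_allele=(
                np.concatenate([p.anc_allele for p in panels]) if has_alleles else None
            ),
            der_allele=(
                np.concatenate([p.der_allele for p in panels]) if has_alleles else None
            ),
        )

    def derived_frequencies(self, population: str | None = None) -> np.ndarray:
        """Sample derived-allele frequency at each SNP."""
        rows = (
            slice(None)
            if population is None
            else self.haplotype_indices(population)
        )
        return self.matrix[rows].mean(axis=0)

    def frequency_table(self, population: str) -> pd.DataFrame:
        """Per-SNP derived-allele sample frequency table for one population."""
        rows = self.haplotype_indices(population)
        sub = self.matrix[rows]
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "gpos": self.gpos if self.gpos is not None else np.nan,
                "freq": sub.mean(axis=0),
                "count": sub.sum(axis=0).astype(int),
                "n_chrom": sub.shape[0],
            }
        )
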
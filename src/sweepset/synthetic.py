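"""Synthetic population-genetic data with the structure the pipeline assumes.

Three generators:

* :func:`simulate_divergence_freqs` — per-SNP derived-allele frequencies for
  diverged populations under the Balding–Nichols model (beta-distributed
  population frequencies around a shared ancestral frequency, differentiation
  parameter ``F``), with binomial allele-count sampling.
* :func:`simulate_sweep_panel` — phased, polarized haplotype panels from a
  forward diploid Wright–Fisher simulation with additive selection at a
  chosen sweep site and Poisson crossovers on the genetic map. Supports hard
  (run to fixation) and incomplete (stop at a target derived frequency)
  sweeps from standing variation.
* :func:`generate_annotation_bundle` — gene models with isoforms tiling the
  chromosome, overlapping gene sets including a "planted" set containing the
  genes over the sweep region, and a disease-gene list.

All generators are bit-deterministic under a fixed ``rng_seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import SweepsetError, ValidationError
from .genes import GeneModel
from .panel import GeneticMap, HaplotypePanel

logger = logging.getLogger(__name__)

# Ancestral-frequency prior keeps simulated SNPs likely polymorphic; the
# pipeline filters monomorphic sites anyway, mimicking SNP-array ascertainment.
ANC_FREQ_LOW = 0.05
ANC_FREQ_HIGH = 0.95


@dataclass
class SimulationConfig:
    """All generator knobs; one config reproduces one dataset bit-for-bit.

    Notes on defaults: the chromosome is a 1 Mb segment with a total genetic
    length of 1 Morgan (``recomb_rate`` 100 cM/Mb). Because every statistic
    here works in genetic distance, this is a full-length chromosome analog
    (about 100 Mb at the human-average 1 cM/Mb) with physical coordinates
    compressed a hundredfold. A map of order one Morgan means essentially
    every meiosis recombines, so haplotype homozygosity decays well inside
    the chromosome and EHH curves terminate before its ends.
    """

    populations: tuple[str, ...] = ("POP1", "POP2")
    n_diploids: int = 100  # per population
    n_snps: int = 2000
    chromosome_length: int = 1_000_000
    chrom: str = "1"
    recomb_rate: float | list[tuple[int, int, float]] = 100.0  # cM/Mb
    divergence_F: tuple[float, ...] = (0.05, 0.05)  # per population, in [0, 1)
    sweep_site: int | None = None  # SNP index in the first population
    selection_coefficient: float = 0.0  # additive fitness 1, 1+s, 1+2s
    sweep_mode: str = "hard"  # "hard" | "incomplete"
    sweep_target_freq: float = 1.0  # stop threshold for incomplete sweeps
    sweep_init_freq: float = 0.02  # standing-variation start frequency
    sweep_origin: str = "single"  # "single" | "multiple" haplotype backgrounds
    n_generations: int = 150
    founder_haplotypes: int = 20  # K: mosaic founders per population
    founder_switch_rate: float = 30.0  # expected mosaic switches per Morgan
    rng_seed: int = 0
    max_sweep_retries: int = 100

    def __post_init__(self) -> None:
        if len(self.divergence_F) != len(self.populations):
            raise ValidationError("need one divergence F per population")
        for f in self.divergence_F:
            if not (0.0 <= f < 1.0):
                raise ValidationError(f"divergence F must be in [0, 1); got {f}")
        if self.selection_coefficient < 0:
            raise ValidationError("selection coefficient must be >= 0")
        if not (0.0 < self.sweep_target_freq <= 1.0):
            raise ValidationError("sweep target frequency must be in (0, 1]")
        if self.sweep_mode not in ("hard", "incomplete"):
            raise ValidationError(f"unknown sweep mode {self.sweep_mode!r}")
        if self.founder_haplotypes < 2:
            raise ValidationError("need at least 2 founder haplotypes")
        if self.n_snps < 1:
            raise ValidationError("need at least one SNP")

    def genetic_map(self) -> GeneticMap:
        if isinstance(self.recomb_rate, (int, float)):
            segments = [(1, self.chromosome_length, float(self.recomb_rate))]
        else:
            segments = list(self.recomb_rate)
        return GeneticMap.from_rate_segments(self.chrom, segments)


@dataclass
class SweepRecord:
    """Ground truth for a planted sweep."""

    population: str
    chrom: str
    snp_index: int
    position: int
    selection_coefficient: float
    mode: str
    initial_freq: float
    final_freq: float
    n_generations_run: int
    n_attempts: int
    trajectory: list[float] = field(repr=False, default_factory=list)


class SweepLostError(SweepsetError):
    """The beneficial allele was lost in every allowed attempt."""


def _draw_positions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    pos = rng.choice(
        np.arange(1, config.chromosome_length + 1), size=config.n_snps, replace=False
    )
    return np.sort(pos)


def simulate_divergence_freqs(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Balding–Nichols derived-allele frequencies and sampled counts.

    The ancestral frequency of each SNP is Uniform(0.05, 0.95); each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) (equal to the
    ancestral frequency when F = 0); allele counts are Binomial(2n, freq).
    SNPs monomorphic in a sample are flagged via ``poly_<pop>`` columns for
    the polymorphic-in-both filter.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    pos = _draw_positions(config, rng)
    p_anc = rng.uniform(ANC_FREQ_LOW, ANC_FREQ_HIGH, config.n_snps)
    out = pd.DataFrame(
        {
            "snp": [f"snp{i}" for i in range(config.n_snps)],
            "chrom": config.chrom,
            "pos": pos,
            "p_anc": p_anc,
        }
    )
    n_chrom = 2 * config.n_diploids
    for pop, f in zip(config.populations, config.divergence_F):
        if f == 0.0:
            p = p_anc.copy()
        else:
            scale = (1.0 - f) / f
            p = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
        count = rng.binomial(n_chrom, p)
        out[f"p_{pop}"] = p
        out[f"count_{pop}"] = count
        out[f"freq_{pop}"] = count / n_chrom
        out[f"poly_{pop}"] = (count > 0) & (count < n_chrom)
    return out


def _founder_mosaics(
    n_hap: int,
    founders: np.ndarray,
    gpos_morgans: np.ndarray,
    switch_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial haplotypes copied in segments from K founders.

    Switch points follow a Poisson process along the genetic map, creating
    LD that decays on the 1/switch_rate Morgan scale.
    """
    total = gpos_morgans[-1] - gpos_morgans[0]
    k = founders.shape[0]
    out = np.empty((n_hap, founders.shape[1]), dtype=np.uint8)
    for h in range(n_hap):
        n_switch = rng.poisson(switch_rate * total)
        breaks = np.sort(rng.uniform(gpos_morgans[0], gpos_morgans[-1], n_switch))
        seg_of_snp = np.searchsorted(breaks, gpos_morgans, side="right")
        founder_per_seg = rng.integers(0, k, n_switch + 1)
        out[h] = founders[founder_per_seg[seg_of_snp], np.arange(founders.shape[1])]
    return out


def _recombine(
    haps: np.ndarray,
    parents: np.ndarray,
    gpos_morgans: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiosis per gamete: Poisson crossovers on the genetic map."""
    n_gam = parents.size
    n_snps = haps.shape[1]
    total = gpos_morgans[-1] - gpos_morgans[0]
    n_cx = rng.poisson(total, n_gam)
    phase = rng.integers(0, 2, n_gam)
    child = np.empty((n_gam, n_snps), dtype=np.uint8)
    simple = n_cx == 0
    child[simple] = haps[2 * parents[simple] + phase[simple]]
    for i in np.flatnonzero(~simple):
        cx = rng.uniform(gpos_morgans[0], gpos_morgans[-1], n_cx[i])
        n_before = np.searchsorted(np.sort(cx), gpos_morgans, side="right")
        use_other = (n_before % 2).astype(bool)
        a = haps[2 * parents[i] + phase[i]]
        b = haps[2 * parents[i] + 1 - phase[i]]
        child[i] = np.where(use_other, b, a)
    return child


def _evolve_population(
    haps: np.ndarray,
    gpos_morgans: np.ndarray,
    n_generations: int,
    rng: np.random.Generator,
    sweep_site: int | None,
    s: float,
    stop_freq: float | None,
) -> tuple[np.ndarray, list[float], bool, int]:
    """Wright–Fisher evolution; returns (haps, trajectory, lost, gens_run).

    ``stop_freq`` stops the simulation the first generation the derived
    frequency at ``sweep_site`` reaches it (fixation for hard sweeps, the
    target frequency for incomplete ones); ``None`` runs all generations.
    """
    n_hap = haps.shape[0]
    n_dip = n_hap // 2
    traj: list[float] = []
    if sweep_site is not None:
        traj.append(haps[:, sweep_site].mean())
    for gen in range(1, n_generations + 1):
        if sweep_site is not None and s > 0:
            gt = haps[0::2, sweep_site].astype(float) + haps[1::2, sweep_site]
            fitness = 1.0 + s * gt
            weights = fitness / fitness.sum()
            parents = rng.choice(n_dip, size=n_hap, p=weights)
        else:
            parents = rng.integers(0, n_dip, n_hap)
        haps = _recombine(haps, parents, gpos_morgans, rng)
        if sweep_site is not None:
            freq = haps[:, sweep_site].mean()
            traj.append(freq)
            if freq == 0.0:
                return haps, traj, True, gen
            if stop_freq is not None and freq >= stop_freq:
                return haps, traj, False, gen
    return haps, traj, False, n_generations


def simulate_sweep_panel(
    config: SimulationConfig,
) -> tuple[HaplotypePanel, SweepRecord | None]:
    """Forward Wright–Fisher haplotype panel with an optional planted sweep.

    Each population starts from mosaics of K random founder haplotypes whose
    allele frequencies follow the Balding–Nichols draw for that population,
    then evolves by random-mating diploid Wright–Fisher reproduction with
    per-generation Poisson crossovers. Additive selection (fitness 1, 1+s,
    1+2s) acts at ``sweep_site`` in the first population. If the beneficial
    allele is lost, the whole simulation retries with an incremented seed up
    to ``max_sweep_retries`` times before raising :class:`SweepLostError`.
    """
    for attempt in range(config.max_sweep_retries + 1):
        # large-stride retry seeds so nearby user seeds stay independent
        cfg = replace(
            config, rng_seed=(config.rng_seed + attempt * 15_485_863) % 2**31
        )
        result = _simulate_panel_once(cfg, attempt + 1)
        if result is not None:
            panel, record = result
            if attempt:
                logger.info("sweep succeeded on attempt %d", attempt + 1)
            return panel, record
    raise SweepLostError(
        f"beneficial allele lost in all {config.max_sweep_retries + 1} attempts"
    )


def _simulate_panel_once(
    config: SimulationConfig, attempt: int
) -> tuple[HaplotypePanel, SweepRecord | None] | None:
    rng = np.random.default_rng(config.rng_seed)
    freqs = simulate_divergence_freqs(config, rng)
    gmap = config.genetic_map()
    pos = freqs["pos"].to_numpy()
    gpos_cm = gmap.interpolate(config.chrom, pos)
    gpos_m = gpos_cm / 100.0
    n_hap = 2 * config.n_diploids

    sweep_site = config.sweep_site
    selected = config.selection_coefficient > 0 and sweep_site is not None
    if sweep_site is not None and not (0 <= sweep_site < config.n_snps):
        raise ValidationError("sweep site index out of range")

    # The sweep population evolves first; every other population is then run
    # for the same number of generations so all samples are contemporaneous.
    matrices: list[np.ndarray | None] = [None] * len(config.populations)
    record: SweepRecord | None = None
    n_generations_all = config.n_generations

    p_pop0 = freqs[f"p_{config.populations[0]}"].to_numpy()
    founders = (
        rng.random((config.founder_haplotypes, config.n_snps)) < p_pop0
    ).astype(np.uint8)
    haps = _founder_mosaics(n_hap, founders, gpos_m, config.founder_switch_rate, rng)
    init_freq = np.nan
    if sweep_site is not None:
        n_init = max(1, round(config.sweep_init_freq * n_hap))
        carriers = rng.choice(n_hap, n_init, replace=False)
        if config.sweep_origin == "single" and n_init > 1:
            # all initial copies share one haplotype background (single-origin
            # standing variant: classic hard-sweep LD signature)
            haps[carriers[1:]] = haps[carriers[0]]
        haps[:, sweep_site] = 0
        haps[carriers, sweep_site] = 1
        init_freq = n_init / n_hap
    if selected:
        stop = 1.0 if config.sweep_mode == "hard" else config.sweep_target_freq
    else:
        stop = None
    haps, traj, lost, gens = _evolve_population(
        haps,
        gpos_m,
        config.n_generations,
        rng,
        sweep_site,
        config.selection_coefficient,
        stop,
    )
    if selected:
        final = haps[:, sweep_site].mean()
        reached = final >= (
            1.0 if config.sweep_mode == "hard" else config.sweep_target_freq
        )
        if lost or not reached:
            return None  # retry with next seed
        n_generations_all = gens
        record = SweepRecord(
            population=config.populations[0],
            chrom=config.chrom,
            snp_index=sweep_site,
            position=int(pos[sweep_site]),
            selection_coefficient=config.selection_coefficient,
            mode=config.sweep_mode,
            initial_freq=float(init_freq),
            final_freq=float(final),
            n_generations_run=gens,
            n_attempts=attempt,
            trajectory=[float(x) for x in traj],
        )
    elif sweep_site is not None:
        # neutral marked site: no completion criterion, keep the truth record
        record = SweepRecord(
            population=config.populations[0],
            chrom=config.chrom,
            snp_index=sweep_site,
            position=int(pos[sweep_site]),
            selection_coefficient=0.0,
            mode="neutral",
            initial_freq=float(init_freq),
            final_freq=float(haps[:, sweep_site].mean()),
            n_generations_run=gens,
            n_attempts=attempt,
            trajectory=[float(x) for x in traj],
        )
    matrices[0] = haps

    for pop_i, pop in enumerate(config.populations[1:], start=1):
        p_pop = freqs[f"p_{pop}"].to_numpy()
        founders = (
            rng.random((config.founder_haplotypes, config.n_snps)) < p_pop
        ).astype(np.uint8)
        haps = _founder_mosaics(
            n_hap, founders, gpos_m, config.founder_switch_rate, rng
        )
        haps, _, _, _ = _evolve_population(
            haps, gpos_m, n_generations_all, rng, None, 0.0, None
        )
        matrices[pop_i] = haps

    matrix = np.vstack(matrices)
    samples = []
    sample_pop = {}
    for pop in config.populations:
        for i in range(config.n_diploids):
            sid = f"{pop}_s{i}"
            samples.append(sid)
            sample_pop[sid] = pop
    # REF/ALT letters: ancestral A, derived G throughout (polarity is what matters)
    panel = HaplotypePanel(
        snp_ids=freqs["snp"].to_numpy(dtype=object),
        chrom=np.full(config.n_snps, config.chrom, dtype=object),
        pos=pos,
        matrix=matrix,
        samples=samples,
        sample_population=sample_pop,
        gpos=gpos_cm,
        anc_allele=np.full(config.n_snps, "A", dtype=object),
        der_allele=np.full(config.n_snps, "G", dtype=object),
    )
    return panel, record


def _tile_genes(
    chrom: str, length: int, n_genes: int, rng: np.random.Generator,
    prefix: str = "gene",
) -> list[GeneModel]:
    """Genes tiling [1, length] with variable lengths and 1-3 isoforms each."""
    bounds = np.linspace(1, length, n_genes + 1).astype(int)
    genes: list[GeneModel] = []
    for i in range(n_genes):
        lo, hi = int(bounds[i]), int(bounds[i + 1] - 1)
        span = hi - lo
        # variable gene length: 40-95 % of the tile
        glen = int(span * rng.uniform(0.4, 0.95))
        gstart = int(lo + rng.integers(0, span - glen + 1))
        gend = gstart + glen
        n_iso = int(rng.integers(1, 4))
        isoforms = []
        for _ in range(n_iso):
            a, b = np.sort(rng.integers(gstart, gend + 1, 2))
            isoforms.append((int(a), int(max(a + 1, b))))
        # force the union interval to span exactly [gstart, gend]
        isoforms[0] = (gstart, isoforms[0][1])
        isoforms[-1] = (isoforms[-1][0], gend)
        if isoforms[-1][0] > gend:
            isoforms[-1] = (gstart, gend)
        genes.append(GeneModel(f"{prefix}{i:03d}", chrom, isoforms))
    return genes


@dataclass
class AnnotationBundle:
    """Gene models, gene sets, and a disease list matched to a panel."""

    genes: list[GeneModel]
    gene_sets: dict[str, set[str]]
    disease_genes: list[str]
    planted_set: str | None

    def __post_init__(self) -> None:
        known = {g.gene_id for g in self.genes}
        for name, members in self.gene_sets.items():
            unknown = set(members) - known
            if unknown:
                raise ValidationError(
                    f"gene set {name} references unknown genes: {sorted(unknown)[:5]}"
                )


def generate_annotation_bundle(
    config: SimulationConfig,
    panel: HaplotypePanel,
    sweep_record: SweepRecord | None = None,
    n_genes: int = 80,
    n_sets: int = 30,
    set_size: int = 15,
    overlap_pairs: list[tuple[float, float]] | None = None,
    sweep_flank: int = 25_000,
    n_disease: int = 20,
    disease_sweep_overlap: float = 0.3,
    rng: np.random.Generator | None = None,
) -> AnnotationBundle:
    """Gene models tiling the chromosome, gene sets, and a disease list.

    Genes tile the chromosome with variable lengths and 1–3 isoforms each;
    the union interval of the isoforms spans the gene. ``overlap_pairs`` is a
    list of Jaccard-similarity targets; for each, an extra pair of sets with
    that (integer-rounded) realized Jaccard is appended. When a sweep is
    present, the set named ``"planted"`` contains every gene overlapping
    ``position ± sweep_flank``, padded with random genes up to ``set_size``.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 10_007)
    if n_sets < 1 or set_size < 1:
        raise ValidationError("need at least one set of at least one gene")
    if set_size > n_genes:
        raise ValidationError("requested set size exceeds gene count")
    genes = _tile_genes(config.chrom, config.chromosome_length, n_genes, rng)

    gene_ids = [g.gene_id for g in genes]
    gene_sets: dict[str, set[str]] = {}
    planted_name: str | None = None
    if sweep_record is not None:
        center = sweep_record.position
        in_window = [
            g.gene_id
            for g in genes
            if g.union_interval[0] <= center + sweep_flank
            and g.union_interval[1] >= center - sweep_flank
        ]
        members = set(in_window)
        pool = [g for g in gene_ids if g not in members]
        extra = set_size - len(members)
        if extra > 0:
            members |= set(rng.choice(pool, size=extra, replace=False))
        planted_name = "planted"
        gene_sets[planted_name] = members
    for j in range(n_sets - len(gene_sets)):
        gene_sets[f"set{j:03d}"] = set(
            rng.choice(gene_ids, size=set_size, replace=False)
        )
    for i, jaccard in enumerate(overlap_pairs or []):
        target = float(jaccard) if not isinstance(jaccard, tuple) else jaccard[0]
        if not (0.0 <= target <= 1.0):
            raise ValidationError("overlap Jaccard target must be in [0, 1]")
        shared = round(2 * set_size * target / (1.0 + target))
        a = list(rng.choice(gene_ids, size=set_size, replace=False))
        rest = [g for g in gene_ids if g not in a]
        if set_size - shared > len(rest):
            raise ValidationError("not enough genes for requested overlap pair")
        b = a[:shared] + list(rng.choice(rest, size=set_size - shared, replace=False))
        gene_sets[f"ovlA{i}"] = set(a)
        gene_sets[f"ovlB{i}"] = set(b)

    sweep_pool = (
        sorted(gene_sets[planted_name]) if planted_name is not None else gene_ids
    )
    n_sweep = min(int(round(n_disease * disease_sweep_overlap)), len(sweep_pool))
    disease = list(rng.choice(sweep_pool, size=n_sweep, replace=False))
    rest = [g for g in gene_ids if g not in disease]
    disease += list(rng.choice(rest, size=n_disease - n_sweep, replace=False))
    return AnnotationBundle(
        genes=genes,
        gene_sets=gene_sets,
        disease_genes=sorted(disease),
        planted_set=planted_name,
    )


def simulate_polygenic_study(
    config: SimulationConfig,
    n_chromosomes: int = 3,
    n_genes_per_chrom: int = 80,
    n_sets: int = 30,
    set_size: int = 20,
    sweep_flank: int = 35_000,
    n_disease: int = 20,
    disease_sweep_overlap: float = 0.3,
) -> tuple[HaplotypePanel, AnnotationBundle, list[SweepRecord]]:
    """A multi-chromosome study with one planted sweep per chromosome.

    Polygenic adaptation spreads weak-to-moderate sweeps over several loci of
    one pathway; this generator emulates that by simulating ``n_chromosomes``
    independent chromosomes from ``config`` (seeds strided per chromosome)
    and planting ``config``'s sweep on each. The ``"planted"`` gene set is
    the union over chromosomes of the genes overlapping each sweep position
    ± ``sweep_flank``, padded with random genes up to ``set_size``; the other
    sets are drawn across all chromosomes.
    """
    rng = np.random.default_rng(config.rng_seed + 20_011)
    panels: list[HaplotypePanel] = []
    records: list[SweepRecord] = []
    genes: list[GeneModel] = []
    for c in range(n_chromosomes):
        cfg = replace(
            config,
            chrom=str(c + 1),
            rng_seed=(config.rng_seed + c * 7_368_787) % 2**31,
        )
        panel, record = simulate_sweep_panel(cfg)
        panel.snp_ids = np.array(
            [f"c{cfg.chrom}_{s}" for s in panel.snp_ids], dtype=object
        )
        panels.append(panel)
        if record is not None:
            records.append(record)
        genes.extend(
            _tile_genes(
                cfg.chrom, cfg.chromosome_length, n_genes_per_chrom, rng,
                prefix=f"c{cfg.chrom}_gene",
            )
        )
    panel = HaplotypePanel.concat(panels)

    gene_ids = [g.gene_id for g in genes]
    gene_sets: dict[str, set[str]] = {}
    planted_name: str | None = None
    if records:
        members: set[str] = set()
        for rec in records:
            members |= {
                g.gene_id
                for g in genes
                if g.chrom == rec.chrom
                and g.union_interval[0] <= rec.position + sweep_flank
                and g.union_interval[1] >= rec.position - sweep_flank
            }
        pool = [g for g in gene_ids if g not in members]
        extra = set_size - len(members)
        if extra > 0:
            members |= set(rng.choice(pool, size=extra, replace=False))
        planted_name = "planted"
        gene_sets[planted_name] = members
    for j in range(n_sets - len(gene_sets)):
        gene_sets[f"set{j:03d}"] = set(
            rng.choice(gene_ids, size=set_size, replace=False)
        )
    sweep_pool = (
        sorted(gene_sets[planted_name]) if planted_name is not None else gene_ids
    )
    n_sweep = min(int(round(n_disease * disease_sweep_overlap)), len(sweep_pool))
    disease = list(rng.choice(sweep_pool, size=n_sweep, replace=False))
    rest = [g for g in gene_ids if g not in disease]
    disease += list(rng.choice(rest, size=n_disease - n_sweep, replace=False))
    bundle = AnnotationBundle(
        genes=genes,
        gene_sets=gene_sets,
        disease_genes=sorted(disease),
        planted_set=planted_name,
    )
    return panel, bundle, records
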
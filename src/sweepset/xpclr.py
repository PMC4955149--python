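"""Cross-population composite-likelihood-ratio selection scan.

The scan contrasts, at grid points laid every 200 bp along each chromosome,
a selective-sweep model against neutral drift for the objective population's
allele frequencies given the reference population's. Under drift alone the
objective frequency p1 at a SNP is modelled as a normal around the reference
frequency p2 with variance omega * p2 * (1 - p2), truncated to (0, 1) and
renormalized (omega is a drift coefficient estimated from the data by the
method of moments). Under a sweep centred at the grid point, a lineage at
recombination distance r escapes the sweep with probability
c = 1 - exp(-r / q), where q (Morgans) scales with sweep strength: with
probability p2 the sampled allele hitchhiked with the beneficial allele
(p1 = (1 - c) + c Z) and with probability 1 - p2 it did not (p1 = c Z),
Z being the truncated-normal drift variable. q = 0 forces c = 1 and
collapses the sweep density to the neutral one exactly.

The window around each grid point holds the 50 retained SNPs nearest to it
(up to 25 per side); SNP k is down-weighted by 1/m_k where m_k counts the
window SNPs in strong LD with it (r^2 >= 0.95 in the reference population).
The grid score is 2 * (max over the q grid of the weighted log composite
likelihood minus its neutral value), hence >= 0. Each SNP inherits the score
of its nearest grid point, and SNP scores are genome-normalized to zero mean
and unit variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._util import ValidationError
from .panel import HaplotypePanel

logger = logging.getLogger(__name__)


def _default_q_grid() -> np.ndarray:
    return np.concatenate([[0.0], np.logspace(-6, -1, 15)])


@dataclass
class XpclrModelConfig:
    """Model and windowing parameters for the scan."""

    grid_spacing_bp: int = 200
    window_snps: int = 50
    q_grid: np.ndarray = field(default_factory=_default_q_grid)
    ld_r2_threshold: float = 0.95
    omega_floor: float = 1e-4
    # e^-20 is far below any density resolvable from sample frequencies with
    # hundreds of chromosomes; a deeper floor would let a single out-of-support
    # SNP dominate a whole window's composite score
    log_density_floor: float = -20.0

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        if 0.0 not in self.q_grid:
            raise ValidationError("the sweep-scale grid must include q = 0")
        if self.grid_spacing_bp <= 0:
            raise ValidationError("grid spacing must be positive")
        if self.window_snps < 1:
            raise ValidationError("window size must be >= 1")


def polymorphic_filter(
    freqs_obj: pd.DataFrame, freqs_ref: pd.DataFrame
) -> pd.Index:
    """SNP ids with 0 < sample frequency < 1 in both populations.

    Both tables need columns ``snp`` and ``freq`` and must cover the same
    SNP ids.
    """
    a = freqs_obj.set_index("snp")["freq"]
    b = freqs_ref.set_index("snp")["freq"]
    if not a.index.equals(b.index):
        raise ValidationError("frequency tables must be indexed by the same SNPs")
    keep = a.index[(a > 0) & (a < 1) & (b > 0) & (b < 1)]
    logger.info("polymorphic-in-both filter: %d of %d SNPs retained", len(keep), len(a))
    if keep.empty:
        raise ValidationError("no SNP polymorphic in both populations; nothing to scan")
    return keep


def estimate_drift(
    freqs_obj: pd.DataFrame,
    freqs_ref: pd.DataFrame,
    retained: pd.Index,
    omega_floor: float = 1e-4,
) -> float:
    """Method-of-moments drift coefficient omega.

    Mean over retained SNPs of (p1 - p2)^2 / (p2 (1 - p2)), floored at
    ``omega_floor`` so a zero-differentiation limit stays usable as a
    variance parameter.
    """
    if len(retained) < 1:
        raise ValidationError("need at least one retained SNP")
    p1 = freqs_obj.set_index("snp")["freq"].loc[retained].to_numpy()
    p2 = freqs_ref.set_index("snp")["freq"].loc[retained].to_numpy()
    omega = float(np.mean((p1 - p2) ** 2 / (p2 * (1.0 - p2))))
    return max(omega, omega_floor)


def _truncnorm_pdf(z: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """Density of Normal(mu, sd^2) truncated to (0, 1), renormalized."""
    norm_mass = ndtr((1.0 - mu) / sd) - ndtr((0.0 - mu) / sd)
    inside = (z > 0.0) & (z < 1.0)
    pdf = np.where(
        inside,
        np.exp(-0.5 * ((z - mu) / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi)),
        0.0,
    )
    return pdf / norm_mass


def sweep_density(
    p1: np.ndarray | float,
    p2: float,
    omega: float,
    c: np.ndarray | float,
) -> np.ndarray:
    """Density of the objective frequency under the sweep mixture model.

    c is the escape probability; c = 1 recovers the neutral truncated-normal
    drift density exactly.
    """
    p1 = np.asarray(p1, dtype=float)
    c = np.asarray(c, dtype=float)
    sd = np.sqrt(omega * p2 * (1.0 - p2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z_hitch = (p1 - (1.0 - c)) / c
        z_escape = p1 / c
    safe_c = np.where(c > 0, c, np.nan)
    dens = (
        p2 * _truncnorm_pdf(z_hitch, p2, sd) / safe_c
        + (1.0 - p2) * _truncnorm_pdf(z_escape, p2, sd) / safe_c
    )
    return np.where(c > 0, dens, 0.0)


def window_composite_loglik(
    p1: np.ndarray,
    p2: np.ndarray,
    r_morgans: np.ndarray,
    weights: np.ndarray,
    omega: float,
    q: float,
    log_density_floor: float = -20.0,
) -> float:
    """Weighted log composite likelihood of one window at sweep scale q.

    Per-SNP log densities below ``log_density_floor`` are floored (underflow
    or out-of-support observations under small escape probabilities).
    """
    if q < 0:
        raise ValidationError("sweep scale q must be >= 0")
    c = np.ones_like(r_morgans) if q == 0.0 else 1.0 - np.exp(-r_morgans / q)
    total = 0.0
    for k in range(p1.size):
        dens = float(sweep_density(p1[k], float(p2[k]), omega, float(c[k])))
        log_d = np.log(dens) if dens > 0 else -np.inf
        total += weights[k] * max(log_d, log_density_floor)
    return float(total)


def _window_logliks(
    p1: np.ndarray,
    p2: np.ndarray,
    r: np.ndarray,
    weights: np.ndarray,
    omega: float,
    q_grid: np.ndarray,
    floor: float,
) -> np.ndarray:
    """Vectorized per-q weighted log composite likelihoods for one window."""
    nq, nk = q_grid.size, p1.size
    with np.errstate(divide="ignore", over="ignore"):
        c = 1.0 - np.exp(-r[None, :] / q_grid[:, None])  # (nq, nk)
    c[q_grid == 0.0, :] = 1.0
    sd = np.sqrt(omega * p2 * (1.0 - p2))  # (nk,)
    norm_mass = ndtr((1.0 - p2) / sd) - ndtr(-p2 / sd)

    def tr_pdf(z: np.ndarray) -> np.ndarray:
        inside = (z > 0.0) & (z < 1.0)
        pdf = np.where(
            inside,
            np.exp(-0.5 * ((z - p2[None, :]) / sd[None, :]) ** 2)
            / (sd[None, :] * np.sqrt(2.0 * np.pi)),
            0.0,
        )
        return pdf / norm_mass[None, :]

    with np.errstate(divide="ignore", invalid="ignore"):
        z_hitch = (p1[None, :] - (1.0 - c)) / c
        z_escape = p1[None, :] / c
        dens = (p2[None, :] * tr_pdf(z_hitch) + (1.0 - p2[None, :]) * tr_pdf(z_escape)) / c
    dens = np.where(c > 0.0, dens, 0.0)
    with np.errstate(divide="ignore"):
        log_d = np.where(dens > 0.0, np.log(np.where(dens > 0.0, dens, 1.0)), -np.inf)
    log_d = np.maximum(log_d, floor)
    return log_d @ weights  # (nq,)


def xpclr_scan(
    freqs_obj: pd.DataFrame,
    freqs_ref: pd.DataFrame,
    ref_panel: HaplotypePanel,
    config: XpclrModelConfig | None = None,
    omega: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grid scores and genome-normalized SNP scores.

    Parameters
    ----------
    freqs_obj, freqs_ref
        Per-SNP frequency tables (columns ``snp, chrom, pos, gpos, freq``)
        for the objective and reference populations, on the same SNPs.
    ref_panel
        Reference-population haplotypes, used only for the LD (r^2)
        down-weighting; its SNP order must match the frequency tables.
    omega
        Drift coefficient; estimated from the retained SNPs when None.

    Returns
    -------
    (grid, snps)
        ``grid``: chrom, grid position, window size, best q, raw score.
        ``snps``: per-SNP raw and genome-normalized scores.
    """
    config = config or XpclrModelConfig()
    retained = polymorphic_filter(freqs_obj, freqs_ref)
    if omega is None:
        omega = estimate_drift(freqs_obj, freqs_ref, retained, config.omega_floor)
    logger.info("drift coefficient omega = %.5f", omega)

    obj = freqs_obj.set_index("snp").loc[retained]
    ref = freqs_ref.set_index("snp").loc[retained]
    col_of = {s: i for i, s in enumerate(ref_panel.snp_ids)}
    missing = [s for s in obj.index if s not in col_of]
    if missing:
        raise ValidationError(f"LD panel lacks SNPs: {missing[:5]}")
    obj = obj.assign(_col=[col_of[s] for s in obj.index])
    obj = obj.sort_values(["chrom", "pos"], kind="stable")
    ref = ref.loc[obj.index]
    half = config.window_snps // 2

    grid_rows = []
    snp_rows = []
    for chrom in dict.fromkeys(obj["chrom"]):
        mask = (obj["chrom"] == chrom).to_numpy()
        pos = obj.loc[mask, "pos"].to_numpy()
        gpos_cm = obj.loc[mask, "gpos"].to_numpy()
        p1 = obj.loc[mask, "freq"].to_numpy()
        p2 = ref.loc[mask, "freq"].to_numpy()
        snp_ids = obj.index.to_numpy()[mask]
        ref_H = ref_panel.matrix[:, obj.loc[mask, "_col"].to_numpy()]

        grid_pos = np.arange(pos[0], pos[-1] + 1, config.grid_spacing_bp)
        grid_gpos = np.interp(grid_pos, pos, gpos_cm)
        scores = np.full(grid_pos.size, np.nan)
        qhats = np.full(grid_pos.size, np.nan)
        win_cache: dict[tuple[int, int], np.ndarray] = {}
        for gi, (g, gcm) in enumerate(zip(grid_pos, grid_gpos)):
            iright = int(np.searchsorted(pos, g, side="right"))
            lo = max(0, iright - half)
            hi = min(pos.size, iright + half)
            if hi - lo < 2:
                logger.info("grid point %s:%d skipped (<2 window SNPs)", chrom, g)
                continue
            key = (lo, hi)
            if key not in win_cache:
                r2 = np.corrcoef(ref_H[:, lo:hi].T) ** 2
                m = (r2 >= config.ld_r2_threshold).sum(axis=1)
                win_cache[key] = 1.0 / m
            weights = win_cache[key]
            r = np.abs(gpos_cm[lo:hi] - gcm) / 100.0  # cM -> Morgans
            lls = _window_logliks(
                p1[lo:hi], p2[lo:hi], r, weights, omega,
                config.q_grid, config.log_density_floor,
            )
            neutral = lls[config.q_grid == 0.0][0]
            best = int(np.argmax(lls))
            scores[gi] = 2.0 * (lls[best] - neutral)
            qhats[gi] = config.q_grid[best]
        grid_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "grid_pos": grid_pos,
                    "qhat": qhats,
                    "score": scores,
                }
            )
        )
        # SNP score = score of the nearest scored grid point (ties -> lower coord)
        ok = ~np.isnan(scores)
        gp, gs = grid_pos[ok], scores[ok]
        idx = np.searchsorted(gp, pos)
        idx = np.clip(idx, 1, gp.size - 1)
        d_left = pos - gp[idx - 1]
        d_right = gp[idx] - pos
        nearest = np.where(d_left <= d_right, idx - 1, idx)  # tie -> lower coordinate
        snp_rows.append(
            pd.DataFrame(
                {
                    "snp": snp_ids,
                    "chrom": chrom,
                    "pos": pos,
                    "freq_obj": p1,
                    "freq_ref": p2,
                    "score_raw": gs[nearest],
                }
            )
        )
    grid = pd.concat(grid_rows, ignore_index=True)
    snps = pd.concat(snp_rows, ignore_index=True)
    raw = snps["score_raw"].to_numpy()
    sd = raw.std()
    snps["score_norm"] = 0.0 if sd == 0 else (raw - raw.mean()) / sd
    return grid, snps
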
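"""Haplotype-homozygosity selection scan (EHH, iHH, iHS).

EHH at a flanking SNP is the probability that two random haplotypes carrying
the same core allele at the focal SNP are identical over the whole stretch
from the focal SNP to that flanking SNP. It is 1 at the focal SNP and can
only decrease outward. iHH is the trapezoidal integral of the EHH decay
curve against genetic distance (cM), accumulated separately to the left and
right and summed; iHS is ln(iHH_ancestral / iHH_derived), standardized to
zero mean and unit variance within derived-allele-frequency bins.

Curve construction stops at the first flanking SNP where EHH drops below the
stopping value (default 0.05, included in the integral), at the chromosome
end, or at a physical gap between consecutive SNPs larger than 200 kb. In
the latter two cases the integral never reaches the stopping value and the
statistic is undefined for that core allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import UndefinedStatisticError, merge_small_bins
from .panel import HaplotypePanel

logger = logging.getLogger(__name__)

EHH_STOP = 0.05
MAX_GAP_BP = 200_000


@dataclass
class EhhCurve:
    """EHH decay to one side of a focal SNP.

    ``distance_cm`` starts at 0 (the focal SNP, EHH = 1) and increases
    outward; ``termination`` is one of ``threshold_reached``,
    ``chromosome_end``, ``gap``.
    """

    direction: str  # "left" | "right"
    distance_cm: np.ndarray
    ehh: np.ndarray
    termination: str


def compute_ehh(
    panel: HaplotypePanel,
    focal: int,
    core_allele: int,
    direction: str,
    ehh_stop: float = EHH_STOP,
    max_gap_bp: int = MAX_GAP_BP,
) -> EhhCurve:
    """EHH decay curve among carriers of ``core_allele`` at SNP ``focal``.

    The panel must be single-chromosome with genetic positions attached.
    At each successive SNP the carriers are partitioned by their extended
    haplotype from the focal SNP; EHH = sum over groups of C(n_h, 2) divided
    by C(n_core, 2).
    """
    if direction not in ("left", "right"):
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
    if panel.gpos is None:
        raise UndefinedStatisticError("panel has no genetic positions")
    H = panel.matrix
    carriers = np.flatnonzero(H[:, focal] == core_allele)
    n = carriers.size
    if n < 2:
        raise UndefinedStatisticError(
            f"<2 haplotypes carry allele {core_allele} at SNP {focal}"
        )
    denom = n * (n - 1) // 2
    step = 1 if direction == "right" else -1
    sub = H[carriers]
    group = np.zeros(n, dtype=np.int64)
    dist = [0.0]
    ehh_vals = [1.0]
    j = focal
    termination = None
    while True:
        jn = j + step
        if jn < 0 or jn >= panel.n_snps:
            termination = "chromosome_end"
            break
        if abs(int(panel.pos[jn]) - int(panel.pos[j])) > max_gap_bp:
            termination = "gap"
            break
        j = jn
        _, group = np.unique(group * 2 + sub[:, j], return_inverse=True)
        counts = np.bincount(group)
        ehh = float((counts * (counts - 1) // 2).sum() / denom)
        dist.append(abs(float(panel.gpos[j]) - float(panel.gpos[focal])))
        ehh_vals.append(ehh)
        if ehh < ehh_stop:
            termination = "threshold_reached"
            break
    return EhhCurve(
        direction=direction,
        distance_cm=np.asarray(dist),
        ehh=np.asarray(ehh_vals),
        termination=termination,
    )


def compute_ihh(curve: EhhCurve) -> float | None:
    """Area (cM) under an EHH curve, or None when undefined.

    The trapezoidal integral runs from the focal SNP up to and including the
    first point below the stopping value. Curves cut off by the chromosome
    end or a gap never reach the stopping value, so their integral — and any
    iHS built on it — is undefined; a zero-area (single-point or flat-map)
    curve is undefined too since it would put a zero in the iHS log-ratio.
    """
    if curve.termination != "threshold_reached":
        return None
    area = float(np.trapezoid(curve.ehh, curve.distance_cm))
    if area <= 0.0:
        return None
    return area


def _allele_ihh(
    panel: HaplotypePanel, focal: int, allele: int, ehh_stop: float, max_gap_bp: int
) -> tuple[float | None, str]:
    """Summed left+right iHH for one core allele; (value, reason-if-undefined)."""
    total = 0.0
    for direction in ("left", "right"):
        try:
            curve = compute_ehh(panel, focal, allele, direction, ehh_stop, max_gap_bp)
        except UndefinedStatisticError:
            return None, "too_few_carriers"
        ihh = compute_ihh(curve)
        if ihh is None:
            reason = curve.termination if curve.termination != "threshold_reached" else "zero_area"
            return None, reason
        total += ihh
    return total, ""


def ihs_scan(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    n_bins: int = 20,
    ehh_stop: float = EHH_STOP,
    max_gap_bp: int = MAX_GAP_BP,
) -> pd.DataFrame:
    """Raw and frequency-standardized iHS for every eligible SNP.

    SNPs with minor-allele frequency below ``maf_min`` or with any undefined
    EHH component are flagged ``defined=False`` with a reason and excluded
    from the bin moments. Standardization uses ``n_bins`` equal-width
    derived-frequency bins; bins with fewer than two defined scores are
    merged into a neighbor.

    Returns a per-SNP table: ``snp, chrom, pos, freq, ihh_a, ihh_d, raw, std,
    defined, reason``.
    """
    frames = []
    for chrom in dict.fromkeys(panel.chrom):
        frames.append(
            _scan_chromosome(
                panel.for_chromosome(str(chrom)), maf_min, ehh_stop, max_gap_bp
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["std"] = np.nan
    defined = out["defined"].to_numpy()
    if defined.sum() >= 2:
        freq = out.loc[defined, "freq"].to_numpy()
        raw = out.loc[defined, "raw"].to_numpy()
        bin_idx = np.clip((freq * n_bins).astype(int), 0, n_bins - 1)
        bin_idx = merge_small_bins(bin_idx, n_bins, min_count=2)
        std = np.empty_like(raw)
        for b in np.unique(bin_idx):
            mask = bin_idx == b
            mu = raw[mask].mean()
            sd = raw[mask].std()
            std[mask] = 0.0 if sd == 0 else (raw[mask] - mu) / sd
        out.loc[defined, "std"] = std
    else:
        logger.warning("fewer than 2 defined iHS scores; standardization skipped")
    return out


def _scan_chromosome(
    panel: HaplotypePanel, maf_min: float, ehh_stop: float, max_gap_bp: int
) -> pd.DataFrame:
    freq = panel.matrix.mean(axis=0)
    rows = []
    for j in range(panel.n_snps):
        f = float(freq[j])
        rec = {
            "snp": panel.snp_ids[j],
            "chrom": panel.chrom[j],
            "pos": int(panel.pos[j]),
            "freq": f,
            "ihh_a": np.nan,
            "ihh_d": np.nan,
            "raw": np.nan,
            "defined": False,
            "reason": "",
        }
        if min(f, 1.0 - f) < maf_min:
            rec["reason"] = "maf_below_min"
            rows.append(rec)
            continue
        ihh_a, reason_a = _allele_ihh(panel, j, 0, ehh_stop, max_gap_bp)
        ihh_d, reason_d = _allele_ihh(panel, j, 1, ehh_stop, max_gap_bp)
        if ihh_a is None or ihh_d is None:
            rec["reason"] = reason_a if ihh_a is None else reason_d
            rows.append(rec)
            continue
        rec.update(
            ihh_a=ihh_a,
            ihh_d=ihh_d,
            raw=float(np.log(ihh_a / ihh_d)),
            defined=True,
        )
        rows.append(rec)
    return pd.DataFrame(rows)
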
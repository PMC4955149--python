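"""Shared fixtures: small deterministic panels and random-panel factories."""

from __future__ import annotations

import numpy as np
import pytest

from sweepset import HaplotypePanel


def make_panel(
    matrix: np.ndarray,
    pos: np.ndarray | None = None,
    gpos: np.ndarray | None = None,
    chrom: str = "1",
) -> HaplotypePanel:
    """Panel from a raw 0/1 matrix (rows = haplotypes, columns = SNPs)."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    n_hap, n_snps = matrix.shape
    assert n_hap % 2 == 0
    if pos is None:
        pos = np.arange(1, n_snps + 1) * 1000
    if gpos is None:
        gpos = np.asarray(pos, dtype=float) / 1e6 * 100.0  # 100 cM/Mb
    samples = [f"s{i}" for i in range(n_hap // 2)]
    return HaplotypePanel(
        snp_ids=np.array([f"snp{j}" for j in range(n_snps)], dtype=object),
        chrom=np.array([chrom] * n_snps, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        matrix=matrix,
        samples=samples,
        sample_population={s: "POP1" for s in samples},
        gpos=np.asarray(gpos, dtype=float),
    )


def random_panel(
    rng: np.random.Generator, n_hap: int = 12, n_snps: int = 20
) -> HaplotypePanel:
    """Random panel with clustered haplotypes so EHH decays gradually."""
    k = max(2, n_hap // 3)
    founders = rng.integers(0, 2, (k, n_snps))
    rows = founders[rng.integers(0, k, n_hap)].copy()
    flip = rng.random(rows.shape) < 0.15
    rows = np.where(flip, 1 - rows, rows)
    return make_panel(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
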
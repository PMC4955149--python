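"""Shared helpers: error types, seed fan-out, small-bin merging."""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31


class SweepsetError(Exception):
    """Base class for all package errors."""


class ValidationError(SweepsetError):
    """Malformed or inconsistent input."""


class UndefinedStatisticError(SweepsetError):
    """A statistic cannot be computed for this input (e.g. <2 core haplotypes)."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a global seed by stable hashing.

    Stable across runs and platforms (crc32, not Python's salted hash), so a
    stage re-run in isolation with the same global seed reproduces its stream.
    """
    return (zlib.crc32(stage.encode("utf-8")) ^ int(global_seed)) % MAX_SEED


def merge_small_bins(bin_idx: np.ndarray, n_bins: int, min_count: int) -> np.ndarray:
    """Merge bins holding fewer than ``min_count`` items into a neighbor.

    Bins are assumed ordered (index 0 .. n_bins-1 along an axis such as
    allele frequency or SNP count). Underfull bins are absorbed into the
    nearest lower non-empty neighbor, or the next higher one at the left
    edge. Returns a remapped index array with contiguous labels.
    """
    bin_idx = np.asarray(bin_idx)
    counts = np.bincount(bin_idx, minlength=n_bins)
    mapping = np.arange(n_bins)
    # walk upward absorbing small bins into the previous surviving bin
    for b in range(n_bins):
        if 0 < counts[b] < min_count:
            prev = b - 1
            while prev >= 0 and counts[prev] == 0:
                prev -= 1
            if prev >= 0:
                counts[prev] += counts[b]
                counts[b] = 0
                mapping[mapping == b] = mapping[prev]
            else:
                nxt = b + 1
                while nxt < n_bins and counts[nxt] == 0:
                    nxt += 1
                if nxt < n_bins:
                    counts[nxt] += counts[b]
                    counts[b] = 0
                    mapping[mapping == b] = nxt
                # else: single underfull bin overall; nothing to merge into
    remapped = mapping[bin_idx]
    _, contiguous = np.unique(remapped, return_inverse=True)
    return contiguous
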
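"""Read-level methylation statistics and the read homogeneity index (RHI).

A sequenced molecule is a :class:`ReadCalls`: an ordered list of CpG positions
with a call at each (methylated / unmethylated / missing).  The RHI asks
whether the methylated calls in a region are concentrated on a subset of
molecules (molecule-specific methylation) or scattered across all of them
(mosaic methylation).  It compares the observed number of adjacent-call
transitions against the median transition count under random reassignment of
the same calls to the same slots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval

logger = logging.getLogger(__name__)

MISSING = -1
UNMETH = 0
METH = 1


@dataclass
class ReadCalls:
    """Ordered CpG methylation calls for one sequenced molecule.

    ``calls`` uses 1 = methylated, 0 = unmethylated, -1 = missing. Positions
    must be strictly increasing.
    """

    read_id: str
    chrom: str
    positions: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.positions.shape != self.calls.shape:
            raise ValueError("positions and calls must have the same length")
        if len(self.positions) == 0:
            raise ValueError(f"read {self.read_id} has no positions")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"read {self.read_id}: positions not strictly increasing")
        if not np.isin(self.calls, (METH, UNMETH, MISSING)).all():
            raise ValueError(f"read {self.read_id}: calls must be in {{-1, 0, 1}}")
        if not (self.calls != MISSING).any():
            raise ValueError(f"read {self.read_id} has no called CpGs")

    @property
    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    @property
    def n_called(self) -> int:
        return int(self.called_mask.sum())

    def called_values(self) -> np.ndarray:
        return self.calls[self.called_mask]


@dataclass
class RhiResult:
    """Outcome of the RHI permutation procedure for one region."""

    region: GenomicInterval
    observed_transitions: int
    randomized_transitions: list[int] = field(repr=False)
    median_randomized: float
    rhi: float  # NaN when observed_transitions == 0
    n_reads: int
    n_called_positions: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.rhi)


def read_methylation(read: ReadCalls, min_cpgs: int = 4) -> Optional[float]:
    """Mean methylation over the read's called CpGs, or None if too short.

    Reads with fewer than ``min_cpgs`` called CpGs are excluded from
    read-level methylation distributions.
    """
    values = read.called_values()
    if len(values) < min_cpgs:
        return None
    return float(values.mean())


def clip_reads_to_region(
    reads: Iterable[ReadCalls], region: GenomicInterval
) -> list[ReadCalls]:
    """Drop calls outside [region.start, region.end); drop reads with no
    called in-region CpGs."""
    clipped = []
    for read in reads:
        if read.chrom != region.chrom:
            continue
        keep = (read.positions >= region.start) & (read.positions < region.end)
        if not keep.any():
            continue
        calls = read.calls[keep]
        if not (calls != MISSING).any():
            continue
        clipped.append(
            ReadCalls(read.read_id, read.chrom, read.positions[keep], calls)
        )
    return clipped


def count_transitions(reads: Iterable[ReadCalls]) -> int:
    """Total adjacent-call mismatches over all reads.

    Adjacency is between consecutive *called* CpGs within a read; missing
    calls are skipped, not treated as breaks.
    """
    total = 0
    for read in reads:
        values = read.called_values()
        if len(values) >= 2:
            total += int(np.count_nonzero(values[1:] != values[:-1]))
    return total


def _pooled_layout(reads: Sequence[ReadCalls]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate called values across reads; return (values, left, right)
    where (left[i], right[i]) index adjacent within-read pairs."""
    values = []
    left = []
    right = []
    offset = 0
    for read in reads:
        vals = read.called_values()
        k = len(vals)
        values.append(vals)
        if k >= 2:
            idx = np.arange(offset, offset + k)
            left.append(idx[:-1])
            right.append(idx[1:])
        offset += k
    pooled = np.concatenate(values) if values else np.empty(0, dtype=np.int8)
    left_a = np.concatenate(left) if left else np.empty(0, dtype=np.int64)
    right_a = np.concatenate(right) if right else np.empty(0, dtype=np.int64)
    return pooled, left_a, right_a


def lower_median(values: Sequence[int]) -> float:
    """Median taking the lower of the two central order statistics when the
    count is even.  Keeps worked examples stable under n_rand=1000."""
    arr = np.sort(np.asarray(values))
    if len(arr) == 0:
        raise ValueError("median of empty sequence")
    return float(arr[(len(arr) - 1) // 2])


def normalized_index(observed_transitions: int, median_randomized: float) -> float:
    """The RHI ratio: median randomized transition count over observed count.

    Undefined (NaN) when the observed count is zero.
    """
    if observed_transitions < 0:
        raise ValueError("observed transition count cannot be negative")
    if observed_transitions == 0:
        return float("nan")
    return median_randomized / observed_transitions


def compute_rhi(
    reads: Iterable[ReadCalls],
    region: GenomicInterval,
    n_rand: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> RhiResult:
    """Permutation RHI for one region.

    Reads are clipped to the region; the multiset of called values is then
    repeatedly permuted uniformly across all called slots in the cluster
    (read boundaries and missing positions preserved), the transition count
    recorded each time, and the RHI computed as the lower median of the
    ``n_rand`` counts divided by the observed count.  Every permutation has
    exactly the observed number of methylated calls.
    """
    clipped = clip_reads_to_region(reads, region)
    if not any(r.n_called >= 2 for r in clipped):
        raise ValueError(
            f"no read with >= 2 called CpGs in {region.chrom}:{region.start}-{region.end}"
        )
    values, left, right = _pooled_layout(clipped)
    observed = int(np.count_nonzero(values[left] != values[right]))
    if rng is None:
        rng = np.random.default_rng(seed)
    randomized = []
    for _ in range(n_rand):
        perm = rng.permutation(values)
        randomized.append(int(np.count_nonzero(perm[left] != perm[right])))
    median_rand = lower_median(randomized)
    rhi = normalized_index(observed, median_rand)
    if np.isnan(rhi):
        logger.info(
            "RHI undefined (0 observed transitions) at %s:%d-%d",
            region.chrom, region.start, region.end,
        )
    return RhiResult(
        region=region,
        observed_transitions=observed,
        randomized_transitions=randomized,
        median_randomized=median_rand,
        rhi=rhi,
        n_reads=len(clipped),
        n_called_positions=int(len(values)),
    )


def region_mean_methylation(reads: Iterable[ReadCalls], region: GenomicInterval) -> float:
    """Pooled mean methylation over all called in-region calls."""
    clipped = clip_reads_to_region(reads, region)
    values = np.concatenate([r.called_values() for r in clipped]) if clipped else np.empty(0)
    if len(values) == 0:
        raise ValueError("no called CpGs in region")
    return float(values.mean())


def rhi_eligible(
    reads: Sequence[ReadCalls],
    region: GenomicInterval,
    band: tuple[float, float] = (0.1, 0.9),
    min_reads: int = 5,
) -> bool:
    """Default eligibility: intermediately methylated cluster with enough reads."""
    clipped = clip_reads_to_region(reads, region)
    if len(clipped) < min_reads:
        return False
    mean = region_mean_methylation(clipped, region)
    return band[0] <= mean <= band[1]


def compare_rhi(
    rhi_set_a: Sequence[float], rhi_set_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (tie-corrected) between two RHI sets.

    NaN entries (undefined RHIs) are removed first.
    """
    a = np.asarray(rhi_set_a, dtype=float)
    b = np.asarray(rhi_set_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both RHI sets must be non-empty after NA removal")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
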
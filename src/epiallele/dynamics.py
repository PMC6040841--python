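"""Stage-wise methylation summaries for developmental series.

Each developmental stage carries one or more replicates of per-CpG counts; a
CpG contributes one observation per replicate in which it is covered.  The
module also provides the stratified pre/post-stage transition analysis with
bootstrap confidence intervals, and a chi-squared two-proportion test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import CpGSiteRecord, GenomicInterval, IntervalLookup

logger = logging.getLogger(__name__)

INTERMEDIATE_LO = 0.10
INTERMEDIATE_HI = 0.90


@dataclass
class StageSummary:
    """Methylation summary for one developmental stage."""

    stage: str
    n_observations: int  # replicate-CpG occurrences
    mean_methylation: float
    histogram: np.ndarray  # mass per bin, sums to 1
    bin_edges: np.ndarray
    intermediate_fraction: float


def _replicate_fractions(
    replicates: Sequence[Iterable[CpGSiteRecord]],
    regions: Optional[Sequence[GenomicInterval]],
    min_depth: int,
    max_depth: Optional[int],
) -> np.ndarray:
    lookup = IntervalLookup(regions) if regions is not None else None
    values = []
    for recs in replicates:
        recs = list(recs)
        if not recs:
            continue
        chroms = np.array([r.chrom for r in recs], dtype=object)
        pos = np.array([r.pos for r in recs], dtype=np.int64)
        meth = np.array([r.n_meth for r in recs], dtype=np.int64)
        total = np.array([r.n_total for r in recs], dtype=np.int64)
        keep = total >= min_depth
        if max_depth is not None:
            keep &= total <= max_depth
        if lookup is not None:
            inside = np.zeros(len(recs), dtype=bool)
            for chrom in np.unique(chroms):
                sel = chroms == chrom
                inside[sel] = lookup.contains_positions(str(chrom), pos[sel])
            keep &= inside
        values.append(meth[keep] / total[keep])
    if not values:
        return np.empty(0)
    return np.concatenate(values)


def stage_summary(
    stage: str,
    replicates: Sequence[Iterable[CpGSiteRecord]],
    regions: Optional[Sequence[GenomicInterval]] = None,
    min_depth: int = 10,
    max_depth: Optional[int] = None,
    n_bins: int = 10,
    lo: float = INTERMEDIATE_LO,
    hi: float = INTERMEDIATE_HI,
) -> StageSummary:
    """Summarize one stage: mean, histogram and intermediate fraction.

    Each CpG is counted once per replicate in which its total depth is at
    least ``min_depth`` (and at most ``max_depth``, when a cap is set).  When
    ``regions`` is given, only CpGs inside those intervals contribute.
    """
    fractions = _replicate_fractions(replicates, regions, min_depth, max_depth)
    if len(fractions) == 0:
        raise ValueError(f"stage {stage!r}: no covered CpGs after filtering")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _ = np.histogram(fractions, bins=edges)
    return StageSummary(
        stage=stage,
        n_observations=len(fractions),
        mean_methylation=float(fractions.mean()),
        histogram=hist / hist.sum(),
        bin_edges=edges,
        intermediate_fraction=intermediate_fraction(fractions, lo=lo, hi=hi),
    )


def intermediate_fraction(
    values: Sequence[float], lo: float = INTERMEDIATE_LO, hi: float = INTERMEDIATE_HI
) -> float:
    """Fraction of values in the closed interval [lo, hi]."""
    arr = np.asarray(values, dtype=float)
    if len(arr) == 0:
        raise ValueError("intermediate_fraction of empty input")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("methylation values must lie in [0, 1]")
    return float(((arr >= lo) & (arr <= hi)).mean())


@dataclass
class StratumResult:
    """Post-stage methylation distribution for one pre-stage stratum."""

    stratum: tuple[float, float]
    values: np.ndarray
    median: float
    ci_low: float  # NaN when the stratum is empty
    ci_high: float
    n: int


def _fraction_maps(
    replicates: Sequence[Iterable[CpGSiteRecord]], min_depth: int, max_depth: Optional[int]
) -> list[dict[tuple[str, int], float]]:
    maps = []
    for recs in replicates:
        d = {}
        for r in recs:
            if r.n_total < min_depth:
                continue
            if max_depth is not None and r.n_total > max_depth:
                continue
            d[(r.chrom, r.pos)] = r.fraction
        maps.append(d)
    return maps


def stratified_transition(
    pre_replicates: Sequence[Iterable[CpGSiteRecord]],
    post_replicates: Sequence[Iterable[CpGSiteRecord]],
    strata_bins: Sequence[float],
    n_boot: int = 1000,
    seed: Optional[int] = None,
    min_depth: int = 10,
    max_depth: Optional[int] = None,
    regions: Optional[Sequence[GenomicInterval]] = None,
) -> list[StratumResult]:
    """Post-stage methylation stratified by pre-stage methylation.

    For each CpG covered in at least one replicate of each stage, every
    (pre-replicate, post-replicate) pair in which the CpG is covered in both
    contributes one (pre, post) observation.  Observations are stratified by
    the pre value into ``strata_bins`` (half-open bins, last bin closed) and
    each stratum reports the post distribution, its median, and a percentile
    bootstrap CI of the median from ``n_boot`` resamples.
    """
    rng = np.random.default_rng(seed)
    lookup = IntervalLookup(regions) if regions is not None else None
    pre_maps = _fraction_maps(pre_replicates, min_depth, max_depth)
    post_maps = _fraction_maps(post_replicates, min_depth, max_depth)
    pre_vals: list[float] = []
    post_vals: list[float] = []
    for pre in pre_maps:
        for post in post_maps:
            for key in pre.keys() & post.keys():
                if lookup is not None and not lookup.contains_positions(
                    key[0], np.asarray([key[1]])
                )[0]:
                    continue
                pre_vals.append(pre[key])
                post_vals.append(post[key])
    pre_arr = np.asarray(pre_vals)
    post_arr = np.asarray(post_vals)
    edges = np.asarray(list(strata_bins), dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("strata_bins must be an increasing sequence of >= 2 edges")
    results = []
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        if i == len(edges) - 2:
            mask = (pre_arr >= lo) & (pre_arr <= hi)
        else:
            mask = (pre_arr >= lo) & (pre_arr < hi)
        vals = post_arr[mask]
        if len(vals) == 0:
            logger.warning("stratum [%.3g, %.3g) is empty; CI undefined", lo, hi)
            results.append(
                StratumResult((lo, hi), vals, float("nan"), float("nan"), float("nan"), 0)
            )
            continue
        med = float(np.median(vals))
        boots = np.median(
            vals[rng.integers(0, len(vals), size=(n_boot, len(vals)))], axis=1
        )
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        results.append(StratumResult((lo, hi), vals, med, float(ci_low), float(ci_high), len(vals)))
    return results


def regions_with_coverage(
    replicates: Sequence[Iterable[CpGSiteRecord]],
    regions: Sequence[GenomicInterval],
    min_depth: int = 10,
) -> int:
    """Count regions containing >= 1 CpG covered in at least one replicate."""
    covered: dict[str, set[int]] = {}
    for recs in replicates:
        for r in recs:
            if r.n_total >= min_depth:
                covered.setdefault(r.chrom, set()).add(r.pos)
    by_chrom = {c: np.sort(np.fromiter(ps, dtype=np.int64)) for c, ps in covered.items()}
    n = 0
    for iv in regions:
        arr = by_chrom.get(iv.chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr, iv.start, side="left")
        if lo < len(arr) and arr[lo] < iv.end:
            n += 1
    return n


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, correction: bool = False
) -> tuple[float, float]:
    """Chi-squared test for a difference between two proportions.

    No continuity correction by default. Returns (statistic, p-value).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table.sum(axis=0).min() == 0:
        # degenerate margin: identical all-0 or all-1 proportions
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)
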
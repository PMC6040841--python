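"""Enrichment statistics over genomic intervals.

All tests bottom out in Fisher's exact test on a 2x2 contingency table built
from fixed-size genome tiles or from annotated CpG sets: proximal-feature
enrichment, chromatin-state overlap, mQTL enrichment and region-overlap
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, IntervalLookup, merge_intervals

logger = logging.getLogger(__name__)

DEFAULT_TILE_SIZE = 1000
DEFAULT_WINDOW = 10_000

# 15-state chromHMM labels collapsed to 8 groups.  Overridable via a
# two-column TSV (state -> group).
DEFAULT_STATE_MAP: dict[str, str] = {
    "TssA": "TSS", "TssAFlnk": "TSS",
    "Enh": "Enhancer", "EnhG": "Enhancer",
    "Tx": "Transcription", "TxWk": "Transcription", "TxFlnk": "Transcription",
    "ZNF/Rpts": "ZNF",
    "Het": "Heterochromatin",
    "TssBiv": "Bivalent", "BivFlnk": "Bivalent", "EnhBiv": "Bivalent",
    "ReprPC": "Repressed-Polycomb", "ReprPCWk": "Repressed-Polycomb",
    "Quies": "Quiescent",
}


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a, b / c, d of a 2x2 table (rows: exposure, cols: outcome)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is all zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class EnrichmentResult:
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    test: str = "fisher_exact"
    window: Optional[int] = None
    extra: Optional[dict] = None


def fisher_exact(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher's exact test.

    The odds ratio is the sample estimate (a*d)/(b*c), reported as ``inf``
    when b*c == 0 with a*d > 0 and as NaN when both products vanish.
    """
    odds, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(odds), float(p)


def tile_genome(
    chrom_sizes: Mapping[str, int], tile_size: int = DEFAULT_TILE_SIZE
) -> list[GenomicInterval]:
    """Cut each chromosome into half-open tiles; the final partial tile is kept."""
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    tiles = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for start in range(0, size, tile_size):
            tiles.append(GenomicInterval(chrom, start, min(start + tile_size, size)))
    return tiles


def _tile_flags(
    tiles: Sequence[GenomicInterval], intervals: Iterable[GenomicInterval]
) -> np.ndarray:
    lookup = IntervalLookup(intervals)
    flags = np.zeros(len(tiles), dtype=bool)
    for i, t in enumerate(tiles):
        flags[i] = lookup.overlaps_interval(t)
    return flags


def _expand(intervals: Iterable[GenomicInterval], window: int) -> list[GenomicInterval]:
    return [
        GenomicInterval(iv.chrom, max(0, iv.start - window), iv.end + window)
        for iv in intervals
    ]


def tile_enrichment(
    features: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    tile_size: int = DEFAULT_TILE_SIZE,
    cpg_weights: Optional[Sequence[int]] = None,
) -> EnrichmentResult:
    """FET over genome tiles: feature overlap x proximity to a region.

    Each tile is flagged for overlapping at least one feature and for lying
    within ``window`` bp of at least one region (the tile intersects a
    region expanded by the window).  ``cpg_weights`` optionally weights each
    tile by its CpG count instead of 1.
    """
    if not features:
        raise ValueError("empty feature set")
    if not regions:
        raise ValueError("empty region set")
    tiles = tile_genome(chrom_sizes, tile_size)
    has_feature = _tile_flags(tiles, features)
    near_region = _tile_flags(tiles, _expand(regions, window))
    if cpg_weights is not None:
        w = np.asarray(cpg_weights, dtype=np.int64)
        if len(w) != len(tiles):
            raise ValueError("cpg_weights must have one entry per tile")
    else:
        w = np.ones(len(tiles), dtype=np.int64)
    a = int(w[has_feature & near_region].sum())
    b = int(w[~has_feature & near_region].sum())
    c = int(w[has_feature & ~near_region].sum())
    d = int(w[~has_feature & ~near_region].sum())
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError(
            "degenerate tile table (a margin is zero); enrichment is undefined"
        )
    table = ContingencyTable(a, b, c, d)
    odds, p = fisher_exact(table)
    return EnrichmentResult(table, odds, p, window=window)


def proximity_profile(
    regions: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    thresholds: Sequence[int] = (0, 1000, 10_000),
) -> dict[int, float]:
    """Proportion of regions with a feature within each distance threshold.

    Distance is the interval gap in bp: 0 for overlapping (or abutting)
    pairs, otherwise the number of bases separating the intervals.
    Proportions are cumulative in the threshold.
    """
    if not regions:
        return {int(t): float("nan") for t in thresholds}
    feats = merge_intervals(features)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for f in feats:
        by_chrom.setdefault(f.chrom, []).append(f)
    starts = {c: np.array([f.start for f in fs]) for c, fs in by_chrom.items()}
    ends = {c: np.array([f.end for f in fs]) for c, fs in by_chrom.items()}
    min_gaps = np.full(len(regions), np.inf)
    for i, r in enumerate(regions):
        if r.chrom not in by_chrom:
            continue
        s, e = starts[r.chrom], ends[r.chrom]
        gaps = np.maximum(0, np.maximum(s - r.end, r.start - e))
        min_gaps[i] = gaps.min()
    return {int(t): float((min_gaps <= t).mean()) for t in thresholds}


def load_state_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["state", "group"], comment="#")
    return dict(zip(df["state"], df["group"]))


def chromhmm_overlap(
    regions: Sequence[GenomicInterval],
    state_segments: Sequence[GenomicInterval],
    state_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Base-pair overlap proportions of regions and genome per collapsed state.

    ``state_segments`` carry the raw state label; every label must map to a
    collapsed group. Returns a frame with columns ``region_proportion`` and
    ``genome_proportion`` indexed by group; when segments tile the genome each
    column sums to 1.
    """
    if state_map is None:
        state_map = DEFAULT_STATE_MAP
    groups = sorted(set(state_map.values()))
    region_bp = {g: 0 for g in groups}
    genome_bp = {g: 0 for g in groups}
    regs = merge_intervals(regions)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regs:
        by_chrom.setdefault(r.chrom, []).append(r)
    for seg in state_segments:
        if seg.label not in state_map:
            raise ValueError(f"unmapped chromatin state label {seg.label!r}")
        g = state_map[seg.label]
        genome_bp[g] += len(seg)
        for r in by_chrom.get(seg.chrom, ()):
            ov = min(seg.end, r.end) - max(seg.start, r.start)
            if ov > 0:
                region_bp[g] += ov
    region_total = sum(region_bp.values())
    genome_total = sum(genome_bp.values())
    if region_total == 0:
        raise ValueError("regions share no bases with the state segmentation")
    return pd.DataFrame(
        {
            "region_proportion": [region_bp[g] / region_total for g in groups],
            "genome_proportion": [genome_bp[g] / genome_total for g in groups],
        },
        index=pd.Index(groups, name="state_group"),
    )


def mqtl_enrichment(
    me_regions: Sequence[GenomicInterval], array_cpg_table: pd.DataFrame
) -> EnrichmentResult:
    """FET of (CpG inside an ME region) x (mQTL-associated at any time point).

    The table needs columns ``chrom``, ``pos``, ``mqtl`` (bool) and
    ``reliable`` (bool); only CpGs that are mQTL-associated or reliable
    non-associated enter the test.
    """
    required = {"chrom", "pos", "mqtl", "reliable"}
    if array_cpg_table.empty:
        raise ValueError("empty array CpG table")
    if not required.issubset(array_cpg_table.columns):
        raise ValueError(f"array table must have columns {sorted(required)}")
    df = array_cpg_table[array_cpg_table["mqtl"] | array_cpg_table["reliable"]]
    lookup = IntervalLookup(me_regions)
    inside = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom"):
        inside[df.index.get_indexer(sub.index)] = lookup.contains_positions(
            str(chrom), sub["pos"].to_numpy()
        )
    mqtl = df["mqtl"].to_numpy(dtype=bool)
    if not inside.any():
        raise ValueError("no array CpGs fall inside the regions")
    table = ContingencyTable(
        a=int((inside & mqtl).sum()),
        b=int((inside & ~mqtl).sum()),
        c=int((~inside & mqtl).sum()),
        d=int((~inside & ~mqtl).sum()),
    )
    odds, p = fisher_exact(table)
    return EnrichmentResult(table, odds, p)


def variance_explained_summary(
    variance_table: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> tuple[float, tuple[float, float]]:
    """Median and IQR of variance-explained for CpGs inside the regions.

    The table needs columns ``chrom``, ``pos`` and ``variance_explained``
    with values in [0, 1].
    """
    required = {"chrom", "pos", "variance_explained"}
    if not required.issubset(variance_table.columns):
        raise ValueError(f"variance table must have columns {sorted(required)}")
    v = variance_table["variance_explained"]
    if len(v) and (v.min() < 0 or v.max() > 1):
        raise ValueError("variance_explained must lie in [0, 1]")
    lookup = IntervalLookup(regions)
    inside = np.zeros(len(variance_table), dtype=bool)
    for chrom, sub in variance_table.groupby("chrom"):
        inside[variance_table.index.get_indexer(sub.index)] = lookup.contains_positions(
            str(chrom), sub["pos"].to_numpy()
        )
    vals = v.to_numpy()[inside]
    if len(vals) == 0:
        raise ValueError("no CpGs overlap the regions")
    q25, med, q75 = np.percentile(vals, [25, 50, 75])
    return float(med), (float(q25), float(q75))


def region_overlap_enrichment(
    query_regions: Sequence[GenomicInterval],
    target_regions: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    tile_size: int = DEFAULT_TILE_SIZE,
) -> EnrichmentResult:
    """FET over tiles of (overlaps query) x (overlaps target).

    Also reports the raw count of query regions intersecting >= 1 target in
    ``extra['n_query_overlapping']``.
    """
    if not query_regions or not target_regions:
        raise ValueError("query and target region sets must be non-empty")
    tiles = tile_genome(chrom_sizes, tile_size)
    q = _tile_flags(tiles, query_regions)
    t = _tile_flags(tiles, target_regions)
    table = ContingencyTable(
        a=int((q & t).sum()),
        b=int((q & ~t).sum()),
        c=int((~q & t).sum()),
        d=int((~q & ~t).sum()),
    )
    odds, p = fisher_exact(table)
    target_lookup = IntervalLookup(target_regions)
    n_overlap = sum(1 for r in query_regions if target_lookup.overlaps_interval(r))
    return EnrichmentResult(
        table, odds, p, extra={"n_query_overlapping": n_overlap}
    )
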
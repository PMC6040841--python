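"""Screen for metastable epiallele (ME) regions.

Three steps: (i) flag CpGs whose methylation differs between individuals by at
least ``inter_threshold`` while staying concordant across tissues within each
individual (the intertissue spread may not exceed ``intra_ratio`` times the
interindividual spread); (ii) chain flagged CpGs into clusters with
single-linkage at ``max_gap`` bp and keep clusters of at least ``min_cpgs``
members; (iii) keep clusters with at least ``purity_ratio`` times as many
qualifying as non-qualifying covered CpGs.  Control clusters are drawn from
the all-CpG background with the same clustering parameters, matched on the
joint (span, CpG count) distribution of the ME set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, IntervalLookup, MethylationMatrix

logger = logging.getLogger(__name__)

DEFAULT_INTER_THRESHOLD = 0.15
DEFAULT_INTRA_RATIO = 1.0 / 3.0
DEFAULT_SNP_WINDOW = 60
DEFAULT_MAX_GAP = 300
DEFAULT_MIN_CPGS = 4
DEFAULT_PURITY_RATIO = 2.0


@dataclass
class MECluster:
    """A candidate ME (or matched control) region."""

    interval: GenomicInterval
    me_cpg_positions: list[int]
    n_non_me_cpgs: int = 0
    role: str = "ME"

    @property
    def n_me_cpgs(self) -> int:
        return len(self.me_cpg_positions)

    @property
    def span(self) -> int:
        return len(self.interval)


def detect_me_cpgs(
    matrix: MethylationMatrix,
    inter_threshold: float = DEFAULT_INTER_THRESHOLD,
    intra_ratio: float = DEFAULT_INTRA_RATIO,
) -> pd.DataFrame:
    """Per-CpG metastability verdicts for one dataset.

    Returns a frame indexed by (chrom, pos) with columns ``d_inter`` (max
    pairwise difference of the individuals' tissue-averaged methylation),
    ``d_intra`` (max within-individual between-tissue difference) and
    ``passes``.
    """
    individuals = matrix.individuals()
    tissues = matrix.tissues()
    if len(individuals) < 2:
        raise ValueError("need >= 2 individuals to assess interindividual variation")
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues to assess intertissue concordance")
    frac = matrix.fractions()
    by_individual: dict[str, list[str]] = {}
    for s in matrix.samples:
        by_individual.setdefault(s.individual, []).append(s.sample_id)

    tissue_means = pd.DataFrame(
        {ind: frac[ids].mean(axis=1) for ind, ids in by_individual.items()}
    )
    d_inter = tissue_means.max(axis=1) - tissue_means.min(axis=1)
    intra_spread = pd.DataFrame(
        {ind: frac[ids].max(axis=1) - frac[ids].min(axis=1) for ind, ids in by_individual.items()}
    )
    d_intra = intra_spread.max(axis=1)
    passes = (d_inter >= inter_threshold) & (d_intra <= d_inter * intra_ratio)
    out = pd.DataFrame({"d_inter": d_inter, "d_intra": d_intra, "passes": passes})
    logger.info(
        "detect_me_cpgs: %d/%d CpGs pass (inter>=%.3g, intra<=%.3g*inter)",
        int(passes.sum()), len(out), inter_threshold, intra_ratio,
    )
    return out


def filter_snp_proximal(
    cpgs: pd.DataFrame | Sequence[tuple[str, int]],
    snps: Mapping[str, Sequence[int]],
    window: int = DEFAULT_SNP_WINDOW,
) -> pd.DataFrame | list[tuple[str, int]]:
    """Remove CpGs within ``window`` bp (inclusive) of any SNP.

    ``cpgs`` is either a frame indexed by (chrom, pos) or a list of
    (chrom, pos) pairs; the same shape comes back. SNP sets are per-dataset
    and must be applied before cross-dataset combination.
    """
    as_frame = isinstance(cpgs, pd.DataFrame)
    if as_frame:
        pairs = list(cpgs.index)
    else:
        pairs = list(cpgs)
    keep_mask = np.ones(len(pairs), dtype=bool)
    chroms = np.array([c for c, _ in pairs], dtype=object)
    positions = np.array([p for _, p in pairs], dtype=np.int64)
    for chrom, snp_positions in snps.items():
        snp_arr = np.sort(np.asarray(snp_positions, dtype=np.int64))
        if len(snp_arr) == 0:
            continue
        sel = chroms == chrom
        if not sel.any():
            continue
        pos = positions[sel]
        # nearest SNP distance via the insertion point
        idx = np.searchsorted(snp_arr, pos)
        dist = np.full(len(pos), np.iinfo(np.int64).max)
        has_right = idx < len(snp_arr)
        dist[has_right] = np.abs(snp_arr[idx[has_right]] - pos[has_right])
        has_left = idx > 0
        dist[has_left] = np.minimum(
            dist[has_left], np.abs(pos[has_left] - snp_arr[idx[has_left] - 1])
        )
        keep_mask[sel] &= dist > window
    n_dropped = int((~keep_mask).sum())
    if n_dropped:
        logger.info("filter_snp_proximal: dropped %d/%d CpGs within %d bp of a SNP",
                    n_dropped, len(pairs), window)
    if as_frame:
        return cpgs.loc[keep_mask]
    return [p for p, k in zip(pairs, keep_mask) if k]


def combine_datasets(
    per_dataset: Sequence[Iterable[tuple[str, int]]], mode: str = "intersection"
) -> set[tuple[str, int]]:
    """Combine per-dataset passing CpG sets by intersection or union."""
    sets = [set(s) for s in per_dataset]
    if not sets:
        return set()
    if mode == "intersection":
        out = set.intersection(*sets)
    elif mode == "union":
        out = set.union(*sets)
    else:
        raise ValueError(f"unknown combine mode {mode!r}")
    return out


def cluster_cpgs(
    positions: Iterable[tuple[str, int]],
    max_gap: int = DEFAULT_MAX_GAP,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    role: str = "ME",
) -> list[MECluster]:
    """Single-linkage chaining of CpG positions into clusters.

    Consecutive positions on the same chromosome join a cluster when they are
    at most ``max_gap`` bp apart; clusters with fewer than ``min_cpgs``
    members are discarded. The cluster interval spans the first to last
    member dyad (end = last position + 2, covering both strands of the dyad).
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)
    clusters = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom])
        run: list[int] = []
        for pos in ps:
            if run and pos - run[-1] > max_gap:
                if len(run) >= min_cpgs:
                    clusters.append(_make_cluster(chrom, run, role))
                run = []
            run.append(pos)
        if len(run) >= min_cpgs:
            clusters.append(_make_cluster(chrom, run, role))
    return clusters


def _make_cluster(chrom: str, run: list[int], role: str) -> MECluster:
    return MECluster(
        interval=GenomicInterval(chrom, run[0], run[-1] + 2, label=role),
        me_cpg_positions=list(run),
        role=role,
    )


def purity_filter(
    clusters: Iterable[MECluster],
    covered_cpgs: Iterable[tuple[str, int]],
    min_ratio: float = DEFAULT_PURITY_RATIO,
) -> list[MECluster]:
    """Keep clusters with >= min_ratio times as many ME as non-ME covered CpGs.

    ``covered_cpgs`` is the set of all depth-passing CpGs; those inside a
    cluster interval but not among its ME-CpGs count as non-ME.
    """
    clusters = list(clusters)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in covered_cpgs:
        by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    by_chrom = {c: np.sort(np.asarray(ps)) for c, ps in by_chrom.items()}
    kept = []
    for cluster in clusters:
        iv = cluster.interval
        arr = by_chrom.get(iv.chrom, np.empty(0, dtype=np.int64))
        lo = np.searchsorted(arr, iv.start, side="left")
        hi = np.searchsorted(arr, iv.end, side="left")
        inside = arr[lo:hi]
        n_non_me = int(len(inside) - np.isin(inside, cluster.me_cpg_positions).sum())
        cluster.n_non_me_cpgs = n_non_me
        if cluster.n_me_cpgs >= min_ratio * n_non_me:
            kept.append(cluster)
    logger.info("purity_filter: %d clusters kept of %d", len(kept), len(clusters))
    return kept


def generate_control_clusters(
    all_covered_cpgs: Iterable[tuple[str, int]],
    me_clusters: Sequence[MECluster],
    n_controls: int,
    seed: Optional[int] = None,
    max_gap: int = DEFAULT_MAX_GAP,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    n_bins: int = 5,
    rng: Optional[np.random.Generator] = None,
) -> list[MECluster]:
    """Sample control clusters matching the ME joint (span, CpG count) law.

    The candidate pool is produced by clustering *all* covered CpGs with the
    ME clustering parameters (no metastability filter), then removing
    candidates that overlap an ME cluster.  Sampling is stratified over a
    ``n_bins`` x ``n_bins`` grid of span and CpG-count quantile bins computed
    on the ME set, with cell targets proportional to the ME joint histogram;
    cells whose pool runs short are reallocated proportionally with a warning.
    """
    if not me_clusters:
        raise ValueError("cannot match controls to an empty ME set")
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    pool = cluster_cpgs(all_covered_cpgs, max_gap=max_gap, min_cpgs=min_cpgs, role="control")
    me_lookup = IntervalLookup([c.interval for c in me_clusters])
    pool = [c for c in pool if not me_lookup.overlaps_interval(c.interval)]
    if not pool:
        raise ValueError("candidate pool is empty after removing ME overlaps")
    if n_controls > len(pool):
        logger.warning(
            "requested %d controls but pool has only %d candidates; capping",
            n_controls, len(pool),
        )
        n_controls = len(pool)

    me_spans = np.array([c.span for c in me_clusters], dtype=float)
    me_counts = np.array([c.n_me_cpgs for c in me_clusters], dtype=float)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    span_edges = np.quantile(me_spans, qs)
    count_edges = np.quantile(me_counts, qs)

    def cell_of(span: float, count: float) -> tuple[int, int]:
        return (
            int(np.searchsorted(span_edges, span, side="right")),
            int(np.searchsorted(count_edges, count, side="right")),
        )

    me_hist: dict[tuple[int, int], int] = {}
    for c in me_clusters:
        me_hist[cell_of(c.span, c.n_me_cpgs)] = me_hist.get(cell_of(c.span, c.n_me_cpgs), 0) + 1
    pool_by_cell: dict[tuple[int, int], list[MECluster]] = {}
    for c in pool:
        pool_by_cell.setdefault(cell_of(c.span, c.n_me_cpgs), []).append(c)

    # Largest-remainder allocation of n_controls over ME cells.
    total_me = sum(me_hist.values())
    raw = {cell: n_controls * n / total_me for cell, n in me_hist.items()}
    targets = {cell: int(np.floor(x)) for cell, x in raw.items()}
    short = n_controls - sum(targets.values())
    for cell, _ in sorted(raw.items(), key=lambda kv: kv[1] - np.floor(kv[1]), reverse=True)[:short]:
        targets[cell] += 1

    chosen: list[MECluster] = []
    deficit = 0
    for cell in sorted(targets):
        want = targets[cell]
        have = pool_by_cell.get(cell, [])
        take = min(want, len(have))
        if take < want:
            logger.warning(
                "control bin %s: pool has %d candidates for target %d; reallocating %d",
                cell, len(have), want, want - take,
            )
            deficit += want - take
        if take:
            idx = rng.choice(len(have), size=take, replace=False)
            picked = [have[i] for i in sorted(idx)]
            chosen.extend(picked)
            pool_by_cell[cell] = [c for i, c in enumerate(have) if i not in set(idx)]
    if deficit:
        leftovers = [c for cell in sorted(pool_by_cell) for c in pool_by_cell[cell]
                     if c not in chosen]
        take = min(deficit, len(leftovers))
        if take:
            idx = rng.choice(len(leftovers), size=take, replace=False)
            chosen.extend(leftovers[i] for i in sorted(idx))
    for c in chosen:
        c.role = "control"
        c.interval = GenomicInterval(
            c.interval.chrom, c.interval.start, c.interval.end, label="control"
        )
    logger.info("generate_control_clusters: %d controls sampled from pool of %d",
                len(chosen), len(pool))
    return sorted(chosen, key=lambda c: (c.interval.chrom, c.interval.start))


@dataclass
class ScreenResult:
    me_clusters: list[MECluster]
    verdicts: dict[str, pd.DataFrame] = field(default_factory=dict)
    passing_cpgs: set[tuple[str, int]] = field(default_factory=set)
    covered_cpgs: set[tuple[str, int]] = field(default_factory=set)


def run_screen(
    matrices: Mapping[str, MethylationMatrix],
    snps: Mapping[str, Mapping[str, Sequence[int]]] | None = None,
    inter_threshold: float = DEFAULT_INTER_THRESHOLD,
    intra_ratio: float = DEFAULT_INTRA_RATIO,
    snp_window: int = DEFAULT_SNP_WINDOW,
    max_gap: int = DEFAULT_MAX_GAP,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    purity_ratio: float = DEFAULT_PURITY_RATIO,
    combine_mode: str = "intersection",
) -> ScreenResult:
    """Full three-step screen across one or more datasets.

    ``matrices`` maps dataset name to its depth-filtered matrix; ``snps``
    maps dataset name to that dataset's SNP positions (missing entries skip
    the SNP filter for that dataset, with a warning).
    """
    per_dataset_passing = []
    verdicts: dict[str, pd.DataFrame] = {}
    covered: set[tuple[str, int]] = set()
    for name, matrix in matrices.items():
        v = detect_me_cpgs(matrix, inter_threshold=inter_threshold, intra_ratio=intra_ratio)
        passing = v[v["passes"]]
        if snps is not None and name in snps:
            passing = filter_snp_proximal(passing, snps[name], window=snp_window)
        elif snps is not None:
            logger.warning("no SNP set for dataset %r; SNP-proximity filter skipped", name)
        verdicts[name] = v
        per_dataset_passing.append(set(passing.index))
        covered |= set(matrix.positions())
    passing_cpgs = combine_datasets(per_dataset_passing, mode=combine_mode)
    clusters = cluster_cpgs(sorted(passing_cpgs), max_gap=max_gap, min_cpgs=min_cpgs)
    # the purity denominator: CpGs covered in every sample of >= 1 dataset
    me_clusters = purity_filter(clusters, sorted(covered), min_ratio=purity_ratio)
    logger.info("run_screen: %d ME clusters from %d passing CpGs", len(me_clusters),
                len(passing_cpgs))
    return ScreenResult(
        me_clusters=me_clusters,
        verdicts=verdicts,
        passing_cpgs=passing_cpgs,
        covered_cpgs=covered,
    )
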
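"""Synthetic data generators for every pipeline stage.

Emits multi-individual multi-tissue CpG count tables with planted systemically
variable regions and SNPs, developmental stage series with configurable
demethylation/remethylation trajectories and post-gastrulation intermediate
methylation, per-read call sets with tunable molecule-specific vs. mosaic
methylation, and feature tracks with planted proximity enrichment.  Planted
truth is returned alongside every dataset.

Determinism: one master seed; every operation derives a child generator with
:func:`child_rng` via ``SeedSequence(master_seed, spawn_key=...)`` where the
spawn key encodes the operation name (CRC32 of the string) and any stream
qualifiers.  Identical configuration and seed give bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import CpGSiteRecord, GenomicInterval, SampleMeta
from .readlevel import ReadCalls

__all__ = [
    "BetaMixture",
    "ReadModel",
    "StageParams",
    "SimulationConfig",
    "CohortData",
    "child_rng",
    "simulate_cohort",
    "simulate_stage_series",
    "simulate_cluster_reads",
    "simulate_feature_tracks",
]


def child_rng(master_seed: int, *key) -> np.random.Generator:
    """Derive a deterministic child generator from the master seed.

    String key parts are hashed with CRC32; integer parts pass through.
    """
    parts = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=parts))


@dataclass(frozen=True)
class BetaMixture:
    """Two-component Beta mixture for bimodal background methylation."""

    w_hypo: float = 0.3
    a_hypo: float = 1.0
    b_hypo: float = 19.0
    a_hyper: float = 19.0
    b_hyper: float = 1.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        hypo = rng.random(n) < self.w_hypo
        out = np.empty(n)
        out[hypo] = rng.beta(self.a_hypo, self.b_hypo, hypo.sum())
        out[~hypo] = rng.beta(self.a_hyper, self.b_hyper, (~hypo).sum())
        return out


@dataclass(frozen=True)
class ReadModel:
    """How reads are laid over a cluster's CpGs."""

    n_cpgs_mean: float = 6.0     # Poisson(+1) number of consecutive CpGs
    p_homog: float = 0.5         # probability a molecule is epigenetically uniform
    missing_rate: float = 0.05   # per-call probability of an uncalled cytosine
    cpg_spacing: int = 20        # default dyad spacing when positions not given


@dataclass(frozen=True)
class StageParams:
    """Generator settings for one developmental stage."""

    background_mean: float
    me_mean: float
    intermediate_fraction: float = 0.0  # ME-region CpGs drawn U[0.1, 0.9]
    n_replicates: int = 2
    background_concentration: float = 0.3  # Beta concentration; small => bimodal


@dataclass
class SimulationConfig:
    """All knobs for the synthetic generators. Probabilities are validated."""

    chrom_sizes: Mapping[str, int] = field(default_factory=lambda: {"chr1": 200_000})
    cpg_spacing_mean: float = 100.0
    n_individuals: int = 2
    tissues: Sequence[str] = ("T1", "T2")
    depth_mean: float = 30.0
    planted_me_regions: Sequence[
        tuple[GenomicInterval, Optional[Sequence[float]]]
    ] = ()
    # Interindividual spread of planted latent levels.  Kept wide: with the
    # binomial noise of ~30x data, the intertissue-concordance criterion only
    # passes reliably when individuals sit near opposite extremes, matching
    # the bimodal cross-individual pattern the screen targets.
    me_spread_range: tuple[float, float] = (0.6, 0.9)
    snp_density: float = 0.0
    n_snps_near_me: int = 0
    background_mix: BetaMixture = field(default_factory=BetaMixture)
    stage_trajectory: Mapping[str, StageParams] = field(default_factory=dict)
    read_model: ReadModel = field(default_factory=ReadModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.cpg_spacing_mean <= 3:
            raise ValueError("cpg_spacing_mean must exceed the dyad width")
        for p in (
            self.read_model.p_homog,
            self.read_model.missing_rate,
            self.background_mix.w_hypo,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        lo, hi = self.me_spread_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("me_spread_range must satisfy 0 < lo <= hi <= 1")
        for iv, levels in self.planted_me_regions:
            size = self.chrom_sizes.get(iv.chrom)
            if size is None or iv.end > size:
                raise ValueError(f"planted region {iv} outside chrom_sizes")
            if levels is not None and any(not 0 <= l <= 1 for l in levels):
                raise ValueError(f"latent levels for {iv} outside [0, 1]")
        for stage, params in self.stage_trajectory.items():
            for p in (params.background_mean, params.me_mean, params.intermediate_fraction):
                if not 0 <= p <= 1:
                    raise ValueError(f"stage {stage!r}: probability {p} outside [0, 1]")
            if params.n_replicates < 1:
                raise ValueError(f"stage {stage!r}: need >= 1 replicate")


@dataclass
class CohortData:
    """One simulated dataset plus its planted truth."""

    samples: dict[str, list[CpGSiteRecord]]
    metas: list[SampleMeta]
    snps: dict[str, list[int]]
    truth: list[GenomicInterval]
    cpg_positions: dict[str, np.ndarray]


def _genome_positions(config: SimulationConfig) -> dict[str, np.ndarray]:
    """CpG dyad positions per chromosome; fixed by the master seed alone, so
    every dataset simulated from the same config shares its genome."""
    rng = child_rng(config.seed, "genome")
    positions = {}
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        # steps: dyad width 2 plus geometric tail, mean == cpg_spacing_mean
        p = 1.0 / (config.cpg_spacing_mean - 2.0)
        n_guess = int(size / config.cpg_spacing_mean * 1.5) + 10
        steps = 2 + rng.geometric(p, size=n_guess)
        pos = np.cumsum(steps)
        while pos[-1] < size:
            extra = 2 + rng.geometric(p, size=n_guess)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        positions[chrom] = pos[pos < size - 1]
    return positions


def _planted_levels(
    config: SimulationConfig, dataset: str
) -> list[tuple[GenomicInterval, np.ndarray]]:
    """Resolve per-individual latent levels for every planted region.

    Explicit levels are used as given; otherwise individuals receive evenly
    spaced levels spanning a random spread drawn from ``me_spread_range``,
    shuffled across individuals. Levels differ between datasets.
    """
    out = []
    for i, (iv, levels) in enumerate(config.planted_me_regions):
        if levels is not None:
            arr = np.asarray(levels, dtype=float)
            if len(arr) != config.n_individuals:
                raise ValueError(
                    f"planted region {iv}: {len(arr)} levels for "
                    f"{config.n_individuals} individuals"
                )
        else:
            rng = child_rng(config.seed, "latent", dataset, i)
            lo_s, hi_s = config.me_spread_range
            spread = rng.uniform(lo_s, hi_s)
            base = rng.uniform(0.02, 1.0 - spread - 0.02)
            arr = np.linspace(base, base + spread, config.n_individuals)
            rng.shuffle(arr)
        out.append((iv, arr))
    return out


def _region_mask(pos: np.ndarray, intervals: Sequence[GenomicInterval], chrom: str) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask |= (pos >= iv.start) & (pos < iv.end)
    return mask


def _records(chrom: str, pos: np.ndarray, meth: np.ndarray, total: np.ndarray) -> list[CpGSiteRecord]:
    return [
        CpGSiteRecord(chrom, int(p), int(m), int(t))
        for p, m, t in zip(pos, meth, total)
    ]


def simulate_cohort(config: SimulationConfig, dataset: str = "D0") -> CohortData:
    """Simulate one multi-individual multi-tissue dataset.

    Outside planted regions every sample shares one latent per-site level
    drawn from the background Beta mixture (no interindividual signal);
    inside a planted region each individual draws one latent level shared
    across its tissues.  Counts are Binomial(Poisson depth, level).  SNPs are
    placed at ``snp_density`` per bp, plus ``n_snps_near_me`` placed within
    60 bp of planted ME-CpGs to exercise the proximity filter.
    """
    if config.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    if len(config.tissues) < 2:
        raise ValueError("need >= 2 tissues")
    genome = _genome_positions(config)
    planted = _planted_levels(config, dataset)
    truth = [iv for iv, _ in planted]
    individuals = [f"{dataset}_I{i + 1}" for i in range(config.n_individuals)]
    metas = [
        SampleMeta(
            sample_id=f"{dataset}_I{i + 1}_{t}",
            individual=ind,
            tissue=t,
            dataset=dataset,
        )
        for i, ind in enumerate(individuals)
        for t in config.tissues
    ]
    samples: dict[str, list[CpGSiteRecord]] = {m.sample_id: [] for m in metas}

    level_rng = child_rng(config.seed, "cohort-levels", dataset)
    count_rng = child_rng(config.seed, "cohort-counts", dataset)
    for chrom in sorted(genome):
        pos = genome[chrom]
        background = config.background_mix.sample(level_rng, len(pos))
        me_mask = _region_mask(pos, truth, chrom)
        for i_ind, ind in enumerate(individuals):
            levels = background.copy()
            for iv, latents in planted:
                if iv.chrom != chrom:
                    continue
                sel = (pos >= iv.start) & (pos < iv.end)
                levels[sel] = latents[i_ind]
            for tissue in config.tissues:
                depth = np.maximum(1, count_rng.poisson(config.depth_mean, len(pos)))
                meth = count_rng.binomial(depth, levels)
                samples[f"{dataset}_I{i_ind + 1}_{tissue}"].extend(
                    _records(chrom, pos, meth, depth)
                )
        del me_mask

    snp_rng = child_rng(config.seed, "snps", dataset)
    snps: dict[str, list[int]] = {}
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        n = snp_rng.poisson(config.snp_density * size)
        if n:
            snps[chrom] = sorted(int(x) for x in snp_rng.integers(0, size, n))
    for k in range(config.n_snps_near_me):
        if not truth:
            break
        iv = truth[int(snp_rng.integers(0, len(truth)))]
        region_pos = genome[iv.chrom]
        inside = region_pos[(region_pos >= iv.start) & (region_pos < iv.end)]
        if len(inside) == 0:
            continue
        anchor = int(inside[int(snp_rng.integers(0, len(inside)))])
        offset = int(snp_rng.integers(-60, 61))
        snps.setdefault(iv.chrom, []).append(max(0, anchor + offset))
    snps = {c: sorted(ps) for c, ps in snps.items()}
    return CohortData(
        samples=samples, metas=metas, snps=snps, truth=truth, cpg_positions=genome
    )


def simulate_stage_series(
    config: SimulationConfig,
) -> dict[str, list[list[CpGSiteRecord]]]:
    """Simulate per-stage replicate count tables along a trajectory.

    Background CpGs draw levels from a bimodal Beta centered on the stage's
    background mean; CpGs in planted regions draw around the stage's ME mean,
    except that a configured fraction is drawn uniformly in [0.1, 0.9]
    (the post-gastrulation intermediate excess).
    """
    if not config.stage_trajectory:
        raise ValueError("stage_trajectory is empty")
    genome = _genome_positions(config)
    truth = [iv for iv, _ in config.planted_me_regions]
    out: dict[str, list[list[CpGSiteRecord]]] = {}
    for stage in config.stage_trajectory:
        params = config.stage_trajectory[stage]
        replicates = []
        for rep in range(params.n_replicates):
            rng = child_rng(config.seed, "stage", stage, rep)
            records: list[CpGSiteRecord] = []
            for chrom in sorted(genome):
                pos = genome[chrom]
                levels = _stage_levels(rng, len(pos), params.background_mean,
                                       params.background_concentration)
                me_mask = _region_mask(pos, truth, chrom)
                n_me = int(me_mask.sum())
                if n_me:
                    me_levels = _extreme_levels(rng, n_me, params.me_mean)
                    inter = rng.random(n_me) < params.intermediate_fraction
                    me_levels[inter] = rng.uniform(0.1, 0.9, int(inter.sum()))
                    levels[me_mask] = me_levels
                depth = np.maximum(1, rng.poisson(config.depth_mean, len(pos)))
                meth = rng.binomial(depth, levels)
                records.extend(_records(chrom, pos, meth, depth))
            replicates.append(records)
        out[stage] = replicates
    return out


def _stage_levels(rng: np.random.Generator, n: int, mean: float, concentration: float) -> np.ndarray:
    mean = min(max(mean, 1e-6), 1 - 1e-6)
    return rng.beta(concentration * mean, concentration * (1 - mean), n)


def _extreme_levels(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    """Near-0/near-1 levels whose expectation is ``mean``; keeps binomial
    leakage into the intermediate band negligible."""
    high = rng.random(n) < mean
    out = np.empty(n)
    out[high] = rng.uniform(0.98, 1.0, int(high.sum()))
    out[~high] = rng.uniform(0.0, 0.02, int((~high).sum()))
    return out


def simulate_cluster_reads(
    region: GenomicInterval,
    n_reads: int,
    read_model: ReadModel,
    mean_methylation: float,
    seed: int,
    cpg_positions: Optional[Sequence[int]] = None,
) -> list[ReadCalls]:
    """Simulate sequenced molecules over one cluster.

    With probability ``p_homog`` a molecule is uniformly methylated or
    unmethylated (the choice Bernoulli(mean_methylation), so the expected
    pooled mean is preserved); otherwise each call is an independent
    Bernoulli(mean_methylation).  A ``missing_rate`` fraction of calls is
    masked, never leaving a read without called CpGs.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= mean_methylation <= 1:
        raise ValueError("mean_methylation must lie in [0, 1]")
    if cpg_positions is None:
        cpg_positions = np.arange(region.start, region.end, read_model.cpg_spacing)
    else:
        cpg_positions = np.asarray(sorted(cpg_positions))
        inside = (cpg_positions >= region.start) & (cpg_positions < region.end)
        cpg_positions = cpg_positions[inside]
    if len(cpg_positions) == 0:
        raise ValueError(f"region {region} contains no CpGs")
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        n_cpgs = min(len(cpg_positions), 1 + rng.poisson(max(read_model.n_cpgs_mean - 1, 0)))
        start_idx = int(rng.integers(0, len(cpg_positions) - n_cpgs + 1))
        pos = cpg_positions[start_idx : start_idx + n_cpgs]
        if rng.random() < read_model.p_homog:
            state = int(rng.random() < mean_methylation)
            calls = np.full(n_cpgs, state, dtype=np.int8)
        else:
            calls = (rng.random(n_cpgs) < mean_methylation).astype(np.int8)
        missing = rng.random(n_cpgs) < read_model.missing_rate
        if missing.all():
            missing[int(rng.integers(0, n_cpgs))] = False
        calls = calls.copy()
        calls[missing] = -1
        reads.append(ReadCalls(read_id=f"r{i}", chrom=region.chrom, positions=pos, calls=calls))
    return reads


def simulate_feature_tracks(
    truth_regions: Sequence[GenomicInterval],
    enrichment_factor: float,
    background_density: float,
    seed: int,
    chrom_sizes: Mapping[str, int],
    feature_length: int = 300,
    window: int = 10_000,
) -> list[GenomicInterval]:
    """Place features as a Poisson process, boosted near truth regions.

    The per-bp rate is ``background_density`` genome-wide, multiplied by
    ``enrichment_factor`` within ``window`` bp of a truth region (implemented
    by superposing an extra process at rate (factor - 1) * density on the
    expanded truth intervals).
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    if background_density < 0:
        raise ValueError("background_density must be >= 0")
    rng = np.random.default_rng(seed)
    features: list[GenomicInterval] = []
    expanded: dict[str, list[tuple[int, int]]] = {}
    for iv in truth_regions:
        expanded.setdefault(iv.chrom, []).append(
            (max(0, iv.start - window), min(chrom_sizes.get(iv.chrom, iv.end + window), iv.end + window))
        )
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_base = rng.poisson(background_density * size)
        starts = list(rng.integers(0, max(1, size - feature_length), n_base)) if n_base else []
        extra_rate = (enrichment_factor - 1.0) * background_density
        for lo, hi in expanded.get(chrom, ()):
            span = hi - lo
            n_extra = rng.poisson(extra_rate * span)
            if n_extra:
                starts.extend(int(lo + x) for x in rng.integers(0, span, n_extra))
        for s in sorted(int(x) for x in starts):
            features.append(
                GenomicInterval(chrom, s, min(s + feature_length, size), label="feature")
            )
    return features


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of the config with a different master seed."""
    return replace(config, seed=seed)
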
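"""End-to-end orchestration: config, manifest, stage wiring, demo run.

The pipeline configuration is a flat key=value file whose defaults are the
published analysis constants (15% interindividual difference, 1/3 intertissue
ratio, 60 bp SNP window, 300 bp clustering gap, 4 CpGs per cluster, 2:1
purity ratio, depth 10, 200x depth cap for read-level work, [0.10, 0.90]
intermediate band, 1000 randomizations, 1000 bootstrap resamples, 1 kb tiles,
10 kb proximity window).  Every output file carries the config hash, and a
rerun with identical inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import dynamics, enrichment, io, readlevel, screen, simulate
from .core import GenomicInterval, MethylationMatrix, SampleMeta

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every threshold and seed used by the stages, with published defaults."""

    inter_threshold: float = 0.15
    intra_ratio: float = 1.0 / 3.0
    snp_window: int = 60
    max_gap: int = 300
    min_cpgs: int = 4
    purity_ratio: float = 2.0
    combine_mode: str = "intersection"
    min_depth: int = 10
    max_depth: int = 200          # read-level depth cap
    band_lo: float = 0.10
    band_hi: float = 0.90
    n_rand: int = 1000
    n_boot: int = 1000
    tile_size: int = 1000
    window: int = 10_000
    n_controls: int = 200
    min_reads: int = 5
    control_bins: int = 5
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat key=value file; unknown keys are rejected."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                ftype = fields[key].type
                if ftype in ("int", int):
                    kwargs[key] = int(value)
                elif ftype in ("float", float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def to_text(self) -> str:
        lines = [
            f"{f.name}={getattr(self, f.name)!r}".replace("'", "")
            for f in dataclasses.fields(self)
        ]
        return "\n".join(lines) + "\n"

    def hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]


class ManifestError(KeyError):
    pass


def read_manifest(path) -> dict[str, str]:
    """Flat key=value manifest naming one input file per role.

    Recognized keys: ``dataset.<name>.samples`` (sample-sheet TSV with
    columns sample_id, individual, tissue, path), ``dataset.<name>.snps``
    (VCF), ``stage.<name>.replicates`` (comma-separated count files),
    ``regions``, ``controls``, ``features`` (BED), ``reads`` (read-call
    TSV), ``chrom_sizes`` (TSV chrom<TAB>size), ``array_table``,
    ``variance_table``, ``state_segments``, ``state_map``.
    """
    manifest = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = (part.strip() for part in line.split("=", 1))
            manifest[key] = value
    return manifest


def _require(manifest: Mapping[str, str], key: str, stage: str) -> str:
    if key not in manifest:
        raise ManifestError(f"stage {stage!r} requires manifest entry {key!r}")
    return manifest[key]


def load_dataset_matrix(
    sample_sheet: str, dataset: str, min_depth: int
) -> MethylationMatrix:
    sheet = pd.read_csv(sample_sheet, sep="\t")
    base = Path(sample_sheet).parent
    metas, per_sample = [], {}
    for row in sheet.itertuples():
        meta = SampleMeta(
            sample_id=str(row.sample_id),
            individual=str(row.individual),
            tissue=str(row.tissue),
            dataset=dataset,
        )
        metas.append(meta)
        p = Path(row.path)
        per_sample[meta.sample_id] = io.read_cytosine_report(
            p if p.is_absolute() else base / p, min_depth=min_depth
        )
    return MethylationMatrix.from_records(per_sample, metas)


def _region_table(
    clusters: Sequence[screen.MECluster],
    matrices: Mapping[str, MethylationMatrix] | None = None,
) -> pd.DataFrame:
    rows = []
    for c in clusters:
        row = {
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "role": c.role,
            "n_me_cpg": c.n_me_cpgs,
            "n_non_me_cpg": c.n_non_me_cpgs,
        }
        if matrices:
            for ds, matrix in matrices.items():
                frac = matrix.fractions()
                idx = frac.index
                sel = (
                    (idx.get_level_values("chrom") == c.interval.chrom)
                    & (idx.get_level_values("pos") >= c.interval.start)
                    & (idx.get_level_values("pos") < c.interval.end)
                )
                sub = frac[sel]
                for sample_id in sub.columns:
                    row[f"mean_meth.{sample_id}"] = (
                        round(float(sub[sample_id].mean()), 6) if len(sub) else float("nan")
                    )
        rows.append(row)
    return pd.DataFrame(rows)


def _demo_simulation_config(config: PipelineConfig) -> simulate.SimulationConfig:
    rng = np.random.default_rng(config.seed)
    chrom_sizes = {"chr1": 300_000, "chr2": 200_000}
    planted = []
    for chrom, size in chrom_sizes.items():
        n = 8 if chrom == "chr1" else 5
        starts = np.sort(rng.choice(np.arange(5_000, size - 7_000, 2_000), n, replace=False))
        for s in starts:
            planted.append((GenomicInterval(chrom, int(s), int(s) + 1_500, "ME"), None))
    return simulate.SimulationConfig(
        chrom_sizes=chrom_sizes,
        cpg_spacing_mean=80.0,
        n_individuals=2,
        tissues=("T1", "T2"),
        depth_mean=30.0,
        planted_me_regions=planted,
        snp_density=2e-5,
        n_snps_near_me=2,
        stage_trajectory={
            "oocyte": simulate.StageParams(0.35, 0.20, 0.0),
            "ICM": simulate.StageParams(0.40, 0.25, 0.0),
            "embryonic_liver": simulate.StageParams(0.80, 0.55, 0.5),
        },
        read_model=simulate.ReadModel(p_homog=0.8, missing_rate=0.05),
        seed=config.seed,
    )


def write_demo_inputs(config: PipelineConfig, outdir: Path) -> dict[str, str]:
    """Generate a fully synthetic input set and a manifest pointing at it."""
    sim = _demo_simulation_config(config)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    with open(inputs / "chrom_sizes.tsv", "w") as fh:
        for chrom in sorted(sim.chrom_sizes):
            fh.write(f"{chrom}\t{sim.chrom_sizes[chrom]}\n")
    manifest["chrom_sizes"] = str(inputs / "chrom_sizes.tsv")
    for ds in ("D1", "D2"):
        cohort = simulate.simulate_cohort(sim, dataset=ds)
        rows = []
        for meta in cohort.metas:
            path = inputs / f"{meta.sample_id}.counts.tsv"
            io.write_cytosine_counts(cohort.samples[meta.sample_id], path)
            rows.append(
                {
                    "sample_id": meta.sample_id,
                    "individual": meta.individual,
                    "tissue": meta.tissue,
                    "path": path.name,
                }
            )
        sheet = inputs / f"{ds}.samples.tsv"
        pd.DataFrame(rows).to_csv(sheet, sep="\t", index=False)
        manifest[f"dataset.{ds}.samples"] = str(sheet)
        vcf = inputs / f"{ds}.snps.vcf"
        io.write_vcf_positions(cohort.snps, vcf)
        manifest[f"dataset.{ds}.snps"] = str(vcf)
    io.write_bed(cohort.truth, inputs / "truth.bed")
    manifest["truth"] = str(inputs / "truth.bed")
    stages = simulate.simulate_stage_series(sim)
    stage_names = list(stages)
    for stage_name, replicates in stages.items():
        paths = []
        for i, recs in enumerate(replicates):
            p = inputs / f"stage.{stage_name}.rep{i}.counts.tsv"
            io.write_cytosine_counts(recs, p)
            paths.append(str(p))
        manifest[f"stage.{stage_name}.replicates"] = ",".join(paths)
    manifest["stage.pre"] = stage_names[-2]
    manifest["stage.post"] = stage_names[-1]
    features = simulate.simulate_feature_tracks(
        cohort.truth, enrichment_factor=15.0, background_density=2e-5,
        seed=config.seed + 1, chrom_sizes=sim.chrom_sizes,
    )
    io.write_bed(features, inputs / "features.bed")
    manifest["features"] = str(inputs / "features.bed")
    with open(inputs / "manifest.txt", "w") as fh:
        for k in sorted(manifest):
            fh.write(f"{k}={manifest[k]}\n")
    return manifest


def run_pipeline(
    config: PipelineConfig,
    manifest: Mapping[str, str] | None,
    outdir,
    demo: bool = False,
    stages: Sequence[str] = ("screen", "controls", "dynamics", "rhi", "enrich"),
) -> dict[str, object]:
    """Run the requested stages in dependency order and write TSV/BED outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if demo:
        manifest = write_demo_inputs(config, outdir)
    if manifest is None:
        raise ValueError("either a manifest or --demo is required")
    cfg_hash = config.hash()
    (outdir / "config.txt").write_text(config.to_text())
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    results: dict[str, object] = {}
    dataset_names = sorted(
        {k.split(".")[1] for k in manifest if k.startswith("dataset.") and k.endswith(".samples")}
    )
    chrom_sizes = None
    if "chrom_sizes" in manifest:
        chrom_sizes = {}
        with open(manifest["chrom_sizes"]) as fh:
            for line in fh:
                if line.strip():
                    chrom, size = line.split()
                    chrom_sizes[chrom] = int(size)

    matrices: dict[str, MethylationMatrix] = {}
    me_clusters: list[screen.MECluster] = []
    controls: list[screen.MECluster] = []
    screen_result = None

    if "screen" in stages or "controls" in stages:
        if not dataset_names:
            raise ManifestError("stage 'screen' requires at least one dataset.<name>.samples entry")
        snps: dict[str, dict[str, list[int]]] = {}
        for ds in dataset_names:
            sheet = _require(manifest, f"dataset.{ds}.samples", "screen")
            matrices[ds] = load_dataset_matrix(sheet, ds, config.min_depth)
            log(f"screen: dataset {ds}: {matrices[ds].n_sites} CpGs covered in all samples")
            if f"dataset.{ds}.snps" in manifest:
                snps[ds] = io.read_vcf_positions(manifest[f"dataset.{ds}.snps"])
            else:
                log(f"screen: no SNP file for dataset {ds}; SNP filter skipped")
        screen_result = screen.run_screen(
            matrices,
            snps=snps,
            inter_threshold=config.inter_threshold,
            intra_ratio=config.intra_ratio,
            snp_window=config.snp_window,
            max_gap=config.max_gap,
            min_cpgs=config.min_cpgs,
            purity_ratio=config.purity_ratio,
            combine_mode=config.combine_mode,
        )
        me_clusters = screen_result.me_clusters
        log(f"screen: {len(screen_result.passing_cpgs)} passing CpGs -> "
            f"{len(me_clusters)} ME clusters")
        io.write_bed([c.interval for c in me_clusters], outdir / "me_regions.bed")
        io.write_regions(
            _region_table(me_clusters, matrices), outdir / "me_regions.tsv",
            header_comment=f"config_hash={cfg_hash}",
        )
        results["me_clusters"] = me_clusters

    if "controls" in stages and me_clusters:
        controls = screen.generate_control_clusters(
            sorted(screen_result.covered_cpgs),
            me_clusters,
            n_controls=config.n_controls,
            seed=config.seed,
            max_gap=config.max_gap,
            min_cpgs=config.min_cpgs,
            n_bins=config.control_bins,
        )
        log(f"controls: {len(controls)} control clusters sampled")
        io.write_bed([c.interval for c in controls], outdir / "control_regions.bed")
        io.write_regions(
            _region_table(controls, matrices), outdir / "control_regions.tsv",
            header_comment=f"config_hash={cfg_hash}",
        )
        results["controls"] = controls

    stage_names = sorted(
        {k.split(".")[1] for k in manifest if k.startswith("stage.") and k.endswith(".replicates")}
    )
    if "dynamics" in stages:
        if not stage_names:
            raise ManifestError("stage 'dynamics' requires stage.<name>.replicates entries")
        regions = [c.interval for c in me_clusters] or None
        if regions is None and "regions" in manifest:
            regions = io.read_bed(manifest["regions"])
        rows = []
        for stage_name in stage_names:
            paths = manifest[f"stage.{stage_name}.replicates"].split(",")
            replicates = [io.read_cytosine_report(p, min_depth=1) for p in paths]
            for scope, reg in (("background", None), ("me_regions", regions)):
                if scope == "me_regions" and reg is None:
                    continue
                summary = dynamics.stage_summary(
                    stage_name, replicates, regions=reg,
                    min_depth=config.min_depth,
                    lo=config.band_lo, hi=config.band_hi,
                )
                rows.append(
                    {
                        "stage": stage_name,
                        "scope": scope,
                        "n_observations": summary.n_observations,
                        "mean_methylation": round(summary.mean_methylation, 6),
                        "intermediate_fraction": round(summary.intermediate_fraction, 6),
                    }
                )
                log(f"dynamics: {stage_name}/{scope}: {summary.n_observations} observations")
        df = pd.DataFrame(rows)
        io.write_regions(df, outdir / "stage_summaries.tsv",
                         header_comment=f"config_hash={cfg_hash}")
        results["stage_summaries"] = df

    if "rhi" in stages:
        rhi_rows = []
        region_sets: dict[str, list[GenomicInterval]] = {}
        if me_clusters:
            region_sets["ME"] = [c.interval for c in me_clusters]
        if controls:
            region_sets["control"] = [c.interval for c in controls]
        if not region_sets and "regions" in manifest:
            region_sets["regions"] = io.read_bed(manifest["regions"])
        if "reads" in manifest:
            reads = io.read_read_calls(manifest["reads"])
        elif demo:
            reads = _demo_reads(config, region_sets)
        else:
            raise ManifestError("stage 'rhi' requires manifest entry 'reads'")
        for role, regions in region_sets.items():
            for iv in regions:
                overlapping = readlevel.clip_reads_to_region(reads, iv)
                if not readlevel.rhi_eligible(
                    overlapping, iv, band=(config.band_lo, config.band_hi),
                    min_reads=config.min_reads,
                ):
                    continue
                result = readlevel.compute_rhi(
                    overlapping, iv, n_rand=config.n_rand,
                    rng=simulate.child_rng(config.seed, "rhi", iv.chrom, iv.start),
                )
                rhi_rows.append(
                    {
                        "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                        "role": role,
                        "observed_transitions": result.observed_transitions,
                        "median_randomized": result.median_randomized,
                        "rhi": round(result.rhi, 6) if result.defined else "NA",
                        "n_reads": result.n_reads,
                        "n_called_positions": result.n_called_positions,
                    }
                )
        df = pd.DataFrame(rhi_rows)
        io.write_regions(df, outdir / "rhi.tsv", header_comment=f"config_hash={cfg_hash}")
        log(f"rhi: {len(rhi_rows)} eligible clusters scored")
        results["rhi"] = df

    if "enrich" in stages:
        if chrom_sizes is None:
            raise ManifestError("stage 'enrich' requires manifest entry 'chrom_sizes'")
        features = io.read_bed(_require(manifest, "features", "enrich"))
        regions = [c.interval for c in me_clusters]
        if not regions and "regions" in manifest:
            regions = io.read_bed(manifest["regions"])
        if not regions:
            raise ManifestError("stage 'enrich' requires screened regions or a 'regions' entry")
        res = enrichment.tile_enrichment(
            features, regions, chrom_sizes,
            window=config.window, tile_size=config.tile_size,
        )
        prox = enrichment.proximity_profile(regions, features)
        df = pd.DataFrame(
            [
                {
                    "test": "tile_fet",
                    "a": res.table.a, "b": res.table.b,
                    "c": res.table.c, "d": res.table.d,
                    "odds_ratio": round(res.odds_ratio, 6),
                    "p_value": res.p_value,
                    "window": res.window,
                }
            ]
        )
        io.write_regions(df, outdir / "enrichment.tsv",
                         header_comment=f"config_hash={cfg_hash}")
        io.write_regions(
            pd.DataFrame(
                [{"threshold_bp": t, "proportion": round(p, 6)} for t, p in prox.items()]
            ),
            outdir / "proximity.tsv", header_comment=f"config_hash={cfg_hash}",
        )
        log(f"enrich: OR={res.odds_ratio:.3g} p={res.p_value:.3g}")
        results["enrichment"] = res

    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return results


def _demo_reads(
    config: PipelineConfig, region_sets: Mapping[str, Sequence[GenomicInterval]]
) -> list[readlevel.ReadCalls]:
    """Synthetic reads for the demo: molecule-specific in MEs, mosaic elsewhere."""
    reads: list[readlevel.ReadCalls] = []
    counter = 0
    for role, regions in region_sets.items():
        p_homog = 0.85 if role == "ME" else 0.1
        for iv in regions:
            model = simulate.ReadModel(p_homog=p_homog, missing_rate=0.05)
            seed = int(
                simulate.child_rng(config.seed, "demo-reads", iv.chrom, iv.start).integers(2**31)
            )
            for r in simulate.simulate_cluster_reads(
                iv, n_reads=30, read_model=model, mean_methylation=0.5, seed=seed
            ):
                r.read_id = f"{role}_{counter}_{r.read_id}"
                reads.append(r)
            counter += 1
    return reads
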
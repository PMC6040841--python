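import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiallele import screen
from epiallele.core import CpGSiteRecord, GenomicInterval, MethylationMatrix, SampleMeta
from epiallele.screen import (
    MECluster,
    cluster_cpgs,
    combine_datasets,
    detect_me_cpgs,
    filter_snp_proximal,
    generate_control_clusters,
    purity_filter,
    run_screen,
)
from epiallele.simulate import SimulationConfig, simulate_cohort


def matrix_from_fractions(frac_by_sample, depth=100, dataset="D"):
    """Build a matrix from {(individual, tissue): [fractions]} at fixed depth."""
    metas, per_sample = [], {}
    for (ind, tis), fracs in frac_by_sample.items():
        sid = f"{ind}_{tis}"
        metas.append(SampleMeta(sid, ind, tis, dataset))
        per_sample[sid] = [
            CpGSiteRecord("chr1", 100 * (i + 1), round(f * depth), depth)
            for i, f in enumerate(fracs)
        ]
    return MethylationMatrix.from_records(per_sample, metas)


class TestDetectMeCpgs:
    def test_worked_example(self):
        # hand evaluation: tissue means A=0.31, B=0.51 -> d_inter=0.20;
        # within-individual spreads 0.02 -> d_intra=0.02 <= 0.20/3
        m = matrix_from_fractions(
            {("A", "t1"): [0.30], ("A", "t2"): [0.32],
             ("B", "t1"): [0.50], ("B", "t2"): [0.52]}
        )
        v = detect_me_cpgs(m)
        assert v["d_inter"].iloc[0] == pytest.approx(0.20)
        assert v["d_intra"].iloc[0] == pytest.approx(0.02)
        assert bool(v["passes"].iloc[0])

    def test_identical_samples_fail(self):
        m = matrix_from_fractions(
            {("A", "t1"): [0.4], ("A", "t2"): [0.4],
             ("B", "t1"): [0.4], ("B", "t2"): [0.4]}
        )
        v = detect_me_cpgs(m)
        assert v["d_inter"].iloc[0] == 0
        assert not v["passes"].any()

    def test_grid_sweep_matches_inequalities(self):
        # brute-force oracle: construct each (d_inter, d_intra) cell directly
        # and evaluate the stated inequalities independently
        # grid values offset from the 0.15 and 1/3-ratio boundaries so the
        # verdict is not decided by float rounding at exact equality
        for d_inter in np.round(np.arange(0.0, 0.55, 0.05) + 0.012, 4):
            for d_intra in np.round(np.arange(0.0, 0.3, 0.05) + 0.007, 4):
                base = 0.2
                m = matrix_from_fractions(
                    {
                        ("A", "t1"): [base],
                        ("A", "t2"): [base + d_intra],
                        ("B", "t1"): [base + d_inter],
                        ("B", "t2"): [base + d_inter + d_intra],
                    },
                    depth=1000,
                )
                v = detect_me_cpgs(m)
                got_inter = v["d_inter"].iloc[0]
                got_intra = v["d_intra"].iloc[0]
                # oracle values under the max-pairwise definitions
                samples = {
                    ("A", "t1"): base, ("A", "t2"): base + d_intra,
                    ("B", "t1"): base + d_inter, ("B", "t2"): base + d_inter + d_intra,
                }
                tmean = {
                    ind: np.mean([v2 for (i, _), v2 in samples.items() if i == ind])
                    for ind in ("A", "B")
                }
                exp_inter = abs(tmean["A"] - tmean["B"])
                exp_intra = max(
                    abs(samples[(ind, "t1")] - samples[(ind, "t2")]) for ind in ("A", "B")
                )
                # depth=1000 quantization is the only source of difference
                assert got_inter == pytest.approx(exp_inter, abs=1e-9)
                assert got_intra == pytest.approx(exp_intra, abs=1e-9)
                expected_pass = exp_inter >= 0.15 and exp_intra <= exp_inter / 3
                assert bool(v["passes"].iloc[0]) == expected_pass

    def test_three_individuals_max_pairwise(self):
        m = matrix_from_fractions(
            {("A", "t1"): [0.1], ("A", "t2"): [0.1],
             ("B", "t1"): [0.3], ("B", "t2"): [0.3],
             ("C", "t1"): [0.6], ("C", "t2"): [0.6]}
        )
        v = detect_me_cpgs(m)
        assert v["d_inter"].iloc[0] == pytest.approx(0.5)  # C - A

    def test_single_individual_errors(self):
        m = matrix_from_fractions({("A", "t1"): [0.3], ("A", "t2"): [0.4]})
        with pytest.raises(ValueError, match="individuals"):
            detect_me_cpgs(m)

    def test_single_tissue_errors(self):
        m = matrix_from_fractions({("A", "t1"): [0.3], ("B", "t1"): [0.4]})
        with pytest.raises(ValueError, match="tissues"):
            detect_me_cpgs(m)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        frac = {
            (ind, tis): list(rng.random(80))
            for ind in "AB" for tis in ("t1", "t2")
        }
        m = matrix_from_fractions(frac, depth=50)
        counts = [
            detect_me_cpgs(m, inter_threshold=t)["passes"].sum()
            for t in (0.05, 0.10, 0.15, 0.25, 0.4)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSnpFilter:
    def test_inclusive_boundary(self):
        kept = filter_snp_proximal([("chr1", 1000)], {"chr1": [1060]}, window=60)
        assert kept == []
        kept = filter_snp_proximal([("chr1", 1000)], {"chr1": [1061]}, window=60)
        assert kept == [("chr1", 1000)]

    def test_no_snps_identity(self):
        cpgs = [("chr1", 10), ("chr2", 20)]
        assert filter_snp_proximal(cpgs, {}) == cpgs

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.integers(0, 5000), min_size=1, max_size=60),
        st.lists(st.integers(0, 5000), max_size=20),
    )
    def test_matches_all_pairs_oracle(self, cpg_pos, snp_pos):
        cpgs = [("chr1", p) for p in sorted(set(cpg_pos))]
        kept = filter_snp_proximal(cpgs, {"chr1": snp_pos}, window=60)
        oracle = [
            (c, p) for c, p in cpgs
            if all(abs(p - s) > 60 for s in snp_pos)
        ]
        assert kept == oracle

    def test_frame_input(self):
        df = pd.DataFrame(
            {"passes": [True, True]},
            index=pd.MultiIndex.from_tuples(
                [("chr1", 100), ("chr1", 500)], names=["chrom", "pos"]
            ),
        )
        out = filter_snp_proximal(df, {"chr1": [130]}, window=60)
        assert list(out.index) == [("chr1", 500)]


class TestCombine:
    def test_intersection(self):
        assert combine_datasets([{"a", "b", "c"}, {"b", "c", "d"}], "intersection") == {"b", "c"}

    def test_union(self):
        assert combine_datasets([{"a", "b", "c"}, {"b", "c", "d"}], "union") == {"a", "b", "c", "d"}

    def test_empty_intersection(self):
        assert combine_datasets([set(), {"a"}], "intersection") == set()

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            combine_datasets([{"a"}], "xor")


def brute_force_clusters(positions, max_gap, min_cpgs):
    """Quadratic single-linkage oracle."""
    by_chrom = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)
    out = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom])
        # connected components under |a-b| <= max_gap adjacency (sorted order
        # makes consecutive-link equivalence exact for single linkage)
        comps = [[ps[0]]] if ps else []
        for p in ps[1:]:
            if any(abs(p - q) <= max_gap for q in comps[-1]):
                comps[-1].append(p)
            else:
                comps.append([p])
        out.extend((chrom, tuple(c)) for c in comps if len(c) >= min_cpgs)
    return out


class TestClustering:
    def test_chain_of_four(self):
        clusters = cluster_cpgs([("chr1", p) for p in (0, 250, 500, 750)])
        assert len(clusters) == 1
        assert clusters[0].me_cpg_positions == [0, 250, 500, 750]
        assert clusters[0].interval == GenomicInterval("chr1", 0, 752)

    def test_isolated_positions(self):
        assert cluster_cpgs([("chr1", p) for p in (0, 400, 800, 1200)]) == []

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.integers(0, 20_000), max_size=150))
    def test_matches_brute_force(self, raw):
        positions = [("chr1", p) for p in sorted(set(raw))]
        got = [
            (c.interval.chrom, tuple(c.me_cpg_positions))
            for c in cluster_cpgs(positions, max_gap=300, min_cpgs=4)
        ]
        assert got == brute_force_clusters(positions, 300, 4)

    def test_min_cpgs_boundary(self):
        pos = [("chr1", p) for p in (0, 100, 200)]
        assert cluster_cpgs(pos, min_cpgs=4) == []
        assert len(cluster_cpgs(pos, min_cpgs=3)) == 1


class TestPurity:
    def _cluster(self, me_positions):
        return MECluster(
            interval=GenomicInterval("chr1", me_positions[0], me_positions[-1] + 2),
            me_cpg_positions=list(me_positions),
        )

    def test_ratio_kept(self):
        c = self._cluster([0, 100, 200, 300])
        covered = [("chr1", p) for p in (0, 100, 150, 175, 200, 300)]  # 2 non-ME
        assert purity_filter([c], covered) == [c]
        assert c.n_non_me_cpgs == 2

    def test_ratio_dropped(self):
        c = self._cluster([0, 100, 200, 300])
        covered = [("chr1", p) for p in (0, 50, 100, 150, 175, 200, 300)]  # 3 non-ME
        assert purity_filter([c], covered) == []

    def test_no_non_me(self):
        c = self._cluster([0, 100, 200, 300])
        covered = [("chr1", p) for p in (0, 100, 200, 300)]
        assert purity_filter([c], covered) == [c]


class TestControls:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        # covered CpGs: dense tracts so the pool has many clusters
        covered = []
        pos = 0
        for _ in range(600):
            pos += int(rng.integers(50, 250))
            covered.append(("chr1", pos))
        me_positions = [("chr1", p) for p in range(10**6, 10**6 + 4 * 120, 120)]
        me = cluster_cpgs(me_positions)
        covered.extend(me_positions)
        return covered, me

    def test_empty_me_set_errors(self):
        with pytest.raises(ValueError, match="empty ME set"):
            generate_control_clusters([("chr1", 0)], [], n_controls=5, seed=0)

    def test_no_overlap_with_me(self):
        covered, me = self._setup()
        controls = generate_control_clusters(covered, me, n_controls=20, seed=1)
        assert controls
        for c in controls:
            assert all(not c.interval.overlaps(m.interval) for m in me)
            assert c.role == "control"

    def test_capped_when_pool_small(self, caplog):
        covered, me = self._setup()
        controls = generate_control_clusters(covered, me, n_controls=10**6, seed=1)
        assert len(controls) < 10**6

    def test_deterministic_under_seed(self):
        covered, me = self._setup()
        a = generate_control_clusters(covered, me, n_controls=25, seed=9)
        b = generate_control_clusters(covered, me, n_controls=25, seed=9)
        assert [c.interval for c in a] == [c.interval for c in b]

    def test_joint_histogram_matches_me(self):
        # sampling-design check: chi-squared GOF of the sampled joint
        # histogram against the ME histogram scaled to n_controls
        rng = np.random.default_rng(7)
        covered = []
        for chrom in ("chr1", "chr2", "chr3"):
            pos = 0
            for _ in range(4000):
                pos += int(rng.integers(40, 200))
                covered.append((chrom, pos))
        me_positions = []
        base = 4 * 10**6
        for i in range(60):
            start = base + i * 5000
            n = int(rng.integers(4, 12))
            me_positions.extend(("chr9", start + j * int(rng.integers(30, 150))) for j in range(n))
        me = cluster_cpgs(sorted(me_positions))
        assert len(me) >= 40
        controls = generate_control_clusters(covered, me, n_controls=200, seed=3)
        from scipy import stats

        qs = np.linspace(0, 1, 6)[1:-1]
        spans = np.array([c.span for c in me])
        counts = np.array([c.n_me_cpgs for c in me])
        s_edges, c_edges = np.quantile(spans, qs), np.quantile(counts, qs)

        def hist(clusters):
            h = np.zeros((5, 5))
            for c in clusters:
                i = np.searchsorted(s_edges, c.span, side="right")
                j = np.searchsorted(c_edges, c.n_me_cpgs, side="right")
                h[i, j] += 1
            return h

        me_h = hist(me).ravel()
        ctl_h = hist(controls).ravel()
        expected = me_h / me_h.sum() * ctl_h.sum()
        keep = expected > 0
        stat = ((ctl_h[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(stat, keep.sum() - 1)
        assert p > 0.01


class TestFullScreen:
    def _matrices(self, config, datasets=("D1", "D2")):
        matrices, snps, truth = {}, {}, None
        for ds in datasets:
            cohort = simulate_cohort(config, dataset=ds)
            matrices[ds] = MethylationMatrix.from_records(cohort.samples, cohort.metas)
            snps[ds] = cohort.snps
            truth = cohort.truth
        return matrices, snps, truth

    def test_recovers_planted_regions(self, cohort_config):
        matrices, snps, truth = self._matrices(cohort_config)
        result = run_screen(matrices, snps=snps)
        assert result.me_clusters
        for iv in truth:
            assert any(c.interval.overlaps(iv) for c in result.me_clusters)

    def test_deterministic(self, cohort_config):
        matrices, snps, _ = self._matrices(cohort_config)
        a = run_screen(matrices, snps=snps)
        b = run_screen(matrices, snps=snps)
        assert [c.interval for c in a.me_clusters] == [c.interval for c in b.me_clusters]

    def test_raising_threshold_never_adds_cpgs(self, cohort_config):
        matrices, snps, _ = self._matrices(cohort_config)
        n = [
            len(run_screen(matrices, snps=snps, inter_threshold=t).passing_cpgs)
            for t in (0.10, 0.15, 0.30)
        ]
        assert n == sorted(n, reverse=True)
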
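"""Core domain types shared by all stages.

Coordinate convention: 0-based, half-open. A CpG dyad is addressed by the
position of its plus-strand cytosine; counts from the minus strand are merged
onto that coordinate before any depth filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGSiteRecord",
    "GenomicInterval",
    "SampleMeta",
    "MethylationMatrix",
]


@dataclass(frozen=True, order=True)
class CpGSiteRecord:
    """Methylation counts for one CpG dyad in one sample.

    ``pos`` is the 0-based position of the plus-strand C. ``n_total`` is the
    combined depth of both strands.
    """

    chrom: str
    pos: int
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError(
                f"n_total must be positive at {self.chrom}:{self.pos}, got {self.n_total}"
            )
        if not 0 <= self.n_meth <= self.n_total:
            raise ValueError(
                f"n_meth must satisfy 0 <= n_meth <= n_total at "
                f"{self.chrom}:{self.pos}: {self.n_meth}/{self.n_total}"
            )

    @property
    def fraction(self) -> float:
        return self.n_meth / self.n_total


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with an optional label."""

    chrom: str
    start: int
    end: int
    label: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"start must be < end: {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """bp separating the two intervals; 0 when they overlap or abut.

        Returns None for intervals on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one methylation sample within a cohort."""

    sample_id: str
    individual: str
    tissue: str
    dataset: str
    stage: Optional[str] = None


class MethylationMatrix:
    """CpG sites x samples table of (methylated, total) counts.

    Only sites covered in *every* sample are retained, matching the screen's
    requirement that a CpG be assessable in all individuals and tissues of a
    dataset.
    """

    def __init__(self, counts: pd.DataFrame, samples: Sequence[SampleMeta]):
        # counts: MultiIndex (chrom, pos) rows; MultiIndex (sample_id, field)
        # columns with field in {meth, total}.
        self.counts = counts
        self.samples = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in cohort")
        triples = [(s.individual, s.tissue, s.dataset) for s in self.samples]
        if len(set(triples)) != len(triples):
            raise ValueError("(individual, tissue, dataset) triples must be unique")

    @classmethod
    def from_records(
        cls,
        per_sample: Mapping[str, Iterable[CpGSiteRecord]],
        samples: Sequence[SampleMeta],
    ) -> "MethylationMatrix":
        frames = {}
        for meta in samples:
            recs = list(per_sample[meta.sample_id])
            if recs:
                df = pd.DataFrame(
                    {
                        "chrom": [r.chrom for r in recs],
                        "pos": [r.pos for r in recs],
                        "meth": [r.n_meth for r in recs],
                        "total": [r.n_total for r in recs],
                    }
                ).set_index(["chrom", "pos"])
            else:
                df = pd.DataFrame(
                    {"meth": [], "total": []},
                    index=pd.MultiIndex.from_arrays([[], []], names=["chrom", "pos"]),
                )
            frames[meta.sample_id] = df
        counts = pd.concat(frames, axis=1, join="inner").sort_index()
        counts.columns.names = ["sample_id", "field"]
        return cls(counts, samples)

    @property
    def n_sites(self) -> int:
        return len(self.counts)

    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.individual, None)
        return list(seen)

    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.tissue, None)
        return list(seen)

    def fractions(self) -> pd.DataFrame:
        """Per-site methylation fraction, one column per sample."""
        meth = self.counts.xs("meth", axis=1, level="field")
        total = self.counts.xs("total", axis=1, level="field")
        return meth / total

    def positions(self) -> pd.MultiIndex:
        return self.counts.index


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals; labels are dropped."""
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class IntervalLookup:
    """Sorted-array membership and overlap queries against a fixed interval set."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        merged = merge_intervals(intervals)
        for iv in merged:
            self._by_chrom.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
        starts: dict[str, list[int]] = {c: [] for c in self._by_chrom}
        ends: dict[str, list[int]] = {c: [] for c in self._by_chrom}
        for iv in merged:
            starts[iv.chrom].append(iv.start)
            ends[iv.chrom].append(iv.end)
        for c in self._by_chrom:
            self._by_chrom[c] = (np.asarray(starts[c]), np.asarray(ends[c]))

    def contains_positions(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: does each position fall inside any interval?"""
        pos = np.asarray(pos)
        if chrom not in self._by_chrom:
            return np.zeros(len(pos), dtype=bool)
        starts, ends = self._by_chrom[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        mask = np.zeros(len(pos), dtype=bool)
        mask[ok] = pos[ok] < ends[idx[ok]]
        return mask

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        if iv.chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[iv.chrom]
        i = np.searchsorted(ends, iv.start, side="right")
        return i < len(starts) and starts[i] < iv.end
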
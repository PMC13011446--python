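"""Windowed repeat-density tracks, peak calls, and fine-scale cluster scans.

Density is defined as the merged-coverage fraction of a window: features of
all families within one category are clipped to the window, overlaps merged,
and covered bases divided by the window's true width, giving a value in
[0, 1].  Windows tile each chromosome from coordinate 0; the final partial
window is kept and normalized by its own width so telomeric signal is not
lost.

The :class:`CoverageIndex` provides O(log m) covered-base queries over merged
intervals via prefix sums, vectorized across query arrays; the permutation
test in :mod:`karyoshift.enrichment` relies on it to evaluate tens of
thousands of candidate windows per inversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CategoryScheme, GenomeIndex, Interval, RepeatFeature

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10_000


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping intervals into disjoint sorted intervals."""
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    # a new merged run starts where the start exceeds the running max of ends
    run_max = np.maximum.accumulate(e)
    new_run = np.empty(len(s), dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > run_max[:-1]
    idx = np.flatnonzero(new_run)
    merged_s = s[idx]
    merged_e = np.append(run_max[idx[1:] - 1], run_max[-1])
    return merged_s, merged_e


class ChromCoverage:
    """Merged coverage on one chromosome with prefix-sum queries."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        self.starts, self.ends = merge_intervals(starts, ends)
        lengths = self.ends - self.starts
        self.cum = np.concatenate(([0], np.cumsum(lengths)))

    def covered_upto(self, x: np.ndarray | int) -> np.ndarray:
        """Total covered bases in [0, x)."""
        x = np.asarray(x, dtype=np.int64)
        j = np.searchsorted(self.starts, x, side="right") - 1
        jj = np.maximum(j, 0)
        partial = np.clip(x - self.starts[jj], 0, self.ends[jj] - self.starts[jj]) \
            if len(self.starts) else np.zeros_like(x)
        base = self.cum[jj] if len(self.starts) else np.zeros_like(x)
        return np.where(j >= 0, base + partial, 0)

    def covered(self, a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
        """Covered bases within [a, b), elementwise over arrays."""
        return self.covered_upto(b) - self.covered_upto(a)


class CoverageIndex:
    """Per-chromosome merged coverage for one density category."""

    def __init__(self, repeats: Iterable[RepeatFeature], classes: frozenset[str]):
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for f in repeats:
            if f.repeat_class in classes:
                s, e = by_chrom.setdefault(f.chrom, ([], []))
                s.append(f.start)
                e.append(f.end)
        self._cov = {
            chrom: ChromCoverage(np.array(s), np.array(e))
            for chrom, (s, e) in by_chrom.items()
        }

    def chrom(self, name: str) -> ChromCoverage:
        return self._cov.get(name) or ChromCoverage(np.empty(0), np.empty(0))

    def covered(self, chrom: str, a, b) -> np.ndarray:
        return self.chrom(chrom).covered(a, b)


def _window_edges(length: int, w: int, origin: int = 0) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(origin, length, w, dtype=np.int64)
    ends = np.minimum(starts + w, length)
    return starts, ends


def compute_window_densities(
    repeats: Sequence[RepeatFeature],
    genome: GenomeIndex,
    w: int = DEFAULT_WINDOW,
    scheme: CategoryScheme | None = None,
) -> pd.DataFrame:
    """Tile every chromosome with non-overlapping w-bp windows and compute
    the merged-coverage density of each category per window.

    Returns a DataFrame with columns chrom, start, end and one column per
    category.  Features on chromosomes absent from ``genome`` raise an error.
    """
    if w <= 0:
        raise ValueError("window width must be positive")
    scheme = scheme or CategoryScheme()
    unknown = sorted({f.chrom for f in repeats if f.chrom not in genome})
    if unknown:
        raise ValueError(f"repeat features on unknown chromosomes: {', '.join(unknown)}")
    indexes = {cat: CoverageIndex(repeats, scheme.classes_for(cat))
               for cat in scheme.categories}
    frames = []
    for chrom, length in genome.items():
        starts, ends = _window_edges(length, w)
        data = {"chrom": chrom, "start": starts, "end": ends}
        widths = (ends - starts).astype(float)
        for cat in scheme.categories:
            data[cat] = indexes[cat].covered(chrom, starts, ends) / widths
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class PeakCall:
    chrom: str
    start: int
    end: int
    category: str
    density: float
    chrom_median: float
    chrom_p95: float
    is_peak: bool


def call_peaks(track: pd.DataFrame, category: str, percentile: float = 95.0) -> list[PeakCall]:
    """Flag windows whose density strictly exceeds the chromosome-level
    percentile of the same category (default 95th, linear interpolation)."""
    if track.empty:
        raise ValueError("empty density track")
    if category not in track.columns:
        raise KeyError(f"category {category!r} not in track")
    calls: list[PeakCall] = []
    for chrom, grp in track.groupby("chrom", sort=False):
        dens = grp[category].to_numpy(float)
        if len(dens) < 20:
            logger.warning("chromosome %s has only %d windows; percentile unstable",
                           chrom, len(dens))
        med = float(np.median(dens))
        ref = float(np.percentile(dens, percentile))
        for start, end, d in zip(grp["start"], grp["end"], dens):
            calls.append(PeakCall(chrom, int(start), int(end), category,
                                  float(d), med, ref, bool(d > ref)))
    return calls


def peaks_to_frame(calls: Sequence[PeakCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def region_density(
    repeats: Sequence[RepeatFeature] | Mapping[str, CoverageIndex],
    region: Interval,
    w: int = DEFAULT_WINDOW,
    scheme: CategoryScheme | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Tile ``region`` from its own start into w-bp subwindows and return the
    per-subwindow densities plus the median density per category.

    The final subwindow may be fractional; its density is a fraction of its
    true width.  ``repeats`` may be pre-built :class:`CoverageIndex` objects
    keyed by category (used by the permutation test to avoid re-indexing).
    """
    scheme = scheme or CategoryScheme()
    if isinstance(repeats, Mapping):
        indexes = repeats
    else:
        indexes = {cat: CoverageIndex(repeats, scheme.classes_for(cat))
                   for cat in scheme.categories}
    starts = np.arange(region.start, region.end, w, dtype=np.int64)
    ends = np.minimum(starts + w, region.end)
    widths = (ends - starts).astype(float)
    data = {"chrom": region.chrom, "start": starts, "end": ends}
    medians = {}
    for cat, idx in indexes.items():
        dens = idx.covered(region.chrom, starts, ends) / widths
        data[cat] = dens
        medians[cat] = float(np.median(dens))
    return pd.DataFrame(data), medians


def cluster_density(
    repeats: Sequence[RepeatFeature],
    cluster: Interval,
    genome: GenomeIndex | None = None,
    flank: int = 25_000,
    w: int = 500,
    scheme: CategoryScheme | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fine-scale density across a gene cluster plus flanks (default 500-bp
    windows over the cluster ± 25 kb), e.g. for antifreeze-glycoprotein loci."""
    start = max(0, cluster.start - flank)
    end = cluster.end + flank
    if genome is not None and cluster.chrom in genome:
        end = min(end, genome[cluster.chrom])
    return region_density(repeats, Interval(cluster.chrom, start, end, cluster.name),
                          w=w, scheme=scheme)


def shared_te_families(
    repeats: Sequence[RepeatFeature],
    regions: Sequence[Interval],
) -> dict[str, list[tuple[str, list[RepeatFeature]]]]:
    """Families with insertions in at least two of the given regions.

    Returns family -> list of (region name, insertions in that region);
    families present in exactly one region are excluded.
    """
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    per_family: dict[str, dict[str, list[RepeatFeature]]] = {}
    for region in regions:
        for f in repeats:
            if f.chrom == region.chrom and f.start < region.end and f.end > region.start:
                per_family.setdefault(f.family, {}).setdefault(region.name, []).append(f)
    return {
        fam: sorted(((rname, feats) for rname, feats in hits.items()),
                    key=lambda t: t[0])
        for fam, hits in per_family.items()
        if len(hits) >= 2
    }


def write_bedgraph(track: pd.DataFrame, category: str, path: str | Path) -> None:
    cols = track[["chrom", "start", "end", category]]
    cols.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
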
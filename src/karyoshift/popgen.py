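"""Windowed π, D_XY and F_ST from genotype tables that include invariant
sites, with missing-data-aware ratio-of-sums aggregation.

The estimators follow the count-based form popularized by pixy: per window,
difference counts and comparison counts are summed over all sites (invariant
sites contribute comparisons but no differences) and the window value is the
ratio of the sums, never a mean of per-site ratios.  Windows whose comparison
denominator is zero are reported as missing (NaN), not zero.  F_ST uses the
Weir–Cockerham variance components in the haploid-sample (haplotype count)
formulation, summed over polymorphic sites only; Hudson's estimator is
available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeIndex, GenotypeTable, Interval

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10_000


@dataclass
class SiteCounts:
    """Per-site non-missing ref/alt allele counts per population."""

    chroms: np.ndarray           # str array, one entry per site
    positions: np.ndarray        # 0-based
    counts: dict[str, tuple[np.ndarray, np.ndarray]]  # pop -> (n_ref, n_alt)

    @classmethod
    def from_genotypes(
        cls, gt: GenotypeTable, populations: Mapping[str, str]
    ) -> "SiteCounts":
        """``populations`` maps haplotype/sample column name to population.

        Columns named ``sample_1``/``sample_2`` (diploid expansion) fall back
        to the bare sample name when only that is listed.
        """
        alleles = np.asarray(gt.alleles, dtype=np.int8)
        if alleles.size == 0:
            alleles = alleles.reshape(0, len(gt.samples))
        pop_of: list[str | None] = []
        for name in gt.samples:
            pop = populations.get(name)
            if pop is None and "_" in name:
                pop = populations.get(name.rsplit("_", 1)[0])
            pop_of.append(pop)
        counts = {}
        for pop in sorted({p for p in pop_of if p is not None}):
            cols = [i for i, p in enumerate(pop_of) if p == pop]
            sub = alleles[:, cols]
            counts[pop] = (
                (sub == 0).sum(axis=1).astype(np.int64),
                (sub == 1).sum(axis=1).astype(np.int64),
            )
        return cls(np.asarray(gt.chroms), np.asarray(gt.positions, dtype=np.int64), counts)

    def __len__(self) -> int:
        return len(self.positions)


def _window_frame(genome: GenomeIndex, w: int) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.items():
        starts = np.arange(0, length, w, dtype=np.int64)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.minimum(starts + w, length),
        }))
    return pd.concat(rows, ignore_index=True)


def _aggregate(
    sites: SiteCounts, genome: GenomeIndex, w: int,
    num: np.ndarray, den: np.ndarray, colname: str,
) -> pd.DataFrame:
    """Ratio-of-sums aggregation of per-site numerators/denominators into
    tiling windows; dens of zero yield NaN."""
    frame = _window_frame(genome, w)
    df = pd.DataFrame({
        "chrom": sites.chroms,
        "widx": sites.positions // w,
        "num": num,
        "den": den,
        "used": (den > 0).astype(np.int64),
    })
    agg = df.groupby(["chrom", "widx"], sort=False).sum().reset_index()
    frame["widx"] = frame["start"] // w
    out = frame.merge(agg, on=["chrom", "widx"], how="left").drop(columns="widx")
    out[["num", "den", "used"]] = out[["num", "den", "used"]].fillna(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[colname] = np.where(out["den"] > 0, out["num"] / out["den"], np.nan)
    return out.rename(columns={"num": "count_diffs", "den": "count_comparisons",
                               "used": "n_sites"})


def windowed_pi(
    sites: SiteCounts, population: str, genome: GenomeIndex, w: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Nucleotide diversity per window for one population.

    Per site with n1 ref and n2 alt non-missing alleles, differences are
    n1·n2 and comparisons (n1+n2)(n1+n2−1)/2; invariant sites contribute
    comparisons only, which is what keeps the estimator unbiased when they
    are retained.
    """
    n_ref, n_alt = sites.counts[population]
    n = n_ref + n_alt
    k = (n_ref * n_alt).astype(np.float64)
    c = (n * (n - 1) / 2).astype(np.float64)
    if len(sites) and not np.any((n_ref > 0) & (n_alt > 0)):
        pass  # all-monomorphic input is fine; pi will be 0 where defined
    return _aggregate(sites, genome, w, k, c, "avg_pi")


def windowed_dxy(
    sites: SiteCounts, pop_x: str, pop_y: str, genome: GenomeIndex,
    w: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Absolute between-population divergence per window (ratio of summed
    cross-population difference counts to cross-population comparisons)."""
    xr, xa = sites.counts[pop_x]
    yr, ya = sites.counts[pop_y]
    k = (xr * ya + xa * yr).astype(np.float64)
    c = ((xr + xa) * (yr + ya)).astype(np.float64)
    return _aggregate(sites, genome, w, k, c, "avg_dxy")


def _wc_components(
    xr: np.ndarray, xa: np.ndarray, yr: np.ndarray, ya: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham components for two haploid samples.

    Returns (a, a_plus_b, usable) where a is the among-population component
    and a_plus_b the total; within-haplotype variance is identically zero for
    haplotype counts, so c = 0.
    """
    n1 = (xr + xa).astype(np.float64)
    n2 = (yr + ya).astype(np.float64)
    ntot = n1 + n2
    alt = (xa + ya).astype(np.float64)
    polymorphic = (alt > 0) & (alt < ntot)
    usable = polymorphic & (n1 > 0) & (n2 > 0) & (ntot - 2 > 0) & ((n1 - 1) + (n2 - 1) > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, xa / np.maximum(n1, 1), 0.0)
        p2 = np.where(n2 > 0, ya / np.maximum(n2, 1), 0.0)
        pbar = alt / np.maximum(ntot, 1)
        r = 2.0
        n_c = (ntot - (n1 ** 2 + n2 ** 2) / np.maximum(ntot, 1)) / (r - 1)
        msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / np.maximum((n1 - 1) + (n2 - 1), 1)
        a = (msp - msg) / np.maximum(n_c, 1e-300)
        a_b = (msp + (n_c - 1) * msg) / np.maximum(n_c, 1e-300)
    a = np.where(usable, a, 0.0)
    a_b = np.where(usable, a_b, 0.0)
    return a, a_b, usable


def _hudson_components(xr, xa, yr, ya):
    n1 = (xr + xa).astype(np.float64)
    n2 = (yr + ya).astype(np.float64)
    alt = (xa + ya).astype(np.float64)
    usable = (alt > 0) & (alt < n1 + n2) & (n1 > 1) & (n2 > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = xa / np.maximum(n1, 1)
        p2 = ya / np.maximum(n2, 1)
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
               - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return np.where(usable, num, 0.0), np.where(usable, den, 0.0), usable


def windowed_fst(
    sites: SiteCounts, pop_x: str, pop_y: str, genome: GenomeIndex,
    w: int = DEFAULT_WINDOW, estimator: str = "weir_cockerham",
) -> pd.DataFrame:
    """Window F_ST as a ratio of summed variance components over polymorphic
    biallelic sites; windows without usable sites are NaN.  Negative values
    are reported as computed."""
    xr, xa = sites.counts[pop_x]
    yr, ya = sites.counts[pop_y]
    if estimator == "weir_cockerham":
        num, den, usable = _wc_components(xr, xa, yr, ya)
    elif estimator == "hudson":
        num, den, usable = _hudson_components(xr, xa, yr, ya)
    else:
        raise ValueError(f"unknown F_ST estimator {estimator!r}")
    out = _aggregate(sites, genome, w, num, den, "avg_fst")
    # n_sites should count usable polymorphic sites, not all den>0 sites
    df = pd.DataFrame({"chrom": sites.chroms, "widx": sites.positions // w,
                       "usable": usable.astype(np.int64)})
    agg = df.groupby(["chrom", "widx"], sort=False)["usable"].sum().reset_index()
    out["widx"] = out["start"] // w
    out = out.merge(agg, on=["chrom", "widx"], how="left").drop(columns="widx")
    out["n_sites"] = out["usable"].fillna(0).astype(int)
    out = out.drop(columns="usable")
    out.loc[out["n_sites"] == 0, "avg_fst"] = np.nan
    return out


def scan_conserved_tracts(
    fst_windows: pd.DataFrame, fst_threshold: float = 0.5,
    value_col: str = "avg_fst",
) -> list[Interval]:
    """Maximal runs of consecutive windows with F_ST below the threshold,
    bridged across at most one missing window; the field's signature of
    conserved (low-differentiation) stretches on an otherwise highly
    differentiated background."""
    tracts: list[Interval] = []
    for chrom, grp in fst_windows.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        run_start = None
        run_end = None
        gap = 0
        for _, row in grp.iterrows():
            v = row[value_col]
            if np.isnan(v):
                if run_start is not None:
                    gap += 1
                    if gap > 1:
                        tracts.append(Interval(chrom, run_start, run_end, "tract"))
                        run_start, gap = None, 0
                continue
            if v < fst_threshold:
                if run_start is None:
                    run_start = int(row["start"])
                run_end = int(row["end"])
                gap = 0
            else:
                if run_start is not None:
                    tracts.append(Interval(chrom, run_start, run_end, "tract"))
                run_start, gap = None, 0
        if run_start is not None:
            tracts.append(Interval(chrom, run_start, run_end, "tract"))
    return [Interval(t.chrom, t.start, t.end, f"tract_{i+1}")
            for i, t in enumerate(tracts)]
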
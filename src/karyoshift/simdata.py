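"""Synthetic genomes, repeat landscapes, rearrangements, ortholog anchor
tables, two-population genotypes, and Brownian-motion trait data.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale, with exact ground truth:

* repeats per family are a homogeneous Poisson process along each
  chromosome, with the rate multiplied by an enrichment factor λ inside the
  ±50 kb flanks of planted inversion breakpoints (λ = 1 makes flanks
  statistically indistinguishable from background);
* the ancestral (reference-like) genome carries an even gene order; fusions
  concatenate ancestral chromosome pairs into derived chromosomes,
  inversions mirror the contained gene run, and translocations move gene
  runs, yielding one ortholog anchor pair per gene;
* genotypes are haploid sequences per sample over a contiguous block of
  sites: each site is independently a fixed between-population difference
  (rate d, reduced inside conserved tracts), a within-population
  polymorphism (calibrated so the expected pixy-style π equals the requested
  rate), or invariant — invariant sites are retained;
* quantitative traits evolve by Brownian motion on a given tree:
  trait = intercept + slope · predictor + residual, residuals multivariate
  normal with covariance σ²C.

One integer seed determines everything; independent substreams are derived
per stage, chromosome and family, so partial re-runs are stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .genome_io import GenomeIndex, GenotypeTable, Interval, RepeatFeature
from .phylotrait import phylo_covariance
from . import synteny as _synteny

BREAKPOINT_FLANK = 50_000

# substream tags, so per-stage RNGs never collide
_STAGE_LANDSCAPE = 101
_STAGE_GENOTYPES = 301
_STAGE_TRAITS = 401


@dataclass(frozen=True)
class TEFamily:
    name: str
    te_class: str  # DNA, LINE, SINE, LTR, Simple_repeat, ...
    rate: float    # insertions per bp
    length_range: tuple[int, int] = (100, 1000)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"family {self.name}: negative insertion rate")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError(f"family {self.name}: bad length range {self.length_range}")


@dataclass(frozen=True)
class PlantedInversion:
    chrom: str
    start: int
    end: int
    enrichment: float = 1.0          # λ; 1 = background
    enriched_families: tuple[str, ...] | None = None  # None = all families

    def __post_init__(self) -> None:
        if self.enrichment < 0:
            raise ValueError("enrichment factor λ must be >= 0")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad inversion interval {self.start}-{self.end}")

    def as_interval(self, name: str) -> Interval:
        return Interval(self.chrom, self.start, self.end, name)


@dataclass(frozen=True)
class Fusion:
    partners: tuple[str, str]
    name: str | None = None

    @property
    def product(self) -> str:
        return self.name or "+".join(self.partners)


@dataclass(frozen=True)
class Translocation:
    src_chrom: str
    src_start: int
    src_end: int
    dest_chrom: str
    dest_pos: int


@dataclass(frozen=True)
class ConservedTract:
    start: int
    end: int
    d_factor: float = 0.0  # multiplies the fixed-difference rate inside


@dataclass(frozen=True)
class PopGenConfig:
    chrom: str = "pg1"
    n_sites: int = 100_000
    n_haplotypes_per_pop: int = 28   # 14 diploid individuals per species
    d: float = 0.005                 # fixed-difference rate between pops
    pi_x: float = 0.002
    pi_y: float = 0.004
    conserved_tracts: tuple[ConservedTract, ...] = ()
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        for r in (self.d, self.pi_x, self.pi_y, self.missing_rate):
            if not (0 <= r <= 1):
                raise ValueError("popgen rates must lie in [0, 1]")


@dataclass(frozen=True)
class BMConfig:
    tree_newick: str
    intercept: float
    slope: float
    sigma2: float
    predictors: tuple[tuple[str, float], ...] = ()


@dataclass
class SimConfig:
    seed: int
    chromosomes: list[tuple[str, int]]            # ancestral genome
    te_families: list[TEFamily] = field(default_factory=list)
    inversions: list[PlantedInversion] = field(default_factory=list)
    fusions: list[Fusion] = field(default_factory=list)
    translocations: list[Translocation] = field(default_factory=list)
    genes_per_mb: float = 10.0
    popgen: PopGenConfig | None = None
    bm: BMConfig | None = None

    def __post_init__(self) -> None:
        self.ancestral = GenomeIndex(self.chromosomes)
        fused = [p for f in self.fusions for p in f.partners]
        if len(set(fused)) != len(fused):
            raise ValueError("a chromosome participates in more than one fusion")
        for p in fused:
            if p not in self.ancestral:
                raise ValueError(f"fusion partner {p!r} not an ancestral chromosome")
        self.derived = self._derive_genome()
        by_chrom: dict[str, list[PlantedInversion]] = {}
        for inv in self.inversions:
            if inv.chrom not in self.derived:
                raise ValueError(f"inversion on unknown derived chromosome {inv.chrom!r}")
            if inv.end > self.derived[inv.chrom]:
                raise ValueError(f"inversion {inv.chrom}:{inv.start}-{inv.end} exceeds chromosome")
            by_chrom.setdefault(inv.chrom, []).append(inv)
        for chrom, invs in by_chrom.items():
            invs = sorted(invs, key=lambda i: i.start)
            for a, b in zip(invs, invs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping planted inversions on {chrom}")
        for tr in self.translocations:
            for c, pos in ((tr.src_chrom, tr.src_end), (tr.dest_chrom, tr.dest_pos)):
                if c not in self.derived or pos > self.derived[c]:
                    raise ValueError("translocation outside chromosome bounds")

    def _derive_genome(self) -> GenomeIndex:
        consumed = {p for f in self.fusions for p in f.partners}
        entries: list[tuple[str, int]] = []
        placed: set[str] = set()
        for name, length in self.chromosomes:
            if name not in consumed:
                entries.append((name, length))
                continue
            fusion = next(f for f in self.fusions if name in f.partners)
            if fusion.product in placed:
                continue
            entries.append((fusion.product,
                            sum(self.ancestral[p] for p in fusion.partners)))
            placed.add(fusion.product)
        return GenomeIndex(entries)


@dataclass
class GroundTruth:
    """Planted features, recoverable by coordinate lookup."""

    ancestral_genome: GenomeIndex
    derived_genome: GenomeIndex
    inversions: list[Interval] = field(default_factory=list)
    fusions: list[dict] = field(default_factory=list)           # product/partners/junction
    translocations: list[Translocation] = field(default_factory=list)
    conserved_tracts: list[Interval] = field(default_factory=list)
    bm_params: dict | None = None
    anchor_spacing: dict[str, float] = field(default_factory=dict)


def _base_truth(config: SimConfig) -> GroundTruth:
    truth = GroundTruth(config.ancestral, config.derived)
    truth.inversions = [inv.as_interval(f"inv_{i+1}")
                        for i, inv in enumerate(config.inversions)]
    offset = 0
    for f in config.fusions:
        lens = [(p, config.ancestral[p]) for p in f.partners]
        junctions = np.cumsum([l for _, l in lens])[:-1].tolist()
        truth.fusions.append({"product": f.product, "partners": lens,
                              "junctions": junctions})
    truth.translocations = list(config.translocations)
    if config.popgen:
        truth.conserved_tracts = [
            Interval(config.popgen.chrom, t.start, t.end, f"tract_{i+1}")
            for i, t in enumerate(config.popgen.conserved_tracts)
        ]
    if config.bm:
        truth.bm_params = {"intercept": config.bm.intercept, "slope": config.bm.slope,
                           "sigma2": config.bm.sigma2}
    return truth


def simulate_landscape(config: SimConfig) -> tuple[GenomeIndex, list[RepeatFeature], GroundTruth]:
    """Draw the repeat annotation of the derived genome.

    Per family, insertions follow a homogeneous Poisson process at the
    configured rate, except inside the ±50 kb breakpoint flanks of planted
    inversions that enrich the family, where the rate is multiplied by λ
    (thinning for λ < 1, superposition for λ > 1 — both exact).
    """
    genome = config.derived
    truth = _base_truth(config)
    feats: list[RepeatFeature] = []
    flanks_by_chrom: dict[str, list[tuple[int, int, float, tuple[str, ...] | None]]] = {}
    for inv in config.inversions:
        L = genome[inv.chrom]
        for point in (inv.start, inv.end):
            flanks_by_chrom.setdefault(inv.chrom, []).append(
                (max(0, point - BREAKPOINT_FLANK), min(L, point + BREAKPOINT_FLANK),
                 inv.enrichment, inv.enriched_families))
    for ci, (chrom, L) in enumerate(genome.items()):
        for fi, fam in enumerate(config.te_families):
            rng = np.random.default_rng([config.seed, _STAGE_LANDSCAPE, ci, fi])
            n_bg = rng.poisson(fam.rate * L)
            starts = rng.integers(0, L, size=n_bg) if n_bg else np.empty(0, dtype=np.int64)
            keep = np.ones(len(starts), dtype=bool)
            extra: list[np.ndarray] = []
            for flo, fhi, lam, famset in flanks_by_chrom.get(chrom, ()):
                if famset is not None and fam.name not in famset:
                    continue
                if lam == 1.0:
                    continue
                inside = (starts >= flo) & (starts < fhi)
                if lam < 1.0:
                    keep &= ~inside | (rng.random(len(starts)) < lam)
                else:
                    n_extra = rng.poisson(fam.rate * (lam - 1.0) * (fhi - flo))
                    if n_extra:
                        extra.append(rng.integers(flo, fhi, size=n_extra))
            all_starts = np.concatenate([starts[keep]] + extra) if extra else starts[keep]
            lo, hi = fam.length_range
            lengths = rng.integers(lo, hi + 1, size=len(all_starts))
            strands = rng.random(len(all_starts)) < 0.5
            for s, ln, plus in zip(all_starts, lengths, strands):
                feats.append(RepeatFeature(chrom, int(s), int(min(s + ln, L)),
                                           fam.name, fam.te_class,
                                           "+" if plus else "-"))
    feats.sort(key=lambda f: (f.chrom, f.start, f.end))
    return genome, feats, truth


def simulate_anchor_table(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Lay an even ancestral gene order, apply fusions, inversions and
    translocations, and emit one ortholog anchor pair per gene (query =
    derived genome, reference = ancestral genome)."""
    if config.genes_per_mb <= 0:
        raise ValueError("genes_per_mb must be positive")
    truth = _base_truth(config)
    rows = []
    for chrom, L in config.ancestral.items():
        n = max(1, round(L / 1e6 * config.genes_per_mb))
        spacing = L // (n + 1)
        if spacing == 0:
            raise ValueError(f"chromosome {chrom} too short for {n} genes")
        glen = max(1, min(1000, spacing // 2))
        for i in range(n):
            s = spacing * (i + 1)
            rows.append({"gene": f"{chrom}_g{i:05d}", "rchrom": chrom,
                         "rstart": s, "rend": s + glen,
                         "qchrom": chrom, "qstart": s, "qend": s + glen})
    df = pd.DataFrame(rows)
    # fusions: concatenate partner coordinates onto the product chromosome
    for f in config.fusions:
        offset = 0
        for partner in f.partners:
            sel = df["qchrom"] == partner
            df.loc[sel, "qstart"] += offset
            df.loc[sel, "qend"] += offset
            df.loc[sel, "qchrom"] = f.product
            offset += config.ancestral[partner]
    # inversions: mirror fully contained genes
    for inv in config.inversions:
        sel = ((df["qchrom"] == inv.chrom)
               & (df["qstart"] >= inv.start) & (df["qend"] <= inv.end))
        new_start = inv.start + (inv.end - df.loc[sel, "qend"])
        new_end = inv.start + (inv.end - df.loc[sel, "qstart"])
        df.loc[sel, "qstart"] = new_start
        df.loc[sel, "qend"] = new_end
    # translocations: move contained gene runs, preserving internal offsets
    for tr in config.translocations:
        sel = ((df["qchrom"] == tr.src_chrom)
               & (df["qstart"] >= tr.src_start) & (df["qstart"] < tr.src_end))
        df.loc[sel, "qstart"] = tr.dest_pos + (df.loc[sel, "qstart"] - tr.src_start)
        df.loc[sel, "qend"] = df.loc[sel, "qstart"] + 1000
        df.loc[sel, "qchrom"] = tr.dest_chrom
    df = _synteny.rank_anchors(df[_synteny.ANCHOR_COLUMNS])
    for chrom, grp in df.groupby("qchrom"):
        ss = np.sort(grp["qstart"].to_numpy())
        truth.anchor_spacing[str(chrom)] = float(np.diff(ss).mean()) if len(ss) > 1 else float("inf")
    return df, truth


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeTable, GroundTruth]:
    """Two-population haplotype matrix over a contiguous block of sites.

    Each site is exactly one of: fixed difference between the populations
    (rate d, multiplied by d_factor inside conserved tracts), polymorphic in
    X only, polymorphic in Y only, or invariant.  Polymorphic sites draw
    their alternate-allele count uniformly from 1..n−1, and the polymorphism
    probability is calibrated so the expected ratio-of-sums π equals the
    requested rate: E[j(n−j)] / (n(n−1)/2) = (n+1)/(3(n−1)) per polymorphic
    site, hence P(poly) = π · 3(n−1)/(n+1).
    """
    pg = config.popgen
    if pg is None:
        raise ValueError("config has no popgen block")
    truth = _base_truth(config)
    rng = np.random.default_rng([config.seed, _STAGE_GENOTYPES])
    L, n = pg.n_sites, pg.n_haplotypes_per_pop
    if n < 2:
        raise ValueError("need >= 2 haplotypes per population")
    p_x = pg.pi_x * 3 * (n - 1) / (n + 1)
    p_y = pg.pi_y * 3 * (n - 1) / (n + 1)
    d_site = np.full(L, pg.d)
    for t in pg.conserved_tracts:
        d_site[t.start:min(t.end, L)] = pg.d * t.d_factor
    if float(d_site.max(initial=0)) + p_x + p_y > 1:
        raise ValueError("per-site event probabilities exceed 1")
    tract = np.zeros(L, dtype=bool)
    for t in pg.conserved_tracts:
        tract[t.start:min(t.end, L)] = True
    u = rng.random(L)
    fixed = u < d_site
    poly_x = ~fixed & (u < d_site + p_x)
    poly_y = ~fixed & ~poly_x & (u < d_site + p_x + p_y)
    # inside conserved tracts polymorphisms are shared between the
    # populations (same allele count in both), the signature of conserved
    # low-divergence haplotypes: F_ST collapses while π stays high
    shared = tract & (poly_x | poly_y)
    alleles = np.zeros((L, 2 * n), dtype=np.int8)
    alleles[fixed, n:] = 1  # Y carries the alternate allele at fixed diffs

    def scatter(idx: np.ndarray, cols: slice, j: np.ndarray) -> None:
        order = np.argsort(rng.random((len(idx), n)), axis=1)
        carrier = order < j[:, None]
        block = alleles[idx, cols]
        block[carrier] = 1
        alleles[idx, cols] = block

    for mask, cols in ((poly_x & ~shared, slice(0, n)),
                       (poly_y & ~shared, slice(n, 2 * n))):
        idx = np.flatnonzero(mask)
        if len(idx):
            scatter(idx, cols, rng.integers(1, n, size=len(idx)))
    idx = np.flatnonzero(shared)
    if len(idx):
        j = rng.integers(1, n, size=len(idx))
        scatter(idx, slice(0, n), j)
        scatter(idx, slice(n, 2 * n), j)
    if pg.missing_rate > 0:
        alleles[rng.random(alleles.shape) < pg.missing_rate] = -1
    is_variant = [(row == 1).any() for row in alleles]
    samples = []
    for pop in ("X", "Y"):
        for k in range(n):
            samples.append(f"{pop}{k // 2 + 1:02d}_{k % 2 + 1}")
    gt = GenotypeTable(samples, [pg.chrom] * L, list(range(L)),
                       alleles.tolist(), is_variant)
    return gt, truth


def population_map(config: SimConfig) -> dict[str, str]:
    """Sample (individual) name -> population for the simulated genotypes."""
    n = config.popgen.n_haplotypes_per_pop
    out = {}
    for pop in ("X", "Y"):
        for k in range(0, n, 2):
            out[f"{pop}{k // 2 + 1:02d}"] = pop
    return out


def simulate_bm_traits(
    tree: dendropy.Tree,
    intercept: float,
    slope: float,
    sigma2: float,
    predictors: Mapping[str, float],
    seed: int,
) -> pd.DataFrame:
    """Traits = intercept + slope·predictor + BM residual with covariance
    σ²C; σ² = 0 gives the exact linear response."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    labels, C = phylo_covariance(tree)
    missing = [lab for lab in labels if lab not in predictors]
    if missing:
        raise KeyError(f"missing predictor values for tips: {missing}")
    x = np.array([float(predictors[lab]) for lab in labels])
    mean = intercept + slope * x
    if sigma2 == 0:
        traits = mean
    else:
        rng = np.random.default_rng([seed, _STAGE_TRAITS])
        # C can be singular (e.g. zero-length cherries); eigendecomposition
        # handles the PSD case that Cholesky rejects
        w, V = np.linalg.eigh(C)
        w = np.clip(w, 0, None)
        z = rng.standard_normal(len(labels))
        traits = mean + np.sqrt(sigma2) * (V @ (np.sqrt(w) * z))
    return pd.DataFrame({"species": labels, "predictor": x, "trait": traits})


# ---------------------------------------------------------------------------
# writers

def write_vcf(gt: GenotypeTable, genome: GenomeIndex, path: str | Path) -> None:
    """Plain-text diploid VCF with invariant sites; haplotype columns are
    paired into individuals in order; missing alleles become '.'."""
    base_names = []
    for name in gt.samples[::2]:
        base_names.append(name.rsplit("_", 1)[0])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in genome.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(base_names) + "\n")
        for site in range(len(gt)):
            row = gt.alleles[site]
            alt = "T" if gt.is_variant[site] else "."
            gts = []
            for k in range(0, len(row), 2):
                a, b = row[k], row[k + 1]
                gts.append(f"{'.' if a < 0 else a}/{'.' if b < 0 else b}")
            fh.write(f"{gt.chroms[site]}\t{gt.positions[site] + 1}\t.\tA\t{alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def write_anchor_table(df: pd.DataFrame, path: str | Path) -> None:
    df[_synteny.ANCHOR_COLUMNS].to_csv(path, sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "ancestral_genome": dict(truth.ancestral_genome.items()),
        "derived_genome": dict(truth.derived_genome.items()),
        "inversions": [vars(iv) for iv in truth.inversions],
        "fusions": truth.fusions,
        "translocations": [asdict(t) for t in truth.translocations],
        "conserved_tracts": [vars(iv) for iv in truth.conserved_tracts],
        "bm_params": truth.bm_params,
        "anchor_spacing": truth.anchor_spacing,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
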
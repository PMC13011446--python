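"""Collinear synteny blocks from gene-order anchors, and the rearrangement
calls built on them: chromosomal fusions, translocated segments, cross-genome
interval projection, and cross-species inversion overlaps.

An anchor is one ortholog pair with coordinates in a query and a reference
genome; ranks are dense gene orders per chromosome.  A block is a maximal
run of anchors whose consecutive query- and reference-rank gaps both stay
within ``max_gap`` (default 10, the MCScanX default gene gap) and whose
reference ranks are strictly monotone with a fixed sign — forward or reverse.

Chaining is greedy over the query gene order with several chains open at
once: each anchor joins the compatible open chain with the nearest reference
rank, except that an anchor sitting at a local extremum of the reference
order (its bond to the next gene is tighter than the one to the chain and
points the other way) starts a new chain instead, so an inversion's first
gene is not swallowed by the preceding forward block.  If this partition ever
covers fewer anchors than the single best collinear chain (computable by
dynamic programming), the chromosome is re-chained by iterated extraction of
the DP-optimal chain; in practice the fallback triggers only on adversarial
gene orders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import Interval

logger = logging.getLogger(__name__)

ANCHOR_COLUMNS = ["gene", "qchrom", "qstart", "qend", "rchrom", "rstart", "rend"]


@dataclass(frozen=True)
class ChainParams:
    max_gap: int = 10
    min_anchors: int = 5

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")


@dataclass
class SyntenyBlock:
    qchrom: str
    rchrom: str
    orientation: str  # "forward" | "reverse"
    anchors: pd.DataFrame  # rows in chain order

    @property
    def n(self) -> int:
        return len(self.anchors)

    @property
    def qstart(self) -> int:
        return int(self.anchors["qstart"].min())

    @property
    def qend(self) -> int:
        return int(self.anchors["qend"].max())

    @property
    def rstart(self) -> int:
        return int(self.anchors["rstart"].min())

    @property
    def rend(self) -> int:
        return int(self.anchors["rend"].max())

    @property
    def genes(self) -> list[str]:
        return list(self.anchors["gene"])


def read_anchor_table(path: str | Path) -> pd.DataFrame:
    """Read the 8-column anchor TSV (gene, query chrom/start/end paired with
    the ortholog's gene name implied equal, reference chrom/start/end)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANCHOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"anchor table missing columns: {missing}")
    return df


def rank_anchors(df: pd.DataFrame) -> pd.DataFrame:
    """Add dense per-chromosome gene-order ranks (qrank, rrank) by start."""
    out = df.copy()
    out["qrank"] = out.groupby("qchrom")["qstart"].rank(method="first").astype(int) - 1
    out["rrank"] = out.groupby("rchrom")["rstart"].rank(method="first").astype(int) - 1
    return out


def swap_anchor_table(df: pd.DataFrame) -> pd.DataFrame:
    """Exchange query and reference genomes (ranks recomputed)."""
    out = df.rename(columns={
        "qchrom": "rchrom", "qstart": "rstart", "qend": "rend",
        "rchrom": "qchrom", "rstart": "qstart", "rend": "qend",
    })
    return rank_anchors(out[ANCHOR_COLUMNS])


def _dp_best_chain(q: np.ndarray, r: np.ndarray, rch: np.ndarray,
                   max_gap: int, avail: np.ndarray) -> list[int]:
    """Longest single collinear chain (either sign) among available anchors,
    O(n · max_gap) thanks to dense query ranks."""
    n = len(q)
    best_len = np.zeros((n, 2), dtype=np.int64)  # [:,0] increasing, [:,1] decreasing
    parent = np.full((n, 2), -1, dtype=np.int64)
    idx_avail = np.flatnonzero(avail)
    pos_of = {int(q[i]): i for i in idx_avail}
    for i in idx_avail:
        best_len[i] = 1
        for dq in range(1, max_gap + 1):
            jq = int(q[i]) - dq
            j = pos_of.get(jq)
            if j is None:
                continue
            if rch[j] != rch[i]:
                continue
            d = int(r[i]) - int(r[j])
            if 1 <= d <= max_gap and best_len[j, 0] + 1 > best_len[i, 0]:
                best_len[i, 0] = best_len[j, 0] + 1
                parent[i, 0] = j
            if 1 <= -d <= max_gap and best_len[j, 1] + 1 > best_len[i, 1]:
                best_len[i, 1] = best_len[j, 1] + 1
                parent[i, 1] = j
    if len(idx_avail) == 0:
        return []
    flat = best_len[idx_avail]
    k = int(np.argmax(flat))
    i, sign = int(idx_avail[k // 2]), int(k % 2)
    chain = []
    while i >= 0:
        chain.append(i)
        i = int(parent[i, sign])
    chain.reverse()
    return chain


def _greedy_chains(q: np.ndarray, r: np.ndarray, rch: np.ndarray,
                   max_gap: int) -> list[list[int]]:
    """Greedy multi-chain growth in query order; returns index lists."""
    order = np.argsort(q, kind="stable")
    open_chains: list[dict] = []  # {idx: [...], sign: 0/±1, last_q, last_r, rch}
    closed: list[list[int]] = []
    for pos, i in enumerate(order):
        qi, ri, ci = int(q[i]), int(r[i]), rch[i]
        # retire chains that can no longer be extended
        still = []
        for ch in open_chains:
            if qi - ch["last_q"] > max_gap:
                closed.append(ch["idx"])
            else:
                still.append(ch)
        open_chains = still
        # lookahead: the next gene on the query, if chainable from i
        preferred = 0
        d_next = None
        if pos + 1 < len(order):
            k = int(order[pos + 1])
            if rch[k] == ci and int(q[k]) - qi <= max_gap:
                dk = int(r[k]) - ri
                if 1 <= abs(dk) <= max_gap:
                    preferred = 1 if dk > 0 else -1
                    d_next = abs(dk)
        best = None
        best_d = None
        for ch in open_chains:
            if ch["rch"] != ci:
                continue
            d = ri - ch["last_r"]
            if not (1 <= abs(d) <= max_gap):
                continue
            s = 1 if d > 0 else -1
            if ch["sign"] not in (0, s):
                continue
            # local-extremum veto: bond to the next gene is tighter and flips
            if preferred and s != preferred and d_next is not None and abs(d) > d_next:
                continue
            key = (abs(d), qi - ch["last_q"])  # prefer tight ref bond, then query continuity
            if best is None or key < best_d:
                best, best_d = ch, key
        if best is None:
            open_chains.append({"idx": [i], "sign": 0, "last_q": qi,
                                "last_r": ri, "rch": ci})
        else:
            s = 1 if ri - best["last_r"] > 0 else -1
            best["idx"].append(i)
            best["sign"] = s
            best["last_q"], best["last_r"] = qi, ri
    closed.extend(ch["idx"] for ch in open_chains)
    return closed


def chain_indices(q: np.ndarray, r: np.ndarray, rch: np.ndarray,
                  params: ChainParams = ChainParams()) -> list[list[int]]:
    """Array-level chaining core: anchor index lists (chain order) for one
    query chromosome, after the min-anchor filter and DP fallback."""
    chains = _greedy_chains(q, r, rch, params.max_gap)
    kept = [c for c in chains if len(c) >= params.min_anchors]
    coverage = sum(len(c) for c in kept)
    best = _dp_best_chain(q, r, rch, params.max_gap, np.ones(len(q), dtype=bool))
    if len(best) >= params.min_anchors and coverage < len(best):
        # adversarial order fragmented the greedy partition: extract
        # DP-optimal chains instead
        logger.debug("chain_indices: DP fallback (greedy %d < best %d)",
                     coverage, len(best))
        kept = []
        avail = np.ones(len(q), dtype=bool)
        while True:
            chain = _dp_best_chain(q, r, rch, params.max_gap, avail)
            if len(chain) < params.min_anchors:
                break
            kept.append(chain)
            avail[chain] = False
    return kept


def chain_blocks(anchors: pd.DataFrame, params: ChainParams = ChainParams()) -> list[SyntenyBlock]:
    """Chain ranked anchors into collinear blocks, per query chromosome."""
    if anchors["gene"].duplicated().any():
        dup = anchors.loc[anchors["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene id in anchor table: {dup!r}")
    if "qrank" not in anchors.columns:
        anchors = rank_anchors(anchors)
    blocks: list[SyntenyBlock] = []
    for qchrom, grp in anchors.groupby("qchrom", sort=False):
        grp = grp.sort_values("qrank").reset_index(drop=True)
        q = grp["qrank"].to_numpy()
        r = grp["rrank"].to_numpy()
        rch = grp["rchrom"].to_numpy()
        for chain in chain_indices(q, r, rch, params):
            rows = grp.iloc[chain]
            rr = rows["rrank"].to_numpy()
            orientation = "forward" if rr[1] > rr[0] else "reverse"
            blocks.append(SyntenyBlock(str(qchrom), str(rows["rchrom"].iloc[0]),
                                       orientation, rows.reset_index(drop=True)))
    return blocks


@dataclass
class FusionCall:
    qchrom: str
    partners: list[tuple[str, int, tuple[int, int]]]  # (rchrom, n_anchors, qspan)
    junctions: list[int]                               # between adjacent partners


def detect_fusions(
    blocks: Sequence[SyntenyBlock],
    coverage_min: float = 0.8,
    partner_min_frac: float = 0.1,
) -> list[FusionCall]:
    """Call a query chromosome a fusion product when at least two reference
    chromosomes each account for >= ``partner_min_frac`` of its block anchors
    and the major partners jointly cover >= ``coverage_min`` of them."""
    calls = []
    for qchrom in dict.fromkeys(b.qchrom for b in blocks):
        mine = [b for b in blocks if b.qchrom == qchrom]
        total = sum(b.n for b in mine)
        per_ref: dict[str, list[SyntenyBlock]] = {}
        for b in mine:
            per_ref.setdefault(b.rchrom, []).append(b)
        major = []
        for rchrom, bs in per_ref.items():
            n = sum(b.n for b in bs)
            if n >= partner_min_frac * total:
                span = (min(b.qstart for b in bs), max(b.qend for b in bs))
                major.append((rchrom, n, span))
        if len(major) < 2:
            continue
        if sum(n for _, n, _ in major) < coverage_min * total:
            continue
        major.sort(key=lambda t: t[2][0])
        junctions = []
        for (_, _, left), (_, _, right) in zip(major, major[1:]):
            junctions.append((left[1] + right[0]) // 2)
        calls.append(FusionCall(qchrom, major, junctions))
    return calls


@dataclass
class TranslocationCall:
    qchrom: str
    source_rchrom: str
    qstart: int
    qend: int
    n_anchors: int
    flanking_rchrom: str | None  # None when terminal
    terminal: bool


def detect_translocations(
    blocks: Sequence[SyntenyBlock],
    min_anchors_seg: int = 5,
    partner_min_frac: float = 0.1,
) -> list[TranslocationCall]:
    """Segments of blocks whose reference chromosome is a minority partner
    on the query chromosome, embedded between (or flanking) major-partner
    blocks.  A run at a chromosome end is flagged terminal."""
    calls = []
    for qchrom in dict.fromkeys(b.qchrom for b in blocks):
        mine = sorted((b for b in blocks if b.qchrom == qchrom), key=lambda b: b.qstart)
        total = sum(b.n for b in mine)
        anchors_per_ref: dict[str, int] = {}
        for b in mine:
            anchors_per_ref[b.rchrom] = anchors_per_ref.get(b.rchrom, 0) + b.n
        major = {rc for rc, n in anchors_per_ref.items() if n >= partner_min_frac * total}
        major_blocks = [b for b in mine if b.rchrom in major]
        # group consecutive minority blocks by rchrom
        runs: list[tuple[str, list[SyntenyBlock]]] = []
        for b in mine:
            if b.rchrom in major:
                runs.append(("", []))  # breaks minority runs
                continue
            if runs and runs[-1][0] == b.rchrom:
                runs[-1][1].append(b)
            else:
                runs.append((b.rchrom, [b]))
        for rchrom, bs in runs:
            if not bs:
                continue
            n = sum(b.n for b in bs)
            if n < min_anchors_seg:
                continue
            s = min(b.qstart for b in bs)
            e = max(b.qend for b in bs)
            # spatial embedding: a segment is internal when major-partner
            # anchors lie on both sides of it (a single block may span it)
            left = [b for b in major_blocks if b.qstart < s]
            right = [b for b in major_blocks if b.qend > e]
            terminal = not left or not right
            flank: str | None = None
            spanning = [b for b in major_blocks if b.qstart <= s and b.qend >= e]
            if spanning:
                flank = spanning[0].rchrom
            elif left and right:
                lch = max(left, key=lambda b: b.qend).rchrom
                rch_ = min(right, key=lambda b: b.qstart).rchrom
                flank = lch if lch == rch_ else None
            elif left or right:
                flank = (max(left, key=lambda b: b.qend) if left
                         else min(right, key=lambda b: b.qstart)).rchrom
            calls.append(TranslocationCall(qchrom, rchrom, s, e, n, flank, terminal))
    return calls


def project_interval(
    blocks: Sequence[SyntenyBlock], interval: Interval
) -> list[Interval]:
    """Map a query-genome interval into reference coordinates through the
    blocks intersecting it, by linear interpolation between block endpoints
    (reverse blocks flip endpoint order); merged per reference chromosome."""
    pieces: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        if b.qchrom != interval.chrom:
            continue
        lo = max(interval.start, b.qstart)
        hi = min(interval.end, b.qend)
        if lo >= hi:
            continue
        qw = b.qend - b.qstart
        rw = b.rend - b.rstart
        if b.orientation == "forward":
            rs = b.rstart + round((lo - b.qstart) * rw / qw)
            re = b.rstart + round((hi - b.qstart) * rw / qw)
        else:
            rs = b.rend - round((hi - b.qstart) * rw / qw)
            re = b.rend - round((lo - b.qstart) * rw / qw)
        if re > rs:
            pieces.setdefault(b.rchrom, []).append((int(rs), int(re)))
    if not pieces:
        logger.warning("interval %s:%d-%d hits no synteny block",
                       interval.chrom, interval.start, interval.end)
        return []
    out = []
    from .density import merge_intervals
    for rchrom, ivs in pieces.items():
        s, e = merge_intervals(np.array([p[0] for p in ivs]),
                               np.array([p[1] for p in ivs]))
        out.extend(Interval(rchrom, int(a), int(bb), interval.name)
                   for a, bb in zip(s, e))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


@dataclass
class OverlapCall:
    inv_a: Interval
    inv_b: Interval
    projected: list[Interval]      # inv_a in reference-genome coordinates
    overlap_bp: int
    frac_a: float                  # overlap / projected width of A
    frac_b: float                  # overlap / width of B
    partly_overlapping: bool
    # per-side contact: the projected interval's low/high boundary ± flank
    # intersects one of B's breakpoint regions
    breakpoint_start: bool
    breakpoint_end: bool


def _intersect_len(ivs: Sequence[Interval], other: Interval) -> int:
    return sum(max(0, min(iv.end, other.end) - max(iv.start, other.start))
               for iv in ivs if iv.chrom == other.chrom)


def inversion_overlap(
    inv_a: Interval,
    inv_b: Interval,
    blocks: Sequence[SyntenyBlock],
    flank: int = 50_000,
    min_overlap: int = 10_000,
) -> OverlapCall:
    """Project inversion A (query genome) into B's genome and quantify the
    overlap with inversion B, including per-side breakpoint-region contact."""
    projected = project_interval(blocks, inv_a)
    overlap = _intersect_len(projected, inv_b)
    proj_width = sum(iv.length for iv in projected if iv.chrom == inv_b.chrom)
    frac_a = overlap / proj_width if proj_width else 0.0
    frac_b = overlap / inv_b.length

    def breakpoint_regions(iv: Interval) -> list[Interval]:
        out = []
        for point in (iv.start, iv.end):
            lo, hi = max(0, point - flank), point + flank
            if hi > lo:
                out.append(Interval(iv.chrom, lo, hi))
        return out

    b_regions = breakpoint_regions(inv_b)
    # A's breakpoints in B coordinates are the boundaries of the projected
    # interval (projecting the flanks themselves would map each one to both
    # ends of an inverted block)
    on_b = [iv for iv in projected if iv.chrom == inv_b.chrom]
    flags = [False, False]
    if on_b:
        pmin = min(iv.start for iv in on_b)
        pmax = max(iv.end for iv in on_b)
        for k, point in enumerate((pmin, pmax)):
            lo, hi = max(0, point - flank), point + flank
            region = Interval(inv_b.chrom, lo, hi)
            flags[k] = any(max(0, min(region.end, br.end) - max(region.start, br.start)) > 0
                           for br in b_regions)
    return OverlapCall(inv_a, inv_b, projected, int(overlap), frac_a, frac_b,
                       bool(overlap >= min_overlap), flags[0], flags[1])


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame([
        {"qchrom": b.qchrom, "qstart": b.qstart, "qend": b.qend,
         "rchrom": b.rchrom, "rstart": b.rstart, "rend": b.rend,
         "orientation": b.orientation, "n_anchors": b.n}
        for b in blocks
    ])
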
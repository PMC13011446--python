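"""Readers and writers for the standard formats used across the pipeline.

All coordinates are 0-based half-open internally.  The only places where
1-based inclusive coordinates appear are the format boundaries themselves
(RepeatMasker ``.out``, VCF, GFF3), each converted exactly once on read or
write.

Repeat classes follow the RepeatMasker class/family convention: the class is
the prefix of the family string before the first ``/`` (e.g. ``DNA/MITE-224``
has class ``DNA``).  Classes are grouped into the density categories used by
the downstream scans: retroelements (LINE, SINE, LTR), DNA elements (DNA, RC),
all interspersed TEs (the union plus Unknown), and simple tandem repeats
(Simple_repeat, Low_complexity, Satellite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

logger = logging.getLogger(__name__)

KNOWN_CLASSES = frozenset(
    {"DNA", "LINE", "SINE", "LTR", "RC", "Unknown",
     "Simple_repeat", "Low_complexity", "Satellite"}
)


@dataclass(frozen=True)
class RepeatFeature:
    """One annotated repeat interval; the atom of all density computations."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    family: str
    repeat_class: str
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid repeat interval {self.chrom}:{self.start}-{self.end}"
            )


class GenomeIndex:
    """Ordered mapping of chromosome name to length in bp."""

    def __init__(self, lengths: Iterable[tuple[str, int]]):
        self._lengths: dict[str, int] = {}
        for name, length in lengths:
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            self._lengths[name] = int(length)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def items(self) -> Iterable[tuple[str, int]]:
        return self._lengths.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and dict(self.items()) == dict(other.items())

    @classmethod
    def read(cls, path: str | Path) -> "GenomeIndex":
        """Read a two-column TSV of chromosome name and length."""
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{i}: expected name<TAB>length")
                if parts[0] == "chrom" and not parts[1].isdigit():
                    continue  # header
                rows.append((parts[0], int(parts[1])))
        return cls(rows)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class CategoryScheme:
    """Grouping of repeat classes into density categories.

    ``all_te`` covers every interspersed class: a feature of Unknown class
    counts toward ``all_te`` but toward neither the DNA nor the retroelement
    subcategory, so the three tracks form an additive-with-remainder family.
    """

    retro: frozenset[str] = frozenset({"LINE", "SINE", "LTR"})
    dna: frozenset[str] = frozenset({"DNA", "RC"})
    simple: frozenset[str] = frozenset({"Simple_repeat", "Low_complexity", "Satellite"})
    extra_interspersed: frozenset[str] = frozenset({"Unknown"})

    @property
    def all_te(self) -> frozenset[str]:
        return self.retro | self.dna | self.extra_interspersed

    def classes_for(self, category: str) -> frozenset[str]:
        try:
            return {
                "all_te": self.all_te,
                "dna": self.dna,
                "retro": self.retro,
                "simple": self.simple,
            }[category]
        except KeyError:
            raise KeyError(f"unknown density category {category!r}") from None

    @property
    def categories(self) -> tuple[str, ...]:
        return ("all_te", "dna", "retro", "simple")


@dataclass(frozen=True)
class Interval:
    """A named genomic interval (inversion, breakpoint region, tract...)."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.name} {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def repeat_class_from_family(family: str) -> str:
    """Derive the repeat class from a class/family string.

    The portion before the first ``/`` is the class; query suffixes like
    ``LINE?`` are stripped.  Anything unrecognized maps to ``Unknown``.
    """
    cls = family.split("/", 1)[0].rstrip("?")
    if cls in KNOWN_CLASSES:
        return cls
    # common RepeatMasker spellings
    aliases = {"Retroposon": "Unknown", "rRNA": "Unknown", "tRNA": "Unknown",
               "snRNA": "Unknown", "scRNA": "Unknown", "srpRNA": "Unknown"}
    if cls in aliases:
        return aliases[cls]
    logger.warning("unknown repeat class %r (family %r); mapped to Unknown", cls, family)
    return "Unknown"


def read_repeat_annotation(path: str | Path, fmt: str = "bed") -> list[RepeatFeature]:
    """Read a repeat annotation in BED or RepeatMasker ``.out`` dialect.

    BED uses columns chrom,start,end,family[,score,strand[,class]]; if the
    seventh column is absent the class is derived from the family string.
    RepeatMasker ``.out`` is whitespace-separated with 1-based inclusive
    coordinates (converted here) and the class/family in column 11.
    """
    if fmt == "bed":
        return _read_repeat_bed(path)
    if fmt == "rm_out":
        return _read_repeat_rm_out(path)
    raise ValueError(f"unknown repeat annotation format {fmt!r}")


def _read_repeat_bed(path: str | Path) -> list[RepeatFeature]:
    feats = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{i}: BED repeat line needs >= 4 columns")
            try:
                chrom, start, end, family = parts[0], int(parts[1]), int(parts[2]), parts[3]
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: malformed BED line: {exc}") from None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-." else "."
            cls = parts[6] if len(parts) > 6 else repeat_class_from_family(family)
            if cls not in KNOWN_CLASSES:
                logger.warning("%s:%d: unknown class %r mapped to Unknown", path, i, cls)
                cls = "Unknown"
            feats.append(RepeatFeature(chrom, start, end, family, cls, strand))
    return feats


def _read_repeat_rm_out(path: str | Path) -> list[RepeatFeature]:
    feats = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            # header lines start with "SW"/"score" or are blank
            if parts[0] in ("SW", "score") or not parts[0][0].isdigit():
                continue
            if len(parts) < 11:
                raise ValueError(f"{path}:{i}: truncated RepeatMasker line")
            try:
                chrom = parts[4]
                start = int(parts[5]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(parts[6])
                strand = "+" if parts[8] == "+" else "-"
                family = parts[10]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{i}: malformed RepeatMasker line: {exc}") from None
            feats.append(
                RepeatFeature(chrom, start, end, family,
                              repeat_class_from_family(family), strand)
            )
    return feats


def write_repeat_bed(feats: Sequence[RepeatFeature], path: str | Path) -> None:
    """Write BED6 + class column; round-trips through :func:`read_repeat_annotation`."""
    with open(path, "w") as fh:
        for f in feats:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.family}\t0\t{f.strand}\t{f.repeat_class}\n")


def read_intervals(path: str | Path, fmt: str = "bed", one_based: bool = False) -> list[Interval]:
    """Read named intervals from BED or a chrom/start/end/name TSV.

    ``one_based=True`` treats starts as 1-based inclusive (decremented on read);
    BED input is always 0-based half-open.
    """
    out = []
    with open(path) as fh:
        header_seen = False
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if fmt == "tsv" and not header_seen:
                header_seen = True
                if parts[:3] == ["chrom", "start", "end"]:
                    continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: interval line needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: malformed interval: {exc}") from None
            if one_based and fmt == "tsv":
                start -= 1
            name = parts[3] if len(parts) > 3 else "."
            if start >= end:
                raise ValueError(f"{path}:{i}: start >= end")
            out.append(Interval(parts[0], start, end, name))
    return out


def write_intervals(intervals: Sequence[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


@dataclass
class GenotypeTable:
    """Per-site allele calls for a set of haplotype-resolved samples.

    ``alleles`` holds, per site, one integer per haplotype: 0 = REF, 1 = ALT,
    -1 = missing.  Positions are 0-based.  Invariant sites (no ALT) are
    retained and flagged; multiallelic sites are excluded at read time with a
    counter, mirroring a hard-filtered biallelic call set.
    """

    samples: list[str]          # one name per haplotype column
    chroms: list[str]
    positions: list[int]
    alleles: list[list[int]]    # site-major
    is_variant: list[bool]
    n_multiallelic_dropped: int = 0

    def __len__(self) -> int:
        return len(self.positions)


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read a VCF (invariant sites supported) into a haplotype-level table.

    Diploid genotypes contribute two haplotype columns per sample; ``./.``
    yields two missing alleles.  Sites with more than one ALT allele are
    dropped and counted.
    """
    vf = pysam.VariantFile(str(path))
    sample_names: list[str] = []
    ploidy_known = False
    chroms: list[str] = []
    positions: list[int] = []
    alleles: list[list[int]] = []
    is_variant: list[bool] = []
    dropped = 0
    for rec in vf:
        alts = [a for a in (rec.alts or ()) if a not in (None, ".", "<NON_REF>")]
        if len(alts) > 1:
            dropped += 1
            continue
        row: list[int] = []
        for sname in rec.samples:
            call = rec.samples[sname]["GT"]
            if not ploidy_known:
                for k in range(len(call)):
                    sample_names.append(f"{sname}_{k+1}" if len(call) > 1 else sname)
            for allele in call:
                row.append(-1 if allele is None else int(allele))
        ploidy_known = True
        chroms.append(rec.chrom)
        positions.append(rec.pos - 1)  # VCF is 1-based
        alleles.append(row)
        is_variant.append(len(alts) == 1)
    if dropped:
        logger.info("read_genotypes: dropped %d multiallelic sites", dropped)
    return GenotypeTable(sample_names, chroms, positions, alleles, is_variant, dropped)
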
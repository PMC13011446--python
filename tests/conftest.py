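"""Shared fixtures: tiny deterministic genomes, repeats and anchor tables."""

import numpy as np
import pandas as pd
import pytest

from karyoshift.genome_io import GenomeIndex, Interval, RepeatFeature
from karyoshift import synteny


@pytest.fixture
def small_genome() -> GenomeIndex:
    return GenomeIndex([("chr1", 1_000_000), ("chr2", 500_000)])


@pytest.fixture
def ten_mb_genome() -> GenomeIndex:
    return GenomeIndex([("chr1", 10_000_000)])


def make_anchor_frame(perm, qchrom="q1", rchrom="r1", spacing=1000, prefix="g"):
    """Anchors whose reference gene order is the given permutation of the
    query order; spacing in bp between gene starts."""
    rows = []
    for qi, rv in enumerate(perm):
        rows.append({
            "gene": f"{prefix}{qi:04d}",
            "qchrom": qchrom, "qstart": qi * spacing, "qend": qi * spacing + spacing // 2,
            "rchrom": rchrom, "rstart": rv * spacing, "rend": rv * spacing + spacing // 2,
        })
    return synteny.rank_anchors(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)


def random_repeats(rng, chrom, chrom_len, n, classes=("DNA", "LINE", "Simple_repeat")):
    feats = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - 1))
        length = int(rng.integers(1, 5000))
        cls = classes[int(rng.integers(0, len(classes)))]
        feats.append(RepeatFeature(chrom, start, min(start + length, chrom_len),
                                   f"{cls}/fam-{i % 7}", cls))
    return feats
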
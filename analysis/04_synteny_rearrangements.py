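#!/usr/bin/env python
"""Synteny blocks and rearrangement calls from the ortholog anchor table.

Chains the derived-vs-ancestral anchors into collinear blocks (gene gap 10,
minimum 5 anchors), then calls chromosomal fusions, translocated segments,
and projects the planted inversions back into ancestral coordinates.
"""

from pathlib import Path

import pandas as pd

from karyoshift import genome_io, synteny

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "worked_example"
OUT = BASE / "synteny"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    anchors = synteny.rank_anchors(synteny.read_anchor_table(SIM / "anchors.tsv"))
    blocks = synteny.chain_blocks(anchors)
    synteny.blocks_to_frame(blocks).to_csv(OUT / "blocks.tsv", sep="\t", index=False)
    print(f"{len(blocks)} collinear blocks from {len(anchors)} anchors")

    fusions = synteny.detect_fusions(blocks)
    pd.DataFrame([
        {"qchrom": f.qchrom, "partners": ",".join(p[0] for p in f.partners),
         "junction": ",".join(map(str, f.junctions))}
        for f in fusions
    ]).to_csv(OUT / "fusions.tsv", sep="\t", index=False)
    for f in fusions:
        print(f"fusion: {f.qchrom} = " + " + ".join(p[0] for p in f.partners)
              + f" (junction ~{f.junctions[0] / 1e6:.2f} Mb)")

    trans = synteny.detect_translocations(blocks)
    pd.DataFrame([t.__dict__ for t in trans]).to_csv(
        OUT / "translocations.tsv", sep="\t", index=False)
    for t in trans:
        kind = "terminal" if t.terminal else f"inside {t.flanking_rchrom}-homologous span"
        print(f"translocation: {t.qstart/1e6:.2f}-{t.qend/1e6:.2f} Mb of "
              f"{t.qchrom} from {t.source_rchrom} ({t.n_anchors} genes, {kind})")

    inversions = genome_io.read_intervals(SIM / "inversions.bed")
    rows = []
    for inv in inversions:
        for proj in synteny.project_interval(blocks, inv):
            rows.append({"inversion": inv.name, "derived": f"{inv.chrom}:"
                         f"{inv.start}-{inv.end}", "ancestral":
                         f"{proj.chrom}:{proj.start}-{proj.end}"})
            print(f"{inv.name}: {rows[-1]['derived']} -> {rows[-1]['ancestral']}")
    pd.DataFrame(rows).to_csv(OUT / "inversion_projections.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
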
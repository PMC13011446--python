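#!/usr/bin/env python
"""Permutation test for TE enrichment at inversion breakpoints.

For every simulated inversion, pools the 10-kb subwindow densities of the
two ±50 kb breakpoint regions and compares their median against 1,000
same-chromosome pairs of random 100-kb non-breakpoint regions.  The first
inversion was planted with 6x DNA-element enrichment at its breakpoints,
the second with none; the test should separate them.
"""

from pathlib import Path

from karyoshift import enrichment, genome_io

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "worked_example"
SEED = 17


def main() -> None:
    genome = genome_io.GenomeIndex.read(SIM / "derived_genome.tsv")
    repeats = genome_io.read_repeat_annotation(SIM / "repeats.bed", "bed")
    inversions = genome_io.read_intervals(SIM / "inversions.bed")
    cfg = enrichment.PermutationConfig(n_replicates=1000, seed=SEED,
                                       category="all_te")
    results = enrichment.run_enrichment(repeats, inversions, genome, cfg)
    report = enrichment.enrichment_report(results, adjust="bonferroni")
    report.to_csv(BASE / "breakpoint_enrichment.tsv", sep="\t", index=False)
    for _, row in report.iterrows():
        verdict = "ENRICHED" if row["significant"] else "background"
        print(f"{row['inversion']} ({row['chrom']}): observed median "
              f"{row['observed']:.4f} vs null 95th pct {row['null_p95']:.4f} "
              f"-> {verdict} (p = {row['p']:.4g})")


if __name__ == "__main__":
    main()
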
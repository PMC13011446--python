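"""End-to-end orchestration of the analysis stages from a single config.

A run config is a flat mapping with one section per stage plus global
``seed`` and ``outdir``.  Stages execute in dependency order

    simulate -> density -> enrichment
    simulate -> synteny (fusions, translocations, overlaps)
    simulate | vcf -> popgen -> conserved tracts
    tree + traits -> pgls

and a JSON manifest records every parameter, the seed, package version and
a checksum per output file, so two runs with the same seed produce
identical manifests apart from the timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import dendropy
import pandas as pd
import yaml

from . import __version__, density, enrichment, genome_io, phylotrait, popgen, simdata, synteny

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def simconfig_from_dict(d: dict, seed: int) -> simdata.SimConfig:
    """Build a :class:`simdata.SimConfig` from a plain (YAML-friendly) dict."""
    pg = d.get("popgen")
    bm = d.get("bm")
    return simdata.SimConfig(
        seed=seed,
        chromosomes=[(c["name"], int(c["length"])) for c in d.get("chromosomes", [])],
        te_families=[simdata.TEFamily(f["name"], f["class"], float(f["rate"]),
                                      tuple(f.get("length_range", (100, 1000))))
                     for f in d.get("te_families", [])],
        inversions=[simdata.PlantedInversion(
            i["chrom"], int(i["start"]), int(i["end"]),
            float(i.get("enrichment", 1.0)),
            tuple(i["enriched_families"]) if i.get("enriched_families") else None)
            for i in d.get("inversions", [])],
        fusions=[simdata.Fusion(tuple(f["partners"]), f.get("name"))
                 for f in d.get("fusions", [])],
        translocations=[simdata.Translocation(t["src_chrom"], int(t["src_start"]),
                                              int(t["src_end"]), t["dest_chrom"],
                                              int(t["dest_pos"]))
                        for t in d.get("translocations", [])],
        genes_per_mb=float(d.get("genes_per_mb", 10.0)),
        popgen=simdata.PopGenConfig(
            chrom=pg.get("chrom", "pg1"), n_sites=int(pg["n_sites"]),
            n_haplotypes_per_pop=int(pg.get("n_haplotypes_per_pop", 28)),
            d=float(pg.get("d", 0.005)), pi_x=float(pg.get("pi_x", 0.002)),
            pi_y=float(pg.get("pi_y", 0.004)),
            conserved_tracts=tuple(simdata.ConservedTract(int(t["start"]), int(t["end"]),
                                                          float(t.get("d_factor", 0.0)))
                                   for t in pg.get("conserved_tracts", [])),
            missing_rate=float(pg.get("missing_rate", 0.0))) if pg else None,
        bm=simdata.BMConfig(bm["tree_newick"], float(bm["intercept"]),
                            float(bm["slope"]), float(bm["sigma2"]),
                            tuple((k, float(v)) for k, v in bm.get("predictors", {}).items()))
        if bm else None,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict[str, Any], outdir: str | Path | None = None) -> dict:
    """Execute the enabled stages and return (and write) the run manifest."""
    outdir = Path(outdir or config.get("outdir", "karyoshift_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages") or [
        s for s in ("simulate", "density", "enrichment", "synteny", "popgen", "pgls")
        if s in config
    ]
    manifest: dict[str, Any] = {
        "version": __version__, "seed": seed, "timestamp": time.time(),
        "stages": {}, "parameters": {s: config.get(s) for s in stages},
    }
    state: dict[str, Any] = {}

    def record(stage: str, outputs: dict[str, Path], **info) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(p) for k, p in outputs.items()},
            "checksums": {k: _sha256(p) for k, p in outputs.items()},
            **info,
        }

    try:
        if "simulate" in stages:
            sim = simconfig_from_dict(config.get("simulate", {}), seed)
            genome, repeats, truth = simdata.simulate_landscape(sim)
            anchors, truth = simdata.simulate_anchor_table(sim)
            outs: dict[str, Path] = {}
            genome.write(outdir / "derived_genome.tsv")
            outs["genome"] = outdir / "derived_genome.tsv"
            genome_io.write_repeat_bed(repeats, outdir / "repeats.bed")
            outs["repeats"] = outdir / "repeats.bed"
            simdata.write_anchor_table(anchors, outdir / "anchors.tsv")
            outs["anchors"] = outdir / "anchors.tsv"
            genome_io.write_intervals(truth.inversions, outdir / "inversions.bed")
            outs["inversions"] = outdir / "inversions.bed"
            if sim.popgen:
                gt, truth = simdata.simulate_genotypes(sim)
                pg_genome = genome_io.GenomeIndex([(sim.popgen.chrom, sim.popgen.n_sites)])
                simdata.write_vcf(gt, pg_genome, outdir / "genotypes.vcf")
                outs["vcf"] = outdir / "genotypes.vcf"
                state["pg_genome"] = pg_genome
                state["popmap"] = simdata.population_map(sim)
            simdata.write_ground_truth(truth, outdir / "ground_truth.json")
            outs["ground_truth"] = outdir / "ground_truth.json"
            state.update(genome=genome, repeats=repeats, anchors=anchors, truth=truth,
                         inversions=truth.inversions)
            record("simulate", outs, n_repeats=len(repeats), n_anchors=len(anchors))

        if "density" in stages:
            pars = config.get("density") or {}
            if "repeats" not in state:
                if "repeats" not in pars or "genome" not in pars:
                    raise PipelineError("density stage needs simulate outputs or "
                                        "explicit 'repeats' and 'genome' paths")
                state["repeats"] = genome_io.read_repeat_annotation(
                    pars["repeats"], pars.get("format", "bed"))
                state["genome"] = genome_io.GenomeIndex.read(pars["genome"])
            w = int(pars.get("window", density.DEFAULT_WINDOW))
            track = density.compute_window_densities(state["repeats"], state["genome"], w=w)
            track.to_csv(outdir / "density.tsv", sep="\t", index=False)
            peaks = density.peaks_to_frame(
                density.call_peaks(track, pars.get("category", "all_te"),
                                   float(pars.get("percentile", 95))))
            peaks.to_csv(outdir / "peaks.tsv", sep="\t", index=False)
            state["track"] = track
            record("density", {"track": outdir / "density.tsv",
                               "peaks": outdir / "peaks.tsv"},
                   window=w, n_peaks=int(peaks["is_peak"].sum()))

        if "enrichment" in stages:
            pars = config.get("enrichment") or {}
            if "inversions" not in state:
                if "inversions" not in pars:
                    raise PipelineError("enrichment stage needs planted or explicit inversions")
                state["inversions"] = genome_io.read_intervals(pars["inversions"])
            if "repeats" not in state:
                raise PipelineError("enrichment stage needs the density/simulate inputs")
            cfg = enrichment.PermutationConfig(
                n_replicates=int(pars.get("n_replicates", 1000)),
                region_length=int(pars.get("region_length", 100_000)),
                percentile=float(pars.get("percentile", 95)),
                seed=seed, category=pars.get("category", "all_te"))
            results = enrichment.run_enrichment(state["repeats"], state["inversions"],
                                                state["genome"], cfg)
            report = enrichment.enrichment_report(results, pars.get("adjust", "none"))
            report.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            record("enrichment", {"report": outdir / "enrichment.tsv"},
                   n_significant=int(report["significant"].sum()))

        if "synteny" in stages:
            pars = config.get("synteny") or {}
            if "anchors" not in state:
                if "anchors" not in pars:
                    raise PipelineError("synteny stage needs an anchor table")
                state["anchors"] = synteny.read_anchor_table(pars["anchors"])
            params = synteny.ChainParams(int(pars.get("max_gap", 10)),
                                         int(pars.get("min_anchors", 5)))
            blocks = synteny.chain_blocks(synteny.rank_anchors(state["anchors"]), params)
            synteny.blocks_to_frame(blocks).to_csv(outdir / "blocks.tsv", sep="\t", index=False)
            fusions = synteny.detect_fusions(blocks)
            pd.DataFrame([{"qchrom": f.qchrom,
                           "partners": ",".join(p[0] for p in f.partners),
                           "junctions": ",".join(map(str, f.junctions))}
                          for f in fusions]).to_csv(outdir / "fusions.tsv", sep="\t", index=False)
            trans = synteny.detect_translocations(blocks)
            pd.DataFrame([t.__dict__ for t in trans]).to_csv(
                outdir / "translocations.tsv", sep="\t", index=False)
            record("synteny", {"blocks": outdir / "blocks.tsv",
                               "fusions": outdir / "fusions.tsv",
                               "translocations": outdir / "translocations.tsv"},
                   n_blocks=len(blocks), n_fusions=len(fusions))

        if "popgen" in stages:
            pars = config.get("popgen") or {}
            if "vcf" in pars:
                gt = genome_io.read_genotypes(pars["vcf"])
                popmap = dict(line.split("\t")[:2] for line in
                              Path(pars["populations"]).read_text().splitlines() if line)
                pg_genome = genome_io.GenomeIndex.read(pars["genome"])
            elif "popmap" in state:
                gt = genome_io.read_genotypes(
                    manifest["stages"]["simulate"]["outputs"]["vcf"])
                popmap = state["popmap"]
                pg_genome = state["pg_genome"]
            else:
                raise PipelineError("popgen stage needs a VCF or a simulate block with popgen")
            sites = popgen.SiteCounts.from_genotypes(gt, popmap)
            pops = sorted(sites.counts)
            w = int(pars.get("window", popgen.DEFAULT_WINDOW))
            fst = popgen.windowed_fst(sites, pops[0], pops[1], pg_genome, w=w)
            fst.to_csv(outdir / "fst.tsv", sep="\t", index=False)
            dxy = popgen.windowed_dxy(sites, pops[0], pops[1], pg_genome, w=w)
            dxy.to_csv(outdir / "dxy.tsv", sep="\t", index=False)
            outs = {"fst": outdir / "fst.tsv", "dxy": outdir / "dxy.tsv"}
            for pop in pops:
                pi = popgen.windowed_pi(sites, pop, pg_genome, w=w)
                pi.to_csv(outdir / f"pi_{pop}.tsv", sep="\t", index=False)
                outs[f"pi_{pop}"] = outdir / f"pi_{pop}.tsv"
            tracts = popgen.scan_conserved_tracts(
                fst, float(pars.get("fst_threshold", 0.5)))
            genome_io.write_intervals(tracts, outdir / "conserved_tracts.bed")
            outs["tracts"] = outdir / "conserved_tracts.bed"
            record("popgen", outs, n_tracts=len(tracts))

        if "pgls" in stages:
            pars = config.get("pgls") or {}
            if "tree" in pars:
                tree = dendropy.Tree.get(path=pars["tree"], schema="newick")
                traits = pd.read_csv(pars["traits"], sep="\t")
            elif state.get("truth") is not None and config.get("simulate", {}).get("bm"):
                bmc = simconfig_from_dict(config["simulate"], seed).bm
                tree = dendropy.Tree.get(data=bmc.tree_newick, schema="newick")
                traits = simdata.simulate_bm_traits(
                    tree, bmc.intercept, bmc.slope, bmc.sigma2,
                    dict(bmc.predictors), seed)
                traits = traits.rename(columns={"predictor": pars.get("predictor", "predictor"),
                                                "trait": pars.get("response", "trait")})
            else:
                raise PipelineError("pgls stage needs a tree and trait table")
            resp = pars.get("response", "trait")
            pred = pars.get("predictor", "predictor")
            res = phylotrait.pgls_bm(
                tree,
                dict(zip(traits["species"], traits[resp])),
                dict(zip(traits["species"], traits[pred])))
            res.p_adjusted = phylotrait.bonferroni([res.p], int(pars.get("n_tests", 1)))[0]
            pd.DataFrame([res.__dict__]).to_csv(outdir / "pgls.tsv", sep="\t", index=False)
            record("pgls", {"pgls": outdir / "pgls.tsv"}, slope=res.slope, p=res.p)
    except Exception as exc:
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
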
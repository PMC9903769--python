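"""End-to-end pipeline: dereplication -> biogeography -> novelty ->
functional landscape -> niche projection.

Each stage reads the TSV inputs it needs, writes its outputs under the run
directory, and the run finishes with a provenance log recording the config
hash, seed, and per-stage outputs.  Identical config + seed + inputs produce
byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import biogeography, dereplication, functional, niche, novelty
from .config import PipelineConfig
from .io import read_table, write_table

logger = logging.getLogger("oceanmags")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_derep(inputs: dict, outdir: Path, config: PipelineConfig) -> dict:
    genomes = read_table(inputs["genomes"], "genomes")
    pairs = read_table(inputs["pairs"], "pairs")
    components, reps = dereplication.dereplicate(genomes, pairs, config)
    table = dereplication.components_table(components)
    write_table(table, outdir / "derep_components.tsv")
    write_table(pd.DataFrame({"genome_id": reps}), outdir / "derep_representatives.tsv")
    return {"n_components": len(components), "n_representatives": len(reps)}


def _stage_biogeo(inputs: dict, outdir: Path, config: PipelineConfig) -> dict:
    genomes = read_table(inputs["genomes"], "genomes")
    profiles = read_table(inputs["recruitment"], "recruitment")
    metagenomes = read_table(inputs["metagenomes"], "metagenomes")
    summary = biogeography.summarize(genomes, profiles, metagenomes, config,
                                     subset="station_subset_1")
    write_table(summary, outdir / "biogeography_summary.tsv")
    filt, proj = biogeography.read_matrices(profiles, genomes, config)
    filt.to_csv(outdir / "reads_filtered_matrix.tsv", sep="\t")
    proj.to_csv(outdir / "reads_projected_matrix.tsv", sep="\t")
    frac = biogeography.fraction_recruited(profiles, metagenomes, config)
    per_mg = biogeography.fraction_recruited(profiles, metagenomes, config,
                                             per_metagenome=True)
    per_mg.rename("fraction_recruited").to_csv(
        outdir / "fraction_recruited_per_metagenome.tsv", sep="\t")
    return {"fraction_recruited": frac, "n_genomes": len(summary)}


def _stage_novelty(inputs: dict, outdir: Path, config: PipelineConfig) -> dict:
    hits = read_table(inputs["marker_hits"], "marker_hits")
    genomes = read_table(inputs["genomes"], "genomes")
    table, excluded = novelty.novelty_table(hits, list(genomes["genome_id"]))
    write_table(table, outdir / "novelty.tsv")
    (outdir / "novelty_excluded.txt").write_text("\n".join(excluded) + "\n")
    return {"n_scored": len(table), "n_excluded": len(excluded)}


def _stage_funcland(inputs: dict, outdir: Path, config: PipelineConfig) -> dict:
    genomes = read_table(inputs["genomes"], "genomes")
    annotations = read_table(inputs["gene_annotations"], "gene_annotations")
    matrix, empty = functional.build_occurrence_matrix(annotations, genomes)

    retro_flags = (annotations.loc[annotations["og_id"] != ""]
                   .groupby("og_id")["retro_flag"].any().to_dict())
    largest = genomes.loc[genomes["length"].idxmax(), "genome_id"]
    matrix, dropped_genomes, dropped_functions = functional.filter_functions(
        matrix, config, exclusions=empty, cap_reference_genome=largest,
        retro_flags=retro_flags)

    model = functional.FunctionalLandscape(matrix, config)
    res = model.fit()

    matrix.to_csv(outdir / "occurrence_matrix.tsv", sep="\t")
    res.groups.rename("group_label").to_csv(outdir / "functional_groups.tsv", sep="\t")
    (outdir / "dendrogram.nwk").write_text(res.newick() + "\n")
    write_table(res.differential, outdir / "differential_functions.tsv")
    write_table(res.top_functions, outdir / "differential_top100.tsv")
    write_table(functional.redundancy_table(matrix), outdir / "functional_redundancy.tsv")

    groups = functional.consensus_annotation(annotations)
    retained = functional.prevalence_filter(groups, annotations, genomes, config)
    cons = pd.DataFrame([
        {"group_id": g.group_id, "consensus_og": g.consensus_og,
         "n_genes": len(g.member_genes), "prevalence": g.prevalence}
        for g in retained])
    write_table(cons, outdir / "consensus_gene_groups.tsv")
    return {
        "n_genomes": len(matrix), "n_functions": matrix.shape[1],
        "dropped_functions": dropped_functions,
        "n_significant": res.n_significant,
        "n_consensus_groups_retained": len(retained),
    }


def _stage_niche(inputs: dict, outdir: Path, config: PipelineConfig) -> dict:
    genomes = read_table(inputs["genomes"], "genomes")
    profiles = read_table(inputs["recruitment"], "recruitment")
    metagenomes = read_table(inputs["metagenomes"], "metagenomes")
    stations = read_table(inputs["station_env"], "station_env")
    grid1 = read_table(inputs["grid_period1"], "env_grid")
    grid2 = read_table(inputs["grid_period2"], "env_grid")
    res_deg = _grid_resolution(grid1)

    rows = []
    fitted = 0
    for gid in genomes["genome_id"]:
        det = biogeography.station_detections(gid, profiles, metagenomes, config)
        det &= set(stations["station_id"])
        if len(det) < config.min_stations_for_niche:
            rows.append({"genome_id": gid, "n_stations": len(det), "fitted": False,
                         "area_km2_period1": float("nan"),
                         "area_km2_period2": float("nan"),
                         "top_driver_expansion": "", "top_driver_reduction": ""})
            continue
        result = niche.NicheEnvelope(det, stations, config, gid).fit()
        p1 = result.project(grid1)
        p2 = result.project(grid2)
        drivers, shares = result.drivers(grid1, grid2)
        top = {"expansion": "", "reduction": ""}
        for region in top:
            sub = shares[shares["region"] == region]
            if len(sub):
                top[region] = sub.sort_values("share_percent", ascending=False
                                              ).iloc[0]["driver"]
        rows.append({
            "genome_id": gid, "n_stations": len(det), "fitted": True,
            "area_km2_period1": niche.presence_area(p1, grid1, config, res_deg),
            "area_km2_period2": niche.presence_area(p2, grid2, config, res_deg),
            "top_driver_expansion": top["expansion"],
            "top_driver_reduction": top["reduction"],
        })
        fitted += 1
    summary = pd.DataFrame(rows)
    write_table(summary, outdir / "niche_summary.tsv")
    fitted_rows = summary[summary["fitted"]]
    return {
        "n_fitted": fitted,
        "mean_area_km2_period1": float(fitted_rows["area_km2_period1"].mean()),
        "mean_area_km2_period2": float(fitted_rows["area_km2_period2"].mean()),
    }


def _grid_resolution(grid: pd.DataFrame) -> float:
    lats = sorted(grid["lat"].unique())
    if len(lats) < 2:
        return 1.0
    return float(lats[1] - lats[0])


STAGES = {
    "derep": _stage_derep,
    "biogeo": _stage_biogeo,
    "novelty": _stage_novelty,
    "funcland": _stage_funcland,
    "niche": _stage_niche,
}


def run_pipeline(config: PipelineConfig, inputs: dict[str, str | Path],
                 outdir: str | Path,
                 stages: list[str] | None = None) -> dict:
    """Run the analysis chain and write per-stage outputs plus provenance.

    ``inputs`` maps input names (genomes, pairs, recruitment, metagenomes,
    gene_annotations, marker_hits, station_env, grid_period1, grid_period2)
    to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    summary: dict = {"config_digest": config.digest(), "seed": config.rng_seed,
                     "stages": {}}
    for name in STAGES:
        if name not in stages:
            continue
        logger.info("running stage %s", name)
        try:
            summary["stages"][name] = STAGES[name](inputs, outdir, config)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
    (outdir / "provenance.json").write_text(json.dumps(summary, indent=2,
                                                       default=str) + "\n")
    return summary
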
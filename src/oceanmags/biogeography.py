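"""Detection calls, read filtering/projection, and cosmopolitan scores.

A genome is detected in a metagenome when the breadth of coverage (fraction of
its length covered at least 1x) is strictly above the detection threshold
(default 0.25); recruited reads from non-detections are zeroed before any
summary.  Filtered read counts are projected to a complete-genome equivalent
by scaling with 100/completion, except for genomes below the completion floor
(default 10%) whose counts are preserved as-is.  The cosmopolitan score of a
genome is the fraction of stations of a metagenome subset at which it is
detected in at least one metagenome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig


def call_detection(breadth: float | np.ndarray, config: PipelineConfig):
    """True where breadth of coverage strictly exceeds the detection threshold."""
    return breadth > config.detection_breadth_threshold


def filter_reads(recruited_reads, breadth, config: PipelineConfig):
    """Zero the read count of every non-detection; vectorized."""
    detected = call_detection(np.asarray(breadth), config)
    return np.where(detected, np.asarray(recruited_reads), 0)


def project_reads(filtered_reads, completion, config: PipelineConfig):
    """Scale filtered reads to a complete-genome equivalent.

    Reads are multiplied by 100/completion and rounded half-up to an integer;
    genomes with completion below the floor keep their actual counts (the
    projection would otherwise blow up small denominators).
    """
    reads = np.asarray(filtered_reads, dtype=float)
    comp = np.asarray(completion, dtype=float)
    if np.any(comp < 0) or np.any(comp > 100):
        raise ValueError("completion must lie in [0, 100]")
    scaled = np.where(comp >= config.completion_floor,
                      reads * 100.0 / np.where(comp == 0, np.nan, comp),
                      reads)
    return np.floor(scaled + 0.5).astype(np.int64)


def _detected_profiles(profiles: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    return profiles[call_detection(profiles["breadth"].to_numpy(), config)]


def station_detections(genome_id: str, profiles: pd.DataFrame,
                       metagenomes: pd.DataFrame, config: PipelineConfig) -> set[str]:
    """Stations where the genome is detected in >=1 metagenome (OR over samples)."""
    det = _detected_profiles(profiles[profiles["genome_id"] == genome_id], config)
    station_of = dict(zip(metagenomes["metagenome_id"], metagenomes["station_id"]))
    return {station_of[m] for m in det["metagenome_id"] if m in station_of}


def _subset_mask(metagenomes: pd.DataFrame, subset: str) -> pd.Series:
    labels = metagenomes["subset_labels"].str.split(",")
    mask = labels.apply(lambda ls: subset in [l.strip() for l in ls])
    if not mask.any():
        raise ValueError(f"unknown or empty metagenome subset {subset!r}")
    return mask


def cosmopolitan_score(genome_id: str, profiles: pd.DataFrame,
                       metagenomes: pd.DataFrame, subset: str,
                       config: PipelineConfig) -> tuple[float, int]:
    """Fraction (and raw count) of subset stations with a detection.

    Station-level detection is the OR over that station's subset metagenomes.
    """
    sub = metagenomes[_subset_mask(metagenomes, subset)]
    stations = set(sub["station_id"])
    det = _detected_profiles(profiles[profiles["genome_id"] == genome_id], config)
    det_mg = set(det["metagenome_id"]) & set(sub["metagenome_id"])
    station_of = dict(zip(sub["metagenome_id"], sub["station_id"]))
    hit = {station_of[m] for m in det_mg}
    return len(hit) / len(stations), len(hit)


def summarize(genomes: pd.DataFrame, profiles: pd.DataFrame,
              metagenomes: pd.DataFrame, config: PipelineConfig,
              subset: str | None = None) -> pd.DataFrame:
    """Per-genome biogeography summary.

    Columns: detected metagenome/station counts, filtered and projected read
    totals, and (when a subset is named) the cosmopolitan score as both a
    fraction of subset stations and a raw station count.
    """
    merged = profiles.merge(
        genomes[["genome_id", "completion"]], on="genome_id", how="left", validate="m:1"
    )
    if merged["completion"].isna().any():
        bad = merged.loc[merged["completion"].isna(), "genome_id"].unique()
        raise ValueError(f"profiles reference unknown genomes: {list(bad)[:5]}")
    merged = merged.merge(metagenomes[["metagenome_id", "station_id"]],
                          on="metagenome_id", how="left", validate="m:1")

    merged["detected"] = call_detection(merged["breadth"].to_numpy(), config)
    merged["filtered_reads"] = filter_reads(
        merged["recruited_reads"].to_numpy(), merged["breadth"].to_numpy(), config)
    merged["projected_reads"] = project_reads(
        merged["filtered_reads"].to_numpy(), merged["completion"].to_numpy(), config)

    rows = []
    for gid, grp in merged.groupby("genome_id", sort=True):
        det = grp[grp["detected"]]
        row = {
            "genome_id": gid,
            "n_detected_metagenomes": int(det["metagenome_id"].nunique()),
            "n_detected_stations": int(det["station_id"].nunique()),
            "filtered_reads": int(grp["filtered_reads"].sum()),
            "projected_reads": int(grp["projected_reads"].sum()),
        }
        if subset is not None:
            frac, count = cosmopolitan_score(gid, profiles, metagenomes, subset, config)
            row["cosmopolitan_score"] = frac
            row["cosmopolitan_stations"] = count
        rows.append(row)
    return pd.DataFrame(rows)


def read_matrices(profiles: pd.DataFrame, genomes: pd.DataFrame,
                  config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome x metagenome matrices of filtered and projected reads."""
    merged = profiles.merge(genomes[["genome_id", "completion"]], on="genome_id")
    merged["filtered"] = filter_reads(
        merged["recruited_reads"].to_numpy(), merged["breadth"].to_numpy(), config)
    merged["projected"] = project_reads(
        merged["filtered"].to_numpy(), merged["completion"].to_numpy(), config)
    filt = merged.pivot_table(index="genome_id", columns="metagenome_id",
                              values="filtered", fill_value=0, aggfunc="sum")
    proj = merged.pivot_table(index="genome_id", columns="metagenome_id",
                              values="projected", fill_value=0, aggfunc="sum")
    return filt, proj


def fraction_recruited(profiles: pd.DataFrame, metagenomes: pd.DataFrame,
                       config: PipelineConfig, per_metagenome: bool = False):
    """Fraction of all sequenced reads recruited after detection filtering.

    Pooled by default (sum of filtered reads over the sum of total reads);
    ``per_metagenome=True`` returns a per-sample Series instead, since the
    two conventions answer different questions.
    """
    total = metagenomes.set_index("metagenome_id")["total_reads"]
    if (total <= 0).any() or total.sum() == 0:
        raise ValueError("metagenome total_reads must be positive")
    filtered = pd.Series(
        filter_reads(profiles["recruited_reads"].to_numpy(),
                     profiles["breadth"].to_numpy(), config),
        index=profiles["metagenome_id"],
    ).groupby(level=0).sum().reindex(total.index, fill_value=0)
    if per_metagenome:
        return filtered / total
    return float(filtered.sum() / total.sum())
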
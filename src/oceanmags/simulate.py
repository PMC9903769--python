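"""Synthetic input bundles with planted, recoverable structure.

Every table the pipeline consumes — genome records, pairwise ANI, recruitment
profiles, metagenome metadata, gene annotations, marker best-hit identities,
station environments, and two-period climatology grids — is generated here
with known ground truth, so each downstream stage can be tested end to end
without any external data.

The planted structure mirrors the shapes of the real study system:

* genome lengths log-uniform between 10 Mbp and 1.3 Gbp, BUSCO-style
  completions over a configurable range;
* redundant genome pairs with ANI ~ U(98.1, 99.9) and aligned fraction above
  0.25, against a non-redundant background below 97% ANI;
* per-genome Gaussian environmental niches over the 7 physicochemical
  parameters; stations inside a niche receive high breadth of coverage
  (detections), stations outside receive low breadth;
* Poisson function-occurrence counts with group-marker functions shifted by a
  configurable effect size in member genomes, a retrotransposon-like set of
  runaway functions in the largest genome, and remote-homology gene clusters
  with majority-consistent orthologous-group labels plus label noise;
* smooth latitudinal climatology fields on a lat/lon grid, with the
  second-period grid offset by per-parameter shifts.

Distributions are declared stand-ins chosen for recoverability, not claims
about the observational data they emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ENV_PARAMETERS, write_table

LINEAGES = ["Alveolata", "Amoebozoa", "Archaeplastida", "Cryptista",
            "Haptista", "Opisthokonta", "Rhizaria", "Stramenopiles"]
SIZE_FRACTIONS = ["0.8-5", "5-20", "20-180", "180-2000"]
MARKER_IDS = [f"{s}-{p}" for s in ("RNAP-a", "RNAP-b")
              for p in ("polI", "polII", "polIII")]


class SpecError(ValueError):
    """Simulation parameters are inconsistent."""


@dataclass
class SimulationSpec:
    n_genomes: int = 120
    n_redundant_pairs: int = 10
    n_stations: int = 60
    metagenomes_per_station: int = 2
    n_functions: int = 600
    n_groups: int = 4
    #: mean occurrence shift of group-marker functions over the baseline
    group_effect_size: float = 5.0
    #: Poisson baseline for function occurrence counts
    lambda_base: float = 1.0
    #: marker functions planted per group (half known, half unknown OGs)
    markers_per_group: int = 20
    #: fraction of non-marker functions that are unknown-function OGs
    unknown_fraction: float = 0.44
    #: extra genes per genome with no annotation, as a fraction of annotated
    unannotated_fraction: float = 0.3
    #: fraction of clustered genes whose OG label is swapped (minority votes)
    label_noise: float = 0.05
    #: retrotransposon-like functions planted above the occurrence cap
    n_retro_functions: int = 3
    #: occurrence count given to retro functions in the largest genome
    retro_count: int = 600
    completion_range: tuple[float, float] = (5.0, 95.0)
    length_range: tuple[float, float] = (1e7, 1.3e9)
    #: per-genome niche width, as multiples of the station-level parameter sd
    niche_width_range: tuple[float, float] = (0.6, 1.6)
    #: squared standardized distance below which a station is inside the niche
    niche_inside_d2: float = 1.0
    #: per-parameter additive offsets applied to the period-2 grid
    env_shift: dict = field(default_factory=lambda: {"sst": 2.0, "nitrate": -0.5})
    grid_resolution_deg: float = 1.0
    rng_seed: int = 0

    @property
    def n_metagenomes(self) -> int:
        return self.n_stations * self.metagenomes_per_station

    def validate(self) -> None:
        if self.n_groups < 2:
            raise SpecError("n_groups must be >= 2")
        if self.n_redundant_pairs > self.n_genomes // 2:
            raise SpecError("n_redundant_pairs exceeds n_genomes/2")
        if self.n_groups * self.markers_per_group > self.n_functions:
            raise SpecError("marker functions exceed n_functions")
        if not (0 <= self.unknown_fraction <= 1 and 0 <= self.label_noise <= 1):
            raise SpecError("fractions must lie in [0, 1]")
        lo, hi = self.completion_range
        if not (0 <= lo <= hi <= 100):
            raise SpecError("completion_range must be within [0, 100]")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream per simulation stage."""
        return np.random.default_rng([self.rng_seed, stage])


@dataclass
class SimulatedTruth:
    """Ground truth planted by the generator, for recovery tests."""
    components: list[frozenset] = field(default_factory=list)
    group_of: dict = field(default_factory=dict)           # genome -> group idx
    marker_functions: dict = field(default_factory=dict)   # group idx -> [fid]
    retro_functions: list = field(default_factory=list)
    detections: dict = field(default_factory=dict)         # genome -> {station}
    niche_optima: pd.DataFrame | None = None               # genome x parameter
    niche_widths: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genomes and pairwise similarity
# ---------------------------------------------------------------------------


def simulate_genomes(spec: SimulationSpec
                     ) -> tuple[pd.DataFrame, pd.DataFrame, SimulatedTruth]:
    """Genome records, pairwise ANI table, and redundancy/group truth."""
    spec.validate()
    rng = spec.rng(1)
    n = spec.n_genomes
    ids = [f"MAG_{i:05d}" for i in range(n)]

    lo, hi = spec.length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(np.int64)
    clo, chi = spec.completion_range
    completion = rng.uniform(clo, chi, size=n)
    genomes = pd.DataFrame({
        "genome_id": ids,
        "length": lengths,
        "completion": np.round(completion, 2),
        "redundancy": np.round(rng.uniform(0, 5, size=n), 2),
        "lineage": rng.choice(LINEAGES, size=n),
        "source": rng.choice(["MAG", "SAG"], size=n, p=[0.95, 0.05]),
        "is_phytoplankton": rng.random(n) < 0.4,
    })

    # planted redundant pairs: disjoint genome pairs above both thresholds
    chosen = rng.choice(n, size=2 * spec.n_redundant_pairs, replace=False)
    pair_rows = []
    components = []
    paired: set[tuple[str, str]] = set()
    for k in range(spec.n_redundant_pairs):
        a, b = ids[chosen[2 * k]], ids[chosen[2 * k + 1]]
        pair_rows.append({
            "genome_a": a, "genome_b": b,
            "ani": round(float(rng.uniform(98.1, 99.9)), 3),
            "aligned_fraction_smaller": round(float(rng.uniform(0.3, 0.9)), 3),
        })
        components.append(frozenset({a, b}))
        paired.add(tuple(sorted((a, b))))
    in_pair = {g for c in components for g in c}
    components.extend(frozenset({g}) for g in ids if g not in in_pair)

    # non-redundant background comparisons, all below 97% ANI
    n_background = min(3 * n, n * (n - 1) // 2 - spec.n_redundant_pairs)
    seen = set(paired)
    while len(seen) - len(paired) < n_background:
        a, b = rng.choice(n, size=2, replace=False)
        key = tuple(sorted((ids[a], ids[b])))
        if key in seen:
            continue
        seen.add(key)
        pair_rows.append({
            "genome_a": key[0], "genome_b": key[1],
            "ani": round(float(rng.uniform(75.0, 96.9)), 3),
            "aligned_fraction_smaller": round(float(rng.uniform(0.0, 1.0)), 3),
        })
    pairs = pd.DataFrame(pair_rows)

    # planted functional groups (balanced, shuffled)
    group_idx = np.resize(np.arange(spec.n_groups), n)
    rng.shuffle(group_idx)
    truth = SimulatedTruth(components=sorted(components, key=sorted),
                           group_of=dict(zip(ids, (int(g) for g in group_idx))))
    return genomes, pairs, truth


# ---------------------------------------------------------------------------
# environment and stations
# ---------------------------------------------------------------------------


def _smooth_fields(lat: np.ndarray, lon: np.ndarray) -> dict[str, np.ndarray]:
    """Analytic climatology stand-ins with latitudinal gradients."""
    latr = np.radians(lat)
    lonr = np.radians(lon)
    nitrate = 0.5 + 25.0 * np.sin(latr) ** 2
    return {
        "sst": -1.0 + 29.0 * np.cos(latr) ** 2,
        "salinity": 34.0 + 1.5 * np.cos(2 * latr),
        "silicate": 2.0 + 80.0 * np.sin(latr) ** 2,
        "nitrate": nitrate,
        "phosphate": 0.05 + nitrate / 16.0,
        "iron": 0.2 + 0.15 * (1.0 + np.sin(lonr)),
        "si_no3": np.sin(latr) ** 2,
    }


def simulate_environment(spec: SimulationSpec
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Station environments and climatology grids for the two periods.

    The land mask is analytic (meridional band continents); stations are
    sampled from period-1 ocean cells, so their environments are co-located
    with the grid.
    """
    spec.validate()
    rng = spec.rng(2)
    res = spec.grid_resolution_deg
    lats = np.arange(-90 + res / 2, 90, res)
    lons = np.arange(-180 + res / 2, 180, res)
    glon, glat = np.meshgrid(lons, lats)
    glat = glat.ravel()
    glon = glon.ravel()

    land = (np.cos(np.radians(glat)) * np.sin(2 * np.radians(glon) + 1.0)) > 0.75
    fields = _smooth_fields(glat, glon)
    grid1 = pd.DataFrame({"lat": glat, "lon": glon, "ocean": ~land, **fields})

    grid2 = grid1.copy()
    for param, shift in spec.env_shift.items():
        if param not in ENV_PARAMETERS:
            raise SpecError(f"env_shift for unknown parameter {param!r}")
        grid2[param] = grid2[param] + shift

    ocean_idx = np.flatnonzero(~land)
    pick = rng.choice(ocean_idx, size=spec.n_stations, replace=False)
    stations = grid1.iloc[pick].reset_index(drop=True)
    stations.insert(0, "station_id",
                    [f"ST_{i:03d}" for i in range(spec.n_stations)])
    stations = stations.drop(columns=["lat", "lon", "ocean"])
    return stations, grid1, grid2


# ---------------------------------------------------------------------------
# recruitment profiles
# ---------------------------------------------------------------------------


def simulate_recruitment(spec: SimulationSpec, genomes: pd.DataFrame,
                         stations: pd.DataFrame, truth: SimulatedTruth
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recruitment profiles and metagenome metadata from planted niches.

    Each genome gets a Gaussian niche centered near one of the stations;
    stations with squared standardized distance below ``niche_inside_d2`` are
    inside the niche and receive breadth ~ U(0.3, 0.9) in every metagenome,
    outside stations receive breadth ~ U(0, 0.2).  Recruited reads are
    proportional to genome length times vertical coverage.  Truth detections
    and niche parameters are written into ``truth``.
    """
    spec.validate()
    rng = spec.rng(3)
    env = stations.set_index("station_id")[ENV_PARAMETERS]
    sd = env.std(axis=0, ddof=0).replace(0.0, 1.0)

    ids = list(genomes["genome_id"])
    lengths = dict(zip(genomes["genome_id"], genomes["length"]))

    optima = {}
    widths = {}
    detections: dict[str, set[str]] = {}
    for gid in ids:
        home = env.iloc[int(rng.integers(len(env)))]
        width_factor = rng.uniform(*spec.niche_width_range)
        sigma = width_factor * sd
        mu = home + rng.normal(0, 0.1, size=len(ENV_PARAMETERS)) * sd
        d2 = (((env - mu) / sigma) ** 2).mean(axis=1)
        detections[gid] = set(env.index[d2 <= spec.niche_inside_d2])
        optima[gid] = mu
        widths[gid] = sigma

    truth.detections = detections
    truth.niche_optima = pd.DataFrame(optima).T.rename_axis("genome_id")
    truth.niche_widths = pd.DataFrame(widths).T.rename_axis("genome_id")

    # metagenomes: SRF/DCM per station, one size fraction each
    mg_rows = []
    for s_i, sid in enumerate(env.index):
        for d_i in range(spec.metagenomes_per_station):
            layer = "SRF" if d_i % 2 == 0 else "DCM"
            mg_rows.append({
                "metagenome_id": f"MG_{s_i:03d}_{layer}",
                "station_id": sid,
                "depth_layer": layer,
                "size_fraction": SIZE_FRACTIONS[(s_i + d_i) % len(SIZE_FRACTIONS)],
                "total_reads": 0,  # filled after profiles below
                "subset_labels": "station_subset_1",
            })
    metagenomes = pd.DataFrame(mg_rows)

    prof_rows = []
    for gid in ids:
        inside = detections[gid]
        for _, mg in metagenomes.iterrows():
            if mg["station_id"] in inside:
                breadth = rng.uniform(0.3, 0.9)
                coverage = rng.uniform(1.0, 10.0)
            else:
                breadth = rng.uniform(0.0, 0.2)
                coverage = rng.uniform(0.0, 0.3)
            reads = int(round(lengths[gid] * coverage * breadth / 150.0))
            prof_rows.append({
                "genome_id": gid,
                "metagenome_id": mg["metagenome_id"],
                "recruited_reads": reads,
                "breadth": round(float(breadth), 4),
                "mean_coverage": round(float(coverage), 4),
            })
    profiles = pd.DataFrame(prof_rows)

    recruited = profiles.groupby("metagenome_id")["recruited_reads"].sum()
    totals = []
    for mgid in metagenomes["metagenome_id"]:
        r = int(recruited.get(mgid, 0))
        frac = rng.uniform(0.05, 0.3)
        totals.append(max(int(round(r / frac)), 1_000_000))
    metagenomes["total_reads"] = totals
    return profiles, metagenomes


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------


def simulate_annotations(spec: SimulationSpec, genomes: pd.DataFrame,
                         truth: SimulatedTruth) -> pd.DataFrame:
    """Gene annotation table with planted group markers and gene clusters.

    Occurrence counts are Poisson(lambda_base); the marker functions of a
    genome's planted group get Poisson(lambda_base + group_effect_size).
    Retrotransposon-like functions receive ``retro_count`` occurrences in the
    largest genome.  Each function's genes share one remote-homology gene
    cluster whose orthologous-group labels are majority-consistent up to
    ``label_noise``; unknown-function OGs yield clusters with no annotated
    members, and a fraction of genes is left entirely unannotated.
    """
    spec.validate()
    rng = spec.rng(4)
    ids = list(genomes["genome_id"])
    n = len(ids)
    n_mark = spec.n_groups * spec.markers_per_group

    # function ids: group markers first (half known / half unknown per group),
    # then background functions split by unknown_fraction
    function_ids: list[str] = []
    known_flags: list[bool] = []
    truth.marker_functions = {}
    for g in range(spec.n_groups):
        fids = []
        for m in range(spec.markers_per_group):
            known = m < spec.markers_per_group // 2 or spec.markers_per_group == 1
            prefix = "OG" if known else "UOG"
            fid = f"{prefix}_G{g}_{m:03d}"
            fids.append(fid)
            function_ids.append(fid)
            known_flags.append(known)
        truth.marker_functions[g] = fids
    n_bg = spec.n_functions - n_mark
    n_bg_unknown = int(round(spec.unknown_fraction * n_bg))
    for b in range(n_bg):
        known = b >= n_bg_unknown
        prefix = "OG" if known else "UOG"
        function_ids.append(f"{prefix}_BG_{b:04d}")
        known_flags.append(known)
    known_of = dict(zip(function_ids, known_flags))

    # retro functions: known background functions, flagged, runaway counts in
    # the largest genome
    background_known = [f for f in function_ids
                        if f.startswith("OG_BG_")][: spec.n_retro_functions]
    truth.retro_functions = background_known
    largest = genomes.loc[genomes["length"].idxmax(), "genome_id"]

    lam = np.full((n, spec.n_functions), spec.lambda_base)
    col_of = {f: j for j, f in enumerate(function_ids)}
    for i, gid in enumerate(ids):
        for fid in truth.marker_functions[truth.group_of[gid]]:
            lam[i, col_of[fid]] += spec.group_effect_size
    counts = rng.poisson(lam)
    for fid in truth.retro_functions:
        counts[ids.index(largest), col_of[fid]] = spec.retro_count

    # expand counts into one gene row per occurrence
    genome_idx = np.repeat(np.arange(n), counts.sum(axis=1))
    func_idx = np.concatenate([
        np.repeat(np.arange(spec.n_functions), counts[i]) for i in range(n)
    ]) if counts.sum() else np.array([], dtype=int)
    og = np.array(function_ids, dtype=object)[func_idx]
    known_arr = np.array([known_of[f] for f in og], dtype=bool)

    # gene clusters: one remote-homology cluster per function; a label_noise
    # fraction of known genes get a swapped OG label (minority votes)
    cluster = np.array([f"GC_{f}" for f in og], dtype=object)
    noise = (rng.random(len(og)) < spec.label_noise) & known_arr
    if noise.any():
        known_fids = [f for f in function_ids if known_of[f]]
        og = og.copy()
        og[noise] = rng.choice(known_fids, size=int(noise.sum()))

    ann = pd.DataFrame({
        "genome_id": np.array(ids, dtype=object)[genome_idx],
        "og_id": og,
        "og_known": known_arr,
        "agnostos_cluster": cluster,
        "retro_flag": np.isin(og, truth.retro_functions),
    })

    # unannotated genes: no OG, no cluster
    n_extra = int(round(spec.unannotated_fraction * len(ann)))
    if n_extra:
        extra = pd.DataFrame({
            "genome_id": rng.choice(ids, size=n_extra),
            "og_id": "",
            "og_known": False,
            "agnostos_cluster": "",
            "retro_flag": False,
        })
        ann = pd.concat([ann, extra], ignore_index=True)
    ann.insert(0, "gene_id", [f"gene_{i:07d}" for i in range(len(ann))])
    return ann


def simulate_marker_hits(spec: SimulationSpec, genomes: pd.DataFrame) -> pd.DataFrame:
    """Up to six RNA-polymerase marker best-hit identities per genome."""
    spec.validate()
    rng = spec.rng(5)
    rows = []
    for gid in genomes["genome_id"]:
        k = int(rng.integers(1, 7))
        markers = rng.choice(MARKER_IDS, size=k, replace=False)
        base = rng.uniform(40.0, 95.0)
        for m in sorted(markers):
            ident = float(np.clip(base + rng.normal(0, 3.0), 0.0, 100.0))
            rows.append({"genome_id": gid, "marker_id": m,
                         "best_hit_identity": round(ident, 2)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------


def simulate_bundle(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate the full input bundle and write it as TSVs plus truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)

    genomes, pairs, truth = simulate_genomes(spec)
    stations, grid1, grid2 = simulate_environment(spec)
    profiles, metagenomes = simulate_recruitment(spec, genomes, stations, truth)
    annotations = simulate_annotations(spec, genomes, truth)
    markers = simulate_marker_hits(spec, genomes)

    paths = {}
    for name, df, schema in [
        ("genomes", genomes, "genomes"),
        ("pairs", pairs, "pairs"),
        ("metagenomes", metagenomes, "metagenomes"),
        ("recruitment", profiles, "recruitment"),
        ("gene_annotations", annotations, "gene_annotations"),
        ("marker_hits", markers, "marker_hits"),
        ("station_env", stations, "station_env"),
    ]:
        p = outdir / f"{name}.tsv"
        write_table(df, p, schema)
        paths[name] = p
    for name, df in [("grid_period1", grid1), ("grid_period2", grid2)]:
        p = outdir / f"{name}.tsv"
        write_table(df, p, "env_grid")
        paths[name] = p

    # truth tables for recovery tests and audits
    comp = pd.DataFrame(
        [{"genome_id": g, "component": i}
         for i, c in enumerate(truth.components) for g in sorted(c)])
    write_table(comp, truth_dir / "components.tsv")
    grp = pd.DataFrame(sorted(truth.group_of.items()),
                       columns=["genome_id", "group"])
    write_table(grp, truth_dir / "groups.tsv")
    det = pd.DataFrame(
        [{"genome_id": g, "station_id": s}
         for g, ss in truth.detections.items() for s in sorted(ss)])
    write_table(det, truth_dir / "detections.tsv")
    mark = pd.DataFrame(
        [{"group": g, "function_id": f}
         for g, fs in truth.marker_functions.items() for f in fs])
    write_table(mark, truth_dir / "marker_functions.tsv")
    write_table(truth.niche_optima.reset_index(), truth_dir / "niche_optima.tsv")
    write_table(truth.niche_widths.reset_index(), truth_dir / "niche_widths.tsv")
    paths["truth"] = truth_dir
    return paths
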
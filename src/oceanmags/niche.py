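"""Environmental niche fitting, projection, and driver attribution.

Seven physicochemical parameters define the niche space: sea surface
temperature, salinity, dissolved silica, nitrate, phosphate, iron, and a
seasonality index of nitrate.  A genome detected at enough stations (default
at least five) gets a Gaussian envelope: each parameter is standardized with
the training-station mean/sd, the niche optimum is the mean of the presence
stations and the spread their sd (floored to keep degenerate axes finite).

The probability of presence in a grid cell is

    P(cell) = exp(-1/2 * kappa * D2(cell)),
    D2 = mean_j ((z_j - m_j) / s_j)^2,

with kappa calibrated at fit time so that the mean presence-station D2 maps to
P = 0.5 — the midpoint of the presence color scale.  P is 1 exactly at the
optimum and decays with standardized distance.

Projected onto climatology grids for two periods, the per-cell change
dP = P2 - P1 flags expansion (dP > 0.1) and reduction (dP < -0.1) regions, and
a one-at-a-time parameter-substitution experiment attributes each flagged cell
to the environmental parameter whose inter-period change moves P the most.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import ENV_PARAMETERS

EARTH_RADIUS_KM = 6371.0


class GridMismatchError(ValueError):
    """Two grids do not share the same cells."""


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class NicheModel:
    genome_id: str
    parameter_means: np.ndarray     # standardized optimum, length 7
    parameter_spreads: np.ndarray   # standardized spreads, length 7
    standardization: pd.DataFrame   # index=parameter, columns=[mean, sd]
    kappa: float
    n_presence_stations: int

    def raw_optimum(self) -> pd.Series:
        """Niche optimum expressed in the original parameter units."""
        mu = self.standardization["mean"].to_numpy()
        sd = self.standardization["sd"].to_numpy()
        return pd.Series(mu + self.parameter_means * sd, index=ENV_PARAMETERS)


def fit_niche(detections: set[str], environments: pd.DataFrame,
              config: PipelineConfig, genome_id: str = "") -> NicheModel:
    """Fit a Gaussian niche envelope from presence stations.

    Parameters
    ----------
    detections : station ids where the genome is detected.
    environments : ``station_env``-schema table over the training stations.
    """
    if len(detections) < config.min_stations_for_niche:
        raise ValueError(
            f"genome {genome_id!r}: {len(detections)} presence stations "
            f"< required {config.min_stations_for_niche}")
    missing = detections - set(environments["station_id"])
    if missing:
        raise ValueError(f"detections at unknown stations: {sorted(missing)[:5]}")

    env = environments.set_index("station_id")[ENV_PARAMETERS]
    mu = env.mean(axis=0)
    sd = env.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (env - mu) / sd

    presence = z.loc[sorted(detections)]
    means = presence.mean(axis=0).to_numpy()
    spreads = np.maximum(presence.std(axis=0, ddof=0).to_numpy(),
                         config.niche_spread_floor)

    d2 = (((presence.to_numpy() - means) / spreads) ** 2).mean(axis=1)
    mean_d2 = float(d2.mean())
    # kappa maps the mean presence-station distance to P = 0.5
    kappa = 2.0 * np.log(2.0) / mean_d2 if mean_d2 > 0 else 1.0

    standardization = pd.DataFrame({"mean": mu, "sd": sd})
    return NicheModel(genome_id=genome_id, parameter_means=means,
                      parameter_spreads=spreads, standardization=standardization,
                      kappa=kappa, n_presence_stations=len(detections))


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def _grid_z(model: NicheModel, grid: pd.DataFrame) -> np.ndarray:
    mu = model.standardization["mean"].to_numpy()
    sd = model.standardization["sd"].to_numpy()
    return (grid[ENV_PARAMETERS].to_numpy(dtype=float) - mu) / sd


def project_presence(model: NicheModel, grid: pd.DataFrame) -> pd.Series:
    """Probability of presence on each ocean cell of a climatology grid.

    Land cells and cells with a missing parameter get NaN (skipped, counted by
    the caller); ocean cells get P in [0, 1].
    """
    z = _grid_z(model, grid)
    d2 = (((z - model.parameter_means) / model.parameter_spreads) ** 2).mean(axis=1)
    p = np.exp(-0.5 * model.kappa * d2)
    ocean = grid["ocean"].to_numpy(dtype=bool)
    p = np.where(ocean & np.isfinite(d2), p, np.nan)
    return pd.Series(p, index=grid.index, name="p_presence")


def cell_area_km2(lat: np.ndarray, resolution_deg: float = 1.0) -> np.ndarray:
    """Spherical area of grid cells centered at ``lat`` degrees.

    A = R^2 * dlambda * (sin(lat_top) - sin(lat_bottom)), R = 6371 km.
    """
    lat = np.asarray(lat, dtype=float)
    half = resolution_deg / 2.0
    top = np.radians(np.minimum(lat + half, 90.0))
    bottom = np.radians(np.maximum(lat - half, -90.0))
    dlon = np.radians(resolution_deg)
    return EARTH_RADIUS_KM**2 * dlon * (np.sin(top) - np.sin(bottom))


def presence_area(p: pd.Series, grid: pd.DataFrame, config: PipelineConfig,
                  resolution_deg: float = 1.0) -> float:
    """Total area (km^2) of ocean cells with P strictly above the threshold."""
    mask = (p.to_numpy() > config.presence_threshold) & grid["ocean"].to_numpy(bool)
    return float(cell_area_km2(grid.loc[mask, "lat"].to_numpy(), resolution_deg).sum())


def delta_p_map(p1: pd.Series, p2: pd.Series,
                config: PipelineConfig) -> pd.DataFrame:
    """Per-cell change in presence probability and expansion/reduction flags."""
    if len(p1) != len(p2) or not (p1.index == p2.index).all():
        raise GridMismatchError("probability maps computed on different grids")
    dp = p2 - p1
    return pd.DataFrame({
        "delta_p": dp,
        "expansion": dp > config.delta_p_threshold,
        "reduction": dp < -config.delta_p_threshold,
    })


def _check_same_cells(grid1: pd.DataFrame, grid2: pd.DataFrame) -> None:
    if len(grid1) != len(grid2):
        raise GridMismatchError("grids have different cell counts")
    same = (grid1["lat"].to_numpy() == grid2["lat"].to_numpy()).all() and \
           (grid1["lon"].to_numpy() == grid2["lon"].to_numpy()).all()
    if not same:
        raise GridMismatchError("grids cover different cells")


def attribute_drivers(model: NicheModel, grid1: pd.DataFrame, grid2: pd.DataFrame,
                      config: PipelineConfig,
                      magnitude_weighted: bool = False
                      ) -> tuple[pd.Series, pd.DataFrame]:
    """First-rank environmental driver of the projected presence shift.

    For each cell where |dP| exceeds the threshold, every parameter j is
    substituted one at a time with its period-2 value, and the driver is the
    parameter maximizing |P(substituted) - P(period 1)| (ties broken
    lexicographically and logged via the returned labels).  Region-level
    shares report, separately over expansion and reduction cells, the percent
    of flagged cells attributed to each driver; ``magnitude_weighted`` weights
    cells by |dP| instead of counting them.

    Returns (per-cell driver labels — NaN where unflagged, shares table).
    """
    _check_same_cells(grid1, grid2)
    p1 = project_presence(model, grid1)
    p2 = project_presence(model, grid2)
    dp = delta_p_map(p1, p2, config)
    flagged = (dp["expansion"] | dp["reduction"]).to_numpy()

    drivers = pd.Series(np.full(len(grid1), None, dtype=object), index=grid1.index,
                        name="driver")
    shares = pd.DataFrame(columns=["region", "driver", "share_percent"])
    if not flagged.any():
        return drivers, shares

    # one-at-a-time substitution of each parameter's period-2 field
    effects = np.zeros((len(grid1), len(ENV_PARAMETERS)))
    for j, param in enumerate(ENV_PARAMETERS):
        hybrid = grid1.copy()
        hybrid[param] = grid2[param].to_numpy()
        effects[:, j] = (project_presence(model, hybrid) - p1).to_numpy()

    # lexicographic tie-break: parameters are visited in a fixed sorted order
    order = np.argsort(ENV_PARAMETERS)
    abs_eff = np.nan_to_num(np.abs(effects), nan=0.0)[:, order]
    best = np.argmax(abs_eff, axis=1)
    sorted_params = sorted(ENV_PARAMETERS)
    labels = np.array([sorted_params[b] for b in best], dtype=object)
    drivers[flagged] = labels[flagged]

    rows = []
    for region, mask in (("expansion", dp["expansion"].to_numpy()),
                         ("reduction", dp["reduction"].to_numpy())):
        total = (np.abs(dp["delta_p"].to_numpy()[mask]).sum()
                 if magnitude_weighted else mask.sum())
        if total == 0:
            continue
        for param in sorted_params:
            sel = mask & (drivers.to_numpy() == param)
            weight = (np.abs(dp["delta_p"].to_numpy()[sel]).sum()
                      if magnitude_weighted else sel.sum())
            if weight > 0:
                rows.append({"region": region, "driver": param,
                             "share_percent": 100.0 * weight / total})
    shares = pd.DataFrame(rows, columns=["region", "driver", "share_percent"])
    return drivers, shares


# ---------------------------------------------------------------------------
# model-object facade
# ---------------------------------------------------------------------------


class NicheEnvelope:
    """Gaussian niche-envelope model for one genome.

    ``NicheEnvelope(detections, environments, config).fit()`` returns a
    :class:`NicheEnvelopeResults` carrying the fitted optimum, spreads, and
    calibration, with projection and attribution methods.
    """

    def __init__(self, detections: set[str], environments: pd.DataFrame,
                 config: PipelineConfig | None = None, genome_id: str = ""):
        self.detections = set(detections)
        self.environments = environments
        self.config = config or PipelineConfig()
        self.genome_id = genome_id

    def fit(self) -> "NicheEnvelopeResults":
        model = fit_niche(self.detections, self.environments, self.config,
                          self.genome_id)
        return NicheEnvelopeResults(self, model)


class NicheEnvelopeResults:
    def __init__(self, envelope: NicheEnvelope, model: NicheModel):
        self.envelope = envelope
        self.model = model
        self.config = envelope.config

    def project(self, grid: pd.DataFrame) -> pd.Series:
        return project_presence(self.model, grid)

    def area(self, grid: pd.DataFrame, resolution_deg: float = 1.0) -> float:
        return presence_area(self.project(grid), grid, self.config, resolution_deg)

    def delta(self, grid1: pd.DataFrame, grid2: pd.DataFrame) -> pd.DataFrame:
        return delta_p_map(self.project(grid1), self.project(grid2), self.config)

    def drivers(self, grid1: pd.DataFrame, grid2: pd.DataFrame,
                magnitude_weighted: bool = False):
        return attribute_drivers(self.model, grid1, grid2, self.config,
                                 magnitude_weighted)

    def summary(self) -> str:
        opt = self.model.raw_optimum()
        lines = [
            f"Niche envelope: {self.model.genome_id or '(unnamed genome)'}",
            "=" * 40,
            f"presence stations : {self.model.n_presence_stations}",
            f"kappa             : {self.model.kappa:.4f}",
            "optimum (raw units):",
        ]
        for param in ENV_PARAMETERS:
            lines.append(f"  {param:<10} {opt[param]: .4g}")
        return "\n".join(lines)
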
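"""Pipeline configuration.

All stage thresholds live in a single :class:`PipelineConfig` so that a run is
fully described by one flat key=value file plus a seed.  Defaults follow the
published filtering rules for the analysis chain: redundancy at ANI > 98% with
> 25% of the smaller genome aligned, detection at > 25% breadth of coverage,
read projection suspended below 10% completion, differential occurrence at
p < 1e-5 across 4 functional groups, the 500-occurrence retrotransposon cap,
the 2% gene-group prevalence floor, niche fitting from at least five stations,
and |dP| > 0.1 for expansion/reduction calls.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


class ConfigError(ValueError):
    """Raised when a configuration value is outside its natural range."""


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ConfigError(f"{name}={value!r} outside [{lo}, {hi}]")


@dataclass
class PipelineConfig:
    #: genome pairs with ANI strictly above this are redundancy candidates (%)
    ani_threshold: float = 98.0
    #: minimum aligned fraction of the smaller genome (strict) for redundancy
    align_fraction_threshold: float = 0.25
    #: breadth of coverage strictly above this calls a detection
    detection_breadth_threshold: float = 0.25
    #: completion (%) below which read counts are not projected
    completion_floor: float = 10.0
    #: upstream read-mapping identity cutoff; metadata only, never recomputed
    mapping_identity_note: float = 90.0
    #: Welch ANOVA significance threshold for differential occurrence
    anova_p_threshold: float = 1e-5
    #: number of functional groups cut from the dendrogram
    group_count: int = 4
    #: occurrence count above which flagged functions are dropped
    occurrence_cap: int = 500
    #: gene groups present in fewer than this fraction of genomes are dropped
    min_group_prevalence: float = 0.02
    #: minimum presence stations required to fit a niche model
    min_stations_for_niche: int = 5
    #: |dP| strictly above this flags expansion/reduction cells
    delta_p_threshold: float = 0.1
    #: probability of presence above which a cell counts toward surface area
    presence_threshold: float = 0.5
    #: floor on per-parameter niche spread, in standardized units
    niche_spread_floor: float = 0.5
    #: seed for every stochastic stage
    rng_seed: int = 0

    _INT_FIELDS = ("group_count", "occurrence_cap", "min_stations_for_niche", "rng_seed")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_range("ani_threshold", self.ani_threshold, 0, 100)
        _check_range("align_fraction_threshold", self.align_fraction_threshold, 0, 1)
        _check_range("detection_breadth_threshold", self.detection_breadth_threshold, 0, 1)
        _check_range("completion_floor", self.completion_floor, 0, 100)
        _check_range("mapping_identity_note", self.mapping_identity_note, 0, 100)
        _check_range("anova_p_threshold", self.anova_p_threshold, 0, 1)
        _check_range("min_group_prevalence", self.min_group_prevalence, 0, 1)
        _check_range("delta_p_threshold", self.delta_p_threshold, 0, 1)
        _check_range("presence_threshold", self.presence_threshold, 0, 1)
        if self.group_count < 2:
            raise ConfigError("group_count must be >= 2")
        if self.occurrence_cap < 0:
            raise ConfigError("occurrence_cap must be >= 0")
        if self.min_stations_for_niche < 1:
            raise ConfigError("min_stations_for_niche must be >= 1")
        if self.niche_spread_floor <= 0:
            raise ConfigError("niche_spread_floor must be > 0")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k}={v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        d: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key in cls._INT_FIELDS:
                d[key] = int(value)
            else:
                d[key] = float(value)
        return cls.from_dict(d)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
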
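"""Novelty scores from RNA-polymerase marker best-hit identities.

Each genome carries up to six markers: the two largest subunits (RNAP-a,
RNAP-b) of the three DNA-dependent RNA polymerases.  The novelty score is 100
minus the unweighted mean best-hit percent identity across the genome's
available markers, so a genome whose markers average 64% identity scores 36.
For display alongside a tree the score is additionally clipped into [30, 60].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("oceanmags")

VALID_MARKERS = frozenset(
    f"{subunit}-{pol}" for subunit in ("RNAP-a", "RNAP-b") for pol in ("polI", "polII", "polIII")
)

DISPLAY_MIN = 30.0
DISPLAY_MAX = 60.0


@dataclass(frozen=True)
class NoveltyResult:
    genome_id: str
    n_markers: int
    mean_identity: float
    novelty_score: float


def novelty_score(genome_id: str, identities: list[float],
                  marker_ids: list[str] | None = None) -> NoveltyResult:
    """Novelty of one genome from its marker best-hit identities.

    When a marker id occurs more than once (several curated copies of the
    same gene), copies are averaged within the marker first so each of the up
    to six markers contributes equally.
    """
    if len(identities) == 0:
        raise ValueError(f"genome {genome_id!r} has no marker hits")
    if any(not (0 <= i <= 100) for i in identities):
        raise ValueError("best-hit identity must lie in [0, 100]")
    if marker_ids is not None and len(set(marker_ids)) < len(marker_ids):
        logger.info("genome %s has duplicated marker copies; averaging within marker",
                    genome_id)
        per_marker = pd.Series(identities, index=marker_ids).groupby(level=0).mean()
        identities = list(per_marker)
    if len(identities) > 6:
        raise ValueError(f"genome {genome_id!r} has more than six markers")
    mean_identity = float(sum(identities) / len(identities))
    return NoveltyResult(genome_id, len(identities), mean_identity, 100.0 - mean_identity)


def clip_for_display(score: float,
                     lo: float = DISPLAY_MIN, hi: float = DISPLAY_MAX) -> float:
    """Clip a novelty score into the display range used on tree figures."""
    return min(max(score, lo), hi)


def novelty_table(hits: pd.DataFrame,
                  all_genomes: list[str] | None = None) -> tuple[pd.DataFrame, list[str]]:
    """One novelty result per genome with >=1 marker hit.

    Parameters
    ----------
    hits : ``marker_hits``-schema table.
    all_genomes : optional full genome list; genomes without any marker are
        returned as exclusions rather than rows.

    Returns
    -------
    (table, excluded) where the table has raw and display-clipped scores and
    ``excluded`` lists genomes lacking markers.
    """
    bad = set(hits["marker_id"]) - VALID_MARKERS
    if bad:
        raise ValueError(f"unknown marker ids: {sorted(bad)[:5]}")
    rows = []
    for gid, grp in hits.groupby("genome_id", sort=True):
        res = novelty_score(gid, list(grp["best_hit_identity"]), list(grp["marker_id"]))
        rows.append({
            "genome_id": gid,
            "n_markers": res.n_markers,
            "mean_identity": res.mean_identity,
            "novelty_score": res.novelty_score,
            "novelty_display": clip_for_display(res.novelty_score),
        })
    table = pd.DataFrame(
        rows, columns=["genome_id", "n_markers", "mean_identity",
                       "novelty_score", "novelty_display"])
    excluded: list[str] = []
    if all_genomes is not None:
        excluded = sorted(set(all_genomes) - set(table["genome_id"]))
    return table, excluded
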
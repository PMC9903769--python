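"""Genome dereplication by average nucleotide identity.

A pair of genomes is redundant when its ANI is strictly above the threshold
(default 98%) and the aligned fraction of the smaller genome is strictly above
the alignment-fraction threshold (default 0.25).  Redundant pairs induce a
graph whose connected components are redundancy groups; the longest member of
each group (ties broken lexicographically by id) represents it.  A
pairwise-only greedy mode is available for comparison, since transitive
grouping versus iterative removal is a modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .config import PipelineConfig
from .io import IntegrityError


@dataclass(frozen=True)
class RedundancyComponent:
    member_ids: frozenset[str]
    representative_id: str


def is_redundant_pair(ani: float, aligned_fraction_smaller: float,
                      config: PipelineConfig) -> bool:
    """Strict-inequality redundancy rule on one genome pair."""
    return (ani > config.ani_threshold
            and aligned_fraction_smaller > config.align_fraction_threshold)


def _representative(members: list[str], lengths: dict[str, int]) -> str:
    # longest member; lexicographic id breaks length ties deterministically
    return min(members, key=lambda g: (-lengths[g], g))


def dereplicate(genomes: pd.DataFrame, pairs: pd.DataFrame, config: PipelineConfig,
                transitive: bool = True) -> tuple[list[RedundancyComponent], list[str]]:
    """Partition genomes into redundancy components and pick representatives.

    Parameters
    ----------
    genomes : ``genomes``-schema table (genome_id, length, ...).
    pairs : ``pairs``-schema table of pairwise ANI / aligned fraction.
    transitive : group by connected components of the redundant-pair graph
        (default).  When false, a greedy pairwise mode is used instead: pairs
        are visited by decreasing ANI and the shorter genome of each redundant
        pair is absorbed into the longer survivor's component.

    Returns
    -------
    (components, representatives) where every genome belongs to exactly one
    component and representatives are the per-component longest members, in
    sorted genome-id order.
    """
    ids = list(genomes["genome_id"])
    known = set(ids)
    lengths = dict(zip(genomes["genome_id"], genomes["length"].astype(int)))

    unknown = (set(pairs["genome_a"]) | set(pairs["genome_b"])) - known
    if unknown:
        raise IntegrityError(f"pairs reference unknown genome ids: {sorted(unknown)[:5]}")

    mask = np.fromiter(
        (is_redundant_pair(a, f, config)
         for a, f in zip(pairs["ani"], pairs["aligned_fraction_smaller"])),
        dtype=bool, count=len(pairs))
    redundant = pairs.loc[mask]

    index = {g: i for i, g in enumerate(sorted(ids))}
    order = sorted(ids)

    if transitive:
        if len(redundant):
            rows = redundant["genome_a"].map(index).to_numpy()
            cols = redundant["genome_b"].map(index).to_numpy()
            data = np.ones(len(redundant), dtype=np.int8)
            adj = coo_matrix((data, (rows, cols)), shape=(len(order), len(order)))
            _, labels = connected_components(adj, directed=False)
        else:
            labels = np.arange(len(order))
        groups: dict[int, list[str]] = {}
        for g, lab in zip(order, labels):
            groups.setdefault(int(lab), []).append(g)
        member_sets = list(groups.values())
    else:
        # greedy pairwise removal: strongest pairs first, shorter genome absorbed
        parent = {g: g for g in order}
        absorbed: set[str] = set()
        ranked = redundant.sort_values(["ani", "genome_a", "genome_b"],
                                       ascending=[False, True, True])
        for a, b in zip(ranked["genome_a"], ranked["genome_b"]):
            if a in absorbed or b in absorbed:
                continue
            loser = max((a, b), key=lambda g: (-lengths[g], g))
            winner = a if loser == b else b
            parent[loser] = winner
            absorbed.add(loser)
        groups = {}
        for g in order:
            root = g
            while parent[root] != root:
                root = parent[root]
            groups.setdefault(root, []).append(g)  # type: ignore[arg-type]
        member_sets = list(groups.values())

    components = sorted(
        (RedundancyComponent(frozenset(m), _representative(m, lengths)) for m in member_sets),
        key=lambda c: c.representative_id,
    )
    representatives = sorted(c.representative_id for c in components)
    return components, representatives


def components_table(components: list[RedundancyComponent]) -> pd.DataFrame:
    """Flatten components into a TSV-friendly table (one row per member)."""
    rows = [
        {"genome_id": g, "representative_id": c.representative_id,
         "component_size": len(c.member_ids)}
        for c in components for g in sorted(c.member_ids)
    ]
    return pd.DataFrame(rows, columns=["genome_id", "representative_id", "component_size"])
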
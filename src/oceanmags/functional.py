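"""Genome-wide functional landscape: occurrence matrices, clustering, and
differential-occurrence statistics.

The occurrence matrix counts, per genome, how many genes are annotated to each
orthologous group (function).  Genomes are classified by agglomerative
clustering of their occurrence rows (Euclidean distance, Ward linkage) and the
resulting partition is interrogated function-by-function with Welch's
heteroscedastic ANOVA; significant functions (p below a strict threshold,
default 1e-5, uncorrected by design — Benjamini-Hochberg q-values are reported
alongside for transparency) receive Games-Howell pairwise comparisons.

Welch's F for k groups with sizes n_i, means m_i, variances s_i^2::

    w_i = n_i / s_i^2,  W = sum(w_i),  mw = sum(w_i m_i) / W
    A   = sum(w_i (m_i - mw)^2) / (k - 1)
    B   = 1 + 2(k-2)/(k^2-1) * sum((1 - w_i/W)^2 / (n_i - 1))
    F   = A / B,  df1 = k-1,  df2 = (k^2-1) / (3 sum((1 - w_i/W)^2/(n_i-1)))

Games-Howell compares groups i, j with t = (m_i - m_j)/sqrt(s_i^2/n_i +
s_j^2/n_j), Welch-Satterthwaite degrees of freedom, and a p-value from the
studentized-range distribution with q = |t|*sqrt(2) and k groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig

# ---------------------------------------------------------------------------
# occurrence matrix
# ---------------------------------------------------------------------------


def build_occurrence_matrix(annotations: pd.DataFrame,
                            genomes: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Genome x function matrix of annotated-gene counts.

    Genes without an orthologous-group assignment are ignored.  Returns the
    matrix (rows indexed by genome_id, sorted; columns by function id, sorted)
    and the list of genomes with zero annotated genes (all-zero rows, flagged).
    """
    known_genomes = set(genomes["genome_id"])
    bad = set(annotations["genome_id"]) - known_genomes
    if bad:
        raise ValueError(f"annotations reference unknown genomes: {sorted(bad)[:5]}")
    annotated = annotations[annotations["og_id"].astype(str).str.strip() != ""]
    counts = (annotated.groupby(["genome_id", "og_id"]).size()
              .unstack(fill_value=0))
    matrix = counts.reindex(sorted(known_genomes), fill_value=0)
    matrix = matrix[sorted(matrix.columns)].astype(np.int64)
    empty = sorted(matrix.index[matrix.sum(axis=1) == 0])
    return matrix, empty


def functional_redundancy(matrix: pd.DataFrame, genome_id: str) -> float:
    """Fraction of a genome's annotated genes whose function occurs >= 2 times.

    Sum of counts over functions with count >= 2 in that genome, divided by
    the genome's total annotated-gene count.
    """
    row = matrix.loc[genome_id]
    total = int(row.sum())
    if total == 0:
        raise ValueError(f"genome {genome_id!r} has no annotated genes")
    return float(row[row >= 2].sum() / total)


def redundancy_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """functional_redundancy for every genome with >=1 annotated gene."""
    rows = []
    for gid in matrix.index:
        if matrix.loc[gid].sum() > 0:
            rows.append({"genome_id": gid,
                         "functional_redundancy": functional_redundancy(matrix, gid)})
    return pd.DataFrame(rows)


def filter_functions(matrix: pd.DataFrame, config: PipelineConfig,
                     exclusions: Iterable[str] = (),
                     cap_reference_genome: str | None = None,
                     retro_flags: dict[str, bool] | None = None,
                     ) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Drop excluded genomes and runaway repeat-associated functions.

    A function column is dropped when its count in the reference genome (the
    gigabase-scale assembly in the study design) is strictly above the
    occurrence cap AND the function carries a retrotransposon flag; such
    functions connect otherwise unrelated genomes through repeat content.

    Returns (filtered matrix, dropped genome ids, dropped function ids).
    """
    exclusions = set(exclusions)
    missing = exclusions - set(matrix.index)
    if missing:
        raise ValueError(f"excluded genomes not in matrix: {sorted(missing)[:5]}")
    out = matrix.drop(index=sorted(exclusions))

    dropped_functions: list[str] = []
    if cap_reference_genome is not None:
        if cap_reference_genome not in matrix.index:
            raise ValueError(f"unknown cap reference genome {cap_reference_genome!r}")
        flags = retro_flags or {}
        ref = matrix.loc[cap_reference_genome]
        dropped_functions = sorted(
            f for f in matrix.columns
            if ref[f] > config.occurrence_cap and flags.get(f, False)
        )
        out = out.drop(columns=dropped_functions)
    return out, sorted(exclusions), dropped_functions


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

GROUP_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class FunctionalGroupAssignment:
    groups: pd.Series                 # genome_id -> group label, non-outgroup only
    linkage: np.ndarray               # Ward linkage over non-outgroup genomes
    leaf_order: list[str]             # dendrogram leaf order (non-outgroup)
    outgroup: list[str]
    full_linkage: np.ndarray | None   # linkage over all genomes incl. outgroup
    full_leaf_order: list[str] = field(default_factory=list)


def cluster_genomes(matrix: pd.DataFrame, config: PipelineConfig,
                    outgroup: Iterable[str] = (),
                    log_transform: bool = False) -> FunctionalGroupAssignment:
    """Ward/Euclidean clustering of occurrence rows into functional groups.

    Outgroup genomes (small animals, in the study design) are included in the
    full dendrogram but excluded from group extraction; the remaining genomes
    are cut into ``config.group_count`` groups.  Group labels (A, B, ...) are
    assigned by order of first appearance along the dendrogram leaf order, so
    the partition and its labels are invariant to input row order.  Raw counts
    are clustered by default; ``log_transform`` applies log10(x+1) first.
    """
    outgroup = sorted(set(outgroup))
    missing = set(outgroup) - set(matrix.index)
    if missing:
        raise ValueError(f"outgroup genomes not in matrix: {sorted(missing)[:5]}")

    matrix = matrix.sort_index()
    data = matrix.to_numpy(dtype=float)
    if log_transform:
        data = np.log10(data + 1.0)

    in_mask = ~matrix.index.isin(outgroup)
    ingroup_ids = list(matrix.index[in_mask])
    if len(ingroup_ids) < config.group_count + 1:
        raise ValueError(
            f"need more than {config.group_count} non-outgroup genomes, "
            f"got {len(ingroup_ids)}")

    Z = hierarchy.linkage(data[in_mask], method="ward")
    flat = hierarchy.fcluster(Z, t=config.group_count, criterion="maxclust")
    leaves = hierarchy.leaves_list(Z)
    leaf_order = [ingroup_ids[i] for i in leaves]

    # relabel clusters A, B, ... by first appearance along the dendrogram
    label_map: dict[int, str] = {}
    for leaf in leaves:
        c = int(flat[leaf])
        if c not in label_map:
            label_map[c] = GROUP_LABELS[len(label_map)]
    groups = pd.Series([label_map[int(c)] for c in flat], index=ingroup_ids,
                       name="group_label").sort_index()

    full_Z = None
    full_leaf_order: list[str] = []
    if outgroup:
        full_Z = hierarchy.linkage(data, method="ward")
        full_leaf_order = [matrix.index[i] for i in hierarchy.leaves_list(full_Z)]

    return FunctionalGroupAssignment(groups=groups, linkage=Z, leaf_order=leaf_order,
                                     outgroup=outgroup, full_linkage=full_Z,
                                     full_leaf_order=full_leaf_order)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0) if parent_height else 0.0
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    left = walk(tree.get_left(), tree.dist)
    right = walk(tree.get_right(), tree.dist)
    return f"({left},{right});"


# ---------------------------------------------------------------------------
# Welch ANOVA and Games-Howell
# ---------------------------------------------------------------------------


class DegenerateGroupError(ValueError):
    """A group has fewer than two observations or zero variance."""


def welch_anova(samples: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Parameters
    ----------
    samples : one 1-D array of occurrence values per group (k >= 2 groups,
        each with >= 2 observations and nonzero variance).

    Returns
    -------
    (F, df1, df2, p_value)
    """
    k = len(samples)
    if k < 2:
        raise DegenerateGroupError("need at least two groups")
    n = np.array([len(s) for s in samples], dtype=float)
    if (n < 2).any():
        raise DegenerateGroupError("every group needs at least two observations")
    means = np.array([np.mean(s) for s in samples])
    variances = np.array([np.var(s, ddof=1) for s in samples])
    if (variances == 0).any():
        raise DegenerateGroupError("a group has zero variance")

    w = n / variances
    W = w.sum()
    mw = (w * means).sum() / W
    a = (w * (means - mw) ** 2).sum() / (k - 1)
    tail = (((1 - w / W) ** 2) / (n - 1)).sum()
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * tail
    F = a / b
    df1 = float(k - 1)
    df2 = (k**2 - 1) / (3.0 * tail)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, float(df2), p


def welch_anova_matrix(values: np.ndarray, labels: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch ANOVA over the columns of ``values``.

    ``values`` is observations x functions; ``labels`` assigns each row to a
    group.  Functions where any group has zero variance get NaN statistics
    (the caller records and skips them).

    Returns (F, df2, p, valid) arrays of length n_functions; df1 is k-1.
    """
    groups = np.unique(labels)
    k = len(groups)
    n = np.array([(labels == g).sum() for g in groups], dtype=float)
    if (n < 2).any():
        raise DegenerateGroupError("every group needs at least two observations")
    means = np.stack([values[labels == g].mean(axis=0) for g in groups])
    variances = np.stack([values[labels == g].var(axis=0, ddof=1) for g in groups])

    valid = (variances > 0).all(axis=0)
    var_safe = np.where(variances == 0, np.nan, variances)
    w = n[:, None] / var_safe
    W = w.sum(axis=0)
    mw = (w * means).sum(axis=0) / W
    a = (w * (means - mw) ** 2).sum(axis=0) / (k - 1)
    tail = (((1 - w / W) ** 2) / (n - 1)[:, None]).sum(axis=0)
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * tail
    with np.errstate(invalid="ignore", divide="ignore"):
        F = a / b
        df2 = (k**2 - 1) / (3.0 * tail)
        p = stats.f.sf(F, k - 1, df2)
    F = np.where(valid, F, np.nan)
    df2 = np.where(valid, df2, np.nan)
    p = np.where(valid, p, np.nan)
    return F, df2, p, valid


def games_howell(sample_i: np.ndarray, sample_j: np.ndarray,
                 k_groups: int) -> tuple[float, float]:
    """Games-Howell pairwise comparison between two groups of a k-group design.

    Returns (mean_difference, p_value); p comes from the studentized-range
    distribution with q = |t| * sqrt(2) and Welch-Satterthwaite df.
    """
    ni, nj = len(sample_i), len(sample_j)
    if ni < 2 or nj < 2:
        raise DegenerateGroupError("both groups need at least two observations")
    mi, mj = float(np.mean(sample_i)), float(np.mean(sample_j))
    vi = float(np.var(sample_i, ddof=1))
    vj = float(np.var(sample_j, ddof=1))
    se2 = vi / ni + vj / nj
    if se2 == 0:
        raise DegenerateGroupError("zero pooled variance in pairwise comparison")
    diff = mi - mj
    t = diff / np.sqrt(se2)
    df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
    q = abs(t) * np.sqrt(2.0)
    p = float(stats.studentized_range.sf(q, k_groups, df))
    return diff, p


# ---------------------------------------------------------------------------
# differential occurrence
# ---------------------------------------------------------------------------


def differential_functions(matrix: pd.DataFrame, groups: pd.Series,
                           config: PipelineConfig,
                           top_n: int = 100) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-function Welch ANOVA across functional groups, with post hocs.

    Functions with p strictly below ``config.anova_p_threshold`` are marked
    significant and receive Games-Howell pairwise comparisons.  Returns the
    full results sorted by p (with BH q-values for transparency), the
    ``top_n`` lowest-p functions (the display set), and the list of functions
    skipped for degenerate within-group variance.
    """
    shared = matrix.index.intersection(groups.index)
    sub = matrix.loc[shared].sort_index()
    labels = groups.loc[sub.index].to_numpy()
    values = sub.to_numpy(dtype=float)
    group_names = sorted(np.unique(labels))
    k = len(group_names)

    F, df2, p, valid = welch_anova_matrix(values, labels)
    skipped = [str(f) for f, ok in zip(sub.columns, valid) if not ok]

    group_means = {
        g: values[labels == g].mean(axis=0) for g in group_names
    }
    rows = []
    for idx, fid in enumerate(sub.columns):
        if not valid[idx]:
            continue
        rows.append({
            "function_id": str(fid),
            **{f"mean_{g}": float(group_means[g][idx]) for g in group_names},
            "welch_F": float(F[idx]),
            "df1": float(k - 1),
            "df2": float(df2[idx]),
            "p_value": float(p[idx]),
            "significant": bool(p[idx] < config.anova_p_threshold),
        })
    results = pd.DataFrame(rows)
    if len(results):
        results["q_value"] = multipletests(results["p_value"], method="fdr_bh")[1]
        results = results.sort_values(["p_value", "function_id"]).reset_index(drop=True)

        # Games-Howell only for significant functions
        pair_cols: dict[str, list] = {}
        pairs = [(gi, gj) for a, gi in enumerate(group_names)
                 for gj in group_names[a + 1:]]
        for gi, gj in pairs:
            pair_cols[f"gh_diff_{gi}_{gj}"] = []
            pair_cols[f"gh_p_{gi}_{gj}"] = []
        col_index = {str(f): i for i, f in enumerate(sub.columns)}
        for _, row in results.iterrows():
            idx = col_index[row["function_id"]]
            for gi, gj in pairs:
                if row["significant"]:
                    diff, gp = games_howell(values[labels == gi, idx],
                                            values[labels == gj, idx], k)
                    pair_cols[f"gh_diff_{gi}_{gj}"].append(diff)
                    pair_cols[f"gh_p_{gi}_{gj}"].append(gp)
                else:
                    pair_cols[f"gh_diff_{gi}_{gj}"].append(np.nan)
                    pair_cols[f"gh_p_{gi}_{gj}"].append(np.nan)
        for col, vals in pair_cols.items():
            results[col] = vals

    top = results.head(top_n).copy() if len(results) else results
    return results, top, skipped


# ---------------------------------------------------------------------------
# consensus annotation of gene clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsensusGeneGroup:
    group_id: str
    member_genes: frozenset[str]
    consensus_og: str          # orthologous-group id or "unknown"
    prevalence: float


def consensus_annotation(annotations: pd.DataFrame) -> list[ConsensusGeneGroup]:
    """Consensus-annotate remote-homology gene clusters by majority vote.

    For each gene cluster the consensus is the orthologous-group label held by
    strictly more than half of its annotated members; clusters without such a
    majority are "unresolved" and treated as unknown.  Clusters sharing an
    identical resolved consensus are merged into one group; unknown-function
    clusters pass through unmerged.  Prevalence is left at NaN here (it needs
    the genome set; see :func:`prevalence_filter`).
    """
    clustered = annotations[annotations["agnostos_cluster"].astype(str).str.strip() != ""]
    resolved: dict[str, list[str]] = {}
    groups: list[ConsensusGeneGroup] = []
    for cid, grp in clustered.groupby("agnostos_cluster", sort=True):
        votes = grp.loc[grp["og_known"] & (grp["og_id"].astype(str).str.strip() != ""),
                        "og_id"]
        consensus = "unknown"
        if len(votes):
            counts = votes.value_counts()
            top_label, top_votes = counts.index[0], int(counts.iloc[0])
            if 2 * top_votes > len(votes):
                consensus = str(top_label)
        if consensus == "unknown":
            groups.append(ConsensusGeneGroup(str(cid), frozenset(grp["gene_id"]),
                                             "unknown", float("nan")))
        else:
            resolved.setdefault(consensus, []).extend(grp["gene_id"])
    for og, genes in sorted(resolved.items()):
        groups.append(ConsensusGeneGroup(f"merged:{og}", frozenset(genes), og,
                                         float("nan")))
    return sorted(groups, key=lambda g: g.group_id)


def prevalence_filter(groups: list[ConsensusGeneGroup], annotations: pd.DataFrame,
                      genomes: pd.DataFrame, config: PipelineConfig
                      ) -> list[ConsensusGeneGroup]:
    """Drop gene groups present in fewer than ``min_group_prevalence`` genomes.

    Prevalence is the fraction of analyzed genomes containing at least one
    member gene; groups at or above the floor are retained (the exclusion rule
    is a strict "less than").
    """
    n_genomes = genomes["genome_id"].nunique()
    if n_genomes == 0:
        raise ValueError("empty genome set")
    genome_of = dict(zip(annotations["gene_id"], annotations["genome_id"]))
    out = []
    for g in groups:
        hit = {genome_of[gene] for gene in g.member_genes if gene in genome_of}
        prev = len(hit) / n_genomes
        if prev >= config.min_group_prevalence:
            out.append(ConsensusGeneGroup(g.group_id, g.member_genes,
                                          g.consensus_og, prev))
    return out


# ---------------------------------------------------------------------------
# model-object facade
# ---------------------------------------------------------------------------


class FunctionalLandscape:
    """Functional classification model over a genome x function matrix.

    ``FunctionalLandscape(matrix, config).fit()`` clusters the genomes and
    tests every function for differential occurrence, returning a
    :class:`FunctionalLandscapeResults`.
    """

    def __init__(self, matrix: pd.DataFrame, config: PipelineConfig | None = None,
                 outgroup: Iterable[str] = (), log_transform: bool = False):
        self.matrix = matrix
        self.config = config or PipelineConfig()
        self.outgroup = list(outgroup)
        self.log_transform = log_transform

    @classmethod
    def from_annotations(cls, annotations: pd.DataFrame, genomes: pd.DataFrame,
                         config: PipelineConfig | None = None,
                         **kwargs) -> "FunctionalLandscape":
        matrix, _ = build_occurrence_matrix(annotations, genomes)
        return cls(matrix, config, **kwargs)

    def fit(self) -> "FunctionalLandscapeResults":
        assignment = cluster_genomes(self.matrix, self.config, self.outgroup,
                                     self.log_transform)
        results, top, skipped = differential_functions(
            self.matrix.drop(index=self.outgroup, errors="ignore"),
            assignment.groups, self.config)
        return FunctionalLandscapeResults(self, assignment, results, top, skipped)


class FunctionalLandscapeResults:
    def __init__(self, model: FunctionalLandscape,
                 assignment: FunctionalGroupAssignment,
                 differential: pd.DataFrame, top_functions: pd.DataFrame,
                 skipped_functions: list[str]):
        self.model = model
        self.assignment = assignment
        self.groups = assignment.groups
        self.differential = differential
        self.top_functions = top_functions
        self.skipped_functions = skipped_functions

    @property
    def n_significant(self) -> int:
        if not len(self.differential):
            return 0
        return int(self.differential["significant"].sum())

    def newick(self) -> str:
        ids = sorted(set(self.model.matrix.index) - set(self.model.outgroup))
        return linkage_to_newick(self.assignment.linkage, ids)

    def summary(self) -> str:
        sizes = self.groups.value_counts().sort_index()
        lines = [
            "Functional landscape",
            "====================",
            f"genomes clustered      : {len(self.groups)}",
            f"outgroup genomes       : {len(self.model.outgroup)}",
            f"functions tested       : {len(self.differential)}",
            f"functions skipped      : {len(self.skipped_functions)}",
            f"significant functions  : {self.n_significant} "
            f"(Welch ANOVA p < {self.model.config.anova_p_threshold:g})",
            "group sizes            : "
            + ", ".join(f"{g}={n}" for g, n in sizes.items()),
        ]
        return "\n".join(lines)
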
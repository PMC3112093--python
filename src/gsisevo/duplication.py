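"""Duplication-history vectors, their clustering, and group (anti)clustering tests.

Each gene's duplication history is summarized as a vector of counts of
duplication-flagged gene-tree nodes on the root-to-gene ancestral path, binned
by the taxon/age label of the node (oldest vertebrate bin first).  Genes with
identical vectors merge at height zero in a hierarchical clustering of the
pairwise Euclidean distances; whether a pathway's members have unusually
similar (clustered) or unusually diverse (anticlustered) histories is tested
by rank-summing within-group pairwise distances against all remaining pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .core_io import GeneTree

__all__ = [
    "TaxonBin",
    "DuplicationVector",
    "GroupTestResult",
    "DEFAULT_SCHEDULE",
    "extract_duplication_vector",
    "euclidean_distance_matrix",
    "hierarchical_cluster",
    "identical_history_groups",
    "group_clustering_test",
    "exclude_gene_and_retest",
]


@dataclass(frozen=True)
class TaxonBin:
    """One bin of the vertebrate duplication timeline."""

    taxon: str
    age: float  # MYA
    order_index: int  # 0 = oldest


def make_schedule(pairs: Sequence[tuple[str, float]]) -> tuple[TaxonBin, ...]:
    """Build a bin schedule from (taxon, age MYA) pairs, oldest first."""
    ages = [a for _, a in pairs]
    if any(nxt >= prev for prev, nxt in zip(ages[:-1], ages[1:])):
        raise ValueError("schedule ages must strictly decrease oldest-to-youngest")
    return tuple(TaxonBin(t, a, i) for i, (t, a) in enumerate(pairs))


# Vertebrate taxon bins named by the study, root of the bony vertebrates down
# to the catarrhine primates.  Extensible via make_schedule.
DEFAULT_SCHEDULE = make_schedule(
    [
        ("Euteleostomi", 420.0),
        ("Tetrapoda", 359.0),
        ("Clupeocephala", 320.0),
        ("Percomorpha", 190.0),
        ("Theria", 166.0),
        ("Eutheria", 102.0),
        ("Murinae", 37.0),
        ("Catarrhini", 31.0),
    ]
)


@dataclass(frozen=True)
class DuplicationVector:
    """Binned counts of ancestral duplications for one gene."""

    gene: str
    counts: tuple[int, ...]
    schedule: tuple[TaxonBin, ...] = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.schedule):
            raise ValueError("vector length must equal schedule length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    def total(self) -> int:
        return int(sum(self.counts))


def extract_duplication_vector(
    tree: GeneTree,
    focal_gene: str,
    schedule: Sequence[TaxonBin] = DEFAULT_SCHEDULE,
    *,
    strict: bool = True,
) -> DuplicationVector:
    """Count duplications on the focal gene's ancestral path, per taxon bin.

    Only duplication-flagged nodes on the root-to-focal-leaf path contribute;
    each adds 1 to the bin matching its taxon label.  Nodes whose taxon is not
    in the schedule (e.g. pre-vertebrate duplications) contribute nothing: in
    strict mode an unmappable *duplication* node raises; in lenient mode it is
    dropped with a warning.  Nodes at or above a family-founding duplication
    marker (NHX ``F=Y``) are excluded, truncating the vector to the history of
    the focal gene's own family.
    """
    schedule = tuple(schedule)
    bin_index = {b.taxon: b.order_index for b in schedule}
    path = tree.path_from_root(focal_gene)

    # Truncate above the youngest family-founding marker on the path.
    start = 0
    for i, node in enumerate(path):
        if node.is_family_founder:
            start = i + 1
    counts = [0] * len(schedule)
    for node in path[start:]:
        if not node.is_duplication:
            continue
        if node.taxon is None or node.taxon not in bin_index:
            if node.taxon is not None and strict:
                raise ValueError(
                    f"duplication node taxon {node.taxon!r} not in schedule"
                )
            if node.taxon is not None:
                warnings.warn(
                    f"dropping duplication at unmapped taxon {node.taxon!r}",
                    stacklevel=2,
                )
            continue
        counts[bin_index[node.taxon]] += 1
    return DuplicationVector(focal_gene, tuple(counts), schedule)


def euclidean_distance_matrix(
    vectors: Sequence[DuplicationVector],
) -> tuple[list[str], np.ndarray]:
    """Pairwise Euclidean distances between duplication vectors.

    Returns gene labels and the symmetric zero-diagonal matrix.  All vectors
    must share one schedule.
    """
    if not vectors:
        raise ValueError("no vectors")
    sched = vectors[0].schedule
    if any(v.schedule != sched for v in vectors):
        raise ValueError("vectors use mixed bin schedules")
    genes = [v.gene for v in vectors]
    arr = np.asarray([v.counts for v in vectors], dtype=float)
    dm = squareform(pdist(arr, metric="euclidean"))
    return genes, dm


def hierarchical_cluster(distmat: np.ndarray, linkage: str = "complete"):
    """Agglomerative clustering of a distance matrix (scipy linkage matrix)."""
    distmat = np.asarray(distmat, dtype=float)
    if distmat.ndim != 2 or distmat.shape[0] != distmat.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(distmat, distmat.T):
        raise ValueError("distance matrix must be symmetric")
    return hierarchy.linkage(squareform(distmat, checks=False), method=linkage)


def identical_history_groups(
    genes: Sequence[str], distmat: np.ndarray, linkage: str = "complete"
) -> list[frozenset[str]]:
    """Flat clusters at merge height zero: groups with identical histories.

    Cutting the dendrogram at height 0 groups exactly the genes whose
    duplication vectors coincide, for any linkage.  Ordered by size, largest
    first.
    """
    z = hierarchical_cluster(distmat, linkage)
    flat = hierarchy.fcluster(z, t=0.0, criterion="distance")
    groups: dict[int, set[str]] = {}
    for gene, cid in zip(genes, flat):
        groups.setdefault(int(cid), set()).add(gene)
    return sorted(
        (frozenset(g) for g in groups.values()), key=lambda g: (-len(g), sorted(g))
    )


def dendrogram_newick(genes: Sequence[str], z: np.ndarray) -> str:
    """Serialize a scipy linkage matrix as a Newick string with merge heights."""
    tree = hierarchy.to_tree(z)

    def fmt(node, parent_height: float) -> str:
        length = parent_height - (node.dist if not node.is_leaf() else 0.0)
        if node.is_leaf():
            return f"{genes[node.id]}:{length:g}"
        left = fmt(node.get_left(), node.dist)
        right = fmt(node.get_right(), node.dist)
        return f"({left},{right}):{length:g}"

    return fmt(tree, tree.dist).rsplit(":", 1)[0] + ";"


# ---------------------------------------------------------------------------
# Group clustering / anticlustering tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupTestResult:
    """Within-group vs background comparison of pairwise history distances."""

    group: str
    n_within_pairs: int
    n_background_pairs: int
    u_statistic: float
    p_raw: float
    p_bonferroni: float
    direction: str  # "clustered", "anticlustered" or "none"
    within_median: float
    background_median: float


def _pair_distances(
    genes: Sequence[str], distmat: np.ndarray, members: set[str]
) -> tuple[np.ndarray, np.ndarray]:
    idx = {g: i for i, g in enumerate(genes)}
    member_idx = {idx[g] for g in members}
    within, background = [], []
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            d = distmat[i, j]
            if i in member_idx and j in member_idx:
                within.append(d)
            else:
                background.append(d)
    return np.asarray(within), np.asarray(background)


def group_clustering_test(
    genes: Sequence[str],
    distmat: np.ndarray,
    membership: Mapping[str, str],
    group: str,
    n_groups_tested: int = 1,
    *,
    alpha: float = 0.05,
    exact_max_pairs: int = 8,
) -> GroupTestResult:
    """Mann-Whitney test of within-group vs all-other pairwise distances.

    Smaller within-group distances than background mean the group's members
    share duplication histories ("clustered"); larger mean they are unusually
    diverse ("anticlustered").  Two-sided p; the exact null distribution is
    enumerated when both pair sets have ≤ ``exact_max_pairs`` elements and no
    ties span the two samples, otherwise the normal approximation with tie
    correction is used.  Bonferroni multiplies by ``n_groups_tested``.
    """
    members = {g for g, grp in membership.items() if grp == group}
    if len(members) < 2:
        raise ValueError(f"group {group!r} needs >= 2 members")
    missing = members - set(genes)
    if missing:
        raise ValueError(f"group members absent from matrix: {sorted(missing)}")
    within, background = _pair_distances(genes, np.asarray(distmat, float), members)
    if background.size == 0:
        raise ValueError("no background pairs")

    small = within.size <= exact_max_pairs and background.size <= exact_max_pairs
    has_cross_ties = bool(set(within.tolist()) & set(background.tolist()))
    method = "exact" if (small and not has_cross_ties) else "asymptotic"
    res = stats.mannwhitneyu(within, background, alternative="two-sided", method=method)
    p_raw = float(res.pvalue)
    w_med, b_med = float(np.median(within)), float(np.median(background))
    if p_raw < alpha and w_med < b_med:
        direction = "clustered"
    elif p_raw < alpha and w_med > b_med:
        direction = "anticlustered"
    else:
        direction = "none"
    return GroupTestResult(
        group=group,
        n_within_pairs=int(within.size),
        n_background_pairs=int(background.size),
        u_statistic=float(res.statistic),
        p_raw=p_raw,
        p_bonferroni=min(1.0, p_raw * n_groups_tested),
        direction=direction,
        within_median=w_med,
        background_median=b_med,
    )


def exclude_gene_and_retest(
    genes: Sequence[str],
    distmat: np.ndarray,
    membership: Mapping[str, str],
    group: str,
    gene: str,
    n_groups_tested: int = 1,
    **kwargs,
) -> GroupTestResult:
    """Re-run the group test with one gene's row/column removed.

    Used to check whether a group's signal is driven by a single member (the
    study's GAPD leave-out check for glycolysis anticlustering).  Removing a
    gene outside the matrix is an error; the group must retain ≥ 2 members.
    """
    genes = list(genes)
    if gene not in genes:
        raise KeyError(f"gene {gene!r} not in matrix")
    if membership.get(gene) != group:
        # Excluding a gene outside the tested group leaves the test unchanged.
        return group_clustering_test(
            genes, distmat, membership, group, n_groups_tested, **kwargs
        )
    keep = [i for i, g in enumerate(genes) if g != gene]
    sub = np.asarray(distmat, float)[np.ix_(keep, keep)]
    sub_genes = [genes[i] for i in keep]
    sub_membership = {g: grp for g, grp in membership.items() if g != gene}
    return group_clustering_test(
        sub_genes, sub, sub_membership, group, n_groups_tested, **kwargs
    )
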
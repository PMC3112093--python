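"""Phylogenetic-age classification and shared-homologue clusters.

A protein's phylogenetic profile — which genomes of a fixed panel contain a
detectable homologue — determines its age class:

* Universal (U): hits in more than five prokaryote species;
* Eukaryote-specific (E): otherwise, at least one non-metazoan eukaryote hit;
* Metazoan-specific (M): otherwise, at least one non-mammalian metazoan hit;
* Vertebrate-specific (V): otherwise.

The rule is applied in that fixed order and is non-hierarchical: only the
first matching clause counts.  Profiles also reveal proteins sharing
homologues in other genomes — evidence of ancient duplication — reported here
as single-linkage connected components of the shared-homologue graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
from scipy import stats

from .core_io import HIT_CATEGORIES, PhyloClass, ProteinRecord

__all__ = [
    "HitProfile",
    "CompositionTest",
    "profile_from_hits",
    "classify",
    "class_composition",
    "compare_composition",
    "shared_homolog_clusters",
]

PROFILE_CATEGORIES = (
    "prokaryote",
    "nonmetazoan_eukaryote",
    "nonmammalian_metazoan",
    "vertebrate",
)


@dataclass(frozen=True)
class HitProfile:
    """Distinct-genome hit counts per taxonomic category for one protein."""

    protein: str
    prokaryote: int = 0
    nonmetazoan_eukaryote: int = 0
    nonmammalian_metazoan: int = 0
    vertebrate: int = 0
    homolog_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for cat in PROFILE_CATEGORIES:
            if getattr(self, cat) < 0:
                raise ValueError(f"{self.protein}: negative count for {cat}")

    def counts(self) -> tuple[int, int, int, int]:
        return (
            self.prokaryote,
            self.nonmetazoan_eukaryote,
            self.nonmammalian_metazoan,
            self.vertebrate,
        )


def profile_from_hits(
    protein: str, hits: Sequence[tuple[str, str, float]]
) -> HitProfile:
    """Build a profile from ``read_hit_table`` rows for one protein.

    Counts are of distinct genomes per category; "mammal" hits collapse into
    the vertebrate category, which is the terminal class of the rule.
    """
    genomes: dict[str, set[str]] = {cat: set() for cat in PROFILE_CATEGORIES}
    ids = set()
    for genome, category, _evalue in hits:
        if category not in HIT_CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        cat = "vertebrate" if category == "mammal" else category
        genomes[cat].add(genome)
        ids.add(genome)
    return HitProfile(
        protein=protein,
        prokaryote=len(genomes["prokaryote"]),
        nonmetazoan_eukaryote=len(genomes["nonmetazoan_eukaryote"]),
        nonmammalian_metazoan=len(genomes["nonmammalian_metazoan"]),
        vertebrate=len(genomes["vertebrate"]),
        homolog_ids=frozenset(ids),
    )


def classify(profile: HitProfile, *, universal_min_prokaryotes: int = 6) -> PhyloClass:
    """Assign the phylogenetic age class from a hit profile.

    "More than five prokaryote species" is the Universal criterion, so the
    default threshold is ≥ 6 distinct prokaryote genomes.
    """
    if profile.prokaryote >= universal_min_prokaryotes:
        return PhyloClass.U
    if profile.nonmetazoan_eukaryote >= 1:
        return PhyloClass.E
    if profile.nonmammalian_metazoan >= 1:
        return PhyloClass.M
    return PhyloClass.V


def class_composition(
    records: Sequence[ProteinRecord] | Sequence[PhyloClass],
) -> dict[str, dict[str, float]]:
    """Counts and rounded integer percentages per phylogenetic class."""
    classes = [
        r.phylo_class if isinstance(r, ProteinRecord) else PhyloClass(r)
        for r in records
    ]
    counts = {c.value: 0 for c in PhyloClass}
    for c in classes:
        counts[c.value] += 1
    total = sum(counts.values())
    percents = {
        k: (round(100 * v / total) if total else 0) for k, v in counts.items()
    }
    return {"counts": counts, "percent": percents}


@dataclass(frozen=True)
class CompositionTest:
    """Pearson goodness-of-fit of observed class counts against reference proportions."""

    observed_counts: tuple[int, ...]
    expected_proportions: tuple[float, ...]
    chi2: float
    df: int
    p: float


def compare_composition(
    observed: Sequence[int] | Mapping[str, int],
    reference: Sequence[float] | Mapping[str, float],
) -> CompositionTest:
    """Chi-squared goodness-of-fit of the network's U/E/M/V mix vs a reference.

    ``reference`` proportions are normalized to sum to one; expected counts are
    ``total * proportion``.  df = k - 1, upper-tail p.
    """
    if isinstance(observed, Mapping):
        keys = [c.value for c in PhyloClass] if set(observed) >= {"U", "E", "M", "V"} else sorted(observed)
        obs = [observed[k] for k in keys]
        ref = [reference[k] for k in keys] if isinstance(reference, Mapping) else list(reference)
    else:
        obs = list(observed)
        ref = (
            [reference[k] for k in sorted(reference)]
            if isinstance(reference, Mapping)
            else list(reference)
        )
    if len(obs) != len(ref):
        raise ValueError("observed and reference lengths differ")
    total = sum(obs)
    if total <= 0:
        raise ValueError("observed total must be positive")
    norm = sum(ref)
    props = [r / norm for r in ref]
    expected = [total * p for p in props]
    for o, e in zip(obs, expected):
        if e == 0 and o > 0:
            raise ValueError("expected count 0 with nonzero observed")
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return CompositionTest(
        observed_counts=tuple(int(o) for o in obs),
        expected_proportions=tuple(props),
        chi2=float(chi2),
        df=len(obs) - 1,
        p=float(p),
    )


def shared_homolog_clusters(
    profiles: Sequence[HitProfile], min_shared: int = 1
) -> list[tuple[frozenset[str], int]]:
    """Clusters of proteins sharing homologues in other genomes.

    Builds a graph with edge weight ``|homolog_ids(a) ∩ homolog_ids(b)|`` and
    returns connected components over edges of weight ≥ ``min_shared``
    (single linkage), each with the maximal pairwise shared count inside it.
    Singletons are reported with a shared count of 0.  Ordered largest shared
    count first, then by size, then lexicographically.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    g = nx.Graph()
    g.add_nodes_from(p.protein for p in profiles)
    for i, a in enumerate(profiles):
        for b in profiles[i + 1 :]:
            shared = len(a.homolog_ids & b.homolog_ids)
            if shared >= min_shared:
                g.add_edge(a.protein, b.protein, weight=shared)
    out = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        best = max((d["weight"] for _, _, d in sub.edges(data=True)), default=0)
        out.append((frozenset(comp), int(best)))
    out.sort(key=lambda c: (-c[1], -len(c[0]), sorted(c[0])))
    return out
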
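"""Generators emulating every input the pipeline consumes, with ground truth.

These generators target the statistical structure the analysis consumes —
protein pairs of a chosen percent similarity, hit profiles that classify to a
chosen age class, NHX gene trees with known per-bin duplication counts, and
record cohorts with planted group means and a planted rank correlation — and
return the ground truth alongside the data so every pipeline stage has a
recovery test.  They make no attempt to simulate realistic protein evolution.

All randomness flows from a single integer seed via ``numpy.random.Generator``
(fixed integer-state algorithm), so identical seeds give identical outputs
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .conservation import align_global, blosum62
from .core_io import GeneTree, GeneTreeNode, PhyloClass, ProteinRecord, PathwayCode
from .duplication import (
    DEFAULT_SCHEDULE,
    DuplicationVector,
    TaxonBin,
)
from .profiles import HitProfile, classify

__all__ = [
    "SynthConfig",
    "synth_protein_pair",
    "synth_hit_profile",
    "synth_gene_tree",
    "synth_cohort",
    "synth_hit_table",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SynthConfig:
    """Shared knobs for the generators.

    ``group_spec`` maps group label → (mean similarity, sd, size) for cohort
    generation; ``dup_rates`` maps taxon bins to per-bin Poisson rates;
    ``indel_rate``/``sub_rate`` shape the sequence-pair mutation process.
    """

    seed: int = 0
    n_genes: int = 69
    group_spec: Mapping[str, tuple[float, float, int]] = field(
        default_factory=lambda: {
            # Emulates the two-coalition structure: conserved core pathways
            # vs faster-evolving respiratory chain and glutathione groups.
            "G": (97.9, 1.6, 11),
            "T": (96.0, 3.6, 16),
            "PN": (95.4, 4.7, 10),
            "M": (97.9, 2.0, 2),
            "R": (91.0, 3.3, 24),
            "S": (88.7, 7.1, 6),
        }
    )
    dup_rates: Mapping[str, float] = field(
        default_factory=lambda: {b.taxon: 0.5 for b in DEFAULT_SCHEDULE}
    )
    indel_rate: float = 0.01
    sub_rate: float = 0.05
    max_retries: int = 50

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _rng_of(config_or_rng) -> np.random.Generator:
    if isinstance(config_or_rng, np.random.Generator):
        return config_or_rng
    if isinstance(config_or_rng, SynthConfig):
        return config_or_rng.rng()
    return np.random.default_rng(config_or_rng)


# ---------------------------------------------------------------------------
# Protein pairs with a target percent similarity
# ---------------------------------------------------------------------------


def synth_protein_pair(
    length: int,
    target_similarity: float,
    config: SynthConfig | np.random.Generator | int = 0,
    *,
    tolerance: float = 2.0,
) -> tuple[str, str]:
    """A protein pair whose aligned percent similarity hits a target ±2 points.

    The second sequence derives from the first by point substitutions drawn
    preferentially among residue pairs with non-positive BLOSUM62 scores plus
    occasional short indels; the realized similarity is measured with the
    package aligner and the draw repeated (bounded retries) until within
    tolerance.  Supported targets span 50-100 percent.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    if not 50.0 <= target_similarity <= 100.0:
        raise ValueError("target similarity must be in [50, 100]")
    rng = _rng_of(config)
    config = config if isinstance(config, SynthConfig) else SynthConfig()
    matrix = blosum62()
    seq_a = "".join(rng.choice(list(_AA20), size=length))
    if target_similarity == 100.0:
        return seq_a, seq_a

    dissimilar: dict[str, list[str]] = {
        a: [b for b in _AA20 if b != a and matrix[a, b] <= 0] for a in _AA20
    }
    p_mut = 1.0 - target_similarity / 100.0
    for _ in range(config.max_retries):
        out = []
        for ch in seq_a:
            u = rng.random()
            if u < config.indel_rate / 2:
                continue  # deletion
            if u < config.indel_rate:
                out.append(ch)
                out.append(rng.choice(list(_AA20)))  # insertion
                continue
            if rng.random() < p_mut:
                if rng.random() < 0.85:
                    out.append(str(rng.choice(dissimilar[ch])))
                else:
                    choices = [b for b in _AA20 if b != ch]
                    out.append(str(rng.choice(choices)))
            else:
                out.append(ch)
        seq_b = "".join(out)
        if not seq_b:
            continue
        aln = align_global(seq_a, seq_b, matrix)
        if abs(aln.percent_similarity - target_similarity) <= tolerance:
            return seq_a, seq_b
    raise RuntimeError(
        f"could not realize similarity {target_similarity} within "
        f"{config.max_retries} retries"
    )


# ---------------------------------------------------------------------------
# Hit profiles with a known true class
# ---------------------------------------------------------------------------


def synth_hit_profile(
    true_class: PhyloClass | str,
    config: SynthConfig | np.random.Generator | int = 0,
    *,
    protein: str = "synthetic",
) -> HitProfile:
    """A hit profile guaranteed to classify to ``true_class``.

    Hard constraints mirror the classification rule: U draws more than five
    prokaryote genomes; E draws at most five prokaryotes and at least one
    non-metazoan eukaryote; M additionally zeroes the eukaryote count; V
    leaves only vertebrate hits.
    """
    true_class = PhyloClass(true_class)
    rng = _rng_of(config)
    vert = int(rng.integers(1, 30))
    if true_class is PhyloClass.U:
        prof = HitProfile(
            protein,
            prokaryote=int(rng.integers(6, 100)),
            nonmetazoan_eukaryote=int(rng.integers(0, 20)),
            nonmammalian_metazoan=int(rng.integers(0, 20)),
            vertebrate=vert,
        )
    elif true_class is PhyloClass.E:
        prof = HitProfile(
            protein,
            prokaryote=int(rng.integers(0, 6)),
            nonmetazoan_eukaryote=int(rng.integers(1, 20)),
            nonmammalian_metazoan=int(rng.integers(0, 20)),
            vertebrate=vert,
        )
    elif true_class is PhyloClass.M:
        prof = HitProfile(
            protein,
            prokaryote=int(rng.integers(0, 6)),
            nonmetazoan_eukaryote=0,
            nonmammalian_metazoan=int(rng.integers(1, 20)),
            vertebrate=vert,
        )
    else:
        prof = HitProfile(protein, 0, 0, 0, vertebrate=vert)
    assert classify(prof) is true_class
    return prof


def synth_hit_table(
    true_classes: Mapping[str, PhyloClass | str],
    config: SynthConfig | np.random.Generator | int = 0,
) -> str:
    """A TSV hit table (dialect of ``read_hit_table``) realizing given classes.

    Each protein's profile is drawn with :func:`synth_hit_profile` and expanded
    into one row per genome hit with E-values below the default cutoff.
    """
    rng = _rng_of(config)
    lines = ["query\tgenome\tcategory\tevalue"]
    for protein, cls in true_classes.items():
        prof = synth_hit_profile(cls, rng, protein=protein)
        for cat, count in zip(
            ("prokaryote", "nonmetazoan_eukaryote", "nonmammalian_metazoan", "vertebrate"),
            prof.counts(),
        ):
            for k in range(count):
                ev = 10 ** float(rng.uniform(-30, 0))
                lines.append(f"{protein}\t{cat[:4]}_{protein}_{k}\t{cat}\t{ev:.3g}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Gene trees with known duplication vectors
# ---------------------------------------------------------------------------


def synth_gene_tree(
    focal: str,
    schedule: Sequence[TaxonBin] = DEFAULT_SCHEDULE,
    dup_rates: Mapping[str, float] | None = None,
    config: SynthConfig | np.random.Generator | int = 0,
) -> tuple[GeneTree, DuplicationVector]:
    """A ladderized gene tree with Poisson-placed duplications on the focal lineage.

    Walking from the root towards the focal leaf, each schedule bin receives
    ``Poisson(rate)`` duplication nodes (NHX ``D=Y`` with the bin's taxon and
    age), each emitting a paralog leaf; a plain speciation node with an
    outgroup leaf separates consecutive bins.  Returns the tree and the
    ground-truth duplication vector.
    """
    schedule = tuple(schedule)
    if not schedule:
        raise ValueError("schedule must be non-empty")
    if dup_rates is None:
        dup_rates = (
            config.dup_rates
            if isinstance(config, SynthConfig)
            else {b.taxon: 0.5 for b in schedule}
        )
    rng = _rng_of(config)

    root = GeneTreeNode()
    current = root
    counts = []
    paralog_i = 0
    for bin_ in schedule:
        k = int(rng.poisson(float(dup_rates.get(bin_.taxon, 0.0))))
        counts.append(k)
        for _ in range(k):
            dup = GeneTreeNode(is_duplication=True, taxon=bin_.taxon, age=bin_.age)
            paralog = GeneTreeNode(name=f"{focal}_paralog{paralog_i}")
            paralog_i += 1
            dup.parent = current
            current.children.append(dup)
            paralog.parent = dup
            dup.children.append(paralog)
            current = dup
        spec = GeneTreeNode(taxon=bin_.taxon, age=bin_.age)  # speciation marker
        outgroup = GeneTreeNode(name=f"{focal}_out_{bin_.taxon}")
        spec.parent = current
        current.children.append(spec)
        outgroup.parent = spec
        spec.children.append(outgroup)
        current = spec
    leaf = GeneTreeNode(name=focal)
    leaf.parent = current
    current.children.append(leaf)

    tree = GeneTree(root)
    truth = DuplicationVector(focal, tuple(counts), schedule)
    return tree, truth


# ---------------------------------------------------------------------------
# Record cohorts with planted effects
# ---------------------------------------------------------------------------


def synth_cohort(
    config: SynthConfig,
    *,
    duplication_rho: float = 0.0,
    duplication_mean: float = 2.0,
) -> list[ProteinRecord]:
    """A cohort of protein records with planted group means and correlation.

    Similarities are group-specific Gaussians truncated to [0, 100]; each
    record also receives a duplication count drawn through a Gaussian copula
    so that the similarity-duplication rank correlation targets
    ``duplication_rho``.  Phylogenetic classes are drawn from the network's
    observed class mix.
    """
    if not config.group_spec:
        raise ValueError("group_spec must be non-empty")
    rng = config.rng()
    # Gaussian-copula correlation giving Spearman rho_s: r = 2 sin(pi rho_s/6).
    r = (
        2 * np.sin(np.pi * duplication_rho / 6)
        if abs(duplication_rho) < 1
        else float(np.sign(duplication_rho))
    )
    groups: list[str] = []
    sims: list[float] = []
    for group, (mean, sd, size) in config.group_spec.items():
        for _ in range(size):
            groups.append(group)
            sims.append(round(float(np.clip(mean + sd * rng.standard_normal(), 0.0, 100.0)), 1))
    sim_arr = np.asarray(sims)
    n = sim_arr.size
    # Couple duplication counts to the overall similarity ranks, not the
    # within-group residuals, so the planted correlation is cohort-wide.
    ranks = sps.rankdata(sim_arr, method="average")
    z_sim = sps.norm.ppf((ranks - 0.5) / n)
    z2 = r * z_sim + np.sqrt(max(0.0, 1 - r**2)) * rng.standard_normal(n)
    ndup = sps.poisson.ppf(sps.norm.cdf(z2), mu=duplication_mean).astype(int)

    class_probs = {"U": 0.77, "E": 0.17, "M": 0.03, "V": 0.03}
    classes = rng.choice(list(class_probs), size=n, p=list(class_probs.values()))
    records = []
    for i, group in enumerate(groups):
        code = group[0] if group[0] in PathwayCode.__members__ else "G"
        records.append(
            ProteinRecord(
                abbrev=f"{group}{i}",
                swissprot_id=f"P{i:05d}",
                pathways=(PathwayCode(code),),
                phylo_class=PhyloClass(str(classes[i])),
                hm_similarity=sims[i],
                n_duplications=int(ndup[i]),
            )
        )
    return records
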
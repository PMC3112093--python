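"""Domain model, packaged study fixture, and readers/writers for external formats.

The study unit is a 69-protein network behind glucose-stimulated insulin
secretion (GSIS) in the pancreatic beta-cell.  Each protein carries its
sub-pathway membership, a phylogenetic age class, a human-mouse percent
similarity, and optional positive-selection and disease annotations.  The
packaged ``gsis69`` fixture transcribes the published protein table verbatim;
FASTA, NHX gene trees and tabular homology-hit files are the external inputs.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "PathwayCode",
    "PhyloClass",
    "ProteinRecord",
    "StudyFixture",
    "GeneTree",
    "GeneTreeNode",
    "HIT_CATEGORIES",
    "load_fixture",
    "write_fixture",
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "read_gene_tree",
    "write_gene_tree",
]

# The five taxonomic categories a homology-hit table may carry.  "mammal" is
# collapsed into "vertebrate" for age classification (see profiles module).
HIT_CATEGORIES = (
    "prokaryote",
    "nonmetazoan_eukaryote",
    "nonmammalian_metazoan",
    "vertebrate",
    "mammal",
)

_AA = set("ACDEFGHIKLMNPQRSTVWYBZXUO*")


class PathwayCode(str, enum.Enum):
    """Sub-pathways of the GSIS biochemical network."""

    G = "G"  # glycolysis
    T = "T"  # TCA cycle
    P = "P"  # pyruvate cycle
    N = "N"  # NADH shuttle
    R = "R"  # respiratory chain
    M = "M"  # metabolite transport
    S = "S"  # glutathione pathway

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class PhyloClass(str, enum.Enum):
    """Phylogenetic age class: how taxonomically widely homologues are found.

    Universal genes have detectable prokaryotic homologues; the remaining
    classes narrow stepwise to eukaryote-, metazoan- and vertebrate-specific.
    """

    U = "U"
    E = "E"
    M = "M"
    V = "V"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ProteinRecord:
    """One network protein with its evolutionary annotations.

    ``pathways`` is ordered as printed; the first-listed code is taken as the
    primary pathway when a single group assignment is needed.
    ``n_duplications`` is ``None`` when no duplication count is available.
    """

    abbrev: str
    swissprot_id: str
    pathways: tuple[PathwayCode, ...]
    phylo_class: PhyloClass
    hm_similarity: float
    name: str = ""
    n_duplications: int | None = None
    positive_selection_episodes: tuple[tuple[str, float], ...] = ()
    disease_omim: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValueError(f"{self.abbrev}: pathways must be non-empty")
        if not 0.0 <= self.hm_similarity <= 100.0:
            raise ValueError(
                f"{self.abbrev}: hm_similarity {self.hm_similarity} outside [0, 100]"
            )
        if self.n_duplications is not None and self.n_duplications < 0:
            raise ValueError(f"{self.abbrev}: negative duplication count")
        for code, _disease in self.disease_omim:
            if not re.fullmatch(r"\d{6}", code):
                raise ValueError(f"{self.abbrev}: malformed OMIM code {code!r}")

    @property
    def primary_pathway(self) -> PathwayCode:
        return self.pathways[0]

    @property
    def has_positive_selection(self) -> bool:
        return len(self.positive_selection_episodes) > 0

    @property
    def has_disease(self) -> bool:
        return len(self.disease_omim) > 0


@dataclass(frozen=True)
class StudyFixture:
    """The packaged study data set plus genome-wide reference proportions."""

    records: tuple[ProteinRecord, ...]
    genome_reference_proportions: Mapping[str, float]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, abbrev: str) -> ProteinRecord:
        for rec in self.records:
            if rec.abbrev == abbrev:
                return rec
        raise KeyError(abbrev)


# ---------------------------------------------------------------------------
# Fixture loading
# ---------------------------------------------------------------------------

_FIXTURES = {"gsis69"}


def _data_text(filename: str) -> str:
    return (resources.files("gsisevo") / "data" / filename).read_text()


def load_fixture(name: str = "gsis69") -> StudyFixture:
    """Load a packaged study fixture by name.

    ``"gsis69"`` is the 69-protein GSIS network with sub-pathway codes,
    phylogenetic classes, human-mouse percent similarities, positive-selection
    episodes and OMIM disease associations, all transcribed from the published
    tables.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")

    records_txt = _data_text("gsis69_records.tsv")
    selection_txt = _data_text("gsis69_selection.tsv")
    disease_txt = _data_text("gsis69_disease.tsv")
    meta = json.loads(_data_text("gsis69_meta.json"))

    selection: dict[str, list[tuple[str, float]]] = {}
    for row in _tsv_rows(selection_txt):
        selection.setdefault(row["abbrev"], []).append(
            (row["taxon"], float(row["age_mya"]))
        )
    disease: dict[str, list[tuple[str, str]]] = {}
    for row in _tsv_rows(disease_txt):
        disease.setdefault(row["abbrev"], []).append((row["omim_code"], row["disease"]))

    records = []
    for row in _tsv_rows(records_txt):
        ab = row["abbrev"]
        records.append(
            ProteinRecord(
                abbrev=ab,
                swissprot_id=row["swissprot_id"],
                pathways=tuple(PathwayCode(c) for c in row["pathways"].split(",")),
                phylo_class=PhyloClass(row["phylo_class"]),
                hm_similarity=float(row["hm_similarity"]),
                name=row["name"],
                n_duplications=(
                    int(row["n_duplications"])
                    if row.get("n_duplications") not in (None, "", "NA")
                    else None
                ),
                positive_selection_episodes=tuple(selection.get(ab, ())),
                disease_omim=tuple(disease.get(ab, ())),
            )
        )
    return StudyFixture(
        records=tuple(records),
        genome_reference_proportions=dict(meta["genome_reference_proportions"]),
        metadata=meta,
    )


def _tsv_rows(text: str) -> Iterable[dict[str, str]]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    for ln in lines[1:]:
        yield dict(zip(header, ln.split("\t")))


def write_fixture(fixture: StudyFixture, directory: str | Path) -> dict[str, Path]:
    """Write a fixture back to TSV files mirroring the packaged layout.

    Returns the paths written.  ``load_fixture`` composed with this writer is a
    round trip (used as a self-check of the transcription).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rec_path = directory / "records.tsv"
    sel_path = directory / "selection.tsv"
    dis_path = directory / "disease.tsv"
    meta_path = directory / "meta.json"

    with rec_path.open("w") as fh:
        fh.write("name\tabbrev\tswissprot_id\tpathways\tphylo_class\thm_similarity\tn_duplications\n")
        for r in fixture.records:
            nd = "" if r.n_duplications is None else str(r.n_duplications)
            paths = ",".join(p.value for p in r.pathways)
            fh.write(
                f"{r.name}\t{r.abbrev}\t{r.swissprot_id}\t{paths}\t"
                f"{r.phylo_class.value}\t{r.hm_similarity:g}\t{nd}\n"
            )
    with sel_path.open("w") as fh:
        fh.write("abbrev\ttaxon\tage_mya\n")
        for r in fixture.records:
            for taxon, age in r.positive_selection_episodes:
                fh.write(f"{r.abbrev}\t{taxon}\t{age:g}\n")
    with dis_path.open("w") as fh:
        fh.write("abbrev\tomim_code\tdisease\n")
        for r in fixture.records:
            for code, dis in r.disease_omim:
                fh.write(f"{r.abbrev}\t{code}\t{dis}\n")
    meta_path.write_text(json.dumps(dict(fixture.metadata), indent=2) + "\n")
    return {"records": rec_path, "selection": sel_path, "disease": dis_path, "meta": meta_path}


def read_fixture(directory: str | Path) -> StudyFixture:
    """Read a fixture previously written by :func:`write_fixture`."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    selection: dict[str, list[tuple[str, float]]] = {}
    for row in _tsv_rows((directory / "selection.tsv").read_text()):
        selection.setdefault(row["abbrev"], []).append((row["taxon"], float(row["age_mya"])))
    disease: dict[str, list[tuple[str, str]]] = {}
    for row in _tsv_rows((directory / "disease.tsv").read_text()):
        disease.setdefault(row["abbrev"], []).append((row["omim_code"], row["disease"]))
    records = []
    for row in _tsv_rows((directory / "records.tsv").read_text()):
        ab = row["abbrev"]
        records.append(
            ProteinRecord(
                abbrev=ab,
                swissprot_id=row["swissprot_id"],
                pathways=tuple(PathwayCode(c) for c in row["pathways"].split(",")),
                phylo_class=PhyloClass(row["phylo_class"]),
                hm_similarity=float(row["hm_similarity"]),
                name=row["name"],
                n_duplications=(int(row["n_duplications"]) if row.get("n_duplications") else None),
                positive_selection_episodes=tuple(selection.get(ab, ())),
                disease_omim=tuple(disease.get(ab, ())),
            )
        )
    return StudyFixture(
        records=tuple(records),
        genome_reference_proportions=dict(meta["genome_reference_proportions"]),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path_or_text: str | Path, *, strict: bool = True) -> list[tuple[str, str]]:
    """Read protein FASTA into ``(id, sequence)`` pairs.

    IDs are the first whitespace-delimited token of the header; sequences are
    uppercased with line folding removed.  In strict mode any character outside
    the amino-acid alphabet (incl. ambiguity codes) raises ``ValueError``; in
    lenient mode offending characters are dropped.
    """
    text = _maybe_read(path_or_text)
    if not text.strip():
        raise ValueError("empty FASTA input")
    entries: list[tuple[str, list[str]]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            entries.append((line[1:].split()[0] if line[1:].split() else "", []))
        else:
            if not entries:
                raise ValueError("sequence data before first FASTA header")
            entries[-1][1].append(line.upper())
    out = []
    for name, chunks in entries:
        seq = "".join(chunks)
        bad = set(seq) - _AA
        if bad:
            if strict:
                raise ValueError(f"non-amino-acid characters in {name!r}: {sorted(bad)}")
            seq = "".join(c for c in seq if c in _AA)
        out.append((name, seq))
    return out


def write_fasta(entries: Sequence[tuple[str, str]], path: str | Path, *, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _maybe_read(path_or_text: str | Path) -> str:
    if isinstance(path_or_text, Path):
        return path_or_text.read_text()
    s = path_or_text
    # Inline data rather than a path: multi-line, FASTA or Newick markers.
    if "\n" in s or s.startswith(">") or "(" in s or ";" in s:
        return s
    try:
        p = Path(s)
        if p.exists():
            return p.read_text()
    except OSError:
        pass
    return s


# ---------------------------------------------------------------------------
# Homology-hit tables
# ---------------------------------------------------------------------------

def read_hit_table(
    path_or_text: str | Path, *, evalue_cutoff: float = 10.0
) -> dict[str, list[tuple[str, str, float]]]:
    """Read a tab-separated homology-hit table.

    Columns: query protein, subject genome id, genome taxonomic category, and
    BLAST E-value.  Rows with E-value above the cutoff (default 10, the value
    used to build the phylogenetic profiles) are dropped, and only the best
    (lowest-E) hit per query/genome pair is retained.

    Returns ``{protein: [(genome, category, evalue), ...]}``.
    """
    text = _maybe_read(path_or_text)
    best: dict[tuple[str, str], tuple[str, float]] = {}
    order: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "query" and lineno == 1:
            continue  # optional header
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: expected 4 tab-separated columns")
        query, genome, category, ev = parts
        if category not in HIT_CATEGORIES:
            raise ValueError(f"line {lineno}: unknown category {category!r}")
        try:
            evalue = float(ev)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed E-value {ev!r}") from exc
        if evalue > evalue_cutoff:
            continue
        key = (query, genome)
        if key not in best or evalue < best[key][1]:
            best[key] = (category, evalue)
        if query not in order:
            order.append(query)
    out: dict[str, list[tuple[str, str, float]]] = {q: [] for q in order}
    for (query, genome), (category, evalue) in best.items():
        out[query].append((genome, category, evalue))
    for hits in out.values():
        hits.sort()
    return out


# ---------------------------------------------------------------------------
# Gene trees (Newick/NHX)
# ---------------------------------------------------------------------------


class GeneTreeNode:
    """A gene-tree node exposing duplication annotations.

    NHX tags understood: ``D=Y/N`` (duplication), ``T=`` (taxon label),
    ``A=`` (age, MYA), ``F=Y`` (family-founding duplication, a truncation
    marker for duplication-vector extraction).  Unknown tags are ignored.
    """

    __slots__ = ("name", "is_duplication", "taxon", "age", "is_family_founder", "children", "parent")

    def __init__(self, name=None, is_duplication=False, taxon=None, age=None, is_family_founder=False):
        self.name = name
        self.is_duplication = is_duplication
        self.taxon = taxon
        self.age = age
        self.is_family_founder = is_family_founder
        self.children: list[GeneTreeNode] = []
        self.parent: GeneTreeNode | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        flag = "D" if self.is_duplication else "-"
        return f"<GeneTreeNode {self.name or self.taxon or '?'} {flag}>"


class GeneTree:
    """A rooted, duplication-annotated gene tree."""

    def __init__(self, root: GeneTreeNode):
        self.root = root

    def preorder(self) -> Iterable[GeneTreeNode]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def leaves(self) -> list[GeneTreeNode]:
        return [nd for nd in self.preorder() if nd.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [nd.name for nd in self.leaves()]

    def find_leaf(self, name: str) -> GeneTreeNode:
        for nd in self.leaves():
            if nd.name == name:
                return nd
        raise KeyError(f"leaf {name!r} not in tree")

    def path_from_root(self, name: str) -> list[GeneTreeNode]:
        """Ancestral path root → focal leaf, inclusive of both ends."""
        node = self.find_leaf(name)
        path = [node]
        while node.parent is not None:
            node = node.parent
            path.append(node)
        return list(reversed(path))

    def duplication_nodes(self) -> list[GeneTreeNode]:
        return [nd for nd in self.preorder() if nd.is_duplication]


def read_gene_tree(path_or_text: str | Path) -> GeneTree:
    """Parse a Newick/NHX gene tree with duplication annotations.

    Internal (or leaf) nodes may carry an NHX comment such as
    ``[&&NHX:D=Y:T=Euteleostomi:A=420]``.  Leaf names must be unique.
    """
    text = _maybe_read(path_or_text).strip()
    if not text:
        raise ValueError("empty tree input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"malformed Newick/NHX: {exc}") from exc

    def convert(dnode) -> GeneTreeNode:
        ann = {a.name: a.value for a in dnode.annotations}
        age = ann.get("A")
        node = GeneTreeNode(
            name=(dnode.taxon.label if dnode.taxon is not None else dnode.label),
            is_duplication=str(ann.get("D", "N")).upper() == "Y",
            taxon=ann.get("T"),
            age=(float(age) if age is not None else None),
            is_family_founder=str(ann.get("F", "N")).upper() == "Y",
        )
        for child in dnode.child_nodes():
            cnode = convert(child)
            cnode.parent = node
            node.children.append(cnode)
        return node

    tree = GeneTree(convert(dtree.seed_node))
    names = [n for n in tree.leaf_names() if n is not None]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicated leaf names: {sorted(dupes)}")
    return tree


def write_gene_tree(tree: GeneTree, path: str | Path | None = None) -> str:
    """Serialize a gene tree to the NHX dialect read by :func:`read_gene_tree`."""

    def fmt(node: GeneTreeNode) -> str:
        if node.children:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        else:
            body = ""
        label = node.name or ""
        tags = []
        if node.is_duplication:
            tags.append("D=Y")
        if node.taxon is not None:
            tags.append(f"T={node.taxon}")
        if node.age is not None:
            tags.append(f"A={node.age:g}")
        if node.is_family_founder:
            tags.append("F=Y")
        nhx = f"[&&NHX:{':'.join(tags)}]" if tags else ""
        return f"{body}{label}{nhx}"

    text = fmt(tree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
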
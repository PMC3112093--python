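"""Global pairwise protein alignment and conservation summaries.

Human-mouse percent similarity — the fraction of global-alignment columns
whose residue pair scores positively under BLOSUM62 — is the conservation
proxy used throughout the analysis.  This module provides the aligner
(Needleman-Wunsch with affine gaps, Gotoh three-state recurrences), the
similarity/identity definitions, cohort summaries, quintile binning for the
network diagram shading, and per-pathway Tukey-fence outlier detection, which
is the operational definition of the rapidly evolving "adapter" proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .core_io import ProteinRecord

__all__ = [
    "AlignmentResult",
    "ConservationSummary",
    "PathwayOutlier",
    "blosum62",
    "align_global",
    "percent_identity",
    "percent_similarity",
    "conservation_summary",
    "quintile_bins",
    "pathway_outliers",
]

_GAP = "-"


def blosum62():
    """The BLOSUM62 substitution matrix (Biopython Array, indexable by pair)."""
    return substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment of two protein sequences.

    ``score`` is the substitution-score sum minus affine gap penalties, where
    a gap run of length L costs ``gap_open + (L - 1) * gap_extend``.
    """

    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    percent_similarity: float
    gap_columns: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")

    def __len__(self) -> int:
        return len(self.aligned_a)

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.aligned_a, self.aligned_b)


def align_global(
    seq_a: str,
    seq_b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    *,
    penalize_end_gaps: bool = True,
) -> AlignmentResult:
    """Optimal global alignment with affine gap penalties.

    Three-state dynamic programming (match / gap-in-b / gap-in-a) with a
    deterministic traceback preferring diagonal over up (gap in ``seq_b``)
    over left (gap in ``seq_a``).  Defaults reproduce the EMBOSS/EBI "needle"
    settings used for the human-mouse comparisons: BLOSUM62, gap open 10,
    gap extend 0.5, end gaps penalized.  ``penalize_end_gaps=False`` gives
    semi-global (end-gap-free) alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if matrix is None:
        matrix = blosum62()
    alphabet = set(matrix.alphabet)
    for s in (seq_a, seq_b):
        missing = set(s) - alphabet
        if missing:
            raise ValueError(f"residues absent from matrix: {sorted(missing)}")

    n, m = len(seq_a), len(seq_b)
    NEG = -np.inf
    # State matrices: M diagonal, X gap in seq_b (consume a, move down),
    # Y gap in seq_a (consume b, move left->right).
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    # Pointers: 0 from M, 1 from X, 2 from Y; -1 start.
    ptrM = np.full((n + 1, m + 1), -1, dtype=np.int8)
    ptrX = np.full((n + 1, m + 1), -1, dtype=np.int8)
    ptrY = np.full((n + 1, m + 1), -1, dtype=np.int8)

    def gap_cost(length: int) -> float:
        return gap_open + (length - 1) * gap_extend if length > 0 else 0.0

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if not penalize_end_gaps else -gap_cost(i)
        ptrX[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if not penalize_end_gaps else -gap_cost(j)
        ptrY[0, j] = 2 if j > 1 else 0

    for i in range(1, n + 1):
        row_scores = np.array([matrix[seq_a[i - 1], b] for b in seq_b])
        for j in range(1, m + 1):
            s = row_scores[j - 1]
            # Diagonal state: best predecessor, tie-break M > X > Y.
            cands = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(cands))
            M[i, j] = cands[k] + s
            ptrM[i, j] = k
            # Gap in seq_b (vertical). End-column gaps may be free.
            go, ge = (0.0, 0.0) if (not penalize_end_gaps and j == m) else (gap_open, gap_extend)
            cands = (M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            k = int(np.argmax(cands))
            X[i, j] = cands[k]
            ptrX[i, j] = k
            # Gap in seq_a (horizontal).
            go, ge = (0.0, 0.0) if (not penalize_end_gaps and i == n) else (gap_open, gap_extend)
            cands = (M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
            k = int(np.argmax(cands))
            Y[i, j] = cands[k]
            ptrY[i, j] = k

    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))
    score = float(finals[state])

    # Traceback.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            out_a.append(seq_a[i - 1])
            out_b.append(_GAP)
            state = int(ptrX[i, j])
            i -= 1
        else:
            out_a.append(_GAP)
            out_b.append(seq_b[j - 1])
            state = int(ptrY[i, j])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))

    ident = _percent_identity_cols(aligned_a, aligned_b)
    simil = _percent_similarity_cols(aligned_a, aligned_b, matrix)
    gaps = sum(1 for a, b in zip(aligned_a, aligned_b) if a == _GAP or b == _GAP)
    return AlignmentResult(aligned_a, aligned_b, score, ident, simil, gaps)


def _percent_identity_cols(a: str, b: str) -> float:
    same = sum(1 for x, y in zip(a, b) if x == y and x != _GAP)
    return 100.0 * same / len(a)


def _percent_similarity_cols(a: str, b: str, matrix) -> float:
    pos = sum(
        1
        for x, y in zip(a, b)
        if x != _GAP and y != _GAP and matrix[x, y] > 0
    )
    return 100.0 * pos / len(a)


def percent_identity(alignment: AlignmentResult) -> float:
    """Identical columns over all alignment columns (gap columns count in the denominator)."""
    return _percent_identity_cols(alignment.aligned_a, alignment.aligned_b)


def percent_similarity(alignment: AlignmentResult, matrix=None) -> float:
    """Columns with a positive substitution score over all alignment columns.

    Gap columns enter the denominator only (EMBOSS convention); identities
    count as similar because diagonal BLOSUM62 entries are positive.
    """
    if matrix is None:
        matrix = blosum62()
    return _percent_similarity_cols(alignment.aligned_a, alignment.aligned_b, matrix)


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConservationSummary:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    threshold: float
    n_above_threshold: int


def _similarities(records: Sequence[ProteinRecord] | Sequence[float]) -> np.ndarray:
    vals = [
        r.hm_similarity if isinstance(r, ProteinRecord) else float(r) for r in records
    ]
    return np.asarray(vals, dtype=float)


def conservation_summary(
    records: Sequence[ProteinRecord] | Sequence[float], threshold: float = 99.0
) -> ConservationSummary:
    """Mean, sample SD, range and above-threshold count of percent similarity.

    The sample (n-1) standard deviation is used, matching R's ``sd``.
    """
    v = _similarities(records)
    if v.size < 2:
        raise ValueError("need at least 2 records for a summary (sample SD)")
    return ConservationSummary(
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        min=float(v.min()),
        max=float(v.max()),
        threshold=float(threshold),
        n_above_threshold=int((v > threshold).sum()),
    )


def quintile_bins(records: Sequence[ProteinRecord]) -> dict[str, int]:
    """Assign each protein to a similarity quintile, 1 (lowest) to 5 (highest).

    Bins are the five quantile intervals of the empirical distribution, sized
    as equally as possible; tied values all take the lowest bin any of them
    would occupy, so identical inputs always share a bin.
    """
    if len(records) < 5:
        raise ValueError("need at least 5 records for quintiles")
    v = _similarities(records)
    names = [r.abbrev for r in records]
    order = np.argsort(v, kind="stable")
    n = len(v)
    # Provisional bin by rank position: sizes differ by at most 1.
    provisional = np.empty(n, dtype=int)
    edges = [round(k * n / 5) for k in range(6)]
    for b in range(5):
        provisional[order[edges[b] : edges[b + 1]]] = b + 1
    # Ties take the lower bin.
    out: dict[str, int] = {}
    value_bin: dict[float, int] = {}
    for idx in order:
        val = v[idx]
        value_bin.setdefault(val, int(provisional[idx]))
        out[names[idx]] = value_bin[val]
    return out


# ---------------------------------------------------------------------------
# Pathway outliers ("adapter" detection)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayOutlier:
    protein: str
    group: str
    similarity: float
    side: str  # "low" or "high"

    def __iter__(self):  # unpacks as (protein, group)
        return iter((self.protein, self.group))


def pathway_outliers(
    records: Sequence[ProteinRecord],
    grouping: Mapping[str, str],
    *,
    k: float = 1.5,
) -> list[PathwayOutlier]:
    """Tukey-fence outliers of percent similarity within each pathway group.

    A protein is flagged when its similarity falls below Q1 - k*IQR or above
    Q3 + k*IQR of its group, with quartiles by linear interpolation.  Groups
    with fewer than 4 members yield no outliers and a warning, since fences
    from so few points are not meaningful.
    """
    if not grouping:
        raise ValueError("empty grouping")
    by_group: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        if rec.abbrev in grouping:
            by_group.setdefault(grouping[rec.abbrev], []).append(rec)
    outliers: list[PathwayOutlier] = []
    for group in sorted(by_group):
        members = by_group[group]
        if len(members) < 4:
            warnings.warn(
                f"group {group!r} has {len(members)} members (<4); no fences computed",
                stacklevel=2,
            )
            continue
        vals = _similarities(members)
        q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        for rec in members:
            if rec.hm_similarity < lo:
                outliers.append(PathwayOutlier(rec.abbrev, group, rec.hm_similarity, "low"))
            elif rec.hm_similarity > hi:
                outliers.append(PathwayOutlier(rec.abbrev, group, rec.hm_similarity, "high"))
    return outliers
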
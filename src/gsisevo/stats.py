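"""The statistical battery over protein records.

Covers the divergence analyses reported for the network: one-way ANOVA of
human-mouse similarity across sub-pathway groups (with an optional sequential
multi-factor decomposition), Tukey HSD pairwise comparisons, Spearman rank
correlation of divergence against duplication counts, and the disease-gene
comparisons (similarity t-test, Universal-proportion goodness of fit, and the
positive-selection 2x2 table).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core_io import ProteinRecord

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "CorrelationResult",
    "GROUPING_SCHEMES",
    "assign_anova_groups",
    "divergence_anova",
    "multifactor_anova",
    "tukey_hsd",
    "spearman_correlation",
    "disease_comparisons",
]

# Grouping schemes for the pathway ANOVA.  Multi-pathway proteins take their
# first-listed code.  six_group merges pyruvate cycle and NADH shuttle (P∪N,
# label "PN"); the boxplot scheme additionally merges the TCA cycle in ("TPN").
GROUPING_SCHEMES = ("six_group", "five_group_figure3")


def assign_anova_groups(
    records: Sequence[ProteinRecord], scheme: str = "six_group"
) -> dict[str, str]:
    """Map each protein to its analysis group under the chosen scheme."""
    if scheme not in GROUPING_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    out = {}
    for rec in records:
        if not rec.pathways:
            raise ValueError(f"{rec.abbrev}: no pathway codes")
        code = rec.primary_pathway.value
        if scheme == "six_group":
            group = {"P": "PN", "N": "PN"}.get(code, code)
        else:
            group = {"T": "TPN", "P": "TPN", "N": "TPN"}.get(code, code)
        out[rec.abbrev] = group
    return out


@dataclass(frozen=True)
class AnovaResult:
    factor: str
    f_statistic: float
    df_between: int
    df_within: int
    p: float
    group_means: Mapping[str, float]


def _group_values(
    records: Sequence[ProteinRecord], grouping: Mapping[str, str]
) -> dict[str, np.ndarray]:
    by_group: dict[str, list[float]] = {}
    for rec in records:
        if rec.abbrev in grouping:
            by_group.setdefault(grouping[rec.abbrev], []).append(rec.hm_similarity)
    return {g: np.asarray(v, float) for g, v in by_group.items()}


def divergence_anova(
    records: Sequence[ProteinRecord],
    grouping: Mapping[str, str],
    factor: str = "pathway",
) -> AnovaResult:
    """One-way fixed-effects ANOVA of percent similarity across groups."""
    groups = _group_values(records, grouping)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    values = list(groups.values())
    if all(len(v) < 2 for v in values):
        raise ValueError("need at least one group with >= 2 members")
    grand = np.concatenate(values)
    if np.ptp(grand) == 0:
        raise ValueError("F undefined: zero between- and within-group variance")
    f, p = sps.f_oneway(*values)
    n = grand.size
    return AnovaResult(
        factor=factor,
        f_statistic=float(f),
        df_between=len(groups) - 1,
        df_within=n - len(groups),
        p=float(p),
        group_means={g: float(v.mean()) for g, v in groups.items()},
    )


def multifactor_anova(
    records: Sequence[ProteinRecord],
    grouping: Mapping[str, str],
    factors: Sequence[str] = ("pathway", "phylo_class", "positive_selection", "disease"),
) -> pd.DataFrame:
    """Sequential (type-I) ANOVA of similarity on several factors at once.

    Factors are entered in the given order; available names: ``pathway`` (the
    supplied grouping), ``phylo_class``, ``n_duplications`` (skipped when
    missing for any record), ``positive_selection``, ``disease``.  Returns the
    statsmodels ANOVA table.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "similarity": rec.hm_similarity,
                "pathway": grouping.get(rec.abbrev),
                "phylo_class": rec.phylo_class.value,
                "n_duplications": rec.n_duplications,
                "positive_selection": int(rec.has_positive_selection),
                "disease": int(rec.has_disease),
            }
        )
    df = pd.DataFrame(rows)
    terms = []
    for f in factors:
        if f == "n_duplications" and df["n_duplications"].isna().any():
            continue
        terms.append(f"C({f})" if f in ("pathway", "phylo_class") else f)
    model = smf.ols("similarity ~ " + " + ".join(terms), data=df).fit()
    return sm.stats.anova_lm(model, typ=1)


@dataclass(frozen=True)
class TukeyResult:
    """All pairwise group comparisons with studentized-range adjusted p."""

    pairs: tuple[tuple[str, str, float, float], ...]  # (a, b, mean b-a, p_adj)
    alpha: float

    def significant(self) -> list[tuple[str, str, float, float]]:
        return [p for p in self.pairs if p[3] < self.alpha]

    def p_adjusted(self, a: str, b: str) -> float:
        for ga, gb, _, p in self.pairs:
            if {ga, gb} == {a, b}:
                return p
        raise KeyError((a, b))


def tukey_hsd(
    records: Sequence[ProteinRecord],
    grouping: Mapping[str, str],
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey honest-significant-difference test across all group pairs."""
    groups = _group_values(records, grouping)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
    if np.ptp(values) == 0:
        raise ValueError("Tukey HSD undefined: zero total variance")
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    # statsmodels orders pairs as combinations of the sorted unique groups
    combos = list(itertools.combinations(res.groupsunique, 2))
    pairs = tuple(
        (str(a), str(b), float(diff), float(p))
        for (a, b), diff, p in zip(combos, res.meandiffs, res.pvalues)
    )
    return TukeyResult(pairs=pairs, alpha=alpha)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_two_tailed: float
    n: int


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], *, exact_max_n: int = 9
) -> CorrelationResult:
    """Spearman rank correlation with a two-tailed p-value.

    Ties take midranks.  For n ≤ ``exact_max_n`` the permutation null is
    enumerated exactly; for larger n the t approximation is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        # Exact permutation null of the rank-Pearson statistic.
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        obs = abs(float(rx_c @ ry_c))
        perms = np.array(list(itertools.permutations(range(n))))
        stats_all = np.abs(rx_c[perms] @ ry_c)
        p = float(np.mean(stats_all >= obs - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_two_tailed=min(1.0, p), n=n)


def disease_comparisons(
    records: Sequence[ProteinRecord],
    *,
    equal_var: bool = False,
    yates: bool = False,
) -> dict[str, float]:
    """Compare disease-associated proteins with the rest of the network.

    Three comparisons: (i) two-sample t-test of percent similarity, Welch by
    default (R's ``t.test`` convention; ``equal_var=True`` pools variances);
    (ii) chi-squared goodness of fit of the Universal proportion among disease
    genes against the whole network's proportion; (iii) chi-squared (1 df) of
    positive-selection history vs disease membership from the 2x2 table.
    """
    disease = [r for r in records if r.has_disease]
    other = [r for r in records if not r.has_disease]
    if len(disease) < 2 or len(other) < 2:
        raise ValueError("need >= 2 records in both arms")
    vd = np.array([r.hm_similarity for r in disease])
    vo = np.array([r.hm_similarity for r in other])
    t_res = sps.ttest_ind(vd, vo, equal_var=equal_var)

    n_dis_u = sum(1 for r in disease if r.phylo_class.value == "U")
    n_all_u = sum(1 for r in records if r.phylo_class.value == "U")
    p_u = n_all_u / len(records)
    if 0.0 < p_u < 1.0:
        exp = [len(disease) * p_u, len(disease) * (1 - p_u)]
        chi2_u, p_chi2_u = sps.chisquare([n_dis_u, len(disease) - n_dis_u], f_exp=exp)
    else:
        # Degenerate reference (every record, or none, is Universal).
        chi2_u, p_chi2_u = float("nan"), float("nan")

    table = np.array(
        [
            [
                sum(1 for r in disease if r.has_positive_selection),
                sum(1 for r in disease if not r.has_positive_selection),
            ],
            [
                sum(1 for r in other if r.has_positive_selection),
                sum(1 for r in other if not r.has_positive_selection),
            ],
        ]
    )
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2_ps, p_ps, _, _ = sps.chi2_contingency(table, correction=yates)
    else:
        chi2_ps, p_ps = float("nan"), float("nan")

    return {
        "n_disease": len(disease),
        "n_other": len(other),
        "mean_disease": float(vd.mean()),
        "mean_other": float(vo.mean()),
        "t_statistic": float(t_res.statistic),
        "t_p": float(t_res.pvalue),
        "n_disease_universal": int(n_dis_u),
        "class_chi2": float(chi2_u),
        "class_chi2_p": float(p_chi2_u),
        "possel_chi2": float(chi2_ps),
        "possel_chi2_p": float(p_ps),
    }
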
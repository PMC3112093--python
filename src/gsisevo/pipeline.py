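"""End-to-end orchestration of the network evolution analysis.

``run_full_analysis`` runs every stage the provided inputs allow, in the order
the results are reported: conservation summary and quintiles, class
composition and the composition test, shared-homologue clusters (when a hit
table is given), duplication vectors / dendrogram / group tests (when gene
trees are given), pathway ANOVA with Tukey HSD, divergence-duplication
correlation (when duplication counts are present), and the disease
comparisons.  Stages whose inputs are missing are marked skipped with a
warning, never silently omitted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import conservation, duplication, profiles, stats
from .core_io import ProteinRecord, StudyFixture, load_fixture, read_gene_tree, read_hit_table

__all__ = ["RunConfig", "run_full_analysis", "REPORT_SCHEMA_VERSION"]

log = logging.getLogger("gsisevo")

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """Inputs and parameters of a full analysis run."""

    fixture: str | None = "gsis69"
    hit_table: str | Path | None = None
    tree_paths: Mapping[str, str | Path] | None = None  # gene -> NHX path
    evalue_cutoff: float = 10.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    grouping_scheme: str = "six_group"
    alpha: float = 0.05
    linkage: str = "complete"
    min_shared: int = 1
    n_pathway_groups_tested: int = 7
    seed: int = 0
    output_dir: str | Path | None = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.grouping_scheme not in stats.GROUPING_SCHEMES:
            raise ValueError(f"unknown grouping scheme {self.grouping_scheme!r}")
        for path in self._paths():
            if not Path(path).exists():
                raise FileNotFoundError(path)

    def _paths(self):
        if self.hit_table is not None:
            yield self.hit_table
        if self.tree_paths:
            yield from self.tree_paths.values()


def _skip(report: dict, stage: str, reason: str) -> None:
    log.warning("stage %s skipped: %s", stage, reason)
    report["stages"][stage] = {"status": "skipped", "reason": reason}


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage the config's inputs support; return the JSON-able report."""
    config.validate()
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "tree_paths"
        },
        "stages": {},
    }

    fixture: StudyFixture | None = load_fixture(config.fixture) if config.fixture else None
    records: Sequence[ProteinRecord] = fixture.records if fixture else ()
    log.info("loaded %d protein records", len(records))

    # --- conservation -----------------------------------------------------
    if len(records) >= 2:
        summ = conservation.conservation_summary(records, threshold=99.0)
        quint = conservation.quintile_bins(records)
        grouping_fig3 = stats.assign_anova_groups(records, "five_group_figure3")
        outliers = conservation.pathway_outliers(records, grouping_fig3)
        report["stages"]["conservation"] = {
            "status": "ok",
            "summary": dataclasses.asdict(summ),
            "quintile_bins": quint,
            "outliers": [dataclasses.asdict(o) for o in outliers],
        }
        log.info("conservation: n=%d mean=%.2f sd=%.2f", summ.n, summ.mean, summ.sd)
    else:
        _skip(report, "conservation", "no protein records")

    # --- class composition ------------------------------------------------
    if records and fixture is not None:
        comp = profiles.class_composition(records)
        test = profiles.compare_composition(
            comp["counts"], fixture.genome_reference_proportions
        )
        report["stages"]["composition"] = {
            "status": "ok",
            "composition": comp,
            "test": dataclasses.asdict(test),
        }
        log.info("composition: %s chi2=%.2f p=%.4g", comp["counts"], test.chi2, test.p)
    else:
        _skip(report, "composition", "no records/reference proportions")

    # --- shared-homologue clusters ----------------------------------------
    if config.hit_table is not None:
        hits = read_hit_table(Path(config.hit_table), evalue_cutoff=config.evalue_cutoff)
        profs = [profiles.profile_from_hits(p, h) for p, h in hits.items()]
        clusters = profiles.shared_homolog_clusters(profs, min_shared=config.min_shared)
        report["stages"]["shared_homolog_clusters"] = {
            "status": "ok",
            "n_proteins": len(profs),
            "clusters": [
                {"members": sorted(c), "max_shared": s} for c, s in clusters
            ],
        }
        log.info("clusters: %d components from %d proteins", len(clusters), len(profs))
    else:
        _skip(report, "shared_homolog_clusters", "no hit table given")

    # --- duplication history ----------------------------------------------
    if config.tree_paths:
        vectors = []
        for gene, path in config.tree_paths.items():
            tree = read_gene_tree(Path(path))
            vectors.append(duplication.extract_duplication_vector(tree, gene))
        genes, dm = duplication.euclidean_distance_matrix(vectors)
        z = duplication.hierarchical_cluster(dm, linkage=config.linkage)
        ident = duplication.identical_history_groups(genes, dm, linkage=config.linkage)
        grouping = (
            stats.assign_anova_groups(records, config.grouping_scheme) if records else {}
        )
        group_tests = []
        tested = sorted(
            {g for g in grouping.values() if sum(v == g for v in grouping.values()) >= 2}
        )
        for grp in tested:
            if not set(genes) & {g for g, gg in grouping.items() if gg == grp}:
                continue
            try:
                res = duplication.group_clustering_test(
                    genes, dm, grouping, grp, n_groups_tested=len(tested), alpha=config.alpha
                )
            except ValueError:
                continue
            group_tests.append(dataclasses.asdict(res))
        report["stages"]["duplication"] = {
            "status": "ok",
            "genes": genes,
            "vectors": {v.gene: list(v.counts) for v in vectors},
            "dendrogram_newick": duplication.dendrogram_newick(genes, z),
            "identical_history_groups": [sorted(g) for g in ident],
            "group_tests": group_tests,
        }
        log.info("duplication: %d vectors, %d zero-height groups", len(vectors), len(ident))
    else:
        _skip(report, "duplication", "no gene trees given")

    # --- ANOVA / Tukey ----------------------------------------------------
    if len(records) >= 3:
        grouping = stats.assign_anova_groups(records, config.grouping_scheme)
        anova = stats.divergence_anova(records, grouping)
        tukey = stats.tukey_hsd(records, grouping, alpha=config.alpha)
        report["stages"]["anova"] = {
            "status": "ok",
            "anova": dataclasses.asdict(anova),
            "tukey": {
                "alpha": tukey.alpha,
                "pairs": [list(p) for p in tukey.pairs],
                "significant": [list(p) for p in tukey.significant()],
            },
        }
        log.info("anova: F=%.2f df=(%d,%d) p=%.2g", anova.f_statistic,
                 anova.df_between, anova.df_within, anova.p)
    else:
        _skip(report, "anova", "fewer than 3 records")

    # --- divergence vs duplication correlation ----------------------------
    with_dups = [r for r in records if r.n_duplications is not None]
    if len(with_dups) >= 3:
        corr = stats.spearman_correlation(
            [r.hm_similarity for r in with_dups],
            [r.n_duplications for r in with_dups],
        )
        report["stages"]["correlation"] = {"status": "ok", **dataclasses.asdict(corr)}
        log.info("correlation: rho=%.3f p=%.3g n=%d", corr.rho, corr.p_two_tailed, corr.n)
    else:
        _skip(report, "correlation", "duplication counts missing")

    # --- disease comparisons ----------------------------------------------
    if records and any(r.has_disease for r in records):
        report["stages"]["disease"] = {
            "status": "ok",
            **stats.disease_comparisons(records),
        }
    else:
        _skip(report, "disease", "no disease annotations")

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        _write_tsv_tables(report, outdir)
    return report


def _write_tsv_tables(report: dict, outdir: Path) -> None:
    stages = report["stages"]
    if stages.get("conservation", {}).get("status") == "ok":
        with (outdir / "quintiles.tsv").open("w") as fh:
            fh.write("protein\tquintile\n")
            for prot, b in stages["conservation"]["quintile_bins"].items():
                fh.write(f"{prot}\t{b}\n")
    if stages.get("duplication", {}).get("status") == "ok":
        dup = stages["duplication"]
        with (outdir / "duplication_vectors.tsv").open("w") as fh:
            for gene, counts in dup["vectors"].items():
                fh.write(gene + "\t" + "\t".join(map(str, counts)) + "\n")
        (outdir / "dendrogram.nwk").write_text(dup["dendrogram_newick"] + "\n")
    if stages.get("anova", {}).get("status") == "ok":
        with (outdir / "tukey.tsv").open("w") as fh:
            fh.write("group_a\tgroup_b\tmean_diff\tp_adj\n")
            for a, b, d, p in stages["anova"]["tukey"]["pairs"]:
                fh.write(f"{a}\t{b}\t{d:.4f}\t{p:.4g}\n")
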
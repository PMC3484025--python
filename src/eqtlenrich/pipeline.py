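"""Study-level orchestration: the full analysis grid plus pooled summaries.

Runs the enrichment test for every (GWAS analysis x eQTL tissue)
combination, pools the annotated rows of the designated tissues, and
produces the descriptive SNP-level and gene-level summaries and tissue
overlap reports.  Each combination is tested independently with its own
resampled null; no cross-tissue multiplicity correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import annotate_hits
from .config import EnrichmentConfig
from .enrichment import EnrichmentResult, EqtlEnrichment
from .io import GwasHitList, SnpUniverse
from .summarize import (
    GeneSummary,
    MultiplicityTotals,
    OverlapReport,
    RegulationBreakdown,
    collapse_genes,
    fisher_overlap,
    overlap_counts,
    pool_annotated,
    regulation_breakdown,
    snp_multiplicity,
)

__all__ = ["StudyResult", "run_study"]

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """All per-combination enrichment results plus pooled descriptives.

    ``enrichment[(analysis, tissue)]`` holds the fitted
    :class:`~eqtlenrich.enrichment.EnrichmentResult`; the pooled summaries
    cover the ``pooled_tissues`` passed to :func:`run_study` (by default the
    brain tissues, matching how such studies pool their tissue-enriched
    hits).
    """

    enrichment: dict
    pooled: pd.DataFrame
    multiplicity: MultiplicityTotals
    per_snp_genes: pd.Series
    regulation: RegulationBreakdown
    gene_summaries: list
    tissue_overlaps: list
    pooled_tissues: tuple

    def p_table(self) -> pd.DataFrame:
        """Empirical enrichment P-values, analyses x tissues."""
        analyses = sorted({a for a, _ in self.enrichment})
        tissues = sorted({t for _, t in self.enrichment})
        return pd.DataFrame(
            [
                [self.enrichment[(a, t)].empirical_p for t in tissues]
                for a in analyses
            ],
            index=analyses,
            columns=tissues,
        )

    def summary(self) -> str:
        lines = ["Enrichment P-values (empirical, MAF-matched null)", ""]
        table = self.p_table()
        display = table.copy().astype(object)
        for a in table.index:
            for t in table.columns:
                display.loc[a, t] = self.enrichment[(a, t)].p_display
        lines.append(display.to_string())
        m = self.multiplicity
        lines += [
            "",
            f"Pooled tissues: {', '.join(self.pooled_tissues)}",
            f"pooled eQTL rows: {m.total_rows}",
            f"distinct eQTL SNPs: {m.distinct_rsids}",
            f"  single-target: {m.single_target} ({m.pct_single_target}%)"
            f"   multi-target: {m.multi_target} ({m.pct_multi_target}%)",
            f"distinct target genes: {len(self.gene_summaries)}",
        ]
        for rep in self.tissue_overlaps:
            lines.append(
                f"overlap {rep.set_a_label}/{rep.set_b_label}: "
                f"{rep.n_intersection} of {rep.n_a}/{rep.n_b} genes "
                f"(Fisher two-sided P = {rep.fisher_p:.3g})"
            )
        return "\n".join(lines)


def run_study(
    universe: SnpUniverse,
    eqtl_tables: Mapping[str, pd.DataFrame],
    hit_lists: Sequence[GwasHitList],
    config: EnrichmentConfig | None = None,
    pooled_tissues: Iterable[str] | None = None,
    gene_universe_size: int | None = None,
    n_sets: int | None = None,
    seed: int | None = None,
) -> StudyResult:
    """Run the whole pipeline over an analysis grid.

    Parameters
    ----------
    universe, eqtl_tables, hit_lists
        The three study inputs: platform manifest, per-tissue raw eQTL
        tables, and one hit list per GWAS primary analysis.
    pooled_tissues
        Tissues whose annotated rows enter the pooled descriptive
        summaries; defaults to every non-LCL tissue (all tissues if that
        leaves none).
    gene_universe_size
        Gene universe for the Fisher overlap tests; defaults to the number
        of distinct genes appearing anywhere in the raw eQTL tables (the
        testable panel).  P-values depend on this choice, so pass the
        expression platform's gene count when it is known.
    seed
        Master seed; combination ``i`` of the grid uses ``seed + i`` so the
        nulls are independent but the whole study is reproducible.
    """
    config = config or EnrichmentConfig()
    seed = config.seed if seed is None else int(seed)
    tissues = list(eqtl_tables)
    if pooled_tissues is None:
        pooled_tissues = [t for t in tissues if t.lower() != "lcl"] or tissues
    pooled_tissues = tuple(pooled_tissues)

    enrichment: dict = {}
    pooled_parts = []
    for i, (hits, tissue) in enumerate(
        [(h, t) for h in hit_lists for t in tissues]
    ):
        model = EqtlEnrichment(
            hits, eqtl_tables[tissue], universe, config=config, tissue=tissue
        )
        res = model.fit(n_sets=n_sets, seed=seed + i)
        enrichment[(hits.analysis_label, tissue)] = res
        if tissue in pooled_tissues:
            pooled_parts.append(res.annotation.annotated)

    pooled = pool_annotated(pooled_parts)
    per_snp, totals = snp_multiplicity(pooled)
    regulation = regulation_breakdown(pooled)
    gene_summaries = collapse_genes(pooled)

    # per-tissue gene sets over the full grid (not only pooled tissues)
    all_annotated = pool_annotated(
        [r.annotation.annotated for r in enrichment.values()]
    )
    gene_sets = {
        t: set(all_annotated.loc[all_annotated["tissue"] == t, "gene"])
        for t in tissues
    }
    gene_sets = {t: s for t, s in gene_sets.items() if s}
    overlaps = []
    if len(gene_sets) >= 2:
        counts = overlap_counts(gene_sets)
        testable = set()
        for table in eqtl_tables.values():
            if len(table):
                testable |= set(table["gene"])
        n_universe_genes = gene_universe_size or len(testable)
        for (a, b), n_int in counts["pairs"].items():
            overlaps.append(
                OverlapReport(
                    set_a_label=a,
                    set_b_label=b,
                    n_a=counts["sizes"][a],
                    n_b=counts["sizes"][b],
                    n_intersection=n_int,
                    universe_size=max(
                        n_universe_genes,
                        counts["sizes"][a] + counts["sizes"][b] - n_int,
                    ),
                    fisher_p=fisher_overlap(
                        counts["sizes"][a],
                        counts["sizes"][b],
                        n_int,
                        max(
                            n_universe_genes,
                            counts["sizes"][a] + counts["sizes"][b] - n_int,
                        ),
                    ),
                )
            )

    return StudyResult(
        enrichment=enrichment,
        pooled=pooled,
        multiplicity=totals,
        per_snp_genes=per_snp,
        regulation=regulation,
        gene_summaries=gene_summaries,
        tissue_overlaps=overlaps,
        pooled_tissues=pooled_tissues,
    )
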
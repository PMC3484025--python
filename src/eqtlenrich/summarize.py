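"""Descriptive summaries of annotated eQTL hits.

After each GWAS analysis x tissue combination has been annotated, the rows
are pooled (with provenance) and summarised the way such studies report
them: distinct eQTL SNPs vs. raw pooled rows, per-SNP target multiplicity,
cis/trans composition within the single- and multi-target strata,
gene-level collapsing (how many distinct SNPs implicate each gene, across
how many analyses and tissues), pairwise and all-way overlaps of per-tissue
gene sets with Fisher's exact test, and intersection with an external gene
list.

Counting conventions: "unique eQTL SNPs" are distinct rsids pooled across
tissues and analyses; SNP-gene pairs are counted separately and labelled as
such.  All counts use set semantics, so they are invariant to row order and
duplicated rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError

__all__ = [
    "pool_annotated",
    "MultiplicityTotals",
    "snp_multiplicity",
    "RegulationBreakdown",
    "regulation_breakdown",
    "GeneSummary",
    "collapse_genes",
    "overlap_counts",
    "fisher_overlap",
    "OverlapReport",
    "gene_list_intersection",
]

logger = logging.getLogger(__name__)

_POOL_COLUMNS = ["analysis_label", "tissue", "rsid", "gene", "regulation"]


def pool_annotated(hit_tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-analysis annotated tables, preserving (analysis,
    tissue) provenance; total row count is the sum of the inputs."""
    tables = [t for t in hit_tables]
    if not tables:
        return pd.DataFrame(columns=_POOL_COLUMNS)
    pooled = pd.concat(tables, ignore_index=True)
    missing = [c for c in _POOL_COLUMNS if c not in pooled.columns]
    if missing:
        raise ValidationError(f"pooled table missing column(s): {missing}")
    return pooled.reset_index(drop=True)


@dataclass(frozen=True)
class MultiplicityTotals:
    """SNP-level multiplicity tallies over a pooled table."""

    total_rows: int
    distinct_snp_gene_pairs: int
    distinct_rsids: int
    single_target: int
    multi_target: int

    @property
    def pct_single_target(self) -> int:
        """Single-target share of distinct rsids, to the nearest integer
        percent (0 when there are no SNPs)."""
        if self.distinct_rsids == 0:
            return 0
        return round(100 * self.single_target / self.distinct_rsids)

    @property
    def pct_multi_target(self) -> int:
        if self.distinct_rsids == 0:
            return 0
        return round(100 * self.multi_target / self.distinct_rsids)


def snp_multiplicity(pooled: pd.DataFrame) -> tuple[pd.Series, MultiplicityTotals]:
    """Distinct-target-gene count per rsid, with totals.

    Returns ``(per_rsid, totals)`` where ``per_rsid`` maps each distinct
    rsid to its number of distinct target genes (pooled over tissues and
    analyses) and ``totals`` partitions the distinct rsids into
    single-target and multi-target strata.
    """
    if len(pooled) == 0:
        empty = pd.Series(dtype=np.int64, name="n_genes")
        return empty, MultiplicityTotals(0, 0, 0, 0, 0)
    per_rsid = (
        pooled.groupby("rsid")["gene"].nunique().astype(np.int64).rename("n_genes")
    )
    per_rsid = per_rsid.sort_values(ascending=False, kind="stable").sort_index(
        kind="stable"
    )
    single = int((per_rsid == 1).sum())
    multi = int((per_rsid > 1).sum())
    totals = MultiplicityTotals(
        total_rows=len(pooled),
        distinct_snp_gene_pairs=int(len(pooled.drop_duplicates(["rsid", "gene"]))),
        distinct_rsids=int(per_rsid.size),
        single_target=single,
        multi_target=multi,
    )
    return per_rsid, totals


@dataclass(frozen=True)
class RegulationBreakdown:
    """Cis/trans composition at SNP level, stratified by target
    multiplicity.

    Single-target SNPs are either cis or trans; multi-target SNPs split
    into all-cis, all-trans and mixed regulators.  Within each stratum the
    classes are disjoint and exhaustive.
    """

    single_cis: int
    single_trans: int
    multi_cis_only: int
    multi_trans_only: int
    multi_mixed: int

    @property
    def single_total(self) -> int:
        return self.single_cis + self.single_trans

    @property
    def multi_total(self) -> int:
        return self.multi_cis_only + self.multi_trans_only + self.multi_mixed


def regulation_breakdown(pooled: pd.DataFrame) -> RegulationBreakdown:
    """Classify every distinct SNP by the regulation classes of its pooled
    rows (cis-only / trans-only / both), within single- and multi-target
    strata."""
    if len(pooled) == 0:
        return RegulationBreakdown(0, 0, 0, 0, 0)
    bad = set(pooled["regulation"]) - {"cis", "trans"}
    if bad:
        raise ValidationError(f"unknown regulation class(es): {sorted(bad)}")
    per = pooled.groupby("rsid").agg(
        n_genes=("gene", "nunique"), classes=("regulation", lambda s: frozenset(s))
    )
    single = per["n_genes"] == 1
    has_cis = per["classes"].map(lambda c: "cis" in c)
    has_trans = per["classes"].map(lambda c: "trans" in c)
    return RegulationBreakdown(
        single_cis=int((single & has_cis & ~has_trans).sum()),
        single_trans=int((single & has_trans & ~has_cis).sum()),
        multi_cis_only=int((~single & has_cis & ~has_trans).sum()),
        multi_trans_only=int((~single & has_trans & ~has_cis).sum()),
        multi_mixed=int((~single & has_cis & has_trans).sum()),
    )


@dataclass(frozen=True)
class GeneSummary:
    """Gene-level collapse of pooled annotated eQTL rows: every distinct
    SNP implicating the gene, in which tissues/analyses, and by which
    regulation class(es)."""

    gene: str
    tissues: frozenset
    analyses: frozenset
    regulation_classes: frozenset
    snp_rsids: frozenset

    def __post_init__(self) -> None:
        for name in ("tissues", "analyses", "regulation_classes", "snp_rsids"):
            object.__setattr__(self, name, frozenset(getattr(self, name)))
        if not self.snp_rsids or not self.tissues or not self.analyses:
            raise ValidationError(f"gene {self.gene!r}: summary sets must be non-empty")

    @property
    def n_distinct_snps(self) -> int:
        return len(self.snp_rsids)


def collapse_genes(pooled: pd.DataFrame) -> list[GeneSummary]:
    """One :class:`GeneSummary` per distinct target gene, sorted by the
    number of distinct implicating SNPs (descending, ties broken
    lexicographically by gene label for deterministic output)."""
    if len(pooled) == 0:
        return []
    grouped = pooled.groupby("gene").agg(
        tissues=("tissue", lambda s: frozenset(s)),
        analyses=("analysis_label", lambda s: frozenset(s)),
        regulation_classes=("regulation", lambda s: frozenset(s)),
        snp_rsids=("rsid", lambda s: frozenset(s)),
    )
    summaries = [
        GeneSummary(
            gene=str(gene),
            tissues=row.tissues,
            analyses=row.analyses,
            regulation_classes=row.regulation_classes,
            snp_rsids=row.snp_rsids,
        )
        for gene, row in grouped.iterrows()
    ]
    return sorted(summaries, key=lambda g: (-g.n_distinct_snps, g.gene))


def overlap_counts(gene_sets: Mapping[str, Iterable]) -> dict:
    """Pairwise and all-way intersections of labelled sets.

    Returns ``{"sizes": {label: n}, "pairs": {(a, b): n}, "all_way": n}``
    with pairs keyed in input-label order.
    """
    labels = list(gene_sets)
    if len(labels) < 2:
        raise ValidationError("overlap_counts needs at least two sets")
    sets = {k: set(v) for k, v in gene_sets.items()}
    pairs = {
        (a, b): len(sets[a] & sets[b])
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }
    all_way = len(set.intersection(*sets.values()))
    return {
        "sizes": {k: len(v) for k, v in sets.items()},
        "pairs": pairs,
        "all_way": all_way,
    }


@dataclass(frozen=True)
class OverlapReport:
    """Overlap of two labelled sets against a common universe, optionally
    with a two-sided Fisher exact P-value."""

    set_a_label: str
    set_b_label: str
    n_a: int
    n_b: int
    n_intersection: int
    universe_size: int
    fisher_p: float | None = None
    n_unmatched: int = 0

    def __post_init__(self) -> None:
        if not (
            0 <= self.n_intersection <= min(self.n_a, self.n_b) <= self.universe_size
        ):
            raise ValidationError(
                "inconsistent overlap counts: need n_int <= min(n_a, n_b) <= N"
            )


def fisher_overlap(
    n_a: int, n_b: int, n_intersection: int, universe_size: int
) -> float:
    """Two-sided Fisher's exact test for the overlap of two sets drawn from
    a universe of ``universe_size`` elements.

    The 2x2 table is ``[[n_int, n_a - n_int], [n_b - n_int,
    N - n_a - n_b + n_int]]``; the two-sided P is the sum of probabilities
    of all tables no more likely than the observed one (the common
    convention).  Degenerate margins give P = 1.
    """
    if min(n_a, n_b, n_intersection, universe_size) < 0:
        raise ValidationError("overlap counts must be non-negative")
    if n_intersection > min(n_a, n_b):
        raise ValidationError("n_intersection exceeds a set size")
    if universe_size < n_a + n_b - n_intersection:
        raise ValidationError(
            f"universe_size {universe_size} smaller than the union "
            f"{n_a + n_b - n_intersection}"
        )
    table = np.array(
        [
            [n_intersection, n_a - n_intersection],
            [n_b - n_intersection, universe_size - n_a - n_b + n_intersection],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(min(p, 1.0))


def gene_list_intersection(
    summaries: Sequence[GeneSummary],
    external_genes: Iterable[str],
    external_label: str = "external",
    summary_label: str = "eqtl_targets",
) -> OverlapReport:
    """Intersect the collapsed gene set with an external gene list.

    Matching is case-insensitive on gene symbol; duplicate external symbols
    are deduplicated (and logged) before counting.  No Fisher test is run —
    external lists rarely share a well-defined universe with the eQTL
    panel — so ``universe_size`` is the union size and ``fisher_p`` is None.
    """
    external = [str(g) for g in external_genes]
    if not external:
        raise ValidationError("external gene list must be non-empty")
    ext_norm = {}
    for g in external:
        ext_norm.setdefault(g.casefold(), g)
    n_dupes = len(external) - len(ext_norm)
    if n_dupes:
        logger.info(
            "gene_list_intersection: %d duplicate external symbol(s) removed", n_dupes
        )
    ours = {g.gene.casefold(): g.gene for g in summaries}
    inter = set(ours) & set(ext_norm)
    return OverlapReport(
        set_a_label=summary_label,
        set_b_label=external_label,
        n_a=len(ours),
        n_b=len(ext_norm),
        n_intersection=len(inter),
        universe_size=len(set(ours) | set(ext_norm)),
        fisher_p=None,
        n_unmatched=len(ext_norm) - len(inter),
    )
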
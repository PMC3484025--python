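"""Pooling, multiplicity, gene collapsing, overlaps and Fisher's test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eqtlenrich import (
    ValidationError,
    collapse_genes,
    fisher_overlap,
    gene_list_intersection,
    overlap_counts,
    pool_annotated,
    regulation_breakdown,
    snp_multiplicity,
)


def rows(*triples, analysis="a1", tissue="parietal"):
    """(rsid, gene, regulation) triples -> pooled-format frame."""
    return pd.DataFrame(
        [
            {
                "analysis_label": analysis,
                "tissue": tissue,
                "rsid": r,
                "gene": g,
                "regulation": reg,
            }
            for r, g, reg in triples
        ]
    )


def hypergeom_two_sided(n_a, n_b, n_int, N):
    """Independent oracle: enumerate the hypergeometric support and sum the
    probabilities of all tables no more likely than the observed one."""
    lo = max(0, n_a + n_b - N)
    hi = min(n_a, n_b)
    denom = math.comb(N, n_b)
    pmf = {
        k: math.comb(n_a, k) * math.comb(N - n_a, n_b - k) / denom
        for k in range(lo, hi + 1)
    }
    p_obs = pmf[n_int]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


class TestPoolAnnotated:
    def test_additivity_with_provenance(self):
        parts = [
            rows(("s1", "gA", "cis"), ("s2", "gA", "cis"), analysis="a1"),
            rows(("s1", "gA", "cis"), analysis="a2"),
            rows(analysis="a3"),
        ]
        pooled = pool_annotated(parts)
        assert len(pooled) == 3
        # same (rsid, gene, tissue) from two analyses stays as two rows
        assert set(pooled["analysis_label"]) == {"a1", "a2"}

    def test_empty_input(self):
        assert len(pool_annotated([])) == 0


class TestSnpMultiplicity:
    def test_direct_count(self):
        pooled = rows(("s1", "gA", "cis"), ("s1", "gB", "cis"), ("s2", "gA", "cis"))
        per, totals = snp_multiplicity(pooled)
        assert per["s1"] == 2 and per["s2"] == 1
        assert totals.distinct_rsids == 2
        assert totals.single_target == 1 and totals.multi_target == 1
        assert totals.total_rows == 3

    def test_duplicated_rows_do_not_inflate(self):
        pooled = rows(
            ("s1", "gA", "cis"),
            ("s1", "gA", "cis"),  # same pair again (other analysis)
        )
        per, totals = snp_multiplicity(pooled)
        assert per["s1"] == 1
        assert totals.distinct_snp_gene_pairs == 1
        assert totals.single_target == 1

    def test_partition_identity(self):
        pooled = rows(
            ("s1", "gA", "cis"),
            ("s2", "gA", "trans"),
            ("s2", "gB", "cis"),
            ("s3", "gC", "cis"),
        )
        _, totals = snp_multiplicity(pooled)
        assert totals.single_target + totals.multi_target == totals.distinct_rsids


class TestRegulationBreakdown:
    def test_strata(self):
        pooled = rows(
            ("s1", "gA", "cis"),  # single cis
            ("s2", "gB", "trans"),  # single trans
            ("s3", "gA", "cis"),
            ("s3", "gB", "cis"),  # multi, all cis
            ("s4", "gA", "trans"),
            ("s4", "gB", "trans"),  # multi, all trans
            ("s5", "gA", "cis"),
            ("s5", "gB", "trans"),  # multi, mixed
        )
        b = regulation_breakdown(pooled)
        assert (b.single_cis, b.single_trans) == (1, 1)
        assert (b.multi_cis_only, b.multi_trans_only, b.multi_mixed) == (1, 1, 1)
        _, totals = snp_multiplicity(pooled)
        assert b.single_total == totals.single_target
        assert b.multi_total == totals.multi_target

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError):
            regulation_breakdown(rows(("s1", "gA", "upstream")))


class TestCollapseGenes:
    def test_counts_and_ranking(self):
        pooled = rows(
            ("s1", "gA", "cis"),
            ("s2", "gA", "cis"),
            ("s1", "gB", "trans"),
        )
        genes = collapse_genes(pooled)
        assert [g.gene for g in genes] == ["gA", "gB"]
        assert genes[0].n_distinct_snps == 2
        assert genes[1].regulation_classes == {"trans"}

    def test_tie_broken_lexicographically(self):
        pooled = rows(("s1", "gB", "cis"), ("s2", "gA", "cis"))
        assert [g.gene for g in collapse_genes(pooled)] == ["gA", "gB"]

    def test_analyses_accumulate(self):
        parts = [
            rows(("s1", "gA", "cis"), analysis=f"a{i}") for i in range(1, 5)
        ]
        genes = collapse_genes(pool_annotated(parts))
        assert len(genes) == 1 and len(genes[0].analyses) == 4

    def test_snp_total_identity(self):
        pooled = rows(
            ("s1", "gA", "cis"), ("s2", "gA", "cis"), ("s1", "gB", "cis")
        )
        genes = collapse_genes(pooled)
        _, totals = snp_multiplicity(pooled)
        # summing per-gene SNPs >= distinct rsids; equality iff no SNP
        # targets two genes
        assert sum(g.n_distinct_snps for g in genes) >= totals.distinct_rsids

    def test_row_order_invariance(self):
        pooled = rows(
            ("s1", "gA", "cis"), ("s2", "gA", "cis"), ("s1", "gB", "trans")
        )
        shuffled = pooled.sample(frac=1, random_state=0).reset_index(drop=True)
        assert collapse_genes(pooled) == collapse_genes(shuffled)


class TestOverlapCounts:
    def test_pairwise(self):
        out = overlap_counts({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        assert out["pairs"][("A", "B")] == 2

    def test_disjoint_and_allway(self):
        out = overlap_counts(
            {"A": {"a"}, "B": {"b"}, "C": {"a", "b", "z"}}
        )
        assert out["pairs"][("A", "B")] == 0
        assert out["all_way"] == 0
        out2 = overlap_counts({"A": {"x", "1"}, "B": {"x", "2"}, "C": {"x"}})
        assert out2["all_way"] == 1


class TestFisherOverlap:
    def test_enumeration_example(self):
        # N=4, two sets of 2 overlapping completely: support {0,1,2} with
        # probabilities 1/6, 4/6, 1/6 -> two-sided p = 2/6
        assert fisher_overlap(2, 2, 2, 4) == pytest.approx(1 / 3)
        assert hypergeom_two_sided(2, 2, 2, 4) == pytest.approx(1 / 3)

    def test_null_consistent_table_near_one(self):
        # overlap at its independence expectation: 10*10/50 = 2
        assert fisher_overlap(10, 10, 2, 50) > 0.5

    def test_degenerate_margin(self):
        assert fisher_overlap(0, 5, 0, 20) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_overlap(5, 5, 6, 20)
        with pytest.raises(ValidationError):
            fisher_overlap(15, 10, 0, 20)

    @given(
        n=st.integers(min_value=1, max_value=60),
        data=st.data(),
    )
    @settings(derandomize=True, max_examples=150)
    def test_matches_hypergeometric_enumeration(self, n, data):
        """Fisher's two-sided P agrees with direct enumeration of the
        hypergeometric support for random tables with universe <= 60."""
        n_a = data.draw(st.integers(min_value=0, max_value=n))
        n_b = data.draw(st.integers(min_value=0, max_value=n))
        lo = max(0, n_a + n_b - n)
        n_int = data.draw(st.integers(min_value=lo, max_value=min(n_a, n_b)))
        assert fisher_overlap(n_a, n_b, n_int, n) == pytest.approx(
            hypergeom_two_sided(n_a, n_b, n_int, n), rel=1e-8, abs=1e-12
        )


class TestGeneListIntersection:
    def _summaries(self, genes):
        pooled = rows(*[(f"s{i}", g, "cis") for i, g in enumerate(genes)])
        return collapse_genes(pooled)

    def test_case_insensitive_match(self):
        summaries = self._summaries(["SLC25A12", "PANX1", "OTHER"])
        rep = gene_list_intersection(summaries, ["slc25a12", "Panx1", "NOPE"])
        assert rep.n_intersection == 2
        assert rep.n_unmatched == 1
        assert rep.fisher_p is None

    def test_disjoint(self):
        rep = gene_list_intersection(self._summaries(["A", "B"]), ["C"])
        assert rep.n_intersection == 0

    def test_duplicates_deduplicated(self):
        rep = gene_list_intersection(
            self._summaries(["A", "B"]), ["A", "a", "A", "X"]
        )
        assert rep.n_b == 2
        assert rep.n_intersection == 1

    def test_empty_external_rejected(self):
        with pytest.raises(ValidationError):
            gene_list_intersection(self._summaries(["A"]), [])


def test_descriptive_counts_on_synthetic_stand_in():
    """A synthetic pooled table (stand-in for a study's supplementary eQTL
    table) built with known structure: the summary counts must reproduce
    the construction exactly and satisfy the partition identities."""
    rng = np.random.default_rng(7)
    parts = []
    # 30 single-target SNPs (18 cis, 12 trans), 10 multi-target SNPs
    # (4 all-cis, 2 all-trans, 4 mixed), some rows duplicated across analyses
    for i in range(18):
        parts.append((f"s{i:03d}", f"g{i % 7}", "cis"))
    for i in range(18, 30):
        parts.append((f"s{i:03d}", f"g{i % 7}", "trans"))
    for i in range(30, 34):
        parts += [(f"s{i:03d}", "gM1", "cis"), (f"s{i:03d}", "gM2", "cis")]
    for i in range(34, 36):
        parts += [(f"s{i:03d}", "gM1", "trans"), (f"s{i:03d}", "gM3", "trans")]
    for i in range(36, 40):
        parts += [(f"s{i:03d}", "gM2", "cis"), (f"s{i:03d}", "gM3", "trans")]
    pooled = pool_annotated(
        [
            rows(*parts, analysis="a1"),
            rows(*[parts[k] for k in rng.choice(len(parts), 20, replace=False)],
                 analysis="a2"),
        ]
    )
    per, totals = snp_multiplicity(pooled)
    assert totals.distinct_rsids == 40
    assert totals.single_target == 30 and totals.multi_target == 10
    assert totals.pct_single_target == 75
    b = regulation_breakdown(pooled)
    assert (b.single_cis, b.single_trans) == (18, 12)
    assert (b.multi_cis_only, b.multi_trans_only, b.multi_mixed) == (4, 2, 4)
    genes = collapse_genes(pooled)
    assert sum(g.n_distinct_snps for g in genes) >= totals.distinct_rsids
    # duplicated rows across analyses never inflate distinct counts
    per2, totals2 = snp_multiplicity(
        pool_annotated([rows(*parts, analysis="a1"), rows(*parts, analysis="a1b")])
    )
    assert totals2.distinct_rsids == totals.distinct_rsids
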
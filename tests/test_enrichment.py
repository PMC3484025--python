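"""MAF binning, matched null sampling and the empirical P-value."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eqtlenrich import (
    BinProfile,
    EnrichmentConfig,
    EqtlEnrichment,
    GwasHitList,
    InfeasibleSampleError,
    SnpUniverse,
    ValidationError,
    assign_maf_bin,
    bin_profile,
    empirical_p,
    run_enrichment,
    sample_matched_null,
    significant_eqtl_rsids,
)


class TestAssignMafBin:
    @pytest.mark.parametrize(
        "maf, expected",
        [
            (0.02, 0),
            (0.05, 1),  # bins are left-closed
            (0.049999, 0),
            (0.249, 4),
            (0.45, 9),
            (0.50, 9),  # top bin is closed
            (0.0, 0),
        ],
    )
    def test_examples(self, maf, expected):
        assert assign_maf_bin(maf) == expected

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            assign_maf_bin(0.51)
        with pytest.raises(ValidationError):
            assign_maf_bin(-0.001)

    @given(st.floats(min_value=0.0, max_value=0.5, allow_nan=False))
    @settings(derandomize=True, max_examples=200)
    def test_bin_contains_its_maf(self, maf):
        """Every MAF falls inside its assigned half-open interval (top bin
        closed)."""
        cfg = EnrichmentConfig()
        b = assign_maf_bin(maf, cfg)
        assert 0 <= b < cfg.n_bins
        lo, hi = b * cfg.bin_width, (b + 1) * cfg.bin_width
        assert lo <= maf < hi or (b == cfg.n_bins - 1 and maf <= 0.5)


class TestBinProfile:
    def test_direct_tally(self, tiny_universe):
        prof = bin_profile(["rs1", "rs4", "rs5"], tiny_universe)
        # mafs 0.02, 0.01 -> bin 0; 0.30 -> bin 6
        assert prof.counts[0] == 2 and prof.counts[6] == 1
        assert prof.total == 3

    def test_empty(self, tiny_universe):
        assert bin_profile([], tiny_universe).total == 0

    def test_unknown_rsid_named(self, tiny_universe):
        with pytest.raises(ValidationError, match="rs_missing"):
            bin_profile(["rs1", "rs_missing"], tiny_universe)


class TestSampleMatchedNull:
    def test_forced_composition_is_permutation(self, tiny_universe):
        """A universe whose bins are exactly exhausted forces every set to
        be a permutation of the observed list."""
        observed = list(tiny_universe.rsids)
        prof = bin_profile(observed, tiny_universe)
        sets = sample_matched_null(tiny_universe, prof, n_sets=20, seed=0)
        for s in sets:
            assert sorted(s) == sorted(observed)

    def test_all_zero_profile(self, tiny_universe):
        prof = BinProfile(np.zeros(10, dtype=int))
        sets = sample_matched_null(tiny_universe, prof, n_sets=5, seed=0)
        assert len(sets) == 5 and all(len(s) == 0 for s in sets)

    def test_inclusion_frequency_binomial(self):
        """4-of-10 uniform draws: per-SNP inclusion frequency over 1,000
        sets stays within 3 binomial standard errors of 0.4."""
        frame = pd.DataFrame(
            {
                "rsid": [f"rs{i}" for i in range(10)],
                "chrom": "1",
                "pos": np.arange(1, 11),
                "maf": np.linspace(0.005, 0.045, 10),
            }
        )
        uni = SnpUniverse(frame)
        prof = BinProfile(np.array([4] + [0] * 9))
        sets = sample_matched_null(uni, prof, n_sets=1000, seed=42)
        freq = pd.Series([r for s in sets for r in s]).value_counts() / 1000
        se = math.sqrt(0.4 * 0.6 / 1000)
        assert len(sets) == 1000
        for s in sets:
            assert len(set(s)) == 4  # distinct within a set
        assert np.all(np.abs(freq.reindex(frame["rsid"], fill_value=0) - 0.4) <= 3 * se)

    def test_infeasible_bin_reports_deficit(self, tiny_universe):
        prof = BinProfile(np.array([9] + [0] * 9))  # bin 0 holds only 4 SNPs
        with pytest.raises(InfeasibleSampleError, match="bin 0.*deficit 5"):
            sample_matched_null(tiny_universe, prof, n_sets=2, seed=0)

    def test_seed_reproducibility_and_divergence(self, tiny_universe):
        prof = BinProfile(np.array([2, 0, 0, 0, 0, 2, 0, 0, 0, 1]))
        a = sample_matched_null(tiny_universe, prof, n_sets=50, seed=7)
        b = sample_matched_null(tiny_universe, prof, n_sets=50, seed=7)
        c = sample_matched_null(tiny_universe, prof, n_sets=50, seed=8)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))


class TestEmpiricalP:
    @pytest.mark.parametrize(
        "observed, null, expected_p, expected_display",
        [
            (3, [0, 1, 2, 3, 4], 0.4, "0.4"),
            (6, [1, 2, 3, 4, 5], 0.0, "<0.2"),
            (0, [5, 0, 2], 1.0, "1"),
        ],
    )
    def test_examples(self, observed, null, expected_p, expected_display):
        p, display = empirical_p(observed, null)
        assert p == pytest.approx(expected_p)
        assert display == expected_display

    def test_zero_exceedance_display_at_1000(self):
        assert empirical_p(10, [0] * 1000)[1] == "<0.001"

    def test_empty_null_rejected(self):
        with pytest.raises(ValidationError):
            empirical_p(1, [])

    @given(
        null=st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=50),
        counts=st.tuples(
            st.integers(min_value=0, max_value=31), st.integers(min_value=0, max_value=31)
        ),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_observed(self, null, counts):
        """A larger observed count never yields a larger empirical P."""
        lo, hi = min(counts), max(counts)
        assert empirical_p(hi, null)[0] <= empirical_p(lo, null)[0]


class TestRunEnrichment:
    def test_empty_eqtl_degenerate(self, tiny_hits, tiny_universe):
        empty = pd.DataFrame(
            columns=["rsid", "tissue", "gene", "probe_chrom", "probe_pos", "eqtl_p"]
        )
        res = run_enrichment(
            tiny_hits, empty, "none", tiny_universe, n_sets=50, seed=0
        )
        assert res.observed_count == 0
        assert np.all(res.null_counts == 0)
        assert res.empirical_p == 1.0

    def test_saturated_universe(self, tiny_universe):
        """Every universe SNP an eQTL: observed = list size = every null
        count, so P = 1."""
        records = pd.DataFrame(
            {
                "rsid": tiny_universe.rsids,
                "tissue": "t",
                "gene": "G1",
                "probe_chrom": tiny_universe.frame["chrom"],
                "probe_pos": tiny_universe.frame["pos"],
                "eqtl_p": 1e-9,
            }
        )
        hits = GwasHitList(
            "a",
            pd.DataFrame({"rsid": ["rs1", "rs5", "rs9"], "gwas_p": [1e-4] * 3}),
        )
        res = run_enrichment(hits, records, "t", tiny_universe, n_sets=40, seed=1)
        assert res.observed_count == 3
        assert np.all(res.null_counts == 3)
        assert res.empirical_p == 1.0

    def test_bit_identical_under_seed(self, tiny_hits, tiny_eqtl, tiny_universe):
        r1 = run_enrichment(
            tiny_hits, tiny_eqtl, "parietal", tiny_universe, n_sets=100, seed=5
        )
        r2 = run_enrichment(
            tiny_hits, tiny_eqtl, "parietal", tiny_universe, n_sets=100, seed=5
        )
        assert np.array_equal(r1.null_counts, r2.null_counts)
        assert r1.empirical_p == r2.empirical_p

    def test_summary_mentions_key_quantities(
        self, tiny_hits, tiny_eqtl, tiny_universe
    ):
        res = run_enrichment(
            tiny_hits, tiny_eqtl, "parietal", tiny_universe, n_sets=100, seed=5
        )
        text = res.summary()
        assert "parietal" in text and "Spec|All" in text
        assert str(res.observed_count) in text
        assert res.p_display in text


def exact_tail_probability(universe, eqtl_rsids, hit_rsids, config=None):
    """Brute-force oracle: enumerate every bin-respecting subset of the
    universe with the hit list's MAF profile and return the exact
    probability that its eQTL count matches or exceeds the observed one."""
    config = config or EnrichmentConfig()
    prof = bin_profile(hit_rsids, universe, config)
    observed = len(set(hit_rsids) & set(eqtl_rsids))
    bins = assign_maf_bin(universe.maf, config)
    members = [
        list(universe.rsids[bins == b]) for b in range(config.n_bins)
    ]
    per_bin_choices = [
        list(itertools.combinations(members[b], int(k)))
        for b, k in enumerate(prof.counts)
        if k > 0
    ]
    total = 0
    tail = 0
    for combo in itertools.product(*per_bin_choices):
        snps = set(itertools.chain.from_iterable(combo))
        total += 1
        if len(snps & set(eqtl_rsids)) >= observed:
            tail += 1
    return observed, tail / total


def test_empirical_p_matches_exact_enumeration_small_instance():
    """20-SNP universe, 4-SNP hit list: the Monte-Carlo empirical P at
    N=2000 lies within 3 MC standard errors of the exactly enumerated
    matched-sampling tail probability."""
    rng = np.random.default_rng(2024)
    frame = pd.DataFrame(
        {
            "rsid": [f"rs{i:02d}" for i in range(20)],
            "chrom": "1",
            "pos": rng.integers(1, 10**8, size=20),
            "maf": np.r_[rng.uniform(0.0, 0.05, 10), rng.uniform(0.25, 0.30, 10)],
        }
    )
    uni = SnpUniverse(frame)
    eqtl_rsids = ["rs00", "rs03", "rs11", "rs12", "rs17"]
    records = pd.DataFrame(
        {
            "rsid": eqtl_rsids,
            "tissue": "t",
            "gene": [f"G{i}" for i in range(5)],
            "probe_chrom": "1",
            "probe_pos": uni.frame.set_index("rsid").loc[eqtl_rsids, "pos"].to_numpy(),
            "eqtl_p": 1e-8,
        }
    )
    hit_rsids = ["rs00", "rs05", "rs11", "rs15"]  # 2 eQTLs, bins 0 and 5
    hits = GwasHitList("a", pd.DataFrame({"rsid": hit_rsids, "gwas_p": [1e-4] * 4}))

    observed, p_exact = exact_tail_probability(uni, eqtl_rsids, hit_rsids)
    assert 0 < p_exact < 1  # a non-degenerate instance

    res = run_enrichment(hits, records, "t", uni, n_sets=2000, seed=99)
    assert res.observed_count == observed
    se = math.sqrt(p_exact * (1 - p_exact) / 2000)
    assert abs(res.empirical_p - p_exact) <= 3 * se


def test_model_requires_tissue_disambiguation(tiny_hits, tiny_eqtl, tiny_universe):
    two = pd.concat(
        [tiny_eqtl, tiny_eqtl.assign(tissue="cerebellum")], ignore_index=True
    )
    with pytest.raises(ValidationError, match="tissue"):
        EqtlEnrichment(tiny_hits, two, tiny_universe)
    model = EqtlEnrichment(tiny_hits, two, tiny_universe, tissue="cerebellum")
    assert model.tissue == "cerebellum"
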
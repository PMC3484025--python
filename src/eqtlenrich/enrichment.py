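"""Empirical eQTL-enrichment test with a MAF-matched resampling null.

The test asks whether a GWAS top-SNP list contains more eQTL SNPs for a
tissue than expected by chance.  Chance is defined by randomized SNP sets
drawn without replacement from the genotyping platform's SNP universe,
matched to the hit list's minor-allele-frequency composition: every SNP is
assigned to one of ten 5% MAF bins (0–5%, 5–10%, …, 45–50%) and each null
set reproduces the hit list's per-bin tallies exactly.  The enrichment
P-value is the proportion of null sets whose eQTL count matches or exceeds
the observed count.

The statistic — for the observed list and every null set alike — is the
number of *distinct* SNPs with at least one significant eQTL in the tissue;
a SNP regulating several genes counts once.

:class:`EqtlEnrichment` is the model object (hit list + eQTL table +
universe + configuration); :meth:`EqtlEnrichment.fit` draws the null and
returns an :class:`EnrichmentResult` with the observed count, the full null
distribution, the empirical P-value, a text ``summary()`` and a
``plot_null()`` histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import InfeasibleSampleError, ValidationError
from .annotation import AnnotationResult, annotate_hits, significant_eqtl_rsids
from .config import EnrichmentConfig
from .io import GwasHitList, SnpUniverse

__all__ = [
    "assign_maf_bin",
    "BinProfile",
    "bin_profile",
    "sample_matched_null",
    "empirical_p",
    "EqtlEnrichment",
    "EnrichmentResult",
    "run_enrichment",
]

logger = logging.getLogger(__name__)

# cap on floats materialised per sampling block; keeps peak memory modest
# when one MAF bin holds most of a large universe
_MAX_BLOCK = 1 << 24


def assign_maf_bin(maf, config: EnrichmentConfig | None = None):
    """Map minor allele frequencies to bin indices.

    Bins are left-closed/right-open (``[0, 0.05), [0.05, 0.10), ...``) except
    the top bin, which is closed so maf = 0.5 belongs to bin ``n_bins - 1``.
    Accepts a scalar or array; returns the same shape.
    """
    config = config or EnrichmentConfig()
    arr = np.asarray(maf, dtype=float)
    if np.any((arr < 0) | (arr > 0.5)):
        bad = arr[(arr < 0) | (arr > 0.5)].flat[0]
        raise ValidationError(f"maf must lie in [0, 0.5], got {bad}")
    # the small epsilon keeps exact multiples of the bin width (0.05, 0.30,
    # ...) in their left-closed bin despite binary rounding of the quotient
    bins = np.minimum(
        np.floor(arr / config.bin_width + 1e-9).astype(np.int64), config.n_bins - 1
    )
    return int(bins) if np.isscalar(maf) else bins


@dataclass(frozen=True)
class BinProfile:
    """Per-MAF-bin SNP tallies of a hit list — the composition every
    randomized null set must reproduce exactly."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or np.any(counts < 0):
            raise ValidationError("bin counts must be a 1-D array of non-negatives")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, BinProfile) and np.array_equal(
            self.counts, other.counts
        )


def bin_profile(
    rsids, universe: SnpUniverse, config: EnrichmentConfig | None = None
) -> BinProfile:
    """Tally the MAF-bin composition of a set of SNPs.

    Every rsid must exist in the universe; the tallies sum to ``len(rsids)``.
    """
    config = config or EnrichmentConfig()
    rsids = list(rsids)
    if not rsids:
        return BinProfile(np.zeros(config.n_bins, dtype=np.int64))
    idx = universe.indices_of(rsids)
    bins = assign_maf_bin(universe.maf[idx], config)
    return BinProfile(np.bincount(bins, minlength=config.n_bins))


def _universe_bin_members(
    universe: SnpUniverse, config: EnrichmentConfig
) -> list[np.ndarray]:
    """Universe row indices grouped by MAF bin."""
    bins = assign_maf_bin(universe.maf, config)
    order = np.argsort(bins, kind="stable")
    edges = np.searchsorted(bins[order], np.arange(config.n_bins + 1))
    return [order[edges[b] : edges[b + 1]] for b in range(config.n_bins)]


def _sample_bin_block(
    members: np.ndarray, k: int, n_sets: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_sets`` independent k-subsets (without replacement within a
    set) from ``members``; returns an (n_sets, k) index matrix.

    When sets are small relative to the bin (k^2 <= m) the draw is by
    rejection: sample k member slots with replacement and redraw any row
    containing a duplicate, which yields uniform distinct k-tuples and so
    uniform k-subsets.  Otherwise each set ranks the bin's members by
    i.i.d. uniform keys and takes the k smallest (random-keys
    construction), in blocks of sets to bound peak memory.
    """
    m = len(members)
    if k >= m:
        return np.tile(members, (n_sets, 1))
    if k * k <= m:  # duplicate probability per row <~ 0.5: rejection is cheap
        picked = rng.integers(0, m, size=(n_sets, k))
        while True:
            srt = np.sort(picked, axis=1)
            bad = (np.diff(srt, axis=1) == 0).any(axis=1) if k > 1 else np.zeros(n_sets, bool)
            n_bad = int(bad.sum())
            if n_bad == 0:
                break
            picked[bad] = rng.integers(0, m, size=(n_bad, k))
        return members[picked]
    out = np.empty((n_sets, k), dtype=members.dtype)
    block = max(1, _MAX_BLOCK // m)
    for start in range(0, n_sets, block):
        stop = min(start + block, n_sets)
        keys = rng.random((stop - start, m))
        picked = np.argpartition(keys, k - 1, axis=1)[:, :k]
        out[start:stop] = members[picked]
    return out


def _sample_null_index_matrix(
    universe: SnpUniverse,
    profile: BinProfile,
    n_sets: int,
    rng: np.random.Generator,
    config: EnrichmentConfig,
) -> np.ndarray:
    """(n_sets, profile.total) matrix of universe row indices, each row a
    MAF-matched null set (bin-ordered within the row)."""
    if len(profile.counts) != config.n_bins:
        raise ValidationError(
            f"profile has {len(profile.counts)} bins, config expects {config.n_bins}"
        )
    members = _universe_bin_members(universe, config)
    for b, k in enumerate(profile.counts):
        if k > len(members[b]):
            raise InfeasibleSampleError(
                f"MAF bin {b} needs {int(k)} SNPs but the universe holds only "
                f"{len(members[b])} (deficit {int(k) - len(members[b])})"
            )
    parts = [
        _sample_bin_block(members[b], int(k), n_sets, rng)
        for b, k in enumerate(profile.counts)
        if k > 0
    ]
    if not parts:
        return np.empty((n_sets, 0), dtype=np.int64)
    return np.concatenate(parts, axis=1)


def sample_matched_null(
    universe: SnpUniverse,
    profile: BinProfile,
    n_sets: int,
    seed: int,
    config: EnrichmentConfig | None = None,
) -> list[np.ndarray]:
    """Draw ``n_sets`` MAF-matched randomized SNP sets.

    Each set contains exactly ``profile.counts[b]`` distinct SNPs from bin
    ``b``, sampled without replacement within the set; the same SNP may
    recur across different sets, and nothing is excluded from the frame.
    Fully reproducible given ``seed``.

    Returns a list of rsid arrays.  (:class:`EqtlEnrichment` uses the
    index-level sampler directly to score sets without materialising rsids.)
    """
    config = config or EnrichmentConfig()
    rng = np.random.default_rng(seed)
    matrix = _sample_null_index_matrix(universe, profile, n_sets, rng, config)
    rsids = universe.rsids
    return [rsids[row] for row in matrix]


def empirical_p(observed_count: int, null_counts) -> tuple[float, str]:
    """Empirical enrichment P-value.

    The proportion of null sets whose eQTL count matches or exceeds the
    observed count.  When no null set reaches the observed count the stored
    proportion is 0.0 and the display string is ``"<1/N"`` (e.g. "<0.001"
    for N = 1000); no pseudo-count is added.
    """
    null_counts = np.asarray(null_counts)
    if null_counts.size == 0:
        raise ValidationError("null_counts must be non-empty")
    if np.any(null_counts < 0):
        raise ValidationError("null counts must be non-negative")
    n = null_counts.size
    exceed = int((null_counts >= observed_count).sum())
    p = exceed / n
    display = f"<{1 / n:g}" if exceed == 0 else f"{p:.4g}"
    return p, display


@dataclass
class EnrichmentResult:
    """Fitted enrichment test for one hit list in one tissue.

    Attributes
    ----------
    analysis_label, tissue : str
        Which GWAS primary analysis and which eQTL tissue were tested.
    observed_count : int
        Distinct hit SNPs with at least one significant eQTL in the tissue.
    null_counts : numpy.ndarray
        eQTL counts of the ``n_null_sets`` MAF-matched randomized sets.
    empirical_p : float
        Proportion of null counts >= observed.
    p_display : str
        Publication-style rendering ("0.004", or "<0.001" at zero
        exceedances).
    n_hits : int
        Hit-list size entering the test (after universe filtering).
    seed : int
        Seed that drew the null.
    annotation : AnnotationResult or None
        Row-level annotated join behind the observed count, when fitted via
        :class:`EqtlEnrichment`.
    """

    analysis_label: str
    tissue: str
    observed_count: int
    null_counts: np.ndarray
    empirical_p: float
    p_display: str
    n_null_sets: int
    n_hits: int
    seed: int
    annotation: AnnotationResult | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.null_counts = np.asarray(self.null_counts, dtype=np.int64)
        if self.n_null_sets != self.null_counts.size:
            raise ValidationError("n_null_sets disagrees with null_counts length")

    @property
    def null_mean(self) -> float:
        return float(self.null_counts.mean())

    @property
    def null_std(self) -> float:
        return float(self.null_counts.std(ddof=1)) if self.n_null_sets > 1 else 0.0

    def summary(self) -> str:
        """Plain-text summary table of the fitted test."""
        lines = [
            "eQTL enrichment (MAF-matched resampling null)",
            "=" * 54,
            f"{'GWAS analysis:':<28}{self.analysis_label}",
            f"{'eQTL tissue:':<28}{self.tissue}",
            f"{'hit-list size:':<28}{self.n_hits}",
            f"{'observed eQTL SNPs:':<28}{self.observed_count}",
            f"{'null sets:':<28}{self.n_null_sets}",
            f"{'null mean (sd):':<28}{self.null_mean:.2f} ({self.null_std:.2f})",
            f"{'enrichment P:':<28}{self.p_display}",
            f"{'seed:':<28}{self.seed}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def plot_null(self, ax=None):
        """Histogram of the null eQTL-count distribution with the observed
        count marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo = int(min(self.null_counts.min(), self.observed_count))
        hi = int(max(self.null_counts.max(), self.observed_count))
        ax.hist(
            self.null_counts,
            bins=np.arange(lo - 0.5, hi + 1.5),
            color="0.7",
            edgecolor="0.4",
        )
        ax.plot([self.observed_count], [0], "ko", markersize=8, clip_on=False)
        ax.axvline(self.observed_count, color="k", linestyle="--", linewidth=1)
        ax.set_xlabel("eQTL SNPs per set")
        ax.set_ylabel("null sets")
        ax.set_title(
            f"{self.analysis_label} / {self.tissue}  (P = {self.p_display})"
        )
        return ax

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "analysis_label": self.analysis_label,
            "tissue": self.tissue,
            "observed_count": int(self.observed_count),
            "empirical_p": float(self.empirical_p),
            "p_display": self.p_display,
            "n_null_sets": int(self.n_null_sets),
            "n_hits": int(self.n_hits),
            "seed": int(self.seed),
            "null_counts": [int(c) for c in self.null_counts],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnrichmentResult":
        return cls(
            analysis_label=d["analysis_label"],
            tissue=d["tissue"],
            observed_count=int(d["observed_count"]),
            null_counts=np.asarray(d["null_counts"], dtype=np.int64),
            empirical_p=float(d["empirical_p"]),
            p_display=d["p_display"],
            n_null_sets=int(d["n_null_sets"]),
            n_hits=int(d["n_hits"]),
            seed=int(d["seed"]),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, EnrichmentResult):
            return NotImplemented
        return self.to_dict() == other.to_dict()


class EqtlEnrichment:
    """Model object for the eQTL-enrichment test.

    Parameters
    ----------
    hits : GwasHitList
        Top SNPs of one GWAS primary analysis.
    eqtl_records : pandas.DataFrame
        Raw eQTL association table (``rsid, tissue, gene, probe_chrom,
        probe_pos, eqtl_p``); significance and cis/trans status are derived
        here under ``config``'s rules.
    universe : SnpUniverse
        Platform SNP manifest — the MAF source and the null sampling frame.
    config : EnrichmentConfig, optional
    tissue : str, optional
        Restrict the eQTL table to one tissue; required when the table
        carries several.

    Examples
    --------
    >>> model = EqtlEnrichment(hits, eqtl_df, universe, tissue="parietal")
    >>> result = model.fit(seed=7)
    >>> print(result.summary())
    """

    def __init__(
        self,
        hits: GwasHitList,
        eqtl_records: pd.DataFrame,
        universe: SnpUniverse,
        config: EnrichmentConfig | None = None,
        tissue: str | None = None,
    ):
        self.config = config or EnrichmentConfig()
        tissues = (
            list(pd.unique(eqtl_records["tissue"])) if len(eqtl_records) else []
        )
        if tissue is None:
            if len(tissues) > 1:
                raise ValidationError(
                    f"eQTL table holds tissues {tissues}; pass tissue= to pick one"
                )
            tissue = tissues[0] if tissues else "none"
        else:
            eqtl_records = eqtl_records.loc[eqtl_records["tissue"] == tissue]
        self.hits = hits
        self.eqtl_records = eqtl_records
        self.universe = universe
        self.tissue = str(tissue)

    @classmethod
    def from_files(
        cls,
        hits_path,
        eqtl_path,
        universe_path,
        tissue: str,
        config: EnrichmentConfig | None = None,
        analysis_label: str | None = None,
    ) -> "EqtlEnrichment":
        """Build the model straight from the three TSV inputs."""
        from .io import read_eqtl_table, read_gwas_hits, read_snp_universe

        config = config or EnrichmentConfig()
        return cls(
            hits=read_gwas_hits(
                hits_path,
                threshold=config.gwas_p_threshold,
                analysis_label=analysis_label,
            ),
            eqtl_records=read_eqtl_table(eqtl_path, tissue),
            universe=read_snp_universe(universe_path),
            config=config,
            tissue=tissue,
        )

    def fit(
        self, n_sets: int | None = None, seed: int | None = None
    ) -> EnrichmentResult:
        """Draw the MAF-matched null and compute the empirical P-value.

        ``n_sets`` and ``seed`` default to the configuration's values.  The
        observed and null counts are scored with the identical rule: number
        of distinct set members flagged as significant eQTL SNPs in the
        tissue.
        """
        cfg = self.config
        n_sets = cfg.n_null_sets if n_sets is None else int(n_sets)
        seed = cfg.seed if seed is None else int(seed)
        if n_sets < 1:
            raise ValidationError("n_sets must be positive")

        ann = annotate_hits(self.hits, self.eqtl_records, self.universe, cfg)
        kept_rsids = ann.is_eqtl.index.to_numpy()
        observed = ann.n_eqtl_snps

        # per-universe-row eQTL flag, shared by observed and null scoring
        flag = np.zeros(len(self.universe), dtype=bool)
        eqtl_rsids = significant_eqtl_rsids(self.eqtl_records, self.universe, cfg)
        if eqtl_rsids:
            flag[self.universe.indices_of(sorted(eqtl_rsids))] = True

        profile = bin_profile(kept_rsids, self.universe, cfg)
        rng = np.random.default_rng(seed)
        matrix = _sample_null_index_matrix(self.universe, profile, n_sets, rng, cfg)
        self._check_bin_match(matrix, profile, cfg)
        null_counts = (
            flag[matrix].sum(axis=1).astype(np.int64)
            if matrix.size
            else np.zeros(n_sets, dtype=np.int64)
        )
        p, display = empirical_p(observed, null_counts)
        return EnrichmentResult(
            analysis_label=self.hits.analysis_label,
            tissue=self.tissue,
            observed_count=observed,
            null_counts=null_counts,
            empirical_p=p,
            p_display=display,
            n_null_sets=n_sets,
            n_hits=len(kept_rsids),
            seed=seed,
            annotation=ann,
        )

    def _check_bin_match(
        self, matrix: np.ndarray, profile: BinProfile, cfg: EnrichmentConfig
    ) -> None:
        """Assert every null set reproduces the observed bin profile exactly
        (cheap structural self-check, run on every fit)."""
        if matrix.size == 0:
            assert profile.total == 0
            return
        bins = assign_maf_bin(self.universe.maf, cfg)[matrix]
        tallies = np.stack([(bins == b).sum(axis=1) for b in range(cfg.n_bins)], axis=1)
        if not np.all(tallies == profile.counts):
            raise AssertionError("null set violates the MAF bin profile")


def run_enrichment(
    hits: GwasHitList,
    eqtl_records: pd.DataFrame,
    tissue: str,
    universe: SnpUniverse,
    config: EnrichmentConfig | None = None,
    n_sets: int | None = None,
    seed: int | None = None,
) -> EnrichmentResult:
    """Functional one-shot wrapper around
    ``EqtlEnrichment(...).fit(n_sets, seed)``."""
    model = EqtlEnrichment(hits, eqtl_records, universe, config=config, tissue=tissue)
    return model.fit(n_sets=n_sets, seed=seed)
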
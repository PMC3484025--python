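"""eQTL determination and GWAS-hit annotation.

A SNP-probe association is *cis* when the SNP lies within the cis window
(default 4 Mb, inclusive) of the probe site on the same chromosome, and
*trans* otherwise (including all cross-chromosome pairs).  Cis associations
are significant at P < ``cis_alpha`` (default 1e-4); trans associations at
the Bonferroni threshold ``trans_alpha_numerator / n_probes``
(default 0.05 / 25,834 ≈ 1.94e-6).  Both comparisons are strict.

The enrichment statistic downstream counts *distinct SNPs* with at least one
significant eQTL in a tissue — a SNP regulating several genes is one eQTL
SNP.  :func:`annotate_hits` therefore returns both the row-level annotated
join and the per-hit boolean eQTL-status vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .config import EnrichmentConfig
from .io import GwasHitList, SnpLocus, SnpUniverse, normalize_chrom

__all__ = [
    "classify_regulation",
    "eqtl_significant",
    "derive_eqtl_status",
    "significant_eqtl_rsids",
    "annotate_hits",
    "AnnotationResult",
]

logger = logging.getLogger(__name__)

ANNOTATED_COLUMNS = [
    "analysis_label",
    "tissue",
    "rsid",
    "gene",
    "regulation",
    "eqtl_p",
    "gwas_p",
]


def classify_regulation(
    snp: SnpLocus,
    probe_chrom: str,
    probe_pos: int,
    cis_window_bp: int = 4_000_000,
) -> str:
    """Classify one SNP-probe pair as ``"cis"`` or ``"trans"``.

    Cis iff the probe is on the same (normalized) chromosome and
    ``|snp.pos - probe_pos| <= cis_window_bp`` — the window is inclusive.
    Pairs on different chromosomes are trans regardless of coordinates.
    """
    if probe_pos < 1:
        raise ValidationError(f"probe_pos must be >= 1, got {probe_pos}")
    same = snp.chrom == normalize_chrom(probe_chrom)
    if same and abs(int(snp.pos) - int(probe_pos)) <= cis_window_bp:
        return "cis"
    return "trans"


def eqtl_significant(
    eqtl_p: float, regulation: str, config: EnrichmentConfig | None = None
) -> bool:
    """Is an association significant under its class-specific threshold?

    Cis: ``eqtl_p < cis_alpha``; trans: ``eqtl_p < trans_alpha_numerator /
    n_probes``.  Strict inequality in both cases.
    """
    config = config or EnrichmentConfig()
    if not (0 < eqtl_p <= 1):
        raise ValidationError(f"eqtl_p must lie in (0, 1], got {eqtl_p}")
    if regulation == "cis":
        return eqtl_p < config.cis_alpha
    if regulation == "trans":
        return eqtl_p < config.trans_alpha
    raise ValidationError(f"unknown regulation class: {regulation!r}")


def derive_eqtl_status(
    eqtl_records: pd.DataFrame,
    universe: SnpUniverse,
    config: EnrichmentConfig | None = None,
) -> pd.DataFrame:
    """Vectorised eQTL determination over a raw association table.

    Adds ``regulation`` and ``significant`` columns derived from the SNP's
    universe coordinates and the probe location.  Records whose rsid is not
    in the universe are dropped (logged): without a manifest entry the SNP
    has no coordinates to classify and no MAF for the null, so it can belong
    to neither the observed nor the randomized frame.
    """
    config = config or EnrichmentConfig()
    records = eqtl_records.copy()
    uni = universe.frame.set_index("rsid")[["chrom", "pos"]]
    known = records["rsid"].isin(uni.index)
    if not known.all():
        n_missing = int((~known).sum())
        logger.warning(
            "derive_eqtl_status: dropping %d record(s) whose rsid is not in "
            "the universe",
            n_missing,
        )
        records = records.loc[known].reset_index(drop=True)
    if len(records) == 0:
        records["regulation"] = pd.Series(dtype=str)
        records["significant"] = pd.Series(dtype=bool)
        return records
    snp_chrom = records["rsid"].map(uni["chrom"]).to_numpy()
    snp_pos = records["rsid"].map(uni["pos"]).to_numpy(dtype=np.int64)
    probe_chrom = records["probe_chrom"].to_numpy()
    probe_pos = records["probe_pos"].to_numpy(dtype=np.int64)
    is_cis = (snp_chrom == probe_chrom) & (
        np.abs(snp_pos - probe_pos) <= config.cis_window_bp
    )
    records["regulation"] = np.where(is_cis, "cis", "trans")
    p = records["eqtl_p"].to_numpy(dtype=float)
    records["significant"] = np.where(
        is_cis, p < config.cis_alpha, p < config.trans_alpha
    )
    return records


def significant_eqtl_rsids(
    eqtl_records: pd.DataFrame,
    universe: SnpUniverse,
    config: EnrichmentConfig | None = None,
) -> set[str]:
    """Distinct rsids with at least one significant eQTL in the table."""
    derived = derive_eqtl_status(eqtl_records, universe, config)
    return set(derived.loc[derived["significant"], "rsid"])


@dataclass
class AnnotationResult:
    """Output of :func:`annotate_hits`.

    Attributes
    ----------
    annotated : pandas.DataFrame
        One row per (analysis, tissue, rsid, gene) for each significant eQTL
        record matching a hit; columns :data:`ANNOTATED_COLUMNS`.
    is_eqtl : pandas.Series
        Boolean, indexed by hit rsid (in hit-list order): does the hit have
        at least one significant eQTL in this tissue?  This is the per-SNP
        statistic the enrichment null is scored with.
    missing_rsids : list of str
        Hit rsids absent from the universe manifest, excluded from both
        observed and null frames.
    """

    annotated: pd.DataFrame
    is_eqtl: pd.Series
    missing_rsids: list

    @property
    def n_eqtl_snps(self) -> int:
        """Distinct hit SNPs that are significant eQTLs (multi-gene SNPs
        counted once)."""
        return int(self.is_eqtl.sum())


def annotate_hits(
    hits: GwasHitList,
    eqtl_records: pd.DataFrame,
    universe: SnpUniverse,
    config: EnrichmentConfig | None = None,
) -> AnnotationResult:
    """Join a GWAS hit list against significant eQTL records, per tissue.

    The join is an inner join on rsid restricted to records passing the
    class-specific significance threshold.  Hits missing from the universe
    are excluded (and reported), keeping the observed frame consistent with
    the sampling frame of the null.  An empty eQTL table is valid and yields
    an all-false annotation.
    """
    config = config or EnrichmentConfig()
    in_universe = np.fromiter(
        (r in universe for r in hits.rsids), dtype=bool, count=len(hits)
    )
    missing = [str(r) for r in hits.rsids[~in_universe]]
    if missing:
        logger.warning(
            "annotate_hits(%s): %d hit rsid(s) not in universe, excluded: %s%s",
            hits.analysis_label,
            len(missing),
            ", ".join(missing[:5]),
            "..." if len(missing) > 5 else "",
        )
    kept = hits.frame.loc[in_universe].reset_index(drop=True)

    derived = derive_eqtl_status(eqtl_records, universe, config)
    sig = derived.loc[derived["significant"]]
    if len(sig) == 0:
        logger.warning(
            "annotate_hits(%s): no significant eQTL records", hits.analysis_label
        )
        annotated = pd.DataFrame(columns=ANNOTATED_COLUMNS)
    else:
        merged = kept.merge(sig, on="rsid", how="inner")
        merged["analysis_label"] = hits.analysis_label
        # one row per (rsid, tissue, gene, analysis): collapse duplicate raw
        # rows to the strongest evidence
        merged = (
            merged.sort_values("eqtl_p", kind="stable")
            .drop_duplicates(subset=["analysis_label", "tissue", "rsid", "gene"])
            .sort_values(["tissue", "rsid", "gene"], kind="stable")
            .reset_index(drop=True)
        )
        annotated = merged[ANNOTATED_COLUMNS]

    eqtl_rsids = set(sig["rsid"]) if len(sig) else set()
    is_eqtl = pd.Series(
        [r in eqtl_rsids for r in kept["rsid"]],
        index=kept["rsid"].to_numpy(),
        dtype=bool,
        name="is_eqtl",
    )
    return AnnotationResult(annotated=annotated, is_eqtl=is_eqtl, missing_rsids=missing)
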
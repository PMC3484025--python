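"""Domain containers and delimited-text I/O.

All pipeline stages exchange tab-separated text with a header row.  Because
real source files name their columns inconsistently, every reader accepts a
*dialect*: a mapping from the canonical column names used here (``rsid``,
``chrom``, ``pos``, ``maf``, ``gwas_p``, ``gene``, ``probe_chrom``,
``probe_pos``, ``eqtl_p``) to the names actually present in the file.

Containers wrap :class:`pandas.DataFrame` objects so downstream stages can
work vectorised; invariants (unique rsids, MAF in [0, 0.5], P-values in
(0, 1]) are enforced at construction and at read time with line numbers in
error messages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import FormatError, ValidationError

__all__ = [
    "SnpLocus",
    "SnpUniverse",
    "GwasHit",
    "GwasHitList",
    "ReadStats",
    "normalize_chrom",
    "read_snp_universe",
    "read_gwas_hits",
    "read_eqtl_table",
    "write_report",
    "read_enrichment_result",
    "read_gene_summaries",
    "EQTL_COLUMNS",
]

logger = logging.getLogger(__name__)

#: canonical column order of a raw (underived) eQTL association table
EQTL_COLUMNS = ["rsid", "tissue", "gene", "probe_chrom", "probe_pos", "eqtl_p"]


def normalize_chrom(label) -> str:
    """Normalize a chromosome label: strip a leading ``chr`` and upper-case
    sex chromosomes, so ``chr1`` == ``1`` and ``chrx`` == ``X``."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.lower() in ("x", "y", "mt", "m"):
        s = s.upper()
    if not s:
        raise ValidationError(f"empty chromosome label: {label!r}")
    return s


@dataclass(frozen=True)
class SnpLocus:
    """A genotyped SNP: identifier, genomic position and minor allele
    frequency (the matching covariate of the resampling null)."""

    rsid: str
    chrom: str
    pos: int
    maf: float

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.maf <= 0.5):
            raise ValidationError(
                f"{self.rsid}: maf must lie in [0, 0.5], got {self.maf}"
            )
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


@dataclass(frozen=True)
class ReadStats:
    """Row accounting for one reader invocation.

    ``ingested == kept + dropped + rejected`` always holds; readers raise on
    invalid rows, so ``rejected`` is non-zero only for policies that tolerate
    them (none currently do)."""

    ingested: int
    kept: int
    dropped: int = 0
    rejected: int = 0

    def __post_init__(self) -> None:
        if self.ingested != self.kept + self.dropped + self.rejected:
            raise ValidationError("read stats do not balance")


class SnpUniverse:
    """The full set of typed SNPs on the genotyping platform — the sampling
    frame for MAF-matched null sets.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``rsid`` (unique, non-empty), ``chrom``, ``pos`` (>= 1) and
        ``maf`` (in [0, 0.5]).  Row order is preserved.
    platform_label : str
        Free-text name of the array/platform the manifest describes.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        platform_label: str = "unknown",
        read_stats: ReadStats | None = None,
    ):
        required = ["rsid", "chrom", "pos", "maf"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise FormatError(f"universe frame missing column(s): {missing}")
        if len(frame) == 0:
            raise ValidationError("SNP universe must be non-empty")
        frame = frame.loc[:, required].reset_index(drop=True)
        frame["rsid"] = frame["rsid"].astype(str)
        if (frame["rsid"] == "").any():
            raise ValidationError("universe contains an empty rsid")
        dup = frame["rsid"].duplicated()
        if dup.any():
            first = frame.loc[dup.idxmax(), "rsid"]
            raise ValidationError(f"duplicate rsid in universe: {first!r}")
        frame["chrom"] = frame["chrom"].map(normalize_chrom)
        frame["pos"] = pd.to_numeric(frame["pos"], errors="raise").astype(np.int64)
        if (frame["pos"] < 1).any():
            bad = frame.loc[frame["pos"] < 1, "rsid"].iloc[0]
            raise ValidationError(f"position < 1 for SNP {bad!r}")
        frame["maf"] = pd.to_numeric(frame["maf"], errors="raise").astype(float)
        out = ~frame["maf"].between(0.0, 0.5)
        if out.any():
            i = int(np.flatnonzero(out.to_numpy())[0])
            raise ValidationError(
                f"maf outside [0, 0.5] for SNP {frame['rsid'].iloc[i]!r} "
                f"(value {frame['maf'].iloc[i]})"
            )
        self.frame = frame
        self.platform_label = platform_label
        self.read_stats = read_stats
        self._index: pd.Series = pd.Series(
            np.arange(len(frame)), index=frame["rsid"].to_numpy()
        )

    # -- basic container protocol -----------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index.index

    def __repr__(self) -> str:
        return f"SnpUniverse(n={len(self)}, platform={self.platform_label!r})"

    @property
    def rsids(self) -> np.ndarray:
        return self.frame["rsid"].to_numpy()

    @property
    def maf(self) -> np.ndarray:
        return self.frame["maf"].to_numpy()

    def indices_of(self, rsids: Sequence[str]) -> np.ndarray:
        """Positional indices of ``rsids`` within the universe; raises
        :class:`ValidationError` naming the first unknown rsid."""
        rsids = np.asarray(list(rsids), dtype=object)
        try:
            return self._index.loc[rsids].to_numpy()
        except KeyError:
            known = self._index.index
            for r in rsids:
                if r not in known:
                    raise ValidationError(f"rsid not in universe: {r!r}") from None
            raise

    def loci(self) -> list[SnpLocus]:
        return [
            SnpLocus(r.rsid, r.chrom, int(r.pos), float(r.maf))
            for r in self.frame.itertuples(index=False)
        ]

    @classmethod
    def from_loci(
        cls, loci: Iterable[SnpLocus], platform_label: str = "unknown"
    ) -> "SnpUniverse":
        rows = [(s.rsid, s.chrom, s.pos, s.maf) for s in loci]
        return cls(
            pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "maf"]),
            platform_label,
        )


@dataclass(frozen=True)
class GwasHit:
    """One SNP from a GWAS top-signal list."""

    rsid: str
    gwas_p: float

    def __post_init__(self) -> None:
        if not (0 < self.gwas_p <= 1):
            raise ValidationError(
                f"{self.rsid}: gwas_p must lie in (0, 1], got {self.gwas_p}"
            )


class GwasHitList:
    """Top SNPs from one GWAS primary analysis (one diagnosis/ancestry
    stratum), already filtered at the inclusion threshold."""

    def __init__(
        self,
        analysis_label: str,
        frame: pd.DataFrame,
        read_stats: ReadStats | None = None,
    ):
        required = ["rsid", "gwas_p"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise FormatError(f"hit list frame missing column(s): {missing}")
        frame = frame.loc[:, required].reset_index(drop=True)
        frame["rsid"] = frame["rsid"].astype(str)
        dup = frame["rsid"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate rsid in hit list {analysis_label!r}: "
                f"{frame.loc[dup.idxmax(), 'rsid']!r}"
            )
        frame["gwas_p"] = pd.to_numeric(frame["gwas_p"], errors="raise").astype(float)
        bad = ~((frame["gwas_p"] > 0) & (frame["gwas_p"] <= 1))
        if bad.any():
            raise ValidationError(
                f"gwas_p outside (0, 1] for SNP "
                f"{frame.loc[bad.idxmax(), 'rsid']!r}"
            )
        self.analysis_label = analysis_label
        self.frame = frame
        self.read_stats = read_stats

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        return f"GwasHitList({self.analysis_label!r}, n={len(self)})"

    @property
    def rsids(self) -> np.ndarray:
        return self.frame["rsid"].to_numpy()

    def hits(self) -> list[GwasHit]:
        return [
            GwasHit(r.rsid, float(r.gwas_p)) for r in self.frame.itertuples(index=False)
        ]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _resolve_columns(
    df: pd.DataFrame, required: Sequence[str], dialect: Mapping[str, str] | None, path
) -> pd.DataFrame:
    """Rename source columns to canonical names per the dialect, then check
    that every required canonical column is present."""
    if dialect:
        rename = {src: canon for canon, src in dialect.items() if src in df.columns}
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)} (use a dialect mapping to rename)"
        )
    return df


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file has no header row") from None


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna() & df[col].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise FormatError(
            f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
            f"in column {col!r} on line {line}"
        )
    if values.isna().any():
        line = int(np.flatnonzero(values.isna().to_numpy())[0]) + 2
        raise FormatError(f"{path}: missing value in column {col!r} on line {line}")
    return values.to_numpy()


def read_snp_universe(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    platform_label: str | None = None,
) -> SnpUniverse:
    """Read a SNP manifest TSV (``rsid  chrom  pos  maf``) into a
    :class:`SnpUniverse`.

    Duplicate rsids and out-of-range MAFs raise :class:`ValidationError`
    citing the offending line; row order is preserved.
    """
    df = _read_tsv(path)
    df = _resolve_columns(df, ["rsid", "chrom", "pos", "maf"], dialect, path)
    maf = _numeric(df, "maf", path)
    out = ~((maf >= 0) & (maf <= 0.5))
    if out.any():
        line = int(np.flatnonzero(out)[0]) + 2
        raise ValidationError(
            f"{path}: maf={maf[out.argmax()]} outside [0, 0.5] on line {line}"
        )
    dup = df["rsid"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValidationError(
            f"{path}: duplicate rsid {df['rsid'][dup.idxmax()]!r} on line {line}"
        )
    frame = pd.DataFrame(
        {
            "rsid": df["rsid"],
            "chrom": df["chrom"],
            "pos": _numeric(df, "pos", path).astype(np.int64),
            "maf": maf,
        }
    )
    stats = ReadStats(ingested=len(df), kept=len(df))
    logger.info(
        "read_snp_universe(%s): ingested=%d kept=%d dropped=0 rejected=0",
        path,
        stats.ingested,
        stats.kept,
    )
    return SnpUniverse(
        frame,
        platform_label=platform_label or Path(path).stem,
        read_stats=stats,
    )


def read_gwas_hits(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    threshold: float = 1e-3,
    analysis_label: str | None = None,
) -> GwasHitList:
    """Read a GWAS top-SNP TSV (``rsid  gwas_p``), keeping only rows with
    ``gwas_p <= threshold``.

    Filtering is applied here rather than trusted from the source file: the
    canonical inputs are pre-filtered, but arbitrary re-users' files may not
    be.  The number of dropped rows is logged and recorded in
    ``result.read_stats``.
    """
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold}")
    df = _read_tsv(path)
    df = _resolve_columns(df, ["rsid", "gwas_p"], dialect, path)
    gwas_p = _numeric(df, "gwas_p", path)
    bad = ~((gwas_p > 0) & (gwas_p <= 1))
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValidationError(
            f"{path}: gwas_p={gwas_p[bad.argmax()]} outside (0, 1] on line {line}"
        )
    keep = gwas_p <= threshold
    dropped = int((~keep).sum())
    frame = pd.DataFrame({"rsid": df["rsid"][keep], "gwas_p": gwas_p[keep]})
    stats = ReadStats(ingested=len(df), kept=int(keep.sum()), dropped=dropped)
    if stats.kept == 0:
        logger.warning("read_gwas_hits(%s): no rows pass threshold %g", path, threshold)
    logger.info(
        "read_gwas_hits(%s): ingested=%d kept=%d dropped=%d rejected=0",
        path,
        stats.ingested,
        stats.kept,
        dropped,
    )
    return GwasHitList(
        analysis_label or Path(path).stem, frame.reset_index(drop=True), stats
    )


def read_eqtl_table(
    path: str | Path,
    tissue: str,
    dialect: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a raw per-tissue eQTL association TSV
    (``rsid  gene  probe_chrom  probe_pos  eqtl_p``).

    Rows are tagged with ``tissue``; ``regulation`` and ``significant`` are
    deliberately *not* derived here — that is the annotation stage's job.
    Duplicate (rsid, gene) rows are kept and warned about (deduplication
    belongs to the summary stage).  P-values of exactly 0 are rejected rather
    than clamped, since they signal an upstream computation problem.
    """
    df = _read_tsv(path)
    df = _resolve_columns(
        df, ["rsid", "gene", "probe_chrom", "probe_pos", "eqtl_p"], dialect, path
    )
    eqtl_p = _numeric(df, "eqtl_p", path)
    bad = ~((eqtl_p > 0) & (eqtl_p <= 1))
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValidationError(
            f"{path}: eqtl_p={eqtl_p[bad.argmax()]} outside (0, 1] on line {line}"
        )
    probe_pos = _numeric(df, "probe_pos", path).astype(np.int64)
    if (probe_pos < 1).any():
        line = int(np.flatnonzero(probe_pos < 1)[0]) + 2
        raise ValidationError(f"{path}: probe_pos < 1 on line {line}")
    out = pd.DataFrame(
        {
            "rsid": df["rsid"].astype(str),
            "tissue": tissue,
            "gene": df["gene"].astype(str),
            "probe_chrom": df["probe_chrom"].map(normalize_chrom),
            "probe_pos": probe_pos,
            "eqtl_p": eqtl_p,
        }
    )
    ndup = int(out.duplicated(subset=["rsid", "gene"]).sum())
    if ndup:
        logger.warning(
            "read_eqtl_table(%s): %d duplicate (rsid, gene) rows kept", path, ndup
        )
    stats = ReadStats(ingested=len(df), kept=len(out))
    out.attrs["read_stats"] = stats
    logger.info(
        "read_eqtl_table(%s, %s): ingested=%d kept=%d dropped=0 rejected=0",
        path,
        tissue,
        stats.ingested,
        stats.kept,
    )
    return out


# ---------------------------------------------------------------------------
# report writers / round-trip readers
# ---------------------------------------------------------------------------

_GENE_SUMMARY_COLUMNS = [
    "gene",
    "n_distinct_snps",
    "n_analyses",
    "tissues",
    "analyses",
    "regulation_classes",
    "snp_rsids",
]


def write_report(result, path: str | Path) -> None:
    """Serialise an :class:`~eqtlenrich.enrichment.EnrichmentResult` (JSON
    plus a ``*_null_counts.tsv`` companion holding the full null
    distribution) or a list of :class:`~eqtlenrich.summarize.GeneSummary`
    (TSV) with a deterministic field order, such that re-reading reproduces
    the object."""
    from .enrichment import EnrichmentResult
    from .summarize import GeneSummary

    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(result, EnrichmentResult):
        payload = result.to_dict()
        null_counts = payload.pop("null_counts")
        payload["null_counts_file"] = path.with_suffix("").name + "_null_counts.tsv"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=False)
            fh.write("\n")
        pd.DataFrame({"null_set": np.arange(len(null_counts)), "eqtl_count": null_counts}).to_csv(
            path.parent / payload["null_counts_file"], sep="\t", index=False
        )
    elif isinstance(result, (list, tuple)) and all(
        isinstance(g, GeneSummary) for g in result
    ):
        rows = [
            {
                "gene": g.gene,
                "n_distinct_snps": g.n_distinct_snps,
                "n_analyses": len(g.analyses),
                "tissues": ",".join(sorted(g.tissues)),
                "analyses": ",".join(sorted(g.analyses)),
                "regulation_classes": ",".join(sorted(g.regulation_classes)),
                "snp_rsids": ",".join(sorted(g.snp_rsids)),
            }
            for g in result
        ]
        pd.DataFrame(rows, columns=_GENE_SUMMARY_COLUMNS).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise TypeError(f"cannot serialise object of type {type(result)!r}")


def read_enrichment_result(path: str | Path):
    """Round-trip reader for :func:`write_report` JSON output."""
    from .enrichment import EnrichmentResult

    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    counts_file = path.parent / payload.pop("null_counts_file")
    payload["null_counts"] = pd.read_csv(counts_file, sep="\t")["eqtl_count"].to_numpy()
    return EnrichmentResult.from_dict(payload)


def read_gene_summaries(path: str | Path):
    """Round-trip reader for the gene-summary TSV."""
    from .summarize import GeneSummary

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for r in df.itertuples(index=False):
        out.append(
            GeneSummary(
                gene=r.gene,
                tissues=frozenset(filter(None, r.tissues.split(","))),
                analyses=frozenset(filter(None, r.analyses.split(","))),
                regulation_classes=frozenset(
                    filter(None, r.regulation_classes.split(","))
                ),
                snp_rsids=frozenset(filter(None, r.snp_rsids.split(","))),
            )
        )
    return out
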
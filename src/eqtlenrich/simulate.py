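"""Synthetic SNP universes, eQTL maps and GWAS hit lists.

The generator emulates the statistical structure the enrichment analysis
assumes, so every stage of the pipeline can be exercised end-to-end without
any external download:

* a SNP universe over a synthetic genome (22 autosomes of 250 Mb) with a
  configurable MAF distribution;
* per-tissue binary eQTL status — each SNP is independently a significant
  eQTL with a base rate that may vary by MAF bin — realised as raw
  association rows whose probe placement and P-value are consistent with the
  drawn cis/trans class, plus non-significant decoy rows that straddle the
  significance thresholds;
* GWAS top-SNP lists drawn without replacement with a planted enrichment:
  eQTL SNPs enter the list with odds multiplied by ``enrichment_multiplier``
  (multiplier 1 = the null, simple random sampling).

Enrichment is planted through the hit-list sampling weights rather than by
re-labelling eQTL status among hits, which keeps the universe's annotation
fixed — mirroring the real workflow where the eQTL map exists before the
GWAS list is drawn.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigError, ValidationError
from .config import EnrichmentConfig
from .enrichment import assign_maf_bin
from .io import EQTL_COLUMNS, GwasHitList, SnpUniverse

__all__ = [
    "SimConfig",
    "EqtlMap",
    "StudyBundle",
    "simulate_universe",
    "simulate_eqtl_map",
    "simulate_gwas_hits",
    "simulate_study",
]

N_CHROMS = 22
CHROM_LENGTH = 250_000_000
# nearby cis targets share a gene label at this granularity, giving the
# multiply-implicated-gene pattern real data shows
_GENE_BLOCK_BP = 2_000_000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults match the scale the enrichment properties are stated at: a
    50,000-SNP universe, 500-SNP hit lists, a 5% per-tissue eQTL base rate,
    and the observed tissue/analysis layout (two brain tissues plus LCL,
    four overlapping GWAS primary analyses).  ``enrichment_multiplier`` is
    the planted effect: 1 is the null.
    """

    n_universe: int = 50_000
    maf_model: tuple = ("uniform", 0.01, 0.5)
    tissue_labels: tuple = ("parietal", "cerebellum", "lcl")
    analysis_labels: tuple = (
        "Spec|All",
        "Strict|All",
        "Spec|WestEur",
        "Strict|WestEur",
    )
    eqtl_base_rate: float | tuple = 0.05
    multi_gene_rate: float = 0.16
    cis_fraction: float = 0.58
    decoy_rate: float = 0.10
    n_hits: int = 500
    enrichment_multiplier: float = 1.0
    enriched_tissues: tuple | None = None
    seed: int = 0
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def __post_init__(self) -> None:
        if self.n_universe < 1:
            raise ConfigError("n_universe must be >= 1")
        if not (0 < self.n_hits <= self.n_universe):
            raise ConfigError("need 0 < n_hits <= n_universe")
        for name in ("multi_gene_rate", "cis_fraction", "decoy_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        rates = np.atleast_1d(np.asarray(self.eqtl_base_rate, dtype=float))
        if np.any((rates < 0) | (rates > 1)):
            raise ConfigError("eqtl_base_rate values must lie in [0, 1]")
        if rates.size not in (1, self.enrichment.n_bins):
            raise ConfigError(
                f"eqtl_base_rate must be scalar or length {self.enrichment.n_bins}"
            )
        if self.enrichment_multiplier < 0:
            raise ConfigError("enrichment_multiplier must be >= 0")
        kind = self.maf_model[0]
        if kind == "uniform":
            _, lo, hi = self.maf_model
            if not (0 <= lo < hi <= 0.5):
                raise ConfigError(f"uniform MAF bounds must satisfy 0<=lo<hi<=0.5")
        elif kind == "beta":
            _, a, b = self.maf_model
            if a <= 0 or b <= 0:
                raise ConfigError("beta MAF shape parameters must be positive")
        else:
            raise ConfigError(f"unknown maf_model kind: {kind!r}")

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    @property
    def effective_enriched_tissues(self) -> tuple:
        """Tissues whose eQTL SNPs receive the planted hit-list weight:
        every non-LCL tissue by default, else the first tissue."""
        if self.enriched_tissues is not None:
            unknown = set(self.enriched_tissues) - set(self.tissue_labels)
            if unknown:
                raise ConfigError(f"enriched_tissues not simulated: {sorted(unknown)}")
            return tuple(self.enriched_tissues)
        non_lcl = tuple(t for t in self.tissue_labels if t.lower() != "lcl")
        return non_lcl or (self.tissue_labels[0],)

    def per_bin_rates(self) -> np.ndarray:
        rates = np.atleast_1d(np.asarray(self.eqtl_base_rate, dtype=float))
        if rates.size == 1:
            rates = np.full(self.enrichment.n_bins, float(rates[0]))
        return rates


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    # one deterministic stream per generator stage, all rooted at cfg.seed
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


def simulate_universe(cfg: SimConfig) -> SnpUniverse:
    """Draw a synthetic platform manifest: rsids ``sim_rs000001...``,
    positions uniform over 22 autosomes of 250 Mb, MAFs from
    ``cfg.maf_model``.  Deterministic given ``cfg.seed``."""
    rng = _rng(cfg, 1)
    n = cfg.n_universe
    kind = cfg.maf_model[0]
    if kind == "uniform":
        _, lo, hi = cfg.maf_model
        maf = rng.uniform(lo, hi, size=n)
    else:  # beta, scaled onto (0, 0.5]
        _, a, b = cfg.maf_model
        maf = 0.5 * rng.beta(a, b, size=n)
    frame = pd.DataFrame(
        {
            "rsid": [f"sim_rs{i + 1:06d}" for i in range(n)],
            "chrom": rng.integers(1, N_CHROMS + 1, size=n).astype(str),
            "pos": rng.integers(1, CHROM_LENGTH + 1, size=n),
            "maf": maf,
        }
    )
    return SnpUniverse(frame, platform_label=f"synthetic-{n}")


@dataclass
class EqtlMap:
    """Per-tissue synthetic eQTL association tables plus the ground-truth
    significance flags used to plant hit-list enrichment.

    ``tables[tissue]`` is a raw association DataFrame in the canonical
    column layout; ``truth_flags[tissue]`` is a boolean array over universe
    rows marking the SNPs generated as significant eQTLs there.
    """

    tables: dict
    truth_flags: dict

    def truth_union(self, tissues) -> np.ndarray:
        flags = [self.truth_flags[t] for t in tissues]
        return np.logical_or.reduce(flags)


def _place_probes(
    chrom: np.ndarray,
    pos: np.ndarray,
    is_cis: np.ndarray,
    cis_window_bp: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Probe coordinates consistent with each row's cis/trans class.

    Cis probes land within the window on the SNP's chromosome (clipping to
    the chromosome keeps the distance inside the window); trans probes land
    uniformly on a different chromosome.
    """
    n = len(pos)
    offset = rng.integers(-cis_window_bp, cis_window_bp + 1, size=n)
    probe_pos = np.clip(pos + offset, 1, CHROM_LENGTH)
    probe_chrom = chrom.astype(np.int64).copy()
    n_trans = int((~is_cis).sum())
    if n_trans:
        shift = rng.integers(1, N_CHROMS, size=n_trans)
        probe_chrom[~is_cis] = (probe_chrom[~is_cis] - 1 + shift) % N_CHROMS + 1
        probe_pos[~is_cis] = rng.integers(1, CHROM_LENGTH + 1, size=n_trans)
    return probe_chrom, probe_pos


def _log_uniform(
    lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_eqtl_map(universe: SnpUniverse, cfg: SimConfig) -> EqtlMap:
    """Generate one raw eQTL association table per tissue.

    Each SNP is independently flagged as a significant eQTL per tissue with
    its MAF bin's base rate.  Flagged SNPs receive a cis row (probability
    ``cis_fraction``) or trans row with a P-value log-uniform between 1e-12
    and the class threshold, and with probability ``multi_gene_rate`` a
    second target gene; unflagged SNPs receive a decoy row (probability
    ``decoy_rate``) with a P-value log-uniform between the class threshold
    and 1, exercising the significance boundary without crossing it.
    """
    rng = _rng(cfg, 2)
    ecfg = cfg.enrichment
    n = len(universe)
    chrom = universe.frame["chrom"].to_numpy()
    pos = universe.frame["pos"].to_numpy()
    rates = cfg.per_bin_rates()[assign_maf_bin(universe.maf, ecfg)]
    thresholds = {"cis": ecfg.cis_alpha, "trans": ecfg.trans_alpha}

    tables, truth = {}, {}
    for tissue in cfg.tissue_labels:
        flag = rng.random(n) < rates
        rows = []
        # significant rows: one per flagged SNP plus optional second target
        sig_idx = np.flatnonzero(flag)
        extra = sig_idx[rng.random(sig_idx.size) < cfg.multi_gene_rate]
        for idx in (sig_idx, extra):
            if idx.size == 0:
                continue
            is_cis = rng.random(idx.size) < cfg.cis_fraction
            p = np.where(
                is_cis,
                _log_uniform(1e-12, thresholds["cis"], idx.size, rng),
                _log_uniform(1e-12, thresholds["trans"], idx.size, rng),
            )
            # a hair below the threshold to be safe against fp rounding
            p = np.minimum(p, np.where(is_cis, thresholds["cis"], thresholds["trans"]) * 0.999)
            pc, pp = _place_probes(chrom[idx], pos[idx], is_cis, ecfg.cis_window_bp, rng)
            rows.append((idx, is_cis, pc, pp, p))
        # decoy rows: non-significant, straddling the thresholds from above
        decoy_idx = np.flatnonzero(~flag)
        decoy_idx = decoy_idx[rng.random(decoy_idx.size) < cfg.decoy_rate]
        if decoy_idx.size:
            is_cis = rng.random(decoy_idx.size) < cfg.cis_fraction
            p = np.where(
                is_cis,
                _log_uniform(thresholds["cis"], 1.0, decoy_idx.size, rng),
                _log_uniform(thresholds["trans"], 1.0, decoy_idx.size, rng),
            )
            p = np.maximum(
                p, np.where(is_cis, thresholds["cis"], thresholds["trans"])
            )
            pc, pp = _place_probes(
                chrom[decoy_idx], pos[decoy_idx], is_cis, ecfg.cis_window_bp, rng
            )
            rows.append((decoy_idx, is_cis, pc, pp, p))

        if rows:
            idx = np.concatenate([r[0] for r in rows])
            probe_chrom = np.concatenate([r[2] for r in rows])
            probe_pos = np.concatenate([r[3] for r in rows])
            p = np.concatenate([r[4] for r in rows])
            gene = np.char.add(
                np.char.add("G", probe_chrom.astype(str)),
                np.char.add("_", (probe_pos // _GENE_BLOCK_BP).astype(str)),
            )
            table = pd.DataFrame(
                {
                    "rsid": universe.rsids[idx],
                    "tissue": tissue,
                    "gene": gene,
                    "probe_chrom": probe_chrom.astype(str),
                    "probe_pos": probe_pos.astype(np.int64),
                    "eqtl_p": p,
                }
            )
        else:
            table = pd.DataFrame(columns=EQTL_COLUMNS)
        tables[tissue] = table
        truth[tissue] = flag
    return EqtlMap(tables=tables, truth_flags=truth)


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Sequential weighted draw of k items without replacement
    (exponential-keys construction: smallest Exp(1)/w win)."""
    keys = rng.exponential(size=weights.size) / weights
    if k >= weights.size:
        return np.arange(weights.size)
    return np.argpartition(keys, k - 1)[:k]


def simulate_gwas_hits(
    universe: SnpUniverse,
    eqtl_map: EqtlMap,
    tissue,
    cfg: SimConfig,
    analysis_label: str = "sim",
    rng: np.random.Generator | None = None,
) -> GwasHitList:
    """Draw a top-SNP list with planted enrichment for a tissue (or an
    iterable of tissues, enriched for their union of eQTL SNPs).

    SNPs enter the ``n_hits``-sized list by sequential weighted sampling
    without replacement with weight ``enrichment_multiplier`` for eQTL SNPs
    and 1 otherwise; multiplier 1 is simple random sampling.  GWAS P-values
    are uniform on (0, gwas_p_threshold].
    """
    if rng is None:
        rng = _rng(cfg, 3)
    tissues = (tissue,) if isinstance(tissue, str) else tuple(tissue)
    flag = eqtl_map.truth_union(tissues)
    weights = np.where(flag, cfg.enrichment_multiplier, 1.0)
    if not np.any(weights > 0):
        raise ValidationError("all sampling weights are zero")
    weights = np.where(weights > 0, weights, 1e-300)  # multiplier 0: exclude softly
    idx = _weighted_sample_without_replacement(weights, cfg.n_hits, rng)
    gwas_p = cfg.enrichment.gwas_p_threshold * (
        1.0 - rng.random(idx.size)
    )  # uniform on (0, threshold]
    frame = pd.DataFrame({"rsid": universe.rsids[idx], "gwas_p": gwas_p})
    return GwasHitList(analysis_label, frame)


@dataclass
class StudyBundle:
    """A complete synthetic study: universe, per-tissue eQTL tables and one
    hit list per GWAS primary analysis."""

    universe: SnpUniverse
    eqtl_map: EqtlMap
    hit_lists: list
    config: SimConfig

    def write(self, out_dir: str | Path) -> dict:
        """Write the bundle in the pipeline's canonical TSV formats plus a
        ``manifest.json`` recording the generating configuration and seed.
        Returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"universe": out / "snp_universe.tsv"}
        self.universe.frame.to_csv(paths["universe"], sep="\t", index=False)
        for tissue, table in self.eqtl_map.tables.items():
            p = out / f"eqtl_{tissue}.tsv"
            table.drop(columns=["tissue"], errors="ignore").to_csv(
                p, sep="\t", index=False
            )
            paths[f"eqtl_{tissue}"] = p
        for hits in self.hit_lists:
            slug = hits.analysis_label.replace("|", "_").replace("/", "_")
            p = out / f"gwas_hits_{slug}.tsv"
            hits.frame.to_csv(p, sep="\t", index=False)
            paths[f"hits_{hits.analysis_label}"] = p
        cfg_dict = dataclasses.asdict(self.config)
        cfg_dict["enrichment"] = self.config.enrichment.to_dict()
        manifest = {
            "seed": int(self.config.seed),
            "sim_config": cfg_dict,
            "files": {k: v.name for k, v in paths.items()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=list)
            fh.write("\n")
        paths["manifest"] = out / "manifest.json"
        return paths


def simulate_study(cfg: SimConfig, out_dir: str | Path | None = None) -> StudyBundle:
    """Generate the full fixture set: universe, eQTL maps for every tissue
    and one planted-enrichment hit list per analysis label.

    Analyses share the enriched sampling frame (weights from the union of
    ``effective_enriched_tissues``), so their lists overlap the way
    non-independent GWAS strata do.  With ``out_dir`` set the bundle is also
    written in the canonical TSV formats.
    """
    universe = simulate_universe(cfg)
    eqtl_map = simulate_eqtl_map(universe, cfg)
    rng = _rng(cfg, 3)
    hit_lists = [
        simulate_gwas_hits(
            universe,
            eqtl_map,
            cfg.effective_enriched_tissues,
            cfg,
            analysis_label=label,
            rng=rng,
        )
        for label in cfg.analysis_labels
    ]
    bundle = StudyBundle(
        universe=universe, eqtl_map=eqtl_map, hit_lists=hit_lists, config=cfg
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
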
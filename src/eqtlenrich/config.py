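"""Analysis configuration.

:class:`EnrichmentConfig` gathers every threshold and tuning constant of the
enrichment pipeline in one serialisable object.  Defaults reproduce the
standard study design: SNPs within 4 Mb of the expression probe are *cis*
candidates tested at P < 1e-4, all other SNP-probe pairs are *trans* and held
to the Bonferroni threshold 0.05 / 25,834 probes, GWAS hit lists are truncated
at P < 1e-3, and the null is built from 1,000 randomized SNP sets matched on
minor allele frequency in ten 5% bins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from ._errors import ConfigError

__all__ = ["EnrichmentConfig"]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Thresholds and sampling parameters for the enrichment analysis.

    Parameters
    ----------
    n_null_sets : int
        Number of randomized MAF-matched SNP sets forming the null
        distribution.
    bin_width : float
        Width of each minor-allele-frequency bin (fraction, not percent).
    n_bins : int
        Number of MAF bins; ``n_bins * bin_width`` must cover (0, 0.5].
    cis_window_bp : int
        Maximum SNP-to-probe distance (bp, inclusive) for a *cis* eQTL on the
        same chromosome.
    cis_alpha : float
        Significance threshold for cis eQTL P-values (strict ``<``).
    trans_alpha_numerator : float
        Numerator of the Bonferroni trans threshold; the effective trans
        alpha is ``trans_alpha_numerator / n_probes``.
    n_probes : int
        Number of expression probes used for the trans Bonferroni correction.
    gwas_p_threshold : float
        Inclusion threshold applied to GWAS association P-values at read time.
    seed : int
        Default seed for the null-set sampler (overridable per run).
    """

    n_null_sets: int = 1000
    bin_width: float = 0.05
    n_bins: int = 10
    cis_window_bp: int = 4_000_000
    cis_alpha: float = 1e-4
    trans_alpha_numerator: float = 0.05
    n_probes: int = 25_834
    gwas_p_threshold: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null_sets < 1:
            raise ConfigError("n_null_sets must be a positive integer")
        if not (0 < self.bin_width <= 0.5):
            raise ConfigError("bin_width must lie in (0, 0.5]")
        if self.n_bins < 1:
            raise ConfigError("n_bins must be positive")
        # bins must tile (0, 0.5] exactly so maf=0.5 lands in the top bin
        if abs(self.n_bins * self.bin_width - 0.5) > 1e-9:
            raise ConfigError(
                f"n_bins * bin_width must equal 0.5, got "
                f"{self.n_bins} * {self.bin_width} = {self.n_bins * self.bin_width}"
            )
        if self.cis_window_bp < 0:
            raise ConfigError("cis_window_bp must be non-negative")
        for name in ("cis_alpha", "trans_alpha_numerator", "gwas_p_threshold"):
            value = getattr(self, name)
            if not (0 < value < 1):
                raise ConfigError(f"{name} must lie in (0, 1), got {value}")
        if self.n_probes < 1:
            raise ConfigError("n_probes must be positive")

    @property
    def trans_alpha(self) -> float:
        """Effective trans-eQTL significance threshold (0.05 / n_probes)."""
        return self.trans_alpha_numerator / self.n_probes

    def replace(self, **changes) -> "EnrichmentConfig":
        return dataclasses.replace(self, **changes)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EnrichmentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnrichmentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
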
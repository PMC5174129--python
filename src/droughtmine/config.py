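"""Analysis configuration: every tunable threshold of the pipeline in one place.

The defaults are the study's printed constants: DEG calling at FDR < 0.05
(replicated libraries) or p < 0.05 (unreplicated), |log2FC| >= 1, the 1e-5
FPKM pseudocount, the VIP > 1.0 / p < 0.05 dual criterion for differential
metabolites, the |r| > 0.6 / p < 0.05 Pearson rule, heatmap caps of +-6
(genes) and +-10 (metabolites), and the 18% / 15% soil-water-content
thresholds separating mild from severe drought.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when an AnalysisConfig violates its invariants."""


_PROPORTIONS = (
    "deg_fdr_threshold",
    "deg_p_threshold",
    "dm_p_threshold",
    "corr_r_threshold",
    "corr_p_threshold",
)
_POSITIVE = _PROPORTIONS + (
    "deg_lfc_threshold",
    "fpkm_pseudocount",
    "vip_threshold",
    "heatmap_cap_genes",
    "heatmap_cap_metabolites",
    "swc_mild_threshold",
    "swc_severe_threshold",
    "divergence_lfc_threshold",
    "opls_tol",
)


@dataclass
class AnalysisConfig:
    """Thresholds and switches for every pipeline stage.

    Attributes
    ----------
    deg_fdr_threshold, deg_p_threshold, deg_lfc_threshold
        Significance and effect-size cut-offs for DEG calling.
    fpkm_pseudocount
        Added to both FPKM means before the log2 ratio so the fold change
        is finite for zero expression.
    vip_threshold, dm_p_threshold
        Dual criterion for differential metabolites.
    corr_r_threshold, corr_p_threshold
        Pearson edge retention rule, applied two-sided on |r|.
    heatmap_cap_genes, heatmap_cap_metabolites
        Symmetric clamps applied to log2FC profiles destined for heatmaps.
    swc_mild_threshold, swc_severe_threshold
        Soil water content (%) cut-offs for drought periods I and II.
    divergence_lfc_threshold
        Minimum |difference of mean log2FC between genotypes| (in any
        drought period) for a metabolite to count as divergently regulated.
    ttest_variant
        "welch" (default) or "student" for all two-sample t-tests.
    dev_dependent_scope
        "per_genotype" (default) or "global": whether the development-
        dependent exclusion set is built and applied per genotype or pooled.
    trait_corr_mode
        "replicate" (default): correlate drought-sample feature values
        against replicate-level trait values. "profile": correlate
        per-timepoint log2FC against the trait's drought/watered fold change.
    metabolite_missing_policy
        "propagate" (default): missing peaks stay NA through normalization
        and are dropped only where a model needs a complete matrix.
        "drop": metabolites with any missing value are removed up front.
    n_orthogonal
        Orthogonal components in the OPLS-DA model (0 = plain PLS-DA).
    """

    deg_fdr_threshold: float = 0.05
    deg_p_threshold: float = 0.05
    deg_lfc_threshold: float = 1.0
    fpkm_pseudocount: float = 0.00001
    vip_threshold: float = 1.0
    dm_p_threshold: float = 0.05
    corr_r_threshold: float = 0.6
    corr_p_threshold: float = 0.05
    heatmap_cap_genes: float = 6.0
    heatmap_cap_metabolites: float = 10.0
    swc_mild_threshold: float = 18.0
    swc_severe_threshold: float = 15.0
    divergence_lfc_threshold: float = 1.0
    ttest_variant: str = "welch"
    dev_dependent_scope: str = "per_genotype"
    trait_corr_mode: str = "replicate"
    metabolite_missing_policy: str = "propagate"
    n_orthogonal: int = 1
    opls_tol: float = 1e-10
    opls_max_iter: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _POSITIVE:
            value = getattr(self, name)
            if not (value > 0):
                raise ConfigError(f"{name} must be strictly positive, got {value!r}")
        for name in _PROPORTIONS:
            value = getattr(self, name)
            if value > 1:
                raise ConfigError(f"{name} is a proportion and must be <= 1, got {value!r}")
        if not self.swc_severe_threshold < self.swc_mild_threshold:
            raise ConfigError(
                "swc_severe_threshold must be below swc_mild_threshold "
                f"({self.swc_severe_threshold} vs {self.swc_mild_threshold})"
            )
        if self.ttest_variant not in ("welch", "student"):
            raise ConfigError(f"unknown ttest_variant {self.ttest_variant!r}")
        if self.dev_dependent_scope not in ("per_genotype", "global"):
            raise ConfigError(f"unknown dev_dependent_scope {self.dev_dependent_scope!r}")
        if self.trait_corr_mode not in ("replicate", "profile"):
            raise ConfigError(f"unknown trait_corr_mode {self.trait_corr_mode!r}")
        if self.metabolite_missing_policy not in ("propagate", "drop"):
            raise ConfigError(
                f"unknown metabolite_missing_policy {self.metabolite_missing_policy!r}"
            )
        if self.n_orthogonal < 0:
            raise ConfigError("n_orthogonal must be >= 0")
        if self.opls_max_iter < 1:
            raise ConfigError("opls_max_iter must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
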
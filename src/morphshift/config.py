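"""Parameter blocks for every pipeline stage, plus YAML loading.

Defaults follow the study design the package targets: 4 CP + 4 OP clonal
lineages with 2 replicates per (lineage, morph), TMM at the 0.75 quantile,
CPM > 1 expression filtering, exact-test classification at adjusted
p < 0.05 with |log2FC| > 1 (biased) and > 2 (limited), and an OP-to-CP
log2 ratio with a 0.05 CPM pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class NormalizationParams:
    ref_quantile: float = 0.75
    logratio_trim: float = 0.30
    abs_trim: float = 0.05
    cpm_threshold: float = 1.0
    min_libraries: int = 8

    def __post_init__(self) -> None:
        if not (0 <= self.logratio_trim < 0.5 and 0 <= self.abs_trim < 0.5):
            raise ValueError("trim fractions must lie in [0, 0.5)")
        if self.cpm_threshold <= 0:
            raise ValueError("cpm_threshold must be positive")
        if self.min_libraries < 1:
            raise ValueError("min_libraries must be >= 1")


@dataclass
class ClassificationParams:
    alpha: float = 0.05
    lfc_biased: float = 1.0
    lfc_limited: float = 2.0
    prior_count: float = 2.0  # count-scale prior used in fold-change CPMs
    dispersion: str = "common"  # reserved switch; only "common" implemented

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.lfc_limited > self.lfc_biased > 0:
            raise ValueError("need lfc_limited > lfc_biased > 0")
        if self.dispersion != "common":
            raise ValueError("only common dispersion is implemented")


@dataclass
class ShiftParams:
    pseudocount: float = 0.05  # CPM added to numerator and denominator

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class VariantFilterParams:
    min_gq: float = 20.0   # strict: GQ must exceed this
    min_depth: float = 80.0  # inclusive: DP >= min_depth in every library
    require_all_samples: bool = True

    def __post_init__(self) -> None:
        if self.min_gq < 0 or self.min_depth < 0:
            raise ValueError("thresholds must be non-negative")


def _normalize_shift_spec(spec: dict) -> dict:
    """Accept (morph, selector) tuples, 'morph|selector' strings, or a
    nested morph -> selector -> delta mapping (the YAML-friendly form)."""
    out: dict[tuple[str, str], float] = {}
    for key, value in (spec or {}).items():
        if isinstance(key, tuple):
            out[(key[0], key[1])] = float(value)
        elif isinstance(value, dict):
            for selector, delta in value.items():
                out[(str(key), str(selector))] = float(delta)
        elif isinstance(key, str) and "|" in key:
            morph, selector = key.split("|", 1)
            out[(morph, selector)] = float(value)
        else:
            raise ValueError(f"cannot interpret shift_spec entry {key!r}")
    return out


@dataclass
class SimulationConfig:
    """Synthetic RNA-seq study design.

    The focal design is 4 CP lineages x 3 morphs x 2 replicates plus 4 OP
    lineages x 2 morphs x 2 replicates (40 libraries); the whole-body
    outgroup has 3 morphs x 2 replicates and the tissue outgroup
    3 morphs x 3 tissues x 2 replicates.
    """

    n_genes: int = 4000
    frac_class: dict = field(
        default_factory=lambda: {"M": 0.10, "F": 0.10, "P": 0.10, "unbiased": 0.70}
    )
    lfc_bias: float = 2.0        # log2 morph effect for biased (+) genes
    lfc_limited: float = 3.5     # log2 morph effect for limited (++) genes
    lfc_limited_frac: float = 0.3  # fraction of biased genes that are limited
    tissue_bias_frac: float = 0.5  # fraction of biased genes with a tissue bias
    tissue_lfc: float = 2.5      # log2 tissue effect within the bias morph
    shift_spec: dict = field(default_factory=dict)  # (morph, selector) -> delta
    # per-gene NB dispersion ~ logNormal(log(phi_median), phi_sigma)
    phi_median: float = 0.05
    phi_sigma: float = 0.4
    # baseline log2 CPM-scale expression ~ Normal(base_log2_mean, base_log2_sd)
    base_log2_mean: float = 5.0
    base_log2_sd: float = 2.0
    # library sizes ~ logNormal around libsize_mean with CV libsize_cv
    libsize_mean: float = 1.5e6
    libsize_cv: float = 0.15
    n_lineages_per_mode: int = 4
    n_replicates: int = 2
    lineage_sd: float = 0.08     # SD of per-(lineage, gene) log2 random effect
    frac_x_linked: float = 0.3
    x_male_bias_enrichment: float = 0.0  # extra X probability for M-class genes
    seed: int = 0

    def __post_init__(self) -> None:
        self.shift_spec = _normalize_shift_spec(self.shift_spec)
        total = sum(self.frac_class.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frac_class must sum to 1 (got {total})")
        if set(self.frac_class) != {"M", "F", "P", "unbiased"}:
            raise ValueError("frac_class must have keys M, F, P, unbiased")
        for name in ("lfc_limited_frac", "tissue_bias_frac", "frac_x_linked"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.phi_median <= 0:
            raise ValueError("dispersion median must be positive")
        if self.n_genes < 1 or self.n_lineages_per_mode < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class GenotypeSimConfig:
    """Synthetic biallelic SNP genotypes for 2 mode clusters of lineages."""

    n_snps: int = 5000
    n_lineages_per_mode: int = 4
    divergence_between_mode: float = 0.15  # SD of mode-level allele-freq drift
    divergence_within_mode: float = 0.05   # SD of lineage-level drift
    depth_mean: float = 120.0
    gq_mean: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_lineages_per_mode < 1:
            raise ValueError("counts must be >= 1")
        if self.divergence_between_mode < 0 or self.divergence_within_mode < 0:
            raise ValueError("drift SDs must be non-negative")


@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulation mode or file inputs)."""

    simulate: bool = True
    counts_path: str | None = None
    metadata_path: str | None = None
    outgroup_counts_path: str | None = None
    outgroup_metadata_path: str | None = None
    tissue_counts_path: str | None = None
    tissue_metadata_path: str | None = None
    annotation_path: str | None = None
    vcf_path: str | None = None

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    genotype_sim: GenotypeSimConfig = field(default_factory=GenotypeSimConfig)
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    shift: ShiftParams = field(default_factory=ShiftParams)
    variant_filter: VariantFilterParams = field(default_factory=VariantFilterParams)

    n_bootstrap: int = 200
    n_permutations: int = 999
    transcriptomic_standardize: str = "zscore"  # or "center"
    run_leave_one_out: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.simulate:
            needed = [self.counts_path, self.metadata_path]
            if any(p is None for p in needed):
                raise ValueError(
                    "counts_path and metadata_path are required unless simulate=True"
                )


def _build(cls, data: dict):
    return cls(**data) if data else cls()


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    nested = {
        "sim": SimulationConfig,
        "genotype_sim": GenotypeSimConfig,
        "normalization": NormalizationParams,
        "classification": ClassificationParams,
        "shift": ShiftParams,
        "variant_filter": VariantFilterParams,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = _build(nested[key], value or {})
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)
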
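"""Synthetic RNA-seq and genotype data with the study's design.

The count generator emulates a two-mode clonal design: CP lineages carry
all three morphs (male, sexual female, parthenogenetic female), OP
lineages only males and parthenogenetic females, two replicates each.
Gene-level ground truth (morph-bias class, degree, tissue bias,
X linkage) is drawn once from a dedicated random stream so that the
focal, whole-body outgroup and tissue outgroup datasets share the same
true classes; counts are negative binomial around compositional means

    mu_gs = w_gs / sum_g(w_gs) * libsize_s,
    w_gs = baseline_g * 2^(morph effect + lineage effect + injected shift),

with per-gene dispersion phi_g. Injected OP-to-CP shifts (``shift_spec``)
apply only to OP samples of the targeted morph and gene class, so the
downstream class median recovers the injected delta.

The genotype generator produces biallelic SNP dosages for the eight
lineages with hierarchical allele-frequency drift (mode cluster, then
lineage), plus per-genotype depth and quality for filter testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import GenotypeSimConfig, SimulationConfig
from .containers import (
    CLASS_TO_MORPH,
    CountMatrix,
    GenotypeMatrix,
    MORPHS,
    TISSUES,
)

_STREAMS = {"genes": 0, "focal": 1, "outgroup_wb": 2, "outgroup_tissue": 3}


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(cfg_seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


def gene_truth(cfg: SimulationConfig) -> pd.DataFrame:
    """Ground-truth gene table shared by all simulated datasets.

    Columns: morph_bias (morph name or 'unbiased'), degree, lfc (log2
    morph effect), tissue_bias (tissue or 'none', relative to the bias
    morph), chromosome ('X' or 'A1'), chromosome_class.
    """
    rng = _rng(cfg.seed, "genes")
    n = cfg.n_genes
    classes = np.concatenate(
        [
            np.repeat(c, int(round(cfg.frac_class[c] * n)))
            for c in ("M", "F", "P", "unbiased")
        ]
    )
    # rounding may leave a small remainder; pad with unbiased genes
    if classes.size < n:
        classes = np.concatenate([classes, np.repeat("unbiased", n - classes.size)])
    classes = classes[:n]
    rng.shuffle(classes)

    biased = classes != "unbiased"
    limited = biased & (rng.random(n) < cfg.lfc_limited_frac)
    lfc = np.where(limited, cfg.lfc_limited, np.where(biased, cfg.lfc_bias, 0.0))

    has_tissue = biased & (rng.random(n) < cfg.tissue_bias_frac)
    tissue = np.where(has_tissue, rng.choice(TISSUES, size=n), "none")

    p_x = np.full(n, cfg.frac_x_linked)
    p_x[classes == "M"] = np.clip(
        cfg.frac_x_linked + cfg.x_male_bias_enrichment, 0, 1
    )
    on_x = rng.random(n) < p_x

    baseline = 2.0 ** rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=n)
    phi = np.exp(rng.normal(np.log(cfg.phi_median), cfg.phi_sigma, size=n))

    return pd.DataFrame(
        {
            "morph_bias": [
                CLASS_TO_MORPH.get(c, "unbiased") for c in classes
            ],
            "bias_class": classes,
            "degree": np.where(limited, "++", np.where(biased, "+", "none")),
            "lfc": lfc,
            "tissue_bias": tissue,
            "chromosome": np.where(on_x, "X", "A1"),
            "chromosome_class": np.where(on_x, "X", "autosome"),
            "baseline": baseline,
            "phi": phi,
        },
        index=pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id"),
    )


def _shift_delta(cfg: SimulationConfig, truth: pd.DataFrame, morph: str
                 ) -> np.ndarray:
    """Injected log2 shift per gene for OP samples of ``morph``.

    ``shift_spec`` keys are (morph, selector) with selector a class code
    ('M', 'F', 'P', 'unbiased') or 'CLASS:tissue' (e.g. 'M:gonads' =
    male-biased genes that are gonad-biased, i.e. testis-biased).
    """
    delta = np.zeros(len(truth))
    for (m, selector), d in cfg.shift_spec.items():
        if m != morph:
            continue
        if ":" in selector:
            cls, tis = selector.split(":", 1)
            mask = (truth["bias_class"] == cls) & (truth["tissue_bias"] == tis)
        else:
            mask = truth["bias_class"] == selector
        delta[mask.to_numpy()] += d
    return delta


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray
             ) -> np.ndarray:
    """NB counts with mean mu and variance mu + phi mu^2 (Poisson at phi=0)."""
    phi_b = np.broadcast_to(phi[:, None], mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = phi_b < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / phi_b[nb]
        out[nb] = rng.negative_binomial(r, r / (r + mu[nb]))
    return out


def _library_sizes(rng, cfg: SimulationConfig, n: int) -> np.ndarray:
    sigma = np.sqrt(np.log1p(cfg.libsize_cv**2))
    mu = np.log(cfg.libsize_mean) - sigma**2 / 2
    return np.exp(rng.normal(mu, sigma, size=n))


def _counts_for_samples(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    truth: pd.DataFrame,
    sample_specs: list[dict],
    lineage_effects: dict[str, np.ndarray],
) -> pd.DataFrame:
    baseline = truth["baseline"].to_numpy()
    phi = truth["phi"].to_numpy()
    lib = _library_sizes(rng, cfg, len(sample_specs))
    cols = {}
    for s, spec in enumerate(sample_specs):
        log2_eff = np.zeros(len(truth))
        is_bias_morph = (truth["morph_bias"] == spec["morph"]).to_numpy()
        log2_eff[is_bias_morph] += truth.loc[is_bias_morph, "lfc"].to_numpy()
        log2_eff += lineage_effects[spec["lineage"]]
        if spec.get("mode") == "OP":
            log2_eff += _shift_delta(cfg, truth, spec["morph"])
        if spec.get("tissue") not in (None, "whole_body"):
            t_mask = (
                (truth["tissue_bias"] == spec["tissue"])
                & (truth["morph_bias"] == spec["morph"])
            ).to_numpy()
            log2_eff[t_mask] += cfg.tissue_lfc
        w = baseline * 2.0**log2_eff
        mu = w / w.sum() * lib[s]
        cols[spec["sample_id"]] = _nb_draw(rng, mu[:, None], phi)[:, 0]
    return pd.DataFrame(cols, index=truth.index)


def _focal_design(cfg: SimulationConfig) -> list[dict]:
    specs = []
    for mode in ("CP", "OP"):
        morphs = MORPHS if mode == "CP" else (
            "male", "parthenogenetic_female",
        )
        for i in range(1, cfg.n_lineages_per_mode + 1):
            lineage = f"{mode}{i}"
            for morph in morphs:
                for rep in range(1, cfg.n_replicates + 1):
                    specs.append(
                        {
                            "sample_id": f"{lineage}_{morph}_r{rep}",
                            "lineage": lineage,
                            "mode": mode,
                            "morph": morph,
                            "replicate": rep,
                            "tissue": "whole_body",
                        }
                    )
    return specs


def simulate_counts(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Focal whole-body dataset: counts, metadata and gene-level truth.

    Default design: 4 CP lineages x 3 morphs x 2 replicates plus 4 OP
    lineages x 2 morphs x 2 replicates = 40 libraries.
    """
    truth = gene_truth(cfg)
    rng = _rng(cfg.seed, "focal")
    specs = _focal_design(cfg)
    lineages = sorted({s["lineage"] for s in specs})
    lineage_effects = {
        l: rng.normal(0.0, cfg.lineage_sd, size=len(truth)) for l in lineages
    }
    counts = _counts_for_samples(rng, cfg, truth, specs, lineage_effects)
    meta = pd.DataFrame(specs).set_index("sample_id")
    meta["dataset"] = "focal"
    return CountMatrix(counts), meta, truth


def simulate_outgroup(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Outgroup datasets sharing the focal gene truth.

    Returns (whole-body 3 morphs x 2 reps, tissue 3 morphs x 3 tissues x
    2 reps, combined metadata). The outgroup carries the same true morph
    effects but no injected OP shift, so classes called on it transfer to
    the focal data.
    """
    truth = gene_truth(cfg)

    rng_wb = _rng(cfg.seed, "outgroup_wb")
    wb_specs = [
        {
            "sample_id": f"OUT_{morph}_r{rep}",
            "lineage": "OUT",
            "mode": "outgroup",
            "morph": morph,
            "replicate": rep,
            "tissue": "whole_body",
        }
        for morph in MORPHS
        for rep in range(1, cfg.n_replicates + 1)
    ]
    eff_wb = {"OUT": rng_wb.normal(0.0, cfg.lineage_sd, size=len(truth))}
    wb_counts = _counts_for_samples(rng_wb, cfg, truth, wb_specs, eff_wb)

    rng_t = _rng(cfg.seed, "outgroup_tissue")
    t_specs = [
        {
            "sample_id": f"OUT_{morph}_{tissue}_r{rep}",
            "lineage": "OUT",
            "mode": "outgroup",
            "morph": morph,
            "replicate": rep,
            "tissue": tissue,
        }
        for morph in MORPHS
        for tissue in TISSUES
        for rep in range(1, cfg.n_replicates + 1)
    ]
    eff_t = {"OUT": rng_t.normal(0.0, cfg.lineage_sd, size=len(truth))}
    t_counts = _counts_for_samples(rng_t, cfg, truth, t_specs, eff_t)

    meta = pd.DataFrame(wb_specs + t_specs).set_index("sample_id")
    meta["dataset"] = ["outgroup_wholebody"] * len(wb_specs) + [
        "outgroup_tissue"
    ] * len(t_specs)
    return CountMatrix(wb_counts), CountMatrix(t_counts), meta


def simulate_genotypes(gcfg: GenotypeSimConfig) -> GenotypeMatrix:
    """Biallelic SNP dosages for 2 mode clusters of lineages.

    Allele frequencies drift hierarchically (ancestral -> mode cluster ->
    lineage, clamped to [0, 1]); dosages are binomial(2, freq) draws, and
    each genotype carries a Poisson depth and a clipped-normal quality.
    """
    rng = np.random.default_rng(gcfg.seed)
    n, k = gcfg.n_snps, gcfg.n_lineages_per_mode
    lineages = [f"CP{i + 1}" for i in range(k)] + [f"OP{i + 1}" for i in range(k)]
    ancestral = rng.uniform(0.1, 0.9, size=n)
    # allele-copy draws share uniforms across lineages, so genotype
    # differences reflect frequency drift only (zero drift -> clones)
    u = rng.uniform(size=(n, 2))
    dosage = np.empty((n, 2 * k), dtype=np.int64)
    for m, mode in enumerate(("CP", "OP")):
        mode_freq = np.clip(
            ancestral + rng.normal(0.0, gcfg.divergence_between_mode, size=n),
            0.0,
            1.0,
        )
        for i in range(k):
            f = np.clip(
                mode_freq + rng.normal(0.0, gcfg.divergence_within_mode, size=n),
                0.0,
                1.0,
            )
            dosage[:, m * k + i] = (u[:, 0] < f).astype(np.int64) + (
                u[:, 1] < f
            )
    depth = rng.poisson(gcfg.depth_mean, size=dosage.shape)
    quality = np.clip(
        np.rint(rng.normal(gcfg.gq_mean, 15.0, size=dosage.shape)), 0, 99
    ).astype(np.int64)
    ids = pd.Index([f"snp{i:06d}" for i in range(n)], name="snp_id")
    return GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=ids, columns=lineages),
        depth=pd.DataFrame(depth, index=ids, columns=lineages),
        quality=pd.DataFrame(quality, index=ids, columns=lineages),
    )
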
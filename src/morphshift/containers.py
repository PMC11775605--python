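"""Core in-memory containers shared across the pipeline.

Counts, metadata and genotype tables are thin validated wrappers around
pandas DataFrames so that every stage can exchange plain tables while the
constructors enforce the structural invariants (uniqueness, non-negativity,
symmetry) the downstream statistics rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MORPHS = ("male", "sexual_female", "parthenogenetic_female")
MODES = ("CP", "OP")
TISSUES = ("head", "legs", "gonads")

#: morph-bias class codes: M = male-biased, F = sexual female-biased,
#: P = parthenogenetic female-biased.
BIAS_CLASSES = ("M", "F", "P", "unbiased")

MORPH_TO_CLASS = {
    "male": "M",
    "sexual_female": "F",
    "parthenogenetic_female": "P",
}
CLASS_TO_MORPH = {v: k for k, v in MORPH_TO_CLASS.items()}


@dataclass
class CountMatrix:
    """Gene x sample read-count table.

    counts may be fractional (multi-mapper-aware quantification produces
    fractional values); stages that require integers round explicitly.
    """

    counts: pd.DataFrame  # genes in rows, samples in columns

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in count matrix")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in count matrix")
        if (c.to_numpy() < 0).any():
            raise ValueError("negative entries in count matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_size(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)].copy())


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table (index = sample id).

    Required columns: lineage, mode, morph, replicate; optional: tissue,
    dataset.
    """
    required = {"lineage", "mode", "morph", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample identifiers in metadata")
    bad_morph = set(meta["morph"]) - set(MORPHS)
    if bad_morph:
        raise ValueError(f"unknown morphs in metadata: {sorted(bad_morph)}")
    bad_mode = set(meta["mode"]) - set(MODES) - {"outgroup"}
    if bad_mode:
        raise ValueError(f"unknown reproductive modes: {sorted(bad_mode)}")
    return meta


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (0/1/2 alt-allele copies) per lineage."""

    dosage: pd.DataFrame  # SNPs in rows, lineages in columns
    depth: pd.DataFrame | None = None
    quality: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        d = self.dosage.to_numpy()
        if not np.isin(d, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")

    @property
    def lineage_ids(self) -> pd.Index:
        return self.dosage.columns

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[0]

    def allele_freq(self) -> pd.DataFrame:
        """Alt-allele frequency per (SNP, lineage): dosage / 2."""
        return self.dosage / 2.0


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix (genetic, transcriptomic, ...)."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if np.nanmax(np.abs(np.diag(v))) > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        finite = v[np.isfinite(v)]
        if (finite < -1e-12).any():
            raise ValueError("negative distances")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def pair(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]
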
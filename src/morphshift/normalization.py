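"""Library normalization: TMM scaling factors, CPM, filtering, averaging.

The TMM (trimmed mean of M-values) implementation follows the canonical
published algorithm: a reference library is chosen by the upper-quartile
rule, per-library log2 ratios (M) against the reference are trimmed jointly
on M (30%) and on average log intensity A (5%), and the remaining M-values
are combined with inverse-variance (precision) weights from the binomial
delta-method approximation. Factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import NormalizationParams
from .containers import CountMatrix


def _as_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """Single TMM factor of an observed library against the reference."""
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    o, r = p_obs[keep], p_ref[keep]
    oc, rc = obs[keep], ref[keep]

    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # delta-method variance of M: (N - n) / (N n) summed over the two libraries
    v = (lib_obs - oc) / (lib_obs * oc) + (lib_ref - rc) / (lib_ref * rc)

    if np.max(np.abs(m)) < 1e-6:
        return 1.0

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not sel.any():
        return 1.0
    f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts, params: NormalizationParams | None = None
) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    The reference sample is the one whose upper-quantile count fraction
    (quantile of counts divided by library size, at ``ref_quantile``) is
    closest to the mean of those fractions across samples.
    """
    params = params or NormalizationParams()
    df = _as_frame(counts)
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    lib = df.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"all-zero library: {list(zero.index)}")

    x = df.to_numpy(dtype=float)
    lib_v = lib.to_numpy(dtype=float)
    f_q = np.quantile(x, params.ref_quantile, axis=0) / lib_v
    if np.median(f_q) < 1e-20:
        raise ValueError("libraries have mostly zero counts at the reference quantile")
    ref_idx = int(np.argmin(np.abs(f_q - f_q.mean())))

    factors = np.array(
        [
            _tmm_pair(
                x[:, i],
                x[:, ref_idx],
                lib_v[i],
                lib_v[ref_idx],
                params.logratio_trim,
                params.abs_trim,
            )
            for i in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="norm_factor")


def cpm(counts, factors: pd.Series) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    df = _as_frame(counts)
    if set(factors.index) != set(df.columns):
        raise ValueError("normalization factors do not match sample identifiers")
    if (factors <= 0).any():
        raise ValueError("normalization factors must be strictly positive")
    eff = df.sum(axis=0) * factors.reindex(df.columns)
    return df.div(eff, axis=1) * 1e6


def effective_library_size(counts, factors: pd.Series) -> pd.Series:
    df = _as_frame(counts)
    return df.sum(axis=0) * factors.reindex(df.columns)


def filter_expressed(
    cpm_table: pd.DataFrame, params: NormalizationParams | None = None
) -> pd.Index:
    """Genes with CPM strictly above the threshold in >= min_libraries."""
    params = params or NormalizationParams()
    n_pass = (cpm_table > params.cpm_threshold).sum(axis=1)
    return cpm_table.index[n_pass >= params.min_libraries]


def average_expression(
    cpm_table: pd.DataFrame,
    meta: pd.DataFrame,
    by: list[str] | str,
) -> pd.DataFrame:
    """Arithmetic mean of CPM within each metadata group.

    Columns of the result are tuples of the grouping values (or plain
    values for a single key).
    """
    keys = [by] if isinstance(by, str) else list(by)
    for k in keys:
        if k not in meta.columns:
            raise ValueError(f"grouping key not in metadata: {k}")
    sub = meta.loc[cpm_table.columns]
    grouped = cpm_table.T.groupby([sub[k] for k in keys]).mean().T
    if grouped.shape[1] == 0:
        raise ValueError(f"no groups formed for keys {keys}")
    return grouped


def two_stage_average(
    cpm_table: pd.DataFrame,
    meta: pd.DataFrame,
    morph: str,
) -> pd.DataFrame:
    """Replicates averaged within lineage, then lineages within mode.

    Restricted to one morph; returns genes x modes. Two-stage averaging
    matters when replicate CPMs are unbalanced across lineages.
    """
    samples = meta.index[meta["morph"] == morph]
    samples = [s for s in samples if s in cpm_table.columns]
    if not samples:
        raise ValueError(f"no samples for morph {morph}")
    sub_meta = meta.loc[samples]
    by_lineage = average_expression(cpm_table[samples], sub_meta, ["mode", "lineage"])
    modes = by_lineage.columns.get_level_values(0)
    return by_lineage.T.groupby(modes).mean().T


def lineage_average(
    cpm_table: pd.DataFrame, meta: pd.DataFrame, morph: str
) -> pd.DataFrame:
    """Replicate-averaged CPM per lineage for one morph (genes x lineages)."""
    samples = meta.index[meta["morph"] == morph]
    samples = [s for s in samples if s in cpm_table.columns]
    if not samples:
        raise ValueError(f"no samples for morph {morph}")
    return average_expression(cpm_table[samples], meta.loc[samples], "lineage")


def normalize_and_filter(
    counts, params: NormalizationParams | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.Index]:
    """TMM + CPM + expression filter in one step.

    Returns (cpm table restricted to retained genes, factors, retained ids).
    """
    params = params or NormalizationParams()
    factors = tmm_factors(counts, params)
    cpm_table = cpm(counts, factors)
    kept = filter_expressed(cpm_table, params)
    return cpm_table.loc[kept], factors, kept
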
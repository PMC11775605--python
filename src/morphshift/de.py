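"""Morph- and tissue-biased gene classification via NB exact tests.

Two-group differences in means are tested with the classic exact test for
negative-binomially distributed counts: after equalizing effective library
sizes, the group-A total conditioned on the grand total follows a
beta-binomial (negative hypergeometric) law with shape parameters
n_A/phi and n_B/phi, which reduces to a binomial when phi = 0 (Poisson).
The two-sided p-value doubles the smaller tail mass. A single common
dispersion phi is estimated for the whole dataset by conditional maximum
likelihood, the standard companion of the exact test when replication is
too low for genewise dispersions.

Classification: a gene is biased towards a morph when it is significantly
overexpressed by that morph in BOTH pairwise comparisons against the other
two morphs (BH-adjusted p < alpha and |log2FC| > 1, strict), and limited
when additionally |log2FC| > 2 in both. Tissue bias within a morph uses
the same dual-comparison rule across the three tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import betabinom, binom
from statsmodels.stats.multitest import multipletests

from .config import ClassificationParams
from .containers import MORPHS, TISSUES

_PHI_EPS = 1e-8


def _check_integer(arr: np.ndarray, what: str) -> np.ndarray:
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded, atol=1e-8):
        raise ValueError(
            f"{what} must be integers for the exact test; round counts upstream"
        )
    return rounded.astype(np.int64)


def equalize_counts(counts: pd.DataFrame, eff_sizes: pd.Series) -> pd.DataFrame:
    """Scale counts to a common (geometric-mean) effective library size.

    Mean-preserving proportional adjustment; the result keeps fractional
    values so callers control when rounding happens.
    """
    sizes = eff_sizes.reindex(counts.columns)
    common = float(np.exp(np.mean(np.log(sizes))))
    return counts * (common / sizes)


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    eff_sizes: pd.Series | None = None,
) -> float:
    """Common NB dispersion by quantile-adjusted conditional ML.

    Library sizes are equalized first; the conditional log-likelihood of
    the counts given each group total (which does not involve the mean) is
    summed over genes and groups and maximized over phi.
    """
    if counts.to_numpy().sum() <= 0:
        raise ValueError("cannot estimate dispersion from an all-zero matrix")
    groups = pd.Series(groups).reindex(counts.columns)
    if eff_sizes is None:
        eff_sizes = counts.sum(axis=0)
    pseudo = equalize_counts(counts, eff_sizes)

    blocks = []  # (y genes x n_k, group size)
    for _, cols in groups.groupby(groups).groups.items():
        y = pseudo[list(cols)].to_numpy(dtype=float)
        if y.shape[1] >= 2:  # groups of one carry no conditional information
            blocks.append(y)
    if not blocks:
        raise ValueError("need at least one group with >= 2 samples")

    def neg_cll(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        total = 0.0
        for y in blocks:
            n_k = y.shape[1]
            z = y.sum(axis=1)
            total += float(
                np.sum(gammaln(y + r))
                + np.sum(gammaln(n_k * r) - gammaln(z + n_k * r))
                - y.shape[0] * n_k * gammaln(r)
            )
        return -total

    lo, hi = np.log(1e-6), np.log(20.0)
    res = minimize_scalar(neg_cll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    phi = float(np.exp(res.x))
    if phi <= 1.2e-6:  # boundary: data are consistent with Poisson
        return 0.0
    return phi


def _conditional_tails(
    sum_a: np.ndarray, totals: np.ndarray, n_a: int, n_b: int, phi: float
) -> tuple[np.ndarray, np.ndarray]:
    """P(S_A <= a | T = t) and P(S_A >= a | T = t) under the null."""
    if phi < _PHI_EPS:
        p = n_a / (n_a + n_b)
        lower = binom.cdf(sum_a, totals, p)
        upper = binom.sf(sum_a - 1, totals, p)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        lower = betabinom.cdf(sum_a, totals, r_a, r_b)
        upper = betabinom.sf(sum_a - 1, totals, r_a, r_b)
    return lower, upper


def nb_exact_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    sizes_a: pd.Series,
    sizes_b: pd.Series,
    phi: float,
    params: ClassificationParams | None = None,
) -> pd.DataFrame:
    """Genewise two-group NB exact test.

    Returns a frame indexed by gene with columns ``log2_fold_change``
    (group B over group A, computed on CPM means with a proportional
    prior count), ``p_value`` and ``adj_p`` (Benjamini-Hochberg).
    """
    params = params or ClassificationParams()
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("gene sets of the two groups differ")
    a = _check_integer(counts_a.to_numpy(dtype=float), "group A counts")
    b = _check_integer(counts_b.to_numpy(dtype=float), "group B counts")
    sa = sizes_a.reindex(counts_a.columns).to_numpy(dtype=float)
    sb = sizes_b.reindex(counts_b.columns).to_numpy(dtype=float)
    if (sa <= 0).any() or (sb <= 0).any():
        raise ValueError("effective library sizes must be positive")

    n_a, n_b = a.shape[1], b.shape[1]
    common = float(np.exp(np.mean(np.log(np.concatenate([sa, sb])))))
    pseudo_a = np.rint((a * (common / sa)).sum(axis=1)).astype(np.int64)
    pseudo_b = np.rint((b * (common / sb)).sum(axis=1)).astype(np.int64)
    totals = pseudo_a + pseudo_b

    lower, upper = _conditional_tails(pseudo_a, totals, n_a, n_b, phi)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p[totals == 0] = 1.0

    # fold change on CPM means with a prior count proportional to size
    prior_cpm = params.prior_count / (common / 1e6)
    cpm_a = (a / sa * 1e6).mean(axis=1)
    cpm_b = (b / sb * 1e6).mean(axis=1)
    lfc = np.log2((cpm_b + prior_cpm) / (cpm_a + prior_cpm))

    out = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "adj_p": bh_adjust(p),
        },
        index=counts_a.index,
    )
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# classification


@dataclass
class Comparison:
    """One pairwise exact-test result with its group orientation."""

    group_a: str
    group_b: str
    table: pd.DataFrame  # log2_fold_change (B over A), p_value, adj_p

    def overexpressed_by(self, member: str, lfc_threshold: float, alpha: float
                         ) -> pd.Series:
        """Boolean per gene: significantly overexpressed by ``member``."""
        if member == self.group_b:
            sign = 1.0
        elif member == self.group_a:
            sign = -1.0
        else:
            raise ValueError(f"{member} is not part of this comparison")
        t = self.table
        return (sign * t["log2_fold_change"] > lfc_threshold) & (
            t["adj_p"] < alpha
        )


def _dual_rule(
    comparisons: list[Comparison],
    members: tuple[str, ...],
    params: ClassificationParams,
) -> tuple[pd.Series, pd.Series]:
    """Label per gene under the dual-comparison overexpression rule.

    Returns (label, limited): the member consistently overexpressed in both
    of its comparisons (or 'none'), and whether both fold-changes also
    exceed the limited threshold.
    """
    index = comparisons[0].table.index
    label = pd.Series("none", index=index, dtype=object)
    limited = pd.Series(False, index=index)
    for member in members:
        involved = [
            c for c in comparisons if member in (c.group_a, c.group_b)
        ]
        if len(involved) != 2:
            raise ValueError(
                f"expected exactly 2 comparisons involving {member}, "
                f"got {len(involved)}"
            )
        hit = np.logical_and.reduce(
            [c.overexpressed_by(member, params.lfc_biased, params.alpha)
             for c in involved]
        )
        strong = np.logical_and.reduce(
            [c.overexpressed_by(member, params.lfc_limited, params.alpha)
             for c in involved]
        )
        label[hit] = member
        limited[hit] = strong[hit]
    return label, limited


def classify_morph_bias(
    comparisons: list[Comparison],
    params: ClassificationParams | None = None,
) -> pd.DataFrame:
    """Morph-bias labels from the three pairwise morph comparisons.

    Returns a frame with ``morph_bias`` (morph name or 'unbiased') and
    ``degree`` ('+', '++' or 'none').
    """
    params = params or ClassificationParams()
    if len(comparisons) != 3:
        raise ValueError("need the three pairwise morph comparisons")
    label, limited = _dual_rule(comparisons, MORPHS, params)
    morph_bias = label.replace({"none": "unbiased"})
    degree = pd.Series("none", index=label.index, dtype=object)
    degree[morph_bias != "unbiased"] = "+"
    degree[limited] = "++"
    return pd.DataFrame({"morph_bias": morph_bias, "degree": degree})


def classify_tissue_bias(
    tissue_comparisons: dict[str, list[Comparison]],
    params: ClassificationParams | None = None,
) -> pd.DataFrame:
    """Tissue-bias label per (gene, morph) from within-morph comparisons.

    ``tissue_comparisons`` maps each morph to its three pairwise tissue
    comparisons. Returns a frame indexed by gene with one column per morph
    holding the biased tissue or 'none'.
    """
    params = params or ClassificationParams()
    cols = {}
    for morph, comps in tissue_comparisons.items():
        if len(comps) != 3:
            raise ValueError(f"need 3 tissue comparisons for morph {morph}")
        present = {c.group_a for c in comps} | {c.group_b for c in comps}
        missing = set(TISSUES) - present
        if missing:
            raise ValueError(f"missing tissues for {morph}: {sorted(missing)}")
        label, _ = _dual_rule(comps, TISSUES, params)
        cols[morph] = label
    return pd.DataFrame(cols)


def _pairwise_comparison(
    counts: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    name_a: str,
    name_b: str,
    eff_sizes: pd.Series,
    phi: float,
    params: ClassificationParams,
) -> Comparison:
    table = nb_exact_test(
        counts[samples_a].round(),
        counts[samples_b].round(),
        eff_sizes[samples_a],
        eff_sizes[samples_b],
        phi,
        params,
    )
    return Comparison(name_a, name_b, table)


def classify_wholebody(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    norm_params=None,
    class_params: ClassificationParams | None = None,
) -> pd.DataFrame:
    """Morph-bias classes from a whole-body reference dataset.

    Normalizes (TMM), filters expressed genes, estimates a common
    dispersion across the morph groups, runs the three pairwise morph
    exact tests and applies the dual-comparison rule.
    """
    from .config import NormalizationParams
    from .normalization import effective_library_size, normalize_and_filter, tmm_factors

    norm_params = norm_params or NormalizationParams(min_libraries=2)
    class_params = class_params or ClassificationParams()
    _, factors, kept = normalize_and_filter(counts, norm_params)
    eff = effective_library_size(counts, factors)
    sub = counts.loc[kept].round()
    groups = meta.loc[sub.columns, "morph"]
    phi = estimate_common_dispersion(sub, groups, eff)

    by_morph = {
        m: [s for s in sub.columns if groups[s] == m] for m in MORPHS
    }
    for m, cols in by_morph.items():
        if not cols:
            raise ValueError(f"reference dataset lacks morph {m}")
    pairs = [
        ("male", "parthenogenetic_female"),
        ("sexual_female", "parthenogenetic_female"),
        ("sexual_female", "male"),
    ]
    comparisons = [
        _pairwise_comparison(
            sub, by_morph[a], by_morph[b], a, b, eff, phi, class_params
        )
        for a, b in pairs
    ]
    return classify_morph_bias(comparisons, class_params)


def classify_tissues(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    norm_params=None,
    class_params: ClassificationParams | None = None,
) -> pd.DataFrame:
    """Tissue-bias classes per morph from a 3-morph x 3-tissue dataset."""
    from .config import NormalizationParams
    from .normalization import effective_library_size, normalize_and_filter

    norm_params = norm_params or NormalizationParams(min_libraries=2)
    class_params = class_params or ClassificationParams()
    _, factors, kept = normalize_and_filter(counts, norm_params)
    eff = effective_library_size(counts, factors)
    sub = counts.loc[kept].round()

    tissue_comparisons: dict[str, list[Comparison]] = {}
    for morph in MORPHS:
        cols = [
            s for s in sub.columns if meta.loc[s, "morph"] == morph
        ]
        if not cols:
            raise ValueError(f"tissue dataset lacks morph {morph}")
        morph_counts = sub[cols]
        groups = meta.loc[cols, "tissue"]
        phi = estimate_common_dispersion(morph_counts, groups, eff[cols])
        by_tissue = {
            t: [s for s in cols if groups[s] == t] for t in TISSUES
        }
        pairs = [("head", "legs"), ("head", "gonads"), ("legs", "gonads")]
        tissue_comparisons[morph] = [
            _pairwise_comparison(
                morph_counts, by_tissue[a], by_tissue[b], a, b, eff, phi,
                class_params,
            )
            for a, b in pairs
        ]
    return classify_tissue_bias(tissue_comparisons, class_params)


def annotate_chromosome(
    gene_ids: pd.Index, annotation: pd.Series | pd.DataFrame
) -> pd.Series:
    """Map genes to {X, autosome, unplaced} from a gene -> chromosome table."""
    if isinstance(annotation, pd.DataFrame):
        annotation = annotation.iloc[:, 0]
    chrom = annotation.reindex(gene_ids)
    n_missing = int(chrom.isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} gene(s) absent from the chromosome annotation; "
            "labelled 'unplaced'",
            stacklevel=2,
        )
    out = pd.Series("autosome", index=gene_ids, dtype=object)
    out[chrom.isna()] = "unplaced"
    is_x = chrom.astype(str).str.upper().isin({"X", "CHRX", "CHR_X"})
    out[is_x] = "X"
    return out.rename("chromosome_class")
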
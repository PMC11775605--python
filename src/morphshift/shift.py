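"""OP-to-CP expression-shift statistics.

For each gene, within one morph, the shift statistic is

    log2((mean_OP + eps) / (mean_CP + eps)),    eps = 0.05 CPM,

where the means are two-stage averages (replicates within lineage, then
lineages within reproductive mode). Positive values mean higher expression
in obligately parthenogenetic (OP) than in cyclically parthenogenetic (CP)
lineages. Per gene class the median shift (Mdn) is tested against zero
with a Wilcoxon signed-rank test: exact for small classes, normal
approximation with continuity correction otherwise, zero differences
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .config import ClassificationParams, NormalizationParams, ShiftParams
from .containers import CLASS_TO_MORPH, MORPH_TO_CLASS

#: classes of size <= this use the exact signed-rank distribution
EXACT_N_MAX = 25


def op_cp_ratio(
    mean_op: pd.Series,
    mean_cp: pd.Series,
    morph: str | None = None,
    params: ShiftParams | None = None,
) -> pd.Series:
    """Per-gene log2 OP/CP expression ratio with pseudocount."""
    params = params or ShiftParams()
    if not mean_op.index.equals(mean_cp.index):
        raise ValueError("OP and CP means are not aligned on the same genes")
    eps = params.pseudocount
    ratio = np.log2((mean_op + eps) / (mean_cp + eps))
    ratio.name = f"op_cp_log2_{morph}" if morph else "op_cp_log2"
    return ratio


def shift_table(
    avg_by_mode: pd.DataFrame,
    morph: str,
    class_table: pd.DataFrame,
    params: ShiftParams | None = None,
) -> pd.DataFrame:
    """Ratio per gene joined with its classification keys.

    ``avg_by_mode`` is genes x {CP, OP} (two-stage averaged CPM for one
    morph); ``class_table`` carries morph_bias / degree / chromosome_class
    and optionally tissue-bias columns.
    """
    for mode in ("OP", "CP"):
        if mode not in avg_by_mode.columns:
            raise ValueError(f"averaged CPM table lacks mode {mode}")
    genes = avg_by_mode.index.intersection(class_table.index)
    ratio = op_cp_ratio(
        avg_by_mode.loc[genes, "OP"], avg_by_mode.loc[genes, "CP"], morph, params
    )
    out = class_table.loc[genes].copy()
    out.insert(0, "ratio", ratio)
    out.insert(0, "morph", morph)
    return out


@dataclass
class ClassTestResult:
    label: str
    n_genes: int
    median: float
    statistic: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "class": self.label,
            "n": self.n_genes,
            "median": self.median,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }


def wilcoxon_class_test(ratios: pd.Series | np.ndarray, label: str = ""
                        ) -> ClassTestResult:
    """Two-sided signed-rank test of the class ratios against zero.

    The reported median is over all supplied ratios; zeros are dropped
    only for the test itself.
    """
    x = np.asarray(ratios, dtype=float)
    if x.size == 0:
        raise ValueError(f"empty gene class: {label!r}")
    med = float(np.median(x))
    nz = x[x != 0]
    if nz.size == 0:
        return ClassTestResult(label, int(x.size), med, np.nan, 1.0)
    method = "exact" if nz.size <= EXACT_N_MAX else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on exact with ties
        try:
            res = wilcoxon(nz, alternative="two-sided", correction=True,
                           method=method, zero_method="wilcox")
        except ValueError:
            res = wilcoxon(nz, alternative="two-sided", correction=True,
                           method="approx", zero_method="wilcox")
    return ClassTestResult(label, int(x.size), med, float(res.statistic),
                           float(res.pvalue))


def class_tests(shift: pd.DataFrame, key: str = "morph_bias"
                  ) -> list[ClassTestResult]:
    """One Wilcoxon test per level of ``key`` (classes in fixed order)."""
    order = [CLASS_TO_MORPH.get(c, c) for c in ("F", "P", "M")] + ["unbiased"]
    levels = [v for v in order if v in set(shift[key])]
    levels += [v for v in sorted(set(shift[key])) if v not in levels]
    return [
        wilcoxon_class_test(shift.loc[shift[key] == lvl, "ratio"], str(lvl))
        for lvl in levels
    ]


def subdivide_and_test(
    shift: pd.DataFrame,
    by: str,
    classes: tuple[str, ...] | None = None,
) -> list[ClassTestResult]:
    """Wilcoxon tests per (morph-bias class x subdivision level).

    ``by`` is one of 'degree', 'chromosome_class' or 'tissue_bias'. For
    the tissue panel, genes without a tissue-bias call in their own bias
    morph are excluded. Empty levels are skipped with a warning.
    """
    if by not in shift.columns and by != "tissue_bias":
        raise ValueError(f"unknown subdivision key: {by}")
    results: list[ClassTestResult] = []
    biased = shift[shift["morph_bias"] != "unbiased"]
    wanted = classes or tuple(sorted(set(biased["morph_bias"])))
    for morph in wanted:
        sub = biased[biased["morph_bias"] == morph]
        if by == "tissue_bias":
            key = sub["tissue_bias"] if "tissue_bias" in sub else None
            if key is None:
                raise ValueError("shift table lacks a tissue_bias column")
            sub = sub[key != "none"]
            levels = sub["tissue_bias"]
        else:
            levels = sub[by]
        for level in sorted(set(levels)):
            grp = sub.loc[levels == level, "ratio"]
            label = f"{MORPH_TO_CLASS.get(morph, morph)}|{by}={level}"
            if grp.empty:
                warnings.warn(f"empty subdivision level skipped: {label}",
                              stacklevel=2)
                continue
            results.append(wilcoxon_class_test(grp, label))
    return results


def pairwise_lineage_ratios(
    avg_by_lineage: pd.DataFrame,
    meta: pd.DataFrame,
    class_table: pd.DataFrame,
    params: ShiftParams | None = None,
) -> pd.DataFrame:
    """Class medians of the log2 ratio for every (OP lineage, CP lineage) pair.

    ``avg_by_lineage`` is genes x lineages (replicate-averaged CPM for one
    morph). Returns a long frame (op_lineage, cp_lineage, class, n, median).
    """
    params = params or ShiftParams()
    lineage_mode = meta.drop_duplicates("lineage").set_index("lineage")["mode"]
    op_lin = [l for l in avg_by_lineage.columns if lineage_mode.get(l) == "OP"]
    cp_lin = [l for l in avg_by_lineage.columns if lineage_mode.get(l) == "CP"]
    genes = avg_by_lineage.index.intersection(class_table.index)
    cls = class_table.loc[genes, "morph_bias"]
    rows = []
    for ol in op_lin:
        for cl in cp_lin:
            ratio = op_cp_ratio(
                avg_by_lineage.loc[genes, ol], avg_by_lineage.loc[genes, cl],
                params=params,
            )
            for level in sorted(set(cls)):
                vals = ratio[cls == level]
                rows.append(
                    {
                        "op_lineage": ol,
                        "cp_lineage": cl,
                        "class": level,
                        "n": int(vals.size),
                        "median": float(np.median(vals)),
                    }
                )
    return pd.DataFrame(rows)


def leave_one_out_check(
    focal_counts,
    meta: pd.DataFrame,
    annotation: pd.Series | None = None,
    norm_params: NormalizationParams | None = None,
    class_params: ClassificationParams | None = None,
    shift_params: ShiftParams | None = None,
) -> pd.DataFrame:
    """Circularity check: classify on one held-out CP lineage, shift on the rest.

    For each CP lineage with all three morphs, its six libraries form a
    mini reference dataset on which morph-bias classes are called; the
    OP-to-CP ratio is then recomputed from the remaining CP lineages and
    all OP lineages, and per-class medians are reported per fold.
    """
    from .de import annotate_chromosome, classify_wholebody
    from .normalization import normalize_and_filter, two_stage_average

    norm_params = norm_params or NormalizationParams()
    class_params = class_params or ClassificationParams()
    shift_params = shift_params or ShiftParams()
    counts_df = focal_counts.counts if hasattr(focal_counts, "counts") else focal_counts

    cp_lineages = sorted(set(meta.loc[meta["mode"] == "CP", "lineage"]))
    rows = []
    for held in cp_lineages:
        held_samples = meta.index[meta["lineage"] == held]
        if set(meta.loc[held_samples, "morph"]) != {
            "male", "sexual_female", "parthenogenetic_female",
        }:
            raise ValueError(f"held-out lineage {held} lacks a morph")
        ref_params = NormalizationParams(
            ref_quantile=norm_params.ref_quantile,
            logratio_trim=norm_params.logratio_trim,
            abs_trim=norm_params.abs_trim,
            cpm_threshold=norm_params.cpm_threshold,
            min_libraries=2,
        )
        held_counts = counts_df[list(held_samples)]
        classes = classify_wholebody(
            held_counts, meta.loc[held_samples], ref_params, class_params
        )
        if annotation is not None:
            classes["chromosome_class"] = annotate_chromosome(
                classes.index, annotation
            )

        rest = meta.index[(meta["mode"] == "OP") | (meta["lineage"] != held)]
        rest = [s for s in rest if s in counts_df.columns]
        cpm_rest, _, kept = normalize_and_filter(counts_df[list(rest)], norm_params)
        for morph in ("parthenogenetic_female", "male"):
            avg = two_stage_average(cpm_rest, meta.loc[rest], morph)
            st = shift_table(avg, morph, classes, shift_params)
            for res in class_tests(st):
                rows.append(
                    {"held_out": held, "morph": morph, **res.as_dict()}
                )
    return pd.DataFrame(rows)
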
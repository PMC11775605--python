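"""Genetic and transcriptomic divergence between reproductive modes.

Genetic side: biallelic SNPs filtered on genotype quality (strictly above
a threshold) and per-library depth (inclusive), Nei (1972) standard
distance from per-lineage allele frequencies, neighbour-joining with
bootstrap support over loci, and PCA on dosages.

Transcriptomic side: Euclidean distances between per-gene-standardized
lineage expression profiles within a morph, Mantel correlation against
the genetic distances, and per-lineage mean same-mode divergence compared
between modes with an exact Mann-Whitney test (optionally after dividing
each pairwise transcriptomic distance by the genetic one).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.distance import mantel as skbio_mantel
from skbio.tree import TreeNode, nj

from .config import VariantFilterParams
from .containers import DistanceMatrix, GenotypeMatrix


def filter_variants(
    vcf_path: str,
    params: VariantFilterParams | None = None,
) -> GenotypeMatrix:
    """Read a VCF and keep biallelic SNPs passing GQ/DP filters everywhere.

    Genotype quality must be strictly above ``min_gq`` and depth at least
    ``min_depth`` in every library. Multi-allelic and non-SNP records are
    excluded.
    """
    from cyvcf2 import VCF

    params = params or VariantFilterParams()
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    ids, dosages, depths, quals = [], [], [], []
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue  # SNPs only, biallelic only
        gq_f, dp_f = v.format("GQ"), v.format("DP")
        if gq_f is None or dp_f is None:
            raise ValueError(f"record {v.CHROM}:{v.POS} lacks GQ/DP fields")
        gq = gq_f.ravel().astype(float)
        dp = dp_f.ravel().astype(float)
        gt = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        if np.any(gt == 2):
            continue
        ok = np.all(gq > params.min_gq) and np.all(dp >= params.min_depth)
        if params.require_all_samples and not ok:
            continue
        dose = np.where(gt == 3, 2, gt)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        dosages.append(dose)
        depths.append(dp.copy())
        quals.append(gq.copy())
    if not ids:
        return GenotypeMatrix(
            pd.DataFrame(np.empty((0, len(samples)), dtype=int), columns=samples)
        )
    return GenotypeMatrix(
        dosage=pd.DataFrame(np.array(dosages), index=ids, columns=samples),
        depth=pd.DataFrame(np.array(depths), index=ids, columns=samples),
        quality=pd.DataFrame(np.array(quals), index=ids, columns=samples),
    )


def _nei_from_freqs(freq: np.ndarray) -> np.ndarray:
    """Nei (1972) D from an (loci x lineages) alt-allele frequency matrix.

    With biallelic loci the identity probabilities are
    J_xy = mean_l(p_x p_y + (1-p_x)(1-p_y)); D = -ln(J_xy / sqrt(J_x J_y)).
    """
    n_loci = freq.shape[0]
    p, q = freq, 1.0 - freq
    jxy = (p.T @ p + q.T @ q) / n_loci
    jx = np.diag(jxy)
    denom = np.sqrt(np.outer(jx, jx))
    with np.errstate(divide="ignore"):
        d = -np.log(jxy / denom)
    d[jxy == 0] = np.inf
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)  # clip float negatives at identity
    return (d + d.T) / 2.0


def nei_distance(genotypes: GenotypeMatrix) -> DistanceMatrix:
    """Nei standard genetic distance between lineages.

    A heterozygous diploid genotype contributes allele frequency 0.5
    (dosage / 2) — the allele-frequency estimate with one individual per
    clonal lineage.
    """
    if genotypes.n_snps == 0:
        raise ValueError("no SNPs available for distance computation")
    freq = genotypes.allele_freq().to_numpy(dtype=float)
    d = _nei_from_freqs(freq)
    return DistanceMatrix(list(genotypes.lineage_ids), d, kind="genetic")


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Unrooted neighbour-joining tree (Saitou-Nei agglomeration)."""
    if len(dist.labels) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.isfinite(dist.values).all():
        raise ValueError("distance matrix has non-finite entries")
    return nj(SkbioDM(dist.values, ids=dist.labels))


def _bipartitions(tree: TreeNode, labels: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions of ``tree``, each canonicalized as the
    side not containing the first label."""
    all_set = frozenset(labels)
    ref = labels[0]
    out = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = clade if ref not in clade else all_set - clade
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return out


def bootstrap_support(
    genotypes: GenotypeMatrix,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict[frozenset, float]:
    """Bootstrap (over loci) support, in %, for the NJ tree's bipartitions."""
    if len(genotypes.lineage_ids) < 4:
        raise ValueError("bootstrap support needs at least 4 taxa")
    labels = list(genotypes.lineage_ids)
    freq = genotypes.allele_freq().to_numpy(dtype=float)
    main = _bipartitions(
        nj_tree(DistanceMatrix(labels, _nei_from_freqs(freq), "genetic")), labels
    )
    counts = {bp: 0 for bp in main}
    rng = np.random.default_rng(seed)
    n_loci = freq.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_loci, size=n_loci)
        d = _nei_from_freqs(freq[idx])
        if not np.isfinite(d).all():
            continue
        bps = _bipartitions(
            nj_tree(DistanceMatrix(labels, d, "genetic")), labels
        )
        for bp in main:
            if bp in bps:
                counts[bp] += 1
    return {bp: 100.0 * c / n_boot for bp, c in counts.items()}


def genotype_pca(
    genotypes: GenotypeMatrix, scale: bool = False, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of lineages on centered (optionally unit-variance) dosages.

    Returns (coordinates lineages x PCs, variance fraction per axis).
    """
    from sklearn.decomposition import PCA

    x = genotypes.dosage.to_numpy(dtype=float).T  # lineages x snps
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 lineages")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0)
        x = x[:, sd > 0] / sd[sd > 0]
    if not np.any(x.std(axis=0) > 0):
        raise ValueError("constant genotype matrix: no variation to decompose")
    k = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    frame = pd.DataFrame(
        coords,
        index=genotypes.lineage_ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return frame, pca.explained_variance_ratio_


def transcriptomic_distance(
    cpm_by_lineage: pd.DataFrame,
    standardize: str = "zscore",
) -> DistanceMatrix:
    """Euclidean distance between lineages after per-gene standardization.

    ``cpm_by_lineage`` is genes x lineages (one morph, replicate-averaged).
    ``standardize`` is 'zscore' (center and scale per gene) or 'center'.
    Genes with zero variance across lineages are dropped (they carry no
    signal and are undefined under scaling).
    """
    if cpm_by_lineage.shape[1] < 2:
        raise ValueError("need at least 2 lineages")
    if standardize not in {"zscore", "center"}:
        raise ValueError("standardize must be 'zscore' or 'center'")
    x = cpm_by_lineage.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance gene(s) dropped before "
            "distance computation",
            stacklevel=2,
        )
        x = x[sd > 0]
        sd = sd[sd > 0]
    x = x - x.mean(axis=1, keepdims=True)
    if standardize == "zscore":
        x = x / sd[:, None]
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(x.T, metric="euclidean"))
    return DistanceMatrix(list(cpm_by_lineage.columns), d, kind="transcriptomic")


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices (permutation p)."""
    if set(d1.labels) != set(d2.labels):
        raise ValueError("distance matrices have different labels")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    order = d1.labels
    m2 = d2.to_frame().loc[order, order].to_numpy()
    r, p, _ = skbio_mantel(
        SkbioDM(d1.values, ids=order),
        SkbioDM(m2, ids=order),
        method=method,
        permutations=n_perm,
        alternative=alternative,
        seed=seed,
    )
    return float(r), float(p)


def focal_mode_divergence(
    dist: DistanceMatrix,
    lineage_mode: pd.Series,
    correct_by: DistanceMatrix | None = None,
) -> tuple[pd.DataFrame, float]:
    """Mean same-mode divergence per focal lineage, compared between modes.

    For each lineage, the mean over its same-mode pairs of the distance
    (or of the transcriptomic/genetic distance ratio when ``correct_by``
    is given). The two per-mode samples of focal means are compared with
    an exact two-sided Mann-Whitney test.
    """
    modes = lineage_mode.reindex(dist.labels)
    if modes.isna().any():
        raise ValueError("mode missing for some lineages")
    rows = []
    for focal in dist.labels:
        partners = [
            l for l in dist.labels if l != focal and modes[l] == modes[focal]
        ]
        if not partners:
            raise ValueError(f"lineage {focal} has no same-mode partner")
        vals = []
        for other in partners:
            d = dist.pair(focal, other)
            if correct_by is not None:
                g = correct_by.pair(focal, other)
                if g == 0:
                    raise ValueError(
                        f"zero genetic distance for pair ({focal}, {other})"
                    )
                d = d / g
            vals.append(d)
        rows.append(
            {"lineage": focal, "mode": modes[focal], "mean_distance": np.mean(vals)}
        )
    table = pd.DataFrame(rows).set_index("lineage")
    mode_names = sorted(set(modes))
    if len(mode_names) != 2:
        raise ValueError("need exactly two reproductive modes")
    x = table.loc[table["mode"] == mode_names[0], "mean_distance"]
    y = table.loc[table["mode"] == mode_names[1], "mean_distance"]
    res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    return table, float(res.pvalue)
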
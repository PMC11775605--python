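import numpy as np
import pandas as pd
import pytest

from morphshift.config import VariantFilterParams
from morphshift.containers import DistanceMatrix, GenotypeMatrix
from morphshift.distance import (
    _nei_from_freqs,
    bootstrap_support,
    filter_variants,
    focal_mode_divergence,
    genotype_pca,
    mantel_test,
    nei_distance,
    nj_tree,
    transcriptomic_distance,
)
from morphshift.io import write_vcf
from morphshift.simulate import simulate_genotypes
from morphshift.config import GenotypeSimConfig


# ---------------------------------------------------------------- VCF filter

def _vcf(tmp_path, body: str) -> str:
    header = (
        "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="D">\n'
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Q">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL1\tL2\n"
    )
    path = tmp_path / "test.vcf"
    path.write_text(header + body)
    return str(path)


class TestVariantFilter:
    def test_thresholds_strict_gq_inclusive_depth(self, tmp_path):
        body = (
            "1\t1\tpass_site\tA\tG\t.\tPASS\t.\tGT:DP:GQ\t0/1:80:21\t1/1:80:21\n"
            "1\t2\tgq_at_20\tA\tG\t.\tPASS\t.\tGT:DP:GQ\t0/1:80:20\t1/1:80:21\n"
            "1\t3\tdp_at_79\tA\tG\t.\tPASS\t.\tGT:DP:GQ\t0/1:79:21\t1/1:80:21\n"
        )
        gm = filter_variants(_vcf(tmp_path, body))
        assert list(gm.dosage.index) == ["pass_site"]
        assert list(gm.dosage.loc["pass_site"]) == [1, 2]

    def test_multiallelic_and_indel_records_excluded(self, tmp_path):
        body = (
            "1\t1\tmulti\tA\tG,T\t.\tPASS\t.\tGT:DP:GQ\t0/1:99:99\t1/1:99:99\n"
            "1\t2\tindel\tA\tAT\t.\tPASS\t.\tGT:DP:GQ\t0/1:99:99\t1/1:99:99\n"
            "1\t3\tsnp\tA\tG\t.\tPASS\t.\tGT:DP:GQ\t0/0:99:99\t1/1:99:99\n"
        )
        gm = filter_variants(_vcf(tmp_path, body))
        assert list(gm.dosage.index) == ["snp"]

    def test_roundtrip_through_vcf_writer(self, tmp_path):
        gm = simulate_genotypes(GenotypeSimConfig(n_snps=200, seed=3))
        path = tmp_path / "sim.vcf"
        write_vcf(gm, path)
        back = filter_variants(
            str(path), VariantFilterParams(min_gq=0, min_depth=0)
        )
        assert np.array_equal(back.dosage.to_numpy(), gm.dosage.to_numpy())
        assert list(back.dosage.columns) == list(gm.dosage.columns)


# ----------------------------------------------------------------------- Nei

class TestNei:
    def test_identical_lineages_zero(self):
        freq = np.tile(np.array([[0.3], [0.8]]), (1, 2))
        d = _nei_from_freqs(freq)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_single_locus(self):
        d = _nei_from_freqs(np.array([[1.0, 0.5]]))
        assert d[0, 1] == pytest.approx(-np.log(0.5 / np.sqrt(0.5)))
        assert d[0, 1] == pytest.approx(0.34657, abs=1e-5)

    def test_matches_locuswise_oracle(self, rng):
        freq = rng.uniform(size=(50, 4))
        d = _nei_from_freqs(freq)

        def oracle(px, py):
            jx = np.mean(px**2 + (1 - px) ** 2)
            jy = np.mean(py**2 + (1 - py) ** 2)
            jxy = np.mean(px * py + (1 - px) * (1 - py))
            return -np.log(jxy / np.sqrt(jx * jy))

        for i in range(4):
            for j in range(4):
                assert d[i, j] == pytest.approx(
                    oracle(freq[:, i], freq[:, j]) if i != j else 0.0, abs=1e-12
                )

    def test_disjoint_alleles_give_infinite_distance(self):
        gm = GenotypeMatrix(
            pd.DataFrame({"x": [2, 2], "y": [0, 0]}, index=["s1", "s2"])
        )
        d = nei_distance(gm)
        assert np.isinf(d.pair("x", "y"))


# ------------------------------------------------------------------------ NJ

def _tree_patristic(tree, a, b):
    ta = tree.find(a)
    return ta.distance(tree.find(b))


class TestNJ:
    def test_recovers_additive_four_taxon_matrix(self):
        labels = ["a", "b", "c", "d"]
        vals = np.array(
            [
                [0.0, 5.0, 9.0, 9.5],
                [5.0, 0.0, 10.0, 10.5],
                [9.0, 10.0, 0.0, 8.5],
                [9.5, 10.5, 8.5, 0.0],
            ]
        )
        dm = DistanceMatrix(labels, vals)
        tree = nj_tree(dm)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert _tree_patristic(tree, a, b) == pytest.approx(dm.pair(a, b))

    def test_three_taxa_closed_form_branch_lengths(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = nj_tree(dm)
        # x+y=3, x+z=4, y+z=5 -> x=1, y=2, z=3
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_ultrametric_matrix_matches_upgma_clusters(self):
        from scipy.cluster.hierarchy import average, fcluster
        from scipy.spatial.distance import squareform

        labels = ["a", "b", "c", "d", "e", "f"]
        # two clean clusters {a,b,c} and {d,e,f}
        vals = np.full((6, 6), 10.0)
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    vals[i, j] = 2.0
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(labels, vals)
        tree = nj_tree(dm)
        clade = {
            frozenset(t.name for t in n.tips())
            for n in tree.non_tips(include_self=False)
        }
        upgma = fcluster(average(squareform(vals)), t=2, criterion="maxclust")
        groups = {
            frozenset(np.array(labels)[upgma == k]) for k in set(upgma)
        }
        assert groups & ({frozenset("abc"), frozenset("def")})
        assert frozenset("abc") in clade or frozenset("def") in clade

    def test_infinite_entries_rejected(self):
        vals = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], vals))


@pytest.fixture(scope="module")
def separated():
    return simulate_genotypes(
        GenotypeSimConfig(
            n_snps=800,
            divergence_between_mode=0.3,
            divergence_within_mode=0.02,
            seed=11,
        )
    )


class TestBootstrapAndPCA:

    def test_mode_split_has_full_support(self, separated):
        support = bootstrap_support(separated, n_boot=50, seed=5)
        mode_bp = frozenset({"OP1", "OP2", "OP3", "OP4"})
        assert support.get(mode_bp, 0.0) == pytest.approx(100.0)

    def test_bootstrap_deterministic_under_seed(self, separated):
        s1 = bootstrap_support(separated, n_boot=20, seed=9)
        s2 = bootstrap_support(separated, n_boot=20, seed=9)
        assert s1 == s2

    def test_pure_noise_supports_below_100(self):
        gm = simulate_genotypes(
            GenotypeSimConfig(
                n_snps=300,
                divergence_between_mode=0.0,
                divergence_within_mode=0.3,
                seed=2,
            )
        )
        support = bootstrap_support(gm, n_boot=60, seed=1)
        assert min(support.values(), default=0.0) < 90.0

    def test_pca_single_direction_explains_everything(self):
        dosage = pd.DataFrame(
            {"l1": [0, 0, 0], "l2": [1, 1, 1], "l3": [2, 2, 2]},
            index=["s1", "s2", "s3"],
        )
        _, var = genotype_pca(GenotypeMatrix(dosage))
        assert var[0] == pytest.approx(1.0)

    def test_pca_duplicated_lineage_coincides(self, separated):
        dup = GenotypeMatrix(
            separated.dosage.assign(DUP=separated.dosage["CP1"])
        )
        coords, _ = genotype_pca(dup)
        assert np.allclose(coords.loc["CP1"], coords.loc["DUP"], atol=1e-8)

    def test_pca_constant_matrix_rejected(self):
        dosage = pd.DataFrame({"l1": [1, 1], "l2": [1, 1]}, index=["s1", "s2"])
        with pytest.raises(ValueError):
            genotype_pca(GenotypeMatrix(dosage))

    def test_pca_variance_matches_eigendecomposition(self, separated):
        _, var = genotype_pca(separated)
        x = separated.dosage.to_numpy(dtype=float).T
        x = x - x.mean(axis=0)
        eig = np.linalg.eigvalsh(x @ x.T)[::-1]
        assert np.allclose(var, (eig / eig.sum())[: len(var)], atol=1e-9)


# ------------------------------------------------- transcriptomic / Mantel

class TestTranscriptomicDistance:
    def test_identical_profiles_zero(self, rng):
        prof = rng.gamma(2, 10, 20)
        table = pd.DataFrame({"l1": prof, "l2": prof, "l3": prof * 0 + 1})
        with np.errstate(all="ignore"):
            d = transcriptomic_distance(table, "center")
        assert d.pair("l1", "l2") == pytest.approx(0.0, abs=1e-9)

    def test_hand_pythagorean_distance(self):
        # two genes, centered values differ by (3, 4) -> distance 5
        table = pd.DataFrame({"l1": [0.0, 0.0], "l2": [3.0, 4.0]})
        d = transcriptomic_distance(table, "center")
        assert d.pair("l1", "l2") == pytest.approx(5.0)

    def test_global_rescaling_invariance_under_zscore(self, rng):
        table = pd.DataFrame(rng.gamma(2, 10, (30, 4)), columns=list("abcd"))
        d1 = transcriptomic_distance(table, "zscore")
        d2 = transcriptomic_distance(table * 2, "zscore")
        assert np.allclose(d1.values, d2.values)

    def test_zero_variance_gene_dropped_with_warning(self, rng):
        table = pd.DataFrame(rng.gamma(2, 10, (5, 3)), columns=list("abc"))
        table.iloc[0] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            transcriptomic_distance(table, "zscore")


class TestMantelAndDivergence:
    def _dist(self, rng, labels):
        x = rng.normal(size=(len(labels), 3))
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix(labels, squareform(pdist(x)))

    def test_self_correlation_is_one(self, rng):
        d = self._dist(rng, list("abcdefgh"))
        r, p = mantel_test(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_rank_invariance_under_monotone_transform(self, rng):
        d = self._dist(rng, list("abcdefgh"))
        d2 = DistanceMatrix(d.labels, d.values**2)
        r, _ = mantel_test(d, d2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_seeded_determinism(self, rng):
        d1 = self._dist(rng, list("abcdefgh"))
        d2 = self._dist(rng, list("abcdefgh"))
        out1 = mantel_test(d1, d2, n_perm=199, seed=4)
        assert out1 == mantel_test(d1, d2, n_perm=199, seed=4)

    def test_extreme_separation_exact_p(self):
        labels = list("abcdefgh")
        modes = pd.Series(["A"] * 4 + ["B"] * 4, index=labels)
        vals = np.zeros((8, 8))
        for i in range(8):
            for j in range(i + 1, 8):
                same = (i < 4) == (j < 4)
                vals[i, j] = vals[j, i] = (
                    (1.0 + 0.01 * i + 0.001 * j) if same and i < 4
                    else (10.0 + 0.01 * i) if same
                    else 5.0
                )
        table, p = focal_mode_divergence(DistanceMatrix(labels, vals), modes)
        assert p == pytest.approx(2 / 70)
        assert set(table["mode"]) == {"A", "B"}

    def test_proportional_correction_gives_p_one(self):
        labels = list("abcdefgh")
        modes = pd.Series(["A"] * 4 + ["B"] * 4, index=labels)
        base = np.abs(np.subtract.outer(np.arange(8.0), np.arange(8.0)))
        trans = DistanceMatrix(labels, base * 3.0)
        gen = DistanceMatrix(labels, base)
        _, p = focal_mode_divergence(trans, modes, correct_by=gen)
        assert p == pytest.approx(1.0)
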
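"""Data containers, file round-trips, and score-statistic computation."""

import numpy as np
import pytest
from scipy import stats as sps

from protscan.data import (
    UNMAPPED,
    IndividualData,
    SummaryStats,
    VariantTable,
    compute_score_stats,
    read_spatial_map,
    read_summary_stats,
    variant_table_from_genotypes,
    write_spatial_map,
    write_summary_stats,
)

from .conftest import make_variants


def _write_score_file(path, variants, U):
    df = variants.to_dataframe()
    df["U"] = U
    df.to_csv(path, sep="\t", index=False)


class TestSummaryStatsIO:
    def test_identity_covariance(self, tmp_path):
        variants = make_variants(3)
        _write_score_file(tmp_path / "s.tsv", variants, [1.0, -0.5, 2.0])
        np.savetxt(tmp_path / "v.txt", np.eye(3))
        vt, ss = read_summary_stats(tmp_path / "s.tsv", tmp_path / "v.txt")
        assert ss.m == 3
        np.testing.assert_allclose(ss.V, np.eye(3))
        np.testing.assert_allclose(ss.U, [1.0, -0.5, 2.0])

    def test_long_format_diagonal_only(self, tmp_path):
        variants = make_variants(3)
        _write_score_file(tmp_path / "s.tsv", variants, [0.0, 0.0, 0.0])
        with open(tmp_path / "v.tsv", "w") as fh:
            fh.write("id_i\tid_j\tv\n")
            for i, vid in enumerate(variants.variant_id):
                fh.write(f"{vid}\t{vid}\t{i + 1.0}\n")
        _, ss = read_summary_stats(tmp_path / "s.tsv", tmp_path / "v.tsv")
        np.testing.assert_allclose(ss.V, np.diag([1.0, 2.0, 3.0]))

    def test_long_format_symmetrised(self, tmp_path):
        variants = make_variants(2)
        _write_score_file(tmp_path / "s.tsv", variants, [0.0, 0.0])
        with open(tmp_path / "v.tsv", "w") as fh:
            fh.write("v1\tv1\t2.0\nv2\tv2\t2.0\nv1\tv2\t0.5\n")
        _, ss = read_summary_stats(tmp_path / "s.tsv", tmp_path / "v.tsv")
        np.testing.assert_allclose(ss.V, [[2.0, 0.5], [0.5, 2.0]])

    def test_round_trip(self, tmp_path, rng):
        m = 6
        variants = make_variants(m, maf=rng.uniform(0.001, 0.5, m))
        A = rng.standard_normal((m, m))
        ss = SummaryStats(U=rng.standard_normal(m), V=A @ A.T)
        write_summary_stats(variants, ss, tmp_path / "s.tsv", tmp_path / "v.txt")
        vt2, ss2 = read_summary_stats(tmp_path / "s.tsv", tmp_path / "v.txt")
        assert list(vt2.variant_id) == list(variants.variant_id)
        np.testing.assert_allclose(ss2.U, ss.U, rtol=1e-12)
        np.testing.assert_allclose(ss2.V, ss.V, rtol=1e-12)

    def test_asymmetric_dense_rejected(self, tmp_path):
        variants = make_variants(2)
        _write_score_file(tmp_path / "s.tsv", variants, [0.0, 0.0])
        np.savetxt(tmp_path / "v.txt", [[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            read_summary_stats(tmp_path / "s.tsv", tmp_path / "v.txt")

    def test_dimension_mismatch_rejected(self, tmp_path):
        variants = make_variants(3)
        _write_score_file(tmp_path / "s.tsv", variants, [0.0, 0.0, 0.0])
        np.savetxt(tmp_path / "v.txt", np.eye(2))
        with pytest.raises(ValueError):
            read_summary_stats(tmp_path / "s.tsv", tmp_path / "v.txt")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            VariantTable(
                variant_id=["a", "a"], chrom=["1", "1"], pos=[1, 2],
                maf=[0.1, 0.1], mac=[5, 5],
            )


class TestSpatialMapIO:
    def test_partial_mapping(self, tmp_path):
        variants = make_variants(12)
        with open(tmp_path / "map.tsv", "w") as fh:
            fh.write("variant_id\tstructure_id\tx\ty\tz\n")
            for i in range(10):
                fh.write(f"v{i + 1}\tP1\t{i}.0\t0.0\t0.0\n")
        smap = read_spatial_map(tmp_path / "map.tsv", variants)
        assert int((~smap.mapped).sum()) == 2
        assert smap.structure_id[11] == UNMAPPED

    def test_multi_structure_priority(self, tmp_path):
        # experimental id beats a computational model id
        variants = make_variants(3)
        with open(tmp_path / "map.tsv", "w") as fh:
            fh.write("variant_id\tstructure_id\tx\ty\tz\n")
            fh.write("v1\tmodel_abc\t0\t0\t0\n")
            fh.write("v1\t1XYZ\t1\t1\t1\n")
            fh.write("v2\t1XYZ\t2\t2\t2\n")
        smap = read_spatial_map(tmp_path / "map.tsv", variants)
        assert smap.structure_id[0] == "1XYZ"
        np.testing.assert_allclose(smap.coords[0], [1, 1, 1])

    def test_empty_file_all_unmapped(self, tmp_path):
        variants = make_variants(4)
        (tmp_path / "map.tsv").write_text("variant_id\tstructure_id\tx\ty\tz\n")
        smap = read_spatial_map(tmp_path / "map.tsv", variants)
        assert not smap.mapped.any()

    def test_unknown_variant_dropped_with_warning(self, tmp_path):
        variants = make_variants(2)
        with open(tmp_path / "map.tsv", "w") as fh:
            fh.write("variant_id\tstructure_id\tx\ty\tz\n")
            fh.write("v1\tP\t0\t0\t0\nbogus\tP\t1\t1\t1\n")
        with pytest.warns(UserWarning, match="not in the variant table"):
            smap = read_spatial_map(tmp_path / "map.tsv", variants)
        assert smap.mapped.tolist() == [True, False]

    def test_round_trip(self, tmp_path, rng):
        variants = make_variants(5)
        coords = rng.standard_normal((5, 3))
        from .conftest import make_spatial

        smap = make_spatial(coords)
        write_spatial_map(variants, smap, tmp_path / "map.tsv")
        smap2 = read_spatial_map(tmp_path / "map.tsv", variants)
        np.testing.assert_allclose(smap2.coords, coords, rtol=1e-12)


class TestScoreStats:
    def test_genotypes_in_covariate_span_give_zero_scores(self, rng):
        # residuals are orthogonal to span(Z); genotypes inside that span
        # must produce null scores
        n = 200
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = Z @ [1.0, 0.5] + rng.standard_normal(n)
        G = Z @ np.abs(rng.standard_normal((2, 4)))
        ss = compute_score_stats(IndividualData(G=G, y=y, Z=Z))
        np.testing.assert_allclose(ss.U, 0.0, atol=1e-8)

    def test_single_variant_matches_linear_regression_score_test(self, rng):
        n = 500
        g = rng.binomial(2, 0.3, size=n).astype(float)
        y = 0.2 * g + rng.standard_normal(n)
        Z = np.ones((n, 1))
        ss = compute_score_stats(IndividualData(G=g[:, None], y=y, Z=Z))
        z2 = ss.U[0] ** 2 / ss.V[0, 0]
        p_score = sps.chi2.sf(z2, df=1)
        # independent oracle: classical score test for simple linear regression
        gc = g - g.mean()
        r = y - y.mean()
        s2 = (r @ r) / (n - 1)
        z2_oracle = (gc @ y) ** 2 / (s2 * (gc @ gc))
        p_oracle = sps.chi2.sf(z2_oracle, df=1)
        assert p_score == pytest.approx(p_oracle, abs=1e-10)

    def test_null_z_statistics_standard_normal(self, rng):
        # 5000 independent null replicates of a single variant's Z-score
        n = 60
        zs = np.empty(5000)
        for i in range(5000):
            g = rng.binomial(2, 0.25, size=n).astype(float)
            if g.std() == 0:
                g[0] += 1
            y = rng.standard_normal(n)
            ss = compute_score_stats(
                IndividualData(G=g[:, None], y=y, Z=np.ones((n, 1)))
            )
            zs[i] = ss.U[0] / np.sqrt(ss.V[0, 0])
        assert sps.kstest(zs, "norm").pvalue > 0.01

    def test_v_symmetric_psd(self, rng):
        n, m = 300, 8
        G = rng.binomial(2, 0.2, size=(n, m)).astype(float)
        y = rng.standard_normal(n)
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        ss = compute_score_stats(IndividualData(G=G, y=y, Z=Z))
        np.testing.assert_allclose(ss.V, ss.V.T, atol=1e-10)
        evals = np.linalg.eigvalsh(ss.V)
        assert evals.min() >= -1e-8 * np.trace(ss.V)

    def test_singular_covariates_rejected(self, rng):
        n = 50
        Z = np.ones((n, 2))  # duplicated intercept
        with pytest.raises(np.linalg.LinAlgError):
            compute_score_stats(
                IndividualData(G=rng.integers(0, 3, (n, 2)).astype(float),
                               y=rng.standard_normal(n), Z=Z)
            )

    def test_maf_mac_recomputed_from_genotypes(self):
        G = np.array([[0, 1], [1, 1], [0, 1], [1, 0]], dtype=float)
        vt = variant_table_from_genotypes(G)
        assert vt.mac.tolist() == [2, 3]
        np.testing.assert_allclose(vt.maf, [2 / 8, 3 / 8])
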
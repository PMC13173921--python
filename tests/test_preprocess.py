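import numpy as np
import pytest

from wbtdc import (
    ExpressionMatrix,
    ProbeMap,
    ValidationError,
    collapse_probes,
    iqr_filter,
    remove_rbc_genes,
    restrict_to_coding,
    transform_counts,
)


def _counts(genes, samples, values):
    return ExpressionMatrix(genes, samples, np.asarray(values, float), "counts")


class TestRemoveRbcGenes:
    def test_globin_rows_dropped(self):
        m = _counts(["HBB", "HBA1", "g1", "g2", "g3"], ["a", "b"],
                    [[1, 2]] * 5)
        with pytest.warns(UserWarning, match="2 red-blood-cell"):
            out = remove_rbc_genes(m)
        assert out.gene_ids == ["g1", "g2", "g3"]

    def test_absent_genes_noop(self, small_matrix):
        assert remove_rbc_genes(small_matrix) is small_matrix

    def test_empty_set_noop(self, small_matrix):
        assert remove_rbc_genes(small_matrix, set()) is small_matrix


class TestRestrictToCoding:
    def test_set_filter(self):
        m = _counts(["g1", "g2", "g3", "g4"], ["a", "b"], [[1, 1]] * 4)
        out = restrict_to_coding(m, {"g2", "g4"})
        assert out.gene_ids == ["g2", "g4"]

    def test_zero_count_coding_gene_dropped(self):
        m = _counts(["g1", "g2"], ["a", "b"], [[0, 0], [1, 2]])
        out = restrict_to_coding(m, {"g1", "g2"})
        assert out.gene_ids == ["g2"]

    def test_superset_identity(self, small_matrix):
        out = restrict_to_coding(small_matrix, set(small_matrix.gene_ids))
        assert out.gene_ids == small_matrix.gene_ids


class TestCollapseProbes:
    def test_highest_mean_probe_kept(self):
        m = ExpressionMatrix(
            ["p1", "p2"], ["a", "b"], [[4.0, 6.0], [6.0, 8.0]], "log2_intensity"
        )
        out = collapse_probes(m, ProbeMap({"p1": "G", "p2": "G"}))
        assert out.gene_ids == ["G"]
        assert out.values.tolist() == [[6.0, 8.0]]

    def test_one_probe_per_gene_values_unchanged(self):
        m = ExpressionMatrix(
            ["p1", "p2"], ["a"], [[1.0], [2.0]], "log2_intensity"
        )
        out = collapse_probes(m, ProbeMap({"p1": "gB", "p2": "gA"}))
        # output sorted by gene ID: gA came from p2
        assert out.gene_ids == ["gA", "gB"]
        assert out.values.tolist() == [[2.0], [1.0]]

    def test_exact_tie_lexicographic(self):
        m = ExpressionMatrix(
            ["p2", "p1"], ["a", "b"], [[5.0, 5.0], [5.0, 5.0]], "log2_intensity"
        )
        out = collapse_probes(m, ProbeMap({"p1": "G", "p2": "G"}))
        # p1 wins the tie; its row is the second input row
        assert out.values.tolist() == [[5.0, 5.0]]

    def test_unmapped_probes_warn(self):
        m = ExpressionMatrix(["p1", "px"], ["a"], [[1.0], [2.0]], "log2_intensity")
        with pytest.warns(UserWarning, match="without a gene mapping"):
            out = collapse_probes(m, ProbeMap({"p1": "G"}))
        assert out.gene_ids == ["G"]

    def test_collapsed_mean_equals_max_probe_mean(self, rng):
        probes = [f"p{i}" for i in range(12)]
        mapping = {p: f"G{i % 4}" for i, p in enumerate(probes)}
        vals = rng.normal(5, 2, size=(12, 6))
        m = ExpressionMatrix(probes, [f"s{j}" for j in range(6)], vals, "log2_intensity")
        out = collapse_probes(m, ProbeMap(mapping))
        for g in out.gene_ids:
            members = [i for i, p in enumerate(probes) if mapping[p] == g]
            expected = max(vals[i].mean() for i in members)
            got = out.values[out.gene_ids.index(g)].mean()
            assert got == pytest.approx(expected)


class TestIqrFilter:
    def test_lowest_quartile_removed(self):
        # 4 genes with IQRs 0,1,2,3: ramps 0..2x have IQR = x (for 4 points,
        # quartiles at linear interpolation: q75-q25 = half the range)
        genes = ["g0", "g1", "g2", "g3"]
        values = np.array([
            [0.0, 0.0, 0.0, 0.0],   # IQR 0
            [0.0, 2/3, 4/3, 2.0],   # IQR 1
            [0.0, 4/3, 8/3, 4.0],   # IQR 2
            [0.0, 2.0, 4.0, 6.0],   # IQR 3
        ])
        from wbtdc.preprocess import gene_iqr
        assert gene_iqr(values).tolist() == [0.0, 1.0, 2.0, 3.0]
        m = ExpressionMatrix(genes, list("abcd"), values, "log2_intensity")
        out = iqr_filter(m, 0.25)
        # cutoff = 0.25-quantile of {0,1,2,3} = 0.75 -> only IQR-0 gene goes
        assert out.gene_ids == ["g1", "g2", "g3"]

    def test_drop_fraction_zero_identity(self, small_matrix):
        assert iqr_filter(small_matrix, 0.0) is small_matrix

    def test_constant_matrix_errors(self):
        m = ExpressionMatrix(["g1", "g2"], list("abcd"),
                             np.ones((2, 4)), "log2_intensity")
        with pytest.raises(ValidationError, match="every gene"):
            iqr_filter(m, 0.25)

    def test_row_permutation_equivariance(self, rng):
        vals = rng.normal(size=(20, 8))
        genes = [f"g{i:02d}" for i in range(20)]
        m = ExpressionMatrix(genes, [f"s{j}" for j in range(8)], vals, "log2_intensity")
        perm = rng.permutation(20)
        mp = ExpressionMatrix([genes[i] for i in perm], m.sample_ids,
                              vals[perm], "log2_intensity")
        out, outp = iqr_filter(m, 0.25), iqr_filter(mp, 0.25)
        assert sorted(out.gene_ids) == sorted(outp.gene_ids)


class TestTransformCounts:
    def test_identical_samples_unit_factors(self):
        m = _counts(["g1", "g2"], ["a", "b"], [[4, 4], [9, 9]])
        out, params = transform_counts(m)
        assert np.allclose(params.size_factors, [1.0, 1.0])
        assert np.allclose(out.values[:, 0], out.values[:, 1])

    def test_doubled_sample_median_of_ratios(self):
        # sample b = 2 * sample a: factors (1/sqrt2, sqrt2), columns equalize
        m = _counts(["g1", "g2"], ["a", "b"], [[10, 20], [40, 80]])
        out, params = transform_counts(m)
        assert np.allclose(params.size_factors, [2**-0.5, 2**0.5])
        assert np.allclose(out.values[:, 0], out.values[:, 1])

    def test_zero_count_maps_to_zero(self):
        m = _counts(["g1", "g2"], ["a", "b"], [[0, 0], [5, 5]])
        out, _ = transform_counts(m)
        assert out.values[0, 0] == pytest.approx(0.0)

    def test_zero_total_sample_errors(self):
        m = _counts(["g1"], ["a", "b"], [[0, 3]])
        with pytest.raises(ValidationError, match="zero total"):
            transform_counts(m)

    def test_global_rescale_invariance(self, rng):
        counts = rng.integers(0, 500, size=(60, 6)).astype(float)
        counts[:50] += 1  # ensure >= 50 all-positive reference genes
        genes = [f"g{i:02d}" for i in range(60)]
        m = _counts(genes, [f"s{j}" for j in range(6)], counts)
        m2 = _counts(genes, [f"s{j}" for j in range(6)], counts * 2)
        out, p1 = transform_counts(m)
        out2, p2 = transform_counts(m2)
        # doubling all counts doubles nothing after size-factor normalization
        # (factors are normalized to geometric mean 1, so values shift by +1 count unit)
        assert np.allclose(p1.size_factors, p2.size_factors)
        assert np.allclose(
            2 ** out2.values - 1, 2 * (2 ** out.values - 1), rtol=1e-10
        )

    def test_size_factor_geometric_mean_one(self, rng):
        counts = rng.poisson(100, size=(80, 5)).astype(float) + 1
        m = _counts([f"g{i}" for i in range(80)], list("abcde"), counts)
        _, params = transform_counts(m)
        assert np.exp(np.mean(np.log(params.size_factors))) == pytest.approx(1.0, abs=1e-6)
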
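import numpy as np
import pytest
from scipy import stats

from oracles import wilcoxon_exact_bruteforce
from wbtdc import (
    ExpressionMatrix,
    PhenotypeTable,
    ValidationError,
    normality_gate,
    read_gmt,
    sample_gene_sets,
    scan_set_sizes,
    wilcoxon_rank_sum,
    write_gmt,
)
from wbtdc.diffexpr import RankedDegPools
from wbtdc.genesets import GeneSet, GeneSetCollection, _plateau


class TestNormalityGate:
    def test_right_skewed_rejected(self):
        """Squared-normal draws are flagged non-normal in >= 95/100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, is_normal = normality_gate(rng.normal(size=500) ** 2)
            hits += not is_normal
        assert hits >= 95

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValidationError):
            normality_gate(np.array([1.0, 2.0]))

    def test_exact_normal_quantiles_pass(self):
        # van der Waerden scores: as normal as n=100 data can be
        q = stats.norm.ppf((np.arange(1, 101)) / 101.0)
        _, is_normal = normality_gate(q)
        assert is_normal

    def test_large_input_thinned(self, rng):
        p, _ = normality_gate(rng.normal(size=20000))
        assert 0 <= p <= 1


class TestWilcoxonRankSum:
    def test_exact_worked_example(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) >= 0.99

    def test_swap_symmetry(self, rng):
        x, y = rng.normal(size=9), rng.normal(1, 1, size=14)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_rank_sum(y, x))

    def test_matches_enumeration_bruteforce(self, rng):
        worst = 0.0
        for _ in range(400):
            nx, ny = rng.integers(2, 8, size=2)
            vals = rng.permutation(rng.uniform(size=int(nx + ny)))
            x, y = vals[:nx], vals[nx:]
            worst = max(
                worst, abs(wilcoxon_rank_sum(x, y) - wilcoxon_exact_bruteforce(x, y))
            )
        assert worst <= 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])


class TestPlateauRule:
    def test_smallest_size_of_longest_run(self):
        sizes = np.array([10, 20, 50, 100, 200])
        m = np.array([0.5, 2.0, 2.0, 2.0, 1.0])
        rng_, chosen = _plateau(sizes, m)
        assert rng_ == (20, 100)
        assert chosen == 20

    def test_saturating_curve_picks_saturation_onset(self):
        sizes = np.array([10, 20, 50, 100, 200])
        m = np.array([1.0, 5.0, 14.0, 14.0, 14.0])
        rng_, chosen = _plateau(sizes, m)
        assert chosen == 50


def _scan_inputs(rng, n_genes=120, n_per_group=12, signal_genes=0, effect=2.0):
    genes = [f"g{i:03d}" for i in range(n_genes)]
    n = 2 * n_per_group
    samples = [f"s{j}" for j in range(n)]
    labels = ["disease"] * n_per_group + ["control"] * n_per_group
    vals = rng.normal(8, 1, size=(n_genes, n))
    for i in range(signal_genes):
        vals[i, :n_per_group] += effect
    m = ExpressionMatrix(genes, samples, vals, "transformed")
    pheno = PhenotypeTable(samples, labels)
    pools = RankedDegPools(up=genes[: n_genes // 2], down=genes[n_genes // 2 :])
    return m, pheno, pools


class TestScanSetSizes:
    def test_one_record_per_size_and_direction(self, rng):
        m, pheno, pools = _scan_inputs(rng)
        res = scan_set_sizes(m, pheno, pools, grid=(10, 20, 40), reps_per_direction=5, seed=3)
        assert len(res.records) == 3 * 2
        assert len(res.by_size) == 3
        assert res.chosen_range[0] <= res.chosen_size <= res.chosen_range[1]

    def test_bit_reproducible(self, rng):
        m, pheno, pools = _scan_inputs(rng)
        r1 = scan_set_sizes(m, pheno, pools, grid=(10, 30), reps_per_direction=5, seed=9)
        r2 = scan_set_sizes(m, pheno, pools, grid=(10, 30), reps_per_direction=5, seed=9)
        assert r1.records.equals(r2.records)
        assert r1.chosen_size == r2.chosen_size

    def test_grid_clamped_to_pool(self, rng):
        m, pheno, pools = _scan_inputs(rng)
        with pytest.warns(UserWarning, match="clamped"):
            res = scan_set_sizes(
                m, pheno, pools, grid=(10, 500), reps_per_direction=4, seed=0
            )
        assert res.by_size["size"].max() == 60

    def test_small_pool_rejected(self, rng):
        m, pheno, pools = _scan_inputs(rng)
        tiny = RankedDegPools(up=pools.up[:5], down=pools.down)
        with pytest.raises(ValidationError, match="fewer than 10"):
            scan_set_sizes(m, pheno, tiny, grid=(10,), reps_per_direction=3, seed=0)

    def test_null_scan_flags_no_stable_significance(self):
        """Permuted-label (null) data: median rank-sum p stays moderate."""
        medians = []
        stable = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m, pheno, pools = _scan_inputs(rng, signal_genes=0)
            res = scan_set_sizes(
                m, pheno, pools, grid=(10, 20, 30, 40, 50, 60),
                reps_per_direction=20, seed=seed,
            )
            medians.extend(res.by_size["p_median"].tolist())
            stable.append(res.stable_significance)
        frac_moderate = np.mean([0.2 <= p <= 0.8 for p in medians])
        assert frac_moderate >= 20 / 30
        assert sum(stable) <= 1


class TestSampleGeneSets:
    def _pools(self):
        return RankedDegPools(
            up=[f"u{i:03d}" for i in range(50)],
            down=[f"d{i:03d}" for i in range(50)],
        )

    def test_composition_100_up_100_down(self):
        coll = sample_gene_sets(self._pools(), set_size=10, seed=1)
        assert len(coll) == 200
        assert sum(s.direction == "up" for s in coll.sets) == 100

    def test_sets_are_subsets_without_replacement(self):
        pools = self._pools()
        coll = sample_gene_sets(pools, set_size=12, n_up=20, n_down=20, seed=5)
        for s in coll.sets:
            assert len(s.members) == 12
            assert len(set(s.members)) == 12
            ref = pools.up if s.direction == "up" else pools.down
            assert set(s.members) <= set(ref)

    def test_full_pool_size_forces_identical_sets(self):
        coll = sample_gene_sets(self._pools(), set_size=50, n_up=3, n_down=0, seed=2)
        assert all(set(s.members) == set(coll.sets[0].members) for s in coll.sets)

    def test_seed_determinism_and_divergence(self):
        pools = self._pools()
        a = sample_gene_sets(pools, set_size=10, seed=4)
        b = sample_gene_sets(pools, set_size=10, seed=4)
        c = sample_gene_sets(pools, set_size=10, seed=5)
        assert [s.members for s in a.sets] == [s.members for s in b.sets]
        assert [s.members for s in a.sets] != [s.members for s in c.sets]

    def test_oversized_request_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            sample_gene_sets(self._pools(), set_size=60, seed=0)


class TestGmtRoundTrip:
    def test_write_read_preserves_sets(self, tmp_path):
        coll = GeneSetCollection([
            GeneSet("up_001", "up", ["g1", "g2", "g3"]),
            GeneSet("down_001", "down", ["g4", "g5"]),
        ])
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert [s.set_id for s in back.sets] == ["up_001", "down_001"]
        assert back.sets[1].members == ["g4", "g5"]
        assert back.checksum() == coll.checksum()
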
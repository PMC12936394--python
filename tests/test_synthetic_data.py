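import filecmp

import numpy as np
import pytest
from scipy import stats

from nicrosize.data_io import read_occurrence_table
from nicrosize.synthetic_data import (
    SyntheticConfig,
    generate_dataset,
    generate_species_means,
    pairs_from_means,
    simulate_centroids,
    simulate_occurrences,
    simulate_sister_pairs,
    simulate_tip_sizes,
    simulate_tree,
)


class TestSimulateTree:
    def test_two_tips_is_a_cherry_with_equal_pendants(self):
        t = simulate_tree(2, seed=0)
        assert t.n_tips == 2
        lengths = [lf.edge.length for lf in t.tree.leaf_node_iter()]
        assert lengths[0] == pytest.approx(lengths[1])

    def test_deterministic_newick(self):
        a = simulate_tree(70, seed=5).as_newick()
        b = simulate_tree(70, seed=5).as_newick()
        assert a == b

    @pytest.mark.parametrize("n", [2, 5, 23, 70])
    def test_bifurcating_internal_node_count(self, n):
        t = simulate_tree(n, seed=n)
        assert len(t.internal_nodes()) == n - 1
        assert t.max_ultrametric_deviation < 1e-9

    def test_waiting_time_scaling(self):
        # higher birth rate -> proportionally shallower trees on average
        h_slow = np.mean([simulate_tree(20, 0.05, seed=s).root_height for s in range(40)])
        h_fast = np.mean([simulate_tree(20, 0.5, seed=s).root_height for s in range(40)])
        assert h_slow / h_fast == pytest.approx(10.0, rel=0.05)


class TestSimulateTipSizes:
    def test_tiny_rate_collapses_to_root_state(self):
        t = simulate_tree(10, seed=1)
        x = simulate_tip_sizes(t, root_state=6.67, sigma2=1e-12, seed=2)
        assert np.allclose(list(x.values()), 6.67, atol=1e-4)

    def test_nonpositive_rate_fatal(self):
        t = simulate_tree(5, seed=1)
        with pytest.raises(ValueError):
            simulate_tip_sizes(t, sigma2=0.0)

    def test_bounded_values(self):
        t = simulate_tree(50, seed=3)
        x = simulate_tip_sizes(t, 6.67, 1.0, 1.0, bounds=(4.0, 11.0), seed=4)
        v = np.array(list(x.values()))
        assert v.min() >= 4.0 and v.max() <= 11.0

    def test_bm_covariance_matches_shared_path_lengths(self):
        # empirical tip covariance over replicates converges on sigma2 * C
        t = simulate_tree(6, seed=5)
        names, C = t.vcv()
        sigma2 = 0.05
        draws = np.array([
            [simulate_tip_sizes(t, 0.0, sigma2, 1.0, None, seed=s)[n] for n in names]
            for s in range(400)])
        emp = np.cov(draws.T)
        scale = sigma2 * C
        assert np.allclose(emp, scale, atol=4 * sigma2 * C.max() / np.sqrt(400))

    def test_lambda_zero_gives_iid_tips(self):
        t = simulate_tree(6, seed=6)
        names, C = t.vcv()
        draws = np.array([
            [simulate_tip_sizes(t, 0.0, 0.05, 0.0, None, seed=s)[n] for n in names]
            for s in range(400)])
        emp = np.corrcoef(draws.T)
        off = emp[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.2


class TestSpeciesMeans:
    def test_span_and_gap(self):
        cfg = SyntheticConfig()
        for seed in range(5):
            m = generate_species_means(cfg, seed=seed)
            assert m.min() == pytest.approx(4.15)
            assert m.max() == pytest.approx(10.97)
            assert not np.any((m > 8.0) & (m < 9.0))
            assert len(m) == 70

    def test_right_skewed(self):
        m = generate_species_means(SyntheticConfig(), seed=1)
        assert stats.skew(m) > 0.5

    def test_gap_optional(self):
        cfg = SyntheticConfig(gap_interval=None)
        m = generate_species_means(cfg, seed=2)
        assert len(m) == 70


class TestSimulateOccurrences:
    def test_fixed_count_identity(self):
        cfg = SyntheticConfig(records_per_species=30, n_species=70)
        means = {f"s{i:02d}": 5.0 + 0.05 * i for i in range(70)}
        recs = simulate_occurrences(means, cfg, seed=0)
        assert len(recs) == 2100

    def test_widths_within_bounds(self):
        cfg = SyntheticConfig(records_per_species=50)
        means = {"a": 4.2, "b": 10.9}
        recs = simulate_occurrences(means, cfg, seed=1)
        w = [r.width_mm for r in recs if r.width_mm is not None]
        assert min(w) >= 4.0 and max(w) <= 11.0

    def test_temperate_concentration(self):
        # the centroid model should put well over half the records at 25-60 N
        cfg = SyntheticConfig(records_per_species=30)
        fracs = []
        for seed in range(20):
            means = dict(zip([f"s{i}" for i in range(70)],
                             generate_species_means(cfg, seed=seed)))
            recs = simulate_occurrences(means, cfg, seed=seed)
            lats = np.array([r.latitude for r in recs])
            fracs.append(np.mean((lats >= 25) & (lats <= 60)))
        assert min(fracs) > 0.6

    def test_literature_rows_lack_widths(self):
        cfg = SyntheticConfig(records_per_species=200, literature_fraction=0.25)
        recs = simulate_occurrences({"a": 6.0}, cfg, seed=3)
        lit = [r for r in recs if r.source == "literature"]
        assert lit and all(r.width_mm is None for r in lit)
        assert 0.1 < len(lit) / len(recs) < 0.4


class TestSisterPairs:
    def test_two_cherries_two_pairs(self):
        from nicrosize.data_io import DatedTree
        t = DatedTree.from_newick("((A:1,B:1):2,(C:2,D:2):1);")
        cfg = SyntheticConfig()
        pairs, _ = simulate_sister_pairs(t, {"A": 5, "B": 6, "C": 7, "D": 8}, cfg, seed=0)
        assert len(pairs) == 2
        assert set(pairs.columns) == {"species_a", "species_b", "status"}

    def test_displacement_pushes_sympatric_pairs_apart(self):
        t = simulate_tree(40, seed=7)
        sizes = simulate_tip_sizes(t, 6.67, 0.02, 1.0, (4, 11), seed=8)
        cfg = SyntheticConfig(displacement_boost=0.3, p_sympatric=1.0)
        pairs, adj = simulate_sister_pairs(t, sizes, cfg, seed=9)
        for row in pairs.itertuples():
            before = abs(sizes[row.species_a] - sizes[row.species_b])
            after = abs(adj[row.species_a] - adj[row.species_b])
            assert after >= before - 1e-12

    def test_zero_boost_groups_indistinguishable(self):
        # with no displacement, |mean difference| must not differ by sympatry
        insignificant = 0
        n_seeds = 50
        for s in range(n_seeds):
            t = simulate_tree(70, seed=s)
            sizes = simulate_tip_sizes(t, 6.67, 0.02, 1.0, (4, 11), seed=1000 + s)
            cfg = SyntheticConfig(displacement_boost=0.0, p_sympatric=0.5)
            pairs, adj = simulate_sister_pairs(t, sizes, cfg, seed=2000 + s)
            d_sym = [abs(adj[r.species_a] - adj[r.species_b])
                     for r in pairs.itertuples() if r.status == "sympatric"]
            d_non = [abs(adj[r.species_a] - adj[r.species_b])
                     for r in pairs.itertuples() if r.status == "non-sympatric"]
            if len(d_sym) < 2 or len(d_non) < 2:
                insignificant += 1
                continue
            _, p = stats.mannwhitneyu(d_sym, d_non, alternative="two-sided")
            insignificant += p > 0.05
        assert insignificant > 0.9 * n_seeds

    def test_centroid_rule_defines_sympatry(self):
        from nicrosize.data_io import DatedTree
        t = DatedTree.from_newick("((A:1,B:1):2,(C:2,D:2):1);")
        cents = {"A": (45.0, 10.0), "B": (45.5, 10.5),  # ~70 km apart
                 "C": (45.0, 10.0), "D": (20.0, -100.0)}
        pairs, _ = simulate_sister_pairs(t, {"A": 5, "B": 6, "C": 7, "D": 8},
                                         SyntheticConfig(), seed=0, centroids=cents)
        status = dict(zip(pairs.species_a + "-" + pairs.species_b, pairs.status))
        assert status["A-B"] == "sympatric"
        assert status["C-D"] == "non-sympatric"


class TestGenerateDataset:
    def test_identical_seed_byte_identical_outputs(self, tmp_path):
        d1 = generate_dataset(SyntheticConfig(seed=4, records_per_species=20))
        d2 = generate_dataset(SyntheticConfig(seed=4, records_per_species=20))
        a, b = tmp_path / "a", tmp_path / "b"
        d1.write(a)
        d2.write(b)
        for name in ("occurrences.csv", "tree.nwk", "sister_pairs.csv", "species_means.csv"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_written_table_round_trips(self, tmp_path):
        ds = generate_dataset(SyntheticConfig(seed=5, records_per_species=10))
        ds.write(tmp_path)
        recs, errs = read_occurrence_table(tmp_path / "occurrences.csv")
        assert errs == []
        assert len(recs) == len(ds.records)

    def test_means_respect_span_and_signal_is_present(self):
        ds = generate_dataset(SyntheticConfig(seed=6, records_per_species=10))
        m = np.array(list(ds.species_means.values()))
        assert m.min() >= 4.0 and m.max() <= 11.0
        assert len(ds.pairs) >= 5
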
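import numpy as np
import pytest

from plantarqc.dataio import Dataset
from plantarqc.spm import (Cluster, NormativeModel, SPMConfig, classify_spm,
                           compute_pmap, find_clusters,
                           nearest_rank_percentile,
                           null_max_cluster_distribution, pixel_pvalue,
                           tune_spm)
from plantarqc.types import Side


def brute_force_pvalue(t, values):
    """Independent O(n) counting oracle for the two-tailed rank p."""
    values = list(values)
    n = len(values)
    ge = sum(1 for x in values if x >= t)
    le = sum(1 for x in values if x <= t)
    return min(1.0, 2 * min(1 + ge, 1 + le) / (n + 1))


class TestPixelPValue:
    def test_matches_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            values = rng.choice([0.0, rng.random()], size=n)
            t = rng.choice([0.0, rng.random(),
                            values[int(rng.integers(n))]])
            assert pixel_pvalue(t, values) == pytest.approx(
                brute_force_pvalue(t, values))

    def test_extreme_value_small_p(self):
        values = np.arange(99) / 100.0
        assert pixel_pvalue(2.0, values) == pytest.approx(2 / 100)

    def test_central_value_capped_at_one(self):
        assert pixel_pvalue(3, [1, 2, 3, 4, 5]) == 1.0

    def test_background_full_ties_give_one(self):
        assert pixel_pvalue(0.0, np.zeros(50)) == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            pixel_pvalue(0.5, [])


class TestComputePMap:
    def test_off_footprint_pressure_hits_minimum_p(self, cohort_stack):
        model = NormativeModel(side=Side.LEFT, stack=cohort_stack)
        n = model.n
        grid = cohort_stack[0].copy()
        # a corner where the whole cohort is zero
        assert np.all(cohort_stack[:, 0, 0] == 0)
        grid[0, 0] = 0.8
        pmap = compute_pmap(grid, model)
        assert pmap[0, 0] == pytest.approx(2 / (n + 1))

    def test_p_bounded_below_by_formula(self, cohort_stack):
        model = NormativeModel(side=Side.LEFT, stack=cohort_stack)
        pmap = compute_pmap(cohort_stack[3], model)
        assert pmap.min() >= 2 / (model.n + 1) - 1e-12
        assert pmap.max() <= 1.0

    def test_cohort_median_grid_has_no_small_p(self, cohort_stack):
        model = NormativeModel(side=Side.LEFT, stack=cohort_stack)
        median_grid = np.median(cohort_stack, axis=0)
        pmap = compute_pmap(median_grid, model)
        assert pmap.min() > 0.05


class TestFindClusters:
    def _pmap(self, coords, shape=(4, 4)):
        p = np.ones(shape)
        for rc in coords:
            p[rc] = 0.001
        return p

    def test_component_sizes(self):
        pmap = self._pmap([(0, 0), (0, 1), (1, 1), (3, 3)])
        sizes = sorted(c.size for c in find_clusters(pmap, 0.05, 0, 8))
        assert sizes == [1, 3]

    def test_min_cluster_filters_small_components(self):
        pmap = self._pmap([(0, 0), (0, 1), (1, 1), (3, 3)])
        sizes = [c.size for c in find_clusters(pmap, 0.05, 2, 8)]
        assert sizes == [3]

    def test_connectivity_convention(self):
        pmap = self._pmap([(0, 0), (1, 1)])
        assert len(find_clusters(pmap, 0.05, 0, 4)) == 2
        assert len(find_clusters(pmap, 0.05, 0, 8)) == 1

    def test_matches_connected_component_oracle(self):
        """Cluster pixel sets equal a brute-force flood fill."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            pmap = np.where(rng.random((12, 12)) < 0.3, 0.001, 1.0)
            ours = {frozenset(c.pixels)
                    for c in find_clusters(pmap, 0.05, 0, 8)}
            # flood fill oracle
            mask = pmap < 0.05
            seen = set()
            oracle = set()
            for r in range(12):
                for c in range(12):
                    if mask[r, c] and (r, c) not in seen:
                        comp, stack = set(), [(r, c)]
                        while stack:
                            y, x = stack.pop()
                            if (y, x) in comp or not (
                                    0 <= y < 12 and 0 <= x < 12) \
                                    or not mask[y, x]:
                                continue
                            comp.add((y, x))
                            for dy in (-1, 0, 1):
                                for dx in (-1, 0, 1):
                                    stack.append((y + dy, x + dx))
                        seen |= comp
                        oracle.add(frozenset(comp))
            assert ours == oracle


class TestNullDistribution:
    def test_identical_cohort_gives_all_zero_sizes(self):
        stack = np.tile(np.random.default_rng(0).random((64, 64)), (10, 1, 1))
        model = NormativeModel(side=Side.LEFT, stack=stack)
        null = null_max_cluster_distribution(
            model, SPMConfig(alpha_forming=0.05, n_permutations=100), seed=0)
        assert np.all(null == 0)

    def test_deterministic_for_seed(self, cohort_stack):
        model = NormativeModel(side=Side.LEFT, stack=cohort_stack)
        cfg = SPMConfig(n_permutations=200)
        a = null_max_cluster_distribution(model, cfg, seed=4)
        b = null_max_cluster_distribution(model, cfg, seed=4)
        assert np.array_equal(a, b)

    def test_nearest_rank_percentile_matches_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.integers(0, 50, size=1000)
        q = 0.95
        ours = nearest_rank_percentile(values, q)
        srt = np.sort(values)
        assert ours == srt[int(np.ceil(q * len(values))) - 1]

    def test_cohort_too_small_rejected(self):
        model = NormativeModel(side=Side.LEFT, stack=np.zeros((1, 64, 64)))
        with pytest.raises(ValueError):
            null_max_cluster_distribution(model, SPMConfig(), seed=0)


class TestClassify:
    def test_no_candidate_clusters_not_outlier(self, cohort_stack):
        model = NormativeModel(side=Side.LEFT, stack=cohort_stack)
        decision = classify_spm(np.median(cohort_stack, axis=0), model,
                                SPMConfig(alpha_forming=0.01),
                                np.zeros(1000))
        assert not decision.is_outlier

    def test_strict_exceedance_of_threshold(self, cohort_stack):
        model = NormativeModel(side=Side.LEFT, stack=cohort_stack)
        cfg = SPMConfig(alpha_forming=0.05, min_cluster=0)
        grid = cohort_stack[0].copy()
        grid[0:2, 0:2] = 0.9          # 4-pixel off-footprint cluster
        null_equal = np.full(1000, 4)  # threshold exactly 4
        d = classify_spm(grid, model, cfg, null_equal)
        sizes = [c.size for c in d.clusters]
        assert 4 in sizes
        assert not any(c.size == 4 for c in d.significant)
        null_below = np.full(1000, 3)
        d2 = classify_spm(grid, model, cfg, null_below)
        assert d2.is_outlier

    def test_decision_invariant_to_cohort_order(self, cohort_stack):
        cfg = SPMConfig(alpha_forming=0.05, min_cluster=3)
        grid = cohort_stack[0].copy()
        grid[:3, :3] = 0.9
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cohort_stack))
        d1 = classify_spm(grid, NormativeModel(side=Side.LEFT,
                                               stack=cohort_stack),
                          cfg, np.zeros(100))
        d2 = classify_spm(grid, NormativeModel(side=Side.LEFT,
                                               stack=cohort_stack[perm]),
                          cfg, np.zeros(100))
        assert d1.is_outlier == d2.is_outlier
        assert np.array_equal(d1.pmap, d2.pmap)

    def test_larger_deviant_region_never_shrinks_max_cluster(
            self, cohort_stack):
        model = NormativeModel(side=Side.LEFT, stack=cohort_stack)
        cfg = SPMConfig(alpha_forming=0.05, min_cluster=0)
        base = np.median(cohort_stack, axis=0)
        last = 0
        for extent in (2, 4, 8, 12):
            grid = base.copy()
            grid[:extent, :extent] = 0.9
            d = classify_spm(grid, model, cfg, np.zeros(100))
            biggest = max((c.size for c in d.clusters), default=0)
            assert biggest >= last
            last = biggest


class TestTuneSPM:
    def _tiny_sets(self, cohort_stack):
        train = Dataset.from_samples([])
        # build train/val datasets directly from grids
        from plantarqc.types import PressureSample
        tr = [PressureSample(sample_id=f"t{i}", grid=g, subject_id=f"T{i}",
                             side=Side.LEFT)
              for i, g in enumerate(cohort_stack[:30])]
        va = []
        for i, g in enumerate(cohort_stack[30:40]):
            va.append(PressureSample(sample_id=f"v{i}", grid=g,
                                     subject_id=f"V{i}", side=Side.LEFT))
        for i, g in enumerate(cohort_stack[40:50]):
            out = g.copy()
            out[:6, :6] = 0.95
            va.append(PressureSample(sample_id=f"o{i}", grid=out,
                                     subject_id=f"O{i}", side=Side.LEFT,
                                     label=1, provenance="synthetic",
                                     source_ids=["x"]))
        # add one right-side sample so both sides have cohorts
        tr.append(PressureSample(sample_id="r0", grid=np.fliplr(
            cohort_stack[0]), subject_id="R0", side=Side.RIGHT))
        tr.append(PressureSample(sample_id="r1", grid=np.fliplr(
            cohort_stack[1]), subject_id="R1", side=Side.RIGHT))
        return Dataset.from_samples(tr), Dataset.from_samples(va)

    def test_seeded_candidates_deterministic(self, cohort_stack):
        train, val = self._tiny_sets(cohort_stack)
        a = tune_spm(train, val, n_candidates=3, seed=5, n_permutations=100)
        b = tune_spm(train, val, n_candidates=3, seed=5, n_permutations=100)
        assert (a[0].alpha_forming, a[0].min_cluster) == \
               (b[0].alpha_forming, b[0].min_cluster)

    def test_single_candidate_returned(self, cohort_stack):
        train, val = self._tiny_sets(cohort_stack)
        cfg, f1 = tune_spm(train, val, n_candidates=1, seed=2,
                           n_permutations=100)
        assert 0.01 <= cfg.alpha_forming <= 0.05
        assert 0 <= cfg.min_cluster <= 30

    def test_single_class_validation_rejected(self, cohort_stack):
        train, val = self._tiny_sets(cohort_stack)
        only_valid = val.subset(
            (val.manifest["label"].astype(int) == 0).to_numpy())
        with pytest.raises(ValueError):
            tune_spm(train, only_valid, n_candidates=2, seed=0,
                     n_permutations=100)
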
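import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from phaseloop import (
    LoopCandidate,
    YF17D_STAGE_MAP,
    center_to_baseline,
    evaluate,
    impute_missing_timepoints,
    knn_predict,
    ks_two_sample,
    loocv,
    noise_sensitivity,
    predict_pair,
    random_pair_null,
    split_by_individuals,
    split_stratified_by_time,
)
from phaseloop.synthetic import SimulationConfig, generate


def brute_force_knn(train_points, test_points, k):
    """Independent oracle: exhaustive distances, same tie-break contract."""
    out = []
    for tx, ty in test_points:
        scored = [
            (np.hypot(x - tx, y - ty), i, lab)
            for i, (x, y, lab) in enumerate(train_points)
        ]
        scored.sort(key=lambda s: (s[0], s[1]))
        top = scored[:k]
        counts = {}
        for _, _, lab in top:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        out.append(winners[0] if len(winners) == 1 else top[0][2])
    return out


class TestKnnPredict:
    def test_unanimous_colocated_neighbors(self):
        train = [(1.0, 1.0, "t=4h")] * 3
        assert knn_predict(train, [(1.0, 1.0)], k=3) == ["t=4h"]

    def test_majority_of_three_nearest(self):
        train = [(0, 0, "A"), (1, 0, "A"), (0, 1, "B"), (5, 5, "B")]
        assert knn_predict(train, [(0.1, 0.1)], k=3) == ["A"]

    def test_majority_beats_nearest_single_neighbor(self):
        train = [(0, 0, "A"), (0.6, 0, "B"), (0, 0.6, "B"), (9, 9, "A")]
        assert knn_predict(train, [(0.1, 0.1)], k=3) == ["B"]

    def test_vote_tie_goes_to_nearest(self):
        train = [(0, 0, "A"), (2, 0, "B"), (0, 2, "B"), (2, 2, "A")]
        assert knn_predict(train, [(0.5, 0.5)], k=4) == ["A"]

    def test_insufficient_training_points_rejected(self):
        with pytest.raises(ValueError, match="k=3"):
            knn_predict([(0, 0, "A")], [(1, 1)], k=3)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            n_train = int(rng.integers(3, 50))
            train = [
                (float(x), float(y), f"L{int(l)}")
                for x, y, l in zip(
                    rng.normal(size=n_train),
                    rng.normal(size=n_train),
                    rng.integers(0, 4, size=n_train),
                )
            ]
            test = [tuple(map(float, p)) for p in rng.normal(size=(8, 2))]
            assert knn_predict(train, test, k=3) == brute_force_knn(train, test, 3)


class TestEvaluate:
    def test_perfect_prediction_diagonal_matrix(self):
        res = evaluate(["a", "b", "a"], ["a", "b", "a"])
        assert res.accuracy == 1.0
        off_diag = res.confusion.to_numpy() - np.diag(np.diag(res.confusion))
        assert off_diag.sum() == 0

    def test_base_days_interchangeable_under_stage_map(self):
        res = evaluate([0, 3, 7, 14], [14, 3, 7, 28], stage_map=YF17D_STAGE_MAP)
        assert res.accuracy == 1.0

    def test_fractional_accuracy(self):
        truth = list("aaaaabbbbb")
        pred = list("aaaaabbbbc")
        assert evaluate(truth, pred).accuracy == 0.9

    def test_unmapped_time_rejected_by_name(self):
        with pytest.raises(ValueError, match="60"):
            evaluate([60.0], [0.0], stage_map=YF17D_STAGE_MAP)

    def test_invariant_under_bijective_relabeling(self):
        rng = np.random.default_rng(0)
        truth = list(rng.integers(0, 4, size=30))
        pred = list(rng.integers(0, 4, size=30))
        base = evaluate(truth, pred).accuracy
        relabel = {0: "w", 1: "x", 2: "y", 3: "z"}
        remapped = evaluate(
            [relabel[t] for t in truth], [relabel[p] for p in pred]
        ).accuracy
        assert remapped == base

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            evaluate([1], [1, 2])


class TestLoocv:
    def test_duplicate_individuals_predict_each_other(self):
        from phaseloop import ExpressionDataset

        profile = np.array([[0.0, 2.0, 4.0, 2.0, 0.0], [0.0, 0.0, 2.0, 4.0, 2.0]])
        samples, cols = [], []
        for ind in ("A", "B"):
            for t in range(5):
                samples.append((ind, float(t)))
                cols.append(profile[:, t])
        ds = ExpressionDataset(["lead", "lag"], samples, np.column_stack(cols))
        res = loocv(ds, ("lead", "lag"))
        assert res["min"] == res["max"] == 1.0

    def test_low_noise_cohort_recovers_time(self, stage_map_default):
        ds, truth = generate(
            SimulationConfig(seed=11, n_individuals=6, noise_sd=0.1,
                             n_background_genes=5)
        )
        prep = center_to_baseline(impute_missing_timepoints(ds))
        res = loocv(prep, truth.pairs[0], stage_map=stage_map_default)
        assert res["median"] >= 0.9

    def test_shuffled_labels_fall_to_chance(self, stage_map_default):
        rng = np.random.default_rng(9)
        ds, truth = generate(
            SimulationConfig(seed=11, n_individuals=6, noise_sd=0.1,
                             n_background_genes=5)
        )
        prep = center_to_baseline(impute_missing_timepoints(ds))
        # destroy the time structure by permuting sample times within individuals
        shuffled = prep.copy()
        for ind in shuffled.individuals:
            idx = [i for i, (s, _) in enumerate(shuffled.samples) if s == ind]
            perm = rng.permutation(idx)
            for i, j in zip(idx, perm):
                shuffled.values[:, i] = prep.values[:, j]
        res = loocv(shuffled, truth.pairs[0], stage_map=stage_map_default)
        n_labels = len(set(stage_map_default.values()))
        assert res["median"] <= 2.5 / n_labels

    def test_single_individual_rejected(self, tiny_ds):
        with pytest.raises(ValueError, match="2 individuals"):
            loocv(tiny_ds.subset_individuals(["D1"]), ("IL1A", "TNIP3"))


@pytest.fixture(scope="module")
def cohorts(stage_map_default):
    a, _ = generate(SimulationConfig(seed=31, noise_sd=0.2))
    b, _ = generate(SimulationConfig(seed=32, noise_sd=0.2))
    prep = lambda d: center_to_baseline(impute_missing_timepoints(d))
    return prep(a), prep(b), stage_map_default


class TestNoiseSensitivity:
    def test_zero_noise_reproduces_noiseless_accuracy(self, cohorts):
        train, test, smap = cohorts
        res = noise_sensitivity(
            train, test, ("LEAD_00", "LAG_00"), stage_map=smap,
            n_reps=3, seed=1, sd_scale=0.0,
        )
        assert res["noisy_accuracy"] == res["noiseless_accuracy"]

    def test_moderate_noise_shifts_accuracy_little(self, cohorts):
        train, test, smap = cohorts
        res = noise_sensitivity(
            train, test, ("LEAD_00", "LAG_00"), stage_map=smap,
            n_reps=30, seed=7, sd_scale=1.0,
        )
        assert abs(res["noisy_accuracy"] - res["noiseless_accuracy"]) <= 0.1

    def test_extreme_noise_approaches_majority_frequency(self, cohorts):
        train, test, smap = cohorts
        res = noise_sensitivity(
            train, test, ("LEAD_00", "LAG_00"), stage_map=smap,
            n_reps=30, seed=7, sd_scale=100.0,
        )
        majority = 2 / 9  # first and last time share the 'base' stage
        assert abs(res["noisy_accuracy"] - majority) < 0.1


class TestRandomPairNull:
    def test_identical_samples_have_zero_ks(self):
        stat, _ = ks_two_sample([0.1, 0.5, 0.9] * 4, [0.1, 0.5, 0.9] * 4)
        assert stat == 0.0

    def test_disjoint_supports_have_unit_ks(self):
        stat, p = ks_two_sample([1.0] * 10, [0.0] * 10)
        assert stat == 1.0
        assert p < 0.01

    def test_planted_pairs_separate_from_random(self, stage_map_default):
        ds, truth = generate(
            SimulationConfig(seed=3, n_planted_pairs=5, noise_sd=0.2)
        )
        prep = center_to_baseline(impute_missing_timepoints(ds))
        train, test = split_stratified_by_time(prep, 0.5, seed=3)
        cands = [LoopCandidate(0, l, g) for l, g in truth.pairs]
        res = random_pair_null(
            train, test, cands, n_random=50, stage_map=stage_map_default, seed=3
        )
        assert res.ks_statistic >= 0.5
        # direct ECDF sup-difference oracle
        grid = np.unique(res.candidate_accuracies + res.random_accuracies)
        ecdf = lambda xs, g: np.mean(np.asarray(xs)[:, None] <= g, axis=0)
        oracle = np.max(
            np.abs(
                ecdf(res.candidate_accuracies, grid) - ecdf(res.random_accuracies, grid)
            )
        )
        assert res.ks_statistic == pytest.approx(oracle)
        # planted accuracies stochastically dominate random ones
        mw = mannwhitneyu(
            res.candidate_accuracies, res.random_accuracies, alternative="greater"
        )
        assert mw.pvalue < 0.01

    def test_insufficient_random_pool_rejected(self, tiny_ds):
        cands = [LoopCandidate(0, "IL1A", "TNIP3"), LoopCandidate(0, "TNIP3", "GAPDH")]
        with pytest.raises(ValueError, match="non-candidate"):
            random_pair_null(tiny_ds, tiny_ds, cands, n_random=10)


class TestSplits:
    def test_stratified_split_covers_every_time_evenly(self, prepared_noisy):
        _, ds, _ = prepared_noisy
        train, test = split_stratified_by_time(ds, 0.5, seed=0)
        for t in ds.times:
            n = sum(1 for _, st in ds.samples if st == t)
            n_train = sum(1 for _, st in train.samples if st == t)
            assert abs(n_train - 0.5 * n) <= 1
        assert train.n_samples + test.n_samples == ds.n_samples

    def test_split_by_individuals_partitions(self, prepared_noisy):
        _, ds, _ = prepared_noisy
        train, test = split_by_individuals(ds, ["S00", "S01"])
        assert set(test.individuals) == {"S00", "S01"}
        assert not set(train.individuals) & set(test.individuals)

    def test_unknown_individual_rejected(self, tiny_ds):
        with pytest.raises(ValueError, match="nobody"):
            split_by_individuals(tiny_ds, ["nobody"])


def test_cross_cohort_prediction_recovers_stage(stage_map_default):
    a, _ = generate(SimulationConfig(seed=41, noise_sd=0.2))
    b, _ = generate(SimulationConfig(seed=42, noise_sd=0.2))
    prep = lambda d: center_to_baseline(impute_missing_timepoints(d))
    res = predict_pair(prep(a), prep(b), ("LEAD_00", "LAG_00"), stage_map=stage_map_default)
    assert res.accuracy >= 0.8
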
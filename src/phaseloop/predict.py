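"""Staging withheld samples on a loop map with K-nearest neighbors.

A fitted loop's two genes span a 2-D expression plane; training samples land
there labeled by their (possibly stage-mapped) time point, and a withheld
sample is labeled by majority vote of its K = 3 nearest training samples
under Euclidean distance.  The module also provides the evaluation machinery
used to judge loop maps: confusion matrices, leave-one-individual-out
cross-validation, Gaussian noise sensitivity, and a random-pair null
comparison via the two-sample Kolmogorov-Smirnov statistic.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .expression_io import ExpressionDataset
from .saxloop import LoopCandidate, possible_pair_count

logger = logging.getLogger("phaseloop")

#: Stage map for the 28-day vaccination design: days 0/14/28 are
#: interchangeable baseline, days 3/7/10 are early/middle/late perturbation.
YF17D_STAGE_MAP: dict[float, str] = {
    0.0: "base",
    14.0: "base",
    28.0: "base",
    3.0: "early",
    7.0: "middle",
    10.0: "late",
}


@dataclass
class StagePrediction:
    """Per-sample truth/prediction pairs with confusion matrix and accuracy."""

    true_labels: list
    predicted_labels: list
    confusion: pd.DataFrame
    accuracy: float
    neighbor_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if int(self.confusion.to_numpy().sum()) != len(self.true_labels):
            raise ValueError("confusion matrix total does not match sample count")
        if not 0 <= self.accuracy <= 1:
            raise ValueError("accuracy must lie in [0, 1]")


def apply_stage_map(labels: Sequence, stage_map: Mapping | None):
    """Map raw time labels to stages; identity when no map is given."""
    if stage_map is None:
        return list(labels)
    mapped = []
    for lab in labels:
        key = lab
        if key not in stage_map:
            try:
                key = float(lab)
            except (TypeError, ValueError):
                key = lab
        if key not in stage_map:
            raise ValueError(f"no stage mapping for time {lab!r}")
        mapped.append(stage_map[key])
    return mapped


def knn_predict(
    train_points: Sequence[tuple[float, float, Hashable]],
    test_points: Sequence[tuple[float, float]],
    k: int = 3,
) -> list:
    """Label each test point by majority vote of its k nearest training points.

    Euclidean distance in the raw 2-gene plane; distance ties resolve by
    training input order (stable sort) and vote ties by the label of the
    single nearest neighbor.
    """
    if len(train_points) < k:
        raise ValueError(
            f"need at least k={k} training points, got {len(train_points)}"
        )
    train_xy = np.array([[x, y] for x, y, _ in train_points], dtype=float)
    labels = [lab for _, _, lab in train_points]
    out = []
    for x, y in test_points:
        d = np.hypot(train_xy[:, 0] - x, train_xy[:, 1] - y)
        order = np.argsort(d, kind="stable")[:k]
        votes = Counter(labels[i] for i in order)
        top = max(votes.values())
        winners = {lab for lab, c in votes.items() if c == top}
        if len(winners) == 1:
            out.append(next(iter(winners)))
        else:
            out.append(labels[order[0]])
    return out


def evaluate(
    true_labels: Sequence,
    predicted_labels: Sequence,
    stage_map: Mapping | None = None,
) -> StagePrediction:
    """Compare predictions with truth, optionally through a stage map."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    truth = apply_stage_map(true_labels, stage_map)
    pred = apply_stage_map(predicted_labels, stage_map)
    classes = sorted({str(l) for l in truth} | {str(l) for l in pred})
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    hits = 0
    for t, p in zip(truth, pred):
        confusion.loc[str(t), str(p)] += 1
        hits += t == p
    accuracy = hits / len(truth) if truth else 0.0
    return StagePrediction(
        true_labels=truth,
        predicted_labels=pred,
        confusion=confusion,
        accuracy=accuracy,
    )


def pair_coordinates(
    ds: ExpressionDataset,
    pair: LoopCandidate | tuple[str, str],
    excluded_times: Sequence[float] = (),
) -> tuple[np.ndarray, list[float], list[str]]:
    """Extract a pair's 2-D sample coordinates, time labels and individuals."""
    lead, lag = _pair_genes(pair)
    excluded = {float(t) for t in excluded_times}
    keep = [i for i, (_, t) in enumerate(ds.samples) if t not in excluded]
    xy = np.column_stack(
        [ds.gene_values(lead)[keep], ds.gene_values(lag)[keep]]
    )
    times = [ds.samples[i][1] for i in keep]
    individuals = [ds.samples[i][0] for i in keep]
    return xy, times, individuals


def _pair_genes(pair) -> tuple[str, str]:
    if isinstance(pair, LoopCandidate):
        return pair.lead_gene, pair.lag_gene
    lead, lag = pair
    return lead, lag


def predict_pair(
    train: ExpressionDataset,
    test: ExpressionDataset,
    pair,
    k: int = 3,
    stage_map: Mapping | None = None,
    excluded_times: Sequence[float] = (),
) -> StagePrediction:
    """Train KNN on a pair's plane in one dataset and stage another."""
    train_xy, train_times, _ = pair_coordinates(train, pair, excluded_times)
    test_xy, test_times, _ = pair_coordinates(test, pair, excluded_times)
    train_labels = apply_stage_map(train_times, stage_map)
    train_points = [
        (x, y, lab) for (x, y), lab in zip(train_xy, train_labels)
    ]
    predicted = knn_predict(train_points, [tuple(p) for p in test_xy], k=k)
    return evaluate(apply_stage_map(test_times, stage_map), predicted)


def loocv(
    ds: ExpressionDataset,
    pair,
    k: int = 3,
    stage_map: Mapping | None = None,
    excluded_times: Sequence[float] = (),
) -> dict:
    """Leave-one-individual-out cross-validation of a loop pair.

    Returns per-individual accuracies plus their min/median/max.
    """
    individuals = ds.individuals
    if len(individuals) < 2:
        raise ValueError("LOOCV needs at least 2 individuals")
    accuracies: dict[str, float] = {}
    for holdout in individuals:
        train = ds.subset_individuals([i for i in individuals if i != holdout])
        test = ds.subset_individuals([holdout])
        res = predict_pair(
            train, test, pair, k=k, stage_map=stage_map, excluded_times=excluded_times
        )
        accuracies[holdout] = res.accuracy
    vals = list(accuracies.values())
    return {
        "accuracies": accuracies,
        "min": min(vals),
        "median": float(np.median(vals)),
        "max": max(vals),
    }


def noise_sensitivity(
    train: ExpressionDataset,
    test: ExpressionDataset,
    pair,
    k: int = 3,
    stage_map: Mapping | None = None,
    excluded_times: Sequence[float] = (),
    n_reps: int = 100,
    seed: int = 0,
    sd_scale: float = 1.0,
) -> dict:
    """Accuracy before and after adding Gaussian noise to the test coordinates.

    Noise is zero-mean with a per-gene, per-time standard deviation estimated
    from the training data (optionally scaled by ``sd_scale``), emulating
    measurement scatter around the training profile.
    """
    lead, lag = _pair_genes(pair)
    noiseless = predict_pair(
        train, test, pair, k=k, stage_map=stage_map, excluded_times=excluded_times
    ).accuracy

    train_xy, train_times, _ = pair_coordinates(train, pair, excluded_times)
    train_labels = apply_stage_map(train_times, stage_map)
    train_points = [(x, y, lab) for (x, y), lab in zip(train_xy, train_labels)]
    test_xy, test_times, _ = pair_coordinates(test, pair, excluded_times)
    truth = apply_stage_map(test_times, stage_map)

    # per-time sd of each pair gene across training individuals
    sd_at: dict[float, np.ndarray] = {}
    tt = np.array(train_times)
    for t in np.unique(tt):
        sd_at[float(t)] = train_xy[tt == t].std(axis=0)
    fallback = train_xy.std(axis=0)
    sds = np.array(
        [sd_at.get(float(t), fallback) for t in test_times]
    ) * sd_scale

    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_reps):
        noisy = test_xy + rng.normal(0.0, 1.0, test_xy.shape) * sds
        pred = knn_predict(train_points, [tuple(p) for p in noisy], k=k)
        accs.append(evaluate(truth, pred).accuracy)
    return {
        "noiseless_accuracy": noiseless,
        "noisy_accuracy": float(np.mean(accs)),
        "rep_accuracies": accs,
    }


@dataclass
class NullComparison:
    """Loop-candidate vs random-pair accuracy distributions and their KS test."""

    candidate_accuracies: list[float]
    random_accuracies: list[float]
    ks_statistic: float
    p_value: float


def ks_two_sample(a: Sequence[float], b: Sequence[float], exact: bool = False):
    """Two-sample KS statistic and p-value (asymptotic unless ``exact``)."""
    res = ks_2samp(a, b, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue)


def random_pair_null(
    train: ExpressionDataset,
    test: ExpressionDataset,
    candidates: Sequence[LoopCandidate],
    n_random: int = 50,
    k: int = 3,
    stage_map: Mapping | None = None,
    excluded_times: Sequence[float] = (),
    seed: int = 0,
    exact_p: bool = False,
) -> NullComparison:
    """Compare candidate-pair holdout accuracy with randomly drawn gene pairs.

    Random pairs are sampled uniformly without replacement from all unordered
    gene pairs of the dataset that are not loop candidates.  The two accuracy
    samples are compared with the two-sample Kolmogorov-Smirnov test.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 loop candidates")
    if n_random < 10:
        raise ValueError("n_random must be at least 10")
    candidate_sets = {frozenset((c.lead_gene, c.lag_gene)) for c in candidates}
    n_genes = len(train.genes)
    n_available = possible_pair_count(n_genes) - len(candidate_sets)
    if n_available < n_random:
        raise ValueError(
            f"only {n_available} non-candidate pairs available, need {n_random}"
        )
    rng = np.random.default_rng(seed)
    random_pairs: list[tuple[str, str]] = []
    chosen: set[frozenset] = set()
    while len(random_pairs) < n_random:
        i, j = rng.choice(n_genes, size=2, replace=False)
        key = frozenset((train.genes[i], train.genes[j]))
        if key in candidate_sets or key in chosen:
            continue
        chosen.add(key)
        random_pairs.append((train.genes[i], train.genes[j]))

    def acc(pair) -> float:
        return predict_pair(
            train, test, pair, k=k, stage_map=stage_map, excluded_times=excluded_times
        ).accuracy

    cand_accs = [acc(c) for c in candidates]
    rand_accs = [acc(p) for p in random_pairs]
    stat, p = ks_two_sample(cand_accs, rand_accs, exact=exact_p)
    return NullComparison(
        candidate_accuracies=cand_accs,
        random_accuracies=rand_accs,
        ks_statistic=stat,
        p_value=p,
    )


def split_by_individuals(
    ds: ExpressionDataset, test_individuals: Sequence[str]
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Split a dataset into (train, test) by individual id."""
    test_set = set(test_individuals)
    unknown = test_set - set(ds.individuals)
    if unknown:
        raise ValueError(f"unknown individual(s): {sorted(unknown)}")
    train_inds = [i for i in ds.individuals if i not in test_set]
    if not train_inds:
        raise ValueError("no individuals left for training")
    return ds.subset_individuals(train_inds), ds.subset_individuals(sorted(test_set))


def split_stratified_by_time(
    ds: ExpressionDataset, train_fraction: float = 0.5, seed: int = 0
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Random split covering all time points evenly.

    Within every time point the samples are shuffled and ``train_fraction``
    of them (rounded) go to the training set, so each time point's split is
    within one sample of the target fraction.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for t in ds.times:
        idx = [i for i, (_, st) in enumerate(ds.samples) if st == t]
        idx = list(rng.permutation(idx))
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else n_train
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return ds.subset_samples(sorted(train_idx)), ds.subset_samples(sorted(test_idx))
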
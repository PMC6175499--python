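"""Imputation, baseline centering, composite profiles, and dynamic-gene filtering.

The preprocessing chain mirrors how longitudinal expression data are prepared
before loop search: missing time points are imputed with the per-time median
across the other individuals, every individual's series is rescaled to its
time-0 baseline, a composite median profile across individuals is built, and
the genes with the largest temporal dispersion (top 0.5% by standard
deviation, by default) are kept for the pair search.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .expression_io import ExpressionDataset

logger = logging.getLogger("phaseloop")

MIN_RECOMMENDED_TIMEPOINTS = 6


@dataclass
class CompositeProfile:
    """Per-gene median expression over the time grid, baseline-centered.

    ``values[g, j]`` is the median over individuals of gene ``g`` at
    ``times[j]``, minus the gene's value at the first time point, so the
    baseline column is exactly zero.
    """

    genes: list[str]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (len(self.genes), len(self.times)):
            raise ValueError("values shape does not match genes x times")
        if self.n_timepoints < MIN_RECOMMENDED_TIMEPOINTS:
            warnings.warn(
                f"profile has only {self.n_timepoints} time points; at least "
                f"{MIN_RECOMMENDED_TIMEPOINTS} are recommended to resolve a "
                "full rise-and-return trajectory",
                stacklevel=2,
            )

    @property
    def n_timepoints(self) -> int:
        """T, the number of sampled intervals."""
        return len(self.times)

    def gene_profile(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]


@dataclass
class FilterConfig:
    """How to pick the most dynamic genes.

    ``top_fraction`` is the fraction of genes kept (ceiling convention), and
    ``dispersion_statistic`` is either the population standard deviation
    (``"stdev"``, default) or the max-min range of the centered profile.
    """

    top_fraction: float = 0.005
    dispersion_statistic: str = "stdev"

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.dispersion_statistic not in ("stdev", "range"):
            raise ValueError("dispersion_statistic must be 'stdev' or 'range'")


def impute_missing_timepoints(
    ds: ExpressionDataset, grid: Sequence[float] | None = None
) -> ExpressionDataset:
    """Fill each individual's missing grid times with cross-individual medians.

    For every individual lacking a sample at a grid time, a sample is added
    whose per-gene value is the median across the individuals observed at that
    time.  Observed values are untouched.  ``grid`` defaults to all times
    observed anywhere in the dataset; samples at off-grid times are dropped
    (logged).  The output samples are ordered individual-by-individual (first
    appearance order) with times ascending.
    """
    grid_arr = np.unique(ds.times if grid is None else np.asarray(grid, float))
    observed: dict[float, list[int]] = {t: [] for t in grid_arr}
    sample_pos = {s: i for i, s in enumerate(ds.samples)}
    for (ind, t), i in sample_pos.items():
        if t in observed:
            observed[t].append(i)
    for t, cols in observed.items():
        if not cols:
            raise ValueError(f"grid time {t} observed in no individual")
    n_dropped = sum(1 for _, t in ds.samples if t not in observed)
    if n_dropped:
        logger.info("impute: dropped %d sample(s) at off-grid times", n_dropped)

    medians = {t: np.median(ds.values[:, cols], axis=1) for t, cols in observed.items()}
    individuals = ds.individuals
    samples: list[tuple[str, float]] = []
    columns: list[np.ndarray] = []
    n_imputed = 0
    for ind in individuals:
        for t in grid_arr:
            samples.append((ind, float(t)))
            key = (ind, float(t))
            if key in sample_pos:
                columns.append(ds.values[:, sample_pos[key]])
            else:
                columns.append(medians[t])
                n_imputed += 1
    if n_imputed:
        logger.info(
            "impute: filled %d missing (individual, time) sample(s)", n_imputed
        )
    return ExpressionDataset(
        genes=list(ds.genes),
        samples=samples,
        values=np.column_stack(columns),
        time_unit=ds.time_unit,
    )


def center_to_baseline(obj):
    """Rescale each series to its baseline (first time point) value.

    For an :class:`ExpressionDataset`, each individual's time-0 value (per
    gene) is subtracted from that individual's whole series; for a
    :class:`CompositeProfile`, the first column is subtracted.  Centering is
    idempotent.
    """
    if isinstance(obj, CompositeProfile):
        return CompositeProfile(
            genes=list(obj.genes),
            times=obj.times.copy(),
            values=obj.values - obj.values[:, [0]],
        )
    ds: ExpressionDataset = obj
    baseline_time = float(np.min(ds.times))
    sample_pos = {s: i for i, s in enumerate(ds.samples)}
    baseline_col: dict[str, np.ndarray] = {}
    for ind in ds.individuals:
        key = (ind, baseline_time)
        if key not in sample_pos:
            raise ValueError(
                f"individual {ind!r} has no baseline (time {baseline_time:g}) sample"
            )
        baseline_col[ind] = ds.values[:, sample_pos[key]]
    values = np.empty_like(ds.values)
    for j, (ind, _) in enumerate(ds.samples):
        values[:, j] = ds.values[:, j] - baseline_col[ind]
    return ExpressionDataset(
        genes=list(ds.genes),
        samples=list(ds.samples),
        values=values,
        time_unit=ds.time_unit,
    )


def composite_median_profile(ds: ExpressionDataset) -> CompositeProfile:
    """Median expression across individuals per time point, baseline-centered.

    The dataset should already be imputed onto a common grid so each time
    point aggregates the same individuals.
    """
    times = ds.times
    cols_at = {
        t: [i for i, (_, st) in enumerate(ds.samples) if st == t] for t in times
    }
    values = np.column_stack(
        [np.median(ds.values[:, cols_at[t]], axis=1) for t in times]
    )
    profile = CompositeProfile(genes=list(ds.genes), times=times, values=values)
    return center_to_baseline(profile)


def filter_top_dynamic(profile: CompositeProfile, cfg: FilterConfig | None = None) -> list[str]:
    """Return the most temporally dynamic genes of a composite profile.

    Keeps ``n = ceil(top_fraction * n_genes)`` genes ranked by the dispersion
    statistic over the T time points; ties at the cutoff are broken by
    lexicographic gene symbol so the selection is deterministic.
    """
    cfg = cfg or FilterConfig()
    if len(profile.genes) == 0:
        raise ValueError("profile contains no genes")
    if cfg.dispersion_statistic == "stdev":
        stat = np.std(profile.values, axis=1)  # population convention
    else:
        stat = np.ptp(profile.values, axis=1)
    n = math.ceil(cfg.top_fraction * len(profile.genes))
    order = sorted(range(len(profile.genes)), key=lambda i: (-stat[i], profile.genes[i]))
    return [profile.genes[i] for i in order[:n]]
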
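"""Monte-Carlo validation utilities for the design-based area estimator.

Two independent checks of the stratified estimator:

* :func:`simulate_area_estimation` draws whole synthetic populations with a
  known confusion structure, runs the estimator on a stratified sample of
  each, and reports bias of the adjusted areas and empirical coverage of
  the 95% intervals against each replicate's realised truth.
* :func:`stratified_bootstrap_se` re-estimates the standard error of the
  reference-class proportion by resampling reference labels within each
  map stratum, a brute-force alternative to the closed-form variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .accuracy import (ErrorMatrix, adjusted_area, confidence_interval,
                       proportion_matrix, proportion_se)


@dataclass
class SimulationSummary:
    """Aggregate of the estimator over simulated assessments."""

    n_replicates: int
    categories: int
    true_area_mean: np.ndarray       # km², mean realised truth per category
    adjusted_area_mean: np.ndarray   # km², mean estimate per category
    bias: np.ndarray                 # km², mean (estimate - truth)
    bias_mc_se: np.ndarray           # km², Monte-Carlo SE of the bias
    coverage: np.ndarray             # fraction of 95% CIs containing truth


def simulate_area_estimation(
    n_replicates: int = 500,
    n_pixels: int = 10_000,
    n_per_stratum: int = 50,
    true_proportions: tuple[float, ...] = (0.2, 0.3, 0.5),
    correct_rate: float = 0.9,
    total_area_km2: float = 100.0,
    seed: int = 0,
) -> SimulationSummary:
    """Repeatedly map, sample, and estimate; summarise bias and CI coverage.

    Each replicate draws ``n_pixels`` truth labels from
    ``true_proportions``, corrupts them into map labels with a symmetric
    confusion (``correct_rate`` on the diagonal, the rest spread evenly),
    samples ``n_per_stratum`` pixels per map stratum, and runs the
    estimator.  Truth is the replicate's realised truth, so coverage
    targets the population actually mapped.
    """
    q = len(true_proportions)
    probs = np.asarray(true_proportions, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("true_proportions must sum to 1")
    confusion = np.full((q, q), (1.0 - correct_rate) / (q - 1))
    np.fill_diagonal(confusion, correct_rate)

    rng = np.random.default_rng(seed)
    px_area = total_area_km2 / n_pixels

    true_areas = np.empty((n_replicates, q))
    estimates = np.empty((n_replicates, q))
    covered = np.zeros((n_replicates, q), dtype=bool)

    for r in range(n_replicates):
        truth = rng.choice(q, size=n_pixels, p=probs)
        # truth label -> map label through the confusion matrix
        u = rng.random(n_pixels)
        cum = confusion.cumsum(axis=1)
        mapped = (u[:, None] > cum[truth]).sum(axis=1)

        counts = np.zeros((q, q), dtype=int)
        mapped_areas = np.empty(q)
        for i in range(q):
            stratum = np.flatnonzero(mapped == i)
            mapped_areas[i] = stratum.size * px_area
            take = min(n_per_stratum, stratum.size)
            sample = rng.choice(stratum, size=take, replace=False)
            counts[i] = np.bincount(truth[sample], minlength=q)

        em = ErrorMatrix(counts, [str(j) for j in range(q)],
                         mapped_areas, total_area_km2)
        pm = proportion_matrix(em)
        est = adjusted_area(pm, total_area_km2)
        half = confidence_interval(total_area_km2, proportion_se(em))

        true_areas[r] = np.bincount(truth, minlength=q) * px_area
        estimates[r] = est
        covered[r] = np.abs(est - true_areas[r]) <= half

    bias = (estimates - true_areas).mean(axis=0)
    bias_se = (estimates - true_areas).std(axis=0, ddof=1) / np.sqrt(n_replicates)
    return SimulationSummary(
        n_replicates=n_replicates,
        categories=q,
        true_area_mean=true_areas.mean(axis=0),
        adjusted_area_mean=estimates.mean(axis=0),
        bias=bias,
        bias_mc_se=bias_se,
        coverage=covered.mean(axis=0),
    )


def stratified_bootstrap_se(em: ErrorMatrix, n_boot: int = 4000,
                            seed: int = 0) -> np.ndarray:
    """Bootstrap SE of p_.j by resampling reference labels within map rows."""
    rng = np.random.default_rng(seed)
    q = len(em.categories)
    weights = em.mapped_areas / em.total_area
    rows = em.row_totals
    boot = np.zeros((n_boot, q))
    for i in range(q):
        if rows[i] == 0:
            continue
        row_p = em.counts[i] / rows[i]
        draws = rng.multinomial(rows[i], row_p, size=n_boot)  # (n_boot, q)
        boot += weights[i] * draws / rows[i]
    return boot.std(axis=0, ddof=1)
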
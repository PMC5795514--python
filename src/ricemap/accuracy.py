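"""Design-based accuracy assessment and error-adjusted area estimation.

Mapped ("pixel-counting") areas are biased by classification error.  Given
an error matrix of sample counts n_ij (rows i = map categories, columns
j = reference categories) and the mapped area A_m,i of each map stratum,
the stratified estimator

    p_ij = (A_m,i / A_tot) * (n_ij / n_i.)

yields an unbiased estimate of the area proportion of each reference
category, p_.j, hence the adjusted area A_a,j = A_tot * p_.j, its standard
error

    S(p_.j) = sqrt( sum_i (A_m,i/A_tot)^2 * (n_ij/n_i.)(1 - n_ij/n_i.)
                                           / (n_i. - 1) )

and the approximate 95% interval A_a,j +/- 1.96 * A_tot * S(p_.j).
User's, producer's and overall accuracy come from the proportion matrix
(U_i = p_ii/p_i., PR_j = p_jj/p_.j, O = trace); the kappa coefficient is
the conventional chance-corrected agreement on the raw sample counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .fusion import CategoricalMap, LABEL_OF

Z_95 = 1.96  # normal quantile for the approximate 95% interval


class UndefinedStratumError(ValueError):
    """A map stratum has positive area but no reference samples."""


@dataclass
class ErrorMatrix:
    """q x q sample counts with the mapped stratum areas.

    counts[i, j] = samples mapped as category i whose reference label is j.
    """

    counts: np.ndarray
    categories: list[str]
    mapped_areas: np.ndarray          # km² per map category
    total_area: float                 # km²

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.mapped_areas = np.asarray(self.mapped_areas, dtype=float)
        q = len(self.categories)
        if self.counts.shape != (q, q):
            raise ValueError(f"counts must be {q}x{q}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative sample counts")
        if (self.mapped_areas < 0).any():
            raise ValueError("negative mapped areas")
        if self.mapped_areas.sum() > self.total_area + 1e-6:
            raise ValueError("mapped areas exceed total area")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class ProportionMatrix:
    """Estimated area-proportion matrix p_ij; grand total 1 for a complete legend."""

    p: np.ndarray
    categories: list[str]

    @property
    def row_totals(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.p.sum(axis=0)


@dataclass
class AreaEstimate:
    """Per-category adjusted area with uncertainty and accuracies."""

    category: str
    mapped_area_km2: float
    proportion: float
    adjusted_area_km2: float
    se_proportion: float
    ci_halfwidth_km2: float
    user_accuracy: float | None
    producer_accuracy: float | None


def build_error_matrix(map_labels: CategoricalMap,
                       reference_labels: CategoricalMap,
                       legend: list[str], pixel_size: float | None = None,
                       sample_mask: np.ndarray | None = None) -> ErrorMatrix:
    """Cross-tabulate map vs reference labels at assessment pixels.

    ``sample_mask`` restricts the tally to an assessment region (e.g.
    survey quadrats or a stratified sample); mapped areas and the total
    area always come from the full map.
    """
    from .grids import check_coregistered
    check_coregistered(map_labels.labels, reference_labels.labels)
    if pixel_size is None:
        pixel_size = map_labels.labels.pixel_size
    codes = []
    for name in legend:
        if name not in LABEL_OF:
            raise KeyError(f"label {name!r} outside legend dictionary")
        codes.append(LABEL_OF[name])
    valid = map_labels.labels.valid_mask & reference_labels.labels.valid_mask
    region = valid if sample_mask is None else (valid & sample_mask)

    mv = map_labels.labels.values[region]
    rv = reference_labels.labels.values[region]
    for side, vals in (("map", mv), ("reference", rv)):
        extra = set(np.unique(vals)) - set(codes)
        if extra:
            names = [map_labels.legend.get(int(c), int(c)) for c in extra]
            raise KeyError(f"{side} labels outside assessment legend: {names}")

    q = len(legend)
    idx = {code: k for k, code in enumerate(codes)}
    counts = np.zeros((q, q), dtype=int)
    for code_i, code_j in zip(mv, rv):
        counts[idx[int(code_i)], idx[int(code_j)]] += 1

    px_km2 = pixel_size * pixel_size / 1e6
    mapped = np.array([
        float((map_labels.labels.values[valid] == code).sum()) * px_km2
        for code in codes
    ])
    total = float(valid.sum()) * px_km2
    return ErrorMatrix(counts, list(legend), mapped, total)


def proportion_matrix(em: ErrorMatrix) -> ProportionMatrix:
    """Estimated area proportions p_ij = (A_m,i/A_tot)(n_ij/n_i.)."""
    weights = em.mapped_areas / em.total_area
    rows = em.row_totals
    bad = (rows == 0) & (em.mapped_areas > 0)
    if bad.any():
        names = [em.categories[i] for i in np.flatnonzero(bad)]
        raise UndefinedStratumError(
            f"strata with mapped area but no samples: {names}"
        )
    safe_rows = np.where(rows == 0, 1, rows)
    p = weights[:, None] * em.counts / safe_rows[:, None]
    p[rows == 0] = 0.0
    return ProportionMatrix(p, list(em.categories))


def adjusted_area(pm: ProportionMatrix, total_area: float) -> np.ndarray:
    """Unbiased per-category area A_a,j = A_tot * p_.j (km²)."""
    return total_area * pm.column_totals


def proportion_se(em: ErrorMatrix) -> np.ndarray:
    """Standard error of p_.j under stratified random sampling."""
    weights = em.mapped_areas / em.total_area
    rows = em.row_totals
    contributing = weights > 0
    if (rows[contributing] < 2).any():
        names = [em.categories[i]
                 for i in np.flatnonzero(contributing & (rows < 2))]
        raise UndefinedStratumError(
            f"strata need >= 2 samples for a variance: {names}"
        )
    safe = np.where(rows == 0, 2, rows)
    phat = em.counts / safe[:, None]
    var = (weights[:, None] ** 2) * phat * (1 - phat) / (safe[:, None] - 1)
    var[~contributing] = 0.0
    return np.sqrt(var.sum(axis=0))


def confidence_interval(total_area: float, se: float | np.ndarray) -> np.ndarray:
    """95% halfwidth in km²: 1.96 * A_tot * S(p_.j)."""
    se = np.asarray(se, dtype=float)
    if (se < 0).any():
        raise ValueError("standard error must be non-negative")
    return Z_95 * total_area * se


def accuracies(pm: ProportionMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """(user's, producer's, overall) from the proportion matrix.

    Categories with a zero denominator get NaN (undefined), never 0.
    """
    diag = np.diag(pm.p)
    with np.errstate(divide="ignore", invalid="ignore"):
        user = np.where(pm.row_totals > 0, diag / pm.row_totals, np.nan)
        producer = np.where(pm.column_totals > 0, diag / pm.column_totals, np.nan)
    overall = float(diag.sum())
    return user, producer, overall


def kappa(em: ErrorMatrix) -> float:
    """Cohen's kappa on the raw sample counts (not area-weighted)."""
    n = em.n
    if n == 0:
        raise ValueError("empty error matrix")
    po = np.trace(em.counts) / n
    pe = float((em.counts.sum(axis=1) * em.counts.sum(axis=0)).sum()) / n**2
    if pe == 1.0:
        raise ValueError("kappa undefined: chance agreement is 1")
    return (po - pe) / (1 - pe)


def season_shares(areas: dict[str, float], grouping: str = "total") -> dict[str, float]:
    """Percentage shares of rice area by season.

    grouping='total' shares each of early/middle/late against their sum;
    grouping='early_season' shares early vs middle (the two crops standing
    during the early season) against early+middle.
    """
    if grouping == "total":
        keys = [k for k in ("early_rice", "middle_rice", "late_rice") if k in areas]
    elif grouping == "early_season":
        keys = [k for k in ("early_rice", "middle_rice") if k in areas]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    vals = {k: float(areas[k]) for k in keys}
    if any(v < 0 for v in vals.values()):
        raise ValueError("areas must be non-negative")
    denom = sum(vals.values())
    if denom <= 0:
        raise ValueError("group sum must be positive")
    return {k: 100.0 * v / denom for k, v in vals.items()}


class StratifiedAreaEstimator(BaseEstimator):
    """Error-adjusted area estimation from an error matrix.

    ``fit`` takes an :class:`ErrorMatrix` and exposes the full set of
    design-based estimates as fitted attributes.

    Attributes
    ----------
    categories_ : category names, row/column order
    proportions_ : q x q estimated area-proportion matrix
    adjusted_area_km2_ : per-category adjusted areas
    se_proportion_ : per-category standard errors of p_.j
    ci_halfwidth_km2_ : 95% interval halfwidths
    user_accuracy_, producer_accuracy_ : per-category (NaN when undefined)
    overall_accuracy_ : trace of the proportion matrix
    kappa_ : chance-corrected agreement on sample counts
    """

    def __init__(self, confidence_z: float = Z_95):
        self.confidence_z = confidence_z

    def fit(self, X: ErrorMatrix, y=None):
        pm = proportion_matrix(X)
        user, producer, overall = accuracies(pm)
        se = proportion_se(X)
        self.error_matrix_ = X
        self.categories_ = list(X.categories)
        self.proportions_ = pm.p
        self.proportion_totals_ = pm.column_totals
        self.adjusted_area_km2_ = adjusted_area(pm, X.total_area)
        self.se_proportion_ = se
        self.ci_halfwidth_km2_ = self.confidence_z * X.total_area * se
        self.user_accuracy_ = user
        self.producer_accuracy_ = producer
        self.overall_accuracy_ = overall
        self.kappa_ = kappa(X)
        return self

    def estimates(self) -> list[AreaEstimate]:
        check_is_fitted(self, "adjusted_area_km2_")
        out = []
        for k, name in enumerate(self.categories_):
            out.append(AreaEstimate(
                category=name,
                mapped_area_km2=float(self.error_matrix_.mapped_areas[k]),
                proportion=float(self.proportion_totals_[k]),
                adjusted_area_km2=float(self.adjusted_area_km2_[k]),
                se_proportion=float(self.se_proportion_[k]),
                ci_halfwidth_km2=float(self.ci_halfwidth_km2_[k]),
                user_accuracy=None if np.isnan(self.user_accuracy_[k])
                else float(self.user_accuracy_[k]),
                producer_accuracy=None if np.isnan(self.producer_accuracy_[k])
                else float(self.producer_accuracy_[k]),
            ))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Per-category report, rounded the way areas are conventionally printed."""
        rows = []
        for est in self.estimates():
            rows.append({
                "category": est.category,
                "mapped_area_km2": round(est.mapped_area_km2, 2),
                "proportion": round(est.proportion, 4),
                "adjusted_area_km2": round(est.adjusted_area_km2, 2),
                "se_proportion": round(est.se_proportion, 4),
                "ci_halfwidth_km2": round(est.ci_halfwidth_km2, 2),
                "user_accuracy": None if est.user_accuracy is None
                else round(est.user_accuracy, 4),
                "producer_accuracy": None if est.producer_accuracy is None
                else round(est.producer_accuracy, 4),
            })
        return pd.DataFrame(rows)

    def write_report(self, csv_path, json_path) -> None:
        check_is_fitted(self, "adjusted_area_km2_")
        frame = self.to_frame()
        frame.to_csv(csv_path, index=False)
        payload = {
            "categories": self.categories_,
            "error_matrix_counts": self.error_matrix_.counts.tolist(),
            "mapped_areas_km2": self.error_matrix_.mapped_areas.tolist(),
            "total_area_km2": self.error_matrix_.total_area,
            "proportion_matrix": np.round(self.proportions_, 6).tolist(),
            "per_category": frame.to_dict(orient="records"),
            "overall_accuracy": round(self.overall_accuracy_, 4),
            "kappa": round(self.kappa_, 4),
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
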
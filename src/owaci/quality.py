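"""Quality tests for a composite indicator: explanatory power (Spearman
rank correlation against an external validation variable), discriminant
power (entropy of the score distribution, in two variants), and the
proportion of atypical measurements (bivariate Mahalanobis outliers
against the chi-square ellipse).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateSeriesError,
    SingularCovarianceError,
    ValidationError,
)

__all__ = [
    "QualityReport",
    "explanatory_power",
    "discriminant_power_eq4",
    "discriminant_power_reported",
    "mahalanobis_distances",
    "outlier_proportion",
    "quality_report",
]


@dataclass
class QualityReport:
    """All three quality statistics plus per-unit outlier diagnostics."""

    explanatory_power: float
    discriminant_power_eq4: float
    discriminant_power_reported: float  # bits
    outlier_proportion: float
    distances: np.ndarray        # per-unit squared Mahalanobis distance
    flags: np.ndarray            # per-unit atypical flag
    threshold: float             # chi-square quantile used for flagging
    quantile: float = 0.975
    level: str = "final"

    def to_frame(self, units: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        df = pd.DataFrame({"mahalanobis_sq": self.distances,
                           "atypical": self.flags})
        if units is not None:
            df = pd.concat([units.reset_index(drop=True), df], axis=1)
        return df

    def summary(self) -> dict:
        return {
            "level": self.level,
            "explanatory_power": self.explanatory_power,
            "discriminant_power_eq4": self.discriminant_power_eq4,
            "discriminant_power_reported": self.discriminant_power_reported,
            "outlier_proportion": self.outlier_proportion,
            "chi2_quantile": self.quantile,
            "chi2_threshold": self.threshold,
        }


def explanatory_power(scores, external) -> float:
    """Spearman rank correlation between the scores and the external
    variable, with midranks for ties (equivalently, Pearson correlation
    of the two rank vectors)."""
    s = np.asarray(scores, dtype=float)
    e = np.asarray(external, dtype=float)
    if s.shape != e.shape:
        raise ValidationError("scores and external series must have equal length")
    if s.size < 3:
        raise ValidationError(f"need at least 3 units, got {s.size}")
    if np.unique(s).size == 1 or np.unique(e).size == 1:
        raise DegenerateSeriesError("a series with zero rank variance has no "
                                    "defined rank correlation")
    rho = stats.spearmanr(s, e).statistic
    return float(rho)


def discriminant_power_eq4(scores) -> float:
    """Entropy-style dispersion of the raw scores themselves:

        H' = -(1/ln delta) * sum_w s_w ln s_w,      0*ln 0 := 0,

    over the delta unit scores s_w in [0, 1]. This treats the scores as
    if they were probability masses; it is kept verbatim alongside the
    frequency-entropy variant below (see docs/methods.md)."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValidationError("need at least 2 scores")
    if np.isnan(s).any() or s.min() < -1e-9 or s.max() > 1 + 1e-9:
        raise ValidationError("scores must lie in [0, 1]")
    s = np.clip(s, 0.0, 1.0)  # forgive aggregation round-off at the bounds
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(s > 0, s * np.log(s), 0.0)
    return float(-terms.sum() / np.log(s.size))


def discriminant_power_reported(scores) -> float:
    """Base-2 Shannon entropy of the empirical frequency distribution of
    the score values (exactly equal scores share a class), in bits.

    With delta pairwise-distinct scores this equals log2(delta) — e.g.
    log2(54) ≈ 5.755 for 54 distinguishable decision units — and it is 0
    when all scores coincide."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValidationError("need at least 2 scores")
    _, counts = np.unique(s, return_counts=True)
    p = counts / s.size
    return float(-(p * np.log2(p)).sum())


def rescale_external(external) -> np.ndarray:
    """Min-max rescale the external variable to [0, 1] so that the
    (score, external) pair is commensurate for the bivariate distance."""
    e = np.asarray(external, dtype=float)
    lo, hi = e.min(), e.max()
    if hi == lo:
        raise DegenerateSeriesError("external variable is constant")
    return (e - lo) / (hi - lo)


def mahalanobis_distances(scores, external, rescale: bool = True) -> np.ndarray:
    """Squared Mahalanobis distance of each (score, external) pair from
    the bivariate sample mean, using the classical covariance estimator
    (denominator delta - 1)."""
    s = np.asarray(scores, dtype=float)
    e = rescale_external(external) if rescale else np.asarray(external, dtype=float)
    if s.shape != e.shape:
        raise ValidationError("scores and external series must have equal length")
    if s.size < 3:
        raise ValidationError(f"need at least 3 units, got {s.size}")
    X = np.column_stack([s, e])
    d = X - X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    det = np.linalg.det(cov)
    if not np.isfinite(det) or abs(det) < 1e-15:
        raise SingularCovarianceError(
            "bivariate sample covariance is singular; the two series are "
            "degenerate or perfectly collinear"
        )
    inv = np.linalg.inv(cov)
    return np.einsum("ij,jk,ik->i", d, inv, d)


def outlier_proportion(distances, quantile: float = 0.975):
    """Flag units whose squared distance exceeds the chi-square quantile
    with 2 degrees of freedom (the dimensionality of the pair); return
    (B, flags) where B is the flagged fraction."""
    if not 0.0 < quantile < 1.0:
        raise ValidationError(f"quantile must lie in (0, 1), got {quantile}")
    d = np.asarray(distances, dtype=float)
    threshold = float(stats.chi2.ppf(quantile, df=2))
    flags = d > threshold
    return float(flags.mean()), flags


def quality_report(scores, external, quantile: float = 0.975,
                   level: str = "final") -> QualityReport:
    """Run all three quality tests on one score vector."""
    dists = mahalanobis_distances(scores, external)
    B, flags = outlier_proportion(dists, quantile)
    return QualityReport(
        explanatory_power=explanatory_power(scores, external),
        discriminant_power_eq4=discriminant_power_eq4(scores),
        discriminant_power_reported=discriminant_power_reported(scores),
        outlier_proportion=B,
        distances=dists,
        flags=flags,
        threshold=float(stats.chi2.ppf(quantile, df=2)),
        quantile=quantile,
        level=level,
    )
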
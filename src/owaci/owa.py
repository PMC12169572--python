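"""Ordered weighted averaging (OWA) primitives.

The composite indicator is built in five steps: min-max normalize each
sub-indicator across decision units, orient so that higher = more
adversity, sort each unit's normalized values in descending order,
weight the ordered positions, and take the weighted average

    OWA(x_1, ..., x_rho) = sum_l beta_l * a_l,

where a_l is the l-th largest value and the position weights beta
satisfy beta_l in [0, 1], sum beta_l = 1. With uniform weights the OWA
is the arithmetic mean; an *emphasis* zeroes out the top (negative
emphasis: the largest values are the best-performing oriented factors
and are discounted) or bottom ordered positions, spreading the weight
uniformly over the remainder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateColumnError,
    InfeasibleEmphasisError,
    OwaciError,
    ValidationError,
)

__all__ = [
    "EmphasisSpec",
    "minmax_normalize",
    "orient",
    "build_owa_weights",
    "owa_aggregate",
]


@dataclass(frozen=True)
class EmphasisSpec:
    """Direction and intensity of the ordered-position emphasis.

    direction: 'none', 'negative' (zero-weight the highest ordered
    positions) or 'positive' (zero-weight the lowest). intensity is the
    fraction of positions zeroed, in [0, 1); with direction != 'none'
    and intensity > 0 at least one position is always zeroed.
    """

    direction: str = "none"
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("none", "negative", "positive"):
            raise ValidationError(f"unknown emphasis direction {self.direction!r}")
        if not 0.0 <= self.intensity < 1.0:
            raise ValidationError(
                f"emphasis intensity must lie in [0, 1), got {self.intensity}"
            )
        if self.direction == "none" and self.intensity != 0.0:
            raise ValidationError("direction 'none' requires intensity 0")

    def n_zeroed(self, rho: int) -> int:
        """Number of ordered positions given zero weight for rho inputs."""
        if self.direction == "none" or self.intensity == 0.0:
            return 0
        return max(1, math.floor(self.intensity * rho))

    @classmethod
    def parse(cls, text: str) -> "EmphasisSpec":
        """Parse 'none', 'negative:<intensity>' or 'positive:<intensity>'."""
        text = text.strip()
        if text == "none":
            return cls()
        if ":" not in text:
            raise ValidationError(
                f"emphasis {text!r}: expected 'none', 'negative:<f>' or 'positive:<f>'"
            )
        direction, intensity = text.split(":", 1)
        return cls(direction.strip(), float(intensity))

    def __str__(self) -> str:
        if self.direction == "none":
            return "none"
        return f"{self.direction}:{self.intensity:g}"


def minmax_normalize(column) -> np.ndarray:
    """Map a raw column onto [0, 1] via (x - min) / (max - min).

    Missing entries (NaN) stay missing; the min/max are taken over the
    non-missing values. A constant column has no spread to normalize and
    raises :class:`DegenerateColumnError` (remove the factor instead).
    """
    col = np.asarray(column, dtype=float)
    finite = col[~np.isnan(col)]
    if len(finite) < 2:
        raise ValidationError("need at least 2 non-missing values to normalize")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise DegenerateColumnError(
            f"column is constant (all values {lo!r}); min-max normalization is "
            "undefined — remove this factor from the registry for this run"
        )
    return (col - lo) / (hi - lo)


def orient(column, direction: str) -> np.ndarray:
    """Orient a normalized column so that higher = more adversity.

    adversity_increasing columns pass through; protective columns are
    reflected to 1 - x. Values must already lie in [0, 1].
    """
    col = np.asarray(column, dtype=float)
    finite = col[~np.isnan(col)]
    if len(finite) and (finite.min() < 0 or finite.max() > 1):
        raise OwaciError("orient() requires normalized values in [0, 1]")
    if direction == "adversity_increasing":
        return col.copy()
    if direction == "protective":
        return 1.0 - col
    raise ValidationError(f"unknown direction {direction!r}")


def build_owa_weights(rho: int, emphasis: EmphasisSpec = EmphasisSpec()) -> np.ndarray:
    """Ordered-position weights beta of length rho for the given emphasis.

    No emphasis gives the uniform vector 1/rho. A negative emphasis with
    intensity t zeroes the k = max(1, floor(t * rho)) highest ordered
    positions and puts 1/(rho - k) on the rest; a positive emphasis
    mirrors this on the lowest positions.
    """
    if rho < 1:
        raise ValidationError(f"rho must be >= 1, got {rho}")
    k = emphasis.n_zeroed(rho)
    if k >= rho:
        raise InfeasibleEmphasisError(
            f"emphasis {emphasis} would zero all {rho} ordered positions"
        )
    beta = np.full(rho, 1.0 / (rho - k))
    if k:
        if emphasis.direction == "negative":
            beta[:k] = 0.0   # discount the largest ordered values
        else:
            beta[rho - k:] = 0.0
    return beta


def owa_aggregate(values, weights) -> float:
    """Sort the unit's values in descending order and dot with beta.

    The result lies between min(values) and max(values); with uniform
    weights it is the arithmetic mean.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValidationError("owa_aggregate: empty value vector")
    if np.isnan(vals).any():
        raise ValidationError("owa_aggregate: NaN in values; drop and reweight first")
    beta = np.asarray(weights, dtype=float)
    if beta.shape != vals.shape:
        raise ValidationError(
            f"weights length {beta.size} != values length {vals.size}"
        )
    if (beta < 0).any() or (beta > 1).any() or abs(beta.sum() - 1.0) > 1e-12:
        raise ValidationError("weights must lie in [0,1] and sum to 1")
    ordered = np.sort(vals)[::-1]
    return float(ordered @ beta)


def owa_aggregate_matrix(matrix: np.ndarray, emphasis: EmphasisSpec) -> np.ndarray:
    """Row-wise OWA over a units × sub-indicators matrix.

    NaN cells are dropped per row and the weights rebuilt for the
    reduced number of available sub-indicators (the exclude_reweight
    missing policy). Rows must keep at least one value.
    """
    mat = np.asarray(matrix, dtype=float)
    scores = np.empty(mat.shape[0])
    full = build_owa_weights(mat.shape[1], emphasis) if mat.shape[1] else None
    for i, row in enumerate(mat):
        vals = row[~np.isnan(row)]
        if vals.size == 0:
            raise ValidationError(f"unit at row {i} has no available sub-indicators")
        beta = full if vals.size == mat.shape[1] else build_owa_weights(
            vals.size, emphasis)
        scores[i] = owa_aggregate(vals, beta)
    return scores
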
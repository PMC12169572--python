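"""Two-stage construction of the composite indicator.

Stage 1 aggregates the oriented, normalized factors of each dimension
(socioeconomic, vulnerability, risk/insecurity) into a per-country
dimension score. Stage 2 treats the three dimension scores as
sub-indicators and aggregates them — without renormalizing — into the
final composite indicator. Quality tests run against the external
variable at both levels; continent summaries and dimension-proportion
decompositions support regional comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import AlignedDataset, apply_missing_policy
from .errors import DegenerateColumnError, ValidationError
from .owa import EmphasisSpec, minmax_normalize, orient, owa_aggregate_matrix
from .quality import QualityReport, quality_report
from .registry import DIMENSIONS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Knobs of a full study run."""

    stage1_emphasis: EmphasisSpec = field(default_factory=EmphasisSpec)
    stage2_emphasis: EmphasisSpec = field(default_factory=EmphasisSpec)
    quantile: float = 0.975
    missing_policy: str = "exclude_reweight"

    def echo(self) -> dict:
        return {
            "stage1_emphasis": str(self.stage1_emphasis),
            "stage2_emphasis": str(self.stage2_emphasis),
            "chi2_quantile": self.quantile,
            "missing_policy": self.missing_policy,
        }


@dataclass
class StudyResult:
    """Everything a full run produces, unit order preserved throughout."""

    units: pd.DataFrame
    dimension_scores: pd.DataFrame        # units × three dimensions
    final_scores: pd.Series
    quality: dict[str, QualityReport]     # per dimension + "final"
    continent_summary: pd.DataFrame
    proportions: pd.DataFrame             # per-unit dimension shares
    continent_proportions: pd.DataFrame
    config: dict

    def scores_frame(self) -> pd.DataFrame:
        df = pd.concat([self.units.reset_index(drop=True),
                        self.dimension_scores.reset_index(drop=True)], axis=1)
        df["final"] = self.final_scores.to_numpy()
        return df


def normalized_oriented_matrix(dataset: AlignedDataset, dimension: str) -> pd.DataFrame:
    """Min-max normalize and orient every factor column of one dimension.

    Degenerate (constant) columns raise with the factor named so the
    caller can drop it from the registry."""
    cols = [c for c in dataset.table.values.columns
            if c in dataset.registry.dimension_ids(dimension)]
    if len(cols) < 2:
        raise ValidationError(
            f"dimension {dimension!r} has {len(cols)} factor columns; need >= 2"
        )
    out = {}
    for c in cols:
        try:
            norm = minmax_normalize(dataset.table.values[c].to_numpy())
        except DegenerateColumnError as exc:
            raise DegenerateColumnError(f"factor {c!r}: {exc}") from exc
        out[c] = orient(norm, dataset.registry.get(c).direction)
    return pd.DataFrame(out, index=dataset.table.values.index)


def compute_dimension_indicator(dataset: AlignedDataset, dimension: str,
                                emphasis: EmphasisSpec = EmphasisSpec()) -> np.ndarray:
    """Stage-1 composite score of one dimension for every unit.

    Missing cells are dropped per unit with the weights rebuilt over the
    remaining factors (the exclude_reweight policy must have validated
    coverage beforehand)."""
    mat = normalized_oriented_matrix(dataset, dimension)
    return owa_aggregate_matrix(mat.to_numpy(), emphasis)


def compute_dimension_scores(dataset: AlignedDataset,
                             emphasis: EmphasisSpec = EmphasisSpec()) -> pd.DataFrame:
    return pd.DataFrame(
        {d: compute_dimension_indicator(dataset, d, emphasis) for d in DIMENSIONS},
        index=dataset.table.values.index,
    )


def compute_final_indicator(dimension_scores: pd.DataFrame,
                            emphasis: EmphasisSpec = EmphasisSpec()) -> pd.Series:
    """Stage-2 OWA over the three dimension scores of each unit.

    The dimension scores are used as-is (no second min-max pass), so the
    final score inherits their [0, 1] range and a no-emphasis run is the
    plain mean of the three."""
    missing = [d for d in DIMENSIONS if d not in dimension_scores.columns]
    if missing:
        raise ValidationError(f"dimension scores missing columns {missing}")
    scores = owa_aggregate_matrix(
        dimension_scores[list(DIMENSIONS)].to_numpy(), emphasis)
    return pd.Series(scores, index=dimension_scores.index, name="final")


def compare_emphasis_models(dataset: AlignedDataset,
                            emphases: Sequence[EmphasisSpec],
                            quantile: float = 0.975,
                            missing_policy: str = "exclude_reweight"
                            ) -> pd.DataFrame:
    """Quality-test grid over dimensions × emphasis models.

    One row per (dimension, emphasis) with explanatory power, atypical
    ratio and discriminant power (frequency-entropy variant, bits)."""
    if not emphases:
        raise ValidationError("need at least one emphasis model")
    ds = AlignedDataset(apply_missing_policy(dataset.table, missing_policy),
                        dataset.external, dataset.registry)
    rows = []
    for dim in DIMENSIONS:
        for emph in emphases:
            scores = compute_dimension_indicator(ds, dim, emph)
            rep = quality_report(scores, ds.external.values.to_numpy(),
                                 quantile=quantile, level=dim)
            rows.append({
                "dimension": dim,
                "emphasis": str(emph),
                "explanatory_power": rep.explanatory_power,
                "atypical_ratio": rep.outlier_proportion,
                "discriminant_power": rep.discriminant_power_reported,
            })
    return pd.DataFrame(rows)


def summarize_by_continent(units: pd.DataFrame, dimension_scores: pd.DataFrame,
                           final_scores: pd.Series) -> pd.DataFrame:
    """Per-continent mean/min/max of the final score with the extreme
    countries named, plus per-dimension means and a Global row."""
    if units["continent"].isna().any():
        bad = units.loc[units["continent"].isna(), "country_id"].tolist()
        raise ValidationError(f"units without continent label: {bad}")
    df = units.reset_index(drop=True).copy()
    for d in DIMENSIONS:
        df[d] = dimension_scores[d].to_numpy()
    df["final"] = final_scores.to_numpy()
    rows = []
    for cont, grp in df.groupby("continent", sort=True):
        row = {
            "continent": cont,
            "n": len(grp),
            "final_mean": grp["final"].mean(),
            "final_min": grp["final"].min(),
            "final_max": grp["final"].max(),
            "min_country": grp.loc[grp["final"].idxmin(), "name"],
            "max_country": grp.loc[grp["final"].idxmax(), "name"],
        }
        for d in DIMENSIONS:
            row[f"{d}_mean"] = grp[d].mean()
        rows.append(row)
    glob = {
        "continent": "Global", "n": len(df),
        "final_mean": df["final"].mean(),
        "final_min": df["final"].min(), "final_max": df["final"].max(),
        "min_country": df.loc[df["final"].idxmin(), "name"],
        "max_country": df.loc[df["final"].idxmax(), "name"],
    }
    for d in DIMENSIONS:
        glob[f"{d}_mean"] = df[d].mean()
    rows.append(glob)
    return pd.DataFrame(rows)


def dimension_proportions(dimension_scores: pd.DataFrame) -> pd.DataFrame:
    """Share of each dimension in a unit's composite: score_d / sum_d score_d.

    Requires strictly positive dimension-score sums; shares are
    non-negative and sum to 1 per unit."""
    mat = dimension_scores[list(DIMENSIONS)].to_numpy()
    if (mat < 0).any():
        raise ValidationError("dimension scores must be non-negative")
    totals = mat.sum(axis=1)
    if (totals <= 0).any():
        idx = int(np.argmin(totals))
        raise ValidationError(
            f"unit at row {idx} has all-zero dimension scores; shares undefined"
        )
    return pd.DataFrame(mat / totals[:, None], columns=list(DIMENSIONS),
                        index=dimension_scores.index)


def continent_dimension_proportions(units: pd.DataFrame,
                                    dimension_scores: pd.DataFrame) -> pd.DataFrame:
    """Continent-level shares: the shares of the continent-mean dimension
    scores (not the mean of per-unit shares)."""
    df = dimension_scores.copy()
    df["continent"] = units["continent"].to_numpy()
    means = df.groupby("continent", sort=True)[list(DIMENSIONS)].mean()
    shares = means.div(means.sum(axis=1), axis=0)
    return shares.reset_index()


def run_full_study(dataset: AlignedDataset,
                   config: Optional[RunConfig] = None) -> StudyResult:
    """Execute the whole pipeline: missing policy, stage-1 dimension
    indicators, stage-2 final indicator, quality tests at every level,
    continent summaries and dimension proportions."""
    config = config or RunConfig()
    logger.info("run configuration: %s", config.echo())
    table = apply_missing_policy(dataset.table, config.missing_policy)
    ds = AlignedDataset(table, dataset.external, dataset.registry)

    dims = compute_dimension_scores(ds, config.stage1_emphasis)
    final = compute_final_indicator(dims, config.stage2_emphasis)
    ext = ds.external.values.to_numpy()

    quality = {d: quality_report(dims[d].to_numpy(), ext,
                                 quantile=config.quantile, level=d)
               for d in DIMENSIONS}
    quality["final"] = quality_report(final.to_numpy(), ext,
                                      quantile=config.quantile, level="final")

    summary = summarize_by_continent(ds.table.units, dims, final)
    props = dimension_proportions(dims)
    cont_props = continent_dimension_proportions(ds.table.units, dims)

    return StudyResult(
        units=ds.table.units,
        dimension_scores=dims,
        final_scores=final,
        quality=quality,
        continent_summary=summary,
        proportions=props,
        continent_proportions=cont_props,
        config=config.echo(),
    )
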
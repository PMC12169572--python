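"""Country-level indicator table, external validation series, alignment
and the missing-data policy.

The decision units are countries; the canonical unit order is the row
order of the input file and is preserved by every downstream operation.
Missing cells are NaN in the ``values`` frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .registry import DIMENSIONS, FactorRegistry

logger = logging.getLogger(__name__)

CONTINENTS = ("Africa", "Americas", "Asia", "Europe", "Oceania")

#: columns that must precede the factor columns in an indicator CSV
UNIT_COLUMNS = ("country_id", "name", "continent")

MISSING_POLICIES = ("exclude_reweight", "median_impute")


@dataclass
class IndicatorTable:
    """Raw factor values for an ordered set of decision units.

    ``units`` holds country_id, name, continent (one row per unit, in
    canonical order); ``values`` holds the units × factors float matrix
    with NaN for missing cells, positionally aligned with ``units``.
    """

    units: pd.DataFrame
    values: pd.DataFrame
    registry: FactorRegistry

    @property
    def n_units(self) -> int:
        return len(self.units)

    def copy(self) -> "IndicatorTable":
        return IndicatorTable(self.units.copy(), self.values.copy(), self.registry)


@dataclass
class ExternalSeries:
    """Per-unit external validation variable (a percentage in [0, 100])."""

    values: pd.Series  # positionally aligned with the table's units

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AlignedDataset:
    """Indicator table, external series and registry with identical unit order."""

    table: IndicatorTable
    external: ExternalSeries
    registry: FactorRegistry

    def __post_init__(self) -> None:
        if len(self.external) != self.table.n_units:
            raise ValidationError(
                f"external series has {len(self.external)} values for "
                f"{self.table.n_units} units"
            )
        bad = set(self.table.units["continent"]) - set(CONTINENTS)
        if bad:
            raise ValidationError(
                f"unknown continent labels {sorted(bad)}; expected one of {CONTINENTS}"
            )

    @property
    def n_units(self) -> int:
        return self.table.n_units


def _check_bounds(series: pd.Series, factor, colname: str) -> None:
    lo, hi = factor.bounds
    vals = series.dropna()
    out = vals[(vals < lo) | (vals > hi)]
    if len(out):
        row = out.index[0]
        raise ValidationError(
            f"value {out.iloc[0]!r} in column {colname!r}, row {row} "
            f"outside bounds [{lo}, {hi}] for value_kind {factor.value_kind!r}"
        )


def validate_indicator_table(table: IndicatorTable) -> IndicatorTable:
    """Check shape, bounds and per-dimension coverage; returns the table."""
    if table.n_units < 3:
        raise ValidationError(f"need at least 3 decision units, got {table.n_units}")
    for fid in table.values.columns:
        _check_bounds(table.values[fid], table.registry.get(fid), fid)
    return table


def read_indicator_table(path, registry: FactorRegistry) -> IndicatorTable:
    """Read a country × factor CSV (columns: country_id, name, continent,
    then factor ids). Unknown columns are logged and ignored; row order
    is preserved. Raises on out-of-bounds or unparseable values."""
    df = pd.read_csv(path, dtype={"country_id": str, "name": str, "continent": str})
    for col in UNIT_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    known = set(registry.ids())
    factor_cols = [c for c in df.columns if c in known]
    unknown = [c for c in df.columns if c not in known and c not in UNIT_COLUMNS]
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, unknown)
    values = pd.DataFrame(index=df.index)
    for c in factor_cols:
        try:
            values[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: column {c!r} is not numeric: {exc}") from exc
    table = IndicatorTable(df[list(UNIT_COLUMNS)].copy(), values, registry)
    return validate_indicator_table(table)


def write_indicator_table(table: IndicatorTable, path) -> None:
    """Write the table back to CSV with 10-significant-digit floats."""
    df = pd.concat([table.units.reset_index(drop=True),
                    table.values.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False, float_format="%.10g")


def read_external_series(path) -> pd.Series:
    """Read a country_id,value CSV into a series indexed by country_id."""
    df = pd.read_csv(path, dtype={"country_id": str})
    for col in ("country_id", "value"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    vals = pd.to_numeric(df["value"], errors="raise")
    if ((vals < 0) | (vals > 100)).any():
        raise ValidationError(f"{path}: external values must lie in [0, 100]")
    return pd.Series(vals.to_numpy(), index=df["country_id"].to_numpy())


def align(table: IndicatorTable, external: pd.Series,
          registry: Optional[FactorRegistry] = None) -> AlignedDataset:
    """Join the table with the external series on country_id.

    Units lacking an external value are excluded with a logged warning;
    the table's row order is otherwise preserved.
    """
    registry = registry or table.registry
    ids = table.units["country_id"]
    have = ids.isin(external.index) & ids.map(
        lambda i: pd.notna(external.get(i, np.nan)))
    dropped = ids[~have].tolist()
    if dropped:
        logger.warning("excluding units without external value: %s", dropped)
    keep = have.to_numpy()
    sub = IndicatorTable(
        table.units.loc[keep].reset_index(drop=True),
        table.values.loc[keep].reset_index(drop=True),
        registry,
    )
    ext = ExternalSeries(pd.Series(
        [float(external[i]) for i in sub.units["country_id"]],
        index=sub.units.index,
    ))
    return AlignedDataset(sub, ext, registry)


def apply_missing_policy(table: IndicatorTable, policy: str = "exclude_reweight"
                         ) -> IndicatorTable:
    """Apply the configured missing-data policy.

    ``exclude_reweight`` leaves NaNs in place (the OWA step later drops
    them and reweights over the unit's available factors) but requires
    every unit to retain >= 2 non-missing factors in every dimension.
    ``median_impute`` fills each missing cell with its column median and
    logs every imputation.
    """
    if policy not in MISSING_POLICIES:
        raise ValidationError(f"unknown missing policy {policy!r}")
    out = table.copy()
    if policy == "median_impute":
        for col in out.values.columns:
            mask = out.values[col].isna()
            if mask.any():
                med = float(out.values[col].median())
                out.values.loc[mask, col] = med
                for row in out.values.index[mask]:
                    logger.info("imputed %s for unit %s with column median %g",
                                col, out.units.loc[row, "country_id"], med)
        return out
    # exclude_reweight: verify coverage per dimension
    for dim in DIMENSIONS:
        cols = [c for c in out.values.columns if c in table.registry.dimension_ids(dim)]
        if not cols:
            continue
        n_ok = out.values[cols].notna().sum(axis=1)
        bad = n_ok[n_ok < 2]
        if len(bad):
            unit = out.units.loc[bad.index[0], "country_id"]
            raise ValidationError(
                f"unit {unit!r} has {int(bad.iloc[0])} non-missing factors in "
                f"dimension {dim!r}; exclude_reweight requires at least 2"
            )
    return out
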
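"""Factor registry: the adversity factors entering the composite indicator.

Each factor is a country-level aggregate (a survey mean or percentage)
assigned to one of three adversity dimensions — socioeconomic,
vulnerability, risk/insecurity — and given an orientation:

* ``adversity_increasing`` — a larger raw value means more adversity
  (e.g. prevalence of violent discipline);
* ``protective`` — a larger raw value means less adversity (e.g. GDP per
  inhabitant, household asset ownership); such columns are reflected
  (``1 - x``) after normalization so that every oriented sub-indicator
  reads "higher = more propensity to childhood anxiety and depression".

Orientation is data, not code: the default registry encodes one explicit,
overridable assignment, and users may supply their own via YAML/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import yaml

from .errors import ValidationError

DIMENSIONS = ("socioeconomic", "vulnerability", "risk_insecurity")
DIRECTIONS = ("adversity_increasing", "protective")
VALUE_KINDS = ("percentage", "nonneg_mean", "ordinal_mean", "currency_mean")


@dataclass(frozen=True)
class FactorDefinition:
    """One sub-indicator: id, human label, dimension, orientation, value kind.

    ``bounds`` gives the admissible raw range: fixed at (0, 100) for
    percentages, the declared scale endpoints for ordinal means, and
    (0, inf) for non-negative and currency means.
    """

    factor_id: str
    label: str
    dimension: str
    direction: str
    value_kind: str
    bounds: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValidationError(
                f"factor {self.factor_id!r}: unknown dimension {self.dimension!r}"
            )
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"factor {self.factor_id!r}: direction must be one of "
                f"{DIRECTIONS}, got {self.direction!r}"
            )
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"factor {self.factor_id!r}: unknown value_kind {self.value_kind!r}"
            )
        if self.value_kind == "percentage" and self.bounds is None:
            object.__setattr__(self, "bounds", (0.0, 100.0))
        if self.value_kind in ("nonneg_mean", "currency_mean") and self.bounds is None:
            object.__setattr__(self, "bounds", (0.0, float("inf")))
        if self.value_kind == "ordinal_mean" and self.bounds is None:
            raise ValidationError(
                f"factor {self.factor_id!r}: ordinal_mean requires explicit scale bounds"
            )


@dataclass
class FactorRegistry:
    """Ordered collection of factor definitions, unique by id."""

    factors: Sequence[FactorDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.factors:
            if f.factor_id in seen:
                raise ValidationError(f"duplicate factor_id {f.factor_id!r}")
            seen.add(f.factor_id)

    def __len__(self) -> int:
        return len(self.factors)

    def __iter__(self):
        return iter(self.factors)

    def ids(self) -> list[str]:
        return [f.factor_id for f in self.factors]

    def get(self, factor_id: str) -> FactorDefinition:
        for f in self.factors:
            if f.factor_id == factor_id:
                return f
        raise KeyError(factor_id)

    def dimension_ids(self, dimension: str) -> list[str]:
        if dimension not in DIMENSIONS:
            raise ValidationError(f"unknown dimension {dimension!r}")
        return [f.factor_id for f in self.factors if f.dimension == dimension]

    def dimension_counts(self) -> dict[str, int]:
        return {d: len(self.dimension_ids(d)) for d in DIMENSIONS}


# (factor_id, label, dimension, direction, value_kind, bounds-or-None)
_EDU = "0-No education, 1-Primary, 2-Secondary (lower), 3-Secondary (upper), 4-Technical or higher"
_UNHAPPY = "1-happy ... 5-very unhappy"

_DEFAULT_SPEC: list[tuple] = [
    # socioeconomic (15)
    ("gdp_per_capita", "Average GDP per inhabitant",
     "socioeconomic", "protective", "currency_mean", None),
    ("child_education", f"Average level of education of children/adolescents ({_EDU})",
     "socioeconomic", "protective", "ordinal_mean", (0, 4)),
    ("mother_education", f"Mothers' average education level ({_EDU})",
     "socioeconomic", "protective", "ordinal_mean", (0, 4)),
    ("father_education", f"Average level of education of the fathers ({_EDU})",
     "socioeconomic", "protective", "ordinal_mean", (0, 4)),
    ("mother_age", "Mean age of the mothers interviewed",
     "socioeconomic", "protective", "nonneg_mean", None),
    ("father_age", "Average age of the fathers interviewed",
     "socioeconomic", "protective", "nonneg_mean", None),
    ("hh_electricity", "Percentage of households with some type of electricity",
     "socioeconomic", "protective", "percentage", None),
    ("hh_tv", "Percentage of households with colour or black-and-white TV",
     "socioeconomic", "protective", "percentage", None),
    ("hh_refrigerator", "Percentage of households with a refrigerator",
     "socioeconomic", "protective", "percentage", None),
    ("hh_computer", "Percentage of households with a computer",
     "socioeconomic", "protective", "percentage", None),
    ("hh_mobile_phone", "Percentage of households with a mobile phone",
     "socioeconomic", "protective", "percentage", None),
    ("hh_internet", "Percentage of households with access to the internet",
     "socioeconomic", "protective", "percentage", None),
    ("child_health_insurance", "Percentage of children/adolescents with some health insurance",
     "socioeconomic", "protective", "percentage", None),
    ("mother_health_insurance", "Percentage of mothers with some health insurance",
     "socioeconomic", "protective", "percentage", None),
    ("father_health_insurance", "Percentage of fathers with some health insurance",
     "socioeconomic", "protective", "percentage", None),
    # vulnerability (9)
    ("mother_life_worse_now", "Percentage of mothers who believe life has worsened vs last year",
     "vulnerability", "adversity_increasing", "percentage", None),
    ("father_life_worse_now", "Percentage of fathers who believe life has worsened vs last year",
     "vulnerability", "adversity_increasing", "percentage", None),
    ("mother_life_worse_next", "Percentage of mothers who believe next year will be worse",
     "vulnerability", "adversity_increasing", "percentage", None),
    ("father_life_worse_next", "Percentage of fathers who believe next year will be worse",
     "vulnerability", "adversity_increasing", "percentage", None),
    ("mother_unhappiness", f"Average general unhappiness of mothers ({_UNHAPPY})",
     "vulnerability", "adversity_increasing", "ordinal_mean", (1, 5)),
    ("father_unhappiness", f"Average general unhappiness of fathers ({_UNHAPPY})",
     "vulnerability", "adversity_increasing", "ordinal_mean", (1, 5)),
    ("father_coresident", "Percentage of biological fathers living with the child in the same household",
     "vulnerability", "protective", "percentage", None),
    ("mother_coresident", "Percentage of biological mothers living with the child in the same household",
     "vulnerability", "protective", "percentage", None),
    ("father_alive", "Percentage of biological fathers who are alive",
     "vulnerability", "protective", "percentage", None),
    # risk/insecurity (13)
    ("violent_discipline", "Percentage of children suffering aggressive or violent discipline by an adult family member",
     "risk_insecurity", "adversity_increasing", "percentage", None),
    ("mother_alcohol_days", "Average number of days mothers consumed alcohol in the last month",
     "risk_insecurity", "adversity_increasing", "nonneg_mean", None),
    ("mother_safe_home_dark", "Percentage of mothers who feel safe alone at home after dark",
     "risk_insecurity", "protective", "percentage", None),
    ("father_safe_home_dark", "Percentage of fathers who feel safe alone at home after dark",
     "risk_insecurity", "protective", "percentage", None),
    ("mother_safe_streets_dark", "Percentage of mothers who feel safe walking the streets alone after dark",
     "risk_insecurity", "protective", "percentage", None),
    ("father_safe_streets_dark", "Percentage of fathers who feel safe walking the streets alone after dark",
     "risk_insecurity", "protective", "percentage", None),
    ("child_paid_work", "Percentage of children who worked in a paid service to help the family last week",
     "risk_insecurity", "adversity_increasing", "percentage", None),
    ("child_hazardous_work", "Percentage of children who performed unhealthy, arduous or dangerous work last week",
     "risk_insecurity", "adversity_increasing", "percentage", None),
    ("child_fetch_water", "Percentage of children who had to fetch water outside the home last week",
     "risk_insecurity", "adversity_increasing", "percentage", None),
    ("child_collect_wood", "Percentage of children who needed to collect firewood for the household",
     "risk_insecurity", "adversity_increasing", "percentage", None),
    ("punishment_belief", "Percentage of mothers who believe children must be physically punished to be educated",
     "risk_insecurity", "adversity_increasing", "percentage", None),
    ("parent_violence_victim", "Percentage of parents who were victims of urban violence in the last 12 months",
     "risk_insecurity", "adversity_increasing", "percentage", None),
    ("parent_discrimination", "Percentage of parents who felt personally discriminated against in the last year",
     "risk_insecurity", "adversity_increasing", "percentage", None),
]


def default_registry() -> FactorRegistry:
    """The built-in 37-factor registry (15 socioeconomic, 9 vulnerability,
    13 risk/insecurity)."""
    return FactorRegistry(
        [FactorDefinition(*row) for row in _DEFAULT_SPEC]
    )


def load_factor_registry(source=None) -> FactorRegistry:
    """Build a registry from a YAML/JSON path, a mapping, an iterable of
    factor dicts, or — with no argument — the built-in default.

    Each entry must provide ``factor_id`` (or ``id``), ``dimension`` and
    ``direction``; ``label`` defaults to the id, ``value_kind`` to
    ``percentage``. Ordinal factors must declare ``bounds``.
    """
    if source is None:
        return default_registry()
    if isinstance(source, FactorRegistry):
        return source
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        source = (json.loads(text) if str(source).endswith(".json")
                  else yaml.safe_load(text))
    if isinstance(source, Mapping):
        source = source.get("factors", source)
    if not isinstance(source, Iterable):
        raise ValidationError("registry source must be a path, mapping or iterable")

    factors = []
    for entry in source:
        if isinstance(entry, FactorDefinition):
            factors.append(entry)
            continue
        entry = dict(entry)
        fid = entry.get("factor_id") or entry.get("id")
        if not fid:
            raise ValidationError(f"registry entry without factor_id: {entry!r}")
        for required in ("dimension", "direction"):
            if not entry.get(required):
                raise ValidationError(
                    f"factor {entry.get('label', fid)!r}: missing required field "
                    f"{required!r}"
                )
        bounds = entry.get("bounds")
        factors.append(
            FactorDefinition(
                factor_id=fid,
                label=entry.get("label", fid),
                dimension=entry["dimension"],
                direction=entry["direction"],
                value_kind=entry.get("value_kind", "percentage"),
                bounds=tuple(bounds) if bounds is not None else None,
            )
        )
    return FactorRegistry(factors)
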
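"""Reference distributions of EVOO chemistry, as printed binned tables.

Ten parameters are packaged, each a :class:`BinTable` giving the percentage
of samples per value range for one or more study cohorts: the 2013 harvest
(no olive-fly pressure), the 2014 harvest (strong olive-fly attack),
commercial bottlings, and for the fatty-acid parameters six countries of
origin.  The printed percentages are the ground truth here: queries only sum
printed bins and refuse thresholds that are not bin edges — no interpolation.
"""

from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Bin",
    "BinTable",
    "TABLE_NAMES",
    "builtin_table",
    "tail_percentage",
    "range_percentage",
]

#: parameter -> (units, printed decimal places)
_TABLE_META: dict[str, tuple[str, int]] = {
    "free_acidity": ("% oleic acid", 1),
    "peroxide_value": ("meq O2/kg", 1),
    "k232": ("dimensionless", 1),
    "k270": ("dimensionless", 1),
    "oleic": ("%", 0),
    "linoleic": ("%", 1),
    "sfa": ("%", 1),
    "ratio": ("dimensionless", 0),
    "phenolics": ("mg/kg", 1),
    "tocopherols": ("mg/kg", 1),
}

TABLE_NAMES: tuple[str, ...] = tuple(_TABLE_META)


class Bin(BaseModel):
    """One value range with its per-cohort percentages; ``hi`` may be +inf."""

    model_config = ConfigDict(frozen=True)

    lo: float
    hi: float
    percents: dict[str, float]

    @model_validator(mode="after")
    def _ordered(self) -> "Bin":
        if not self.lo < self.hi:
            raise ValueError(f"bin lo {self.lo} must be < hi {self.hi}")
        return self

    @property
    def open_ended(self) -> bool:
        return math.isinf(self.hi)


class BinTable(BaseModel):
    """An ordered, contiguous set of bins for one parameter.

    ``precision`` is the number of decimals the source prints; columns
    printed to one decimal sum to 100 +- 0.5, whereas integer-printed
    columns can drift further (up to +-1 is observed) — :meth:`audit`
    returns the sums so callers can apply the tolerance they need.
    """

    model_config = ConfigDict(frozen=True)

    parameter: str
    units: str
    precision: int
    cohorts: tuple[str, ...]
    bins: tuple[Bin, ...]

    @model_validator(mode="after")
    def _contiguous(self) -> "BinTable":
        for a, b in zip(self.bins, self.bins[1:]):
            if a.hi != b.lo:
                raise ValueError(
                    f"{self.parameter}: bins must be contiguous "
                    f"({a.lo}-{a.hi} then {b.lo}-{b.hi})"
                )
        for b in self.bins:
            missing = set(self.cohorts) - set(b.percents)
            if missing:
                raise ValueError(f"{self.parameter}: bin {b.lo}-{b.hi} lacks {missing}")
        return self

    def column_sum(self, cohort: str) -> float:
        self._require_cohort(cohort)
        return round(sum(b.percents[cohort] for b in self.bins), 10)

    def audit(self) -> dict[str, float]:
        """Per-cohort column sums (should be ~100 up to printed rounding)."""
        return {c: self.column_sum(c) for c in self.cohorts}

    def edges(self) -> tuple[float, ...]:
        finite = [b.lo for b in self.bins] + [
            b.hi for b in self.bins if not b.open_ended
        ]
        return tuple(sorted(set(finite)))

    def _require_cohort(self, cohort: str) -> None:
        if cohort not in self.cohorts:
            raise KeyError(
                f"unknown cohort {cohort!r} for {self.parameter}; "
                f"available: {list(self.cohorts)}"
            )

    def _require_edge(self, value: float) -> None:
        if not any(math.isclose(value, e, rel_tol=0.0, abs_tol=1e-9) for e in self.edges()):
            raise ValueError(
                "threshold must align with printed bins: "
                f"{value} is not an edge of {self.parameter} {self.edges()}"
            )


@lru_cache(maxsize=None)
def builtin_table(name: str) -> BinTable:
    """Load one packaged reference table by parameter name."""
    if name not in _TABLE_META:
        raise KeyError(
            f"unknown table {name!r}; available tables: {sorted(_TABLE_META)}"
        )
    units, precision = _TABLE_META[name]
    path = resources.files("evoo_nvs").joinpath(f"data/tables/{name}.csv")
    with resources.as_file(path) as p:
        frame = pd.read_csv(p, dtype={"cohort": str})
    frame["hi"] = frame["hi"].fillna(math.inf)
    cohorts = tuple(dict.fromkeys(frame["cohort"]))
    bins = []
    for (lo, hi), grp in frame.groupby(["lo", "hi"], sort=True):
        bins.append(
            Bin(lo=float(lo), hi=float(hi),
                percents=dict(zip(grp["cohort"], grp["percent"].astype(float))))
        )
    return BinTable(
        parameter=name, units=units, precision=precision, cohorts=cohorts,
        bins=tuple(bins),
    )


def tail_percentage(
    table: BinTable,
    cohort: str,
    threshold: float,
    direction: Literal["above", "below"],
) -> float:
    """Percent of the cohort strictly beyond a bin edge, to one decimal.

    ``above`` sums bins entirely above the threshold (open-ended top bin
    included); ``below`` sums bins entirely below it.
    """
    table._require_cohort(cohort)
    table._require_edge(threshold)
    if direction == "above":
        total = sum(b.percents[cohort] for b in table.bins if b.lo >= threshold)
    elif direction == "below":
        total = sum(b.percents[cohort] for b in table.bins if b.hi <= threshold)
    else:
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    return round(total, 1)


def range_percentage(table: BinTable, cohort: str, lo: float, hi: float) -> float:
    """Percent of the cohort within ``[lo, hi)``; both ends must be bin edges."""
    table._require_cohort(cohort)
    table._require_edge(lo)
    table._require_edge(hi)
    if not lo < hi:
        raise ValueError(f"range requires lo < hi, got [{lo}, {hi})")
    total = sum(b.percents[cohort] for b in table.bins if b.lo >= lo and b.hi <= hi)
    return round(total, 1)
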
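"""Pesticide toxic loads: from pounds applied to lethal doses per acre.

The chain is: pounds applied to a land class in a year are converted to
micrograms, divided by the honey-bee contact LD50 of the active ingredient
(µg/bee) to give the number of lethal doses applied, divided by the acreage
of the class to give a per-acre toxic load, and summed across chemicals.
Three annual loads per class are then collapsed to low/medium/high scenario
loads as their minimum, median, and maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: grams per pound times micrograms per gram: 1 lb = 453,592,370 µg.
MICROGRAMS_PER_POUND = 453_592_370

LEVELS = ("low", "medium", "high")


class ToxicLoadError(ValueError):
    pass


class MissingLD50Error(KeyError):
    pass


class MissingAcreageError(KeyError):
    pass


def pounds_to_micrograms(pounds: float) -> float:
    """Convert pounds of active ingredient to micrograms (×453,592,370)."""
    if pounds < 0:
        raise ToxicLoadError(f"pounds must be nonnegative, got {pounds}")
    return pounds * MICROGRAMS_PER_POUND


def lethal_doses(micrograms: float, ld50_ug_per_bee: float) -> float:
    """Number of honey-bee contact LD50 doses in ``micrograms`` of product."""
    if ld50_ug_per_bee <= 0:
        raise ToxicLoadError(f"LD50 must be positive, got {ld50_ug_per_bee}")
    if micrograms < 0:
        raise ToxicLoadError(f"micrograms must be nonnegative, got {micrograms}")
    return micrograms / ld50_ug_per_bee


def per_acre_load(doses: float, acres: float) -> float:
    """Lethal doses per acre of the land class they were applied to."""
    if acres <= 0:
        raise ToxicLoadError(f"acres must be positive, got {acres}")
    if doses < 0:
        raise ToxicLoadError(f"doses must be nonnegative, got {doses}")
    return doses / acres


def class_annual_load(
    records: pd.DataFrame,
    ld50s: pd.Series,
    acreage: pd.Series,
    land_class: str,
    year: int,
) -> float:
    """Total toxic load (LD50 doses/acre) of one land class in one year.

    Sums ``per_acre_load(lethal_doses(pounds_to_micrograms(lbs), ld50), acres)``
    over every chemical applied to the class that year.  A class present in
    the records but silent in this year contributes 0.
    """
    if land_class not in acreage.index:
        raise MissingAcreageError(f"no acreage for land class {land_class!r}")
    acres = float(acreage[land_class])
    sub = records[(records["land_class"] == land_class) & (records["year"] == year)]
    total = 0.0
    for _, rec in sub.iterrows():
        chem = rec["chemical"]
        if chem not in ld50s.index:
            raise MissingLD50Error(f"no contact LD50 for chemical {chem!r}")
        total += per_acre_load(
            lethal_doses(pounds_to_micrograms(float(rec["pounds"])), float(ld50s[chem])),
            acres,
        )
    return total


@dataclass
class ToxicLoadTable:
    """Annual and scenario-collapsed per-acre toxic loads.

    ``annual`` is indexed by (land_class, year); ``scenario`` is a DataFrame
    indexed by land_class with columns low/medium/high.
    """

    annual: pd.Series
    scenario: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.annual < 0).any():
            raise ToxicLoadError("negative annual load")
        s = self.scenario
        if not ((s["low"] <= s["medium"]) & (s["medium"] <= s["high"])).all():
            raise ToxicLoadError("scenario loads not ordered low <= medium <= high")

    def load(self, land_class: str, level: str) -> float:
        return float(self.scenario.loc[land_class, level])

    @property
    def classes(self) -> list[str]:
        return list(self.scenario.index)


def compute_annual_loads(
    records: pd.DataFrame,
    ld50s: pd.Series,
    acreage: pd.Series,
    years: tuple[int, ...] | None = None,
    exclude_classes: tuple[str, ...] = (),
) -> pd.Series:
    """Annual loads for every (class, year); silent years filled with 0.

    ``exclude_classes`` drops record categories that should not contribute
    (e.g. structural pest control).
    """
    records = records[~records["land_class"].isin(exclude_classes)]
    if years is None:
        years = tuple(sorted(records["year"].unique()))
    classes = sorted(records["land_class"].unique())
    idx = pd.MultiIndex.from_product([classes, years], names=["land_class", "year"])
    vals = [
        class_annual_load(records, ld50s, acreage, lc, yr) for lc, yr in idx
    ]
    return pd.Series(vals, index=idx, name="doses_per_acre")


def collapse_to_scenarios(annual: pd.Series) -> pd.DataFrame:
    """Collapse exactly three annual loads per class to (min, median, max).

    Classes with no records in any year must already have been excluded;
    classes whose three values are all zero are kept (a genuinely untreated
    class is a valid low-resistance class).
    """
    rows = {}
    for land_class, grp in annual.groupby(level="land_class"):
        vals = np.asarray(grp.values, dtype=float)
        if len(vals) != 3:
            raise ToxicLoadError(
                f"class {land_class!r} has {len(vals)} annual values; exactly 3 required"
            )
        rows[land_class] = {
            "low": float(np.min(vals)),
            "medium": float(np.median(vals)),
            "high": float(np.max(vals)),
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(LEVELS)).rename_axis(
        "land_class"
    )


def build_toxic_load_table(
    records: pd.DataFrame,
    ld50s: pd.Series,
    acreage: pd.Series,
    years: tuple[int, ...] | None = None,
    exclude_classes: tuple[str, ...] = ("structural pest control",),
) -> ToxicLoadTable:
    """Full pipeline: records + LD50s + acreage -> :class:`ToxicLoadTable`."""
    annual = compute_annual_loads(records, ld50s, acreage, years, exclude_classes)
    missing = [
        lc
        for lc, grp in annual.groupby(level="land_class")
        if (grp == 0).all() and not (records["land_class"] == lc).any()
    ]
    if missing:
        logger.warning("classes with no records in any year excluded: %s", missing)
        annual = annual.drop(index=missing, level="land_class")
    return ToxicLoadTable(annual=annual, scenario=collapse_to_scenarios(annual))
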
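"""Ratio-method area-burned estimation and fire rotation.

The fire rotation (FR) is the expected time for cumulative burned area to
equal the landscape area; it is the reference rate against which interval
estimators are calibrated.  Where fire perimeters are unmapped, annual
burned area is estimated by the non-spatial ratio method: the area burned
in year *i* is taken proportional to the fraction of scarred trees (or
plots) recording a fire that year,

    A_i = AT * NS_i / (NST - NRE)

with AT the study-area size, NS_i the scarred trees recording year *i*,
NST the total scarred trees, and NRE those eliminated by subsequent fires.
FR then follows from the observation period and the summed burned
fraction:

    FR = observation_period / fraction_burned
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import FireHistorySite, NoUsableRecordError

__all__ = [
    "RatioInputs",
    "RotationInputs",
    "ratio_area_burned",
    "fire_rotation",
    "fr_from_site",
]


@dataclass(frozen=True)
class RatioInputs:
    """Inputs to the ratio area-burned estimator for one study area."""

    AT: float
    NST: int
    NRE: int = 0

    def __post_init__(self) -> None:
        if self.AT <= 0:
            raise ValueError("study-area size AT must be > 0")
        if not (0 <= self.NRE < self.NST):
            raise ValueError("need 0 <= NRE < NST")


@dataclass(frozen=True)
class RotationInputs:
    observation_period: float
    fraction_burned: float

    def __post_init__(self) -> None:
        if self.observation_period <= 0:
            raise ValueError("observation period must be > 0")
        if self.fraction_burned < 0:
            raise ValueError("fraction burned cannot be negative")


def ratio_area_burned(inputs: RatioInputs, ns_i: int) -> float:
    """Area burned in one fire year: ``AT * NS_i / (NST - NRE)`` (ha)."""
    if not (0 <= ns_i <= inputs.NST):
        raise ValueError("need 0 <= NS_i <= NST")
    denom = inputs.NST - inputs.NRE
    if denom <= 0:
        raise ZeroDivisionError(
            "NST equals NRE: the ratio area-burned estimate is undefined"
        )
    return inputs.AT * ns_i / denom


def fire_rotation(inputs: RotationInputs) -> float:
    """Fire rotation in years: observation period over fraction burned."""
    if inputs.fraction_burned == 0:
        raise ZeroDivisionError(
            "fraction burned is zero: the fire rotation is infinite"
        )
    return inputs.observation_period / inputs.fraction_burned


def fr_from_site(
    site: FireHistorySite,
    basis: str = "total_scarred",
    deduct_eliminated: bool = False,
) -> float:
    """Fire rotation of a (restricted) site from per-year scarred fractions.

    For each fire year the burned fraction is the number of qualifying
    series scarred that year over the qualifying series alive that year:

    * ``basis="total_scarred"`` — qualifying series are all series scarred
      at least once during the record;
    * ``basis="recorders"`` — qualifying series are recorders by that year
      (a series is a recorder from its first scar onward).

    The record is scar-to-scar: fractions are summed over fire years after
    the first fire, and the observation period is last fire year minus
    first fire year.  With ``deduct_eliminated`` the denominator is the
    total qualifying series minus those whose record ended before the fire
    year; by default it is the series alive in that year, so early sparse
    periods do not deflate fractions.
    """
    if basis not in ("total_scarred", "recorders"):
        raise ValueError(f"unknown basis {basis!r}")
    fires = site.fire_years
    if len(fires) < 2:
        raise NoUsableRecordError(
            f"site {site.site_id!r}: fewer than two fire years, no rotation"
        )
    scarred = site.scarred_series
    if not scarred:
        raise NoUsableRecordError(f"site {site.site_id!r}: no scarred series")

    first_fire, last_fire = fires[0], fires[-1]
    fraction = 0.0
    for year in fires[1:]:
        if basis == "total_scarred":
            pool = scarred
        else:
            pool = [s for s in scarred if s.is_recorder(year)]
        if deduct_eliminated:
            denom = len(pool) - sum(1 for s in pool if s.last_year < year)
        else:
            denom = sum(1 for s in pool if s.is_alive(year))
        if denom <= 0:
            continue
        num = sum(1 for s in pool if (s.code_at(year) or "").isupper())
        fraction += num / denom
    if fraction == 0.0:
        raise NoUsableRecordError(
            f"site {site.site_id!r}: zero summed burned fraction"
        )
    return fire_rotation(
        RotationInputs(observation_period=last_fire - first_fire, fraction_burned=fraction)
    )
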
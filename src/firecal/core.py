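"""Core domain objects for fire-scar chronologies.

A fire-history site is a collection of tree series. Each series records,
for every calendar year the tree was sampled ("alive" in the record), one
FHX-style cell code:

* an uppercase letter — a fire scar (the letter is a season code, kept but
  never interpreted by the statistics);
* a lowercase letter — a non-scar injury;
* ``|`` — recording year with no event (open scar face, fires would be seen);
* ``.`` — year inside the record in which the tree was not recording;
* ``[`` / ``]`` — pith / bark at the record boundary;
* ``{`` / ``}`` — innermost / outermost measured ring (no pith/bark).

Years outside ``[first_year, last_year]`` are not part of the series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "TreeSeries",
    "FireHistorySite",
    "FHXParseError",
    "NoUsableRecordError",
    "ShortRecordError",
    "InsufficientIntervalsError",
    "SCAR_SEASON_CODES",
]

#: Conventional season letters for scars (U = undetermined).
SCAR_SEASON_CODES = "UEMLAD"

_BOUNDARY_OPEN = "[{"
_BOUNDARY_CLOSE = "]}"


class FHXParseError(ValueError):
    """Malformed FHX document."""


class NoUsableRecordError(ValueError):
    """A site has no fire record usable under the requested analysis window."""


class ShortRecordError(NoUsableRecordError):
    """The restricted record is shorter than the minimum record length."""


class InsufficientIntervalsError(ValueError):
    """Fewer than two fire years: no interval can be formed."""


@dataclass(frozen=True)
class TreeSeries:
    """One sampled tree's annual event record."""

    series_id: str
    first_year: int
    last_year: int
    codes: str

    def __post_init__(self) -> None:
        if self.last_year < self.first_year:
            raise ValueError(
                f"series {self.series_id!r}: last_year {self.last_year} "
                f"precedes first_year {self.first_year}"
            )
        span = self.last_year - self.first_year + 1
        if len(self.codes) != span:
            raise ValueError(
                f"series {self.series_id!r}: {len(self.codes)} codes for a "
                f"{span}-year span"
            )

    # -- year arithmetic ---------------------------------------------------

    @property
    def span_years(self) -> int:
        return self.last_year - self.first_year + 1

    def code_at(self, year: int) -> str | None:
        if year < self.first_year or year > self.last_year:
            return None
        return self.codes[year - self.first_year]

    def is_alive(self, year: int) -> bool:
        return self.first_year <= year <= self.last_year

    # -- events ------------------------------------------------------------

    @property
    def scar_years(self) -> tuple[int, ...]:
        return tuple(
            self.first_year + i
            for i, c in enumerate(self.codes)
            if c.isalpha() and c.isupper()
        )

    @property
    def injury_years(self) -> tuple[int, ...]:
        return tuple(
            self.first_year + i
            for i, c in enumerate(self.codes)
            if c.isalpha() and c.islower()
        )

    @property
    def n_scars(self) -> int:
        return len(self.scar_years)

    @property
    def first_scar_year(self) -> int | None:
        scars = self.scar_years
        return scars[0] if scars else None

    def is_recorder(self, year: int | None = None) -> bool:
        """A recorder is a tree scarred at least once; from its first scar
        onward it records subsequent fires with elevated probability."""
        first = self.first_scar_year
        if first is None:
            return False
        if year is None:
            return True
        return year >= first

    # -- manipulation ------------------------------------------------------

    def truncate(self, start_year: int, end_year: int) -> "TreeSeries | None":
        """Clip the series to ``[start_year, end_year]``; ``None`` if the
        series does not overlap the window."""
        lo = max(self.first_year, start_year)
        hi = min(self.last_year, end_year)
        if hi < lo:
            return None
        codes = self.codes[lo - self.first_year : hi - self.first_year + 1]
        # boundary pith/bark markers that were clipped off must not reappear
        return TreeSeries(self.series_id, lo, hi, codes)


@dataclass
class FireHistorySite:
    """A collection of tree series with site metadata."""

    site_id: str
    series: list[TreeSeries] = field(default_factory=list)
    area_ha: float | None = None
    latitude: float | None = None
    longitude: float | None = None
    forest_type: str = "unknown"
    state_code: str | None = None

    def __post_init__(self) -> None:
        if self.area_ha is not None and self.area_ha <= 0:
            raise ValueError(f"site {self.site_id!r}: area_ha must be > 0")

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def first_year(self) -> int:
        return min(s.first_year for s in self.series)

    @property
    def last_year(self) -> int:
        return max(s.last_year for s in self.series)

    def alive_count(self, year: int) -> int:
        return sum(s.is_alive(year) for s in self.series)

    @property
    def fire_years(self) -> tuple[int, ...]:
        """Years in which at least one series carries a fire scar."""
        years: set[int] = set()
        for s in self.series:
            years.update(s.scar_years)
        return tuple(sorted(years))

    @property
    def scarred_series(self) -> list[TreeSeries]:
        """Series scarred at least once in the record."""
        return [s for s in self.series if s.n_scars > 0]

    def with_series(self, series: list[TreeSeries]) -> "FireHistorySite":
        out = replace(self)
        out.series = series
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FireHistorySite):
            return NotImplemented
        return (
            self.site_id == other.site_id
            and self.series == other.series
            and self.area_ha == other.area_ha
            and self.latitude == other.latitude
            and self.longitude == other.longitude
            and self.forest_type == other.forest_type
            and self.state_code == other.state_code
        )
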
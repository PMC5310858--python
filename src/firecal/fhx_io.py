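"""Read and write FHX fire-scar chronology files and tabular site datasets.

The FHX ("Fire History Exchange") dialect handled here is the plain-text
matrix format distributed by the International Multiproxy Paleofire
Database: free-text header lines, a ``FHX2 FORMAT`` (or ``FIRE2 FORMAT``)
declaration, a line giving the first matrix year, the number of series and
the series-name length, vertically written series names, and then one row
per year with one code column per series followed by the year.

Site metadata (id, area, coordinates) is carried in ``// key: value``
comment lines before the declaration so that a written site reads back
identically; foreign FHX files simply lack the comments and get default
metadata.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import FHXParseError, FireHistorySite, TreeSeries

__all__ = ["read_fhx", "write_fhx", "read_site_table", "SiteTable"]

logger = logging.getLogger(__name__)

_DECLARATIONS = ("FHX2 FORMAT", "FIRE2 FORMAT")

#: matrix characters with a defined meaning; anything alphabetic is a scar
#: (uppercase) or injury (lowercase); other unknown characters are logged
#: and preserved as opaque injury-like codes.
_KNOWN_PUNCT = set("|.[]{}")

_META_FIELDS = ("site_id", "area_ha", "latitude", "longitude", "forest_type", "state_code")


def _parse_meta(lines: list[str]) -> dict:
    meta: dict = {}
    for line in lines:
        text = line.strip()
        if not text.startswith("//"):
            continue
        body = text[2:].strip()
        if ":" not in body:
            continue
        key, _, value = body.partition(":")
        key = key.strip()
        value = value.strip()
        if key not in _META_FIELDS or value in ("", "None"):
            continue
        if key in ("area_ha", "latitude", "longitude"):
            try:
                meta[key] = float(value)
            except ValueError:
                continue
        else:
            meta[key] = value
    return meta


def read_fhx(stream) -> FireHistorySite:
    """Parse an FHX2-dialect document into a :class:`FireHistorySite`.

    ``stream`` may be a file-like object or a string holding the document.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()

    decl_idx = None
    for i, line in enumerate(lines):
        if line.strip().upper() in _DECLARATIONS:
            decl_idx = i
            break
    if decl_idx is None:
        raise FHXParseError(
            "no 'FHX2 FORMAT' or 'FIRE2 FORMAT' declaration line found"
        )
    meta = _parse_meta(lines[:decl_idx])

    # header: first year, number of series, series-name length
    hdr_idx = decl_idx + 1
    while hdr_idx < len(lines) and not lines[hdr_idx].strip():
        hdr_idx += 1
    if hdr_idx >= len(lines):
        raise FHXParseError(f"line {decl_idx + 2}: missing header line")
    parts = lines[hdr_idx].split()
    if len(parts) != 3:
        raise FHXParseError(
            f"line {hdr_idx + 1}: header must hold exactly three integers "
            f"(first year, series count, name length), got {lines[hdr_idx]!r}"
        )
    try:
        first_year, n_series, name_len = (int(p) for p in parts)
    except ValueError as exc:
        raise FHXParseError(f"line {hdr_idx + 1}: non-integer header field: {exc}") from exc
    if n_series < 1 or name_len < 1:
        raise FHXParseError(
            f"line {hdr_idx + 1}: series count and name length must be >= 1"
        )

    # vertically written series names
    name_rows = lines[hdr_idx + 1 : hdr_idx + 1 + name_len]
    if len(name_rows) < name_len:
        raise FHXParseError(
            f"line {hdr_idx + 2}: expected {name_len} series-name rows, "
            f"found {len(name_rows)}"
        )
    names = []
    for j in range(n_series):
        chars = [row[j] if j < len(row) else " " for row in name_rows]
        names.append("".join(chars).strip())
    for j, name in enumerate(names):
        if not name:
            names[j] = f"S{j + 1}"

    # year matrix
    columns: list[list[str]] = [[] for _ in range(n_series)]
    year = first_year
    n_years = 0
    for offset, raw in enumerate(lines[hdr_idx + 1 + name_len :]):
        if not raw.strip():
            continue
        lineno = hdr_idx + 2 + name_len + offset
        cells, tail = raw[:n_series], raw[n_series:].strip()
        if len(cells) < n_series or not tail or any(c.isspace() for c in cells):
            raise FHXParseError(
                f"line {lineno}: year row for {n_series} declared series must "
                f"hold {n_series} code columns plus the year, got {raw!r}"
            )
        try:
            row_year = int(tail.split()[0])
        except ValueError as exc:
            raise FHXParseError(f"line {lineno}: unparseable year {tail!r}") from exc
        if row_year != year:
            raise FHXParseError(
                f"line {lineno}: expected year {year}, found {row_year}"
            )
        for j, c in enumerate(cells):
            if not c.isalpha() and c not in _KNOWN_PUNCT:
                logger.warning(
                    "series %s year %d: unknown code %r preserved as-is",
                    names[j], year, c,
                )
            columns[j].append(c)
        year += 1
        n_years += 1
    if n_years == 0:
        raise FHXParseError("document declares series but holds no year rows")

    series = []
    for j, col in enumerate(columns):
        non_dot = [i for i, c in enumerate(col) if c != "."]
        if non_dot:
            lo, hi = non_dot[0], non_dot[-1]
        else:  # never sampled in any visible way; keep the full span
            lo, hi = 0, n_years - 1
        series.append(
            TreeSeries(
                series_id=names[j],
                first_year=first_year + lo,
                last_year=first_year + hi,
                codes="".join(col[lo : hi + 1]),
            )
        )

    return FireHistorySite(site_id=meta.pop("site_id", ""), series=series, **meta)


def write_fhx(site: FireHistorySite) -> str:
    """Serialize a site to FHX2 text that :func:`read_fhx` parses back."""
    if not site.series:
        raise ValueError(f"site {site.site_id!r}: cannot write a site with no series")
    for s in site.series:
        if s.span_years < 1:
            raise ValueError(f"series {s.series_id!r}: zero-length span")

    first = site.first_year
    last = site.last_year
    n = site.n_series
    name_len = max(len(s.series_id) for s in site.series)
    name_len = max(name_len, 1)

    out = ["// firecal FHX export"]
    for key in _META_FIELDS:
        value = getattr(site, key)
        if value is not None and value != "":
            out.append(f"// {key}: {value}")
    out.append("FHX2 FORMAT")
    out.append(f"{first} {n} {name_len}")
    for i in range(name_len):
        out.append(
            "".join(
                s.series_id[i] if i < len(s.series_id) else " " for s in site.series
            )
        )
    out.append("")
    for year in range(first, last + 1):
        cells = "".join(s.code_at(year) or "." for s in site.series)
        out.append(f"{cells} {year}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# tabular site datasets


@dataclass
class SiteTable:
    """A typed per-site table (one row per calibration/prediction case).

    ``data`` holds canonical column names; ``problems`` lists cells that
    could not be parsed (the rows are retained with missing values).
    """

    data: pd.DataFrame
    problems: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)


def read_site_table(
    stream,
    schema: dict[str, str] | None = None,
    required: tuple[str, ...] = (),
    numeric: tuple[str, ...] | None = None,
    sep: str = ",",
) -> SiteTable:
    """Read a delimited per-site table.

    Parameters
    ----------
    schema
        Mapping from canonical column name to the column name in the file;
        unmapped file columns are kept under their own names.
    required
        Canonical columns that must be present after renaming.
    numeric
        Columns to coerce to float; unparseable cells become missing and are
        reported in :attr:`SiteTable.problems`, never silently dropped.
        Defaults to all required columns.
    """
    if isinstance(stream, str) and "\n" not in stream:
        df = pd.read_csv(stream, sep=sep)
    elif isinstance(stream, str):
        df = pd.read_csv(io.StringIO(stream), sep=sep)
    else:
        df = pd.read_csv(stream, sep=sep)

    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)

    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"site table is missing mandatory column(s): {missing}")

    problems: list[str] = []
    for col in numeric if numeric is not None else required:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for idx in bad:
            problems.append(f"row {idx}: column {col!r} value {df.at[idx, col]!r} unparseable")
        df[col] = coerced
    return SiteTable(data=df, problems=problems)
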
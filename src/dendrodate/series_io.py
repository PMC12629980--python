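"""Reading, writing and validation of annual ring-width series.

Two plain-text dialects standard in dendrochronology are supported, plus CSV:

* **Tucson RWL** — decade rows ``<id> <year> v1 … v10`` with an end-of-series
  sentinel (999 for files stored in 0.01 mm, -9999 for 0.001 mm).
* **Heidelberg FH** — a ``HEADER:`` keyword block (``DateEnd``, ``Length``,
  ``Unit`` …) followed by a ``DATA:`` block of raw integer widths.
* **CSV** — two columns ``year,width_mm`` with consecutive calendar years.

All calendar arithmetic is in plain CE integers (every panel-painting board
this package targets grew in the 2nd millennium CE).  Widths are strictly
positive: a zero value in a file (sometimes used elsewhere for a locally
absent ring) is rejected rather than imputed, because the crossdating and
error-localization analyses assume complete measured sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RingSeries",
    "Chronology",
    "SeriesFormatError",
    "SeriesValidationError",
    "read_series",
    "write_series",
    "year_span",
    "UNIT_HUNDREDTH_MM",
    "UNIT_THOUSANDTH_MM",
]

UNIT_HUNDREDTH_MM = 0.01
UNIT_THOUSANDTH_MM = 0.001

_STOP_HUNDREDTH = 999
_STOP_THOUSANDTH = -9999


class SeriesFormatError(ValueError):
    """A ring-width file could not be parsed in the requested dialect."""


class SeriesValidationError(ValueError):
    """Decoded values violate the ring-series contract."""


@dataclass(frozen=True)
class RingSeries:
    """A dated sequence of annual ring widths.

    Parameters
    ----------
    series_id
        Short text code identifying the sample (a board, a core, a panel).
    widths
        Ring widths in mm, oldest ring first.  All values must be > 0.
    last_ring_year
        Calendar year CE of the outermost (youngest) measured ring.
    n_sapwood
        Number of sapwood rings at the outer end (0 if sapwood is absent).
    hw_sw_border_is_last_ring
        True when the outermost ring is known to be the last *heartwood*
        ring (the heartwood/sapwood border); implies ``n_sapwood == 0``.
    pith_present
        True when the innermost ring reaches the pith.
    units_raw
        Storage unit of the source file in mm per integer step
        (0.01 or 0.001).
    reconstructed_years
        Calendar years of rings that were inserted as placeholders by an
        editing operation rather than measured.
    """

    series_id: str
    widths: np.ndarray
    last_ring_year: int
    n_sapwood: int = 0
    hw_sw_border_is_last_ring: bool = False
    pith_present: bool = False
    units_raw: float = UNIT_HUNDREDTH_MM
    reconstructed_years: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.widths, dtype=float)
        object.__setattr__(self, "widths", w)
        if w.ndim != 1 or w.size == 0:
            raise SeriesValidationError(
                f"series {self.series_id!r}: widths must be a non-empty 1-D sequence"
            )
        if not np.all(np.isfinite(w)) or not np.all(w > 0):
            raise SeriesValidationError(
                f"series {self.series_id!r}: all ring widths must be finite and > 0"
            )
        if not 0 <= int(self.n_sapwood) <= w.size:
            raise SeriesValidationError(
                f"series {self.series_id!r}: n_sapwood must be between 0 and the series length"
            )
        if self.hw_sw_border_is_last_ring and self.n_sapwood != 0:
            raise SeriesValidationError(
                f"series {self.series_id!r}: a series ending at the heartwood/sapwood "
                "border has no measured sapwood rings"
            )

    @property
    def n(self) -> int:
        """Number of measured rings."""
        return int(self.widths.size)

    @property
    def first_ring_year(self) -> int:
        """Calendar year CE of the innermost ring (inclusive span)."""
        return int(self.last_ring_year) - self.n + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_ring_year, self.last_ring_year + 1)


@dataclass(frozen=True)
class Chronology(RingSeries):
    """A dated reference series (master chronology).

    Same shape as :class:`RingSeries` plus an optional per-year replication
    depth (number of contributing trees) and a region label.  Chronologies
    are consumed as dated references; this package never builds them.
    """

    replication_depth: np.ndarray | None = None
    region: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.replication_depth is not None:
            d = np.asarray(self.replication_depth, dtype=int)
            object.__setattr__(self, "replication_depth", d)
            if d.shape != self.widths.shape:
                raise SeriesValidationError(
                    f"chronology {self.series_id!r}: replication_depth needs one entry per ring"
                )


def year_span(first_year: int, last_year: int) -> int:
    """Inclusive number of rings between two calendar years.

    ``year_span(1397, 1606) == 210``.
    """
    if last_year < first_year:
        raise ValueError(f"reversed year span: {first_year}..{last_year}")
    return int(last_year) - int(first_year) + 1


# ---------------------------------------------------------------------------
# Tucson RWL
# ---------------------------------------------------------------------------

def _parse_rwl(text: str, *, unit: float | None, source: str) -> list[RingSeries]:
    state: dict[str, dict] = {}
    order: list[str] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) < 3:
            raise SeriesFormatError(f"{source}, line {lineno}: malformed decade row")
        ident = tokens[0]
        try:
            year = int(tokens[1])
        except ValueError:
            raise SeriesFormatError(
                f"{source}, line {lineno}: malformed decade row (bad decade year {tokens[1]!r})"
            ) from None
        try:
            vals = [int(v) for v in tokens[2:]]
        except ValueError:
            raise SeriesFormatError(
                f"{source}, line {lineno}: malformed decade row (non-integer width value)"
            ) from None

        st = state.get(ident)
        if st is None:
            st = {"start": year, "vals": [], "stop_unit": None}
            state[ident] = st
            order.append(ident)
        else:
            if st["stop_unit"] is not None:
                raise SeriesFormatError(
                    f"{source}, line {lineno}: data for {ident!r} after its end-of-series marker"
                )
            expected = st["start"] + len(st["vals"])
            if year != expected:
                raise SeriesFormatError(
                    f"{source}, line {lineno}: malformed decade row "
                    f"(year {year}, expected {expected} for series {ident!r})"
                )
        for v in vals:
            if st["stop_unit"] is not None:
                break
            if v == _STOP_THOUSANDTH:
                st["stop_unit"] = UNIT_THOUSANDTH_MM
            elif v == _STOP_HUNDREDTH and unit != UNIT_THOUSANDTH_MM:
                # 999 is a legal width (0.999 mm) in 0.001 mm files.
                st["stop_unit"] = UNIT_HUNDREDTH_MM
            else:
                st["vals"].append(v)

    out: list[RingSeries] = []
    for ident in order:
        st = state[ident]
        marker_unit = st["stop_unit"]
        if unit is not None and marker_unit is not None and marker_unit != unit:
            raise SeriesFormatError(
                f"{source}: series {ident!r} carries a "
                f"{'-9999' if marker_unit == UNIT_THOUSANDTH_MM else '999'} marker, "
                f"conflicting with the explicit unit {unit} mm"
            )
        chosen = unit if unit is not None else marker_unit
        if chosen is None:
            raise SeriesFormatError(
                f"{source}: series {ident!r} has no end-of-series marker; the storage "
                "unit is ambiguous — pass unit=0.01 or unit=0.001 explicitly"
            )
        raw = np.asarray(st["vals"], dtype=int)
        if raw.size == 0:
            raise SeriesFormatError(f"{source}: series {ident!r} has no width values")
        if np.any(raw <= 0):
            raise SeriesValidationError(
                f"{source}: series {ident!r} contains a non-positive ring width"
            )
        out.append(
            RingSeries(
                series_id=ident,
                widths=raw * chosen,
                last_ring_year=st["start"] + raw.size - 1,
                units_raw=chosen,
            )
        )
    return out


def _format_rwl(series: list[RingSeries]) -> str:
    lines: list[str] = []
    for s in series:
        unit = s.units_raw
        if unit == UNIT_HUNDREDTH_MM:
            stop = _STOP_HUNDREDTH
        elif unit == UNIT_THOUSANDTH_MM:
            stop = _STOP_THOUSANDTH
        else:
            raise SeriesValidationError(
                f"series {s.series_id!r}: Tucson files store 0.01 or 0.001 mm, not {unit}"
            )
        if len(s.series_id) > 8 or " " in s.series_id:
            raise SeriesValidationError(
                f"series id {s.series_id!r} does not fit the 8-character Tucson field"
            )
        if s.first_ring_year < 0 or s.last_ring_year + 1 > 9999:
            raise SeriesValidationError(
                f"series {s.series_id!r}: year span exceeds the Tucson format's capacity"
            )
        vals = np.rint(s.widths / unit).astype(int)
        if np.any(vals <= 0):
            raise SeriesValidationError(
                f"series {s.series_id!r}: a width falls below the storage precision"
            )
        limit = _STOP_HUNDREDTH if unit == UNIT_HUNDREDTH_MM else 99999
        if np.any(vals >= limit):
            raise SeriesValidationError(
                f"series {s.series_id!r}: width too large for {unit} mm storage; "
                "use 0.001 mm units"
            )
        items = list(zip(range(s.first_ring_year, s.last_ring_year + 2),
                         list(vals) + [stop]))
        i = 0
        while i < len(items):
            row_year = items[i][0]
            take = 10 - (row_year % 10)
            chunk = items[i:i + take]
            lines.append(
                f"{s.series_id:<8}{row_year:>4d}"
                + "".join(f"{v:>6d}" for _, v in chunk)
            )
            i += take
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Heidelberg FH
# ---------------------------------------------------------------------------

_FH_UNITS = {"1/100 mm": UNIT_HUNDREDTH_MM, "1/1000 mm": UNIT_THOUSANDTH_MM}


def _parse_fh(text: str, *, source: str) -> list[RingSeries]:
    lines = text.splitlines()
    out: list[RingSeries] = []
    i = 0
    while i < len(lines):
        stripped = lines[i].strip()
        if not stripped:
            i += 1
            continue
        if stripped.upper() != "HEADER:":
            raise SeriesFormatError(
                f"{source}, line {i + 1}: expected 'HEADER:' block, found {stripped!r}"
            )
        i += 1
        meta: dict[str, str] = {}
        while i < len(lines) and "=" in lines[i]:
            key, val = lines[i].split("=", 1)
            meta[key.strip()] = val.strip()
            i += 1
        if i >= len(lines) or not lines[i].strip().upper().startswith("DATA"):
            raise SeriesFormatError(f"{source}, line {i + 1}: missing DATA block")
        i += 1
        try:
            length = int(meta["Length"])
            date_end = int(meta["DateEnd"])
        except (KeyError, ValueError) as exc:
            raise SeriesFormatError(
                f"{source}: header needs integer Length and DateEnd ({exc})"
            ) from None
        unit_label = meta.get("Unit", "1/100 mm")
        if unit_label not in _FH_UNITS:
            raise SeriesFormatError(
                f"{source}: unknown Unit {unit_label!r}; expected '1/100 mm' or '1/1000 mm'"
            )
        unit = _FH_UNITS[unit_label]
        vals: list[int] = []
        while i < len(lines) and len(vals) < length:
            for tok in lines[i].split():
                try:
                    vals.append(int(tok))
                except ValueError:
                    raise SeriesFormatError(
                        f"{source}, line {i + 1}: non-integer width value {tok!r}"
                    ) from None
            i += 1
        if len(vals) != length:
            raise SeriesFormatError(
                f"{source}: series {meta.get('KeyCode', '?')!r} declares Length={length} "
                f"but {len(vals)} values were found"
            )
        raw = np.asarray(vals, dtype=int)
        if np.any(raw <= 0):
            raise SeriesValidationError(
                f"{source}: series {meta.get('KeyCode', '?')!r} contains a non-positive width"
            )
        if "DateBegin" in meta and int(meta["DateBegin"]) != date_end - length + 1:
            raise SeriesFormatError(
                f"{source}: DateBegin/DateEnd/Length are inconsistent for "
                f"series {meta.get('KeyCode', '?')!r}"
            )
        out.append(
            RingSeries(
                series_id=meta.get("KeyCode", "UNNAMED"),
                widths=raw * unit,
                last_ring_year=date_end,
                n_sapwood=int(meta.get("SapWoodRings", 0)),
                pith_present=meta.get("Pith", "").lower() in ("p", "present", "yes", "true"),
                units_raw=unit,
            )
        )
    return out


def _format_fh(series: list[RingSeries]) -> str:
    blocks: list[str] = []
    for s in series:
        unit = s.units_raw
        label = next((k for k, v in _FH_UNITS.items() if v == unit), None)
        if label is None:
            raise SeriesValidationError(
                f"series {s.series_id!r}: FH files store 0.01 or 0.001 mm, not {unit}"
            )
        vals = np.rint(s.widths / unit).astype(int)
        if np.any(vals <= 0):
            raise SeriesValidationError(
                f"series {s.series_id!r}: a width falls below the storage precision"
            )
        head = [
            "HEADER:",
            f"KeyCode={s.series_id}",
            f"DateBegin={s.first_ring_year}",
            f"DateEnd={s.last_ring_year}",
            f"Length={s.n}",
            f"Unit={label}",
        ]
        if s.n_sapwood:
            head.append(f"SapWoodRings={s.n_sapwood}")
        if s.pith_present:
            head.append("Pith=P")
        head.append("DATA:Single")
        body = [
            "".join(f"{v:>6d}" for v in vals[j:j + 10]) for j in range(0, len(vals), 10)
        ]
        blocks.append("\n".join(head + body))
    return "\n".join(blocks) + ("\n" if blocks else "")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _parse_csv(path: Path) -> list[RingSeries]:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["year", "width_mm"]:
        raise SeriesFormatError(f"{path}: expected header 'year,width_mm'")
    if len(df) == 0:
        return []
    years = df["year"].to_numpy(dtype=int)
    if not np.all(np.diff(years) == 1):
        raise SeriesFormatError(f"{path}: years must be consecutive and ascending")
    widths = df["width_mm"].to_numpy(dtype=float)
    if np.any(~np.isfinite(widths)) or np.any(widths <= 0):
        raise SeriesValidationError(f"{path}: all widths must be finite and > 0")
    return [
        RingSeries(
            series_id=Path(path).stem,
            widths=widths,
            last_ring_year=int(years[-1]),
            units_raw=UNIT_HUNDREDTH_MM,
        )
    ]


def _format_csv(series: list[RingSeries]) -> str:
    if len(series) > 1:
        raise SeriesValidationError("the CSV dialect holds a single series per file")
    rows = ["year,width_mm"]
    for s in series:
        for y, w in zip(s.years, s.widths):
            rows.append(f"{y},{w:.6g}")
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

_SUFFIXES = {".rwl": "rwl", ".tuc": "rwl", ".fh": "heidelberg", ".csv": "csv"}


def _detect_format(path: Path, text: str) -> str:
    fmt = _SUFFIXES.get(path.suffix.lower())
    if fmt:
        return fmt
    head = text.lstrip()[:16].upper()
    if head.startswith("HEADER:"):
        return "heidelberg"
    if head.startswith("YEAR,"):
        return "csv"
    return "rwl"


def read_series(path, format: str = "auto", unit: float | None = None) -> list[RingSeries]:
    """Read all ring-width series from ``path``.

    Parameters
    ----------
    path
        File in Tucson RWL, Heidelberg FH or ``year,width_mm`` CSV format.
    format
        One of ``{"rwl", "heidelberg", "csv", "auto"}``; ``"auto"`` dispatches
        on the file suffix, then on the content.
    unit
        Explicit storage unit override for Tucson files whose end-of-series
        marker is absent or whose 999 values are data rather than a sentinel.
    """
    path = Path(path)
    text = path.read_text()
    if format == "auto":
        format = _detect_format(path, text)
    if format == "rwl":
        return _parse_rwl(text, unit=unit, source=str(path))
    if format == "heidelberg":
        return _parse_fh(text, source=str(path))
    if format == "csv":
        return _parse_csv(path)
    raise ValueError(f"unknown format {format!r}")


def write_series(series: list[RingSeries], path, format: str = "auto") -> None:
    """Write series to ``path``; the output re-reads bit-identically at the
    source precision (widths are quantized to ``units_raw``)."""
    path = Path(path)
    if format == "auto":
        format = _SUFFIXES.get(path.suffix.lower(), "rwl")
    if format == "rwl":
        path.write_text(_format_rwl(list(series)))
    elif format == "heidelberg":
        path.write_text(_format_fh(list(series)))
    elif format == "csv":
        path.write_text(_format_csv(list(series)))
    else:
        raise ValueError(f"unknown format {format!r}")
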
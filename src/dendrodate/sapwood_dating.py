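"""Felling-date and production-date estimation from sapwood statistics.

A dated outermost ring only bounds the felling year of the tree: boards are
usually trimmed, so some or all sapwood rings (and possibly heartwood rings)
are lost.  Regional sapwood statistics — here the Polish oak range of 9 to
24 sapwood rings (median 15) at 90% confidence — convert the date of the
last surviving ring into a felling estimate:

* last ring at the **heartwood/sapwood border**: felling within the closed
  interval ``[last + sw_min, last + sw_max]``;
* **heartwood only** (border position unknown): a *terminus post quem* at
  ``last + sw_min``;
* **partial sapwood** (k sapwood rings survive): the interval shifts by the
  sapwood already present, and its lower bound can never precede the last
  measured ring;
* **bark edge**: the felling year is the final ring's year, exactly.

A seasoning allowance (drying/transport time between felling and use of the
board) then turns felling bounds into production-date windows for the
artwork: the fixed 2-year allowance used in 1990s reports, or the modern
2-to-5-year range.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SapwoodStats",
    "SeasoningPolicy",
    "FellingEstimate",
    "ProductionEstimate",
    "POLAND_WAZNY",
    "SAPWOOD_PRESETS",
    "SEASONING_PRESETS",
    "estimate_felling",
    "estimate_production",
    "hw_sw_border_year",
]


@dataclass(frozen=True)
class SapwoodStats:
    """Regional sapwood ring-count distribution summary."""

    region: str
    sw_min: int
    sw_median: int
    sw_max: int
    confidence: float

    def __post_init__(self) -> None:
        if not self.sw_min <= self.sw_median <= self.sw_max:
            raise ValueError("need sw_min <= sw_median <= sw_max")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")


@dataclass(frozen=True)
class SeasoningPolicy:
    """Years of wood seasoning between felling and use, as a closed range."""

    s_min: int
    s_max: int

    def __post_init__(self) -> None:
        if not 0 <= self.s_min <= self.s_max:
            raise ValueError("need 0 <= s_min <= s_max")


#: Sapwood statistics for oak grown in Poland (9-24 rings, median 15, 90%).
POLAND_WAZNY = SapwoodStats("Poland (Wazny)", 9, 15, 24, 0.90)

SAPWOOD_PRESETS = {"poland_wazny": POLAND_WAZNY}

SEASONING_PRESETS = {
    "klein_1990s": SeasoningPolicy(2, 2),   # fixed 2-year allowance
    "replication": SeasoningPolicy(2, 5),   # modern 2-to-5-year allowance
}


@dataclass(frozen=True)
class FellingEstimate:
    """Estimated felling date of the tree.

    ``kind`` is ``"interval"`` (closed range), ``"terminus_post_quem"``
    (open upper bound, ``upper is None``) or ``"exact"``.
    """

    kind: str
    lower: int
    upper: int | None
    median_year: int | None
    confidence: float
    basis: SapwoodStats

    def __post_init__(self) -> None:
        if self.kind not in ("interval", "terminus_post_quem", "exact"):
            raise ValueError(f"unknown felling-estimate kind {self.kind!r}")
        if self.kind == "terminus_post_quem" and self.upper is not None:
            raise ValueError("a terminus post quem has an open upper bound")
        if self.kind != "terminus_post_quem" and self.upper is None:
            raise ValueError("closed estimates need an upper bound")
        if self.upper is not None and self.upper < self.lower:
            raise ValueError("upper bound precedes lower bound")


@dataclass(frozen=True)
class ProductionEstimate:
    """Production-date windows for the artwork.

    ``earliest_window`` brackets the *earliest possible* production year
    (felling lower bound plus the seasoning range).  ``likely`` is the likely
    production span; its upper bound is ``None`` (open) when the felling
    estimate was a terminus post quem.
    """

    earliest_window: tuple[int, int]
    likely: tuple[int, int | None]


def estimate_felling(
    last_ring_year: int,
    context: str,
    stats: SapwoodStats = POLAND_WAZNY,
    k: int | None = None,
) -> FellingEstimate:
    """Felling estimate for a board whose outermost ring dates to
    ``last_ring_year``.

    ``context`` is one of ``"hw_sw_border"``, ``"heartwood_only"``,
    ``"partial_sapwood"`` (requires ``k``, the surviving sapwood ring count)
    or ``"bark_edge"``.

    Examples
    --------
    A border ring dated 1606 with Polish statistics gives the interval
    1615-1630 (median 1621); a heartwood-only board ending 1602 gives a
    terminus post quem of 1611.
    """
    y = int(last_ring_year)
    if context == "hw_sw_border":
        return FellingEstimate(
            kind="interval",
            lower=y + stats.sw_min,
            upper=y + stats.sw_max,
            median_year=y + stats.sw_median,
            confidence=stats.confidence,
            basis=stats,
        )
    if context == "heartwood_only":
        return FellingEstimate(
            kind="terminus_post_quem",
            lower=y + stats.sw_min,
            upper=None,
            median_year=None,
            confidence=stats.confidence,
            basis=stats,
        )
    if context == "partial_sapwood":
        if k is None or k < 0:
            raise ValueError("partial_sapwood requires a non-negative sapwood count k")
        # A tree cannot be felled before its last existing ring.
        lower = max(y + 1, y - k + stats.sw_min)
        upper = y - k + stats.sw_max
        if upper < lower:
            raise ValueError(
                f"k={k} sapwood rings exceed the regional maximum {stats.sw_max}"
            )
        return FellingEstimate(
            kind="interval",
            lower=lower,
            upper=upper,
            median_year=max(lower, y - k + stats.sw_median),
            confidence=stats.confidence,
            basis=stats,
        )
    if context == "bark_edge":
        return FellingEstimate(
            kind="exact",
            lower=y,
            upper=y,
            median_year=y,
            confidence=1.0,
            basis=stats,
        )
    raise ValueError(f"unknown felling context {context!r}")


def estimate_production(
    felling: FellingEstimate, seasoning: SeasoningPolicy
) -> ProductionEstimate:
    """Production windows from a felling estimate plus a seasoning allowance.

    For a felling interval [L, U]: earliest possible production within
    ``[L + s_min, L + s_max]`` and likely production within
    ``[L + s_min, U + s_max]``.  For a terminus post quem F the likely
    production is open-ended after ``F + s_min``.
    """
    lo = felling.lower
    earliest = (lo + seasoning.s_min, lo + seasoning.s_max)
    if felling.kind == "terminus_post_quem":
        likely: tuple[int, int | None] = (lo + seasoning.s_min, None)
    else:
        likely = (lo + seasoning.s_min, felling.upper + seasoning.s_max)
    return ProductionEstimate(earliest_window=earliest, likely=likely)


def hw_sw_border_year(last_ring_year: int, n_sapwood: int) -> int:
    """Calendar year of the last heartwood ring, given the outermost ring's
    year and the sapwood ring count (e.g. 1614 with 8 sapwood rings: 1606)."""
    if n_sapwood < 0:
        raise ValueError("sapwood ring count cannot be negative")
    return int(last_ring_year) - int(n_sapwood)
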
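"""Normalization of raw ring widths for crossdating statistics.

Two derived signals are computed from a :class:`~dendrodate.series_io.RingSeries`:

* the **log-ratio index** (Baillie–Pilcher normalization): the natural
  logarithm of each ring width divided by the centered 5-year mean of its
  neighbourhood.  This removes the age trend and low-frequency growth-rate
  differences, leaving the year-to-year signal on which the Pearson
  correlation (and hence the t statistic) is computed.  Two boundary years
  are dropped at each end so every index is a true 5-year ratio.
* the **difference-sign series**: the ternary sign (+1/0/-1) of each
  first difference, the ingredient of the percentage of parallel variation
  (%PV, Gleichläufigkeit).

The log-ratio index is invariant under multiplicative rescaling of the
parent widths, so series measured in different units or with different
calibration crossdate identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .series_io import RingSeries

__all__ = ["TransformedSeries", "SignSeries", "bp_transform", "sign_series"]

#: rings trimmed at each end by the centered 5-year window
_EDGE = 2


@dataclass(frozen=True)
class TransformedSeries:
    """Log-ratio indices; ``first_year`` is the parent's first year + 2."""

    values: np.ndarray
    first_year: int
    parent_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.n - 1


@dataclass(frozen=True)
class SignSeries:
    """Signs of first differences; interval *i* covers years *i* → *i+1* and
    is labelled by its first year."""

    values: np.ndarray
    first_interval_year: int
    parent_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=int))

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def last_interval_year(self) -> int:
        return self.first_interval_year + self.n - 1


def bp_transform(series: RingSeries) -> TransformedSeries:
    """Baillie–Pilcher log-ratio normalization.

    ``value[i] = ln(w[i] / mean(w[i-2 : i+3]))`` for the interior years; the
    two boundary years at each end are dropped rather than computed with a
    shrunken window.
    """
    w = series.widths
    if w.size < 2 * _EDGE + 1:
        raise ValueError(
            f"series {series.series_id!r}: need at least 5 rings for the 5-year window"
        )
    means = sliding_window_view(w, 2 * _EDGE + 1).mean(axis=1)
    values = np.log(w[_EDGE:-_EDGE] / means)
    return TransformedSeries(
        values=values,
        first_year=series.first_ring_year + _EDGE,
        parent_id=series.series_id,
    )


def sign_series(series: RingSeries) -> SignSeries:
    """Ternary signs of year-to-year width changes; ``sign(0) == 0`` (ties are
    kept, their %PV contribution is decided by the crossdating module)."""
    w = series.widths
    if w.size < 2:
        raise ValueError(f"series {series.series_id!r}: need at least 2 rings")
    return SignSeries(
        values=np.sign(np.diff(w)).astype(int),
        first_interval_year=series.first_ring_year,
        parent_id=series.series_id,
    )
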
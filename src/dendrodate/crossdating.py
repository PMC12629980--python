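"""Sliding-offset crossdating of a sample series against a dated reference.

At each admissible end-year the module computes, on the overlap:

* ``r`` — Pearson correlation of the log-ratio (Baillie–Pilcher) indices;
* ``t_bp`` — the derived Student's t, ``r * sqrt(n - 2) / sqrt(1 - r**2)``
  with ``n`` the number of overlapping *transformed* values;
* ``%PV`` (Gleichläufigkeit) — the percentage of year-to-year intervals in
  which both series change width in the same direction, with a one-sided
  significance from the normal approximation of the binomial
  (mean 1/2, sd ``1 / (2 sqrt(n))`` over ``n`` overlapping intervals);

and classifies the candidate against the field's conventional thresholds
(t >= 3.5 at >= 100 rings of overlap: potential; t >= 5 with %PV > 63 at
p < 0.05: accepted).  An exceptionally strong match between two boards can
additionally be flagged as a same-tree candidate.

Bookkeeping note: the overlap ``Ol`` reported to users counts raw
overlapping rings, while the t formula uses the transformed-value overlap
(raw - 4 when one series is fully nested in the other).  Both are carried on
the result to avoid off-by-four confusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .ring_signal import SignSeries, TransformedSeries, bp_transform, sign_series
from .series_io import RingSeries

__all__ = [
    "MatchPolicy",
    "CrossdateResult",
    "UndefinedStatisticError",
    "tbp_statistic",
    "glk_statistic",
    "glk_significance",
    "classify_match",
    "scan_offsets",
    "assess_same_tree",
    "T_CAP",
    "SIGNIFICANCE_MARKS",
]

#: t value reported for a numerically perfect correlation (|r| -> 1); keeps
#: the ranking total when a series is compared with itself or a duplicate.
T_CAP = 9999.0
_R_CAP = 1.0 - 1e-12

SIGNIFICANCE_MARKS = {"none": "", "p05": "#", "p01": "##", "p001": "###"}


class UndefinedStatisticError(ValueError):
    """Raised when an overlap is too short or has zero variance."""


@dataclass(frozen=True)
class MatchPolicy:
    """Thresholds used to classify crossdating candidates.

    Defaults follow the conventional criteria for Baltic oak panel series:
    t >= 3.5 over >= 100 rings marks a *potential* match, t >= 5 together
    with %PV above 63 at p < 0.05 an *accepted* one.  The same-tree t
    threshold is a configuration default (there is no field-wide numeric
    criterion); same-tree verdicts additionally require %PV significance at
    p < 0.001.
    """

    t_potential: float = 3.5
    min_overlap_potential: int = 100
    t_accepted: float = 5.0
    glk_min: float = 63.0
    glk_p_max: float = 0.05
    t_same_tree: float = 10.0
    min_overlap_scan: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.t_potential <= self.t_accepted):
            raise ValueError("need 0 < t_potential <= t_accepted")
        if min(self.min_overlap_potential, self.min_overlap_scan) < 3:
            raise ValueError("overlap minima must be at least 3 rings")


@dataclass(frozen=True)
class CrossdateResult:
    """Statistics of one candidate alignment of ``sample`` on ``reference``."""

    sample_id: str
    reference_id: str
    proposed_end_year: int
    overlap: int            # raw overlapping rings (Ol)
    overlap_t: int          # overlapping transformed values entering t
    r: float
    t_bp: float
    glk: float              # %PV in [0, 100]
    glk_p: float
    significance_class: str  # none | p05 | p01 | p001
    match_class: str         # no_match | potential | accepted | same_tree_candidate

    @property
    def significance_marks(self) -> str:
        return SIGNIFICANCE_MARKS[self.significance_class]


def _overlap(a_first: int, a_n: int, b_first: int, b_n: int):
    lo = max(a_first, b_first)
    hi = min(a_first + a_n - 1, b_first + b_n - 1)
    if hi < lo:
        return None
    return lo, hi


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedStatisticError("zero variance in an overlap segment")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def _t_from_r(r: float, n: int) -> float:
    if r >= _R_CAP:
        return T_CAP
    if r <= -_R_CAP:
        return -T_CAP
    return r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)


def tbp_statistic(
    a: TransformedSeries, b: TransformedSeries, end_year: int
) -> tuple[float, float, int]:
    """Correlation and TBP t of ``a`` slid so that its parent's last raw ring
    falls on ``end_year``, against ``b`` at its own dates.

    Returns ``(r, t, n)`` with ``n`` the transformed-value overlap.  The
    statistic is symmetric in its two series.
    """
    a_first = a.first_year + ((end_year - 2) - a.last_year)
    ov = _overlap(a_first, a.n, b.first_year, b.n)
    if ov is None or ov[1] - ov[0] + 1 < 3:
        raise UndefinedStatisticError(
            f"overlap shorter than 3 transformed values at end year {end_year}"
        )
    lo, hi = ov
    x = a.values[lo - a_first : hi - a_first + 1]
    y = b.values[lo - b.first_year : hi - b.first_year + 1]
    r = _pearson(x, y)
    return r, _t_from_r(r, x.size), int(x.size)


def glk_significance(glk: float, n: int) -> tuple[float, str]:
    """One-sided p for a %PV of ``glk`` over ``n`` intervals, via the normal
    approximation with mean 1/2 and sd ``1 / (2 sqrt(n))``, plus its class."""
    z = (glk / 100.0 - 0.5) * 2.0 * math.sqrt(n)
    p = float(_scipy_stats.norm.sf(z))
    p = max(p, 1e-300)
    if p < 0.001:
        cls = "p001"
    elif p < 0.01:
        cls = "p01"
    elif p < 0.05:
        cls = "p05"
    else:
        cls = "none"
    return p, cls


def glk_statistic(
    a: SignSeries, b: SignSeries, end_year: int
) -> tuple[float, float, str]:
    """%PV of ``a`` slid so that its parent's last raw ring falls on
    ``end_year``, against ``b`` at its own dates.

    Per interval the agreement score is ``|s_a + s_b| / 2``: 1 for the same
    non-zero sign, 0 for opposite signs, 1/2 when exactly one series has a
    tie, 0 when both do.  Ties contribute to the score but do not reduce the
    interval count entering the significance.
    """
    a_first = a.first_interval_year + ((end_year - 1) - a.last_interval_year)
    ov = _overlap(a_first, a.n, b.first_interval_year, b.n)
    if ov is None or ov[1] - ov[0] + 1 < 2:
        raise UndefinedStatisticError(
            f"overlap shorter than 2 intervals at end year {end_year}"
        )
    lo, hi = ov
    sa = a.values[lo - a_first : hi - a_first + 1]
    sb = b.values[lo - b.first_interval_year : hi - b.first_interval_year + 1]
    both_zero = (sa == 0) & (sb == 0)
    score = np.abs(sa + sb) / 2.0
    score[both_zero] = 0.0
    glk = float(100.0 * score.mean())
    p, cls = glk_significance(glk, score.size)
    return glk, p, cls


def classify_match(
    t: float, overlap: int, glk: float, glk_p: float, policy: MatchPolicy
) -> str:
    if t >= policy.t_accepted and glk >= policy.glk_min and glk_p <= policy.glk_p_max:
        return "accepted"
    if t >= policy.t_potential and overlap >= policy.min_overlap_potential:
        return "potential"
    return "no_match"


def scan_offsets(
    sample: RingSeries,
    reference: RingSeries,
    policy: MatchPolicy | None = None,
) -> list[CrossdateResult]:
    """Statistics for every end year at which ``sample`` overlaps
    ``reference`` by at least ``policy.min_overlap_scan`` rings, ranked by
    t (descending), then %PV, then overlap, then earlier end year.

    Offsets whose overlap statistics are undefined (too short after
    transformation, or zero variance) are skipped.  An empty list means no
    admissible offset, which is not an error.
    """
    policy = policy or MatchPolicy()
    if reference.n < policy.min_overlap_scan:
        raise ValueError("reference shorter than the minimum scanning overlap")
    at, bt = bp_transform(sample), bp_transform(reference)
    asgn, bsgn = sign_series(sample), sign_series(reference)
    n, m = sample.n, policy.min_overlap_scan
    results: list[CrossdateResult] = []
    for end in range(reference.first_ring_year + m - 1, reference.last_ring_year + n - m + 1):
        ol = min(end, reference.last_ring_year) - max(end - n + 1, reference.first_ring_year) + 1
        try:
            r, t, nt = tbp_statistic(at, bt, end)
            glk, p, sig = glk_statistic(asgn, bsgn, end)
        except UndefinedStatisticError:
            continue
        results.append(
            CrossdateResult(
                sample_id=sample.series_id,
                reference_id=reference.series_id,
                proposed_end_year=end,
                overlap=ol,
                overlap_t=nt,
                r=r,
                t_bp=t,
                glk=glk,
                glk_p=p,
                significance_class=sig,
                match_class=classify_match(t, ol, glk, p, policy),
            )
        )
    results.sort(key=lambda c: (-c.t_bp, -c.glk, -c.overlap, c.proposed_end_year))
    return results


def _masked_stats(
    a: RingSeries,
    b: RingSeries,
    end_year: int,
    disregard: tuple[int, int] | None,
):
    """(r, t, n_t, glk, p, sig, Ol) at a fixed alignment, optionally excluding
    a calendar-year window from both statistics."""
    at, bt = bp_transform(a), bp_transform(b)
    shift = end_year - a.last_ring_year
    ov = _overlap(at.first_year + shift, at.n, bt.first_year, bt.n)
    if ov is None or ov[1] - ov[0] + 1 < 3:
        raise UndefinedStatisticError("transformed overlap shorter than 3 values")
    lo, hi = ov
    years = np.arange(lo, hi + 1)
    x = at.values[lo - (at.first_year + shift) : hi - (at.first_year + shift) + 1]
    y = bt.values[lo - bt.first_year : hi - bt.first_year + 1]
    keep = np.ones(years.size, dtype=bool)
    if disregard is not None:
        y0, y1 = disregard
        keep = (years < y0) | (years > y1)
    if keep.sum() < 3:
        raise UndefinedStatisticError("fewer than 3 values left after the disregard window")
    r = _pearson(x[keep], y[keep])
    t = _t_from_r(r, int(keep.sum()))

    asgn, bsgn = sign_series(a), sign_series(b)
    ovs = _overlap(asgn.first_interval_year + shift, asgn.n, bsgn.first_interval_year, bsgn.n)
    if ovs is None or ovs[1] - ovs[0] + 1 < 2:
        raise UndefinedStatisticError("fewer than 2 overlapping intervals")
    slo, shi = ovs
    iyears = np.arange(slo, shi + 1)
    sa = asgn.values[slo - (asgn.first_interval_year + shift) : shi - (asgn.first_interval_year + shift) + 1]
    sb = bsgn.values[slo - bsgn.first_interval_year : shi - bsgn.first_interval_year + 1]
    ikeep = np.ones(iyears.size, dtype=bool)
    if disregard is not None:
        y0, y1 = disregard
        ikeep = (iyears < y0) | (iyears > y1)
    if ikeep.sum() < 2:
        raise UndefinedStatisticError("fewer than 2 intervals left after the disregard window")
    sa, sb = sa[ikeep], sb[ikeep]
    score = np.abs(sa + sb) / 2.0
    score[(sa == 0) & (sb == 0)] = 0.0
    glk = float(100.0 * score.mean())
    p, sig = glk_significance(glk, score.size)

    ol_raw = (
        min(end_year, b.last_ring_year)
        - max(end_year - a.n + 1, b.first_ring_year)
        + 1
    )
    return r, t, int(keep.sum()), glk, p, sig, int(ol_raw)


def assess_same_tree(
    a: RingSeries,
    b: RingSeries,
    aligned_end_year: int,
    policy: MatchPolicy | None = None,
    disregard: tuple[int, int] | None = None,
) -> CrossdateResult:
    """Judge whether two boards were sawn from one trunk at a given alignment.

    ``aligned_end_year`` is the calendar end year asserted for ``a`` on the
    calendar of ``b`` (from :func:`scan_offsets` or external dating).  The
    verdict is ``same_tree_candidate`` iff the TBP t reaches
    ``policy.t_same_tree`` and the %PV is significant at p < 0.001.
    ``disregard`` optionally names an inclusive calendar-year window that is
    excluded from the statistics (e.g. a span known to carry measurement
    errors in one of the series).
    """
    policy = policy or MatchPolicy()
    r, t, nt, glk, p, sig, ol = _masked_stats(a, b, aligned_end_year, disregard)
    if ol < 3:
        raise UndefinedStatisticError("overlap below minimum")
    if t >= policy.t_same_tree and p < 0.001:
        verdict = "same_tree_candidate"
    else:
        verdict = classify_match(t, ol, glk, p, policy)
    return CrossdateResult(
        sample_id=a.series_id,
        reference_id=b.series_id,
        proposed_end_year=aligned_end_year,
        overlap=ol,
        overlap_t=nt,
        r=r,
        t_bp=t,
        glk=glk,
        glk_p=p,
        significance_class=sig,
        match_class=verdict,
    )
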
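"""Localization of single-ring measurement errors between two series.

Given a trusted, correctly dated ``reference`` series and a ``suspect``
series presumed to record the same ring sequence (two boards from one tree,
or two measurements of one panel), the module locates single-ring
*deletions* (a ring missed during measurement) and *duplications* (a ring
measured twice) in the suspect, and proposes corrections.

A single-ring slip misaligns everything on one side of the faulty position,
so the search proceeds greedily, one edit at a time:

1. a windowed best-lag profile (default 30-ring windows, lags within
   ±``max_events``) is computed on the log-ratio indices; change-points in
   the profile delimit candidate regions.  A slip inside the outermost or
   innermost window never dominates a window, leaving the profile flat, so
   when no change-point is found the head and tail window regions are
   scanned instead;
2. within the candidate regions every single *correction* is tried —
   merging an adjacent ring pair into one (duplication hypothesis, the
   exact inverse of a ring measured twice) or inserting a local-median
   placeholder ring (missing-ring hypothesis) — and each trial is scored by
   the whole-series TBP t at its best end-year shift within
   ±``max_events``.  Re-dating the trial is essential: with two
   compensating errors no single edit improves the fixed-alignment t.
   Trialling the corrections themselves (rather than destructive
   stand-ins such as halving a ring) keeps the trial score equal to the
   improvement the reported correction actually delivers;
3. the best edit is kept only if it improves t by
   ``max(min_delta_t, rel_delta * |t|)``; the relative term scales the
   required evidence with the match strength, keeping the false-event rate
   on clean pairs low.  Accepted edits are applied and the search repeats.

The ±1-ring ambiguity inherent in deciding *which* of two near-identical
rings was duplicated (or on which side of a boundary a ring is missing) is
reported via ``year_uncertainty``, never silently resolved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .crossdating import _pearson, _t_from_r, UndefinedStatisticError
from .ring_signal import TransformedSeries, bp_transform
from .series_io import RingSeries, SeriesValidationError

__all__ = ["EditEvent", "localize_edits", "apply_edits"]


@dataclass(frozen=True)
class EditEvent:
    """A localized single-ring error in the suspect series.

    ``year_estimate`` is expressed in the corrected (reference) calendar;
    ``year_uncertainty`` is the ± ring ambiguity of that estimate and
    ``delta_t`` the whole-series TBP t improvement the correction yields.
    """

    kind: str               # "missing_in_b" | "doubled_in_b"
    year_estimate: int
    year_uncertainty: int
    delta_t: float

    def __post_init__(self) -> None:
        if self.kind not in ("missing_in_b", "doubled_in_b"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.year_uncertainty < 0 or self.delta_t < 0:
            raise ValueError("uncertainty and delta_t must be non-negative")


# ---------------------------------------------------------------------------
# elementary series edits
# ---------------------------------------------------------------------------

def _redate(s: RingSeries, new_last: int) -> RingSeries:
    return replace(s, last_ring_year=int(new_last))


def _merge_rings(s: RingSeries, pos: int) -> RingSeries:
    w = s.widths.copy()
    w[pos] = w[pos] + w[pos + 1]
    w = np.delete(w, pos + 1)
    return replace(s, widths=w, last_ring_year=s.last_ring_year - 1)


def _insert_median(s: RingSeries, pos: int, year: int) -> RingSeries:
    lo = max(0, pos - 2)
    med = float(np.median(s.widths[lo : pos + 3]))
    w = np.insert(s.widths, pos, med)
    return replace(
        s,
        widths=w,
        last_ring_year=s.last_ring_year + 1,
        reconstructed_years=tuple(sorted((*s.reconstructed_years, int(year)))),
    )


def _insert_predicted(s: RingSeries, pos: int, reference: RingSeries) -> RingSeries:
    """Insert a trial ring at ``pos`` whose width is the reference ring at
    the same calendar label, rescaled to the suspect's local growth level.

    Used only while *searching*: a near-true trial width makes the correct
    insertion position score distinctly better than its neighbours, where a
    neutral placeholder would leave the score profile flat over locally
    smooth growth.  The published correction (:func:`apply_edits`) inserts a
    local-median placeholder instead, so no reference widths leak into the
    corrected series.
    """
    year = s.first_ring_year + pos
    rp = year - reference.first_ring_year
    if not 0 <= rp < reference.n:
        return _insert_median(s, pos, year)
    lo, hi = max(0, pos - 3), min(s.n, pos + 3)
    rlo, rhi = max(0, rp - 3), min(reference.n, rp + 3)
    scale = float(np.median(s.widths[lo:hi])) / float(np.median(reference.widths[rlo:rhi]))
    w_ins = max(float(reference.widths[rp]) * scale, 1e-6)
    w = np.insert(s.widths, pos, w_ins)
    return replace(
        s,
        widths=w,
        last_ring_year=s.last_ring_year + 1,
        reconstructed_years=tuple(sorted((*s.reconstructed_years, int(year)))),
    )


# ---------------------------------------------------------------------------
# alignment scoring
# ---------------------------------------------------------------------------

def _t_at(ref_t: TransformedSeries, sus_t: TransformedSeries, shift: int) -> float:
    a_first = sus_t.first_year + shift
    lo = max(a_first, ref_t.first_year)
    hi = min(a_first + sus_t.n - 1, ref_t.last_year)
    if hi - lo + 1 < 10:
        return -math.inf
    x = sus_t.values[lo - a_first : hi - a_first + 1]
    y = ref_t.values[lo - ref_t.first_year : hi - ref_t.first_year + 1]
    try:
        r = _pearson(x, y)
    except UndefinedStatisticError:
        return -math.inf
    return _t_from_r(r, x.size)


def _best_alignment(
    ref_t: TransformedSeries, suspect: RingSeries, shifts
) -> tuple[float, int]:
    sus_t = bp_transform(suspect)
    best_t, best_s = -math.inf, 0
    for s in shifts:
        t = _t_at(ref_t, sus_t, s)
        if t > best_t:
            best_t, best_s = t, s
    return best_t, best_s


def _plateau(score_fn, pos: int, t_best: float, lo_bound: int, hi_bound: int):
    """Contiguous run of positions scoring within a small band of the best."""
    eps = max(0.25, 0.01 * abs(t_best))
    lo_p = pos
    while lo_p - 1 >= lo_bound and score_fn(lo_p - 1) >= t_best - eps:
        lo_p -= 1
    hi_p = pos
    while hi_p + 1 <= hi_bound and score_fn(hi_p + 1) >= t_best - eps:
        hi_p += 1
    return lo_p, hi_p


def _local_sse(
    reference: RingSeries,
    edited: RingSeries,
    shift: int,
    pos: int,
    halfwin: int = 6,
    mask_pos: bool = False,
) -> float:
    """Mean-adjusted log-width residual around an edit, at a given re-dating.

    The whole-series t barely changes between neighbouring candidate
    positions (one or two ring pairs out of hundreds), so near-tied
    positions are separated by this local residual instead: at the true
    position every ring in the window matches the reference up to
    measurement noise, while an off-by-one edit leaves a lag-one mismatch
    whose size is the typical year-to-year width change.

    With ``mask_pos`` the edited ring itself is excluded: an inserted
    placeholder is an artificial construct whose own (built-in) fit to the
    reference is not evidence about the error position.
    """
    s = _redate(edited, edited.last_ring_year + shift)
    lo = max(s.first_ring_year, reference.first_ring_year,
             s.first_ring_year + pos - halfwin)
    hi = min(s.last_ring_year, reference.last_ring_year,
             s.first_ring_year + pos + halfwin)
    if hi - lo < 4:
        return math.inf
    x = np.log(s.widths[lo - s.first_ring_year : hi - s.first_ring_year + 1])
    y = np.log(reference.widths[lo - reference.first_ring_year : hi - reference.first_ring_year + 1])
    d = x - y
    if mask_pos:
        slot = s.first_ring_year + pos - lo
        if 0 <= slot < d.size:
            d = np.delete(d, slot)
    d = d - d.mean()
    return float(d @ d) / d.size


# ---------------------------------------------------------------------------
# candidate regions
# ---------------------------------------------------------------------------

def _candidate_regions(
    ref_t: TransformedSeries,
    working: RingSeries,
    window: int,
    lag_range: int,
    max_events: int,
) -> tuple[list[list[int]], bool]:
    """Candidate ring-position regions from the windowed best-lag profile.

    Returns ``(regions, change_points_found)``.  Each change-point in the
    profile yields one region covering the transition window.  When the
    profile is flat the head and tail window regions are returned instead (a
    slip inside the outermost windows never dominates any window).
    """
    wt = bp_transform(working)
    lo = max(wt.first_year, ref_t.first_year)
    hi = min(wt.last_year, ref_t.last_year)
    length = hi - lo + 1
    n = working.n
    if length < window + 2:
        return [list(range(n))], False

    lags = []
    for p0 in range(length - window + 1):
        best_lag, best_r = 0, -math.inf
        seg_lo = lo + p0
        y = ref_t.values[seg_lo - ref_t.first_year : seg_lo - ref_t.first_year + window]
        for lag in range(-lag_range, lag_range + 1):
            a0 = seg_lo + lag - wt.first_year
            if a0 < 0 or a0 + window > wt.n:
                continue
            x = wt.values[a0 : a0 + window]
            try:
                r = _pearson(x, y)
            except UndefinedStatisticError:
                continue
            if r > best_r:
                best_r, best_lag = r, lag
        lags.append(best_lag)

    change_points = [p for p in range(1, len(lags)) if lags[p] != lags[p - 1]]
    if not change_points:
        head = list(range(0, min(window, n)))
        tail = list(range(max(0, n - window), n))
        return [head, tail], False
    if len(change_points) > max_events:
        warnings.warn(
            f"{len(change_points)} lag change-points found but max_events="
            f"{max_events}; the returned events may be a partial result",
            stacklevel=3,
        )
    # merge runs of consecutive change-points (one slip moves the profile
    # once, but noise can split the transition)
    groups: list[list[int]] = []
    for cp in change_points:
        if groups and cp - groups[-1][-1] <= window // 2:
            groups[-1].append(cp)
        else:
            groups.append([cp])
    regions: list[list[int]] = []
    for g in groups:
        y0 = lo + g[0] - 3          # transition lies inside [cp, cp + window)
        y1 = lo + g[-1] + window + 3
        p0 = max(0, y0 - working.first_ring_year)
        p1 = min(n - 1, y1 - working.first_ring_year)
        regions.append(list(range(p0, p1 + 1)))
    return regions, True


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def localize_edits(
    reference: RingSeries,
    suspect: RingSeries,
    max_events: int = 3,
    window: int = 30,
    lag_range: int = 3,
    min_delta_t: float = 0.5,
    rel_delta: float = 0.08,
) -> list[EditEvent]:
    """Locate up to ``max_events`` single-ring deletions/duplications in
    ``suspect`` relative to ``reference``.

    Both series must be at least three windows long and their stated end
    years within ``max_events`` rings of each other.  Returned events are
    sorted by year and, applied in that order by :func:`apply_edits`, yield
    a whole-series t at least as high as the unedited alignment's.
    """
    if reference.n < 3 * window or suspect.n < 3 * window:
        raise ValueError("series must be at least three windows long")
    overlap = (
        min(reference.last_ring_year, suspect.last_ring_year)
        - max(reference.first_ring_year, suspect.first_ring_year)
        + 1
    )
    if overlap < 3 * window:
        raise ValueError(
            "reference and suspect overlap by fewer than three windows at their "
            "stated dates; crossdate them first (dating errors beyond "
            "max_events rings are out of scope here)"
        )
    ref_t = bp_transform(reference)
    shifts = range(-max_events, max_events + 1)
    base_t, base_shift = _best_alignment(ref_t, suspect, shifts)
    if not math.isfinite(base_t):
        raise SeriesValidationError("no alignment with a finite t was found")
    working = _redate(suspect, suspect.last_ring_year + base_shift)
    cur_t = base_t

    def _apply_single(s: RingSeries, kind: str, pos: int) -> RingSeries:
        if kind == "doubled_in_b":
            return _merge_rings(s, pos)
        return _insert_predicted(s, pos, reference)

    events: list[EditEvent] = []
    while len(events) < max_events:
        regions, _ = _candidate_regions(ref_t, working, window, lag_range, max_events)
        rank_cache: dict[tuple[str, int], tuple[float, int]] = {}

        def _rank(kind: str, pos: int) -> tuple[float, int]:
            key = (kind, pos)
            if key not in rank_cache:
                edited = _apply_single(working, kind, pos)
                rank_cache[key] = _best_alignment(ref_t, edited, shifts)
            return rank_cache[key]

        cands = sorted({p for reg in regions for p in reg})
        best = None
        for pos in cands:
            for kind in ("doubled_in_b", "missing_in_b"):
                if kind == "doubled_in_b" and pos > working.n - 2:
                    continue
                score = _rank(kind, pos)[0]
                if best is None or score > best[0]:
                    best = (score, kind, pos)

        accepted = None
        if best is not None and best[0] - cur_t >= max(min_delta_t, rel_delta * abs(cur_t)):
            _, kind, pos = best
            # Neighbouring edit positions often score within the t noise
            # band; refine within that plateau by the local residual.
            hi_pos = working.n - 2 if kind == "doubled_in_b" else working.n - 1
            lo_p, hi_p = _plateau(
                lambda p: _rank(kind, p)[0], pos, best[0], 0, hi_pos
            )
            sses = {
                p: _local_sse(reference, _apply_single(working, kind, p), _rank(kind, p)[1], p)
                for p in range(lo_p, hi_p + 1)
            }
            pos = min(sses, key=sses.get)
            near = [p for p, v in sses.items() if v <= 2.0 * sses[pos]]
            unc = min(3, max(abs(p - pos) for p in near))
            t_new, sh = _rank(kind, pos)
            edited = _apply_single(working, kind, pos)
            working = _redate(edited, edited.last_ring_year + sh)
            events.append(
                EditEvent(
                    kind=kind,
                    year_estimate=int(working.first_ring_year + pos),
                    year_uncertainty=unc,
                    delta_t=float(t_new - cur_t),
                )
            )
            accepted = t_new

        if accepted is None and len(regions) >= 2 and max_events - len(events) >= 2:
            # Two compensating errors (missing + doubled) with a short middle
            # segment: no single re-dated edit improves t, so search
            # opposite-kind pairs across consecutive change-point regions.
            pair = _joint_pair_search(
                ref_t, working, regions, shifts, _apply_single, reference
            )
            if pair is not None:
                t_new, sh, (k_lo, p_lo), (k_hi, p_hi_final), edited, uncs = pair
                if t_new - cur_t >= max(2 * min_delta_t, rel_delta * abs(cur_t)):
                    working = _redate(edited, edited.last_ring_year + sh)
                    gain = float(t_new - cur_t)
                    for kind, pos, unc in (
                        (k_lo, p_lo, uncs[0]),
                        (k_hi, p_hi_final, uncs[1]),
                    ):
                        events.append(
                            EditEvent(
                                kind=kind,
                                year_estimate=int(working.first_ring_year + pos),
                                year_uncertainty=unc,
                                delta_t=gain / 2.0,
                            )
                        )
                    accepted = t_new

        if accepted is None:
            break
        cur_t = accepted

    events.sort(key=lambda e: e.year_estimate)
    if events:
        # Events found early in the greedy loop were positioned while later
        # errors still misaligned part of the series; re-score the years
        # jointly in the final, fully corrected frame.
        events = _refine_years(reference, ref_t, suspect, events, shifts)
    return events


def _replay(suspect: RingSeries, reference: RingSeries, planned) -> RingSeries | None:
    """Apply (kind, year) trial corrections to the original suspect, oldest
    first, with years in the corrected calendar (as :func:`apply_edits`)."""
    s = suspect
    for kind, year in sorted(planned, key=lambda e: e[1]):
        pos = year - s.first_ring_year
        if kind == "doubled_in_b":
            if not 0 <= pos <= s.n - 2:
                return None
            s = _merge_rings(s, pos)
        else:
            if not 0 <= pos <= s.n - 1:
                return None
            s = _insert_predicted(s, pos, reference)
    return s


def _refine_years(reference, ref_t, suspect, events, shifts, halfspan=4):
    """Joint re-scoring of all event years in the final corrected frame.

    Every combination of per-event year offsets within ±``halfspan`` is
    replayed from the original suspect and scored by whole-series t; within
    the t plateau the combination minimizing the summed local residuals
    (inserted slots masked) wins.
    """
    import itertools

    scored: dict[tuple[int, ...], tuple[float, tuple[float, ...]]] = {}
    for deltas in itertools.product(range(-halfspan, halfspan + 1), repeat=len(events)):
        plan = [(e.kind, e.year_estimate + d) for e, d in zip(events, deltas)]
        years = [y for _, y in plan]
        if len(set(years)) < len(years):
            continue
        s = _replay(suspect, reference, plan)
        if s is None:
            continue
        t, sh = _best_alignment(ref_t, s, shifts)
        if not math.isfinite(t):
            continue
        sses = tuple(
            _local_sse(
                reference, s, sh, y - s.first_ring_year,
                mask_pos=(k == "missing_in_b"),
            )
            for k, y in plan
        )
        scored[deltas] = (t, sses)
    if not scored:
        return sorted(events, key=lambda e: e.year_estimate)

    t_max = max(v[0] for v in scored.values())
    eps = max(0.25, 0.01 * abs(t_max))
    near_t = {d: v for d, v in scored.items() if v[0] >= t_max - eps}
    best = min(near_t, key=lambda d: sum(near_t[d][1]))
    best_sses = near_t[best][1]

    refined = []
    for i, ev in enumerate(events):
        # coordinate-wise ambiguity: offsets along axis i (others at optimum)
        # whose residual stays within a factor two of the best
        near = [
            d[i]
            for d, v in near_t.items()
            if all(d[j] == best[j] for j in range(len(events)) if j != i)
            and v[1][i] <= 2.0 * max(best_sses[i], 1e-12)
        ]
        unc = min(3, max((abs(d - best[i]) for d in near), default=0))
        refined.append(
            replace(ev, year_estimate=ev.year_estimate + best[i], year_uncertainty=unc)
        )
    refined.sort(key=lambda e: e.year_estimate)
    return refined


def _joint_pair_search(ref_t, working, regions, shifts, apply_single, reference):
    """Best opposite-kind edit pair across two candidate regions.

    Returns ``(t, shift, (kind_lo, pos_lo), (kind_hi, pos_hi_final), edited,
    (amb_lo, amb_hi))`` or None.  The higher-position edit is applied first so
    the lower position is unaffected; the higher position is then shifted by
    the lower edit's length change.
    """

    def _trial(k_lo, p_lo, k_hi, p_hi):
        if k_hi == "doubled_in_b" and p_hi > working.n - 2:
            return None
        e1 = apply_single(working, k_hi, p_hi)
        if k_lo == "doubled_in_b" and p_lo > e1.n - 2:
            return None
        e2 = apply_single(e1, k_lo, p_lo)
        p_hi_final = p_hi + (1 if k_lo == "missing_in_b" else -1)
        score = _best_alignment(ref_t, e2, shifts)[0]
        return score, p_hi_final, e2

    best = None
    cache: dict[tuple, tuple | None] = {}

    def _cached(k_lo, p_lo, k_hi, p_hi):
        key = (k_lo, p_lo, k_hi, p_hi)
        if key not in cache:
            cache[key] = _trial(k_lo, p_lo, k_hi, p_hi)
        return cache[key]

    for i in range(len(regions) - 1):
        lo_reg, hi_reg = regions[i], regions[i + 1]
        for k_lo, k_hi in (
            ("missing_in_b", "doubled_in_b"),
            ("doubled_in_b", "missing_in_b"),
        ):
            for p_lo in lo_reg:
                for p_hi in hi_reg:
                    if p_hi <= p_lo + 1:
                        continue
                    res = _cached(k_lo, p_lo, k_hi, p_hi)
                    if res is None:
                        continue
                    score, p_hi_final, e2 = res
                    if best is None or score > best[0]:
                        best = (score, k_lo, p_lo, k_hi, p_hi, p_hi_final, e2)
    if best is None:
        return None
    score, k_lo, p_lo, k_hi, p_hi, p_hi_final, e2 = best

    # refine each coordinate on its score plateau (the other held fixed)
    # by the local residual around the edit
    def _score_lo(p: int) -> float:
        res = _cached(k_lo, p, k_hi, p_hi)
        return res[0] if res is not None else -math.inf

    def _score_hi(p: int) -> float:
        res = _cached(k_lo, p_lo, k_hi, p)
        return res[0] if res is not None else -math.inf

    def _refine(score_fn, pos, lo_bound, hi_bound, sse_fn):
        lo_p, hi_p = _plateau(score_fn, pos, score, lo_bound, hi_bound)
        sses = {p: sse_fn(p) for p in range(lo_p, hi_p + 1)}
        p_best = min(sses, key=sses.get)
        near = [p for p, v in sses.items() if v <= 2.0 * sses[p_best]]
        return p_best, min(3, max(abs(p - p_best) for p in near))

    def _sse_lo(p: int) -> float:
        res = _cached(k_lo, p, k_hi, p_hi)
        if res is None:
            return math.inf
        _, _, e = res
        sh = _best_alignment(ref_t, e, shifts)[1]
        return _local_sse(reference, e, sh, p)

    def _sse_hi(p: int) -> float:
        res = _cached(k_lo, p_lo, k_hi, p)
        if res is None:
            return math.inf
        _, p_f, e = res
        sh = _best_alignment(ref_t, e, shifts)[1]
        return _local_sse(reference, e, sh, p_f)

    p_lo, unc_lo = _refine(_score_lo, p_lo, 0, p_hi - 2, _sse_lo)
    p_hi, unc_hi = _refine(_score_hi, p_hi, p_lo + 2, working.n - 1, _sse_hi)
    res = _cached(k_lo, p_lo, k_hi, p_hi)
    if res is None:
        return None
    score, p_hi_final, e2 = res
    t, sh = _best_alignment(ref_t, e2, shifts)
    return t, sh, (k_lo, p_lo), (k_hi, p_hi_final), e2, (unc_lo, unc_hi)


def apply_edits(series: RingSeries, events: list[EditEvent]) -> RingSeries:
    """Correct ``series`` according to ``events``.

    A duplication is corrected by summing the two implicated widths into one
    ring (the exact inverse of a split); a missing ring is corrected by
    inserting a placeholder with the local 5-ring median width, flagged in
    ``reconstructed_years``.  Event years are interpreted in the corrected
    calendar, which assumes the series is correctly dated at its first ring;
    events are applied oldest first.
    """
    s = series
    for ev in sorted(events, key=lambda e: e.year_estimate):
        pos = ev.year_estimate - s.first_ring_year
        if ev.kind == "doubled_in_b":
            if not 0 <= pos <= s.n - 2:
                raise SeriesValidationError(
                    f"doubled-ring event at {ev.year_estimate} outside the series"
                )
            s = _merge_rings(s, pos)
        else:
            if not 0 <= pos <= s.n - 1:
                raise SeriesValidationError(
                    f"missing-ring event at {ev.year_estimate} outside the series"
                )
            s = _insert_median(s, pos, ev.year_estimate)
    return s
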
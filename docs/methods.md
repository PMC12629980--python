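# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `dendrodate`, in the order the analyses use them.

## Ring-width series and file formats

A series is a strictly positive vector of annual ring widths (mm) anchored
by the calendar year of its outermost ring; the first year is derived
(`last − n + 1`, inclusive).  Calendars are plain CE integers — all
material this package targets grew in the 2nd millennium CE, so no
year-zero or astronomical-year handling exists.  Width 0, sometimes used
in archives to mark a locally absent ring, is rejected rather than
imputed: the crossdating statistics and the error-localization model both
assume complete measured sequences, and an imputed ring would silently
bias them.

Tucson RWL files are decoded by decade rows with continuity checking; the
end-of-series sentinel doubles as the unit flag (999 → 0.01 mm,
−9999 → 0.001 mm; 999 is ordinary data in 0.001 mm files).  A file whose
series lacks a sentinel is ambiguous and the reader demands an explicit
`unit=` argument rather than guessing.  Heidelberg FH files use the
keyword header (`DateEnd`, `Length`, `Unit`, `SapWoodRings`).  Writing
quantizes to the storage unit, so write-then-read is exact at source
precision; a width ≥ 9.99 mm cannot be stored in the 0.01 mm dialect
(it would collide with the sentinel) and raises instead of clipping.

## Normalization

Crossdating statistics are computed on Baillie–Pilcher log-ratio indices:
`x_i = ln(w_i / mean(w_{i-2..i+2}))`.  The two boundary years at each end
are dropped rather than computed with a shrunken window, so every index is
a true centered 5-year ratio; a series of `n` rings yields `n − 4`
indices.  The transform is invariant under multiplicative rescaling of the
widths, which is what makes series measured in different units or with
different calibration comparable.  The index anchors carry calendar years
(`first + 2`), and all overlap arithmetic downstream is done in calendar
space, never by array position.

The %PV ingredient is the ternary sign of each first difference;
`sign(0) = 0` is kept as a tie and resolved only in the scoring rule.

## Crossdating statistics

At a candidate alignment, `r` is the Pearson correlation of the
overlapping transformed values and `t = r·√(n−2)/√(1−r²)` with `n` the
*transformed* overlap.  The raw ring overlap (Ol) is reported separately;
the two differ by 4 when one series nests inside the other, and carrying
both avoids a classic off-by-four confusion when comparing printed
overlaps.  When `r` is numerically 1 (self-match, duplicate detection) the
formula diverges; `t` is reported as the fixed cap 9999 so the ranking
stays total.

%PV scores each overlapping interval `|s_a + s_b| / 2`: 1 for the same
non-zero direction, 0 for opposite directions, ½ when exactly one series
has a tie, and 0 when both do (no shared movement is no evidence of
agreement).  Significance is the one-sided normal approximation of the
binomial: mean ½, sd `1/(2√n)`, with ties contributing to the score but
not reducing `n` — the classic treatment.  Classes are marked `#`, `##`,
`###` for p < 0.05, 0.01, 0.001.

Match classification uses the field's conventional thresholds, shipped as
a `MatchPolicy`: *potential* at t ≥ 3.5 over ≥ 100 rings; *accepted* at
t ≥ 5 with %PV > 63 at p < 0.05.  The same-tree criterion (t ≥ 10 and %PV
significant at p < 0.001) is a configuration default, not a published
constant: the literature gives no numeric same-tree rule, and the
threshold sits far above what distinct trees sharing a regional signal
reach (t ≈ 5–7 at these overlaps) yet far below same-tree pairs
(t ≳ 30).  `assess_same_tree` accepts a disregard window — an inclusive
span of calendar years excluded from both statistics — for the situation
where part of one series is known to be corrupt.

The offset scan visits every end year with at least `min_overlap_scan`
(default 50) raw rings of overlap and sorts by t, then %PV, then overlap,
then earlier end year: a deterministic total order.

## Error localization

The model is a single-ring slip: a deletion shifts every later ring one
year early; a duplication shifts them one year late.  Two compensating
slips leave the ring count unchanged — the hardest, and historically the
most deceptive, configuration.

The search works on a trusted reference and a suspect sharing at least
three analysis windows of overlap at their stated dates:

1. **Candidate regions.**  A windowed best-lag profile (30-ring windows,
   lags ±3 by default) on the transformed values; change-points in the
   profile delimit the regions where a slip can sit.  A slip inside the
   outermost or innermost window never dominates any window, so a flat
   profile falls back to scanning the head and tail window regions.
   Runs of change-points closer than half a window are merged (noise can
   split one transition).
2. **Greedy single corrections.**  Within the candidate regions every
   single correction is trialled: merging an adjacent ring pair
   (duplication hypothesis — the exact inverse of a ring measured twice)
   or inserting a ring (missing hypothesis).  Each trial is scored by the
   whole-series t at its best end-year shift within ±`max_events`;
   re-dating the trial is essential, because with two compensating errors
   no single edit improves the fixed-alignment t.  For search purposes the
   inserted ring's width is predicted from the reference at the same
   calendar label, rescaled by the ratio of local median widths: a
   near-true trial width makes the correct insertion position score
   distinctly better than its neighbours.  The published correction
   (`apply_edits`) instead inserts a local 5-ring median and flags the
   ring as reconstructed, so no reference widths leak into corrected data.
3. **Acceptance threshold.**  An edit is kept only if it improves t by
   `max(0.5, 0.08·|t|)`.  The relative term matters: at the high t of a
   same-tree pair, removing a chance outlier near a series end can raise t
   by a unit or two, so a purely absolute threshold cannot control the
   false-event rate on clean pairs.
4. **Joint pair fallback.**  When the best single edit fails the threshold
   but the lag profile shows two change-point regions, opposite-kind pairs
   (one insertion, one merge) are searched across the two regions jointly.
   This handles the geometry in which the segment between two compensating
   errors is shorter than both outer segments — there, any single edit
   *reduces* the aligned mass and a greedy monotone search necessarily
   stalls.  The pair's t gain is attributed half to each event.
5. **Final joint refinement.**  Events found early were positioned while
   later errors still misaligned part of the series, so all event years
   are re-scored jointly in the final frame: every combination of per-event
   offsets within ±4 is replayed from the original suspect; within the t
   plateau (t within `max(0.25, 1%)` of the best) the combination with the
   smallest local log-width residual wins.  The residual around an edit is
   computed over ±6 rings, mean-adjusted, and for insertions the inserted
   slot itself is masked: a placeholder's built-in fit to the reference is
   construction, not evidence.

Position ambiguity is intrinsic, not algorithmic: over a patch of
near-equal ring widths, neighbouring edit positions produce statistically
indistinguishable corrections (and with two identical half-rings, deciding
*which* was the duplicate is impossible in principle).  The reported
`year_uncertainty` is the spread of positions whose residual stays within
a factor two of the best; it is reported, never silently resolved.
Localization degrades gracefully at the extreme ends: a slip in the last
~5 rings moves too few transformed values to clear the acceptance
threshold and is left unreported rather than guessed.

`apply_edits` interprets event years in the corrected calendar, applies
them oldest-first (merge the rings at labels Y and Y+1; insert before
label Y), and assumes the series is correctly dated at its first ring.
Summation-merge is the exact inverse of the generator's split-in-half
duplication, by design.

## Sapwood dating

Shipped statistics: Polish oak, 9–24 sapwood rings, median 15, at 90%
confidence; other regions are config-loadable, not shipped, and no sapwood
distributions are re-fitted from data.  The arithmetic is pure integer
bookkeeping:

- border ring dated Y → felling in [Y+9, Y+24], median Y+15;
- heartwood only → terminus post quem Y+9 (upper bound open);
- k surviving sapwood rings → [max(Y+1, Y−k+9), Y−k+24]: the lower clamp
  encodes that a tree cannot be felled before its last existing ring (a
  conservative generalization; the shipped statistics never trigger it for
  k ≤ 8);
- bark edge → felling = Y exactly.

Whether the quoted 90% attaches to the whole interval or to each tail is
not resolvable from the sources; the confidence is carried through
verbatim, never reinterpreted.  Seasoning allowances are closed ranges
added to felling bounds: the fixed 2-year preset used in 1990s reports and
the modern 2-to-5-year preset.  For a felling interval [L, U] the earliest
possible production window is [L+s_min, L+s_max] and the likely window
[L+s_min, U+s_max]; a terminus post quem stays open-ended.

## Synthetic data

The generator produces, deterministically under a seed (independent
`SeedSequence` streams per component, stable across platforms):

- a **master** signal: stationary unit-variance AR(1), default
  `phi = 0.3` — the modest ring-to-ring persistence typical of oak ring
  series — over 1100–1650 CE (551 years, covering the study period);
- **trees**: log ring width = age trend plus
  `master_sd · (√s · master + √(1−s) · tree-noise)` with
  `master_sd = 0.25` (a realistic interannual variation of ~25%) and
  tree-signal share `s = 0.45`, which yields sample-versus-master
  correlations of about 0.6–0.7 on transformed values — the regime in
  which crossdating is expected to work, and the stated study condition.
  The age trend is negative-exponential from 2.5 mm (juvenile) to a 1.0 mm
  asymptote at 0.02/yr;
- **boards**: tree widths plus independent N(0, 0.05 mm) measurement
  noise (bounded resampling keeps widths positive), a sapwood count drawn
  uniformly over the regional 9–24 range (only the range and median are
  quoted in the sources, so no distribution shape is assumed), or fixed
  per board spec;
- **injected errors**: a missing ring removes one ring and lowers the end
  year by one; a doubled ring splits one ring into two half-width rings
  and raises it by one.  The split conserves total width so the
  summation-merge correction is its exact inverse.

`study_scenario()` mirrors the study's panel structure (210 rings ending
1606 at the border and 231 rings with 8 sapwood ending 1614 from one tree;
99 rings ending 1601 from another).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: real masters are replicated means with
time-varying depth, not single AR(1) paths; real trees have
frequency-dependent coherence, growth releases and suppressions, and
occasionally genuinely absent rings; measurement error in historical
hand-lens series is not white (systematic rounding to 0.1 mm, drift);
and provenance structure (a network of regional chronologies) is absent
entirely, so provenance inference is out of scope.

In the recovery benchmarks, injected error positions are drawn at least
10 rings from either series end (and ≥ 20 rings apart): the generator
targets the pattern-comparison problem, and an error in the outermost
rings changes the ring count at the end, which in practice is caught by
ring counting rather than statistical alignment.

## Numerical and testing choices

- Pearson correlations are computed from centered dot products; zero
  variance in an overlap raises an explicit undefined-statistic error
  rather than returning NaN.
- %PV p-values are floored at 1e-300 to keep them in (0, 1].
- Monte-Carlo suite sizes: 200 scenarios for crossdating recovery, 1000
  pairs for null calibration, 200 pairs for error-localization recovery —
  large enough for the claimed rates (95%, 1%, 90%) to be meaningfully
  testable, small enough that the full test suite runs in about two
  minutes on one CPU.  Property tests (hypothesis) run derandomized.
- The acceptance script (`scripts/acceptance.py`) involves no randomness:
  the dating arithmetic is exact; its `--seed` argument exists for
  interface uniformity.

## Known limitations

- Only single-ring slips are modelled; multi-ring blocks of missing or
  invented rings are out of scope (`max_events` bounds the count, not the
  block width).
- Error localization requires a trusted single reference series; checking
  a series against a mean chronology dilutes single-ring evidence and is
  deliberately unsupported.
- Chronology *building* (averaging many trees into a master) is out of
  scope; chronologies are consumed as dated references.
- The same-tree verdict is statistical; in practice it should be (and in
  the field always is) confirmed by visual inspection of the ring
  patterns, which no threshold replaces.
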
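"""Seeded synthetic tree-ring data with the structure the analyses assume.

The museum series this package was written around are request-only, so every
analysis is exercised on synthetic material instead.  The generator emulates
the features the statistics rely on:

* a multi-century **master signal** with AR(1) persistence (the regional
  climate-driven growth signal);
* **trees** whose log ring-width mixes the master signal with tree-level
  AR(1) noise (``tree_signal_share`` sets the variance fraction coming from
  the master, hence the expected inter-tree correlation) on top of a
  negative-exponential age trend;
* **boards** cut from a tree, i.e. the tree's widths plus small independent
  measurement noise, with a sapwood ring count drawn from regional
  statistics, optionally flagged as ending at the heartwood/sapwood border;
* injected single-ring **measurement errors**: a deleted (missing) ring or a
  ring split in two (measured twice).

All noise is multiplicative (log-space) so widths stay positive and the
log-ratio crossdating transform is the natural analysis scale.  Everything
is deterministic under ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .sapwood_dating import POLAND_WAZNY, SapwoodStats
from .series_io import Chronology, RingSeries, SeriesValidationError

__all__ = [
    "BoardSpec",
    "SyntheticScenario",
    "generate_master",
    "generate_boards",
    "inject_errors",
    "study_scenario",
    "scenario_from_dict",
]


@dataclass(frozen=True)
class BoardSpec:
    """Explicit description of one board to cut from a synthetic tree."""

    tree: int
    n_rings: int
    end_year: int
    board_id: str | None = None
    n_sapwood: int | None = None        # None: draw from the sapwood statistics
    hw_sw_border_is_last_ring: bool = False
    events: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults emulate the southern-Baltic oak panel setting: a 551-year
    master (1100-1650 CE), moderate ring-to-ring persistence (phi = 0.3),
    a log-scale index standard deviation of 0.25, a master variance share
    of 0.45 (sample-versus-master correlation of roughly 0.6-0.7 on
    transformed values), a juvenile-to-mature width trend from 2.5 mm down
    to 1.0 mm, 0.05 mm measurement noise, and Polish sapwood counts.
    """

    seed: int = 0
    master_span: tuple[int, int] = (1100, 1650)
    ar1_phi: float = 0.3
    master_sd: float = 0.25
    tree_signal_share: float = 0.45
    trend: tuple[float, float, float] = (2.5, 0.02, 1.0)  # initial mm, decay /yr, asymptote mm
    measurement_sd: float = 0.05
    n_trees: int = 2
    boards_per_tree: int = 1
    board_length: int = 210
    sapwood_stats: SapwoodStats = POLAND_WAZNY
    injected_events: tuple = ()   # (kind, year) for board 0, or (kind, year, board_index)
    board_specs: tuple[BoardSpec, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in [0, 1)")
        if not 0.0 <= self.tree_signal_share <= 1.0:
            raise ValueError("tree_signal_share must lie in [0, 1]")
        if self.master_span[1] - self.master_span[0] + 1 < 100:
            raise ValueError("the master span must cover at least 100 years")


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary, unit-marginal-variance AR(1) path of length ``n``."""
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]
    scale = math.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + scale * e[t]
    return x


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _master_signal(scenario: SyntheticScenario) -> np.ndarray:
    n = scenario.master_span[1] - scenario.master_span[0] + 1
    return _ar1(_rng(scenario.seed, 11), n, scenario.ar1_phi)


def generate_master(scenario: SyntheticScenario) -> Chronology:
    """The scenario's master chronology: ``exp(master_sd * AR(1))`` stored as
    a dimensionless width index around 1.  Deterministic under the seed and
    identical to the master used by :func:`generate_boards`."""
    x = _master_signal(scenario)
    return Chronology(
        series_id="MASTER",
        widths=np.exp(scenario.master_sd * x),
        last_ring_year=scenario.master_span[1],
        region="synthetic",
    )


def _default_specs(scenario: SyntheticScenario) -> tuple[BoardSpec, ...]:
    lo, hi = scenario.master_span
    rng = _rng(scenario.seed, 17)
    specs = []
    for tree in range(scenario.n_trees):
        n_rings = scenario.board_length
        end = int(rng.integers(lo + n_rings - 1, hi + 1))
        for b in range(scenario.boards_per_tree):
            specs.append(
                BoardSpec(
                    tree=tree,
                    n_rings=n_rings,
                    end_year=end,
                    board_id=f"T{tree}B{b}",
                )
            )
    return tuple(specs)


def generate_boards(
    scenario: SyntheticScenario,
) -> tuple[list[RingSeries], dict]:
    """Boards plus a truth record.

    The truth record holds, per board, the true end year (before any injected
    error), the tree id, the heartwood/sapwood border year (when known) and
    the injected events, so recovery tests can score against construction
    truth.
    """
    lo, hi = scenario.master_span
    x = _master_signal(scenario)
    specs = scenario.board_specs or _default_specs(scenario)

    extra: dict[int, list[tuple[str, int]]] = {}
    for ev in scenario.injected_events:
        if len(ev) == 3:
            kind, year, idx = ev
        else:
            kind, year = ev
            idx = 0
        extra.setdefault(int(idx), []).append((str(kind), int(year)))

    # per-tree spans = union of that tree's board spans
    tree_span: dict[int, tuple[int, int]] = {}
    for sp in specs:
        first = sp.end_year - sp.n_rings + 1
        cur = tree_span.get(sp.tree)
        tree_span[sp.tree] = (
            (first, sp.end_year)
            if cur is None
            else (min(cur[0], first), max(cur[1], sp.end_year))
        )

    share = scenario.tree_signal_share
    init, decay, asym = scenario.trend
    tree_widths: dict[int, np.ndarray] = {}
    for tree, (t0, t1) in sorted(tree_span.items()):
        if t0 < lo or t1 > hi:
            raise ValueError(
                f"tree {tree}: span {t0}-{t1} falls outside the master span {lo}-{hi}"
            )
        n = t1 - t0 + 1
        noise = _ar1(_rng(scenario.seed, 23, tree), n, scenario.ar1_phi)
        log_sig = scenario.master_sd * (
            math.sqrt(share) * x[t0 - lo : t1 - lo + 1]
            + math.sqrt(1.0 - share) * noise
        )
        age = np.arange(n, dtype=float)
        trend = asym + (init - asym) * np.exp(-decay * age)
        tree_widths[tree] = trend * np.exp(log_sig)

    boards: list[RingSeries] = []
    truth_boards: list[dict] = []
    for idx, sp in enumerate(specs):
        board_id = sp.board_id or f"T{sp.tree}B{idx}"
        rng_b = _rng(scenario.seed, 29, idx)
        t0 = tree_span[sp.tree][0]
        first = sp.end_year - sp.n_rings + 1
        base = tree_widths[sp.tree][first - t0 : sp.end_year - t0 + 1]
        w = base + rng_b.normal(0.0, scenario.measurement_sd, sp.n_rings)
        for _ in range(100):
            bad = w <= 0
            if not bad.any():
                break
            w[bad] = base[bad] + rng_b.normal(0.0, scenario.measurement_sd, int(bad.sum()))
        else:
            raise SeriesValidationError(
                f"board {board_id!r}: could not draw positive widths"
            )
        if sp.hw_sw_border_is_last_ring:
            n_sap = 0
        elif sp.n_sapwood is not None:
            n_sap = sp.n_sapwood
        else:
            st = scenario.sapwood_stats
            n_sap = int(rng_b.integers(st.sw_min, st.sw_max + 1))
        series = RingSeries(
            series_id=board_id,
            widths=w,
            last_ring_year=sp.end_year,
            n_sapwood=n_sap,
            hw_sw_border_is_last_ring=sp.hw_sw_border_is_last_ring,
        )
        events = tuple(sp.events) + tuple(extra.get(idx, ()))
        if events:
            series = inject_errors(series, events)
        if sp.hw_sw_border_is_last_ring:
            border: int | None = sp.end_year
        elif n_sap > 0:
            border = sp.end_year - n_sap
        else:
            border = None
        boards.append(series)
        truth_boards.append(
            {
                "board_id": board_id,
                "tree": sp.tree,
                "true_end_year": sp.end_year,
                "n_rings": sp.n_rings,
                "n_sapwood": n_sap,
                "hw_sw_border_year": border,
                "events": [list(e) for e in events],
            }
        )
    truth = {
        "seed": scenario.seed,
        "master_span": list(scenario.master_span),
        "boards": truth_boards,
    }
    return boards, truth


_EVENT_KINDS = {"missing": "missing", "doubled": "doubled",
                "missing_in_b": "missing", "doubled_in_b": "doubled"}


def inject_errors(series: RingSeries, events) -> RingSeries:
    """Inject single-ring measurement errors.

    ``events`` is an iterable of ``(kind, year)`` with kind ``"missing"``
    (the ring of that calendar year is dropped; the end year decreases by 1)
    or ``"doubled"`` (the ring is split into two half-width rings, as if
    measured twice; the end year increases by 1).  Years refer to the input
    series' calendar.  Splitting conserves total width, so the sum-merge
    correction applied later is its exact inverse.
    """
    evs = []
    for kind, year in events:
        k = _EVENT_KINDS.get(str(kind))
        if k is None:
            raise ValueError(f"unknown event kind {kind!r}")
        evs.append((k, int(year)))
    years = [y for _, y in evs]
    if len(set(years)) != len(years):
        raise ValueError("overlapping injected events (duplicate years)")
    for _, y in evs:
        if not series.first_ring_year <= y <= series.last_ring_year:
            raise ValueError(f"event year {y} outside the series span")

    w = list(series.widths)
    last = series.last_ring_year
    first = series.first_ring_year
    # descending order: earlier positions are untouched by later-year edits
    for kind, y in sorted(evs, key=lambda e: -e[1]):
        pos = y - first
        if kind == "missing":
            del w[pos]
            last -= 1
        else:
            half = w[pos] / 2.0
            w[pos : pos + 1] = [half, half]
            last += 1
    return replace(series, widths=np.asarray(w), last_ring_year=last)


def study_scenario(seed: int = 0) -> SyntheticScenario:
    """A scenario mirroring the panel structure of the study this package
    re-implements: a 210-ring board ending 1606 at the heartwood/sapwood
    border and a 231-ring board with 8 sapwood rings ending 1614 from one
    tree, plus a 99-ring heartwood board ending 1601 from a second tree,
    under a 1100-1650 master."""
    return SyntheticScenario(
        seed=seed,
        n_trees=2,
        board_specs=(
            BoardSpec(tree=0, n_rings=210, end_year=1606, board_id="GNM",
                      hw_sw_border_is_last_ring=True),
            BoardSpec(tree=0, n_rings=231, end_year=1614, board_id="RM",
                      n_sapwood=8),
            BoardSpec(tree=1, n_rings=99, end_year=1601, board_id="MH",
                      n_sapwood=0),
        ),
    )


def scenario_from_dict(cfg: dict) -> SyntheticScenario:
    """Build a scenario from a plain dict (the YAML schema of the CLI)."""
    cfg = dict(cfg)
    if "sapwood_stats" in cfg and isinstance(cfg["sapwood_stats"], dict):
        cfg["sapwood_stats"] = SapwoodStats(**cfg["sapwood_stats"])
    if "board_specs" in cfg and cfg["board_specs"] is not None:
        cfg["board_specs"] = tuple(
            BoardSpec(**{**sp, "events": tuple(tuple(e) for e in sp.get("events", ()))})
            for sp in cfg["board_specs"]
        )
    for key in ("master_span", "trend"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    if "injected_events" in cfg:
        cfg["injected_events"] = tuple(tuple(e) for e in cfg["injected_events"])
    return SyntheticScenario(**cfg)
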
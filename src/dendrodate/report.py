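"""Dating reports: a structured result object and markdown/JSON renderers.

A dating report never states a bare date: every felling or production
estimate must be accompanied by the crossdating statistics that support the
calendar position (end year, overlap, r, TBP t, %PV with significance
marks), the references used, the sapwood statistics applied and the
software version and seed — so that a reader can assess *how* the date was
obtained and re-run the analysis.  The JSON rendering round-trips
losslessly and carries a schema version.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from . import __version__
from .crossdating import CrossdateResult
from .sapwood_dating import (
    FellingEstimate,
    ProductionEstimate,
    SapwoodStats,
)

__all__ = ["DatingReport", "ReportValidationError", "render_report", "parse_report",
           "format_estimates", "crossdate_table"]

SCHEMA_VERSION = "1"


class ReportValidationError(ValueError):
    """The report violates the reporting standard (e.g. a date without its
    supporting statistics)."""


@dataclass(frozen=True)
class DatingReport:
    """All results backing one dated sample."""

    sample: dict                      # id, n_rings, first/last ring year, sapwood…
    references: tuple[dict, ...]      # {"id": …, "span": …} per reference used
    crossdating: tuple[CrossdateResult, ...]
    felling: FellingEstimate | None = None
    production: ProductionEstimate | None = None
    software_version: str = __version__
    seed: int | None = None
    config: dict = field(default_factory=dict)


def _validate(report: DatingReport) -> None:
    if report.felling is not None and not report.crossdating:
        raise ReportValidationError(
            "a felling estimate without supporting crossdating statistics "
            "violates the reporting standard"
        )
    if report.crossdating and report.felling is None:
        raise ReportValidationError(
            "a crossdating table without a felling estimate is incomplete"
        )
    if report.production is not None and report.felling is None:
        raise ReportValidationError("a production estimate requires a felling estimate")


def crossdate_table(rows) -> str:
    """Markdown table of crossdating results with the conventional columns."""
    lines = [
        "| End year | Ol | r | TBP | %PV | Sig. | Class |",
        "|---:|---:|---:|---:|---:|:---|:---|",
    ]
    for c in rows:
        lines.append(
            f"| {c.proposed_end_year} | {c.overlap} | {c.r:.2f} | {c.t_bp:.2f} "
            f"| {c.glk:.1f} | {c.significance_marks} | {c.match_class} |"
        )
    return "\n".join(lines)


def format_estimates(
    felling: FellingEstimate | None, production: ProductionEstimate | None
) -> str:
    """Human-readable felling/production summary (also used standalone by the
    ``date-report`` command when no crossdating evidence is attached)."""
    out = []
    if felling is not None:
        st = felling.basis
        basis = f"{st.region} {st.sw_min}–{st.sw_max} sapwood rings"
        if felling.kind == "interval":
            out.append(
                f"Estimated felling date: between {felling.lower} and {felling.upper}"
                + (f" (median {felling.median_year})" if felling.median_year else "")
                + f" at {felling.confidence:.0%} confidence ({basis})."
            )
        elif felling.kind == "terminus_post_quem":
            out.append(f"Estimated felling date: after {felling.lower} ({basis}).")
        else:
            out.append(f"Felling date: {felling.lower} (bark edge present).")
    if production is not None:
        lo, hi = production.earliest_window
        out.append(f"Earliest possible production date: between {lo} and {hi}.")
        llo, lhi = production.likely
        if lhi is None:
            out.append(f"Likely production date: after {llo}.")
        else:
            out.append(f"Likely production date: between {llo} and {lhi}.")
    return "\n".join(out)


def render_report(report: DatingReport, format: str = "markdown") -> str:
    """Render a validated report as markdown or JSON."""
    _validate(report)
    if format == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "sample": report.sample,
            "references": [dict(r) for r in report.references],
            "crossdating": [asdict(c) for c in report.crossdating],
            "felling": asdict(report.felling) if report.felling else None,
            "production": asdict(report.production) if report.production else None,
            "software_version": report.software_version,
            "seed": report.seed,
            "config": report.config,
        }
        return json.dumps(payload, indent=2)
    if format == "markdown":
        s = report.sample
        lines = [
            f"# Dating report: {s.get('id', '?')}",
            "",
            f"Software: dendrodate {report.software_version}"
            + (f", seed {report.seed}" if report.seed is not None else ""),
            "",
            f"Sample: {s.get('n_rings', '?')} rings, "
            f"{s.get('first_ring_year', '?')}–{s.get('last_ring_year', '?')} CE, "
            f"{s.get('n_sapwood', 0)} sapwood rings.",
            "",
            "References: " + ", ".join(str(r["id"]) for r in report.references) + ".",
            "",
            "## Crossdating statistics",
            "",
            crossdate_table(report.crossdating),
            "",
            "## Dating estimates",
            "",
            format_estimates(report.felling, report.production),
            "",
        ]
        return "\n".join(lines)
    raise ValueError(f"unknown report format {format!r}")


def parse_report(text: str) -> DatingReport:
    """Parse a JSON rendering back into an equal :class:`DatingReport`."""
    d = json.loads(text)
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ReportValidationError(
            f"unsupported report schema version {d.get('schema_version')!r}"
        )
    felling = None
    if d["felling"] is not None:
        f = dict(d["felling"])
        f["basis"] = SapwoodStats(**f["basis"])
        felling = FellingEstimate(**f)
    production = None
    if d["production"] is not None:
        p = d["production"]
        production = ProductionEstimate(
            earliest_window=tuple(p["earliest_window"]),
            likely=tuple(p["likely"]),
        )
    return DatingReport(
        sample=d["sample"],
        references=tuple(d["references"]),
        crossdating=tuple(CrossdateResult(**c) for c in d["crossdating"]),
        felling=felling,
        production=production,
        software_version=d["software_version"],
        seed=d["seed"],
        config=d["config"],
    )
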
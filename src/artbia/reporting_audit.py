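"""Render the model's result tables and audit them against published cell values.

Rendering reproduces the publication's display conventions: outcome counts to
the nearest 100 with semantic signs (+ for pregnancies gained, - for
reductions), money totals in millions of EUR at a per-magnitude-band precision,
and an em-dash for outcomes with no published evidence.

The audit recomputes every published, non-dash cell from the model and compares
it at the precision the cell was printed at (match iff the absolute difference
is at most half the printed resolution).  Cells the fixture curator marked as
internally inconsistent in the source - the publication contains a handful -
are reported with status ``flagged-inconsistency`` and an explanatory note
rather than silently "corrected".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional

from .config_io import SCENARIOS, DisplayConvention, ModelConfig
from .effects import display_round
from .scenarios import InterventionResult, ScenarioResult

__all__ = [
    "EM_DASH",
    "CellAudit",
    "AuditReport",
    "render_tables",
    "audit_against_printed",
]

EM_DASH = "—"  # the publication's "no published evidence" marker

_T2_SPONT = "spontaneous"


# --------------------------------------------------------------------------
# Rendering


def _fmt_count(value: float, sign: str, display: DisplayConvention) -> str:
    rounded = display_round(value, display.count_resolution)
    return f"{sign}{rounded:,.0f}"


def _fmt_count_pct(
    value: Optional[float], denom: float, sign: str, display: DisplayConvention
) -> str:
    if value is None:
        return EM_DASH
    pct = value / denom * 100.0
    return f"{_fmt_count(value, sign, display)} ({sign}{pct:.1f})"


def _money_decimals(resolution_eur: float) -> int:
    if resolution_eur >= 1e6:
        return 0
    if resolution_eur >= 1e5:
        return 1
    if resolution_eur >= 1e4:
        return 2
    return 3


def _fmt_millions(amount_eur: float, display: DisplayConvention) -> str:
    res = display.money_resolution(amount_eur)
    rounded = display_round(amount_eur, res)
    return f"€{rounded / 1e6:.{_money_decimals(res)}f} M"


def _fmt_money_triple(triple: dict, display: DisplayConvention) -> str:
    c, lo, hi = (triple["central"], triple["least"], triple["most"])
    return (
        f"{_fmt_millions(c, display)} "
        f"({_fmt_millions(lo, display)}, {_fmt_millions(hi, display)})"
    )


def _table2_cells(ir: InterventionResult, modalities: list[str], display) -> dict:
    d = ir.deltas["central"]
    cells = {
        _T2_SPONT: _fmt_count_pct(d.spontaneous_gain, d.denominator_used, "+", display)
    }
    for m in modalities:
        cells[m] = _fmt_count_pct(
            d.cycles_avoided.get(m), d.denominator_used, "-", display
        )
    return cells


def _table3_cells(ir: InterventionResult, complications: list[str], display) -> dict:
    d = ir.deltas["central"]
    cells = {}
    for c in complications:
        if c in d.complications_avoided:
            cells[c] = _fmt_count_pct(
                d.complications_avoided[c],
                d.complication_denominators[c],
                "-",
                display,
            )
        else:
            cells[c] = EM_DASH
    return cells


def _table4_cells(ir: InterventionResult, display) -> dict:
    pcb = ir.cost.per_couple_benefit
    return {
        "per_couple": (
            f"€{pcb['central']:,.0f} "
            f"(€{pcb['least']:,.0f}, €{pcb['most']:,.0f})"
        ),
        "target_group": f"{ir.group_size:,}",
        "total_saving": _fmt_money_triple(ir.cost.total_saving, display),
        "art_only_saving": _fmt_money_triple(ir.cost.art_only_saving, display),
    }


def _complication_order(results: ScenarioResult) -> list[str]:
    seen: list[str] = []
    for ir in results.interventions.values():
        for c in ir.deltas["central"].complications_avoided:
            if c not in seen:
                seen.append(c)
    return seen


def _as_csv(header: list[str], rows: list[list[str]]) -> str:
    import csv
    import io

    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(header)
    w.writerows(rows)
    return buf.getvalue()


def _as_markdown(header: list[str], rows: list[list[str]]) -> str:
    lines = [
        "| " + " | ".join(header) + " |",
        "| " + " | ".join("---" for _ in header) + " |",
    ]
    lines += ["| " + " | ".join(r) + " |" for r in rows]
    return "\n".join(lines) + "\n"


def render_tables(
    results: ScenarioResult,
    display: Optional[DisplayConvention] = None,
    format: Literal["csv", "markdown", "json"] = "markdown",
) -> dict[str, str]:
    """Render the clinical-outcome and cost-saving tables as text documents.

    Returns a mapping ``{"table2", "table3", "table4"} -> document``.
    Deterministic and locale-independent (fixed separators, ASCII minus).
    """
    if format not in ("csv", "markdown", "json"):
        raise ValueError(f"unknown format: {format!r}")
    display = display or DisplayConvention()
    modalities = list(results.baseline.cycles_per_modality)
    complications = _complication_order(results)

    tables: dict[str, tuple[list[str], dict[str, dict[str, str]]]] = {
        "table2": (
            ["intervention", _T2_SPONT, *modalities],
            {
                iid: _table2_cells(ir, modalities, display)
                for iid, ir in results.interventions.items()
            },
        ),
        "table3": (
            ["intervention", *complications],
            {
                iid: _table3_cells(ir, complications, display)
                for iid, ir in results.interventions.items()
            },
        ),
        "table4": (
            [
                "intervention",
                "per_couple",
                "target_group",
                "total_saving",
                "art_only_saving",
            ],
            {
                iid: _table4_cells(ir, display)
                for iid, ir in results.interventions.items()
            },
        ),
    }

    out: dict[str, str] = {}
    for name, (header, by_row) in tables.items():
        if format == "json":
            out[name] = json.dumps(by_row, indent=2, ensure_ascii=False) + "\n"
            continue
        rows = [[iid, *(cells[col] for col in header[1:])] for iid, cells in by_row.items()]
        out[name] = (
            _as_csv(header, rows) if format == "csv" else _as_markdown(header, rows)
        )
    return out


# --------------------------------------------------------------------------
# Audit

Status = Literal["match", "mismatch", "flagged-inconsistency", "not-recomputable"]


@dataclass(frozen=True)
class CellAudit:
    """One published cell versus its recomputed value."""

    table: str
    row: str
    column: str
    printed: object
    recomputed: object
    resolution: object
    status: Status
    note: str = ""


@dataclass(frozen=True)
class AuditReport:
    records: list[CellAudit] = field(default_factory=list)

    def by_status(self, status: Status) -> list[CellAudit]:
        return [r for r in self.records if r.status == status]

    @property
    def n_match(self) -> int:
        return len(self.by_status("match"))

    @property
    def n_flagged(self) -> int:
        return len(self.by_status("flagged-inconsistency"))

    @property
    def unexplained_mismatches(self) -> list[CellAudit]:
        return self.by_status("mismatch")

    @property
    def ok(self) -> bool:
        """True when every published cell is matched, flagged, or non-recomputable."""
        return not self.unexplained_mismatches

    def to_dict(self) -> dict:
        return {
            "summary": {
                "match": self.n_match,
                "flagged_inconsistency": self.n_flagged,
                "mismatch": len(self.unexplained_mismatches),
                "not_recomputable": len(self.by_status("not-recomputable")),
            },
            "records": [
                {
                    "table": r.table,
                    "row": r.row,
                    "column": r.column,
                    "printed": r.printed,
                    "recomputed": r.recomputed,
                    "resolution": r.resolution,
                    "status": r.status,
                    "note": r.note,
                }
                for r in self.records
            ],
        }


def _close(printed: float, recomputed: Optional[float], resolution: float) -> bool:
    if recomputed is None:
        return False
    # half the printed grain, with a relative guard for float round-off
    tol = 0.5 * resolution * (1.0 + 1e-9) + 1e-9
    return abs(printed - recomputed) <= tol


_PCT_RESOLUTION = 0.1  # published percentages carry one decimal


def _status(comparison_ok: bool, anomaly_note: Optional[str]) -> tuple[Status, str]:
    if anomaly_note is not None:
        return "flagged-inconsistency", anomaly_note
    return ("match", "") if comparison_ok else ("mismatch", "")


def audit_against_printed(
    results: ScenarioResult, fixture: ModelConfig
) -> AuditReport:
    """Compare recomputed central-scenario values against every published cell.

    Every non-dash cell of the published tables appears exactly once.  A cell
    matches when the recomputed value is within half the printed resolution;
    cells carried in the fixture's anomaly list are flagged with their note.
    """
    printed = fixture.printed
    if printed is None:
        raise ValueError("fixture carries no printed table block to audit against")
    count_res = fixture.display.count_resolution
    anomalies = {(a.table, a.row, a.column): a.note for a in printed.anomalies}
    records: list[CellAudit] = []

    def count_pct_record(
        table: str,
        iid: str,
        col: str,
        cell,
        rec_count: Optional[float],
        denom: Optional[float],
    ) -> None:
        rec_pct = (
            rec_count / denom * 100.0
            if (rec_count is not None and denom)
            else None
        )
        ok = _close(cell.count, rec_count, count_res) and _close(
            cell.pct, rec_pct, _PCT_RESOLUTION
        )
        status, note = _status(ok, anomalies.get((table, iid, col)))
        records.append(
            CellAudit(
                table=table,
                row=iid,
                column=col,
                printed=(cell.count, cell.pct),
                recomputed=(rec_count, rec_pct),
                resolution=(count_res, _PCT_RESOLUTION),
                status=status,
                note=note,
            )
        )

    # Tables 2 and 3: count (percentage) cells at the central scenario
    for iid, cells in printed.table2.items():
        ir = results.interventions.get(iid)
        delta = ir.deltas["central"] if ir else None
        for col, cell in cells.items():
            if delta is None:
                rec, denom = None, None
            elif col == _T2_SPONT:
                rec, denom = delta.spontaneous_gain, delta.denominator_used
            else:
                rec, denom = delta.cycles_avoided.get(col), delta.denominator_used
            count_pct_record("table2", iid, col, cell, rec, denom)

    for iid, cells in printed.table3.items():
        ir = results.interventions.get(iid)
        delta = ir.deltas["central"] if ir else None
        for col, cell in cells.items():
            if delta is None or col not in delta.complications_avoided:
                rec, denom = None, None
            else:
                rec = delta.complications_avoided[col]
                denom = delta.complication_denominators[col]
            count_pct_record("table3", iid, col, cell, rec, denom)

    # Table 4: business-case rows
    for iid, row in printed.table4.items():
        ir = results.interventions.get(iid)

        # target-group size
        rec_group = ir.group_size if ir else None
        status, note = _status(
            rec_group == row.group_size, anomalies.get(("table4", iid, "target_group"))
        )
        records.append(
            CellAudit(
                table="table4",
                row=iid,
                column="target_group",
                printed=row.group_size,
                recomputed=rec_group,
                resolution=1,
                status=status,
                note=note,
            )
        )

        # annual incident target group: stored, not derivable from the model
        records.append(
            CellAudit(
                table="table4",
                row=iid,
                column="incidence",
                printed=row.incidence,
                recomputed=None,
                resolution=1,
                status="not-recomputable",
                note="annual inflow is an input with no role in the computation",
            )
        )

        pcb = ir.cost.per_couple_benefit if ir else None
        adopted = (
            tuple(pcb[s] for s in SCENARIOS) if pcb is not None else (None,) * 3
        )
        ok = all(_close(p, a, 1.0) for p, a in zip(row.per_couple, adopted))
        status, note = _status(ok, anomalies.get(("table4", iid, "per_couple")))
        records.append(
            CellAudit(
                table="table4",
                row=iid,
                column="per_couple",
                printed=row.per_couple,
                recomputed=adopted,
                resolution=1,
                status=status,
                note=note,
            )
        )

        totals = (
            tuple(ir.cost.total_saving[s] for s in SCENARIOS) if ir else (None,) * 3
        )
        ok = all(
            _close(p, t, res)
            for p, t, res in zip(row.total, totals, row.total_resolution)
        )
        status, note = _status(ok, anomalies.get(("table4", iid, "total_saving")))
        records.append(
            CellAudit(
                table="table4",
                row=iid,
                column="total_saving",
                printed=row.total,
                recomputed=totals,
                resolution=row.total_resolution,
                status=status,
                note=note,
            )
        )

        arts = (
            tuple(ir.cost.art_only_saving[s] for s in SCENARIOS) if ir else (None,) * 3
        )
        ok = all(
            _close(p, a, res) for p, a, res in zip(row.art, arts, row.art_resolution)
        )
        status, note = _status(ok, anomalies.get(("table4", iid, "art")))
        records.append(
            CellAudit(
                table="table4",
                row=iid,
                column="art",
                printed=row.art,
                recomputed=arts,
                resolution=row.art_resolution,
                status=status,
                note=note,
            )
        )

    return AuditReport(records=records)
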
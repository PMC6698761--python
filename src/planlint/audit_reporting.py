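"""Persist check runs and compute first-vs-final error-rate statistics.

Every check run is appended to an audit store (a plain JSON-lines file: one
record per line, diffable, no server).  The headline statistic is the error
rate — failed checks over total checked items, excluding NOT_APPLICABLE
results from the denominator — compared between the *first* and the *final*
check run of each plan: a drop between the two shows errors being caught
and fixed before approval rather than propagating downstream.

WARN counts as a defect by default (a WARN demands reviewer attention);
pass ``count_warn=False`` to count only hard FAILs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .check_engine import CheckCategory, CheckReport, CheckStatus, default_registry

__all__ = [
    "AuditRecord",
    "AuditDB",
    "record_run",
    "error_rate",
    "ErrorRate",
    "first_final_comparison",
    "render_report",
]


@dataclass(frozen=True)
class AuditRecord:
    plan_id: str
    run_index: int           # 1-based, increments per plan
    report: CheckReport
    timestamp: Optional[str] = None

    def to_dict(self) -> dict:
        d = {"plan_id": self.plan_id, "run_index": self.run_index,
             "report": self.report.to_dict()}
        if self.timestamp is not None:
            d["timestamp"] = self.timestamp
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AuditRecord":
        return cls(plan_id=d["plan_id"], run_index=int(d["run_index"]),
                   report=CheckReport.from_dict(d["report"]),
                   timestamp=d.get("timestamp"))


@dataclass
class AuditDB:
    """Append-only collection of audit records, with JSON-lines persistence."""

    records: list[AuditRecord] = field(default_factory=list)

    def next_run_index(self, plan_id: str) -> int:
        return 1 + sum(1 for r in self.records if r.plan_id == plan_id)

    def append(self, record: AuditRecord) -> None:
        expected = self.next_run_index(record.plan_id)
        if record.run_index != expected:
            raise ValueError(
                f"run_index {record.run_index} for plan {record.plan_id!r} "
                f"violates append-only ordering (expected {expected})")
        self.records.append(record)

    def first_runs(self) -> list[AuditRecord]:
        return [r for r in self.records if r.run_index == 1]

    def final_runs(self) -> list[AuditRecord]:
        last: dict[str, AuditRecord] = {}
        for r in self.records:
            if r.plan_id not in last or r.run_index > last[r.plan_id].run_index:
                last[r.plan_id] = r
        return list(last.values())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(r.to_dict(), sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "AuditDB":
        db = cls()
        for line in Path(path).read_text().splitlines():
            if line.strip():
                db.records.append(AuditRecord.from_dict(json.loads(line)))
        return db


def record_run(db: AuditDB, plan_id: str, report: CheckReport,
               timestamp: Optional[str] = None) -> AuditRecord:
    """Append a report to the store, assigning the next run index."""
    rec = AuditRecord(plan_id=plan_id, run_index=db.next_run_index(plan_id),
                      report=report, timestamp=timestamp)
    db.append(rec)
    return rec


@dataclass(frozen=True)
class ErrorRate:
    numerator: int          # defect results (FAIL, plus WARN when counted)
    denominator: int        # all results except NOT_APPLICABLE

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    def __float__(self) -> float:
        return self.value


def error_rate(records: Iterable[AuditRecord], count_warn: bool = True) -> ErrorRate:
    """Failed checks over total checked items across a selection of records."""
    defect_statuses = {CheckStatus.FAIL}
    if count_warn:
        defect_statuses.add(CheckStatus.WARN)
    num = den = 0
    records = list(records)
    if not records:
        raise ValueError("error_rate over an empty selection is undefined")
    for rec in records:
        for res in rec.report.results:
            if res.status is CheckStatus.NOT_APPLICABLE:
                continue
            den += 1
            if res.status in defect_statuses:
                num += 1
    if den == 0:
        raise ValueError("no applicable check results in selection")
    return ErrorRate(num, den)


def _category_of(check_id: str) -> str:
    if check_id.startswith("flag_"):
        return CheckCategory.FLAGS.value
    try:
        return default_registry().get(check_id).category.value
    except KeyError:
        return "OTHER"


def first_final_comparison(db: AuditDB, count_warn: bool = True) -> pd.DataFrame:
    """Per-category first-run vs final-run error rates, plus an overall row.

    Categories are sorted by first-run rate descending; the overall row sits
    last.  Empty databases yield an empty frame.
    """
    if not db.records:
        return pd.DataFrame(columns=["category", "first_rate", "final_rate",
                                     "first_n", "final_n"])
    rows = []
    firsts, finals = db.first_runs(), db.final_runs()

    def tally(records):
        counts: dict[str, list[int]] = {}
        for rec in records:
            for res in rec.report.results:
                if res.status is CheckStatus.NOT_APPLICABLE:
                    continue
                cat = _category_of(res.check_id)
                num_den = counts.setdefault(cat, [0, 0])
                num_den[1] += 1
                if res.status is CheckStatus.FAIL or (
                        count_warn and res.status is CheckStatus.WARN):
                    num_den[0] += 1
        return counts

    first_c, final_c = tally(firsts), tally(finals)
    for cat in sorted(set(first_c) | set(final_c)):
        fn, fd = first_c.get(cat, [0, 0])
        ln, ld = final_c.get(cat, [0, 0])
        rows.append({"category": cat,
                     "first_rate": fn / fd if fd else 0.0,
                     "final_rate": ln / ld if ld else 0.0,
                     "first_n": fd, "final_n": ld})
    df = pd.DataFrame(rows).sort_values("first_rate", ascending=False,
                                        kind="stable")
    overall_first = error_rate(firsts, count_warn)
    overall_final = error_rate(finals, count_warn)
    overall = pd.DataFrame([{
        "category": "OVERALL",
        "first_rate": overall_first.value, "final_rate": overall_final.value,
        "first_n": overall_first.denominator, "final_n": overall_final.denominator,
    }])
    return pd.concat([df, overall], ignore_index=True)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_ANSI = {CheckStatus.PASS: "\033[32m", CheckStatus.WARN: "\033[33m",
         CheckStatus.FAIL: "\033[31m", CheckStatus.NOT_APPLICABLE: "\033[90m"}
_RESET = "\033[0m"
_HTML_COLOR = {CheckStatus.PASS: "#2e7d32", CheckStatus.WARN: "#f9a825",
               CheckStatus.FAIL: "#c62828", CheckStatus.NOT_APPLICABLE: "#9e9e9e"}


def render_report(report: CheckReport, format: str = "text",
                  color: bool = True) -> str:
    """Render a check report for humans (text/html) or machines (json).

    The JSON form round-trips losslessly through
    :meth:`~planlint.check_engine.CheckReport.from_json`.
    """
    if format == "json":
        return report.to_json()
    if format == "text":
        lines = [f"Plan check report — {report.plan_id} "
                 f"(config {report.config_fingerprint})"]
        for r in report.results:
            status = r.status.value
            if color:
                status = f"{_ANSI[r.status]}{status}{_RESET}"
            lines.append(f"  [{status:<14s}] {r.check_id}: {r.message}")
        c = report.counts()
        lines.append(f"  {c['PASS']} pass / {c['WARN']} warn / {c['FAIL']} fail"
                     f" / {c['NOT_APPLICABLE']} n/a")
        return "\n".join(lines)
    if format == "html":
        rows = []
        for r in report.results:
            rows.append(
                f"<tr><td>{r.check_id}</td>"
                f"<td style=\"color:{_HTML_COLOR[r.status]};font-weight:bold\">"
                f"{r.status.value}</td><td>{r.message}</td></tr>")
        return (
            "<html><head><title>Plan check report</title></head><body>"
            f"<h1>Plan check report — {report.plan_id}</h1>"
            f"<p>config fingerprint: <code>{report.config_fingerprint}</code></p>"
            "<table border=\"1\" cellpadding=\"4\">"
            "<tr><th>check</th><th>status</th><th>message</th></tr>"
            + "".join(rows) + "</table></body></html>")
    raise ValueError(f"unknown report format {format!r}")
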
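"""Bundled benchmark counts from a published 12-lead PTB evaluation.

The package ships two small fixtures transcribed from the reported results
of a Shannon-energy QRS detector evaluated on 12-lead records of the PTB
Diagnostic ECG Database:

* ``ptb_benchmark_records.csv`` — per-record (TP, FN, FP) counts and the
  reported DER/Se/+P/Acc percentages (3 decimals), plus the corpus Total row;
* ``ptb_benchmark_leads_s0020arem.csv`` — the per-lead counts of record
  s0020arem, whose sum equals that record's corpus row.

These let the metric formulas be validated against published numbers without
downloading the database. Note the published Total row is *not* the
arithmetic sum of the per-record column (the source tables are internally
inconsistent for a few records), so verification is strictly row-by-row.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .errors import FormatError, ReproductionMismatch
from .evaluate import DetectionCounts, compute_metrics, render_percent

__all__ = [
    "BenchmarkRow",
    "load_benchmark_records",
    "load_benchmark_leads",
    "verify_benchmark_table",
]


@dataclass(frozen=True)
class BenchmarkRow:
    """One published row: counts plus the reported 3-decimal percentages."""

    case: str
    counts: DetectionCounts
    der: str
    se: str
    pp: str
    acc: str


def _open_fixture(name: str):
    return resources.files("seeqrs.data").joinpath(name).open()


def load_benchmark_records(path: str | None = None) -> list[BenchmarkRow]:
    """Load the per-record benchmark table (72 records + Total)."""
    fh = open(path) if path else _open_fixture("ptb_benchmark_records.csv")
    rows: list[BenchmarkRow] = []
    with fh:
        for rec in csv.DictReader(fh):
            try:
                rows.append(
                    BenchmarkRow(
                        case=rec["case"],
                        counts=DetectionCounts(int(rec["tp"]), int(rec["fn"]), int(rec["fp"])),
                        der=rec["der"],
                        se=rec["se"],
                        pp=rec["pp"],
                        acc=rec["acc"],
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise FormatError(f"malformed benchmark row {rec!r}: {exc}") from exc
    return rows


def load_benchmark_leads(record: str = "s0020arem") -> dict[str, DetectionCounts]:
    """Per-lead counts of the bundled appendix record."""
    with _open_fixture(f"ptb_benchmark_leads_{record}.csv") as fh:
        return {
            rec["lead"]: DetectionCounts(int(rec["tp"]), int(rec["fn"]), int(rec["fp"]))
            for rec in csv.DictReader(fh)
        }


def verify_benchmark_table(path: str | None = None) -> str:
    """Recompute every published percentage from its counts and diff them.

    Returns the recomputed CSV report. Raises :class:`ReproductionMismatch`
    naming the first offending row if any recomputed 3-decimal cell differs
    from the published one.
    """
    rows = load_benchmark_records(path)
    out = ["Case,TP,FN,FP,DER%,Se%,+P,Acc"]
    for row in rows:
        m = compute_metrics(row.counts)
        computed = {
            "DER": render_percent(m.der),
            "Se": render_percent(m.se),
            "+P": render_percent(m.pp),
            "Acc": render_percent(m.acc),
        }
        published = {"DER": row.der, "Se": row.se, "+P": row.pp, "Acc": row.acc}
        for key in computed:
            if computed[key] != published[key]:
                raise ReproductionMismatch(
                    f"row {row.case}: {key} recomputed {computed[key]} "
                    f"!= published {published[key]}"
                )
        c = row.counts
        out.append(
            f"{row.case},{c.tp},{c.fn},{c.fp},"
            f"{computed['DER']},{computed['Se']},{computed['+P']},{computed['Acc']}"
        )
    return "\n".join(out) + "\n"
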
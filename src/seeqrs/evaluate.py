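"""Beat-level evaluation: matching, counts and the four summary metrics.

Detections are matched one-to-one to reference beats within a time tolerance
(default 150 ms, the ANSI/AAMI EC57 convention). From the resulting counts —
TP (matched beats), FN (missed references), FP (spurious detections) — the
four standard percentages are

    Se  = TP / (TP + FN) * 100        sensitivity
    +P  = TP / (TP + FP) * 100        positive predictivity
    Acc = TP / (TP + FN + FP) * 100   detection accuracy
    DER = (FP + FN) / TP * 100        detection error rate

Percentages are kept at full precision internally and rendered to three
decimals (round-half-even) only in report output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "DetectionCounts",
    "DetectionMetrics",
    "match_beats",
    "compute_metrics",
    "aggregate",
    "report_table",
    "render_percent",
]


@dataclass(frozen=True)
class DetectionCounts:
    """True-positive / false-negative / false-positive beat counts."""

    tp: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise InputError("counts must be non-negative")

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(self.tp + other.tp, self.fn + other.fn, self.fp + other.fp)


@dataclass(frozen=True)
class DetectionMetrics:
    """The four derived percentages; ``der`` is ``inf`` when TP == 0."""

    se: float
    pp: float
    acc: float
    der: float


def _indices(x) -> np.ndarray:
    if hasattr(x, "r_samples"):
        return np.asarray(x.r_samples, dtype=np.int64)
    return np.asarray(x, dtype=np.int64)


def match_beats(dets, refs, tolerance: int) -> DetectionCounts:
    """One-to-one greedy nearest-first matching within ``tolerance`` samples.

    All (reference, detection) pairs closer than the tolerance are considered
    in order of increasing distance (ties: earlier reference, then earlier
    detection); each beat participates in at most one pair. Matched pairs are
    TP, leftover references FN, leftover detections FP.

    ``dets``/``refs`` may be index arrays or objects with ``r_samples`` (and
    ``fs``, which must agree when both carry one).
    """
    fs_d = getattr(dets, "fs", None)
    fs_r = getattr(refs, "fs", None)
    if fs_d is not None and fs_r is not None and fs_d != fs_r:
        raise InputError(f"sampling rates differ: detections {fs_d} Hz vs reference {fs_r} Hz")
    d = _indices(dets)
    r = _indices(refs)
    pairs = []
    for i, ri in enumerate(r):
        lo = np.searchsorted(d, ri - tolerance, side="left")
        hi = np.searchsorted(d, ri + tolerance, side="right")
        for j in range(int(lo), int(hi)):
            pairs.append((abs(int(d[j]) - int(ri)), i, j))
    pairs.sort()
    used_r: set[int] = set()
    used_d: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_r or j in used_d:
            continue
        used_r.add(i)
        used_d.add(j)
        tp += 1
    return DetectionCounts(tp=tp, fn=int(r.size) - tp, fp=int(d.size) - tp)


def compute_metrics(c: DetectionCounts) -> DetectionMetrics:
    """Exact Se / +P / Acc / DER percentages from a count triplet."""
    if c.tp + c.fn + c.fp == 0:
        raise InputError("all counts are zero: metrics are undefined")
    if c.tp + c.fn == 0 or c.tp + c.fp == 0:
        raise InputError("need at least one reference beat and one detection")
    se = c.tp / (c.tp + c.fn) * 100.0
    pp = c.tp / (c.tp + c.fp) * 100.0
    acc = c.tp / (c.tp + c.fn + c.fp) * 100.0
    der = (c.fp + c.fn) / c.tp * 100.0 if c.tp > 0 else math.inf
    return DetectionMetrics(se=se, pp=pp, acc=acc, der=der)


def aggregate(counts: Iterable[DetectionCounts]) -> DetectionCounts:
    """Elementwise sum of count triplets (per-lead -> per-record -> corpus)."""
    counts = list(counts)
    if not counts:
        raise InputError("cannot aggregate an empty list of counts")
    total = DetectionCounts(0, 0, 0)
    for c in counts:
        total = total + c
    return total


def render_percent(value: float) -> str:
    """Render a percentage to three decimals, round-half-even; inf -> 'inf'."""
    if math.isinf(value):
        return "inf"
    return f"{value:.3f}"


def _row(case: str, c: DetectionCounts) -> str:
    if c.tp + c.fn + c.fp == 0:
        return f"{case},0,0,0,NA,NA,NA,NA"
    m = compute_metrics(c)
    return (
        f"{case},{c.tp},{c.fn},{c.fp},"
        f"{render_percent(m.der)},{render_percent(m.se)},"
        f"{render_percent(m.pp)},{render_percent(m.acc)}"
    )


def report_table(per_record: Mapping[str, DetectionCounts]) -> str:
    """CSV report with one row per record plus an aggregated Total row.

    Columns: ``Case,TP,FN,FP,DER%,Se%,+P,Acc``; percentages to three
    decimals. An empty mapping yields a Total row of zeros with metric
    cells flagged ``NA``.
    """
    lines = ["Case,TP,FN,FP,DER%,Se%,+P,Acc"]
    for case, c in per_record.items():
        lines.append(_row(case, c))
    total = aggregate(per_record.values()) if per_record else DetectionCounts(0, 0, 0)
    lines.append(_row("Total", total))
    return "\n".join(lines) + "\n"
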
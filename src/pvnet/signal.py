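"""Disproportionality signal detection with reporting odds ratios.

For a drug D and adverse-event term E, every deduplicated report falls in
exactly one cell of the 2x2 contingency table

              E reported    E not reported
    D reported        a             b
    D not             c             d

The reporting odds ratio ROR = (a*d)/(b*c) compares the odds of E being
reported with D against the odds of E with every other drug. The 95% CI is
the Wald interval on the log scale, exp(ln ROR +/- z*sqrt(1/a+1/b+1/c+1/d)).
A pair is flagged a signal when the CI lower bound exceeds 1 and the pair has
at least two co-reports (a >= 2).
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .reports import ReportStore, normalize_drug_name

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "build_table",
    "compute_ror",
    "scan_events",
    "write_signals_tsv",
]

Z_95 = 1.959964  # 97.5% normal quantile


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, numbers.Integral) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True, slots=True)
class SignalResult:
    drug: str
    event: str
    level: str  # "PT" or "SOC"
    table: ContingencyTable
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    z: float
    corrected: bool
    is_signal: bool


def _report_flags(
    store: ReportStore, drug: str, event: str, level: str
) -> Iterable[tuple[bool, bool]]:
    target = normalize_drug_name(drug)
    for r in store.reports:
        exposed = any(d.drug_name == target for d in r.drugs)
        if level == "PT":
            positive = any(e.pt == event for e in r.events)
        else:
            positive = any(e.soc == event for e in r.events)
        yield exposed, positive


def build_table(
    store: ReportStore, drug: str, event: str, level: str = "PT"
) -> ContingencyTable:
    """Count reports into the drug x event 2x2 table.

    A report is drug-exposed if any retained drug entry matches ``drug``
    (after name normalization) and event-positive if any event matches
    ``event`` at the requested level; each report contributes exactly once to
    exactly one cell. An unknown drug or event is not an error — it simply
    yields an empty margin.
    """
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    a = b = c = d = 0
    for exposed, positive in _report_flags(store, drug, event, level):
        if exposed and positive:
            a += 1
        elif exposed:
            b += 1
        elif positive:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compute_ror(
    table: ContingencyTable,
    z: float = Z_95,
    zero_cell: str = "undefined",
    drug: str = "",
    event: str = "",
    level: str = "PT",
) -> SignalResult:
    """Point estimate, Wald CI and signal flag for one 2x2 table.

    With a zero cell the ROR is not estimable: ``zero_cell="undefined"``
    reports it (and the CI) as undefined with ``is_signal=False``;
    ``zero_cell="haldane"`` applies the Haldane–Anscombe correction (add 0.5
    to every cell) and marks the result ``corrected``. The signal rule —
    CI lower bound > 1 and a >= 2 — always uses the *observed* a.
    """
    if zero_cell not in ("undefined", "haldane"):
        raise ValueError(f"unknown zero_cell policy {zero_cell!r}")

    corrected = False
    if table.has_zero_cell():
        if zero_cell == "undefined":
            return SignalResult(
                drug=drug, event=event, level=level, table=table,
                ror=None, ci_low=None, ci_high=None, z=z,
                corrected=False, is_signal=False,
            )
        corrected = True
        a, b, c, d = (table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5)
    else:
        a, b, c, d = table.a, table.b, table.c, table.d

    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(ror) - z * se)
    ci_high = math.exp(math.log(ror) + z * se)
    is_signal = ci_low > 1.0 and table.a >= 2
    return SignalResult(
        drug=drug, event=event, level=level, table=table,
        ror=ror, ci_low=ci_low, ci_high=ci_high, z=z,
        corrected=corrected, is_signal=is_signal,
    )


def scan_events(
    store: ReportStore,
    drug: str,
    level: str = "PT",
    min_a: int = 1,
    z: float = Z_95,
    zero_cell: str = "undefined",
) -> list[SignalResult]:
    """One :class:`SignalResult` per event term co-reported with ``drug``.

    Terms with fewer than ``min_a`` co-reports are omitted. Results are
    sorted by descending ROR (undefined RORs last) with alphabetical
    tie-break on the event term, so output is stable across runs.
    """
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    target = normalize_drug_name(drug)
    n_total = len(store.reports)
    n_exposed = 0
    # per-term counts over one pass: a (exposed & positive), col (positive)
    a_counts: dict[str, int] = {}
    col_counts: dict[str, int] = {}
    for r in store.reports:
        exposed = any(d.drug_name == target for d in r.drugs)
        if exposed:
            n_exposed += 1
        if level == "PT":
            terms = {e.pt for e in r.events}
        else:
            terms = {e.soc for e in r.events if e.soc is not None}
        for t in terms:
            col_counts[t] = col_counts.get(t, 0) + 1
            if exposed:
                a_counts[t] = a_counts.get(t, 0) + 1

    results: list[SignalResult] = []
    for term, a in a_counts.items():
        if a < min_a:
            continue
        b = n_exposed - a
        c = col_counts[term] - a
        d = n_total - a - b - c
        res = compute_ror(
            ContingencyTable(a, b, c, d), z=z, zero_cell=zero_cell,
            drug=target, event=term, level=level,
        )
        results.append(res)
    results.sort(key=lambda r: (-(r.ror if r.ror is not None else -math.inf), r.event))
    return results


def write_signals_tsv(results: Iterable[SignalResult], path: str | Path) -> None:
    """Serialize scan results; undefined statistics are written as NA."""

    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.6g}"

    lines = ["drug\tevent\tlevel\ta\tb\tc\td\tror\tci_low\tci_high\tcorrected\tis_signal"]
    for r in results:
        t = r.table
        lines.append(
            f"{r.drug}\t{r.event}\t{r.level}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
            f"{fmt(r.ror)}\t{fmt(r.ci_low)}\t{fmt(r.ci_high)}\t"
            f"{str(r.corrected).lower()}\t{str(r.is_signal).lower()}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
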
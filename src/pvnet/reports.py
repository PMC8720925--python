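"""Spontaneous adverse-event report store.

Ingests FAERS-style quarterly tables (DEMO / DRUG / REAC) in either the
classic ``$``-delimited dialect or a tab-separated dialect with the same
schemas, normalizes them into :class:`CaseReport` records, and provides the
standard pharmacovigilance preprocessing steps: case-level deduplication
(keep the latest version of each case), drug-role filtering (e.g. primary
suspect only), and preferred-term → system-organ-class mapping.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Role",
    "DrugEntry",
    "EventEntry",
    "CaseReport",
    "TermMap",
    "ReportStore",
    "SchemaError",
    "read_faers_tables",
    "write_store_tsv",
    "deduplicate",
    "filter_by_role",
    "apply_term_map",
    "normalize_drug_name",
]


class SchemaError(ValueError):
    """An input table is missing a required column or is otherwise malformed."""


class Role(enum.Enum):
    """FAERS drug role codes: anticipated degree of involvement in the event."""

    PS = "PS"  # primary suspect
    SS = "SS"  # secondary suspect
    C = "C"  # concomitant
    I = "I"  # interacting


_WS_RUN = re.compile(r"\s+")


def normalize_drug_name(name: str) -> str:
    """Case-fold, trim and collapse internal whitespace runs."""
    return _WS_RUN.sub(" ", name.strip()).casefold()


@dataclass(frozen=True, slots=True)
class DrugEntry:
    drug_name: str  # normalized
    role: Role

    def __post_init__(self) -> None:
        if not self.drug_name:
            raise ValueError("drug_name must be non-empty")


@dataclass(frozen=True, slots=True)
class EventEntry:
    pt: str
    soc: str | None = None

    def __post_init__(self) -> None:
        if not self.pt:
            raise ValueError("pt must be non-empty")


@dataclass(slots=True)
class CaseReport:
    """One submitted version of one spontaneous report."""

    case_id: str
    report_key: str
    version_rank: tuple[int, int]
    drugs: list[DrugEntry] = field(default_factory=list)
    events: list[EventEntry] = field(default_factory=list)


@dataclass
class TermMap:
    """Flat preferred-term → system-organ-class mapping.

    A lookup of a PT outside the declared domain is an explicit miss
    (:meth:`lookup` returns ``None``); it is never silently mapped to "".
    """

    pt_to_soc: dict[str, str]

    def lookup(self, pt: str) -> str | None:
        return self.pt_to_soc.get(pt)

    def __contains__(self, pt: str) -> bool:
        return pt in self.pt_to_soc

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TermMap":
        df = _read_table(path, "\t", {"pt", "soc"}, "term map")
        return cls(pt_to_soc=dict(zip(df["pt"], df["soc"])))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.pt_to_soc.items()), columns=["pt", "soc"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class ReportStore:
    """A collection of case reports plus ingest/processing provenance."""

    reports: list[CaseReport]
    provenance: dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reports)

    def report_keys(self) -> set[str]:
        return {r.report_key for r in self.reports}


# ---------------------------------------------------------------------------
# ingest


def _read_table(
    path: str | Path, sep: str, required: set[str], label: str
) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=sep,
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
        encoding_errors="replace",
        engine="python" if sep == "$" else "c",
    )
    df.columns = [c.strip().lower() for c in df.columns]
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"{label} table {path}: missing required column(s) "
            + ", ".join(sorted(missing))
        )
    return df


def _count_replacement_chars(df: pd.DataFrame) -> int:
    return int(sum(df[c].str.count("�").sum() for c in df.columns))


def read_faers_tables(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    dialect: str = "tsv",
) -> ReportStore:
    """Join DEMO/DRUG/REAC tables into one :class:`CaseReport` per report key.

    ``dialect`` is ``"dollar"`` for the FAERS ASCII ``$``-delimited layout or
    ``"tsv"`` for the tab-separated fixture layout (identical schemas).
    Drug/event rows referencing a report key absent from DEMO, and drug rows
    with an unreadable role code, are dropped and counted in provenance.
    """
    if dialect not in ("dollar", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "$" if dialect == "dollar" else "\t"

    demo = _read_table(demo_path, sep, {"primaryid", "caseid"}, "DEMO")
    drug = _read_table(drug_path, sep, {"primaryid", "role_cod", "drugname"}, "DRUG")
    reac = _read_table(reac_path, sep, {"primaryid", "pt"}, "REAC")

    reports: dict[str, CaseReport] = {}
    for i, row in enumerate(demo.itertuples(index=False)):
        key = str(row.primaryid).strip()
        if not key or key in reports:
            continue
        if "caseversion" in demo.columns and str(row.caseversion).strip():
            rank = (0, int(str(row.caseversion).strip()))
        elif "fda_dt" in demo.columns and str(row.fda_dt).strip():
            rank = (1, int(str(row.fda_dt).strip()))
        else:
            rank = (2, i)  # file order as a last resort
        reports[key] = CaseReport(
            case_id=str(row.caseid).strip(), report_key=key, version_rank=rank
        )

    orphan_drug = orphan_reac = bad_role = empty_drug = 0
    for row in drug.itertuples(index=False):
        key = str(row.primaryid).strip()
        rep = reports.get(key)
        if rep is None:
            orphan_drug += 1
            continue
        name = normalize_drug_name(str(row.drugname))
        if not name:
            empty_drug += 1
            continue
        try:
            role = Role[str(row.role_cod).strip().upper()]
        except KeyError:
            bad_role += 1
            continue
        rep.drugs.append(DrugEntry(drug_name=name, role=role))

    for row in reac.itertuples(index=False):
        key = str(row.primaryid).strip()
        rep = reports.get(key)
        if rep is None:
            orphan_reac += 1
            continue
        pt = str(row.pt).strip()
        if pt:
            rep.events.append(EventEntry(pt=pt))

    dropped = orphan_drug + orphan_reac + bad_role + empty_drug
    provenance = {
        "sources": {
            "demo": str(demo_path),
            "drug": str(drug_path),
            "reac": str(reac_path),
        },
        "rows_parsed": {"demo": len(demo), "drug": len(drug), "reac": len(reac)},
        "rows_dropped": {
            "orphan_drug": orphan_drug,
            "orphan_reac": orphan_reac,
            "bad_role": bad_role,
            "empty_drug_name": empty_drug,
            "total": dropped,
        },
        "undecodable_bytes_replaced": sum(
            _count_replacement_chars(t) for t in (demo, drug, reac)
        ),
    }
    return ReportStore(reports=list(reports.values()), provenance=provenance)


def write_store_tsv(store: ReportStore, out_dir: str | Path) -> dict[str, Path]:
    """Write the store back out in the tsv dialect (DEMO/DRUG/REAC files)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    demo_rows, drug_rows, reac_rows = [], [], []
    for r in store.reports:
        kind, value = r.version_rank[0], r.version_rank[1]
        demo_rows.append(
            {
                "primaryid": r.report_key,
                "caseid": r.case_id,
                "caseversion": value if kind == 0 else "",
                "fda_dt": value if kind == 1 else "",
            }
        )
        for d in r.drugs:
            drug_rows.append(
                {
                    "primaryid": r.report_key,
                    "role_cod": d.role.value,
                    "drugname": d.drug_name,
                }
            )
        for e in r.events:
            reac_rows.append({"primaryid": r.report_key, "pt": e.pt})
    paths = {
        "demo": out / "demo.tsv",
        "drug": out / "drug.tsv",
        "reac": out / "reac.tsv",
    }
    pd.DataFrame(demo_rows, columns=["primaryid", "caseid", "caseversion", "fda_dt"]).to_csv(
        paths["demo"], sep="\t", index=False
    )
    pd.DataFrame(drug_rows, columns=["primaryid", "role_cod", "drugname"]).to_csv(
        paths["drug"], sep="\t", index=False
    )
    pd.DataFrame(reac_rows, columns=["primaryid", "pt"]).to_csv(
        paths["reac"], sep="\t", index=False
    )
    return paths


# ---------------------------------------------------------------------------
# preprocessing


def deduplicate(store: ReportStore) -> ReportStore:
    """Keep exactly one report per case: the one with the highest version rank.

    Ties on version rank break to the lexicographically greatest report key so
    the outcome is deterministic. Idempotent.
    """
    best: dict[str, CaseReport] = {}
    for r in store.reports:
        cur = best.get(r.case_id)
        if cur is None or (r.version_rank, r.report_key) > (
            cur.version_rank,
            cur.report_key,
        ):
            best[r.case_id] = r
    kept = list(best.values())
    prov = dict(store.provenance)
    prov["dedup"] = {
        "before": len(store.reports),
        "kept": len(kept),
        "dropped": len(store.reports) - len(kept),
    }
    return ReportStore(reports=kept, provenance=prov)


def filter_by_role(store: ReportStore, roles: Iterable[Role]) -> ReportStore:
    """Keep only drug entries whose role is in ``roles``.

    Reports left with no drug entry at all are excluded (they carry no
    exposure information under the chosen role policy). The input store is
    not modified.
    """
    roleset = set(roles)
    if not roleset:
        raise ValueError("roles must be a non-empty set of role codes")
    kept: list[CaseReport] = []
    for r in store.reports:
        drugs = [d for d in r.drugs if d.role in roleset]
        if drugs:
            kept.append(replace(r, drugs=drugs, events=list(r.events)))
    prov = dict(store.provenance)
    prov["role_filter"] = {
        "roles": sorted(x.value for x in roleset),
        "before": len(store.reports),
        "kept": len(kept),
    }
    return ReportStore(reports=kept, provenance=prov)


def apply_term_map(
    store: ReportStore, term_map: TermMap, on_miss: str = "keep_unmapped"
) -> ReportStore:
    """Annotate every event with its system organ class.

    ``on_miss`` controls unmapped preferred terms: ``"drop"`` removes the
    event, ``"keep_unmapped"`` keeps it with ``soc=None``, ``"error"`` raises
    naming the first offending PT. Misses are counted in provenance.
    """
    if on_miss not in ("drop", "keep_unmapped", "error"):
        raise ValueError(f"unknown on_miss policy {on_miss!r}")
    misses = 0
    out: list[CaseReport] = []
    for r in store.reports:
        events: list[EventEntry] = []
        for e in r.events:
            soc = term_map.lookup(e.pt)
            if soc is None:
                if on_miss == "error":
                    raise KeyError(f"preferred term not in term map: {e.pt!r}")
                misses += 1
                if on_miss == "drop":
                    continue
                events.append(EventEntry(pt=e.pt, soc=None))
            else:
                events.append(EventEntry(pt=e.pt, soc=soc))
        out.append(replace(r, drugs=list(r.drugs), events=events))
    prov = dict(store.provenance)
    prov["term_map"] = {"on_miss": on_miss, "misses": misses}
    return ReportStore(reports=out, provenance=prov)
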
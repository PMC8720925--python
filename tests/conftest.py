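from pathlib import Path

import pytest
from hypothesis import settings

from pvnet.reports import CaseReport, DrugEntry, EventEntry, normalize_drug_name

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


def write(path: Path, text: str) -> Path:
    path.write_text(text)
    return path


def make_report(case_id, key, rank, drugs=(), events=()):
    """Small literal CaseReport for table-level tests."""
    return CaseReport(
        case_id=case_id,
        report_key=key,
        version_rank=(0, rank),
        drugs=[DrugEntry(normalize_drug_name(d), r) for d, r in drugs],
        events=[EventEntry(pt=e) for e in events],
    )


@pytest.fixture
def faers_tsv(tmp_path):
    """Three joined reports plus one orphan drug row (key 99 not in DEMO)."""
    demo = write(
        tmp_path / "demo.tsv",
        "primaryid\tcaseid\tcaseversion\tfda_dt\n"
        "1001\tC1\t1\t\n"
        "1002\tC2\t1\t\n"
        "1003\tC3\t1\t\n",
    )
    drug = write(
        tmp_path / "drug.tsv",
        "primaryid\trole_cod\tdrugname\n"
        "1001\tPS\tMontelukast\n"
        "1001\tC\tAspirin\n"
        "1002\tPS\tAspirin\n"
        "1003\tSS\t  Montelukast  Sodium \n"
        "99\tPS\tGhostdrug\n",
    )
    reac = write(
        tmp_path / "reac.tsv",
        "primaryid\tpt\n"
        "1001\tSuicidal ideation\n"
        "1002\tHeadache\n"
        "1003\tNausea\n",
    )
    return demo, drug, reac


@pytest.fixture
def mitab_file(tmp_path):
    """Five interaction rows: one self-loop, one duplicated pair, one mouse row."""

    def row(a, b, taxa="taxid:9606(Homo sapiens)", taxb="taxid:9606(Homo sapiens)"):
        return "\t".join(
            [
                f"uniprotkb:{a}_ID",
                f"uniprotkb:{b}_ID",
                "-",
                "-",
                f"hgnc:{a}",
                f"hgnc:{b}",
                'psi-mi:"MI:0004"(affinity chromatography technology)',
                "-",
                "pubmed:1",
                taxa,
                taxb,
                'psi-mi:"MI:0915"(physical association)',
                "psi-mi:0000",
                "rec1",
                "-",
            ]
        )

    lines = [
        row("AAA", "BBB"),
        row("AAA", "BBB"),  # duplicate pair
        row("BBB", "CCC"),
        row("CCC", "CCC"),  # self-interaction
        row("CCC", "DDD"),
        row("AAA", "EEE", taxb="taxid:10090(Mus musculus)"),  # mouse partner
    ]
    path = tmp_path / "interactions.mitab.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
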
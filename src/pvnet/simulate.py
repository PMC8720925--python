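"""Synthetic data generators with known ground truth.

Three generators emulate the statistical structure of the pipeline's inputs
so that every stage can be exercised and verified without any external
download:

* :func:`simulate_reports` — spontaneous reports with independent background
  drug exposures, baseline event odds, and injected drug–event associations
  of known odds ratio (the event odds are multiplied by the injected OR when
  the drug is exposed, so the injected OR is exactly the estimand the
  reporting odds ratio targets). One exposed drug per report is marked
  primary suspect; a configurable fraction of cases also emits an earlier
  case version, giving the deduplication step real work.
* :func:`simulate_ppi` — a planted-module interactome: dense modules
  (within-module edge probability ``p_in``) over a sparse background
  (``p_out`` for every pair involving a background node). Distinct planted
  modules are not wired to each other, so module recovery measures dense-
  region detection rather than bridge-following. Written as minimal
  PSI-MITAB plus a seed-gene file.
* :func:`simulate_genesets` — gene-set collections aligned with the planted
  modules (each planted set = module members plus 10% random decoys) among
  uniform-random noise sets, in GMT and disease-TSV form.

Every generator draws from a single numpy Generator seeded once per run and
is bit-reproducible from its config.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .network import write_mitab_minimal
from .reports import (
    CaseReport,
    DrugEntry,
    EventEntry,
    ReportStore,
    Role,
    TermMap,
    write_store_tsv,
)
from .signal import ContingencyTable

__all__ = [
    "ReportSimConfig",
    "PpiSimConfig",
    "ReportSimTruth",
    "PpiSimTruth",
    "default_report_config",
    "default_ppi_config",
    "simulate_report_store",
    "simulate_reports",
    "simulate_ppi",
    "simulate_genesets",
    "sample_null_tables",
    "table_from_truth",
]


# ---------------------------------------------------------------------------
# spontaneous reports


@dataclass(frozen=True)
class ReportSimConfig:
    n_reports: int
    drugs: tuple[tuple[str, float], ...]  # (name, exposure_prob)
    events: tuple[tuple[str, str, float], ...]  # (pt, soc, baseline_odds)
    injected: tuple[tuple[str, str, float], ...] = ()  # (drug, pt, odds_ratio)
    n_versions_dup_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        for _, p in self.drugs:
            if not (0.0 < p < 1.0):
                raise ValueError("exposure probabilities must be in (0, 1)")
        for _, _, o in self.events:
            if o <= 0:
                raise ValueError("baseline odds must be > 0")
        for _, _, r in self.injected:
            if r <= 0:
                raise ValueError("injected odds ratios must be > 0")
        if not (0.0 <= self.n_versions_dup_frac < 1.0):
            raise ValueError("n_versions_dup_frac must be in [0, 1)")


def default_report_config(
    seed: int = 0,
    n_reports: int = 20_000,
    injected_or: float = 10.0,
) -> ReportSimConfig:
    """Study conditions for signal-recovery experiments.

    A drug of interest plus nine background drugs, each with 5% independent
    exposure probability; eight preferred terms across three organ classes,
    each with baseline reporting odds 0.01; one injected association between
    the drug of interest and "Suicidal ideation"; 10% of cases emitted with
    a duplicate earlier version.
    """
    drugs = tuple(
        [("montelukast", 0.05)]
        + [(f"comparator{i:02d}", 0.05) for i in range(1, 10)]
    )
    events = (
        ("Suicidal ideation", "Psychiatric disorders", 0.01),
        ("Depression", "Psychiatric disorders", 0.01),
        ("Anxiety", "Psychiatric disorders", 0.01),
        ("Headache", "Nervous system disorders", 0.01),
        ("Dizziness", "Nervous system disorders", 0.01),
        ("Nausea", "Gastrointestinal disorders", 0.01),
        ("Diarrhoea", "Gastrointestinal disorders", 0.01),
        ("Fatigue", "General disorders", 0.01),
    )
    injected = (
        (("montelukast", "Suicidal ideation", injected_or),)
        if injected_or != 1.0
        else ()
    )
    return ReportSimConfig(
        n_reports=n_reports,
        drugs=drugs,
        events=events,
        injected=injected,
        n_versions_dup_frac=0.1,
        seed=seed,
    )


@dataclass
class ReportSimTruth:
    """Per-case ground truth (latest case version), aligned with case order."""

    case_ids: list[str]
    exposure: dict[str, np.ndarray]  # drug -> bool array over cases
    events: dict[str, np.ndarray]  # pt -> bool array over cases
    ps_drug: list[str | None]  # primary-suspect drug per case (None: no drug)
    n_duplicates: int


def table_from_truth(
    truth: ReportSimTruth, drug: str, pt: str
) -> ContingencyTable:
    """2x2 recount straight from the truth flags (any-exposure definition)."""
    x = truth.exposure[drug]
    y = truth.events[pt]
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    return ContingencyTable(a, b, c, d)


def simulate_report_store(
    config: ReportSimConfig,
) -> tuple[ReportStore, ReportSimTruth]:
    """Draw the report corpus in memory (see module docstring for the model)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_names = [d for d, _ in config.drugs]
    pts = [pt for pt, _, _ in config.events]

    p_exp = np.array([p for _, p in config.drugs])
    exposed = rng.random((n, len(drug_names))) < p_exp

    odds = np.tile([o for _, _, o in config.events], (n, 1))
    for drug, pt, ratio in config.injected:
        j = drug_names.index(drug)
        e = pts.index(pt)
        odds[:, e] *= np.where(exposed[:, j], ratio, 1.0)
    occurred = rng.random((n, len(pts))) < odds / (1.0 + odds)

    ps_pick = rng.random(n)  # uniform pick among exposed drugs per report

    reports: list[CaseReport] = []
    ps_drug: list[str | None] = []
    case_ids: list[str] = []
    for i in range(n):
        case_id = f"C{i + 1:06d}"
        case_ids.append(case_id)
        exp_idx = np.flatnonzero(exposed[i])
        drugs: list[DrugEntry] = []
        if exp_idx.size:
            ps_j = exp_idx[int(ps_pick[i] * exp_idx.size)]
            ps_drug.append(drug_names[ps_j])
            for j in exp_idx:
                role = Role.PS if j == ps_j else Role.C
                drugs.append(DrugEntry(drug_name=drug_names[j], role=role))
        else:
            ps_drug.append(None)
        events = [EventEntry(pt=pts[e]) for e in np.flatnonzero(occurred[i])]
        reports.append(
            CaseReport(
                case_id=case_id,
                report_key=f"{case_id}-2",
                version_rank=(0, 2),
                drugs=drugs,
                events=events,
            )
        )

    n_dup = int(round(config.n_versions_dup_frac * n))
    if n_dup:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        for i in sorted(dup_idx):
            r = reports[i]
            reports.append(
                CaseReport(
                    case_id=r.case_id,
                    report_key=f"{r.case_id}-1",
                    version_rank=(0, 1),
                    drugs=list(r.drugs),
                    events=list(r.events),
                )
            )

    truth = ReportSimTruth(
        case_ids=case_ids,
        exposure={d: exposed[:, j].copy() for j, d in enumerate(drug_names)},
        events={pt: occurred[:, e].copy() for e, pt in enumerate(pts)},
        ps_drug=ps_drug,
        n_duplicates=n_dup,
    )
    store = ReportStore(
        reports=reports,
        provenance={"generator": "simulate_report_store", "seed": config.seed},
    )
    return store, truth


def simulate_reports(
    config: ReportSimConfig, out_dir: str | Path
) -> tuple[dict[str, Path], ReportSimTruth]:
    """Draw the corpus and emit it in the tsv report dialect.

    Writes demo/drug/reac tables, the PT->SOC term map, and a plain-text
    truth sidecar; returns the file paths and the in-memory truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    store, truth = simulate_report_store(config)
    paths = write_store_tsv(store, out)
    term_map = TermMap({pt: soc for pt, soc, _ in config.events})
    paths["term_map"] = out / "term_map.tsv"
    term_map.write_tsv(paths["term_map"])

    lines = ["case_id\tps_drug\texposed\tevents"]
    for i, case_id in enumerate(truth.case_ids):
        exp = ",".join(d for d in truth.exposure if truth.exposure[d][i])
        evs = ",".join(pt for pt in truth.events if truth.events[pt][i])
        lines.append(f"{case_id}\t{truth.ps_drug[i] or ''}\t{exp}\t{evs}")
    paths["truth"] = out / "truth_reports.tsv"
    paths["truth"].write_text("\n".join(lines) + "\n")
    return paths, truth


def sample_null_tables(
    n_tables: int,
    n_reports: int = 2_000,
    p_drug: float = 0.1,
    p_event: float = 0.1,
    rng: np.random.Generator | None = None,
) -> list[ContingencyTable]:
    """Tables drawn with independent exposure and event (true OR = 1)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    probs = [
        p_drug * p_event,
        p_drug * (1 - p_event),
        (1 - p_drug) * p_event,
        (1 - p_drug) * (1 - p_event),
    ]
    draws = rng.multinomial(n_reports, probs, size=n_tables)
    return [ContingencyTable(*(int(x) for x in row)) for row in draws]


# ---------------------------------------------------------------------------
# planted-module interactome


@dataclass(frozen=True)
class PpiSimConfig:
    n_background: int = 100
    module_sizes: tuple[int, ...] = (12, 12)
    p_in: float = 0.9
    p_out: float = 0.02
    seed_genes_per_module: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if any(m < 2 for m in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if self.seed_genes_per_module < 1 or any(
            self.seed_genes_per_module > m for m in self.module_sizes
        ):
            raise ValueError("seed_genes_per_module must fit inside every module")


def default_ppi_config(seed: int = 0) -> PpiSimConfig:
    return PpiSimConfig(seed=seed)


@dataclass
class PpiSimTruth:
    modules: list[frozenset[str]]
    seeds: list[str]  # seed genes across modules
    background: frozenset[str]
    n_nodes_emitted: int
    n_edges_emitted: int

    def all_genes(self) -> frozenset[str]:
        out = set(self.background)
        for m in self.modules:
            out |= m
        return frozenset(out)


def simulate_ppi(
    config: PpiSimConfig, out_dir: str | Path | None = None
) -> tuple[nx.Graph, PpiSimTruth, dict[str, Path]]:
    """Planted-module graph over a sparse background (see module docstring).

    Node names are GENE0001, GENE0002, ... — modules first, then background.
    When ``out_dir`` is given, emits minimal PSI-MITAB (taxid:9606) plus the
    seed-gene file.
    """
    n_total = sum(config.module_sizes) + config.n_background
    if n_total > 9999:
        raise ValueError("too many nodes for the GENE#### naming scheme")
    rng = np.random.default_rng(config.seed)
    names = [f"GENE{i + 1:04d}" for i in range(n_total)]

    modules: list[frozenset[str]] = []
    pos = 0
    module_of = {}
    for mi, size in enumerate(config.module_sizes):
        mem = names[pos : pos + size]
        for v in mem:
            module_of[v] = mi
        modules.append(frozenset(mem))
        pos += size
    background = frozenset(names[pos:])

    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(n_total):
        for j in range(i + 1, n_total):
            u, v = names[i], names[j]
            mu, mv = module_of.get(u), module_of.get(v)
            if mu is not None and mu == mv:
                p = config.p_in
            elif mu is None or mv is None:  # pair involves background
                p = config.p_out
            else:  # distinct planted modules stay unwired
                continue
            if rng.random() < p:
                g.add_edge(u, v, n_records=1)

    seeds = [
        s for mod in modules for s in sorted(mod)[: config.seed_genes_per_module]
    ]
    truth = PpiSimTruth(
        modules=modules,
        seeds=seeds,
        background=background,
        n_nodes_emitted=g.number_of_nodes(),
        n_edges_emitted=g.number_of_edges(),
    )
    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths["mitab"] = out / "interactome.mitab.txt"
        write_mitab_minimal(g, paths["mitab"])
        paths["seeds"] = out / "seed_genes.txt"
        paths["seeds"].write_text("\n".join(seeds) + "\n")
        lines = ["gene\trole\tmodule"]
        for mi, mod in enumerate(modules):
            for v in sorted(mod):
                lines.append(f"{v}\tmodule\t{mi + 1}")
        for v in sorted(background):
            lines.append(f"{v}\tbackground\t0")
        paths["truth"] = out / "truth_ppi.tsv"
        paths["truth"].write_text("\n".join(lines) + "\n")
    return g, truth, paths


# ---------------------------------------------------------------------------
# gene-set collections


def simulate_genesets(
    truth: PpiSimTruth,
    n_noise_sets: int = 30,
    noise_set_size: int = 15,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[str]], dict[str, Path]]:
    """Collections aligned with the planted modules.

    One planted set per module (its members plus 10% random decoy genes) and
    ``n_noise_sets`` uniform random sets over all gene names; the same sets
    are written both as a GMT pathway collection and as a disease-gene TSV.
    Returns ``{"planted": [...], "noise": [...]}`` term ids and the paths.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(truth.all_genes())
    gmt_lines: list[str] = []
    dis_lines: list[str] = ["disease_id\tdisease_name\tgene"]
    planted_ids: list[str] = []

    for mi, mod in enumerate(truth.modules):
        members = sorted(mod)
        n_decoys = max(1, int(round(0.1 * len(members))))
        pool = [g for g in universe if g not in mod]
        decoys = list(rng.choice(pool, size=n_decoys, replace=False))
        genes = members + sorted(decoys)
        tid = f"PLANTED_M{mi + 1}"
        planted_ids.append(tid)
        gmt_lines.append("\t".join([tid, f"planted module {mi + 1}", *genes]))
        for gsym in genes:
            dis_lines.append(f"{tid}\tplanted module {mi + 1}\t{gsym}")

    noise_ids: list[str] = []
    for si in range(n_noise_sets):
        genes = sorted(rng.choice(universe, size=noise_set_size, replace=False))
        tid = f"NOISE_{si + 1:04d}"
        noise_ids.append(tid)
        gmt_lines.append("\t".join([tid, f"noise set {si + 1}", *genes]))
        for gsym in genes:
            dis_lines.append(f"{tid}\tnoise set {si + 1}\t{gsym}")

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths["gmt"] = out / "pathways.gmt"
        paths["gmt"].write_text("\n".join(gmt_lines) + "\n")
        paths["disease"] = out / "disease_genes.tsv"
        paths["disease"].write_text("\n".join(dis_lines) + "\n")
    return {"planted": planted_ids, "noise": noise_ids}, paths
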
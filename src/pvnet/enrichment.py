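"""Over-representation analysis of gene lists.

Given a query gene set and a collection of annotated gene sets (KEGG-like
pathways from GMT files, or disease–gene associations from a 3-column TSV),
each term is tested with the hypergeometric upper tail: drawing ``n`` query
genes from a universe of ``N`` genes of which ``K`` belong to the term, the
p-value is P(X >= k) for the observed overlap ``k``. P-values are adjusted
across all tested terms with Benjamini–Hochberg step-up; by default the
q-value equals the BH-adjusted p (pi0 = 1), with Storey's pi0 smoother
available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichParams",
    "EnrichmentResult",
    "read_gmt",
    "read_disease_tsv",
    "hypergeom_upper",
    "bh_adjust",
    "storey_pi0",
    "enrich",
    "results_table",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Mapping term_id -> (term_name, gene set); genes are uppercased."""

    sets: dict[str, tuple[str, frozenset[str]]]
    kind: str = "pathway"  # or "disease"

    def __len__(self) -> int:
        return len(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass(frozen=True)
class EnrichParams:
    p_cutoff: float = 0.05
    adjust_method: str = "BH"
    q_cutoff: float = 0.1
    q_method: str = "bh"  # "bh" (pi0 = 1) or "storey"

    def __post_init__(self) -> None:
        for name in ("p_cutoff", "q_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.adjust_method != "BH":
            raise ValueError("only BH adjustment is supported")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # overlap
    n: int  # query size within universe
    K: int  # term size within universe
    N: int  # universe size
    p: float
    p_adj: float
    q: float
    gene_hits: tuple[str, ...]
    significant: bool


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``term_id TAB description TAB gene TAB gene ...``."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        term_id, name, *genes = fields
        if term_id in sets:
            raise ValueError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
        geneset = frozenset(g.strip().upper() for g in genes if g.strip())
        if not geneset:
            raise ValueError(f"{path}:{lineno}: term {term_id!r} has no genes")
        sets[term_id] = (name, geneset)
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets, kind="pathway")


def read_disease_tsv(path: str | Path) -> GeneSetCollection:
    """Read ``disease_id TAB disease_name TAB gene`` rows into a collection."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = {"disease_id", "disease_name", "gene"}
    if missing := need - set(df.columns):
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for did, grp in df.groupby("disease_id", sort=True):
        genes = frozenset(g.strip().upper() for g in grp["gene"] if g.strip())
        if genes:
            sets[str(did)] = (str(grp["disease_name"].iloc[0]), genes)
    if not sets:
        raise ValueError(f"{path}: no disease-gene rows")
    return GeneSetCollection(sets=sets, kind="disease")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable for extreme tails."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]  # enforce monotonicity
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def storey_pi0(pvals: Sequence[float]) -> float:
    """Storey's pi0 estimate via the cubic-smoother-over-lambda recipe."""
    p = np.asarray(pvals, dtype=float)
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_hat = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
    )
    if p.size < 8 or np.all(pi0_hat == 0):
        return 1.0
    coef = np.polynomial.polynomial.polyfit(lambdas, pi0_hat, deg=3)
    pi0 = float(np.polynomial.polynomial.polyval(lambdas[-1], coef))
    return float(min(max(pi0, 1e-8), 1.0))


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    params: EnrichParams = EnrichParams(),
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Test every collection term for over-representation in ``query``.

    The universe defaults to the union of all collection genes; the query is
    intersected with it first. Terms with zero overlap are not reported but
    every term with k >= 1 enters the BH adjustment. Results are sorted by
    ascending adjusted p, ties by term_id.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    q = {g.strip().upper() for g in query if g.strip()}
    if not q:
        raise ValueError("empty query gene set")
    uni = frozenset(g.strip().upper() for g in universe) if universe is not None \
        else collection.all_genes()
    q_in = q & uni
    if not q_in:
        warnings.warn("query does not intersect the universe; no terms tested")
        return []
    N, n = len(uni), len(q_in)

    tested: list[tuple[str, str, int, int, tuple[str, ...], float]] = []
    for term_id in sorted(collection.sets):
        name, genes = collection.sets[term_id]
        genes_in = genes & uni
        hits = tuple(sorted(genes_in & q_in))
        k, K = len(hits), len(genes_in)
        if k == 0:
            continue
        tested.append((term_id, name, k, K, hits, hypergeom_upper(k, K, n, N)))
    if not tested:
        return []

    pvals = [t[5] for t in tested]
    p_adj = bh_adjust(pvals)
    if params.q_method == "storey":
        pi0 = storey_pi0(pvals)
        qvals = [min(pi0 * a, 1.0) for a in p_adj]
    else:
        qvals = list(p_adj)

    results = [
        EnrichmentResult(
            term_id=tid, term_name=name, k=k, n=n, K=K, N=N,
            p=p, p_adj=pa, q=qv, gene_hits=hits,
            significant=(p <= params.p_cutoff and qv <= params.q_cutoff),
        )
        for (tid, name, k, K, hits, p), pa, qv in zip(tested, p_adj, qvals)
    ]
    results.sort(key=lambda r: (r.p_adj, r.term_id))
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Results as a DataFrame with GeneRatio/BgRatio dot-plot columns."""
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.k,
            "n": r.n,
            "K": r.K,
            "N": r.N,
            "GeneRatio": f"{r.k}/{r.n}",
            "BgRatio": f"{r.K}/{r.N}",
            "p": f"{r.p:.6g}",
            "p_adj": f"{r.p_adj:.6g}",
            "q": f"{r.q:.6g}",
            "gene_hits": ",".join(r.gene_hits),
            "significant": str(r.significant).lower(),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "k", "n", "K", "N", "GeneRatio",
            "BgRatio", "p", "p_adj", "q", "gene_hits", "significant",
        ],
    )
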
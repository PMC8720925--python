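"""Synthetic-data generators: reproducibility and truth consistency."""

import numpy as np
import pytest

from pvnet import mcode, reports, signal, simulate
from pvnet.enrichment import read_gmt
from pvnet.network import SeedSet, expand_seed, read_mitab, read_seed_genes
from pvnet.simulate import (
    PpiSimConfig,
    ReportSimConfig,
    default_report_config,
    sample_null_tables,
    simulate_genesets,
    simulate_ppi,
    simulate_report_store,
    simulate_reports,
)

SMALL = ReportSimConfig(
    n_reports=300,
    drugs=(("alpha", 0.2), ("beta", 0.15)),
    events=(("E1", "S1", 0.1), ("E2", "S2", 0.05)),
    injected=(("alpha", "E1", 5.0),),
    n_versions_dup_frac=0.2,
    seed=21,
)


class TestReportGenerator:
    def test_bit_reproducible_and_seed_sensitive(self, tmp_path):
        p1, _ = simulate_reports(SMALL, tmp_path / "a")
        p2, _ = simulate_reports(SMALL, tmp_path / "b")
        assert p1["drug"].read_bytes() == p2["drug"].read_bytes()
        assert p1["reac"].read_bytes() == p2["reac"].read_bytes()
        p3, _ = simulate_reports(
            ReportSimConfig(**{**SMALL.__dict__, "seed": 22}), tmp_path / "c"
        )
        assert p1["reac"].read_bytes() != p3["reac"].read_bytes()

    def test_planted_duplicates_removed_exactly_by_dedup(self):
        cfg = ReportSimConfig(
            n_reports=100,
            drugs=(("alpha", 0.2),),
            events=(("E1", "S1", 0.1),),
            n_versions_dup_frac=0.2,
            seed=5,
        )
        store, truth = simulate_report_store(cfg)
        assert len(store) == 120
        assert truth.n_duplicates == 20
        assert len(reports.deduplicate(store)) == 100

    def test_emitted_files_accepted_with_zero_drops(self, tmp_path):
        paths, _ = simulate_reports(SMALL, tmp_path)
        store = reports.read_faers_tables(
            paths["demo"], paths["drug"], paths["reac"], dialect="tsv"
        )
        assert store.provenance["rows_dropped"]["total"] == 0
        term_map = reports.TermMap.read_tsv(paths["term_map"])
        mapped = reports.apply_term_map(store, term_map, on_miss="error")
        assert len(mapped) == len(store)

    def test_tables_from_files_equal_truth_recount(self, tmp_path):
        paths, truth = simulate_reports(SMALL, tmp_path)
        store = reports.read_faers_tables(
            paths["demo"], paths["drug"], paths["reac"], dialect="tsv"
        )
        store = reports.deduplicate(store)
        for drug in ("alpha", "beta"):
            for pt in ("E1", "E2"):
                assert signal.build_table(store, drug, pt) == \
                    simulate.table_from_truth(truth, drug, pt)

    def test_null_simulation_ror_near_one(self):
        """With no injected association the CI covers 1 at its nominal rate."""
        covered = defined = 0
        for rep in range(60):
            cfg = ReportSimConfig(
                n_reports=2_000,
                drugs=(("alpha", 0.1),),
                events=(("E1", "S1", 0.1),),
                seed=700 + rep,
            )
            store, _ = simulate_report_store(cfg)
            res = signal.compute_ror(signal.build_table(store, "alpha", "E1"))
            if res.ror is None:
                continue
            defined += 1
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert defined >= 55
        assert covered / defined >= 0.85


class TestNullTables:
    def test_true_or_one_coverage(self):
        rng = np.random.default_rng(99)
        tabs = sample_null_tables(400, rng=rng)
        cov = sum(
            1
            for t in tabs
            if (r := signal.compute_ror(t)).ror is not None
            and r.ci_low <= 1.0 <= r.ci_high
        )
        assert 0.91 <= cov / len(tabs) <= 0.99

    def test_total_preserved(self):
        for t in sample_null_tables(20, n_reports=500):
            assert t.n == 500


class TestPpiGenerator:
    def test_round_trip_counts_match_internal_tally(self, tmp_path):
        g, truth, paths = simulate_ppi(PpiSimConfig(seed=13), tmp_path)
        back = read_mitab(paths["mitab"], taxon="taxid:9606")
        assert back.number_of_nodes() == truth.n_nodes_emitted - sum(
            1 for v in g.nodes if g.degree[v] == 0
        )
        assert back.number_of_edges() == truth.n_edges_emitted
        seeds = read_seed_genes(paths["seeds"])
        assert len(seeds) == len(truth.seeds)

    def test_p_out_zero_isolates_modules(self):
        g, truth, _ = simulate_ppi(
            PpiSimConfig(n_background=30, module_sizes=(6, 6), p_out=0.0, seed=2)
        )
        first = truth.modules[0]
        res = expand_seed(g, SeedSet(frozenset(sorted(first)[:2])))
        assert not (set(res.network.nodes) & truth.modules[1])

    def test_complete_module_recovered_with_score_equal_size(self):
        g, truth, _ = simulate_ppi(
            PpiSimConfig(n_background=0, module_sizes=(5,), p_in=1.0, p_out=0.0,
                         seed=1)
        )
        clusters = mcode.predict_complexes(g)
        assert len(clusters) == 1
        assert clusters[0].members == truth.modules[0]
        assert clusters[0].score == pytest.approx(5.0)

    def test_reproducible(self):
        g1, _, _ = simulate_ppi(PpiSimConfig(seed=4))
        g2, _, _ = simulate_ppi(PpiSimConfig(seed=4))
        assert set(g1.edges) == set(g2.edges)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PpiSimConfig(p_in=0.5, p_out=0.6)
        with pytest.raises(ValueError):
            PpiSimConfig(module_sizes=(1,))
        with pytest.raises(ValueError):
            simulate_ppi(PpiSimConfig(n_background=20_000))


class TestGenesetGenerator:
    def test_planted_set_contains_module_plus_decoys(self, tmp_path):
        _, truth, _ = simulate_ppi(PpiSimConfig(seed=6))
        ids, paths = simulate_genesets(truth, n_noise_sets=5, seed=6,
                                       out_dir=tmp_path)
        coll = read_gmt(paths["gmt"])
        planted = coll.sets["PLANTED_M1"][1]
        assert truth.modules[0] <= planted
        assert len(planted) == len(truth.modules[0]) + 1  # 10% decoys of 12

    def test_no_noise_sets_gives_one_line_per_module(self, tmp_path):
        _, truth, _ = simulate_ppi(PpiSimConfig(seed=6))
        _, paths = simulate_genesets(truth, n_noise_sets=0, seed=6,
                                     out_dir=tmp_path)
        lines = paths["gmt"].read_text().splitlines()
        assert len(lines) == len(truth.modules)

    def test_disease_and_gmt_collections_agree(self, tmp_path):
        from pvnet.enrichment import read_disease_tsv

        _, truth, _ = simulate_ppi(PpiSimConfig(seed=8))
        _, paths = simulate_genesets(truth, n_noise_sets=3, seed=8,
                                     out_dir=tmp_path)
        gmt = read_gmt(paths["gmt"])
        dis = read_disease_tsv(paths["disease"])
        assert {t: g for t, (_, g) in gmt.sets.items()} == {
            t: g for t, (_, g) in dis.sets.items()
        }
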
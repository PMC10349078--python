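"""Screening pipeline stages and inverse target ranking."""

import numpy as np
import pytest

from seq2drug.screening import (
    DEFAULT_PAINS_SUBSET,
    ScreeningConfig,
    cluster_compounds,
    fingerprint,
    lipinski_filter,
    load_pains_catalog,
    novelty_check,
    pains_filter,
    rank_targets,
    run_screening,
    score_library,
    select_representatives,
    tanimoto,
)


class TestLipinski:
    def test_methane_passes_clean(self):
        passed, violations = lipinski_filter("C", max_violations=1)
        assert passed and violations == []

    def test_heavy_polyol_fails_at_default(self):
        # long polyol: MW > 500 and far more than 5 H-bond donors
        smiles = "OC" + "C(O)" * 16 + "CO"
        passed, violations = lipinski_filter(smiles, max_violations=1)
        assert not passed and len(violations) >= 2

    def test_vacuous_threshold_accepts_everything(self):
        smiles = "OC" + "C(O)" * 16 + "CO"
        passed, _ = lipinski_filter(smiles, max_violations=4)
        assert passed


class TestPains:
    def test_methane_clean(self):
        flagged, matched = pains_filter("C")
        assert not flagged and matched == []

    def test_quinone_flagged_with_pattern_id(self):
        flagged, matched = pains_filter("O=C1C=CC(=O)C=C1")
        assert flagged and "quinone_a" in matched

    def test_empty_catalog_flags_nothing(self):
        flagged, matched = pains_filter("O=C1C=CC(=O)C=C1", catalog=[])
        assert not flagged

    def test_malformed_pattern_rejected_by_name(self, tmp_path):
        path = tmp_path / "catalog.tsv"
        path.write_text("ok\tcc\nbroken\t[[Q\n")
        with pytest.raises(ValueError, match="broken"):
            load_pains_catalog(path)

    def test_bundled_subset_compiles(self):
        assert len(load_pains_catalog()) == len(DEFAULT_PAINS_SUBSET)


class TestFingerprint:
    def test_self_tanimoto_is_one(self):
        fp = fingerprint("CC(=O)Nc1ccncc1")
        assert tanimoto(fp, fp) == 1.0

    def test_smiles_order_irrelevant(self):
        assert fingerprint("CCO") == fingerprint("OCC")

    def test_benzene_vs_cyclohexane_differ(self):
        assert tanimoto(fingerprint("c1ccccc1"), fingerprint("C1CCCCC1")) < 1.0


class TestClustering:
    def test_identical_fingerprints_one_cluster(self):
        fps = [frozenset({1, 2, 3})] * 5
        assert cluster_compounds(fps, 0.4).tolist() == [0] * 5

    def test_disjoint_sets_all_singletons(self):
        fps = [frozenset({i}) for i in range(6)]
        assert sorted(cluster_compounds(fps, 0.9).tolist()) == list(range(6))

    def test_hand_simulated_leader_assignment(self):
        fps = [frozenset({1, 2, 3, 4}),   # leader A
               frozenset({1, 2, 3, 5}),   # T=0.6 vs A, dist 0.4 <= 0.4 -> A
               frozenset({9, 10}),        # leader B
               frozenset({9, 10, 11}),    # T=2/3 vs B, dist 1/3 -> B
               frozenset({20}),           # leader C
               frozenset({1, 2, 3, 4})]   # identical to A
        # sizes: A=3, B=2, C=1 -> relabelled 0, 1, 2
        assert cluster_compounds(fps, 0.4).tolist() == [0, 0, 1, 1, 2, 0]

    def test_partition_property_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            fps = [frozenset(rng.choice(64, size=rng.integers(1, 12), replace=False).tolist())
                   for _ in range(rng.integers(1, 30))]
            assignment = cluster_compounds(fps, float(rng.uniform(0.1, 0.9)))
            assert len(assignment) == len(fps)
            assert set(assignment) == set(range(assignment.max() + 1))


class TestRepresentatives:
    def test_singleton_clusters_follow_global_ranking(self):
        scores = {"a": 0.9, "b": 0.5, "c": 0.7}
        clusters = {"a": 0, "b": 1, "c": 2}
        assert set(select_representatives(scores, clusters, 1)) == {"a", "b", "c"}

    def test_two_cluster_hand_fixture(self):
        scores = {"a": 0.9, "b": 0.8, "c": 0.7, "d": 0.95, "e": 0.1}
        clusters = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1}
        assert select_representatives(scores, clusters, 1) == ["a", "d"]

    def test_k_larger_than_cluster_takes_whole_cluster(self):
        scores = {"a": 0.9, "b": 0.8}
        clusters = {"a": 0, "b": 0}
        assert select_representatives(scores, clusters, 5) == ["a", "b"]


class TestNovelty:
    def test_query_present_gives_one(self):
        fp = fingerprint("CCO")
        sim, ident = novelty_check(fp, [("x", fingerprint("CCC")), ("y", fp)])
        assert sim == 1.0 and ident == "y"

    def test_disjoint_gives_zero(self):
        sim, _ = novelty_check(frozenset({1}), [("x", frozenset({2}))])
        assert sim == 0.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        refs = [(f"r{i}", frozenset(rng.choice(128, size=10, replace=False).tolist()))
                for i in range(10)]
        query = frozenset(rng.choice(128, size=10, replace=False).tolist())
        best = max(tanimoto(query, fp) for _, fp in refs)
        assert novelty_check(query, refs)[0] == best

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            novelty_check(frozenset({1}), [])


class TestScoreLibrary:
    def test_single_entry(self, trained_runs):
        run = trained_runs[0]
        df = score_library(run.model, run.provider, [("c0", "CCO")], "MKVWKDHW")
        assert len(df) == 1 and df.iloc[0]["id"] == "c0"

    def test_scores_equal_per_pair_prediction(self, trained_runs):
        from seq2drug.chem_graph import molecule_graph, parse_molecule
        from seq2drug.interaction_model import predict_interaction
        from seq2drug.protein_seq import embed_protein, tokenize

        run = trained_runs[0]
        library = [(f"c{i}", s) for i, s in enumerate(run.world.compound_has_key)][:6]
        seq = run.motif_protein()
        df = score_library(run.model, run.provider, library, seq)
        emb = embed_protein(tokenize(seq), run.provider)
        for row in df.itertuples(index=False):
            direct = predict_interaction(
                run.model, molecule_graph(parse_molecule(row.smiles)), emb)
            assert abs(row.score - direct.probability) < 1e-12

    def test_ranking_invariant_to_input_shuffling(self, trained_runs):
        rng = np.random.default_rng(2)
        run = trained_runs[0]
        library = [(f"c{i}", s) for i, s in enumerate(run.world.compound_has_key)]
        seq = run.motif_protein()
        a = score_library(run.model, run.provider, library, seq)
        shuffled = [library[i] for i in rng.permutation(len(library))]
        b = score_library(run.model, run.provider, shuffled, seq)
        assert sorted(zip(a["score"], a["id"])) == sorted(zip(b["score"], b["id"]))


class TestPipeline:
    def test_stage_counts_non_increasing_and_deterministic(self, trained_runs):
        run = trained_runs[0]
        library = [(f"c{i}", s) for i, s in enumerate(run.world.compound_has_key)]
        cfg = ScreeningConfig(top_fraction=0.5, cluster_cutoff=0.6)
        rep1 = run_screening(run.model, run.provider, library, run.motif_protein(), cfg)
        rep2 = run_screening(run.model, run.provider, library, run.motif_protein(), cfg)
        c = rep1.stage_counts
        assert c["scored"] >= c["top_fraction"] >= c["pains"] >= c["lipinski"] >= c["representatives"]
        assert rep1.stage_counts == rep2.stage_counts
        assert rep1.representatives == rep2.representatives


class TestRankTargets:
    def test_panel_of_one(self, trained_runs):
        run = trained_runs[0]
        df = rank_targets(run.model, run.provider, "CCO", [("p0", "MKVWKDHW")])
        assert df.iloc[0]["protein_id"] == "p0"

    def test_motif_protein_ranked_first_in_most_seeds(self, trained_runs):
        hits = 0
        for run in trained_runs:
            panel = [(pid, seq) for pid, seq in run.world.proteins[:12]]
            flags = {pid: run.world.protein_has_motif[seq] for pid, seq in panel}
            assert any(flags.values()) and not all(flags.values())
            df = rank_targets(run.model, run.provider, run.key_compound(), panel)
            if flags[df.iloc[0]["protein_id"]]:
                hits += 1
        assert hits >= 8, f"planted target ranked first in only {hits}/10 seeds"
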
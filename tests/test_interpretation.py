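"""Mutation scanning and substitution-effect analysis."""

import numpy as np
import pytest

from seq2drug.interpretation import (
    MutationScanResult,
    important_sites,
    model_scorer,
    mutation_scan,
    relative_activity_change,
    substitution_effect,
    write_scan_tsv,
)
from seq2drug.synthetic_data import generate_substitution_pairs, pair_oracle


class TestRelativeActivityChange:
    def test_hand_computed_three_position_fixture(self):
        # position means: 0.02, 0.05, 0.01 -> dR = (0.4, 1.0, 0.2)
        delta_S = np.zeros((3, 20))
        delta_S[0, :4] = 0.1
        delta_S[1, :10] = 0.1
        delta_S[2, :2] = 0.1
        bar, rel = relative_activity_change(delta_S)
        np.testing.assert_allclose(bar, [0.02, 0.05, 0.01], atol=1e-15)
        np.testing.assert_allclose(rel, [0.4, 1.0, 0.2], atol=1e-12)

    def test_constant_positive_matrix_gives_all_ones(self):
        _, rel = relative_activity_change(np.full((5, 20), 0.3))
        np.testing.assert_array_equal(rel, np.ones(5))

    def test_zero_matrix_gives_zeros(self):
        _, rel = relative_activity_change(np.zeros((4, 20)))
        np.testing.assert_array_equal(rel, np.zeros(4))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            relative_activity_change(np.empty((0, 20)))


class TestImportantSites:
    def test_absolute_threshold(self):
        assert important_sites(np.array([1.0, 0.2, 0.5]), "absolute", 0.38) == [1, 3]

    def test_quantile_count_on_length_100(self):
        rng = np.random.default_rng(0)
        profile = rng.permutation(np.linspace(0, 1, 100))
        assert len(important_sites(profile, "quantile", 0.05)) == 5

    def test_modes_agree_when_quantile_sits_at_cutoff(self):
        # 95th percentile value is exactly 0.38: absolute > 0.38 = top 5%
        profile = np.concatenate([np.linspace(0.0, 0.38, 95),
                                  np.linspace(0.5, 1.0, 5)])
        assert (important_sites(profile, "absolute", 0.38)
                == important_sites(profile, "quantile", 0.05))

    def test_quantile_out_of_range(self):
        with pytest.raises(ValueError):
            important_sites(np.array([0.5]), "quantile", 1.5)


@pytest.fixture(scope="module")
def scan(tiny_model, tiny_provider):
    return mutation_scan(tiny_model, tiny_provider, "MKVWKDHWAAGH", "CCOc1ccncc1")


class TestMutationScan:
    def test_wild_type_columns_exactly_zero(self, scan):
        for i, aa in enumerate(scan.wild_type):
            j = scan.alphabet.index(aa)
            assert scan.delta_S[i, j] == 0.0

    def test_delta_s_nonnegative(self, scan):
        assert np.all(scan.delta_S >= 0.0)

    def test_max_delta_r_is_one(self, scan):
        assert scan.delta_S_bar.max() > 0.0
        assert scan.delta_R.max() == 1.0

    def test_exactly_20L_plus_1_evaluations(self, scan):
        assert scan.n_evaluations == 20 * len(scan.wild_type) + 1

    def test_spot_check_entry_against_independent_forward(self, scan, tiny_model, tiny_provider):
        from seq2drug.chem_graph import molecule_graph, parse_molecule
        from seq2drug.interaction_model import score_batch
        from seq2drug.protein_seq import embed_protein, tokenize

        i, j = 3, 11  # arbitrary position / residue
        seq = scan.wild_type
        mutant = seq[:i] + scan.alphabet[j] + seq[i + 1:]
        g = molecule_graph(parse_molecule("CCOc1ccncc1"))
        s_prime = score_batch(
            tiny_model, [(g, embed_protein(tokenize(mutant), tiny_provider))])[0].probability
        assert scan.delta_S[i, j] == abs(scan.base_score - s_prime)

    def test_batch_size_does_not_change_result(self, scan, tiny_model, tiny_provider):
        other = mutation_scan(tiny_model, tiny_provider, scan.wild_type,
                              "CCOc1ccncc1", batch_size=17)
        np.testing.assert_array_equal(scan.delta_S, other.delta_S)

    def test_raw_average_mode_uses_mutant_scores(self, tiny_model, tiny_provider):
        raw = mutation_scan(tiny_model, tiny_provider, "MKVWK", "CCO", average="raw")
        np.testing.assert_allclose(raw.delta_S_bar, raw.s_prime.mean(axis=1))

    def test_scan_output_depends_on_compound(self, tiny_model, tiny_provider):
        a = mutation_scan(tiny_model, tiny_provider, "MKVWKDHW", "CCOc1ccncc1")
        b = mutation_scan(tiny_model, tiny_provider, "MKVWKDHW", "C1CCCCC1")
        assert not np.array_equal(a.s_prime, b.s_prime)

    def test_scan_tsv_export(self, scan, tmp_path):
        write_scan_tsv(scan, tmp_path / "scan", protein_id="prot1")
        delta_s = (tmp_path / "scan.delta_s.tsv").read_text().splitlines()
        assert len(delta_s) == len(scan.wild_type) + 1
        sites = (tmp_path / "scan.sites.tsv").read_text().splitlines()
        assert len(sites) == len(scan.important_sites) + 1


class TestPlantedRecovery:
    def test_motif_positions_dominate_background_delta_r(self, trained_runs):
        hits = 0
        for run in trained_runs:
            seq = run.motif_protein()
            scan = mutation_scan(run.model, run.provider, seq, run.key_compound())
            start = seq.find(run.world.spec.motif)
            motif = list(range(start, start + len(run.world.spec.motif)))
            background = [i for i in range(len(seq)) if i not in motif]
            if scan.delta_R[motif].mean() > scan.delta_R[background].mean():
                hits += 1
        assert hits >= 8, f"motif recovery in only {hits}/10 seeds"


@pytest.fixture(scope="module")
def pairs():
    return generate_substitution_pairs(50, seed=5)


class TestSubstitutionEffect:
    def test_oracle_scorer_reaches_perfect_accuracy(self, pairs):
        result = substitution_effect(pair_oracle(pairs), pairs)
        assert result.accuracy == 1.0

    def test_negated_oracle_is_always_wrong(self, pairs):
        oracle = pair_oracle(pairs)
        result = substitution_effect(lambda s, q: -oracle(s, q), pairs)
        assert result.accuracy == 0.0

    def test_constant_scorer_is_wrong_under_strict_sign_rule(self, pairs):
        result = substitution_effect(lambda s, q: 0.42, pairs)
        assert result.accuracy == 0.0

    def test_unparseable_pair_skipped_and_excluded(self, pairs):
        rows = pairs.to_dict("records")
        rows.append({"smiles_ch3": "C(", "smiles_cf3": "C(F)(F)F",
                     "pact_ch3": 6.0, "pact_cf3": 7.5, "sequence": "MKV"})
        result = substitution_effect(pair_oracle(pairs), rows)
        assert result.n_skipped == 1
        assert len(result.pairs) == len(pairs)

    def test_model_scorer_runs_on_trained_model(self, trained_runs, pairs):
        run = trained_runs[0]
        result = substitution_effect(model_scorer(run.model, run.provider), pairs.head(4))
        assert len(result.pairs) == 4
        assert 0.0 <= result.accuracy <= 1.0
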
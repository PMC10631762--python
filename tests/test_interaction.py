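"""Interaction matrix, trigram triads, loop-helix potentials and breakdowns."""

import numpy as np
import pandas as pd
import pytest

from tcrmhc.alphabet import AMINO_ACIDS
from tcrmhc.interaction import (
    DEFAULT_CLASSES,
    DEFAULT_RULES,
    InteractionMatrix,
    ResidueClassMap,
    build_matrix,
    enumerate_gene_pairings,
    gene_allele_scores,
    helix_distributions,
    loop_helix_potential,
    per_residue_breakdown,
    relu_normalize,
    score_trigram_pair,
)

from conftest import make_record


def brute_force_potential(loop, helix, matrix, validity="all_weak"):
    """Independent exhaustive enumeration of all trigram-pair totals."""
    total = 0
    for a in range(len(loop) - 2):
        for b in range(len(helix) - 2):
            scores = [matrix.score(loop[a + i], helix[b + i]) for i in range(3)]
            if validity == "all_weak":
                ok = all(s >= 1 for s in scores)
            else:
                ok = all(s >= 0 for s in scores) and any(s >= 1 for s in scores)
            if ok:
                total += sum(scores)
    return total


class TestBuildMatrix:
    def test_default_matrix_is_symmetric(self, matrix):
        assert np.abs(matrix.scores - matrix.scores.T).max() == 0

    def test_charge_complementarity_scores_plus_two(self, matrix):
        assert matrix.score("K", "E") == 2
        assert matrix.score("E", "K") == 2

    def test_noninteracting_residues_zero_out_their_rows(self, matrix):
        g = AMINO_ACIDS.index("G")
        assert (matrix.scores[g] == 0).all()
        assert (matrix.scores[:, g] == 0).all()

    def test_class_invariants(self, matrix):
        # positive x negative > hydrophilic pair > 0 > phob-phil > like-charge
        assert matrix.score("K", "D") > matrix.score("S", "T") > 0
        assert 0 > matrix.score("F", "S") > matrix.score("K", "R")
        assert matrix.score("D", "E") == matrix.score("K", "R") == -2

    def test_missing_rule_pair_is_an_error(self):
        rules = dict(DEFAULT_RULES)
        del rules[frozenset(["positive", "negative"])]
        with pytest.raises(ValueError, match="positive"):
            build_matrix(rule_scores=rules)

    def test_class_map_must_cover_all_residues(self):
        bad = dict(DEFAULT_CLASSES)
        del bad["W"]
        with pytest.raises(ValueError):
            ResidueClassMap(bad)

    def test_self_check_rejects_a_scheme_missing_the_worked_examples(self):
        # zero matrix scores NNK/EDQ as (0,0,0): not the implemented scheme
        with pytest.raises(ValueError, match="self-check"):
            m = InteractionMatrix(scores=np.zeros((20, 20), dtype=int))
            m.self_check()

    def test_csv_override_round_trip(self, matrix, tmp_path):
        path = tmp_path / "matrix.csv"
        matrix.to_frame().to_csv(path)
        loaded = InteractionMatrix.from_csv(path)
        assert np.array_equal(loaded.scores, matrix.scores)


class TestScoreTrigramPair:
    def test_productive_worked_example(self, matrix):
        triad = score_trigram_pair("NNK", "EDQ", matrix)
        assert triad.pair_scores == (1, 1, 1)
        assert triad.valid
        assert triad.total == 3

    def test_clashing_worked_example_discounted(self, matrix):
        triad = score_trigram_pair("KEL", "RKA", matrix)
        assert triad.pair_scores == (-2, 2, 0)
        assert not triad.valid
        assert triad.total == 0

    def test_noninteracting_triad_invalid(self, matrix):
        triad = score_trigram_pair("GGG", "GGG", matrix)
        assert triad.pair_scores == (0, 0, 0)
        assert not triad.valid

    def test_alternative_validity_rule_reproduces_worked_examples(self, matrix):
        assert score_trigram_pair("NNK", "EDQ", matrix, validity="no_clash").valid
        assert not score_trigram_pair("KEL", "RKA", matrix, validity="no_clash").valid

    def test_nonstandard_residue_scores_zero_without_raising(self, matrix):
        triad = score_trigram_pair("NXK", "EDQ", matrix)
        assert triad.pair_scores == (1, 0, 1)

    def test_wrong_length_rejected(self, matrix):
        with pytest.raises(ValueError):
            score_trigram_pair("NN", "EDQ", matrix)


class TestLoopHelixPotential:
    def test_worked_sequences_match_exhaustive_oracle(self, matrix):
        res = loop_helix_potential("YNNKEL", "EDQRKA", matrix)
        assert res.n_triads == 16
        assert res.score == brute_force_potential("YNNKEL", "EDQRKA", matrix)

    def test_poly_alanine_helix_scores_zero(self, matrix):
        assert loop_helix_potential("YNNKEL", "AAAAAA", matrix).score == 0

    def test_short_input_warns_and_scores_zero(self, matrix):
        with pytest.warns(UserWarning):
            assert loop_helix_potential("YN", "EDQRKA", matrix).score == 0

    def test_attribution_sums_to_total(self, matrix, rng):
        for _ in range(25):
            loop = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 9)))
            helix = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 9)))
            res = loop_helix_potential(loop, helix, matrix)
            assert res.helix_attribution.sum() == pytest.approx(res.score)

    def test_matches_oracle_on_random_pairs(self, matrix, rng):
        for validity in ("all_weak", "no_clash"):
            for _ in range(100):
                loop = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 11)))
                helix = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 11)))
                res = loop_helix_potential(loop, helix, matrix, validity=validity)
                assert res.score == brute_force_potential(loop, helix, matrix, validity)

    def test_appending_residues_never_decreases_potential(self, matrix, rng):
        loop = "".join(rng.choice(list(AMINO_ACIDS), size=5))
        helix = "".join(rng.choice(list(AMINO_ACIDS), size=8))
        base = loop_helix_potential(loop, helix, matrix).score
        for extra in "KDSYF":
            longer = loop_helix_potential(loop + extra, helix, matrix).score
            assert longer >= base

    def test_role_symmetry(self, matrix, rng):
        for _ in range(20):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=6))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=7))
            assert (
                loop_helix_potential(a, b, matrix).score
                == loop_helix_potential(b, a, matrix).score
            )

    def test_per_pair_normalization(self, matrix):
        raw = loop_helix_potential("YNNKEL", "EDQRKA", matrix)
        norm = loop_helix_potential("YNNKEL", "EDQRKA", matrix, normalize=True)
        assert norm.score == pytest.approx(raw.score / 16)


def _toy_families():
    tcr = [
        make_record("TRAV-hi", {"CDR1": "NNKS", "CDR2": "SNKT"}, family="TRAV"),
        make_record("TRAV-lo", {"CDR1": "GAGA", "CDR2": "PAGP"}, family="TRAV"),
    ]
    mhc = [
        make_record("HLA-A*01", {"helix1": "EDQSN", "helix2": "AGAGA"}, family="HLA-I"),
        make_record("HLA-B*07", {"helix1": "EDQTN", "helix2": "EDKSA"}, family="HLA-I"),
    ]
    return tcr, mhc


class TestGeneAlleleScores:
    def test_single_pair_yields_four_entries(self, matrix):
        tcr, mhc = _toy_families()
        table = gene_allele_scores(tcr[:1], mhc[:1], matrix)
        assert len(table.frame) == 4
        assert set(table.frame.loop) == {"CDR1", "CDR2"}
        assert set(table.frame.helix) == {"helix1", "helix2"}

    def test_complete_cross_product(self, matrix):
        tcr, mhc = _toy_families()
        table = gene_allele_scores(tcr, mhc, matrix)
        assert len(table.frame) == 2 * 2 * 2 * 2
        assert (table.frame.score >= 0).all()

    def test_scores_invariant_to_record_order(self, matrix):
        tcr, mhc = _toy_families()
        t1 = gene_allele_scores(tcr, mhc, matrix).frame
        t2 = gene_allele_scores(tcr[::-1], mhc[::-1], matrix).frame
        key = ["gene", "loop", "allele", "helix"]
        merged = t1.merge(t2, on=key, suffixes=("_a", "_b"))
        assert (merged.score_a == merged.score_b).all()

    def test_empty_side_rejected(self, matrix):
        tcr, mhc = _toy_families()
        with pytest.raises(ValueError):
            gene_allele_scores([], mhc, matrix)

    def test_gene_pairing_enumeration_counts_cross_product(self):
        trav = [make_record(f"TRAV{i}", {"CDR1": "NNK"}) for i in range(45)]
        trbv = [make_record(f"TRBV{i}", {"CDR1": "NNK"}) for i in range(48)]
        assert len(enumerate_gene_pairings(trav, trbv)) == 2160


class TestHelixDistributions:
    def test_single_cell_distribution_equals_loop_mean(self, matrix):
        tcr, mhc = _toy_families()
        table = gene_allele_scores(tcr[:1], mhc[:1], matrix)
        dist = helix_distributions(table, {"HLA-A*01": "A"})
        h1 = dist[dist.helix == "helix1"]
        expected = table.frame[table.frame.helix == "helix1"].score.mean()
        assert len(h1) == 1
        assert h1.score.iloc[0] == pytest.approx(expected)

    def test_distribution_sizes_are_genes_times_alleles(self, matrix):
        tcr, mhc = _toy_families()
        table = gene_allele_scores(tcr, mhc, matrix)
        dist = helix_distributions(table, {"HLA-A*01": "A", "HLA-B*07": "B"})
        sizes = dist.groupby(["group", "chain", "helix"]).size()
        assert (sizes == 2 * 1).all()  # 2 genes x 1 allele per group

    def test_unknown_group_label_is_an_error(self, matrix):
        tcr, mhc = _toy_families()
        table = gene_allele_scores(tcr, mhc, matrix)
        with pytest.raises(ValueError):
            helix_distributions(table, {"HLA-A*01": "A"})

    def test_planted_class_shift_orders_medians(self, matrix):
        # group S alleles are rich in hydrophilic partners, group W in
        # noninteracting residues: S must dominate
        tcr = [make_record("g", {"CDR1": "NNKS", "CDR2": "STNQ"})]
        strong = [make_record("S1", {"helix1": "SSTTN", "helix2": "NNQQS"})]
        weak = [make_record("W1", {"helix1": "GAGAG", "helix2": "AAGGA"})]
        table = gene_allele_scores(tcr, strong + weak, matrix)
        dist = helix_distributions(table, {"S1": "S", "W1": "W"})
        med = dist.groupby("group")["median"].first()
        assert med["S"] > med["W"]


class TestPerResidueBreakdown:
    def test_noninteracting_columns_are_exactly_zero(self, matrix):
        tcr, _ = _toy_families()
        rec = make_record("HLA", {"helix1": "EAQGN", "helix2": "AGAGA"}, family="HLA-I")
        out = per_residue_breakdown(tcr, rec, matrix)
        assert out["helix1"][1] == 0.0  # A at position 1
        assert out["helix1"][3] == 0.0  # G at position 3
        assert out["helix2"] == pytest.approx(np.zeros(5))

    def test_position_sums_conserve_mean_potential(self, matrix):
        tcr, mhc = _toy_families()
        rec = mhc[1]
        out = per_residue_breakdown(tcr, rec, matrix)
        for helix in ("helix1", "helix2"):
            scores = [
                loop_helix_potential(t.segments[loop], rec.segments[helix], matrix).score
                for t in tcr
                for loop in ("CDR1", "CDR2")
            ]
            assert out[helix].sum() == pytest.approx(np.mean(scores))

    def test_two_gene_case_matches_hand_enumeration(self, matrix):
        # Loops KDN and NNK against helix EDQ: a single triad each.
        # KDN/EDQ pairs: (K,E)=+2,(D,D)=-2,(N,Q)=+1 -> invalid, contributes 0.
        # NNK/EDQ pairs: (N,E)=+1,(N,D)=+1,(K,Q)=+1 -> valid.
        tcr = [
            make_record("g1", {"CDR1": "KDN"}),
            make_record("g2", {"CDR1": "NNK"}),
        ]
        rec = make_record("HLA", {"helix1": "EDQ"}, family="HLA-I")
        out = per_residue_breakdown(tcr, rec, matrix, loops=("CDR1",),
                                    helices=("helix1",))
        assert out["helix1"] == pytest.approx(np.array([1, 1, 1]) / 2.0)


class TestReluNormalize:
    def test_all_positive_unchanged(self):
        x = np.array([1.0, 2.0, 3.0])
        assert relu_normalize(x) == pytest.approx(x)

    def test_negatives_mapped_to_zero(self):
        assert relu_normalize(np.array([-2, 2, 0])).tolist() == [0, 2, 0]

    def test_idempotent_on_arrays_and_frames(self):
        x = np.array([[-1.5, 0.5], [2.0, -3.0]])
        once = relu_normalize(x)
        assert relu_normalize(once) == pytest.approx(once)
        df = pd.DataFrame(x)
        pd.testing.assert_frame_equal(relu_normalize(relu_normalize(df)),
                                      relu_normalize(df))
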
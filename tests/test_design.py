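"""Design scoring, virtual Ala scan, codon searches, mixed-library assembly."""

import numpy as np
import pytest

from dadl import (RuleOracle, ala_scan, assemble_mixed_library,
                  design_diversity, evaluate_design, parse_design_spec,
                  reference_mixed_designs, score_design, search_codon_pairs,
                  search_position_codons)
from dadl.design import MixedLibrary


# -- evaluate_design ------------------------------------------------------

def test_constant_predictor_gives_its_value(constant_predictor):
    ds = evaluate_design(constant_predictor(0.7), parse_design_spec("(nnk)8"),
                         n=200, seed=0)
    assert ds.E == pytest.approx(0.7)
    assert ds.D == 20 ** 8


def test_single_sequence_design_exact_for_any_n(oracle):
    design = parse_design_spec("(gcg)8")
    expected = oracle.score("A" * 8)
    for n in (1, 7, 500):
        assert evaluate_design(oracle, design, n=n, seed=1).E == pytest.approx(expected)


def test_evaluation_deterministic_under_seed(oracle, nnk11):
    a = evaluate_design(oracle, nnk11, n=2000, seed=4)
    b = evaluate_design(oracle, nnk11, n=2000, seed=4)
    assert a.E == b.E


def test_exhaustive_mode_agrees_with_monte_carlo(oracle):
    design = parse_design_spec("dsk gcg gcg gcg gcg nnu")  # D = 7*15 = 105
    exact = evaluate_design(oracle, design, exhaustive=True)
    mc = evaluate_design(oracle, design, n=40_000, seed=0)
    assert exact.D == 105
    assert mc.E == pytest.approx(exact.E, abs=0.02)


def test_exhaustive_mode_bounded():
    with pytest.raises(ValueError, match="exhaustive"):
        evaluate_design(RuleOracle(), parse_design_spec("(nnk)8"),
                        exhaustive=True)


# -- score function -------------------------------------------------------

def test_score_normalized_at_reference_diversity():
    for mode in ("long", "short"):
        assert score_design(0.5, 20 ** 11, mode, length=11) == pytest.approx(0.5)


def test_short_mode_penalizes_diversity_deficit_more():
    D = 7 * 20 ** 9 * 15
    m_long = score_design(0.5, D, "long", length=11)
    m_short = score_design(0.5, D, "short", length=11)
    assert m_short < m_long < 0.5


def test_score_linear_in_efficiency():
    D = 20 ** 8
    assert score_design(0.6, D, "long", length=8) == pytest.approx(
        2 * score_design(0.3, D, "long", length=8))


def test_score_monotone_in_both_arguments():
    for mode in ("long", "short"):
        assert score_design(0.6, 10 ** 9, mode, length=11) > \
            score_design(0.5, 10 ** 9, mode, length=11)
        assert score_design(0.5, 10 ** 10, mode, length=11) > \
            score_design(0.5, 10 ** 9, mode, length=11)


def test_score_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        score_design(0.5, 0, "long", length=8)
    with pytest.raises(ValueError):
        score_design(1.5, 10, "long", length=8)


# -- virtual Ala scan -----------------------------------------------------

def test_constant_predictor_scan_has_zero_deltas(constant_predictor, nnk8):
    scan = ala_scan(constant_predictor(0.4), nnk8, n=100, seed=0)
    assert scan.delta_E == pytest.approx([0.0] * 8)
    assert len(scan.position_scores) == 8


def test_scan_requires_fully_random_baseline(oracle):
    with pytest.raises(ValueError, match="fully randomized"):
        ala_scan(oracle, parse_design_spec("dsk (nnk)9 nnu"), n=10, seed=0)


def test_planted_oracle_scan_ranks_boundaries_first(oracle, nnk11):
    scan = ala_scan(oracle, nnk11, n=10_000, seed=2)
    assert set(scan.ranked_positions()[:2]) == {1, 11}
    # the next ring out (positions 2 and 10) carries the next-largest effects
    assert set(scan.ranked_positions()[2:4]) == {2, 10}


# -- codon searches -------------------------------------------------------

def test_single_candidate_search_equals_baseline(oracle, nnk11):
    ranked = search_position_codons(oracle, nnk11, 1, ["nnk"], n=500, seed=3)
    baseline = evaluate_design(oracle, nnk11, n=500, seed=3)
    assert len(ranked) == 1
    assert ranked[0].E == pytest.approx(baseline.E)


def test_constant_predictor_prefers_higher_diversity(constant_predictor, nnk8):
    ranked = search_position_codons(constant_predictor(0.5), nnk8, 1,
                                    ["gcg", "nnk"], n=50, seed=0)
    assert ranked[0].design.insert_codons[0].symbols == "nnk"


def test_codon_excluding_penalized_residues_outranks_nnk(nnk8):
    dsk_aas = set("ACGRSTW")

    class PositionOneOracle:
        """Penalizes every residue outside the dsk set at position 1."""

        def predict_fitness(self, inserts):
            return np.array([0.9 if s[0] in dsk_aas else 0.1 for s in inserts])

    ranked = search_position_codons(PositionOneOracle(), nnk8, 1,
                                    ["dsk", "nnk"], n=4000, seed=0)
    assert ranked[0].design.insert_codons[0].symbols == "dsk"


def test_search_ranking_stable_under_repeats(oracle, nnk11):
    kw = dict(position=1, candidate_codons=["dsk", "dbk", "rsu", "nnk"],
              n=1000, seed=6)
    first = [d.design.spec for d in search_position_codons(oracle, nnk11, **kw)]
    second = [d.design.spec for d in search_position_codons(oracle, nnk11, **kw)]
    assert first == second


def test_pair_search_cross_product(oracle, nnk11):
    cands_a = ["dsk", "dsu", "nsu", "dbk", "rsu"]
    cands_b = ["dbk", "nyu", "nyk", "nnu", "nnk"]
    ranked = search_codon_pairs(oracle, nnk11, 1, 11, cands_a, cands_b,
                                n=800, seed=1)
    assert len(ranked) == 25
    # the grid contains every single-position winner, so the best pair
    # cannot score below the best position-1-only substitution
    single = search_position_codons(oracle, nnk11, 1, cands_a, n=800, seed=1)
    assert ranked[0].M >= single[0].M - 1e-12


def test_one_by_one_pair_search(oracle, nnk11):
    ranked = search_codon_pairs(oracle, nnk11, 1, 11, ["dsk"], ["nnu"],
                                n=200, seed=0)
    assert len(ranked) == 1
    assert ranked[0].design.spec.split()[0] == "dsk"


def test_boundary_search_improves_on_random_baseline(oracle, nnk11):
    """Searched boundary codons beat the all-nnk design in true fitness."""
    baseline = evaluate_design(oracle, nnk11, n=6000, seed=5)
    ranked = search_codon_pairs(oracle, nnk11, 1, 11,
                                ["dsk", "dsu", "nsu", "dbk", "rsu"],
                                ["dbk", "nyu", "nyk", "nnu"],
                                mode="long", n=6000, seed=5)
    best_true = evaluate_design(oracle, ranked[0].design, n=6000, seed=8)
    assert best_true.E > baseline.E


# -- mixed library assembly ----------------------------------------------

def test_seven_single_sequence_designs_total_diversity():
    designs = {n: parse_design_spec(f"(gcg){n}") for n in range(6, 13)}
    lib = assemble_mixed_library(designs)
    assert lib.total_diversity == 7
    assert sum(lib.fractions.values()) == pytest.approx(1.0)


def test_missing_length_rejected():
    designs = {n: parse_design_spec(f"(nnk){n}") for n in range(6, 12)}
    with pytest.raises(ValueError, match="12"):
        assemble_mixed_library(designs)


def test_reference_design_map_diversities():
    designs = reference_mixed_designs()
    assert design_diversity(designs[11]) == 7 * 20 ** 9 * 15
    assert design_diversity(designs[12]) == 7 * 20 ** 10 * 15
    assert design_diversity(designs[6]) == 12 * 20 ** 5
    assert designs[8].spec == "dbk nnk nnk nnk nnk nnk nnk nnk"


def test_manifest_round_trip(tmp_path):
    lib = assemble_mixed_library(reference_mixed_designs())
    path = tmp_path / "library.yaml"
    lib.write(path)
    loaded = MixedLibrary.read(path)
    assert loaded.total_diversity == lib.total_diversity
    assert {k: d.spec for k, d in loaded.designs.items()} == \
        {k: d.spec for k, d in lib.designs.items()}
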
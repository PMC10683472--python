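"""Peptide encoding, classifier architecture, training and the rule oracle."""

import numpy as np
import pytest

from dadl import (FitnessCNN, ModelConfig, OracleParams, RuleOracle,
                  build_classifier, build_labeled_dataset, decode_encoding,
                  encode_peptide, evaluate, load_model, sample_peptides,
                  save_model, parse_design_spec)
from dadl.model import N_CHANNELS, PAD_INDEX


# -- encoder --------------------------------------------------------------

def test_center_padding_splits_deficit():
    m = encode_peptide("ACDEFGHI", max_len=12)
    # width = 2 (pre) + 12 + 5 (post); 4 pad columns, 2 on each side
    assert m.shape == (19, N_CHANNELS)
    pad_cols = np.flatnonzero(m[:, PAD_INDEX])
    assert pad_cols.tolist() == [2, 3, 12, 13]
    assert m.sum() == 19  # exactly one hot per column


def test_encoding_injective_and_invertible():
    a, b = "ACDEFGHI", "ACDEFGHL"
    assert not np.array_equal(encode_peptide(a), encode_peptide(b))
    for insert in ("ACDEFG", "MKLVNQRTAWG", "WWWWWWWWWWWW"):
        assert decode_encoding(encode_peptide(insert)) == insert


def test_unknown_residue_rejected():
    with pytest.raises(ValueError, match="residue"):
        encode_peptide("ACDEFGHX")
    with pytest.raises(ValueError, match="max_len"):
        encode_peptide("A" * 13)


# -- architecture ---------------------------------------------------------

def test_default_architecture_matches_published_facts():
    model = build_classifier()
    assert model.net_.n_conv_layers == 12
    assert abs(model.n_parameters_ - 1.2e7) / 1.2e7 < 0.05


def test_toy_config_builds_and_predicts_in_unit_interval():
    model = FitnessCNN(n_conv_layers=1, channels=8).build()
    p = model.predict_fitness(["ACDEFGHI", "MKLVNQRT"])
    assert np.all((p >= 0) & (p <= 1))


def test_invalid_layout_rejected():
    with pytest.raises(ValueError):
        ModelConfig(n_conv_layers=0)
    with pytest.raises(ValueError):
        FitnessCNN(n_conv_layers=2, channels=0).build()


# -- training -------------------------------------------------------------

def _toy_dataset(n=2000, seed=0):
    """Linearly separable: label decided by the first-position residue."""
    design = parse_design_spec("(nnk)8")
    peps = sample_peptides(design, n, seed=seed)
    labels = np.array([int(p[0] in set("ACDEFGHIK")) for p in peps])
    return peps, labels


def test_separable_toy_dataset_learned_to_high_accuracy():
    peps, labels = _toy_dataset()
    model = FitnessCNN(n_conv_layers=2, channels=24, epochs=20, seed=0,
                       validation_fraction=0.25)
    model.fit(peps, labels)
    assert model.history_[-1]["val_accuracy"] >= 0.99


def test_random_labels_give_chance_accuracy():
    peps, _ = _toy_dataset(n=2000, seed=1)
    rng = np.random.default_rng(0)
    null_labels = rng.integers(0, 2, len(peps))  # balanced permutation null
    model = FitnessCNN(n_conv_layers=2, channels=24, epochs=5, seed=0,
                       validation_fraction=0.25)
    model.fit(peps, null_labels)
    assert model.history_[-1]["val_accuracy"] == pytest.approx(0.5, abs=0.05)


def test_single_class_training_data_rejected():
    peps, _ = _toy_dataset(n=50)
    with pytest.raises(ValueError, match="single class"):
        FitnessCNN(n_conv_layers=1, channels=8).fit(peps, np.ones(len(peps)))


def test_training_is_seed_reproducible():
    peps, labels = _toy_dataset(n=600)
    runs = []
    for _ in range(2):
        m = FitnessCNN(n_conv_layers=1, channels=12, epochs=2, seed=3,
                       validation_fraction=0.2)
        m.fit(peps, labels)
        runs.append(m.history_[-1]["val_accuracy"])
    assert runs[0] == runs[1]


# -- inference ------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_model():
    peps, labels = _toy_dataset(n=800)
    m = FitnessCNN(n_conv_layers=1, channels=12, epochs=3, seed=0,
                   validation_fraction=0.0)
    return m.fit(peps, labels)


def test_predict_contracts(tiny_model):
    assert tiny_model.predict_fitness([]).shape == (0,)
    p = tiny_model.predict_fitness(["ACDEFGHI"] * 3)
    assert np.all(p == p[0])
    assert np.all((p >= 0) & (p <= 1))
    with pytest.raises(ValueError, match="1..12"):
        tiny_model.predict_fitness(["A" * 14])


def test_predictions_invariant_under_batch_size(tiny_model):
    peps = sample_peptides(parse_design_spec("(nnk)8"), 300, seed=7)
    whole = tiny_model.predict_fitness(peps)
    parts = np.concatenate([tiny_model.predict_fitness(peps[i:i + 17])
                            for i in range(0, 300, 17)])
    # float32 BLAS reductions may reorder across batch shapes
    np.testing.assert_allclose(whole, parts, atol=1e-6)


def test_checkpoint_round_trip(tiny_model, tmp_path):
    path = tmp_path / "model.npz"
    save_model(tiny_model, path)
    loaded = load_model(path)
    peps = sample_peptides(parse_design_spec("(nnk)8"), 50, seed=9)
    np.testing.assert_array_equal(tiny_model.predict_fitness(peps),
                                  loaded.predict_fitness(peps))


# -- evaluation -----------------------------------------------------------

def _mini_dataset():
    sel = ["AAAAAA", "CCCCCC", "DDDDDD"]
    anti = ["EEEEEE", "FFFFFF", "GGGGGG", "HHHHHH"]
    return build_labeled_dataset(sel, anti, seed=0,
                                 split_fractions=(0.0, 0.0, 1.0))


class _Stub:
    def __init__(self, fn):
        self.fn = fn

    def predict(self, inserts):
        return np.array([int(self.fn(s) > 0.5) for s in inserts])


def test_perfect_predictor_accuracy_one():
    ds = _mini_dataset()
    truth = dict(zip(ds.frame["insert"], ds.frame["label"]))
    metrics = evaluate(_Stub(lambda s: float(truth[s])), ds, "test")
    assert metrics["accuracy"] == 1.0
    assert metrics["confusion"]["fp"] == metrics["confusion"]["fn"] == 0


def test_constant_half_predictor_ties_break_to_label_zero():
    ds = _mini_dataset()
    metrics = evaluate(_Stub(lambda s: 0.5), ds, "test")
    majority0 = (ds.frame["label"] == 0).mean()
    assert metrics["accuracy"] == pytest.approx(majority0)


# -- rule oracle ----------------------------------------------------------

def test_zero_weight_oracle_is_half():
    params = OracleParams(boundary_scale=0.0, bias=0.0)
    oracle = RuleOracle(params)
    assert oracle("ACDEFGHIKLM") == pytest.approx(0.5)


def test_oracle_monotone_at_argmax():
    oracle = RuleOracle()
    L = 8
    off = oracle._offsets(L)
    best = "".join("ACDEFGHIKLMNPQRSTVWY"[int(np.argmax(oracle.weights_[o]))]
                   for o in off)
    z_best = oracle.logit(best)
    for pos in range(L):
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            if aa == best[pos]:
                continue
            neighbor = best[:pos] + aa + best[pos + 1:]
            assert oracle.logit(neighbor) < z_best


def test_boundary_substitution_dominates_interior():
    oracle = RuleOracle()
    rng = np.random.default_rng(0)
    design = parse_design_spec("(nnk)11")
    peps = sample_peptides(design, 200, seed=0)
    boundary_shift, interior_shift = [], []
    for pep in peps:
        for aa in "AW":
            boundary_shift.append(abs(oracle.logit(aa + pep[1:])
                                      - oracle.logit(pep)))
            interior_shift.append(abs(oracle.logit(pep[:5] + aa + pep[6:])
                                      - oracle.logit(pep)))
    assert np.mean(boundary_shift) > np.mean(interior_shift)


def test_oracle_batch_matches_scalar():
    oracle = RuleOracle()
    peps = sample_peptides(parse_design_spec("(nnk)8"), 100, seed=4)
    batch = oracle.predict_fitness(peps)
    np.testing.assert_allclose(batch, [oracle.score(p) for p in peps],
                               atol=1e-12)


def test_oracle_pairwise_terms_apply():
    params = OracleParams(boundary_scale=1e-9, bias=0.0, sharpness=1.0,
                          pairwise={((0, "W"), (0, "C")): 2.0})
    oracle = RuleOracle(params)
    with_pair = oracle.score("WAAAAAC")
    without = oracle.score("AAAAAAA")
    assert with_pair > without
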
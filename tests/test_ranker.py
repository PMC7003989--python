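"""Masked-softmax ranking: scoring invariants, training, evaluation."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import pytest

from metabopred.featurize import FeatureBlock, featurize_candidate_set
from metabopred.ranker import (
    MetaboliteRanker,
    TrainConfig,
    UniformRandomScorer,
    build_ranker,
    cross_validate,
    predict_metabolites,
    score_candidates,
    topk_accuracy,
    train_ranker,
)
from metabopred.reaction_io import record_from_reaction_smiles
from metabopred.synthetic import candidate_sets_from_records, default_template_library
from metabopred.templates import TemplateLibrary, generate_candidates


def _random_block(rng, n=7, d=32, n_masked=0):
    mat = (rng.random((n + n_masked, d)) < 0.2).astype(np.float32)
    mask = np.array([1.0] * n + [0.0] * n_masked, dtype=np.float32)
    return FeatureBlock(matrix=mat, mask=mask, radius=2, n_bits=d // 2)


class TestScoringInvariants:
    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            model = build_ranker(32, (16, 8), seed=trial)
            block = _random_block(rng)
            p = score_candidates(model, block).probabilities
            assert abs(p.sum() - 1.0) < 1e-6
            assert np.all((p >= 0) & (p <= 1))

    def test_masked_padding_rows_do_not_disturb(self):
        rng = np.random.default_rng(1)
        model = build_ranker(32, (16,), seed=0)
        block = _random_block(rng, n=6)
        base = score_candidates(model, block).probabilities
        padded = FeatureBlock(
            matrix=np.vstack([block.matrix, rng.random((5, 32)).astype(np.float32)]),
            mask=np.concatenate([block.mask, np.zeros(5, dtype=np.float32)]),
            radius=2, n_bits=16,
        )
        p = score_candidates(model, padded).probabilities
        assert np.all(p[6:] == 0.0)
        assert np.allclose(p[:6], base, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        model = build_ranker(32, (16, 8), seed=5)
        block = _random_block(rng, n=8)
        p = score_candidates(model, block).probabilities
        perm = rng.permutation(8)
        permuted = FeatureBlock(matrix=block.matrix[perm], mask=block.mask[perm],
                                radius=2, n_bits=16)
        q = score_candidates(model, permuted).probabilities
        assert np.allclose(q, p[perm], atol=1e-12)

    def test_zero_init_gives_uniform(self):
        rng = np.random.default_rng(3)
        model = build_ranker(32, (16,), seed=0, zero_init=True)
        block = _random_block(rng, n=9)
        p = score_candidates(model, block).probabilities
        assert np.allclose(p, 1.0 / 9)

    def test_single_candidate_probability_one(self):
        model = build_ranker(16, (8,), seed=0)
        block = _random_block(np.random.default_rng(4), n=1, d=16)
        assert score_candidates(model, block).probabilities[0] == pytest.approx(1.0)

    def test_all_masked_raises(self):
        model = build_ranker(16, (), seed=0)
        block = _random_block(np.random.default_rng(5), n=0, d=16, n_masked=3)
        with pytest.raises(ValueError):
            score_candidates(model, block)

    def test_rank_ties_broken_by_smiles(self):
        model = build_ranker(16, (), seed=0, zero_init=True)  # all scores equal
        block = _random_block(np.random.default_rng(6), n=3, d=16)
        pred = score_candidates(model, block, ["CCO", "CCC", "CCN"])
        assert [pred.candidate_smiles[i] for i in pred.ranks] == ["CCC", "CCN", "CCO"]


class TestBuildRanker:
    def test_deterministic_construction(self):
        a = build_ranker(64, (32, 16), seed=9)
        b = build_ranker(64, (32, 16), seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.mlp.W, b.mlp.W))

    def test_linear_scorer_allowed(self):
        model = build_ranker(16, (), seed=0)
        assert model.mlp.dims == [16, 1]

    def test_invalid_dim(self):
        with pytest.raises(ValueError):
            build_ranker(0)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _amide_corpus(n):
    """Records whose unique positive is the amide N-dealkylation product;
    ring hydroxylations provide negatives."""
    acyls = ["C", "CC", "CCC", "CCCC", "CC(C)C"]
    records = []
    for i in range(n):
        acyl = acyls[i % len(acyls)]
        tail = "C" * (1 + (i // len(acyls)) % 3)
        rxn = (f"{acyl}C(=O)[NH:1][CH2:2]{tail}c1ccccc1"
               f">>[NH2:1][CH2:2]{tail}c1ccccc1")
        records.append(record_from_reaction_smiles(rxn, f"tr{i}"))
    return records


@pytest.fixture(scope="module")
def separable_examples():
    lib = default_template_library()
    sets = candidate_sets_from_records(_amide_corpus(40), lib)
    return [(cs, featurize_candidate_set(cs, n_bits=128)) for cs in sets]


class TestTrainRanker:
    def test_initial_loss_is_log_n_for_uniform_model(self, separable_examples):
        model = build_ranker(256, (16,), seed=0, zero_init=True)
        losses = []
        for cs, block in separable_examples:
            p = score_candidates(model, block).probabilities
            pos = cs.positive_indices
            losses.append(-math.log(p[pos[0]]))
            assert p[pos[0]] == pytest.approx(1.0 / cs.n_candidates)
        mean_ln_n = np.mean([math.log(cs.n_candidates) for cs, _ in separable_examples])
        assert np.mean(losses) == pytest.approx(mean_ln_n, abs=1e-9)

    def test_history_length_and_descent(self, separable_examples):
        config = TrainConfig(epochs=12, seed=0, hidden_dims=(64,), batch_size=8)
        model, hist = train_ranker(separable_examples, config)
        assert len(hist) == 12
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_separable_corpus_reaches_top1(self, separable_examples):
        config = TrainConfig(epochs=40, seed=0, hidden_dims=(64,), batch_size=8)
        model, _ = train_ranker(separable_examples, config)
        assert topk_accuracy(model, separable_examples, 1) == 1.0

    def test_zero_positive_record_skipped_with_warning(self, separable_examples, caplog):
        lib = default_template_library()
        no_pos = generate_candidates("CCCCCCC", lib, recorded_products=["CCCCCCCN"],
                                     record_id="nopos")
        extra = (no_pos, featurize_candidate_set(no_pos, n_bits=128))
        with caplog.at_level(logging.WARNING, logger="metabopred"):
            model, _ = train_ranker(list(separable_examples) + [extra],
                                    TrainConfig(epochs=1, seed=0, hidden_dims=(16,)))
        assert "nopos" in caplog.text

    def test_validation_selects_best_epoch(self, separable_examples):
        config = TrainConfig(epochs=6, seed=0, hidden_dims=(32,), batch_size=8)
        model, hist = train_ranker(separable_examples[:30], config,
                                   validation=separable_examples[30:])
        assert {"val_loss", "val_top1"} <= set(hist.columns)
        best = hist["val_top1"].max()
        assert topk_accuracy(model, separable_examples[30:], 1) == pytest.approx(best)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

class TestTopkAccuracy:
    def test_oracle_scorer_perfect_for_every_k(self, separable_examples):
        positives = {id(block): cs.positive_indices for cs, block in separable_examples}

        def oracle(block):
            s = np.zeros(block.n)
            s[positives[id(block)]] = 10.0
            return s

        for k in (1, 3, 6, 10):
            assert topk_accuracy(oracle, separable_examples, k) == 1.0

    def test_k_exhausts_candidates(self, separable_examples):
        model = build_ranker(256, (8,), seed=1)
        kmax = max(cs.n_candidates for cs, _ in separable_examples)
        assert topk_accuracy(model, separable_examples, kmax) == 1.0

    def test_zero_positive_records_count_as_misses(self, separable_examples):
        lib = default_template_library()
        no_pos = generate_candidates("CCCCCCC", lib, recorded_products=["CCCCCCCN"])
        extra = (no_pos, featurize_candidate_set(no_pos, n_bits=128))
        data = list(separable_examples) + [extra]
        kmax = max(cs.n_candidates for cs, _ in data)
        assert topk_accuracy(build_ranker(256, (), seed=0), data, kmax) == pytest.approx(
            len(separable_examples) / len(data)
        )

    def test_invalid_args(self, separable_examples):
        model = build_ranker(256, (), seed=0)
        with pytest.raises(ValueError):
            topk_accuracy(model, separable_examples, 0)
        with pytest.raises(ValueError):
            topk_accuracy(model, [], 1)


class TestCrossValidate:
    def test_fold_structure_and_table_shape(self, separable_examples):
        config = TrainConfig(epochs=2, folds=5, seed=3, hidden_dims=(16,), batch_size=8)
        df = cross_validate(separable_examples, config)
        assert list(df.index) == ["Top-1", "Top-3", "Top-6", "Top-10"]
        assert list(df.columns) == [f"fold{i}" for i in range(1, 6)] + ["mean"]
        fold_cols = df[[f"fold{i}" for i in range(1, 6)]]
        assert np.allclose(df["mean"], fold_cols.mean(axis=1))
        # Top-k nesting: accuracy nondecreasing in k for every fold
        for col in fold_cols:
            assert (fold_cols[col].diff().dropna() >= -1e-12).all()

    def test_folds_partition_records(self):
        # fold assignment is seeded permutation mod folds: balanced by design
        rng = np.random.default_rng(TrainConfig(seed=4).seed)
        assignment = rng.permutation(100) % 5
        sizes = np.bincount(assignment)
        assert sizes.tolist() == [20] * 5

    def test_more_folds_than_records_raises(self, separable_examples):
        with pytest.raises(ValueError):
            cross_validate(separable_examples[:3], TrainConfig(folds=5, epochs=1))


@pytest.fixture(scope="module")
def fitted(separable_examples):
    config = TrainConfig(epochs=10, seed=0, hidden_dims=(64,), batch_size=8)
    model, _ = train_ranker(separable_examples, config)
    model.feature_meta["n_bits"] = 128
    return model


class TestPredictMetabolites:
    def test_topk_slice_and_descending_probs(self, fitted, default_library):
        out = predict_metabolites("CC(=O)NCCc1ccccc1", fitted, default_library, k=10)
        assert 0 < len(out) <= 10
        probs = [p for _, p in out]
        assert probs == sorted(probs, reverse=True)

    def test_k_larger_than_candidates_returns_all(self, fitted, default_library):
        out = predict_metabolites("CCSCC", fitted, default_library, k=500)
        cs = generate_candidates("CCSCC", default_library)
        assert len(out) == cs.n_candidates

    def test_deterministic(self, fitted, default_library):
        a = predict_metabolites("CC(=O)NCCc1ccccc1", fitted, default_library, k=5)
        b = predict_metabolites("CC(=O)NCCc1ccccc1", fitted, default_library, k=5)
        assert a == b

    def test_no_match_returns_empty(self, fitted):
        lib = TemplateLibrary(templates=[default_template_library()["pyridine_n_oxidation"]])
        assert predict_metabolites("CCCC", fitted, lib, k=5) == []


class TestModelResultsSurface:
    def test_fit_and_summary(self, separable_examples):
        sets = [cs for cs, _ in separable_examples]
        ranker = MetaboliteRanker(sets[:30], n_bits=128, library=default_template_library())
        res = ranker.fit(TrainConfig(epochs=4, seed=0, hidden_dims=(32,), batch_size=8),
                         validation=sets[30:])
        text = res.summary(eval_sets=sets[30:])
        assert "Top-10" in text and "candidate sets" in text
        assert len(res.history) == 4
        assert 0.0 <= res.topk_accuracy(sets[30:], k=3) <= 1.0


class TestPersistence:
    def test_checkpoint_roundtrip(self, tmp_path, separable_examples):
        from metabopred.ranker import load_ranker, save_ranker

        config = TrainConfig(epochs=2, seed=0, hidden_dims=(32,), batch_size=8)
        model, _ = train_ranker(separable_examples, config)
        save_ranker(model, tmp_path / "ckpt")
        back = load_ranker(tmp_path / "ckpt")
        assert back.feature_meta == model.feature_meta
        cs, block = separable_examples[0]
        assert np.allclose(back.scores(block.matrix), model.scores(block.matrix))

    def test_metrics_report_files(self, tmp_path, separable_examples):
        from metabopred.ranker import write_metrics_report

        config = TrainConfig(epochs=1, folds=2, seed=0, hidden_dims=(16,), batch_size=8)
        df = cross_validate(separable_examples[:10], config, ks=(1, 3))
        write_metrics_report(df, tmp_path / "metrics")
        assert (tmp_path / "metrics.tsv").exists()
        assert (tmp_path / "metrics.json").exists()
        back = pd.read_csv(tmp_path / "metrics.tsv", sep="\t", index_col=0)
        assert np.allclose(back.values, df.values)
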
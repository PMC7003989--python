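"""Shared-weight neural ranking of candidate metabolites.

Every candidate in a set is scored by the same fully-connected network (one
scalar per candidate); a masked softmax over the set turns scores into a
probability distribution ("which of these candidates is the recorded
metabolite"), trained with cross-entropy against the recorded product(s).
Evaluation is Top-k accuracy: the fraction of reactions whose recorded
metabolite ranks within the k highest-probability candidates.

Two entry points are provided: the statsmodels-style ``MetaboliteRanker``
model object whose ``fit()`` returns a ``RankerResults``, and the flat
functions (``build_ranker``, ``train_ranker``, ``score_candidates``,
``topk_accuracy``, ``cross_validate``, ``predict_metabolites``) the class
delegates to.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .featurize import FeatureBlock, featurize_candidate_set
from .nn import MLP, Adam, masked_softmax
from .templates import CandidateSet, TemplateLibrary, generate_candidates

logger = logging.getLogger("metabopred")

#: one training/evaluation example: the labeled candidate set and its features
Example = tuple[CandidateSet, FeatureBlock]


@dataclass
class TrainConfig:
    epochs: int = 200
    folds: int = 5
    split_ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    hidden_dims: tuple[int, ...] = (512, 256)
    learning_rate: float = 1e-3
    batch_size: int = 32  # candidate sets per batch
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split_ratios must sum to 1")


@dataclass
class RankerModel:
    """Shared per-candidate scoring network. One parameter set scores all
    candidates; scoring is a pure function of (parameters, feature row)."""

    mlp: MLP
    feature_meta: dict
    config: Optional[TrainConfig] = None

    @property
    def feature_dim(self) -> int:
        return self.mlp.dims[0]

    def scores(self, matrix: np.ndarray) -> np.ndarray:
        out, _ = self.mlp.forward(np.asarray(matrix, dtype=np.float64))
        return out[:, 0]


@dataclass
class Prediction:
    candidate_smiles: list[str]
    probabilities: np.ndarray
    ranks: list[int]  # candidate indices, best first


def build_ranker(feature_dim: int, hidden_dims: Sequence[int] = (512, 256), seed: int = 0,
                 zero_init: bool = False, feature_meta: Optional[dict] = None) -> RankerModel:
    """Seeded construction of the shared scoring network (scalar head).

    Empty ``hidden_dims`` gives a linear scorer. ``zero_init`` produces the
    uniform-probability baseline model.
    """
    if feature_dim < 1:
        raise ValueError("feature_dim must be >= 1")
    mlp = MLP([feature_dim, *hidden_dims, 1], seed=seed, zero_init=zero_init)
    return RankerModel(mlp=mlp, feature_meta=feature_meta or {"d": feature_dim})


Scorer = Callable[[FeatureBlock], np.ndarray]


def _raw_scores(model: "RankerModel | Scorer", block: FeatureBlock) -> np.ndarray:
    if isinstance(model, RankerModel):
        return model.scores(block.matrix)
    return np.asarray(model(block))


def score_candidates(model: "RankerModel | Scorer", block: FeatureBlock,
                     candidate_smiles: Optional[Sequence[str]] = None) -> Prediction:
    """Masked softmax over per-candidate scores.

    Masked (padding) rows receive probability exactly 0; ranks sort
    probabilities descending with lexicographic SMILES tie-break.
    """
    scores = _raw_scores(model, block)
    probs = masked_softmax(scores[None, :], block.mask[None, :])[0]
    smiles = list(candidate_smiles) if candidate_smiles is not None else [""] * block.n
    real = [i for i in range(block.n) if block.mask[i] > 0]
    ranks = sorted(real, key=lambda i: (-probs[i], smiles[i]))
    return Prediction(candidate_smiles=smiles, probabilities=probs, ranks=ranks)


class UniformRandomScorer:
    """Seeded random scores; the analytic Top-k baseline is k/m."""

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)

    def __call__(self, block: FeatureBlock) -> np.ndarray:
        return self.rng.random(block.n)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _usable(example: Example) -> bool:
    cs, _ = example
    if cs.n_candidates < 2 or not cs.positive_indices:
        logger.warning("skipping record %s: %d candidates, %d positives",
                       cs.record_id, cs.n_candidates, len(cs.positive_indices))
        return False
    return True


def _targets(cs: CandidateSet) -> np.ndarray:
    """Uniform target mass over all recorded (positive) candidates."""
    y = np.zeros(cs.n_candidates)
    pos = cs.positive_indices
    y[pos] = 1.0 / len(pos)
    return y


def _batch_loss_and_grads(model: RankerModel, batch: list[Example], dropout: float,
                          rng: Optional[np.random.Generator]):
    mats = [ex[1].matrix for ex in batch]
    sizes = [m.shape[0] for m in mats]
    X = np.concatenate(mats).astype(np.float64)
    out, cache = model.mlp.forward(X, dropout=dropout, rng=rng)
    scores = out[:, 0]
    dscores = np.empty_like(scores)
    loss = 0.0
    start = 0
    for ex, n in zip(batch, sizes):
        s = scores[start:start + n]
        s = s - s.max()
        e = np.exp(s)
        p = e / e.sum()
        y = _targets(ex[0])
        loss += float(-(y * np.log(p + 1e-12)).sum())
        dscores[start:start + n] = (p - y) / len(batch)
        start += n
    grads = model.mlp.backward(cache, dscores[:, None])
    return loss / len(batch), grads


def _mean_loss(model: RankerModel, data: list[Example]) -> float:
    total = 0.0
    for cs, block in data:
        p = score_candidates(model, block).probabilities
        y = _targets(cs)
        total += float(-(y * np.log(p + 1e-12)).sum())
    return total / len(data)


def train_ranker(train: Sequence[Example], config: TrainConfig,
                 validation: Optional[Sequence[Example]] = None) -> tuple[RankerModel, pd.DataFrame]:
    """Minimize cross-entropy between predicted and target distributions.

    The target puts uniform mass on all positives of a set. Records with no
    positive (or a single candidate) are skipped with a warning. When
    validation examples are given, the returned parameters are those of the
    epoch with the best validation Top-1. The history frame logs per-epoch
    train loss and, when available, validation loss and Top-1.
    """
    usable = [ex for ex in train if _usable(ex)]
    if not usable:
        raise ValueError("no usable training examples")
    d = usable[0][1].d
    model = build_ranker(d, config.hidden_dims, seed=config.seed,
                         feature_meta={"d": d, "radius": usable[0][1].radius,
                                       "n_bits": usable[0][1].n_bits})
    model.config = config
    opt = Adam(model.mlp.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    drop_rng = np.random.default_rng(config.seed + 2)

    rows = []
    best = (-1.0, None)
    for epoch in range(config.epochs):
        order = rng.permutation(len(usable))
        epoch_loss, nb = 0.0, 0
        for start in range(0, len(usable), config.batch_size):
            batch = [usable[i] for i in order[start:start + config.batch_size]]
            loss, grads = _batch_loss_and_grads(model, batch, config.dropout, drop_rng)
            opt.step(model.mlp, grads)
            epoch_loss += loss
            nb += 1
        row = {"epoch": epoch, "train_loss": epoch_loss / nb}
        if validation:
            row["val_loss"] = _mean_loss(model, list(validation))
            row["val_top1"] = topk_accuracy(model, validation, k=1)
            if row["val_top1"] > best[0]:
                best = (row["val_top1"], (copy.deepcopy(model.mlp.W), copy.deepcopy(model.mlp.b)))
        rows.append(row)
    if validation and best[1] is not None:
        model.mlp.W, model.mlp.b = best[1]
    return model, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def topk_accuracy(model: "RankerModel | Scorer", eval_records: Sequence[Example], k: int) -> float:
    """Fraction of records with ANY positive candidate ranked within the top k.

    Records whose candidate set contains no positive count as misses: when the
    template library cannot generate the recorded metabolite the model cannot
    rank it, which caps achievable accuracy.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not eval_records:
        raise ValueError("empty evaluation set")
    hits = 0
    for cs, block in eval_records:
        pos = set(cs.positive_indices)
        if not pos or cs.n_candidates == 0:
            continue
        pred = score_candidates(model, block, [c.smiles for c in cs.candidates])
        if pos & set(pred.ranks[:k]):
            hits += 1
    return hits / len(eval_records)


def cross_validate(records: Sequence[Example], config: TrainConfig,
                   ks: Sequence[int] = (1, 3, 6, 10)) -> pd.DataFrame:
    """Seeded k-fold cross-validation; returns the Top-k accuracy table.

    Rows Top-1/3/6/10, one column per fold plus the arithmetic mean. Each
    record appears in exactly one validation fold.
    """
    if config.folds > len(records):
        raise ValueError("more folds than records")
    rng = np.random.default_rng(config.seed)
    assignment = rng.permutation(len(records)) % config.folds
    table = {}
    for fold in range(config.folds):
        train = [records[i] for i in range(len(records)) if assignment[i] != fold]
        held = [records[i] for i in range(len(records)) if assignment[i] == fold]
        model, _ = train_ranker(train, config)
        table[f"fold{fold + 1}"] = [topk_accuracy(model, held, k) for k in ks]
    df = pd.DataFrame(table, index=[f"Top-{k}" for k in ks])
    df["mean"] = df.mean(axis=1)
    return df


def predict_metabolites(substrate_smiles: str, model: RankerModel, library: TemplateLibrary,
                        k: int = 10, encoder: Optional[Callable] = None,
                        max_candidates: int = 128) -> list[tuple[str, float]]:
    """Rank the template-generated metabolites of a substrate.

    Returns at most k (smiles, probability) pairs, probabilities descending.
    An empty list (with a logged notice) means no template matched.
    """
    meta = model.feature_meta
    cs = generate_candidates(substrate_smiles, library, max_candidates=max_candidates)
    if cs.n_candidates == 0:
        logger.info("no template matches substrate %s", substrate_smiles)
        return []
    block = featurize_candidate_set(cs, radius=meta.get("radius", 2), n_bits=meta.get("n_bits", 1024))
    if encoder is not None:
        from .featurize import encode_block
        block = encode_block(block, encoder)
    pred = score_candidates(model, block, [c.smiles for c in cs.candidates])
    return [(pred.candidate_smiles[i], float(pred.probabilities[i])) for i in pred.ranks[:k]]


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------

class MetaboliteRanker:
    """Candidate-ranking model over labeled candidate sets.

    Parameters
    ----------
    candidate_sets:
        Labeled :class:`CandidateSet` objects (positives = recorded products).
    radius, n_bits:
        Morgan fingerprint parameters; the input dimension is ``2 * n_bits``.
    encoder:
        Optional row encoder (e.g. a trained autoencoder) applied to every
        feature block before scoring.
    library:
        The template library used at prediction time.
    """

    def __init__(self, candidate_sets: Sequence[CandidateSet], radius: int = 2,
                 n_bits: int = 1024, encoder: Optional[Callable] = None,
                 library: Optional[TemplateLibrary] = None):
        self.candidate_sets = list(candidate_sets)
        self.radius = radius
        self.n_bits = n_bits
        self.encoder = encoder
        self.library = library
        self._examples: Optional[list[Example]] = None

    @property
    def examples(self) -> list[Example]:
        if self._examples is None:
            self._examples = [(cs, self._featurize(cs)) for cs in self.candidate_sets]
        return self._examples

    def _featurize(self, cs: CandidateSet) -> FeatureBlock:
        block = featurize_candidate_set(cs, radius=self.radius, n_bits=self.n_bits)
        if self.encoder is not None:
            from .featurize import encode_block
            block = encode_block(block, self.encoder)
        return block

    def fit(self, config: Optional[TrainConfig] = None,
            validation: Optional[Sequence[CandidateSet]] = None) -> "RankerResults":
        config = config or TrainConfig()
        val_examples = None
        if validation is not None:
            val_examples = [(cs, self._featurize(cs)) for cs in validation]
        model, history = train_ranker(self.examples, config, val_examples)
        return RankerResults(self, model, history, config)

    def cross_validate(self, config: Optional[TrainConfig] = None,
                       ks: Sequence[int] = (1, 3, 6, 10)) -> pd.DataFrame:
        return cross_validate(self.examples, config or TrainConfig(), ks=ks)


class RankerResults:
    """Fitted ranker: parameters, training history and evaluation helpers."""

    def __init__(self, model_spec: MetaboliteRanker, model: RankerModel,
                 history: pd.DataFrame, config: TrainConfig):
        self.model_spec = model_spec
        self.model = model
        self.history = history
        self.config = config

    def topk_accuracy(self, candidate_sets: Optional[Sequence[CandidateSet]] = None,
                      k: int = 10) -> float:
        if candidate_sets is None:
            examples = self.model_spec.examples
        else:
            examples = [(cs, self.model_spec._featurize(cs)) for cs in candidate_sets]
        return topk_accuracy(self.model, examples, k)

    def predict(self, substrate_smiles: str, k: int = 10) -> list[tuple[str, float]]:
        if self.model_spec.library is None:
            raise ValueError("no template library attached to this model")
        return predict_metabolites(substrate_smiles, self.model, self.model_spec.library,
                                   k=k, encoder=self.model_spec.encoder)

    def summary(self, eval_sets: Optional[Sequence[CandidateSet]] = None,
                ks: Sequence[int] = (1, 3, 6, 10)) -> str:
        lines = [
            "Metabolite candidate ranker",
            "=" * 42,
            f"candidate sets (train): {len(self.model_spec.candidate_sets)}",
            f"feature dim:            {self.model.feature_dim}"
            f" (radius {self.model.feature_meta.get('radius')}, "
            f"{self.model.feature_meta.get('n_bits')} bits/molecule)",
            f"hidden layers:          {tuple(self.config.hidden_dims)}",
            f"epochs:                 {self.config.epochs}",
            f"final train loss:       {self.history['train_loss'].iloc[-1]:.4f}",
        ]
        if "val_top1" in self.history:
            lines.append(f"best val Top-1:         {self.history['val_top1'].max():.4f}")
        if eval_sets is not None:
            lines.append("-" * 42)
            for k in ks:
                acc = self.topk_accuracy(eval_sets, k=k)
                lines.append(f"Top-{k:<2} accuracy:        {acc:.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_ranker(model: RankerModel, path) -> None:
    """Checkpoint: parameter file (.npz) + JSON metadata sidecar."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {}
    for i, (W, b) in enumerate(model.mlp.params()):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "dims": model.mlp.dims,
        "feature_meta": model.feature_meta,
        "config": dataclasses.asdict(model.config) if model.config else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def load_ranker(path) -> RankerModel:
    import json
    from pathlib import Path

    from .nn import MLP

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    mlp = MLP(meta["dims"], zero_init=True)
    npz = np.load(path.with_suffix(".npz"))
    for i in range(len(mlp.W)):
        mlp.W[i] = npz[f"W{i}"]
        mlp.b[i] = npz[f"b{i}"]
    config = TrainConfig(**{**meta["config"],
                            "split_ratios": tuple(meta["config"]["split_ratios"]),
                            "hidden_dims": tuple(meta["config"]["hidden_dims"])}) \
        if meta.get("config") else None
    return RankerModel(mlp=mlp, feature_meta=meta["feature_meta"], config=config)


def write_metrics_report(table: pd.DataFrame, path) -> None:
    """Per-fold Top-k table as TSV plus a JSON twin."""
    from pathlib import Path

    path = Path(path)
    table.to_csv(path.with_suffix(".tsv"), sep="\t")
    path.with_suffix(".json").write_text(table.to_json(indent=1), encoding="utf-8")
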
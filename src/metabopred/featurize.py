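"""Morgan-fingerprint featurization of (substrate, candidate) pairs.

Each candidate metabolite is represented as the concatenation of the
substrate's and the candidate's hashed circular (Morgan/ECFP) fingerprints:
radius 2 with 1024 bits per molecule gives the default 2048-dimensional
input row. Radius-3 fingerprints (ECFP6-equivalent) can be compressed with a
small autoencoder before ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .nn import MLP, Adam
from .templates import CandidateSet

_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return _GENERATORS[key]


def morgan_fingerprint(molecule: Chem.Mol | str, radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    """Hashed binary circular fingerprint, deterministic for a given molecule."""
    mol = Chem.MolFromSmiles(molecule) if isinstance(molecule, str) else molecule
    if mol is None:
        raise ValueError(f"invalid molecule {molecule!r}")
    if n_bits < 1 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError("n_bits must be a power of two")
    return _generator(radius, n_bits).GetFingerprintAsNumPy(mol).astype(np.float32)


def featurize_pair(substrate: Chem.Mol | str, candidate: Chem.Mol | str,
                   radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    """[fp(substrate) || fp(candidate)] concatenated feature row (length 2*n_bits)."""
    return np.concatenate([
        morgan_fingerprint(substrate, radius, n_bits),
        morgan_fingerprint(candidate, radius, n_bits),
    ])


@dataclass
class FeatureBlock:
    """Per-candidate feature matrix for one candidate set, with validity mask."""

    matrix: np.ndarray  # (n, d)
    mask: np.ndarray  # (n,), 1 = real candidate, 0 = padding
    radius: int
    n_bits: int

    @property
    def d(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def n(self) -> int:
        return int(self.matrix.shape[0])


def featurize_candidate_set(cs: CandidateSet, radius: int = 2, n_bits: int = 1024) -> FeatureBlock:
    """One feature row per candidate, in candidate-set order.

    The substrate half is computed once and shared across rows.
    """
    sub_fp = morgan_fingerprint(cs.substrate_smiles, radius, n_bits)
    n = cs.n_candidates
    mat = np.zeros((n, 2 * n_bits), dtype=np.float32)
    for i, cand in enumerate(cs.candidates):
        mat[i, :n_bits] = sub_fp
        mat[i, n_bits:] = morgan_fingerprint(cand.smiles, radius, n_bits)
    return FeatureBlock(matrix=mat, mask=np.ones(n, dtype=np.float32), radius=radius, n_bits=n_bits)


def save_features(blocks: Sequence[FeatureBlock], path: str | Path) -> None:
    """Binary matrix cache (.npz) with a JSON sidecar describing the layout."""
    path = Path(path)
    np.savez_compressed(
        path,
        **{f"m{i}": b.matrix for i, b in enumerate(blocks)},
    )
    sidecar = {
        "n_blocks": len(blocks),
        "radius": blocks[0].radius if blocks else None,
        "n_bits": blocks[0].n_bits if blocks else None,
        "d": blocks[0].d if blocks else None,
        "rows": [b.n for b in blocks],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar), encoding="utf-8")


def load_features(path: str | Path) -> list[FeatureBlock]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    npz = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    blocks = []
    for i in range(meta["n_blocks"]):
        m = npz[f"m{i}"]
        blocks.append(FeatureBlock(matrix=m, mask=np.ones(m.shape[0], dtype=np.float32),
                                   radius=meta["radius"], n_bits=meta["n_bits"]))
    return blocks


# ---------------------------------------------------------------------------
# Autoencoder compression
# ---------------------------------------------------------------------------

@dataclass
class AutoencoderSpec:
    input_dim: int = 2048
    latent_dim: int = 256
    hidden_dims: tuple[int, ...] = (512,)
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim >= self.input_dim:
            raise ValueError("latent_dim must be smaller than input_dim")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class Autoencoder:
    """Symmetric encoder/decoder with sigmoid reconstruction of bit vectors."""

    def __init__(self, spec: AutoencoderSpec):
        self.spec = spec
        dims = [spec.input_dim, *spec.hidden_dims, spec.latent_dim]
        self.encoder = MLP(dims, seed=spec.seed)
        self.decoder = MLP(list(reversed(dims)), seed=spec.seed + 1)
        self.loss_history: list[float] = []

    def encode(self, rows: np.ndarray) -> np.ndarray:
        out, _ = self.encoder.forward(rows)
        return out

    def __call__(self, rows: np.ndarray) -> np.ndarray:
        return self.encode(rows)

    def _loss_and_grads(self, x: np.ndarray):
        z, enc_cache = self.encoder.forward(x)
        logits, dec_cache = self.decoder.forward(z)
        # stable sigmoid BCE
        p = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        loss = -np.mean(x * np.log(p + eps) + (1 - x) * np.log(1 - p + eps))
        dlogits = (p - x) / x.size
        dec_grads, dz = self.decoder.backward(dec_cache, dlogits, return_dinput=True)
        enc_grads = self.encoder.backward(enc_cache, dz)
        return loss, enc_grads, dec_grads

    def reconstruction_loss(self, x: np.ndarray) -> float:
        loss, _, _ = self._loss_and_grads(x)
        return float(loss)


def train_autoencoder(rows: np.ndarray, spec: AutoencoderSpec) -> Autoencoder:
    """Fit the autoencoder by minimizing binary reconstruction loss.

    Deterministic for a given spec (seeded shuffling and init). Raises on
    degenerate all-zero input.
    """
    rows = np.asarray(rows, dtype=np.float64)
    if rows.ndim != 2 or rows.shape[0] < spec.latent_dim:
        raise ValueError("need at least latent_dim rows")
    if not rows.any():
        raise ValueError("all-zero feature matrix")
    if rows.shape[1] != spec.input_dim:
        raise ValueError(f"rows have dim {rows.shape[1]}, spec expects {spec.input_dim}")
    ae = Autoencoder(spec)
    opt_e = Adam(ae.encoder.params(), lr=spec.learning_rate)
    opt_d = Adam(ae.decoder.params(), lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed + 2)
    n = rows.shape[0]
    for _ in range(spec.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for start in range(0, n, spec.batch_size):
            batch = rows[perm[start:start + spec.batch_size]]
            loss, enc_grads, dec_grads = ae._loss_and_grads(batch)
            opt_e.step(ae.encoder, enc_grads)
            opt_d.step(ae.decoder, dec_grads)
            epoch_loss += loss
            nb += 1
        ae.loss_history.append(epoch_loss / max(nb, 1))
    return ae


def encode_block(block: FeatureBlock, encoder: Callable[[np.ndarray], np.ndarray]) -> FeatureBlock:
    """Row-wise encoding of a feature block; the mask is unchanged."""
    if isinstance(encoder, Autoencoder) and block.d != encoder.spec.input_dim:
        raise ValueError(f"encoder expects dim {encoder.spec.input_dim}, block has {block.d}")
    encoded = np.asarray(encoder(block.matrix.astype(np.float64)))
    if encoded.shape[0] != block.n:
        raise ValueError("encoder changed the number of rows")
    return FeatureBlock(matrix=encoded.astype(np.float32), mask=block.mask.copy(),
                        radius=block.radius, n_bits=block.n_bits)
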
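"""Gated convolutional scorer with TF / cell-line embeddings.

One shared bank of convolutional motif detectors scans both strands of the
input; a gate in (0,1) per filter, computed from the concatenated TF and
cell-line embeddings, modulates the pooled detector outputs, and the final
score is the max over a fully connected layer, maximized over strands.

Implemented directly on NumPy with hand-derived gradients (validated by a
finite-difference check in the test suite).  All math is float64 and
single-threaded-deterministic under a fixed seed.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from motifgate.sequences import encode_indices, BASE_ORDER

# one-hot lookup rows for codes 0..4 (N -> all-zero row)
_OH = np.vstack([np.eye(4), np.zeros((1, 4))])


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters and vocabularies."""

    seq_length: int
    filter_length: int
    num_filters: int
    pool_window: int
    fc_size: int
    tf_vocab: Tuple[str, ...]
    cell_vocab: Tuple[str, ...]
    embed_dim: int = 50
    relu_mode: str = "literal"  # {"literal", "shifted"}

    def __post_init__(self):
        object.__setattr__(self, "tf_vocab", tuple(self.tf_vocab))
        object.__setattr__(self, "cell_vocab", tuple(self.cell_vocab))
        if self.filter_length > self.seq_length:
            raise ValueError("filter_length must not exceed seq_length")
        if self.pool_window < 1:
            raise ValueError("pool_window must be >= 1")
        if self.relu_mode not in ("literal", "shifted"):
            raise ValueError(f"unknown relu_mode {self.relu_mode!r}")

    @property
    def conv_rows(self) -> int:
        return self.seq_length - self.filter_length + 1

    @property
    def num_windows(self) -> int:
        return -(-self.conv_rows // self.pool_window)

    def tf_index(self, name: str) -> int:
        try:
            return self.tf_vocab.index(name)
        except ValueError:
            raise KeyError(f"TF {name!r} not in training vocabulary; "
                           "the model cannot be applied") from None

    def cell_index(self, name: str) -> int:
        try:
            return self.cell_vocab.index(name)
        except ValueError:
            raise KeyError(f"cell line {name!r} not in training vocabulary; "
                           "the model cannot be applied") from None


@dataclass
class ModelParameters:
    """All learnable arrays; shapes are fixed by a ModelConfig."""

    E_tf: np.ndarray     # (|tf_vocab|, embed_dim)
    E_cell: np.ndarray   # (|cell_vocab|, embed_dim)
    W: np.ndarray        # (K, F, 4) filter bank, columns in BASE_ORDER
    b: np.ndarray        # (K,) rectifier thresholds
    W1: np.ndarray       # (K, 2*embed_dim) gate weights
    b1: np.ndarray       # (K,)
    W2: np.ndarray       # (fc_size, K*num_windows)
    b2: np.ndarray       # (fc_size,)

    GROUP_NAMES = ("E_tf", "E_cell", "W", "b", "W1", "b1", "W2", "b2")

    def groups(self) -> Dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.GROUP_NAMES}

    def copy(self) -> "ModelParameters":
        return ModelParameters(**{k: v.copy() for k, v in self.groups().items()})

    def check_finite(self) -> None:
        for name, arr in self.groups().items():
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite values in parameter group {name}")


def init_parameters(config: ModelConfig, rng: np.random.Generator,
                    weight_sd: float = 0.01, relu_threshold: float = -4.0
                    ) -> ModelParameters:
    """Gaussian(0, weight_sd^2) weights; rectifier thresholds at
    ``relu_threshold``; all other biases zero."""
    K, F, d = config.num_filters, config.filter_length, config.embed_dim
    nw, fc = config.num_windows, config.fc_size
    g = lambda *shape: rng.normal(0.0, weight_sd, size=shape)
    return ModelParameters(
        E_tf=g(len(config.tf_vocab), d),
        E_cell=g(len(config.cell_vocab), d),
        W=g(K, F, 4),
        b=np.full(K, relu_threshold, dtype=float),
        W1=g(K, 2 * d),
        b1=np.zeros(K),
        W2=g(fc, K * nw),
        b2=np.zeros(fc),
    )


# ---------------------------------------------------------------------------
# functional building blocks (single-instance reference path)
# ---------------------------------------------------------------------------

def convolve(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Valid (no padding) convolution of a one-hot matrix with a filter bank.

    X: (N, 4); W: (K, F, 4).  Output Y: (N-F+1, K) with
    Y[r, k] = sum_{i,j} W[k, i, j] * X[r+i, j].
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    N = X.shape[0]
    K, F, _ = W.shape
    if N < F:
        raise ValueError(f"sequence length {N} shorter than filter length {F}")
    # (N-F+1, F, 4) windows -> flatten -> matmul
    Xw = np.lib.stride_tricks.sliding_window_view(X, F, axis=0)  # (R, 4, F)
    Xw = np.ascontiguousarray(Xw.transpose(0, 2, 1)).reshape(N - F + 1, F * 4)
    return Xw @ W.reshape(K, F * 4).T


def thresholded_relu(y, b, mode: str = "literal"):
    """Rectifier with a per-filter threshold.

    literal: y if y > b else 0 (may pass negatives when b < 0);
    shifted: max(0, y - b).
    """
    y = np.asarray(y, dtype=float)
    if mode == "literal":
        return np.where(y > b, y, 0.0)
    if mode == "shifted":
        return np.maximum(y - b, 0.0)
    raise ValueError(f"unknown relu_mode {mode!r}")


def max_pool(Z: np.ndarray, pool_window: int) -> np.ndarray:
    """Max over consecutive non-overlapping windows of conv-output rows.

    Z: (R, K) -> (ceil(R / pool_window), K); the last window may be shorter.
    """
    Z = np.asarray(Z, dtype=float)
    R = Z.shape[0]
    return np.stack([
        Z[s: s + pool_window].max(axis=0)
        for s in range(0, R, pool_window)
    ])


def embed(tf_id: int, cell_id: int, E_tf: np.ndarray, E_cell: np.ndarray
          ) -> np.ndarray:
    """Concatenated (TF, cell-line) embedding, TF half first."""
    if not 0 <= tf_id < E_tf.shape[0]:
        raise IndexError(f"TF id {tf_id} outside vocabulary of size "
                         f"{E_tf.shape[0]}; the model cannot be applied")
    if not 0 <= cell_id < E_cell.shape[0]:
        raise IndexError(f"cell-line id {cell_id} outside vocabulary of size "
                         f"{E_cell.shape[0]}; the model cannot be applied")
    return np.concatenate([E_tf[tf_id], E_cell[cell_id]])


def sigmoid(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def compute_gates(e: np.ndarray, W1: np.ndarray, b1: np.ndarray) -> np.ndarray:
    """Per-filter gates: sigmoid(W1 e + b1), each strictly in (0, 1)."""
    return sigmoid(W1 @ e + b1)


def strand_score(seq: str, tf_id: int, cell_id: int,
                 params: ModelParameters, config: ModelConfig) -> float:
    """Single-strand score: max over the fully connected output vector."""
    if len(seq) != config.seq_length:
        raise ValueError(f"sequence length {len(seq)} does not match model "
                         f"input length {config.seq_length}")
    X = _OH[encode_indices(seq)]
    Y = convolve(X, params.W)
    Z = thresholded_relu(Y, params.b, config.relu_mode)
    P = max_pool(Z, config.pool_window)               # (nw, K)
    g = compute_gates(embed(tf_id, cell_id, params.E_tf, params.E_cell),
                      params.W1, params.b1)
    M = P * g                                          # gate broadcast over windows
    return float((params.W2 @ M.reshape(-1) + params.b2).max())


def predict(seq: str, tf_id: int, cell_id: int,
            params: ModelParameters, config: ModelConfig) -> float:
    """Strand-symmetric score: max over forward and reverse-complement."""
    from motifgate.sequences import reverse_complement
    return max(strand_score(seq, tf_id, cell_id, params, config),
               strand_score(reverse_complement(seq), tf_id, cell_id,
                            params, config))


def predict_prob(seq: str, tf_id: int, cell_id: int,
                 params: ModelParameters, config: ModelConfig) -> float:
    return float(sigmoid(predict(seq, tf_id, cell_id, params, config)))


# ---------------------------------------------------------------------------
# batched model with analytic gradients
# ---------------------------------------------------------------------------

def codes_for(seqs: Sequence[str], seq_length: int) -> np.ndarray:
    """Pack sequences into a (B, N) uint8 code matrix (A=0..T=3, N=4)."""
    out = np.empty((len(seqs), seq_length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        c = encode_indices(s)
        if c.shape[0] != seq_length:
            raise ValueError(f"sequence {i} has length {c.shape[0]}, "
                             f"expected {seq_length}")
        out[i] = c
    return out


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    rc = np.where(codes == 4, 4, 3 - codes.astype(np.int16)).astype(np.uint8)
    return rc[:, ::-1]


class GatedConvModel:
    """Config + parameters with batched scoring and backprop."""

    def __init__(self, config: ModelConfig, params: Optional[ModelParameters] = None,
                 rng: Optional[np.random.Generator] = None):
        self.config = config
        if params is None:
            params = init_parameters(config, rng or np.random.default_rng(0))
        self.params = params

    # -- forward ------------------------------------------------------------

    def _strand_forward(self, codes2: np.ndarray, g2: np.ndarray,
                        want_cache: bool):
        """codes2: (M, N) both-strand codes; g2: (M, K) gates."""
        cfg, p = self.config, self.params
        F, K, nw = cfg.filter_length, cfg.num_filters, cfg.num_windows
        M_, N = codes2.shape
        R = cfg.conv_rows

        X = _OH[codes2]                                       # (M, N, 4)
        Xw = np.lib.stride_tricks.sliding_window_view(X, F, axis=1)
        Xw = np.ascontiguousarray(Xw.transpose(0, 1, 3, 2)).reshape(M_ * R, F * 4)
        Y = (Xw @ p.W.reshape(K, F * 4).T).reshape(M_, R, K)

        if cfg.relu_mode == "literal":
            mask = Y > p.b
            Z = np.where(mask, Y, 0.0)
        else:
            mask = Y > p.b
            Z = np.where(mask, Y - p.b, 0.0)

        P = np.empty((M_, nw, K))
        pool_arg = np.empty((M_, nw, K), dtype=np.int64)
        for w, s in enumerate(range(0, R, cfg.pool_window)):
            block = Z[:, s: s + cfg.pool_window]
            am = block.argmax(axis=1)
            pool_arg[:, w] = am + s
            P[:, w] = np.take_along_axis(block, am[:, None, :], axis=1)[:, 0]

        Mg = P * g2[:, None, :]                               # (M, nw, K)
        Mflat = Mg.reshape(M_, nw * K)
        H = Mflat @ p.W2.T + p.b2                             # (M, fc)
        h_arg = H.argmax(axis=1)
        s = H[np.arange(M_), h_arg]
        cache = None
        if want_cache:
            cache = dict(Xw=Xw, Y=Y, mask=mask, P=P, pool_arg=pool_arg,
                         Mflat=Mflat, h_arg=h_arg, g2=g2)
        return s, cache

    def forward(self, codes: np.ndarray, tf_ids: np.ndarray,
                cell_ids: np.ndarray, want_cache: bool = False):
        """Strand-max scores for a batch.  Returns (scores, cache)."""
        p = self.params
        B = codes.shape[0]
        e = np.concatenate([p.E_tf[tf_ids], p.E_cell[cell_ids]], axis=1)
        A = e @ p.W1.T + p.b1
        g = sigmoid(A)                                        # (B, K)
        codes2 = np.vstack([codes, revcomp_codes(codes)])
        g2 = np.vstack([g, g])
        s, cache = self._strand_forward(codes2, g2, want_cache)
        fwd, rev = s[:B], s[B:]
        winner = fwd >= rev                                   # ties -> forward
        scores = np.where(winner, fwd, rev)
        if want_cache:
            cache.update(e=e, g=g, winner=winner, tf_ids=tf_ids,
                         cell_ids=cell_ids, B=B)
        return scores, cache

    def predict_scores(self, seqs: Sequence[str], tf_ids, cell_ids,
                       batch_size: int = 256) -> np.ndarray:
        """Strand-max raw scores for sequences given per-instance ids."""
        codes = codes_for(seqs, self.config.seq_length)
        return self.predict_scores_codes(codes, np.asarray(tf_ids),
                                         np.asarray(cell_ids), batch_size)

    def predict_scores_codes(self, codes, tf_ids, cell_ids,
                             batch_size: int = 256) -> np.ndarray:
        out = np.empty(codes.shape[0])
        for s in range(0, codes.shape[0], batch_size):
            sl = slice(s, s + batch_size)
            out[sl], _ = self.forward(codes[sl], tf_ids[sl], cell_ids[sl])
        return out

    def predict_probs(self, seqs, tf_ids, cell_ids, batch_size: int = 256):
        return sigmoid(self.predict_scores(seqs, tf_ids, cell_ids, batch_size))

    # -- loss & gradients ----------------------------------------------------

    def loss_and_grads(self, codes, tf_ids, cell_ids, labels):
        """Mean binary cross-entropy (on the strand-max logit) and gradients
        for every parameter group."""
        cfg, p = self.config, self.params
        B = codes.shape[0]
        K, F, nw = cfg.num_filters, cfg.filter_length, cfg.num_windows
        d = cfg.embed_dim
        scores, c = self.forward(codes, tf_ids, cell_ids, want_cache=True)
        y = np.asarray(labels, dtype=float)

        # numerically stable BCE-with-logits
        loss = float(np.mean(np.maximum(scores, 0) - scores * y
                             + np.log1p(np.exp(-np.abs(scores)))))
        dscore = (sigmoid(scores) - y) / B                    # (B,)

        M2 = 2 * B
        ds = np.zeros(M2)
        rows = np.where(c["winner"], np.arange(B), np.arange(B) + B)
        ds[rows] = dscore

        dH = np.zeros((M2, cfg.fc_size))
        dH[np.arange(M2), c["h_arg"]] = ds
        gW2 = dH.T @ c["Mflat"]
        gb2 = dH.sum(axis=0)
        dM = (dH @ p.W2).reshape(M2, nw, K)

        P, g2 = c["P"], c["g2"]
        dg2 = (dM * P).sum(axis=1)                            # (M2, K)
        dg = dg2[:B] + dg2[B:]
        dP = dM * g2[:, None, :]

        # gate net
        gmat = c["g"]
        dA = dg * gmat * (1.0 - gmat)                         # (B, K)
        gW1 = dA.T @ c["e"]
        gb1 = dA.sum(axis=0)
        de = dA @ p.W1                                        # (B, 2d)
        gE_tf = np.zeros_like(p.E_tf)
        gE_cell = np.zeros_like(p.E_cell)
        np.add.at(gE_tf, tf_ids, de[:, :d])
        np.add.at(gE_cell, cell_ids, de[:, d:])

        # unpool
        R = cfg.conv_rows
        dZ = np.zeros((M2, R, K))
        bidx = np.arange(M2)[:, None, None]
        kidx = np.arange(K)[None, None, :]
        np.add.at(dZ, (bidx, c["pool_arg"], kidx), dP)

        # rectifier
        mask = c["mask"]
        dY = np.where(mask, dZ, 0.0)
        if cfg.relu_mode == "shifted":
            gb = -dY.sum(axis=(0, 1))
        else:
            # literal rectifier is piecewise constant in b: zero subgradient
            gb = np.zeros(K)

        gW = (dY.reshape(M2 * R, K).T @ c["Xw"]).reshape(K, F, 4)

        grads = dict(E_tf=gE_tf, E_cell=gE_cell, W=gW, b=gb,
                     W1=gW1, b1=gb1, W2=gW2, b2=gb2)
        return loss, grads

    # -- serialization -------------------------------------------------------

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        meta = dict(format_version=self.FORMAT_VERSION,
                    base_order=BASE_ORDER,
                    config=asdict(self.config))
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            **self.params.groups())

    @classmethod
    def load(cls, path) -> "GatedConvModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta["format_version"] != cls.FORMAT_VERSION:
                raise ValueError(f"unsupported model format version "
                                 f"{meta['format_version']}")
            if meta["base_order"] != BASE_ORDER:
                raise ValueError("model serialized under a different one-hot "
                                 "column order")
            cfg = ModelConfig(**meta["config"])
            params = ModelParameters(**{k: z[k] for k in
                                        ModelParameters.GROUP_NAMES})
        return cls(cfg, params)
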
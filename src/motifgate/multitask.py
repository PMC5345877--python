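"""Multi-TF variant: CNN + GRU with cell-line-embedding gates.

For long inputs, the per-(TF, cell) scorer is replaced by a structure that
scores all TFs at once: the cell-line embedding has length equal to the
number of filters and is squashed directly into gates; the gated pooled
convolution signal (window 50 by default) is fed through a GRU, and the
last hidden state maps linearly to one output per TF.  Strand handling
mirrors the base model: per-output max over forward and reverse complement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from motifgate.model import _OH, sigmoid, revcomp_codes, codes_for
from motifgate.sequences import encode_indices


@dataclass(frozen=True)
class MultiTFConfig:
    seq_length: int
    filter_length: int
    num_filters: int
    hidden_size: int
    tf_vocab: Tuple[str, ...]
    cell_vocab: Tuple[str, ...]
    pool_window: int = 50
    relu_mode: str = "literal"

    def __post_init__(self):
        object.__setattr__(self, "tf_vocab", tuple(self.tf_vocab))
        object.__setattr__(self, "cell_vocab", tuple(self.cell_vocab))
        if self.filter_length > self.seq_length:
            raise ValueError("filter_length must not exceed seq_length")

    @property
    def conv_rows(self) -> int:
        return self.seq_length - self.filter_length + 1

    @property
    def num_steps(self) -> int:
        return -(-self.conv_rows // self.pool_window)


class MultiTFModel:
    """CNN-GRU multi-TF scorer; gates are sigmoid(cell embedding)."""

    PARAM_NAMES = ("W", "b", "E_cell", "Wz", "Wr", "Wh", "Uz", "Ur", "Uh",
                   "bz", "br", "bh", "Wout", "bout")

    def __init__(self, config: MultiTFConfig,
                 params: Optional[Dict[str, np.ndarray]] = None,
                 rng: Optional[np.random.Generator] = None,
                 weight_sd: float = 0.01, relu_threshold: float = -4.0):
        self.config = config
        if params is None:
            rng = rng or np.random.default_rng(0)
            K, F, H = config.num_filters, config.filter_length, config.hidden_size
            T = len(config.tf_vocab)
            g = lambda *s: rng.normal(0.0, weight_sd, size=s)
            params = dict(
                W=g(K, F, 4), b=np.full(K, relu_threshold, dtype=float),
                E_cell=g(len(config.cell_vocab), K),
                Wz=g(K, H), Wr=g(K, H), Wh=g(K, H),
                Uz=g(H, H), Ur=g(H, H), Uh=g(H, H),
                bz=np.zeros(H), br=np.zeros(H), bh=np.zeros(H),
                Wout=g(T, H), bout=np.zeros(T),
            )
        self.params = params

    # -- forward -------------------------------------------------------------

    def _features(self, codes2: np.ndarray, want_cache: bool):
        """Conv + rectify + pool: codes2 (M, N) -> (M, T_steps, K)."""
        cfg, p = self.config, self.params
        K, F = cfg.num_filters, cfg.filter_length
        M_, N = codes2.shape
        R = cfg.conv_rows
        X = _OH[codes2]
        Xw = np.lib.stride_tricks.sliding_window_view(X, F, axis=1)
        Xw = np.ascontiguousarray(Xw.transpose(0, 1, 3, 2)).reshape(M_ * R, F * 4)
        Y = (Xw @ p["W"].reshape(K, F * 4).T).reshape(M_, R, K)
        mask = Y > p["b"]
        Z = np.where(mask, Y, 0.0) if cfg.relu_mode == "literal" \
            else np.where(mask, Y - p["b"], 0.0)
        T = cfg.num_steps
        P = np.empty((M_, T, K))
        pool_arg = np.empty((M_, T, K), dtype=np.int64)
        for w, s in enumerate(range(0, R, cfg.pool_window)):
            block = Z[:, s: s + cfg.pool_window]
            am = block.argmax(axis=1)
            pool_arg[:, w] = am + s
            P[:, w] = np.take_along_axis(block, am[:, None, :], axis=1)[:, 0]
        cache = dict(Xw=Xw, mask=mask, pool_arg=pool_arg, P=P) if want_cache else None
        return P, cache

    def _gru(self, Xseq: np.ndarray, want_cache: bool):
        """Xseq: (M, T, K) -> last hidden state (M, H)."""
        p = self.params
        M_, T, _ = Xseq.shape
        H = self.config.hidden_size
        h = np.zeros((M_, H))
        steps = []
        for t in range(T):
            x = Xseq[:, t]
            z = sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
            hh = np.tanh(x @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
            h_new = (1.0 - z) * h + z * hh
            if want_cache:
                steps.append(dict(x=x, h_prev=h, z=z, r=r, hh=hh))
            h = h_new
        return h, steps

    def forward(self, codes: np.ndarray, cell_ids: np.ndarray,
                want_cache: bool = False):
        """Strand-max scores for every TF: (B, |tf_vocab|)."""
        cfg, p = self.config, self.params
        B = codes.shape[0]
        g = sigmoid(p["E_cell"][cell_ids])                    # (B, K)
        codes2 = np.vstack([codes, revcomp_codes(codes)])
        g2 = np.vstack([g, g])
        P, fcache = self._features(codes2, want_cache)
        Xseq = P * g2[:, None, :]
        h, steps = self._gru(Xseq, want_cache)
        O = h @ p["Wout"].T + p["bout"]                       # (2B, |tf|)
        fwd, rev = O[:B], O[B:]
        winner = fwd >= rev
        scores = np.where(winner, fwd, rev)
        cache = None
        if want_cache:
            cache = dict(fcache=fcache, steps=steps, h=h, g=g, g2=g2,
                         winner=winner, B=B, cell_ids=cell_ids, Xseq=Xseq)
        return scores, cache

    def predict_scores(self, seqs: Sequence[str], cell_ids,
                       batch_size: int = 256) -> np.ndarray:
        codes = codes_for(seqs, self.config.seq_length)
        cell_ids = np.asarray(cell_ids)
        out = np.empty((codes.shape[0], len(self.config.tf_vocab)))
        for s in range(0, codes.shape[0], batch_size):
            sl = slice(s, s + batch_size)
            out[sl], _ = self.forward(codes[sl], cell_ids[sl])
        return out

    # -- gradients -----------------------------------------------------------

    def loss_and_grads(self, codes, cell_ids, tf_ids, labels):
        """BCE on the output unit of each instance's TF only."""
        cfg, p = self.config, self.params
        B = codes.shape[0]
        K, Fl = cfg.num_filters, cfg.filter_length
        scores, c = self.forward(codes, cell_ids, want_cache=True)
        tf_ids = np.asarray(tf_ids)
        y = np.asarray(labels, dtype=float)
        s = scores[np.arange(B), tf_ids]
        loss = float(np.mean(np.maximum(s, 0) - s * y
                             + np.log1p(np.exp(-np.abs(s)))))
        dsc = (sigmoid(s) - y) / B

        M2 = 2 * B
        dO = np.zeros((M2, len(cfg.tf_vocab)))
        win = c["winner"][np.arange(B), tf_ids]               # forward strand won?
        rows = np.where(win, np.arange(B), np.arange(B) + B)
        dO[rows, tf_ids] = dsc

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wout"] = dO.T @ c["h"]
        grads["bout"] = dO.sum(axis=0)
        dh = dO @ p["Wout"]                                   # (M2, H)

        dXseq = np.zeros_like(c["Xseq"])
        for t in range(cfg.num_steps - 1, -1, -1):
            st = c["steps"][t]
            x, h_prev, z, r, hh = st["x"], st["h_prev"], st["z"], st["r"], st["hh"]
            dz = dh * (hh - h_prev)
            dhh = dh * z
            dh_prev = dh * (1.0 - z)
            dah = dhh * (1.0 - hh ** 2)
            grads["Wh"] += x.T @ dah
            grads["Uh"] += (r * h_prev).T @ dah
            grads["bh"] += dah.sum(axis=0)
            drh = dah @ p["Uh"].T
            dr = drh * h_prev
            dh_prev += drh * r
            daz = dz * z * (1.0 - z)
            grads["Wz"] += x.T @ daz
            grads["Uz"] += h_prev.T @ daz
            grads["bz"] += daz.sum(axis=0)
            dh_prev += daz @ p["Uz"].T
            dar = dr * r * (1.0 - r)
            grads["Wr"] += x.T @ dar
            grads["Ur"] += h_prev.T @ dar
            grads["br"] += dar.sum(axis=0)
            dh_prev += dar @ p["Ur"].T
            dXseq[:, t] = dah @ p["Wh"].T + daz @ p["Wz"].T + dar @ p["Wr"].T
            dh = dh_prev

        P, g2 = c["fcache"]["P"], c["g2"]
        dP = dXseq * g2[:, None, :]
        dg2 = (dXseq * P).sum(axis=1)                         # (M2, K)
        dg = dg2[:B] + dg2[B:]
        gmat = c["g"]
        dE_rows = dg * gmat * (1.0 - gmat)
        np.add.at(grads["E_cell"], cell_ids, dE_rows)

        R = cfg.conv_rows
        dZ = np.zeros((M2, R, K))
        bidx = np.arange(M2)[:, None, None]
        kidx = np.arange(K)[None, None, :]
        np.add.at(dZ, (bidx, c["fcache"]["pool_arg"], kidx), dP)
        mask = c["fcache"]["mask"]
        dY = np.where(mask, dZ, 0.0)
        if cfg.relu_mode == "shifted":
            grads["b"] = -dY.sum(axis=(0, 1))
        grads["W"] = (dY.reshape(M2 * R, K).T @ c["fcache"]["Xw"]).reshape(K, Fl, 4)
        return loss, grads


def multi_tf_forward(seq: str, cell_id: int, model: MultiTFModel) -> np.ndarray:
    """Score vector over the TF vocabulary for one sequence in one cell."""
    codes = codes_for([seq], model.config.seq_length)
    scores, _ = model.forward(codes, np.asarray([cell_id]))
    return scores[0]
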
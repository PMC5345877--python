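"""Downstream analyses on a trained model: SNP allele-effect matrices,
PCA enhancer-activity signature with top/bottom testing, and hierarchical
clustering of learned embeddings."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr, ttest_ind

from motifgate.model import GatedConvModel


@dataclass
class SnpSpec:
    """A flanking sequence with one marked variant position and two alleles."""
    id: str
    flank: str
    pos: int          # 0-based position of the variant within flank
    allele_a: str
    allele_b: str

    def __post_init__(self):
        self.flank = self.flank.upper()
        self.allele_a = self.allele_a.upper()
        self.allele_b = self.allele_b.upper()
        if not 0 <= self.pos < len(self.flank):
            raise ValueError(f"{self.id}: variant position {self.pos} outside "
                             f"flank of length {len(self.flank)}")
        if len(self.allele_a) != 1 or len(self.allele_b) != 1:
            raise ValueError(f"{self.id}: alleles must be single bases")

    def sequence_with(self, allele: str) -> str:
        return self.flank[: self.pos] + allele + self.flank[self.pos + 1:]


def snp_delta(model: GatedConvModel, snp: SnpSpec,
              tf_set: Optional[Sequence[str]] = None,
              cell_set: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """TF x cell matrix of predicted-probability differences,
    P(bind | allele_a) - P(bind | allele_b); entries lie in (-1, 1).

    Swapping the alleles negates the matrix exactly; identical alleles give
    an all-zero matrix.
    """
    cfg = model.config
    if len(snp.flank) != cfg.seq_length:
        raise ValueError(f"{snp.id}: flank length {len(snp.flank)} does not "
                         f"match model input length {cfg.seq_length}")
    if snp.flank[snp.pos] not in (snp.allele_a, snp.allele_b):
        raise ValueError(f"{snp.id}: flank base {snp.flank[snp.pos]!r} at the "
                         f"marked position matches neither allele")
    tfs = list(tf_set) if tf_set is not None else list(cfg.tf_vocab)
    cells = list(cell_set) if cell_set is not None else list(cfg.cell_vocab)
    tf_ids = np.array([cfg.tf_index(t) for t in tfs])
    cell_ids = np.array([cfg.cell_index(c) for c in cells])

    seq_a = snp.sequence_with(snp.allele_a)
    seq_b = snp.sequence_with(snp.allele_b)
    tt, cc = np.meshgrid(tf_ids, cell_ids, indexing="ij")
    n = tt.size
    pa = model.predict_probs([seq_a] * n, tt.ravel(), cc.ravel())
    pb = model.predict_probs([seq_b] * n, tt.ravel(), cc.ravel())
    delta = (pa - pb).reshape(len(tfs), len(cells))
    return pd.DataFrame(delta, index=tfs, columns=cells)


def affinity_matrix(model: GatedConvModel, sequences: Sequence[str],
                    cell: str, tf_set: Optional[Sequence[str]] = None
                    ) -> pd.DataFrame:
    """Sequences x TFs matrix of predicted binding probabilities in one cell."""
    cfg = model.config
    tfs = list(tf_set) if tf_set is not None else list(cfg.tf_vocab)
    cid = cfg.cell_index(cell)
    n = len(sequences)
    cols = {}
    for t in tfs:
        tid = cfg.tf_index(t)
        cols[t] = model.predict_probs(list(sequences),
                                      np.full(n, tid), np.full(n, cid))
    return pd.DataFrame(cols)


def enhancer_signature(model: GatedConvModel, sequences: Sequence[str],
                       cell: str, tf_set: Optional[Sequence[str]] = None
                       ) -> np.ndarray:
    """First-principal-component scores of the column-centered affinity
    matrix, one value per sequence.

    The PC sign is fixed so the signature correlates non-negatively with the
    per-sequence mean affinity (the raw sign is arbitrary).
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    A = affinity_matrix(model, sequences, cell, tf_set).to_numpy()
    if A.shape[1] < 2:
        raise ValueError("need at least 2 TFs")
    centered = A - A.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    if S[0] <= 0:
        raise ValueError("affinity matrix has rank 0 after centering")
    signature = U[:, 0] * S[0]
    row_mean = A.mean(axis=1)
    if np.std(row_mean) > 0 and np.std(signature) > 0:
        r = np.corrcoef(signature, row_mean)[0, 1]
        if r < 0:
            signature = -signature
    return signature


def top_bottom_test(signature: np.ndarray, activities: np.ndarray,
                    k: int = 100) -> Tuple[float, float]:
    """Welch two-sample t-test between the signatures of the k most and k
    least active sequences (ranked by measured activity)."""
    signature = np.asarray(signature, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if signature.shape != activities.shape:
        raise ValueError("signature and activities must align")
    if len(signature) < 2 * k:
        raise ValueError(f"need at least {2 * k} sequences for top/bottom-{k}")
    order = np.argsort(activities, kind="stable")
    bottom = signature[order[:k]]
    top = signature[order[-k:]]
    t, p = ttest_ind(top, bottom, equal_var=False)
    return float(t), float(p)


def spearman_signature(signature: np.ndarray, activities: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties); NaN when either
    vector is constant."""
    signature = np.asarray(signature, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if len(signature) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(signature == signature[0]) or np.all(activities == activities[0]):
        return float("nan")
    rho, _ = spearmanr(signature, activities)
    return float(rho)


def cluster_embeddings(E: np.ndarray, entity_names: Sequence[str]
                       ) -> Tuple[np.ndarray, List[str]]:
    """Agglomerative clustering (average linkage, correlation distance) of
    embedding rows.  Returns the scipy linkage matrix and the leaf names."""
    E = np.asarray(E, dtype=float)
    names = list(entity_names)
    if E.shape[0] != len(names):
        raise ValueError("one name per embedding row required")
    if E.shape[0] < 2:
        raise ValueError("need at least 2 entities")
    dist = pdist(E, metric="correlation")
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    Z = linkage(dist, method="average")
    return Z, names


def linkage_to_newick(Z: np.ndarray, names: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a newick string with leaf names."""
    tree = to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = max(node.dist - node.left.dist, 0.0)
        dr = max(node.dist - node.right.dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"
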
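"""Deterministic sequence-level transforms.

Column order for all one-hot encodings and serialized filters is fixed
globally as (A, C, G, T).  Ambiguous bases (``N``) encode as an all-zero
row, contributing nothing under any linear filter.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

#: Global, immutable one-hot column order.
BASE_ORDER = "ACGT"

_BASE_INDEX: Dict[str, int] = {b: i for i, b in enumerate(BASE_ORDER)}
_BASE_INDEX["N"] = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Row 4 (N) is all zeros; rows 0..3 are the identity.
_ONE_HOT_ROWS = np.vstack([np.eye(4, dtype=np.uint8), np.zeros((1, 4), dtype=np.uint8)])


def _validate(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in _BASE_INDEX:
            raise ValueError(
                f"invalid character {ch!r} at position {pos}: "
                f"alphabet is A/C/G/T/N"
            )
    return seq


def encode_indices(seq: str) -> np.ndarray:
    """Map a sequence to integer codes: A=0, C=1, G=2, T=3, N=4."""
    seq = _validate(seq)
    return np.frombuffer(
        seq.encode("ascii")
        .translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8,
    ).copy()


def one_hot_encode(seq: str) -> np.ndarray:
    """One-hot encode a sequence as an N x 4 matrix with columns (A, C, G, T).

    Row i carries a single 1 in the column of base i; an ``N`` yields an
    all-zero row.
    """
    return _ONE_HOT_ROWS[encode_indices(seq)]


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed; ``N`` maps to ``N``."""
    return _validate(seq).translate(_COMPLEMENT)[::-1]


def dinucleotide_count_vector(seq: str) -> np.ndarray:
    """16-dim count vector of overlapping dinucleotides (AA, AC, ..., TT)."""
    idx = encode_indices(seq)
    if np.any(idx == 4):
        raise ValueError("dinucleotide counts undefined over N")
    counts = np.zeros(16, dtype=np.int64)
    np.add.at(counts, idx[:-1] * 4 + idx[1:], 1)
    return counts


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact multiset of dinucleotides.

    Eulerian-path (Altschul-Erickson) algorithm: the sequence is a walk on
    the 4-vertex dinucleotide multigraph; a random terminal arborescence is
    drawn by rejection, the remaining out-edges of each vertex are permuted,
    and the walk is replayed.  First and last base, all 16 dinucleotide
    counts (hence mononucleotide counts) are preserved exactly.
    """
    seq = _validate(seq)
    if len(seq) < 2:
        raise ValueError("dinucleotide shuffle requires length >= 2")
    if "N" in seq:
        raise ValueError("dinucleotide shuffle undefined over N")

    idx = encode_indices(seq).astype(np.int64)
    first, last = int(idx[0]), int(idx[-1])

    # out-edge target lists per vertex
    edges: List[List[int]] = [[] for _ in range(4)]
    for a, b in zip(idx[:-1], idx[1:]):
        edges[a].append(int(b))

    vertices = [v for v in range(4) if edges[v] or v == last]
    non_terminal = [v for v in vertices if v != last and edges[v]]

    # Draw the designated last out-edge of every non-terminal vertex; accept
    # when following those edges from each vertex reaches the terminal.
    if non_terminal:
        while True:
            last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in non_terminal}
            ok = True
            for v in non_terminal:
                seen = set()
                u = v
                while u != last and u in last_edge:
                    if u in seen:
                        break
                    seen.add(u)
                    u = last_edge[u]
                if u != last:
                    ok = False
                    break
            if ok:
                break
    else:
        last_edge = {}

    shuffled: List[List[int]] = []
    for v in range(4):
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        order = rng.permutation(len(pool))
        out = [pool[i] for i in order]
        if v in last_edge:
            out.append(last_edge[v])
        shuffled.append(out)

    # replay the walk
    result = [first]
    ptr = [0, 0, 0, 0]
    u = first
    for _ in range(len(seq) - 1):
        nxt = shuffled[u][ptr[u]]
        ptr[u] += 1
        result.append(nxt)
        u = nxt
    return "".join(BASE_ORDER[i] for i in result)


def read_fasta(path) -> Dict[str, str]:
    """Read a (multi-)FASTA into an ordered dict of uppercase sequences.

    Soft-masked lowercase is accepted and uppercased.
    """
    records: Dict[str, str] = {}
    name = None
    parts: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(parts).upper()
                name = line[1:].split()[0]
                parts = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                parts.append(line)
    if name is not None:
        records[name] = "".join(parts).upper()
    return records


def write_fasta(path, records: Dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
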
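"""Metrics and controls: AUC (pooled / grouped), recall at FDR, label-field
shuffling, genome-bin labeling."""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wilcoxon


def roc_auc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative,
    ties counted 1/2 (Mann-Whitney / rank formulation).

    Raises ValueError on single-class input (AUC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one "
                         "negative")
    ranks = rankdata(scores)  # average ranks for ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(records)


def grouped_auc(records, key: str = "tf") -> Tuple[pd.Series, float]:
    """Per-group AUC (groups ordered by name) and the mean over groups.

    ``records``: DataFrame (or records) with columns score, label, tf, cell.
    ``key``: 'tf' or 'tf_cell'.  Single-class groups are dropped with a
    warning.
    """
    df = _records_frame(records)
    if key == "tf":
        group_cols: Union[str, List[str]] = "tf"
    elif key in ("tf_cell", "tf-cell"):
        group_cols = ["tf", "cell"]
    else:
        raise ValueError(f"unknown grouping key {key!r}")
    out = {}
    for name, grp in df.groupby(group_cols, sort=True):
        try:
            out[name] = roc_auc(grp["score"].to_numpy(), grp["label"].to_numpy())
        except ValueError:
            warnings.warn(f"group {name!r} has a single class; dropped from "
                          "grouped AUC")
    series = pd.Series(out, dtype=float)
    return series, float(series.mean()) if len(series) else float("nan")


def recall_at_fdr(scores, labels, q: float) -> float:
    """Recall at the smallest score threshold t such that the prediction set
    {score >= t} has FDR = FP/(FP+TP) <= q; 0 if no threshold qualifies.

    All records with score >= t are called positive (ties included).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order] == 1
    P = int(y.sum())
    if P == 0 or P == len(y):
        raise ValueError("recall at FDR requires both classes")
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # thresholds = distinct scores; the prediction set for threshold s[i]
    # ends at the last index sharing that score
    last_of_tie = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    fdr = fp[last_of_tie] / (fp[last_of_tie] + tp[last_of_tie])
    ok = fdr <= q
    if not np.any(ok):
        return 0.0
    # smallest qualifying threshold = largest qualifying prediction set
    best = last_of_tie[ok][-1]
    return float(tp[best] / P)


def shuffle_field(records, field: str, rng: np.random.Generator):
    """Uniformly permute one field (column) across records; everything else
    untouched.  Accepts a DataFrame or a PackedInstances."""
    from motifgate.datasets import PackedInstances
    if isinstance(records, PackedInstances):
        out = PackedInstances(records.codes, records.tf_ids.copy(),
                              records.cell_ids.copy(), records.labels,
                              records.tf_vocab, records.cell_vocab)
        if field == "tf":
            out.tf_ids = out.tf_ids[rng.permutation(len(out))]
        elif field == "cell":
            out.cell_ids = out.cell_ids[rng.permutation(len(out))]
        else:
            raise ValueError(f"unknown field {field!r}")
        return out
    df = _records_frame(records).copy()
    if field not in df.columns:
        raise ValueError(f"unknown field {field!r}")
    df[field] = df[field].to_numpy()[rng.permutation(len(df))]
    return df


def bin_and_label(chrom_sizes: Dict[str, int], bin_length: int,
                  peaks) -> pd.DataFrame:
    """Consecutive non-overlapping bins per chromosome (last bin truncated);
    a bin is labeled 1 iff >= 1 peak center falls in [bin_start, bin_end).

    Peak center = summit when present, else interval midpoint.  ``peaks``
    may be PeakRecords or (chrom, start, end) tuples.
    """
    if bin_length < 1:
        raise ValueError("bin_length must be >= 1")
    centers: Dict[str, List[int]] = {}
    for p in peaks:
        if hasattr(p, "summit"):
            chrom, center = p.chrom, p.summit
        else:
            chrom, start, end = p[:3]
            center = (start + end) // 2
        centers.setdefault(chrom, []).append(center)
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        cs = np.sort(np.array(centers.get(chrom, []), dtype=np.int64))
        for start in range(0, size, bin_length):
            end = min(start + bin_length, size)
            i = np.searchsorted(cs, start, side="left")
            j = np.searchsorted(cs, end, side="left")
            rows.append((chrom, start, end, int(j > i)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def paired_auc_test(auc_a: Sequence[float], auc_b: Sequence[float]):
    """Wilcoxon signed-rank test between two paired AUC vectors."""
    return wilcoxon(np.asarray(auc_a, float), np.asarray(auc_b, float))
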
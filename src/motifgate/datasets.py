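"""Dataset construction: peak files + metadata -> labeled instances and splits.

Coordinates are 0-based half-open throughout.  Peak ranking uses the
narrowPeak signalValue column, ties broken by (chrom, start).  A fixed-width
window of even width w around a summit s is [s - w/2, s + w/2).
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from motifgate.sequences import dinucleotide_shuffle, encode_indices

Region = Tuple[str, int, int]  # (chrom, start, end), half-open


@dataclass
class PeakRecord:
    chrom: str
    start: int
    end: int
    summit_offset: int  # offset from start, always resolved (midpoint fallback)
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid peak interval [{self.start}, {self.end})")
        if not (0 <= self.summit_offset < self.end - self.start):
            raise ValueError(f"summit offset {self.summit_offset} outside peak "
                             f"[{self.start}, {self.end})")

    @property
    def summit(self) -> int:
        return self.start + self.summit_offset


@dataclass(frozen=True)
class ExperimentMeta:
    experiment_id: str
    tf_name: str
    cell_line: str
    replicate_label: str = "rep1"

    @property
    def combination(self) -> Tuple[str, str]:
        return (self.tf_name, self.cell_line)


@dataclass
class LabeledInstance:
    """A <label, TF, cell line, sequence> quadruple.

    TF and cell line are stored by name; integer ids are assigned only when
    instances are packed against fixed vocabularies (see pack_instances).
    """
    label: int
    tf: str
    cell: str
    seq: str


@dataclass
class CombinationPartition:
    base: Set[Tuple[str, str]]
    testset2: Set[Tuple[str, str]]   # subset of base (>=2 replicates)
    validset2: Set[Tuple[str, str]]
    testset3: Set[Tuple[str, str]]

    def validate(self) -> None:
        if not self.testset2 <= self.base:
            raise ValueError("testset2 must be a subset of base")
        holdout = self.validset2 | self.testset3
        if self.validset2 & self.testset3:
            raise ValueError("validset2 and testset3 must be disjoint")
        if holdout & self.base:
            raise ValueError("holdout combinations must not appear in base")
        base_tfs = {t for t, _ in self.base}
        base_cells = {c for _, c in self.base}
        for t, c in holdout:
            if t not in base_tfs:
                raise ValueError(f"TF {t!r} in holdout not represented in base")
            if c not in base_cells:
                raise ValueError(f"cell {c!r} in holdout not represented in base")

    def to_json(self) -> str:
        return json.dumps({k: sorted(getattr(self, k))
                           for k in ("base", "testset2", "validset2", "testset3")},
                          indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CombinationPartition":
        d = json.loads(text)
        return cls(**{k: {tuple(x) for x in d[k]}
                      for k in ("base", "testset2", "validset2", "testset3")})


@dataclass
class InstanceSplit:
    trainset: List[LabeledInstance]
    validset1: List[LabeledInstance]
    testset1: List[LabeledInstance]


# ---------------------------------------------------------------------------
# peak file I/O
# ---------------------------------------------------------------------------

def load_peaks(path) -> List[PeakRecord]:
    """Parse BED (3-6 col) or narrowPeak (10 col) into PeakRecords.

    narrowPeak column 10 supplies the summit offset when >= 0; otherwise
    (and for plain BED) the summit defaults to the region midpoint.
    Ranking score: narrowPeak signalValue (column 7), else BED score
    (column 5) when present, else 0.
    """
    peaks: List[PeakRecord] = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                if len(fields) < 3:
                    raise ValueError("fewer than 3 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if len(fields) >= 10:  # narrowPeak
                    score = float(fields[6])
                    summit = int(fields[9])
                    if summit < 0:
                        summit = (end - start) // 2
                elif len(fields) >= 5:
                    score = float(fields[4])
                    summit = (end - start) // 2
                else:
                    score = 0.0
                    summit = (end - start) // 2
                peaks.append(PeakRecord(chrom, start, end, summit, score))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from None
    return peaks


def read_metadata(path) -> List[ExperimentMeta]:
    """TSV with header: experiment_id, tf, cell_line, replicate."""
    metas: List[ExperimentMeta] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["experiment_id", "tf", "cell_line", "replicate"]
        if header[:4] != required:
            raise ValueError(f"{path}: expected header columns {required}, "
                             f"got {header[:4]}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: malformed line {lineno}")
            metas.append(ExperimentMeta(*fields[:4]))
    return metas


def write_instances(path, instances: Iterable[LabeledInstance]) -> None:
    """Write instances as (optionally gzipped) TSV: label tf cell_line sequence."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("label\ttf\tcell_line\tsequence\n")
        for inst in instances:
            fh.write(f"{inst.label}\t{inst.tf}\t{inst.cell}\t{inst.seq}\n")


def read_instances(path) -> List[LabeledInstance]:
    opener = gzip.open if str(path).endswith(".gz") else open
    out: List[LabeledInstance] = []
    with opener(path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("label\t"):
            raise ValueError(f"{path}: missing instance TSV header")
        for line in fh:
            label, tf, cell, seq = line.rstrip("\n").split("\t")
            out.append(LabeledInstance(int(label), tf, cell, seq))
    return out


# ---------------------------------------------------------------------------
# positives / negatives
# ---------------------------------------------------------------------------

def select_top_peaks(peaks: Sequence[PeakRecord], n: int, window: int
                     ) -> List[Region]:
    """Top-n peaks by score (descending, ties by coordinate), each as a
    fixed-width window centered on its summit."""
    ranked = sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start))
    out = []
    for p in ranked[:n]:
        start = p.summit - window // 2
        out.append((p.chrom, start, start + window))
    return out


def alternating_split(top_peaks: Sequence) -> Tuple[list, list]:
    """(odd-ranked, even-ranked) under 1-based ranks; input must be rank-ordered."""
    return list(top_peaks[0::2]), list(top_peaks[1::2])


def build_shuffled_negatives(positives: Sequence[LabeledInstance],
                             rng: np.random.Generator) -> List[LabeledInstance]:
    """One dinucleotide-preserving shuffled negative per N-free positive.

    Positives containing N are excluded (the shuffle is undefined over N);
    callers should drop those positives from the dataset as well.
    """
    out = []
    for p in positives:
        if "N" in p.seq.upper():
            continue
        out.append(LabeledInstance(0, p.tf, p.cell,
                                   dinucleotide_shuffle(p.seq, rng)))
    return out


def merge_regions(regions: Iterable[Region]) -> List[Region]:
    """Sort and merge overlapping (half-open) regions."""
    regs = sorted(regions)
    merged: List[list] = []
    for chrom, start, end in regs:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [tuple(r) for r in merged]


def build_union_dhs(dnase_peak_sets: Sequence[Sequence[PeakRecord]],
                    window: int = 300) -> List[Region]:
    """Trim every DNase peak to a summit-centered window, then merge across
    all datasets into sorted non-overlapping regions."""
    windows: List[Region] = []
    for peaks in dnase_peak_sets:
        for p in peaks:
            start = p.summit - window // 2
            windows.append((p.chrom, start, start + window))
    return merge_regions(windows)


def _overlaps_any(region: Region, sorted_peaks: Dict[str, np.ndarray]) -> bool:
    chrom, start, end = region
    if chrom not in sorted_peaks:
        return False
    starts, ends = sorted_peaks[chrom]
    # candidate peaks with start < end(region); check their ends
    i = np.searchsorted(starts, end, side="left")
    return bool(np.any(ends[:i] > start))


def build_dhs_negatives(union_dhs: Sequence[Region],
                        tf_peaks: Sequence[Region],
                        n: int, window: int,
                        rng: np.random.Generator) -> List[Region]:
    """Sample n fixed-width negative windows from union-DHS regions that have
    zero overlap with any TF peak."""
    by_chrom: Dict[str, np.ndarray] = {}
    for chrom in {r[0] for r in tf_peaks}:
        regs = sorted((r[1], r[2]) for r in tf_peaks if r[0] == chrom)
        starts = np.array([r[0] for r in regs])
        ends = np.maximum.accumulate(np.array([r[1] for r in regs]))
        by_chrom[chrom] = (starts, ends)
    pool = [r for r in union_dhs if not _overlaps_any(r, by_chrom)]
    if len(pool) < n:
        warnings.warn(f"negative pool ({len(pool)}) smaller than requested "
                      f"({n}); emitting all")
        chosen = pool
    else:
        idx = rng.choice(len(pool), size=n, replace=False)
        chosen = [pool[i] for i in sorted(idx)]
    out = []
    for chrom, start, end in chosen:
        c = (start + end) // 2
        s = c - window // 2
        out.append((chrom, s, s + window))
    return out


# ---------------------------------------------------------------------------
# combination / instance partitioning
# ---------------------------------------------------------------------------

def _max_bipartite_matching(combos: Sequence[Tuple[str, str]]
                            ) -> List[Tuple[str, str]]:
    """Deterministic Kuhn's algorithm over the TF/cell bipartite graph."""
    tfs = sorted({t for t, _ in combos})
    cells = sorted({c for _, c in combos})
    cell_idx = {c: i for i, c in enumerate(cells)}
    adj = {t: sorted(cell_idx[c] for tt, c in combos if tt == t) for t in tfs}
    match_cell = [-1] * len(cells)  # cell -> tf index

    def try_assign(ti: int, seen: set) -> bool:
        for cj in adj[tfs[ti]]:
            if cj in seen:
                continue
            seen.add(cj)
            if match_cell[cj] == -1 or try_assign(match_cell[cj], seen):
                match_cell[cj] = ti
                return True
        return False

    for ti in range(len(tfs)):
        try_assign(ti, set())
    return [(tfs[ti], cells[cj]) for cj, ti in enumerate(match_cell) if ti != -1]


def minimum_edge_cover(combos: Sequence[Tuple[str, str]]) -> Set[Tuple[str, str]]:
    """Minimum set of combinations touching every TF and every cell line.

    Gallai: |min edge cover| = |vertices| - |maximum matching|; built as a
    maximum matching plus one (lexicographically first) edge per unmatched
    vertex.
    """
    matching = _max_bipartite_matching(combos)
    cover = set(matching)
    covered_tfs = {t for t, _ in cover}
    covered_cells = {c for _, c in cover}
    for t, c in sorted(combos):
        if t not in covered_tfs:
            cover.add((t, c))
            covered_tfs.add(t)
            covered_cells.add(c)
    for t, c in sorted(combos):
        if c not in covered_cells:
            cover.add((t, c))
            covered_tfs.add(t)
            covered_cells.add(c)
    return cover


def partition_combinations(combos: Iterable[Tuple[str, str]],
                           replicates: Sequence[ExperimentMeta],
                           holdout_valid_size: int = 20,
                           rng: Optional[np.random.Generator] = None,
                           min_base_support: int = 1) -> CombinationPartition:
    """Partition (TF, cell) combinations into base / testset2 / validset2 /
    testset3.

    The holdout (validset2 + testset3) is made as large as possible subject
    to every TF and cell line it contains still occurring in base: base is
    taken as a minimum edge cover of the combination graph (exact via
    maximum bipartite matching), optionally thickened to ``min_base_support``
    combinations per held-out entity.  testset2 = base combinations backed
    by >= 2 replicate experiments.
    """
    rng = rng or np.random.default_rng(0)
    combos = sorted(set(combos))
    if not combos:
        raise ValueError("no combinations to partition")
    base = minimum_edge_cover(combos)

    if min_base_support > 1:
        def support(entity, axis):
            return sum(1 for e in base if e[axis] == entity)
        changed = True
        while changed:
            changed = False
            holdout_now = [e for e in combos if e not in base]
            for t, c in holdout_now:
                if support(t, 0) < min_base_support or support(c, 1) < min_base_support:
                    base.add((t, c))
                    changed = True

    holdout = sorted(e for e in combos if e not in base)
    if holdout_valid_size > len(holdout):
        raise ValueError(f"holdout_valid_size {holdout_valid_size} exceeds "
                         f"holdout size {len(holdout)}")
    pick = rng.choice(len(holdout), size=holdout_valid_size, replace=False) \
        if holdout_valid_size else np.array([], dtype=int)
    validset2 = {holdout[i] for i in pick}
    testset3 = set(holdout) - validset2

    n_exp: Dict[Tuple[str, str], int] = {}
    for m in replicates:
        n_exp[m.combination] = n_exp.get(m.combination, 0) + 1
    testset2 = {e for e in base if n_exp.get(e, 0) >= 2}

    part = CombinationPartition(base=base, testset2=testset2,
                                validset2=validset2, testset3=testset3)
    part.validate()
    return part


def split_instances(instances: Sequence[LabeledInstance],
                    sizes: Tuple[int, int, int],
                    rng: np.random.Generator) -> InstanceSplit:
    """Uniform random disjoint split into (train, valid1, test1); any
    remainder joins the training set."""
    train_n, valid_n, test_n = sizes
    if min(sizes) < 0:
        raise ValueError("split sizes must be non-negative")
    total = len(instances)
    if train_n + valid_n + test_n > total:
        raise ValueError(f"requested split sizes {sizes} exceed {total} instances")
    perm = rng.permutation(total)
    valid = [instances[i] for i in perm[:valid_n]]
    test = [instances[i] for i in perm[valid_n: valid_n + test_n]]
    train = [instances[i] for i in perm[valid_n + test_n:]]
    return InstanceSplit(trainset=train, validset1=valid, testset1=test)


# ---------------------------------------------------------------------------
# sequence extraction and packing
# ---------------------------------------------------------------------------

def extract_sequences(regions: Sequence[Region], genome) -> List[str]:
    """0-based half-open slices, uppercased.  ``genome`` is a dict of
    chromosome sequences or a FASTA path (indexed with pyfaidx)."""
    if not isinstance(genome, dict):
        import pyfaidx
        fa = pyfaidx.Fasta(str(genome))
        genome = {name: fa[name] for name in fa.keys()}
    out = []
    for chrom, start, end in regions:
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if end <= start:
            raise ValueError(f"zero/negative-length region {chrom}:{start}-{end}")
        chrom_len = len(genome[chrom])
        if start < 0 or end > chrom_len:
            raise ValueError(f"region {chrom}:{start}-{end} outside chromosome "
                             f"bounds [0, {chrom_len})")
        out.append(str(genome[chrom][start:end]).upper())
    return out


@dataclass
class PackedInstances:
    """Instances packed against fixed vocabularies for the model."""
    codes: np.ndarray     # (n, seq_length) uint8
    tf_ids: np.ndarray    # (n,)
    cell_ids: np.ndarray  # (n,)
    labels: np.ndarray    # (n,) in {0,1}
    tf_vocab: Tuple[str, ...]
    cell_vocab: Tuple[str, ...]

    def __len__(self) -> int:
        return self.codes.shape[0]

    def subset(self, idx) -> "PackedInstances":
        return PackedInstances(self.codes[idx], self.tf_ids[idx],
                               self.cell_ids[idx], self.labels[idx],
                               self.tf_vocab, self.cell_vocab)

    @classmethod
    def concat(cls, parts: Sequence["PackedInstances"]) -> "PackedInstances":
        first = parts[0]
        for p in parts[1:]:
            if p.tf_vocab != first.tf_vocab or p.cell_vocab != first.cell_vocab:
                raise ValueError("cannot concatenate instances over different "
                                 "vocabularies")
        return cls(np.concatenate([p.codes for p in parts]),
                   np.concatenate([p.tf_ids for p in parts]),
                   np.concatenate([p.cell_ids for p in parts]),
                   np.concatenate([p.labels for p in parts]),
                   first.tf_vocab, first.cell_vocab)


def pack_instances(instances: Sequence[LabeledInstance],
                   tf_vocab: Sequence[str],
                   cell_vocab: Sequence[str]) -> PackedInstances:
    tf_vocab, cell_vocab = tuple(tf_vocab), tuple(cell_vocab)
    tf_idx = {t: i for i, t in enumerate(tf_vocab)}
    cell_idx = {c: i for i, c in enumerate(cell_vocab)}
    if not instances:
        raise ValueError("no instances to pack")
    length = len(instances[0].seq)
    codes = np.empty((len(instances), length), dtype=np.uint8)
    tf_ids = np.empty(len(instances), dtype=np.int64)
    cell_ids = np.empty(len(instances), dtype=np.int64)
    labels = np.empty(len(instances), dtype=np.int8)
    for i, inst in enumerate(instances):
        c = encode_indices(inst.seq)
        if c.shape[0] != length:
            raise ValueError(f"instance {i} has length {c.shape[0]}, expected {length}")
        codes[i] = c
        try:
            tf_ids[i] = tf_idx[inst.tf]
            cell_ids[i] = cell_idx[inst.cell]
        except KeyError as exc:
            raise KeyError(f"instance {i}: {exc.args[0]!r} not in vocabulary") from None
        labels[i] = inst.label
    return PackedInstances(codes, tf_ids, cell_ids, labels, tf_vocab, cell_vocab)
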
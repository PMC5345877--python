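"""Synthetic planted-motif worlds.

A world is a set of per-TF position probability matrices (PWMs), a binary
TF x cell activity matrix, and an order-1 Markov background model.  Every
pipeline stage — dataset construction, training, imputation on held-out
(TF, cell) combinations, variant and enhancer analyses — is testable against
this known ground truth without any download.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from motifgate.datasets import LabeledInstance, ExperimentMeta
from motifgate.sequences import BASE_ORDER

_IDX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass
class SyntheticWorld:
    pwms: Dict[str, np.ndarray]          # tf -> (L, 4) rows sum to 1
    activity: np.ndarray                 # (num_tfs, num_cells) in {0,1}
    init_probs: np.ndarray               # (4,) background initial distribution
    trans_probs: np.ndarray              # (4, 4) order-1 transition rows
    tf_names: Tuple[str, ...]
    cell_names: Tuple[str, ...]
    seed: Optional[int] = None

    @property
    def motif_length(self) -> int:
        return next(iter(self.pwms.values())).shape[0]

    def is_active(self, tf: str, cell: str) -> bool:
        return bool(self.activity[self.tf_names.index(tf),
                                  self.cell_names.index(cell)])

    def active_combos(self) -> List[Tuple[str, str]]:
        return [(t, c) for i, t in enumerate(self.tf_names)
                for j, c in enumerate(self.cell_names) if self.activity[i, j]]

    def all_combos(self) -> List[Tuple[str, str]]:
        return [(t, c) for t in self.tf_names for c in self.cell_names]

    def consensus(self, tf: str) -> str:
        return "".join(BASE_ORDER[i] for i in self.pwms[tf].argmax(axis=1))

    def to_json(self) -> str:
        return json.dumps(dict(
            pwms={t: m.tolist() for t, m in self.pwms.items()},
            activity=self.activity.tolist(),
            init_probs=self.init_probs.tolist(),
            trans_probs=self.trans_probs.tolist(),
            tf_names=list(self.tf_names),
            cell_names=list(self.cell_names),
            seed=self.seed), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticWorld":
        d = json.loads(text)
        return cls(pwms={t: np.array(m) for t, m in d["pwms"].items()},
                   activity=np.array(d["activity"], dtype=np.int8),
                   init_probs=np.array(d["init_probs"]),
                   trans_probs=np.array(d["trans_probs"]),
                   tf_names=tuple(d["tf_names"]),
                   cell_names=tuple(d["cell_names"]),
                   seed=d.get("seed"))


def make_world(num_tfs: int, num_cells: int, motif_length: int,
               activity_density: float, gc: float = 0.41,
               rng: Optional[np.random.Generator] = None,
               share_pwm: bool = True,
               min_consensus_prob: float = 0.8,
               seed: Optional[int] = None) -> SyntheticWorld:
    """Sample a world with sharp-consensus PWMs and a repaired Bernoulli
    activity matrix.

    When ``share_pwm`` and num_tfs >= 3, the last TF reuses the PWM of the
    second-to-last, making embedding-clustering behaviour testable.
    """
    if not 0 < activity_density <= 1:
        raise ValueError("activity_density must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    tf_names = tuple(f"TF{i}" for i in range(num_tfs))
    cell_names = tuple(f"CELL{j}" for j in range(num_cells))

    pwms: Dict[str, np.ndarray] = {}
    for t in tf_names:
        pwm = np.empty((motif_length, 4))
        for i in range(motif_length):
            cons = rng.integers(4)
            p_max = rng.uniform(min_consensus_prob, 0.95)
            rest = rng.dirichlet(np.ones(3)) * (1.0 - p_max)
            row = np.empty(4)
            row[cons] = p_max
            row[[j for j in range(4) if j != cons]] = rest
            pwm[i] = row / row.sum()
        pwms[t] = pwm
    if share_pwm and num_tfs >= 3:
        pwms[tf_names[-1]] = pwms[tf_names[-2]].copy()

    activity = (rng.random((num_tfs, num_cells)) < activity_density).astype(np.int8)
    for i in range(num_tfs):                  # every TF active somewhere
        if not activity[i].any():
            activity[i, rng.integers(num_cells)] = 1
    for j in range(num_cells):                # every cell has an active TF
        if not activity[:, j].any():
            activity[rng.integers(num_tfs), j] = 1

    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    # mild same-base persistence makes dinucleotide structure non-trivial
    trans = 0.75 * np.tile(base, (4, 1)) + 0.25 * np.eye(4)
    trans /= trans.sum(axis=1, keepdims=True)
    return SyntheticWorld(pwms=pwms, activity=activity, init_probs=base,
                          trans_probs=trans, tf_names=tf_names,
                          cell_names=cell_names, seed=seed)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_background_codes(world: SyntheticWorld, n: int, length: int,
                            rng: np.random.Generator) -> np.ndarray:
    """(n, length) uint8 codes from the order-1 Markov background,
    vectorized across rows."""
    cum_init = np.cumsum(world.init_probs)
    cum_trans = np.cumsum(world.trans_probs, axis=1)
    out = np.empty((n, length), dtype=np.uint8)
    u = rng.random((n, length))
    out[:, 0] = np.searchsorted(cum_init, u[:, 0])
    for j in range(1, length):
        rows = cum_trans[out[:, j - 1]]
        out[:, j] = (u[:, j, None] >= rows[:, :3]).sum(axis=1)
    return np.minimum(out, 3)


def sample_motif_codes(pwm: np.ndarray, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """(n, L) uint8 motif draws from a PWM."""
    L = pwm.shape[0]
    cum = np.cumsum(pwm, axis=1)
    u = rng.random((n, L))
    out = (u[:, :, None] >= cum[None, :, :3]).sum(axis=2)
    return np.minimum(out, 3).astype(np.uint8)


def _revcomp_codes_1d(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASE_ORDER[i] for i in codes)


def scan_pwm_codes(codes: np.ndarray, pwm: np.ndarray,
                   background: np.ndarray) -> np.ndarray:
    """Max log-odds PWM score over all offsets and both strands.

    The ideal-observer oracle: its AUC upper-bounds what any trained model
    can achieve on the synthetic task.
    """
    codes = np.atleast_2d(codes)
    L = pwm.shape[0]
    logodds = np.log(pwm + 1e-12) - np.log(background + 1e-12)[None, :]
    rc = logodds[::-1, ::-1]

    windows = np.lib.stride_tricks.sliding_window_view(codes, L, axis=1)
    # windows: (n, N-L+1, L); index per-position log-odds
    pos = np.arange(L)
    fwd = logodds[pos, windows].sum(axis=2)
    rev = rc[pos, windows].sum(axis=2)
    return np.maximum(fwd, rev).max(axis=1)


def generate_instances(world: SyntheticWorld,
                       combos: Sequence[Tuple[str, str]],
                       n_per_combo: int, seq_len: int,
                       rng: np.random.Generator) -> List[LabeledInstance]:
    """Balanced labeled instances per combination.

    For an active (tf, cell): label-1 sequences carry one PWM draw planted at
    a uniform offset on a uniform strand; label-0 sequences are background.
    For inactive combinations binding is absent, so label-1 sequences are
    background too.  ``n_per_combo`` counts total instances (half per label).
    """
    L = world.motif_length
    if seq_len < L:
        raise ValueError(f"seq_len {seq_len} shorter than motif length {L}")
    for t, c in combos:
        if t not in world.tf_names or c not in world.cell_names:
            raise ValueError(f"combination ({t}, {c}) outside the world grid")
    out: List[LabeledInstance] = []
    n_pos = n_per_combo // 2
    n_neg = n_per_combo - n_pos
    for tf, cell in combos:
        bg = sample_background_codes(world, n_pos + n_neg, seq_len, rng)
        if world.is_active(tf, cell):
            motifs = sample_motif_codes(world.pwms[tf], n_pos, rng)
            offsets = rng.integers(0, seq_len - L + 1, size=n_pos)
            strands = rng.random(n_pos) < 0.5
            for i in range(n_pos):
                m = motifs[i] if strands[i] else _revcomp_codes_1d(motifs[i])
                bg[i, offsets[i]: offsets[i] + L] = m
        for i in range(n_pos):
            out.append(LabeledInstance(1, tf, cell, codes_to_str(bg[i])))
        for i in range(n_pos, n_pos + n_neg):
            out.append(LabeledInstance(0, tf, cell, codes_to_str(bg[i])))
    return out


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------

@dataclass
class GenomeFixture:
    genome_path: str
    peak_paths: Dict[str, str]           # experiment_id -> narrowPeak path
    dnase_paths: Dict[str, str]          # cell -> narrowPeak path
    metadata_path: str
    truth_path: str
    metas: List[ExperimentMeta]
    plant_sites: Dict[str, List[Tuple[str, int]]]  # experiment -> (chrom, pos)


def generate_genome_fixture(world: SyntheticWorld, rng: np.random.Generator,
                            out_dir: str,
                            chrom_lengths: Sequence[int] = (80_000, 60_000, 40_000),
                            peaks_per_experiment: int = 30,
                            peak_halfwidth: int = 150,
                            n_replicated: int = 2,
                            dnase_extra_per_cell: int = 40) -> GenomeFixture:
    """A small multi-chromosome genome with planted binding sites recorded as
    narrowPeak files, DNase peaks covering all active regions plus extra open
    background, and a metadata TSV.

    The first ``n_replicated`` active combinations get two replicate
    experiments (sharing plant sites, jittered peak scores) so replicate-based
    partitioning (testset2) is exercised.
    """
    from motifgate.sequences import write_fasta
    os.makedirs(out_dir, exist_ok=True)
    L = world.motif_length
    chroms = {f"chr{i + 1}": sample_background_codes(world, 1, n, rng)[0]
              for i, n in enumerate(chrom_lengths)}
    chrom_names = list(chroms)

    # allocate non-overlapping slots so plants never collide
    slot = 2 * peak_halfwidth + 10
    all_slots = [(c, s) for c in chrom_names
                 for s in range(peak_halfwidth + 5,
                                len(chroms[c]) - peak_halfwidth - L - 5, slot)]
    order = rng.permutation(len(all_slots))
    slot_iter = iter(order)

    metas: List[ExperimentMeta] = []
    peak_paths: Dict[str, str] = {}
    plant_sites: Dict[str, List[Tuple[str, int]]] = {}
    active = world.active_combos()
    for k, (tf, cell) in enumerate(active):
        sites = []
        for _ in range(peaks_per_experiment):
            try:
                c, pos = all_slots[next(slot_iter)]
            except StopIteration:
                raise ValueError("genome too small for the requested number "
                                 "of peaks") from None
            m = sample_motif_codes(world.pwms[tf], 1, rng)[0]
            chroms[c][pos: pos + L] = m
            sites.append((c, int(pos)))
        n_reps = 2 if k < n_replicated else 1
        for rep in range(1, n_reps + 1):
            exp_id = f"EXP{k:03d}_{tf}_{cell}_rep{rep}"
            metas.append(ExperimentMeta(exp_id, tf, cell, f"rep{rep}"))
            path = os.path.join(out_dir, f"{exp_id}.narrowPeak")
            peak_paths[exp_id] = path
            plant_sites[exp_id] = sites
            with open(path, "w") as fh:
                for c, pos in sites:
                    start = pos - peak_halfwidth
                    end = pos + peak_halfwidth
                    score = float(rng.uniform(1.0, 10.0))
                    fh.write(f"{c}\t{start}\t{end}\t.\t0\t.\t{score:.3f}\t-1\t-1\t"
                             f"{peak_halfwidth}\n")

    dnase_paths: Dict[str, str] = {}
    for j, cell in enumerate(world.cell_names):
        path = os.path.join(out_dir, f"DNASE_{cell}.narrowPeak")
        dnase_paths[cell] = path
        rows = []
        for exp_id, sites in plant_sites.items():
            meta = next(m for m in metas if m.experiment_id == exp_id)
            if meta.cell_line == cell:
                rows.extend(sites)
        for _ in range(dnase_extra_per_cell):  # open background regions
            c, pos = all_slots[next(slot_iter)]
            rows.append((c, int(pos)))
        with open(path, "w") as fh:
            for c, pos in sorted(set(rows)):
                start, end = pos - peak_halfwidth, pos + peak_halfwidth
                fh.write(f"{c}\t{start}\t{end}\t.\t0\t.\t1.0\t-1\t-1\t"
                         f"{peak_halfwidth}\n")

    genome_path = os.path.join(out_dir, "genome.fa")
    write_fasta(genome_path, {c: codes_to_str(v) for c, v in chroms.items()})
    metadata_path = os.path.join(out_dir, "metadata.tsv")
    with open(metadata_path, "w") as fh:
        fh.write("experiment_id\ttf\tcell_line\treplicate\n")
        for m in metas:
            fh.write(f"{m.experiment_id}\t{m.tf_name}\t{m.cell_line}\t"
                     f"{m.replicate_label}\n")
    truth_path = os.path.join(out_dir, "truth.json")
    with open(truth_path, "w") as fh:
        fh.write(world.to_json())
    return GenomeFixture(genome_path=genome_path, peak_paths=peak_paths,
                         dnase_paths=dnase_paths, metadata_path=metadata_path,
                         truth_path=truth_path, metas=metas,
                         plant_sites=plant_sites)


def generate_mpra_fixture(world: SyntheticWorld, cell: str, n: int,
                          seq_len: int, noise_sd: float,
                          rng: np.random.Generator
                          ) -> Tuple[List[str], np.ndarray]:
    """Reporter-assay-like fixture: each sequence carries 0-3 planted motifs
    of TFs active in ``cell``; activity = motif count + Gaussian noise."""
    if n < 200:
        raise ValueError("need n >= 200 so top/bottom-100 groups exist")
    j = world.cell_names.index(cell)
    active_tfs = [t for i, t in enumerate(world.tf_names) if world.activity[i, j]]
    if not active_tfs:
        raise ValueError(f"no TFs active in {cell}")
    L = world.motif_length
    n_slots = 3
    slot_w = seq_len // n_slots
    if slot_w < L:
        raise ValueError("seq_len too short for 3 motif slots")
    codes = sample_background_codes(world, n, seq_len, rng)
    counts = rng.integers(0, n_slots + 1, size=n)
    for i in range(n):
        slots = rng.choice(n_slots, size=counts[i], replace=False)
        for s in slots:
            tf = active_tfs[rng.integers(len(active_tfs))]
            m = sample_motif_codes(world.pwms[tf], 1, rng)[0]
            off = s * slot_w + rng.integers(0, slot_w - L + 1)
            codes[i, off: off + L] = m
    activities = counts.astype(float)
    if noise_sd > 0:
        activities = activities + rng.normal(0.0, noise_sd, size=n)
    return [codes_to_str(c) for c in codes], activities


def generate_snp_fixture(world: SyntheticWorld, tf: str, seq_len: int,
                         rng: np.random.Generator, n_snps: int = 5):
    """SNPs that break a planted consensus: allele_a keeps the PWM's
    consensus base at its most informative position, allele_b substitutes the
    least likely base."""
    from motifgate.downstream import SnpSpec
    if tf not in world.tf_names:
        raise ValueError(f"unknown TF {tf!r}")
    pwm = world.pwms[tf]
    L = pwm.shape[0]
    if seq_len < L:
        raise ValueError("seq_len shorter than motif")
    col = int(pwm.max(axis=1).argmax())       # most informative position
    cons_base = BASE_ORDER[int(pwm[col].argmax())]
    worst_base = BASE_ORDER[int(pwm[col].argmin())]
    out = []
    offset = (seq_len - L) // 2
    for i in range(n_snps):
        # reject flanks whose best scan window avoids the planted site, so
        # breaking the consensus base strictly lowers the max log-odds score
        for _ in range(200):
            bg = sample_background_codes(world, 1, seq_len, rng)[0]
            m = sample_motif_codes(pwm, 1, rng)[0]
            bg[offset: offset + L] = m
            bg[offset + col] = _IDX[cons_base]
            broken = bg.copy()
            broken[offset + col] = _IDX[worst_base]
            sa = scan_pwm_codes(bg, pwm, world.init_probs)[0]
            sb = scan_pwm_codes(broken, pwm, world.init_probs)[0]
            if sa > sb:
                break
        else:
            raise RuntimeError("could not build a discriminating SNP flank")
        out.append(SnpSpec(id=f"{tf}_snp{i}", flank=codes_to_str(bg),
                           pos=offset + col, allele_a=cons_base,
                           allele_b=worst_base))
    return out
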
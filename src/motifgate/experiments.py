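"""Reproducible synthetic-world experiments.

These drive the end-to-end checks: imputation on held-out (TF, cell)
combinations with shuffled-TF / shuffled-cell controls, and a final model
trained on everything (merge-then-retrain) for the downstream variant and
enhancer analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from motifgate.datasets import PackedInstances, pack_instances
from motifgate.evaluation import roc_auc
from motifgate.model import GatedConvModel, ModelConfig
from motifgate.synthetic import (SyntheticWorld, generate_instances,
                                 make_world, scan_pwm_codes)
from motifgate.training import (MergeRetrainResult, TrainingConfig,
                                merge_and_retrain, train)


def select_holdout_combos(active: Sequence[Tuple[str, str]], k: int
                          ) -> List[Tuple[str, str]]:
    """Pick k active combinations with pairwise-distinct TFs and cells such
    that each TF and each cell still occurs in another active combination
    (so the holdout is imputable).  Deterministic given the input order."""
    held: List[Tuple[str, str]] = []
    used_t, used_c = set(), set()
    for t, c in active:
        if len(held) == k:
            break
        if t in used_t or c in used_c:
            continue
        rest = [x for x in active if x != (t, c) and x not in held]
        if any(x[0] == t for x in rest) and any(x[1] == c for x in rest):
            held.append((t, c))
            used_t.add(t)
            used_c.add(c)
    if len(held) < k:
        raise ValueError(f"could only find {len(held)} imputable holdout "
                         f"combinations, needed {k}")
    return held


def _per_combo_auc(scores: np.ndarray, packed: PackedInstances,
                   combos: Sequence[Tuple[str, str]]) -> Dict[Tuple[str, str], float]:
    out = {}
    for t, c in combos:
        ti = packed.tf_vocab.index(t)
        ci = packed.cell_vocab.index(c)
        mask = (packed.tf_ids == ti) & (packed.cell_ids == ci)
        out[(t, c)] = roc_auc(scores[mask], packed.labels[mask])
    return out


@dataclass
class ImputationResult:
    world: SyntheticWorld
    model: GatedConvModel
    held_combos: List[Tuple[str, str]]
    auc_per_combo: Dict[Tuple[str, str], float]
    mean_auc: float
    shuffled_tf_mean_auc: float
    shuffled_cell_mean_auc: float
    scanner_mean_auc: float
    scanner_per_combo: Dict[Tuple[str, str], float]
    valid1_auc: float


def run_imputation_experiment(seed: int,
                              num_tfs: int = 8, num_cells: int = 5,
                              motif_length: int = 8,
                              activity_density: float = 0.7,
                              n_per_combo: int = 2000,
                              seq_len: int = 100,
                              num_filters: int = 64,
                              filter_length: int = 12,
                              pool_window: int = 100,
                              fc_size: int = 16,
                              epochs: int = 5,
                              n_holdout: int = 4,
                              n_eval_per_combo: int = 400,
                              adadelta_eps: float = 1e-5,
                              eval_interval: int = 25_000,
                              include_inactive: bool = False,
                              verbose: bool = False) -> ImputationResult:
    """Train on active combinations minus a held-out set; measure mean
    per-combination AUC on the holdout, plus shuffled-TF / shuffled-cell
    controls and the PWM-scanner ceiling."""
    rng = np.random.default_rng(seed)
    world = make_world(num_tfs, num_cells, motif_length, activity_density,
                       rng=rng, seed=seed)
    active = world.active_combos()
    held = select_holdout_combos(active, n_holdout)
    train_combos = [x for x in active if x not in held]
    if include_inactive:
        train_combos = train_combos + [x for x in world.all_combos()
                                       if x not in active]

    tp = pack_instances(generate_instances(world, train_combos, n_per_combo,
                                           seq_len, rng),
                        world.tf_names, world.cell_names)
    eval_rng = np.random.default_rng(seed + 1000)
    v1 = pack_instances(generate_instances(world, train_combos[:6], 100,
                                           seq_len, eval_rng),
                        world.tf_names, world.cell_names)
    v2 = pack_instances(generate_instances(world, held, 150, seq_len, eval_rng),
                        world.tf_names, world.cell_names)
    test = pack_instances(generate_instances(world, held, n_eval_per_combo,
                                             seq_len, eval_rng),
                          world.tf_names, world.cell_names)

    config = ModelConfig(seq_length=seq_len, filter_length=filter_length,
                         num_filters=num_filters, pool_window=pool_window,
                         fc_size=fc_size, tf_vocab=world.tf_names,
                         cell_vocab=world.cell_names)
    model = GatedConvModel(config, rng=np.random.default_rng(seed))
    tconf = TrainingConfig(epochs=epochs, eval_interval=eval_interval,
                           seed=seed, adadelta_eps=adadelta_eps)
    result = train(model, tp, v1, v2, tconf, verbose=verbose)
    model.params = result.best_for_imputation.parameters

    scores = model.predict_scores_codes(test.codes, test.tf_ids, test.cell_ids)
    auc = _per_combo_auc(scores, test, held)

    ctrl_rng = np.random.default_rng(seed + 2000)
    perm = ctrl_rng.permutation(len(test))
    shuf_tf = model.predict_scores_codes(test.codes, test.tf_ids[perm],
                                         test.cell_ids)
    shuf_cell = model.predict_scores_codes(test.codes, test.tf_ids,
                                           test.cell_ids[perm])
    auc_shuf_tf = _per_combo_auc(shuf_tf, test, held)
    auc_shuf_cell = _per_combo_auc(shuf_cell, test, held)

    scanner = {}
    for t, c in held:
        ti = test.tf_vocab.index(t)
        ci = test.cell_vocab.index(c)
        mask = (test.tf_ids == ti) & (test.cell_ids == ci)
        ideal = scan_pwm_codes(test.codes[mask], world.pwms[t],
                               world.init_probs)
        scanner[(t, c)] = roc_auc(ideal, test.labels[mask])

    return ImputationResult(
        world=world, model=model, held_combos=held, auc_per_combo=auc,
        mean_auc=float(np.mean(list(auc.values()))),
        shuffled_tf_mean_auc=float(np.mean(list(auc_shuf_tf.values()))),
        shuffled_cell_mean_auc=float(np.mean(list(auc_shuf_cell.values()))),
        scanner_mean_auc=float(np.mean(list(scanner.values()))),
        scanner_per_combo=scanner,
        valid1_auc=result.best_for_within.metric_valid1)


@dataclass
class DownstreamModel:
    world: SyntheticWorld
    model: GatedConvModel
    retrain: MergeRetrainResult


def train_downstream_model(seed: int,
                           num_tfs: int = 8, num_cells: int = 5,
                           motif_length: int = 8,
                           activity_density: float = 0.5,
                           n_per_combo: int = 1200,
                           seq_len: int = 100,
                           num_filters: int = 48,
                           filter_length: int = 12,
                           fc_size: int = 16,
                           epochs: int = 8,
                           adadelta_eps: float = 1e-5,
                           verbose: bool = False) -> DownstreamModel:
    """Final model for the SNP / enhancer analyses: trained on instances from
    every combination (inactive ones included, so the model can learn which
    gates to close) via the merge-then-retrain protocol."""
    rng = np.random.default_rng(seed)
    world = make_world(num_tfs, num_cells, motif_length, activity_density,
                       rng=rng, seed=seed)
    combos = world.all_combos()
    merged = pack_instances(generate_instances(world, combos, n_per_combo,
                                               seq_len, rng),
                            world.tf_names, world.cell_names)
    v2 = pack_instances(generate_instances(world, world.active_combos(), 100,
                                           seq_len,
                                           np.random.default_rng(seed + 1000)),
                        world.tf_names, world.cell_names)
    config = ModelConfig(seq_length=seq_len, filter_length=filter_length,
                         num_filters=num_filters, pool_window=100,
                         fc_size=fc_size, tf_vocab=world.tf_names,
                         cell_vocab=world.cell_names)
    tconf = TrainingConfig(epochs=epochs, eval_interval=10_000, seed=seed,
                           adadelta_eps=adadelta_eps)
    rr = merge_and_retrain(config, [merged], v2, tconf, verbose=verbose)
    return DownstreamModel(world=world, model=rr.model, retrain=rr)
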
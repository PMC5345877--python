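# motifgate

Cell-line-specific transcription-factor (TF) binding prediction from DNA
sequence with a multi-task gated convolutional network, plus everything
around it: dataset construction from ChIP-seq/DNase-seq peak files,
AdaDelta training with dual-validation checkpointing, evaluation
(grouped AUC, recall at FDR, shuffle controls, genome binning), variant- and
enhancer-effect analyses, and a synthetic planted-motif world that makes the
whole pipeline testable offline.

## Model

Each instance is a `<label, TF, cell line, sequence>` quadruple.  The
sequence is one-hot encoded (column order A, C, G, T; `N` rows are all
zeros), scanned by a bank of convolutional motif detectors, rectified with a
per-filter threshold, and max-pooled over non-overlapping windows.  TFs and
cell lines are embedded as learned vectors; the concatenated embedding feeds
a one-layer sigmoid network that emits one gate in (0,1) per filter, which
multiplies the pooled signal.  A fully connected layer follows; the score is
its maximum, and the final prediction is the maximum over the forward and
reverse-complement strands (exactly strand-symmetric).  Because held-out
(TF, cell line) pairs reuse embeddings learned from other pairs, the model
can impute binding for combinations never seen in training.

A multi-TF CNN-GRU variant (`motifgate.multitask`) scores all TFs at once
for long inputs: the cell-line embedding (length = number of filters) is
squashed directly into gates, pooled windows feed a GRU, and the last hidden
state maps to one output per TF.

The network is implemented directly on NumPy with hand-derived analytic
gradients (validated against finite differences in the test suite) so that
training is exactly reproducible and has no framework dependency.

## CLI

```sh
# generate a synthetic world (genome FASTA, narrowPeak files, metadata TSV,
# instances TSV, ground-truth JSON)
motifgate simulate --num-tfs 8 --num-cells 5 --motif-len 8 \
    --activity-density 0.7 --out-dir world/ --seed 1

# build labeled instances from peak files
motifgate build-dataset --peaks-dir world/ --meta world/metadata.tsv \
    --genome world/genome.fa --background shuffle --top-n 1000 \
    --window 100 --out-dir dataset/ --seed 1
# ... or with the union-DHS background and combination partitions
motifgate build-dataset --peaks-dir world/ --meta world/metadata.tsv \
    --genome world/genome.fa --background dhs --top-n 5000 --window 300 \
    --out-dir dataset/ --seed 1

# train, predict, evaluate
motifgate train --instances dataset/train.tsv.gz --valid1 dataset/test.tsv.gz \
    --out model.npz --log train_log.tsv --seed 1
motifgate predict --model model.npz --sequences queries.fa \
    --tf TF0 --cell CELL0 --out predictions.tsv
motifgate evaluate --predictions scored.tsv --group-by tf \
    --metrics auc,recall --fdr 0.05 --out metrics.tsv

# downstream analyses
motifgate snp-effect --model model.npz --snps snps.tsv --out effects.tsv
motifgate enhancer-signature --model model.npz --sequences enhancers.fa \
    --cell CELL0 --activities activities.tsv --top-k 100 --out signature.tsv
```

## Layout

| module | contents |
| --- | --- |
| `motifgate.sequences` | one-hot encoding, reverse complement, Eulerian-path dinucleotide shuffle, FASTA I/O |
| `motifgate.datasets` | peak parsing (BED/narrowPeak), top-peak selection, union-DHS negatives, combination/instance partitioning, packing |
| `motifgate.model` | gated convolutional scorer, analytic gradients, serialization |
| `motifgate.multitask` | CNN-GRU multi-TF variant |
| `motifgate.training` | AdaDelta with step-size decay, dual-validation checkpoints, merge-then-retrain protocol |
| `motifgate.evaluation` | AUC (pooled/grouped), recall at FDR, field shuffling, genome binning |
| `motifgate.downstream` | SNP allele-delta matrices, PCA enhancer signature, embedding clustering |
| `motifgate.synthetic` | synthetic worlds: PWMs, activity matrix, Markov background, fixtures |
| `motifgate.experiments` | end-to-end imputation and downstream experiments |
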
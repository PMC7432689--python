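# lncfusion

Alignment-free classification of long non-coding RNAs (lncRNAs) versus
protein-coding transcripts with a multimodal neural framework.

Each transcript is represented in three modalities:

1. **OFH vector** — longest-ORF length and coverage, Fickett TESTCODE
   score, and hexamer (6-mer) log-ratio score against a trained
   coding/noncoding hexamer frequency table;
2. **k-mer frequencies** — all 4^k sliding-window frequencies (default
   k = 6, 4096 dimensions);
3. **one-hot matrix** — a 4 × `maxlen` binary encoding (default
   `maxlen` = 3000; 5′ truncation / zero right-padding).

Two dense submodels (OFH, k-mer) and one convolutional submodel
(one-hot: convolution → batch normalization → ReLU → max-pooling blocks)
are pretrained independently; their last-hidden-layer *descriptors* are
then concatenated into a dense fusion classifier, trained first with the
submodels frozen and then fine-tuned end-to-end at a reduced learning
rate.  The positive class (label 1) is lncRNA.

The neural layers are implemented in numpy inside `lncfusion.nn` (dense,
1-D convolution, batch normalization, max pooling, dropout, Adam,
binary cross-entropy), fully seeded and gradient-checked in the test
suite, so the package has no deep-learning framework dependency.

A synthetic-transcript generator (`lncfusion.synthetic`) produces
labeled benchmarks with the discriminative structure the classifier
exploits — coding-like transcripts with one long codon-usage-biased ORF
flanked by UTRs, and length/GC-matched noncoding-like transcripts with
no long ORF — so the whole pipeline is testable without downloads.

## Command-line usage

```bash
# 1. generate a synthetic benchmark (FASTA + labels + manifest)
lncfusion simulate --n 500 --seed 7 --out bench/

# 2. split classes and train (config file is optional `key = value` text)
lncfusion train --lnc-fasta lnc.fa --pc-fasta pc.fa --out run/
lncfusion train --lnc-fasta lnc.fa --pc-fasta pc.fa --folds 10 --out cv/   # cross-validation
lncfusion train --lnc-fasta lnc.fa --pc-fasta pc.fa --modality kmer --out run_kmer/  # ablation

# 3. predict and evaluate
lncfusion predict input.fa --model run/model.npz --out preds.tsv
lncfusion predict input.fa --model run/model.npz --vote --out preds_vote.tsv
lncfusion evaluate --predictions preds.tsv --labels labels.tsv \
    --compare preds_vote.tsv   # adds a McNemar comparison

# feature export (OFH + k-mer TSV)
lncfusion features input.fa --coding-fasta pc.fa --noncoding-fasta lnc.fa --out features.tsv
```

Model archives (`model.npz`) bundle the network parameters together with
the training-time hexamer table and feature normalization; predictions
are undefined without them.

## Package layout

- `lncfusion.sequence_io` — FASTA I/O, normalization (U→T, foreign
  characters→N), ≥200 nt filtering, labeled-dataset assembly.
- `lncfusion.features` — longest-ORF search, Fickett TESTCODE score,
  hexamer table/score, k-mer vectors, one-hot encoding.
- `lncfusion.nn` — numpy layer library with explicit backprop.
- `lncfusion.model` — submodels, fusion, two-step training, voting
  baseline, persistence.
- `lncfusion.evaluation` — ACC/Sn/Sp/MCC, stratified k-fold
  cross-validation (feature tables re-fitted per fold), McNemar's test.
- `lncfusion.synthetic` — benchmark generator.
- `lncfusion.cli` — `simulate` / `features` / `train` / `predict` /
  `evaluate` subcommands.
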
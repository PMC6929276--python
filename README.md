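# sepredict

Super-enhancer calling and CNN-based super-enhancer prediction from ChIP-seq
feature tables, exercisable end-to-end on synthetic data.

The pipeline has three stages:

1. **Quantify & call** — compute normalized read densities (rpm/bp) of
   aligned reads over enhancer intervals, stitch enhancers within 12.5 kb
   into entities, rank entities by total background-normalized coactivator
   signal, and designate everything above the elbow of the scaled
   rank/signal curve as a super-enhancer (`signal_quant`, `se_calling`).
2. **Features & model** — assemble a canonical 36-column feature matrix
   (31 signal/TF densities or PWM binding affinities + AT/GC content,
   conservation mean/proportion, repeat fraction) and train small 1-D
   convolutional classifiers with 2, 3 or 4 conv layers on it
   (`feature_table`, `cnn_model`). The CNN — forward pass, backprop, Adam,
   dropout — is implemented directly in numpy and is fully deterministic
   under a seed.
3. **Evaluate & rank** — confusion-matrix metrics, ROC/AUC (Mann–Whitney),
   and feature ranking by absolute point-biserial Pearson correlation
   (`evaluation`).

`synthetic_fixtures` provides seeded generators (planted-peak read sets,
class-imbalanced Gaussian feature tables with planted effect sizes, and a
complete super-enhancer calling fixture) so every stage is testable with no
external data.

## CLI

All stages are exposed through one entry point (see `--help` on each
subcommand for options; a YAML file passed via `--config` can pre-set any
option of the invoked subcommand):

```sh
sepredict simulate --kind table --seed 1 --out sim/
sepredict quantify --reads med1=reads.sam --regions enhancers.bed --out dens.tsv
sepredict call-se --enhancers enhancers.bed --med1 med1.sam --gap 12500 --out se.bed
sepredict build-features --dens dens.tsv --fasta genome.fa --cons cons.wig \
    --pwms motifs.jaspar --labels se.bed --out features.tsv
sepredict train --features features.tsv --layers 4 --alpha 5e-5 --epochs 130 \
    --seed 1 --out model.json
sepredict tune --features features.tsv --out surface.tsv
sepredict predict --model model.json --features new.tsv --out preds.tsv
sepredict evaluate --preds preds.tsv --labels features.tsv --out report.json
sepredict rank-features --features features.tsv --out ranking.tsv
```

Exit codes: 0 success, 1 usage/configuration error, 2 data/parse error.

## Notes

- Coordinates are 0-based half-open everywhere internally; SAM's 1-based
  starts and wiggle's 1-based positions are converted on ingest.
- SAM support is deliberately minimal (mandatory 11 columns, CIGAR ignored,
  read span = POS..POS+len(SEQ)); a 4-column chrom/start/end/strand TSV is
  accepted interchangeably.
- Control (input) subtraction is unfloored: background-normalized densities
  may be negative, which preserves rank order in the signal totals.
- Negatives for training are simply stitched entities below the cutoff
  ("typical enhancers"); no further filtering is applied.
- The model treats the 36 features as a 1-D single-channel signal in the
  registry's canonical order; convolving over an arbitrary feature ordering
  is a modelling quirk inherited from the original method.
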
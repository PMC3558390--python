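# ervkit

Toolkit for relating endogenous retroelement loci to cell-type-specific
ChIP-seq peaks and for quantifying repeat-element expression from RNA-seq
alignments, with a synthetic-data generator so the whole pipeline runs
end-to-end without any external downloads.

## What it does

* **Association** — classifies each element by the distance from its nearer
  edge to the nearest peak (distance 0 inside the element) and scores the
  enrichment against random control loci with the β-weighted harmonic mean
  of precision and sensitivity (F_β, β = 0.5 by default, window 2 kb,
  100,000 controls). Significance comes from a one-sided Fisher exact test
  computed in log space, so extreme enrichments never underflow. Window
  sweeps (0.5 kb steps up to 10 kb) produce per-cell-type profiles.
* **Clustering** — agglomerative clustering of cell types by the Euclidean
  distance between their F-score profiles, cut into k groups (default 3)
  ordered high/medium/low by mean F.
* **Quantification** — unique-read counting by the hit-midpoint rule,
  single-round probabilistic reassignment of multimapping reads weighted by
  the unique-read count of each candidate hit's flanking context, RPKM
  (10⁶·N_r/(L_kb·N_T)), and a specific-vs-unspecific transcription estimate
  U(s) = R(c)/2, T(s) = max(0, R(s) − U(s)) with context counts normalized
  to the element's length scale.
* **Expression analyses** — element-internal coverage profiles normalized to
  the 5′LTR, top-k expression concentration, differentiation trajectories
  normalized to a housekeeping series, Spearman/Pearson trajectory
  correlation, TF-peak proximity and ordering relative to element TSSs.
* **Mandala plots** — polar per-chromosome scatters: position → angle,
  log-scaled marker distance (0 to 1 Mb) → radius, within-window dots blue.
* **Simulation** — deterministic generators for chromosome sizes, element
  annotations (focal family with internal region maps plus background
  families), planted peak sets, alignment records with a configurable
  unique:multiread split and sister-copy hit sharing, spanning-gene
  read-through, and stage-decay expression series — each with its ground
  truth emitted alongside.

## Formats

BED3/BED6, ENCODE narrowPeak, RepeatMasker `.out`, SAM/BAM (read-only,
name-grouped), two-column `chrom.sizes`, and a plain tabular alignment
format (`#read_id  chrom  start  end`, one line per candidate hit).
All internal coordinates are 0-based half-open.

## Command line

```sh
ervkit simulate --seed 1 --outdir fixtures/
ervkit associate --elements fixtures/elements.out --peaks fixtures/peaks.narrowPeak \
    --sizes fixtures/chrom.sizes --family ERVF --window 2000 --seed 1 --out assoc.tsv
ervkit profile   --elements fixtures/elements.out --peaks fixtures/peaks.narrowPeak \
    --sizes fixtures/chrom.sizes --family ERVF --cell-type ES --out profile.tsv
ervkit cluster   --profiles matrix.tsv --k 3 --out clusters.tsv
ervkit quantify  --alignments fixtures/alignments.tsv --elements fixtures/elements.out \
    --sizes fixtures/chrom.sizes --out expr.tsv
ervkit coverage-profile --alignments fixtures/alignments.tsv \
    --elements fixtures/elements.out --regions fixtures/regions.bed \
    --sizes fixtures/chrom.sizes --out coverage.tsv
ervkit tf-analysis --elements fixtures/elements.out --peaks nanog.narrowPeak \
    --peaks oct4.narrowPeak --peaks sox2.narrowPeak \
    --sizes fixtures/chrom.sizes --family ERVF --out tf.tsv
ervkit trajectory --series series.tsv --normalizer BRD2 --out traj.tsv
ervkit mandala --elements fixtures/elements.out --peaks fixtures/peaks.narrowPeak \
    --sizes fixtures/chrom.sizes --chrom chr1 --family ERVF --out chr1.svg
```

`--help` on any subcommand lists every option; stochastic commands log the
seed they used.

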
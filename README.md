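# glycodemux

Simulation, demultiplexing and evaluation of **sample-barcoded single-cell /
single-nucleus RNA-seq** droplet data.

In sample multiplexing ("hashing"), each sample's cells or nuclei are labeled
with a distinct oligonucleotide sample tag before pooling, so that every
sequenced droplet carries both a transcriptome and a tag-count vector.
Demultiplexing assigns each droplet back to its sample of origin (singlet),
to two samples (cross-tag doublet), or to none (negative).  This package
implements the complete computational side of such an experiment for
glycan-anchored sample tags, aimed at method developers and analysts who want
a fully ground-truthed testbed:

* a **synthetic-data generator** for multiplexed droplet experiments
  (2/6/12-plex cell-line pools, human/mouse barnyard mixes, PBMC pools with a
  ~0.5% rare subpopulation), with per-droplet ground truth;
* a **confidence-ratio demultiplexer**: with background-corrected tag counts
  `c'_t = max(0, c_t − bg_t)`, the confidence ratio is
  `r = max_t c'_t / Σ_t c'_t`, and a droplet is a singlet when `r ≥ 0.9`
  (default), a doublet when the second tag holds ≥ 20% of the corrected
  total, and negative otherwise;
* a **species/marker reference annotation** for scoring: in a barnyard pool
  the human-gene UMI share `h = human/(human+mouse)` calls each droplet
  human (`h ≥ τ`), mouse (`h ≤ 1−τ`) or mixed;
* **two-stage doublet removal**: tag-called doublets first, then residual
  same-tag doublets via an artificial-doublet kNN score (library-size
  normalize → log1p → top-30 PCs → fraction of synthetic doublets among k
  nearest neighbors, converted to a posterior probability) plus a per-tag
  depth-outlier rule;
* the **evaluation metrics**: overall classification accuracy
  `OCA = (matching singlets + matching nonsinglets) / total droplets`, the
  detectability-corrected total doublet rate
  `d = cross-tag fraction / (1 − Σ_s p_s²)`, input-ratio deviation in
  percentage points, and per-tag rare-population recovery.

## Worked example

Run the whole pipeline on a simulated 2-plex human/mouse single-cell pool
(20,000 droplets, doublet rate 5.42%, 1% unlabeled droplets):

```bash
glycodemux run --design barnyard2 --mode sc --n 20000 --seed 1 --out run_sc
```

which logs, among other things:

```
INFO glycodemux.pipeline: demux calls: {'singlet': 19222, 'doublet': 604, 'negative': 174}
INFO glycodemux.pipeline: OCA 0.9982, deviation 0.05 pp, doublets 0.0565 -> 0.000054
```

and writes `run_sc/report.json`.  Reading the numbers: of 20,000 droplets,
19,222 were confidently assigned to one sample and 604 carried two tags
(cross-tag doublets, removed).  Scored against the species reference, 99.8%
of droplets were classified correctly (`"oca": 0.9982`); the per-tag singlet
proportions deviate from the 50:50 input by 0.05 percentage points; and the
true-doublet fraction among retained droplets drops from 5.65% before
filtering to 0.0054% after the two-stage filter.  Every intermediate table
(`calls.tsv`, `ref.tsv`, `scores.tsv`, `final_cells.tsv`) and the simulated
dataset itself (`data/`, CellRanger-style MTX + TSVs with `truth.tsv`) are
left on disk.

The same analyses, written as narrative steps, live under `analysis/`
(01 simulate → 02 accuracy → 03 ratio fidelity → 04 doublet filtering →
05 rare populations); each prints what it found and writes its tables under
`results/`.  For example `python analysis/04_doublet_filtering.py` prints:

```
sc: cross-tag 2.85% -> estimated total 5.71% (generator 5.42%); residual doublets 5.64% -> 0.0054% after filtering
sn: cross-tag 0.77% -> estimated total 1.55% (generator 1.49%); residual doublets 1.50% -> 0.0000% after filtering
```

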
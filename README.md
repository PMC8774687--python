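# fragcnv

Fetal CNV detection from shallow paired-end WGS of maternal plasma.
`fragcnv` scores each genomic bin of a query sample *within the sample
itself*, against a precomputed map of similarly behaving bins on other
chromosomes, for two signals in parallel:

* **read count** — normalized per-bin fragment counts, and
* **fragment size** — per-bin mean fragment size (fetal cfDNA fragments are
  systematically shorter, so a fetal copy-number gain shifts the affected
  region's size distribution down).

The two per-bin Z tracks are combined (Fisher's method by default, Stouffer
optional), segmented with circular binary segmentation, and thresholded into
gain/loss events.  Because each bin is judged against reference bins of the
*same* sample, the test is robust to between-run technical variation; a PCA
bias model trained on the control panel removes shared technical structure
(e.g. GC bias) from both signals before scoring.

## Layout

| module | role |
| --- | --- |
| `fragcnv.fragio` | SAM/BAM pair filtering (proper pairs, primary only, MAPQ ≥ 1, unique starts) and reduction to (chrom, midpoint, size) fragments; 300 bp size cap |
| `fragcnv.binning` | 5 kb base grid, aggregation to 250 kb–10 Mb analysis scales, per-sample fragment-size reliability filter |
| `fragcnv.refbuild` | normalization, global mask, per-datatype PCA bias models, top-K (default 300) nearest-bin reference tables (Euclidean distance across controls, inverse-distance weights, other chromosomes only) |
| `fragcnv.calling` | within-sample Z-scores, orientation and combination of the tracks, permutation-tested CBS, segment scoring (Stouffer), mode I/II event thresholds (>10 Mb & Z ≥ 5 / >1 Mb & \|Z\| ≥ 5) |
| `fragcnv.simdata` | bin-level synthetic cohorts: Poisson counts with shared multiplicative biases, maternal/fetal size mixture (calibrated to mean 173 bp / SD 56 bp at fetal fraction 7.5%), planted trisomies; toy SAM emitter |
| `fragcnv.cli` | `fragcnv` command with `convert`, `bin`, `reference`, `predict`, `simulate` subcommands |

## CLI

```bash
# alignments -> fragment table
fragcnv convert sample.bam --out sample.frags.tsv --max-size 300 --min-mapq 1

# fragment table -> binned sample (5 kb grid aggregated to the analysis scale)
fragcnv bin sample.frags.tsv --sizes hg19.chrom.sizes --binsize 750000 --out sample.npz

# control panel -> two-datatype reference
fragcnv reference --controls controls_dir/ --binsize 750000 --k 300 --out ref.npz

# query a sample: per-bin Z bedGraphs + event table + JSON report
fragcnv predict sample.npz --ref ref.npz --mode I --combine fisher --out sample_out

# synthetic cohort (YAML-configurable), or a toy SAM for filter testing
fragcnv simulate --config sim.yaml --out cohort_dir --seed 1
fragcnv simulate --sam --out toy.sam
```

Samples must be binned at the reference's bin size; a grid mismatch is a
data error (exit code 2).  Default bin size is 750 kb, the best-performing
analysis scale.

## Notes

* Only autosomes are analyzed; no sex-chromosome reference sets are built.
* Fetal-fraction *estimation* is out of scope; the simulator knows the true
  fetal fraction of every synthetic sample.
* The simulator works at bin level (a truncated-normal size mixture, not the
  full nucleosomal ladder) — sufficient because the caller only consumes
  per-bin means; a read-level emitter exists only for filter fixtures.
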
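# dendtrans

Analysis pipeline for activity-dependent dendritic translation from
proximity-labeling multi-omics, plus a synthetic-data generator with planted
ground truth so the whole pipeline is testable offline.

Stages (one module and one CLI subcommand each):

| module     | what it does |
|------------|--------------|
| `core_io`  | domain types (transcript models, count matrices, thresholds), BED12/GTF/FASTA/TSV/YAML readers and writers |
| `simdata`  | factorial-design synthetic inputs: NB RNA counts with planted dendritic enrichment, region-structured footprints with planted 5'UTR/CDS translation classes, motif-coupled CLIP tags, log-normal protein intensities with MNAR dropout, and a truth table |
| `plclip`   | dendritic RNA enrichment: cpm filtering, per-gene OLS contrasts (condition x bait with batch), optional variance moderation, BH correction, t-statistic localization calls, PCA QC |
| `plribo`   | region-resolved ribosome occupancy: P-site assignment (12 nt from the 3' end), 5'UTR/CDS counting, RPKM + quantile normalization, pulldown/input enrichment, per-transcript NB-GLM likelihood-ratio tests, z-score differential calls with a basemean fallback, permutation t-tests with Bonferroni, uORF filtering |
| `clip4g2`  | 5'UTR CLIP binding: depth normalization, pseudocount log2 fold changes, exact binomial tests, bound-set calls |
| `motifscan`| PWM scanning of 5'UTR sequences (95% score threshold) and hypergeometric motif enrichment with BH FDR |
| `plms`     | proximity proteomics: log2, two-thirds detection filter, downshifted-normal imputation (width 0.3, downshift 1.8), quartile width adjustment, minus-biotin subtraction, paired/unpaired t-tests |
| `integrate`| threshold-coded gene classes (5'UTR-up, CDS-up/down with transcript-level guards), bound-set intersections, KS comparisons, correlations, reporter fold changes, transcript feature statistics |

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` which checks null calibration of the z procedure,
exact agreement with independent enumeration oracles (permutation, binomial,
hypergeometric, OLS, KS, Poisson-limit NB LRT), parameter recovery on the
"strong" synthetic preset, and every strict-inequality threshold boundary.

## CLI walkthrough

```sh
# 1. generate a synthetic dataset (presets: null, strong, paperlike)
dendtrans simulate --preset strong --n-genes 2000 --seed 1 --out-dir data/

# 2. dendritic RNA enrichment
dendtrans plclip --counts data/rna_counts.tsv --samples data/rna_samples.tsv \
    --out-dir out/plclip

# 3. region-resolved translation
dendtrans plribo --region-counts data/region_counts.tsv \
    --samples data/ribo_samples.tsv --annotation data/annotation.bed \
    --orfs data/orfs.tsv --seed 1 --out-dir out/plribo

# 4. CLIP 5'UTR binding
dendtrans clip4g2 --tags data/clip_tags.tsv --out-dir out/clip

# 5. motif enrichment (foreground/background = one transcript id per line)
dendtrans motifs --fasta data/utr5.fa --pwms data/pwm_manifest.tsv \
    --fg fg_ids.txt --bg bg_ids.txt --out-dir out/motifs

# 6. proteomics
dendtrans plms --intensities data/proteins.tsv --samples data/ms_samples.tsv \
    --seed 1 --out-dir out/plms

# 7. integration
dendtrans integrate --plclip-diff out/plclip/plclip_diff.tsv \
    --plribo-utr5 out/plribo/plribo_utr5.tsv \
    --plribo-cds out/plribo/plribo_cds.tsv \
    --clip out/clip/clip4g2.tsv --orfs data/orfs.tsv \
    --annotation data/annotation.bed --out-dir out/sets
```

Every subcommand accepts `--config cfg.yaml` (a YAML file mirroring the
`Thresholds` record field-for-field) and writes a log file with the
thresholds used into its output directory.

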
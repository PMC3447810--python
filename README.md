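# promotile

Genome-wide prediction of bacterial σ70 promoters, validated against
transcription start sites inferred from strand-specific tiling-array
signal.

## Who this is for

Microbial regulatory genomics: you have (or can simulate) a bacterial
genome with annotation and strand-specific tiling-array transcriptome
data, and you want to know which in-silico promoter predictions are
backed by actual transcription initiation. The package implements the
whole chain as a library plus a thin `promotile` CLI, and ships a
ground-truthed synthetic-data generator so every stage can be exercised
and benchmarked without external data.

## The method

**Promoter model.** The housekeeping sigma factor σ70 recognizes a
bipartite promoter: a −35 box (consensus `TTGACA`) and a −10 box
(consensus `TATAAT`) separated by a weakly conserved spacer of 16–22 nt.
Motifs are modelled as position weight matrices (PWMs); for a k-mer
*x* the score is the log-odds

S(x) = Σᵢ log₂ ( pᵢ(xᵢ) / b(xᵢ) )

against a background *b* (by default the genome's mononucleotide
frequencies). Spacer-length variants are derived by deleting or
duplicating the least-informative spacer columns, giving one matrix per
spacer length 16…22.

**Exact significance.** Scores are discretized on a fixed-point grid
(10⁻³ log₂ units) and the exact null distribution of a background
k-mer's score is computed by per-column convolution, giving the tail
probability P(S ≥ s) for every attainable score — no sampling, no
approximation beyond the grid. Scanning both strands keeps hits with
p < 10⁻⁴ (stringent) or 10⁻⁴ ≤ p < 10⁻³ (relaxed band); overlapping
hits are reduced to the most significant, and hits are classified as
intergenic / gene-overlapping / intragenic.

**Transcriptionally active regions (TARs).** Replicate probe tracks
are quantile-normalized and averaged per strand. A normal background is
fitted to the left of the signal mode (the mode from a histogram with
quadratic peak refinement; the sd from the sub-mode root mean square),
and the global transcription threshold is the signal a background probe
exceeds with probability 10⁻⁶: mode + z(1−10⁻⁶)·sd. Runs of
above-threshold probes separated by ≤ 60 nt of uncovered genome are
joined; spans shorter than 120 nt are dropped.

**TSS inference.** At each TAR's 5′ end the adjacent-probe pair with
the steepest signal rise (per nt, in the direction of transcription) is
found within 300 nt upstream plus the first 10 TAR probes; the line
through the downstream probe with that slope is extrapolated back to
the background mode, and its intercept is the TSS. TSSs are labelled
sense / antisense / noncoding against the annotation and ranked into
five expression groups (A strongest … E weakest) by the difference of
mean signal 140 nt downstream vs upstream.

**Co-localization statistics.** Each TSS is matched to the nearest
same-strand promoter 3′ end; |distance| ≤ 40 nt counts as co-localized.
The expected co-localized fraction under randomness comes from a
10,000-replicate Monte-Carlo null that re-places the promoter 3′ ends
uniformly (half per strand); observed vs expected counts are compared
with a one-sided Fisher exact test whose hypergeometric tail is
evaluated in log space (real-genome enrichments underflow double
precision).

## Worked example

Run the whole pipeline on the bundled synthetic conditions (200-kb
genome, 120 genes, 60 planted promoters, two replicate tracks at 14-nt
tiling):

```python
from promotile.pipeline import PipelineConfig, run_all

result = run_all(PipelineConfig(seed=1))
for k, v in result.report.items():
    print(k, v)
```

prints (abridged):

```
planted_promoters 60
genome_length 200000
intergenic_fraction 0.3912
n_matrices 7
hits_stringent 279
hits_relaxed_band 1715
background {'+': {'mode': 6.9454, 'sd': 0.3673, 'threshold': 8.6914},
            '-': {'mode': 6.9944, 'sd': 0.3903, 'threshold': 8.8495}}
tars_total 49
tss_total 49
tss_sense 40
tss_antisense 5
tss_noncoding 4
matched_stringent 28
matched_relaxed_band 4
unmatched_tss 17
null_expected_fraction 0.0553
fisher_log10_pvalue -7.62
```

Reading this: 7 spacer-length matrices scanned both strands and kept
279 stringent hits (the 60 planted promoters plus the false-positive
load expected at p < 10⁻⁴ over ~2.8 M windows). Thresholding the
normalized tracks at the 10⁻⁶ background quantile yields 49 TARs, one
TSS each; 40 are sense (upstream of a gene), 5 antisense, 4 in
gene-free regions. 28 of the 49 TSSs have a stringent promoter within
40 nt against a random expectation of 5.5%, a co-occurrence at Fisher
p ≈ 10⁻⁷·⁶; 4 more are explained by relaxed-band hits only. All 24
planted promoters driving high-expression (group A/B) transcripts are
recovered within 40 nt; high-expression TSSs are placed with a median
error of half a probe step (~8 nt), while low-expression sigmoidal
onsets position much less precisely — the same asymmetry the method
shows on real arrays.

The same run from the shell:

```bash
promotile run-all --seed 1 --outdir out/
```

writes hit tables, TAR/TSS GFF3 and TSV files, the normalized tracks,
the truth tables and `report.json` into `out/`, each independently
reloadable to resume the pipeline mid-way.

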
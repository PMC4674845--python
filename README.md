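# splicejump

Classification-based splice-junction calling from RNA-seq paired-end reads
aligned with a clip-reporting DNA aligner (BWA-style BAM input).

The caller works in three stages:

1. **Candidate sites** — reads are classified (fully mapped / soft-clipped /
   hard-clipped / discarded), clip boundaries and coverage zero-crossings
   become candidate donor/acceptor sites, and nearby sites are merged
   (`-s`, default 10 bp).
2. **Classification** — each site gets four features (reads clipped at the
   site, clipped segments re-aligned onto the site, discordant encompassing
   pairs, and the flanking coverage difference over `-l` = 25 bp regions),
   normalized by the expressed-flank coverage, and an RBF-kernel SVM
   (10-fold CV + grid search) labels sites true/false. Hard-clipped
   segments are first recovered from the original FASTQ by read name.
   Clipped segments are re-aligned flush against candidate sites on the far
   side of the junction, searching nearest-first inside a focal region
   bounded by the mate position (or 1,500,000 bp); placements that would
   make the read pair discordant are rejected.
3. **Junction calling** — two true sites connected by at least one
   re-aligned clipped read form a junction, unless every supporting read's
   implied transcript-space insert is discordant with the insert-size model
   (the conflict filter; filtered junctions are reported with a status
   flag).

A fully self-contained simulator generates toy genomes ("train"/"test"
contigs), spliced transcripts, paired reads, a deterministic clip-reporting
aligner emulation (sorted+indexed BAM) and the truth set, so the entire
pipeline is testable offline.

## CLI

```sh
# generate a benchmark fixture with a known truth set
splicejump simulate -o fx --seed 7

# train the site classifier (simulation truth or annotation TSV/GTF)
splicejump train --bam fx/align.bam --ref fx/ref.fa \
    --fastq fx/reads_1.fastq --fastq fx/reads_2.fastq \
    --truth fx/truth_junctions.tsv -o model.joblib

# call junctions
splicejump call --bam fx/align.bam --ref fx/ref.fa \
    --fastq fx/reads_1.fastq --fastq fx/reads_2.fastq \
    --model model.joblib -o out

# benchmark against the truth set (slack sweep 0..15 + summary)
splicejump evaluate --called out/junctions.tsv \
    --truth fx/truth_junctions.tsv --slack 8
```

Junction output is a TSV (`contig  donor_pos  acceptor_pos  n_clip  n_seg
n_disc  status`) in 0-based half-open coordinates: `donor_pos` is the first
intronic base, `acceptor_pos` the first exonic base after the intron.
`out/` also contains the candidate-site and feature dumps, a per-read
placement report (for mapped-base ratios) and a stage-count log.

## Layout

- `src/splicejump/io_align.py` — BAM/FASTQ/FASTA I/O, read classification,
  coverage track, insert-size model, pair index, hard-clip recovery
- `src/splicejump/candidate_sites.py` — clip / coverage-change site calling,
  merging, orientation
- `src/splicejump/features.py` — the four site features and focal
  re-alignment of clipped segments
- `src/splicejump/classifier.py` — training sets, grid-searched SVM,
  prediction, GTF annotation converter
- `src/splicejump/junctions.py` — connection graph, conflict filter,
  junction calling, end-to-end pipeline
- `src/splicejump/evaluation.py` — slack matching, metrics, overlap counts,
  mapped-base ratios
- `src/splicejump/simulate.py` — fixture generator and aligner emulation
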
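# edscape

Toolkit for mapping an RNA-editing landscape from single-cell RNA-seq
read evidence: a candidate-to-reliable editing-site filter cascade,
site annotation, differential-editing analysis with trajectory
clustering, percent-spliced-in (PSI) / editing-rate association tests,
FDR benchmarks, and a synthetic-data generator with planted truth that
makes every stage verifiable without external downloads.

## What it does

1. **synthio** — generates a miniature genome (FASTA + GTF with mRNA and
   lncRNA transcripts, some overlapping on opposite strands), repeat/TFBS
   BED intervals, per-site read evidence with planted true editing sites
   and confounders (germline SNVs, strand- and position-biased artifacts,
   paralog-confounded sites), a known-SNP catalog VCF, genotypes, and
   per-exon inclusion/exclusion counts whose PSI is coupled to exon
   editing rate at a configurable correlation. Byte-identical outputs for
   identical seeds.
2. **siteflt** — the filter cascade on pileup-level evidence: candidate
   calling (>=2 mismatched reads at base quality >=25, mapping quality
   >=20), known-SNP removal (cDNA-type records retained), recurrence in
   >=2 samples, Fisher-exact strand/read-position bias tests with
   Bonferroni correction at alpha=0.01, BLAT-style paralog screening
   (second hit <95% of best, passing reads must outnumber failing),
   finalization (pooled mismatch frequency >=0.1, >=2 samples with >=5
   high-quality reads and >=2 high-quality variant reads, multi-allelic
   exclusion), and antisense collapse of variant types onto
   A-to-I / C-to-U.
3. **annot** — transcript class (lncRNA-only / mRNA-only / overlap /
   intergenic), splice-site flag (distance-to-exon-boundary window,
   default 300 bp), TFBS overlap, repeat class (Alu > repetitive non-Alu
   > non-repetitive).
4. **diffedit** — sites x samples editing matrix with a coverage mask,
   per-site one-way ANOVA across stages with Benjamini-Hochberg FDR, and
   agglomerative trajectory clustering of z-scored stage-mean curves via
   the Lance-Williams recurrence (single/complete/average/ward).
5. **spliceassoc** — per-exon editing rate (sum G / sum (G+A) over the
   exon's A-to-I sites), PSI, per-exon Pearson correlation, group
   comparisons against a 10,000-pair random baseline, chi-square/Fisher
   enrichment odds ratios (with Haldane correction), and a simple
   stand-in exon DE test (external DE flags can be passed through).
6. **bench** — genotype-based FDR (called sites contradicted by non
   hom-ref genotypes) and knockdown-based FDR per repeat class.

## CLI

```sh
# everything from one config (YAML, keys: sim/filter/annotate/diffedit/splice/benchmark)
edscape all --config config.yaml --outdir out/

# individual stages
edscape simulate  --config config.yaml --outdir sim/
edscape callsites --evidence sim/evidence.tsv --snps sim/snps.vcf \
                  --ref sim/reference.fa --out sites.tsv [--single-sample]
edscape annotate  --sites sites.tsv --gtf sim/annotation.gtf \
                  --repeats sim/repeats.bed --tfbs sim/tfbs.bed \
                  --splice-window 300 --out sites_annotated.tsv
edscape diffedit  --sites sites_annotated.tsv --design sim/design.tsv \
                  --outdir de/ --fdr 0.05 --k 3 --linkage average
edscape splice    --sites sites_annotated.tsv --exons sim/exon_counts.tsv \
                  --design sim/design.tsv --baseline-pairs 10000 --outdir sp/
edscape benchmark genotype-fdr  --sites sites.tsv --genotypes sim/genotypes.tsv
edscape benchmark knockdown-fdr --control ctrl_sites.tsv --knockdown kd_sites.tsv
```

`edscape all` writes a `manifest.json` with the config snapshot, seed,
per-stage wall-clock times and sha256 checksums of every data output;
rerunning with the same config and seed reproduces identical checksums.

## Data formats

All interchange is plain TSV/VCF/GTF/BED/FASTA. The read-evidence table
has one row per read per candidate site per sample with columns
`chrom, pos_1based, sample_id, stage, read_id, allele, base_qual,
map_qual, read_len, pos_in_read_1based, strand, best_hit_score,
second_hit_score, best_hit_overlaps_site`. Sites are 1-based (VCF
convention); interval files are 0-based half-open (BED convention).
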
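# dupfate

Statistical pipeline for studying expression divergence between near-identical
duplicated genes and a single-copy outgroup ortholog. Given expression
matrices, gene-family annotations, copy-number genotypes, genomic intervals,
and paralogous sequences, it infers duplicate-gene expression fates
(conserved / pseudogenized / neofunctionalized / subfunctionalized
candidates), runs copy-number-adjusted paralog differential expression,
reallocates multi-mapping reads across duplicated loci with an EM scheme,
tests peak depletion in duplicated regions by permutation, and compares PWM
motif content between paralogous promoters. A synthetic-data module generates
every input with known ground truth, so the whole pipeline is testable
offline.

## Modules

| Module | Purpose |
| --- | --- |
| `dupfate.synthio` | Synthetic gene families with known fates, duplicated-read sets with known origins, peak landscapes with controlled depletion |
| `dupfate.quantdiv` | Expression divergence, tissue-specificity (tau), cross-tissue correlation, relative expression, promoter divergence counts, ddCt math |
| `dupfate.fates` | Fate classification from member/sum correlations, Fisher test on DE proportions, Poisson-binomial enrichment of most-conserved members, Kruskal–Wallis + Dunn tests |
| `dupfate.cnde` | Wilcoxon signed-rank paralog DE, CN–expression association, CN-adjusted linear model with interaction screen, BH FDR |
| `dupfate.emalloc` | EM reallocation of multi-mapping reads by local unique-coverage support; highest-posterior primary placement |
| `dupfate.sdperm` | Interval merge/intersection, length-preserving region permutation, empirical depletion p-value (M+1)/(N+1), identity-threshold SD filtering |
| `dupfate.motifdiff` | PWM scanning with exact DP p-values, TF expression filtering, paralog-specific motif gain/loss polarized by the ortholog |
| `dupfate.cli_io` | BED/TSV/FASTA/MEME/YAML readers and writers, pipeline driver |

## CLI

```bash
dupfate simulate --seed 7 --outdir out/           # synthetic inputs + truth tables
dupfate stats --expression out/expression_human.tsv \
    --ortholog-expression out/expression_ortholog.tsv \
    --families out/families.tsv --out out/stats.tsv
dupfate fates --stats out/stats.tsv --out out/fates.tsv
dupfate cnde --expression expr.tsv --cn cn.tsv --families fam.tsv --out de.tsv
dupfate alloc --candidates cand.tsv --genome genome.tsv --out alloc.tsv
dupfate depletion --regions sd.bed --peaks peaks.bed --genome genome.tsv \
    --n 1000 --seed 17 --out depletion.tsv
dupfate motifs --sequences homologs.fasta --motifs motifs.meme --out hits.tsv
dupfate run --seed 7 --outdir report/             # full pipeline
```

All coordinates are BED-convention 0-based half-open. Expression TSVs are
long-form (`gene`, `sample`, `tissue`, `TPM`); family TSVs map genes to roles
(`ancestral` / `derived` / `ortholog`); motifs use MEME minimal format.

## Notes on defaults

Paper-derived defaults are used throughout: log pseudocount `1e-4`, fate
margin `0.05` in Pearson r, 1000 permutation replicates, 0.98 fractional
identity for high-identity SD filtering, TF expression filter of >1 TPM in
>75% of libraries, interaction screen at raw p = 0.05 with BH FDR 5% for the
paralog effect.
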
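# dyadtrace

Tools for asking a simple question with two kinds of evidence: **are
bacteria from the maternal vaginal microbiome vertically transmitted to the
infant gut?** The package implements the two analyses that question needs —

1. **Amplicon transfer-event analysis.** Given an ASV read-count table
   (samples × amplicon sequence variants), sample metadata and taxonomy for
   a cohort of mother–infant *dyads* (one maternal vaginal sample, up to two
   infant stool samples at 10 days and 3 months), detect *potential transfer
   events*: the same ASV present at relative abundance ≥ *t* (default
   *t* = 0.001, i.e. 0.1%) in the mother **and** in at least one of her
   infant's samples. Events are counted per dyad and per taxon (transfer
   rate = transfers / maternal detections above threshold), and per-dyad
   counts are compared across delivery modes and intrapartum-antibiotic
   groups with a Kruskal–Wallis test plus Dunn's post hoc comparisons.
   Strain-identity call tables are compared across groups by chi-square.

2. **Genome-level strain identity.** Given a whole-genome alignment and/or
   a gene presence/absence matrix for cultured isolates labelled by dyad,
   compute pairwise SNP distances (snp-dists semantics: only unambiguous
   A/C/G/T mismatches count, gaps and Ns skip the column), k-mer ANI
   (canonical *k*-mers, *k* = 21, Mash formula
   ANI = 1 + ln(2J/(1+J))/k from the Jaccard index *J*), gene-content
   Jaccard distances and UPGMA trees; then contrast within-dyad vs
   between-dyad pairs (Mann–Whitney U) and call dyads identical /
   nonidentical under a SNP bound (≤ 25) or ANI bound (> 99.9%).

A first-class synthetic-data module generates dyad cohorts and genome sets
with exact ground truth (planted transfer events, planted substitution
counts, dyad-private gene blocks), so every stage is testable without any
download.

## Worked example

```bash
python examples/01_transfer_detection.py
```

```
dyads: 50, planted events: 28, detected: 28
detection matches ground truth exactly: True
dyads with >=1 event: 23 of 50 (46.0%)
mean events per dyad by delivery mode: {'elective_CS': 0.5, 'emergency_CS': 0.57, 'vaginal': 0.57}
Kruskal-Wallis H = 0.000, p = 1.000
(transfer probability is identical across modes, so a large p is expected)
```

The generator planted 28 transfer events in a 50-dyad cohort; the detector
recovers exactly those 28 at the 0.1% gate (no false positives, no misses),
and because the simulation plants transfers at the same rate in every
delivery mode, the omnibus test is — correctly — far from significant.

On the genome side (`examples/03_strain_genomics.py`), 8 simulated
mother–infant genome pairs give a median of 16 SNPs within dyads versus
3,988 between dyads (Mann–Whitney p ≈ 2×10⁻⁶), within-dyad ANI of 99.992%
versus 97.990% between, and every dyad called "identical" under the 25-SNP
transmission bound — the planted strain-sharing signal, recovered end to
end.

Other examples: `02_published_table_accounting.py` (aggregating bundled
published per-ASV accounting rows and re-running the strain-typing
contingency statistics), `04_gene_content_clustering.py` (UPGMA on
gene-content Jaccard distances).

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
dyadtrace transfer --table table.tsv --meta meta.tsv --threshold 0.001 --out-dir out/
dyadtrace genomic --alignment aln.fasta --labels labels.tsv --out-dir gout/
dyadtrace partition --matrix gout/snp_matrix.tsv --labels labels.tsv
dyadtrace sim cohort --n-dyads 100 --seed 17 --out-dir sim/
```

Outputs are plain TSV/JSON plus a manifest with input digests.

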
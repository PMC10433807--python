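# Methods

## The transfer-event statistic

A *potential transfer event* is a (dyad, ASV) pair where the ASV's relative
abundance reaches a threshold *t* in the maternal vaginal sample **and** in
at least one stool sample from the corresponding infant. "Potential"
matters: shared presence of a 150-bp amplicon variant is compatible with,
but does not prove, transmission — the variant may arrive via breast milk,
the maternal gut, or the shared environment, and a single barcode gene
cannot resolve strains. The package therefore treats the statistic as a
screening quantity and pairs it with genome-level evidence.

Decisions embedded in the detector:

* **Threshold semantics.** The gate is inclusive (≥ *t*) by default, with a
  strict (>) option; published descriptions of this statistic use both
  spellings and the choice only matters for abundances exactly at the gate.
  The gate is symmetric: it applies to the maternal and the infant
  abundance alike. Default *t* = 0.001 (0.1%).
* **One event per (dyad, ASV).** If both infant samples pass, the event is
  categorised `both` rather than counted twice; the three categories
  (`ten_day_only`, `three_month_only`, `both`) partition the event set, an
  invariant the tests enforce on every dataset.
* **Transfer rate.** Per ASV, the denominator is the number of maternal
  samples in which that ASV clears the gate (one per dyad), not the number
  of dyads — an ASV absent from a mother cannot be transferred from her.
* **Degenerate inputs.** Zero-read samples are retained in the container
  (honest cohort bookkeeping) but excluded from detection; dyads with no
  infant sample are excluded from the analysis and counted in the cohort
  validation report.

## Group statistics

Per-dyad event counts are compared across delivery modes (vaginal,
elective caesarean, emergency caesarean) and intrapartum-antibiotic groups
with the Kruskal–Wallis test (scipy, tie-corrected) followed by Dunn's
pairwise z tests on pooled mean ranks with the standard tie-corrected
variance. Dunn's test is implemented here because no installed package
provides it; the adjustment is Bonferroni-style multiplication by the
number of pairwise comparisons (the behaviour of the commercial software
these analyses are usually run in), exposed as an option.

Contingency tables of identical/nonidentical strain calls are tested with
the Pearson chi-square (scipy). The Yates continuity correction is
available for 2×2 tables but **uncorrected is the default**: recomputing
published strain-typing tables of this kind from their printed counts
reproduces the printed p-values only without the correction, even when the
accompanying caption says "Yates-corrected". One published row (the
bifidobacterial 10-day vs 3-month table) prints "<0.01" where the
uncorrected statistic gives p = 0.011 and Yates gives p = 0.020; the
package computes both and takes no side — the bundled example skips that
row and points here.

Within- vs between-dyad distance contrasts use the Mann–Whitney U test
(normal approximation, tie-corrected, two-sided). Pairwise matrix entries
are not independent observations — each genome participates in many pairs —
so these p-values overstate certainty; the computation is kept (it is the
field's convention for this contrast) and the caveat is recorded here
rather than silently "fixed".

## Genome relatedness

* **SNP distances** follow snp-dists semantics: a column contributes 1 when
  both sequences carry an unambiguous A/C/G/T (case-insensitive) and the
  bases differ; gap, N or ambiguity code in either sequence skips the
  column. Verified against a per-column brute-force oracle on hundreds of
  random fixtures.
* **ANI** is estimated from canonical k-mer sets (lexicographic minimum of
  a k-mer and its reverse complement, k = 21, 2-bit packed) via the Mash
  formula ANI = 1 + ln(2J/(1+J))/k, in exact-set mode or bottom-s MinHash
  (splitmix64 hash, default sketch 5,000; agrees with exact mode within
  0.002 on 100-kb fixtures). k-mer estimation was chosen over fragment
  alignment because it is deterministic in exact mode, fast at desk scale,
  and validated directly against planted mutation rates: on 100-kb genomes
  the estimate recovers 1 − r within ±0.005 for r ≤ 0.05 (the formula's
  own small-J bias dominates at the high end: at r = 0.05 the estimate is
  ≈ 0.949). J = 0 is reported as ANI 0 with an "unrelated" flag rather
  than −∞.
* **Gene content** distance is 1 − Jaccard over gene presence sets from a
  Roary-style matrix (plain 0/1 CSV or the full `gene_presence_absence.csv`
  dialect, non-empty cell = present). Two empty gene sets are defined to be
  at distance 0.
* **UPGMA** is implemented directly (O(n³), fine for isolate-scale inputs)
  rather than via a linkage library because the contract requires
  deterministic tie-breaking — candidate pairs at equal distance are
  resolved by the lexicographically smallest member label — and a newick
  writer; the implementation is cross-checked against scipy's average
  linkage (cophenetic distances equal) and its output is ultrametric by
  construction (asserted to 1e-9 in tests).
* **Identity calls.** A dyad is called *identical* when any maternal–infant
  genome pair within it passes the active bound: SNPs ≤ 25 (inclusive — a
  pair at the published upper bound of transmission thresholds still counts)
  or ANI > 0.999 (exclusive — the bound itself is quoted as ">99.9%").
  Dyads lacking genomes from one side are *not assessable*. Whether a SNP
  bound should scale with alignment length is unsettled; the default is an
  absolute count, configurable.

## The synthetic cohort generator

`simulate_cohort` emulates the structure of a mother–infant transmission
study, and its defaults are the study conditions: 585 dyads; infant sample
availability 568/585 (10 days) and 459/585 (3 months), with at least one
infant sample forced per dyad (the analysis cohort is defined that way);
read depth 20,000 per sample; detection threshold 0.1%. Maternal profiles
are two-class Dirichlet-multinomial — 3 dominant Lactobacillus-like ASVs
drawn from a pool of 8 carrying 95% of the mass, plus 15 rare taxa — rather
than a fit to real community-state-type distributions; that is sufficient
to exercise the threshold logic, which is what the generator exists for.
Transfers are planted independently per *eligible* maternal ASV (one whose
sampled maternal abundance reaches 2× threshold) with probability 0.045,
which lands the positive-dyad fraction near one third and per-positive-dyad
counts in the 1–5 range with mean ≈ 0.45 events/dyad, matching the
motivating cohort's headline figures; the planted category split
(10-day-only : 3-month-only : both = 147 : 72 : 41) mirrors the same
source.

Margin handling is deliberate: planted infant abundances are **pinned** as
deterministic read counts ≥ 2× threshold × depth (background reads are
multinomial over infant-specific ASVs), and non-transferred maternal ASVs
appear in infants at 0 or ≤ 0.5× threshold. This guarantees the
planted/unplanted separation survives count sampling, making exact
precision = recall = 1 recovery a testable invariant instead of a
probabilistic one. The cost is realism at the margin: real transferred
ASVs have no such abundance floor, so the recovery tests certify the
detector's logic, not its sensitivity on real data. Likewise the generator
omits PCR/sequencing error, chimeras, contamination and compositional
correlations; passing tests say nothing about those.

`simulate_genome_cohort` evolves each dyad's ancestor from a common root by
`round(between_rate × length)` substitutions and each of the two dyad
genomes a further `within_subs` substitutions (substitution-only, so the
alignment is free and ground-truth pairwise distances are exact, computed
from per-position bookkeeping including back-mutations and collisions).
Defaults — within_subs = 8 per branch (mother–infant pair ≈ 16 SNPs),
between_rate = 0.011 on 1 Mb (unrelated pair ≈ 21,800 SNPs) — echo the
scale reported for vertically shared *Bifidobacterium breve* strains
(median 15 within vs 21,362 between). Indels are deferred.
`simulate_gene_matrix` gives every genome a shared core, each dyad a
private accessory block, and each genome independent residual accessory
genes (defaults 1,200 core / 300 accessory per genome / 60% dyad-shared).

All generators are driven by one integer seed through a single
`numpy.random.Generator`; identical configuration and seed give
byte-identical outputs.

## Problem sizes in the reproduction script

`scripts/acceptance.py` uses 100-dyad cohorts (100 replicates for the null
calibration), a 12-dyad × 1 Mb genome cohort, 100-kb genomes for ANI
recovery and 50 gene-matrix replicates — sizes chosen so the whole script
runs in well under a minute on one core while keeping every estimate's
Monte-Carlo error small relative to the quantities reported.

## Known limitations

* Transfer events are presence-sharing, not transmission inference; no
  directionality, no source attribution, twins unsupported.
* Pairwise-matrix tests pseudo-replicate (see above).
* Real-data SNP counts depend on upstream alignment masking choices and
  will not be bit-identical to any particular published matrix; published
  real-genome medians are context for the defaults, not test targets.
* The ANI estimator's Mash-formula bias grows with divergence (≈ 0.001 at
  r = 0.05); fine for the >99.9% identity calls it backs, not a substitute
  for alignment-based ANI at species-boundary questions.
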
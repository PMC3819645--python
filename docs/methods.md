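# Methods

## Data model

All analyses operate on strand-specific per-cytosine call tables: one row
per (chromosome, 1-based position, strand) with the number of methylated
(unconverted C) calls and total (C+T) calls. The two strands of a CpG are
never merged; they are tested independently and interleave during
clustering, which doubles the effective number of observations per CpG
unit at the cost of per-site power. Site tables on disk keep 1-based
positions (the convention of BSMAP's methratio output); all interval
arithmetic is 0-based half-open; BED tracks are read verbatim. Ratios are
always recomputed from counts — a stated ratio column is only
consistency-checked.

Pairing two methylomes is an inner join on (chromosome, position, strand):
sites covered in only one sample are dropped rather than imputed. With no
replicates there is no basis for imputing a missing sample's counts, and a
Fisher test needs both margins; the dropped-site counts are reported so
the loss is visible.

## Differential calling

Per paired site, the two-sided Fisher exact p-value is the sum of
hypergeometric point probabilities not exceeding the observed table's
(relative tolerance 1e-7, the standard convention for two-sided tests on
discrete tables, and the one scipy uses). The implementation enumerates
each site's full hypergeometric support vectorised across sites; at 12×
coverage the support is ~25 states, so a 400,000-site genome tests in
about a second. Unit and acceptance tests compare against
scipy.stats.fisher_exact and against an exact integer-arithmetic
enumeration oracle (math.comb), to 1e-9 for all tables with margins ≤ 30.

Significance is *P* < 0.05 with no multiple-testing correction. At
genome scale this deliberately admits ~1% false DMCs (Fisher is
conservative on discrete counts, so the realised rate sits well below the
nominal 5%); the regional clustering is the specificity filter. Requiring
≥ 8 DMCs within consecutive gaps of ≤ 50 bp and a net directional excess
of ≥ 8 makes a false region astronomically unlikely under the null:
isolated false DMCs at ~100-bp mean spacing rarely chain at all, and the
null-calibration test (50,000 CpGs, 20 seeds) observes zero DMRs in ≥ 95%
of runs.

"Net directional change of ≥ 8 DMCs" is implemented as
|n_up − n_down| ≥ 8 within the cluster — the reading under which the unit
"DMCs" is coherent — so a minimal 8-DMC cluster must be direction-unanimous.

Candidate clusters are then scored over **all** paired CpGs in the span,
including non-significant ones: pooled counts give the region methylation
difference (robust at ~11× where per-site ratios are noisy), and coverage
is averaged per site across samples, then across sites. Thresholds
(coverage ≥ 8, |Δ| ≥ 0.10) are inclusive. The DMR span runs from the first
to the last member DMC with no flank extension, matching the compact
(<150 bp) scale of the regions this method targets. A post-hoc validator
re-checks every emitted DMR against all thresholds. A configurable width
sanity bound (default 10 kb) guards against pathological chains; it is
inert at the intended scale.

## QC and summaries

* **Conversion rate** = 1 − Σm/Σt over an unmethylated control contig
  (mitochondrial DNA co-purified with the sample), any cytosine context.
  By construction this plus the observed control methylation is exactly 1.
* **CpG-specificity** = C calls / all calls at non-CpG cytosine positions.
* **Histogram**: per-CpG ratios binned over [0,1] (default 20 bins), with
  the three-way split unmethylated (< 0.05), partial (0.05–0.95 inclusive
  of both boundaries), fully methylated (> 0.95). The boundary semantics
  are strict on both cuts.
* **Compartment means** are unweighted means of per-site ratios; a site in
  overlapping annotations resolves by priority promoter > gene body >
  intergenic. Promoters derived from gene models span TSS −1500/+500 bp.
* **Windows**: 100-kb tiles from coordinate 0 (≥ 10 covered CpGs, an
  anti-noise floor at ~11× coverage) and sliding 5-CpG windows (step 1;
  step = k gives the non-overlapping variant). A window is differential
  when |mean_old − mean_young| > 0.15 (strict).

## Enrichment

DMR-center state enrichment assigns each DMR by its integer midpoint
floor((start+end)/2); uncovered bases form a sentinel "Unsegmented" state
so observed fractions sum to 1; fold = observed fraction / genomic bp
fraction, separately per DMR direction. Region-set enrichment uses
any-overlap (≥ 1 bp) against the genome-average expectation (fraction of
bp covered). Mark profiles score each 50-bp bin around a DMR center 1 if
it overlaps any peak interval (peak files are interval calls, not
coverage, so binary presence averaged over DMRs is the defensible signal),
then average across DMRs; bins off a chromosome end are excluded from that
DMR's denominator. Default flank ±5,000 bp.

Loess smoothing is degree-1 locally weighted regression with tricube
weights over the nearest max(3, ceil(span·n)) bins (span default 0.10),
ties in the neighbour selection broken by index. It reproduces constants
and straight lines exactly and is tested to 1e-9 against an independent
normal-equations oracle. statsmodels' lowess uses a different
neighbourhood rule, so it is not used as the implementation.

## Expression validation

ΔCt values (target − reference Ct; higher = lower expression) are averaged
over replicates per gene/subject, centered per gene to mean 0 over
subjects, and clamped at ±2.5 for display. The clamp is symmetric by
default (an upper-only option exists): the display scale is a diverging
heatmap and an asymmetric clamp would bias it.

The group test is Mann–Whitney U, two-sided. For group sizes ≤ 10 the
p-value is exact over all C(n₁+n₂, n₁) assignments with midranks for ties,
computed by dynamic programming over the doubled-rank-sum distribution
(identical to full enumeration, verified against an itertools oracle for
all sizes ≤ 6); larger groups use the tie-corrected normal approximation.
Centering cannot change the test: it subtracts one constant per gene, and
ranks within a gene are invariant under a common shift, so p-values are
computed on uncentered replicate means.

## Synthetic data

The generator emulates the structure the analysis assumes, not read-level
sequencing (no FASTQ, alignment errors or hemimethylation):

* CpG positions with geometric gaps, mean 100 bp — memoryless background
  spacing, the simplest structure that exercises the algorithms.
* True per-CpG ratios from a three-component beta mixture, weights
  0.10/0.40/0.50 with Beta(1,100), Beta(5,5), Beta(100,1): the low/high
  components sit almost entirely below 0.05 / above 0.95 (leakage ~0.6%),
  so the true-ratio histogram recovers the configured weights, and their
  shapes match the near-0/near-1 ratios of unmethylated and fully
  methylated CpGs.
* Planted DMRs (default 50 per 20 Mb; width 150 bp; |Δ| = 0.4; ≥ 10 CpGs)
  are placed in island-like CpG-dense stretches (mean gap 10 bp inside the
  region). At the background spacing a 150-bp window would hold ~1.5 CpGs;
  compact regulatory DMRs in real genomes sit in CpG-dense sequence, and
  the density is what makes an 8-DMC chain physically possible. The
  baseline inside a DMR is drawn from the partial (mid) component, since a
  ±0.4 shift on a near-0/near-1 baseline would be erased by clipping to
  [0,1] — variation must live where methylation is variable.
* Counts: per strand and sample, Poisson coverage (defaults 11.3×/11.9×)
  and binomial methylated calls at the site's true ratio; both strands
  share the true ratio but have independent counts.
* A control contig with true ratio 0 whose C-call probability equals the
  configured conversion error (defaults 0.16%/0.12%), plus optional
  essentially-unmethylated non-CpG records for specificity QC.
* ΔCt tables: per-gene baseline + group effect (added to the old group) +
  Gaussian noise per replicate; defaults 15 genes, 9 subjects per group,
  2 replicates, noise sd 0.5.

Everything derives from one integer seed. Recovery scoring matches called
to planted DMRs by ≥ 1 bp overlap with direction agreement, counting
one-to-many matches once per side; precision is undefined (reported
missing) when nothing is called.

What passing recovery tests shows — and does not. The generator has clean
Poisson/binomial noise, no PCR or mapping bias, no methylation
autocorrelation outside planted DMRs and no CpG-island structure beyond
them. Precision/recall ≥ 0.8 at the standard scale therefore validates
the algorithmic chain (testing, chaining, net rule, pooled scoring), not
performance on real tissue, where extra dispersion and coverage artefacts
would lower per-site power.

## Problem sizes and numerical choices

The standard synthetic study uses a single 20-Mb chromosome (~200,000
CpGs, ~400,000 strand records) at 12× — large enough for stable
precision/recall over 50 planted DMRs and small enough to run in seconds;
null calibration uses 5 Mb (~50,000 CpGs) × 20 seeds. Fisher p-values are
floats summed over ≤ ~60-state supports (no log-space needed at these
coverages); p is clipped at 1. Degenerate inputs: empty DMC lists
propagate as empty outputs; a loess neighbourhood whose weights collapse
onto one abscissa falls back to the weighted mean; zero-coverage sites are
retained on read but never enter paired analyses.

## Known limitations

* No dispersion-aware (beta-binomial) testing and no replicate modelling:
  the design targets pooled single comparisons; between-subject variance
  is invisible to it.
* Fisher at pooled ~11× has limited per-site power; DMRs narrower than the
  8-DMC rule allows (or in CpG-sparse sequence) are undetectable by
  construction.
* Enrichment folds carry no significance estimate (ratios only).
* The CLI loads whole site tables into memory; tens of millions of rows
  need the library API with per-chromosome iteration.
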
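# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `strt-ega`.

## Problem setting

5′-capturing single-cell RNA-seq of oocytes and cleavage-stage blastomeres
measures, per cell, the genomic positions of transcript far 5′ ends (TFEs)
together with reads from synthetic spike-in RNAs added at a fixed molar
amount per well. Three processes change a transcript's per-cell signal
across developmental stages:

1. **embryonic activation** — new transcription raises absolute per-cell
   molecule counts of specific genes;
2. **passive dilution** — each division splits the maternal RNA pool
   between daughter cells, halving every transcript's per-cell count;
3. **active maternal degradation** — enzymatic (in part 5′-exonucleolytic)
   decay removes or truncates maternal molecules, shifting captured 5′
   ends from the TSS into gene bodies.

Because spike-in molecules per well are constant, expression per spike-in
tag is proportional to molecules per cell, which makes these three
processes statistically separable.

## TFE assembly

Read 5′ ends are points (alignment lengths are ignored). Per sample type,
positions on the same contig and strand are clustered by single linkage
with a maximum gap (default 60 bp): sorted positions split wherever
adjacent tags are more than the gap apart. 5′ tags carry no splice
structure, so full transfrag assembly would add nothing; gap-bounded
linkage recovers exactly the tag pileups around transcription start
regions. Clusters with fewer than 5 supporting tags are discarded. Across
sample types, clusters that share ≥ 1 bp on the same strand are unioned
into one feature (any-bp overlap; a reciprocal-overlap criterion made no
difference on well-separated toy promoters and is harder to reason about).
IDs are assigned in (contig, start) order. The **peak** is the position of
maximal tag multiplicity; ties break toward the transcription-direction
5′-most position so that a flat pileup yields the most upstream start.

## Sample QC

Two tiers, all comparisons strict `<`:

* prefilter: raw reads < 100,000 per well, or zero spike-in reads;
* adaptive: log₁₀ reads < mean − 2 s.d., mapping rate < mean − 2 s.d.
  (both computed over the current cohort), or spike reads < 50.

The sample (n−1) standard deviation is used. Cut-offs are recomputed per
cohort rather than frozen at any particular library's historical values,
since they are by construction cohort-specific; published per-library
values (e.g. 5.34 for log₁₀ reads, 60.65% mapping rate) arise as instances
of this rule.

## Spike-in normalization and RNA content

value(t, s) = count(t, s) / spike_depth(s) × 1,000. The constant 1,000 is
cosmetic (readable magnitudes); any constant cancels in every downstream
test. De-normalization recovers integer counts exactly (by rounding), which
the resampling test relies on. Per-cell relative poly(A) content is the
genomic/spike tag ratio divided by the earlier stage's mean ratio, so the
earlier stage is centered at 1 and a two-division dilution appears as
≈ 0.25. Stage comparisons use the two-sided Wilcoxon rank-sum test: exact
when both groups have ≤ 25 samples and no ties, otherwise the normal
approximation with tie correction; an all-tied comparison returns p = 1.

## Differential expression

A resampling rank test in the SAMseq family, adapted to spike-in depths:

1. **Thinning.** Each sample's counts are binomially thinned with
   probability min(spike depth)/own spike depth, independently in each of
   R resamples (default 20), so expected spike-relative depth is equal
   across samples. Thinning preserves integer counts and the rank test's
   distribution-free character.
2. **Statistic.** Per feature, mid-ranks across samples; the statistic is
   the group-2 rank sum minus its null expectation n₂(n+1)/2, averaged
   over resamples (the statistic is linear in ranks, so the average
   commutes with the group sum). Positive = higher in group 2.
3. **Permutation FDR.** For threshold t = |sᵢ|:
   FDR(t) = median over label permutations of #{permuted |s| ≥ t} divided
   by #{observed |s| ≥ t} (the median, not the mean, following SAM
   convention; no π₀ estimate, which is conservative). When the number of
   distinct label subsets is at most P (default 1,000) the permutations
   are enumerated exhaustively, making small designs exact. A feature's
   q-value is the minimum FDR over all thresholds at or below its own |s|,
   which makes q non-increasing in |s|; values are clipped to [0, 1].
4. **Division correction.** To call *actively reduced* features, the later
   stage's raw counts are multiplied by D = number of intervening cell
   divisions (4 for oocyte→4-cell, 2 for 4→8-cell) before thinning —
   turning per-cell counts into per-embryo-equivalent counts so pure
   dilution cancels. "Down" is only assigned from this corrected run;
   "up" only from the uncorrected run. Both runs are seeded identically,
   so D = 1 reproduces the uncorrected run bit for bit. A feature called
   both ways raises an error (it indicates inconsistent inputs).

Ties are handled by mid-ranks throughout; this is a fixed policy and a
known divergence risk against other implementations of the same family at
very small counts.

## Annotation classes

Nine mutually exclusive classes assigned by first match in priority order:
coding 5′UTR → coding upstream (≤ 500 bp of the TSS, transcription
direction) → CDS → coding 3′UTR → noncoding first exon → noncoding
upstream → noncoding other exon → intron (any transcript) → unannotated.
Overlap means ≥ 1 shared base **on the same strand**: the protocol is
strand-specific, so opposite-strand overlap is treated as no overlap and
typically yields "unannotated". Per-cell class proportions are computed on
normalized expression mass by default (share of molecules), with an option
to weight each detected feature equally (share of distinct TFEs); fractions
sum to 1 per cell.

## Promoter windows, motif discovery, scanning

Windows run from 2,000 bp upstream to 500 bp downstream of the TFE peak:
`[peak−2000, peak+500)` on `+`, the mirrored `[peak−499, peak+2001)` with
reverse-complemented sequence on `−`, clipped (and flagged) at contig ends.

**ZOOPS EM.** Each window carries zero or one motif occurrence (prior γ,
fitted), at a uniformly distributed offset, against a fixed 0-order
background estimated from the windows. EM is restarted from the most
frequent W-mers (5 seeds) and the best final likelihood wins; iteration
stops when the relative log-likelihood change is below 1e-6 or after 200
iterations. A Dirichlet pseudocount (0.01) keeps the PWM strictly
positive. The data log-likelihood is non-decreasing across iterations.
Motif significance is reported as the log-likelihood ratio against the
background-only model; no E-value analogous to external motif programs is
computed — planted-recovery tests stand in for calibration.

**Scanning.** At most one hit per window (the ZOOPS assumption). The best
log-odds offset is reported iff its exact per-position p-value — the
probability under the 0-order background of a score at least as high at a
single position — is below the threshold (default 1e-10, exposed as a
parameter since relaxed secondary-hit thresholds are plausible). The
p-value comes from dynamic programming over the score distribution with
per-column scores discretized at 0.01 bits (configurable); brute-force
enumeration over all 4^W windows reproduces it exactly for small W.

**Alu enrichment.** Observed = mean count of repeat intervals overlapping
the real windows (≥ 1 bp). Null = the same-size window set placed
uniformly at random over the genome (windows fully inside a contig,
contigs weighted by placeable length), repeated n_perm times;
p = (1 + #{null mean ≥ observed}) / (n_perm + 1). The null is genome-wide
uniform, not GC- or chromatin-matched — a deliberate simplification; on
real genomes Alu's GC association makes a matched null stricter.

## Correlation clustering and outliers

Zeros in single-cell 5′-tag profiles are mostly dropout, so pairwise
Spearman correlation is computed on *complete pairs* (features nonzero in
both cells), with mid-ranks; pairs with fewer than 30 complete
observations (configurable) are undefined. P-values use the
t-approximation, Bonferroni-corrected over the pairs tested in the run.
The coefficient matrix rows are clustered by complete linkage on Euclidean
distances (undefined entries imputed as 0 with a warning). Outlier
exclusion replaces multiscale-bootstrap cluster support with a plain
bootstrap consensus: features are resampled with replacement B = 100
times, the matrix re-clustered and cut at k = number of stages, and a cell
flagged if it joins the cluster holding the majority of its own stage's
other cells in fewer than 70% of resamples. Stages with a single cell are
never flagged (no majority exists). This is simpler than approximately
unbiased p-values but tests the same instability notion and is exactly
reproducible.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions the analysis assumes:

* **stage design**: oocyte (12 cells, 100,000 poly(A) molecules/cell) and
  4-cell (12 cells, 25,000 molecules/cell) — per-division halving over two
  divisions; 8-cell stages use 12,500.
* **genome**: one contig, one gene per 7 kb slot (alternating strands),
  three exons, CDS for coding genes (80% by default), plus eight dedicated
  spike contigs with fixed relative abundances.
* **expression**: per-gene lognormal weights (σ = 1); per cell, molecule
  counts are multinomial over the stage budget, so per-cell totals never
  exceed the budget. Activated genes sit `fold` (default 8) below their
  active level until their activation stage.
* **degradation**: a per-stage fraction (default 0.3 after the oocyte —
  the literature does not pin this rate separately from dilution, so it is
  an explicit free parameter) of maternal molecules has its 5′ end moved
  downstream by a geometric draw (mean 300 nt in transcript coordinates,
  clipped at the transcript end), producing internal-exon/CDS/3′UTR tags.
* **capture**: each molecule is observed with probability 0.1 (binomial);
  spike-in wells contain 1,000 molecules split over 8 species, giving
  ≈ 100 spike tags/cell — comfortably above the 50-read QC floor.
* **planting**: activated-gene promoter windows receive Poisson(2.0)
  Alu-like 300-bp repeats; the rest of the genome receives 1.1 repeats per
  2,500 bp of non-promoter sequence. One motif instance (sampled from a
  12-bp PWM at ≈ 1.5 bits/column) is written into each activated promoter,
  inside a planted repeat when one exists.

The generator emits alignments (tags) directly: read sequences, sequencing
errors, barcode errors and PCR duplicates are not modelled, and tags are
jitter-free (intact molecules land exactly on the TSS). Consequently,
passing tests demonstrate the statistical machinery — normalization
geometry, rank-test calibration, FDR control, motif recoverability,
enrichment calibration — not robustness to alignment artefacts, capture
biases along transcripts, or real Alu sequence structure. Real-mode
ingestion (BAM/SAM/BED) is provided separately and rejects reads
soft-clipped by more than 3 bases at the 5′ end, since such clips shift
the inferred start.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere in memory; GTF (1-based
  closed) converts at the I/O boundary only.
* Determinism: every stochastic step takes a seed or `numpy` Generator;
  fixed seed ⇒ byte-identical text outputs, which the manifest (parameter
  echo + input checksums) makes auditable.
* Validation problem sizes (`strt_ega.validation`) were chosen as the
  smallest designs at which the planted effects are unambiguous: 500
  features with 30 planted 8-fold activations at n = 12 vs 12 for the DE
  study; 20 genes × 24 cells for TSS recovery; 60 windows / 40 sites for
  motif recovery; 50 promoters for enrichment; 10 seeds for the
  stochastic studies.

## Known limitations

* No conversion to absolute molecule numbers per cell (needs spike
  molarity bookkeeping beyond tag counts).
* The division correction assumes synchronous, exact divisions; embryos
  with uneven blastomeres violate D as an integer.
* Wilcoxon with n = 12 vs 12 cannot detect activation in fewer than ~3
  cells of a stage (mosaic activation); the rank statistic saturates.
* The Bonferroni family for correlation significance is the per-run pair
  count; cross-library families would need explicit pooling.
* Motif identity (which factor binds) is out of scope: the finder reports
  the PWM, not a database assignment.
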
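# Methods

## The analysis in one paragraph

Dimethyl sulfate (DMS) methylates unpaired adenosines and cytosines in RNA;
a processive reverse transcriptase converts the adducts into cDNA
mismatches, so the per-base mismatch rate of a DMS-treated sample reads out
pairing status. This package turns treated/untreated mismatch pileups into
normalized per-base reactivities, summarizes the structure of each 3' UTR
as the average Gini index of 50-nt reactivity windows, and asks whether
structured 3' UTRs are associated with lower expression (RPKM) and shorter
half-life — the structure-mediated-decay (SRD) hypothesis. A synthetic
generator produces probing data with known ground truth so every stage is
testable without sequencing data.

## Reactivity calling

* **Raw reactivity** r_i = m_i / c_i, the mismatch count over coverage at
  base i. Positions below a coverage floor are masked, not errored
  (default floor 100 for deep single-target amplicon libraries, 20 for
  transcriptome-wide data where coverage is thinner).
* **Background correction** r'_i = max(0, r_treated − r_untreated).
  Subtraction with a floor at zero is the dominant convention in probing
  analysis; a division mode (treated/untreated ratio, masked where the
  control is zero) is available via `background_method="divide"`.
* **Normalization** divides by the median of the top ⌈5%⌉ of
  background-corrected values and caps at 1.0. The order is fixed as
  *correct → normalize*, and the top-5% set is always computed on corrected
  values. Normalization refuses profiles with fewer than 20 usable
  positions; an all-zero profile normalizes to all zeros with a warning.
* Normalization scope is per transcript; for transcriptome-wide (3'-end
  anchored) data the profile is sliced to the 3' UTR before normalization
  so the scale factor is local to the region being scored. This keeps
  profiles comparable across genes with different modification efficiency.
* Properties that hold by construction: values in [0, 1]; the maximum is
  exactly 1 whenever any corrected value is positive; scaling the input by
  k > 0 leaves the output unchanged. Renormalizing a normalized profile is
  an exact identity when the top-5% set has odd size (the median is then the
  capped mid value, 1.0); for even sizes the median of the top pair can fall
  slightly below 1 after capping, so idempotence holds only up to the cap.
* Mismatch counting from BAM/SAM uses primary, uniquely mapped records only
  (NH tag when present, MAPQ > 0 otherwise). Coverage counts aligned read
  bases — deletions do not contribute — and N bases on either side are
  excluded from both coverage and mismatch counts. Indels themselves are
  never counted as mismatches. Replicates are merged by summing counts.

## Windowed Gini index

The Gini index of a window's reactivities,
G = Σ_i Σ_j |x_i − x_j| / (2 n² x̄), measures how unevenly the DMS signal is
spread: pairing concentrates reactivity on the few unpaired A/C bases, so
structured windows score high. Implementation uses the sorted-rank identity
(O(n log n)); tests pin it to the pairwise definition at 1e−12.

* Windows are 50 nt with a 25-nt step; only full windows are emitted, so a
  region of length L yields ⌊(L−50)/25⌋+1 windows.
* A window is trusted only if its mean raw mismatch count over *all*
  positions exceeds 20. Averaging counts over all bases (not only A/C) is
  the plain reading of a count-based filter; the choice is exposed through
  `mismatch_threshold` if a different convention is wanted.
* The Gini itself is computed over unmasked A/C positions only — G/U carry
  no DMS signal and their structural zeros would deflate the index. An
  all-base mode is available (`ac_only=False`).
* Windows whose included values are all zero have an undefined Gini; they
  are emitted with NaN and never enter the per-transcript average. The
  average Gini is the unweighted mean over passed windows; a transcript
  with no passed window has a missing average and is dropped (and counted)
  before classification.

## Meta-gene profile and codon periodicity

Transcripts with ≥100 nt of CDS before the stop codon and ≥100 nt of 3' UTR
after it are aligned on their stop codons; the per-position mean of
unmasked normalized reactivities and the per-position nucleotide frequency
are reported. The stop codon's own three positions belong to neither flank
mean. The CDS-vs-UTR contrast is a two-sided rank-sum test on per-transcript
flank means. Codon-position means are anchored at the stop codon on the CDS
side and at the first base downstream of it on the UTR side.

## Constraint export

`export_constraints` writes the SHAPE-convention two-column file (1-based
position, reactivity; −999 for masked positions and for G/U) for use by an
external thermodynamic folding engine. Folding itself is out of scope here:
the analysis consumes reactivities, not energies.

## Association analyses

* **Decile classes**: exactly ⌊0.10 n⌋ genes in the top and bottom classes,
  ties broken by transcript id (type-7 quantile behaviour at the
  boundaries; ≥/< median membership for the covariate splits). The same
  operation labels Gini classes (high/low), half-life classes (long/short),
  and log2 ratio keys.
* **Group comparisons**: two-sided Wilcoxon rank-sum or two-sample
  Kolmogorov–Smirnov via scipy, with per-group median/quartiles and ECDF
  tables exported for cumulative curves.
* **Correlation**: Pearson R of average Gini against log10(RPKM + 1e−6).
  Whether published scatter analyses used log expression is rarely stated;
  log is the defensible default for lognormal-ish RPKM and is flagged in
  the output name.
* **Stability**: genes can be restricted to average Gini > 0.4 before the
  half-life comparisons (`gini_threshold_filter`); the threshold is a
  parameter, default 0.4.
* **Confounders**: GC content (N-free percentage), poly(A)-tail length and
  UTR length are stratified at the sample median (≥ median = high stratum)
  and the high/low-Gini expression contrast is re-run per stratum; strata
  with fewer than 2 genes of either class are reported as not evaluable.
  miRNA-target overlap uses Fisher's exact test on the 2×2 class-by-flag
  table.
* **RG4 prediction**: four G-tracts of ≥3 Gs separated by 1–7-nt loops,
  matched greedily left-to-right without overlap (the quadparser pattern;
  loops may contain G). The tract length is configurable (2 or 3). RNA mode
  scans the forward strand; DNA mode also reports C-tract (reverse-strand)
  sites. The test oracle is an independent hand-written backtracking
  matcher, not the same regex.
* **Decay fits**: least squares on ln(abundance) vs time, t½ = ln 2 / k.
  Fits need ≥3 timepoints including t = 0 and positive abundances; a
  non-positive k yields t½ = NaN with a warning rather than a bogus number.
* No multiple-testing correction is applied; each comparison is a single
  primary test and all p-values are reported so a user can correct as
  needed.
* Enrichment of the structured design level in the high- vs low-Gini class
  is reported as P(level | high) / P(level | low) with a 0.5-count
  continuity correction, so an empty cell gives a finite fold.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_genes | 300 | two structure levels × 150 genes, enough for decile classes of 30 |
| utr_length_range | 150–300 nt | typical plant 3' UTR lengths; ≥2 full windows |
| pairing_fraction_levels | 0.1, 0.7 | poorly vs highly structured contrast |
| dms_rate_unpaired | 0.05 | per-read modification probability of unpaired A/C, the few-percent regime of DMS mutational profiling |
| dms_rate_paired | 0.005 | small leak onto paired A/C (breathing, incomplete protection) |
| background_error | 0.002 | untreated mismatch rate (RT/sequencing error); unstated in probing studies, exposed in config |
| mean_coverage | 3000 | 3'-anchored libraries concentrate reads on short windows; keeps the >20-mismatch filter satisfiable at rates of ~1% |
| three_prime_bias | 0.5 | coverage c(i) = mean·((i+1)/L)^bias rises toward the poly(A) site; 0 recovers uniform coverage |
| expression slope | −2.0 (log RPKM per pairing unit) | ~3-fold median contrast between the levels, visible above lognormal noise (sd 0.5) |
| half-life slope | −1.0 (log hours) | structured UTRs decay faster; baseline 4 h with sd 0.3 |
| polya_median | 80 nt | matches the median used for the tail-length split |

Structures are *constructed*, not folded: hairpin stems of 4–8 pairs with
≥3-nt loops are placed in an unpaired scaffold until the pairing fraction is
within ±0.05 of the target, deterministically per seed. An unreachable
target raises an error naming the maximum achievable fraction (e.g. 0.8 at
20 nt). Paired positions carry complementary bases so the sequence is
consistent with the structure; the stop codon is pinned to UAA and kept
unpaired. The CDS gets its own constructed structure (default pairing 0.7)
so the meta-gene CDS/UTR contrast has a ground truth. Mismatch counts are
Binomial(coverage, p) with p = background everywhere, plus the unpaired or
paired DMS rate on A/C in treated samples. Covariates are log-linear in the
UTR pairing fraction with Gaussian noise on the log scale; slopes are
constrained to ≤ 0 (0 disables the coupling and is used by the null
control). Poly(A) length is lognormal around 80 nt, independent of
structure unless a coupling slope is set; miRNA-target flags are Bernoulli
(0.3) independent of structure.

What the generator does **not** emulate: read-level effects (FASTQ, RT
drop-off, indels), pseudoknots and long-range pairs, protein footprints,
sequence composition biases, or the correlation structure of real
transcriptomes. Passing tests therefore demonstrate that the *pipeline*
recovers the relationships it assumes when they are present and stays null
when they are absent — not that those relationships hold in any particular
real dataset.

## Numerical and design choices

* All coordinates are 0-based half-open on the transcript; exported BED is
  0-based half-open; constraint files are 1-based. Minus-strand annotation
  features are flipped into transcript coordinates on input.
* All randomness flows through `numpy.random.default_rng` seeded from a
  single `SimConfig.seed` via `SeedSequence.spawn`, so identical config +
  seed reproduce byte-identical outputs.
* `classify_deciles` requires n ≥ 10; `correlate` requires ≥3 finite pairs
  and reports NaN for degenerate variance; `gini` raises for n < 2,
  negative values, or a zero mean, and window scoring converts that into a
  skipped window, never a crash.
* No 1.5×IQR outlier trimming is applied before normalization by default;
  it is relevant only as a pre-step for structure modelling and can be done
  upstream if desired.
* Problem sizes in the analysis drivers and the acceptance script (300
  genes for the association runs, 160 for the monotonicity sweep, 25–50
  seeded null runs) were chosen so the whole analysis reruns in well under
  a minute per stage on a laptop while keeping decile classes of ≥16 genes.

## Known limitations

* The simulator's binomial mismatch model has no overdispersion; real
  libraries show extra-binomial variance, so real-data p-values would be
  less crisp than the synthetic ones.
* The Gini-over-A/C-only convention and the all-base mean-mismatch filter
  are documented choices where the field's descriptions are ambiguous; both
  are switchable.
* Published gene counts tied to specific deposited datasets (numbers of
  high/low-Gini genes, genome-wide RG4 site totals, replicate correlation
  coefficients) require those accessions and are intentionally out of scope;
  the pipeline reproduces the *direction and significance structure* of the
  analysis on synthetic data instead.
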
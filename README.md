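# utr-structurome

Do structured 3' UTRs destabilize mRNAs? This package implements the
genome-scale analysis needed to ask that question from chemical probing
data: it calls per-base DMS reactivities from mismatch pileups, scores the
secondary-structure content of each 3' UTR with a sliding-window Gini
index, and tests whether structure is inversely associated with transcript
expression and half-life (structure-mediated RNA decay, SRD). A synthetic
probing-data generator with known ground truth makes the whole pipeline
verifiable without any sequencing download.

It is written for computational RNA biologists working with DMS mutational
profiling (DMS-MaPseq-style) or 3'-end-anchored probing data in plants or
elsewhere.

## The model in brief

DMS methylates unpaired A and C; a processive RT turns adducts into cDNA
mismatches. For each base, raw reactivity is r_i = m_i / c_i (mismatches
over coverage); the untreated control is subtracted (floored at 0) and the
profile is scaled by the median of its top 5 % of values, capped at 1.

Structure per 3' UTR is summarized by the Gini index of 50-nt reactivity
windows (25-nt step, windows averaging ≤ 20 raw mismatches discarded):

G = Σᵢ Σⱼ |xᵢ − xⱼ| / (2 n² x̄)

Paired regions concentrate reactivity on few bases ⇒ high G; open regions
spread it evenly ⇒ low G. Genes are classified into the 10 % highest /
lowest average-Gini classes and compared by Wilcoxon rank-sum (RPKM),
Pearson R (Gini vs log₁₀ RPKM), and Kolmogorov–Smirnov (Gini between
half-life deciles), with GC / poly(A) median-split stratification, RG4
scanning and first-order decay fits (t½ = ln 2 / k) as supporting analyses.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (each regenerates what it needs deterministically):

```bash
python analysis/01_simulate_probing_data.py
python analysis/02_call_reactivities.py
python analysis/03_score_structure_gini.py
python analysis/04_expression_stability_association.py
python analysis/05_null_control.py
```

Output of the scoring and association steps (seed 1, 300 genes simulated
at 3' UTR pairing fractions 0.1 and 0.7):

```
mean avg Gini by simulated pairing level:
               count   mean
pairing_level
0.1              150  0.129
0.7              150  0.536

300 genes associated; outputs in results/association
  rank-sum RPKM high- vs low-Gini: p = 1.69e-09 (medians 14.8 vs 45.2)
  Pearson R(avg Gini, log10 RPKM) = -0.755 (p = 1.14e-56)
  KS on Gini between half-life deciles: p = 1.69e-17
  high-Gini class enrichment for structured genes: 61.0-fold
```

Read: the window Gini cleanly separates the two simulated structure levels
(0.13 vs 0.54); the 10 % most structured UTRs belong to genes with ~3-fold
lower median expression and shorter half-lives, recovering the inverse
structure–expression/stability association that the generator encodes. The
null control (script 05) repeats the run with the coupling switched off and
finds the same tests non-significant in ~95 % of seeded runs.

The same stages are available as a CLI (`utr-structurome simulate /
reactivity / gini / metagene / associate / rg4 / decay / run`) and as
library functions (`utr_structurome.analyze_dataset` for the in-memory
end-to-end path).

## Layout

```
src/utr_structurome/   library: simulate, reactivity, metrics, association,
                       io, config, pipeline, cli
analysis/              numbered drivers reproducing the study on synthetic data
tests/                 pytest suite incl. property-based acceptance tests
scripts/acceptance.py  headline-number recomputation
docs/methods.md        models, parameters, conventions, limitations
```
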
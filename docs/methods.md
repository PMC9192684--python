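# Methods

`efficow` implements the computational chain of a dairy-cow
feed-efficiency proteomics study as a reusable, tested pipeline: score
and classify cows by residual feed intake, quantify proteins from
peptide intensities, call differentially abundant proteins between
efficiency groups, test annotation-term enrichment, and compute ΔΔCt
qPCR relative expression. A seeded synthetic-data generator provides
ground-truthed inputs for every stage.

## Feed-efficiency scoring

Energy-corrected milk normalises milk yield to a standard energy
density:

    ECM (kg/d) = milk · (0.3887·fat% + 0.2356·protein% + 0.1653·lactose%) / 3.1338

Predicted dry matter intake follows the NRC (2001) form with
herd-calibrated coefficients:

    pred DMI = [0.36·ECM + 0.123·BW^0.73] · (1 − e^(−0.22·(DIM/7 + 5.67)))

Residual feed intake is mean actual minus mean predicted intake over a
35-day window, computed from **per-day** predictions and then averaged,
so body-weight and DIM drift within the window is honoured. Coefficient
tables for this equation often print the lag rate as d = −0.22 inside
`1 − e^(−d·x)`; taken literally this gives a negative factor, so the
package stores the positive magnitude and computes
`1 − exp(−0.22·(DIM/7 + 5.67))`, the only reading that yields a (0,1)
early-lactation ramp.

Classification sorts cows by RFI ascending and labels the
`floor(0.2·N)` lowest-RFI cows HEF (high efficiency — they eat *less*
than predicted) and the same number of highest-RFI cows LEF. ECM/DMI is
reported per cow but does not participate in classification; ties at
the quantile boundary break by ascending cow id. `regression_rfi`
offers the classic alternative — residuals of an OLS fit of intake on
ECM and metabolic body weight (BW^0.75) — for herds without calibrated
prediction coefficients.

## Label-free quantification

Peptide intensities are scaled per sample so every sample's total ion
current equals the **median** raw TIC (robust to one outlier sample;
the reference is a convention, since any common target gives the same
relative abundances). Zeros and empty cells in input files are treated
as *missing*, never as measured zeros, and nothing is imputed.

Protein abundance is the Top-3 (Hi-3) estimate: the arithmetic mean of
the protein's three most abundant peptides, or of all its peptides when
only one or two were detected. Ranking is **global** — by each
peptide's mean intensity across all samples — so every protein uses one
fixed peptide set in all samples; this stabilises between-group ratios
relative to per-sample ranking, which is available behind
`--top3-per-sample` for sensitivity analysis.

PCA QC runs on complete-case proteins (any protein with a missing value
is excluded), centered per protein but not unit-scaled, since log2
intensities already share a scale; variance-explained percentages sum
to 100 over all components.

## Differential abundance

Group means and fold changes are computed on the normalized raw scale
(ratio of arithmetic means, case/control), while the test is a
two-tailed equal-variance Student t on log2 abundances; both scales are
kept per row. Fold changes use the signed display convention: a ratio
r ≥ 1 is +r, a ratio below 1 is −1/r, so |FC| ≥ 1 always and the
r = 1 fixed point maps to +1.

A protein is called differentially abundant (DAP) when p ≤ 0.05 **and**
|FC| ≥ 1.5, both boundaries inclusive. No multiple-testing correction
gates the call; a Benjamini–Hochberg column is emitted for downstream
filtering. Proteins with fewer than two observed values in either group
are kept with status `untested` so the enrichment background still
spans the full quantified universe.

The volcano ranking statistic ("pi-score") is defined here as
`−log10(p) · log2FC` — the standard significance×effect product; a p of
exactly 0 is capped at the smallest positive double before the log.
The heatmap export z-scores each DAP row (ddof = 1) across samples;
zero-variance rows export as zeros with a warning.

## Enrichment

Term over-representation among DAPs uses the upper-tail hypergeometric
probability P(X ≥ k) with N = background size, K = term members in the
background, n = DAPs, k = annotated DAPs, followed by BH adjustment
across tested terms. The default background is the quantified-protein
universe (the set actually testable in the experiment) rather than a
whole genome; it is a parameter because published tools differ. Terms
with fewer than two background members are skipped and reported.
Depletion testing is out of scope. `category_fractions` produces
pie-chart-style per-term coverage percentages of an id set; terms
overlap, so percentages need not sum to 100.

## qPCR relative quantification

ΔΔCt assumes perfect per-cycle doubling (efficiency 2, no correction):
per sample, ΔCt = Ct(target) − Ct(reference), raw RQ = 2^(−ΔCt), and
the final RQ divides by the control group's mean raw RQ, making the
control mean exactly 1 by construction. Subtracting the reference gene
cancels sample-wise loading shifts. Technical replicates are averaged
on the Ct scale before analysis. The reference gene is the candidate
with the smallest SD of raw Ct across all samples — a deliberately
simple stability metric; geNorm/NormFinder-style pairwise metrics are
out of scope. Group comparison reuses the equal-variance t-test on
log2(RQ), reporting means on the RQ scale.

## Synthetic-data generators

All generators are pure functions of their config (seed included) and
emit truth tables alongside the data; the truth is never consumed by
the pipeline under test.

- **Herd** (default 155 cows, 35-d window, DIM 80–140, BW 590±35 kg,
  milk 47±5 kg/d, fat 3.05%, protein 2.98%, lactose 4.91%): each cow
  gets a persistent intake offset (SD 2.0 kg/d) — the true RFI — and
  daily intake noise (SD 1.0 kg/d, a realistic day-to-day residual for
  mid-lactation cows on a uniform ration); daily DMI = predicted + offset
  + noise.
- **Proteome** (default 2,260 proteins, geometric peptides-per-protein
  with mean 8 truncated to 1–30, 5 vs 5 samples): log-normal protein
  abundances, per-peptide response factors, per-sample TIC shifts, and
  a spiked subset of 43 up- and 58 down-regulated proteins with |FC|
  log-uniform on [1.5, 80]. Within-group CV defaults to 20%, a typical
  biological+technical spread for label-free tissue proteomics.
  Missingness (rate 0.1) is intensity-dependent (left-censored-like),
  because label-free MS preferentially drops low-abundance peptides;
  set it to 0 for clean oracle tests. True fold changes act at the
  protein level, so all of a protein's peptides shift together.
- **Annotations**: random GMT terms over the protein universe plus one
  designated term whose members are sampled with configurable odds
  toward the spiked set (odds 1 = null).
- **qPCR** (default 5 vs 5, Ct noise 0.2 cycles — typical replicate
  spread after averaging, loading shift SD 0.3 cycles): target Ct
  values encode configured true case/control ratios (defaults 0.37,
  0.78, 1.03, 0.77) under perfect doubling; candidate reference genes
  are generated at distinct stability SDs with GAPDH the most stable.

What the generators do **not** emulate: shared peptides between
proteins, retention-time or spectrum-level structure, correlated
protein modules, batch effects, and non-Gaussian Ct error. Passing
recovery tests therefore demonstrates correctness of the computational
chain under the stated generative assumptions, not robustness to every
artefact of real acquisitions.

## Numerical and design choices

- Logs are base 2 wherever user-visible; t statistics are base-invariant.
- Missing ≠ zero everywhere; `log_transform` rejects non-positive
  abundances rather than silently dropping them.
- BH adjustment is the standard step-up (via statsmodels), clipped at 1.
- Hypergeometric tails use the survival function at k−1 (inclusive ≥ k).
- Classification tie-break, reference-gene tie-break (lexicographic) and
  mergesort-stable sorts make every output deterministic; the pipeline
  manifest records SHA-256 hashes of all outputs so reruns are
  verifiable byte-for-byte.
- Problem sizes in the test suite use scaled-down generators (tens of
  cows, hundreds of proteins) where the property under test is
  size-independent; full defaults (155 cows, 2,260 proteins, 100 qPCR
  seeds) are exercised in the acceptance suite and script.

## Known limitations

- The equal-variance t-test is the study convention; no
  moderated/empirical-Bayes variance shrinkage, so power at n = 5 vs 5
  is limited for small fold changes.
- RFI here ignores parity, lactation stage beyond the DIM lag, and
  repeated-measures structure; it is a window summary, not a genetic
  evaluation.
- The SD-based reference-gene criterion can be fooled when sample
  loading variation dominates gene-specific stability.
- Enrichment treats terms independently; no term hierarchy or
  redundancy pruning.
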
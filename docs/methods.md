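# Methods

## Measurement model

A protein with PARylation occupancy s ∈ (0,1) contributes two SILAC
channels. The light channel is the boronate-enriched pull-down from L μg of
light lysate: with enrichment efficiency e and nonspecific carryover
fraction f_ns of the unmodified pool, its retained fraction is
e·s + f_ns·(1−s). The heavy channel is an unenriched digest of H μg of
heavy (PARP-inhibited, unmodified) lysate. For a peptide with ionization
response φ from a protein of relative abundance a, the noiseless peak areas
are

    A_H = g · a · φ · H
    A_L = g · a · φ · L · (e·s + f_ns·(1−s))

with g the detector response (`area_scale`, peak-area units per μg per unit
abundance). In the clean limit (e = 1, f_ns = 0) the heavy/light ratio is
r/s with r = H/L, which is what the estimator inverts:

    s_r = r / median_peptides(A_H / A_L),   s = median_r(s_r).

Medians are used at both levels because the per-peptide ratio distribution
is heavy-tailed in practice; the even-count median is the mean of the two
middle values. The estimator is scale invariant (any common rescaling of
areas cancels) and strictly decreasing in the measured H/L median.

## Titration design

The default four-point design (1:2000 = 5 μg : 10 mg, 1:800 = 12.5 μg :
10 mg, 1:200 = 100 μg : 20 mg, 1:50 = 200 μg : 10 mg) spans occupancies
over more than three decades while keeping at least one SILAC pair of each
protein inside the detector's dynamic range (~5000). Mix points where a
channel fell out of range are simply absent from the cross-point median;
nothing is imputed. Ratios are heavy/light everywhere.

## Detector model (simulation)

Two independent causes make a channel missing, both decided on the
*noiseless* area so the rules are exact and monotone: (i) an absolute
floor — area < noise_floor × snr_detect_min (defaults 1.0 and 3); (ii) a
relative limit — the channel is the minor peak of its pair and
major/minor > dynamic_range (default 5000). Reported S/N is area divided by
noise_floor. Reported areas carry independent multiplicative lognormal
noise with coefficient of variation `ratio_cv` (default 0.2), parameterised
median-preserving (σ² = ln(1+cv²), no mean correction) so that per-peptide
H/L ratios — and hence the median rollup — are median-unbiased.

## Synthetic-data defaults and what they emulate

* occupancies log-uniform over 0.01%–35.5% — the observed span of the
  modification; only the span is constrained by data, the log-uniform shape
  is a convention;
* abundances lognormal (σ = 1), per-peptide ionization factors lognormal
  (σ = 0.5), 4–12 Lys-C peptides per protein, each ending in the single
  labeled lysine (C-terminal non-Lys peptides would be SILAC-silent and are
  not generated);
* `area_scale` = 100 per μg puts typical peptides at S/N 10¹–10⁴,
  Orbitrap-like, so detection losses concentrate where they belong: minor
  peaks at extreme ratios and low-abundance proteins at the lowest mix
  point.

The generator starts at integrated peak areas: no m/z, isotope envelopes,
retention times, identification errors, missed cleavages, shared peptides
or protein-inference ambiguity. Passing tests therefore validate the
estimation arithmetic and its robustness to multiplicative noise and
censoring — not the upstream identification/quantification software. Seeds
are split per stage (CRC-derived child streams), so tables are bytewise
reproducible per (config, seed, replicate label).

## Filtering

Defaults: both channels present with S/N strictly > 5 ("both" mode; an
"either" mode is selectable), protein on the curated reference list,
site-carrying peptides excluded. Duplicate observations of one sequence are
separate ratio contributions. Attrition is logged per rule, first failing
rule wins. Filtering is idempotent.

## Replicates and reporting

Default merge is union-mean: a protein seen in any replicate is reported,
its value the arithmetic mean of replicate finals; intersection-mean and
pooled-median are available. The reproducibility report carries the overlap
count and the Pearson correlation of log10 occupancies on the overlap of the
first two replicates. Values are fractions internally and percent in every
output. Estimates above 100% are flagged (`exceeds_one`), never clamped —
they are calibration alarms. `sparse_peptides` flags a protein whose
contributing mix-point median somewhere rests on a single peptide, a choice
made here since no convention exists; `single_mix_point` marks estimates
without cross-ratio confirmation.

## Nonspecific binding

In the 1:1 control the heavy channel is pure carryover, so per protein
control_hl = f_ns/(e·s + f_ns·(1−s)). With e = 1 (supported by the
two-round depletion check: remaining signal (1−e)^k, fitted by a
through-origin log-scale least-squares slope with Student-t intervals) the
product control_hl × s_obs identifies f_ns, and
s = (s_obs − f_ns)/(1 − f_ns) inverts the contamination exactly. The
correction is off by default — the raw estimator is the reference — because
subtracting the carryover amplifies noise where s ≪ f_ns: in the bundled
analysis (f_ns = 2%, cv = 0.2) the corrected median relative error is a few
percent for s > 2% but ~80% below it. Control rows need a passing light
channel only; an absent (or sub-threshold) heavy peak contributes a ratio
of 0, since "no detectable heavy" is the informative outcome. The e ≠ 1
correction algebra has no closed form and is out of scope.

## Enrichment and clustering

Foreground = one occupancy bin, background = the whole analysed list
(never the proteome: the question is what distinguishes heavily from
lightly modified proteins *within* the modified set). p = P(X ≥ k) for
X ~ Hypergeom(N, K, n), computed by scipy; enrichment calls use raw
p < 0.05 (strict) with optional Benjamini–Hochberg behind a flag, off by
default to mirror common list-enrichment practice. Bin boundaries: an inner
edge belongs to the interval it opens (0.1% → "0.1–0.5%"); the top group is
strictly above its edge, so exactly 1.0% falls in "0.5–1%". The x-matrix
sets non-enriched cells to 0 to stay complete for Euclidean distances.

Single-linkage clustering is implemented directly (O(n³), n = enriched
terms, typically tens): at each step the pair at minimum single-linkage
distance merges, ties broken by the lexicographically smallest pair of
cluster representatives (each cluster's smallest member id), and leaves are
ordered by depth-first traversal visiting the smaller-representative
subtree first. This makes the dendrogram a pure function of the matrix
rows, invariant to their order; library implementations reproduce the merge
heights (cross-checked in the tests) but not a documented tie-break.

## Problem sizes

The bundled analyses and validation runs use 300-protein cohorts with two
replicates (~20k peptide observations), 200-protein cohorts for the
contamination study, and exhaustive hypergeometric checks over populations
up to 20 — sizes chosen so every claim is recomputed from scratch in
seconds while leaving the estimator nothing to hide behind: exactness is
asserted at machine precision in the clean limit and accuracy
distributionally under noise.

## Known limitations

Protein-level only (no site-level occupancies); protein identifiers are
taken as given (no inference/razor logic); no vendor-format parsers (the
TSV schema is the contract); annotations are a flat table (no ontology
propagation); the enrichment test is a plain hypergeometric, not the
EASE-penalised variant some services use.
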
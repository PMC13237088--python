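# Methods

## Coordinates and formats

All coordinates are 1-based inclusive internally ("native1"), matching the
BED-like TSV convention the package standardises detector outputs into
(`protein_id<TAB>start<TAB>end[<TAB>method]`, no header).  Standard 0-based
half-open BED ("bed0") is converted at the I/O boundary only.  Method labels
resolve as: explicit argument > 4th column > filename stem.  Regions are
deduplicated but never merged implicitly — raw tool outputs may legitimately
overlap, and merging is an explicit operation.  Regions extending past a
sequence end are an error, not clamped.  Ambiguity codes (X, B, Z, U, O) are
kept as ordinary symbols so length arithmetic is never perturbed; the pooled
amino-acid composition is reported over the 20 standard residues.

## Complexity metrics

For a segment of length L:

* **Shannon entropy** −Σ f·log₂ f over observed residue frequencies, no
  pseudocounts; ceiling log₂(20) ≈ 4.32 bits for uniform usage.
* **Dominance** (y-axis): frequency of the most frequent residue × 100;
  count ties broken lexicographically.
* **Purity** = dominance / 100; hence purity·100 + homorepeat distance = 100
  exactly.
* **Mutational distance to a perfect repeat** (x-axis): for each period
  p = 1..⌊L/2⌋ positions are partitioned by (pos−1) mod p, each phase class
  receives its most frequent symbol as consensus (ties lexicographic), and
  mismatches are counted; the minimum over p (smallest p on ties) is
  reported, with a partial terminal unit allowed.  The ⌊L/2⌋ bound
  guarantees at least two (possibly partial) copies of the repeat unit.
  Because period 1 is admitted, x ≤ 100 − y: the complexity triangle.

Two x-axis variants are exposed, because they genuinely differ: the
min-over-periods distance and the period-1 (homorepeat) distance.  The
worked 10-mer ACDEFEGEIE has homorepeat distance 60% but period-4 distance
40%.  The min-over-periods variant is the default for the LC diagram; the
choice is a parameter (`x_metric`) everywhere it matters.  A caveat worth
knowing: for short windows the min-over-periods metric is biased low — at
periods near L/2 each phase class holds ~2 positions, of which one always
matches consensus — so uniform-random 20-mers land just under x = 50
(long-tandem-repeat zone) rather than in the high-complexity corner that the
homorepeat metric puts them in.  The operational LCR rule is unaffected
because it also requires dominance > 50%.

**Dominant tandem motif**: over unit lengths 1–3, the unit whose maximal run
of at least two exact tandem copies covers the largest sequence fraction
(ties: shorter unit, then lexicographic; no repeat anywhere falls back to
the dominant residue).  Units are reduced to primitive form ("AA" → "A") so
homopolymers do not also count as di-/tripeptides.  A region is classed
Mono-/Di-/Tripeptide when the covered fraction reaches 0.5, else Other.
This tandem-coverage rule is one reasonable operationalisation of
regular-expression motif counting; the threshold is a parameter.

**Triangle zones** use strict inequalities at the operational 50%/50%
thresholds (LCR: x < 50, y > 50; LTR: x < 50, y < 50; HCR: x > 50, y < 50);
exact-boundary points are UNDEFINED rather than silently assigned.

## Reference annotation

Windows of 20 residues at step 10 start at 1, 11, 21, …; if the final
residue would otherwise be uncovered, one right-anchored full-length window
is appended, so C-terminal LCRs are never systematically missed.  Proteins
shorter than the window are scanned as a single whole-protein window rather
than skipped, avoiding a silent bias in true-negative counts.  Passing
windows (mutation % < 50 and dominance % > 50, strict) are merged into
maximal regions; residue-level results are identical whether or not the raw
windows are merged, but region counts are only meaningful for the merged
form.

## Interval algebra and summaries

Merging unites overlapping and bookended intervals (end+1 = next start, the
1-based-inclusive equivalent of half-open abutment).  The multi-way
intersection partitions covered residues into maximal runs of constant
method membership; each run carries its consensus level k (method+mode
configurations, not base tools).  Jaccard similarity is residue-level
intersection over union pooled across proteins, 0 when the union is empty.

Bin-boundary ownership: printed labels such as "0–10, 10–20" overlap at
their edges, so bins are implemented left-open/right-closed — (0,10],
(10,20], … for lengths and coverage (coverage 0 falls in the first bin) and
[1,5], [6,10], [11,15], [16,∞) for per-protein counts.  This changes which
bin boundary values land in and is therefore stated prominently.

## Evaluation

Residues are labelled by reference and prediction, pooled, and counted into
TP/FP/FN/TN; TPR and FPR are exact ratios, reported as missing (never 0)
when a denominator vanishes.  Stratifications: (1) gene-length deciles —
stable sort by (length, id), contiguous groups differing by ≤ 1 in size,
larger groups at the short end; (2) reference-LCR count per protein, 1–6
with ≥ 6 pooled into the top stratum and zero-LCR proteins excluded;
(3) reference coverage of the protein in right-closed bins at 5, 10, 15,
20, > 20%; (4) LCR-to-gene entropy ratio in right-closed bins 0.2 … 1.0,
ratios above 1 clamped to the top bin and zero-entropy proteins excluded.
Within a stratum residues are pooled by default; per-protein averaging is
available behind a flag.  Mean TPR/FPR per method are unweighted means over
strata.

## Boundary estimation

The binned estimator counts labelled points into Δ = 2% half-open bins
(⌊v/Δ⌋, with the 100 edge closed into the last bin so no one-point bin row
exists) and applies the smoothed frequency ratio with pseudocount a = 1,
keeping every bin probability strictly inside (0,1); with a = 0 it reduces
to the empirical frequency where defined, and growing a pulls every bin
monotonically toward ½.  ROC analysis uses the P ≥ t rule over thresholds =
sorted unique scores ∪ {0,1} on a held-out split (stratified 50/50 by
default, fixed seed); t\* maximises Youden's J with ties going to the
smallest threshold.  Contours are extracted by marching squares with linear
interpolation on the grid of bin centers.

The smooth estimator is a tensor-product cubic B-spline logistic model
(8 uniform knots per axis over [0,100]) with an L2 roughness penalty whose
strength is selected by 5-fold cross-validation; it is an analog, not a
replica, of a penalised-regression-spline GAM.  Its contract: probabilities
strictly in (0,1), continuity on the evaluation grid, and recovery of a
planar logistic surface within tolerance when the data come from one.

## Synthetic data

The generator emulates exactly what the analyses need: background sequence
(uniform over 20 residues by default; a human-like composition preset exists
for realism but is arbitrary, not measured), planted homorepeats and tandem
repeats with i.i.d. per-residue substitution noise at a stated rate, and
pseudo-methods with planted sensitivity, false-discovery rate and boundary
jitter.  It does **not** emulate real proteome features — domain structure,
length/composition correlations, the clustering of LCRs at termini, or the
correlated errors of real detectors — so passing tests demonstrate the
correctness of the machinery, not field performance of any detector.
Randomness flows from one integer seed through independently spawned
child streams (background, placement, features), so adding a feature never
perturbs unrelated draws and outputs are byte-identical across runs.

Problem sizes used by the default test run and the acceptance script —
250-protein proteomes with 500 planted 20-residue homorepeats, 60,000-point
boundary clouds, exhaustive oracle enumeration over 3-letter sequences up to
length 8 — were chosen so every check closes in seconds while keeping
binomial error bars (3σ ≈ 5% at n = 500) well inside the asserted
tolerances.

## Known limitations

* TPR/FPR measure agreement with the operational reference definition, not
  biological truth; a region can satisfy the compositional rule without any
  functional role, and vice versa.
* The min-over-periods x-axis is length-biased for short segments (see
  above); cross-length comparisons should fix the window length, as the
  window pipeline does.
* The binned boundary estimator needs dense sampling (tens of points per
  occupied bin) before its Youden threshold stabilises; the smooth surface
  is preferable in sparse regimes.
* The motif classifier counts exact tandem copies only; degenerate repeats
  are the business of dedicated repeat detectors and are out of scope.
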
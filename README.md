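# lcrbench

Protein **low-complexity regions** (LCRs) — homorepeats, tandem repeats and
compositionally biased stretches — are detected by many tools whose outputs
disagree substantially.  `lcrbench` is the tool-agnostic machinery for
comparing such detectors: it characterises sequence segments in a two-axis
complexity space, builds an operational reference annotation, quantifies
multi-method consensus and similarity at residue resolution, scores
predictions by residue-level TPR/FPR, and estimates probabilistic boundaries
of low-complexity sequence space.  It is aimed at anyone benchmarking or
combining LCR detectors; the detectors themselves (SEG, fLPS, T-REKS, …) are
deliberately outside its scope — their predictions enter as plain BED-like
TSV files.

## The model

Every sequence segment is placed in the **complexity triangle**:

* *y* — **compositional dominance**: the percentage of the segment made of
  its most frequent amino acid;
* *x* — **mutational distance to a perfect repeat**: the minimal percentage
  of residues that must change for the segment to become an exact periodic
  repeat (for each period *p*, phase classes get their consensus residue and
  mismatches are counted; the period-1 case is the homorepeat of the
  dominant residue, so *x* ≤ 100 − *y* always).

The operational reference annotation scans each protein with 20-residue
windows at step 10 and keeps windows with mutation % < 50 and dominance
% > 50, merging overlaps.  Predictions are compared against it per residue
(TP/FP/FN/TN → TPR = TP/(TP+FN), FPR = FP/(FP+TN)) under four protein-level
stratifications.  The probabilistic LC boundary discretises the (x, y) plane
into Δ = 2% bins, estimates P(LC | bin) = (n⁺+a)/(n⁺+n⁻+2a) with a = 1,
selects the operating threshold t\* by maximising Youden's J = TPR − FPR on
held-out points, and extracts the contour P = t\*.  A tensor-product spline
logistic fit provides a smooth-surface alternative to the binned estimator.

A synthetic-data module generates proteomes with planted homorepeats and
degenerate tandem repeats plus pseudo-methods of known sensitivity, so the
whole pipeline closes against planted parameters without any downloads.

## Worked example

```python
>>> from lcrbench import profile_segment
>>> p = profile_segment("ACDEFEGEIE")
>>> p.dominant_residue, p.dominance_pct
('E', 40.0)
>>> p.homorepeat_mutation_pct
60.0
>>> p.mutation_pct, p.best_period
(40.0, 4)
```

E is the most frequent residue (4 of 10 → dominance 40%), so 60% of residues
would have to mutate to reach the poly-E homorepeat; allowing any period, a
period-4 consensus needs only 40%.  With dominance below 50% this segment is
not low-complexity under the operational rule.

From the shell, the same pipeline end to end:

```sh
lcrbench simulate --n-proteins 20 --seed 5 -o sim/
lcrbench annotate --fasta sim/proteome.fa -o sim/reference.tsv
lcrbench evaluate --fasta sim/proteome.fa --reference sim/reference.tsv \
    --pred sim/pseudo.tsv --stratify gene_length_decile -o sim/metrics.tsv
```

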
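# plantmir

Supervised prediction of plant microRNAs from short candidate sequences.

Mature plant miRNAs are 20–24 nt RNAs excised from a precursor that folds
back on itself into a stem-loop, pairing the miRNA with its partner strand
(the miRNA\*).  Deep-sequencing predictors lean on read counts, which rules
out genomic and EST input.  `plantmir` instead requires only that the
candidate occurs somewhere in a sequence window large enough to hold its
precursor: everything else — the location of the star partner, the folded
precursor, and the attributes fed to the classifier — is computed from the
sequence itself.  It is aimed at people triaging candidate small RNAs from
genomes, ESTs or sliding-window scans before committing to wet-lab
validation, where false positives are expensive.

## Method

For a candidate *m* at a known offset in context *C*:

1. **Star discovery.** Search a 300-nt window on the chosen side of *m*
   (star upstream or downstream) for the subsequence with the strongest
   antiparallel hybridization to *m* (the miRNA:miRNA\* duplex), at least
   3 nt away from the candidate.
2. **OPR.** The *operative precursor region* is the span between and
   including candidate and star plus 15-nt flanks — an equal-treatment
   stand-in for the annotated precursor, computable for positives,
   negatives and unknowns alike.  The OPR is folded to a dot-bracket
   structure with minimum free energy ΔG.
3. **Attributes.** 29 numeric features: candidate base composition and
   length-normalized Shannon entropy; duplex energy (raw and per-column),
   longest mismatch run, minimum match percent; OPR ΔG (raw and
   length-normalized), longest paired/unpaired runs and loop-head count;
   chromosome length/position ratio; and 14 derived sums and ratios.
4. **Classifier.** C4.5-lineage decision trees (gain-ratio splits at
   midpoint thresholds, pessimistic pruning at confidence factor 0.25)
   boosted with AdaBoost.M1; optional misclassification costs bias the
   decision toward few false positives, and prediction ties resolve to
   not-miRNA.
5. **Validation.** Sensitivity = 100·TP/(TP+FN) and specificity =
   100·TN/(TN+FP) under leave-one-out cross-validation in which every
   sequence >70% similar to the held-out case (global alignment identity)
   is excluded from training too, plus systematic taxon-exclusion runs.

Negative controls are segments sampled from the central regions of ESTs,
matched to the positives' length distribution, rejected if they contain
ambiguity codes or fall outside the positives' entropy band, and scored on
one randomly chosen orientation.  Unknowns are always scored on both
orientations and called miRNA if either side is positive.

Energetics go through a pluggable contract: the default is a deterministic
built-in base-pair-maximization model (Watson–Crick −1.0, G:U wobble −0.5,
−1.0 per stacked pair, hairpin loops ≥ 3 nt); an adapter to the ViennaRNA
`RNAfold`/`RNAduplex` executables provides full nearest-neighbour
thermodynamics when they are on PATH.

## Worked example

`python examples/02_train_and_validate.py` builds a seeded synthetic
benchmark (60 hairpins with planted duplexes, 120 EST segments), trains
and validates:

```
benchmark: 60 positives, 120 negatives
exclusion sets: 6 sequences have a >70%-similar partner
LOOCV (full): sensitivity 98.3%, specificity 100.0%  ConfusionCounts(tp=59, fp=0, tn=120, fn=1)
  exclude cladeA: 20/20 held-out miRNAs recognized (100%)
  exclude cladeB: 20/20 held-out miRNAs recognized (100%)
  exclude cladeC: 19/20 held-out miRNAs recognized (95%)
```

Sensitivity is the share of held-out true miRNAs the model recognizes,
specificity the share of EST segments it correctly rejects; the per-clade
lines show that a model trained with a whole taxon withheld still
recognizes that taxon's miRNAs.  `examples/01_extract_attributes.py`
prints one candidate's attribute vector, and `examples/03_scan_de_novo.py`
recovers a planted miRNA from an unseen precursor by sliding-window
scanning.

A `plantmir` command exposes the same pipeline from the shell
(`simulate`, `extract`, `negatives`, `train`, `validate`, `scan`,
`predict`); run `plantmir --help`.

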
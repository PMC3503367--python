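# Methods

This note documents the models, parameter choices and numerical
conventions behind `plantmir`, including the places where the design was
genuinely open and a choice had to be pinned.

## The operative precursor region

All candidates — positive controls, negative controls and unknowns — are
treated identically: no annotated precursor is ever consulted beyond
declaring, for positive controls, which half of the precursor the mature
sequence sits in.  The star partner is the subsequence of the search
region with the minimum duplex energy against the candidate; the operative
precursor region (OPR) is `[min(candidate, star) − flank, max(candidate,
star) + flank)`, clipped at the context boundary.

* **Search window, 300 nt (`PipelineConfig.search_window`).**  The window
  is anchored at the candidate's far edge and extends 300 nt in the star's
  direction, so candidate + loop + star must fit within 300 nt.  The
  window size reflects how strongly plant precursor lengths concentrate
  below 300 nt (the synthetic benchmark reproduces this: ~95% of its OPRs
  are shorter than 300 nt).  A centered window was the main alternative;
  the directional anchor was chosen because the side of the star is an
  explicit input everywhere the window is used.
* **Minimum candidate–star gap, 3 nt (`min_loop_gap`).**  The universal
  minimal hairpin loop.  Without it the best "star" is frequently a
  self-adjacent overlap.
* **Flank, 15 nt (`flank`).**  Padding on both sides of the
  candidate–star span before folding.
* **Tie-breaking.**  Equal-energy stars resolve to the smaller gap from
  the candidate, then the smaller start coordinate.  Shorter OPRs resemble
  real precursors more closely, and determinism is non-negotiable for
  reproducibility.

Coordinates are 0-based half-open internally; only user-facing reports
(scan hits, FASTA positions) are 1-based.

## Energy model

Energetics are a contract (`fold`, `duplex`, `model_name`) with two
implementations.

The **built-in model** is a deterministic base-pair-maximization scheme:
Watson–Crick pairs contribute −1.0, G:U wobble pairs −0.5, and each pair
directly stacked on another pair earns a further −1.0; hairpin loops
shorter than 3 nt are forbidden.  Folding is a Nussinov-style dynamic
program over three matrices (any structure / paired ends / unpaired ends)
so the stacking bonus is exact; hybridization is an intermolecular
alignment DP (no intramolecular pairs) with the same pair scores, +0.5 per
bulged base on either strand, free region overhangs, and a two-state
(stacked / not) column history.  A duplex must reach energy < 0 to count;
otherwise the candidate has no star on that side.  Bulge columns are
recorded as unpaired (`.`) in the duplex column string, so the
longest-mismatch-run attribute absorbs bulges — mismatch and bulge are not
distinguished.

The built-in model is not a thermodynamic parameterization: its virtue is
that it is exactly reproducible, fast, and simple enough to verify against
brute-force enumeration (the test suite does both).  The **ViennaRNA
adapter** shells out to `RNAfold`/`RNAduplex` for full nearest-neighbour
energetics with the same interface; its duplex column strings are
reconstructed from the query-side structure only.  Swapping models changes
no other code.

Duplex normalization: `DuplexEnergyNorm` divides by the number of
alignment *columns* (not strand length); `minMatchPercent` divides the
paired-column count by the *longer* strand.  Both conventions are pinned
because "duplex length" is ambiguous between columns and strand length.

## Attributes

29 features per candidate-orientation pair (names are the exact table
headers): `chromLen/position`, `ShannonEntropyNorm`, `G%`, `C%`, `T%`,
`A%`, `DuplexEnergy`, `DuplexEnergyNorm`, `MaxMismatch`,
`minMatchPercent`, `DeltaG`, `DeltaGnorm`, `longestDotSet`,
`longestBracketSet`, `loopCountNorm`, plus 14 derived combinations (sums,
ratios, composition over entropy, `NormEnergyRatio`,
`longestBracket/longestDot`).

* Shannon entropy is computed in bits over the 4-letter alphabet and
  divided by sequence length.  The log base and the normalization are a
  recorded convention, not inferred from data.
* Composition and entropy describe the candidate; structure statistics
  describe the OPR; `longestDotSet`, `longestBracketSet`, `loopCountNorm`
  are raw runs divided by OPR length.
* Any ratio with a zero denominator — and `chromLen/position` when the
  genomic position is unknown — carries a dedicated missing marker,
  serialized as `?`.  Zero is a legal value and never stands in for
  missing.
* U is mapped to T on input; IUPAC ambiguity codes disqualify a sequence
  (controls) or skip the window (scans) rather than being masked.

## Controls

**Positives** are located on their source by exact match (both strands)
and scored on their declared side only.  The side is inferred, when a
precursor is available, from whether the candidate's 5′ end lies in the
5′ half — a positional rule that is knowingly wrong for sufficiently
asymmetric precursors, which is exactly why unknowns are evaluated on both
sides.  Unlocatable or duplex-less records are skipped with a log entry.

**Negatives** are sampled from ESTs under quantified qualification rules:

* *Central region*: the segment plus half the search window must fit on
  each side, guaranteeing both orientations have a full search region.
* *Length matched*: segment lengths are drawn from the positives'
  empirical length distribution.
* *Entropy band*: the segment's normalized entropy must lie within the
  positives' observed [min, max] (a percentile band would be stricter;
  min/max is the simplest testable reading and is what is implemented).
* One orientation per segment, fair coin.  EST-hosted candidates use the
  EST's length and in-EST position for `chromLen/position`.

Sampling is a single seeded RNG stream with a fixed draw order, so a seed
reproduces the negative set bit-for-bit; a capped attempt budget (200 per
requested control) turns an impossible request into an explicit
pool-exhausted error.

## Similarity and exclusion

Similarity is percent identity of a global Needleman–Wunsch alignment
over its full length, gaps included: match +5, mismatch −4, gap 10 for
the first column and 0.5 per additional column, end gaps free.  DNA
scoring has no conservative substitutions, so identity and similarity
coincide; this is a recorded interpretation.  Among score-optimal
alignments the one with the most identities (then the shortest) defines
the value — this makes similarity deterministic and exactly invariant
under argument swap and joint reverse complementation, at the price of
being a pinned convention rather than "whatever one aligner happens to
report".

Exclusion sets are pairwise and deliberately non-transitive: A excludes
exactly the sequences >70% similar to A.  Clustering (single-linkage
style) would allow two dissimilar sequences to ride in one cluster and,
worse, similar sequences to land in different clusters; pairwise sets
cannot leak that way.  Positive and negative pools are aligned separately.

## Classifier

C4.5-lineage induction: at each node, every attribute is scanned for
binary threshold splits at midpoints between consecutive distinct known
values; admissible splits need information gain > 0 and ≥ `min_cases`
(default 2) weighted cases per branch; the split with the best gain ratio
wins (ties: higher gain, lower attribute index, lower threshold).  Grown
trees are simplified by pessimistic-error pruning: a subtree collapses
when the Clopper–Pearson upper confidence bound (confidence factor 0.25)
on its error as a single leaf does not exceed the sum over its leaves.

Divergences from C4.5/C5.0, all deliberate:

* **Missing values** are excluded from the gain computation and routed
  whole to the heavier branch, instead of C4.5's fractional cases.
  Deterministic and adequate at 29 attributes.
* **Rule-set generation** and multi-class support are out of scope.
* **Boosting** is textbook AdaBoost.M1 (not C5.0's undocumented variant):
  zero-error trials keep their tree at a capped vote weight and stop;
  a trial with weighted error ≥ 0.5 is discarded and stops boosting,
  except that a first such tree is kept at unit weight so a model always
  exists.  Vote weight is ln((1−ε)/ε).
* **Confidence** is the predicted class's share of total vote weight;
  the reference implementation's confidence formula is undocumented, so
  this definition is declared, not claimed identical.
* **Costs** act at prediction time: the label minimizes expected cost
  under the ensemble's class-probability estimate; exact ties go to
  not-miRNA, encoding the preference for few false positives.
* **Attribute importance** is leave-one-attribute-out retraining (the
  withheld column is treated as entirely missing), reported as the
  percentage-point increase in training error.  Redundant attributes
  score near zero under this measure; it is a coarse overall view, not a
  causal decomposition.

A note on XOR-type interactions: with an exactly class-balanced two-bit
XOR, both marginal splits have information gain exactly 0 and the
admissibility rule leaves the root unsplit.  This one-level blindness is
inherent to greedy gain-based induction; any class imbalance breaks the
tie and the tree then fits XOR with two levels.

Induction is deterministic; the training seed is recorded metadata.  Tree
growth shares one presorted index table per attribute across all nodes,
trials and cross-validation folds, which is what makes full leave-one-out
(~1500 retrainings on the default benchmark) run in about a minute.
Models serialize to JSON with sorted keys; identical data, seed and
parameters give byte-identical files.

## Validation

Leave-one-out: each case is predicted by a model trained on every case
not in its exclusion set.  A grouped fast mode trains once per block of
identical exclusion sets (default above 200 cases, recorded in the
report); fold hygiene is unchanged because cases in one block share their
training set exactly.  A fold whose training set lacks a class raises
rather than silently degenerating.  Group exclusion holds out one
taxonomic group at a time — negatives are held out alongside their
group's positives to prevent leakage through shared source sequence (the
alternative, keeping all negatives, is defensible but leakier; this
choice is recorded).  Reports carry the per-group error count, total,
percent correct and percent of the full set excluded.

## Synthetic benchmark

The generator emulates the structure of the training data, not its
biology: positives are random mature sequences (20–24 nt, GC fraction
0.45) with a planted star — the reverse complement carrying 0–4
substitutions — separated by a 4–30 nt loop inside 40–120 nt flanks;
negatives are i.i.d. sequence ESTs of 400–1200 nt at the same GC
fraction.  Negatives are plain random sequence rather than shuffled
positives or hard structural decoys: the study design trains against
broad, unbiased non-miRNA sequence.  Species and taxon labels are
assigned round-robin (6 species, 3 clades) so group-exclusion runs are
exchangeable by construction.

What passing tests on this benchmark shows: the pipeline finds planted
duplexes exactly, its attributes separate planted hairpins from random
sequence, and the validation machinery is leak-free and deterministic.
What it does not show: performance on real genomes, where negatives are
not i.i.d. (repeats, tRNA/rRNA, real stem-loops), where the energy model
matters quantitatively, and where miRNA families create heavy similarity
structure.  Accuracies on the synthetic benchmark (≈98–99%
sensitivity/specificity at 500/1000, seed 42) are therefore a
verification result, not a claimed real-data accuracy.

Problem sizes used by the shipped experiments: the default benchmark is
500 positives / 1000 negatives with grouped leave-one-out (~1500
training runs); the de novo scan experiment plants 10 fresh precursors
(~10,000 windows, both orientations each).  These sizes exercise every
code path at full fidelity while keeping a complete rerun in the
minutes range on one CPU.

## Numerical conventions

* Traceback value matching uses an absolute tolerance of 1e-9; all DP
  scores are multiples of 0.5, so this is exact in practice.
* Composition percentages must sum to 100 within 1e-9; similarity
  matrices are symmetric within 1e-9 with exactly 100 on the diagonal.
* The pessimistic-error bound uses `scipy.special.betaincinv(e+1, n−e,
  1−cf)`, the Clopper–Pearson upper limit; for e = 0 it reduces to the
  familiar `1 − cf^(1/n)`.
* The zero-error vote-weight cap is ln(1e10).
* Degenerate inputs: sequences too short to pair fold to the open
  structure at energy 0; an empty admissible-split set yields a majority
  leaf (prediction ties to not-miRNA); a segment pool that cannot satisfy
  the negative-control request raises after a capped number of attempts.

## Known limitations

* The built-in energy model ranks structures by pairing, not by real free
  energy; absolute ΔG values are not comparable to thermodynamic tools
  (use the ViennaRNA adapter for that).
* Mismatches and bulges are conflated in duplex statistics.
* Positive-control side inference fails on asymmetric precursors exactly
  as positional rules must; dual-orientation evaluation of unknowns is
  the mitigation, not a fix.
* Whole-chromosome scanning works but is not speed-optimized; windows are
  evaluated independently with no seed-and-extend shortcuts.
* `winnow_importance` understates attributes with redundant partners.
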
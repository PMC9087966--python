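# Methods

## The model

Archaeal transcription initiation depends on two basal factors binding the
core promoter: the TATA-box binding protein (TBP), which recognizes an
AT-rich wTTATwww element near −25, and transcription factor B (TFB), which
contacts the short GC-containing BRE element immediately upstream of the
TATA-box.  Because A:T pairs contribute less duplex-stabilizing free energy
than G:C pairs, this neighbourhood is the least thermodynamically stable
stretch of the core promoter and can be detected from sequence alone.

`archaeoprom` encodes a sequence as a **DNA duplex stability (DDS)
profile**: a sliding dinucleotide window assigns each adjacent base pair
doublet its nearest-neighbor duplex free energy ΔG°37 (kcal/mol).  The
packaged default table is the unified nearest-neighbor ΔG°37 parameter set
(values from −2.24 for GC to −0.58 for TA); it is Watson–Crick symmetric,
so profiles of reverse complements are mirror images.  Alternate tables can
be supplied as two-column text files; they must contain all 16 dinucleotides
with finite negative values, and symmetry violations are warned about but
tolerated.

## Coordinates and corpus handling

Promoter coordinates put the TSS at +1 with no position 0, so −80..+20 is
exactly 100 nt.  TSS-centered source records (1001 nt, TSS at index 501)
yield the core promoter at source indices 421..520.  Three engineered
negative sets stress a classifier:

* **shuffled** — a uniform permutation of the core's letters;
* **downstream** — the +21..+120 window of the source record.  The natural
  reading "+21 to +121" would span 101 positions; we trim to 100 nt so
  negatives match the positive length;
* **blocks** — the core is cut into 20 blocks of 5 nt and 12 randomly
  chosen blocks are permuted among their positions with contents intact
  (an alternate mode shuffles letters *within* the chosen blocks instead).
  At least 8 blocks always stay in place, so local motifs frequently
  survive — this is the deliberately hardest control.

All generators conserve mononucleotide composition exactly and are
bit-reproducible under a fixed seed.

## The interval classifier

The per-sequence statistic is the **sum** of the 7 dinucleotide energies
over a position-specific 8-nt slice of the core promoter.  The default
slice sits at −32..−25, covering the BRE extremity and the TATA-box; a
gapped variant (2 nt BRE + skipped 2-nt spacer + 6 nt TATA, concatenated
before encoding) is available behind a flag.  Fitting computes the
promoter-set mean x̄ and sample standard deviation σ (n−1 denominator) and
sets the closed classification interval [x̄ − σ, x̄ + σ]; a sequence is a
promoter iff its statistic falls inside.  Both boundary conventions
(closed interval, sample sd) are pinned because tests depend on them.

Two consequences worth knowing:

* in-sample recall equals the empirical ±1σ coverage of the statistic,
  roughly 68–87% depending on the distribution's shape — an interval
  classifier cannot reach perfect sensitivity by construction;
* widening σ grows the predicted-positive set monotonically (recall
  non-decreasing, specificity non-increasing).

A fitted model can be applied unchanged to another organism's sequences
(cross-organism transfer); nothing is refitted.

## The neural classifier

The 7 slice energies feed a 7-input, 2-hidden, 1-output perceptron with
logistic activations, trained by resilient backpropagation with weight
backtracking (rprop+) on the sum-of-squared-errors E = ½Σ(o − y)².  Each
weight keeps a private step size, multiplied by η⁺ = 1.2 while its partial
derivative keeps sign and by η⁻ = 0.5 (with the previous update undone)
when it flips; steps start at 0.1 and are capped at 50.  Training stops
when the largest partial derivative drops below 0.01 or after `max_steps`
full-batch iterations (default 200,000); on non-convergence one restart
with a derived seed is attempted before reporting `converged=False`.
Weights initialize uniform(−0.5, 0.5) from the seeded generator, inputs are
fed raw (the default table's values already lie in a narrow bounded range),
and an error trace is logged every 1000 steps so the training trajectory
can be inspected.  Evaluation uses stratified k-fold cross-validation
(default k = 10; stratification guarantees both classes in every fold on
small sets) with test predictions pooled into one confusion matrix, plus
ROC curves over a decision-threshold grid with guaranteed endpoints at
thresholds 0 → (1, 1) and 1 → (0, 0).

## Metrics

Accuracy, precision, recall and specificity from the four-cell error
matrix.  A metric with a zero denominator returns NaN with a warning —
never a silent 0 — and percent formatting (two decimals) happens only at
the presentation layer.

## Annotating upstream regions

Fixed-length upstream regions (RSAT-style, 400 nt per gene) carry no TSS
annotation.  We treat the 3' terminus as +1 — archaeal transcripts are
frequently leaderless, so upstream regions abut the functional start —
and evaluate each model either at its own slice coordinates (`anchored`,
default) or at the window with the maximal DDS sum inside a search region
(default −50..−15; `scan` mode), ties broken toward the TSS.  A region is
annotated as a promoter only if every model in the panel votes promoter
(logical AND; `min_votes` relaxes this).  High-GC organisms' models should
be excluded from mixed panels since their promoter statistics sit far from
low-GC organisms'.  Because AND-consensus is monotone, adding a model can
only shrink the accepted set; with any interval classifier in the panel
the overall sensitivity is capped by its ±1σ coverage (see above), so
panels of neural models are preferable when sensitivity matters.
Kruskal–Wallis rank tests (midranks, tie correction, χ² approximation on
k−1 df) compare positional mean profiles of accepted vs verified sets over
a configurable region (default −40..−1); the degenerate all-identical case
returns H = 0, p = 1 with a warning.

## The synthetic generator

Synthetic corpora emulate the study conditions: i.i.d. background letters
with P(G) = P(C) = gc/2 and a planted IUPAC element, by default
`SSTTATAWWW` (2-nt BRE + TATA template) at −34..−25 so the default slice
reads the TATA part.  Degenerate letters are instantiated per record, which
gives the positive class realistic within-motif variance; `consensus=True`
freezes them.  Background GC defaults to 0.5, with 0.345/0.507/0.661 used
where the three study organisms' genome GC levels are emulated.  Benchmark
sizes: 500 promoters + 500 controls for recovery experiments, 300 per
training class and 150 regions per class for annotation experiments, with
a 20,000-step rprop cap inside cross-validation (convergence on separable
synthetic data occurs within a few hundred steps; the cap only binds on
deliberately non-separable data such as label-permuted nulls).

What the generator does **not** model: compositional heterogeneity along
real promoters (real cores are AT-rich overall with GC-richer stretches),
dinucleotide autocorrelation, codon structure and repeats.  One measurable
consequence: on real data the block-shuffle control is the *easiest* to
separate (its slice statistics sit furthest from promoters) while the full
shuffle is hardest, because full shuffling of an AT-rich core leaves slices
compositionally promoter-like.  On an i.i.d. background this ordering
inverts — block shuffling retains the intact planted element at the slice
in ≈5% of negatives (the three blocks it spans stay in place with
probability C(17,12)/C(20,12) ≈ 0.049, plus identity-permutation returns),
creating an irreducible lookalike floor, while full shuffles are perfectly
separable.  Passing synthetic-recovery tests therefore demonstrates signal
recovery and calibration, not the real-data control ordering.

## Numerical choices and edge cases

* Sequences are uppercased on ingest and U maps to T; strict mode rejects
  other non-ACGT characters naming the position, `skip` mode marks affected
  profile entries NaN and excludes them from statistics.
* The gradient of the SSE matches central finite differences to 1e-6
  relative error (tested), which pins the backpropagation implementation.
* Stratified fold assignment deals each class's shuffled indices
  cyclically, so fold sizes differ by at most one and every fold holds both
  classes whenever each class has ≥ k members.
* Degenerate interval (σ = 0) accepts only exact-match statistics; ROC
  threshold 0/1 endpoints label everything/nothing promoter.

## Known limitations

Single-strand, fixed-architecture analysis: inputs are assumed
sense-strand; the network is fixed at 7-2-1; no temperature or salt
corrections to the thermodynamics; no multi-interval or per-position
statistical models; site localization in upstream regions is heuristic
(anchored or max-DDS scan), not a motif model.
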
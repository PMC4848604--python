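# Methods

This note documents the models, rules and numerical choices behind
`phagetime`, and what the synthetic-data tests do and do not demonstrate.

## The analysis rules

### Total Count normalization

Each sample is scaled by (mean of per-sample scope totals) / (its scope
total).  The reference is the *mean* (not the maximum or a fixed constant)
so normalized values stay near the raw count scale, which matters because
the downstream exclusion threshold (TGR < 10) is applied on the normalized
scale; values are kept real-valued (no re-rounding) for the same reason.
Normalization is idempotent and never happens in place: a raw integer
matrix and its normalized counterpart coexist, flagged.

Three scopes exist, and the pipeline assigns them per stage:

* **temporal classifier: `phage_only`**, over infected samples only.  Phage
  genes are normalized against each other, so the overall rise of phage
  transcription across the time course (the library fraction ramps from
  ~3% to ~16%) cancels and only each gene's *relative* temporal shape
  remains.  Classifying on whole-library-normalized values instead would
  multiply every phage profile by that ~5-fold ramp, pushing flat
  (constitutive) genes over the 40% margin into the late class — the
  classification would reflect phage take-over, not per-gene regulation.
  The uninfected control carries zero phage reads and takes no part in
  classification.
* **host DE: `host_only`**.  The mirror-image argument: as phage reads
  claim up to ~16% of a fixed-size library, whole-library normalization
  deflates every host gene in late samples by ~0.3 log2, which a ±1.5
  log2FC gate then misreads.  Normalizing host genes against each other —
  the standard dual RNA-seq practice of splitting organisms before
  normalization — removes that compositional artifact.  Whole-library
  (`all_reads`) scope remains available as a parameter.
* **coverage: raw bin counts** are reported (conserving read totals);
  `phage_only` scale factors are available where cross-sample comparability
  of the tracks is wanted.

### Temporal classification

Phase averages are arithmetic means over the samples of each phase group
(early = {2, 5}, middle = {10, 15, 21}, late = {28, 35, 42, 49} minutes —
a configuration, not an inference; the grouping map is an input).  The
percent scaling divides by the peak average *first* and multiplies by 100
after, so the peak is exactly 100.0 in floating point and the margin
(100 − second-highest percent) is exact for ties.  Decision rules, in
order:

1. mean normalized TGR over all nine infected samples < `min_tgr` (10) →
   **excluded** (the control is not included: pre-infection expression
   would conflate the average);
2. margin ≥ `margin_threshold` (40) → the arg-max phase;
3. otherwise **constitutive**.

"Difference of average values between phases below 40%" is read on the
percent scale against the runner-up phase; for the runner-up bound this is
equivalent to comparing against both non-maximal phases.  Exact top ties
give margin 0 and are therefore always constitutive.  Both thresholds are
configurable.  Genes with zero reads everywhere are reported separately
(they are trivially excluded, but flag possible annotation errors).

### Host differential expression

The compound rule takes the log2 fold change with pseudocount 1 added to
both numerator and denominator (the rule's source is silent on zeros; a
fixed pseudocount is the minimal convention, configurable down to 0, where
signed infinities are handled as status-eligible extremes).  The second
gate against the single uninfected control asks whether the control value
lies outside the group mean ± 2 SD, with the SD computed from the test
group's samples only (the control has one replicate, so the group's
dispersion is the only dispersion available) using the n−1 denominator.
Both gates must pass ("and", not "or").  Late-vs-early uses the classic
pooled-variance Student *t* (Welch behind a flag); zero pooled variance
yields p = 1 for equal means and p = 0 otherwise, by documented convention.
No multiple-testing correction is applied by default — the historical rule
uses a raw p < 0.01 — and a Benjamini–Hochberg option is provided off by
default.  Comparisons against the 0-min control rest on a single
unreplicated sample and are susceptible to culture bias; output headers
carry this caveat verbatim.  Tallies are stored full-precision and
formatted only at print time (genome fractions to 2 decimals, up-among-DE
fractions to 1), matching the conventional printing.

### Coverage binning and ncRNA detection

Bins are fixed-width (250 bp default), 1-based: [1, 250], [251, 500], …
Each read goes to exactly one bin — the bin containing its 5′ end (interval
start on +, interval end on −) — so bin totals equal stranded read totals
exactly.

The detector finds maximal runs of per-base depth ≥ `min_depth` (10,
matching the TGR-exclusion scale), merges runs separated by ≤ `merge_gap`
(50 bp), drops runs shorter than `min_length` (100 bp; the shortest
reported ncRNA species is ~103 bp), and removes runs with ≥ 90% of their
bases inside the *union* of same-strand genes.  The union (rather than any
single gene) is deliberate: adjacent co-directional genes whose spacing is
below the merge gap produce one operon-style run that no single gene could
explain.  Detection defaults to the mean late-phase depth (greatest phage
signal), configurable to any sample subset.  The original study reports
its ten novel RNA species without stating detection criteria, so these
thresholds are this package's own, principled but not validated against
the original calls.

Relation labels follow the overlapped *gene's* orientation: the overlapped
segment's midpoint lands in the gene's first, middle or last third of
oriented length → antisense to its 5′ end / middle / 3′ end; several
opposite-strand overlaps → `antisense_multi` with per-gene labels; no
overlap on either strand → `intergenic`, reporting the flanking gene pair.
Reversing a gene's strand provably swaps the 5′/3′ labels for the same
coordinates.

## The synthetic-data generator

The generator emulates the study design: 0-min control + nine infected
time points; 120 phage genes on a 50-kb genome laid out without overlap on
both strands; 500 host genes; temporal classes planted in the published
proportions 92 : 8 : 94 : 147 : 26 (early : middle : late : constitutive :
excluded); a phage read fraction ramping linearly from 3% at 2 min to 16%
at 49 min (zero in the control); host effects of |log2FC| = 2 planted in
the published early/late up/down proportions scaled to 500 genes
(13 early-down, 2 early-up, 15 late-up, 12 late-down); and ten unannotated
transcripts (9 antisense, 1 intergenic), mirroring the reported 9 : 1
split.

**Count model.**  Per sample, the phage/host split of the assigned-read
budget is drawn binomially from the configured fraction curve; within each
organism, reads are distributed multinomially with per-gene
gamma-perturbed weights (gamma shape = the dispersion parameter).
Marginally this is a gamma–Poisson (negative-binomial-like) model;
conditioning on the totals makes count conservation exact (gene reads +
ncRNA reads + unassigned = library size, every sample) and keeps the
realized phage fraction within binomial sampling error of the configured
value — independent NB draws per gene would give the fraction several
times the binomial variance.  `dispersion=None` is the Poisson limit.

**Temporal profiles** are piecewise-constant over the three phase groups —
the classification rule sees only phase averages, so this is the minimal
faithful shape — with the peak phase `peak_fold` (5×) above the
off-phases.  Per-class total activity is rebalanced so summed phage
expression is flat across phases: only then can the configured uptake
curve and the planted block profiles coexist (with an unbalanced mix, the
fixed per-sample phage total redistributes shares toward whichever phase
has few peaking genes, systematically distorting every profile).  A
consequence worth knowing: the few middle-class genes are individually
more highly expressed than average.  Excluded genes get flat weights
calibrated to a normalized mean of ~1.5–6, safely below (but not
degenerate against) the threshold of 10.

**Key defaults** (all `SimConfig` fields): library 500,000 reads/sample
(keeps typical per-gene TGR in the hundreds at desk scale); dispersion
size 100, i.e. ~10% extra-Poisson CV — the replicates emulated are
*technical* replicates drawn from one infected flask, for which ~10% is a
realistic magnitude, and the single-replicate control makes DE recovery
degrade quickly if sample-level noise is pushed toward biological-replicate
levels (~20%+); read length 90 bp; 95% of the library assigned to gene
features, the remainder reported as unassigned; planted ncRNAs 150–400 bp
at ~60× plateau depth, placed so their midpoint sits ≥ 30 bp inside the
targeted gene third and the interval ≥ 31 bp inside the gene (otherwise
their coverage would merge across the ≤ 50-bp gap into a neighbouring
same-strand gene's run and the planted relation label would be ambiguous;
where an end third of a short gene cannot satisfy this, the middle third
is used and recorded as the truth).  Simulated reads lie wholly within
their source feature, so gene coverage ends crisply at gene boundaries —
real read-through past gene ends is *not* emulated.

**What passing tests show — and don't.**  Recovery tests demonstrate that
the implemented rules invert the generator's planted structure under
realistic noise (classes ≥ 90% — measured ≈ 99%; DE sensitivity ≥ 90% /
specificity ≥ 95% — measured ≈ 95–100%; all ten planted ncRNAs within
50 bp).  They do not validate the thresholds against real data: real
time courses have autocorrelated profiles rather than phase blocks,
organism-level compositional drift beyond the simulated ramp, rRNA
carry-over, coverage read-through, and biological (not only technical)
replicate noise.  The published per-gene values cannot be reproduced here
at all — they depend on the deposited reads and the original commercial
mapping — which is why the published class sizes, fractions and tallies
enter this package only as simulation defaults and report-layer arithmetic
checks, never as fitted targets.

## Numerical and degenerate-input conventions

* Percent scaling divides before multiplying (exact 100.0 at the peak).
* bedGraph ↔ internal coordinates are an exact bijection
  ([a, b) 0-based ↔ [a+1, b] 1-based); all internal coordinates are
  1-based inclusive.
* A sample with zero scope total refuses to normalize, naming the sample.
* Empty gene sets classify to an empty table with an all-zero summary;
  zero coverage detects nothing; zero DE calls tally to zeros.
* Determinism: one `numpy` generator seeded from `SimConfig.seed` drives
  all randomness; analysis stages are deterministic, so pipeline reruns
  are byte-identical.

## Known limitations

* The 0-min control is a single replicate; the 2-SD gate borrows the test
  group's dispersion and the package cannot repair the resulting culture
  bias, only flag it.
* The ncRNA detector is a principled stand-in for an unstated procedure;
  its calls on real data should be inspected, not trusted blindly.
* BAM input is out of scope; the interval-table interface expects the
  caller to have resolved multi-mapping (primary alignments only is the
  documented policy).
* Host coverage tracks are not simulated (host analyses are count-based).
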
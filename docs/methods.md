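# Methods

This note documents the models and numerical choices behind `erpartition`,
what the synthetic data generator does and does not emulate, and the
problem sizes used by the test suite and the reproduction script.

## Regulation calling in a pooled single-array design

Each fraction (total RNA, ER RNA) contributes one pooled array per
condition, so there is no replicate-based variance estimate.  Instead the
caller models the spread of the log-ratio M = log2(hypoxia) −
log2(control) as a smooth function of the mean intensity A — the familiar
MA-plot heteroscedasticity of microarrays, where spread decays roughly
exponentially with intensity.

**Trend.** trend(A) is a robust lowess fit of M on A (span 0.3, two
bisquare iterations, `delta` interpolation 0.5% of the A-range for n >
2000).

**Spread.** spread(A) is estimated in two stages:

1. an initial robust scale σ₀(A): the running median of |M − trend(A)|
   over a window of `span/3 · n` nearest neighbours in A, scaled by the
   MAD constant 1.4826.  At the edges the centered window is replaced by
   the nearest full-size window, so the scale does not get noisy exactly
   where the data are sparse;
2. a local-linear lowess smooth (span 0.3, no robust iterations) of the
   squared residuals *winsorized* at 2·σ₀(A), divided by the normal
   consistency constant E[min(Z, 2)²] = 0.9205.

The winsorization bounds the influence of the minority of genuinely
regulated genes (which would inflate the spread and cost sensitivity; the
default simulation plants ~14% regulated genes, well within the breakdown
of a 2-SD cap), while the mean-of-squares core retains near-parametric
efficiency — a plain running median wide enough to be similarly precise
is visibly biased where the noise decays quickly, which mis-calibrates
the z-score tails.  Fitted trend and spread grids are clamped to the
inner [2.5%, 97.5%] A-quantiles and evaluated by linear interpolation
with nearest-value continuation outside: local-linear fits at the extreme
boundary have roughly doubled variance, and extrapolating their slope
would create spurious tail z-scores.  The spread is floored at 1e-6; an
all-zero residual vector is a hard error (the design cannot estimate
variance from identical arrays).

**Calls.** z = (M − trend(A))/spread(A); a gene is *up* iff M ≥ log2(1.4)
and z ≥ 3, *down* iff both negated; thresholds are parameters.  The
expression filter removes genes whose mean intensity over all four
samples falls strictly below the 50% linear-interpolation quantile; ties
at the threshold are kept.  Under the default synthetic conditions the
caller reaches ≈0.96 sensitivity at ≈0.001 false calls, and without
planted effects the |z| ≥ 3 tail is ≈0.004 (Gaussian reference 0.0027).

## Partition groups

Calls from the two fractions are intersected into six sets
(up/down × total-only/intersect/ER-only) over the common expressed
universe; genes filtered in either fraction are excluded from all six.
By construction |up_total| = |up_total_only| + |up_intersect| (same for
down) — the identity behind the familiar 615 = 425 + 190 style of
partition summary.

## UTR features

Coordinates are 0-based half-open throughout; BED12 thickStart/thickEnd
is the CDS span.  The 5′UTR is everything upstream of the CDS in mRNA
orientation (exon-aware; minus-strand transcripts reverse-complemented);
UTRs shorter than 30 nt are excluded from feature analysis rather than
scored.  A uAUG is any ATG trinucleotide in the 5′UTR — no reading-frame
or downstream-stop logic, since raw AUG counts are the feature of
interest and uAUGs need not be functional uORFs.  The AUG score is
uAUG count / UTR length (per nucleotide).  Conservation is averaged over
exactly the exonic UTR genomic positions; track gaps are skipped and do
not enter the denominator (`covered_bases` reports how much was seen); a
zero-coverage UTR raises instead of fabricating a mean.  The default
analysis unit is the transcript, with a gene-centered mode that averages
features over a gene's transcripts.

## Group statistics

**Scheirer–Ray–Hare.** All N observations are mid-ranked jointly; two-way
sums of squares are computed on the ranks and each effect's
H = SS_effect / (SS_total/(N−1)) is referred to chi-square with the
effect's df.  Because MS_total is computed from the realized (tied)
ranks, no separate tie-correction divisor is applied; the classical
correction factor is reported for reference.  Unbalanced designs — the
partition groups are strongly unbalanced — use type-II sums of squares via
least-squares model comparison, which reduces to the classical
decomposition when balanced (locked by an oracle suite agreeing to
1e-12).  Null type-I error at nominal 0.05 is ≈0.046 for a balanced 3×2
with 10 per cell.  Empty cells warn and compute from available cells.
The pipeline's factor construction splits the six-group label into
*location* (total_only / intersect / er_only) and *expression direction*
(up / down); unchanged genes carry no direction and are excluded.

**ANOVA + Tukey.** Classical equal-variance one-way ANOVA with
single-step studentized-range adjusted pairwise contrasts
(statsmodels).  A group whose every contrast is significant and whose
mean exceeds (falls below) all others is flagged `#` (`*`), matching the
boxplot annotation convention for the conservation comparisons.

**Enrichment.** Upper-tail hypergeometric p per term (term genes
intersected with the universe first), minimum overlap 2, BH adjustment
over tested terms, top 10 reported.  The recommended universe is the
expressed-gene set after the 50% filter, not the whole annotation.

## Motif discovery

Sequence-level presence (not site counts) in a positive set versus a
reference set is compared by the one-tailed Fisher exact test (upper
hypergeometric tail).  Matching is single-strand — inputs are mRNA-sense
UTRs — and N satisfies no motif position.  Per iteration:

1. every exact word of widths 4–8 present in the positives is scored;
   during enumeration the ids of sequences containing each word are
   recorded, so any IUPAC candidate's presence count reduces to a union
   of id lists (a class motif matches exactly where one of its exact
   words does);
2. the 100 best words are generalized position-by-position into 2- and
   3-letter classes by hill-climbing on p.  Because the climb adapts to
   the data, a step is accepted only when the improvement survives a
   Bonferroni over the refinement round (candidates tried × seed words);
   accepted steps still strictly decrease p;
3. candidates are compared by E-value: p × n_words × (6·width)^depth,
   where depth is the number of accepted generalization steps, and never
   less than p × candidates actually evaluated.  The depth factor counts
   the implicit search space of the adaptive climb; without it the best
   refined motif on *null* data clears E < 0.05 in ~10% of runs (the
   climb finds accidentally extreme presence tables that a correction
   over only the evaluated candidates does not cover), whereas with it
   null runs report zero motifs ≥98% of the time while planted exact
   words (E ≈ 1e-45 in the recovery experiment) and planted classes
   (`C[A,C,G]GCGC`) are still recovered;
4. if the best E-value beats the threshold (0.05), the motif is reported
   and all its sites are masked with N in both sets; otherwise the search
   stops.

Ties on p or E break lexicographically on the rendered word, making the
search deterministic; a seed parameter exists for interface symmetry
only.  By default the positive sequences are removed from the reference
set.  Per-transcript cis-element burden (`scan`) counts sites, with
overlaps, of the 5′ motif set in the 5′UTR plus the 3′ set in the 3′UTR.

## Synthetic data

The generator emulates the study design, not biology:

* **Expression**: gene baselines N(7, 2) in log2 units; one sample per
  fraction × condition; control = baseline; hypoxia = baseline + planted
  effect ± noise with sd(A) = 0.1 + 1.4·e^(−0.5A) (≈0.4 at A=3 down to
  ≈0.1 at A=11), noise applied to the hypoxia samples of both fractions
  independently.  Effect size 1.5 log2 units with sign and compartment
  set by the gene's group.  Default group fractions follow the
  proportions reported for the real arrays (≈2.9/1.3/2.0% up and
  3.4/1.5/3.1% down of expressed genes; down-intersect assumed at the
  same ~31% overlap rate as up since only the up split is printed),
  remainder unchanged.
* **Transcripts**: one transcript per gene, 1–3 exons (so UTRs can span
  splice junctions), both strands, ~100 transcripts per synthetic contig,
  fixed 300 nt CDS, 80 nt introns.  5′UTRs 60–300 nt at GC 0.6, 3′UTRs
  100–600 nt at GC 0.4.
* **uAUGs**: background sequence is scrubbed of spontaneous ATGs, then
  ATGs are planted at a Poisson rate per nucleotide — 0.012 by default
  (the ATG frequency of random GC-0.6 sequence), lowered to 0.004 in the
  up-intersect group, mirroring the direction of the biological finding.
  The recorded truth is the count in the final emitted sequence.
* **Motifs**: IUPAC words instantiated per insertion; defaults plant
  `CCGCGC` (5′) and `TTTA[C,G,A]AAA` (3′) at probability 0.3 in
  up-intersect versus 0.02 background.
* **Conservation**: N(0, 1) per exonic base (introns and intergenic space
  uncovered, exercising the gap-skipping mapper), +1.0 on the UTR bases
  of up-intersect transcripts.

Not emulated: probe-level effects and RMA, batch effects, multiple
isoforms, correlated pathway structure, realistic k-mer composition of
UTRs, and conservation autocorrelation along the genome.  Passing tests
therefore demonstrate correctness of the pipeline's inference under its
own stated noise model, not performance on real arrays or real UTR
sequence composition.

All randomness derives from one root seed expanded per stage
(`SeedSequence(seed, spawn_key=(stage,))`), and fixed seeds give
byte-identical outputs.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 10⁴ genes for caller
sensitivity/false-call and null-z measurements; 5000 replicates for the
SRH type-I rate (balanced 3×2, 10/cell); all 2×2 tables with grand total
≤ 60 for the Fisher oracle; 10⁴ random sequences for the uAUG oracle;
500 positives vs 2000 reference UTRs (150 nt, 30% planting) for motif
recovery and 100 null runs of 100-of-500 subsets (80 nt) for motif null
calibration; 2000 genes for conservation-shift recovery and 20 runs of
200 genes/group for SRH detection power.  The full suite runs in a few
minutes on one CPU.

## Known limitations

* The spread model assumes unimodal, roughly Gaussian noise per intensity
  stratum; heavy-tailed arrays would need a higher winsorization cap or a
  t-based variant.
* The SRH type-II formulation is one of several in the literature;
  alternatives (type I/III, tie-corrected divisor) give different H for
  unbalanced or heavily tied data.  The choice is locked by the oracle
  tests.
* Motif discovery reports at most one motif per iteration and never
  revisits erased sequence; strongly overlapping motif families are
  reported as one representative.
* The E-value is a Bonferroni-style bound, conservative for wide motifs
  with several generalized positions; very weak class motifs may be
  missed at the default threshold.
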
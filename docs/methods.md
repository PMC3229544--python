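# Methods

This note documents the statistical model, the numerical choices and the
limits of what the synthetic benchmarks demonstrate.

## The probe-level model

The method treats each 25-nt probe as an independent reporter and never
summarizes probe sets.  Its two working assumptions are (i) a probe
informs only about transcripts it matches well — operationalized as a
≥ 22-nt ungapped exact match to the transcript minus strand — and (ii)
probes reporting the same transcript faithfully should show the same
differential-expression behaviour across the experiment.  Inference then
splits into a per-probe part (exact rank tests → H/L/E letters → an
expression string per probe) and a per-transcript part (hypergeometric
over-representation of a transcript's probes inside one string cluster).

### Alignment

A hit requires a contiguous exact match of `min_match` (default 22, range
15–25) nucleotides between the reverse complement of the probe and the
transcript plus strand.  The scanner seeds with a `min_match`-mer hash of
the transcriptome and extends each seed to its maximal window; since any
qualifying match contains such a seed, the scan is exhaustive, and it is
verified against a brute-force all-offsets oracle in the tests.  One hit
is kept per (probe, transcript) pair — the longest match, leftmost on
ties — because only the membership relation feeds the statistics.
Mismatch-tolerant alignment is deliberately not implemented: exact
matching is deterministic, oracle-checkable, and sufficient for the
probe-counting role the alignment plays.  Probes with no hit anywhere are
discarded; `T` denotes the retained count.

### Rank normalization

Each array is normalized independently to relative ranks `rank/T` with
mid-ranks on ties, forcing identical marginals across arrays (the
per-array sum of relative ranks is exactly `(T+1)/2`, ties or not).  All
downstream tests run on these ranks, so any strictly monotone transform
of the raw fluorescence — scanner gain, log scaling — leaves every letter,
string and p-value unchanged.

### Exact rank tests and letters

Group sizes in the target design are 3–5 arrays, so both one-sided
Mann–Whitney tail probabilities are computed exactly by enumerating all
`C(n+m, n)` assignments of the pooled mid-ranked values (at most 252 for
5 v 5); each tail includes the observed statistic.  Ties are handled by
mid-ranking before enumeration, which the normal approximation and
standard exact-distribution shortcuts do not do correctly.  The letter
cut is inclusive, p ≤ alpha (default 0.05), with `H` meaning higher in
the experimental group of the comparison.  Since both exact tails include
the observed point, `p_upper + p_lower ≥ 1`, so `H` and `L` can never
co-fire at alpha < 0.5.

The comparison plan is configurable; the default is the seven-comparison
layout of the study design: knockout vs wild-type at 0 h / 90 min / 24 h
(positions 1–3), wild-type 90 min / 24 h vs naive wild-type (4–5), and
knockout 90 min / 24 h vs naive knockout (6–7).  The string order is a
package convention — any fixed order works, as the downstream statistics
only use string identity.

### Attribution and FDR

For transcript `X` and observed profile `A`: `pAX` is the hypergeometric
upper tail of drawing at least `X^A` of the transcript's `X^T` probes
when `A` probes are sampled without replacement from the `T` retained
ones, evaluated through `scipy.stats.hypergeom` (and verified against
exhaustive subset enumeration in the tests).  The all-`E` profile encodes
"no differential expression anywhere" and is never tested.

The BH family is **all indexed transcripts × all observed non-trivial
profiles**, not just the pairs with overlapping probes.  Pairs with no
overlap have `pAX = 1` and are represented implicitly — they can never be
rejected, but they scale the correction.  This matters at small scale:
every singleton-string record has the identical discrete p-value
`X^T/T`, and adjusting only over emitted records lets a chance excess of
singletons cascade through the step-up rule (in null simulations this
called up to ~29 % of transcripts in occasional runs; with the full
family the null call rate is zero).  BH itself is delegated to
`statsmodels`; the tests check it against an independent step-up
implementation.

A transcript is differentially expressed at a comparison when some
attribution with adjusted p strictly below 0.05 carries a non-`E` letter
there.  When significant attributions disagree on the direction at one
position, the minimal-adjusted-p record decides and the call is flagged
ambiguous.  Genotype-contrast sets (naive difference, consistent,
90-min-only, 24-h-only) are built from the per-position resolved letters
of the three genotype comparisons, which makes the four sets disjoint by
construction even for multi-profile transcripts.  Effect sizes are mean
relative-rank differences of the supporting probes, bounded in (−1, 1);
reliability rankings across genotypes order transcripts by the ascending
product of their adjusted p-values, ties broken by identifier.

### Enrichment and ΔΔCt

Gene-list enrichment is the summed hypergeometric density from the
observed intersection `QT` up to `min(Q, T)`; the universe size is a
required user parameter, since it is a property of the annotation, not of
the data.  Identifiers are compared as given — no ID mapping.  The ΔΔCt
fold change is `2^−ΔΔCt` with amplification efficiency fixed at 2;
efficiency calibration is out of scope.

## The synthetic-data generator

The generator emulates the study conditions: a 6-group design with group
sizes (3, 5, 5, 5, 5, 4); transcripts of 500 nt carrying 9 probes of
25 nt each (reverse complements of distinct windows, so the aligner's
strand logic is load-bearing); optional multi-mapping probes created by
duplicating a window into a second transcript (with flanks broken so
exactly one 25-mer is shared); and decoy probes rejection-sampled until
no 22-mer of their reverse complement occurs anywhere, guaranteeing
discard.

Intensities follow a log-additive model: `log I(p, a) = b_p + bump +
ε`, with a per-probe affinity intercept `b_p ~ N(6, 1)` (log fluorescence
units), Gaussian log-scale noise `ε ~ N(0, noise_sd)` (default 0.25,
i.e. a quarter of the between-probe spread), and planted effects of
`ln2 · log2FC` added to the arrays of the experimental groups of the
planted comparison positions.  The method under test is rank-based, so
only the ordering this model induces matters; the model is a documented
stand-in, not a fitted description of fluorescence physics.

Two generator subtleties are worth knowing:

* **Overlapping comparisons.** The six groups enter seven comparisons, so
  a bump to one group shifts every comparison that group participates in;
  an effect planted "only at position 4" necessarily perturbs position 2
  as well.  The ground-truth ledger therefore records the *realized*
  per-comparison profile (from the planted group-level differences),
  which equals the nominal letters exactly for self-consistent position
  sets such as {1,2,3} (constitutive genotype difference) or {4,5,6,7}
  (hypoxia response in both genotypes).  Benchmarks plant such sets.
* **Rank crossing.** Relative ranks are compositional: planted probes
  moving through the rank scale drag the ranks of unplanted probes they
  cross.  With zero noise this turns infinitesimal rank shifts into
  complete separations, so strongly-DE transcripts can pick up spurious
  secondary letters and rank-saturated probes (already at the top of
  every array) cannot display up-regulation at all.  Real data with
  hundreds of thousands of probes and a small DE fraction sits far from
  this regime; the noiseless tests therefore use symmetric plants, and
  recovery is asserted as "correct letter at every affected position",
  not as exclusivity.

What the synthetic benchmarks do **not** show: behaviour under probe-level
affinity biases that correlate with condition (e.g. GC-dependent
saturation), cross-hybridization, spatial array artifacts, or real
transcriptome redundancy (the simulated multi-mapping rate is token).

## Benchmark characteristics

Computed by `scripts/acceptance.py` and the test suite at the study's
design (200 transcripts × 9 probes, group sizes 3/5/5/5/5/4, 10 seeds; a
scale chosen so the whole suite runs in well under a minute per
experiment batch):

* null experiments (nothing planted): mean fraction of transcripts called
  DE at adjusted p < 0.05 is 0 at the benchmark scale;
* recovery: 20 transcripts planted at |log2FC| = 2 under `noise_sd`
  0.25 are recovered with the correct direction at every affected
  comparison in ≥ 99 % of cases; the noiseless limit yields zero
  direction errors among detections;
* alignment: designed probes always recover their source transcript and
  every decoy is discarded.

## Known limitations

* Exact-match alignment only; the published-aligner behaviour on
  near-exact (1–3 mismatch) probe matches is not reproduced.
* The minimum one-sided p for a 5 v 3 comparison is 1/56 ≈ 0.018: single
  comparisons can never be significant below that, which bounds the
  letter resolution at these group sizes.
* The hypergeometric attribution assumes exchangeability of probes across
  clusters given the partition sizes; correlated probe behaviour within a
  transcript that is *not* expression-driven (e.g. shared sequence
  artifacts) will inflate significance.
* The all-`E` exclusion means transcripts whose probes all agree on "no
  change" are simply absent from the output, not reported as tested
  negatives.
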
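# Methods

`ffpemeth` implements the computational arc of a matched FFPE / fresh-frozen
(FF) targeted bisulfite sequencing comparison: strand-resolved CpG
methylation calling, M-bias ("bowing") diagnostics with a 5′-trim sweep, a
strand-resolved C>T deamination test, on/off-target accounting, and
category-concordance / sensitivity profiling against a replicate-consensus
gold standard.  A directional bisulfite read simulator provides data with
known truth, so every stage is testable at desk scale.

## Coordinate and data model

All internal coordinates are 0-based half-open (BED convention); SAM and
VCF are converted at the I/O boundary.  Methylation calls are
*strand-resolved*: each CpG dyad contributes a forward-strand cytosine
(position of the C, strand `+`) and a reverse-strand cytosine (position of
the G, strand `-`), reported separately, matching single-base genotyper
output.  An optional symmetric-merge operation pools the dyad, but is off
by default, since whether published per-site counts merged strands is
generally not knowable from the outside.

## Methylation calling

A read contributes at a site only if it is primary, not a duplicate, has
mapping quality ≥ 30, its bisulfite strand matches the cytosine's strand,
the base lies outside the trimmed read ends (5′ and 3′ trims default 5 bp),
and base quality ≥ 20.  On the original-top (OT) strand, C counts as
methylated and T as unmethylated at a forward cytosine; on the
original-bottom (OB) strand the stored-forward evidence is G (methylated) /
A (converted) at a reverse cytosine.  Any other base counts as "other" and
does not enter coverage.  The bisulfite strand comes from a SAM tag (`XB`)
when present; otherwise it is inferred from the directional-library flag
rule (mate 1 ∧ forward) ∨ (mate 2 ∧ reverse) ⇒ OT.  A tag contradicting the
flags wins, with the discrepancy logged.

Mate overlap is counted once: the base from the mate with the higher base
quality at that position is used, ties going to mate 1.  Category
thresholds are strict at both ends — proportion < 0.20 is hypo-methylated,
\> 0.80 hyper-methylated, and the closed interval [0.20, 0.80]
intermediate — keeping the three-way partition exhaustive.  The base
quality minimum of 20 aligns with the Phred < 20 trimming such data
receives upstream; it is not separately standard for calling, and is
exposed as a parameter.  Sites with zero informative coverage are absent
from the profile rather than emitted with an undefined proportion.

## The simulator

The generator emits a random reference with CpG-enriched target regions,
paired-end 125 bp directional (Lister-type) reads in SAM, target BED,
candidate-C>T VCF, and truth sidecars.  Per-site truth levels are drawn
from a hypo / intermediate / hyper mixture (default weights
0.36 / 0.42 / 0.22, the proportions such intersections report) with the
level uniform within the category range; symmetric CpG pairs share the
level.  Fragments start on-target with probability 0.8, insert sizes are
Gaussian (FFPE 180 ± 40 bp, reflecting fixation-induced fragmentation; FF
250 ± 50 bp), and each fragment's bisulfite strand is uniform.  Unmethylated
cytosines on the converted strand are read as T with conversion efficiency
0.99 by default.

**Bowing** is modelled as position-dependent excess conversion of
*methylated* cytosines, linearly decaying over the first L bases of each
read (both mates): at cycle k ≤ L the methylated base is additionally
converted with probability b0·(1−(k−1)/L), defaults b0 = 0.3, L = 35 for
FFPE-labelled samples and b0 = 0 for FF.  The mechanism of bowing is not
established; the linear ramp is the simplest shape consistent with a
depression over the first ~30–40 cycles that recovers monotonically.  The
FF generative process is otherwise *identical*, so any FFPE−FF difference
on matched seeds is attributable to the bowing parameters.

**Deamination artifacts** are single-strand by construction: at designated
forward-strand non-CpG cytosines, the top strand of a fragment reads T with
a per-fragment probability (default 0.3) while the antisense strand keeps
its G — exactly the property the strand-resolved A/G test exploits.  **True
C>T SNVs** affect both strands at a configurable allele fraction, so
antisense reads show A.  Candidate sites are placed with a minimum spacing
(default 450 bp, above the maximum fragment length) so no fragment spans
two candidates; each informative read then carries evidence for exactly one
site, which makes the overall A/(A+G) fraction exactly binomial and the
recovery checks sharp.

Base qualities are constant Phred 37 and mapping quality constant 60;
quality- and mapq-driven filtering is exercised by dedicated handcrafted
low-quality fixtures rather than an error model.  Sequencing errors,
indels, adapter read-through and PCR duplicates are out of scope (removed
upstream in the workflow this emulates).  What passing tests show is that
the *analysis* behaves correctly under the stated generative model — not
that real FFPE data obeys that model.

## Bias curves and the trim sweep

M-bias curves tally informative CpG observations per mate and per read
cycle, in sequencing order (a read-start phenomenon must be measured in
cycle order, not reference order).  The bowing score is the mean fraction
over a plateau window (cycles 60–100) minus the mean over the head (first
30 cycles); a sample is flagged "bowed" above 0.05.  Both windows and the
threshold are parameters; the threshold is this package's own calibration
(the published account of bowing is graphical) chosen to sit several
standard errors above the null score at the coverage this package targets.

The trim sweep re-aggregates one pass of per-read observations at 5′ trims
5–90 bp in 5 bp steps, counts total calls in the FFPE sample and the
concordant intersection with FF (same site, same category), reports the
concordant fraction, and computes Spearman's rho between the totals and the
concordant counts.  Spearman p-values are exact by permutation enumeration
for n ≤ 8 and use the t approximation otherwise; a constant vector raises a
distinct error rather than returning a silent NaN.

A power analysis of the generative model (category mixture, uniform within
category) shows pairwise category concordance depends on per-site
informative coverage roughly as 1 − c/√λ in the 5–40× range, flattening
only at very low coverage (λ ≈ 1–4 observations/site).  The bundled sweep
experiment therefore runs in that low-coverage regime — which is also the
regime the motivating study's own data occupied — at ~24 000 CpG dyads, 11×
read coverage, where the concordant fraction is stable to < 0.05 across the
whole trim ladder while totals still decline monotonically (making rho
well-defined).

## Deamination test

At candidate C>T sites, only OB-strand (antisense-informative), primary,
non-duplicate reads are inspected, excluding the first and last 10 bases of
each read; stored-forward T counts as antisense A (true T allele), stored C
as antisense G (reference C on the far strand).  Two samples are compared
by a two-sided Fisher exact test on the 2×2 A/G table: p is the sum of
hypergeometric probabilities ≤ the observed table's.  Tables with total
≤ 300 are summed in exact rational arithmetic; larger tables in log space
with a 1e-12 relative tie tolerance.  A zero margin returns p = 1 with a
degenerate flag.  Mate overlap is not clipped here (the 10 bp end-clip is
the only read-geometry filter), mirroring the upstream procedure this
reimplements; overlapping mates carry the same molecule's base, so the
fraction estimate is unbiased though the test's effective n is slightly
optimistic for short inserts.

## On/off-target

A primary, non-duplicate, mapped read is on-target iff its alignment span
overlaps any merged target by ≥ 1 bp.  Off-target alignment spans are
merged with gap 0 (book-ended intervals joined; the gap is a parameter) into
disjoint sorted regions; pairwise cross-sample intersections are reported
in bp and as fractions of each sample's off-target total.  The
preservation-type test on off-target regions is an *interpretation*: the
2×2 table of shared-vs-unique off-target bp for FFPE vs FF, scaled to
region counts via the mean region size — one documented reading of an
under-specified published procedure, labelled as such.

## Concordance, consensus, sensitivity

Profile intersection is a site-keyed join; a paired site is concordant iff
the categories match.  Patient-pair concordance applies no coverage filter
by default; the replicate consensus keeps sites covered ≥ 10× in both
replicates, assigning the shared category or `off` on disagreement.
Discordant sites are binned by d = proportion_FFPE − proportion_FF over
[−1, 1] in 0.02 half-open bins, the last bin closed; the histogram edges
are rounded to exact decimals so boundary values land deterministically.
The sign convention follows the difference formula (FFPE minus FF): +1
means fully methylated in FFPE only.

Sensitivity against the gold consensus is TP/(TP+FP) among sample calls at
gold non-`off` sites with coverage ≥ c, for c = 1..30; `off` sites are
excluded entirely rather than counted as false positives, so replicate
disagreement does not bias the comparison.  The consensus retains
categories; proportions are carried as an annotation (replicate mean) only.

Validation-target selection keeps regions containing at least one site
covered ≥ 10× in every sample and carrying a non-`off`, gold-agreed call in
every consensus, annotating TP/FP status and a sharing stratum
(unique / subset / all) of gold-concordant samples — a generalization of
selecting events unique to one pair, shared by a subset, or shared by all.

## Truth-sharing and the sensitivity plateau

The simulator can derive a "related" truth sharing a chosen fraction of CpG
dyads with a donor truth; non-shared dyads are re-drawn with a category
*different* from the donor's (weights renormalized).  Forcing a category
change makes the sharing fraction identifiable: if non-shared sites could
re-draw the same category, chance agreement (≈ Σ w² ≈ 0.35 under the
default mixture) would inflate the plateau well above the configured
fraction.  With deep coverage (≥ 90× in the bundled check) the sensitivity
plateau recovers the sharing fraction within ±0.05.

## The demo and problem sizes

`ffpemeth demo --seed N` simulates the full comparison design — three
tumors split into FFPE (bowed) and FF halves, plus two cell-line-style
replicates sharing a truth that each tumor matches at 60% of dyads — over
16 kb of CpG-dense targets at 30×, then runs every stage and emits a report
validated against the pydantic-generated JSON schema published at
`docs/report.schema.json`.  No timestamps or absolute paths enter the
report, so a rerun at the same seed is byte-identical.  The bundled
experiment sizes (tens of kb of targets, 10⁴–10⁵ read pairs) were chosen so
each check resolves its stated tolerance with a few standard errors of
margin on a single CPU.

## Numerical and degenerate-input choices

* Proportions at zero coverage are undefined: such sites are absent, and
  asking for the proportion raises rather than returning NaN.
* Exact binomial recovery checks run at conversion efficiency 1.0: with
  incomplete conversion the generative observable is m + (1−m)(1−ce), not
  m, and a site at m = 0 would fall outside its interval by construction.
* Fisher p is computed in exact rational arithmetic for small tables, so
  tie handling at the observed probability is unambiguous.
* Spearman with a constant margin raises `ConstantInputError`; rho = ±1
  yields p = 0 under the t approximation.
* Region merging treats book-ended intervals as joined at gap 0; the
  half-open convention makes "touching" unambiguous.

## Known limitations

The simulator's truth distribution (uniform within category) puts more mass
near the 20%/80% thresholds than real, strongly bimodal methylomes; real
concordance numbers are therefore expected to be *higher* than the
simulated ones at matched coverage.  No sequencing-error or quality model
is included; CHG/CHH contexts, genotype-aware calling at C/T
polymorphisms, indel realignment and quality recalibration are out of
scope.  The bowing flag threshold is calibrated for aggregate curves at
the coverage this package targets and will be noisy for very shallow
samples.
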
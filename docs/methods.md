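# Methods

This note records the statistical model behind `recphen`, the parameters
that matter, what the simulator does and does not emulate, and the design
choices made where the problem was genuinely open.

## Crossover calling from sib-pair sharing

For each family × parent × chromosome the caller works on the *informative*
markers: target parent heterozygous (dosage 1), other parent homozygous
(dosage 0 or 2), both genotyped.  At such a marker the allele a child
received from the target parent is `code = child − other/2`, valid only when
the result is 0 or 1; Mendelian inconsistencies and missing child genotypes
leave that child undetermined at that site only (no family- or site-wide
removal — isolated errors are cheaper to absorb in the smoothing step than
to discard wholesale).  Genotypes are never imputed.

The first listed child is the reference.  For each sibling, the sharing
sequence over sites where both are determined is 1 when the pair received
the same parental allele.  Calling proceeds by iterated left-to-right
smoothing: while any run of constant state is shorter than `min_run`
(default 5), the leftmost such run is deleted and its equal-state neighbours
merge; at the fixed point every remaining state change is one event.  The
event interval runs from just before the last site of the left run to the
first site of the right run (0-based half-open; the true crossover lies
strictly inside), and the two run lengths are reported as left/right
support.  Requiring `min_run` concordant markers on *both* flanks is the
stricter of the two possible readings of a "five consecutive markers" rule
and is what suppresses the tight double-recombinants that isolated genotype
errors create: a single flipped genotype yields a run of length 1, which the
smoothing removes.

With `k > 2` children, events from the `k−1` (reference, sibling) pairs are
clustered greedily left-to-right by interval overlap (running intersection).
A cluster present in every pair is one crossover in the reference meiosis
(interval = intersection); a single-pair cluster belongs to that sibling's
meiosis; partial-overlap clusters count once with ambiguous attribution.
With `k = 2` attribution is always ambiguous, which is harmless because the
phenotypes are per-parent.

**Resolution limits.** Two consequences follow directly from the smoothing
rule and are intrinsic, not bugs: (i) a crossover within `min_run`
informative sites of a chromosome end or of another switch (in either
child's meiosis) cannot be called — with ~250 informative sites per
chromosome and 4 expected switches per sib pair this loses ~15–20% of true
crossovers, while every called event still contains exactly one true
crossover; (ii) which near-coincident crossover survives can depend on the
reference-child labelling, so the count-symmetry guarantee (reference
relabelling never changes a parent's total) holds for parents whose
crossovers are mutually separated by at least `min_run` sites, and the tests
check it on exactly that domain.  Recovery statistics therefore distinguish
*callable* crossovers (≥ `min_run` usable sites on each flank, no other
switch within `min_run` sites) from all crossovers; the caller recovers
essentially all callable ones.

## Phenotypes

`ARC = |events|/k` uses all events.  The three hotspot phenotypes use only
events whose interval is ≤ `resolution_bp` (default 30,000 bp), applied to
numerator *and* denominator so that `HS_PCT = HS_CNT/(HS_CNT+NHS_CNT)`
holds as an exact identity; applying the filter to only one side would make
the three numbers mutually inconsistent.  `MOTIF` deliberately carries no
resolution filter (its defining ratio is over all events).  "Near the
motif" is operationalised as interval overlap with the motif track expanded
by `motif_window` bp per side (default 0; exposed because "near" has no
canonical width).  Zero-denominator ratios are missing and excluded
listwise per phenotype downstream.

Note that an event interval is the gap between two flanking informative
markers and a crossover falls into a gap with probability proportional to
its length, so the fraction of events passing the 30-kb filter is the
*size-biased* tail of the gap distribution — much smaller than the naive
quantile.  Hotspot phenotypes are only informative on maps whose mean
informative spacing is comparable to the resolution threshold.

## Marker QC and association

MAF and the exact conditional Hardy–Weinberg test (enumeration over
heterozygote counts given allele counts, log-gamma arithmetic) are computed
on parental founders only; children are non-independent copies of parental
alleles and would bias both.  Cut-offs: MAF ≥ 0.02, HWE p ≥ 1e-4.

Association is OLS of phenotype on dosage with intercept, two-sided t test
with n−2 df, one observation per parent, run separately per (cohort × sex)
stratum; strata with fewer than 10 phenotyped parents are refused.  A
numerically perfect fit reports the smallest positive double as its p-value
rather than zero (keeps −log10 finite).  An optional covariate hook
(`covariate_columns`) fits the full multiple regression; it is off by
default because ancestry summaries are used here as QC, not adjustment.
Combined-sex results are obtained by meta-analysing the four strata, never
by pooled regression — pooling would conflate the sex difference in mean
recombination with marker effects.

Meta-analysis is inverse-variance fixed effects with normal p-values,
per-study direction strings (`+`/`-`/`?`; an exact zero renders `+`), and
Cochran's Q / I² reported as diagnostics only.  Markers are matched across
studies by snp id (the intended use is identically-chipped cohorts).
Significance labels are fixed: genome-wide p < 1e-7, suggestive
1e-7 ≤ p < 1e-5; no per-analysis Bonferroni recomputation.  λ_GC is the
median of the χ²₁ quantile transform of the p-values divided by 0.4549.

## Simulator: what it emulates, and what it does not

Defaults encode the study conditions the pipeline targets: families with two
or more children; per-chromosome Poisson crossover rates λ_male = 1.2,
λ_female = 1.8 (the per-autosome average implied by genome-wide counts of
~27 male / ~41 female over 22 autosomes, female:male ≈ 1.5); hotspot usage
h = 0.4 in both sexes (observed range ~30–50%); 200 hotspots of 2 kb per
chromosome (hotspots are 1–2 kb in practice); a 13-bp motif inside half the
hotspots plus a 1/Mb background; marker MAFs uniform on [0.25, 0.5].
Genotyping error independently replaces a dosage with one of the other two
values at rate ε.  The optional trans-acting QTL adds
`beta_count × dosage / n_chromosomes` to the parent's own per-chromosome
rate (so `beta_count` is the genome-wide ARC effect, matching the additive
GWAS model), and/or `beta_usage × dosage` to h (clipped to [0,1]);
`beta_count_male` permits opposite-signed effects by sex.  When a QTL is
configured its marker's allele frequency is pinned at 0.3 so the
minor-allele orientation is stable across cohorts and the signed effect is
identifiable.  All randomness comes from one numpy Generator seeded from
the config; identical configs give byte-identical cohorts.

Deliberately not modelled: crossover interference and obligate chiasma
(Poisson counts suffice to exercise the caller; the phenotype formulas are
insensitive to interference), background LD (the caller uses only
within-family transmission), sex chromosomes, realistic genetic maps, and
population structure.  Passing tests therefore demonstrate correctness of
the calling/phenotype/association machinery under the stated generative
model, not robustness to LD-induced informativity clustering, relatedness
across families, or array-specific error modes in real cohorts.

## Numerical and design notes

* Coordinates: marker bp stay 1-based; every interval (events, tracks) is
  0-based half-open; a marker maps to `[bp−1, bp)`.  One overlap algebra,
  no off-by-one ambiguity.
* Tracks are merged and sorted at load; overlap queries are binary searches
  on the merged arrays.  Merging is idempotent.
* Minor alleles are determined from founders, ties broken toward the
  lexicographically smaller symbol — the same rule in the simulator and the
  PED reader, so write→read round-trips are exact.
* Duplicate marker positions: first kept, rest dropped with a warning
  (strict ordering is required by the switch scan).  The MAP cM column is
  read and ignored (all analysis is in physical coordinates).
* Hotspot placement uses the sorted-uniform spacing construction, giving a
  uniform draw over non-overlapping configurations; crossover placement
  redraws duplicate basepair positions.
* Evaluation problem sizes (see `recphen/evaluation.py`): recovery and
  robustness studies use the 200-family / 1,000-marker single-chromosome
  design; calibration uses 500 fathers × ~10⁴ markers; effect-recovery
  studies use 2 cohorts × 2 sexes × 500 parents on 3 chromosomes × 6,000
  markers, a density chosen so interval-resolution losses attenuate a
  simulated ARC effect by ≲ 6%; the phenotype-identity study uses a 20,000
  marker map so enough events pass the 30-kb filter.

## Known limitations

* Recall is bounded by informative-marker density; sparse maps silently
  lower ARC (and the attenuation grows with the true rate, slightly
  compressing female vs male counts).  Dense panels mitigate this.
* Hotspot phenotypes on sparse maps have very few resolution-passing
  events and correspondingly noisy per-parent values.
* The meta-analysis matches markers by id and assumes a shared strand/
  allele orientation across studies, as holds for identically-chipped
  cohorts and for the bundled simulator.
* X-chromosome recombination, mixed-model relatedness correction and
  imputation are out of scope.
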
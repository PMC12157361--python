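# Methods

This note documents the models, decision rules, parameters and known
limitations of each pipeline stage, and what the synthetic-cohort
validation does and does not demonstrate about real data.

## Copy-number rescaling and seed calling

A segment's log ratio is modelled as arising from a two-population
mixture: a fraction ρ of tumor cells with total copy number TCN and
ploidy ψ, and 1 − ρ diploid normal cells. Read depth is proportional to
DNA content, and the normal reference is diploid, so

    2^logR = (ρ·TCN + 2·(1 − ρ)) / ψ,

which inverts to `TCN = (ψ·2^logR − 2(1 − ρ)) / ρ`. Two notes on this
form:

* The denominator is the tumor ploidy ψ, not the mixture ploidy
  ρψ + 2(1 − ρ). This matches the convention of depth-normalising
  against the tumor ploidy; users whose logR was normalised against
  the mixture average should be aware of the discrepancy. The package
  implements the ψ form exactly, and the synthetic generator uses its
  exact algebraic inverse, so the round trip is machine-precision
  exact at zero noise for any ρ ∈ (0, 1], ψ > 0.
* Under noise at low purity the rescaled value can go negative; it is
  clamped to 0 (clamp counts are logged at DEBUG level).

The naive (uncorrected) estimate `2·2^logR` corresponds to ρ = 1,
ψ = 2 and is retained for comparison; at those values the two
estimators coincide identically.

Seed regions are maximal runs of segments with TCN ≥ `min_cn`
(default 4.5), merged across gaps ≤ `merge_gap` (300 kb) and kept when
the merged span is ≥ `min_len` (50 kb). These thresholds follow the
conventional amplicon-seeding values used by reconstruction tools; all
three are exposed in the API and CLI. Input segments must be sorted
and non-overlapping per chromosome — unsorted input raises rather than
being silently sorted, because silent reordering can mask upstream
coordinate bugs.

## Amplicon graph and classification

Each sub-interval of a padded seed (pad 100 kb, config-exposed)
contributes a left (L) and right (R) extremity node. Segment edges
join L–R within a sub-interval; adjacency edges join R–L of
consecutive sub-intervals; discordant edges attach SV breakends by
orientation (strand `+` to the R extremity at the breakend position,
strand `-` to the L extremity). A physically realisable amplicon
traversal alternates segment and junction edges, so ecDNA detection
asks whether a closed alternating walk using at least one discordant
edge exists. This is decided exactly by building the directed state
graph on (extremity, next-edge-class) pairs and checking whether any
discordant transition lies inside a strongly connected component; unit
tests verify agreement with brute-force enumeration of alternating
closed walks on small graphs.

The orientation-aware construction is what separates BFB from ecDNA: a
duplication-like (head-to-tail) junction closes a cycle through the
reference path, while head-to-head foldback inversions alone cannot —
returning along the reference after a foldback requires a second,
opposite-orientation turnaround.

Classification rules, applied per connected component containing at
least one seed:

1. **ecDNA** — discordant cycle exists and max corrected CN ≥ 4.5.
   Ties between cycle and foldback evidence resolve to ecDNA.
2. **BFB** — foldback junctions (h2h/t2t with breakend distance
   ≤ 30 kb) make up ≥ 25% of the component's SVs.
3. **complex non-cyclic** — any other component with ≥ 1 SV.
4. **linear** — no SVs.

This is a documented simplification, not a re-implementation of
amplicon-reconstruction tools: there is no copy-count deconvolution,
no breakpoint assembly, and no visual-inspection step (the published
workflows include a manual verification pass for which no computable
proxy exists). Strand-pair → SV-type mapping follows the standard
BEDPE convention: (+,−) deletion-like, (−,+) duplication-like, (+,+)
head-to-head inversion, (−,−) tail-to-tail inversion, interchromosomal
= translocation.

A sample is ecDNA-positive when it carries ≥ 1 ecDNA amplicon.

## Genome-instability metrics

* **WGD**: called when the major allele copy number is ≥ 3 over more
  than 50% of the genome. The fraction is length-weighted by default —
  a count-of-segments reading would change with segmentation
  granularity, and the length-weighted form is invariant to segment
  subdivision (tested). A count-based variant sits behind
  `length_weighted=False`. The major-CN cutoff is `major_cn_min` and
  the inequality against 50% is strict.
* **wGII**: sample ploidy is the length-weighted mean TCN over all
  segments; per autosome the aberrant fraction is the length fraction
  whose rounded TCN differs from the rounded ploidy; the 22 fractions
  are summed and divided by 22 (autosomes without segments contribute
  0, and sex chromosomes are excluded by construction). Rounding both
  sides is deliberate: comparing raw TCN to a non-integer ploidy would
  mark essentially every base aberrant.
* **Telomere length**: a read is telomeric when it contains ≥ 7
  non-overlapping TTAGGG repeats or ≥ 7 CCCTAA repeats
  (case-insensitive; CCCTAA covers the reverse complement). Per-read-
  group TL is `c · n_telomeric / n_reads` with scale constant c
  (default 1, arbitrary units); the sample TL is the read-count-
  weighted mean over read groups, and the tumor/normal log2 ratio is
  independent of c. GC-stratified normalisation and genome-constant
  derivation used by dedicated telomere tools are out of scope.
* **Mitochondrial copy number**: from the tumor-sample mito/nuclear
  depth ratio R_t, the mixture nuclear content Pe = ρψ + 2(1 − ρ)
  converts R_t to mitochondrial copies per mixture cell; subtracting
  the normal-cell contribution (2 · mito/nuclear depth ratio of the
  matched normal) and dividing by ρ yields tumor-cell copies. The
  forward model inverts exactly (property-tested).

## Chromothripsis criteria

Intrachromosomal SVs (DUP/DEL/h2hINV/t2tINV) are clustered per
chromosome by single-linkage over breakends with gap ≤ 1 Mb
(equivalent to the transitive closure of pairwise linkage; tested
against a brute-force closure oracle). Each cluster is high-confidence
chromothripsis when all of:

1. more than 6 clustered SVs;
2. more than 7 oscillations — the switch count of the longest run of
   consecutive segments whose rounded TCN alternates between exactly
   two states, no third state tolerated inside the run;
3. breakpoint enrichment p < 0.05, one-sided binomial tail
   P(X ≥ n_region), X ~ Binomial(n_genome, region/genome length);
4. join randomness p > 0.05 (chi-square goodness of fit of the four
   join-type counts against ¼ each, 3 df) **or** ≥ 4 interchromosomal
   rearrangements with a breakend in the region.

The "and/or" in criterion 4 is read as (i)–(iii) always required with
either branch of (iv) sufficient — the most conservative reading.
The binomial and chi-square tests are this package's concrete
stand-ins for the corresponding criteria of dedicated chromothripsis
callers and are swappable via keyword arguments.

ecDNA–chromothripsis overlap is ≥ 1 bp intersection between merged
ecDNA intervals and merged high-confidence regions (the literature does
not define the overlap threshold quantitatively; ≥ 1 bp is the
package's choice and the total overlapping base count is also
returned).

## Cargo and driver mutations

Genes and enhancers count as ecDNA cargo only when 100% contained in
the merged ecDNA intervals (the enhancer containment rule is standard;
applying it to gene bodies is the package's choice, relaxable to ≥ 1 bp
overlap via `gene_containment=False`). Promoters — 1000 bp upstream of
the TSS, strand-aware, clipped at chromosome bounds — count on any
overlap. An ecDNA carrying an oncogene is never categorised as
immunomodulatory; the final category priority is oncogene >
immunomodulatory > other gene > regulatory-only > unknown. Gene
rosters (oncogenes, tumor suppressors, the immunomodulatory set) and
enhancer intervals are inputs; no live database queries are made.

A mutation is a potential driver when any of six criteria hold:
truncating in a tumor suppressor; missense recurring in ≥ 3 samples;
boostDM score > 0.5; OncoKB "Oncogenic"/"Likely Oncogenic"; flagged in
the MC3 driver catalogue; or missense "likely pathogenic" in a tumor
suppressor.

## Statistics

* **Logistic regression**: Newton scoring via statsmodels, convergence
  tolerance 1e-8, Wald CIs. Constant columns are rejected; separation
  (detected via the perfect-separation warning or diverging estimates)
  raises an error pointing at the Firth variant.
* **Firth logistic regression**: maximizes ℓ(β) + ½ log det I(β) by
  modified scoring with step-halving. Estimates are finite under
  complete separation; for a saturated 2×2 design the estimate equals
  the half-cell-corrected cross-product ratio (tested to 1e-6).
  CIs are profile-penalized-likelihood intervals (root-finding on the
  penalized LR curve at the 3.84 cutoff) with Wald fallback when
  profiling fails; p-values are penalized LR tests.
* **BH-FDR**: step-up q(i) = min over j ≥ i of p(j)·m/j, capped at 1,
  order-preserving. Note the step-up adjustment is *not* idempotent in
  general (p = [0.01, 0.04] adjusts to [0.02, 0.04], which re-adjusts
  to [0.04, 0.04]); the tested invariants are dominance q ≥ p,
  monotonicity in sorted order, the cap, and order invariance.
* **Mann-Whitney**: exact two-sided p by enumerating all C(n, n_x)
  rank assignments (mid-ranks for ties) when n_x + n_y ≤ 12; otherwise
  the normal approximation with tie correction.
* **2×2 odds ratios**: sample OR = ad/bc with 0.5 added to every cell
  iff any cell is zero; Fisher's exact two-sided p sums all tables
  (fixed margins) with probability ≤ the observed table's — stated
  explicitly because two-sided conventions differ.
* **Cox proportional hazards**: lifelines partial-likelihood
  maximization with Efron tie handling (Newton precision tightened to
  1e-9 so estimates agree with brute-force maximization to 1e-4 on
  small data). The three-level amplification factor (ecDNA / other
  focal amplification / none) is dummy-encoded with *other focal
  amplification* as the reference level, so the ecDNA coefficient is
  directly the ecDNA-versus-chromosomal-amplification contrast.
* **Association suite**: each model in the spec list is fitted by the
  standard or Firth fitter; covariates are encoded continuous as-is,
  categorical by dummies, and numeric "features" as present/absent
  when present in < 50% of samples or above/below median otherwise.
  q-values are computed within each model family, mirroring
  per-analysis FDR reporting.

## Synthetic cohort: what it emulates, and what it does not

The generator draws, per sample: purity uniform on (0.2, 0.95) by
default (real cohorts report a "wide range" without a published
distribution — this is a configurable guess); WGD with probability
0.40; ecDNA status from a logistic model whose WGD coefficient is
log(4.0) and whose intercept is calibrated to a marginal prevalence of
18.9%; BFB (8%) and linear focal amplifications (15%) as the "other
focal" survival stratum; chromothripsis (25%). Survival is exponential
with hazard ×2.17 for ecDNA-positive samples and independent
exponential censoring tuned to a 30% censored fraction at baseline
hazard (higher-hazard samples are necessarily censored less often; a
censoring time coupled to the event time would be informative and bias
the Cox fit).

Genomes are 22 toy autosomes of 10 Mb (hg38-scale lengths can be
configured; small chromosomes keep the test suite fast), tiled gap-free
with 3–8 segments each. Roughly a quarter of baseline segments carry a
single-copy aberration; gains in WGD samples are skipped so no baseline
segment enters the seeding range — injected events alone determine the
focal-amplification ground truth, which is what makes 100%-agreement
acceptance checks meaningful. logR noise is Gaussian with sd 0.02,
reflecting that segment-level log ratios are means over many bins;
allele-specific noise is not modelled. Injected events: cyclic
amplicons add one head-to-tail junction (copy number 20, 1 Mb);
foldback amplicons add two head-to-head inversions at one boundary
(breakend spacing ≪ 30 kb); chromothripsis replaces a 3 Mb window with
14 segments oscillating between the baseline state and one copy below,
places 14 uniformly-typed intrachromosomal SVs in the window, and adds
4 translocations whose in-window breakends sit at shattered-fragment
junction positions (real chromothripsis commonly reaches multiple
chromosomes; drawing TRA breakends from the fragment junctions keeps
them inside the cluster's breakend span). Background SVs (20 per
sample) are scattered over chromosomes without injected events so
ground-truth labels stay exact. Ploidy is recorded once from the
baseline profile, before event injection, mirroring how purity/ploidy
callers estimate it; injections re-emit logR through the same recorded
ψ, so the rescaling round trip stays exact.

All randomness flows from one seeded generator; per-sample streams are
spawned from a `SeedSequence`, and identical configurations produce
byte-identical output files.

**What passing tests show**: that each decision rule is implemented as
specified, that the corrected pipeline is purity-independent where the
naive one is not, and that the statistics recover injected effects
with nominal CI coverage. **What they do not show**: performance on
real segmentation noise (correlated, caller-specific), on subclonal
copy number, on SV calls with realistic false-positive/negative rates,
or on amplicon architectures more complex than single-cycle ecDNA —
the generator's events are archetypes, not replays of real genomes.

## Problem sizes and numerical choices

The acceptance script uses: 1,000 random (TCN, ρ, ψ) triples for the
round trip; 200 samples for the purity-stratified seeding comparison;
150 samples (≈ 125 events) for classification accuracy; 200 + 100
samples for chromothripsis performance and the null; 300 samples for
detected prevalence; n = 20,000 for single-run effect-size recovery
(the sampling SE of the log odds ratio at n = 1,000 is ≈ 9%, so the
recovery-with-coverage claim is made over 100 replicates at n = 1,000
in the test suite, while the script reports one precise estimate).
Convergence tolerances: logistic 1e-8 (log-likelihood), Firth modified
score 1e-10, Cox Newton precision 1e-9. Ties in seed ordering are
broken by (chromosome, start); amplicon ids are assigned in leftmost-
coordinate order, making all outputs deterministic.
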
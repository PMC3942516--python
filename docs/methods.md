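# Methods

`famlink` implements exact non-parametric allele-sharing linkage analysis for
multiplex nuclear families, together with the surrounding workflow a
family-based gene-mapping study needs: genotype QC, sex-stratified subset
randomization, a staged discovery/extension/replication design, and
linkage-directed transmission-disequilibrium association testing. This note
describes the models, the numerical choices, what the synthetic-data
generator does and does not emulate, and the package's limitations.

## The linkage model

### Inheritance vectors

For a nuclear family with `c` children, the inheritance pattern at a locus is
encoded as a binary vector with one bit per meiosis: the paternal and the
maternal bit of child `k` record which of the parent's two homologous alleles
the child received. The vector space has `4^c` states on autosomes. No
founder-phase symmetry reduction is applied: sibships in this setting have at
most a few children, the full space is at most a few hundred states, and
operating on the unreduced space keeps the enumeration-based tests exact and
the code simple.

Single-marker likelihoods `P(G | v)` sum over ordered founder diplotype
assignments weighted by population allele frequencies, with missing genotypes
marginalized; a family whose genotypes are Mendelian-inconsistent at a marker
has an all-zero likelihood there and is treated as uninformative at that
marker (uniform emission), mirroring how linkage engines drop families
marker-wise. Founder allele frequencies are estimated by counting founder
alleles (all genotyped individuals as a flagged fallback when no founder is
genotyped), with half an allele of pseudocount per allele so estimates stay
inside (0,1).

Multipoint inference is a forward–backward pass of a hidden-Markov chain over
the marker grid. Between adjacent markers each meiosis bit flips
independently with probability `theta = (1 - exp(-2d))/2` (Haldane map
function, `d` in Morgans, no crossover interference), so the transition
probability between vectors is `theta^h (1-theta)^(n-h)` with `h` the Hamming
distance. The analysis grid is the marker positions themselves; peaks are
reported at markers.

### Sharing scores and standardization

Sharing among the affected children is scored per inheritance vector with a
Whittemore–Halpern statistic:

* `S_pairs`: the number of alleles shared identical-by-descent, summed over
  all pairs of affected children;
* `S_all` (default): the average over all ways of picking one allele from
  each affected child of the product of factorials of founder-allele
  multiplicities. For affected sib pairs the two statistics are affine
  transforms of each other and give identical standardized scores.

Each family's score is standardized against the exact null distribution —
uniform over inheritance vectors — computed by full enumeration:
`Z_i = (E[S | data] - mu0) / sigma0`. A family whose posterior is uniform
(uninformative data) scores exactly zero. The minimum attainable
standardized score `z_min_i` for the family's structure is kept alongside;
it bounds the sharing parameter below.

### Kong–Cox linear-model LOD

Family scores are combined by maximizing the one-parameter linear-model
log-likelihood

    l(delta) = sum_i log10(1 + delta * gamma_i * Z_i),   delta >= 0,

with equal weights `gamma_i = 1/sqrt(N)` (the convention of the standard
multipoint engines; Kong & Cox's framework admits others). `delta` is capped
at `delta_max = min_i { -1/(gamma_i * z_min_i) }` over families with negative
attainable minima, which keeps the model a valid likelihood for every
attainable score. The maximization is a bounded scalar search (Brent for the
reference path, vectorized golden-section with 80 iterations for the
randomization test's thousands of subsets); both agree with a 10^6-point grid
search to better than 1e-6. LOD = l(delta_hat); the one-sided boundary gives
LOD = 0 whenever the weighted sharing sum is non-positive.

Pointwise significance is the one-sided normal tail of
`Z = sqrt(2 ln10 * LOD)`, so LOD 0 maps to P = 0.5; externally reported
standardized scores convert via `LOD = Z^2 / (2 ln 10)`. Thresholds follow
the standard complex-trait guidelines: suggestive LOD ≥ 2.2, genome-wide
significant LOD ≥ 3.6, independent replication P < 0.01. Support intervals
walk outward from a peak to the first markers at which the LOD has dropped by
2 (crossing markers included, so the interval is inclusive); if the curve
never drops, the chromosome end is used and flagged. Peak ties break toward
smaller bp.

### X chromosome

In X mode males are hemizygous: the father carries a single X allele
transmitted intact to every daughter, male meioses contribute no bits, and
the vector space is the `2^c` maternal bits. Hemizygous male genotypes are
stored as homozygous diplotypes (the convention of the Merlin/Minx file
dialect). Sharing statistics operate on each child's actual allele-origin
list (sons contribute one allele, daughters two), with `S_all` generalized by
averaging over each child's available alleles. This is an exact treatment
for nuclear families, not an approximation.

## Quality control

Defaults: individuals and SNPs with >5% missing data removed; founder-only
exact Hardy–Weinberg test (log-space enumeration over heterozygote counts
conditional on allele counts) at a 1e-7 floor; minor allele frequency ≥ 0.01;
at most 10 Mendelian errors per SNP. The filter order — individual
missingness, SNP missingness, HWE, MAF, Mendelian cap — is fixed and applied
to the surviving roster at each step, because order changes the removal
counts. HWE and MAF use founders only to avoid relatedness inflation.
After counting, genotypes of offending trios at surviving markers are set
missing so the markers remain usable. Mendelian checking marginalizes
missing parents, so duos are still screened.

LD pruning is greedy within sliding windows (defaults: 50 markers, step 5):
while any retained pair in the window exceeds the r² threshold, the member of
the worst pair with the smaller founder MAF (ties: later position) is
removed. r² is the squared Pearson correlation of founder genotype dosages
(composite LD), matching common tool defaults rather than EM haplotype
frequencies. The linkage panel uses r² ≤ 0.1; regional independent-SNP
counts for multiple-testing correction use r² < 0.3 with a window spanning
the whole region (exact all-pairs behaviour).

Platform merging takes the union (default) or intersection of marker sets,
harmonizes allele coding by symbol, flags any marker whose allele sets
cannot be reconciled, and leaves union-mode samples missing at markers their
platform did not type.

## Sex-stratified randomization test

Multiplex families (≥2 affected children) are labeled male-only (MO — no
affected daughters) or female-containing (FC — at least one affected
daughter); unaffected siblings never change the label. The enrichment test
draws `n_trials` subsets of the subgroup's size, uniformly **without
replacement from the full multiplex cohort** (the subgroup's own families
included — the matched quantity is only the subset size), recomputes the LOD
curve for each subset, and reports per marker the fraction of trials with
`LOD_random > LOD_original` — strict inequality, so ties count against
significance. A `(k+1)/(n+1)` estimator is reported alongside for
small-count stability, but the raw fraction is the primary value. Because
per-family standardized scores do not depend on the subset, they are
computed once and each trial reduces to a Kong–Cox maximization, making
10,000-trial runs feasible and 200-trial desk runs instantaneous. The seed
fully determines the trial sequence.

## Staged workflow

Discovery runs the genome-wide scan per subgroup and defines candidate
regions as 2-LOD support intervals around suggestive peaks. Externally
reported loci join the candidate list after score conversion
(`LOD = Z^2/(2 ln 10)` where only a standardized score is printed); lacking
a curve, they get a configurable ±10 Mb flank around the physical anchor of
their peak marker. Extension retests each region in the combined sample's
matching subgroup (confirmed-suggestive iff LOD ≥ 2.2 inside the interval).
Replication is gated on genome-wide significant discovery evidence
(LOD ≥ 3.6), runs on the independent families only, and declares replication
iff the minimum marker-wise pointwise P inside the interval is < 0.01 — a
deliberately liberal convention (no further multiplicity adjustment inside
the interval), mirroring per-SNP reporting practice; the regional
independent-SNP correction exists in the TDT module for association claims.
The discovery family list is an explicit input, since which families were
"previously evaluated" is a property of study history, not of the data.

## TDT with sibling-consistent gene dropping

For each heterozygous parent × affected child, the minor allele (by founder
frequency) is transmitted (T) or not (U); `chi2 = (T-U)^2/(T+U)` with a 1-df
asymptotic tail and `OR = T/U` (flagged undefined at U = 0). Families of any
structure are flattened to their parent–affected-child trios, so
affected-cousin families contribute through their component trios. In
double-heterozygous trios with a heterozygous child, one minor and one major
transmission are split across the two parents; the attribution is arbitrary
and the permutation distribution is invariant to it.

The empirical null gene-drops: each heterozygous parent's transmissions are
flipped with probability ½, the same flip applied to all of that parent's
affected offspring. This preserves linkage (siblings stay correlated) while
breaking association, which is what makes trios from multiplex families
usable as non-independent units. `EMP1 = (k+1)/(n+1)` with `k` the number of
permuted statistics ≥ observed. Optional adaptive stopping ends permutation
once `k` reaches a configurable count (default 50), at which point the
estimate is resolved far above any interesting significance level; the exact
schedule of the original tools is not reproduced. Regional correction
multiplies by the independent-SNP count (Bonferroni; Šidák optional).

Because the permutation statistic is discrete, EMP1 is valid but
conservative at small transmission counts: its null distribution has mass at
coarse values (visibly at 1.0) and approaches uniformity as counts grow. The
calibration suite therefore checks strict validity plus bounded deviation at
small cohort sizes, and full KS uniformity on a 1,000-family cohort.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume:
nuclear families with 2–3 children (60/40 mix), founders at linkage
equilibrium with marker allele frequencies drawn uniform on a configurable
range, Haldane recombination identical to the linkage engine's transition
kernel, risk loci acting through sex-specific penetrance tables combined as
independent liability channels (`P(affected) = 1 - (1-f0) * prod_l (1 -
f_l(g_l, sex))` with baseline `f0`), ascertainment for ≥2 affected children,
and optional rebalancing to a target MO fraction (default 0.60) via
accept/reject quotas. The default cohort scale is 1,008 multiplex families.
The acceptance rate of the generative stream is recorded so ascertainment
bias is explicit; a rate too low for the requested cohort raises with advice
rather than looping forever. Noise channels: genotype missingness, random
allele flips, and deliberately planted Mendelian violations (opposite-
homozygote parents with a heterozygote-impossible child), all retained in
ground truth.

Two properties of the default design are worth stating. First, risk acts
only through penetrance, so a planted locus produces allele-sharing signal
without marker association — setting `typed=True` on a risk locus exposes it
as a genotyped marker (perfect LD) to create TDT-positive scenarios.
Second, multiplex ascertainment at a *common* risk allele drives carrier
parents toward homozygosity, and homozygous parents carry no sharing
information; sex-differential power experiments therefore model the
male-specific variant as rare and highly penetrant (frequency 0.10, male
carrier penetrance 0.9, female 0, baseline 0.05), which is also the
architecture the male-only enrichment hypothesis posits.

What the generator does **not** emulate: population history and background
LD (an optional block-copy mode exists solely to exercise the pruning code),
ancestral heterogeneity, genotyping-platform batch structure, copy-number or
de-novo variation, and diagnostic uncertainty in the affection label.
Passing tests on this generator demonstrate the statistical machinery is
correct and calibrated under its own assumptions; they do not certify
behaviour under real-cohort artifacts outside those channels.

## Numerical choices

* Posterior normalization at every marker; degenerate chains (single marker)
  reduce to normalized single-marker posteriors; theta is clipped to
  [1e-12, 0.5] so co-located markers do not produce zero transitions.
* `delta` search tolerance 1e-12 (Brent) / 80 golden-section iterations;
  boundary candidates are compared explicitly so a likelihood still rising at
  `delta_max` is handled.
* sigma0 = 0 (structurally uninformative family) gives Z = 0, flagged.
* Peak ties break toward smaller bp; plateau peaks are reported once at their
  smallest-bp position.
* Empirical P-values use strict `>` for the randomization test (raw
  fraction, per its definition) and `>=` with `(k+1)/(n+1)` for gene-drop
  EMP1 (per its definition); the difference is deliberate and matches the
  two procedures' conventions.
* Scales used by the shipped test suites are desk scales chosen for a
  single-CPU run: null calibration at 1,000 families × 100 positions
  (markers 50 cM apart to decorrelate), sex-differential recovery at 400
  families × 200 randomization trials × 10 seeds, TDT calibration at 1,000
  permutations per marker.

## Limitations

Results that depend on the original restricted cohort's genotypes — specific
peak markers and their LOD values, physical interval spans, the replication
P-value at a particular SNP, and the named-SNP association results — cannot
be reproduced here: the underlying family data are access-controlled and no
public accession exists. The synthetic suites above verify the method's
exactness (against enumeration oracles), its calibration (null cohorts), and
its power to recover planted effects; they are properties of the machinery,
not re-derivations of any cohort-specific finding. Analyses are exact only
for nuclear families; extended pedigrees participate in the TDT (flattened
to trios) but not in linkage. Parametric (model-based) linkage,
variance-components traits, genotype imputation and multi-allelic markers
are out of scope.
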
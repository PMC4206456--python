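# Methods

## The problem

Hard selective sweeps drag a single haplotype to high frequency faster
than recombination can break it apart, leaving an uncharacteristically
long haplotype at the swept frequency.  `haplosweep` implements a
long-haplotype scan of phased panels built on that signature, plus the
three companion measurements needed to evaluate whether GWAS risk alleles
for metabolic disease behave like recently selected "thrifty" variants:
haplotype similarity across populations, locus-specific F_ST, and a
four-step catalogue evaluation (selection overlap, risk allele on the
selected haplotype, ancestral/derived state, population differentiation).

## The selection scan

For each bin f of the frequency grid 0.05, 0.10, ..., 0.95 the scan
enumerates, over the whole panel, the maximal allele-specified contiguous
haplotype forms whose carrier fraction is at least f.  A chromosome
carries a form when it matches every accepted site; missing genotypes
count as matching (optimistic carrier assignment — conservative toward
keeping carriers).  The carrier fraction denominator is the full
chromosome count; a seed (SNP, allele) qualifies at bin f when its allele
frequency among non-missing chromosomes reaches f.

Each form is measured two ways: genetic distance spanned (cM, from a
piecewise-linear genetic map, clamped at chromosome ends) and number of
SNPs.  Within the bin's candidate universe (the deduplicated maximal
forms; its size is `n_f`) each measure is ranked genome-wide to give an
empirical p-value — the fraction of candidates at least as extreme, ties
included, the form counting itself — and the score is

    score = p_cm * p_snp * n_f

with scores strictly below 0.05 flagged as putative positive selection.
Because a site with a long haplotype at frequency f usually also has long
haplotypes at lower frequencies, overlapping significant signals within a
population are collapsed to the one at the highest bin (ties: larger
genetic length, then leftmost start).

### Search strategy

Growth from a seed extends outward one SNP at a time, keeping the carrier
set.  Whenever *both* alleles of the next SNP keep the carrier fraction
at or above f, the search forks and follows both — it does not commit to
the majority allele.  A greedy majority rule is not equivalent to window
enumeration: the majority branch can die one SNP later while the minority
branch runs on.  The fork search is cheap (live branches are bounded by
the number of distinct haplotype groups at the bin, roughly 1/f on
complete data; a hard cap of 512 guards pathological missingness) and is
exact: with no skip allowance, every maximal valid window is the unique
leaf of the fork search started from its leftmost site, so the scan's
deduplicated output equals the brute-force enumeration of all O(M²)
windows.  The test suite checks this equivalence against an independent
enumeration oracle on hundreds of random panels.

`grow_longest_form` (the single-seed entry point) additionally explores
all rightward stopping points before extending left, because stopping the
rightward extension early can leave more carriers for the leftward one;
this makes the returned form a genuinely longest valid window through the
seed.  The panel-wide scan does not need that refinement — completeness
at the scan level follows from the leftmost-seed argument — and uses the
faster maximal-extension search.

An optional per-side skip allowance (default 0) lets the extension step
over single SNPs that would otherwise end it, tolerating genotyping
error; skipped SNPs are not part of the form.

### What the score is, and is not

The score is a rank-product outlier criterion, not a calibrated p-value.
A form is flagged when `r_cm * r_snp < 0.05 * n_f` (ranks within the
candidate universe), and the expected number of forms passing that cut in
a *neutral* genome is roughly `0.05 * ln(20 * n_f)` per bin — a slowly
growing quota, of order one per bin at desk scale and a few dozen
genome-wide per population at biobank scale.  Consequently "at least one
significant signal somewhere" is a near-certain event on neutral data at
any scale; the meaningful false-positive control is region-level — how
often a *given* region is flagged at a given bin — which is what the test
suite measures (and what a user asks of a candidate locus).  At the
default simulation settings the region-level neutral flag rate at the
sweep bin measures ≈11% across 300 replicates.

Collapse interacts with sweeps in a way worth knowing: a sweep at carrier
frequency 0.40 also leaves *sub*-haplotypes shared by 45-65% of
chromosomes (donor segments plus chance-matching background) that are
long enough to be flagged at higher bins, and the report-highest-
frequency rule then reports the region at such a bin with a shorter span.
The full implanted form is reliably recovered at the bin matching its
true carrier frequency; the collapsed headline bin can sit higher.  This
mirrors the published observation that the inferred haplotype frequency
of a selected region can differ greatly from the frequencies of alleles
riding on it.

## Haplotype similarity index

For two selected forms on the same chromosome, HSI is the fraction of
identical alleles over the SNPs present in both forms' site lists (forms
must come from panels sharing SNP order and allele coding).  HSI above
0.98 indicates a single mutation event in the shared ancestor of the
populations; below 0.9 indicates convergent sweeps on different
backgrounds; the closed interval [0.9, 0.98] is reported as
indeterminate, and disjoint site sets as no-overlap.  The thresholds are
applied exactly as published (strict inequalities).  Site weighting or
restriction to the overlapping physical span would be alternatives; the
unweighted SNP-set intersection is the simplest definition consistent
with identical forms scoring exactly 1.00.

## Locus-specific F_ST

    p_bar = mean(p_1 ... p_k)          (unweighted)
    F_ST  = mean((p_i - p_bar)^2) / (p_bar (1 - p_bar))

Sample sizes are ignored and no small-sample correction is applied; the
degenerate pooled frequencies 0 and 1 return 0.  The statistic is
symmetric in populations, invariant under allele relabelling, bounded by
[0, 1], and equals 1 exactly for a fixed difference.

A point that is easy to get wrong: if two populations are simulated
around shared ancestral frequencies with Balding–Nichols inflation F
(Beta with mean p and variance F·p(1−p)), the *expected* mean locus F_ST
above is close to F/2, not F — each population contributes variance
F·p(1−p), but squared deviations are taken from the two-sample mean.
`divergence_estimate` inverts the moment relation, F̂ = k·R/(k−1+R) for k
populations with mean locus value R, and recovers F = 0.01/0.05/0.1
within a few percent at 1,000 loci.

## Catalogue evaluation

Index SNPs are kept when the trait matches (type-2 diabetes or obesity)
and the association p-value is strictly below 5×10⁻⁸; duplicate rsIDs
collapse to the most significant row.  A SNP overlaps selection when a
significant signal's region contains it (inclusive boundaries).  Whether
the risk allele sits on the selected haplotype is read off the form when
the SNP is a defining site; otherwise the allele is called from the
form's carrier chromosomes, accepted when one base reaches 90% of
non-missing carriers (configurable), else indeterminate — necessary
because printed allele frequencies exceed haplotype frequencies, so the
index SNP need not be a defining site.  Ancestral/derived classification
requires the outgroup base to match one of the two catalogued alleles
literally; no strand flipping is attempted (silent A/T-C/G flips are
unsafe), otherwise the state is unknown.  A SNP supports the
famine-selection expectation only when selection is East-Asian-specific,
the risk allele is on the selected form, and that allele is derived.

## Synthetic data

The generator provides every input with the structure the scan assumes,
and exact truth records:

* **Neutral panels.**  Per-SNP ancestral frequencies are uniform on
  [maf_floor, 1−maf_floor]; per-population frequencies are Balding–
  Nichols perturbations at the divergence parameter; a founder pool is
  drawn per population, and each chromosome is a Li–Stephens-style mosaic
  of founders with switch probability 1−exp(−rate·gap) per marker gap.
  LD therefore decays with genetic distance.  Everything is reproducible
  from the config seed.
* **Sweeps.**  A donor haplotype (an existing chromosome restricted to
  the region; one donor across populations under shared origin, else one
  per population) is copied onto round(carrier_frequency × 2N) randomly
  chosen chromosomes.  An optional linked risk SNP is placed on the donor
  or exclusively off it, with a configurable background frequency.
  Implanting rather than forward-simulating selection gives exact control
  of the two quantities the scan estimates — carrier frequency and
  haplotype form.
* **Catalogue/outgroup emission** mirrors the implanted truth so the
  four-step evaluation can be exercised end to end.

Default study conditions: 2 populations × 100 diploids, 400 SNPs at
random positions over a 40 Mb chromosome, uniform 1 cM/Mb map, 16
founders, switch rate 3×10⁻⁶/bp (mean copied segment ≈ 330 kb, a few
marker intervals at this density), maf floor 0.05, divergence 0.05.  The
chromosome is deliberately an order of magnitude longer than a sweep
region so the candidate universe is dominated by neutral forms and a
region-level null flag is rare.  The simulated sweep used throughout the
tests spans 4 Mb (≈4 cM, about 34× the median neutral form length at bin
0.40) at carrier frequency 0.40.

What the generator does **not** emulate: demographic history
(bottlenecks, growth), soft or polygenic sweeps (explicitly outside this
method's reach), genotyping error (unless injected via missingness),
recombination-rate variation, and realistic marker ascertainment.
Passing tests therefore show that the scan recovers hard-sweep imprints
of controlled size from mosaic-LD backgrounds — not that it would achieve
the same power on real array data.

The panels behind the packaged published-evidence evaluation are
synthetic stand-ins (`fixture_bundle`): for each printed region a donor
is implanted in the named population at the printed haplotype frequency,
carrying the risk allele exactly when the table says it was found on the
selected haplotype, with index-SNP frequencies steered to the printed
values.  They reproduce the printed evidence structure, not the original
genotypes.

## Numerical choices and edge cases

* Coordinates are 1-based inclusive internally; only BED output converts.
* Carrier thresholds use `ceil(f · 2N − 1e-9)` to avoid float
  boundary artefacts on grid bins.
* Tie-breaks are fixed everywhere for determinism: allele branches are
  explored in a fixed order; collapse prefers higher bin, then longer
  genetic length, then smaller start; `grow_longest_form` prefers more
  SNPs, then longer genetic length, then leftmost start.
* Genetic maps clamp (constant extrapolation) outside their anchors,
  preventing negative or unbounded cM at chromosome ends.
* Empirical p-values count ties and the target itself, so they live in
  (0, 1] and a 1-candidate universe gives p = 1.
* The chromosome-15 published region does not contain the printed
  position of its index SNP (the two appear to come from different
  genome builds); both are stored verbatim and the evaluation reports no
  overlap for that SNP, matching the published negative finding.

## Known limitations

* The scan is exhaustive per bin and panel; its cost grows roughly with
  (seeds × form length × chromosomes).  Desk-scale panels (hundreds of
  SNPs, hundreds of chromosomes) scan in fractions of a second per bin;
  biobank-scale data would need the usual windowing/parallelism.
* HSI matches sites by panel SNP index, so cross-population comparisons
  require panels cut from one consensus SNP set (as the synthetic
  generator and the intended HapMap-style inputs provide).
* The score's outlier-quota behaviour (above) means genome-wide
  significant-signal counts are not a false-discovery control; treat
  flagged regions as ranked candidates.
* The mosaic generator's founder pool adds frequency noise of order
  p(1−p)/K per population, which inflates panel-level differentiation
  beyond the Balding–Nichols parameter unless K is large; tests that
  check divergence recovery from panels use a founder-rich configuration.
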
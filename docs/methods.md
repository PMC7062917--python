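# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic-data generator does and does not
emulate.

## Coordinates and formats

All in-memory coordinates are 1-based inclusive, matching the
per-cytosine report convention; BED output alone is converted to 0-based
half-open at the single write point (`bed_start = start − 1`,
`bed_end = end`). Every TSV written by the package carries one header
line beginning `#`. Per-cytosine input is a 7-column TSV (chrom, pos,
strand, methylated count, unmethylated count, context, trinucleotide);
sites are keyed by (chrom, pos, strand) and duplicates are rejected.

## Context calling

A cytosine's context is read from the two downstream bases on its own
strand: second base G → CG; otherwise third base G → CHG; otherwise CHH
(H = A, T or C). On the minus strand the trinucleotide is the reverse
complement of the 3-mer ending at the site, reported 5′→3′ on that
strand. Cytosines with fewer than two downstream bases (chromosome edge)
or a downstream N have no defined context and are excluded entirely —
exclusion is reproducible, whereas any imputation would not be. The
production path is a vectorised both-strand scan; tests hold it to exact
agreement with an independent per-position 3-mer table scan.

## Methylation levels and non-conversion correction

Site ML is mC/(mC + C); a site with zero coverage is *missing*, never 0.
Window and bin MLs pool raw read counts over covered sites, which makes
them coverage-weighted means of site MLs (an identity the tests assert).
Windows are anchored at position 1 of each chromosome, advance by the
step, and the tail window is truncated at the chromosome end; windows
with no covered site are omitted. The 10-kb bin profile is the special
case window = step.

Bisulfite non-conversion is modelled as an error on unmethylated
molecules only: a site with true level p reads methylated with
probability q = p + (1 − p)·r. The rate r is estimated by pooling all
reads on the unmethylated spike-in chromosome (r̂ = Σ mC / Σ reads),
and the correction is the exact inverse of the error model,
ML_corrected = (ML − r)/(1 − r), clamped at 0. Conversion of methylated
cytosines is assumed perfect; with a symmetric failure rate the
correction would need a second term, which is out of scope.

For genome context percentages a site must first be *testable* (coverage
≥ 5, default) and is called methylated when its one-sided binomial
p-value against r survives BH at q < 0.05 within its context stratum.
The percentage for context c is 100 × (called sites of context c) /
(testable cytosines of all contexts) — so the three percentages add to
the total. Per-chromosome shares normalise instead over the chromosome's
called sites, so the three context shares sum to 1. The calling rule
(binomial vs r with per-context BH) is the package's choice of a
standard, defensible reading; other reasonable denominators exist, and
`call_methylated_sites` exposes both coverage and alpha.

## Functional-element metaprofiles

Gene models collapse multi-transcript genes to the longest-span
transcript (union-of-exons would make intron definition ambiguous).
Promoters are the 2-kb strand-aware region upstream of the TSS (span
start on +, span end on −), truncated at chromosome bounds; introns are
the gaps between consecutive exons; UTRs pass through from the
annotation. Each element is split into 20 equal fractional bins with
floor boundaries — bin k of length L covers offsets
[⌊kL/20⌋, ⌊(k+1)L/20⌋) — so elements of any length scale
proportionally; elements shorter than 20 bp simply leave some bins
empty. Offsets are measured from the biological 5′ end: minus-strand
elements are traversed 3′→5′ in genome coordinates, so bin 1 is always
5′. Each covered site lands in exactly one bin, which gives the exact
count-conservation invariant the tests check. Both strands are pooled;
one curve is reported per context and element type.

## DMR identification

Parameters (defaults): window 1,000 bp, step 100 bp, per-site coverage
≥ 5 in *both* samples, |ΔML| > 0.1, fold change > 2, cytosines > 10
(strict), Fisher p < 0.05, BH FDR < 0.05.

Decisions taken where the procedure admits several readings:

- **Shared-site policy.** The coverage floor applies per cytosine in
  both samples, so the ML difference and the 2×2 test table refer to the
  same loci.
- **Symmetric fold change.** max(ML_t, ML_c) / max(min(ML_t, ML_c),
  0.01). The floor keeps the criterion usable when one ML is 0 and makes
  the rule apply identically to hyper- and hypomethylation.
- **Two-sided Fisher.** The two-sided p is the sum of hypergeometric
  probabilities of all tables with the observed margins whose point
  probability does not exceed the observed one (the conventional
  definition). Tests hold it to 1e-12 against full enumeration.
- **Testing order.** The pre-filter (diff, fold change, cytosine count)
  selects candidate windows; BH runs across all candidates of one
  contrast and context; windows need both p < 0.05 and q < 0.05.
  Contexts are tested separately and DMRs carry their context, because
  CG and CHH behave differently and pooled testing would blur that.
- **Merging.** Because the step is smaller than the window, a true
  region produces a run of overlapping significant windows. Overlapping
  or book-ended (gap 0) windows of the same direction merge into maximal
  runs; pooled statistics and the Fisher p are recomputed on the merged
  span over its *distinct* shared cytosines (no double counting), and BH
  runs once more across the merged regions.

DMRs record every element type they overlap by ≥ 1 bp and every owning
gene; a gene with ≥ 1 DMR becomes a DMG whose methylation ratio is the
pooled treatment ML over pooled control ML across the union of the
gene's DMR intervals (per DMR context, duplicate sites counted once),
with a 0.01 floor on the denominator; ratio ≥ 1.5 is hyper, ≤ 1/1.5
hypo. Gene sets across contrasts are compared with exclusive Venn-region
counts, and clustered with average linkage on the distance 1 − Pearson
r; rows are pre-sorted by gene id so tied merges resolve
deterministically, constant rows are dropped with a warning (Pearson is
undefined on them), and missing values are an error rather than silently
imputed.

A caveat recorded here deliberately: BH over a filtered window family is
not mathematically monotone in the filter thresholds — removing a
low-p window shrinks the family and can in principle promote another
window past the FDR cut. At the generator's conditions, passing windows
have vanishing p-values and the threshold-monotonicity property holds;
on adversarial data it need not.

## Enrichment

A generic over-representation test: per term with K genes in a
background of N, a hit set of n genes overlapping k scores the
hypergeometric upper tail P[X ≥ k] (identical to one-sided Fisher on the
2×2 table, an equivalence the tests assert), with BH across terms. No
gene-length bias correction and no ontology machinery: the module exists
so the pipeline runs end to end on arbitrary term→gene maps.

## Median-effect synergy analysis

Fraction affected from growth: fa = 1 − (treated fresh weight / control
fresh weight), replicates averaged per dose before the transform, and fa
clamped into [0.005, 0.995] because the log-odds transform diverges at
0 and 1. The median-effect model fa/(1 − fa) = (D/Dm)^m is fit by OLS of
log10(fa/(1 − fa)) on log10(D); Dm (the dose with fa = 0.5) is the GI50
for growth-inhibition data. The combination index uses the classic
two-term (mutually exclusive) form CI = d1/Dx1(fa) + d2/Dx2(fa) with
Dx(fa) = Dm·(fa/(1 − fa))^(1/m); the non-exclusive third term
d1·d2/(Dx1·Dx2) is available behind a flag, off by default. Fixed-dose
(non-constant-ratio) combination designs are supported natively. The
self-combination identity — an agent combined with itself at doses
summing to the dose that produces fa has CI exactly 1 — is the test
anchor for the arithmetic.

## Synthetic-data generator

The generator is first-class, tested code, and its defaults are the
study conditions the rest of the package is validated under:

| parameter | default | rationale |
|---|---|---|
| chromosome lengths | 600 kb + 400 kb | 1-Mb genome: large enough for ~65 CG sites per 1-kb window, small enough for desk-scale runs |
| GC fraction | 0.36 | plant-genome-like base composition |
| base levels CG/CHG/CHH | 0.24 / 0.10 / 0.04 | realistic per-context means with the canonical CG > CHG > CHH ordering |
| level dispersion | Beta concentration 20 | visible site-to-site spread without degenerate 0/1 levels; `None` gives flat truth for calibration runs |
| coverage | Poisson, mean 30× | typical WGBS depth; Poisson rather than negative binomial because window pooling dominates site-level overdispersion for the caller's purposes |
| non-conversion rate | 0.004 | conversion efficiency above 99.5% |
| spike-in | "lambda", 48,502 bp, 50% GC | unmethylated control chromosome at the phage genome's length |
| planted regions | 20 × 2 kb, CG, Δ = +0.4 | strong, localised differential signal with recorded coordinates |

Read counts are Binomial(coverage, p + (1 − p)·r) — exactly the error
model the correction inverts. One master seed drives everything;
per-sample streams hash the seed with the sample id, so samples are
independent but reproducible, and arm-specific subsets of the planted
regions (keep probability 0.7) give partially overlapping DMG sets
across the three contrasts. Dose–response tables emulate three agents
(azacitidine-like m = 1.8, Dm = 10 µM; AZD-like Dm = 1 µM; RAP-like
Dm = 5 µM) with lognormal noise (cv 5%), and combination tables are
constructed so the true exclusive CI is 0.5 — a strong synergy.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: mapping bias and coverage
autocorrelation, PCR duplicates, sequence-dependent conversion failure,
methylation spatial autocorrelation beyond the planted blocks,
transposon-dense repeat landscapes, and biological replicate dispersion
(the design pools one library per condition, so the Fisher test measures
sampling error only, not between-replicate variance).

## Problem sizes used in validation

The checked-in validation suite runs at: the full 1-Mb study conditions
for planted-DMR recovery (5 replicate read-samplings of one genome,
metrics pooled) and null calibration (20 replicates, Δ = 0, expecting
zero DMRs in ≥ 95%); a 100-kb flat-truth genome plus full-length lambda
for the correction checks; all 2×2 tables with margins ≤ 12 for the
Fisher oracle sweep; 100 random 10-kb sequences with planted N runs for
the context-caller sweep; and a 250-kb two-chromosome profile for the
end-to-end determinism run, which is compared byte for byte via the
manifest's per-file sha256 digests.

## Known limitations

- Smoothing- or HMM-based DMR callers, replicate-aware dispersion
  models, and per-read (epiallele) analyses are out of scope.
- The Fisher test on pooled counts treats reads as independent Bernoulli
  draws; at high coverage it is anticonservative against biological
  variance the design cannot see (single library per condition).
- The methylated-site calling rule behind the context percentages is a
  convention; absolute percentages shift with coverage and alpha even
  when the underlying methylome is unchanged.
- Fold change depends on an arbitrary ε floor when one ML is ~0; the
  default 0.01 is documented rather than principled.
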
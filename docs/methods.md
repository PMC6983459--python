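# Methods

## Scope and model

`csburden` implements a single-gene, case-control rare-variant
association workflow for a dominant-acting candidate gene. The unit of
analysis is the *subject-level carrier indicator* (CAST-style
collapsing): a subject either carries at least one qualifying variant
in the gene or does not. All association statistics operate on the
resulting 2×2 carrier table; per-variant effects are not modeled.

Qualifying variants are defined by three filters applied in pipeline
order:

1. **QC** — records flagged as failing upstream genotype-quality
   filters are dropped (VCF FILTER column, or a `qc_pass` column in
   flat tables).
2. **Coverage harmonization** — a coding site is pruned when the
   fraction of adequately covered subjects differs between cohorts by
   strictly more than `max_abs_diff` (default 0.10, i.e. 10 percentage
   points on the absolute difference — not a ratio; a difference of
   exactly 0.10 is retained). "Adequate" defaults to depth ≥ 10×
   (`min_depth`), a common exome QC convention, and is only used when
   raw depth vectors are supplied; the pruning rule itself consumes
   pre-computed fractions. Both choices are surfaced in the run
   configuration, never silent.
3. **Novelty** — a variant is novel iff it has *no entry* in any
   resource of the configured novelty list (default: 1KG, ESP, ExAC,
   dbSNP, UMD_FBN1). Presence decides, not frequency: an entry at
   allele frequency 0 disqualifies. gnomAD is annotated but excluded
   from the default list — the packaged reference inventory contains a
   variant present in gnomAD at AF 4.06e-6 that still counts as novel —
   and the list is configurable.

## Classification and strata

Nonsense, frameshift, splice-site and in-frame indel consequences
cluster into a likely gene-disrupting (LGD) class. Missense variants
split at a CADD score of 20, *inclusive* (CADD 20 ≈ top 1% most
deleterious); a missense variant without a score raises an explicit
"unscored" error rather than silently landing in the non-damaging
stratum. Splice-site status is taken from the input annotation; no
distance-from-junction recomputation is attempted. The raw consequence
is carried alongside the class so that burden tables can print
Frameshift / Splicing / Missense sub-rows within the below-threshold
group. In-frame indels classify as LGD but have no dedicated sub-row in
the default table layout, which follows the conventional
Total / CADD < 20 (Frameshift, Splicing, Missense) / CADD ≥ 20
(Missense) shape.

The `n_variants` column counts **qualifying variant alleles** — one per
carrier per variant — so a variant recurring in two subjects
contributes two. This is the convention under which the reference
table's margins are internally consistent (every row's variant count
equals its case + control allele counts) and it coincides with the
distinct-variant count under singleton carriage.

## Statistics

- **Fisher one-sided** (default): the exact hypergeometric upper tail
  P(A ≥ a) at fixed margins, with the enrichment-in-cases alternative.
  Computed via `scipy.stats.hypergeom.sf`; the test suite checks it
  against an exhaustive enumeration oracle with exact integer
  binomials for all tables with n₁, n₂ ≤ 30 to 1e-12.
- **χ² one-sided**: half the two-sided 1-df Pearson p-value when the
  case carrier fraction exceeds the control fraction, 1 − half
  otherwise. The published analyses name the one-sided χ² but not its
  recipe; this signed-half construction is the standard one and is
  recorded in the report config. Continuity correction is off by
  default and configurable. A table with no carriers at all carries no
  information: p = 1 with a warning.
- **Test selection** in stratified tables: Fisher is forced whenever
  any expected cell is below 5; otherwise the configured test applies.
- **Odds ratio**: cross-product on the carrier table with a Woolf
  log-OR 95% CI, z = 1.96. Any zero cell renders the estimate
  undefined ("–" in reports), never infinity. Subject-level counting is
  the default because it is what reproduces the reference table's point
  estimates — e.g. (8/566)/(3/825) = 3.9; an allele-tally helper
  (`allele_counts`) supports the allele-based inventory columns.
- **Rounding for display**: OR to 1 decimal, P to 2 decimals, matching
  the print precision of published burden tables. Internal values are
  never rounded.

Known non-reproducibilities, deliberately left as they are: the
reference table's "Total"-row OR of 1.6 and its printed confidence
bounds do not follow from the standard cross-product/Woolf formulas
(which give 1.7 and slightly different bounds), and its P = 0.15 is not
produced by any of the recipes above; the Frameshift row's printed
P = 0.60 corresponds to the *control*-direction tail (0.59) rather than
the case-enrichment tail used uniformly here. These rows are rendered
from the package's own formulas.

## Cosegregation filter

The dominant filter assumes full penetrance and heterozygous carriage:
a variant cosegregates iff every genotyped affected member carries it
and every genotyped unaffected member does not, with at least two
informative members. Missing genotypes are non-informative, never
violations; an affected non-carrier is a hard violation (phenocopies
are out of model). A `tolerated_unaffected_carriers` knob (default 0)
relaxes the unaffected side for reduced-penetrance screens. Candidate
ranking orders cosegregating variants first, then LGD before damaging
missense before the rest, then descending CADD, stably.

## ACMG combination

The combiner implements the published 2015 combining criteria as a
packaged YAML table (18 rules: 8 Pathogenic, 6 Likely pathogenic, 2
Benign, 2 Likely benign) with minimum-count semantics per evidence
category; range phrasings such as "1–2 moderate" reduce to minimum
counts. Pathogenic- and benign-direction lists are evaluated
independently; if both fire the result is VUS with a warning, as is an
evidence set matching no rule. PP5/BP6 remain in the vocabulary despite
later ClinGen deprecation, because dominant-family loss-of-function
classifications in the literature still cite PP5. Evidence *assignment*
is out of scope: codes come from the curator.

## Synthetic-data generator

`simulate_cohort` emulates the study design end to end: rosters of 574
cases and 828 controls; per-subject carrier draws with control rate
p₀ = 14/828 and case rate p₁ solving p₁/(1−p₁) = OR·p₀/(1−p₀) for the
planted odds ratio; one singleton heterozygous variant per carrier
(a recurrence knob creates doubletons); consequences drawn with an LGD
rate of 2/30; CADD scores from a two-component normal mixture
(means 13 and 27, sds 3.5 and 4, damaging weight 11/30) straddling the
cutoff; frequency-resource leakage at a configurable rate (leaked
variants are later removed by the novelty filter); a coverage matrix
with an *exact* planted count of imbalanced sites (default fraction
0.048) for test stability; and a three-generation pedigree segregating
a planted nonsense variant plus a decoy. Everything is drawn from one
`numpy` generator seeded by the config, so identical configs produce
byte-identical fixture files (verified by SHA-256 manifests).

Variants are placed at coverage-balanced sites by default so the
planted odds ratio flows through pruning undiluted; pruned-site
behaviour is exercised by a dedicated test that plants a variant on an
imbalanced site and checks it never reaches any stratum count.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real exomes: linkage disequilibrium, population
structure, relatedness between cohort members, genotyping error,
covariates, and per-site depth distributions (coverage fractions are
drawn directly). Calibration sweeps (type-I error, power monotonicity,
odds-ratio recovery) draw carrier counts directly as binomials at the
study's cohort sizes, which is exactly the marginal distribution the
full generator induces under singleton carriage; the full generator is
additionally exercised end to end at 40 replicates.

`fbn1_fixture` is the deterministic packaged reference dataset. Its
eight case damaging-missense carrier records carry the published
positions, CADD scores, domain labels and the recurrent variant's
gnomAD frequency; every record the source tables do not itemize
(control carriers, low-CADD records, the coverage matrix, domain
interval boundaries) is synthetic, constructed only to match the
published marginal counts, and labelled as such in the data files.

## Problem sizes and numerical choices

The default test run uses 2000 null replicates for the type-I error
check, 800 per point for the power monotonicity sweep, 300 per planted
odds ratio for recovery (tolerance: median within 25%), and 1000
coding sites per simulated coverage matrix. Exact-test oracle sweeps
enumerate all tables with cohort sizes ≤ 30. Woolf intervals use
z = 1.959963984540054; float TSV IO uses `%.17g` formatting and
round-trip parsing so write/read cycles are exact.

## Limitations

Single-gene focus (the API accepts any gene label but no multi-gene
scan or correction); no covariate adjustment; no mid-p exact variant
(standard tails reproduce the reference p-values at print precision);
dominant model only in the pedigree filter (no recessive, X-linked or
de novo logic); HGVS handling limited to extracting the residue index.
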
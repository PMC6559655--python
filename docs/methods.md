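# Methods

This note documents the statistical model, the conventions and numerical
choices behind `rarecnv`, and what the synthetic-data generator does and
does not emulate.

## Carrier-based exact association

The unit of counting is the **carrier sample**, not the CNV event: a
sample with three qualifying duplications over one gene contributes one
carrier. This makes the 2 × 2 table margins equal to the cohort sizes and
keeps the hypergeometric conditioning valid; event-level counting would
double-count samples and inflate margins.

Conditioning on both margins of the table `[[a, n₁−a], [c, n₂−c]]`
leaves the case-carrier count `X` distributed as Fisher's noncentral
hypergeometric with odds ratio ψ on the support
`[max(0, K−n₂), min(K, n₁)]`, `K = a + c`.

* **Point estimate** — the conditional MLE solves `E_ψ[X] = a`; it is 0
  at the bottom of the support and +∞ at the top (e.g. zero control
  carriers). The sample cross-product ratio `ad/bc` is also reported
  (column `or_sample`) but never used for inference; for very skewed
  tables the two differ noticeably (155.2 vs 154.6 for a 12/231 vs
  1/2987 table).
* **Exact CI** — the lower endpoint solves `P(X ≥ a | ψ) = α/2`, the
  upper `P(X ≤ a | ψ) = α/2`.
* **Two-sided p** — the minimum-likelihood convention: the sum of all
  support probabilities `≤ P(a)·(1 + 10⁻⁷)`. This is the convention of
  both R's `fisher.test` and scipy's `fisher_exact`, verified against
  each independently in the test suite.

### Root-finding and literature compatibility

CI endpoints and the cMLE are located with Brent's *zeroin* — a direct
port of the reference netlib routine used by R's `uniroot` — on the ψ
scale within (0, 1], or on the reciprocal scale 1/ψ when the root
exceeds 1. The default convergence tolerance is `eps^0.25 ≈ 1.22e-4`,
the default of the R implementation that produced most published exact
CIs in this literature.

That default matters for extreme tables: on the reciprocal scale a
tolerance of 1.22e-4 leaves the *upper* limit of a very large odds ratio
only loosely determined, and the widely quoted values inherit this. For
the 12/231-vs-1/2987 table the tail equation `P(X ≤ 12 | ψ) = 0.025` is
exactly solved by ψ = 6635.0, while the standard implementation (and
hence the literature) reports 6349.5. `fisher_exact_2x2(..., ci_tol=1e-12)`
gives the mathematically exact endpoints; the default reproduces the
standard implementation digit-for-digit. The invariant tests check the
tail equations at high precision; the compatibility default is checked
against frozen reference values.

Degenerate tables (no carriers at all, or an empty cohort) return p = 1
with the odds ratio flagged undefined (NaN) rather than raising: an empty
carrier margin carries no evidence either way.

## Multiple testing and rarity

Every gene overlapped (≥ 1 bp) by at least one deletion anywhere in the
study enters the deletion universe, likewise for duplications; a gene can
appear in both. One pooled Benjamini–Hochberg step-up correction runs
over the union (m = deletion tests + duplication tests), matching the
genome-wide practice of correcting across both variant classes at once
rather than per class. `bh_adjust` implements the step-up formula
directly and is cross-checked against statsmodels.

Rarity is a strict control-side threshold: carrier fraction among
post-QC controls `< 0.001`. With ~3,000 controls this means at most two
control carriers. Case frequency plays no role in the rarity label; the
*significant-rare* report requires `is_rare` and `p_adj ≤ 0.01`.

## Consensus merging

"Same event seen by two callers" is operationalised as ≥ 1 bp overlap
with transitive closure: within each (sample, chromosome, type) stratum,
connected components of the interval-overlap graph. This is the most
permissive deterministic reading; `min_reciprocal_overlap` tightens the
edge rule to fractional reciprocal overlap when desired. Components
supported by a single caller are dropped regardless of how many calls
that caller contributed. The emitted span is the outermost union
(min start, max end); size/probe filters are applied to raw calls
*before* merging and the union span is not re-filtered, since a union
can only grow. With half-open coordinates, intervals that merely touch
(`[0, 10)` and `[10, 20)`) share no base and do not merge.

The sweep implementation is validated against an O(n²) union-find oracle
on 1,000 random instances.

Boundary semantics: "at least 5 kb / 5 probes" is implemented
inclusively (`length ≥ 5000`, `n_probes ≥ 5`); `strict_gt` switches the
length rule to strictly-greater for pipelines that quote it that way.

## Region exclusion

Centromere/telomere windows (the centromere ± 100 kb, plus the first and
last 100 kb of every chromosome) exclude on *any* overlap; segmental
duplication and immunoglobulin tracks exclude on overlap fraction
*strictly above* 0.70 of the CNV's length, computed against the merged
union of the track, making the fraction independent of how the track is
split into records. A CNV at exactly 70.0% is kept. Filters run on
stringent CNVs (after merging), with the raw-call alternative available
by reordering the library calls.

## Sample QC

Array-metric QC: call rate < 0.95 fails; `lrr_sd` / `baf_sd` outside
batch mean ± 3 sample-SD (n − 1 denominator) fails, with both bands
computed once on the full batch — no iterative re-screening. A batch of
one has no defined SD; its sample passes the band criteria with a logged
warning. A numerical guard (10⁻⁹ relative) keeps a degenerate band
(SD = 0) from flagging values equal to the mean. Note an arithmetic
consequence of in-batch standardisation: a single outlier in a batch of
m can sit at most (m−1)/√m sample-SDs from the mean, so a 3-SD rule is
only meaningful for batches of a dozen samples or more.

CNV-count QC is one-sided: only counts *above* mean + 3 SD are excluded
(an unusually quiet genome is not a failure mode of the assay). Counts
are of stringent CNVs after region filtering, including zero-count
samples. Sex-inconsistency and relatedness exclusions are accepted as an
external `--exclude-list`, not recomputed.

## Burden comparison

Length classes are half-open upward — [5, 100), [100, 500),
[500, 1000) kb, ≥ 1 Mb — so events land in exactly one class and an
event of exactly 100 kb is in the second class. The group comparison is
an observed-vs-expected construction: the total event count of a cell is
split in proportion to the group sample sizes, rounded half-away-from-zero
with the complement taken by subtraction (preserving the margin), and the
observed pair is tested against the expected pair with the two-tailed
Fisher test. The construction is symmetric under group swap and returns
p = 1 for empty cells.

Two caveats are worth recording. First, testing observed against a
*deterministic* expected doubles the variance the exact test assumes, so
the construction is conservative under the null (the calibration test
bounds, rather than matches, the 5% level). Second, three-decimal
p-values from such tables are sensitive to the expected-rounding and
two-sided-tie conventions: closely related variants (floor/ceil
expecteds, mid-p, Blaker, central, continuous-expected) differ in the
third decimal, and published three-decimal values of this construction
are not, in general, exactly attainable by any integer-table variant.
This package fixes the round-to-nearest + minimum-likelihood convention
and documents it.

## Subgroup contingency tests

Carrier status vs a clinical feature uses the exact 2 × 2 machinery for
two-level features. For r × 2 tables the exact conditional test
(probability ∝ ∏rᵢ!∏cⱼ!/N!∏nᵢⱼ!, summing all margin-compatible tables no
more likely than observed) is enumerated directly when N ≤ 200, else the
chi-square test is used; the method actually applied is recorded in the
result.

## Overrepresentation analysis

One-sided hypergeometric upper-tail enrichment (the standard ORA reading
of "Fisher's exact test"; a two-sided switch exists) of the query gene
set against the background of all CNV-overlapped genes, per gene set,
with BH applied within each library separately. Reported sets need ≥ 2
query hits and adjusted p ≤ 0.25 by default — a deliberately permissive
threshold appropriate for exploratory network interpretation rather than
confirmatory testing. Query genes outside the background are dropped
with a warning (the test is conditional on the background universe).
Hierarchy-aware gene-set filtering (e.g. restricting an ontology to
specific levels) is the responsibility of the supplied GMT files; the
package does not traverse ontology graphs.

## Synthetic studies

`generate_study` emulates the statistical structure of a SNP-array
rare-CNV case-control study on a miniature genome (default 8 chromosomes
× 25 Mb, 640 well-spaced genes of 10–100 kb):

* cohorts of 243 cases (120 CD / 123 UC) and 2,988 controls in 4 batches,
  with Gaussian array metrics (call rate ≈ 0.995 ± 0.002, LRR SD ≈
  0.12 ± 0.02, BAF SD ≈ 0.04 ± 0.008);
* ~18 consensus-detectable background CNVs per sample, placed uniformly,
  with a log-uniform length mixture putting ≈ 88% of events below 100 kb
  (weights 0.881 / 0.108 / 0.0075 / 0.0035 over the four length classes)
  and 65% deletions;
* three callers with sensitivities 0.95 / 0.93 / 0.90, breakpoint jitter
  (truncated normal, SD 300 bp, clipped at ±4 SD), and ~1 spurious call
  per sample per caller;
* probe counts from a uniform implicit density of 1 probe/kb
  (`n_probes = ⌊length × density⌋`), so the 5 kb size floor coincides
  with the 5-probe floor;
* planted signals: case-enriched CNVs at designated genes with *exact*
  carrier counts, each overlapping its gene by ≥ 2 kb before jitter.

Each stochastic component draws from its own child stream of the master
seed, so changing one rate does not reshuffle the others, and identical
configurations are byte-identical.

Three guarantees make planted truth exact rather than approximate, and
they are part of the definition of a planted signal ("n carriers in the
*analyzed* cohort") rather than tuning: planted events always reach ≥ 2
callers (the independent dropout draw is redrawn when it yields < 2);
planted carrier samples receive nominal array metrics and a mean
background CNV load, so sample QC cannot remove them; and background
events and false positives avoid the planted gene neighbourhoods. False
positives are additionally placed so that no same-sample, same-type call
from any caller overlaps them — they are single-caller by construction
and must vanish in consensus. Truth events of one sample and type are
kept ≥ 4 jitter-SD apart so they cannot merge into each other after
jitter.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: locus-specific CNV hotspots and
recurrent rearrangements (placement is uniform), realistic gene density
(≈ 20% of the miniature genome is genic vs ≈ 45% genic CNVs in real
studies), LRR/BAF intensity signals and caller HMM behaviour (dropout and
jitter are independent per caller, while real callers fail in correlated
ways), linkage between CNVs and batch or ancestry structure, and X/Y
chromosomes. Population stratification, relatedness and sex checks are
out of scope and enter only as an external exclusion list.

## Problem sizes used in the shipped checks

The acceptance script runs the full-scale synthetic study (243 / 2,988
samples, ≈ 58,000 true CNVs, ≈ 170,000 raw calls — about 15 s end to
end) plus ten 80/320-sample null replicates for FDR calibration; the
test suite uses the same full-scale study once and otherwise reduced
studies (40–80 cases) chosen to keep the whole suite under a minute
while preserving every qualitative regime (planted recovery, QC outlier
separation ≥ 5 SD, null calibration).
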
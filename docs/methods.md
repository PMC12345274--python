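# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the design decisions where the analysis left
genuine freedom. Every number quoted here is computed by the test suite or
the acceptance script.

## Differential expression

FPKM matrices (genes × replicate samples per condition) are first screened
for full coverage: a gene with an FPKM of zero in any sample of either
condition is excluded before testing. All retained samples are then
quantile normalized together: each column's sorted value vector is replaced
by the per-rank cross-column mean; ties within a column receive the mean of
the normalized values of their tied ranks (dialects differ here — the
mean-of-tied-ranks rule is used and pinned by an oracle test against an
explicit rank-then-mean implementation).

A gene is called differentially expressed when both criteria hold as
*strict* inequalities:

* two-tailed two-sample Student's *t*-test (equal-variance form) on the
  quantile-normalized values, *P* < 0.05;
* fold change > 2 computed on **raw** FPKM condition means, with a
  pseudocount of ε = 0.01 added to both means.

Where the test runs (raw vs normalized values) is switchable
(`deg_test_on_normalized`); the default tests on normalized values and
computes fold change on raw means, the only combination consistent with
normalizing for inference while reporting biological fold changes. The
pseudocount prevents infinite ratios for mutant-silenced genes without
moving any two-fold decision at FPKM ≥ 1. No multiple-testing correction is
applied by default (raw *P* < α); Benjamini–Hochberg is available behind
`deg_fdr`.

Sign convention: log₂FC = log₂(mean WT / mean mutant). Negative log₂FC ⇒
the gene is **up in the deletion mutant** (the regulator represses it);
positive ⇒ down in the mutant. Degenerate rows whose *t* statistic is
undefined (zero variance in both groups with equal means) receive *P* = 1.

Cross-complementation rescue accounting compares two direction-labelled DEG
sets called against the same mutant baseline (WT vs mutant, and
cross-complemented strain vs mutant) and reports, per direction: the cross
set size, its overlap with the WT profile, and the WT-specific remainder
(WT \ cross). The WT-specific remainder is an interpretation choice — the
reference set is the WT profile — and is the reading that makes the three
reported numbers internally consistent.

## Promoter windows and target classes

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) is converted on read, BED passes through. The promoter window is
anchored at the **translation start site** (first CDS base in transcription
order), not the transcription start; when an annotation lacks CDS features
the gene's 5′ end is the documented fallback. For a + strand gene with
translation start t and window w the promoter is [t−w, t); for a − strand
gene it mirrors to [t+1, t+1+w). The translation-start base itself is
excluded (strictly upstream), windows are clipped at chromosome bounds, and
w = 1500 by default.

A gene is bound when at least one peak interval overlaps its window by ≥ 1
base (default mode `interval`); mode `summit` instead requires the peak
summit inside the window — both exist because peak callers and window
conventions vary. A peak overlapping several promoters is assigned to all
of them (the rule is per-gene; no nearest-gene tie-breaking).

Target classes obey set identities enforced in code: direct = bound ∩ DEG,
indirect = DEG \ bound, associated = bound ∪ DEG. Percent-of-universe
figures are rounded to one decimal.

## Motif scanning and enrichment

The NRE motif (5′-GATCT-3′ by default) is counted with overlapping matches
on both strands (the reverse-complement AGATC is scanned on the forward
sequence). Non-ACGT characters never match. Enrichment of bound vs
background promoters uses the difference of mean per-kb occurrence rates as
the statistic and a label-shuffling permutation test with the (r+1)/(n+1)
tail estimator (upper tail: excess in bound).

## Network construction

PPI edges are kept at confidence ≥ 150 — inclusive, matching the "score of
at least 150" convention — with unordered duplicate pairs collapsed to
their maximum confidence and self-loops dropped. The backbone keeps every
filtered edge whose **both** endpoints are associated genes and layers a
direct-binding star from the regulator onto every bound gene (so
direct-binding edges survive export with a `direct` flag). Isolated
associated genes are retained as nodes by default (toggle
`keep_isolated_associated`), a conservative choice since nothing in the
procedure requires connectivity.

Guilt-by-association expansion is exactly depth 1: every node adjacent to a
backbone node is added with origin `neighbor`, along with its connecting
edges; neighbors of neighbors, and edges among two added neighbors, are
never added. A property test applies the expansion twice to guard against
accidental transitive closure.

Core extraction is this package's own deterministic rule (the original
procedure is described only as "approximately 30 genes"): the regulator and
all seed regulators are always included, then neighbors of seeds ranked by
full-network degree (descending) with lexicographic gene-id tie-breaks fill
the remaining slots up to `core_size_target`; the induced subgraph is
returned. The original core memberships are not reproducible from this rule
and are not claimed.

Functional categories come from a fixed seven-label palette (vegetative
growth, asexual development, sexual development, primary metabolism,
secondary metabolism, transcription regulation, unannotated); unmapped
genes are `unannotated`, unknown labels are a hard error.

## Comparative rewiring

The raw ortholog list is reduced to its one-to-one core: any id appearing
in more than one pair discards all its pairs (many-to-many relations are
excluded rather than expanded, so shared-target counts are counts of
pairs). A pair is a **shared target** only when both ends are associated in
their respective species; a gene whose ortholog exists but is not a target
in the other species counts as species-specific. This is the reading under
which |shared| + |specific| equals each species' associated-set size — the
conservation identity the test suite checks on random instances.

The merged network collapses each shared pair into one node carrying both
ids, merges the two regulator nodes into one, labels nodes by side
(shared / A_specific / B_specific) and edges by provenance (A / B / both),
and requires the two gene namespaces to be disjoint apart from paired ids.

## GO enrichment

Upper-tail hypergeometric *P* = P(X ≥ k) for k query hits of a K-gene term
in an n-gene query from an N-gene universe, computed with
`scipy.stats.hypergeom.sf(k-1, N, K, n)` and verified against complete
subset enumeration for N ≤ 12. One-sided over-representation only; flat
annotations (no ontology-graph propagation); no multiple-testing correction
by default. Terms with *P* < α (strict) are ranked by (*P* asc, k desc,
term id asc); "representative categories" are the top rows of that ranking,
a deterministic stand-in for a qualitative curation step.

## Metabolomics

Features are eligible for differential calling when their mean intensity
exceeds 10⁶ in **at least one** condition ("either" rather than "both", so
a genotype-absent metabolite remains callable). The test is Student's
two-sample *t* on log₁₀(intensity + 1) — chosen for symmetry with the
RNA-seq screen, as no specific test is implied by the procedure — with
log₂FC on condition means (pseudocount 1) and the same strict
double-threshold (*P* < 0.05, |log₂FC| > 1).

Presence/absence classes use the same intensity gate as detection
threshold: wt_only / mutant_only / both / neither by condition means.

Identification matches feature m/z to library monoisotopic masses at
±0.001 Da **inclusive** (the boundary case |Δm| = 0.001 matches), plus
±1.5 retention-time units when the library entry has a reference RT.
"Within three decimal digits" for database-only matching is implemented as
the same ±0.001 Da rule for uniformity. Adduct handling is a config shift
(`mass_adduct_shift`, default 0: neutral-mass comparison), since the m/z →
exact-mass conversion of the source data is unspecified. Retention-time
units are assumed to be minutes.

## Synthetic data model

The generator emulates the *processed* forms of the study's inputs, not raw
reads. Defaults (one pseudo-species):

| parameter | default | why |
|---|---|---|
| genes | 2,000 on 2 chromosomes | keeps the full suite under seconds; genome-scale runs only change N |
| gene pitch | 1,200 bp gene + 5,000 bp intergenic | ≥ 3 kb spacing; windows and decoy peaks provably never collide |
| replicates | 3 per condition | standard RNA-seq design; configurable |
| FPKM baseline | log-normal, meanlog 2, sdlog 1 | right-skewed expression, median ≈ 7 FPKM |
| replicate noise | multiplicative log-normal, sdlog 0.25 | mild overdispersion; no noise model is given by the source data, this is the package's choice |
| planted DEG effect | 4-fold, 5% up + 5% down | ≥ 4-fold survives the twofold + *t* screen at n = 3 with > 90% power |
| bound genes | 5%, one 300 bp peak inside the window | strand-correct placement makes a strand-ignoring rule fail |
| decoy genes | 5%, peak ≥ 2 kb upstream | falsifies window-size errors |
| motif copies | 3 per bound promoter, Poisson(0.3) extra in background | background random sequence already carries ≈ 2.9 GATCT/AGATC copies per 1.5 kb |
| PPI | 10 modules × 30 genes, p_within 0.3, p_between 0.01 | stochastic block model; within-module confidence U(150, 999), between U(50, 400) so the 150 floor removes a closed-form fraction |
| orthologs | 60% one-to-one | partial overlap exercises shared/specific partitioning |
| metabolome | 600 features, planted |log₂| = 2 shifts on 10%, 10 WT-only, 5 mutant-only, 10% library hits at ±0.0005 Da | mirrors the differential/presence/identification stages |

What the generator does **not** emulate: read-level noise, peak-shape
artifacts, correlated gene expression (genes are independent), GC/mappability
bias, chromatographic drift, and real fungal genome composition. Passing
the planted-recovery tests therefore demonstrates that the *decision rules*
are implemented correctly and calibrated under the assumed noise model — it
does not certify performance on real libraries, where replicate noise is
correlated and effect sizes are continuous rather than planted.

Null calibration: with no planted signal, the fraction of genes (or
gate-passing features) with *P* < 0.05 must fall inside the two-sided 99%
binomial band around α. The calibrated quantity is the *test's* hit rate;
the full two-threshold screen is conservative by design (the fold-change
gate pushes null calls to ≈ 0) and is checked separately.

Determinism: every stage derives its generator from
`SeedSequence([rng_seed, crc32(species/stream)])`, so each species and data
stream has an independent, reproducible stream and identical specs yield
byte-identical files.

## Problem sizes

The default study (2,000 genes × 2 species, ~21k PPI edges, 600 metabolite
features) is the size at which all property suites, planted-recovery checks
and null calibrations run in seconds; the worked set-integration examples
use the published cardinalities directly (universes of 10,988 and 13,485
ids) because set algebra is size-exact at any scale.

## Known limitations

* Quantile normalization assumes comparable global distributions across
  samples; strongly asymmetric perturbations violate this.
* The equal-variance *t*-test at n = 3 is fragile to outliers; the pipeline
  reports raw *P* values, matching the source convention, so genome-wide
  lists carry the expected ~5% false positives among nulls.
* Ortholog sharedness is pairwise and one-to-one; paralog expansions are
  deliberately excluded.
* GO enrichment treats annotations as flat sets; parent-term propagation
  would change K and is out of scope.
* Core-subnetwork membership depends on the package's own ranking rule and
  should not be compared gene-for-gene with manually curated cores.
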
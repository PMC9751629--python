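# Methods

## Quantification model

Spectral counting treats the number of peptide-spectrum matches (PSMs)
assigned to a protein as its abundance signal. Because longer proteins yield
more observable peptides, the normalized spectral abundance factor divides
the count by amino-acid length before normalizing within the run:
NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j), summed over proteins detected
(SpC > 0) in that run. Consequences the implementation relies on:

- NSAF sums to exactly 1 per (condition, replicate); the test suite asserts
  this to 1e-9 on random tables.
- NSAF is invariant to multiplying a run's counts by a constant — sequencing
  depth cancels.
- NSAF is **compositional**: a protein's value depends on every other
  protein in the run (see *Fold-change identifiability* below).

Normalization happens per replicate *before* the presence filter, the
standard NSAF definition; `compute_nsaf(..., normalize_after_filter=True)`
restricts the denominator to presence-passing proteins for users who prefer
the other reading. Relative abundance (%) is the mean of 100·NSAF over all
replicates of a condition, counting 0 for runs where the protein was
undetected; that zero-counting matters only for diagnostics, since the
final dataset requires detection in every replicate anyway. The replicate
count is never hard-coded: "all replicates" means all provided for that
condition.

The 1% protein-FDR filter acts on an optional per-row q-value; rows without
one pass unchanged, on the assumption that the upstream search engine
already applied its validator. The comparison layer adds no statistical
test — fold changes are descriptive abundance ratios, reported unlogged
(with a log2 column), and the 0.1% average-abundance threshold *flags*
low-abundance proteins rather than dropping them, because proteins below it
can still be biologically informative. Threshold semantics are switchable
(`mean` of the two condition means, default; `both`; `either`).

## Synthetic study generator

`gen_psm_study` draws counts as Poisson(depth · base_abundance · effect ·
length): rate proportional to length is the simplest generative model under
which NSAF's length division is exactly the right correction. The effect is
the planted TD/SR fold change for shared proteins (1 in SR), 1 for a
condition-exclusive protein in its own condition and 0 in the other.
Detection dropout is an independent post-Poisson zeroing of (protein,
replicate) cells, so presence-filter behavior can be stressed independently
of depth. Each protein has its own RNG substream keyed by (seed, protein
id), so adding a protein never changes another's draws.

Default study conditions: 36 TD-exclusive, 476 SR-exclusive, 660 shared
proteins (1,172 total) over biological triplicates; fold changes log-uniform
in [0.25, 4]; base abundances log-uniform in [0.5, 2]; lengths uniform in
[150, 800] aa; depth 2.0. At these settings the smallest planted rate is
λ = 2·0.5·0.25·150 ≈ 37, so with dropout 0 the probability that any planted
protein misses any replicate is below 1e-12 per cell — presence recovery is
deterministic for all practical purposes. Tests rely on λ ≥ 20
(P(zero) = e⁻²⁰ ≈ 2·10⁻⁹ per run).

### Fold-change identifiability

The planted fold change multiplies *counts*, but the pipeline estimates a
ratio of *relative* abundances. Since SAF = count/length, the per-run SAF
total is Σ_j base_j·effect_j·depth, so the expected NSAF ratio for shared
protein *i* is f_i · ΣSAF(SR) / ΣSAF(TD) — the raw multiplier shrunk by one
global compositional factor (≈0.74 when folds are log-uniform in [0.25, 4]
over a large study). The identifiable quantity is therefore the
compositional ratio, which `PlantedProteomeTruth.expected_fold_changes()`
computes exactly from the planted parameters; recovery tests compare the
pipeline's estimates against those values. With triplicates and mean counts
in the hundreds, ≥90% of shared proteins land within 10% relative error on
every tested seed.

What the generator does *not* emulate: peptide-level identification and
shared-peptide ambiguity, run-to-run normalization artifacts, intensity-based
quantification, correlated (batch) noise, and abundance-dependent dropout.
Passing tests therefore demonstrate the pipeline's arithmetic and filtering
logic under a clean counting model, not robustness to those real-data
effects.

## Cluster calling

Subunit labels come first from an ortholog-group map (locus tag → label
token), then from ordered case-insensitive product-keyword rules (an
editable table; B/C patterns are matched before generic catalytic patterns
so "subunit B" never falls through to an A label). Candidate catalytic
subunits (ttrA/phsA) shorter than `min_a_length` are demoted to unlabeled:
catalytic molybdopterin subunits run ~700–1,000 aa, and 500 aa (default,
configurable) conservatively separates them from small homologs when no
published threshold exists.

Complex detection seeds on A subunits — the catalytic subunit anchors the
biological question of which enzyme is present — and gathers same-family B
and C within `max_gap` intervening genes (default 1) on either side, gap
counted from the last accepted member. Completeness: `complete` (A+B+C),
`lacking_C` (A+B), otherwise `partial`. Strand agreement is recorded per
call but never required. With `allow_distant` (ttr only), each remaining
A-only call is joined to the nearest unconsumed adjacent B–C pair anywhere
in the genome and flagged `distant`; no gene ever joins two calls. The YTD
detector reports maximal runs holding at least 3 of the 5 roles
(configurable floor): the complete cluster is the five-gene unit, and the
floor makes partial clusters visible without inflating calls. Both
subunit order readings (AB and BA, BCA and ABC, ...) are accepted; the
observed order is reported in the arrangement string.

Detection is invariant to input row order (genes are sorted internally by
contig and coordinate; start ties break by locus tag), and increasing
`max_gap` never loses complete calls.

## Panel cross-tabulation

"untested" is a first-class phenotype state: the literature distinguishes
species with no disproportionation reports from species tested negative, and
collapsing the two would overstate the evidence. The crosstab is a 2×3
count table (feature ± × yes/no/untested) plus derived counts; no
association test is computed by default, since the scientific claims here
are descriptive. A Fisher exact test on the yes/no subtable is available as
an explicitly labeled extension.

## Reaction balancing

The balancer builds one conservation row per element plus one charge row
(product columns negated) and computes the nullspace with exact rational
arithmetic — a floating-point nullspace would break the gcd normalization
that defines "minimal integer coefficients". A one-dimensional nullspace
with a strictly positive representative yields the unique minimal solution;
mixed signs mean the written reactant/product orientation is infeasible; a
higher-dimensional nullspace is reported as underdetermined with its free
directions. Tetrathionate disproportionation
(S4O6²⁻ → S2O3²⁻ + S3O6²⁻ + SO4²⁻) is underdetermined by conservation
alone; anchoring trithionate and sulfate at one each
(`TETRATHIONATE_ANCHORS`, also a CLI preset) pins the classical 4:4→6:1:1:8
stoichiometry. Anchors are honored exactly rather than rescaled.

Redox feasibility uses ΔE = Em(acceptor) − Em(donor) and ΔG = −nFΔE with
F = 96.485 kJ·mol⁻¹·V⁻¹; midpoint potentials are taken as opaque inputs in
mV, with no activity, pH or temperature corrections (full thermodynamic
modeling is out of scope).

## Genome statistics and formats

Coordinates are 1-based inclusive everywhere, the GFF3/GenBank convention.
G+C content is computed over unambiguous A/C/G/T only; N and other ambiguity
codes count toward total length but are excluded from both numerator and
denominator, matching common assembler reporting. Annotation readers return
records sorted by (contig, start, locus_tag) regardless of file order and
reject duplicate locus tags. `n_genes` reports records parsed, with no claim
about pseudogene inclusion. GFF3 parsing is delegated to gffutils, GenBank
and FASTA to Biopython; the PSM table is a package-defined TSV because
search-engine exports are vendor-specific.

## Problem sizes in tests and the acceptance script

The default test run uses the study sizes above (1,172-protein studies;
20-seed recovery runs with 712 proteins each; 1,000 decoy-genome seeds at 50
genes; 1,000 random NSAF tables of ≤8 proteins), chosen so the planted
effects are resolved with large margins while the whole suite completes in
well under a minute. The acceptance script regenerates the full planted
study and balances the three reactions at run time; nothing it reports is
stored.

## Known limitations

- Per-protein PSM counts are taken as given; shared-peptide apportionment is
  upstream's problem.
- Subunit labeling is annotation-driven — no sequence similarity search or
  HMMs — so unannotated or oddly named genes are invisible to the cluster
  caller.
- The real 93-genome panel's per-species assignments are not bundled; panel
  logic is exercised on synthetic panels with the same shape.
- The balancer handles single reactions; it does not compose half-reactions
  or compute reaction free energies from formation data.
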
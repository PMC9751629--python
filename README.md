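# disproteo

Comparative spectral-count proteomics and sulfur-metabolism genomics for
studies of sulfur-disproportionating bacteria — organisms that split a single
intermediate-oxidation-state sulfur compound (S⁰, thiosulfate, tetrathionate)
simultaneously into sulfide and sulfate. The package is aimed at
microbiologists comparing a disproportionation condition against an
alternative metabolism (e.g. hydrogenotrophic sulfate reduction) by label-free
proteomics, and at comparative genomicists screening genomes for the
molybdoenzyme gene clusters implicated in that metabolism.

## What it computes

**NSAF quantification and two-condition comparison.** For protein *i* in one
run, SAF_i = SpC_i / L_i (peptide-spectrum matches over amino-acid length) and

    NSAF_i = SAF_i / Σ_j SAF_j

over the proteins detected in that run, so NSAF sums to 1 per replicate.
Relative abundance (%) is the replicate mean of 100·NSAF. After a 1% protein
FDR filter, a condition's *final dataset* keeps only proteins detected in all
of its replicates; the two final datasets are partitioned into
condition-exclusive and shared proteins, with unlogged fold changes
(TD mean ÷ SR mean), abundance ranks, and top-N exclusive tables.

**Gene-cluster calling.** Tetrathionate-reductase-type (TtrBCA) and
thiosulfate-reductase-type (PhsAB(C)) complexes are called by labeling
candidate subunits (from ortholog-group annotations or product keywords, with
a length veto on catalytic A subunits) and scanning the gene neighborhood of
each A subunit; a lone *ttrA* may be joined with a distantly encoded
*ttrB–ttrC* pair. The five-gene YTD cluster (YedE, TusA, DsrE-2, Chp2, Chp1)
is called from maximal runs of its roles.

**Ortholog panel cross-tabulation.** Ortholog groups (Orthogroups.tsv dialect)
are annotated by a reference strain's product descriptions; feature presence
across a genome panel is cross-tabulated against sulfur-disproportionation
phenotypes, with "untested" kept distinct from tested-negative.

**Stoichiometry and redox feasibility.** A rational-nullspace balancer yields
exact minimal integer coefficients for disproportionation reactions, e.g.

    4 S0 + 4 H2O -> SO4^2- + 3 HS^- + 5 H^+

and evaluates electron-flow feasibility between midpoint-potential couples
(ΔE = Em_acceptor − Em_donor, ΔG = −nFΔE).

**Synthetic data.** Generators for Poisson spectral-count studies, genomes
with planted clusters among decoy genes, and feature/phenotype panels — all
with recorded ground truth, so every pipeline stage is testable offline.

## Worked example

```python
from disproteo import (PlantedProteomeTruth, gen_psm_study, fdr_filter,
                       compute_nsaf, final_dataset, partition)

truth = PlantedProteomeTruth.generate(seed=42)   # planted study structure
q = compute_nsaf(fdr_filter(gen_psm_study(truth, n_reps=3), q_max=0.01))
part = partition(final_dataset(q, "TD"), final_dataset(q, "SR"))
print(part.n_total, part.n_a_only, part.n_b_only, part.n_shared)
```

prints

    1172 36 476 660

1,172 proteins pass the presence filter in at least one condition; 36 are
exclusive to the thiosulfate-disproportionating condition (TD), 476 to the
sulfate-reducing condition (SR), and 660 are shared — exactly the planted
detection structure, because the study was generated without dropout and
every planted Poisson rate is far above the detection floor. The
`examples/` directory holds one short script per capability (reaction
balancing, proteome comparison, cluster detection, panel cross-tabulation,
genome statistics); each prints its results with a note on what they mean.

A thin CLI wraps the same functions:

```sh
disproteo balance "S0 + H2O -> SO4^2- + HS^- + H^+"
disproteo simulate proteome --seed 4 --out sim/
disproteo quantify --psm sim/psm.tsv --out quant.tsv
disproteo compare --quant sim/psm.tsv --out compare.tsv
disproteo genome-stats genome.fna --gff genome.gff3
```

## PSM table format

Quantification reads a plain TSV with columns `condition`, `replicate`,
`protein_id`, `length_aa`, `psm_count` and optionally `q_value` (protein-level
FDR q-value; rows without one are treated as pre-filtered upstream). Search
engine exports are vendor-specific, so converting to this table is the
caller's one manual step.

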
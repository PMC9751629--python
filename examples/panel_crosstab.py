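"""Cross-tabulate ortholog-group presence against disproportionation phenotype.

Simulates a 93-genome panel (33 sulfur disproportionators) in which the
tetrathionate-reductase feature is enriched among disproportionators, then
builds the presence matrix and the 2x3 feature-vs-phenotype count table.
"untested" is kept separate from tested-negative throughout.
"""

from disproteo import crosstab, gen_panel, presence_matrix

groups, phenotypes, truth = gen_panel(
    n_species=93,
    p_feature_given_disprop=0.8,
    p_feature_given_other=0.1,
    seed=5,
)
matrix = presence_matrix(groups, [g.group_id for g in groups],
                         species=list(truth.index))
table, derived = crosstab(matrix, phenotypes, "OG_ttr")
print(table)
print()
for k, v in derived.items():
    print(f"{k}: {v}")
# n_feature_and_yes counts species that both carry the feature group and are
# confirmed disproportionators; the three phenotype columns always sum to
# the panel size.
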
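"""Call ttr/phs/YTD gene clusters in a synthetic genome.

Plants a contiguous ttrBCA operon, a phsAB pair lacking subunit C, a lone
ttrA with its ttrB-ttrC pair 40 genes away, and the five-gene YTD cluster
among 120 decoy genes, then recovers all four by neighborhood scanning.
"""

from disproteo import (
    PlantSpec,
    detect_complexes,
    detect_ytd,
    gen_genome,
    label_subunits,
    summarize_species,
)

plants = [
    PlantSpec("ttr", "BCA"),
    PlantSpec("phs", "AB"),
    PlantSpec("ttr", distant_gap=40),
    PlantSpec("ytd"),
]
genes, proteins, truth = gen_genome(120, plants, seed=7)

labeled = label_subunits(genes, min_a_length=500)
calls = (
    detect_complexes(labeled, "ttr", max_gap=1, allow_distant=True)
    + detect_complexes(labeled, "phs", max_gap=1)
    + detect_ytd(labeled, max_gap=1)
)
for c in calls:
    print(f"{c.family:>3}  {c.completeness:<10} arrangement={c.arrangement:<26} "
          f"distant={c.distant}  members={','.join(c.locus_tags())}")

print("\nper-species summary (counts per cluster category):")
print(summarize_species({"synthetic_strain": calls}).T)
# 'complete' = A+B+C present; 'lacking_C' = catalytic + electron-transfer
# subunits only; a distant call joins a lone catalytic subunit with a
# remote B-C pair and still counts as one complex.
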
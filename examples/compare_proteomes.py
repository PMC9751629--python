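"""Two-condition spectral-count comparison on a synthetic study.

Generates a triplicate study for a thiosulfate-disproportionating (TD) versus
sulfate-reducing (SR) condition with a planted detection structure, then runs
the full pipeline: 1% FDR filter, per-replicate NSAF normalization, presence-
in-all-replicates filter, shared/exclusive partition, fold changes and the
top-10 table of TD-exclusive proteins.
"""

from disproteo import (
    PlantedProteomeTruth,
    compute_nsaf,
    fdr_filter,
    final_dataset,
    fold_changes,
    gen_psm_study,
    partition,
    top_exclusive,
)

truth = PlantedProteomeTruth.generate(seed=42)  # 36 TD / 476 SR exclusive, 660 shared
records = fdr_filter(gen_psm_study(truth, n_reps=3), q_max=0.01)
q = compute_nsaf(records)

part = partition(final_dataset(q, "TD"), final_dataset(q, "SR"))
print(f"proteins total={part.n_total}  TD-only={part.n_a_only}  "
      f"SR-only={part.n_b_only}  shared={part.n_shared}")

rows = fold_changes(q, part, threshold=0.1)
shared = rows[rows["partition"] == "shared"]
print(f"shared proteins above the 0.1% abundance threshold: "
      f"{int(shared['above_threshold'].sum())} of {len(shared)}")

top = top_exclusive(rows, q, "TD", n=10)
print("\ntop 10 TD-exclusive proteins (mean relative abundance %, TD rank):")
for _, r in top.iterrows():
    print(f"  {r.protein_id}  {r.mean_percent:.3f}%  rank {int(r['rank'])}")
# The partition counts equal the planted structure because dropout is 0 and
# every planted Poisson rate is far above the detection floor.
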
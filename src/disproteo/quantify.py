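"""Label-free quantification by normalized spectral abundance factors (NSAF).

For protein *i* in one replicate run, SAF_i = SpC_i / L_i (spectral count over
amino-acid length) and NSAF_i = SAF_i / Σ_j SAF_j over the proteins detected
in that run, so NSAF sums to 1 per run. Relative protein abundance is the
replicate mean of 100·NSAF. The final dataset of a condition keeps only
proteins detected in every replicate of that condition.

Normalization happens per replicate BEFORE the all-replicates presence
filter (results are combined and then filtered); ``compute_nsaf`` exposes
``normalize_after_filter`` for the alternative reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .formats_io import PsmRecord

__all__ = ["QuantTable", "fdr_filter", "compute_nsaf", "final_dataset"]


@dataclass
class QuantTable:
    """Per-replicate NSAF values plus per-condition summary.

    ``replicate_nsaf`` has columns (condition, replicate, protein_id, psm_count,
    nsaf) with one row per detected protein per run. ``summary`` has columns
    (condition, protein_id, mean_percent, detected, n_replicates), where
    ``mean_percent`` averages 100·NSAF over all replicates of the condition
    (0 for runs where the protein was undetected) and ``detected`` flags
    presence in every replicate of the condition.
    """

    replicate_nsaf: pd.DataFrame
    summary: pd.DataFrame

    def conditions(self) -> list[str]:
        return sorted(self.summary["condition"].unique())

    def mean_percent(self, condition: str, protein_id: str) -> float:
        sel = self.summary[
            (self.summary["condition"] == condition)
            & (self.summary["protein_id"] == protein_id)
        ]
        if sel.empty:
            return 0.0
        return float(sel["mean_percent"].iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        wide = self.replicate_nsaf.pivot_table(
            index=["condition", "protein_id"],
            columns="replicate",
            values="nsaf",
            fill_value=0.0,
        )
        wide.columns = [f"rep{r}_nsaf" for r in wide.columns]
        out = self.summary.set_index(["condition", "protein_id"]).join(wide).reset_index()
        out.to_csv(path, sep="\t", index=False)


def fdr_filter(records: Iterable[PsmRecord], q_max: float = 0.01) -> list[PsmRecord]:
    """Drop rows whose protein-level q-value exceeds ``q_max`` (default 1% FDR).

    Rows without a q-value pass unchanged — they are treated as filtered
    upstream by the search engine.
    """
    if not 0.0 < q_max <= 1.0:
        raise ValueError("q_max must be in (0, 1]")
    return [r for r in records if r.q_value is None or r.q_value <= q_max]


def compute_nsaf(
    records: Iterable[PsmRecord],
    normalize_after_filter: bool = False,
) -> QuantTable:
    """Compute per-replicate NSAF and the per-condition abundance summary.

    A replicate run with zero total spectral counts is an error ("empty
    replicate"). With ``normalize_after_filter`` the NSAF denominator is
    restricted to proteins that pass the all-replicates presence filter.
    """
    df = pd.DataFrame(
        [
            {
                "condition": r.condition,
                "replicate": r.replicate,
                "protein_id": r.protein_id,
                "length_aa": r.length_aa,
                "psm_count": r.psm_count,
            }
            for r in records
        ]
    )
    if df.empty:
        return QuantTable(
            replicate_nsaf=pd.DataFrame(
                columns=["condition", "replicate", "protein_id", "psm_count", "nsaf"]
            ),
            summary=pd.DataFrame(
                columns=["condition", "protein_id", "mean_percent", "detected", "n_replicates"]
            ),
        )

    n_reps = df.groupby("condition")["replicate"].nunique()

    for (cond, rep), grp in df.groupby(["condition", "replicate"]):
        if grp["psm_count"].sum() == 0:
            raise ValueError(f"empty replicate: condition {cond!r} replicate {rep}")

    detected = df[df["psm_count"] > 0].copy()
    if normalize_after_filter:
        reps_per = detected.groupby(["condition", "protein_id"])["replicate"].nunique()
        full = reps_per[reps_per == n_reps.reindex(reps_per.index.get_level_values(0)).values]
        keep = set(full.index)
        detected = detected[
            [
                (c, p) in keep
                for c, p in zip(detected["condition"], detected["protein_id"])
            ]
        ]

    detected["saf"] = detected["psm_count"] / detected["length_aa"]
    detected["nsaf"] = detected["saf"] / detected.groupby(
        ["condition", "replicate"]
    )["saf"].transform("sum")
    replicate_nsaf = detected[
        ["condition", "replicate", "protein_id", "psm_count", "nsaf"]
    ].reset_index(drop=True)

    # mean over ALL replicates of the condition, absent runs contributing 0
    sums = replicate_nsaf.groupby(["condition", "protein_id"])["nsaf"].sum()
    reps_present = replicate_nsaf.groupby(["condition", "protein_id"])["replicate"].nunique()
    summary = pd.DataFrame(
        {
            "nsaf_sum": sums,
            "reps_present": reps_present,
        }
    ).reset_index()
    summary["n_replicates"] = summary["condition"].map(n_reps)
    summary["mean_percent"] = 100.0 * summary["nsaf_sum"] / summary["n_replicates"]
    summary["detected"] = summary["reps_present"] == summary["n_replicates"]
    summary = summary[
        ["condition", "protein_id", "mean_percent", "detected", "n_replicates"]
    ].sort_values(["condition", "protein_id"]).reset_index(drop=True)
    return QuantTable(replicate_nsaf=replicate_nsaf, summary=summary)


def final_dataset(q: QuantTable, condition: str) -> set[str]:
    """Proteins present in all replicates of ``condition`` (the final dataset)."""
    if q.summary.empty:
        return set()
    if condition not in set(q.summary["condition"]):
        raise KeyError(f"unknown condition {condition!r}")
    sel = q.summary[(q.summary["condition"] == condition) & q.summary["detected"]]
    return set(sel["protein_id"])
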
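"""Two-condition comparative layer: partition, fold changes, ranks, top tables.

Proteins passing the all-replicates presence filter in exactly one condition
are "exclusive" to it; those passing in both are "shared". Fold changes are
unlogged ratios of mean relative abundance (TD mean ÷ SR mean); an
abundance-reporting threshold θ (default 0.1% average relative abundance)
flags low-abundance proteins without dropping them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .quantify import QuantTable

__all__ = [
    "PartitionResult",
    "partition",
    "fold_changes",
    "rank_table",
    "top_exclusive",
]


@dataclass(frozen=True)
class PartitionResult:
    """Shared/exclusive partition of two final datasets with counts."""

    labels: Mapping[str, str]  # protein_id -> "shared" | "exclusive:<cond>"
    n_total: int
    n_a_only: int
    n_b_only: int
    n_shared: int
    condition_a: str
    condition_b: str

    def exclusives(self, condition: str) -> set[str]:
        tag = f"exclusive:{condition}"
        return {p for p, lab in self.labels.items() if lab == tag}

    @property
    def shared(self) -> set[str]:
        return {p for p, lab in self.labels.items() if lab == "shared"}


def partition(
    final_a: set[str],
    final_b: set[str],
    condition_a: str = "TD",
    condition_b: str = "SR",
) -> PartitionResult:
    """Partition the union of two final datasets into exclusive/shared sets."""
    a_only = final_a - final_b
    b_only = final_b - final_a
    shared = final_a & final_b
    labels: dict[str, str] = {}
    labels.update({p: f"exclusive:{condition_a}" for p in a_only})
    labels.update({p: f"exclusive:{condition_b}" for p in b_only})
    labels.update({p: "shared" for p in shared})
    return PartitionResult(
        labels=labels,
        n_total=len(final_a | final_b),
        n_a_only=len(a_only),
        n_b_only=len(b_only),
        n_shared=len(shared),
        condition_a=condition_a,
        condition_b=condition_b,
    )


def fold_changes(
    q: QuantTable,
    part: PartitionResult,
    threshold: float = 0.1,
    threshold_mode: str = "mean",
) -> pd.DataFrame:
    """Per-protein comparison rows: partition label, means, fold change, flag.

    ``fold_change`` = mean_percent(condition_a) / mean_percent(condition_b),
    defined only for shared proteins (both means are then positive because
    shared proteins are detected in every replicate of both conditions).
    ``above_threshold`` applies θ to the two condition means according to
    ``threshold_mode`` ("mean", "both" or "either"); proteins below θ are
    flagged, never dropped.
    """
    if threshold_mode not in {"mean", "both", "either"}:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    ca, cb = part.condition_a, part.condition_b
    means = q.summary.pivot_table(
        index="protein_id", columns="condition", values="mean_percent", fill_value=0.0
    )
    rows = []
    for pid, label in sorted(part.labels.items()):
        ma = float(means.at[pid, ca]) if ca in means.columns and pid in means.index else 0.0
        mb = float(means.at[pid, cb]) if cb in means.columns and pid in means.index else 0.0
        if label == "shared":
            if mb <= 0:
                raise AssertionError(
                    f"{pid}: shared protein with nonpositive {cb} mean — "
                    "detected-in-all-replicates makes this impossible"
                )
            fc = ma / mb
        else:
            fc = np.nan
        if threshold_mode == "mean":
            above = (ma + mb) / 2.0 >= threshold
        elif threshold_mode == "both":
            above = ma >= threshold and mb >= threshold
        else:
            above = ma >= threshold or mb >= threshold
        rows.append(
            {
                "protein_id": pid,
                "partition": label,
                f"mean_percent_{ca}": ma,
                f"mean_percent_{cb}": mb,
                "fold_change": fc,
                "log2_fold_change": np.log2(fc) if fc == fc else np.nan,
                "above_threshold": above,
            }
        )
    return pd.DataFrame(rows)


def rank_table(q: QuantTable, condition: str) -> pd.DataFrame:
    """Final-dataset proteins of ``condition`` ranked by mean abundance.

    Ordinal ranks 1..n, descending mean_percent, ties broken by protein_id
    ascending; invariant to input row order.
    """
    if condition not in set(q.summary["condition"]):
        raise KeyError(f"unknown condition {condition!r}")
    sel = q.summary[(q.summary["condition"] == condition) & q.summary["detected"]]
    if sel.empty:
        raise ValueError(f"condition {condition!r} has an empty final dataset")
    ordered = sel.sort_values(
        ["mean_percent", "protein_id"], ascending=[False, True]
    ).reset_index(drop=True)
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    return ordered[["protein_id", "mean_percent", "rank"]]


def top_exclusive(
    rows: pd.DataFrame,
    q: QuantTable,
    condition: str,
    n: int = 10,
) -> pd.DataFrame:
    """The ``n`` most abundant proteins exclusive to ``condition``.

    Returns their mean abundance and within-condition rank (rank computed
    over the condition's full final dataset, exclusives and shared alike).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranks = rank_table(q, condition)
    excl = rows[rows["partition"] == f"exclusive:{condition}"]
    merged = ranks.merge(excl[["protein_id", "partition"]], on="protein_id")
    return merged.head(n).reset_index(drop=True)
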
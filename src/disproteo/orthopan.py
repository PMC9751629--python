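"""Ortholog-group annotation and feature-vs-phenotype cross-tabulation.

Ortholog groups (as emitted by orthology inference in the Orthogroups.tsv
dialect) are annotated by the product descriptions of a reference strain's
members. Feature presence across a genome panel is cross-tabulated against
species-level sulfur-disproportionation phenotypes. "untested" is a
first-class phenotype state distinct from tested-negative — collapsing the
two would overstate what the literature reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

__all__ = [
    "OrthoGroup",
    "PhenotypeRecord",
    "annotate_groups",
    "presence_matrix",
    "crosstab",
]

_PHENO_STATES = ("yes", "no", "untested")


@dataclass
class OrthoGroup:
    """One ortholog group: members per species, plus an assigned annotation."""

    group_id: str
    members: dict[str, list[str]]
    annotation: str | None = None
    reference_members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(self.members.values()):
            raise ValidationError(f"{self.group_id}: group has no members")

    def species(self) -> set[str]:
        return {sp for sp, prots in self.members.items() if prots}


@dataclass(frozen=True)
class PhenotypeRecord:
    """Panel flags for one species."""

    species: str
    sulfur_disproportionation: str
    thiosulfate_disproportionation: str = "untested"
    habitat_thermal: str = "unknown"

    def __post_init__(self) -> None:
        for fld in ("sulfur_disproportionation", "thiosulfate_disproportionation"):
            if getattr(self, fld) not in _PHENO_STATES:
                raise ValidationError(
                    f"{self.species}: {fld} must be one of {_PHENO_STATES}"
                )
        if self.habitat_thermal not in ("yes", "no", "unknown"):
            raise ValidationError(
                f"{self.species}: habitat_thermal must be yes/no/unknown"
            )


def annotate_groups(
    groups: Iterable[OrthoGroup],
    reference_species: str,
    descriptions: Mapping[str, str],
) -> list[OrthoGroup]:
    """Annotate each group by its reference-strain member descriptions.

    The description of the reference member with the lowest protein id wins;
    all reference members are listed in ``reference_members``. Groups with
    no reference member are annotated ``"no reference member"``. Membership
    is never altered.
    """
    out = []
    for g in groups:
        ref = sorted(g.members.get(reference_species, []))
        if ref:
            annotation = descriptions.get(ref[0], "")
        else:
            annotation = "no reference member"
        out.append(
            OrthoGroup(
                group_id=g.group_id,
                members={sp: list(p) for sp, p in g.members.items()},
                annotation=annotation,
                reference_members=ref,
            )
        )
    return out


def presence_matrix(
    source: Iterable[OrthoGroup] | pd.DataFrame,
    features: Sequence[str],
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Species × feature boolean table.

    ``source`` is either a collection of ortholog groups — a feature then
    names a group id or an exact annotation — or a species-summary count
    table from the clusters module, whose columns are the features. A cell
    is true iff the species has at least one member/call for the feature.
    """
    if isinstance(source, pd.DataFrame):
        unknown = [f for f in features if f not in source.columns]
        if unknown:
            raise KeyError(f"unknown features {unknown}")
        mat = (source[list(features)] > 0).copy()
        mat.index.name = "species"
        return mat

    groups = list(source)
    by_id = {g.group_id: g for g in groups}
    by_annot: dict[str, list[OrthoGroup]] = {}
    for g in groups:
        if g.annotation:
            by_annot.setdefault(g.annotation, []).append(g)
    if species is None:
        species = sorted({sp for g in groups for sp in g.species()})
    data = {}
    for feat in features:
        if feat in by_id:
            hit = [by_id[feat]]
        elif feat in by_annot:
            hit = by_annot[feat]
        else:
            raise KeyError(f"unknown feature {feat!r}")
        present = set().union(*(g.species() for g in hit))
        data[feat] = [sp in present for sp in species]
    mat = pd.DataFrame(data, index=list(species))
    mat.index.name = "species"
    return mat


def crosstab(
    matrix: pd.DataFrame,
    phenotypes: Iterable[PhenotypeRecord],
    feature: str,
    phenotype_field: str = "sulfur_disproportionation",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """2×3 count table: feature presence × phenotype {yes, no, untested}.

    Every species in the matrix must carry a phenotype record; missing ones
    are reported by name. Returns the table plus derived counts of the kind
    used in narrative summaries (panel size, species with the feature and a
    confirmed phenotype, ...).
    """
    if feature not in matrix.columns:
        raise KeyError(f"unknown feature {feature!r}")
    pheno = {p.species: p for p in phenotypes}
    missing = [sp for sp in matrix.index if sp not in pheno]
    if missing:
        raise ValidationError(f"species missing phenotype records: {missing}")
    table = pd.DataFrame(
        0, index=["feature+", "feature-"], columns=list(_PHENO_STATES)
    )
    for sp in matrix.index:
        row = "feature+" if bool(matrix.at[sp, feature]) else "feature-"
        state = getattr(pheno[sp], phenotype_field)
        table.at[row, state] += 1
    derived = {
        "n_panel": int(table.values.sum()),
        "n_feature": int(table.loc["feature+"].sum()),
        f"n_{phenotype_field}_yes": int(table[_PHENO_STATES[0]].sum()),
        "n_feature_and_yes": int(table.at["feature+", "yes"]),
        "n_feature_and_untested": int(table.at["feature+", "untested"]),
    }
    return table, derived


def fisher_exact_extension(table: pd.DataFrame) -> tuple[float, float]:
    """Optional 2×2 Fisher exact test on feature × (yes vs no), as an extension.

    Untested species are excluded — this is an add-on beyond the descriptive
    counts, provided for convenience.
    """
    from scipy import stats

    sub = table[["yes", "no"]].to_numpy()
    odds, p = stats.fisher_exact(sub)
    return float(odds), float(p)
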
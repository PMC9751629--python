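"""Gene-neighborhood calling of Ttr, Phs and YTD clusters.

Tetrathionate-reductase-type (Ttr) and thiosulfate-reductase-type (Phs)
proteins are multi-subunit molybdoenzymes: a large catalytic molybdopterin
subunit (A), an electron-transfer subunit (B) and a membrane anchor (C,
NrfD-like). Calling starts from candidate A subunits — labeled from
ortholog-group annotations or product keywords and vetoed if shorter than
a catalytic-subunit length floor — then inspects the gene neighborhood for
B/C subunits (arrangements such as ttrBCA or phsAB(C)). A lone ttrA may be
paired with a distantly encoded ttrB–ttrC pair and still counted as one
complex. The YTD cluster is a five-gene neighborhood (YedE, TusA, DsrE-2,
Chp2, Chp1) implicated in sulfur disproportionation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import GeneRecord

__all__ = [
    "SUBUNIT_LABELS",
    "DEFAULT_KEYWORD_RULES",
    "ComplexCall",
    "label_subunits",
    "detect_complexes",
    "detect_ytd",
    "summarize_species",
]

logger = logging.getLogger(__name__)

SUBUNIT_LABELS = {
    "ttrA", "ttrB", "ttrC",
    "phsA", "phsB", "phsC",
    "yedE", "tusA", "dsrE", "chp1", "chp2",
    "none",
}

#: Catalytic subunits subject to the amino-acid length veto.
_A_SUBUNITS = {"ttrA", "phsA"}

#: Case-insensitive product-keyword rules, applied in order; first hit wins.
#: Editable: pass your own list (or load one from YAML) to label_subunits.
DEFAULT_KEYWORD_RULES: list[tuple[str, str]] = [
    (r"tetrathionate reductase.*subunit\s*b|\bttrb\b", "ttrB"),
    (r"tetrathionate reductase.*subunit\s*c|\bttrc\b", "ttrC"),
    (r"polysulfide reductase\s+nrfd", "ttrC"),
    (r"tetrathionate reductase.*subunit\s*a|\bttra\b", "ttrA"),
    (r"tetrathionate reductase", "ttrA"),
    (r"thiosulfate reductase.*subunit\s*b|\bphsb\b", "phsB"),
    (r"thiosulfate reductase.*subunit\s*c|\bphsc\b", "phsC"),
    (r"thiosulfate reductase.*(molybdopterin|subunit\s*a)|\bphsa\b", "phsA"),
    (r"thiosulfate reductase", "phsA"),
    (r"\byede\b", "yedE"),
    (r"\btusa\b|sulfur carrier protein", "tusA"),
    (r"\bdsre\b|dsre-2|dsre/f", "dsrE"),
    (r"\bchp1\b", "chp1"),
    (r"\bchp2\b", "chp2"),
]


@dataclass(frozen=True)
class ComplexCall:
    """One called multi-subunit cluster.

    ``members`` pairs locus tags with subunit roles in coordinate order;
    ``arrangement`` records the observed role order (e.g. ``BCA``), with
    ``..`` separating neighborhoods of a distant call. ``strands_agree``
    is reported but never required for a call.
    """

    family: str  # ttr | phs | ytd
    members: tuple[tuple[str, str], ...]
    arrangement: str
    completeness: str  # complete | lacking_C | partial
    distant: bool
    contig: str
    strands_agree: bool | None = None

    def locus_tags(self) -> list[str]:
        return [lt for lt, _ in self.members]


def label_subunits(
    genes: Sequence[GeneRecord],
    group_map: Mapping[str, str] | None = None,
    min_a_length: int = 500,
    rules: Sequence[tuple[str, str]] | None = None,
) -> list[GeneRecord]:
    """Assign one subunit label per gene; unlabelable genes get ``none``.

    Ortholog-group annotation tokens (``group_map``: locus tag → label)
    take priority over product-keyword rules. Candidate catalytic (A)
    subunits shorter than ``min_a_length`` amino acids are demoted to
    ``none`` and logged — small homologs of molybdopterin subunits are a
    common annotation trap.
    """
    compiled = [
        (re.compile(pat, re.IGNORECASE), label)
        for pat, label in (rules if rules is not None else DEFAULT_KEYWORD_RULES)
    ]
    out: list[GeneRecord] = []
    for g in genes:
        label = "none"
        if group_map and g.locus_tag in group_map:
            token = group_map[g.locus_tag]
            if token in SUBUNIT_LABELS:
                label = token
        if label == "none":
            for rx, lab in compiled:
                if rx.search(g.product or ""):
                    label = lab
                    break
        if (
            label in _A_SUBUNITS
            and g.protein_length is not None
            and g.protein_length < min_a_length
        ):
            logger.info(
                "length veto: %s labeled %s but only %d aa (< %d), demoted to none",
                g.locus_tag, label, g.protein_length, min_a_length,
            )
            label = "none"
        out.append(replace(g, subunit_label=label))
    return out


def _by_contig(genes: Sequence[GeneRecord]) -> dict[str, list[GeneRecord]]:
    ordered = sorted(genes, key=lambda g: (g.contig, g.start, g.locus_tag))
    contigs: dict[str, list[GeneRecord]] = {}
    for g in ordered:
        contigs.setdefault(g.contig, []).append(g)
    return contigs


def _role(gene: GeneRecord, family: str) -> str | None:
    lab = gene.subunit_label or ""
    if lab.startswith(family) and len(lab) == len(family) + 1:
        return lab[-1].upper()  # A / B / C
    return None


def _mk_call(
    family: str,
    member_genes: list[GeneRecord],
    completeness: str,
    distant: bool,
    arrangement: str | None = None,
) -> ComplexCall:
    member_genes = sorted(member_genes, key=lambda g: (g.contig, g.start))
    roles = [(_role(g, family) or "?") for g in member_genes]
    return ComplexCall(
        family=family,
        members=tuple(
            (g.locus_tag, r) for g, r in zip(member_genes, roles)
        ),
        arrangement=arrangement if arrangement is not None else "".join(roles),
        completeness=completeness,
        distant=distant,
        contig=member_genes[0].contig,
        strands_agree=len({g.strand for g in member_genes}) == 1,
    )


def detect_complexes(
    genes: Sequence[GeneRecord],
    family: str,
    max_gap: int = 1,
    allow_distant: bool = False,
) -> list[ComplexCall]:
    """Call ttr/phs complexes by a greedy left-to-right scan per contig.

    Each unconsumed A-subunit gene seeds a call and gathers the nearest
    unconsumed same-family B and C within ``max_gap`` intervening genes on
    either side (gap counted from the last accepted member on that side).
    Completeness: ``complete`` (A+B+C), ``lacking_C`` (A+B), else
    ``partial``. With ``allow_distant`` (ttr only), each remaining A-only
    call is upgraded by the nearest unconsumed adjacent B–C pair anywhere
    in the genome and flagged ``distant``. No gene joins two calls.
    """
    if family not in {"ttr", "phs"}:
        raise ValueError(f"family must be ttr or phs, got {family!r}")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    contigs = _by_contig(genes)
    consumed: set[str] = set()
    calls: list[tuple[ComplexCall, list[GeneRecord]]] = []

    for contig, cgenes in contigs.items():
        for i, seed in enumerate(cgenes):
            if _role(seed, family) != "A" or seed.locus_tag in consumed:
                continue
            members = {"A": seed}
            for step in (-1, 1):
                gap = 0
                j = i + step
                while 0 <= j < len(cgenes) and gap <= max_gap:
                    g = cgenes[j]
                    r = _role(g, family)
                    if r in ("B", "C") and r not in members and g.locus_tag not in consumed:
                        members[r] = g
                        gap = 0
                    else:
                        gap += 1
                    j += step
            if "B" in members and "C" in members:
                completeness = "complete"
            elif "B" in members:
                completeness = "lacking_C"
            else:
                completeness = "partial"
            mg = list(members.values())
            consumed.update(g.locus_tag for g in mg)
            calls.append((_mk_call(family, mg, completeness, distant=False), mg))

    if allow_distant and family == "ttr":
        calls = _pair_distant(calls, contigs, consumed, max_gap)

    ordered = sorted(
        calls, key=lambda cm: (cm[1][0].contig, min(g.start for g in cm[1]))
    )
    return [c for c, _ in ordered]


def _pair_distant(calls, contigs, consumed, max_gap):
    # adjacent unconsumed B–C pairs, indexed for nearest-neighbor search
    pairs: list[tuple[GeneRecord, GeneRecord, str, int]] = []
    for contig, cgenes in contigs.items():
        for i, g in enumerate(cgenes):
            if _role(g, "ttr") != "B" or g.locus_tag in consumed:
                continue
            for j in range(i + 1, min(i + max_gap + 2, len(cgenes))):
                h = cgenes[j]
                if _role(h, "ttr") == "C" and h.locus_tag not in consumed:
                    pairs.append((g, h, contig, i))
                    break
            else:
                # C may precede B
                for j in range(i - 1, max(i - max_gap - 2, -1), -1):
                    h = cgenes[j]
                    if _role(h, "ttr") == "C" and h.locus_tag not in consumed:
                        pairs.append((g, h, contig, j))
                        break

    upgraded = []
    taken: set[str] = set()
    for call, mg in calls:
        if call.family != "ttr" or call.completeness != "partial" or set(
            r for _, r in call.members
        ) != {"A"}:
            upgraded.append((call, mg))
            continue
        a_gene = mg[0]
        a_contig = a_gene.contig
        a_idx = next(
            i for i, g in enumerate(contigs[a_contig]) if g.locus_tag == a_gene.locus_tag
        )
        best = None
        for b, c, contig, idx in pairs:
            if b.locus_tag in taken or c.locus_tag in taken:
                continue
            dist = abs(idx - a_idx) if contig == a_contig else 10**9 + idx
            key = (dist, contig, b.start)
            if best is None or key < best[0]:
                best = (key, b, c, contig)
        if best is None:
            upgraded.append((call, mg))
            continue
        _, b, c, pair_contig = best
        taken.update({b.locus_tag, c.locus_tag})
        consumed.update({b.locus_tag, c.locus_tag})
        pair_arr = "BC" if b.start <= c.start else "CB"
        if pair_contig == a_contig and a_gene.start <= min(b.start, c.start):
            arrangement = f"A..{pair_arr}"
        elif pair_contig == a_contig:
            arrangement = f"{pair_arr}..A"
        else:
            arrangement = f"A..{pair_arr}"
        new_mg = [a_gene, b, c]
        new_call = _mk_call("ttr", new_mg, "complete", distant=True, arrangement=arrangement)
        # keep the seed's contig for reporting
        new_call = ComplexCall(
            family=new_call.family,
            members=new_call.members,
            arrangement=new_call.arrangement,
            completeness=new_call.completeness,
            distant=True,
            contig=a_contig,
            strands_agree=new_call.strands_agree,
        )
        upgraded.append((new_call, new_mg))
    return upgraded


_YTD_ROLES = ("yedE", "tusA", "dsrE", "chp1", "chp2")


def detect_ytd(
    genes: Sequence[GeneRecord],
    max_gap: int = 1,
    min_roles: int = 3,
) -> list[ComplexCall]:
    """Call YTD clusters: maximal runs holding ≥ ``min_roles`` of the five roles.

    A run extends while successive YTD-labeled genes are separated by at
    most ``max_gap`` intervening genes. ``complete`` requires all five
    roles; smaller qualifying runs are ``partial``. Member order is
    recorded in the arrangement string.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    calls: list[ComplexCall] = []
    for contig, cgenes in _by_contig(genes).items():
        labeled = [
            (i, g) for i, g in enumerate(cgenes) if (g.subunit_label or "") in _YTD_ROLES
        ]
        run: list[GeneRecord] = []
        prev_idx: int | None = None

        def flush(run: list[GeneRecord]) -> None:
            roles = {g.subunit_label for g in run}
            if len(roles) < min_roles:
                return
            completeness = "complete" if len(roles) == len(_YTD_ROLES) else "partial"
            arrangement = "-".join(g.subunit_label for g in run)
            calls.append(
                _mk_call("ytd", run, completeness, distant=False, arrangement=arrangement)
            )

        for idx, g in labeled:
            if prev_idx is not None and idx - prev_idx - 1 > max_gap:
                flush(run)
                run = []
            run.append(g)
            prev_idx = idx
        flush(run)
    return sorted(calls, key=lambda c: (c.contig, c.members[0][0]))


_SUMMARY_COLUMNS = [
    "ttr_complete", "ttr_lacking_C", "ttr_partial", "ttr_distant",
    "phs_complete", "phs_lacking_C", "phs_partial", "phs_present",
    "ytd_complete", "ytd_partial",
]


def summarize_species(
    calls_by_species: Mapping[str, Iterable[ComplexCall]],
) -> pd.DataFrame:
    """Species × cluster-category count matrix for panel cross-tabulation.

    A distant complete ttr call counts in both ``ttr_complete`` and
    ``ttr_distant``; ``phs_present`` counts any phs call. A species may be
    positive in several categories (e.g. a complete TtrBCA plus a TtrAB
    lacking TtrC).
    """
    rows = {}
    for species, calls in calls_by_species.items():
        counts = dict.fromkeys(_SUMMARY_COLUMNS, 0)
        for call in calls:
            key = f"{call.family}_{call.completeness}"
            if key in counts:
                counts[key] += 1
            if call.family == "ttr" and call.distant:
                counts["ttr_distant"] += 1
            if call.family == "phs":
                counts["phs_present"] += 1
        rows[species] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=_SUMMARY_COLUMNS)
    df.index.name = "species"
    return df.fillna(0).astype(int).sort_index()
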
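"""Readers, writers and basic genome statistics.

All genomic coordinates are 1-based inclusive, following the GFF3/GenBank
convention. Any half-open arithmetic is private to the functions that need it.

The per-replicate PSM table is a package-defined TSV (columns ``condition``,
``replicate``, ``protein_id``, ``length_aa``, ``psm_count`` and optionally
``q_value``) because upstream search-engine exports are vendor-specific.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

__all__ = [
    "GeneRecord",
    "PsmRecord",
    "GenomeStats",
    "read_annotation",
    "read_psm_table",
    "write_psm_table",
    "read_orthogroups",
    "write_orthogroups",
    "read_phenotypes",
    "write_phenotypes",
    "write_fasta",
    "genome_stats",
]

PSM_COLUMNS = ["condition", "replicate", "protein_id", "length_aa", "psm_count"]


@dataclass
class GeneRecord:
    """One annotated coding sequence.

    ``start``/``end`` are 1-based inclusive base positions on ``contig``;
    ``strand`` is ``+`` or ``-``. ``subunit_label`` is filled in by the
    clusters module and is ``None`` until then.
    """

    locus_tag: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein_length: int | None = None
    subunit_label: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.locus_tag}: strand must be + or -")


@dataclass(frozen=True)
class PsmRecord:
    """Spectral counts for one protein in one replicate of one condition."""

    condition: str
    replicate: int
    protein_id: str
    length_aa: int
    psm_count: int
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise ValidationError(f"{self.protein_id}: length_aa must be >= 1")
        if self.psm_count < 0:
            raise ValidationError(f"{self.protein_id}: psm_count must be >= 0")
        if self.q_value is not None and not 0.0 <= self.q_value <= 1.0:
            raise ValidationError(f"{self.protein_id}: q_value outside [0, 1]")


@dataclass(frozen=True)
class GenomeStats:
    total_length: int
    gc_percent: float
    n_contigs: int
    n_genes: int


# ---------------------------------------------------------------------------
# annotation


def _check_unique_locus_tags(genes: Sequence[GeneRecord]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.locus_tag in seen:
            raise ValidationError(f"duplicate locus_tag {g.locus_tag!r}")
        seen.add(g.locus_tag)


def _sort_genes(genes: list[GeneRecord]) -> list[GeneRecord]:
    # order is a pure function of coordinates; start ties broken by locus_tag
    return sorted(genes, key=lambda g: (g.contig, g.start, g.locus_tag))


def _read_gff3(path: Path) -> list[GeneRecord]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            id_spec=["ID", "locus_tag", "Name"],
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"{path}: not parseable as GFF3: {exc}") from exc

    genes: list[GeneRecord] = []
    for feat in db.features_of_type("CDS"):
        locus = feat.attributes.get("locus_tag", feat.attributes.get("ID", [feat.id]))[0]
        product = feat.attributes.get("product", [""])[0]
        if feat.strand not in ("+", "-"):
            raise ValidationError(
                f"{path}: CDS {locus!r} has strand {feat.strand!r}, expected + or -"
            )
        genes.append(
            GeneRecord(
                locus_tag=locus,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                product=product,
            )
        )
    return genes


def _read_genbank(path: Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    for rec in records:
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            locus = quals.get("locus_tag", quals.get("gene", ["?"]))[0]
            if feat.location is None or feat.location.strand not in (1, -1):
                raise ValidationError(
                    f"{path}: CDS {locus!r} lacks a stranded location"
                )
            genes.append(
                GeneRecord(
                    locus_tag=locus,
                    contig=rec.id,
                    start=int(feat.location.start) + 1,  # to 1-based inclusive
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand == 1 else "-",
                    product=quals.get("product", [""])[0],
                )
            )
    return genes


def read_annotation(path: str | Path, format: str = "gff3") -> list[GeneRecord]:
    """Read CDS features from a GFF3 or GenBank flat file.

    Returns records sorted by (contig, start, locus_tag) regardless of file
    order; coordinates stay 1-based inclusive. Raises
    :class:`~disproteo.errors.FormatError` on unparseable input and
    :class:`~disproteo.errors.ValidationError` on duplicate locus tags.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gff3":
        genes = _read_gff3(path)
    elif format == "genbank":
        genes = _read_genbank(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    genes = _sort_genes(genes)
    _check_unique_locus_tags(genes)
    return genes


# ---------------------------------------------------------------------------
# PSM tables


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    """Read a per-replicate PSM TSV into typed records.

    The ``q_value`` column is optional; when absent, records carry no q-value
    and the FDR filter passes them unchanged.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"{path}: not a readable TSV: {exc}") from exc
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    has_q = "q_value" in df.columns
    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            q = None
            if has_q:
                raw = getattr(row, "q_value")
                q = None if raw is None or raw != raw or raw == "" else float(raw)
            records.append(
                PsmRecord(
                    condition=str(row.condition),
                    replicate=int(row.replicate),
                    protein_id=str(row.protein_id),
                    length_aa=int(row.length_aa),
                    psm_count=int(row.psm_count),
                    q_value=q,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
    keys = {(r.condition, r.replicate, r.protein_id) for r in records}
    if len(keys) != len(records):
        raise ValidationError(
            f"{path}: duplicate (condition, replicate, protein_id) rows"
        )
    return records


def write_psm_table(records: Iterable[PsmRecord], path: str | Path) -> None:
    recs = list(records)
    has_q = any(r.q_value is not None for r in recs)
    cols = PSM_COLUMNS + (["q_value"] if has_q else [])
    df = pd.DataFrame(
        [
            {
                "condition": r.condition,
                "replicate": r.replicate,
                "protein_id": r.protein_id,
                "length_aa": r.length_aa,
                "psm_count": r.psm_count,
                **({"q_value": r.q_value} if has_q else {}),
            }
            for r in recs
        ],
        columns=cols,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ortholog groups and phenotypes


def read_orthogroups(path: str | Path):
    """Read an Orthogroups.tsv-dialect table.

    First column is the group id, one column per species; a cell holds
    comma+space separated protein ids, an empty cell means the species is
    absent from the group. Ragged rows are a format error.
    """
    from .orthopan import OrthoGroup

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise FormatError(f"{path}: empty orthogroups table")
    header = rows[0]
    species = header[1:]
    groups = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(
                f"{path}: line {lineno}: {len(row)} fields, expected {len(header)}"
            )
        members = {
            sp: cell.split(", ")
            for sp, cell in zip(species, row[1:])
            if cell.strip() != ""
        }
        groups.append(OrthoGroup(group_id=row[0], members=members))
    return groups


def write_orthogroups(groups, path: str | Path) -> None:
    species = sorted({sp for g in groups for sp in g.members})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["Orthogroup"] + species)
        for g in groups:
            w.writerow([g.group_id] + [", ".join(g.members.get(sp, [])) for sp in species])


PHENOTYPE_TOKENS = {"yes", "no", "untested"}
HABITAT_TOKENS = {"yes", "no", "unknown"}


def read_phenotypes(path: str | Path):
    """Read the species phenotype TSV (sulfur-disproportionation panel flags)."""
    from .orthopan import PhenotypeRecord

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("untested")
    required = ["species", "sulfur_disproportionation"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in df.iterrows():
        rec = PhenotypeRecord(
            species=row["species"],
            sulfur_disproportionation=row["sulfur_disproportionation"],
            thiosulfate_disproportionation=row.get(
                "thiosulfate_disproportionation", "untested"
            ),
            habitat_thermal=row.get("habitat_thermal", "unknown"),
        )
        records.append(rec)
    if len({r.species for r in records}) != len(records):
        raise ValidationError(f"{path}: duplicate species ids")
    return records


def write_phenotypes(records, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "species": r.species,
                "sulfur_disproportionation": r.sulfur_disproportionation,
                "thiosulfate_disproportionation": r.thiosulfate_disproportionation,
                "habitat_thermal": r.habitat_thermal,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# genome statistics


def genome_stats(
    fasta: str | Path | Mapping[str, str],
    genes: Sequence[GeneRecord] | None = None,
) -> GenomeStats:
    """Total length, G+C percentage and contig/gene counts for a genome.

    ``gc_percent`` is 100·(G+C)/(A+C+G+T), case-insensitive; N and other
    ambiguity codes count toward ``total_length`` but are excluded from both
    the numerator and denominator of the GC fraction. ``n_genes`` is the
    number of annotation records supplied (0 when none are).
    """
    if isinstance(fasta, (str, Path)):
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    else:
        seqs = dict(fasta)
    if not seqs or all(len(s) == 0 for s in seqs.values()):
        raise FormatError("no sequence")
    total = 0
    gc = 0
    acgt = 0
    for seq in seqs.values():
        s = seq.upper()
        total += len(s)
        g, c, a, t = s.count("G"), s.count("C"), s.count("A"), s.count("T")
        gc += g + c
        acgt += a + c + g + t
    if acgt == 0:
        raise ValidationError("no unambiguous A/C/G/T residues")
    return GenomeStats(
        total_length=total,
        gc_percent=100.0 * gc / acgt,
        n_contigs=len(seqs),
        n_genes=len(genes) if genes is not None else 0,
    )
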
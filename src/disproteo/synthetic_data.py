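"""Synthetic genomes and spectral-count studies with known ground truth.

Everything downstream — NSAF quantification, the shared/exclusive partition,
cluster calling, the ortholog panel — is testable against planted truth
without downloading any real data.

Spectral counts follow a Poisson model with rate proportional to protein
length: for protein *i* in condition *c* and replicate *r*,

    count ~ Poisson(depth · base_abundance_i · effect_{i,c} · length_i)

where the effect is the planted TD/SR fold change for shared proteins (1 in
SR) and zero in the condition a condition-exclusive protein is absent from.
Length-proportional rates make NSAF's length division meaningful. Detection
dropout is an independent post-hoc zeroing of (protein, replicate) cells, so
presence-filter behavior can be stressed separately from sequencing depth.
Each protein draws from its own deterministic RNG substream, so adding a
protein never perturbs another's counts.

With dropout 0 a planted protein is present in every replicate whenever its
rate λ ≥ 20: the Poisson zero probability is then e⁻²⁰ ≈ 2·10⁻⁹ per run.
Tests rely on λ ≥ 20.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneRecord, PsmRecord
from .orthopan import OrthoGroup, PhenotypeRecord

__all__ = [
    "PlantedProteomeTruth",
    "PlantSpec",
    "PlantedGenomeTruth",
    "gen_psm_study",
    "gen_genome",
    "gen_panel",
]

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")


def _substream(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic per-entity RNG stream keyed by (seed, entity ids)."""
    ints = [seed & 0x7FFFFFFF] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(ints)


# ---------------------------------------------------------------------------
# proteome study


@dataclass
class PlantedProteomeTruth:
    """Ground truth of a two-condition spectral-count study.

    ``condition_exclusive`` maps each condition to its exclusive protein
    ids; ``shared`` proteins occur in both conditions with a TD/SR count
    multiplier ``fold_change``. ``base_abundance`` and ``length_aa`` set
    each protein's Poisson rate together with the study depth.
    """

    condition_exclusive: dict[str, set[str]]
    shared: set[str]
    fold_change: dict[str, float]
    base_abundance: dict[str, float]
    length_aa: dict[str, int]
    dropout_prob: float
    seed: int

    def __post_init__(self) -> None:
        sets = list(self.condition_exclusive.values()) + [self.shared]
        n = sum(len(s) for s in sets)
        if len(set().union(*sets)) != n:
            raise ValueError("exclusive and shared sets must be pairwise disjoint")
        missing = self.shared - set(self.fold_change)
        if missing:
            raise ValueError(f"fold_change missing for shared proteins: {sorted(missing)[:5]}")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")

    @property
    def conditions(self) -> list[str]:
        return list(self.condition_exclusive)

    @property
    def fold_condition(self) -> str:
        """Condition in which the fold change multiplies shared proteins."""
        return self.conditions[0]

    def proteins(self) -> list[str]:
        out: list[str] = []
        for s in self.condition_exclusive.values():
            out.extend(sorted(s))
        out.extend(sorted(self.shared))
        return out

    def effect(self, protein: str, condition: str) -> float:
        if protein in self.shared:
            return self.fold_change[protein] if condition == self.fold_condition else 1.0
        if protein in self.condition_exclusive.get(condition, set()):
            return 1.0
        return 0.0

    def expected_fold_changes(self) -> dict[str, float]:
        """Identifiable abundance ratios for shared proteins.

        Relative abundance is compositional: the NSAF ratio between
        conditions estimates f_i · ΣSAF(other) / ΣSAF(fold condition),
        not the raw count multiplier f_i, because every protein shares the
        per-run normalization. This returns those expected compositional
        ratios, computed exactly from the planted parameters (SAF = count/
        length, so lengths cancel from the sums).
        """
        cond_f = self.fold_condition
        others = [c for c in self.conditions if c != cond_f]
        if len(others) != 1:
            raise ValueError("expected a two-condition study")
        cond_o = others[0]
        s_f = sum(
            self.base_abundance[p] * self.effect(p, cond_f) for p in self.proteins()
        )
        s_o = sum(
            self.base_abundance[p] * self.effect(p, cond_o) for p in self.proteins()
        )
        return {p: self.fold_change[p] * s_o / s_f for p in sorted(self.shared)}

    @classmethod
    def generate(
        cls,
        n_exclusive: Mapping[str, int] | None = None,
        n_shared: int = 660,
        fold_range: tuple[float, float] = (0.25, 4.0),
        base_range: tuple[float, float] = (0.5, 2.0),
        length_range: tuple[int, int] = (150, 800),
        dropout_prob: float = 0.0,
        seed: int = 0,
    ) -> "PlantedProteomeTruth":
        """Draw a planted study.

        Defaults reproduce the detection structure of the motivating
        comparison: 36 proteins exclusive to the disproportionation
        condition (TD), 476 exclusive to the sulfate-reduction condition
        (SR), 660 shared (1,172 in total). Fold changes are log-uniform in
        ``fold_range``; base abundances log-uniform in ``base_range``;
        lengths uniform integers in ``length_range``.
        """
        if n_exclusive is None:
            n_exclusive = {"TD": 36, "SR": 476}
        rng = _substream(seed, "truth")
        exclusive = {
            cond: {f"{cond}_{i:05d}" for i in range(n)}
            for cond, n in n_exclusive.items()
        }
        shared = {f"SH_{i:05d}" for i in range(n_shared)}
        proteins = sorted(set().union(shared, *exclusive.values()))
        lo, hi = np.log(fold_range[0]), np.log(fold_range[1])
        blo, bhi = np.log(base_range[0]), np.log(base_range[1])
        fold = {
            p: float(np.exp(rng.uniform(lo, hi))) for p in sorted(shared)
        }
        base = {p: float(np.exp(rng.uniform(blo, bhi))) for p in proteins}
        length = {
            p: int(rng.integers(length_range[0], length_range[1] + 1)) for p in proteins
        }
        return cls(
            condition_exclusive=exclusive,
            shared=shared,
            fold_change=fold,
            base_abundance=base,
            length_aa=length,
            dropout_prob=dropout_prob,
            seed=seed,
        )


def gen_psm_study(
    truth: PlantedProteomeTruth,
    n_reps: int = 3,
    depth: float = 2.0,
) -> list[PsmRecord]:
    """Realize a spectral-count study from planted truth.

    Emits one row per (protein, condition, replicate), zero counts included
    (λ = 0 in the condition an exclusive protein is absent from). Planted
    proteins carry q_value 0.001, comfortably inside a 1% FDR cut.
    Deterministic given ``truth.seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    records: list[PsmRecord] = []
    for p in truth.proteins():
        rng = _substream(truth.seed, "psm", p)
        for cond in truth.conditions:
            lam = depth * truth.base_abundance[p] * truth.effect(p, cond) * truth.length_aa[p]
            counts = rng.poisson(lam, size=n_reps) if lam > 0 else np.zeros(n_reps, dtype=int)
            if truth.dropout_prob > 0:
                drop = rng.random(n_reps) < truth.dropout_prob
                counts = np.where(drop, 0, counts)
            for r in range(1, n_reps + 1):
                records.append(
                    PsmRecord(
                        condition=cond,
                        replicate=r,
                        protein_id=p,
                        length_aa=truth.length_aa[p],
                        psm_count=int(counts[r - 1]),
                        q_value=0.001,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class PlantSpec:
    """One cluster to plant: family, subunit arrangement, optional distance.

    ``arrangement`` is a role string in gene order — e.g. ``"BCA"`` for a
    contiguous ttrBCA operon, ``"AB"`` for phsAB — or, for ytd, a dash-
    separated role list (default the five-gene cluster). ``distant_gap``
    (ttr only) splits an A subunit from a B–C pair by that many intervening
    genes.
    """

    family: str
    arrangement: str = ""
    distant_gap: int | None = None

    def roles(self) -> list[str]:
        if self.family == "ytd":
            arr = self.arrangement or "yedE-tusA-dsrE-chp2-chp1"
            return arr.split("-")
        arr = self.arrangement or ("BCA" if self.family == "ttr" else "AB")
        return [f"{self.family}{ch}" for ch in arr]


@dataclass
class PlantedGenomeTruth:
    """What was planted: complexes (family, members, arrangement, distant flag)."""

    planted_complexes: list[tuple[str, list[str], str, bool]]
    decoy_count: int
    seed: int


_PRODUCTS = {
    "ttrA": "tetrathionate reductase subunit A TtrA",
    "ttrB": "tetrathionate reductase subunit B TtrB",
    "ttrC": "polysulfide reductase NrfD family protein",
    "phsA": "thiosulfate reductase molybdopterin subunit PhsA",
    "phsB": "thiosulfate reductase electron transfer subunit B",
    "phsC": "thiosulfate reductase membrane anchor subunit C",
    "yedE": "YedE family putative sulfur transporter",
    "tusA": "sulfur carrier protein TusA",
    "dsrE": "DsrE-2 family sulfurtransferase",
    "chp1": "conserved hypothetical protein Chp1",
    "chp2": "conserved hypothetical protein Chp2",
}

_LENGTHS = {  # amino acids, typical for each role
    "ttrA": (700, 1000), "phsA": (700, 1000),
    "ttrB": (150, 300), "phsB": (150, 300),
    "ttrC": (200, 400), "phsC": (200, 400),
    "yedE": (300, 450), "tusA": (70, 110), "dsrE": (110, 160),
    "chp1": (90, 200), "chp2": (90, 200),
}

_DECOY_VOCAB = [
    "ribosomal protein L3", "ribosomal protein S7", "elongation factor Tu",
    "DNA polymerase III subunit beta", "DNA gyrase subunit A",
    "ABC transporter permease", "ABC transporter ATP-binding protein",
    "chaperonin GroEL", "cell division protein FtsZ", "RNA polymerase subunit beta",
    "aminotransferase class I", "acyl-CoA dehydrogenase", "enolase",
    "glyceraldehyde-3-phosphate dehydrogenase", "histidine kinase",
    "response regulator receiver protein", "MFS transporter",
    "tRNA ligase class II", "peptidase M23", "outer membrane assembly factor",
    "flagellar hook protein FlgE", "nucleotidyltransferase",
    "phosphoribosyltransferase", "hypothetical membrane protein",
    "TonB-dependent receptor", "signal peptidase I", "ferredoxin",
    "methyltransferase type 11", "GTP-binding protein", "lipoprotein of unknown function",
]


def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    return b"M" + rng.choice(_AA, size=max(n_aa - 1, 0)).tobytes()  # type: ignore[return-value]


def gen_genome(
    n_decoys: int,
    plants: Sequence[PlantSpec] = (),
    seed: int = 0,
    contig: str = "ctg1",
    intergenic: tuple[int, int] = (20, 200),
    emit_sequences: bool = True,
) -> tuple[list[GeneRecord], dict[str, str], PlantedGenomeTruth]:
    """Lay out a single-contig genome with planted clusters among decoys.

    Genes get non-overlapping coordinates with random intergenic gaps of
    20–200 bp; decoy products come from a neutral vocabulary (never matching
    the subunit keyword rules) with lengths 80–1200 aa, while planted
    catalytic A subunits are 700–1,000 aa, above the length veto. Returns
    the gene records, a locus-tag → protein-sequence mapping (empty when
    ``emit_sequences`` is off), and the planted truth. Deterministic given
    ``seed``.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = _substream(seed, "genome")

    # slot list: (role or None for decoy, plant index)
    slots: list[tuple[str | None, int]] = [(None, -1)] * n_decoys
    non_distant = [(i, p) for i, p in enumerate(plants) if p.distant_gap is None]
    distant = [(i, p) for i, p in enumerate(plants) if p.distant_gap is not None]

    for i, plant in non_distant:
        block = [(r, i) for r in plant.roles()]
        pos = int(rng.integers(0, len(slots) + 1))
        slots[pos:pos] = block
    for i, plant in distant:
        if plant.family != "ttr":
            raise ValueError("distant plants are only defined for the ttr family")
        gap = int(plant.distant_gap or 0)
        if gap > len(slots):
            raise ValueError(
                f"requested distance {gap} exceeds genome size {len(slots)}"
            )
        pos = int(rng.integers(0, len(slots) - gap + 1))
        slots[pos:pos] = [("ttrA", i)]
        pair_pos = pos + 1 + gap
        slots[pair_pos:pair_pos] = [("ttrB", i), ("ttrC", i)]

    genes: list[GeneRecord] = []
    seqs: dict[str, str] = {}
    members: dict[int, list[str]] = {i: [] for i in range(len(plants))}
    pos_bp = 1
    for k, (role, plant_idx) in enumerate(slots):
        locus = f"SYN_{(k + 1) * 10:05d}"
        if role is None:
            product = str(rng.choice(_DECOY_VOCAB))
            n_aa = int(rng.integers(80, 1201))
        else:
            product = _PRODUCTS[role]
            lo, hi = _LENGTHS[role]
            n_aa = int(rng.integers(lo, hi + 1))
            members[plant_idx].append(locus)
        gap_bp = int(rng.integers(intergenic[0], intergenic[1] + 1))
        start = pos_bp + gap_bp
        end = start + 3 * n_aa + 2  # CDS including stop codon
        genes.append(
            GeneRecord(
                locus_tag=locus,
                contig=contig,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                product=product,
                protein_length=n_aa,
            )
        )
        if emit_sequences:
            seqs[locus] = _random_protein(rng, n_aa).decode()
        pos_bp = end + 1

    truth = PlantedGenomeTruth(
        planted_complexes=[
            (
                p.family,
                members[i],
                "A..BC" if p.distant_gap is not None else (
                    p.arrangement
                    or {"ttr": "BCA", "phs": "AB", "ytd": "yedE-tusA-dsrE-chp2-chp1"}[p.family]
                ),
                p.distant_gap is not None,
            )
            for i, p in enumerate(plants)
        ],
        decoy_count=n_decoys,
        seed=seed,
    )
    return genes, seqs, truth


# ---------------------------------------------------------------------------
# ortholog panel


def gen_panel(
    n_species: int = 93,
    p_feature_given_disprop: float = 0.8,
    p_feature_given_other: float = 0.1,
    seed: int = 0,
    n_disprop: int | None = None,
    features: Sequence[str] = ("ttr", "phs", "ytd"),
) -> tuple[list[OrthoGroup], list[PhenotypeRecord], pd.DataFrame]:
    """Simulate a genome panel with Bernoulli feature/phenotype coupling.

    Defaults mirror the motivating panel shape: 93 species of which 33 are
    sulfur disproportionators (set ``n_disprop`` to override the exact
    count). Each feature is one ortholog group whose members are the
    feature-positive species; the truth table records flags and feature
    presence per species. Deterministic given ``seed``.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    for p in (p_feature_given_disprop, p_feature_given_other):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    if n_disprop is None:
        n_disprop = round(n_species * 33 / 93)
    if n_disprop > n_species:
        raise ValueError("n_disprop exceeds n_species")
    rng = _substream(seed, "panel")
    species = [f"sp{i:03d}" for i in range(1, n_species + 1)]
    flags = np.zeros(n_species, dtype=bool)
    flags[rng.choice(n_species, size=n_disprop, replace=False)] = True

    truth_rows = {}
    groups = []
    presence = {}
    for feat in features:
        p = np.where(flags, p_feature_given_disprop, p_feature_given_other)
        present = rng.random(n_species) < p
        presence[feat] = present
        members = {
            sp: [f"{sp}_{feat}_1"] for sp, pos in zip(species, present) if pos
        }
        if members:
            groups.append(OrthoGroup(group_id=f"OG_{feat}", members=members))
    phenotypes = [
        PhenotypeRecord(
            species=sp,
            sulfur_disproportionation="yes" if fl else "no",
            thiosulfate_disproportionation="yes" if fl else "untested",
            habitat_thermal="unknown",
        )
        for sp, fl in zip(species, flags)
    ]
    for i, sp in enumerate(species):
        truth_rows[sp] = {
            "sulfur_disproportionation": bool(flags[i]),
            **{feat: bool(presence[feat][i]) for feat in features},
        }
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth.index.name = "species"
    return groups, phenotypes, truth
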
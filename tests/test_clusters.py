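"""Subunit labeling and gene-neighborhood cluster calling."""

from disproteo import (
    GeneRecord,
    PlantSpec,
    detect_complexes,
    detect_ytd,
    gen_genome,
    label_subunits,
    summarize_species,
)


def _genes(spec, contig="c1"):
    """spec: list of (product, protein_length or None)."""
    genes = []
    pos = 1
    for i, (product, length) in enumerate(spec):
        n_aa = length or 100
        genes.append(
            GeneRecord(
                locus_tag=f"L{i:03d}",
                contig=contig,
                start=pos,
                end=pos + 3 * n_aa,
                strand="+",
                product=product,
                protein_length=length,
            )
        )
        pos += 3 * n_aa + 50
    return genes


DECOY = "ribosomal protein L1"


class TestLabelSubunits:
    def test_product_keywords_assign_labels(self):
        genes = label_subunits(
            _genes(
                [
                    ("Tetrathionate reductase subunit TtrA", 750),
                    ("tetrathionate reductase subunit B TtrB", 200),
                    ("Polysulfide reductase NrfD", 300),
                    (DECOY, 200),
                ]
            )
        )
        assert [g.subunit_label for g in genes] == ["ttrA", "ttrB", "ttrC", "none"]

    def test_short_catalytic_subunit_is_vetoed(self):
        genes = label_subunits(
            _genes([("Tetrathionate reductase subunit TtrA", 120)])
        )
        assert genes[0].subunit_label == "none"

    def test_group_map_outranks_product_keywords(self):
        genes = label_subunits(
            _genes([(DECOY, 700)]), group_map={"L000": "phsA"}
        )
        assert genes[0].subunit_label == "phsA"

    def test_thiosulfate_reductase_with_molybdopterin_cue(self):
        genes = label_subunits(
            _genes([("thiosulfate reductase molybdopterin subunit", 800)])
        )
        assert genes[0].subunit_label == "phsA"


class TestDetectComplexes:
    def test_contiguous_ttrBCA_is_one_complete_call(self):
        genes = label_subunits(
            _genes(
                [
                    ("tetrathionate reductase subunit B", 200),
                    ("polysulfide reductase NrfD", 300),
                    ("tetrathionate reductase subunit A", 800),
                ]
            )
        )
        calls = detect_complexes(genes, "ttr")
        assert len(calls) == 1
        assert calls[0].completeness == "complete"
        assert calls[0].arrangement == "BCA"

    def test_phsAB_without_C_is_lacking_C(self):
        genes = label_subunits(
            _genes(
                [
                    ("thiosulfate reductase molybdopterin subunit PhsA", 800),
                    ("thiosulfate reductase electron transfer subunit B", 200),
                ]
            )
        )
        calls = detect_complexes(genes, "phs")
        assert len(calls) == 1
        assert calls[0].completeness == "lacking_C"
        assert calls[0].arrangement == "AB"

    def test_distant_ttrA_pairs_with_remote_BC_only_when_allowed(self):
        spec = [("tetrathionate reductase subunit A", 800)]
        spec += [(DECOY, 150)] * 40
        spec += [
            ("tetrathionate reductase subunit B", 200),
            ("polysulfide reductase NrfD", 300),
        ]
        genes = label_subunits(_genes(spec))
        with_distant = detect_complexes(genes, "ttr", allow_distant=True)
        assert len(with_distant) == 1
        assert with_distant[0].distant and with_distant[0].completeness == "complete"
        without = detect_complexes(genes, "ttr", allow_distant=False)
        assert len(without) == 1
        assert without[0].completeness == "partial" and not without[0].distant

    def test_max_gap_allows_intervening_genes(self):
        genes = label_subunits(
            _genes(
                [
                    ("tetrathionate reductase subunit A", 800),
                    (DECOY, 150),
                    ("tetrathionate reductase subunit B", 200),
                ]
            )
        )
        assert detect_complexes(genes, "ttr", max_gap=1)[0].completeness == "lacking_C"
        assert detect_complexes(genes, "ttr", max_gap=0)[0].completeness == "partial"

    def test_no_gene_joins_two_calls(self):
        genes = label_subunits(
            _genes(
                [
                    ("tetrathionate reductase subunit A", 800),
                    ("tetrathionate reductase subunit B", 200),
                    ("tetrathionate reductase subunit A", 800),
                ]
            )
        )
        calls = detect_complexes(genes, "ttr", max_gap=1)
        tags = [lt for c in calls for lt in c.locus_tags()]
        assert len(tags) == len(set(tags))
        assert sorted(c.completeness for c in calls) == ["lacking_C", "partial"]

    def test_gap_monotonicity_never_loses_complete_calls(self):
        spec = [
            ("tetrathionate reductase subunit B", 200),
            (DECOY, 100),
            ("polysulfide reductase NrfD", 300),
            (DECOY, 100),
            ("tetrathionate reductase subunit A", 800),
        ]
        genes = label_subunits(_genes(spec))
        n_complete = [
            sum(c.completeness == "complete" for c in detect_complexes(genes, "ttr", g))
            for g in (0, 1, 2, 3)
        ]
        assert n_complete == sorted(n_complete)


class TestDetectYtd:
    YTD = [
        ("YedE family putative sulfur transporter", 400),
        ("sulfur carrier protein TusA", 80),
        ("DsrE-2 family sulfurtransferase", 130),
        ("conserved hypothetical protein Chp2", 120),
        ("conserved hypothetical protein Chp1", 120),
    ]

    def test_five_role_run_is_complete(self):
        calls = detect_ytd(label_subunits(_genes(self.YTD)))
        assert len(calls) == 1
        assert calls[0].completeness == "complete"
        assert len(calls[0].members) == 5

    def test_two_roles_fall_below_the_floor(self):
        calls = detect_ytd(label_subunits(_genes(self.YTD[:2])))
        assert calls == []

    def test_three_roles_make_a_partial_call(self):
        calls = detect_ytd(label_subunits(_genes(self.YTD[:3])))
        assert len(calls) == 1 and calls[0].completeness == "partial"

    def test_separated_runs_are_separate_calls(self):
        spec = self.YTD + [(DECOY, 150)] * 10 + self.YTD
        calls = detect_ytd(label_subunits(_genes(spec)))
        assert len(calls) == 2
        assert all(c.completeness == "complete" for c in calls)


class TestSummarizeSpecies:
    def test_complete_and_lacking_C_coexist(self):
        spec = [
            ("tetrathionate reductase subunit B", 200),
            ("polysulfide reductase NrfD", 300),
            ("tetrathionate reductase subunit A", 800),
            (DECOY, 100),
            (DECOY, 100),
            ("tetrathionate reductase subunit A", 800),
            ("tetrathionate reductase subunit B", 200),
        ]
        calls = detect_complexes(label_subunits(_genes(spec)), "ttr")
        df = summarize_species({"spX": calls})
        assert df.at["spX", "ttr_complete"] == 1
        assert df.at["spX", "ttr_lacking_C"] == 1

    def test_species_without_calls_is_all_zero(self):
        df = summarize_species({"empty": []})
        assert (df.loc["empty"] == 0).all()

    def test_recovery_on_planted_panel(self):
        rows = {}
        for i, plants in enumerate(
            [[PlantSpec("ttr", "BCA")], [PlantSpec("phs", "AB")], []]
        ):
            genes, _, _ = gen_genome(30, plants, seed=100 + i, emit_sequences=False)
            labeled = label_subunits(genes)
            rows[f"sp{i}"] = detect_complexes(labeled, "ttr") + detect_complexes(
                labeled, "phs"
            )
        df = summarize_species(rows)
        assert df.at["sp0", "ttr_complete"] == 1 and df.at["sp0", "phs_present"] == 0
        assert df.at["sp1", "phs_lacking_C"] == 1 and df.at["sp1", "ttr_complete"] == 0
        assert (df.loc["sp2"] == 0).all()


def test_detection_invariant_to_input_row_order():
    genes, _, _ = gen_genome(
        30, [PlantSpec("ttr", "BCA"), PlantSpec("ytd")], seed=7, emit_sequences=False
    )
    labeled = label_subunits(genes)
    shuffled = list(reversed(labeled))
    assert detect_complexes(labeled, "ttr") == detect_complexes(shuffled, "ttr")
    assert detect_ytd(labeled) == detect_ytd(shuffled)
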
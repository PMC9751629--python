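from __future__ import annotations

import textwrap

import pytest

from disproteo import PsmRecord


@pytest.fixture
def gff3_file(tmp_path):
    """Three CDS on one contig, written out of coordinate order."""
    text = textwrap.dedent(
        """\
        ##gff-version 3
        ctg1\ttest\tCDS\t500\t700\t.\t-\t0\tID=g2;locus_tag=LT_002;product=beta subunit
        ctg1\ttest\tCDS\t100\t400\t.\t+\t0\tID=g1;locus_tag=LT_001;product=alpha subunit
        ctg1\ttest\tCDS\t900\t1100\t.\t+\t0\tID=g3;locus_tag=LT_003
        """
    )
    path = tmp_path / "genes.gff3"
    path.write_text(text)
    return path


@pytest.fixture
def genbank_file(tmp_path):
    """One record, three CDS features listed in descending coordinate order."""
    seq = ("atgcatgcat" * 120)[:1200]
    origin_lines = []
    for i in range(0, 1200, 60):
        chunk = seq[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        origin_lines.append(f"{i + 1:>9} {blocks}")
    origin = "\n".join(origin_lines)
    text = (
        "LOCUS       testrec                 1200 bp    DNA     linear   BCT 01-JAN-2020\n"
        "DEFINITION  synthetic test record.\n"
        "ACCESSION   testrec\n"
        "VERSION     testrec.1\n"
        "KEYWORDS    .\n"
        "SOURCE      synthetic\n"
        "  ORGANISM  synthetic\n"
        "FEATURES             Location/Qualifiers\n"
        "     CDS             complement(900..1100)\n"
        '                     /locus_tag="G3"\n'
        '                     /product="gamma"\n'
        "     CDS             500..700\n"
        '                     /locus_tag="G2"\n'
        '                     /product="beta"\n'
        "     CDS             10..300\n"
        '                     /locus_tag="G1"\n'
        '                     /product="alpha"\n'
        "ORIGIN\n"
        f"{origin}\n"
        "//\n"
    )
    path = tmp_path / "genes.gbk"
    path.write_text(text)
    return path


@pytest.fixture
def tiny_psm_records():
    """Two proteins x two conditions x three replicates, fully detected."""
    records = []
    for cond in ("TD", "SR"):
        for rep in (1, 2, 3):
            records.append(PsmRecord(cond, rep, "P1", 100, 10, 0.001))
            records.append(PsmRecord(cond, rep, "P2", 50, 5, 0.001))
    return records
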
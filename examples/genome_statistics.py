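"""Genome statistics from FASTA contigs plus an annotation.

Writes a small synthetic genome to disk, reads it back through the standard
formats, and reports total length, G+C content and gene count. On a real
assembly the same two calls apply unchanged (e.g. a downloaded chromosome
FASTA plus its GFF3).
"""

import tempfile
from pathlib import Path

from disproteo import genome_stats, read_annotation

tmp = Path(tempfile.mkdtemp())

(tmp / "genome.fna").write_text(
    ">contig1\n" + "ATGGCGTACGGC" * 50 + "\n>contig2\nATATNNNNGCGC\n"
)
(tmp / "genome.gff3").write_text(
    "##gff-version 3\n"
    "contig1\tdemo\tCDS\t10\t309\t.\t+\t0\tID=g1;locus_tag=DM_0001;product=ferredoxin\n"
    "contig1\tdemo\tCDS\t350\t580\t.\t-\t0\tID=g2;locus_tag=DM_0002;product=enolase\n"
)

genes = read_annotation(tmp / "genome.gff3", "gff3")
stats = genome_stats(tmp / "genome.fna", genes)
print(f"total_length = {stats.total_length} bp   (all residues, N included)")
print(f"gc_percent   = {stats.gc_percent:.1f} %  (over unambiguous A/C/G/T only)")
print(f"n_contigs    = {stats.n_contigs}")
print(f"n_genes      = {stats.n_genes}   (CDS records parsed)")
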
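"""Readers/writers for the bundle formats (FASTA, GFF3, TSV)."""

from __future__ import annotations

import os

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detect import Contig


def read_genome_fasta(path: str, species_id: str | None = None) -> list[Contig]:
    sp = species_id or os.path.splitext(os.path.basename(path))[0]
    return [Contig(rec.id, sp, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, path, "fasta")


def write_truth_tsv(truth: list, path: str) -> None:
    cols = ["species_id", "contig_id", "start", "end", "strand", "family_id",
            "class_label", "divergence_realized", "nesting_depth", "is_fragment"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in truth:
            fh.write("\t".join(str(getattr(r, c)) for c in cols) + "\n")


def write_truth_gff3(truth: list, path: str) -> None:
    """Ground truth as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(truth):
            attrs = (f"ID=planted{i + 1};family_id={r.family_id};"
                     f"class_label={r.class_label.replace('/', '_')};"
                     f"nesting_depth={r.nesting_depth};is_fragment={str(r.is_fragment).lower()}")
            fh.write("\t".join([
                r.contig_id, "belpao_sim", "LTR_retrotransposon",
                str(r.start + 1), str(r.end), ".", r.strand, ".", attrs]) + "\n")


def write_candidates_tsv(cands: list, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tcontig_id\tstart\tend\tltr5_start\tltr5_end\t"
                 "ltr3_start\tltr3_end\tltr_identity\tdetector_tag\tclass_label\n")
        for c in cands:
            fh.write("\t".join(map(str, [
                c.candidate_id, c.contig_id, c.start, c.end,
                c.ltr5[0], c.ltr5[1], c.ltr3[0], c.ltr3[1],
                f"{c.ltr_identity:.4f}", c.detector_tag, c.class_label])) + "\n")


def write_elements_tsv(elements: list, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("element_id\tspecies_id\tcontig_id\tstart\tend\tlength\t"
                 "source_detector\tclass_label\tprovenance\n")
        for e in elements:
            fh.write("\t".join(map(str, [
                e.element_id, e.species_id, e.contig_id, e.start, e.end,
                e.length, e.source_detector, e.class_label, e.provenance])) + "\n")


def write_elements_gff3(elements: list, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in elements:
            attrs = (f"ID={e.element_id};source_detector={e.source_detector};"
                     f"class_label={e.class_label.replace('/', '_')}")
            fh.write("\t".join([
                e.contig_id, "belpao", "LTR_retrotransposon",
                str(e.start + 1), str(e.end), ".", ".", ".", attrs]) + "\n")


def write_partition_tsv(partition, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("element_id\tfamily_id\n")
        for fid in sorted(partition.families):
            for eid in partition.families[fid]:
                fh.write(f"{eid}\t{fid}\n")


def write_edges_tsv(edges: list[tuple[str, str, float]], path: str) -> None:
    """MCL "ABC" interoperable edge list."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tscore\n")
        for a, b, s in edges:
            fh.write(f"{a}\t{b}\t{s:.6f}\n")


def write_panels_fasta(panels: dict, path: str) -> None:
    records = []
    for cls in sorted(panels):
        for dom in sorted(panels[cls]):
            for name, seq in panels[cls][dom]:
                records.append((name.replace("|", "_").replace("/", "-"), seq))
    write_fasta(records, path)
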
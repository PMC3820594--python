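"""Standard-format I/O: FASTA, BED, GFF3, Newick, TSV, config files.

Genomic intervals are 0-based half-open internally; BED is written 0-based
half-open and GFF3 1-based inclusive.  Malformed records are rejected with
their line number.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .records import GenomeRecord, ProteinRecord
from .synteny import GeneFeature, GeneTable

__all__ = [
    "read_protein_fasta",
    "write_protein_fasta",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_gene_table",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "write_locus_models_gff3",
    "read_newick",
    "load_config_dict",
    "dump_config_dict",
    "sha256_of_file",
]


def read_protein_fasta(path, source_tag: str = "") -> list[ProteinRecord]:
    path = Path(path)
    records = [
        ProteinRecord(rec.id, str(rec.seq), source_tag or path.stem)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ParseError("no FASTA records found", str(path))
    return records


def write_protein_fasta(records: list[ProteinRecord], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def read_genome_fasta(path, genome_id: str = "") -> GenomeRecord:
    path = Path(path)
    chroms = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not chroms:
        raise ParseError("no FASTA records found", str(path))
    return GenomeRecord(genome_id or path.stem, chroms)


def write_genome_fasta(genome: GenomeRecord, path) -> None:
    SeqIO.write(
        [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in genome.chromosomes.items()
        ],
        str(path),
        "fasta",
    )


def read_bed(path, genome_id: str = "") -> GeneTable:
    """BED6 (or BED4) gene table: chrom, start, end, name[, score, strand]."""
    path = Path(path)
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError("BED line needs >= 4 columns", str(path), lineno)
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ParseError("BED start/end must be integers", str(path), lineno)
            strand = cols[5] if len(cols) >= 6 else "+"
            if strand not in ("+", "-"):
                raise ParseError(f"bad strand {strand!r}", str(path), lineno)
            if start >= end:
                raise ParseError("BED start must be < end", str(path), lineno)
            features.append(GeneFeature(cols[0], start, end, cols[3], strand))
    return GeneTable(genome_id or path.stem, features)


def write_bed(table: GeneTable, path) -> None:
    with open(path, "w") as fh:
        for f in table.features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.gene_id}\t0\t{f.strand}\n")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path, genome_id: str = "", feature_types=("gene",)) -> GeneTable:
    """Gene features from a GFF3 file (1-based inclusive -> half-open)."""
    path = Path(path)
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError("GFF3 line needs 9 columns", str(path), lineno)
            if cols[2] not in feature_types:
                continue
            try:
                start, end = int(cols[3]) - 1, int(cols[4])
            except ValueError:
                raise ParseError("GFF3 start/end must be integers", str(path), lineno)
            if start < 0 or start >= end:
                raise ParseError("bad GFF3 coordinates", str(path), lineno)
            strand = cols[6]
            if strand not in ("+", "-"):
                raise ParseError(f"bad strand {strand!r}", str(path), lineno)
            attrs = _parse_gff_attributes(cols[8])
            gene_id = attrs.get("ID") or attrs.get("Name")
            if not gene_id:
                raise ParseError("GFF3 record lacks ID attribute", str(path), lineno)
            features.append(GeneFeature(cols[0], start, end, gene_id, strand))
    return GeneTable(genome_id or path.stem, features)


def write_gff3(table: GeneTable, path, source: str = "klfscout") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in table.features:
            fh.write(
                f"{f.chrom}\t{source}\tgene\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.gene_id}\n"
            )


def write_locus_models_gff3(models, path, source: str = "klfscout") -> None:
    """Gene models with exon features and a status attribute.

    ``models`` is a list of (model_id, LocusModel, status) triples.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for model_id, model, status in models:
            if not model.segments:
                continue
            start = min(s.start for s in model.segments)
            end = max(s.end for s in model.segments)
            fh.write(
                f"{model.chrom}\t{source}\tgene\t{start + 1}\t{end}\t.\t{model.strand}\t.\t"
                f"ID={model_id};status={status};intron_structure={model.intron_structure}\n"
            )
            for k, seg in enumerate(model.segments, 1):
                fh.write(
                    f"{model.chrom}\t{source}\texon\t{seg.start + 1}\t{seg.end}\t.\t"
                    f"{model.strand}\t.\tID={model_id}.exon{k};Parent={model_id}\n"
                )


def read_newick(path_or_string: str):
    """Parse a Newick tree (dendropy), from a file path or a literal string."""
    import dendropy

    text = path_or_string
    if not text.strip().startswith("(") and Path(path_or_string).exists():
        text = Path(path_or_string).read_text()
    return dendropy.Tree.get(data=text, schema="newick")


def load_config_dict(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError("config file must contain a key-value mapping", str(path))
    return data


def dump_config_dict(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(data: dict) -> str:
    return hashlib.sha256(json.dumps(data, sort_keys=True).encode()).hexdigest()
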
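"""Serialization of genomes, annotations, liftover maps and reads.

Formats: FASTA (sequence-mode genomes, via Biopython), a JSON sidecar for
everything FASTA cannot carry (lengths, circularity, telomere arrays, truth
domains, interstitial repeats), GFF3/BED6 for genes, BED6 for domains (class
in the name column), TSV for liftover blocks, and 4-line FASTQ for reads.
BED and bedGraph are 0-based half-open; GFF3 is 1-based inclusive.
"""

from __future__ import annotations

import json
import os
from typing import Dict, Iterable, List, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_model import (
    AnnotatedGenome,
    Chromosome,
    Gene,
    InterstitialRepeat,
    LiftBlock,
    LiftoverMap,
    MethylationDomain,
)


# -- FASTA ------------------------------------------------------------------


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- genome JSON sidecar ----------------------------------------------------


def genome_to_dict(genome: AnnotatedGenome) -> dict:
    return {
        "chromosomes": [
            {"name": c.name, "length": c.length, "circular": c.circular}
            for c in genome.chromosomes
        ],
        "telomeres": {k: list(v) for k, v in genome.telomeres.items()},
        "domains": [
            {"chrom": d.chrom, "start": d.start, "end": d.end, "class": d.klass}
            for d in genome.domains
        ],
        "interstitial_repeats": [
            {"chrom": r.chrom, "pos": r.pos, "n": r.n}
            for r in genome.interstitial_repeats
        ],
        "new_capped_ends": [list(x) for x in genome.new_capped_ends],
        "circular_junctions": genome.circular_junctions,
    }


def genome_from_dict(d: dict, sequences=None, genes=None) -> AnnotatedGenome:
    return AnnotatedGenome(
        chromosomes=[
            Chromosome(c["name"], c["length"], c.get("circular", False))
            for c in d["chromosomes"]
        ],
        telomeres={k: tuple(v) for k, v in d["telomeres"].items()},
        genes=list(genes or []),
        domains=[
            MethylationDomain(x["chrom"], x["start"], x["end"], x["class"])
            for x in d["domains"]
        ],
        sequences=sequences,
        interstitial_repeats=[
            InterstitialRepeat(x["chrom"], x["pos"], x["n"])
            for x in d.get("interstitial_repeats", [])
        ],
        new_capped_ends=[tuple(x) for x in d.get("new_capped_ends", [])],
        circular_junctions=d.get("circular_junctions", {}),
    )


# -- genes ------------------------------------------------------------------


def write_genes_gff3(genes: Iterable[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsubtelo\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_genes_gff3(path) -> List[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            genes.append(Gene(f[0], int(f[3]) - 1, int(f[4]), f[6],
                              attrs.get("ID", f"{f[0]}:{f[3]}")))
    return genes


def write_genes_bed(genes: Iterable[Gene], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# -- domains ----------------------------------------------------------------


def write_domains_bed(domains: Iterable[MethylationDomain], path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.klass}\t0\t.\n")


def read_domains_bed(path) -> List[MethylationDomain]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(MethylationDomain(f[0], int(f[1]), int(f[2]), f[3]))
    return out


# -- liftover ---------------------------------------------------------------


def write_liftover_tsv(lift: LiftoverMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#src_chrom\tsrc_start\tsrc_end\ttgt_chrom\ttgt_start\ttgt_end\torient\n")
        for b in lift.blocks:
            fh.write(f"{b.src_chrom}\t{b.src_start}\t{b.src_end}\t"
                     f"{b.tgt_chrom}\t{b.tgt_start}\t{b.tgt_end}\t{b.orient}\n")
        for c, s, e in lift.deleted:
            fh.write(f"#deleted\t{c}\t{s}\t{e}\n")


def read_liftover_tsv(path) -> LiftoverMap:
    blocks, deleted = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#deleted"):
                _, c, s, e = line.rstrip("\n").split("\t")
                deleted.append((c, int(s), int(e)))
                continue
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            blocks.append(LiftBlock(f[0], int(f[1]), int(f[2]),
                                    f[3], int(f[4]), int(f[5]), int(f[6])))
    return LiftoverMap(blocks, deleted=deleted)


# -- FASTQ ------------------------------------------------------------------


def write_fastq(reads: Iterable[Tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> List[Tuple[str, str]]:
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            fh.readline()
            out.append((header[1:].rstrip("\n"), seq))
    return out


# -- whole-genome save/load -------------------------------------------------


def save_genome(genome: AnnotatedGenome, outdir) -> dict:
    """Write genome.json, genes.gff3/bed, domains.bed and (if present)
    genome.fa under ``outdir``; returns the file map."""
    os.makedirs(outdir, exist_ok=True)
    files = {}
    p = os.path.join(outdir, "genome.json")
    with open(p, "w") as fh:
        json.dump(genome_to_dict(genome), fh, indent=1)
    files["genome_json"] = p
    p = os.path.join(outdir, "genes.gff3")
    write_genes_gff3(genome.genes, p)
    files["genes_gff3"] = p
    p = os.path.join(outdir, "genes.bed")
    write_genes_bed(genome.genes, p)
    files["genes_bed"] = p
    p = os.path.join(outdir, "domains.bed")
    write_domains_bed(genome.domains, p)
    files["domains_bed"] = p
    if genome.sequences is not None:
        p = os.path.join(outdir, "genome.fa")
        write_fasta(genome.sequences, p)
        files["fasta"] = p
    return files


def load_genome(outdir) -> AnnotatedGenome:
    with open(os.path.join(outdir, "genome.json")) as fh:
        d = json.load(fh)
    genes = read_genes_gff3(os.path.join(outdir, "genes.gff3"))
    fa = os.path.join(outdir, "genome.fa")
    sequences = read_fasta(fa) if os.path.exists(fa) else None
    return genome_from_dict(d, sequences=sequences, genes=genes)
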
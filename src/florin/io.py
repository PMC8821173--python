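"""Readers and writers for the standard formats the pipeline touches.

GFF3 here is a deliberately minimal gene-level dialect (one feature line per
locus, ``ID`` and a configurable biotype attribute in column 9); FASTA goes
through Biopython, VCF reading through pysam (GT-only), tables through pandas.
All coordinates stay 1-based inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    BIOTYPES,
    ExpressionMatrix,
    GeneFeature,
    GenotypeCalls,
    NetworkEdge,
    PhenotypeTable,
    TranscriptSeq,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GFF3 (minimal gene-level dialect)
# ---------------------------------------------------------------------------

def _parse_attributes(column9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in column9.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"malformed attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | Path, biotype_key: str = "biotype") -> list[GeneFeature]:
    """Read gene features from a GFF3 file.

    Records whose attributes carry ``ID`` and ``biotype_key`` with a value in
    {mRNA, lncRNA} become :class:`GeneFeature`; other records are skipped.
    Malformed lines raise ``ValueError`` naming the line number.
    """
    features: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, _source, _ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: unknown strand {strand!r}")
            try:
                attrs = _parse_attributes(attr_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if "ID" not in attrs or attrs.get(biotype_key) not in BIOTYPES:
                continue
            fid = attrs["ID"]
            if fid in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate feature id {fid!r}")
            seen.add(fid)
            try:
                features.append(GeneFeature(fid, chrom, start, end, strand, attrs[biotype_key]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return features


def write_gff3(features: Iterable[GeneFeature], path: str | Path,
               biotype_key: str = "biotype") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id};{biotype_key}={f.biotype}"
            fh.write(f"{f.chrom}\tflorin\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[TranscriptSeq]:
    """Read sequences; U is normalised to T and case folded to upper."""
    out: list[TranscriptSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: empty sequence for {rec.id!r}")
        out.append(TranscriptSeq(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[TranscriptSeq], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path, unit: str,
                          condition_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV with feature ids in the first column and samples after."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), unit, condition_map)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected accession and class columns")
    return PhenotypeTable(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_phenotypes(phenotypes: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tclass\n")
        for acc, cls in phenotypes.class_of.items():
            fh.write(f"{acc}\t{cls}\n")


# ---------------------------------------------------------------------------
# VCF (minimal GT-only dialect)
# ---------------------------------------------------------------------------

_SNP_ALLELES = frozenset("ACGT")


def read_vcf_minimal(path: str | Path) -> GenotypeCalls:
    """Read biallelic SNPs with GT codes from a VCF.

    Non-biallelic or non-SNP records are skipped (count on ``n_skipped``),
    matching the selection of biallelic SNPs only. ``./.`` becomes missing;
    phased separators are accepted. A record without GT raises ``ValueError``.
    """
    rows, code_rows = [], []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        accessions = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if (len(alts) != 1 or rec.ref not in _SNP_ALLELES
                    or alts[0] not in _SNP_ALLELES):
                n_skipped += 1
                continue
            if "GT" not in rec.format:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} lacks GT")
            codes = np.empty(len(accessions), dtype=np.int8)
            for i, acc in enumerate(accessions):
                alleles = rec.samples[acc]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    codes[i] = -1
                else:
                    codes[i] = sum(alleles)
            rows.append((rec.chrom, rec.pos, rec.ref, alts[0]))
            code_rows.append(codes)
    if n_skipped:
        logger.info("read_vcf_minimal: skipped %d non-biallelic/non-SNP records", n_skipped)
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    codes = np.array(code_rows, dtype=np.int8) if code_rows else np.empty((0, len(accessions)), np.int8)
    return GenotypeCalls(snps, codes, accessions, n_skipped=n_skipped)


def write_vcf_minimal(calls: GenotypeCalls, path: str | Path) -> None:
    contigs = list(dict.fromkeys(calls.snps["chrom"])) if len(calls.snps) else []
    gt_of = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(calls.accessions) + "\n")
        for i, row in enumerate(calls.snps.itertuples(index=False)):
            gts = "\t".join(gt_of[int(c)] for c in calls.codes[i])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Network output
# ---------------------------------------------------------------------------

def write_network(edges: Sequence[NetworkEdge], path: str | Path,
                  format: str = "tsv") -> None:
    """Write edges as a TSV edge list (source, target, kind) or GraphML."""
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tkind\n")
            for e in edges:
                fh.write(f"{e.source}\t{e.target}\t{e.kind}\n")
    elif format == "graphml":
        import networkx as nx

        g = nx.MultiDiGraph()
        for e in edges:
            g.add_edge(e.source, e.target, kind=e.kind)
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> list[NetworkEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [NetworkEdge(r.source, r.target, r.kind) for r in df.itertuples(index=False)]
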
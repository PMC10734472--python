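"""Readers and writers for the standard formats the pipeline touches.

Dialect rules are strict by design: the BLAST tabular parser accepts exactly
the 12-column layout, FASTA headers must be unique, and gene products must
resolve to the controlled vocabulary.  Coordinates are 0-based half-open
internally; conversion to the 1-based inclusive (GFF3) or 0-based half-open
(BED) file conventions happens only at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: Controlled vocabulary of gene product labels used by island typing.
PRODUCT_LABELS = frozenset(
    {
        "pstS", "pstC", "pstA", "pstB", "phoU", "phoR", "phoB",
        "phoX_ALP", "ppk", "ppx_gppA", "sixA", "wzb", "glpF", "dgk",
        "lpxH", "rfaG", "glycosyltransferase", "set_mtase",
        "phnC", "phnD", "phnE", "phnG", "phnH", "phnI", "phnJ", "phnK",
        "phnL", "phnM", "had_hydrolase", "tp", "nucleotidase_5p",
        "pit", "hp",
    }
)

#: Free-text product descriptions mapped onto the controlled vocabulary.
PRODUCT_ALIASES = {
    "methyltransferase": "set_mtase",
    "set domain methyltransferase": "set_mtase",
    "set domain protein": "set_mtase",
    "alkaline phosphatase": "phoX_ALP",
    "phox alkaline phosphatase": "phoX_ALP",
    "polyphosphate kinase": "ppk",
    "exopolyphosphatase": "ppx_gppA",
    "guanosine pentaphosphate phosphatase": "ppx_gppA",
    "phosphohistidine phosphatase": "sixA",
    "protein-tyrosine phosphatase": "wzb",
    "tyrosine phosphatase": "wzb",
    "glycerol uptake facilitator": "glpF",
    "diacylglycerol kinase": "dgk",
    "udp-2,3-diacylglucosamine hydrolase": "lpxH",
    "udp-2,3-diacylglucosamine diphosphatase": "lpxH",
    "lipopolysaccharide core biosynthesis protein": "rfaG",
    "glycosyl transferase": "glycosyltransferase",
    "haloacid dehalogenase": "had_hydrolase",
    "had hydrolase": "had_hydrolase",
    "transmembrane protein": "tp",
    "5'-nucleotidase": "nucleotidase_5p",
    "5'-nucleotidase/apyrase": "nucleotidase_5p",
    "low-affinity phosphate transporter": "pit",
    "hypothetical protein": "hp",
}


def normalize_product(text: str) -> str:
    """Map a product description onto the controlled vocabulary.

    Raises ``ValueError`` for products that neither belong to the vocabulary
    nor have an alias.
    """
    if text in PRODUCT_LABELS:
        return text
    key = text.strip().lower()
    if key in PRODUCT_ALIASES:
        return PRODUCT_ALIASES[key]
    raise ValueError(f"unknown gene product {text!r}")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene on a genome, 0-based half-open coordinates."""

    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str = "+"
    product_label: str = "hp"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid gene interval [{self.start}, {self.end}) for {self.gene_id}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TabularAlignment:
    """One row of 12-column BLAST tabular output (outfmt 6)."""

    read_id: str
    genome_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    read_start: int
    read_end: int
    genome_start: int
    genome_end: int
    evalue: float
    bitscore: float

    def genome_interval(self) -> tuple[int, int]:
        """0-based half-open genome interval, strand-agnostic."""
        lo = min(self.genome_start, self.genome_end) - 1
        hi = max(self.genome_start, self.genome_end)
        return lo, hi


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; sequences are upper-cased; ids must be unique."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), desc))
    if not records:
        raise ValueError(f"empty FASTA file {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Iterate over FASTQ reads (qualities are discarded)."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield SequenceRecord(rec.id, str(rec.seq).upper(), "")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path, quality: int = 40) -> None:
    with open(path, "w") as fh:
        for r in records:
            qual = chr(quality + 33) * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def read_blast_tab(path: str | Path) -> list[TabularAlignment]:
    """Parse 12-column BLAST tabular (outfmt 6); extra columns are rejected."""
    out: list[TabularAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                aln = TabularAlignment(
                    read_id=fields[0],
                    genome_id=fields[1],
                    percent_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    read_start=int(fields[6]),
                    read_end=int(fields[7]),
                    genome_start=int(fields[8]),
                    genome_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if not (0.0 <= aln.percent_identity <= 100.0):
                raise ValueError(
                    f"{path}:{lineno}: percent identity {aln.percent_identity} "
                    "outside [0, 100]"
                )
            if aln.align_length < 1:
                raise ValueError(f"{path}:{lineno}: alignment length < 1")
            out.append(aln)
    if not out:
        logger.warning("empty BLAST tabular file %s", path)
    return out


def write_blast_tab(alignments: Iterable[TabularAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.genome_id}\t{a.percent_identity:.2f}\t"
                f"{a.align_length}\t{a.mismatches}\t{a.gap_opens}\t"
                f"{a.read_start}\t{a.read_end}\t{a.genome_start}\t{a.genome_end}\t"
                f"{a.evalue:.2g}\t{a.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneFeature]:
    """Read gene features from GFF3 (1-based inclusive -> 0-based half-open)."""
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in {"gene", "CDS"}:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr.get("ID") or attr.get("Name")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: feature without ID attribute")
            product = normalize_product(attr.get("product", "hp"))
            feats.append(
                GeneFeature(
                    genome_id=seqid,
                    gene_id=gene_id,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand if strand in {"+", "-"} else "+",
                    product_label=product,
                )
            )
    return feats


def write_gff3(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.genome_id}\tfgislands\tgene\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.gene_id};product={f.product_label}\n"
            )


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedInterval:
    genome_id: str
    start: int
    end: int
    label: str
    score: float = 0.0


def write_bed(islands: Sequence, path: str | Path) -> None:
    """Write island-like objects (genome_id/start/end/label/score attrs) as BED6."""
    with open(path, "w") as fh:
        for isl in islands:
            start, end = int(isl.start), int(isl.end)
            if start < 0 or start >= end:
                raise ValueError(f"invalid BED interval [{start}, {end})")
            label = getattr(isl, "label", None) or getattr(isl, "locus_label", ".")
            score = getattr(isl, "score", None)
            if score is None:
                score = getattr(isl, "depletion_score", 0.0)
            fh.write(
                f"{isl.genome_id}\t{start}\t{end}\t{label}\t{score:.4f}\t.\n"
            )


def read_bed(path: str | Path) -> list[BedInterval]:
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            out.append(
                BedInterval(fields[0], int(fields[1]), int(fields[2]), fields[3], score)
            )
    return out


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_tsv(df, path: str | Path) -> None:
    """Write a pandas DataFrame as TSV with '.' for missing values."""
    df.to_csv(path, sep="\t", index=True, na_rep=".")


def read_tsv(path: str | Path, index_col: int | None = 0):
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["."])
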
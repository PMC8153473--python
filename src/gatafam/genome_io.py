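"""Sequence / gene-model IO and ambiguity-aware CDS translation.

Coordinates are 1-based inclusive throughout (GFF3 convention).  Gene models
come from GFF3 files with ``gene -> mRNA -> exon/CDS`` features linked by
``ID``/``Parent``; UTR lengths are always *derived* from exon minus CDS
extents on the transcript's own strand, never read from the file, so that
annotation dialects cannot disagree with the model.

Translation of a CDS expands every codon over all IUPAC disambiguations of
its ambiguity letters; each codon therefore yields a
:class:`~gatafam.variation.ResidueState` whose amino-acid set has more than
one member exactly when the ambiguity is non-synonymous (a heterozygous
residue).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Data import CodonTable, IUPACData
from Bio.Seq import Seq

from .variation import ResidueState

NUCLEOTIDE_ALPHABET = frozenset("ACGTU") | frozenset(IUPACData.ambiguous_dna_values)
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | frozenset("X*")

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AMBIG_VALUES = {k: v for k, v in IUPACData.ambiguous_dna_values.items()}


class ParseError(ValueError):
    """Malformed input file."""


class StructuralError(ValueError):
    """Inconsistent gene-model structure (CDS outside exon, orphan mRNA...)."""


class TranslationError(ValueError):
    """CDS that cannot be translated under the expansion rules."""


@dataclass
class SequenceRecord:
    id: str
    seq: str
    kind: str = "nucleotide"  # or "protein"

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.seq:
            raise ParseError(f"empty sequence for record {self.id!r}")
        alphabet = (NUCLEOTIDE_ALPHABET if self.kind == "nucleotide"
                    else PROTEIN_ALPHABET)
        bad = set(self.seq) - alphabet
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal {self.kind} character(s) "
                f"{sorted(bad)}")

    def __len__(self):
        return len(self.seq)


@dataclass
class TranscriptModel:
    """One transcript: exons and CDS segments in genomic coordinates.

    ``exons`` and ``cds`` are lists of (start, end), 1-based inclusive,
    sorted by genomic start regardless of strand.
    """

    tx_id: str
    isoform_label: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]]
    strand: str = "+"

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise StructuralError(
                    f"{self.tx_id}: overlapping/unsorted exons")
            if e < s:
                raise StructuralError(f"{self.tx_id}: exon end < start")
            prev_end = e
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise StructuralError(
                    f"{self.tx_id}: CDS segment ({cs},{ce}) outside exons")

    @property
    def cds_len(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def exon_len(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def utr5_len(self) -> int:
        """Exonic bases upstream of the first CDS base, on the tx strand."""
        if not self.cds:
            return self.exon_len
        if self.strand == "+":
            cds_start = self.cds[0][0]
            return sum(min(e, cds_start - 1) - s + 1
                       for s, e in self.exons if s < cds_start)
        cds_end = self.cds[-1][1]
        return sum(e - max(s, cds_end + 1) + 1
                   for s, e in self.exons if e > cds_end)

    @property
    def utr3_len(self) -> int:
        if not self.cds:
            return 0
        return self.exon_len - self.cds_len - self.utr5_len

    def exon_lengths_tx_order(self) -> List[int]:
        lengths = [e - s + 1 for s, e in self.exons]
        return lengths if self.strand == "+" else lengths[::-1]


@dataclass
class GeneModel:
    gene_id: str
    ortholog_key: str
    chromosome: str
    strand: str
    transcripts: List[TranscriptModel] = field(default_factory=list)

    def __post_init__(self):
        if not self.transcripts:
            raise StructuralError(f"{self.gene_id}: gene without transcripts")
        for tx in self.transcripts:
            tx.strand = self.strand

    @property
    def start(self) -> int:
        return min(tx.exons[0][0] for tx in self.transcripts)

    @property
    def end(self) -> int:
        return max(tx.exons[-1][1] for tx in self.transcripts)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, kind: str = "nucleotide") -> List[SequenceRecord]:
    """Read a (possibly folded) multi-record FASTA; sequences uppercased."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        records.append(SequenceRecord(rec.id, str(rec.seq), kind))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path, ortholog_map: Optional[Dict[str, str]] = None
              ) -> List[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    gene_ids = set()
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_ids.add(g.id)
        transcripts = []
        for m in sorted(db.children(g, featuretype=("mRNA", "transcript")),
                        key=lambda m: m.id):
            exons = [(f.start, f.end)
                     for f in db.children(m, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(m, featuretype="CDS")]
            label = m.attributes.get("isoform", [""])[0]
            if not label:
                label = m.id.rsplit(".", 1)[-1] if "." in m.id else "a"
            transcripts.append(
                TranscriptModel(m.id, label, exons, cds, g.strand))
        if not transcripts:
            raise StructuralError(f"{g.id}: gene without mRNA children")
        key = g.attributes.get("ortholog", [None])[0]
        if key is None and ortholog_map:
            key = ortholog_map.get(g.id)
        genes.append(GeneModel(g.id, key or g.id, g.seqid, g.strand,
                               transcripts))
    for m in db.features_of_type(("mRNA", "transcript")):
        parents = m.attributes.get("Parent", [])
        if not parents or not set(parents) & gene_ids:
            raise StructuralError(f"orphan mRNA {m.id}")
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models back out (round-trip stable with :func:`read_gff3`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            fh.write("\t".join([
                g.chromosome, "gatafam", "gene", str(g.start), str(g.end),
                ".", g.strand, ".",
                f"ID={g.gene_id};ortholog={g.ortholog_key}",
            ]) + "\n")
            for tx in g.transcripts:
                fh.write("\t".join([
                    g.chromosome, "gatafam", "mRNA",
                    str(tx.exons[0][0]), str(tx.exons[-1][1]),
                    ".", g.strand, ".",
                    f"ID={tx.tx_id};Parent={g.gene_id};isoform={tx.isoform_label}",
                ]) + "\n")
                for s, e in tx.exons:
                    fh.write("\t".join([
                        g.chromosome, "gatafam", "exon", str(s), str(e),
                        ".", g.strand, ".", f"Parent={tx.tx_id}"]) + "\n")
                for s, e in tx.cds:
                    fh.write("\t".join([
                        g.chromosome, "gatafam", "CDS", str(s), str(e),
                        ".", g.strand, "0", f"Parent={tx.tx_id}"]) + "\n")


def read_ortholog_map(path) -> Dict[str, str]:
    """TSV gene_id -> ortholog_key."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene_id, key = line.split("\t")[:2]
            out[gene_id] = key
    return out


# ---------------------------------------------------------------------------
# CDS extraction and translation

def extract_cds(tx: TranscriptModel, genome: SequenceRecord) -> str:
    """Concatenate CDS segments in transcription order (revcomp on minus).

    IUPAC ambiguity codes are preserved (and complemented on the minus
    strand).
    """
    for s, e in tx.cds:
        if s < 1 or e > len(genome.seq):
            raise ValueError(
                f"{tx.tx_id}: CDS ({s},{e}) outside genome {genome.id}")
    parts = [genome.seq[s - 1:e] for s, e in tx.cds]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def expand_codon(codon: str, max_ambiguous: int = 2) -> List[str]:
    """All disambiguations of a codon's IUPAC letters (capped at 2 positions)."""
    n_amb = sum(1 for c in codon if c not in "ACGT")
    if n_amb > max_ambiguous:
        raise TranslationError(
            f"codon {codon!r} has {n_amb} ambiguous positions (max "
            f"{max_ambiguous})")
    choices = []
    for c in codon:
        if c not in _AMBIG_VALUES:
            raise TranslationError(f"unknown nucleotide {c!r} in codon")
        choices.append(_AMBIG_VALUES[c])
    return ["".join(p) for p in itertools.product(*choices)]


def translate_ambiguous(cds: str, max_ambiguous: int = 2
                        ) -> List[ResidueState]:
    """Translate a CDS into per-position residue *sets* (standard code).

    Stop codons terminate translation; a codon whose disambiguations mix a
    stop with a residue is an error; an internal all-stop codon truncates
    the product with a warning.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    states: List[ResidueState] = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i:3 * i + 3]
        expanded = expand_codon(codon, max_ambiguous)
        aminos = set()
        stops = 0
        for c in expanded:
            if c in _CODON_TABLE.stop_codons:
                stops += 1
            else:
                aminos.add(_CODON_TABLE.forward_table[c])
        if stops and aminos:
            raise TranslationError(
                f"codon {codon!r} expands to both stop and residue")
        if stops:
            if i < n_codons - 1:
                warnings.warn(
                    f"internal stop codon at codon {i + 1}; product truncated",
                    stacklevel=2)
            return states
        states.append(ResidueState(frozenset(aminos), codon))
    return states


def translate_to_string(cds: str, max_ambiguous: int = 2) -> str:
    """Consensus single-letter translation (first member of each set)."""
    return "".join(s.consensus for s in translate_ambiguous(cds, max_ambiguous))
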
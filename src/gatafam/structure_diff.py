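"""Exon/intron/UTR structure comparison across ecotypes and isoforms.

All lengths are reported in transcription order (exon 1 is the 5'-most exon
on the transcript's own strand), so plus- and minus-strand orthologs with
mirrored coordinates produce identical profiles.  When two transcripts have
different exon counts, exons are matched index-by-index in transcription
order and the unmatched tail is reported separately — a computable proxy
for the visual side-by-side comparison of gene-structure diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

from .genome_io import GeneModel, TranscriptModel


@dataclass
class StructureProfile:
    ortholog_key: str
    ecotype: str
    tx_id: str
    n_exons: int
    exon_lengths: List[int]     # transcription order
    utr5_len: int
    utr3_len: int
    cds_len: int


def profile_transcript(tx: TranscriptModel, gene: GeneModel,
                       ecotype: str = "") -> StructureProfile:
    return StructureProfile(
        ortholog_key=gene.ortholog_key,
        ecotype=ecotype,
        tx_id=tx.tx_id,
        n_exons=len(tx.exons),
        exon_lengths=tx.exon_lengths_tx_order(),
        utr5_len=tx.utr5_len,
        utr3_len=tx.utr3_len,
        cds_len=tx.cds_len,
    )


@dataclass
class FeatureComparison:
    feature: str
    conserved: bool
    values: Dict[str, int]              # ecotype -> value
    value_range: Optional[Tuple[int, int]] = None
    outliers: Optional[List[str]] = None


def _compare_feature(name: str, values: Dict[str, int]) -> FeatureComparison:
    distinct = set(values.values())
    if len(distinct) <= 1:
        return FeatureComparison(name, True, values)
    counts: Dict[int, List[str]] = {}
    for eco, v in values.items():
        counts.setdefault(v, []).append(eco)
    majority = max(counts, key=lambda v: (len(counts[v]), -v))
    outliers = sorted(e for v, ecos in counts.items() if v != majority
                      for e in ecos)
    return FeatureComparison(name, False, values,
                             (min(distinct), max(distinct)), outliers)


def compare_ortholog_structures(profiles: Mapping[str, StructureProfile]
                                ) -> List[FeatureComparison]:
    """Conserved/variable report across ecotypes for one ortholog.

    Every compared feature appears exactly once, flagged conserved iff
    identical in all ecotypes; variable features carry (min, max),
    per-ecotype values and the minority ecotypes.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 ecotypes to compare")
    ecos = sorted(profiles)
    out = [
        _compare_feature("n_exons", {e: profiles[e].n_exons for e in ecos}),
        _compare_feature("utr5_len", {e: profiles[e].utr5_len for e in ecos}),
        _compare_feature("utr3_len", {e: profiles[e].utr3_len for e in ecos}),
        _compare_feature("cds_len", {e: profiles[e].cds_len for e in ecos}),
    ]
    max_exons = max(profiles[e].n_exons for e in ecos)
    for i in range(max_exons):
        values = {e: profiles[e].exon_lengths[i]
                  for e in ecos if i < len(profiles[e].exon_lengths)}
        if len(values) == len(ecos):
            out.append(_compare_feature(f"exon_{i + 1}_len", values))
        else:
            # unmatched tail: exon index absent in some ecotypes
            out.append(FeatureComparison(
                f"exon_{i + 1}_len", False, values,
                (min(values.values()), max(values.values())),
                sorted(set(ecos) - set(values))))
    return out


@dataclass
class IsoformDiff:
    shared_exons: List[Tuple[int, int]]
    isoform_specific_exons: Dict[str, List[Tuple[int, int]]]
    differing_exon_indices: List[int]       # transcription order, 1-based
    exon_lengths: Dict[str, List[int]]
    protein_lengths: Dict[str, int]         # aa, stop codon excluded
    tx_start_differs: bool
    tx_end_differs: bool
    translation_start_differs: bool
    translation_end_differs: bool
    leading_peptides: Dict[str, str]


def compare_isoforms_within_gene(gene: GeneModel,
                                 proteins: Optional[Mapping[str, str]] = None
                                 ) -> IsoformDiff:
    """Shared vs isoform-specific structure among one gene's transcripts.

    ``proteins`` optionally maps tx_id to the translated sequence so that a
    translation-start difference can report the leading peptide acquired by
    the longer isoform.
    """
    txs = gene.transcripts
    if len(txs) < 2:
        raise ValueError(f"{gene.gene_id}: need >= 2 isoforms")
    exon_sets = [set(tx.exons) for tx in txs]
    shared = sorted(set.intersection(*exon_sets))
    specific = {tx.tx_id: sorted(set(tx.exons) - set(shared)) for tx in txs}
    lengths = {tx.tx_id: tx.exon_lengths_tx_order() for tx in txs}
    n = max(len(v) for v in lengths.values())
    differing = []
    for i in range(n):
        vals = {v[i] for v in lengths.values() if i < len(v)}
        if len(vals) > 1 or any(i >= len(v) for v in lengths.values()):
            differing.append(i + 1)
    minus = gene.strand == "-"

    def tx_start(tx):
        return tx.exons[-1][1] if minus else tx.exons[0][0]

    def tx_end(tx):
        return tx.exons[0][0] if minus else tx.exons[-1][1]

    def tl_start(tx):
        return tx.cds[-1][1] if minus else tx.cds[0][0]

    def tl_end(tx):
        return tx.cds[0][0] if minus else tx.cds[-1][1]

    protein_lengths = {tx.tx_id: tx.cds_len // 3 - 1 for tx in txs}
    leading: Dict[str, str] = {}
    if proteins and len({tl_start(tx) for tx in txs}) > 1:
        seqs = {t: proteins[t] for t in proteins}
        longest = max(seqs.values(), key=len)
        for t, s in seqs.items():
            if len(s) < len(longest) and longest.endswith(s):
                for t2, s2 in seqs.items():
                    if s2 == longest:
                        leading[t2] = longest[:len(longest) - len(s)]
    return IsoformDiff(
        shared_exons=shared,
        isoform_specific_exons=specific,
        differing_exon_indices=differing,
        exon_lengths=lengths,
        protein_lengths=protein_lengths,
        tx_start_differs=len({tx_start(tx) for tx in txs}) > 1,
        tx_end_differs=len({tx_end(tx) for tx in txs}) > 1,
        translation_start_differs=len({tl_start(tx) for tx in txs}) > 1,
        translation_end_differs=len({tl_end(tx) for tx in txs}) > 1,
        leading_peptides=leading,
    )
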
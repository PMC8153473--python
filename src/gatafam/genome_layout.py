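"""Chromosomal distribution, gene density and proximity pairs."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ._util import round_half_up
from .genome_io import GeneModel


@dataclass
class ChromMap:
    """Ordered gene layout per chromosome, plus chromosome lengths (bp)."""

    genes: Dict[str, List[Tuple[str, int, int]]] = field(default_factory=dict)
    lengths: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for chrom in self.genes:
            self.genes[chrom] = sorted(self.genes[chrom],
                                       key=lambda g: (g[1], g[2], g[0]))
            if chrom in self.lengths:
                max_end = max((e for _, _, e in self.genes[chrom]), default=0)
                if self.lengths[chrom] < max_end:
                    raise ValueError(
                        f"{chrom}: declared length {self.lengths[chrom]} < "
                        f"last gene end {max_end}")

    @classmethod
    def from_gene_models(cls, genes: Sequence[GeneModel],
                         lengths: Optional[Dict[str, int]] = None
                         ) -> "ChromMap":
        by_chrom: Dict[str, List[Tuple[str, int, int]]] = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append(
                (g.ortholog_key, g.start, g.end))
        return cls(by_chrom, dict(lengths or {}))


def chromosome_counts(cmap: ChromMap) -> Dict[str, int]:
    counts = {chrom: len(g) for chrom, g in cmap.genes.items()}
    for chrom in cmap.lengths:
        counts.setdefault(chrom, 0)
    return counts


def gene_density(cmap: ChromMap) -> Dict[str, Optional[float]]:
    """Mb per gene, 2 decimals; None for an empty chromosome."""
    counts = chromosome_counts(cmap)
    out = {}
    for chrom, length in cmap.lengths.items():
        n = counts.get(chrom, 0)
        out[chrom] = round_half_up(length / 1e6 / n, 2) if n else None
    return out


def proximity_pairs(cmap: ChromMap, threshold_bp: int = 170_000,
                    measure: str = "gap"
                    ) -> List[Tuple[str, str, str, int]]:
    """Same-chromosome gene pairs closer than ``threshold_bp`` (strict <).

    ``measure``: ``gap`` (bases between the closest annotated ends,
    ``max(0, later.start - earlier.end - 1)``) or ``start`` (start-to-start
    distance).  Returns (chromosome, gene_a, gene_b, distance) sorted by
    distance then names; invariant to input order.
    """
    if measure not in ("gap", "start"):
        raise ValueError(f"unknown distance measure {measure!r}")
    pairs = []
    for chrom, genes in cmap.genes.items():
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                (ka, sa, ea), (kb, sb, eb) = genes[i], genes[j]
                if (sa, ea) > (sb, eb):
                    (ka, sa, ea), (kb, sb, eb) = genes[j], genes[i]
                if measure == "gap":
                    d = max(0, sb - ea - 1)
                else:
                    d = abs(sb - sa)
                if d < threshold_bp:
                    a, b = sorted((ka, kb))
                    pairs.append((chrom, a, b, d))
    return sorted(pairs, key=lambda p: (p[3], p[0], p[1], p[2]))
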
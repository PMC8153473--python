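"""Class-IV zinc-finger (GATA) domain detection and typing.

The DNA-binding domain of a GATA transcription factor is four cysteines
coordinating a zinc ion — two N-terminal ("leg 1", ``CX{2-4}C``) and two
C-terminal ("leg 2", ``CX2C``) — separated by a 12–21 residue linker and
followed by a basic region.  The scanner implements the generalised grammar

    [ C X{2,4} C ]  X{12,21}  [ C X{2} C ]

where either bracketed leg (but not both) may be absent.  Named spacing
types: ``IV_b`` = (2,18,2), ``IV_c`` = (2,20,2), ``IV_4`` = (4,18,2);
every other grammar-conformant hit (a missing leg, a linker outside
{18,20}, or leg-1 spacing 3) is the partial type ``IV_p``.

A heterozygous residue (amino-acid set from an ambiguous codon) matches a
cysteine anchor whenever C is *a member* of its set, so a C/G heteroallele
at an anchor still nucleates the domain; the variation module is the place
where that ambiguity is reported.

Span conventions for partial hits (the scanner and the published partial
forms anchor on cysteines where possible): a missing leg is replaced by a
lone cysteine at linker distance 12–21 when one exists (nearest first),
otherwise by a plain linker window of up to 21 residues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .variation import ResidueState

LINKER_MIN, LINKER_MAX = 12, 21
LEG1_MIN, LEG1_MAX = 2, 4
LEG2_SPACING = 2
DEFAULT_BASIC_REGION = 30

#: Shipped approximations of the accessory-domain motifs that mark
#: subfamily-III GATA factors (TIFY and CCT).  These are simple consensus
#: patterns, not InterPro profiles; callers with precomputed annotations can
#: bypass :func:`detect_accessory` entirely.
DEFAULT_ACCESSORY_PATTERNS: Dict[str, str] = {
    "TIFY": r"TIF[FY].G",
    "CCT": r"R.AR..RY.E[KR]RK.R",
}


@dataclass
class DomainHit:
    """One located zinc-finger match.

    ``start``/``end`` are 1-based residue positions of the reported domain
    sequence (motif plus trailing basic region); ``motif_end`` is the
    1-based position of the last motif residue.  ``spacing`` is
    (leg1, linker, leg2) with ``None`` for an absent leg.
    """

    protein_id: str
    start: int
    end: int
    motif_end: int
    spacing: Tuple[Optional[int], int, Optional[int]]
    dtype: str
    domain_seq: str
    domain_states: Optional[List[ResidueState]] = field(default=None,
                                                        repr=False)

    @property
    def full(self) -> bool:
        return self.spacing[0] is not None and self.spacing[2] is not None


@dataclass
class AccessoryHit:
    protein_id: str
    name: str
    start: int
    end: int


def _states_of(protein) -> List[frozenset]:
    if isinstance(protein, str):
        return [frozenset(c) for c in protein]
    seq = getattr(protein, "seq", protein)
    if isinstance(seq, str):
        return [frozenset(c) for c in seq]
    return [s.amino_set for s in seq]


def _candidates(states: List[frozenset]):
    """Enumerate every grammar match: (is_full, start, motif_end, spacing)."""
    n = len(states)
    is_c = [("C" in s) for s in states]
    c_pos = [i for i in range(n) if is_c[i]]
    cands = []
    # full hits
    for i in c_pos:
        for a in range(LEG1_MIN, LEG1_MAX + 1):
            j = i + a + 1
            if j >= n or not is_c[j]:
                continue
            for b in range(LINKER_MIN, LINKER_MAX + 1):
                k = j + b + 1
                k2 = k + LEG2_SPACING + 1
                if k2 < n and is_c[k] and is_c[k2]:
                    cands.append((True, i, k2, (a, b, LEG2_SPACING)))
    # leg-1-only
    for i in c_pos:
        for a in range(LEG1_MIN, LEG1_MAX + 1):
            j = i + a + 1
            if j >= n or not is_c[j]:
                continue
            rest = n - 1 - j
            if rest < LINKER_MIN:
                continue
            lone = None
            for p in range(j + 1, n):
                if is_c[p]:
                    g = p - j - 1
                    if LINKER_MIN <= g <= LINKER_MAX:
                        lone = (p, g)
                        break
                    if g > LINKER_MAX:
                        break
            if lone is not None:
                cands.append((False, i, lone[0], (a, lone[1], None)))
            else:
                b = min(rest, LINKER_MAX)
                cands.append((False, i, j + b, (a, b, None)))
    # leg-2-only
    for j in c_pos:
        k2 = j + LEG2_SPACING + 1
        if k2 >= n or not is_c[k2]:
            continue
        if j < LINKER_MIN:
            continue
        lone = None
        for q in range(j - 1, -1, -1):
            if is_c[q]:
                g = j - q - 1
                if LINKER_MIN <= g <= LINKER_MAX:
                    lone = (q, g)
                    break
                if g > LINKER_MAX:
                    break
        if lone is not None:
            cands.append((False, lone[0], k2, (None, lone[1], LEG2_SPACING)))
        else:
            b = min(j, LINKER_MAX)
            cands.append((False, j - b, k2, (None, b, LEG2_SPACING)))
    return cands


def select_hits(cands):
    """Resolve overlaps: full before partial, then leftmost-longest."""
    ordered = sorted(
        cands,
        key=lambda c: (not c[0], c[1], -(c[2] - c[1]),
                       tuple(-1 if x is None else x for x in c[3])))
    accepted = []
    for cand in ordered:
        _, s, e, _ = cand
        if all(e < s2 or s > e2 for _, s2, e2, _ in accepted):
            accepted.append(cand)
    return sorted(accepted, key=lambda c: c[1])


def scan_zinc_fingers(protein, basic_region: int = DEFAULT_BASIC_REGION
                      ) -> List[DomainHit]:
    """All maximal non-overlapping zinc-finger matches in one protein.

    ``protein`` may be a plain string, a record with a ``.seq`` string, or a
    sequence of :class:`~gatafam.variation.ResidueState`.  The reported
    domain sequence extends ``basic_region`` residues past the motif
    (truncated at the protein end).
    """
    protein_id = getattr(protein, "id", "")
    states = _states_of(protein)
    raw = getattr(protein, "seq", protein)
    if not isinstance(raw, str):
        raw = "".join(min(s) for s in states)
    hits = []
    for full, s, e, spacing in select_hits(_candidates(states)):
        seq_end = min(len(states), e + 1 + basic_region)
        hit = DomainHit(
            protein_id=protein_id,
            start=s + 1,
            end=seq_end,
            motif_end=e + 1,
            spacing=spacing,
            dtype="",
            domain_seq=raw[s:seq_end],
        )
        if not isinstance(protein, str) and not isinstance(
                getattr(protein, "seq", None), str):
            hit.domain_states = list(protein[s:seq_end])
        hit.dtype = classify_domain(hit)
        hits.append(hit)
    return hits


def classify_domain(hit: DomainHit) -> str:
    """Assign the spacing type (IV_b / IV_c / IV_4 / IV_p / other)."""
    a, b, c = hit.spacing
    for leg, lo, hi in ((a, LEG1_MIN, LEG1_MAX), (c, LEG2_SPACING, LEG2_SPACING)):
        if leg is not None and not isinstance(leg, int):
            raise ValueError(f"malformed spacing {hit.spacing!r}")
    if not isinstance(b, int) or b < 0:
        raise ValueError(f"malformed spacing {hit.spacing!r}")
    if a is None and c is None:
        raise ValueError("hit with both legs absent")
    if a == 2 and b == 18 and c == 2:
        return "IV_b"
    if a == 2 and b == 20 and c == 2:
        return "IV_c"
    if a == 4 and b == 18 and c == 2:
        return "IV_4"
    leg1_ok = a is None or LEG1_MIN <= a <= LEG1_MAX
    leg2_ok = c is None or c == LEG2_SPACING
    if leg1_ok and leg2_ok and LINKER_MIN <= b <= LINKER_MAX:
        return "IV_p"
    return "other"


def detect_accessory(protein, patterns: Optional[Dict[str, str]] = None
                     ) -> List[AccessoryHit]:
    """Find accessory domains (TIFY/CCT by default) by consensus pattern."""
    if patterns is None:
        patterns = DEFAULT_ACCESSORY_PATTERNS
    protein_id = getattr(protein, "id", "")
    seq = getattr(protein, "seq", protein)
    if not isinstance(seq, str):
        seq = "".join(min(s.amino_set) for s in seq)
    hits = []
    for name, pattern in patterns.items():
        for m in re.finditer(pattern, seq):
            hits.append(AccessoryHit(protein_id, name, m.start() + 1, m.end()))
    return sorted(hits, key=lambda h: (h.start, h.name))


def find_domainless_isoforms(tf_table, gene_cols=("ecotype", "gene_id"),
                             tx_col: str = "tx_id",
                             hit_col: str = "has_domain") -> List[str]:
    """Isoforms lacking a domain in genes whose other isoforms carry one."""
    gene_cols = [c for c in gene_cols if c in tf_table.columns]
    out = []
    for _, grp in tf_table.groupby(gene_cols, sort=True):
        if grp[hit_col].any() and not grp[hit_col].all():
            out.extend(sorted(grp.loc[~grp[hit_col], tx_col]))
    return out
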
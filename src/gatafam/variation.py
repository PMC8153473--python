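"""Cross-ecotype residue variation in aligned domain sequences.

Orthologous domain sequences are aligned (identity mapping for equal-length,
mostly identical inputs; progressive global alignment otherwise), and each
aligned position is summarised as a :class:`ResidueState` — the *set* of
amino acids the underlying codon can encode.  Codons containing IUPAC
ambiguity letters (heterozygous bases in the genome assembly) may expand to
more than one residue; a position is *heterozygous* when that happens, and a
position is *variable* when at least two ecotypes disagree on their state
set.  Ambiguous codons whose expansions all encode the same residue
("heterozygous-but-silent" sites) are reported separately and never counted
as variable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

from Bio import Align
from Bio.Align import substitution_matrices

from ._util import round_half_up

GAP = "-"

#: Default residue property grouping used by :func:`property_change`.
DEFAULT_PROPERTY_GROUPS: Dict[str, str] = {
    "charged": "DEKRH",
    "polar_uncharged": "STNQCY",
    "hydrophobic": "AVLIMFWG",
    "special": "P",
}

_AMBIGUOUS_NT = set("RYSWKMBDHVN")


@dataclass(frozen=True)
class ResidueState:
    """Set of amino acids (or the gap symbol) one aligned position can encode."""

    amino_set: frozenset
    source_codon: str = ""

    def __post_init__(self):
        if not self.amino_set:
            raise ValueError("amino_set must be non-empty")

    @property
    def heterozygous(self) -> bool:
        return len(self.amino_set) > 1

    @property
    def is_gap(self) -> bool:
        return self.amino_set == frozenset(GAP)

    @property
    def ambiguous_codon(self) -> bool:
        """True if the source codon carries an IUPAC ambiguity letter."""
        return any(c in _AMBIGUOUS_NT for c in self.source_codon)

    @property
    def consensus(self) -> str:
        """Single-letter rendering: the alphabetically first member."""
        return min(self.amino_set)

    def render(self) -> str:
        """Human-readable rendering, e.g. ``C`` or ``{C/G}``."""
        if len(self.amino_set) == 1:
            return next(iter(self.amino_set))
        return "{" + "/".join(sorted(self.amino_set)) + "}"

    @classmethod
    def from_residue(cls, residue: str, codon: str = "") -> "ResidueState":
        return cls(frozenset(residue), codon)


GAP_STATE = ResidueState(frozenset(GAP))

StateRow = List[ResidueState]
MSA = Dict[str, StateRow]


def _as_states(seq: Union[str, Sequence[ResidueState]]) -> StateRow:
    if isinstance(seq, str):
        return [ResidueState.from_residue(c) for c in seq]
    return list(seq)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _pairwise_alignment_columns(ref: str, other: str) -> List[Tuple[int, int]]:
    """Aligned column pairs as (ref_index, other_index); -1 marks a gap."""
    aligner = _make_aligner()
    aln = aligner.align(ref, other)[0]
    cols = []
    for (rs, re), (os_, oe) in zip(*aln.aligned):
        cols.append(((rs, re), (os_, oe)))
    # expand block coordinates into per-column index pairs, inserting gap
    # columns between blocks
    pairs: List[Tuple[int, int]] = []
    ri = oi = 0
    for (rs, re), (os_, oe) in cols:
        while ri < rs:
            pairs.append((ri, -1))
            ri += 1
        while oi < os_:
            pairs.append((-1, oi))
            oi += 1
        for k in range(re - rs):
            pairs.append((rs + k, os_ + k))
        ri, oi = re, oe
    while ri < len(ref):
        pairs.append((ri, -1))
        ri += 1
    while oi < len(other):
        pairs.append((-1, oi))
        oi += 1
    return pairs


def align_ortholog_domains(
    domain_seqs: Mapping[str, Union[str, Sequence[ResidueState]]],
    max_identity_mismatch: float = 0.10,
) -> MSA:
    """Align one ortholog's domain sequences across ecotypes.

    Equal-length inputs whose pairwise consensus mismatch fraction is at most
    ``max_identity_mismatch`` are taken as already aligned (identity mapping,
    no gap columns) — the common case for intraspecific domain panels.
    Otherwise a progressive centre-star global alignment (BLOSUM62, affine
    gaps) is built around the first sequence in sorted-key order.
    """
    if not domain_seqs:
        raise ValueError("align_ortholog_domains: empty input")
    keys = sorted(domain_seqs)
    rows = {k: _as_states(domain_seqs[k]) for k in keys}
    lengths = {len(r) for r in rows.values()}
    if len(rows) == 1:
        return rows
    if len(lengths) == 1:
        n = lengths.pop()
        ok = True
        for a, b in itertools.combinations(keys, 2):
            mism = sum(
                1 for x, y in zip(rows[a], rows[b]) if x.consensus != y.consensus
            )
            if n and mism / n > max_identity_mismatch:
                ok = False
                break
        if ok:
            return rows
    # progressive centre-star merge: align every row to the centre, then
    # merge pairwise alignments under "once a gap, always a gap"
    centre = keys[0]
    centre_states = rows[centre]
    centre_str = "".join(s.consensus for s in centre_states)
    per_row_pairs = {}
    for k in keys[1:]:
        other_str = "".join(s.consensus for s in rows[k])
        per_row_pairs[k] = _pairwise_alignment_columns(centre_str, other_str)
    # gap pattern for the centre: for each centre index, how many foreign
    # insertion columns precede it in each pairwise alignment
    n_centre = len(centre_states)
    ins_before = {k: [0] * (n_centre + 1) for k in per_row_pairs}
    for k, pairs in per_row_pairs.items():
        pos = 0
        for ri, oi in pairs:
            if ri == -1:
                ins_before[k][pos] += 1
            else:
                pos = ri + 1
    merged_ins = [max(ins_before[k][i] for k in ins_before) if ins_before else 0
                  for i in range(n_centre + 1)]
    msa: MSA = {}
    # centre row
    row = []
    for i in range(n_centre):
        row.extend([GAP_STATE] * merged_ins[i])
        row.append(centre_states[i])
    row.extend([GAP_STATE] * merged_ins[n_centre])
    msa[centre] = row
    for k, pairs in per_row_pairs.items():
        states = rows[k]
        out: StateRow = []
        pending: StateRow = []  # other-only columns before next centre column
        centre_pos = 0
        for ri, oi in pairs:
            if ri == -1:
                pending.append(states[oi])
            else:
                pad = merged_ins[centre_pos] - len(pending)
                out.extend([GAP_STATE] * pad)
                out.extend(pending)
                pending = []
                out.append(states[oi] if oi != -1 else GAP_STATE)
                centre_pos = ri + 1
        pad = merged_ins[n_centre] - len(pending)
        out.extend([GAP_STATE] * pad)
        out.extend(pending)
        msa[k] = out
    width = len(msa[centre])
    for k in msa:
        if len(msa[k]) != width:  # pragma: no cover - internal consistency
            raise AssertionError("ragged progressive alignment")
    return msa


def trim_trailing_overhang(msa: MSA) -> MSA:
    """Drop trailing columns supported by at most one sequence.

    A single ecotype whose domain runs on past everyone else's (e.g. a
    trailing residue exposed by a small deletion upstream) should not
    contribute countable columns.
    """
    if not msa:
        return msa
    keys = list(msa)
    width = len(msa[keys[0]])
    end = width
    while end > 0:
        non_gap = sum(1 for k in keys if not msa[k][end - 1].is_gap)
        if non_gap <= 1 and len(keys) > 1:
            end -= 1
        else:
            break
    return {k: v[:end] for k, v in msa.items()}


@dataclass
class TFVariation:
    """Per-TF slice of the variation matrix."""

    tf: str
    msa: MSA
    aligned_length: int
    variable_positions: List[int]          # 1-based aligned positions
    silent_het_positions: List[int]        # ambiguous codon, single residue set
    n_forms: int
    form_by_ecotype: Dict[str, str]

    @property
    def n_ecotypes(self) -> int:
        return len(self.msa)


@dataclass
class VariationMatrix:
    """Ortholog x aligned-position variation summary across ecotypes.

    Totals (``n_total_positions``, ``n_variable_positions``) are computed
    over TFs observed in at least two ecotypes; TFs unique to one genome
    have nothing to vary against and are excluded from the percentage, while
    still counting toward the distinct-TF denominator used by
    :func:`count_multiform_tfs`.
    """

    per_tf: Dict[str, TFVariation] = field(default_factory=dict)

    @property
    def n_total_positions(self) -> int:
        return sum(b.aligned_length for b in self.per_tf.values()
                   if b.n_ecotypes >= 2)

    @property
    def n_variable_positions(self) -> int:
        return sum(len(b.variable_positions) for b in self.per_tf.values()
                   if b.n_ecotypes >= 2)

    @property
    def pct_variable(self) -> float:
        total = self.n_total_positions
        if total == 0:
            return 0.0
        return round_half_up(100.0 * self.n_variable_positions / total, 3)

    def variant_table(self):
        """Long-format per-position variant table as a DataFrame."""
        import pandas as pd

        rows = []
        for tf, block in sorted(self.per_tf.items()):
            for pos in block.variable_positions:
                states = {e: block.msa[e][pos - 1] for e in sorted(block.msa)}
                rendered = {}
                for e, st in states.items():
                    rendered.setdefault(st.render(), []).append(e)
                # majority state first
                order = sorted(rendered.items(), key=lambda kv: (-len(kv[1]), kv[0]))
                for state_str, ecos in order:
                    codons = sorted({states[e].source_codon for e in ecos
                                     if states[e].ambiguous_codon})
                    rows.append({
                        "tf": tf,
                        "position": pos,
                        "residue": state_str,
                        "ecotypes": ",".join(ecos),
                        "codon": codons[0] if codons else "",
                    })
        return pd.DataFrame(rows, columns=["tf", "position", "residue",
                                           "ecotypes", "codon"])


def _analyse_block(tf: str, msa: MSA) -> TFVariation:
    keys = sorted(msa)
    width = len(msa[keys[0]]) if keys else 0
    for k in keys:
        if len(msa[k]) != width:
            raise ValueError(f"ragged MSA for {tf}")
    variable, silent = [], []
    for pos in range(width):
        states = [msa[k][pos] for k in keys]
        distinct = {s.amino_set for s in states}
        if len(distinct) >= 2:
            variable.append(pos + 1)
        elif any(s.ambiguous_codon for s in states):
            silent.append(pos + 1)
    forms = {k: "".join(s.render() for s in msa[k]) for k in keys}
    return TFVariation(
        tf=tf,
        msa=msa,
        aligned_length=width,
        variable_positions=variable,
        silent_het_positions=silent,
        n_forms=len(set(forms.values())),
        form_by_ecotype=forms,
    )


def build_variation_matrix(msas: Mapping[str, MSA]) -> VariationMatrix:
    """Summarise per-TF MSAs (ecotype -> aligned ResidueState row) into a matrix."""
    vm = VariationMatrix()
    for tf, msa in msas.items():
        vm.per_tf[tf] = _analyse_block(tf, msa)
    return vm


def count_multiform_tfs(vm: VariationMatrix) -> Tuple[int, int, float]:
    """(TFs with >= 2 domain forms, distinct TFs, percentage to 2 decimals)."""
    n_distinct = len(vm.per_tf)
    n_multi = sum(1 for b in vm.per_tf.values() if b.n_forms >= 2)
    pct = round_half_up(100.0 * n_multi / n_distinct, 2) if n_distinct else 0.0
    return n_multi, n_distinct, pct


# ---------------------------------------------------------------------------
# secondary-structure context


@dataclass
class StructureTrack:
    """Per-position secondary-structure labels over domain coordinates.

    Labels are ``alpha_helix``, ``beta_sheet_1`` .. ``beta_sheet_4`` or
    ``loop``; everything that is not ``loop`` counts as inside a structural
    element.
    """

    labels: List[str]

    def __len__(self):
        return len(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    def in_element(self, pos: int) -> bool:
        """1-based aligned position inside a helix or sheet?"""
        return self.labels[pos - 1] != "loop"

    @classmethod
    def from_segments(cls, segments: Iterable[Tuple[str, int, int]],
                      length: int) -> "StructureTrack":
        """Build from (element, start, end) rows, 1-based inclusive."""
        labels = ["loop"] * length
        for element, start, end in segments:
            if not (1 <= start <= end <= length):
                raise ValueError(f"segment {element} out of range")
            for i in range(start - 1, end):
                labels[i] = element
        return cls(labels)

    def to_segments(self) -> List[Tuple[str, int, int]]:
        segs = []
        i = 0
        n = len(self.labels)
        while i < n:
            if self.labels[i] == "loop":
                i += 1
                continue
            j = i
            while j + 1 < n and self.labels[j + 1] == self.labels[i]:
                j += 1
            segs.append((self.labels[i], i + 1, j + 1))
            i = j + 1
        return segs


def classify_position_context(vm: VariationMatrix,
                              track: StructureTrack) -> Tuple[int, int]:
    """Tally variable positions inside vs outside structural elements.

    The track must cover the longest aligned domain; TFs shorter than the
    track simply use its leading positions.
    """
    inside = outside = 0
    for block in vm.per_tf.values():
        if block.n_ecotypes < 2:
            continue
        if block.aligned_length > len(track):
            raise ValueError(
                f"structure track ({len(track)}) shorter than aligned domain "
                f"{block.tf} ({block.aligned_length})")
        for pos in block.variable_positions:
            if track.in_element(pos):
                inside += 1
            else:
                outside += 1
    return inside, outside


def property_change(a: str, b: str,
                    groups: Mapping[str, str] = DEFAULT_PROPERTY_GROUPS) -> str:
    """``same_group`` if both residues share a physicochemical group."""
    lookup = {}
    for name, members in groups.items():
        for r in members:
            lookup[r] = name
    for r in (a, b):
        if r not in lookup:
            raise ValueError(f"not a groupable residue: {r!r}")
    return "same_group" if lookup[a] == lookup[b] else "different_group"


def heterozygosity_by_subfamily(
    vm: VariationMatrix, subfamily_map: Mapping[str, str]
) -> Dict[str, Tuple[int, Union[float, None]]]:
    """Per-subfamily (variable-position count, frequency over its columns)."""
    counts: Dict[str, int] = {}
    columns: Dict[str, int] = {}
    for tf, block in vm.per_tf.items():
        if tf not in subfamily_map:
            raise KeyError(f"TF without subfamily assignment: {tf}")
        sf = subfamily_map[tf]
        if block.n_ecotypes < 2:
            continue
        counts[sf] = counts.get(sf, 0) + len(block.variable_positions)
        columns[sf] = columns.get(sf, 0) + block.aligned_length
    out = {}
    for sf in sorted(set(counts) | set(columns) | set(subfamily_map.values())):
        n = counts.get(sf, 0)
        cols = columns.get(sf, 0)
        freq = round_half_up(100.0 * n / cols, 2) if cols else None
        out[sf] = (n, freq)
    return out
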
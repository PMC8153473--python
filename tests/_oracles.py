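"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results by enumeration or dynamic
programming, without sharing code paths with the package implementation.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# zinc-finger grammar oracle

LINKER = range(12, 22)
LEG1 = range(2, 5)


def _nearest_anchor(seq: str, idx: int, step: int):
    """Gap to the nearest C scanning outward from idx; None if none in 12-21."""
    gap = 0
    pos = idx + step
    while 0 <= pos < len(seq):
        gap += 1
        if seq[pos] == "C":
            g = gap - 1
            if g in LINKER:
                return pos, g
            if g > max(LINKER):
                return None
        pos += step
    return None


def oracle_candidates(seq: str):
    """Every grammar match as (is_full, start, motif_end, spacing)."""
    n = len(seq)
    out = []
    for i in range(n):
        if seq[i] != "C":
            continue
        # full form: C X{a} C X{b} C X{2} C
        for a in LEG1:
            j = i + a + 1
            if j < n and seq[j] == "C":
                for b in LINKER:
                    k = j + b + 1
                    if k + 3 < n and seq[k] == "C" and seq[k + 3] == "C":
                        out.append((True, i, k + 3, (a, b, 2)))
        # leg-1-only with downstream linker
        for a in LEG1:
            j = i + a + 1
            if j < n and seq[j] == "C" and (n - 1 - j) >= min(LINKER):
                anchor = _nearest_anchor(seq, j, +1)
                if anchor is not None:
                    out.append((False, i, anchor[0], (a, anchor[1], None)))
                else:
                    b = min(n - 1 - j, max(LINKER))
                    out.append((False, i, j + b, (a, b, None)))
    for j in range(n):
        # leg-2-only with upstream linker
        if seq[j] == "C" and j + 3 < n and seq[j + 3] == "C" \
                and j >= min(LINKER):
            anchor = _nearest_anchor(seq, j, -1)
            if anchor is not None:
                out.append((False, anchor[0], j + 3, (None, anchor[1], 2)))
            else:
                b = min(j, max(LINKER))
                out.append((False, j - b, j + 3, (None, b, 2)))
    return out


def oracle_scan(seq: str):
    """Grammar matches after full-first / leftmost-longest overlap removal."""
    chosen = []
    ordered = sorted(
        oracle_candidates(seq),
        key=lambda c: (not c[0], c[1], -(c[2] - c[1]),
                       tuple(-1 if x is None else x for x in c[3])))
    for cand in ordered:
        if all(cand[2] < o[1] or cand[1] > o[2] for o in chosen):
            chosen.append(cand)
    return sorted(chosen, key=lambda c: c[1])


# ---------------------------------------------------------------------------
# codon expansion oracle

from Bio.Data import CodonTable, IUPACData  # noqa: E402

_TABLE = CodonTable.unambiguous_dna_by_id[1]


def oracle_codon_sets(codon: str):
    """(amino set, stop set) over every disambiguation of a codon."""
    aminos, stops = set(), set()
    for bases in itertools.product(*(IUPACData.ambiguous_dna_values[c]
                                     for c in codon)):
        c = "".join(bases)
        if c in _TABLE.stop_codons:
            stops.add(c)
        else:
            aminos.add(_TABLE.forward_table[c])
    return aminos, stops


# ---------------------------------------------------------------------------
# exhaustive three-sequence alignment (sum-of-pairs, linear gaps)

def oracle_align3(a: str, b: str, c: str, match=2, mismatch=-2, gap=-3):
    """Optimal 3-way alignment columns by exhaustive dynamic programming."""
    la, lb, lc = len(a), len(b), len(c)

    def pair(x, y):
        if x is None or y is None:
            return gap
        return match if x == y else mismatch

    NEG = -10 ** 9
    score = np.full((la + 1, lb + 1, lc + 1), NEG, dtype=np.int64)
    back: Dict[Tuple[int, int, int], Tuple[int, int, int]] = {}
    score[0, 0, 0] = 0
    moves = [m for m in itertools.product((0, 1), repeat=3) if any(m)]
    for i in range(la + 1):
        for j in range(lb + 1):
            for k in range(lc + 1):
                s = score[i, j, k]
                if s == NEG:
                    continue
                for di, dj, dk in moves:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if ni > la or nj > lb or nk > lc:
                        continue
                    x = a[i] if di else None
                    y = b[j] if dj else None
                    z = c[k] if dk else None
                    ns = s + pair(x, y) + pair(x, z) + pair(y, z)
                    if ns > score[ni, nj, nk]:
                        score[ni, nj, nk] = ns
                        back[(ni, nj, nk)] = (di, dj, dk)
    cols = []
    i, j, k = la, lb, lc
    while (i, j, k) != (0, 0, 0):
        di, dj, dk = back[(i, j, k)]
        cols.append((a[i - 1] if di else "-", b[j - 1] if dj else "-",
                     c[k - 1] if dk else "-"))
        i, j, k = i - di, j - dj, k - dk
    return cols[::-1]


# ---------------------------------------------------------------------------
# random additive trees

def random_binary_tree(labels: List[str], rng) -> str:
    """Random rooted binary topology over labels, newick with branch lengths."""
    nodes = [(lab, None) for lab in labels]

    def render(node):
        lab, children = node
        L = rng.uniform(0.1, 1.0)
        if children is None:
            return f"{lab}:{L:.4f}", {lab: L}
        (s1, d1), (s2, d2) = render(children[0]), render(children[1])
        dist = {k: v + L for k, v in {**d1, **d2}.items()}
        return f"({s1},{s2}):{L:.4f}", dist

    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = (None, (nodes[i], nodes[j]))
        nodes = [n for t, n in enumerate(nodes) if t not in (i, j)] + [merged]
    (s1, d1), (s2, d2) = render(nodes[0]), render(nodes[1])
    return f"({s1},{s2});"


def patristic_from_newick(newick: str):
    """Leaf-to-leaf path-length matrix computed by dendropy (oracle side)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    D = np.zeros((len(labels), len(labels)))
    for x, lx in enumerate(labels):
        for y, ly in enumerate(labels):
            if x != y:
                tx = tree.taxon_namespace.get_taxon(lx)
                ty = tree.taxon_namespace.get_taxon(ly)
                D[x, y] = pdm.patristic_distance(tx, ty)
    return labels, D
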
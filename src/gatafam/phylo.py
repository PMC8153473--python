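"""Distance-based phylogenetics: p-distance, neighbor joining, bootstrap,
supermatrix concatenation, Robinson–Foulds congruence and monophyly tests.

Neighbor joining is implemented directly (deterministic smallest-index
tie-break, branch lengths clamped at zero) on uncorrected p-distances with
pairwise gap deletion; model-corrected distances are deliberately out of
scope.  Trees are dendropy objects, serialised as newick with bootstrap
supports stored as internal-node labels.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

GAP_CHARS = b"-.NX?"


# ---------------------------------------------------------------------------
# distances

def _msa_array(msa: Mapping[str, str]) -> Tuple[List[str], np.ndarray]:
    names = sorted(msa)
    lengths = {len(msa[n]) for n in names}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    arr = np.frombuffer("".join(msa[n].upper() for n in names).encode(),
                        dtype=np.uint8).reshape(len(names), -1)
    return names, arr


def _pattern_tensors(arr: np.ndarray):
    """Compress to unique site patterns; per-pattern diff and valid tensors."""
    patterns, counts = np.unique(arr, axis=1, return_counts=True)
    gap = np.isin(patterns, np.frombuffer(GAP_CHARS, dtype=np.uint8))
    valid = (~gap[:, None, :]) & (~gap[None, :, :])      # (n, n, P)
    diff = (patterns[:, None, :] != patterns[None, :, :]) & valid
    return patterns, counts.astype(float), diff, valid


def _weighted_pdist(diff, valid, weights) -> np.ndarray:
    d = diff @ weights
    v = valid @ weights
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(v > 0, d / np.maximum(v, 1), 0.0)
    np.fill_diagonal(D, 0.0)
    return D


def pdistance_matrix(msa: Mapping[str, str]) -> pd.DataFrame:
    """Pairwise proportion of differing sites over pairwise-complete columns.

    Columns with a gap (or N/X/?) in either sequence of a pair are ignored
    for that pair.
    """
    names, arr = _msa_array(msa)
    _, counts, diff, valid = _pattern_tensors(arr)
    D = _weighted_pdist(diff, valid, counts)
    return pd.DataFrame(D, index=names, columns=names)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dist: pd.DataFrame) -> dendropy.Tree:
    """Agglomerative neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved toward the smallest (i, j) index
    pair in the current working order; negative branch lengths are clamped
    to zero.  On an additively tree-like matrix the generating topology and
    branch lengths are recovered exactly.
    """
    labels = list(dist.index)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dist.values.astype(float).copy()
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix not symmetric")
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> smallest (i, j) in current working order
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or Q[i, j] < best[0] - 1e-12:
                    best = (Q[i, j], i, j)
        _, i, j = best
        dij = sub[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        ni, nj = nodes[active[i]], nodes[active[j]]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = max(0.0, li)
        nj.edge.length = max(0.0, lj)
        # distances to the new node
        new_d = 0.5 * (sub[i, :] + sub[j, :] - dij)
        D = np.vstack([D, np.zeros((1, D.shape[1]))])
        D = np.hstack([D, np.zeros((D.shape[0], 1))])
        new_idx = D.shape[0] - 1
        for pos, a in enumerate(active):
            D[new_idx, a] = D[a, new_idx] = new_d[pos]
        D[new_idx, new_idx] = 0.0
        nodes.append(parent)
        hi, lo = max(i, j), min(i, j)
        del active[hi], active[lo]
        active.append(new_idx)

    a, b, c = active
    root = dendropy.Node()
    la = (D[a, b] + D[a, c] - D[b, c]) / 2
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2
    for idx, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(0.0, length)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# splits and congruence

def tree_splits(tree: dendropy.Tree) -> set:
    """Non-trivial bipartitions as frozensets of leaf names.

    Each split is normalised to the side that does not contain the
    alphabetically first leaf, so the representation is rooting-invariant.
    """
    leaves = sorted(t.label for t in tree.taxon_namespace
                    if any(l.taxon is t for l in tree.leaf_node_iter()))
    if not leaves:
        return set()
    ref = leaves[0]
    all_set = frozenset(leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = all_set - below if ref in below else below
        if 2 <= len(side) <= len(all_set) - 2:
            splits.add(side)
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Count of non-trivial splits present in exactly one tree."""
    l1 = {l.taxon.label for l in t1.leaf_node_iter()}
    l2 = {l.taxon.label for l in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(tree_splits(t1) ^ tree_splits(t2))


def monophyly_test(tree: dendropy.Tree, groups: Mapping[str, Sequence[str]],
                   outgroup: Optional[str] = None) -> Dict[str, bool]:
    """Is each labelled leaf group exactly one clade (after outgroup rooting)?"""
    work = tree.clone(depth=1)
    leaves = {l.taxon.label for l in work.leaf_node_iter()}
    if outgroup is not None:
        if outgroup not in leaves:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        og = next(l for l in work.leaf_node_iter()
                  if l.taxon.label == outgroup)
        work.reroot_at_edge(og.edge, update_bipartitions=False)
    clades = set()
    for node in work.preorder_node_iter():
        clades.add(frozenset(l.taxon.label for l in node.leaf_iter()))
    out = {}
    for label, members in groups.items():
        members = frozenset(members)
        bad = members - leaves
        if bad:
            raise ValueError(f"group {label!r} members not in tree: "
                             f"{sorted(bad)}")
        out[label] = members in clades or len(members) == 1
    return out


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(msa: Mapping[str, str], B: int, seed: int
                      ) -> dendropy.Tree:
    """NJ point-estimate tree with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement ``B`` times (seeded,
    bit-reproducible); the support of each split of the point tree is the
    percentage of replicate trees containing it, stored as the internal
    node label.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    names, arr = _msa_array(msa)
    _, counts, diff, valid = _pattern_tensors(arr)
    L = int(counts.sum())
    point = nj_tree(pd.DataFrame(_weighted_pdist(diff, valid, counts),
                                 index=names, columns=names))
    point_splits = tree_splits(point)
    tally = {s: 0 for s in point_splits}
    rng = np.random.default_rng(seed)
    p = counts / counts.sum()
    for _ in range(B):
        w = rng.multinomial(L, p).astype(float)
        Db = _weighted_pdist(diff, valid, w)
        rep = nj_tree(pd.DataFrame(Db, index=names, columns=names))
        for s in tree_splits(rep):
            if s in tally:
                tally[s] += 1
    for node in point.preorder_node_iter():
        if node.is_leaf() or node is point.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        ref = sorted(l.taxon.label for l in point.leaf_node_iter())[0]
        all_set = frozenset(l.taxon.label for l in point.leaf_node_iter())
        side = all_set - below if ref in below else below
        if side in tally:
            node.label = f"{100.0 * tally[side] / B:.1f}"
    return point


# ---------------------------------------------------------------------------
# supermatrix

def concat_alignment(gene_msas: Mapping[str, Mapping[str, str]],
                     genes: Optional[Sequence[str]] = None
                     ) -> Tuple[Dict[str, str], List[Tuple[str, int, int]]]:
    """Column-wise concatenation of per-gene alignments in fixed gene order.

    Every taxon must be present in every selected gene; otherwise the
    missing taxon (and gene) is named in the error.  Returns the supermatrix
    and the partition table [(gene, start, end)] (1-based inclusive).
    """
    order = list(genes) if genes is not None else sorted(gene_msas)
    taxa = set()
    for g in order:
        taxa.update(gene_msas[g])
    taxa = sorted(taxa)
    for g in order:
        missing = set(taxa) - set(gene_msas[g])
        if missing:
            raise ValueError(
                f"taxon {sorted(missing)[0]!r} missing from gene {g!r}")
    out = {t: [] for t in taxa}
    partitions = []
    pos = 0
    for g in order:
        width = len(next(iter(gene_msas[g].values())))
        if {len(s) for s in gene_msas[g].values()} != {width}:
            raise ValueError(f"ragged alignment for gene {g!r}")
        for t in taxa:
            out[t].append(gene_msas[g][t])
        partitions.append((g, pos + 1, pos + width))
        pos += width
    return {t: "".join(parts) for t, parts in out.items()}, partitions


# ---------------------------------------------------------------------------
# newick IO

def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick",
                                suppress_rooting=True,
                                unquoted_underscores=True))


def read_newick(source) -> dendropy.Tree:
    """Read a newick tree from a path or a literal newick string."""
    text = str(source)
    if not text.lstrip().startswith("("):
        with open(source) as fh:
            text = fh.read()
    return dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True)
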
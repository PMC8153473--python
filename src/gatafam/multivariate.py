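"""Per-ecotype feature extraction and PCA-based grouping.

Each ecotype is summarised by 28 numeric characteristics spanning five
categories: whole-genome properties, family gene counts, subfamily
composition, alternative-splicing statistics, and domain amino-acid
variation.  Ecotypes are grouped by complete-linkage clustering in the
standardized principal-component score space; on panels where the census
signature determines the features, the recovered partition coincides with
the distribution-type partition.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .family_census import EcotypeCensus, SUBFAMILIES, subfamily_ratios

#: Default 28-feature list (config-replaceable).  ``avg_as`` is deliberately
#: not a feature: it is the ratio of two features already present.
FEATURE_NAMES: List[str] = [
    "genome_n_genes", "genome_n_proteins",
    "n_gata_genes", "n_gata_tfs",
    "genes_sf_I", "genes_sf_II", "genes_sf_III", "genes_sf_IV",
    "tfs_sf_I", "tfs_sf_II", "tfs_sf_III", "tfs_sf_IV",
    "n_genes_with_as", "n_as_forms",
    "ratio_sf_I", "ratio_sf_II", "ratio_sf_III", "ratio_sf_IV",
    "n_absent_orthologs", "n_unique_isoforms",
    "n_variable_positions_carried", "n_heterozygous_sites",
    "n_minor_domain_forms",
    "varpos_sf_I", "varpos_sf_II", "varpos_sf_III", "varpos_sf_IV",
    "n_domainless_isoforms",
]


def extract_features(
    census: EcotypeCensus,
    genome_summary: Mapping[str, int],
    variation_summary: Mapping[str, float],
    n_absent_orthologs: int,
    n_unique_isoforms: int,
    n_domainless_isoforms: int,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> pd.Series:
    """One ecotype's feature vector (fixed order, no missing values).

    ``variation_summary`` carries the per-ecotype variation carriage:
    ``n_variable_positions_carried`` (variable positions at which this
    ecotype holds a minority state), ``n_heterozygous_sites`` (positions
    with an ambiguous source codon in this ecotype), ``n_minor_domain_forms``
    (TFs whose domain form in this ecotype is not the modal form) and
    ``varpos_sf_*`` (the carriage split by subfamily).  Undefined ratios
    (empty subfamily) are imputed 0.
    """
    if len(feature_names) != 28:
        raise ValueError(
            f"feature list must have exactly 28 entries, got "
            f"{len(feature_names)}")
    ratios = subfamily_ratios(census)
    values: Dict[str, float] = {
        "genome_n_genes": genome_summary.get("n_genes", 0),
        "genome_n_proteins": genome_summary.get("n_proteins", 0),
        "n_gata_genes": census.n_genes,
        "n_gata_tfs": census.n_tfs,
        "n_genes_with_as": census.n_genes_with_as,
        "n_as_forms": census.n_as_forms,
        "n_absent_orthologs": n_absent_orthologs,
        "n_unique_isoforms": n_unique_isoforms,
        "n_domainless_isoforms": n_domainless_isoforms,
    }
    for sf in SUBFAMILIES:
        g, t = census.per_subfamily.get(sf, (0, 0))
        values[f"genes_sf_{sf}"] = g
        values[f"tfs_sf_{sf}"] = t
        values[f"ratio_sf_{sf}"] = ratios.get(sf) or 0.0
        values[f"varpos_sf_{sf}"] = variation_summary.get(f"varpos_sf_{sf}", 0)
    for k in ("n_variable_positions_carried", "n_heterozygous_sites",
              "n_minor_domain_forms"):
        values[k] = variation_summary.get(k, 0)
    missing = [f for f in feature_names if f not in values]
    if missing:
        raise ValueError(f"unknown features requested: {missing}")
    return pd.Series([float(values[f]) for f in feature_names],
                     index=list(feature_names), dtype=float)


def run_pca(matrix: pd.DataFrame, n_components: Optional[int] = None
            ) -> Tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the z-standardized feature matrix (ecotypes x features).

    Zero-variance columns are dropped before standardization.  Component
    signs are fixed by making each component's largest-magnitude loading
    positive, so scores are reproducible run to run.

    Returns (scores, loadings, explained_variance_ratio).
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 ecotypes for PCA")
    X = matrix.astype(float)
    keep = X.columns[X.std(axis=0, ddof=0) > 0]
    Xk = X[keep]
    Z = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0, ddof=0)
    max_comp = min(len(Z) - 1, Z.shape[1])
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z.values)
    loadings = pca.components_
    for c in range(k):
        j = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, j] < 0:
            loadings[c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=matrix.index, columns=comp_names)
    loadings_df = pd.DataFrame(loadings, index=comp_names, columns=keep)
    return scores_df, loadings_df, pca.explained_variance_ratio_


def group_scores(scores: pd.DataFrame, k: int) -> Dict[str, int]:
    """Complete-linkage clustering of PCA scores into ``k`` groups.

    Deterministic: rows are processed in sorted ecotype-name order and
    group labels are renumbered 1..k by decreasing size (ties by first
    member name).  Returns ecotype -> group label.
    """
    n = len(scores)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    ordered = scores.sort_index()
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        Z = linkage(ordered.values, method="complete")
        raw = fcluster(Z, t=k, criterion="maxclust")
    groups: Dict[int, List[str]] = {}
    for eco, lab in zip(ordered.index, raw):
        groups.setdefault(int(lab), []).append(eco)
    ordered_groups = sorted(groups.values(),
                            key=lambda m: (-len(m), sorted(m)[0]))
    out: Dict[str, int] = {}
    for i, members in enumerate(ordered_groups, start=1):
        for eco in members:
            out[eco] = i
    return out


def partition_equal(a: Mapping[str, int], b: Mapping[str, int]) -> bool:
    """Same partition of the same elements, irrespective of labels."""
    if set(a) != set(b):
        return False
    blocks_a = {}
    blocks_b = {}
    for e in a:
        blocks_a.setdefault(a[e], set()).add(e)
        blocks_b.setdefault(b[e], set()).add(e)
    return {frozenset(s) for s in blocks_a.values()} == \
        {frozenset(s) for s in blocks_b.values()}
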
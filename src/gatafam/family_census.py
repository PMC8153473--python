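"""Per-ecotype family census: counts, subfamilies, splicing statistics.

The census distinguishes *genes* (loci) from *TFs* (domain-bearing splice
isoforms): gene models carry alternative splicing forms, so the TF count is
at least the gene count, and the mean number of splicing forms per gene is
simply TFs/genes.  Splice isoforms that lose the DNA-binding domain are not
TFs and are excluded from every census quantity (they are tracked by
:func:`gatafam.domain_scan.find_domainless_isoforms`).

Subfamily assignment follows the dicot I–IV scheme: subfamily III is
recognised structurally (the long-linker IV_c spacing and/or TIFY+CCT
accessory domains); the remaining subfamilies are assigned by
nearest-reference global alignment against a labelled reference panel —
a documented proxy for the phylogenetic classification in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from ._util import round_half_up
from .domain_scan import DomainHit
from .variation import _make_aligner

SUBFAMILIES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class SubfamilyRef:
    ref_id: str
    subfamily: str
    domain_seq: str


@dataclass
class EcotypeCensus:
    ecotype: str
    n_genes: int
    n_tfs: int
    per_subfamily: Dict[str, Tuple[int, int]]   # subfamily -> (genes, tfs)
    n_genes_with_as: int
    n_as_forms: int
    presence: Dict[str, bool] = field(default_factory=dict)

    @property
    def avg_as(self) -> float:
        return round_half_up(self.n_tfs / self.n_genes, 2) if self.n_genes else 0.0

    @property
    def signature(self) -> Tuple:
        """Per-subfamily (genes, tfs) vector; the distribution-type key."""
        return tuple((sf, *self.per_subfamily.get(sf, (0, 0)))
                     for sf in SUBFAMILIES)


@dataclass
class DistributionType:
    type_label: int
    member_ecotypes: List[str]
    signature: Tuple


def assign_subfamily(hit: DomainHit, refs: Sequence[SubfamilyRef],
                     accessory_names: Iterable[str] = ()) -> str:
    """Subfamily of one domain hit.

    IV_c spacing or a TIFY/CCT accessory domain puts the protein in
    subfamily III; otherwise the nearest reference (global alignment score,
    BLOSUM62/affine) among the I/II/IV references decides, ties broken by
    smallest ref_id.
    """
    if not refs:
        raise ValueError("empty reference panel")
    covered = {r.subfamily for r in refs}
    missing = set(SUBFAMILIES) - covered
    if missing:
        raise ValueError(f"reference panel missing subfamilies {sorted(missing)}")
    accessory = set(accessory_names)
    if hit.dtype == "IV_c" or accessory & {"TIFY", "CCT"}:
        return "III"
    aligner = _make_aligner()
    best = None
    for ref in sorted(refs, key=lambda r: r.ref_id):
        if ref.subfamily == "III":
            continue
        score = aligner.score(hit.domain_seq, ref.domain_seq)
        if best is None or score > best[0]:
            best = (score, ref.subfamily)
    return best[1]


def build_census(ecotype: str, tf_table: pd.DataFrame,
                 ortholog_keys: Optional[Sequence[str]] = None
                 ) -> EcotypeCensus:
    """Census one ecotype from its TF table.

    ``tf_table`` needs columns ``gene_id``, ``ortholog_key``, ``tx_id``,
    ``subfamily`` and ``has_domain``; rows with ``has_domain == False``
    (domainless isoforms) are dropped before counting.
    """
    if tf_table["tx_id"].duplicated().any():
        dups = tf_table.loc[tf_table["tx_id"].duplicated(), "tx_id"].tolist()
        raise ValueError(f"duplicate tx_id in TF table: {dups}")
    tfs = tf_table[tf_table["has_domain"]]
    genes = tfs.groupby("gene_id", sort=True)
    n_genes = genes.ngroups
    n_tfs = len(tfs)
    per_subfamily = {}
    for sf in SUBFAMILIES:
        sf_rows = tfs[tfs["subfamily"] == sf]
        per_subfamily[sf] = (sf_rows["gene_id"].nunique(), len(sf_rows))
    iso_counts = genes.size()
    as_genes = iso_counts[iso_counts >= 2]
    present_keys = set(tfs["ortholog_key"])
    universe = list(ortholog_keys) if ortholog_keys is not None else sorted(
        present_keys)
    return EcotypeCensus(
        ecotype=ecotype,
        n_genes=n_genes,
        n_tfs=n_tfs,
        per_subfamily=per_subfamily,
        n_genes_with_as=len(as_genes),
        n_as_forms=int(as_genes.sum()),
        presence={k: k in present_keys for k in universe},
    )


def subfamily_ratios(census: EcotypeCensus) -> Dict[str, Optional[float]]:
    """TFs/genes per subfamily, 2 decimals; None where a subfamily is empty."""
    out = {}
    for sf, (g, t) in census.per_subfamily.items():
        out[sf] = round_half_up(t / g, 2) if g else None
    return out


def group_distribution_types(censuses: Sequence[EcotypeCensus]
                             ) -> List[DistributionType]:
    """Partition ecotypes by identical per-subfamily (genes, tfs) signature.

    Types are labelled 1..k in decreasing size, ties broken by the first
    member name; output is invariant to input order.
    """
    if not censuses:
        raise ValueError("no censuses to group")
    groups: Dict[Tuple, List[str]] = {}
    for c in censuses:
        groups.setdefault(c.signature, []).append(c.ecotype)
    ordered = sorted(groups.items(),
                     key=lambda kv: (-len(kv[1]), sorted(kv[1])[0]))
    return [DistributionType(i + 1, sorted(members), sig)
            for i, (sig, members) in enumerate(ordered)]


def pan_isoform_set(tf_tables: Mapping[str, pd.DataFrame]
                    ) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Distinct (ortholog_key, isoform_label) isoforms and presence matrix.

    Returns the sorted distinct-isoform list and a 0/1 DataFrame indexed by
    ``"<ortholog_key>.<label>"`` with one column per ecotype; isoforms seen
    in exactly one ecotype are the ecotype-unique forms.
    """
    ecotypes = sorted(tf_tables)
    distinct = set()
    for eco in ecotypes:
        t = tf_tables[eco]
        tfs = t[t["has_domain"]]
        distinct.update(zip(tfs["ortholog_key"], tfs["isoform_label"]))
    distinct = sorted(distinct)
    index = [f"{k}.{lab}" for k, lab in distinct]
    mat = pd.DataFrame(0, index=index, columns=ecotypes, dtype=int)
    for eco in ecotypes:
        t = tf_tables[eco]
        tfs = t[t["has_domain"]]
        for k, lab in zip(tfs["ortholog_key"], tfs["isoform_label"]):
            mat.loc[f"{k}.{lab}", eco] = 1
    return distinct, mat


def unique_isoforms(presence: pd.DataFrame) -> Dict[str, List[str]]:
    """Ecotype -> isoforms found only in that ecotype."""
    out: Dict[str, List[str]] = {e: [] for e in presence.columns}
    singletons = presence[presence.sum(axis=1) == 1]
    for iso, row in singletons.iterrows():
        out[row.idxmax()].append(iso)
    return out
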
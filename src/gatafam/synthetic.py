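"""Synthetic ecotype panels with fully known ground truth.

The default configuration emulates an intraspecific panel of 19 natural
isolates sharing a 30-gene GATA family: four census signatures (13/4/1/1
ecotypes), one subfamily-III gene absent from four genomes, one extra
splice isoform in each of two genomes, a domainless splice form, one
partial-domain (IV_p) isoform, one IV_4 gene, 21 planted variant records
giving 22 variable aligned positions over 2,195 domain columns (11 inside
and 11 outside secondary-structure elements), five silent heterozygous
codons, and organelle vs gene-tree topologies that are deliberately
incongruent (with one planted country clade in the organelle tree only).

Every emitted file is a deterministic function of the seed; regenerating
with the same seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from .family_census import SubfamilyRef
from .genome_io import (GeneModel, SequenceRecord, TranscriptModel,
                        write_fasta, write_gff3)
from .variation import StructureTrack

# ---------------------------------------------------------------------------
# panel constants

ECOTYPES = ["Col0", "Edi0", "Ct1", "Can0", "Bur0", "Hi0", "Kn0", "Ler0",
            "Mt0", "No0", "Oy0", "Po0", "Rsch4", "Sf2", "Tsu0", "Wil2",
            "Ws0", "Wu0", "Zu0"]

OUTGROUP = "Alyrata"

COUNTRIES = {
    "Col0": "USA", "Edi0": "UK", "Ct1": "Italy", "Can0": "Spain",
    "Bur0": "Ireland", "Hi0": "Netherlands", "Kn0": "Lithuania",
    "Ler0": "Germany", "Mt0": "Libya", "No0": "Germany", "Oy0": "Norway",
    "Po0": "Germany", "Rsch4": "Russia", "Sf2": "Spain", "Tsu0": "Japan",
    "Wil2": "Russia", "Ws0": "Russia", "Wu0": "Germany", "Zu0": "Switzerland",
}

GENES = [f"GATA{i}" for i in range(1, 31)]

SUBFAMILY_OF = {}
for _i in range(1, 31):
    _g = f"GATA{_i}"
    if _i in (24, 25, 28):
        SUBFAMILY_OF[_g] = "III"
    elif _i in (26, 27):
        SUBFAMILY_OF[_g] = "IV"
    elif _i in (12, 15, 16, 17, 18, 19, 20, 21, 22, 23, 30):
        SUBFAMILY_OF[_g] = "II"
    else:
        SUBFAMILY_OF[_g] = "I"

#: baseline isoform labels per gene; "c-" marks the domainless splice form
BASE_ISOFORMS = {g: ["a"] for g in GENES}
for _g in ("GATA2", "GATA4", "GATA8", "GATA10", "GATA11", "GATA28"):
    BASE_ISOFORMS[_g] = ["a", "b"]
BASE_ISOFORMS["GATA24"] = ["a", "b", "c"]      # c is domainless
BASE_ISOFORMS["GATA25"] = ["a", "b", "c"]
BASE_ISOFORMS["GATA26"] = ["a", "b", "c"]      # a is the partial IV_p form

DOMAINLESS = {("GATA24", "c")}
PARTIAL = {("GATA26", "a")}

ABSENT_GENE = "GATA24"
ABSENT_ECOTYPES = ["Hi0", "Ler0", "Mt0", "Ws0"]
UNIQUE_ISOFORMS = {"Col0": ("GATA11", "c"), "Kn0": ("GATA15", "b")}

#: genes whose C-terminal tail after the motif is 28 aa (the rest are 27);
#: together with the motif lengths this puts the multi-ecotype aligned
#: domain total at exactly 2,195 columns.
TAIL28_GENES = {"GATA1", "GATA3", "GATA5", "GATA6", "GATA7", "GATA9",
                "GATA13", "GATA14", "GATA29", "GATA12", "GATA16", "GATA17"}

MINUS_STRAND_GENES = {"GATA3", "GATA20", "GATA27"}

#: planted variant records: (gene, domain position, base residue,
#: alternative residue or None, carrier ecotypes, ambiguous codon or None)
VARIANTS: List[Tuple[str, int, str, Optional[str], Tuple[str, ...],
                     Optional[str]]] = [
    ("GATA6", 1, "C", None, ("Mt0",), "KGT"),            # C/G heteroallele
    ("GATA7", 50, "N", "T", ("Ws0", "Bur0"), None),
    ("GATA10", 13, "I", "T", ("Bur0", "Rsch4", "Wu0"), None),
    ("GATA13", 20, "Q", "L", ("Zu0",), None),
    ("GATA13", 11, "E", "K", ("Wil2",), None),
    ("GATA14", 2, "G", "C", ("Oy0", "Edi0", "Po0"), None),
    ("GATA14", 22, "R", "K", ("No0",), None),
    ("GATA14", 24, "E", "V",
     ("Rsch4", "Sf2", "No0", "Wu0", "Ler0", "Mt0"), None),
    ("GATA14", 34, "A", "V", ("Oy0", "Edi0", "Po0"), None),
    ("GATA29", 10, "M", "I", ("Bur0", "Ct1"), None),
    ("GATA17", 31, "L", None, ("Sf2",), "TTY"),          # -> F
    ("GATA17", 49, "M", "V", ("Bur0", "Sf2", "Tsu0", "Zu0", "Mt0"), None),
    ("GATA18", 8, "S", "T", ("Sf2", "Col0"), None),
    ("GATA18", 25, "V", "I", ("Bur0", "Tsu0"), None),
    ("GATA21", 9, "T", "A", ("Ler0",), None),
    ("GATA21", 14, "N", "S", ("Ler0",), None),
    ("GATA21", 18, "Q", "E", ("Ler0",), None),
    ("GATA22", 50, "A", "P", ("Can0",), None),
    ("GATA23", 16, "H", "Y", ("Wil2", "Can0"), None),
    ("GATA23", 52, "S", "G", ("Wil2", "Can0"), None),
    ("GATA30", 5, "K", None, ("Po0",), "AAY"),           # -> N
]

#: ambiguous codons that do NOT change the residue: (gene, pos, base,
#: codon, ecotype)
HET_SILENT: List[Tuple[str, int, str, str, str]] = [
    ("GATA30", 2, "G", "GGM", "Mt0"),
    ("GATA30", 34, "G", "GGM", "Po0"),
    ("GATA30", 36, "G", "GGM", "Po0"),
    ("GATA17", 33, "F", "TTY", "Sf2"),
    ("GATA20", 47, "T", "ACY", "Hi0"),
]

#: canonical secondary-structure track over domain coordinates
TRACK_SEGMENTS = [
    ("beta_sheet_1", 2, 3), ("beta_sheet_2", 6, 9), ("beta_sheet_3", 12, 15),
    ("alpha_helix", 17, 22), ("beta_sheet_4", 24, 25),
]
TRACK_LENGTH = 58

TIFY_INSTANCE = "TIFYNG"
CCT_INSTANCE = "REARLIRYKEKRKNR"

#: chromosome layout: (gene, gap in bp before this gene; None = default)
CHROM_LAYOUT = {
    "chr1": [("GATA5", None), ("GATA16", None), ("GATA25", None)],
    "chr2": [("GATA1", None), ("GATA12", None), ("GATA17", None)],
    "chr3": [("GATA2", None), ("GATA6", None), ("GATA18", 61_000),
             ("GATA24", None), ("GATA29", 167_000), ("GATA3", None),
             ("GATA19", None), ("GATA7", 120_000), ("GATA9", None),
             ("GATA20", None)],
    "chr4": [("GATA10", None), ("GATA11", 1_638), ("GATA4", None),
             ("GATA8", None), ("GATA13", None), ("GATA21", None),
             ("GATA26", None), ("GATA28", None)],
    "chr5": [("GATA14", None), ("GATA15", None), ("GATA22", None),
             ("GATA23", None), ("GATA27", None), ("GATA30", None)],
}
DEFAULT_GAP = 170_000
CHROM_START = 10_000

CHROM_LENGTHS = {"chr1": 30_420_000, "chr2": 19_700_000, "chr3": 23_500_000,
                 "chr4": 18_560_000, "chr5": 26_970_000}

#: per-ecotype whole-genome summary (genes / proteins), the panel metadata
#: used by the multivariate stage
GENOME_SUMMARY = {
    "Col0": (27949, 48147), "Edi0": (26997, 38813), "Ct1": (27006, 38930),
    "Can0": (26949, 38556), "Bur0": (27014, 38717), "Hi0": (27052, 39015),
    "Kn0": (27002, 38908), "Ler0": (27014, 38997), "Mt0": (27002, 38685),
    "No0": (27018, 38635), "Oy0": (27010, 38596), "Po0": (27045, 38776),
    "Rsch4": (27031, 38557), "Sf2": (26974, 38513), "Tsu0": (27013, 38701),
    "Wil2": (26978, 38558), "Ws0": (27010, 38395), "Wu0": (27024, 38704),
    "Zu0": (27044, 38901),
}

#: planted (incongruent) topologies; the ingroup country clade
#: Rsch4/Wil2/Ws0 exists only in the organelle tree, and the four German
#: ecotypes are scattered in both.
GENE_TOPOLOGY = (
    "(Alyrata,((((Col0,Wil2),(Edi0,Ct1)),((Can0,Bur0),(Hi0,Ler0))),"
    "(((Kn0,Mt0),(No0,Oy0)),(((Po0,Rsch4),(Sf2,Tsu0)),((Ws0,Wu0),Zu0)))));"
)
ORGANELLE_TOPOLOGY = (
    "(Alyrata,(((Rsch4,Wil2),Ws0),((((Col0,Edi0),(Ct1,Can0)),"
    "((Bur0,Hi0),(Kn0,Ler0))),(((Mt0,No0),(Oy0,Po0)),"
    "((Sf2,Tsu0),(Wu0,Zu0))))));"
)

COMMON_GENES = ["GATA1", "GATA3", "GATA5", "GATA9", "GATA12", "GATA16",
                "GATA19", "GATA20", "GATA27"]
PHYLO_CODONS_PER_GENE = 15
ORGANELLE_LENGTH = 20_000

AA_NO_C = "ADEFGHIKLMNPQRSTVWY"
BASIC_AA = "KRKRKRHQNSTA"

_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_SYNONYMS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["AGA", "AGG", "CGT", "CGC", "CGA", "CGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


def _gene_index(gene: str) -> int:
    return int(gene[4:])


def motif_length(gene: str, isoform: str = "a") -> int:
    """Motif (cysteine-anchored core) length of one TF's domain."""
    if (gene, isoform) in PARTIAL:
        return 20        # C X15 C X2 C
    if gene == "GATA29":
        return 28        # C X4 C X18 C X2 C
    if SUBFAMILY_OF[gene] == "III":
        return 28        # C X2 C X20 C X2 C
    return 26            # C X2 C X18 C X2 C


def tail_length(gene: str) -> int:
    return 28 if gene in TAIL28_GENES else 27


def domain_length(gene: str, isoform: str = "a") -> int:
    return motif_length(gene, isoform) + tail_length(gene)


# ---------------------------------------------------------------------------
# domain planting


def plant_domain(dtype: str, rng: np.random.Generator,
                 basic_region: int = 30) -> str:
    """A standalone domain string with exact spacing plus a basic region."""
    def xs(n):
        return "".join(rng.choice(list(AA_NO_C), size=n))

    basic = "".join(rng.choice(list(BASIC_AA), size=basic_region))
    if dtype == "IV_b":
        core = "C" + xs(2) + "C" + xs(18) + "C" + xs(2) + "C"
    elif dtype == "IV_c":
        core = "C" + xs(2) + "C" + xs(20) + "C" + xs(2) + "C"
    elif dtype == "IV_4":
        core = "C" + xs(4) + "C" + xs(18) + "C" + xs(2) + "C"
    elif dtype == "IV_p":
        b = int(rng.integers(12, 22))
        if rng.integers(2):
            core = "C" + xs(b) + "C" + xs(2) + "C"       # leg 2 + lone C
        else:
            a = int(rng.integers(2, 5))
            core = "C" + xs(a) + "C" + xs(b) + "C"       # leg 1 + lone C
    else:
        raise ValueError(f"unknown domain type {dtype!r}")
    return core + basic


# ---------------------------------------------------------------------------
# the plan


@dataclass
class PanelPlan:
    """Everything that determines an emitted panel (a function of the seed)."""

    seed: int
    ecotypes: List[str] = field(default_factory=lambda: list(ECOTYPES))
    with_variants: bool = True
    with_absent: bool = True
    with_unique: bool = True
    basic_region: int = 30

    def __post_init__(self):
        unknown = set(self.ecotypes) - set(ECOTYPES)
        if unknown:
            raise ValueError(f"unknown ecotypes {sorted(unknown)}")
        for gene, pos, _base, _alt, ecos, _codon in self.variants():
            if pos > domain_length(gene):
                raise ValueError(f"variant outside domain: {gene} pos {pos}")
            if self.with_absent and gene == ABSENT_GENE:
                raise ValueError("variant planted on an absent gene")
            if len(set(ecos) & set(self.ecotypes)) > len(self.ecotypes) - 1 \
                    and len(self.ecotypes) > 1:
                raise ValueError(f"variant on {gene} carried by every ecotype")

    def variants(self):
        return VARIANTS if self.with_variants else []

    def het_silent(self):
        return HET_SILENT if self.with_variants else []

    def isoforms(self, gene: str, ecotype: str) -> List[str]:
        labels = list(BASE_ISOFORMS[gene])
        if self.with_unique:
            extra = UNIQUE_ISOFORMS.get(ecotype)
            if extra and extra[0] == gene:
                labels.append(extra[1])
        return labels

    def gene_present(self, gene: str, ecotype: str) -> bool:
        if self.with_absent and gene == ABSENT_GENE:
            return ecotype not in ABSENT_ECOTYPES
        return True


# ---------------------------------------------------------------------------
# generated panel


@dataclass
class Panel:
    plan: PanelPlan
    genomes: Dict[str, Dict[str, SequenceRecord]]
    genes: Dict[str, List[GeneModel]]
    refs: List[SubfamilyRef]
    chrom_lengths: Dict[str, int]
    countries: Dict[str, str]
    track: StructureTrack
    organelles: Dict[str, str]
    outgroup_genes: Dict[str, str]
    genome_summary: Dict[str, Dict[str, int]]
    ground_truth: Dict

    @property
    def ecotypes(self) -> List[str]:
        return list(self.plan.ecotypes)


def _rand_protein(rng, n):
    return "".join(rng.choice(list(AA_NO_C), size=n))


def _rand_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _backtranslate(protein: str, rng, reserved: Dict[int, str]) -> str:
    """Deterministic codon choice; ``reserved`` forces codons at positions."""
    codons = []
    for i, aa in enumerate(protein, start=1):
        if i in reserved:
            codons.append(reserved[i])
        else:
            options = _SYNONYMS[aa]
            codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def _tree_edge_sites(newick: str, leaf_sites: int, internal_sites: int,
                     outgroup_sites: int):
    """Assign disjoint site indices to tree edges; return per-leaf site sets.

    Sites are numbered consecutively in preorder; a leaf's set is the union
    of the sites of every edge on its root path, so pairwise set-symmetric
    differences are exactly additive path lengths.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    per_leaf: Dict[str, set] = {}
    cursor = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.is_leaf():
            k = outgroup_sites if node.taxon.label == OUTGROUP else leaf_sites
        else:
            k = internal_sites
        sites = set(range(cursor, cursor + k))
        cursor += k
        for leaf in node.leaf_iter():
            per_leaf.setdefault(leaf.taxon.label, set()).update(sites)
    return per_leaf, cursor


class _PanelBuilder:
    def __init__(self, plan: PanelPlan):
        self.plan = plan
        self.rng = np.random.default_rng(plan.seed)
        self.consensus: Dict[str, str] = {}
        self.gene_domains: Dict[str, str] = {}          # core+tail, full form
        self.prefixes: Dict[str, str] = {}
        self.cds_templates: Dict[str, str] = {}          # isoform "a", + stop
        self.introns: Dict[str, str] = {}
        self.utr3s: Dict[str, str] = {}
        self.utr5_template = ""
        self.margin = 0
        self.phylo_edits: Dict[str, Dict[str, Dict[int, str]]] = {}
        self.organelle_seqs: Dict[str, str] = {}

    # ---- domain/protein design ------------------------------------------

    def _build_consensus(self):
        rng = self.rng

        def xs(n):
            return "".join(rng.choice(list(AA_NO_C), size=n))

        tail = "".join(rng.choice(list(BASIC_AA), size=28))
        for sf in ("I", "II", "IV"):
            core = "C" + xs(2) + "C" + xs(18) + "C" + xs(2) + "C"
            self.consensus[sf] = core + tail
        core = "C" + xs(2) + "C" + xs(20) + "C" + xs(2) + "C"
        self.consensus["III"] = core + tail

    def _forced_positions(self, gene: str) -> Dict[int, str]:
        forced = {}
        for g, pos, base, _alt, _ecos, _codon in VARIANTS:
            if g == gene:
                forced[pos] = base
        for g, pos, base, _codon, _eco in HET_SILENT:
            if g == gene:
                forced[pos] = base
        return forced

    def _build_gene_domains(self):
        rng = self.rng
        for gene in GENES:
            sf = SUBFAMILY_OF[gene]
            cons = self.consensus[sf]
            core_len = 28 if sf == "III" else 26
            core, tail = cons[:core_len], cons[core_len:]
            if gene == "GATA29":
                ins = _rand_protein(rng, 2)
                core = core[:3] + ins + core[3:]        # leg1 X2 -> X4
                core_len += 2
            tail = tail[:tail_length(gene)]
            domain = list(core + tail)
            anchors = self._anchor_positions(gene)
            forced = self._forced_positions(gene)
            for pos, base in forced.items():
                if pos - 1 < len(domain) and (pos not in anchors or
                                              base == "C"):
                    domain[pos - 1] = base
            # 3 gene-identity mutations at free positions
            free = [i for i in range(len(domain))
                    if (i + 1) not in anchors and (i + 1) not in forced]
            picks = rng.choice(len(free), size=3, replace=False)
            for p in sorted(picks):
                i = free[int(p)]
                current = domain[i]
                choices = [a for a in AA_NO_C if a != current]
                domain[i] = choices[int(rng.integers(len(choices)))]
            self.gene_domains[gene] = "".join(domain)

    @staticmethod
    def _anchor_positions(gene: str) -> set:
        """Cysteine anchors of the gene's full-form core (never mutated)."""
        if gene == "GATA29":
            return {1, 6, 25, 28}       # C X4 C X18 C X2 C
        if SUBFAMILY_OF[gene] == "III":
            return {1, 4, 25, 28}       # C X2 C X20 C X2 C
        return {1, 4, 23, 26}           # C X2 C X18 C X2 C

    def prefix_length(self, gene: str) -> int:
        if SUBFAMILY_OF[gene] == "III":
            return 20 + len(TIFY_INSTANCE) + 8 + len(CCT_INSTANCE) + 8
        return 40 + (_gene_index(gene) % 7)

    def _build_prefixes(self):
        rng = self.rng
        for gene in GENES:
            if SUBFAMILY_OF[gene] == "III":
                prefix = (_rand_protein(rng, 20) + TIFY_INSTANCE +
                          _rand_protein(rng, 8) + CCT_INSTANCE +
                          _rand_protein(rng, 8))
            else:
                prefix = _rand_protein(rng, self.prefix_length(gene))
            prefix = "M" + prefix[1:]
            if gene in COMMON_GENES:
                prefix = prefix[0] + "G" * PHYLO_CODONS_PER_GENE \
                    + prefix[1 + PHYLO_CODONS_PER_GENE:]
            if gene == "GATA15":
                prefix = prefix[:13] + "M" + prefix[14:]
            self.prefixes[gene] = prefix

    def protein_a(self, gene: str) -> str:
        return self.prefixes[gene] + self.gene_domains[gene]

    # ---- nucleotide templates -------------------------------------------

    def _build_templates(self):
        rng = self.rng
        self.utr5_template = _rand_nt(rng, 400)
        for gene in GENES:
            protein = self.protein_a(gene)
            reserved = {}
            if gene in COMMON_GENES:
                for k in range(PHYLO_CODONS_PER_GENE):
                    reserved[2 + k] = "GGT"
            self.cds_templates[gene] = _backtranslate(protein, rng,
                                                      reserved) + "TAA"
            self.introns[gene] = _rand_nt(rng, 150)
            self.utr3s[gene] = _rand_nt(rng, 200)

    # ---- phylogenetic signal --------------------------------------------

    def _build_phylo_edits(self):
        taxa = set(self.plan.ecotypes) | {OUTGROUP}
        per_leaf, n_sites = _tree_edge_sites(GENE_TOPOLOGY, 2, 3, 12)
        pool = [(g, k) for g in COMMON_GENES
                for k in range(PHYLO_CODONS_PER_GENE)]
        if n_sites > len(pool):
            raise ValueError("not enough reserved codons for the gene tree")
        cycle = {"T": "A", "A": "C", "C": "G", "G": "T"}
        for taxon, sites in per_leaf.items():
            if taxon not in taxa:
                continue
            edits: Dict[str, Dict[int, str]] = {}
            for s in sorted(sites):
                gene, k = pool[s]
                codon_pos = 2 + k          # protein position of the codon
                base_codon = "GGT"
                new = base_codon[:2] + cycle[base_codon[2]]
                # each site is owned by exactly one edge, but several edges
                # on one root path may target the same codon only if pools
                # overlapped -- they never do (disjoint site indices)
                edits.setdefault(gene, {})[codon_pos] = new
            self.phylo_edits[taxon] = edits

    def _build_organelles(self):
        rng = self.rng
        backbone = _rand_nt(rng, ORGANELLE_LENGTH)
        per_leaf, n_sites = _tree_edge_sites(ORGANELLE_TOPOLOGY, 5, 8, 60)
        positions = rng.choice(ORGANELLE_LENGTH, size=n_sites, replace=False)
        cycle = {"A": "C", "C": "G", "G": "T", "T": "A"}
        taxa = set(self.plan.ecotypes) | {OUTGROUP}
        for taxon in sorted(taxa):
            seq = list(backbone)
            for s in sorted(per_leaf.get(taxon, ())):
                p = int(positions[s])
                seq[p] = cycle[seq[p]]
            self.organelle_seqs[taxon] = "".join(seq)

    # ---- per-ecotype CDS edits ------------------------------------------

    def _ecotype_edits(self, gene: str, ecotype: str) -> Dict[int, str]:
        """protein position -> replacement codon for this ecotype."""
        edits: Dict[int, str] = {}
        plen = self.prefix_length(gene)
        for g, pos, base, alt, ecos, codon in self.plan.variants():
            if g != gene or ecotype not in ecos:
                continue
            ppos = plen + pos
            edits[ppos] = codon if codon else _CODON_OF[alt]
        for g, pos, _base, codon, eco in self.plan.het_silent():
            if g == gene and eco == ecotype:
                edits[plen + pos] = codon
        for g_edits in (self.phylo_edits.get(ecotype, {}),):
            for ppos, codon in g_edits.get(gene, {}).items():
                edits[ppos] = codon
        return edits

    def ecotype_cds(self, gene: str, ecotype: Optional[str]) -> str:
        cds = self.cds_templates[gene]
        if ecotype is None:
            return cds
        edits = self._ecotype_edits(gene, ecotype)
        if not edits:
            return cds
        cds = list(cds)
        for ppos, codon in edits.items():
            cds[3 * (ppos - 1):3 * ppos] = list(codon)
        return "".join(cds)

    # ---- gene regions and genomes ---------------------------------------

    def utr5_len(self, gene: str, ecotype: str) -> int:
        if gene == "GATA2":
            return 261 if ecotype == "Col0" else 86
        if gene == "GATA4":
            return {"Col0": 335, "No0": 10}.get(ecotype, 100)
        return 100

    def _gene_region(self, gene: str, ecotype: str):
        """(region sequence, list of (label, exons, cds) in local coords)."""
        A = self.margin
        u5 = self.utr5_len(gene, ecotype)
        cds = self.ecotype_cds(gene, ecotype)
        intron = self.introns[gene]
        u3 = self.utr3s[gene]
        split = 120
        region = (_rand_nt_static(gene, A) + self.utr5_template[-u5:] +
                  cds[:split] + intron + cds[split:] + u3)
        e1s, e1e = A + 1, A + u5 + split
        e2s = e1e + len(intron) + 1
        e2e = e2s + (len(cds) - split) + len(u3) - 1
        cds_a = [(A + u5 + 1, e1e), (e2s, e2s + len(cds) - split - 1)]
        plen = self.prefix_length(gene)
        out = []
        for label in self.plan.isoforms(gene, ecotype):
            exons = [(e1s, e1e), (e2s, e2e)]
            cds_segs = list(cds_a)
            if (gene, label) in DOMAINLESS:
                nt = 3 * plen
                cds_segs = [(A + u5 + 1, e1e), (e2s, e2s + (nt - split) - 1)]
            elif (gene, label) in PARTIAL:
                # splice out 6 residues (motif positions 2-7): lone C + X15
                s_aa = plen + 2
                c0 = 3 * (s_aa - 1) + 1          # first removed CDS nt
                g0 = e2s + (c0 - split - 1)      # genomic coord of c0
                exons = [(e1s, e1e), (e2s, g0 - 1), (g0 + 18, e2e)]
                cds_segs = [(A + u5 + 1, e1e), (e2s, g0 - 1),
                            (g0 + 18, e2s + len(cds) - split - 1)]
            elif label == "b" and gene == "GATA15":
                cds_segs = [(A + u5 + 40, e1e), cds_a[1]]
            elif label == "b":
                shift = min(40, u5 - 5)
                exons = [(e1s + shift, e1e), (e2s, e2e)]
            elif label == "c" and gene == "GATA11":
                exons = [(e1s + 25, e1e), (e2s, e2e)]
            elif label == "c":
                exons = [(e1s, e1e), (e2s, e2e - 30)]
            out.append((label, exons, cds_segs))
        return region, out

    def build_genomes(self):
        genomes: Dict[str, Dict[str, SequenceRecord]] = {}
        genes: Dict[str, List[GeneModel]] = {}
        for eco in self.plan.ecotypes:
            chroms: Dict[str, str] = {}
            models: List[GeneModel] = []
            for chrom, layout in CHROM_LAYOUT.items():
                parts: List[str] = []
                cursor = 0
                for gene, gap in layout:
                    gap = DEFAULT_GAP if gap is None else gap
                    lead = (CHROM_START if cursor == 0 else gap)
                    region, isoforms = self._gene_region(gene, eco)
                    start = cursor + lead + 1
                    present = self.plan.gene_present(gene, eco)
                    strand = "-" if gene in MINUS_STRAND_GENES else "+"
                    L = len(region)
                    parts.append("N" * lead)
                    if present:
                        parts.append(region if strand == "+"
                                     else str(Seq(region).reverse_complement()))
                        txs = []
                        gid = f"{eco}_{gene}"
                        for label, exons, cds_segs in isoforms:
                            if strand == "+":
                                g_ex = [(start + a - 1, start + b - 1)
                                        for a, b in exons]
                                g_cds = [(start + a - 1, start + b - 1)
                                         for a, b in cds_segs]
                            else:
                                g_ex = [(start + L - b, start + L - a)
                                        for a, b in exons][::-1]
                                g_cds = [(start + L - b, start + L - a)
                                         for a, b in cds_segs][::-1]
                            txs.append(TranscriptModel(
                                f"{gid}.{label}", label, g_ex, g_cds, strand))
                        models.append(GeneModel(gid, gene, chrom, strand, txs))
                    else:
                        parts.append("N" * L)
                    cursor = start + L - 1
                parts.append("N" * 1000)
                chroms[chrom] = "".join(parts)
            genomes[eco] = {c: SequenceRecord(c, s) for c, s in chroms.items()}
            genes[eco] = models
        return genomes, genes

    # ---- ground truth -----------------------------------------------------

    def ground_truth(self) -> Dict:
        plan = self.plan
        per_ecotype = {}
        for eco in plan.ecotypes:
            counts = {sf: [0, 0] for sf in ("I", "II", "III", "IV")}
            as_genes = as_forms = 0
            for gene in GENES:
                if not plan.gene_present(gene, eco):
                    continue
                labels = [l for l in plan.isoforms(gene, eco)
                          if (gene, l) not in DOMAINLESS]
                sf = SUBFAMILY_OF[gene]
                counts[sf][0] += 1
                counts[sf][1] += len(labels)
                if len(labels) >= 2:
                    as_genes += 1
                    as_forms += len(labels)
            per_ecotype[eco] = {
                "n_genes": sum(v[0] for v in counts.values()),
                "n_tfs": sum(v[1] for v in counts.values()),
                "per_subfamily": {sf: tuple(v) for sf, v in counts.items()},
                "n_genes_with_as": as_genes,
                "n_as_forms": as_forms,
            }
        # distribution types
        sig_groups: Dict[Tuple, List[str]] = {}
        for eco, c in per_ecotype.items():
            sig = tuple((sf, *c["per_subfamily"][sf])
                        for sf in ("I", "II", "III", "IV"))
            sig_groups.setdefault(sig, []).append(eco)
        type_sizes = sorted((len(v) for v in sig_groups.values()),
                            reverse=True)
        # variation truth
        track = StructureTrack.from_segments(TRACK_SEGMENTS, TRACK_LENGTH)
        n_var = inside = outside = 0
        var_by_sf = {"I": 0, "II": 0, "III": 0, "IV": 0}
        multiform = set()
        for gene, pos, _b, _a, ecos, _c in plan.variants():
            if not set(ecos) & set(plan.ecotypes):
                continue
            if len(set(plan.ecotypes) - set(ecos)) == 0:
                continue
            labels = [l for l in BASE_ISOFORMS[gene]
                      if (gene, l) not in DOMAINLESS]
            for l in labels:
                n_var += 1
                multiform.add(f"{gene}.{l}")
                var_by_sf[SUBFAMILY_OF[gene]] += 1
                if track.in_element(pos):
                    inside += 1
                else:
                    outside += 1
        total_columns = 0
        for gene in GENES:
            ecos_with = [e for e in plan.ecotypes
                         if plan.gene_present(gene, e)]
            if len(ecos_with) < 2:
                continue
            for l in BASE_ISOFORMS[gene]:
                if (gene, l) in DOMAINLESS:
                    continue
                total_columns += domain_length(gene, l)
        n_distinct = sum(
            len([l for l in BASE_ISOFORMS[g] if (g, l) not in DOMAINLESS])
            for g in GENES
            if any(plan.gene_present(g, e) for e in plan.ecotypes))
        if plan.with_unique:
            n_distinct += sum(1 for e in plan.ecotypes
                              if e in UNIQUE_ISOFORMS)
        return {
            "ecotypes": list(plan.ecotypes),
            "per_ecotype": per_ecotype,
            "type_sizes": type_sizes,
            "n_types": len(sig_groups),
            "type_members": sorted((sorted(v) for v in sig_groups.values()),
                                   key=lambda m: (-len(m), m[0])),
            "totals": {
                "n_genes": sum(c["n_genes"] for c in per_ecotype.values()),
                "n_tfs": sum(c["n_tfs"] for c in per_ecotype.values()),
            },
            "variation": {
                "n_variable_positions": n_var,
                "n_total_columns": total_columns,
                "context": [inside, outside],
                "by_subfamily": var_by_sf,
                "n_multiform_tfs": len(multiform),
                "n_distinct_tfs": n_distinct,
                "n_silent_het_sites": len(list(plan.het_silent())),
                "multiform_tfs": sorted(multiform),
            },
            "absent": {e: ([ABSENT_GENE] if plan.with_absent and
                           e in ABSENT_ECOTYPES else [])
                       for e in plan.ecotypes},
            "unique_isoforms": {e: [f"{g}.{l}"]
                                for e, (g, l) in UNIQUE_ISOFORMS.items()
                                if plan.with_unique and e in plan.ecotypes},
            "domainless": [f"{g}.{l}" for g, l in sorted(DOMAINLESS)],
            "common_genes": list(COMMON_GENES),
            "gene_topology": GENE_TOPOLOGY,
            "organelle_topology": ORGANELLE_TOPOLOGY,
            "countries": {e: COUNTRIES[e] for e in plan.ecotypes},
            "planted_country_clade": ("Russia",
                                      ["Rsch4", "Wil2", "Ws0"]),
            "scattered_country": ("Germany",
                                  ["Ler0", "No0", "Po0", "Wu0"]),
        }


def _rand_nt_static(key: str, n: int) -> str:
    """Deterministic filler sequence derived from a string key (no RNG state)."""
    rng = np.random.default_rng(abs(hash_stable(key)) % (2 ** 31))
    return "".join(rng.choice(list("ACGT"), size=n))


def hash_stable(s: str) -> int:
    h = 2166136261
    for ch in s:
        h = (h ^ ord(ch)) * 16777619 % (2 ** 32)
    return h


def generate_panel(seed: int = 0, plan: Optional[PanelPlan] = None) -> Panel:
    """Build the in-memory panel (genomes, gene models, metadata, truth)."""
    if plan is None:
        plan = PanelPlan(seed=seed)
    b = _PanelBuilder(plan)
    b._build_consensus()
    b._build_gene_domains()
    b._build_prefixes()
    b._build_templates()
    b._build_phylo_edits()
    b._build_organelles()
    genomes, genes = b.build_genomes()
    refs = [SubfamilyRef(f"ref_{sf}", sf, b.consensus[sf][:((28 if sf == "III"
            else 26) + 28)]) for sf in ("I", "II", "III", "IV")]
    outgroup_genes = {}
    for gene in COMMON_GENES:
        cds = list(b.cds_templates[gene])
        for ppos, codon in b.phylo_edits.get(OUTGROUP, {}).get(gene, {}).items():
            cds[3 * (ppos - 1):3 * ppos] = list(codon)
        outgroup_genes[gene] = "".join(cds)
    return Panel(
        plan=plan,
        genomes=genomes,
        genes=genes,
        refs=refs,
        chrom_lengths=dict(CHROM_LENGTHS),
        countries={e: COUNTRIES[e] for e in plan.ecotypes},
        track=StructureTrack.from_segments(TRACK_SEGMENTS, TRACK_LENGTH),
        organelles=dict(b.organelle_seqs),
        outgroup_genes=outgroup_genes,
        genome_summary={e: {"n_genes": GENOME_SUMMARY[e][0],
                            "n_proteins": GENOME_SUMMARY[e][1]}
                        for e in plan.ecotypes},
        ground_truth=b.ground_truth(),
    )


# ---------------------------------------------------------------------------
# file emission


def write_panel(panel: Panel, outdir) -> Path:
    """Emit the panel as standard files (FASTA/GFF3/TSV/JSON/newick inputs)."""
    out = Path(outdir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    for eco in panel.ecotypes:
        recs = [panel.genomes[eco][c] for c in sorted(panel.genomes[eco])]
        write_fasta(recs, out / "genomes" / f"{eco}.genome.fasta")
        write_gff3(panel.genes[eco], out / "genomes" / f"{eco}.gff3")
    write_fasta([SequenceRecord(r.ref_id, r.domain_seq, "protein")
                 for r in panel.refs], out / "subfamily_refs.fasta")
    write_fasta([SequenceRecord(name, seq)
                 for name, seq in sorted(panel.organelles.items())],
                out / "organelles.fasta")
    write_fasta([SequenceRecord(g, s)
                 for g, s in sorted(panel.outgroup_genes.items())],
                out / "outgroup_genes.fasta")
    with open(out / "chromosomes.tsv", "w") as fh:
        fh.write("chromosome\tlength_bp\n")
        for c, L in sorted(panel.chrom_lengths.items()):
            fh.write(f"{c}\t{L}\n")
    with open(out / "countries.tsv", "w") as fh:
        fh.write("ecotype\tcountry\n")
        for e in panel.ecotypes:
            fh.write(f"{e}\t{panel.countries[e]}\n")
    with open(out / "structure_track.tsv", "w") as fh:
        fh.write("element\tstart\tend\n")
        for el, s, e in panel.track.to_segments():
            fh.write(f"{el}\t{s}\t{e}\n")
        fh.write(f"loop_total_length\t1\t{len(panel.track)}\n")
    with open(out / "genome_summary.tsv", "w") as fh:
        fh.write("ecotype\tn_genes\tn_proteins\n")
        for e in panel.ecotypes:
            gs = panel.genome_summary[e]
            fh.write(f"{e}\t{gs['n_genes']}\t{gs['n_proteins']}\n")
    with open(out / "ortholog_map.tsv", "w") as fh:
        for eco in panel.ecotypes:
            for g in panel.genes[eco]:
                fh.write(f"{g.gene_id}\t{g.ortholog_key}\n")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(panel.ground_truth, fh, indent=1, sort_keys=True)
    return out
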
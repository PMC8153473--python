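"""End-to-end orchestration: scan -> census -> variation -> structure ->
layout -> PCA -> phylogeny, over an ecotype panel (synthetic or loaded from
files), with TSV/JSON/newick report writing.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from . import __version__
from .domain_scan import (detect_accessory, find_domainless_isoforms,
                          scan_zinc_fingers)
from .family_census import (EcotypeCensus, SubfamilyRef, assign_subfamily,
                            build_census, group_distribution_types,
                            pan_isoform_set, subfamily_ratios,
                            unique_isoforms)
from .genome_io import (SequenceRecord, extract_cds, read_fasta, read_gff3,
                        translate_ambiguous)
from .genome_layout import (ChromMap, chromosome_counts, gene_density,
                            proximity_pairs)
from .multivariate import (FEATURE_NAMES, extract_features, group_scores,
                           partition_equal, run_pca)
from .phylo import (bootstrap_support, concat_alignment, monophyly_test,
                    rf_distance, tree_splits, write_newick)
from .structure_diff import compare_ortholog_structures, profile_transcript
from .synthetic import OUTGROUP, Panel, PanelPlan
from .variation import (StructureTrack, align_ortholog_domains,
                        build_variation_matrix, classify_position_context,
                        count_multiform_tfs, heterozygosity_by_subfamily,
                        trim_trailing_overhang, VariationMatrix)


@dataclass
class RunConfig:
    seed: int = 0
    bootstrap: int = 200
    basic_region: int = 30
    proximity_bp: int = 170_000
    pca_groups: Optional[int] = None    # default: number of census types

    def __post_init__(self):
        for name in ("bootstrap", "basic_region", "proximity_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    config: RunConfig
    tf_tables: Dict[str, pd.DataFrame]
    censuses: Dict[str, EcotypeCensus]
    types: list
    presence: pd.DataFrame
    domainless: List[str]
    vm: VariationMatrix
    subfamily_of_tf: Dict[str, str]
    context: Tuple[int, int]
    het_by_subfamily: Dict[str, Tuple[int, Optional[float]]]
    structure_reports: Dict[str, list]
    layout: Dict[str, Dict]
    features: pd.DataFrame
    pca_scores: pd.DataFrame
    pca_variance: list
    pca_partition: Dict[str, int]
    type_partition: Dict[str, int]
    common_genes: List[str]
    gene_tree: object
    organelle_tree: object
    rf_gene_vs_organelle: Optional[int]
    monophyly_gene: Dict[str, bool]
    monophyly_organelle: Dict[str, bool]
    summary: Dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# panel loading (file inputs)


def load_panel(indir) -> Panel:
    """Load a panel directory written by :func:`gatafam.synthetic.write_panel`."""
    from .synthetic import COUNTRIES  # noqa: F401  (same file layout)

    indir = Path(indir)
    countries = {}
    with open(indir / "countries.tsv") as fh:
        next(fh)
        for line in fh:
            eco, country = line.strip().split("\t")
            countries[eco] = country
    ecotypes = list(countries)
    genomes, genes = {}, {}
    for eco in ecotypes:
        recs = read_fasta(indir / "genomes" / f"{eco}.genome.fasta")
        genomes[eco] = {r.id: r for r in recs}
        genes[eco] = read_gff3(indir / "genomes" / f"{eco}.gff3")
    refs = [SubfamilyRef(r.id, r.id.split("_", 1)[1], r.seq)
            for r in read_fasta(indir / "subfamily_refs.fasta", "protein")]
    chrom_lengths = {}
    with open(indir / "chromosomes.tsv") as fh:
        next(fh)
        for line in fh:
            c, L = line.strip().split("\t")
            chrom_lengths[c] = int(L)
    segments, length = [], 0
    with open(indir / "structure_track.tsv") as fh:
        next(fh)
        for line in fh:
            el, s, e = line.strip().split("\t")
            if el == "loop_total_length":
                length = int(e)
            else:
                segments.append((el, int(s), int(e)))
    track = StructureTrack.from_segments(segments, length)
    organelles = {r.id: r.seq for r in read_fasta(indir / "organelles.fasta")}
    outgroup_genes = {r.id: r.seq
                      for r in read_fasta(indir / "outgroup_genes.fasta")}
    genome_summary = {}
    with open(indir / "genome_summary.tsv") as fh:
        next(fh)
        for line in fh:
            eco, ng, npr = line.strip().split("\t")
            genome_summary[eco] = {"n_genes": int(ng), "n_proteins": int(npr)}
    gt_path = indir / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    return Panel(
        plan=PanelPlan(seed=0, ecotypes=ecotypes),
        genomes=genomes, genes=genes, refs=refs,
        chrom_lengths=chrom_lengths, countries=countries, track=track,
        organelles=organelles, outgroup_genes=outgroup_genes,
        genome_summary=genome_summary, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# stages


def scan_panel(panel: Panel, config: RunConfig,
               accessory_annotations: Optional[Mapping[str, set]] = None):
    """Translate, scan and subfamily-assign every transcript of the panel.

    ``accessory_annotations`` optionally maps tx_id to a set of accessory
    domain names (e.g. precomputed TIFY/CCT annotations), bypassing the
    shipped consensus patterns.  Returns (per-ecotype TF tables, per-TF
    per-ecotype domain state rows, per-ecotype CDS of every single-isoform
    gene for the supermatrix).
    """
    tables = {}
    domain_states: Dict[str, Dict[str, list]] = {}
    cds_store: Dict[str, Dict[str, str]] = {}
    for eco in panel.ecotypes:
        rows = []
        genome = panel.genomes[eco]
        for gene in panel.genes[eco]:
            for tx in gene.transcripts:
                cds = extract_cds(tx, genome[gene.chromosome])
                states = translate_ambiguous(cds)
                protein_str = "".join(s.consensus for s in states)
                hits = scan_zinc_fingers(states,
                                         basic_region=config.basic_region)
                if accessory_annotations is not None:
                    accessory_names = set(
                        accessory_annotations.get(tx.tx_id, ()))
                else:
                    accessory_names = {a.name for a in
                                       detect_accessory(protein_str)}
                has_domain = bool(hits)
                subfamily = dtype = domain_seq = ""
                start = end = 0
                spacing = ()
                if has_domain:
                    hit = hits[0]
                    dtype = hit.dtype
                    start, end = hit.start, hit.end
                    spacing = hit.spacing
                    domain_seq = hit.domain_seq
                    subfamily = assign_subfamily(hit, panel.refs,
                                                 accessory_names)
                    tf_key = f"{gene.ortholog_key}.{tx.isoform_label}"
                    domain_states.setdefault(tf_key, {})[eco] = \
                        hit.domain_states
                rows.append({
                    "ecotype": eco,
                    "gene_id": gene.gene_id,
                    "ortholog_key": gene.ortholog_key,
                    "tx_id": tx.tx_id,
                    "isoform_label": tx.isoform_label,
                    "has_domain": has_domain,
                    "dtype": dtype,
                    "subfamily": subfamily,
                    "n_hits": len(hits),
                    "domain_start": start,
                    "domain_end": end,
                    "spacing": "/".join("-" if s is None else str(s)
                                        for s in spacing),
                    "domain_seq": domain_seq,
                    "accessory": ",".join(sorted(accessory_names)),
                })
                cds_store.setdefault(gene.ortholog_key, {})
                if len(gene.transcripts) == 1:
                    cds_store[gene.ortholog_key][eco] = cds
        tables[eco] = pd.DataFrame(rows)
    return tables, domain_states, cds_store


def variation_stage(domain_states, panel: Panel, tf_tables):
    """Align per-TF domains across ecotypes and build the variation matrix."""
    msas = {}
    for tf_key, rows in domain_states.items():
        msa = align_ortholog_domains(rows)
        msas[tf_key] = trim_trailing_overhang(msa)
    vm = build_variation_matrix(msas)
    subfamily_of_tf = {}
    for eco, t in tf_tables.items():
        tfs = t[t["has_domain"]]
        for key, sf in zip(tfs["ortholog_key"] + "." + tfs["isoform_label"],
                           tfs["subfamily"]):
            subfamily_of_tf.setdefault(key, sf)
    return vm, subfamily_of_tf


def variation_carriage(vm: VariationMatrix, subfamily_of_tf,
                       ecotypes) -> Dict[str, Dict[str, float]]:
    """Per-ecotype carriage of minority states, ambiguous codons and minor
    domain forms (the variation block of the feature vectors)."""
    out = {e: {"n_variable_positions_carried": 0, "n_heterozygous_sites": 0,
               "n_minor_domain_forms": 0,
               **{f"varpos_sf_{sf}": 0 for sf in ("I", "II", "III", "IV")}}
           for e in ecotypes}
    for tf, block in vm.per_tf.items():
        sf = subfamily_of_tf.get(tf, "")
        for eco in block.msa:
            n_amb = sum(1 for s in block.msa[eco] if s.ambiguous_codon)
            if eco in out:
                out[eco]["n_heterozygous_sites"] += n_amb
        if block.n_ecotypes < 2:
            continue
        for pos in block.variable_positions:
            states = {e: block.msa[e][pos - 1].amino_set for e in block.msa}
            tally = Counter(states.values())
            modal = max(sorted(tally, key=lambda s: sorted(s)),
                        key=lambda s: tally[s])
            for eco, s in states.items():
                if s != modal and eco in out:
                    out[eco]["n_variable_positions_carried"] += 1
                    if sf:
                        out[eco][f"varpos_sf_{sf}"] += 1
        if block.n_forms >= 2:
            forms = Counter(block.form_by_ecotype.values())
            modal_form = max(sorted(forms), key=lambda f: forms[f])
            for eco, f in block.form_by_ecotype.items():
                if f != modal_form and eco in out:
                    out[eco]["n_minor_domain_forms"] += 1
    return out


def phylo_stage(panel: Panel, tf_tables, vm: VariationMatrix,
                cds_store, config: RunConfig):
    """Common-gene supermatrix tree vs organelle tree, plus monophyly tests.

    A gene is "common" when it is present in every ecotype, has a single
    splice isoform everywhere and a single domain form across the panel
    (the computable version of a conserved single-copy marker set).
    """
    ecotypes = panel.ecotypes
    common = []
    for key in sorted(cds_store):
        per_eco = cds_store[key]
        if set(per_eco) != set(ecotypes):
            continue
        if len({len(s) for s in per_eco.values()}) != 1:
            continue
        tf_forms = [b.n_forms for tf, b in vm.per_tf.items()
                    if tf.startswith(key + ".")]
        if tf_forms and max(tf_forms) > 1:
            continue
        common.append(key)
    usable = [g for g in common if g in panel.outgroup_genes] \
        if panel.outgroup_genes else common
    gene_tree = organelle_tree = None
    rf = None
    mono_gene = mono_org = {}
    groups = {}
    country_counts = Counter(panel.countries.values())
    for eco, country in panel.countries.items():
        if country_counts[country] >= 2:
            groups.setdefault(country, []).append(eco)
    if usable:
        gene_msas = {}
        for g in usable:
            msa = dict(cds_store[g])
            if panel.outgroup_genes:
                msa[OUTGROUP] = panel.outgroup_genes[g]
            gene_msas[g] = msa
        supermatrix, _parts = concat_alignment(gene_msas, usable)
        gene_tree = bootstrap_support(supermatrix, config.bootstrap,
                                      config.seed)
    if panel.organelles:
        organelle_tree = bootstrap_support(panel.organelles, config.bootstrap,
                                           config.seed + 1)
    if gene_tree is not None and organelle_tree is not None:
        g_leaves = {l.taxon.label for l in gene_tree.leaf_node_iter()}
        o_leaves = {l.taxon.label for l in organelle_tree.leaf_node_iter()}
        if g_leaves == o_leaves:
            rf = rf_distance(gene_tree, organelle_tree)
    outgroup = OUTGROUP if panel.outgroup_genes else None
    if gene_tree is not None and groups:
        mono_gene = monophyly_test(gene_tree, groups, outgroup=outgroup)
    if organelle_tree is not None and groups:
        og = OUTGROUP if OUTGROUP in panel.organelles else None
        mono_org = monophyly_test(organelle_tree, groups, outgroup=og)
    return common, gene_tree, organelle_tree, rf, mono_gene, mono_org


# ---------------------------------------------------------------------------
# the full run


def analyze(panel: Panel, config: Optional[RunConfig] = None
            ) -> PipelineResult:
    config = config or RunConfig()
    tf_tables, domain_states, cds_store = scan_panel(panel, config)

    universe = sorted({k for t in tf_tables.values()
                       for k in t.loc[t["has_domain"], "ortholog_key"]})
    censuses = {eco: build_census(eco, tf_tables[eco], universe)
                for eco in panel.ecotypes}
    types = group_distribution_types(list(censuses.values()))
    type_partition = {}
    for t in types:
        for eco in t.member_ecotypes:
            type_partition[eco] = t.type_label

    _distinct, presence = pan_isoform_set(tf_tables)
    uniques = unique_isoforms(presence)
    all_rows = pd.concat(tf_tables.values(), ignore_index=True)
    domainless = find_domainless_isoforms(all_rows)

    vm, subfamily_of_tf = variation_stage(domain_states, panel, tf_tables)
    context = classify_position_context(vm, panel.track) if panel.track \
        else (0, 0)
    het_by_sf = heterozygosity_by_subfamily(vm, subfamily_of_tf)

    # structure comparison of the primary isoform across ecotypes
    structure_reports = {}
    for key in universe:
        profiles = {}
        for eco in panel.ecotypes:
            for gene in panel.genes[eco]:
                if gene.ortholog_key == key:
                    tx = gene.transcripts[0]
                    for cand in gene.transcripts:
                        if cand.isoform_label == "a":
                            tx = cand
                    profiles[eco] = profile_transcript(tx, gene, eco)
        if len(profiles) >= 2:
            structure_reports[key] = compare_ortholog_structures(profiles)

    # chromosomal layout per ecotype
    layout = {}
    for eco in panel.ecotypes:
        cmap = ChromMap.from_gene_models(panel.genes[eco],
                                         panel.chrom_lengths)
        layout[eco] = {
            "counts": chromosome_counts(cmap),
            "density": gene_density(cmap),
            "pairs": proximity_pairs(cmap, config.proximity_bp),
        }

    # features and PCA grouping
    carriage = variation_carriage(vm, subfamily_of_tf, panel.ecotypes)
    feats = {}
    for eco in panel.ecotypes:
        t = tf_tables[eco]
        n_absent = sum(1 for k, present in censuses[eco].presence.items()
                       if not present)
        n_dless = len(find_domainless_isoforms(t))
        feats[eco] = extract_features(
            censuses[eco], panel.genome_summary.get(eco, {}), carriage[eco],
            n_absent, len(uniques.get(eco, [])), n_dless)
    features = pd.DataFrame(feats).T.loc[panel.ecotypes]
    pca_partition = {}
    scores = pd.DataFrame(index=features.index)
    variance = []
    if len(features) >= 2:
        scores, _loadings, variance = run_pca(features)
        k = config.pca_groups or len(types)
        pca_partition = group_scores(scores, min(k, len(features)))

    common, gene_tree, organelle_tree, rf, mono_g, mono_o = phylo_stage(
        panel, tf_tables, vm, cds_store, config)

    n_multi, n_distinct, pct_multi = count_multiform_tfs(vm)
    result = PipelineResult(
        config=config, tf_tables=tf_tables, censuses=censuses, types=types,
        presence=presence, domainless=domainless, vm=vm,
        subfamily_of_tf=subfamily_of_tf, context=context,
        het_by_subfamily=het_by_sf, structure_reports=structure_reports,
        layout=layout, features=features, pca_scores=scores,
        pca_variance=list(variance), pca_partition=pca_partition,
        type_partition=type_partition, common_genes=common,
        gene_tree=gene_tree, organelle_tree=organelle_tree,
        rf_gene_vs_organelle=rf, monophyly_gene=mono_g,
        monophyly_organelle=mono_o)
    result.summary = _summarise(result)
    return result


def _summarise(r: PipelineResult) -> Dict:
    total_genes = sum(c.n_genes for c in r.censuses.values())
    total_tfs = sum(c.n_tfs for c in r.censuses.values())
    as_genes = sum(c.n_genes_with_as for c in r.censuses.values())
    avg_as = sorted(c.avg_as for c in r.censuses.values())
    ratios_iii = sorted({subfamily_ratios(c).get("III")
                         for c in r.censuses.values()} - {None})
    from ._util import round_half_up
    return {
        "version": __version__,
        "seed": r.config.seed,
        "n_ecotypes": len(r.censuses),
        "total_gata_genes": total_genes,
        "total_gata_tfs": total_tfs,
        "n_as_genes": as_genes,
        "as_gene_fraction_pct": round_half_up(
            100.0 * as_genes / total_genes, 2) if total_genes else 0.0,
        "avg_as_min": avg_as[0] if avg_as else 0.0,
        "avg_as_max": avg_as[-1] if avg_as else 0.0,
        "subfamily_iii_ratios": ratios_iii,
        "n_types": len(r.types),
        "type_sizes": [len(t.member_ecotypes) for t in r.types],
        "n_distinct_tfs": len(r.vm.per_tf),
        "n_variable_positions": r.vm.n_variable_positions,
        "n_total_domain_columns": r.vm.n_total_positions,
        "pct_variable": r.vm.pct_variable,
        "n_multiform_tfs": count_multiform_tfs(r.vm)[0],
        "pct_multiform_tfs": count_multiform_tfs(r.vm)[2],
        "context_inside": r.context[0],
        "context_outside": r.context[1],
        "n_domainless_isoforms": len(r.domainless),
        "n_common_genes": len(r.common_genes),
        "rf_gene_vs_organelle": r.rf_gene_vs_organelle,
        "pca_matches_types": partition_equal(r.pca_partition,
                                             r.type_partition),
        "monophyly_gene": r.monophyly_gene,
        "monophyly_organelle": r.monophyly_organelle,
    }


# ---------------------------------------------------------------------------
# report writing


def write_bundle(result: PipelineResult, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for eco, c in result.censuses.items():
        row = {"ecotype": eco, "n_gata_genes": c.n_genes,
               "n_gata_tfs": c.n_tfs, "n_genes_with_as": c.n_genes_with_as,
               "n_as_forms": c.n_as_forms, "avg_as": c.avg_as}
        for sf, (g, t) in c.per_subfamily.items():
            row[f"genes_{sf}"] = g
            row[f"tfs_{sf}"] = t
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "census.tsv", sep="\t", index=False)

    with open(out / "distribution_types.tsv", "w") as fh:
        fh.write("type\tn_members\tmembers\tsignature\n")
        for t in result.types:
            fh.write(f"{t.type_label}\t{len(t.member_ecotypes)}\t"
                     f"{','.join(t.member_ecotypes)}\t{t.signature}\n")

    pd.concat(result.tf_tables.values(), ignore_index=True).to_csv(
        out / "scan.tsv", sep="\t", index=False)
    struct_rows = []
    for key, report in result.structure_reports.items():
        for fc in report:
            struct_rows.append({
                "ortholog_key": key, "feature": fc.feature,
                "conserved": fc.conserved,
                "min": fc.value_range[0] if fc.value_range else "",
                "max": fc.value_range[1] if fc.value_range else "",
                "outliers": ",".join(fc.outliers or []),
            })
    pd.DataFrame(struct_rows).to_csv(out / "structure_report.tsv", sep="\t",
                                     index=False)
    result.presence.to_csv(out / "presence_matrix.tsv", sep="\t")
    result.vm.variant_table().to_csv(out / "variants.tsv", sep="\t",
                                     index=False)
    result.features.to_csv(out / "features.tsv", sep="\t")
    result.pca_scores.to_csv(out / "pca_scores.tsv", sep="\t")
    with open(out / "pca_groups.tsv", "w") as fh:
        fh.write("ecotype\tpca_group\tdistribution_type\n")
        for eco in sorted(result.pca_partition):
            fh.write(f"{eco}\t{result.pca_partition[eco]}\t"
                     f"{result.type_partition.get(eco, '')}\n")
    if result.gene_tree is not None:
        write_newick(result.gene_tree, out / "gene_tree.nwk")
    if result.organelle_tree is not None:
        write_newick(result.organelle_tree, out / "organelle_tree.nwk")

    pair_rows = []
    for eco, lay in result.layout.items():
        for chrom, a, b, d in lay["pairs"]:
            pair_rows.append({"ecotype": eco, "chromosome": chrom,
                              "gene_a": a, "gene_b": b, "distance_bp": d})
    pd.DataFrame(pair_rows).to_csv(out / "proximity_pairs.tsv", sep="\t",
                                   index=False)
    dens_rows = []
    for eco, lay in result.layout.items():
        for chrom in sorted(lay["counts"]):
            dens_rows.append({"ecotype": eco, "chromosome": chrom,
                              "n_genes": lay["counts"][chrom],
                              "mb_per_gene": lay["density"].get(chrom)})
    pd.DataFrame(dens_rows).to_csv(out / "gene_density.tsv", sep="\t",
                                   index=False)

    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True, default=str)
    return out


def run_pipeline(indir, outdir, config: Optional[RunConfig] = None
                 ) -> PipelineResult:
    """Load a panel directory, run every stage, write the report bundle."""
    panel = load_panel(indir)
    result = analyze(panel, config)
    write_bundle(result, outdir)
    return result
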
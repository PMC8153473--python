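# Methods

This note records the models, conventions and defaults behind `gatafam`,
and what the synthetic panels do and do not establish about real data.

## Zinc-finger detection and typing

A class-IV zinc finger is matched by the grammar
`[CX{2,4}C] X{12,21} [CX{2}C]`: leg 1 (`CX₂₋₄C`), a 12–21 residue linker,
and leg 2 (`CX₂C`), with at least one leg present. `X` is any residue, so
linkers may themselves contain cysteines; the enumeration considers every
candidate anchor combination. Spacing `(2,18,2)` is type IV_b, `(2,20,2)`
IV_c, `(4,18,2)` IV_4; every other grammar-conformant hit — a missing leg,
a linker outside {18, 20}, or leg-1 spacing 3 — is the partial type IV_p.

**Partial-hit spans.** Published partial forms are written with anchoring
cysteines (`CX₁₅CX₂C`), so a missing leg is replaced by a lone cysteine at
linker distance 12–21 when one exists (nearest first, scanning outward and
abandoning the search past distance 21); otherwise by a plain linker
window of up to 21 residues. This makes the reported spacing of a partial
hit well defined and reproducible.

**Overlap resolution.** Candidates are ranked full-before-partial, then
leftmost, then longest, then lexicographically by spacing; ranked
candidates are accepted greedily when their motif spans do not overlap.
Multi-domain proteins therefore yield multiple hits.

**Heterozygous residues.** A position whose codon carries an IUPAC
ambiguity letter is a *set* of residues; it matches a cysteine anchor iff
C is a member of the set. A C/G heteroallele at the first conserved
cysteine therefore still nucleates the domain, and the ambiguity is
reported by the variation stage instead of silently discarding the gene.

**Domain sequence.** The reported domain extends `basic_region` residues
(default 30) past the last motif residue, truncated at the protein end —
the basic region that completes the DNA-binding unit. The default gives
~47–58 aa domain rows for typical family members.

**False-positive control.** The only filter is the grammar itself plus the
at-least-one-leg rule. This is a deliberate, documented proxy for
profile-based screening (InterPro-style HMMs are out of scope); the
accessory-domain detector likewise uses shipped consensus patterns for
TIFY and CCT, explicitly labelled approximations, and can be bypassed with
a precomputed annotation table (`scan_panel(..., accessory_annotations=)`).

## Census definitions

A *TF* is a domain-bearing splice isoform; splice forms that lose the
domain are excluded from every count and tracked separately as domainless
isoforms. Per genome: `n_genes` counts loci with at least one TF,
`n_tfs` counts TFs, `avg_as = n_tfs / n_genes` (this matches printed
per-genome means such as 39/29 = 1.34 and 42/30 = 1.40),
`n_genes_with_as` counts genes with ≥ 2 TFs and `n_as_forms` their total
TFs. Ratios are rounded half-up to 2 decimals; an empty subfamily's ratio
is undefined (`None`), imputed 0 only inside feature vectors.

Subfamily III is recognised structurally (IV_c spacing or TIFY/CCT);
subfamilies I/II/IV are assigned by nearest labelled reference under
global alignment (BLOSUM62, gap open −11, extend −1), ties to the smallest
reference id. Nearest-reference is a stated proxy for the literature's
phylogenetic classification; reference panels are caller-supplied.

*Distribution types* partition genomes by identical per-subfamily
(genes, TFs) signatures, labelled 1..k by decreasing size with ties broken
by the first member name — invariant to input order.

## Variation matrix

Orthologous domain rows (per distinct TF = ortholog × isoform label) are
aligned across ecotypes. Equal-length inputs with ≤ 10% pairwise consensus
mismatch are taken as aligned (the intraspecific common case — this also
guarantees the progressive score can never fall below the identity
alignment's); otherwise a centre-star progressive global alignment
(BLOSUM62, affine gaps) is used. Trailing columns supported by a single
sequence are trimmed before counting, so a residue exposed past everyone
else's domain end by an upstream deletion does not create columns.

A position is *variable* iff at least two ecotypes have different state
sets — `{C,G}` vs `{C}` is variable; an ambiguous codon whose expansions
all give one residue (e.g. `GGM` → G) is *silent heterozygosity*, listed
separately, never variable. The gap symbol is a countable state. Domain
*forms* are distinct rendered rows (heterozygous sets render as `{C/G}`).
Totals (variable positions, aligned columns, the percentage printed to 3
decimals half-up) are computed over TFs observed in ≥ 2 genomes; TFs
unique to one genome still count in the distinct-TF denominator of the
multiform fraction (2 decimals).

Structural context uses a per-position track (alpha helix, four beta
sheets, loop) over domain coordinates; a variable position is "inside" iff
its label is not loop. The track must be at least as long as the longest
domain; shorter domains use its prefix.

Residue property groups (config-overridable): charged DEKRH, polar
uncharged STNQCY, hydrophobic AVLIMFWG, special P.

## Structure and layout

Exon indexing is in transcription order starting at 1; when isoform exon
counts differ, exons are matched by order and the unmatched tail reported
separately — a computable proxy for visual diagram comparison. UTR lengths
are always derived (exon minus CDS extents on the transcript's own
strand), never read from annotation fields. Translation starts at the
first CDS base as annotated, which also encodes alternative-start isoform
pairs.

Inter-gene distance defaults to the gap between closest annotated ends,
`max(0, later.start − earlier.end − 1)`, with a strict `< 170 kb`
threshold; start-to-start is available (`measure="start"`) since the
printed pair distances do not state their convention. Densities are
`length_bp / 10⁶ / count`, 2 decimals.

## Features and grouping

28 per-ecotype features spanning five categories: whole-genome size
(genes, proteins), family counts, subfamily composition (4 × genes, 4 ×
TFs, 4 × ratios), splicing (AS genes, AS forms), presence (absent
orthologs, unique isoforms, domainless isoforms) and variation carriage
(minority-state positions overall and per subfamily, ambiguous-codon
sites, minor domain forms). The exact list is config-replaceable;
`avg_as` is excluded as the exact ratio of two included features. Columns
are z-standardized (zero-variance columns dropped); PCA component signs
are fixed by making each component's largest-magnitude loading positive;
grouping is complete-linkage on the score space with k defaulting to the
number of distribution types, labels ordered by group size. Group
*recovery* (partition equality), not score coordinates, is the meaningful
output.

## Phylogenetics

Distances are uncorrected p-distances with pairwise gap deletion
(gap/N/X/? columns ignored per pair); model-corrected distances are
deliberately omitted at intraspecific divergences. Neighbor joining is
implemented directly with a smallest-index tie-break and branch lengths
clamped at zero; on additive matrices it returns the generating topology
and lengths exactly (property-tested against exhaustive reconstruction,
and cross-checked against an independent NJ implementation). Bootstrap
resampling is seeded and bit-reproducible; site patterns are compressed
once and replicate weights drawn multinomially, which makes thousands of
replicates cheap on long organelle alignments. Supports are the
percentage of replicate trees containing each split of the point tree,
stored as internal-node labels in newick.

The supermatrix uses the *common genes*: present in every genome, a single
splice isoform everywhere, and a single domain form across the panel (a
computable conserved single-copy marker criterion; the form condition is
the configurable part). Congruence is quantified by Robinson–Foulds
distance over non-trivial splits — a computable stand-in for visual
incongruence inspection. Monophyly tests reroot at the outgroup and ask
whether a labelled leaf set is exactly one clade.

## The synthetic panel

The default configuration emulates a 19-isolate panel with a 30-gene
family: subfamilies of 14/11/3/2 genes; IV_b domains except one IV_4 gene,
IV_c throughout subfamily III (plus planted TIFY/CCT), and one partial
IV_p splice form; one subfamily-III gene absent from four genomes; one
extra isoform in each of two genomes; one domainless splice form; 21
variant records giving 22 variable aligned positions over 2,195 columns
(11 inside / 11 outside structural elements, planted with the ambiguous
codons KGT, TTY, AAY), five silent heterozygous codons (GGM, TTY, ACY);
form counts 1×4, 3×3, 9×2 over 13 multiform TFs of 43 distinct. Genes sit
on five chromosomes (3/3/10/8/6) with four planted proximity pairs (1,638
bp to 167 kb); declared chromosome lengths give densities of 2.35 and
2.32 Mb/gene on the two dense chromosomes. Phylogenetic signal is planted
as disjoint per-edge substitution sets — third positions of reserved
glycine codons in the nine common genes, arbitrary sites in a 20 kb
organelle backbone — so distances are exactly additive on the planted
topologies, which are mutually incongruent and place a three-isolate
country clade only in the organelle history. Everything emitted is a
deterministic function of the seed.

What the panel does **not** emulate: real intergenic sequence (N filler),
recombination and homoplasy, indel variation inside domains (the default
plan is substitution-only, though the alignment/gap machinery is exercised
separately), profile-quality accessory domains, assembly error, or
realistic codon usage beyond a fixed synonymous-codon choice. Passing on
the panel therefore establishes the pipeline's bookkeeping and recovery
logic under known truth — not scanner sensitivity on diverged real
proteins, nor tree resolution under homoplastic signal.

## Numerical choices and degenerate inputs

Rounding is half-up everywhere a table-parity value is printed (3 decimals
for the global variation percentage, 2 elsewhere). Codon expansion is
capped at two ambiguous positions per codon (observed cases have one);
more is an error. A codon expanding to both stop and residue is an error;
an internal all-stop codon truncates with a warning. Empty reference
panels, ragged alignments, orphan mRNAs, CDS outside exons,
out-of-bounds coordinates and k outside [1, n] raise immediately with the
offending object named. Default problem sizes (19 genomes, ~2.4 kb
supermatrix, 20 kb organelle, 200 bootstrap replicates) keep a full run
under ten seconds; the bootstrap count is a config knob, and published
analyses of this kind use 10,000 replicates.
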
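# Methods

This note documents the models and procedures implemented in `chi_evoscape`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generators do and do not emulate.

## Scope and overall design

The package re-implements, at desk scale, a complete evolutionary-landscape
analysis of the chalcone isomerase (CHI)-fold gene family: identification of
family members in proteomes, five-way CHI typing (types I-V), conserved-motif
occurrence analysis, gene-duplication-mode classification with per-mode
enrichment testing, Ka/Ks selection analysis of duplicate pairs, and
structural-similarity clustering of predicted 3D models. Published analyses
of this kind run on hundreds of downloaded genomes with heavyweight external
tools (profile-HMM search suites, maximum-likelihood tree inference with
model selection, deep-learning structure prediction, synteny detectors).
Those inputs and tools are deliberately out of scope here; every stage is a
self-contained, deterministic, oracle-testable algorithm, and a first-class
synthetic-data module generates all inputs with machine-readable ground
truth, so every downstream claim is checked by truth recovery rather than by
re-downloading data.

## Family identification (`identify`)

A position-specific scoring matrix (PSSM) is built from a user-supplied seed
alignment of the CHI domain. Columns with gap fraction > 0.5 are dropped;
column scores are `log2((count + p*bg) / (nongap + p) / bg)` bits with
pseudocount `p = 0.5` (default) and a uniform default background. Each
proteome sequence is scored by its maximum ungapped window; membership is a
bit-score threshold.

This single-stage PSSM scan stands in for the two-stage BLASTP (E-value
1e-5) + profile-HMM cascade of large-scale surveys. E-value semantics are
replaced by a null-calibrated threshold: the 99.9th percentile of maximal
window scores over 1,000 i.i.d. background decoys (`calibrate_threshold`).
On synthetic proteomes this yields recall >= 0.98 of implanted members at a
decoy false-positive rate <= 0.005. The trade-offs: no insert/delete states,
no true extreme-value E-value calibration — adequate for a compact, highly
conserved domain, and fully testable against a brute-force window oracle.
Redundancy removal is exact sequence-content deduplication (the analogue of
content-based `rmdup`), and domain presence is the pass flag itself.

## Alignment, trees and typing (`classify`)

*Alignment.* A deterministic progressive aligner: guide tree by UPGMA on
3-mer-count cosine distances, then profile-profile merges by Gotoh
affine-gap dynamic programming (BLOSUM62; gap open 10, extend 0.5; column
score = frequency-weighted expected substitution score). For two sequences
this reduces to ordinary global Needleman-Wunsch, which is how it is tested
(independent recursive oracle on short pairs). It makes no claim to match a
production aligner's accuracy on hard alignments; family members here share
a long conserved domain, which progressive alignment handles well.

*Trimming.* Columns are kept iff their non-gap fraction is >= `gt`
(default 0.5). The boundary is keep-if-equal, matching the "gap threshold"
semantics of the standard trimming tool at `-gt 0.5` (a 4-row column with
exactly 2 gaps survives).

*Tree.* Neighbor-joining on Poisson-corrected p-distances
(`d = -ln(1 - p)`) computed over columns where both sequences are ungapped;
p is capped at 0.95 with a warning where the correction would saturate. The
tree is midpoint-rooted. Distance trees replace maximum-likelihood inference
(out of scope); clade assignment is exemplar-anchored monophyly — the
smallest clade containing all user-supplied exemplars of each group — which
is deterministic and testable, unlike manual tree inspection.

*Typing rule.* The active-site position (literature numbering "position
190") is given as a 1-based ungapped position of a named reference sequence
and mapped through the alignment column map. Inside the catalytic (group 3)
clade: threonine -> type II, serine -> type I, any other amino acid ->
type V, a gap or ambiguous X -> unclassified. The group 1 clade is type III,
group 2 is type IV, sequences outside all exemplar clades are unclassified.
Typing uses the *untrimmed* alignment for the column lookup (so reference
numbering stays valid) while the tree is built from the trimmed one; the
pipeline asserts that the active-site column itself survives trimming.

*Properties.* Length, average molecular weight (standard residue masses +
one water; X contributes a nominal 110.0 Da and no charge), and isoelectric
point by bisection on the net-charge curve to |charge| < 1e-4 with a fixed
electrophoresis-calibrated pKa set (N-term 9.094, C-term 2.869, C 7.555,
D 3.872, E 4.412, H 5.637, K 9.052, R 11.84, Y 10.85). pI values are
reproducible only against this stated table; web calculators use different
sets.

## Motifs (`motifs`)

Single-motif ZOOPS (zero-or-one occurrence per sequence) EM over a PWM with
a 0-order background estimated from the input. The E-step computes the
posterior over occurrence offsets plus "absent"; the M-step refits the PWM
(Dirichlet-smoothed, pseudocount 1e-3 per cell) and the occurrence prior
lambda. The quantity asserted non-decreasing every iteration is the smoothed
EM objective (data log-likelihood plus the Dirichlet smoothing term), which
is the quantity this EM provably increases; with the tiny pseudocount it
tracks the data log-likelihood to ~1e-5. Starts are substring-seeded: every
window of a few randomly chosen sequences is probed with two EM iterations
and the best probe is polished to convergence (gain < 1e-6) — far more
reliable than random PWM restarts. Multiple motifs are found sequentially by
masking the posterior-mode occurrence of each found motif with X, up to 15
rounds, stopping when lambda falls below 0.2.

Presence/absence scanning uses the best-window log2-odds score against a
threshold (default 8 bits). The shared/exclusive summary operationalizes
qualitative motif-distribution statements: a motif is *characteristic* of a
type at occurrence fraction >= 0.9 and *absent* at <= 0.1; characteristic of
all types = "shared", of exactly one = "exclusive". Motif numbering is
run-specific (discovery order); only the sharing structure is meaningful.

## Duplication modes and enrichment (`duplication`)

The classifier re-implements the documented decision rules of the standard
duplication-typing tool; collinearity detection itself is not re-implemented
— anchor pairs are inputs. Each paralogous pair is typed WGD if it is a
self-collinearity anchor; else TD if on one chromosome at adjacent order
ranks; else PD at rank gap 2..10 (configurable); else TRD if exactly one
member lies in an outgroup-collinear block; else DSD. A gene's mode is the
highest-priority mode over its pairs (WGD > TD > PD > TRD > DSD), ties in
partner choice broken by smaller id; genes without pairs are singletons.
All proximity arithmetic uses order ranks, never base pairs.

Enrichment per mode is a 2x2 chi-square with Yates continuity correction
(`scipy.stats.chi2_contingency`): family in/not-in mode vs background
in/not-in mode, with family genes removed from the background cells
(the background-universe choice; the alternative — all duplicated genes —
is a one-line change in the caller). Direction is enriched/reduced by
comparing proportions when p < alpha (0.05), else ns. Any expected cell
below 1 flags the result low-expected and forces ns: with small families
the chi-square approximation is not trustworthy there.

## Ka/Ks (`kaks`)

The Nei-Gojobori (1986) counting method, chosen over ML codon models
because it is fully specified, pathway-enumerable and oracle-testable.
Fixed conventions (NG86 variants differ here): single-nucleotide changes to
stop codons are excluded from site denominators; mutational pathways through
stops are discarded; a codon pair whose every pathway crosses a stop is
excluded from the comparison entirely (reported as flagged). Sites are
averaged over the two sequences; `pn = Nd/N`, `ps = Sd/S`; Jukes-Cantor
correction `-3/4 ln(1 - 4p/3)`, undefined on saturation. The ratio is
undefined when Ks = 0 or a correction saturates (such pairs are reported
separately, never folded into rate fractions). Regime: ratio > 1 positive,
< 1 purifying, exactly 1 neutral-ish. Standard genetic code only. Gapped
codon columns are dropped pairwise in whole codons; a utility back-threads a
gapped protein row onto its CDS.

## Structure similarity and clustering (`structclust`)

*Correspondence.* Residue pairs come from a global sequence alignment with
free end gaps (BLOSUM62, gap open -11/extend -1). This replaces
sequence-independent structural alignment — adequate for homologous family
members, and the main divergence from dedicated structure aligners; it would
not hold for remote folds with shuffled sequences.

*TM similarity.* Iterative Kabsch superposition: starting from the full
correspondence and from three contiguous fragments (guarding against bad
initial superpositions), pairs within `d0 + delta` are re-selected under a
shrinking delta schedule (3.5 -> 0.5 A), and
`TM = (1/L_norm) sum 1/(1 + (d_i/d0)^2)` is maximized over all visited
superpositions, with `L_norm = (len1 + len2)/2` (the length-averaging
convention) and `d0(L) = 1.24 (L-15)^(1/3) - 1.8`, floored at 0.5 A where
the formula turns negative (chains shorter than ~21). The matrix is
symmetrized by averaging both orderings.

*Filtering and scaling.* Models with mean per-structure confidence below
0.7 are excluded (predicted-model ranking-score convention; per-structure
mean is used where per-residue confidences are present). The similarity
matrix is min-max scaled over off-diagonal entries; all-equal off-diagonals
are a hard error (degenerate scaling).

*Clustering.* Pairwise dissimilarity between structures is Bray-Curtis
(`sum|u-v| / sum(u+v)`) between their scaled-similarity row profiles,
excluding the two structures' own columns (the ecology-package usage
pattern); `metric="direct"` (1 - scaled TM) is available behind a flag.
UPGMA is implemented in-package with deterministic lexicographic
tie-breaking; merge heights are half the between-cluster average
dissimilarity, asserted monotone on every run, and verified against an
independent average-linkage implementation in tests. The group count k is a
parameter (default 5, the analysis's published outcome); no automatic cut
selection is claimed.

## Synthetic data (`synthetic_data`)

Every generator is deterministic under its seed and records ground truth.

*Proteomes* (`make_chi_proteome`): family members are per-column samples of
the seed profile (conservation ~0.85) in random flanks, with the active-site
residue forced (T/S/other for types II/I/V) and a 40-residue clade-marker
block appended after the domain. The three blocks share a base pattern
(so they align column-wise and survive gap trimming) and differ at the even
positions — the phylogenetic signal that makes the three clades
tree-separable. Every planted member is listed as an exemplar of its clade,
so the smallest clade containing the exemplars spans the planted group
exactly. The default type mix follows the published family census
proportions (III 0.585, I 0.200, IV 0.162, II 0.032, V 0.021). Decoys are
i.i.d. background. Not emulated: real domain architecture variation,
paralog-specific rate variation, alignment-hostile indel patterns — so
passing typing tests shows the rule machinery is correct, not that typing is
robust to badly aligned real families.

*Codon pairs* (`make_codon_pair_set`): acceptance-thinning rather than a
codon-model matrix exponential: candidate single-nucleotide events arrive as
Poisson events (rate calibrated on a first-order candidate census of the
ancestor so that accepted synonymous substitutions per synonymous site
~= `t_s`, default 0.3); a candidate is accepted with probability 1 if
synonymous and omega if nonsynonymous (for omega > 1 the synonymous
acceptance is scaled by 1/omega instead); changes creating stops are
rejected. Ground truth is the realized substitution counts — exactly the
quantity NG86 estimates — which is why this simulator, unlike a fancier
one, supports a clean recovery test (median estimated ratio within 20% of
omega at 200 pairs x 300 codons). Divergence implying expected `ps >= 0.74`
is rejected up front (the JC correction would saturate).

*Duplicated genomes* (`make_duplicated_genome`): planted constructs claim
disjoint windows of consecutive background genes per chromosome, so
constructs cannot disturb each other's rank geometry: TD pairs adjacent, PD
pairs at rank gap 2..max, WGD pairs embedded in >= 5-anchor two-chromosome
collinear blocks (block size configurable by construction), TRD pairs with
exactly one member in an outgroup-collinear block, DSD pairs on different
chromosomes with no anchors; ~20% of unplanted background genes also get
outgroup anchors. `background_mode_counts` plants non-family duplicate
pairs so enrichment backgrounds are realistic. Truth labels are checkable by
direct inspection of ranks/anchors, and the classifier recovers them
exactly; this shows rule fidelity, not robustness to noisy real synteny.

*Structures* (`make_structure_set`): an idealized 3-layer sandwich core
(two strands / two helices / two strands stacked at z = 0/5/10 A, ideal CA
geometry) shared by all groups, plus a group-specific N-terminal random-walk
coil of group-specific length (defaults 4, 11, 18, 25, 32 residues);
instances are randomly rigidly transformed and perturbed by i.i.d. Gaussian
noise (default sd 0.5 A — a free choice; no empirical noise scale exists
for this kind of toy). Sequences are fixed aperiodic strings (a repetitive
core sequence would invite register-shifted alignments). Confidence is 0.9
with a configurable fraction set to 0.55 to exercise the filter; an optional
outgroup group lacks the third layer (emulating distant fold relatives used
as outgroups). Not emulated: side chains, secondary-structure packing
realism, per-residue confidence variation.

## Pipeline and reporting (`pipeline`, `cli`)

`simulate` writes every input class (plus truth JSON) into
`<out>/inputs`; `run_pipeline` executes the stages on those files through
the same readers a user's own data would take, writes per-stage TSVs, a
Newick tree and dendrogram, and a consolidated `summary.json`, then
recomputes the summary counts from the written TSVs and asserts equality.
Every stochastic stage derives its seed from the single run seed; reruns
are byte-identical. Default demo sizes (30 family members among 150 decoys;
40 codon pairs x 300 codons; a 2,000-gene background with a TD-skewed
family of 20 pairs and 150 background duplicate pairs; 5 structure groups
x 4 models plus 10% low-confidence) keep the full demo under a minute while
leaving every stage statistically meaningful. The CLI (`chi-evoscape`)
exposes each stage and the end-to-end `demo`/`run` commands as thin
wrappers.

## Numerical choices and degenerate inputs

- Alignment traceback prefers match states on ties; all tie-breaks
  (guide-tree merges, UPGMA merges, duplication partners) are lexicographic,
  making every output a pure function of the input.
- NJ on an all-zero distance matrix returns an explicit star tree.
- `d0` floor 0.5 A below L ~ 21; saturated p-distances capped at 0.95 with a
  warning; JC saturation yields an undefined ratio, never a clamped number.
- Chi-square tables with any zero margin or expected cell < 1 are reported
  but forced ns.
- Stop codons: terminal `*` stripped on FASTA read; internal stops are
  errors everywhere.

## Known limitations

- The PSSM scan has no insert/delete states; fragmented domains in real
  proteomes would be missed.
- The progressive aligner and NJ trees are adequate for one conserved
  domain family, not for deep or gappy phylogenies; no bootstrap support.
- Sequence-guided structure superposition fails by construction on
  circularly permuted or sequence-shuffled folds.
- NG86 is a counting method; for highly diverged pairs ML codon models give
  better-calibrated ratios, and published Ka/Ks values obtained with other
  models will differ numerically.
- Motif identities (numbering) are not comparable across runs or tools;
  only sharing/exclusivity structure is.
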
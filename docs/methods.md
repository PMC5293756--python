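# Methods

This note documents the models, heuristics and numerical choices behind
`amfsecretome`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the problem was genuinely
open.

## Catalog arbitration

Two assemblies of one organism are merged via a cross-mapping table whose
rows carry a `fragment_flag`: `one_to_one` (single reciprocal map),
`query_fragmented` (several catalog-A fragments covered by one B gene) and
`target_fragmented` (the converse). Arbitration keeps unique genes as-is,
replaces fragments by the complete gene model, and represents one-to-one
pairs by the catalog-A definition. Two override rules apply in order:
if the default winner lacks RNA-seq support and a competitor has it, the
supported definition wins; if neither side is supported, the longer ORF
wins (ties broken by id for determinism). ORF validation (start and stop
present) runs *after* arbitration, so a selected-but-truncated model is
dropped rather than silently replaced. Duplicate removal is exact,
case-insensitive identity of the full amino-acid sequence; the first
record in deterministic (catalog, id) order is kept and duplicates are
recorded in the kept record's provenance. Every input id ends up either
retained with a class label or dropped with a reason, and the result is
invariant under cross-map row permutation. A gene appearing under two
different fragment flags is an input error and raises.

## Secretome filter and built-in predictors

The filter retains a protein iff: signal peptide present ∧ zero
transmembrane segments ∧ not mitochondrial ∧ mature length ≥ 15 aa, then
collapses exact duplicate *mature* sequences (the filter operates
downstream of cleavage, so the secreted moiety defines identity). No
upper size bound is applied. GPI-anchored proteins are not treated as
truly secreted; no GPI predictor is bundled — an optional boolean column
in the override table excludes them.

External predictor output is accepted as a TSV override
(`protein_id has_sp cleavage_pos tm_count targeting [gpi]`) and must
cover every catalog id. The built-in stand-ins exist so the pipeline and
its tests run offline; they are deliberately simple hydropathy heuristics
and do not reproduce the external tools' scores:

* **Signal peptide** — within the first 45 residues, the first 8-residue
  window with mean Kyte–Doolittle hydropathy ≥ 2.0 (starting no later than
  position 35) is the h-region; the cleavage site is the smallest
  downstream position c with small residues ({A,G,S,C,T,V}) at c and c−2
  (the (−3,−1) rule). `cleavage_pos` is the last signal-peptide residue.
* **Transmembrane** — 19-residue windows with mean hydropathy ≥ 1.8,
  merged into segments; segments ending at or before the cleavage site are
  discounted so a signal peptide is not mistaken for an anchor (one TM
  predicate stands in for the two external topology tools, which serve a
  single role in the chain).
* **Mitochondrial presequence** — ≥ 3 arginines and no D/E among the
  first 25 residues.

All window lengths and thresholds live in `FilterParams`.

## Effector features

* **SCR**: mature length < 200 (strict), ≥ 2 cysteines and cysteine
  fraction ≥ 3% (both inclusive), evaluated on the mature sequence —
  cysteines in the signal peptide are not part of the secreted moiety.
* **NLS stand-in**: any 7-residue window with ≥ 6 residues in {K,R}. Note
  the classic SV40 heptapeptide PKKKRKV carries only five basic residues
  and is *below* this threshold; an override table from a dedicated NLS
  predictor wins when provided.
* **Tandem repeats**: lag-correlation detection — for each unit length L
  (3–100), adjacent-unit identities are convolution-scored along the
  sequence; runs of ≥ 3 consecutive units at adjacent identity ≥ 0.7 are
  reported. Arrays whose region is explained by a period smaller than the
  minimum unit (homopolymers, dipeptide stutters) are rejected.
  Overlapping calls resolve to the largest array (copies × unit length),
  ties to the smaller unit, then to the cleanest phase (highest mean
  adjacent identity). The identity floor of 0.7 admits arrays whose
  adjacent copies diverge by up to ~20–30%; the generator plants units
  mutated at 10% from their consensus (≈ 19% expected divergence between
  adjacent copies).
* **KEX2 class**: a repeat protein is cleavable when some unit offset
  carries a [K/R]R dipeptide in at least copies − 1 units — a
  formalization of "repeated motifs all starting with a conserved [KR]R
  signature".
* **Motif scanning**: the degenerate grammar (`x` any residue, `xN` N
  wildcards, `[..]` alternatives) compiles to overlapping-match regular
  expressions; the shipped catalog contains the motifs described in
  effectors of filamentous plant pathogens and is an editable mapping.
* **Enrichment**: presence/absence 2×2 tables tested one-sided
  (hypergeometric upper tail, the Fisher exact enrichment direction) with
  BH correction across features. The test was chosen because the data are
  per-protein presence calls, not counts.
* **Tribes**: single-linkage components of the local-alignment graph,
  linking pairs at ≥ 30% identity over ≥ 50% of the longer sequence
  (both configurable; the external clustering tool's "standard
  parameters" are not published).

## Differential expression

RPKM = count / (transcript kb × library-size millions); library sizes
default to column sums but should be the total mapped reads when known.

The proportion test treats x_i ~ Binomial(N_i, p_i) with p_i Beta-
distributed within a replicate group. The method-of-moments
overdispersion is φ̂ = max(0, S²_p / (p̄(1−p̄)) − mean(1/N_i)) (zero for
single replicates, and whenever replicate scatter is below binomial
expectation). Weights w_i = N_i/(1 + φ̂N_i) interpolate between library
size (φ̂ = 0) and equal weighting (φ̂ large); the weighted group
proportions π̂ and variances V̂ = π̂(1−π̂)/Σw give
t = (π̂₁−π̂₂)/√(V̂₁+V̂₂), referred to t with m₁+m₂−2 df (normal for 1 vs 1).
Degenerate cases are defined, not errors: both groups all-zero → t = 0,
p = 1; zero variance with unequal proportions → ±∞ → p = 0.

Fold change is computed on RPKM group means (a raw-count ratio would
double-count library size), signed as r or −1/r, with ±∞ held internally
and rendered ±999999 only in report files. Calls require FC ≥ |2|,
BH q ≤ 0.05 and |mean raw-count difference| ≥ 10 — every threshold
inclusive. "Expressed" flags use mean raw count ≥ 5 in the condition
(configurable; no published operational definition exists for the
transcriptional-activity statement it mirrors).

## Alignment and cross-species grouping

`local_align` is exact Smith–Waterman with affine gaps on BLOSUM62
(biotite's C implementation; gap of length k costs open + (k−1)·extend,
defaults 11/1). Raw scores convert to bits via S′ = (λS − ln K)/ln 2 with
the gapped constants λ = 0.267, K = 0.041, and E = m·n·2^(−S′). This is a
desk-scale, deterministic replacement for a heuristic BLAST screen;
near-threshold hits can differ from BLAST, so thresholds are configurable
and externally computed hit tables can be imported. Sequence groups are
connected components over hits at e < 1e-5, including within-species
edges so paralogs join one group; groups must contain both species.
An optional shared-5-mer prefilter (BLAST-like seeding) accelerates
all-vs-all runs; it can miss short marginal homologs and is off by
default for cross-species grouping, on for tribes.

Isoform collapse links transcripts at > 97% nucleotide identity when the
alignment covers > 50% of one sequence and > 10% of the other ("query
hit" read as subject coverage), clusters by single linkage and keeps the
longest member.

Reported percentages round half away from zero, matching integer
renderings like 74%; full precision is retained internally.

## Synthetic-data generator

The generator emulates the *structure* of a two-species comparative
study: assembly redundancy (20% A-only, 10% B-only, 5% fragmented loci,
2% unsupported definitions, 2% duplicates), a 10% secretome with planted
feature rates (30% SCR, 10% NLS, 10% repeat proteins half
KEX2-cleavable, 15% catalog motifs vs 3% in the background), membrane
(10%) and mitochondrial (5%) proteins among the non-secreted, 20
cross-species homolog families at 60% identity, and triplicate libraries
(~10⁶ reads, 10% lognormal size spread) over the condition panel.
Protein lengths are lognormal with median 350 aa.

Counts: per gene and condition the mean proportion is baseline × planted
fold change; replicates draw p ~ Beta(mean μ, variance φμ²) and counts ~
Binomial(N, p). φ is therefore the squared biological CV of expression
across replicates — the standard RNA-seq dispersion meaning — with
default φ = 0.005 (BCV ≈ 7%, appropriate for clonal in-vitro cultures,
between canonical technical and genetically-identical-organism values; a
power analysis at the design stage showed this is also the regime in
which an 8-fold planted change is reliably recoverable jointly across
three host comparisons under BH at 3,000 genes with a 4-df t reference).
Planted DE sets (40 common-up, 10 per host, 15 ERM, 15 signal) use
baseline proportions of 2×10⁻⁴–10⁻³ (200–1000 baseline counts); null
genes span 5×10⁻⁶–5×10⁻⁴. An optional negative-binomial mode probes
robustness to the noise model.

Two deliberate couplings keep truth labels consistent with emitted
sequences:

* planted secreted proteins receive n/h/c signal peptides whose c-region
  (`QNAQA`) admits exactly one (−3,−1) site, so the true cleavage
  position is known by construction and the h-region alphabet ({L,I,F})
  contains no small residues that could create earlier sites;
* planted-*negative* proteins are rejection-sampled until no built-in
  predictor fires on them. Without this screen ~11% of natural-
  composition random N-termini qualify as signal peptides, which would
  make the "non-secreted" labels false for data that genuinely look
  secreted — a label-consistency requirement, not an accuracy
  embellishment. Consequently the filter's measured precision/recall on
  synthetic data validates the *decision chain*, not the heuristics'
  accuracy on real proteomes.

Background residues default to average natural (Swiss-Prot-like)
composition rather than a uniform alphabet: a uniform alphabet makes
cysteine 5% of all residues — rendering the ≥ 3% SCR rule vacuous on
short proteins — and distorts hydropathy statistics. The composition
table is configurable.

What the generator does **not** emulate: real signal-peptide sequence
statistics, splice isoforms and read-level noise, genome assembly errors
beyond clean fragmentation, correlated expression programs, unequal
per-condition dispersions, or compositional biases of real secretomes.
Passing tests therefore demonstrate correctness of the arbitration,
filtering logic, statistics and set algebra — not predictor performance
on biological data, for which the external-tool override tables exist.

## Problem sizes and determinism

The default study is 2 species × 3,000 genes × 7 (or 6) conditions × 3
replicates; the full pipeline including the acceptance measurements runs
in well under a minute on one CPU. All randomness flows from a single
integer seed through `numpy.random.Generator`; the same seed reproduces
every FASTA byte and count. Statistical calibration checks (type-I error,
FDR) use 10,000-gene simulations at the proportion-test null
(π = 10⁻⁴, φ = 0.05, 3 vs 3, N ≈ 10⁶).

## Known limitations

* The built-in predictors are stand-ins; use override tables from the
  dedicated external tools for real data.
* The method-of-moments φ̂ is noisy at 3 replicates; the 4-df t reference
  absorbs some but not all of that variability (observed type-I ≈ 0.04
  at nominal 0.05).
* Karlin–Altschul parameters are fixed BLOSUM62-11/1 gapped constants,
  not estimated per scoring system.
* Single-linkage grouping is transitive: one promiscuous sequence can
  bridge otherwise unrelated groups.
* De novo motif discovery (EM/MEME-style) is out of scope; only catalog
  scanning and tandem-repeat detection are implemented.
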
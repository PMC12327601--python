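# Methods

This note documents the models and procedures implemented in `pathseer`,
the assumptions behind them, the defaults that matter, and the places where
the design was genuinely open.

## Input model and rescaling

The pipeline assumes paired observations: a mass-feature table (feature id,
m/z in Da/e, optional retention time in seconds, nonnegative abundance per
sample) and a transcript expression matrix (normalized counts), sharing at
least three sample ids. Samples are aligned by id intersection and ordered
lexicographically; correlation is undefined below three paired samples.

Rows are rescaled with the median absolute deviation,

    MAD(x) = median(|x_i - median(x)|),    x -> (x - median(x)) / MAD(x),

rather than z-scores, because LC-MS abundances and RNA-seq counts are
heavy-tailed: a single saturated sample dominates a standard deviation but
barely moves a median. Rows with MAD = 0 carry no usable signal and are
dropped (logged). Rescaling is an on-by-default stage and can be disabled;
Pearson r itself is affine-invariant, so rescaling mainly affects
degenerate-row handling, not the correlation values.

## Mutual ranks and decay-weighted networks

All transcript x feature Pearson correlations with |r| >= `min_abs_r`
(default 0.1) are retained, with two-sided p-values from
t = r sqrt((n-2)/(1-r^2)) on n-2 df (|r| = 1 maps to p = 0 exactly).
p-values are reported unadjusted; thresholds downstream do the filtering.

Raw correlation thresholds transfer poorly across datasets, so edges are
re-expressed as mutual ranks: rank_t(f) is f's rank among t's partners by
descending |r| (average ranks on ties; the rank lists are cross-omics only),
and MR = sqrt(rank_t(f) * rank_f(t)). MR = 1 means reciprocal best
partners. MR maps to an edge weight via exponential decay,

    w = exp(-(MR - 1) / DR),

at decay rates DR in {5, 10, 25, 50} (one network per rate; weights below
0.01 excluded). Small DR keeps only near-reciprocal-best edges; large DR
admits weaker ones, so the four networks nest as edge sets. Ranking uses
|r| because edges are admitted by absolute correlation; sign is retained on
the edge for interpretation. Tie policy (average) and the sign-agnostic
ranking are implementation choices documented here because multiple
conventions exist.

An expression-only variant of the same machinery produces a
transcript-transcript coexpression network used to merge clusters.

## Functional cluster detection

Overlapping clusters are found by greedy cohesiveness growth: the quality of
a node set C is f(C) = w_in / (w_in + w_bound + p|C|) with penalty p = 2.0.
Seeds are unclustered nodes in descending weighted-degree order (ties by
node id, making the procedure fully deterministic); growth adds or removes
the single node that most improves f until a local optimum; candidate
clusters with overlap score |A∩B|²/(|A||B|) >= 0.8 are merged; clusters
below 3 members are discarded, and only clusters containing both a
transcript and a feature are reported (pure-transcript clusters are kept
internally for coexpression merging). On networks of <= 10 nodes the best
reported cluster provably attains the exhaustive-search cohesiveness
optimum (tested).

Each cluster's p-value is a one-sided rank-sum test of internal vs outgoing
edge weights. Two conventions: a cluster with no boundary edges gets p = 0
(perfect separation, flagged by construction); identical constant weights
inside and outside give p = 1.

Clusters sharing >= 1 mass feature are merged transitively (union-find,
provenance kept); an optional second merge joins clusters linked by a
coexpression edge above a weight threshold.

## Adduct arithmetic and structure annotation

An adduct [nM+X]^z relates neutral mass to observed m/z by
m/z = (n·M + s)/|z| with total ion-level shift s, hence
M = (m/z·|z| - s)/n. The shipped default table has 48 adducts (positive and
negative mode: proton/sodium/potassium/ammonium attachment, water losses,
solvent clusters, multimers up to 3M, charges up to 3); a user CSV overrides
it. Candidate structures are all database records within the ppm tolerance
(default 20 ppm, suiting common Orbitrap/TOF accuracy; tighten to ~5 ppm
for ultra-high-resolution data), with the relative error measured against
the database mass — the lookup direction. Manual feature -> structure
assignments bypass matching. Features with no candidate stay unannotated
and may still anchor reactions through fallback adduct hypotheses.

## Reaction rules and mass transitions

A reaction rule is a single-substrate reaction SMARTS with substrate and
product monoisotopic masses; its mass transition (product - substrate) is
recomputed on load and must agree with the stored masses to 1e-6 Da. Rules
containing stereo tokens (`@`, `/`, `\`) or more than one reactant template
are excluded on load — mass spectrometry cannot distinguish stereoisomers,
and the matching model is single-substrate. Malformed rules are skipped
with warnings rather than aborting batch loads, since public rule dumps
contain unparsable entries.

Rule-enzyme associations carry a tier (strict ⊂ medium ⊂ loose, decreasing
annotation confidence, increasing coverage) and an optional taxon;
filtering is association-level. The Pfam cutoff (default 6) drops
associations whose Pfam is linked to more than that many distinct rules:
very generic domains explain almost any mass difference and mostly
contribute false positives.

The transition index is a sorted multimap transition -> rule ids;
bidirectional rules are indexed under +t and -t. Lookups take an absolute
Da window (default 0.002 Da) or a ppm window against a reference mass.

Database-coverage checks use a χ² goodness-of-fit against the
equal-probability null: E = total/2 per cell, DF = 1. The statistic is
symmetric in found/missing by construction.

## Reaction network, ghosts, and enzyme support

Matching happens in neutral-mass space (transitions are defined on neutral
structures), so each feature contributes one node per distinct neutral-mass
hypothesis, deduplicated at 1e-4 Da. All ordered node pairs whose mass
difference matches an indexed transition within tolerance become candidate
reactions; one pair may carry several rules (parallel edges), and
bidirectional rules yield both orientations.

A candidate is retained as a reaction edge only with omics evidence: at
least one transcript correlated with the substrate or product feature in
the active decay-rate network (default DR = 10) — and, in the default
cluster-restricted mode, co-clustered with it — that is annotated with a
Pfam associated to the rule at the active tier. Edge support is the
maximum supporting edge weight. Edges touching ghost nodes inherit the
evidence of their measured endpoint.

Ghost mass signatures are virtual intermediates for metabolites below the
detection limit: for measured A, C with no single-rule link, if transitions
t1 + t2 equal mass(C) - mass(A) within tolerance, a ghost at
mass(A) + t1 bridges them. Modes: `off`, `auto` (only for nodes that
received no substrate/product assignment — the default), `always`. Ghost
masses are always derived, never free parameters; chaining depth is one
ghost between two measured nodes per round, and the lexicographically first
rule combination is taken per pair for determinism.

In-silico product generation applies rule templates with RDKit behind a
divide-and-conquer substructure prescreen: a hierarchy of keys (atoms ->
simple bonds -> composed patterns) is evaluated top-down, testing a key only
when all its parents matched; a rule is attempted only when the
unambiguous requirements of its reactant template (definite atoms, definite
bond orders) are admissible. Requirements are deliberately conservative —
ambiguous template constraints (wildcards, default bonds next to aromatic
atoms) impose nothing — so the prescreen can prune but never lose an
applicable rule (tested against brute force). Every generated product must
reproduce substrate mass + transition to 0.005 Da or it is discarded.

## DAG extraction and pathway predictions

For a chosen root, reaction distance is the unweighted BFS distance in the
underlying undirected graph (edge counts, not weights — the open choice is
documented here). Edges advancing the distance by one are kept; edges
between equidistant nodes are kept provisionally, and any remaining
directed cycle is broken by deleting its minimum-edge-support edge (ties:
lexicographically smallest (substrate, product, rule)). The result is
acyclic and restricted to root-reachable nodes — property-tested on random
multigraphs.

The pathway prediction is the maximum-edge-count root-originating path
(topological-order dynamic programming; ties by larger summed edge support,
then lexicographically smallest node sequence). The procedure runs twice:
forward from the root, and on the reversed network rooted at the forward
path's terminal metabolite, giving two predictions per input structure.
When the user names no root, each connected component is rooted at the
measured node admitting the longest outgoing pathway (support sums rounded
to 9 decimals before comparison so float addition order cannot flip ties;
exact ties resolve to the smallest node id). Optional iteration rounds
extend the network by applying rules to frontier structures and mapping
products back onto measured masses or ghosts; the network grows
monotonically to a fixpoint or the round limit.

## Reaction-likelihood scores

Per-atom site-of-metabolism scores in [0, 1] are a pluggable input: a CSV
of precomputed scores (heavy-atom indexing, hydrogens not indexed), or a
built-in heuristic baseline (uniform 0.5, or degree-scaled) intended only
for pipeline testing — no trained model ships with the package. The
reaction center is the set of substrate atoms whose bonding changes:
computed primarily from the rule's own atom-mapped template (changed mapped
atoms traced back through the reaction instance, plus atoms the rule
deletes and their attachment atoms), with a maximum-common-substructure
fallback when mapping cannot place the product (atoms outside the MCS plus
attachment atoms on both sides of the correspondence). The reaction
likelihood is the maximum atom score within the center — monotone in every
center atom's score by construction. An identity transformation has no
center and is an error.

Score populations are compared with a two-sided Mann–Whitney U (statistic
of the first sample). The exact null distribution is used when
n1·n2 <= 400 and the pooled data are tie-free; otherwise the normal
approximation with tie and continuity corrections.

## Synthetic data generator

The generator emulates the statistical structure of a treatment-response
paired-omics experiment: a latent step-response induction profile (off in
the first half of samples, on in the second) drives the planted pathway's
transcripts (baseline 5–10, amplitude 2–4 expression units) and metabolite
features (baseline 80–150, amplitude 50–120 abundance units) with additive
Gaussian noise of sd 0.2 x amplitude by default; decoy rows (24 transcripts,
14 features by default) vary independently. Default scale — 3 planted
steps, 24 samples, ~30 transcripts x ~20 features — runs the full pipeline
in seconds and was chosen as the smallest size at which rank statistics are
stable.

The planted chemistry is real: a parent scaffold (octylbenzene) is
transformed by actual reaction SMARTS (aromatic hydroxylation +15.9949 Da,
desaturation −2.0157 Da, O-methylation +14.0157 Da, O-acetylation
+42.0106 Da), so feature m/z values (ionized as [M+H]+) obey the rule
transitions exactly. By default each step draws a *distinct* type: two
same-type steps share a transition and are unidentifiable from mass
differences alone, which would make rule-sequence recovery ill-posed. An
explicit `moves` sequence overrides this (e.g., a pure hydroxylation
ladder). Decoy feature masses are rejection-sampled away from every
single and pairwise-summed transition (0.05 Da margin) so they cannot fake
reaction edges; decoy rules at the looser tiers widen the loose rule space
without explaining planted transitions. All randomness flows from one
integer seed; regeneration is bit-identical.

What the generator does **not** emulate: chromatographic drift, isotopes,
in-source fragmentation, missing values, multiplicative noise, correlated
decoys, multi-pathway cross-talk. Passing tests therefore demonstrate
correctness of the statistical and graph machinery under a favorable
signal-to-noise regime, not performance on real data, where annotation
ambiguity and correlated confounders dominate.

## Numerical choices and degenerate inputs

- CSV float I/O uses `%.17g` writing and round-trip parsing, so
  write -> read is the identity at full precision (also through the SQLite
  project store, which keeps native REAL columns).
- Pair-matching tolerance 0.002 Da absolute by default; annotation 20 ppm;
  product mass check 0.005 Da; node deduplication 1e-4 Da.
- All orderings (seeds, cluster output, pair tables, tie-breaks) are
  deterministic; two identical runs produce byte-identical CSV exports.
- Empty networks, empty rule lists, unparseable SMILES/SMARTS and features
  without annotation degrade gracefully (empty results or logged skips);
  contract violations (duplicate ids, negative abundances, inconsistent
  transitions, missing roots) raise typed validation errors.

## Known limitations

- Single-substrate reactions only; stereochemistry is filtered out.
- Correlation-based support cannot separate co-regulated but causally
  unrelated genes; the tiers and Pfam cutoff mitigate, not solve, this.
- Cluster p-values are rank-sum heuristics without multiplicity control.
- The reaction-center fallback (MCS) can over-approximate the center for
  rearrangements; atom-mapped templates are preferred.
- Adduct hypotheses are propagated per feature without cross-feature
  consistency constraints (no isotope or adduct co-elution grouping).
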
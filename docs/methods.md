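# Methods

This note documents the models, algorithms and design choices behind
bgcforge, in the order of the pipeline. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Sequence input and ORF identification

Coordinates are 0-based half-open on the forward strand everywhere;
GenBank's 1-based inclusive convention is converted once at the parse
boundary. Non-ACGT IUPAC codes map to N, and codons containing N
translate to X — profile scores treat X with a strong fixed penalty
(−4 bits/column), so domains never match across runs of ambiguity.

The ORF caller is deliberately minimal: the longest ATG-to-stop frame
per reading frame on both strands, bacterial translation table, default
minimum 60 aa. Gene-calling sophistication is not the scientific
content here, and the caller's only obligations are the tested ones —
strand symmetry and exact re-translation. When GenBank CDS annotations
exist they are carried through and can be used instead.

## Domain detection

Each domain model is a position-specific scoring profile expanded from
a consensus sequence: +2 bits per matching column, −1 per mismatch,
with a per-model bit threshold stored in the knowledgebase (default:
half the perfect score, i.e. 30 bits for a 30-column model). Every
window of an ORF is scored and the best window per model is reported
iff it reaches the threshold; one best hit per model per ORF.
Under these scores a shuffled background window has expected score
≈ −0.85 bits/column, so the threshold sits far above background while
tolerating the few-percent substitution divergence the synthetic
genomes carry. Substrates (e.g. adenylation-domain specificity) are
read from signature columns of the matched window by exact lookup; a
mutated signature yields no substrate and the downstream engine uses a
wildcard monomer.

The scanner sits behind a small protocol so that a profile-HMM engine
could replace the PSSM slider without changing any downstream type.
A precomputed annotation TSV can bypass scanning entirely.

## Cluster calling

Hit-bearing ORFs are chained left to right while the nucleotide gap
stays within `max_gap_nt` (default 10,000 nt, roughly the upper range
of intergenic spacing within bacterial BGCs; configurable per rule). A
chain becomes a cluster iff a rule is satisfied: at least `min_domains`
hits (default 2 — singleton domains are overwhelmingly false positives)
and the rule's required families present. All satisfied rules
contribute family labels; ≥ 2 labels → category `hybrid`; a single
label outside the structure-predictable set → `other`. Chains touching
a contig edge (within 50 nt) are flagged `possibly_truncated` rather
than dropped, since fragmented assemblies routinely split clusters.
Cluster sets are matched between runs by any nucleotide overlap
(≥ 1 nt, half-open intervals) on the same contig.

## Molecular graphs and SMILES

The chemistry core uses an implicit-hydrogen molecular graph with
persistent atom ids (ids are never reused, so a reaction-site reference
survives unrelated deletions). Bond orders are 1, 2, 3 or aromatic
(valence contribution 1.5; ring-fusion aromatic atoms use the Kekulé
floor ⌊1.5·n⌋). Every mutating operation maintains the hydrogen
ledger: forming a bond consumes implicit H from both endpoints,
breaking one restores it, removing an atom restores H to its
neighbours. Valence violations raise immediately.

The SMILES dialect covers the organic subset, bracket atoms with charge
and explicit-H counts (folded into the implicit count at parse time),
branches, ring closures including `%nn`, aromatic lowercase atoms, dot
components and the wildcard `[*]`. Stereo markers are accepted and
discarded throughout the package: configurations such as glycosidic
bonds cannot be inferred from primary sequence, so the model works on
constitution only. The writer canonicalizes by iterative invariant
refinement (element, aromaticity, charge, H count, degree, then
neighbour ranks), breaking residual ties with BFS-layer signatures —
atoms still tied after that are automorphic, so the output string is
independent of input atom order; aromatic atoms are written lowercase,
so no kekulization is performed on output.

## Fingerprints, descriptors, functional groups

Circular fingerprints follow the extended-connectivity construction
(radius 3, i.e. diameter 6; 1024 bits), hashing every intermediate
atom-environment identifier with a BLAKE2b-based hash that is stable
across processes. The bit assignments deliberately do not reproduce any
external toolkit — every analysis in the package is relative (Tc
distributions, feature averages), so internal consistency is the
requirement, and relabeling invariance plus cross-run stability are
tested. Wildcard atoms contribute only their radius-0 identifier;
growing environments around a site of uncertainty would hash unknown
context into the vector.

Descriptors: molecular weight from standard atomic weights (including
implicit H); H-bond donors as the total count of hydrogens on N/O (the
original rule-of-five OH+NH count); acceptors as the N+O atom count;
logP from a coarse bundled atom-contribution table (hydrophobic
positive); and a Bertz-style complexity combining a
bonding-information term over "connections" (pairs of bond slots
sharing an atom, with bond-order multiplicity, classified by the
elements involved) with a heteroatom-distribution term. Several
variants of the Bertz index exist; this one is validated for rank
order against an external toolkit, not absolute values, and MW/HBD/HBA
are validated exactly (MW to 0.01). Descriptors are undefined on
graphs containing wildcards.

Functional groups are extracted without a prespecified list:
heteroatoms, carbons multiply bonded to heteroatoms, acetal-like
carbons, non-aromatic C=C/C≡C carbons and three-membered
heteroatom rings are marked, and connected marked atoms merge into one
group (so an amide is one group, not C=O plus N). Groups are keyed by
the canonical SMILES of their induced subgraph with hydrogen counts
cleared, which collapses e.g. primary and secondary amines.

## Structure prediction

`derive_pathway` translates a cluster's enzymatic content into
(i) a scaffold specification — ordered modules with monomer choices and
reduction/methylation flags for thiotemplated clusters, or candidate
core peptides for RiPPs (suffixes after each cleavage-motif occurrence,
with a C-terminal window fallback) — and (ii) a reagent pool plus
tailoring-reaction list contributed by tailoring hits. Scaffold hits
are ordered by genomic position; module order follows gene order.
Clusters with neither scaffold nor precursor domains are reported as
detected-but-unpredictable.

Assembly: amino-acid condensation removes the carboxyl hydroxyl and
forms the C–N bond (net loss of one water, realized purely as atom
removal plus H bookkeeping — never atom creation); ketide extension is
the analogous Claisen C–C join, after which the upstream carbonyl takes
the reduction state of the extending module's flags (β-keto →
β-hydroxy → enoyl → methylene); release closes a macrolactam or leaves
the linear acid. Epimerization flags are accepted as no-ops
(stereochemistry is out of model).

Tailoring reactions are declarative: a site predicate (element,
aromaticity, minimum H, neighbour and anti-neighbour constraints, an
optional distinguished partner atom) plus a transformation — a list of
`set_bond_order` / `add_bond` / `remove_bond` / `remove_atom` steps
whose operands refer to the site, its partner, a named neighbour, or a
named attachment atom of the consumed fragment. A static validator
rejects any atom-creating step; new heavy atoms enter a product only by
consuming a pooled reagent subgraph, and an application that would
increase heavy atoms beyond its fragment is an error.

**Plan-space semantics.** Candidate sites for every reaction are
enumerated against the assembled scaffold. A plan is one monomer-choice
combination plus, per reaction, one subset of its candidate sites of
size 0..`max_applications` (the zero-application subset is always
included: the enzyme may act elsewhere or not at all). This makes the
plan count exact and closed-form (products of binomial sums), so spaces
above the structure cap can be sampled uniformly without replacement by
unranking seeded plan indices (mixed-radix over scaffolds and
reactions, combinadic within a reaction). Realization applies reactions
in fixed knowledgebase order and re-validates every chosen site against
the working graph, skipping consumed sites with a warning; products are
deduplicated by canonical SMILES and only the component containing the
scaffold is emitted (unconsumed fragments model enzyme-delivered
moieties, not products). Reaction *orderings* are not enumerated —
order permutation would explode the space for no recall gain on the
bundled chemistry — and sites created by one reaction are not offered
to a later one; both are deliberate scope bounds of the plan-space
definition, checked against a brute-force enumerator implementing the
same definition. The structure cap defaults to 100 per cluster,
matching the evaluation protocol.

## Evaluation machinery

Per cluster, the median and maximum Tc over all prediction × truth
pairs are reported (at most 100 predictions). The random-pair null
takes, for each cluster, the median Tc of its predictions against the
true products of all non-matching clusters — exhaustive rather than
subsampled, which is exact at this scale. Matched-vs-null significance
uses the paired Brunner–Munzel rank test: relative effect
p̂ = P(matched < null) + ½P(=) estimated from mid-cdf placements, with
variance from the per-pair placement differences and a t(n−1)
reference. Below 10 observations per group the t-test is substituted
and flagged, because the rank test's small-sample p-values are
inflated. Complete separation (zero placement variance with effect ≠ ½)
falls back to the exact sign-test bound 2·(½)ⁿ rather than reporting
the no-effect degenerate p = 1; the unpaired analogue uses the exact
rank-permutation bound. The paired variant's correctness is guarded by
a null-calibration test (type-I rate over correlated-pair simulations),
which is how a factor-of-two variance error was caught during
development.

Jensen–Shannon divergence is base-2 (so bounded by [0,1]), computed
between pooled functional-group frequency distributions with one
structure sampled per cluster (seeded); the bootstrap resamples
clusters — jointly for equal-length (paired) sets, so the sd vanishes
as the sets converge. Structure-set summaries drop structures under
100 Da (tiny non-specific fragments), then report the rule-of-five
fraction with its proportion standard error, descriptor distributions,
internal diversity (per-structure median Tc to the rest of the set) and
median Tc to a reference compound set. Proportions are compared with
the 2×2 chi-squared test without continuity correction.

## QPSAR

Fingerprint features are the per-bit mean over a cluster's predicted
structures (a bit set in two of ten structures → 0.2); clusters without
structures are omitted with a warning. The baseline features are counts
of domain-family hits. Each of the five activities is an independent
binary problem; the default classifier is an RBF-kernel SVM (C = 1,
gamma = 'scale') with sigmoid-calibrated probabilities, behind a
pluggable factory. Stratified tenfold CV pools out-of-fold
probabilities into a single ROC/AUC; the final model refits on all
data. AUC-vs-chance uses the Wilcoxon rank-sum test on
positive-vs-negative out-of-fold scores; fingerprint vs domain models
are compared per activity with one-sided DeLong tests (placement-value
covariance) combined across activities by Fisher's method
(−2Σln p ~ χ² with 2m df). The decision threshold per activity is the
smallest probability whose pooled out-of-fold FDR (FP/(FP+TP)) is at or
below 10%; if no threshold achieves it, the maximum score is stored and
flagged. With ~10% label noise the minimum reachable FDR hovers near
the nominal rate, so the flag fires occasionally by design.

A note on evaluation under label noise: if a fraction ε of labels is
flipped, the AUC of *any* scorer measured against the noisy labels is
bounded by 0.5 + (a+b−1)/2 where a, b are the class purities — exactly
0.90 at ε = 0.1 and balanced prevalence, lower otherwise. Recovery of
the planted structure–activity signal is therefore measured against the
clean labels (which the generator knows), while the noisy-label CV AUC
is what a practitioner would observe and is what the model comparison
and FDR calibration use.

## Synthetic data

The generator emulates the study conditions end to end, seeded
throughout. The knowledgebase couples a curated chemistry — 10
proteinogenic monomers plus wildcard, a ketide unit, two sugars, seven
reagent fragments, 20 tailoring reactions, 4 cluster rules — to
seeded random consensus sequences for 27 domain models (adenylation per
substrate, four ketosynthase reduction states, a RiPP precursor,
tailoring enzymes, and two structure-less bacteriocin markers). The
bundled `data/knowledgebase.yaml` is the seed-7 build of this
generator and regeneration is byte-identical.

Genomes are i.i.d.-uniform ACGT carrying back-translated domain genes
(uniform synonymous codons; 3% amino-acid substitution, signature
columns protected) in module order, spacers of 100–400 nt within
clusters and >15 kb between them, tailoring genes randomly on either
strand, plus decoys (isolated single-domain genes and shuffled
pseudo-genes). Families are drawn from a configurable mix (defaults:
NRPS 0.30, PKS 0.20, hybrid 0.10, RiPP 0.20, glycosylated 0.10,
unpredictable 0.10). Cluster specs are constrained so that each
tailoring enzyme has an applicable residue and plan spaces stay within
the 100-structure cap — so exhaustive enumeration covers the truth.

True products are composed by *string templates* (per-residue SMILES
fragments, tailored-variant fragments, polyketide chain tokens) in a
code path that never imports the prediction engine — enforced by a
static import check — so end-to-end recovery of the truth SMILES is a
genuine test. Activity labels are positive iff the true product
contains the activity's pharmacophore substructure (phenol, indole,
thiol, isopropyl, pyranose; subgraph monomorphism on element +
aromaticity), then flipped independently with probability
`label_noise` (default 0.1). Residue weights aim each pharmacophore at
roughly half of the generated clusters.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: realistic genome composition (GC bias, codon
bias, overlapping genes), divergent homologs near detection thresholds,
multi-module single-ORF synthetases, fragmented assemblies, reaction
chemistry outside the bundled registry, and any stereochemistry.
Detection thresholds are calibrated against the uniform background, so
absolute sensitivity/specificity numbers do not transfer to real
genomes.

## Problem sizes and defaults

The end-to-end recovery experiment uses 20 genomes × 3 planted clusters
(seeded); the matched-vs-null comparison a 20-entry gold standard; the
QPSAR experiment 200 training clusters plus 400 held-out (20 replicate
batches of 20) with tenfold CV; permutation oracles use 10,000 draws.
These sizes keep every experiment well-resolved statistically while the
whole suite remains a few minutes of CPU. Key defaults: ORF minimum
60 aa; gap 10 kb; structure cap 100; fingerprint 1024 bits, radius 3;
MW floor 100 Da; FDR 10%; SVM C = 1, gamma = 'scale'.

## Known limitations

Substrate inference is exact-signature lookup, not homology-weighted;
one best hit per model per ORF (multi-module ORFs need per-module model
ids); macrolactone release falls back to linear when no hydroxyl is
available; the plan space ignores reaction-order effects and
reaction-created sites (above); aromaticity is taken from input
lowercase/ring flags, never perceived; logP and Bertz are rank-order
approximations; and the activity model treats the five classes as
independent binary problems, ignoring label correlations.
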
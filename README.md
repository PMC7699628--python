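# bgcforge

Desk-scale genome mining for microbial secondary metabolites: detect
biosynthetic gene clusters (BGCs) in DNA, predict the chemical structures
of their encoded products by combinatorial graph transformation, score
predictions against gold-standard structures, and model biological
activity from the fingerprints of *predicted* (not measured) structures.

## Who this is for

Natural-product and genome-mining researchers who want a small,
fully-inspectable implementation of the classic rule-based mining
workflow — from open reading frames to SMILES to activity calls — with a
seeded synthetic-data generator, so every stage can be tested end to end
on a laptop without any external database.

## The model

**Detection.** Open reading frames are scanned against a library of
domain scoring profiles (position-specific log-odds with per-model bit
thresholds). Hits are chained by genomic proximity (default gap
≤ 10 kb) and a chain becomes a BGC when a cluster rule is satisfied —
generally two or more biosynthetic domains of the right families.
Clusters assigned two or more family labels are *hybrid*; families
without structure logic fall into *other*.

**Structure prediction.** A cluster's product is modeled as a chemical
graph built from subgraphs: monomer residues condensed in module order
for thiotemplated (NRPS/PKS) assembly lines, or a cleaved precursor core
peptide for RiPPs. Tailoring enzymes contribute reagent fragments and
virtual reactions — sequences of bond-order changes, bond additions or
removals, and atom removals, but never atom creation. Because the exact
site of many reactions (halogenation, phosphorylation at "any free
hydroxyl", ...) cannot be inferred from sequence, the engine enumerates
the full plan space: every monomer choice × every subset of candidate
sites per reaction (up to `max_applications`). For a cluster with plan
space *N* ≤ cap (default 100) enumeration is exhaustive; otherwise a
uniform, seeded sample of plans is drawn without replacement.

**Evaluation.** Predicted vs true structures are compared by the
Tanimoto coefficient Tc = |A∩B|/|A∪B| over 1024-bit circular
(ECFP6-style, radius 3) fingerprints, using the median over all
prediction × truth pairs per cluster and the maximum as a recall bound.
Because circular fingerprints are sparse, matched Tc values are judged
against a *random-pair* null (predictions vs the true products of
non-matching clusters) with a Brunner–Munzel rank test (paired variant;
t-test below 10 observations). Functional-group content is compared by
Jensen–Shannon divergence (base 2) with a cluster-bootstrap error.

**QPSAR.** Per-cluster features are the per-bit mean of the fingerprint
over predicted structures (a bit set in 2 of 10 structures → 0.2), or
domain-family counts as a genome-annotation baseline. Five activities
(antibacterial, antifungal, antiviral, antitumor, immunomodulatory) are
independent binary problems for an RBF-kernel SVM with calibrated
probabilities, evaluated by stratified tenfold cross-validation; model
families are compared with one-sided DeLong tests combined by Fisher's
method, and decision thresholds are calibrated to a 10% false-discovery
rate on the pooled out-of-fold scores.

## Worked example

Generate one synthetic genome with three planted clusters, then run the
full pipeline:

```sh
bgcforge simulate --seed 11 --out demo --genomes 1
bgcforge predict demo/genome000.fasta --kb demo/knowledgebase.yaml \
    --out demo/run.json --seed 11
```

which prints

```
1 genomes, 3 planted clusters -> demo
3 clusters, 15 structures -> demo/run.json
```

and writes a JSON run record. For this seed the three detected clusters
are:

```
genome000:471-2752    nrps    plans 15  structures 13
genome000:17725-18576 nrps    plans 1   structures 1
genome000:33537-35322 hybrid  plans 1   structures 1
```

The first cluster is a four-module nonribosomal peptide synthetase
(Tyr–Trp–Trp–Val by adenylation-domain substrate prediction) with a
halogenase: its 15 plans are the unchlorinated scaffold plus
chlorination at each of the 14 candidate aromatic CH sites, collapsing
to 13 distinct molecules after canonical-SMILES deduplication. The
second is an unmodified Ser–Tyr dipeptide (one plan, one structure);
the third is an NRPS/PKS hybrid (Trp–Cys–Cys extended by one ketide
unit). Each record carries the predicted SMILES, the exact plan-space
size, and whether sampling was needed. `demo/truth.json` holds the
planted coordinates and independently composed true products;
`bgcforge evaluate` scores a run against such a gold standard
(max Tc = 1.0 here means the true product is among the predictions).

## Layout

```
src/bgcforge/
  seqio.py          FASTA/GenBank input, ORF calling, translation
  domains.py        profile scanning, annotation tables, substrates
  clusters.py       rule-based BGC calling and cluster matching
  chem/             molecular graphs, SMILES, fingerprints,
                    descriptors, functional groups
  knowledgebase.py  domain models, monomers, reactions, rules (YAML)
  predict.py        scaffold assembly and plan-space enumeration
  evaluate.py       Tc metrics, random-pair null, rank statistics, JSD
  qpsar.py          features, SVM training, DeLong/Fisher, FDR
  simulate.py       seeded synthetic genomes, truths, labels
  cli.py            detect / predict / evaluate / qpsar-* / simulate
  data/knowledgebase.yaml   the bundled knowledgebase
```

See `docs/methods.md` for the modeling assumptions, parameter defaults
and known limitations.
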
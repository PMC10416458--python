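# Methods

## Model

The screen operationalises "gene X of reference species R has an ortholog
in species A" as a conjunction of three conditions evaluated on a
homology-weight matrix:

* **(a) α-homology** — X′ is among the top-*u* homologs of X in A by the
  gene weight W(X, X′), with W strictly above a floor and the pair's
  E-value strictly below a ceiling;
* **(b) local synteny (forward check)** — a required number of *witness*
  pairs (Y, Y′) exists, Y in the neighborhood of X, Y′ in the neighborhood
  of X′, each pair satisfying the (stricter) β-homology condition, BBH by
  default;
* **(c) no closer alternative (backward check)** — no reference gene
  U ≠ X exists that is α-homologous to X′, itself syntenic with X′, and
  closer by more than the margin λ: W(X′, U) − W(X, X′) > λ.

Candidates X′ are examined in decreasing-weight order and the first
survivor is reported; a gene with no surviving candidate is *absent* in A.
The asymmetry is deliberate: at most one ortholog per species is reported,
so a lost paralog is reported as lost even when a co-ortholog exists —
the screen targets changes in gene content, not a complete orthology
graph.

Weights are built from optimal local alignment scores under BLOSUM62 with
affine gap penalties (open 11, extend 1): w(x, y) = 2 s(x, y)/[s(x, x) +
s(y, y)], projected to genes by the maximum over encoded-protein pairs.
The weight is dimensionless, 1 for identical sequences, and deliberately
not clamped (local alignment peculiarities can push it slightly above 1).
The denominator uses the mean of the self-scores by default; `min` and
`max` variants are selectable and behave nearly identically in practice.

## Parameters

| parameter | default | meaning |
|---|---|---|
| u | 3 | candidate homologs retained per (gene, species); a dynamic cut-off — the same weight can rank 1st against one species and 4th against another |
| radius r | 5 Mbp | witness window on either side of a gene, TAD-scale; per-species overrides supported |
| witnesses_required | 1 | witness pairs demanded by the forward check |
| β condition | BBH | witness-pair homology (alternatives: best-hit, top-k) |
| weight_min | 0.07 | strict lower bound on W for table entry |
| e_value_max | 1e-7 | strict upper bound on E for table entry |
| λ | 0 | backward-check margin; higher = harder to reject, in [0, 1] |
| λ₁ | ≥ 1 | raw-score quotient threshold of the alternative backward variant |
| chain radii | 1, 2, 5 Mbp | windows at which the three-species condition is tested |
| FDR cut | 0.01 | strict upper bound for a DE record to count |
| θ floor | 0 | non-strict lower bound on \|logFC\| |

λ = 0 with a strict inequality means an exact weight tie never rejects a
candidate: when two reference genes are equally similar to X′ one cannot
say which is the true ortholog, so the candidate is given the benefit of
the doubt. Raising λ demands that the alternative be *substantially*
closer; each individual call is therefore monotone in λ (absent can flip
to present, never the reverse), while aggregate list lengths need not be
monotone because a gene enters the loss list by becoming present in the
lower group and leaves it by becoming present in the upper group.

## E-values

The built-in aligner assigns a Karlin–Altschul-style surrogate E-value,
E = K·m·n·exp(−λ_KA·S), with the gapped BLOSUM62 constants (λ_KA = 0.267,
K = 0.041), m the query length and n the total database length. It is
monotone decreasing in the raw score at fixed lengths — which is all that
thresholding, ranking and BBH determination consume — but it is not
numerically identical to a search tool's E-value (no edge-length
correction, no sum statistics). When a precomputed score table is supplied
(`query target raw_score e_value`, the standard tabular output of protein
search tools), its E-values are carried verbatim and the built-in aligner
is bypassed.

## Numerical and tie-break choices

* Ties in weight are broken by ascending E-value, then ascending target
  gene id. With the symmetrized matrix this makes ranks deterministic and
  BBH symmetric (rank = back-rank = 1 in one direction implies the same in
  the other).
* Neighborhood membership is interval intersection with
  [start − r, end + r], inclusive at both boundaries, 1-based inclusive
  coordinates; genes on other scaffolds never qualify, and the focal gene
  is excluded from its own neighborhood.
* A witness gene may serve in only one witness pair per check; pairs are
  chosen greedily in descending weight order (with one witness required,
  greedy choice and maximum matching coincide).
* The gene's own-species homolog bucket keeps paralogs but excludes the
  gene itself (a self-entry would occupy rank 1 vacuously); within-species
  paralogs are exactly what the backward check needs to see.
* In the backward check, "U is α-homologous to X′" means U appears in X′'s
  top-u bucket over the reference species; the reciprocal entry may have
  been truncated away on U's side and is not required. The synteny test
  for (U, X′) reuses the forward-check machinery with the same radius.
* Both links of the three-species chain (reference→fish and fish→upper)
  are evaluated at the same radius per flag; the fish species takes the
  reference role in the second link, including for the backward check's
  alternative search.
* Identical protein sequences are deduplicated before alignment and their
  matrix cells re-expanded afterwards; the self-cell exemption from the
  E-value cut applies only to true self pairs.
* Empty matrix cells behave as raw score 0 / E-value ∞; genes with no
  qualifying homolog in a species simply have an empty bucket and are
  called absent there.
* DE filtering: FDR strictly below the cut (an "FDR < c" rule), |logFC|
  at least the floor (a "lower limit" rule); a gene's reported logFC is
  its maximum-|logFC| qualifying record. If a second model's table is
  provided, a gene must qualify in both, matched per gene.

## Synthetic data

The generator emulates the evolutionary scenario the screen is designed
for: an ancestral genome of random peptide genes (i.i.d. residues from the
Robinson–Robinson background composition) laid on chromosomes at fixed
1 Mbp spacing, from which each extant species descends independently (a
star phylogeny). Per species it applies planted per-group losses, optional
tandem duplications (the paralog inserted beside its parent with extra
divergence), per-site substitutions at the configured branch rate (targets
drawn proportional to exp(BLOSUM62 score), so conservative substitutions
dominate), and optional local adjacent-gene order swaps. Coordinates
compact after loss, so windows always contain genes. The default study
design mirrors a lost-gene screen at desk scale: two fish, a reference
amphibian, three middle taxa, two placentals — eight species of 60 genes
(problem sizes in the tests range from 24 to 60 genes so the exhaustive
oracle stays cheap).

What the generator does *not* emulate: indels and length variation,
codon-level models, rate heterogeneity across sites or lineages,
non-star phylogenies, gene fissions/fusions, assembly artifacts, and
multi-isoform genes (one protein per gene). Passing tests therefore
demonstrate the decision logic — candidate ranking, witness geometry,
backward rejection, list bookkeeping — not robustness to every
property of real annotations. On real data the weight thresholds and the
surrogate E-value do the work the generator's clean divergence model does
here.

The brute-force oracle re-derives presence calls by exhaustive
enumeration — every protein pair aligned, every homolog list fully sorted,
every witness pair and every alternative U enumerated — sharing only the
pairwise aligner with the pipeline, and refuses datasets beyond ~300 genes
× 8 species where exhaustive checking would stop being meaningful.

## Design notes

* Orthology information is generated de novo from the input proteomes and
  annotations; no external orthology database is consulted — the point of
  the method is to avoid inheriting their coverage decisions.
* The metacondition language is a minimal boolean grammar over
  `present_in(group, k)` atoms with `and`/`or`/`not` and parentheses,
  parsed by recursive descent; `k` defaults to the group's configured
  minimum (1 unless overridden). Group roles are data, not code: choosing
  the reference among the upper species and swapping roles turns the lost-
  gene screen into an emerged-gene screen unchanged.
* Weight/E-value thresholds are applied uniformly when the table is built,
  before any ranking, so forward lists and the reciprocal lists behind
  back-ranks see the same entries.
* The per-query hit cap of the external-search path interacts with
  symmetrization; cells are capped first and symmetrized after, matching
  the order in which a search tool's output would be post-processed.
* Protein ids must be globally unique across species (accession-style
  ids); duplicates raise immediately.

## Limitations

* Orthologs lacking local synteny are systematically missed; group-level
  aggregation ("present in at least k of the group") damps the impact,
  since a true ortholog would have to lack synteny in every species of the
  group to corrupt a group-level conclusion.
* One-to-many and many-to-many orthology is deliberately collapsed to at
  most one reported ortholog per species.
* The surrogate E-value path should not be compared numerically against
  E-values from a real search tool; mixing the two sources within one run
  is unsupported.
* Runtime is dominated by all-vs-all alignment (quadratic in total protein
  count); for genome-scale inputs, supply a precomputed score table from a
  dedicated search tool instead of the built-in aligner.
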
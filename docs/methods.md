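# Methods

## Overview

`srna-evo` reconstructs when the parts of a bacterial post-transcriptional
regulatory interaction appeared in evolution: the small RNA (sRNA), its
target gene, and the binding sites on both molecules (the sRNA-side site,
sBS, and the mRNA-side site, mBS). Presence or absence of each element is
traced over a rooted species phylogeny with a two-state gain/loss Markov
model; confident ancestral presence defines a *gain node* per element, the
tree distance from the gain node to the focal genome defines its
*evolutionary age*, and comparing ages classifies each interaction into one
of three appearance-order scenarios.

## Gain/loss model

A trait (an ncRNA family, a target-gene ortholog cluster, or an mBS) is a
binary character evolving along the fixed input tree under a continuous-time
Markov chain with gain rate `g` (0→1) and loss rate `l` (1→0). The
transition matrix is closed-form: with `r = g + l` and stationary presence
probability `π1 = g/r`,

    P01(t) = π1 (1 − e^{−rt}),   P10(t) = (1 − π1)(1 − e^{−rt}).

Branch lengths are in amino-acid substitutions per position and are never
re-estimated — the tree is immutable input. Likelihoods use Felsenstein
pruning, vectorised over traits (an `(n_traits, n_leaves)` matrix with NaN
for missing observations; a missing leaf contributes partial likelihood
(1, 1) so the tree stays fixed across traits). The root prior defaults to
the stationary distribution; an explicit prior can be supplied. A
K-category rate mixture is available behind a configuration knob: the trait
likelihood is the weighted sum of per-category likelihoods, and posteriors
mix with the data-conditional category weights. The default is a single
category, which is the identifiable core of the mixture-style model family
used by gain/loss reconstruction tools; the exact parameterisation of those
tools' internal mixtures is not recoverable and is deliberately not guessed.

Rates are fitted by bounded L-BFGS-B over log-rates from a fixed 3×3 grid
of starts (0.1, 1, 10 per rate), bounds `[1e-6, 1e3]`, likelihood tolerance
1e-10. Degenerate inputs (all-absent or all-present collections) pin a rate
at its bound and log a warning rather than fail.

Marginal ancestral posteriors `P(node present | data)` come from an
inside–outside (up–down) pass with per-node rescaling. Per-branch event
expectations (full stochastic mapping) are not computed: every downstream
rule in the analysis consumes node posteriors only.

## Gain nodes and ages

For a trait present in the focal genome, the gain node is the **oldest**
ancestor A such that every node on the path from A down to the focal leaf
has posterior ≥ θ (default 0.7). The first sub-threshold node stops the
upward walk even if older nodes are confident again — an unbroken chain is
required precisely to exclude a loss followed by an independent re-gain,
which would make the older presence irrelevant to the focal lineage's copy.
If the focal leaf's own parent is below θ the trait is lineage-specific
(gain node = leaf, age 0). A variant rule uses marginal ML states
(posterior > 0.5; exact ties resolve to absent) instead of the θ chain and
is used for the broad ncRNA-family age survey, where per-element
stringency matters less than coverage.

Age = patristic distance from the gain node to the focal leaf. On a single
ancestor chain ages strictly increase with depth when branch lengths are
positive, so age comparisons are equivalent to node comparisons.

## Binding-site presence by duplex energy

mBS presence in an orthologous genome is decided by hybridisation free
energy, not sequence identity. The energy model is an intermolecular
nearest-neighbour duplex model: Watson–Crick plus G:U pairs, a stacking
table for adjacent pairs, duplex initiation +4.09 kcal/mol, and an affine
interior/bulge penalty `4.0 + 0.3·(n1+n2)` kcal/mol capped at total loop
size 30. The bundled stack table uses the standard Turner-style values for
the ten Watson–Crick stacks and a representative approximate subset for
wobble-containing stacks, closed under reverse-complement symmetry at load
time (the loader rejects asymmetric tables). Dangling ends and terminal AU
penalties are omitted by default (a configurable additive terminal term
exists). Absolute energies are therefore approximate; the analysis only
ever uses energy *ratios*, which are far less sensitive to the parameter
subset. An adapter to the external RNAduplex executable exists for
cross-checking, never as the implementation.

The minimum free energy over all antiparallel non-crossing pairings is
computed by dynamic programming over "last pair" states (`O(n·m·L²)`); a
brute-force enumeration oracle (inputs ≤ 100 pair candidates) verifies it
exactly in the test suite.

The presence rule: an orthologous site is present iff the ortholog of the
target gene exists in that genome, the aligned site has no gap in its core
columns, and its duplex energy with that genome's own sRNA site reaches at
least `ratio` (default 0.9) of the reference (focal-genome) interaction's
stability: `ΔG_orth ≤ 0.9·ΔG_ref`, boundary inclusive, both energies
negative. Genomes lacking the sRNA are paired against the majority-rule
consensus of the sRNA site over the genomes that have it — a deliberate,
documented stand-in for full ancestral sequence reconstruction. Energies
are computed over the padded (core ± 5 nt) site sequences: the pads give
the energy model stacking context; gaps within the pads do not veto a site.

## Interaction scenarios

The sRNA's gain node stands for its sBS (sRNA sites are conserved wherever
the sRNA exists, so the two are not separately dated; an optional strict
mode verifies consensus-site identity). Comparing the sBS and mBS gain
nodes on the focal genome's ancestor chain yields three mutually exclusive
classes: co-gained at the same node; mBS older (site predates the sRNA);
mBS younger (site evolved after the sRNA). Interaction age = the younger of
the two gain ages. Comparing the mBS with its host gene similarly yields
"site appeared with the gene" vs. "site appeared later". A site older than
its host gene is impossible; the classifier raises a consistency error.
Because the gene and site reconstructions are separate estimates, the
pipeline enforces the constraint up front: an mBS posterior chain that
walks above the gene's own gain node is clamped to the gene's gain node,
with a logged warning. Near-duplicate records of the same (sRNA, target)
pair are merged beforehand when their sites are closer than 10 nt
edge-to-edge on *both* molecules (exactly 10 keeps them distinct; the
anchor is configurable to interval starts).

## Statistics

Age distributions of cis-acting vs trans-acting ncRNA families are compared
with a two-tailed Mann–Whitney test, `U = #{x < y} + ½·ties`. For
`n1 + n2 ≤ 16` the p-value is exact by full enumeration of group labelings
(fraction of labelings with `|U − n1n2/2|` at least the observed
deviation). Above that, an Edgeworth-corrected normal approximation is used
(continuity correction plus the kurtosis term of the exact U null,
`κ4 = −n1n2(n+1)(n1²+n2²+n1n2+n1+n2)/120`), which tracks the exact value to
within ~0.003 at the switchover sizes; with ties it falls back to the
standard tie-corrected normal approximation.

## Synthetic data

The generator replaces the external resources a real run would consume
(curated species tree, ncRNA family annotations, ortholog tables, RefSeq
upstream windows) with simulations carrying full ground truth:

* **Tree** — an ultrametric pure-birth (Yule) tree, branch lengths scaled
  so root-to-leaf depth is 1.0 (the unit of the age axis).
* **Traits** — the two-state chain along the tree, with an optional forced
  gain node; with loss rate 0 a forced gain marks exactly its clade. The
  fixture presets use clean clade profiles for sRNAs and genes (forced
  gain, zero loss): all realistic noise is injected downstream, at the
  sequence level the duplex rule consumes.
* **Sequences** — pre-aligned windows evolving by Jukes–Cantor
  substitutions at rate μ = 0.1 per site per unit branch length. Within a
  binding-site interval, lineages carrying the site mutate at ρμ with
  ρ = 0.05 and the interval is initialised at the gain branch to the
  reverse complement of the sRNA site (at the root itself if the trait
  starts present). The conserved footprint extends 5 nt beyond the core on
  each side, matching the extraction pad: the immediate flanks of a real,
  experimentally delimited binding site belong to the same conserved
  element, and the 0.9 ratio rule's 10% slack presumes they do not drift
  freely. No indels are simulated by default (the pipeline consumes
  alignments, so the fixture provides them pre-aligned); gap injection is
  a separate knob used to exercise the gap-flag logic.
* **Presets** — "minimal" (16 leaves, 1 sRNA, 3 interactions, one per
  scenario class; a smoke fixture, deliberately too small for exact
  gain-node recovery) and "paper-like" (64 leaves, 15 sRNAs, 60
  interactions over ~50 targets, some carrying two sites). The paper-like
  scenario composition is 52 site-succeeds / 6 co-gained / 2 site-precedes
  with gene timing 18 with-gene / 42 after-gene, i.e. the composition
  reported for the real *E. coli* interaction compendium, so the synthetic
  study runs under the same class imbalance. Three sRNAs are "ancient"
  (root gains); the rest gain in mid-chain ancestors of the focal genome.

Everything is a pure function of (config, seed); identical seeds produce
byte-identical fixture directories.

What the generator does **not** emulate: indel evolution and alignment
error (alignments are given, not inferred), horizontal transfer (a real
confounder for one sRNA in the motivating data), rate variation across
lineages, GC heterogeneity, and any correlation between gene loss and site
decay. Passing tests therefore demonstrate the correctness and calibration
of the inference machinery under the model's own assumptions, not the
fidelity of upstream annotation, ortholog inference, or alignment on real
genomes.

## Numerical choices and edge cases

* Coordinates are 0-based half-open internally, 1-based inclusive in all
  TSV I/O (stated in file headers).
* Unlabeled internal nodes get deterministic post-order names ("N0001"…)
  so gain nodes are referable across runs; polytomies are accepted;
  zero-length branches are allowed (identity transition matrix).
* Consensus ties break alphabetically (A < C < G < U) and are logged.
* Homology-hit presence thresholds are inclusive (E ≤ 10 after linear
  normalisation to a 4 Mb reference genome; identity ≥ 30%).
* E-value normalisation scales linearly with search-space size.
* Exact Mann–Whitney switches to the approximation at `n1 + n2 = 16`.
* Pruning a tree collapses degree-2 nodes, summing branch lengths, so
  pairwise distances between retained leaves are preserved exactly.
* The rooted-tree requirement is a documented input contract: the model
  and the chain rules are defined on a rooted topology.

## Problem sizes

Default verification scales: enumeration oracles on trees of ≤ 6 leaves
and duplexes of ≤ 8 nt; rate recovery from 500 traits on 32 leaves;
gain-node recovery over 100 replicates on 64-leaf trees; calibration over
2000 traits on 16 leaves; the end-to-end study on the 64-leaf, 60
interaction paper-like preset. These sizes make every check exact or
well-powered while keeping a full run of the suite and the acceptance
script in the minutes range on one CPU.
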
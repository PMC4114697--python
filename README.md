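# srna-evo

Evolutionary reconstruction of bacterial sRNA–mRNA regulatory
interactions: when did the small RNA, its target gene, and the binding
sites on both molecules appear?

Bacterial small RNAs (sRNAs) regulate mRNAs by base-pairing between a
site on the sRNA (sBS) and a site on the target mRNA (mBS). A regulatory
interaction can only exist once *both* sites exist, so dating each
element on a species phylogeny reveals how the regulatory network was
assembled: were sRNA and target site gained together, did the mRNA site
pre-date the sRNA, or did targets acquire sites only after the sRNA
appeared? This package is for molecular evolution / regulatory RNA
researchers who want that analysis as a tested, reproducible pipeline.

## The model

Presence/absence of each element (ncRNA family, target-gene ortholog,
mBS) is a binary trait evolving along a fixed rooted phylogeny under a
two-state continuous-time Markov chain with gain rate *g* and loss rate
*l*; with *r = g + l* and *π₁ = g/r*,

```
P01(t) = π1 (1 − e^{−rt}),    P10(t) = (1 − π1)(1 − e^{−rt}).
```

Rates are fitted by maximum likelihood (Felsenstein pruning; branch
lengths fixed), and marginal posteriors of ancestral presence come from
inside–outside message passing. The **gain node** of a trait is the
oldest ancestor of the focal genome from which an unbroken chain of
nodes with posterior ≥ θ (default 0.7) leads down to the focal leaf; its
**evolutionary age** is the tree distance (amino-acid substitutions per
position) from the gain node to the focal genome.

mBS presence in each genome is decided by RNA–RNA hybridisation free
energy (nearest-neighbour duplex model, intermolecular only): a site is
present iff its duplex with that genome's sRNA site is at least 90% as
stable as the reference interaction in the focal genome
(ΔG ≤ 0.9·ΔG_ref). Comparing sBS, gene, and mBS gain nodes classifies
every interaction (co-gained / site precedes / site succeeds) and dates
it by the younger gain node. Full details: [docs/methods.md](docs/methods.md).

## Worked example

Everything runs on synthetic data with known ground truth — no
downloads. Simulate a 64-genome compendium (15 sRNAs, 60 interactions)
and run the full pipeline:

```
$ srna-evo simulate --preset paper-like --seed 17 --out scratch/dataset
wrote paper-like fixture to scratch/dataset (focal genome G047, 60 interactions)

$ srna-evo run --fixture scratch/dataset --out scratch/out
families: 36 aged; cis-vs-trans p = 3.0464684816978615e-05
scenario counts: {'CO_GAINED': 4, 'MBS_PRECEDES': 2, 'MBS_SUCCEEDS': 54}
gene-timing counts: {'MBS_WITH_GENE': 18, 'MBS_AFTER_GENE': 42}
manifest 322c6416f471 -> scratch/out
```

Reading the output: most mRNA binding sites (54/60 here) appeared
*after* their sRNA — targets are recruited into the network once the
regulator exists; a small co-gained group and two site-first
interactions complete the picture, and the generator's truth table
confirms the calls (96.7% exact scenario agreement on this run).
Trans-acting ncRNA families are much younger than cis-acting ones
(two-tailed Mann–Whitney p ≈ 3×10⁻⁵), reproducing the expected
late burst of trans-acting sRNA acquisition.

The same steps are available as numbered drivers that write tables under
`results/`:

```
python analysis/01_simulate_dataset.py      # fixture + composition table
python analysis/02_family_ages.py           # family ages, cis-vs-trans test
python analysis/03_interaction_scenarios.py # per-interaction classification
python analysis/04_threshold_robustness.py  # theta x ratio sweep
```

## Layout

```
src/srnaevo/     treeio, gainloss, annotate, duplex, evoanalysis,
                 synthdata, pipeline, cli
analysis/        numbered narrative drivers (write under results/)
tests/           pytest suite incl. enumeration oracles
scripts/         acceptance.py
```
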
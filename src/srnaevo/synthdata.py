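"""Synthetic inputs with known ground truth for every pipeline stage.

The generator stands in for the external resources the analysis would
normally consume (a curated species tree, ncRNA family annotations,
ortholog tables, upstream-region sequences): a Yule tree, binary traits
evolving under the two-state gain/loss chain (optionally with a forced
gain node for recovery tests), and pre-aligned sequence windows in which
a binding-site interval becomes reverse-complementary to an sRNA site at
a chosen ancestral node and stays conserved below it.

Everything is a pure function of (config, seed); the same seed yields
byte-identical fixture directories.  No indels are simulated by default
(the pipeline consumes alignments, so the fixture provides pre-aligned
rows); gap injection is a separate, explicit knob used to exercise the
gap-flag logic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import SiteInterval, write_fasta
from .gainloss import PhyleticProfile, write_profiles_tsv
from .treeio import Phylogeny, parse_newick

__all__ = [
    "SimConfig",
    "ConservedSite",
    "FixtureDataset",
    "simulate_tree",
    "simulate_trait",
    "true_gain_node",
    "simulate_alignment",
    "make_fixture_dataset",
    "revcomp_rna",
]

_ALPHABET = "ACGU"
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp_rna(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


@dataclass
class SimConfig:
    """Knobs shared by the generators; presets override a subset.

    ``mu`` is the substitution rate per site per unit branch length
    (amino-acid substitutions per position, the tree's unit); ``rho``
    scales it down inside a conserved binding site.
    """

    seed: int = 0
    n_leaves: int = 64
    birth_rate: float = 1.0
    depth: float = 1.0
    gain: float = 0.5
    loss: float = 1.0
    forced_gain: str | None = None
    seq_length: int = 200
    mu: float = 0.1
    rho: float = 0.05
    site: tuple[int, int] = (100, 114)
    n_traits: int = 1
    gap_rate: float = 0.0
    implant_mismatches: int = 0


@dataclass
class ConservedSite:
    """A binding-site interval under lineage-dependent conservation.

    ``states`` maps node name -> 0/1 (does the lineage carry the site).
    On the branch where the state switches 0 -> 1 the interval is
    overwritten with ``implant``; below, it mutates at rho * mu.
    ``conserve_pad`` extends the conserved footprint (not the implant)
    by that many columns on each side: the immediate flanks of a real
    binding site belong to the same conserved element, and the
    energy-ratio rule presumes they do not drift freely.
    """

    start: int
    end: int
    states: dict[str, int]
    implant: str | None = None
    rho: float = 0.05
    implant_mismatches: int = 0
    conserve_pad: int = 0


def simulate_tree(
    n_leaves: int, seed: int, birth_rate: float = 1.0, depth: float = 1.0
) -> Phylogeny:
    """Ultrametric pure-birth (Yule) tree scaled to root-leaf ``depth``."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)

    next_id = [0]

    def new_node():
        next_id[0] += 1
        return f"T{next_id[0]}"

    birth_time = {}
    children: dict[str, list[str]] = {}
    root = "root"
    birth_time[root] = 0.0
    active = [root]
    t = 0.0
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        kids = [new_node(), new_node()]
        children[parent] = kids
        for k in kids:
            birth_time[k] = t
        active.extend(kids)
    t_final = t + rng.exponential(1.0 / (birth_rate * n_leaves))
    # the clock starts at the root's first split, so scale by that span
    origin = birth_time[children[root][0]] if root in children else 0.0
    scale = depth / (t_final - origin)

    leaf_counter = [0]

    def newick(node: str, end_time: float | None) -> str:
        if node in children:
            split = birth_time[children[node][0]]
            inner = ",".join(newick(c, None) for c in children[node])
            length = (split - birth_time[node]) * scale
            return f"({inner}):{length:.10g}"
        leaf_counter[0] += 1
        length = (t_final - birth_time[node]) * scale
        return f"G{leaf_counter[0]:03d}:{length:.10g}"

    if root in children:
        split = birth_time[children[root][0]]
        # the root's own branch has length 0
        inner = ",".join(newick(c, None) for c in children[root])
        text = f"({inner}):0;"
    else:  # n_leaves would be < 2; unreachable
        text = "G001:0;"
    return parse_newick(text)


def _branch_p_present(state: int, g: float, l: float, t: float) -> float:
    """P(child present | parent state); tolerates zero rates."""
    r = g + l
    if r == 0 or t == 0:
        return float(state)
    decay = 1.0 - math.exp(-r * t)
    if state == 0:
        return (g / r) * decay
    return 1.0 - (l / r) * decay


def simulate_trait(
    tree: Phylogeny,
    g: float,
    l: float,
    seed: int,
    forced_gain: str | None = None,
    trait_id: str = "trait",
) -> tuple[PhyleticProfile, dict[str, int]]:
    """One trait realized along the tree; returns (profile, node states).

    With ``forced_gain`` the root starts absent and the state is set
    present at the forced node (so with loss rate 0 its whole clade is
    present and everything else reflects chance gains only).  The true
    gain node for a focal leaf follows via :func:`true_gain_node`.
    """
    if g < 0 or l < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    states: dict[str, int] = {}
    r = g + l
    pi1 = g / r if r > 0 else 0.0
    for node in tree.preorder():
        if node.parent is None:
            state = 0 if forced_gain is not None else int(rng.random() < pi1)
        else:
            p = _branch_p_present(states[node.parent], g, l, node.length)
            state = int(rng.random() < p)
        if forced_gain is not None and node.name == forced_gain:
            state = 1
        states[node.name] = state
    profile = PhyleticProfile(
        trait_id=trait_id,
        states={lf: states[lf] for lf in tree.leaves()},
    )
    return profile, states


def true_gain_node(tree: Phylogeny, states: dict[str, int], focal_leaf: str) -> str | None:
    """Oldest ancestor with an unbroken truly-present chain to the leaf."""
    if states.get(focal_leaf) != 1:
        return None
    gain = focal_leaf
    for anc in tree.ancestor_chain(focal_leaf):
        if states.get(anc) != 1:
            break
        gain = anc
    return gain


def _mutate(seq: np.ndarray, rate: float, t: float, rng: np.random.Generator,
            mask: np.ndarray | None = None) -> np.ndarray:
    """Jukes-Cantor step: per-site substitution over a branch of length t."""
    out = seq.copy()
    p_diff = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * rate * t))
    hit = rng.random(seq.size) < p_diff
    if mask is not None:
        hit &= mask
    idx = np.nonzero(hit)[0]
    if idx.size:
        # uniform among the three other bases
        shift = rng.integers(1, 4, size=idx.size)
        out[idx] = (out[idx] + shift) % 4
    return out


def _encode(seq: str) -> np.ndarray:
    return np.array([_ALPHABET.index(c) for c in seq], dtype=np.int64)


def _decode(arr: np.ndarray) -> str:
    return "".join(_ALPHABET[i] for i in arr)


def simulate_alignment(
    tree: Phylogeny,
    root_seq: str,
    mu: float,
    sites: list[ConservedSite],
    seed: int,
    gap_rate: float = 0.0,
    rows: set[str] | None = None,
) -> dict[str, str]:
    """Evolve a pre-aligned sequence window down the tree.

    Sites conserved in a lineage (state 1) mutate at ``rho * mu``; on the
    gain branch the interval is overwritten with the implant (with an
    optional number of mismatches).  Lineages lacking the site carry
    unconstrained sequence there.  ``rows`` restricts the output to a
    leaf subset (e.g. genomes that possess the gene).  With ``gap_rate``
    > 0, a 2-column gap is injected into the first site's core interval
    of randomly chosen rows.
    """
    rng = np.random.default_rng(seed)
    n = len(root_seq)
    for s in sites:
        if not (0 <= s.start < s.end <= n):
            raise ValueError(f"site [{s.start}, {s.end}) outside window of length {n}")
    seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is None:
            base = _encode(root_seq)
            # a trait already present at the root carries its site from the start
            for s in sites:
                if s.states.get(node.name, 0) == 1 and s.implant is not None:
                    base[s.start:s.end] = _encode(s.implant)
            seqs[node.name] = base
            continue
        parent_seq = seqs[node.parent]
        # fast sites (unconstrained everywhere this lineage lacks the trait)
        slow_mask = np.zeros(n, dtype=bool)
        for s in sites:
            if s.states.get(node.name, 0) == 1:
                slow_mask[max(0, s.start - s.conserve_pad):
                          min(n, s.end + s.conserve_pad)] = True
        child = _mutate(parent_seq, mu, node.length, rng, mask=~slow_mask)
        if slow_mask.any():
            child = _mutate(child, mu * max(s.rho for s in sites), node.length,
                            rng, mask=slow_mask)
        for s in sites:
            gained = (
                s.states.get(node.name, 0) == 1
                and s.states.get(node.parent, 0) == 0
            )
            if gained and s.implant is not None:
                imp = _encode(s.implant)
                if imp.size != s.end - s.start:
                    raise ValueError("implant length must equal site length")
                if s.implant_mismatches:
                    pos = rng.choice(imp.size, size=s.implant_mismatches,
                                     replace=False)
                    imp = imp.copy()
                    imp[pos] = (imp[pos] + rng.integers(1, 4, pos.size)) % 4
                child[s.start:s.end] = imp
        seqs[node.name] = child

    leaves = rows if rows is not None else set(tree.leaf_set())
    out = {lf: _decode(seqs[lf]) for lf in tree.leaves() if lf in leaves}
    if gap_rate > 0 and sites:
        core = sites[0]
        for lf in sorted(out):
            if rng.random() < gap_rate:
                pos = int(rng.integers(core.start, core.end - 1))
                row = list(out[lf])
                row[pos] = row[pos + 1] = "-"
                out[lf] = "".join(row)
    return out


# ---------------------------------------------------------------------------
# fixture datasets


@dataclass
class InteractionTruth:
    interaction_id: str
    srna_id: str
    target_id: str
    sbs: SiteInterval
    mbs: SiteInterval
    srna_gain: str
    gene_gain: str
    mbs_gain: str
    scenario: str
    gene_timing: str


@dataclass
class FixtureDataset:
    outdir: Path
    tree: Phylogeny
    focal_leaf: str
    truth: list[InteractionTruth] = field(default_factory=list)

    @property
    def tree_path(self) -> Path:
        return self.outdir / "tree.nwk"


# scenario-group composition of the paper-like preset:
# (scenario, gene_timing, gene-vs-sRNA relation, count)
_PAPER_LIKE_GROUPS = [
    ("CO_GAINED", "MBS_WITH_GENE", "gene_eq_srna", 2),
    ("CO_GAINED", "MBS_AFTER_GENE", "gene_older", 4),
    ("MBS_PRECEDES", "MBS_WITH_GENE", "gene_older", 2),
    ("MBS_SUCCEEDS", "MBS_AFTER_GENE", "gene_older", 18),
    ("MBS_SUCCEEDS", "MBS_WITH_GENE", "gene_younger", 14),
    ("MBS_SUCCEEDS", "MBS_AFTER_GENE", "gene_le_srna", 20),
]

_MINIMAL_GROUPS = [
    ("CO_GAINED", "MBS_WITH_GENE", "gene_eq_srna", 1),
    ("MBS_PRECEDES", "MBS_WITH_GENE", "gene_older", 1),
    ("MBS_SUCCEEDS", "MBS_AFTER_GENE", "gene_older", 1),
]

SBS_CORE = (40, 54)  # core sRNA site within the 100-nt sRNA window
MBS_SITES = [(100, 114), (130, 144)]  # alternative core sites per target window
SRNA_LEN = 100


def _focal_with_longest_chain(tree: Phylogeny) -> str:
    return max(sorted(tree.leaf_set()), key=lambda lf: len(tree.ancestor_chain(lf)))


def _gc_biased_seq(rng: np.random.Generator, n: int) -> str:
    # G/C-rich so reference duplexes are strongly stabilizing
    probs = [0.15, 0.35, 0.35, 0.15]  # A C G U
    return "".join(rng.choice(list(_ALPHABET), size=n, p=probs))


def _assign_interaction_specs(
    chain_len: int, groups, n_srnas: int, rng: np.random.Generator
):
    """Per-interaction (srna_idx, gene_idx, mbs_idx) chain positions.

    Index 0 is the focal leaf; ``chain_len`` is the root.  Ancient sRNAs
    sit at the root; the rest in mid-chain.  Positions are chosen to
    satisfy each group's scenario/timing relations exactly.
    """
    C = chain_len
    if C < 5:
        raise ValueError("focal ancestor chain too short for the preset")
    mid = list(range(2, C - 1)) or [2]
    srna_idx = {}
    n_ancient = min(3, n_srnas // 5)
    for k in range(n_srnas):
        name = f"sRNA{k + 1:02d}"
        if k < n_ancient:
            srna_idx[name] = C
        else:
            srna_idx[name] = mid[(k - n_ancient) % len(mid)]
    srnas = list(srna_idx)
    ancient = [s for s in srnas if srna_idx[s] == C]
    mids = [s for s in srnas if srna_idx[s] < C]

    specs = []  # (srna, s, gene_idx, mbs_idx, scenario, timing)
    cycle = {"mid": 0, "anc": 0}

    def next_srna(pool_name, pool):
        s = pool[cycle[pool_name] % len(pool)]
        cycle[pool_name] += 1
        return s

    for scenario, timing, relation, count in groups:
        for i in range(count):
            if relation == "gene_older" or relation == "gene_eq_srna":
                srna = next_srna("mid", mids)
            else:
                # spread the remaining load over every sRNA incl. ancient ones
                srna = next_srna("anc", ancient + mids) if ancient else next_srna("mid", mids)
            s = srna_idx[srna]
            if scenario == "CO_GAINED":
                m = s
            elif scenario == "MBS_PRECEDES":
                m = min(C, s + 1 + (i % 2))
            else:  # MBS_SUCCEEDS
                m = i % s  # anywhere strictly below the sRNA gain
            if relation == "gene_eq_srna":
                gn = s
            elif relation == "gene_older":
                gn = min(C, max(m, s) + 1)
            elif relation == "gene_younger":
                gn = m  # with-gene timing below the sRNA
            else:  # gene_le_srna
                gn = s if m < s else min(C, m + 1)
            if timing == "MBS_WITH_GENE":
                gn = m
            if not (gn >= m):
                raise AssertionError("gene must not be younger than its site")
            specs.append((srna, s, gn, m, scenario, timing))
    return srna_idx, specs


def make_fixture_dataset(
    preset: str = "paper-like",
    seed: int = 17,
    outdir: str | Path = "fixture",
    config: SimConfig | None = None,
) -> FixtureDataset:
    """Write a complete synthetic input directory plus truth tables.

    Presets: "minimal" (16 leaves, 1 sRNA, 2 targets, 3 interactions,
    one per scenario class) and "paper-like" (64 leaves, 15 sRNAs, 60
    interactions mixing the three scenario classes in the composition
    reported for the real interaction compendium).  Trait histories use
    forced gains with zero loss (clean clade profiles); all realistic
    noise enters through the sequence layer that the duplex-energy rule
    consumes.
    """
    if preset == "paper-like":
        n_leaves, n_srnas, groups = 64, 15, _PAPER_LIKE_GROUPS
    elif preset == "minimal":
        n_leaves, n_srnas, groups = 16, 1, _MINIMAL_GROUPS
    else:
        raise ValueError(f"unknown preset {preset!r}")
    cfg = config or SimConfig(seed=seed, n_leaves=n_leaves)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "alignments").mkdir(exist_ok=True)

    # deterministic retry until the focal chain is deep enough
    for attempt in range(20):
        tree = simulate_tree(n_leaves, seed + 1000 * attempt,
                             cfg.birth_rate, cfg.depth)
        focal = _focal_with_longest_chain(tree)
        chain = [focal] + tree.ancestor_chain(focal)
        if len(chain) - 1 >= 5:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not simulate a tree with a deep focal chain")

    rng = np.random.default_rng(seed + 7)
    C = len(chain) - 1
    srna_idx, specs = _assign_interaction_specs(C, groups, n_srnas, rng)
    node_at = {i: chain[i] for i in range(C + 1)}

    def clade_profile(trait_id: str, node: str) -> PhyleticProfile:
        clade = tree.clade_leaves(node)
        return PhyleticProfile(
            trait_id=trait_id,
            states={lf: (1 if lf in clade else 0) for lf in tree.leaves()},
        )

    # --- sRNAs: profiles, site sequences, alignments
    srna_profiles = []
    sbs_seqs: dict[str, str] = {}
    for srna, idx in srna_idx.items():
        node = node_at[idx]
        srna_profiles.append(clade_profile(srna, node))
        sbs_seqs[srna] = _gc_biased_seq(rng, SBS_CORE[1] - SBS_CORE[0])
        clade = tree.clade_leaves(node)
        site = ConservedSite(
            start=SBS_CORE[0], end=SBS_CORE[1],
            states=_presence_states(tree, node),
            implant=sbs_seqs[srna], rho=cfg.rho, conserve_pad=5,
        )
        aln = simulate_alignment(
            tree,
            root_seq=_decode(rng.integers(0, 4, SRNA_LEN)),
            mu=cfg.mu,
            sites=[site],
            seed=int(rng.integers(2**31)),
            rows=clade,
        )
        write_fasta(aln, outdir / "alignments" / f"srna_{srna}.fasta")
    write_profiles_tsv(srna_profiles, outdir / "srna_profiles.tsv")

    # --- targets: group interactions that share a gene gain node so some
    # targets carry two binding sites (as in real compendia)
    buckets: dict[int, list] = {}
    for spec in specs:
        buckets.setdefault(spec[2], []).append(spec)
    targets: list[tuple[str, int, list]] = []
    tcount = 0
    for gn, bucket in sorted(buckets.items()):
        i = 0
        while i < len(bucket):
            take = bucket[i: i + 2] if (tcount % 5 == 0 and i + 2 <= len(bucket)) \
                else bucket[i: i + 1]
            # a target can host at most one site per distinct window slot
            tcount += 1
            targets.append((f"tgt{tcount:03d}", gn, take))
            i += len(take)

    gene_profiles = []
    truth: list[InteractionTruth] = []
    interaction_rows = []
    for tname, gn, bucket in targets:
        gene_node = node_at[gn]
        gene_profiles.append(clade_profile(tname, gene_node))
        gene_clade = tree.clade_leaves(gene_node)
        sites = []
        for slot, (srna, s, _gn, m, scenario, timing) in enumerate(bucket):
            lo, hi = MBS_SITES[slot]
            sites.append(
                ConservedSite(
                    start=lo, end=hi,
                    states=_presence_states(tree, node_at[m]),
                    implant=revcomp_rna(sbs_seqs[srna]),
                    rho=cfg.rho,
                    implant_mismatches=cfg.implant_mismatches,
                    conserve_pad=5,
                )
            )
            sbs = SiteInterval(srna, SBS_CORE[0], SBS_CORE[1])
            mbs = SiteInterval(tname, lo, hi)
            iid = f"{srna}-{tname}@{lo}"
            interaction_rows.append(
                {
                    "interaction": iid, "srna": srna, "target": tname,
                    "sbs_start": sbs.start + 1, "sbs_end": sbs.end,
                    "mbs_start": mbs.start + 1, "mbs_end": mbs.end,
                    "strand": "+",
                }
            )
            truth.append(
                InteractionTruth(
                    interaction_id=iid, srna_id=srna, target_id=tname,
                    sbs=sbs, mbs=mbs,
                    srna_gain=node_at[s], gene_gain=gene_node,
                    mbs_gain=node_at[m], scenario=scenario, gene_timing=timing,
                )
            )
        aln = simulate_alignment(
            tree,
            root_seq=_decode(rng.integers(0, 4, cfg.seq_length)),
            mu=cfg.mu,
            sites=sites,
            seed=int(rng.integers(2**31)),
            gap_rate=cfg.gap_rate,
            rows=gene_clade,
        )
        write_fasta(aln, outdir / "alignments" / f"target_{tname}.fasta")
    write_profiles_tsv(gene_profiles, outdir / "gene_profiles.tsv")

    # --- ncRNA family fixture for the age analysis: other families are
    # oldest, cis-acting intermediate-to-old, trans-acting youngest
    fam_profiles, fam_groups = [], []
    deep = list(range(max(2, C - 2), C + 1))
    shallow = list(range(1, max(2, C // 2)))
    for k in range(12):
        for grp, pool in (("cis", deep), ("trans", shallow), ("other", [C])):
            fid = f"{grp}_fam{k:02d}"
            fam_profiles.append(clade_profile(fid, node_at[pool[k % len(pool)]]))
            fam_groups.append({"family": fid, "group": grp})
    write_profiles_tsv(fam_profiles, outdir / "families.tsv")

    import pandas as pd

    pd.DataFrame(fam_groups).to_csv(outdir / "family_groups.tsv", sep="\t", index=False)
    pd.DataFrame(interaction_rows).to_csv(
        outdir / "interactions.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "interaction": t.interaction_id, "srna": t.srna_id,
                "target": t.target_id, "srna_gain": t.srna_gain,
                "gene_gain": t.gene_gain, "mbs_gain": t.mbs_gain,
                "scenario": t.scenario, "gene_timing": t.gene_timing,
            }
            for t in truth
        ]
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)

    (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
    (outdir / "focal.txt").write_text(focal + "\n")
    (outdir / "config.json").write_text(
        json.dumps({"preset": preset, "seed": seed, "n_leaves": n_leaves,
                    "mu": cfg.mu, "rho": cfg.rho, "depth": cfg.depth},
                   indent=2) + "\n"
    )
    return FixtureDataset(outdir=outdir, tree=tree, focal_leaf=focal, truth=truth)


def _presence_states(tree: Phylogeny, gain_node: str) -> dict[str, int]:
    """Node -> 1 inside the clade of ``gain_node``, else 0."""
    inside = _nodes_under(tree, gain_node)
    return {nd.name: (1 if nd.name in inside else 0) for nd in tree.preorder()}


def _nodes_under(tree: Phylogeny, node: str) -> set[str]:
    out = set()
    stack = [node]
    while stack:
        cur = stack.pop()
        out.add(cur)
        stack.extend(tree.nodes[cur].children)
    return out
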
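"""End-to-end orchestration: from input tables to the summary artifacts.

Two entry points mirror the two halves of the analysis:

* :func:`run_family_ages` — ncRNA-family gain nodes and evolutionary
  ages by the marginal-ML-state method, per-ancestor group counts, and
  the cis-vs-trans age comparison (two-tailed Mann-Whitney).
* :func:`run_interaction_scenarios` — per-interaction reconstruction:
  sRNA/gene profiles are modeled directly; the mRNA binding-site profile
  is derived genome-by-genome from duplex energies via the ratio rule,
  then all three traits get posterior-chain gain nodes and each
  interaction a scenario and gene-timing class.

Both consume plain TSV/FASTA/newick files and write TSV tables; a
:class:`RunManifest` records inputs, thresholds, and a hash that output
tables reference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate, duplex, evoanalysis, gainloss
from .annotate import SiteInterval
from .evoanalysis import GainNodeCall, InteractionRecord
from .gainloss import GainLossModel, PhyleticProfile
from .treeio import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "RunManifest",
    "FamilyAgeResult",
    "ScenarioResult",
    "run_family_ages",
    "run_interaction_scenarios",
    "run_all",
    "load_interactions_tsv",
]


@dataclass
class RunManifest:
    inputs: dict[str, str] = field(default_factory=dict)
    theta: float = 0.7
    ratio: float = 0.9
    e_max: float = 10.0
    id_min: float = 0.30
    merge_distance: int = 10
    seed: int = 0
    stage_seconds: dict[str, float] = field(default_factory=dict)
    parameter_files: dict[str, str] = field(default_factory=dict)

    @property
    def hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in dataclasses.asdict(self).items()
             if k != "stage_seconds"},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def write(self, path: Path) -> None:
        data = dataclasses.asdict(self)
        data["hash"] = self.hash
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


@dataclass
class FamilyAgeResult:
    table: pd.DataFrame  # family, group, gain_node, age
    ancestor_counts: pd.DataFrame  # gain_node, group, n_families
    mw_u: float | None
    mw_p: float | None


@dataclass
class ScenarioResult:
    table: pd.DataFrame  # per-interaction S2-style table
    counts: dict[str, int]
    timing_counts: dict[str, int]
    records: list[InteractionRecord]
    models: dict[str, GainLossModel]


def _fit_and_posteriors(
    tree: Phylogeny, profiles: list[PhyleticProfile]
) -> tuple[GainLossModel, dict[str, gainloss.PosteriorProfile]]:
    model = gainloss.fit_rates(tree, profiles)
    X, trait_ids, _ = gainloss.profiles_to_matrix(profiles, tree)
    post, order = gainloss.posteriors_matrix(tree, X, model)
    out = {
        tid: gainloss.PosteriorProfile(
            trait_id=tid,
            posteriors={n: float(post[t, j]) for j, n in enumerate(order)},
        )
        for t, tid in enumerate(trait_ids)
    }
    return model, out


def run_family_ages(
    tree: Phylogeny,
    family_profiles: list[PhyleticProfile],
    grouping: dict[str, str],
    focal_leaf: str,
) -> FamilyAgeResult:
    """Gain node + age per ncRNA family (ML-state method) and group summary.

    ``grouping`` maps family id -> "cis" | "trans" | "other" and must
    cover every family.  The Mann-Whitney test compares cis vs trans
    ages; it is skipped (None) when either group is empty.
    """
    missing = [p.trait_id for p in family_profiles if p.trait_id not in grouping]
    if missing:
        raise ValueError(f"grouping is missing families: {missing}")
    model, posteriors = _fit_and_posteriors(tree, family_profiles)
    rows = []
    for prof in family_profiles:
        states = gainloss.marginal_ml_states(posteriors[prof.trait_id])
        if states.get(focal_leaf) != 1:
            logger.warning(
                "family %s absent in focal genome; skipped", prof.trait_id
            )
            continue
        call = evoanalysis.gain_node_by_ml(
            states, tree, focal_leaf, trait_id=prof.trait_id
        )
        rows.append(
            {
                "family": prof.trait_id,
                "group": grouping[prof.trait_id],
                "gain_node": call.gain_node,
                "age": call.age,
            }
        )
    table = pd.DataFrame(rows)
    counts = (
        table.groupby(["gain_node", "group"]).size().rename("n_families").reset_index()
        if len(table)
        else pd.DataFrame(columns=["gain_node", "group", "n_families"])
    )
    cis = table.loc[table.group == "cis", "age"]
    trans = table.loc[table.group == "trans", "age"]
    if len(cis) and len(trans) and len(table) > 1:
        u, p = evoanalysis.mann_whitney_two_tailed(cis, trans)
    else:
        u = p = None
    return FamilyAgeResult(table=table, ancestor_counts=counts, mw_u=u, mw_p=p)


def load_interactions_tsv(path) -> list[InteractionRecord]:
    """Interaction table with 1-based inclusive site coordinates."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(
            InteractionRecord(
                srna_id=row["srna"],
                target_id=row["target"],
                sbs=SiteInterval(row["srna"], int(row["sbs_start"]) - 1,
                                 int(row["sbs_end"])),
                mbs=SiteInterval(row["target"], int(row["mbs_start"]) - 1,
                                 int(row["mbs_end"]), str(row.get("strand", "+"))),
            )
        )
    return records


def _mbs_profile_for(
    rec: InteractionRecord,
    tree: Phylogeny,
    focal_leaf: str,
    srna_states: dict[str, dict[str, int]],
    gene_states: dict[str, dict[str, int]],
    srna_msas: dict[str, dict[str, str]],
    target_msas: dict[str, dict[str, str]],
    ratio: float,
    params: duplex.DuplexParams,
    energy_cache: dict,
) -> tuple[PhyleticProfile, float]:
    """Duplex-energy presence profile for one interaction's mRNA site.

    For each genome with the target gene: extract its aligned site
    (5-nt pads), pair it against that genome's own sRNA site — or the
    clade consensus site when the genome lacks the sRNA — and apply the
    ratio rule against the reference (focal-genome) energy.
    """
    srna_msa = srna_msas[rec.srna_id]
    tgt_msa = target_msas[rec.target_id]
    sbs_x = annotate.map_site_columns(srna_msa, focal_leaf, rec.sbs)
    mbs_x = annotate.map_site_columns(tgt_msa, focal_leaf, rec.mbs)

    # consensus sRNA site (padded columns) for genomes lacking the sRNA
    cols = [i for i, c in enumerate(srna_msa[focal_leaf]) if c != "-"]
    lo = cols[max(0, rec.sbs.start - annotate.SITE_PAD)]
    hi = cols[min(len(cols), rec.sbs.end + annotate.SITE_PAD) - 1] + 1
    consensus_sbs = annotate.consensus_site(
        [srna_msa[g][lo:hi] for g in sorted(srna_msa)]
    ).replace("-", "")

    def energy(a: str, b: str):
        key = (a, b)
        if key not in energy_cache:
            energy_cache[key] = duplex.duplex_energy(a, b, params).dg
        return energy_cache[key]

    ref_site, ref_gap = mbs_x.rows[focal_leaf]
    ref_sbs, _ = sbs_x.rows[focal_leaf]
    if ref_gap:
        raise ValueError(
            f"reference genome has a gap in the site of {rec.interaction_id}"
        )
    dg_ref = energy(ref_sbs, ref_site)
    if isinstance(dg_ref, duplex.NoDuplex) or dg_ref >= 0:
        raise ValueError(
            f"reference interaction {rec.interaction_id} is not stabilizing"
        )

    states: dict[str, int] = {}
    gstates = gene_states[rec.target_id]
    sstates = srna_states[rec.srna_id]
    for genome in tree.leaves():
        if gstates.get(genome) != 1 or genome not in mbs_x.rows:
            states[genome] = 0
            continue
        site_seq, gap_flag = mbs_x.rows[genome]
        if sstates.get(genome) == 1 and genome in sbs_x.rows:
            sbs_seq = sbs_x.rows[genome][0]
        else:
            sbs_seq = consensus_sbs
        dg = energy(sbs_seq, site_seq) if site_seq else duplex.NO_DUPLEX
        states[genome] = duplex.mbs_call(
            dg, dg_ref, ratio=ratio, gap_flag=gap_flag,
            ortholog_present=True,
        )
    return (
        PhyleticProfile(trait_id=rec.interaction_id, states=states),
        float(dg_ref),
    )


def run_interaction_scenarios(
    tree: Phylogeny,
    interactions: list[InteractionRecord],
    srna_profiles: list[PhyleticProfile],
    gene_profiles: list[PhyleticProfile],
    srna_msas: dict[str, dict[str, str]],
    target_msas: dict[str, dict[str, str]],
    focal_leaf: str,
    theta: float = 0.7,
    ratio: float = 0.9,
    merge_distance: int = 10,
    params: duplex.DuplexParams | None = None,
) -> ScenarioResult:
    """Classify every interaction's appearance-order scenario.

    Near-duplicate records of the same (sRNA, target) pair are merged
    first (< ``merge_distance`` nt apart on both molecules).  Gain nodes
    use the posterior-chain rule at ``theta``; site presence uses the
    duplex-energy ratio rule at ``ratio``.
    """
    if params is None:
        params = duplex.default_params()

    by_pair: dict[tuple[str, str], list[InteractionRecord]] = {}
    for rec in interactions:
        by_pair.setdefault((rec.srna_id, rec.target_id), []).append(rec)
    merged: list[InteractionRecord] = []
    for recs in by_pair.values():
        merged.extend(
            annotate.distinct_interactions(recs, min_separation=merge_distance)
        )

    srna_model, srna_post = _fit_and_posteriors(tree, srna_profiles)
    gene_model, gene_post = _fit_and_posteriors(tree, gene_profiles)
    srna_states = {p.trait_id: p.states for p in srna_profiles}
    gene_states = {p.trait_id: p.states for p in gene_profiles}

    energy_cache: dict = {}
    mbs_profiles = []
    dg_refs = {}
    for rec in merged:
        prof, dg_ref = _mbs_profile_for(
            rec, tree, focal_leaf, srna_states, gene_states,
            srna_msas, target_msas, ratio, params, energy_cache,
        )
        mbs_profiles.append(prof)
        dg_refs[rec.interaction_id] = dg_ref
    mbs_model, mbs_post = _fit_and_posteriors(tree, mbs_profiles)

    srna_calls: dict[str, GainNodeCall] = {
        sid: evoanalysis.gain_node_by_posterior(srna_post[sid], tree, focal_leaf, theta)
        for sid in {r.srna_id for r in merged}
    }
    gene_calls: dict[str, GainNodeCall] = {
        tid: evoanalysis.gain_node_by_posterior(gene_post[tid], tree, focal_leaf, theta)
        for tid in {r.target_id for r in merged}
    }

    rows = []
    for rec, mprof in zip(merged, mbs_profiles):
        rec.dg_ref = dg_refs[rec.interaction_id]
        rec.mbs_profile = dict(mprof.states)
        rec.srna_call = srna_calls[rec.srna_id]
        rec.gene_call = gene_calls[rec.target_id]
        rec.mbs_call = evoanalysis.gain_node_by_posterior(
            mbs_post[rec.interaction_id], tree, focal_leaf, theta
        )
        # a site cannot predate its host gene: a posterior chain that walks
        # past the gene's own gain node is clamped to it
        if rec.mbs_call.age > rec.gene_call.age:
            logger.warning(
                "%s: site chain reached %s above the gene gain %s; clamped",
                rec.interaction_id, rec.mbs_call.gain_node,
                rec.gene_call.gain_node,
            )
            rec.mbs_call = GainNodeCall(
                trait_id=rec.interaction_id,
                gain_node=rec.gene_call.gain_node,
                age=rec.gene_call.age,
                posterior_at_gain=mbs_post[rec.interaction_id][
                    rec.gene_call.gain_node
                ],
                method="posterior_chain",
                focal_leaf=focal_leaf,
            )
        rec.scenario, rec.interaction_age = evoanalysis.classify_scenario(
            rec.srna_call, rec.mbs_call
        )
        rec.gene_timing = evoanalysis.classify_gene_timing(
            rec.gene_call, rec.mbs_call
        )
        rows.append(
            {
                "interaction": rec.interaction_id,
                "srna": rec.srna_id,
                "target": rec.target_id,
                "dg_ref": rec.dg_ref,
                "srna_gain": rec.srna_call.gain_node,
                "srna_age": rec.srna_call.age,
                "gene_gain": rec.gene_call.gain_node,
                "gene_age": rec.gene_call.age,
                "mbs_gain": rec.mbs_call.gain_node,
                "mbs_age": rec.mbs_call.age,
                "interaction_age": rec.interaction_age,
                "scenario": rec.scenario.value,
                "gene_timing": rec.gene_timing.value,
            }
        )
    table = pd.DataFrame(rows)
    counts = {s.value: 0 for s in evoanalysis.Scenario}
    timing = {t.value: 0 for t in evoanalysis.GeneTiming}
    for rec in merged:
        counts[rec.scenario.value] += 1
        timing[rec.gene_timing.value] += 1
    return ScenarioResult(
        table=table, counts=counts, timing_counts=timing, records=merged,
        models={"srna": srna_model, "gene": gene_model, "mbs": mbs_model},
    )


def run_all(
    fixture_dir: str | Path,
    out_dir: str | Path,
    theta: float = 0.7,
    ratio: float = 0.9,
    merge_distance: int = 10,
    seed: int = 0,
) -> tuple[FamilyAgeResult, ScenarioResult, RunManifest]:
    """Run both analyses on a fixture-format input directory.

    Reads tree.nwk, focal.txt, families.tsv + family_groups.tsv,
    srna_profiles.tsv, gene_profiles.tsv, interactions.tsv and the
    alignments/ directory; writes family_ages.tsv, ancestor_counts.tsv,
    interaction_scenarios.tsv, scenario_counts.tsv and manifest.json.
    """
    from .treeio import parse_newick

    fixture_dir = Path(fixture_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        inputs={"fixture": str(fixture_dir)},
        theta=theta, ratio=ratio, merge_distance=merge_distance, seed=seed,
    )

    tree = parse_newick((fixture_dir / "tree.nwk").read_text())
    focal = (fixture_dir / "focal.txt").read_text().strip()

    t0 = time.perf_counter()
    fam_profiles = gainloss.read_profiles_tsv(fixture_dir / "families.tsv")
    groups = pd.read_csv(fixture_dir / "family_groups.tsv", sep="\t")
    grouping = dict(zip(groups["family"], groups["group"]))
    fam = run_family_ages(tree, fam_profiles, grouping, focal)
    manifest.stage_seconds["family_ages"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    interactions = load_interactions_tsv(fixture_dir / "interactions.tsv")
    srna_profiles = gainloss.read_profiles_tsv(fixture_dir / "srna_profiles.tsv")
    gene_profiles = gainloss.read_profiles_tsv(fixture_dir / "gene_profiles.tsv")
    srna_msas = {
        p.stem.removeprefix("srna_"): annotate.read_fasta_alignment(p)
        for p in sorted((fixture_dir / "alignments").glob("srna_*.fasta"))
    }
    target_msas = {
        p.stem.removeprefix("target_"): annotate.read_fasta_alignment(p)
        for p in sorted((fixture_dir / "alignments").glob("target_*.fasta"))
    }
    scen = run_interaction_scenarios(
        tree, interactions, srna_profiles, gene_profiles,
        srna_msas, target_msas, focal,
        theta=theta, ratio=ratio, merge_distance=merge_distance,
    )
    manifest.stage_seconds["interaction_scenarios"] = time.perf_counter() - t0

    header = f"# manifest_hash: {manifest.hash}\n# coordinates: 1-based inclusive\n"
    for name, df in (
        ("family_ages.tsv", fam.table),
        ("ancestor_counts.tsv", fam.ancestor_counts),
        ("interaction_scenarios.tsv", scen.table),
    ):
        with open(out_dir / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
    counts_df = pd.DataFrame(
        [{"class": k, "count": v} for k, v in
         list(scen.counts.items()) + list(scen.timing_counts.items())]
    )
    with open(out_dir / "scenario_counts.tsv", "w") as fh:
        fh.write(header)
        counts_df.to_csv(fh, sep="\t", index=False)
    manifest.write(out_dir / "manifest.json")
    return fam, scen, manifest
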
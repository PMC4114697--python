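import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from srnaevo import evoanalysis as ev
from srnaevo.annotate import SiteInterval
from srnaevo.evoanalysis import GainNodeCall, GeneTiming, Scenario
from srnaevo.gainloss import PosteriorProfile
from srnaevo.treeio import parse_newick

# focal leaf E under a 5-deep ancestor chain
CHAIN_TREE = parse_newick(
    "(((((E:0.1,F:0.1)n1:0.1,G:0.2)n2:0.1,H:0.3)n3:0.1,I:0.4)n4:0.1,J:0.5)n5:0;"
)


def post_profile(parent_to_root, leaf_val=1.0, trait="t"):
    vals = dict(zip(["n1", "n2", "n3", "n4", "n5"], parent_to_root))
    vals.update({lf: 0.0 for lf in "FGHIJ"})
    vals["E"] = leaf_val
    return PosteriorProfile(trait, vals)


class TestGainNodeByPosterior:
    def test_first_subthreshold_node_stops_the_walk(self):
        post = post_profile([0.95, 0.8, 0.71, 0.65, 0.9])
        call = ev.gain_node_by_posterior(post, CHAIN_TREE, "E", theta=0.7)
        assert call.gain_node == "n3"  # 0.65 breaks the chain despite 0.9 beyond
        assert call.age == pytest.approx(0.3)

    def test_subthreshold_parent_means_lineage_specific(self):
        post = post_profile([0.69, 0.9, 0.9, 0.9, 0.9])
        call = ev.gain_node_by_posterior(post, CHAIN_TREE, "E", theta=0.7)
        assert call.gain_node == "E"
        assert call.age == 0.0

    def test_fully_confident_chain_reaches_root(self):
        post = post_profile([0.9, 0.9, 0.9, 0.9, 0.9])
        call = ev.gain_node_by_posterior(post, CHAIN_TREE, "E", theta=0.7)
        assert call.gain_node == "n5"

    def test_threshold_boundary_inclusive(self):
        post = post_profile([0.7, 0.6, 0.9, 0.9, 0.9])
        call = ev.gain_node_by_posterior(post, CHAIN_TREE, "E", theta=0.7)
        assert call.gain_node == "n1"

    def test_focal_absent_rejected(self):
        post = post_profile([0.9] * 5, leaf_val=0.0)
        with pytest.raises(ValueError, match="not observed present"):
            ev.gain_node_by_posterior(post, CHAIN_TREE, "E")

    def test_threshold_monotonicity_of_age(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            post = post_profile(rng.uniform(0.5, 1.0, 5))
            ages = {
                th: ev.gain_node_by_posterior(post, CHAIN_TREE, "E", th).age
                for th in (0.7, 0.8, 0.9)
            }
            assert ages[0.9] <= ages[0.8] <= ages[0.7]


class TestGainNodeByML:
    def test_state_chain(self):
        states = {"E": 1, "n1": 1, "n2": 1, "n3": 0, "n4": 1, "n5": 1}
        call = ev.gain_node_by_ml(states, CHAIN_TREE, "E")
        assert call.gain_node == "n2"

    def test_absent_parent_gives_leaf(self):
        states = {"E": 1, "n1": 0, "n2": 1, "n3": 1, "n4": 1, "n5": 1}
        assert ev.gain_node_by_ml(states, CHAIN_TREE, "E").gain_node == "E"

    def test_all_present_gives_root(self):
        states = {n: 1 for n in CHAIN_TREE.nodes}
        assert ev.gain_node_by_ml(states, CHAIN_TREE, "E").gain_node == "n5"


def call_at(node, trait="x", focal="E"):
    return GainNodeCall(
        trait_id=trait,
        gain_node=node,
        age=CHAIN_TREE.patristic_distance(node, focal),
        posterior_at_gain=1.0,
        method="posterior_chain",
        focal_leaf=focal,
    )


class TestScenarioClassification:
    def test_co_gained(self):
        scen, age = ev.classify_scenario(call_at("n2"), call_at("n2"))
        assert scen is Scenario.CO_GAINED
        assert age == pytest.approx(0.2)

    def test_mbs_precedes(self):
        scen, age = ev.classify_scenario(call_at("n1"), call_at("n4"))
        assert scen is Scenario.MBS_PRECEDES
        assert age == pytest.approx(0.1)  # interaction age = younger gain

    def test_mbs_succeeds(self):
        scen, age = ev.classify_scenario(call_at("n4"), call_at("n1"))
        assert scen is Scenario.MBS_SUCCEEDS
        assert age == pytest.approx(0.1)

    def test_interaction_age_bounded_by_both(self):
        rng = np.random.default_rng(3)
        nodes = ["E", "n1", "n2", "n3", "n4", "n5"]
        for _ in range(30):
            a, b = rng.choice(nodes, 2)
            _, age = ev.classify_scenario(call_at(a), call_at(b))
            assert age <= call_at(a).age and age <= call_at(b).age

    def test_different_focal_leaves_rejected(self):
        other = GainNodeCall("y", "n1", 0.1, 1.0, "posterior_chain", "F")
        with pytest.raises(ValueError, match="not comparable"):
            ev.classify_scenario(call_at("n1"), other)

    def test_gene_timing(self):
        assert ev.classify_gene_timing(call_at("n3"), call_at("n3")) \
            is GeneTiming.MBS_WITH_GENE
        assert ev.classify_gene_timing(call_at("n3"), call_at("n1")) \
            is GeneTiming.MBS_AFTER_GENE
        with pytest.raises(ev.ConsistencyError):
            ev.classify_gene_timing(call_at("n1"), call_at("n3"))


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p = ev.mann_whitney_two_tailed([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_small_example_exact(self):
        u, p = ev.mann_whitney_two_tailed([1, 2], [3, 4])
        assert u == 4
        assert p == pytest.approx(2 / 6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ev.mann_whitney_two_tailed([], [1.0])

    def test_exact_agrees_with_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            xs = rng.normal(size=6)
            ys = rng.normal(0.8, 1, size=7)
            _, p = ev.mann_whitney_two_tailed(xs, ys, method="exact")
            p_ref = mannwhitneyu(xs, ys, method="exact",
                                 alternative="two-sided").pvalue
            assert p == pytest.approx(p_ref, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(8, 8), (7, 9), (6, 10), (10, 6), (12, 4)])
    def test_approximation_close_to_exact(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(20):
            xs = rng.normal(size=n1)
            ys = rng.normal(rng.uniform(-1.5, 1.5), 1, size=n2)
            _, pe = ev.mann_whitney_two_tailed(xs, ys, method="exact")
            _, pa = ev.mann_whitney_two_tailed(xs, ys, method="normal")
            assert abs(pe - pa) < 0.01


class TestNetworkTable:
    def _record(self, srna, target, scen, age=0.1):
        rec = ev.InteractionRecord(
            srna_id=srna, target_id=target,
            sbs=SiteInterval(srna, 0, 10), mbs=SiteInterval(target, 0, 10),
        )
        rec.srna_call = call_at("n2", srna)
        rec.gene_call = call_at("n3", target)
        rec.scenario = scen
        rec.interaction_age = age
        return rec

    def test_counts_one_per_class(self):
        recs = [
            self._record("s1", "t1", Scenario.CO_GAINED),
            self._record("s1", "t2", Scenario.MBS_PRECEDES),
            self._record("s2", "t3", Scenario.MBS_SUCCEEDS),
        ]
        nodes, edges, counts = ev.build_network_table(recs)
        assert counts == {"CO_GAINED": 1, "MBS_PRECEDES": 1, "MBS_SUCCEEDS": 1}
        assert len(edges) == 3
        assert len(nodes) == 5  # 2 sRNAs + 3 targets

    def test_empty_input(self):
        nodes, edges, counts = ev.build_network_table([])
        assert len(nodes) == 0 and len(edges) == 0
        assert sum(counts.values()) == 0

    def test_counts_partition_records(self, paper_run):
        scen = paper_run["scen"]
        assert sum(scen.counts.values()) == len(scen.records)
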
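"""Structure learning: CI-test calibration, PC skeleton/orientation against
d-separation oracles, ensemble voting semantics, and graph distances
against brute-force enumeration."""

import itertools

import numpy as np
import pandas as pd
import networkx as nx
import pytest

from ehrcf.structure import (
    FisherZTest, GSquareTest, LogisticLRTest, DSeparationOracle,
    pc_skeleton, orient_edges, ensemble_pc, select_outcome_parents,
    shd, ged, EdgeVoteGraph, TieredPC, EnsembleTieredPC, dag_to_cpdag,
)


# ---------------------------------------------------------------------------
# CI tests
# ---------------------------------------------------------------------------

class TestFisherZ:
    def test_identical_columns_dependent(self, rng):
        x = rng.normal(size=500)
        t = FisherZTest(pd.DataFrame({"x": x, "y": x}), alpha=0.05)
        _, p, indep = t("x", "y")
        assert p < 1e-10 and not indep

    def test_chain_conditional_independence(self, rng):
        n = 4000
        x = rng.normal(size=n)
        z = x + rng.normal(size=n)
        y = z + rng.normal(size=n)
        t = FisherZTest(pd.DataFrame({"x": x, "y": y, "z": z}), alpha=0.05)
        assert not t("x", "y")[2]
        assert t("x", "y", ["z"])[2]

    def test_type_one_error_near_alpha(self, rng):
        """Marginal test on i.i.d. normals rejects at ~alpha."""
        alpha, reps, n = 0.05, 400, 300
        rejects = 0
        for _ in range(reps):
            d = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
            rejects += not FisherZTest(d, alpha)("a", "b")[2]
        rate = rejects / reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_degenerate_column_independent_by_convention(self, rng):
        d = pd.DataFrame({"a": np.ones(100), "b": rng.normal(size=100)})
        stat, p, indep = FisherZTest(d, 0.05)("a", "b")
        assert indep and p == 1.0


class TestOtherTests:
    def test_g_square_detects_binary_association(self, rng):
        x = rng.integers(0, 2, 2000)
        y = np.where(rng.random(2000) < 0.8, x, 1 - x)
        z = rng.integers(0, 2, 2000)
        d = pd.DataFrame({"x": x, "y": y, "z": z})
        t = GSquareTest(d, 0.05)
        assert not t("x", "y")[2]
        assert t("x", "z")[2]

    def test_logistic_lr_binary_vs_continuous(self, rng):
        n = 1500
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * x))).astype(int)
        w = rng.normal(size=n)
        d = pd.DataFrame({"x": x, "y": y, "w": w})
        t = LogisticLRTest(d, 0.05)
        assert not t("y", "x")[2]
        assert t("y", "w")[2]


# ---------------------------------------------------------------------------
# PC with an exact oracle
# ---------------------------------------------------------------------------

def _chain_dag():
    g = nx.DiGraph()
    g.add_edges_from([("x", "z"), ("z", "y")])
    return g


def _collider_dag():
    g = nx.DiGraph()
    g.add_edges_from([("x", "z"), ("y", "z")])
    return g


class TestSkeleton:
    def test_independent_columns_empty_skeleton(self, rng):
        d = pd.DataFrame(rng.normal(size=(3000, 3)), columns=list("abc"))
        skel = pc_skeleton(d, alpha=0.01)
        assert skel.undirected == set()

    def test_chain_skeleton_and_sepset(self):
        dag = _chain_dag()
        skel = pc_skeleton(None, tester=DSeparationOracle(dag),
                           nodes=["x", "y", "z"])
        assert skel.undirected == {frozenset(("x", "z")),
                                   frozenset(("z", "y"))}
        assert skel.sepsets[frozenset(("x", "y"))] == ("z",)

    def test_collider_skeleton_and_empty_sepset(self):
        dag = _collider_dag()
        skel = pc_skeleton(None, tester=DSeparationOracle(dag),
                           nodes=["x", "y", "z"])
        assert skel.undirected == {frozenset(("x", "z")),
                                   frozenset(("y", "z"))}
        assert skel.sepsets[frozenset(("x", "y"))] == ()


class TestOrientation:
    def test_collider_is_oriented(self):
        dag = _collider_dag()
        g = orient_edges(pc_skeleton(None, tester=DSeparationOracle(dag),
                                     nodes=["x", "y", "z"]))
        assert g.directed == {("x", "z"), ("y", "z")}
        assert g.undirected == set()

    def test_chain_stays_unoriented_within_tier(self):
        dag = _chain_dag()
        g = orient_edges(pc_skeleton(None, tester=DSeparationOracle(dag),
                                     nodes=["x", "y", "z"]))
        assert g.directed == set()
        assert len(g.undirected) == 2  # Markov-equivalent chain

    def test_tier_crossing_edge_forced_low_to_high(self):
        dag = _chain_dag()
        tiers = {"x": 1, "z": 2, "y": 2}
        skel = pc_skeleton(None, tester=DSeparationOracle(dag),
                           nodes=["x", "y", "z"], tiers=tiers)
        g = orient_edges(skel)
        assert ("x", "z") in g.directed
        # orientation then propagates down the chain by Meek rule 1
        assert ("z", "y") in g.directed

    def test_no_orientation_into_tier1(self):
        dag = nx.DiGraph([("a", "b")])
        tiers = {"a": 1, "b": 2}
        g = orient_edges(pc_skeleton(None, tester=DSeparationOracle(dag),
                                     nodes=["a", "b"], tiers=tiers))
        assert g.directed == {("a", "b")}
        assert not g.tier_violations()


def _random_dag(n, p, rng):
    nodes = [f"v{i}" for i in range(n)]
    order = rng.permutation(n)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            a, b = (i, j) if order[i] < order[j] else (j, i)
            g.add_edge(nodes[a], nodes[b])
    return g


def _vstructs(g):
    out = set()
    for k in g.nodes:
        for i, j in itertools.combinations(sorted(g.predecessors(k)), 2):
            if not (g.has_edge(i, j) or g.has_edge(j, i)):
                out.add((i, k, j))
    return out


def brute_force_cpdag(dag):
    """Union of orientations over every DAG in the Markov equivalence class
    (same skeleton, same v-structures), by exhaustive orientation."""
    skel = [tuple(sorted(e)) for e in dag.to_undirected().edges]
    vs = _vstructs(dag)
    members = []
    for dirs in itertools.product([0, 1], repeat=len(skel)):
        h = nx.DiGraph()
        h.add_nodes_from(dag.nodes)
        for (u, v), d in zip(skel, dirs):
            h.add_edge(*((u, v) if d == 0 else (v, u)))
        if nx.is_directed_acyclic_graph(h) and _vstructs(h) == vs:
            members.append(h)
    directed, undirected = set(), set()
    for u, v in skel:
        if len({m.has_edge(u, v) for m in members}) == 1:
            directed.add((u, v) if members[0].has_edge(u, v) else (v, u))
        else:
            undirected.add(frozenset((u, v)))
    return directed, undirected


class TestOraclePC:
    def test_recovers_cpdag_of_random_dags(self, rng):
        """Skeleton + orientation with a perfect CI oracle must equal the
        brute-force CPDAG for every small random DAG."""
        for _ in range(40):
            n = int(rng.integers(2, 8))
            dag = _random_dag(n, 0.45, rng)
            skel = pc_skeleton(None, tester=DSeparationOracle(dag),
                               nodes=sorted(dag.nodes))
            g = orient_edges(skel)
            want_d, want_u = brute_force_cpdag(dag)
            assert set(g.directed) == want_d
            assert set(g.undirected) == want_u

    def test_dag_to_cpdag_helper_agrees(self, rng):
        dag = _random_dag(5, 0.5, rng)
        g = dag_to_cpdag(dag)
        want_d, want_u = brute_force_cpdag(dag)
        assert set(g.directed) == want_d and set(g.undirected) == want_u


# ---------------------------------------------------------------------------
# ensemble voting
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def chain_data():
    rng = np.random.default_rng(0)
    n = 3000
    x = rng.normal(size=n)
    z = 2.0 * x + 0.3 * rng.normal(size=n)
    y = 2.0 * z + 0.3 * rng.normal(size=n)
    return pd.DataFrame({"x": x, "z": z, "y": y})


class TestEnsemble:
    def test_strong_signal_chain_gets_full_votes(self, chain_data):
        tiers = {"x": 1, "z": 2, "y": 3}
        votes = ensemble_pc(chain_data, tiers, K=10, seed=4)
        assert votes.votes.get(("x", "z")) == 10
        assert votes.votes.get(("z", "y")) == 10
        assert votes.consensus().directed == {("x", "z"), ("z", "y")}

    def test_vote_threshold_is_strict_majority(self):
        votes = EdgeVoteGraph(nodes=["a", "b", "c"],
                              tiers={"a": 1, "b": 2, "c": 3},
                              votes={("a", "b"): 5, ("a", "c"): 6}, K=10,
                              vote_threshold=0.5)
        cons = votes.consensus()
        assert ("a", "c") in cons.directed
        assert ("a", "b") not in cons.directed

    def test_row_order_invariance(self, chain_data):
        tiers = {"x": 1, "z": 2, "y": 3}
        v1 = ensemble_pc(chain_data, tiers, K=5, seed=9)
        shuffled = chain_data.sample(frac=1, random_state=17)
        v2 = ensemble_pc(shuffled, tiers, K=5, seed=9)
        assert v1.votes == v2.votes

    def test_pure_noise_consensus_empty(self, rng):
        d = pd.DataFrame(rng.normal(size=(2000, 4)), columns=list("abcd"))
        votes = ensemble_pc(d, {c: 1 for c in "abcd"}, K=10, seed=2)
        assert votes.consensus().directed == set()

    def test_outputs_respect_tiers(self, chain_data):
        tiers = {"x": 1, "z": 2, "y": 3}
        votes = ensemble_pc(chain_data, tiers, K=5, seed=1)
        assert votes.consensus().tier_violations() == []

    def test_estimator_facade(self, chain_data):
        est = EnsembleTieredPC(tiers={"x": 1, "z": 2, "y": 3}, K=5, seed=3)
        est.fit(chain_data)
        assert ("z", "y") in est.consensus_.directed
        single = TieredPC(tiers={"x": 1, "z": 2, "y": 3}).fit(chain_data)
        assert ("z", "y") in single.graph_.directed


class TestOutcomeParents:
    def _votes(self, table):
        return EdgeVoteGraph(nodes=["a", "b", "y"],
                             tiers={"a": 2, "b": 2, "y": 3},
                             votes=table, K=10)

    def test_selection_at_default_threshold(self):
        v = self._votes({("a", "y"): 10, ("b", "y"): 7, ("a", "b"): 10})
        assert select_outcome_parents(v, "y") == [("a", 10)]

    def test_lower_threshold_recovers_weaker_edge(self):
        v = self._votes({("a", "y"): 10, ("b", "y"): 7})
        assert select_outcome_parents(v, "y", min_votes=7) == [
            ("a", 10), ("b", 7)]

    def test_empty_votes(self):
        assert select_outcome_parents(self._votes({}), "y") == []

    def test_non_outcome_node_rejected(self):
        with pytest.raises(ValueError):
            select_outcome_parents(self._votes({}), "a")


# ---------------------------------------------------------------------------
# graph distances
# ---------------------------------------------------------------------------

def _pair_status(g, u, v):
    f, b = g.has_edge(u, v), g.has_edge(v, u)
    return "both" if (f and b) else "fwd" if f else "bwd" if b else "none"


def brute_force_ged(g1, g2):
    """Exhaustive minimal edit cost over all partial injective node maps."""
    n1, n2 = sorted(g1.nodes), sorted(g2.nodes)
    best = None
    for r in range(len(n1) + 1):
        for keep in itertools.combinations(n1, r):
            for target in itertools.permutations(n2, r):
                mp = dict(zip(keep, target))
                used = set(mp.values())
                cost = (len(n1) - r) + (len(n2) - r)
                cost += sum(a != b for a, b in mp.items())
                for a, b in itertools.combinations(sorted(mp), 2):
                    if _pair_status(g1, a, b) != _pair_status(g2, mp[a], mp[b]):
                        cost += 1
                for u, v in itertools.combinations(n1, 2):
                    if (u not in mp or v not in mp) \
                            and _pair_status(g1, u, v) != "none":
                        cost += 1
                for u, v in itertools.combinations(n2, 2):
                    if (u not in used or v not in used) \
                            and _pair_status(g2, u, v) != "none":
                        cost += 1
                best = cost if best is None else min(best, cost)
    return best


class TestDistances:
    def test_identical_graphs_zero(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        assert shd(g, g) == 0
        assert ged(g, g) == 0

    def test_reversed_edge_counts_one(self):
        g1 = nx.DiGraph([("a", "b")])
        g2 = nx.DiGraph([("b", "a")])
        g2.add_nodes_from(g1.nodes)
        g1.add_nodes_from(g2.nodes)
        assert shd(g1, g2) == 1
        assert ged(g1, g2) == 1

    def test_extra_edge_counts_one(self):
        g1 = nx.DiGraph([("a", "b")])
        g2 = nx.DiGraph([("a", "b"), ("b", "c")])
        g1.add_nodes_from(g2.nodes)
        assert ged(g1, g2) == 1

    def test_shd_requires_same_node_set(self):
        with pytest.raises(ValueError):
            shd(nx.DiGraph([("a", "b")]), nx.DiGraph([("a", "c")]))

    def test_random_pairs_match_brute_force_and_shd_bound(self, rng):
        nodes = ["a", "b", "c", "d"]
        for _ in range(60):
            g1 = _random_digraph(nodes, 0.4, rng)
            g2 = _random_digraph(nodes, 0.4, rng)
            d_ged, d_shd = ged(g1, g2), shd(g1, g2)
            assert d_ged == brute_force_ged(g1, g2)
            assert d_ged <= d_shd

    def test_disjoint_labels_cost_nodes_plus_edges(self):
        g1 = nx.DiGraph([("a", "b")])
        g2 = nx.DiGraph([("x", "y")])
        # map a->x, b->y: 2 label substitutions, statuses agree
        assert ged(g1, g2) == 2


def _random_digraph(nodes, p, rng):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u, v in itertools.permutations(nodes, 2):
        if rng.random() < p:
            g.add_edge(u, v)
    return g
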
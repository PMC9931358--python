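"""Tiered causal-structure learning with the PC algorithm.

The comorbidity network is modelled as a directed acyclic graph over
phenotype features plus the outcome node, learned under *tiered background
knowledge*: tier-1 chronic comorbidities may cause tier-2 comorbidities and
the tier-3 outcome but not the reverse, and the outcome causes nothing.
Learning is constraint-based:

1. **Skeleton** — order-independent ("stable") PC adjacency search with a
   Fisher-z partial-correlation test by default (a G² test for all-binary
   data and a logistic likelihood-ratio test for a binary column against
   continuous features are available, as is an exact d-separation oracle
   for algorithm verification).
2. **Orientation** — tier-crossing edges run low-tier → high-tier;
   unshielded colliders are oriented from separating sets; Meek rules 1–4
   propagate orientations to closure. Conflicting demands leave an edge
   unoriented and are logged rather than silently overwritten.
3. **Stability ensemble** — the algorithm is re-run on K subsamples that
   each withhold a fraction of subjects; a directed edge enters the
   consensus graph when it appears in more than ``vote_threshold * K``
   runs (majority vote by default).

Graphs are compared by structural Hamming distance (SHD: the number of
node pairs whose edge status — absent / → / ← / both — differs) and by a
unit-cost graph edit distance (GED: minimal node + edge-status edits over
an optimal node correspondence; with identical labelled node sets GED ≤
SHD because the identity correspondence realises the SHD).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "TieredGraph", "EdgeVoteGraph", "FisherZTest", "GSquareTest",
    "LogisticLRTest", "DSeparationOracle", "fisher_z_test", "pc_skeleton",
    "orient_edges", "ensemble_pc", "select_outcome_parents", "shd", "ged",
    "TieredPC", "EnsembleTieredPC", "dag_to_cpdag",
]


# ---------------------------------------------------------------------------
# graph containers
# ---------------------------------------------------------------------------

@dataclass
class TieredGraph:
    """Mixed graph over tier-tagged nodes.

    ``directed`` holds oriented edges ``(u, v)`` meaning u → v;
    ``undirected`` holds unoriented skeleton edges; ``sepsets`` maps an
    unordered non-adjacent pair to the conditioning set that separated it.
    """

    nodes: list[str]
    tiers: dict[str, int]
    directed: set = field(default_factory=set)
    undirected: set = field(default_factory=set)
    sepsets: dict = field(default_factory=dict)
    conflicts: list = field(default_factory=list)

    def copy(self) -> "TieredGraph":
        return TieredGraph(list(self.nodes), dict(self.tiers),
                           set(self.directed), set(self.undirected),
                           dict(self.sepsets), list(self.conflicts))

    def adjacent(self, u: str, v: str) -> bool:
        return ((u, v) in self.directed or (v, u) in self.directed
                or frozenset((u, v)) in self.undirected)

    def neighbors(self, u: str) -> set:
        out = {v for (a, v) in self.directed if a == u}
        out |= {a for (a, v) in self.directed if v == u}
        out |= {next(iter(e - {u})) for e in self.undirected if u in e}
        return out

    def parents(self, v: str) -> set:
        return {a for (a, b) in self.directed if b == v}

    def to_networkx(self) -> nx.DiGraph:
        """Directed part only (the conventional export for a learned DAG)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        return g

    def tier_violations(self) -> list[str]:
        bad = []
        for (u, v) in self.directed:
            tu, tv = self.tiers.get(u), self.tiers.get(v)
            if tv == 1 and tu in (2, 3):
                bad.append(f"{u}->{v} enters tier 1 from tier {tu}")
            if tu == 3:
                bad.append(f"{u}->{v} leaves the tier-3 node")
        return bad

    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(self.directed)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("src\tdst\toriented\n")
            for u, v in sorted(self.directed):
                fh.write(f"{u}\t{v}\t1\n")
            for e in sorted(map(sorted, self.undirected)):
                fh.write(f"{e[0]}\t{e[1]}\t0\n")

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for v in self.nodes:
            lines.append(f'  "{v}" [tier={self.tiers.get(v, 0)}];')
        for u, v in sorted(self.directed):
            lines.append(f'  "{u}" -> "{v}";')
        for e in sorted(map(sorted, self.undirected)):
            lines.append(f'  "{e[0]}" -> "{e[1]}" [dir=none];')
        lines.append("}")
        return "\n".join(lines)


def _forbidden(tiers: dict, u: str, v: str) -> bool:
    """True when the orientation u → v violates the tier ordering."""
    tu, tv = tiers.get(u), tiers.get(v)
    if tv == 1 and tu in (2, 3):
        return True
    return tu == 3


@dataclass
class EdgeVoteGraph:
    """Directed-edge vote tallies over a K-run subsample ensemble."""

    nodes: list[str]
    tiers: dict[str, int]
    votes: dict = field(default_factory=dict)   # (u, v) -> count
    K: int = 10
    vote_threshold: float = 0.5

    def consensus(self, vote_threshold: float | None = None) -> TieredGraph:
        """Edges appearing in more than ``vote_threshold * K`` runs."""
        thr = self.vote_threshold if vote_threshold is None else vote_threshold
        cut = thr * self.K
        g = TieredGraph(list(self.nodes), dict(self.tiers))
        g.directed = {e for e, c in self.votes.items() if c > cut}
        return g

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("src\tdst\tvotes\n")
            for (u, v), c in sorted(self.votes.items()):
                fh.write(f"{u}\t{v}\t{c}\n")


# ---------------------------------------------------------------------------
# conditional-independence tests
# ---------------------------------------------------------------------------

class FisherZTest:
    """Fisher-z test of zero partial correlation.

    z = arctanh(r_{ij|S}) * sqrt(n - |S| - 3); two-sided normal p-value.
    Zero-variance columns are reported independent by convention (with a
    logged warning) — a constant feature carries no dependence information.
    """

    def __init__(self, data: pd.DataFrame, alpha: float = 0.05):
        self.alpha = alpha
        self.columns = list(data.columns)
        self._idx = {c: i for i, c in enumerate(self.columns)}
        x = data.to_numpy(dtype=float)
        self.n = x.shape[0]
        sd = x.std(axis=0)
        self.degenerate = {c for c, s in zip(self.columns, sd) if s == 0}
        if self.degenerate:
            logger.warning("zero-variance columns treated as independent: %s",
                           sorted(self.degenerate))
        with np.errstate(invalid="ignore"):
            self.corr = np.corrcoef(x, rowvar=False)
        self.corr = np.nan_to_num(self.corr, nan=0.0)
        np.fill_diagonal(self.corr, 1.0)

    def __call__(self, i: str, j: str, S=()) -> tuple[float, float, bool]:
        if i in self.degenerate or j in self.degenerate:
            return 0.0, 1.0, True
        S = [s for s in S if s not in self.degenerate]
        k = [self._idx[i], self._idx[j]] + [self._idx[s] for s in S]
        sub = self.corr[np.ix_(k, k)]
        try:
            prec = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            prec = np.linalg.pinv(sub)
        denom = np.sqrt(prec[0, 0] * prec[1, 1])
        r = 0.0 if denom == 0 else -prec[0, 1] / denom
        r = float(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        dof = self.n - len(S) - 3
        if dof <= 0:
            return 0.0, 1.0, True
        z = np.arctanh(r) * np.sqrt(dof)
        p = 2.0 * stats.norm.sf(abs(z))
        return float(z), float(p), p >= self.alpha


def fisher_z_test(data: pd.DataFrame, i: str, j: str, S=(),
                  alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-shot Fisher-z conditional-independence test on named columns."""
    return FisherZTest(data, alpha)(i, j, S)


class GSquareTest:
    """G² (log-likelihood ratio) test for discrete/binary columns."""

    def __init__(self, data: pd.DataFrame, alpha: float = 0.05):
        self.alpha = alpha
        self.data = data

    def __call__(self, i: str, j: str, S=()) -> tuple[float, float, bool]:
        df = self.data
        g2, dof = 0.0, 0
        strata = [df] if not S else [
            s for _, s in df.groupby(list(S), observed=True)]
        for stratum in strata:
            tab = pd.crosstab(stratum[i], stratum[j]).to_numpy(dtype=float)
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                continue
            expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
            mask = tab > 0
            g2 += 2.0 * (tab[mask] * np.log(tab[mask] / expected[mask])).sum()
            dof += (tab.shape[0] - 1) * (tab.shape[1] - 1)
        if dof == 0:
            return 0.0, 1.0, True
        p = float(stats.chi2.sf(g2, dof))
        return float(g2), p, p >= self.alpha


class LogisticLRTest:
    """Likelihood-ratio CI test for a binary column vs. a numeric column.

    Compares the deviance of a logistic model binary ~ S + x against
    binary ~ S. Falls back to Fisher-z when neither column is binary.
    """

    def __init__(self, data: pd.DataFrame, alpha: float = 0.05,
                 binary_columns=None):
        self.alpha = alpha
        self.data = data
        if binary_columns is None:
            binary_columns = [c for c in data.columns
                              if set(np.unique(data[c])) <= {0, 1}]
        self.binary = set(binary_columns)
        self._fisher = FisherZTest(data, alpha)

    @staticmethod
    def _loglik(y: np.ndarray, X: np.ndarray) -> float:
        import statsmodels.api as sm
        model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
        try:
            res = model.fit(disp=0, maxiter=200)
            return float(res.llf)
        except Exception:  # separation etc. — penalized fallback
            res = model.fit_regularized(disp=0, alpha=1e-4, maxiter=200)
            return float(res.llf)

    def __call__(self, i: str, j: str, S=()) -> tuple[float, float, bool]:
        if i not in self.binary and j not in self.binary:
            return self._fisher(i, j, S)
        y_col, x_col = (i, j) if i in self.binary else (j, i)
        y = self.data[y_col].to_numpy(dtype=float)
        if y.std() == 0:
            return 0.0, 1.0, True
        Z = self.data[list(S)].to_numpy(dtype=float) if S else np.empty((len(y), 0))
        x = self.data[[x_col]].to_numpy(dtype=float)
        ll_full = self._loglik(y, np.hstack([Z, x]))
        ll_null = self._loglik(y, Z)
        g = max(2.0 * (ll_full - ll_null), 0.0)
        p = float(stats.chi2.sf(g, 1))
        return float(g), p, p >= self.alpha


class DSeparationOracle:
    """Exact conditional-independence oracle on a known DAG.

    For verifying the PC implementation: reports independence exactly when
    the pair is d-separated given S in the generating graph.
    """

    def __init__(self, dag: nx.DiGraph):
        self.dag = dag

    def __call__(self, i: str, j: str, S=()) -> tuple[float, float, bool]:
        indep = nx.is_d_separator(self.dag, {i}, {j}, set(S))
        return 0.0, (1.0 if indep else 0.0), indep


_TEST_REGISTRY = {
    "fisher_z": FisherZTest,
    "g_square": GSquareTest,
    "logistic_lr": LogisticLRTest,
}


# ---------------------------------------------------------------------------
# PC: skeleton and orientation
# ---------------------------------------------------------------------------

def pc_skeleton(
    data: pd.DataFrame | None,
    alpha: float = 0.05,
    tiers: dict[str, int] | None = None,
    tester=None,
    nodes: list[str] | None = None,
    max_cond_size: int | None = None,
) -> TieredGraph:
    """Order-independent (stable) PC adjacency search.

    Starts from the complete graph (minus pairs forbidden in both
    directions by the tier ordering), and at each conditioning-set size
    ``l`` removes, simultaneously against the adjacency structure frozen at
    the start of the level, every edge (i, j) for which some
    S ⊆ adj(i)\\{j} with |S| = l renders i ⟂ j | S. Separating sets are
    recorded for the orientation phase.

    ``tester`` overrides the default Fisher-z test; pass a
    :class:`DSeparationOracle` for exact verification runs.
    """
    if nodes is None:
        if data is None:
            raise ValueError("need data or an explicit node list")
        nodes = list(data.columns)
    tiers = dict(tiers or {v: 1 for v in nodes})
    for v in nodes:
        tiers.setdefault(v, 1)
    if tester is None:
        tester = FisherZTest(data, alpha)

    g = TieredGraph(list(nodes), tiers)
    g.undirected = {
        frozenset((u, v)) for u, v in itertools.combinations(nodes, 2)
        if not (_forbidden(tiers, u, v) and _forbidden(tiers, v, u))
    }

    level = 0
    while True:
        adj_snapshot = {v: g.neighbors(v) for v in nodes}
        if max_cond_size is not None and level > max_cond_size:
            break
        any_testable = False
        to_remove = []
        for u, v in sorted(map(sorted, g.undirected)):
            separated = False
            for a, b in ((u, v), (v, u)):
                cand = sorted(adj_snapshot[a] - {b})
                if len(cand) < level:
                    continue
                any_testable = True
                for S in itertools.combinations(cand, level):
                    _, _, indep = tester(a, b, S)
                    if indep:
                        g.sepsets[frozenset((a, b))] = tuple(sorted(S))
                        to_remove.append(frozenset((a, b)))
                        separated = True
                        break
                if separated:
                    break
        for e in to_remove:
            g.undirected.discard(e)
        if not any_testable:
            break
        level += 1
    return g


def _orient(g: TieredGraph, u: str, v: str, rule: str) -> bool:
    """Direct the undirected edge {u, v} as u → v; log and skip conflicts."""
    e = frozenset((u, v))
    if (u, v) in g.directed:
        return False
    if (v, u) in g.directed:
        g.conflicts.append(f"{rule}: wanted {u}->{v} but {v}->{u} already set")
        return False
    if e not in g.undirected:
        return False
    if _forbidden(g.tiers, u, v):
        g.conflicts.append(f"{rule}: {u}->{v} forbidden by tiers")
        return False
    g.undirected.discard(e)
    g.directed.add((u, v))
    return True


def _creates_cycle(g: TieredGraph, u: str, v: str) -> bool:
    """Would adding u → v close a directed cycle?"""
    dg = g.to_networkx()
    return v in dg and u in dg and nx.has_path(dg, v, u)


def orient_edges(skeleton: TieredGraph, tiers: dict[str, int] | None = None) -> TieredGraph:
    """Orient a PC skeleton: tier knowledge, v-structures, Meek rules 1–4.

    Conflicting orientation demands (two v-structures pulling an edge both
    ways, or a rule pushing against the tier ordering) leave the edge as is
    and append a record to ``conflicts``.
    """
    g = skeleton.copy()
    if tiers:
        g.tiers = dict(tiers)

    # background knowledge: tier-crossing edges always run low -> high
    for e in sorted(map(sorted, set(g.undirected))):
        u, v = e
        fu, fv = _forbidden(g.tiers, u, v), _forbidden(g.tiers, v, u)
        if fu and not fv:
            _orient(g, v, u, "tier")
        elif fv and not fu:
            _orient(g, u, v, "tier")

    # v-structures i -> k <- j for unshielded triples with k outside sepset(i, j)
    for k in g.nodes:
        nbrs = sorted(g.neighbors(k))
        for i, j in itertools.combinations(nbrs, 2):
            if g.adjacent(i, j):
                continue
            sep = g.sepsets.get(frozenset((i, j)))
            if sep is None or k in sep:
                continue
            _orient(g, i, k, "v-structure")
            _orient(g, j, k, "v-structure")

    # Meek rules to closure
    changed = True
    while changed:
        changed = False
        for e in sorted(map(sorted, set(g.undirected))):
            a, b = e
            for a, b in ((e[0], e[1]), (e[1], e[0])):
                if frozenset((a, b)) not in g.undirected:
                    break
                # R1: c -> a, a - b, c and b non-adjacent  =>  a -> b
                if any((c, a) in g.directed and not g.adjacent(c, b)
                       for c in g.parents(a)):
                    changed |= _orient(g, a, b, "meek1")
                    continue
                # R2 (generalised acyclicity): directed path a => b forces a -> b
                if _creates_cycle(g, b, a):
                    changed |= _orient(g, a, b, "meek2")
                    continue
                # R3: a - c, a - d, c -> b, d -> b, c/d non-adjacent => a -> b
                und_nbrs = [next(iter(x - {a})) for x in g.undirected if a in x]
                pb = g.parents(b)
                hits = [c for c in und_nbrs if c in pb]
                if any(not g.adjacent(c, d)
                       for c, d in itertools.combinations(sorted(hits), 2)):
                    changed |= _orient(g, a, b, "meek3")
                    continue
                # R4: a - d, d -> c, c -> b, a adjacent c, b/d non-adjacent => a -> b
                fired = False
                for c in pb:
                    if not g.adjacent(a, c):
                        continue
                    for d in g.parents(c):
                        if frozenset((a, d)) in g.undirected and not g.adjacent(b, d):
                            changed |= _orient(g, a, b, "meek4")
                            fired = True
                            break
                    if fired:
                        break
    return g


def dag_to_cpdag(dag: nx.DiGraph, tiers: dict[str, int] | None = None) -> TieredGraph:
    """CPDAG of a known DAG via the same orientation machinery.

    Builds the skeleton and exact separating sets from the DAG itself, then
    runs :func:`orient_edges`; used to express ground truth on the scale PC
    can identify.
    """
    oracle = DSeparationOracle(dag)
    skel = pc_skeleton(None, tiers=tiers, tester=oracle, nodes=list(dag.nodes))
    return orient_edges(skel)


# ---------------------------------------------------------------------------
# subsample voting ensemble
# ---------------------------------------------------------------------------

def ensemble_pc(
    data: pd.DataFrame,
    tiers: dict[str, int],
    K: int = 10,
    holdout_fraction: float = 0.1,
    alpha: float = 0.05,
    vote_threshold: float = 0.5,
    seed: int = 0,
    test: str = "fisher_z",
    max_cond_size: int | None = None,
) -> EdgeVoteGraph:
    """Vote directed edges over K runs that each withhold a subject fold.

    Subjects are randomly partitioned into K near-equal folds covering
    ``holdout_fraction`` of the data each; run k learns the graph on all
    subjects except fold k (a 90% sub-dataset at the defaults). Only
    directed edges vote — edges left unoriented within a tier carry no
    directional evidence. Deterministic given ``seed``; the tally is
    invariant to the row order of ``data``.
    """
    n = len(data)
    fold_size = int(n * holdout_fraction)
    if fold_size < 1 or fold_size * K > n:
        raise ValueError("K * holdout_fraction exceeds the data")
    if n - fold_size <= 50:
        raise ValueError("each sub-dataset must keep more than 50 rows")

    data = data.sort_index()  # row-order invariance
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)

    votes: dict[tuple[str, str], int] = {}
    for k in range(K):
        held = perm[k * fold_size:(k + 1) * fold_size]
        sub = data.iloc[np.setdiff1d(np.arange(n), held)]
        try:
            tester = _TEST_REGISTRY[test](sub, alpha)
            skel = pc_skeleton(sub, alpha, tiers, tester=tester,
                               max_cond_size=max_cond_size)
            graph = orient_edges(skel)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"PC failed on sub-dataset {k}: {exc}") from exc
        bad = graph.tier_violations()
        assert not bad, f"tier violation in fold {k}: {bad}"
        for e in graph.directed:
            votes[e] = votes.get(e, 0) + 1

    return EdgeVoteGraph(nodes=list(data.columns), tiers=dict(tiers),
                         votes=votes, K=K, vote_threshold=vote_threshold)


def select_outcome_parents(
    votes: EdgeVoteGraph,
    outcome: str,
    min_votes: int = 9,
) -> list[tuple[str, int]]:
    """Comorbidities with a directed edge into the outcome in ≥ min_votes runs,
    ranked by votes (descending) then label."""
    if votes.tiers.get(outcome) != 3:
        raise ValueError(f"{outcome!r} is not the tier-3 node")
    hits = [(u, c) for (u, v), c in votes.votes.items()
            if v == outcome and c >= min_votes]
    return sorted(hits, key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# graph distances
# ---------------------------------------------------------------------------

def _pair_status(edges: set, u, v) -> str:
    fwd, bwd = (u, v) in edges, (v, u) in edges
    if fwd and bwd:
        return "both"
    if fwd:
        return "fwd"
    if bwd:
        return "bwd"
    return "none"


def _status_map(g) -> tuple[list, dict]:
    """Normalise TieredGraph / nx.DiGraph to (nodes, unordered-pair status)."""
    if isinstance(g, TieredGraph):
        nodes = list(g.nodes)
        edges = set(g.directed)
        both = set(map(tuple, (sorted(e) for e in g.undirected)))
    else:
        dg = nx.DiGraph(g)
        nodes = list(dg.nodes)
        edges = set(dg.edges)
        both = set()
    status = {}
    for u, v in itertools.combinations(nodes, 2):
        key = (u, v) if str(u) <= str(v) else (v, u)
        if tuple(sorted((u, v))) in both or (u, v) in both or (v, u) in both:
            status[key] = "both"
        else:
            s = _pair_status(edges, *key)
            if s != "none":
                status[key] = s
    return nodes, status


def shd(g1, g2) -> int:
    """Structural Hamming distance: node pairs whose edge status differs.

    A missing-vs-present edge and a misoriented edge each count 1; an
    undirected edge (or 2-cycle) counts as its own status. Requires equal
    node sets.
    """
    n1, s1 = _status_map(g1)
    n2, s2 = _status_map(g2)
    if set(n1) != set(n2):
        raise ValueError("SHD requires identical node sets")
    keys = set(s1) | set(s2)
    return sum(s1.get(k, "none") != s2.get(k, "none") for k in keys)


def _ged_mapping_cost(nodes1, nodes2, s1, s2, labels1, labels2, mapping) -> int:
    """Edit cost of one node correspondence (None = delete / unmatched)."""
    cost = 0
    mapped = {a: b for a, b in mapping.items() if b is not None}
    used = set(mapped.values())
    cost += sum(1 for a in nodes1 if mapping.get(a) is None)        # deletions
    cost += sum(1 for b in nodes2 if b not in used)                 # insertions
    cost += sum(1 for a, b in mapped.items() if labels1[a] != labels2[b])
    # edge-status substitutions between mapped pairs
    for a1, a2 in itertools.combinations(sorted(mapped), 2):
        k1 = (a1, a2) if str(a1) <= str(a2) else (a2, a1)
        st1 = s1.get(k1, "none")
        b1, b2 = mapped[a1], mapped[a2]
        k2 = (b1, b2) if str(b1) <= str(b2) else (b2, b1)
        st2 = s2.get(k2, "none")
        # orient statuses consistently with the mapping direction
        st1o = st1 if k1 == (a1, a2) else {"fwd": "bwd", "bwd": "fwd"}.get(st1, st1)
        st2o = st2 if k2 == (b1, b2) else {"fwd": "bwd", "bwd": "fwd"}.get(st2, st2)
        cost += st1o != st2o
    # pairs touching an unmatched node must be cleared / created
    for (u, v) in s1:
        if mapping.get(u) is None or mapping.get(v) is None:
            cost += 1
    for (u, v) in s2:
        if u not in used or v not in used:
            cost += 1
    return cost


def ged(g1, g2, exact_node_limit: int = 10) -> int:
    """Unit-cost graph edit distance over labelled directed graphs.

    Node insertion, deletion and label substitution cost 1 each; an edit of
    an unordered pair's edge status (insert, delete, or orientation change)
    costs 1. Exact branch-and-bound search over node correspondences up to
    ``exact_node_limit`` nodes; beyond that a greedy label-matching upper
    bound is returned with a warning.
    """
    n1, s1 = _status_map(g1)
    n2, s2 = _status_map(g2)
    labels1 = {v: v for v in n1}
    labels2 = {v: v for v in n2}

    # identity / label-greedy mapping gives an upper bound (equals SHD when
    # the node sets coincide)
    greedy = {a: (a if a in set(n2) else None) for a in n1}
    best = _ged_mapping_cost(n1, n2, s1, s2, labels1, labels2, greedy)

    if max(len(n1), len(n2)) > exact_node_limit:
        warnings.warn("node count exceeds exact_node_limit; "
                      "returning an upper bound", stacklevel=2)
        return best

    order = sorted(n1)
    cands = sorted(n2)

    def recurse(idx: int, mapping: dict, used: set, best: int) -> int:
        if idx == len(order):
            return min(best, _ged_mapping_cost(n1, n2, s1, s2,
                                               labels1, labels2, mapping))
        a = order[idx]
        for b in cands + [None]:
            if b is not None and b in used:
                continue
            mapping[a] = b
            if b is not None:
                used.add(b)
            # cheap lower bound: node-op cost so far
            lb = sum(1 for x in list(mapping) if mapping[x] is None)
            lb += sum(1 for x, y in mapping.items()
                      if y is not None and labels1[x] != labels2[y])
            if lb < best:
                best = recurse(idx + 1, mapping, used, best)
            if b is not None:
                used.discard(b)
            del mapping[a]
        return best

    return recurse(0, {}, set(), best)


# ---------------------------------------------------------------------------
# scikit-learn-style estimators
# ---------------------------------------------------------------------------

class TieredPC(BaseEstimator):
    """PC structure learner with tiered background knowledge.

    Parameters
    ----------
    alpha : significance level for the CI test.
    tiers : node -> {1, 2, 3}; nodes absent from the map default to tier 1.
    test : "fisher_z" | "g_square" | "logistic_lr".
    max_cond_size : optional cap on conditioning-set size.

    Attributes
    ----------
    skeleton_ : TieredGraph before orientation.
    graph_ : oriented TieredGraph.
    """

    def __init__(self, alpha: float = 0.05, tiers: dict | None = None,
                 test: str = "fisher_z", max_cond_size: int | None = None):
        self.alpha = alpha
        self.tiers = tiers
        self.test = test
        self.max_cond_size = max_cond_size

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        tiers = self.tiers or {}
        tester = _TEST_REGISTRY[self.test](X, self.alpha)
        self.skeleton_ = pc_skeleton(X, self.alpha, tiers, tester=tester,
                                     max_cond_size=self.max_cond_size)
        self.graph_ = orient_edges(self.skeleton_)
        return self


class EnsembleTieredPC(BaseEstimator):
    """Subsample-voting ensemble around :class:`TieredPC`.

    Attributes
    ----------
    votes_ : EdgeVoteGraph with per-edge counts.
    consensus_ : TieredGraph of edges above the vote threshold.
    """

    def __init__(self, tiers: dict | None = None, K: int = 10,
                 holdout_fraction: float = 0.1, alpha: float = 0.05,
                 vote_threshold: float = 0.5, seed: int = 0,
                 test: str = "fisher_z", max_cond_size: int | None = None):
        self.tiers = tiers
        self.K = K
        self.holdout_fraction = holdout_fraction
        self.alpha = alpha
        self.vote_threshold = vote_threshold
        self.seed = seed
        self.test = test
        self.max_cond_size = max_cond_size

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        self.votes_ = ensemble_pc(
            X, self.tiers or {}, K=self.K,
            holdout_fraction=self.holdout_fraction, alpha=self.alpha,
            vote_threshold=self.vote_threshold, seed=self.seed,
            test=self.test, max_cond_size=self.max_cond_size)
        self.consensus_ = self.votes_.consensus()
        return self
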
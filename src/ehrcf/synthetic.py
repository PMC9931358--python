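"""Synthetic EHR cohorts from a declared tiered causal model.

Real nationwide EHR databases of the kind used in comorbidity→dementia
counterfactual studies are proprietary, so this module provides a generator
with *known* ground truth: a tiered directed acyclic graph over phenotype
nodes (tier 1 = chronic comorbidities with established risk, tier 2 =
comorbidities under investigation, tier 3 = the single outcome, e.g. ADRD),
Bernoulli presence of each condition through a logistic structural equation
over its parents' presences, and count-valued code occurrences on top of
presence. A do-operator Monte-Carlo oracle (:func:`true_effect`) computes
exact-by-simulation interventional risk differences, so every downstream
stage of the pipeline — feature building, matching, structure learning,
effect estimation, refutation — can be tested against a known answer.

Structural model, per node ``v`` in topological order::

    presence_v ~ Bernoulli( sigmoid( intercept_v
                                     + sum_p  w_{p->v} * presence_p
                                     + group_shift[group][v]
                                     + sex_effect[v] * sex ) )
    count_v    = 0                         if presence_v = 0
    count_v    = 1 + Poisson(rate_v - 1)   if presence_v = 1

Group shifts model unequal baseline prevalence between the two demographic
groups (confounding of group membership with tier-1 comorbidities); the
shifted-Poisson count law guarantees at least one recorded occurrence for a
present condition while matching the skewed, over-dispersed look of billing
counts.

Randomness is counter-based per subject: one call draws a ``(n_subjects,
n_streams)`` uniform matrix row-major from a single PCG64 stream, and every
subject-level quantity is an inverse-transform of that subject's row.
Growing ``n_subjects`` therefore appends subjects without reshuffling
earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import networkx as nx
from scipy.special import expit
from scipy.stats import poisson

__all__ = [
    "SyntheticSpec", "CohortTable", "OracleOutcomes",
    "validate_spec", "simulate_cohort", "true_effect",
    "default_spec", "confounded_spec", "null_effect_spec",
]

GROUPS = ("A", "B")

#: Number of demographic uniform streams per subject, in order:
#: group, sex, age_start, duration, censor-select, censor-amount, onset.
_N_DEMO_STREAMS = 7


@dataclass
class SyntheticSpec:
    """Declaration of a ground-truth tiered causal model for cohort simulation.

    Parameters
    ----------
    node_names : list of str
        All phenotype labels plus the single outcome label.
    tier_of : dict
        node -> tier in {1, 2, 3}; exactly one tier-3 node (the outcome).
    parents_of : dict
        node -> ordered list of parent nodes. Edges may run from an
        equal-or-lower tier into a higher tier, or within a tier along the
        declared ``node_names`` order; never downward into tier 1 and never
        out of the tier-3 node.
    intercepts : dict
        node -> baseline log-odds of presence.
    edge_weights : dict
        node -> list of log-odds coefficients aligned with
        ``parents_of[node]``.
    group_shift : dict
        group label -> {node -> additive log-odds shift}; models unequal
        prevalence between demographic groups.
    count_rate : dict
        node -> mean recorded occurrences given presence (>= 1).
    sex_effect : dict
        node -> log-odds coefficient on sex (optional hook; empty by
        default, i.e. sex is independent of the phenotypes).
    n_subjects, group_fractions, censor_fraction, seed
        Cohort size; the two group proportions (sum to 1); fraction of
        non-outcome subjects whose observation end is truncated; master
        RNG seed.
    """

    node_names: list[str]
    tier_of: dict[str, int]
    parents_of: dict[str, list[str]]
    intercepts: dict[str, float]
    edge_weights: dict[str, list[float]]
    group_shift: dict[str, dict[str, float]] = field(default_factory=dict)
    count_rate: dict[str, float] = field(default_factory=dict)
    sex_effect: dict[str, float] = field(default_factory=dict)
    n_subjects: int = 10_000
    group_fractions: tuple[float, float] = (0.5, 0.5)
    censor_fraction: float = 0.2
    seed: int = 0
    age_start_range: tuple[float, float] = (65.0, 85.0)
    mean_observation_years: float = 3.0
    min_observation_years: float = 0.5

    # -- convenience ------------------------------------------------------
    @property
    def outcome(self) -> str:
        """Label of the (unique) tier-3 node."""
        for v in self.node_names:
            if self.tier_of.get(v) == 3:
                return v
        raise ValueError("spec has no tier-3 node")

    @property
    def phenotypes(self) -> list[str]:
        """Tier-1 and tier-2 nodes, in declaration order."""
        return [v for v in self.node_names if self.tier_of.get(v) != 3]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        for child, parents in self.parents_of.items():
            for p in parents:
                g.add_edge(p, child)
        return g

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, ps in self.parents_of.items() for p in ps]

    def weight(self, parent: str, child: str) -> float:
        return self.edge_weights[child][self.parents_of[child].index(parent)]

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["group_fractions"] = list(self.group_fractions)
        payload["age_start_range"] = list(self.age_start_range)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SyntheticSpec":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                payload = json.load(fh)
        payload["group_fractions"] = tuple(payload["group_fractions"])
        if "age_start_range" in payload:
            payload["age_start_range"] = tuple(payload["age_start_range"])
        return cls(**payload)


@dataclass
class CohortTable:
    """Per-subject demographics, outcome, and phenotype count vector.

    ``data`` is indexed by ``subject_id`` with columns ``group``, ``sex``,
    ``age_start``, ``age_end``, ``outcome``, ``onset_age`` and one
    raw-count column per phenotype.
    """

    data: pd.DataFrame
    tiers: dict[str, int]
    phenotypes: list[str]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def outcome_label(self) -> str:
        for v, t in self.tiers.items():
            if t == 3:
                return v
        raise ValueError("no tier-3 node in tier map")

    def counts(self) -> pd.DataFrame:
        """The raw phenotype count block."""
        return self.data[self.phenotypes]

    def to_csv(self, path: str, schema_path: str | None = None) -> None:
        self.data.to_csv(path, index=True, index_label="subject_id")
        if schema_path is None:
            schema_path = str(path) + ".schema.json"
        schema = {
            "columns": ["subject_id"] + list(self.data.columns),
            "tiers": self.tiers,
            "phenotypes": self.phenotypes,
        }
        with open(schema_path, "w", encoding="utf-8") as fh:
            json.dump(schema, fh, indent=2)

    @classmethod
    def from_csv(cls, path: str, schema_path: str | None = None) -> "CohortTable":
        if schema_path is None:
            schema_path = str(path) + ".schema.json"
        with open(schema_path, encoding="utf-8") as fh:
            schema = json.load(fh)
        data = pd.read_csv(path, index_col="subject_id")
        return cls(data=data, tiers={k: int(v) for k, v in schema["tiers"].items()},
                   phenotypes=list(schema["phenotypes"]))


@dataclass
class OracleOutcomes:
    """Monte-Carlo do-operator ground truth for one treatment node."""

    treatment_node: str
    y1_mean: float
    y0_mean: float
    true_ate: float
    mc_reps: int
    mc_se: float


class SpecError(ValueError):
    """Raised when a :class:`SyntheticSpec` fails validation."""


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_spec(spec: SyntheticSpec) -> list[str]:
    """Check every structural invariant; return violation messages (empty if OK).

    Reports rather than raises so that configuration tooling can surface all
    problems at once.
    """
    msgs: list[str] = []
    names = set(spec.node_names)
    if len(names) != len(spec.node_names):
        msgs.append("duplicate node names")
    for v in spec.node_names:
        if spec.tier_of.get(v) not in (1, 2, 3):
            msgs.append(f"node {v!r} has no tier in {{1,2,3}}")
    tier3 = [v for v in spec.node_names if spec.tier_of.get(v) == 3]
    if len(tier3) != 1:
        msgs.append(f"expected exactly one tier-3 node, found {len(tier3)}")

    for child, parents in spec.parents_of.items():
        if child not in names:
            msgs.append(f"parents_of references unknown node {child!r}")
            continue
        for p in parents:
            if p not in names:
                msgs.append(f"unknown parent {p!r} of {child!r}")
                continue
            tp, tc = spec.tier_of.get(p), spec.tier_of.get(child)
            if tc == 1 and tp in (2, 3):
                msgs.append(
                    f"edge {p}->{child} terminates at a tier-1 node from tier {tp}")
            if tp == 3:
                msgs.append(f"tier-3 node has outgoing edge {p}->{child}")
        weights = spec.edge_weights.get(child, [])
        if len(weights) != len(parents):
            msgs.append(
                f"edge_weights[{child!r}] has {len(weights)} entries for "
                f"{len(parents)} parents")

    g = spec.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        msgs.append("cycle: " + " -> ".join(str(e[0]) for e in cycle)
                    + f" -> {cycle[-1][1]}")

    if not np.isclose(sum(spec.group_fractions), 1.0) or min(spec.group_fractions) < 0:
        msgs.append("group_fractions must be non-negative and sum to 1")
    if not 0.0 <= spec.censor_fraction <= 1.0:
        msgs.append("censor_fraction must lie in [0, 1]")
    for v, r in spec.count_rate.items():
        if r < 1.0:
            msgs.append(f"count_rate[{v!r}] = {r} < 1 (mean occurrences given presence)")
    if spec.n_subjects < 1:
        msgs.append("n_subjects must be positive")
    return msgs


def _require_valid(spec: SyntheticSpec) -> None:
    problems = validate_spec(spec)
    if problems:
        raise SpecError("invalid SyntheticSpec:\n  " + "\n  ".join(problems))


# ---------------------------------------------------------------------------
# simulation core
# ---------------------------------------------------------------------------

def _topological_order(spec: SyntheticSpec) -> list[str]:
    # stable within the declared node order so runs are reproducible
    return list(nx.lexicographical_topological_sort(
        spec.graph(), key=spec.node_names.index))


def _draw_presence(
    spec: SyntheticSpec,
    u_presence: np.ndarray,
    group_idx: np.ndarray,
    sex: np.ndarray,
    clamp: dict[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Inverse-transform presence of every node given a uniform matrix.

    ``u_presence`` has one column per node in ``spec.node_names`` order;
    because presence is a deterministic function of the uniforms, clamping a
    node (do-operator) leaves all non-descendants bit-identical.
    """
    col = {v: i for i, v in enumerate(spec.node_names)}
    shift = np.zeros((len(GROUPS), len(spec.node_names)))
    for gi, gname in enumerate(GROUPS):
        for v, s in spec.group_shift.get(gname, {}).items():
            shift[gi, col[v]] = s
    presence: dict[str, np.ndarray] = {}
    for v in _topological_order(spec):
        if clamp is not None and v in clamp:
            presence[v] = np.full(u_presence.shape[0], clamp[v], dtype=np.int8)
            continue
        z = np.full(u_presence.shape[0], spec.intercepts.get(v, 0.0))
        for p, w in zip(spec.parents_of.get(v, []), spec.edge_weights.get(v, [])):
            z = z + w * presence[p]
        z = z + shift[group_idx, col[v]]
        if v in spec.sex_effect:
            z = z + spec.sex_effect[v] * sex
        presence[v] = (u_presence[:, col[v]] < expit(z)).astype(np.int8)
    return presence


def simulate_cohort(spec: SyntheticSpec) -> CohortTable:
    """Simulate a cohort from the structural model; deterministic given seed.

    Raises
    ------
    SpecError
        If :func:`validate_spec` reports violations.
    """
    _require_valid(spec)
    n, m = spec.n_subjects, len(spec.node_names)
    rng = np.random.default_rng(spec.seed)
    # one row-major draw => per-subject streams stable under growing n
    u = rng.random((n, _N_DEMO_STREAMS + 2 * m))
    u_demo, u_presence, u_count = (
        u[:, :_N_DEMO_STREAMS],
        u[:, _N_DEMO_STREAMS:_N_DEMO_STREAMS + m],
        u[:, _N_DEMO_STREAMS + m:],
    )

    group_idx = (u_demo[:, 0] >= spec.group_fractions[0]).astype(np.int8)
    sex = (u_demo[:, 1] < 0.5).astype(np.int8)
    lo, hi = spec.age_start_range
    age_start = lo + u_demo[:, 2] * (hi - lo)
    mean_extra = max(spec.mean_observation_years - spec.min_observation_years, 1e-9)
    duration = spec.min_observation_years - mean_extra * np.log1p(-u_demo[:, 3] * (1 - 1e-12))
    duration = np.minimum(duration, 25.0)
    age_end = age_start + duration

    presence = _draw_presence(spec, u_presence, group_idx, sex)
    outcome = presence[spec.outcome]

    # censor a fraction of the non-outcome subjects: truncate age_end
    censored = (u_demo[:, 4] < spec.censor_fraction) & (outcome == 0)
    trunc = (spec.min_observation_years
             + u_demo[:, 5] * (duration - spec.min_observation_years))
    age_end = np.where(censored, age_start + trunc, age_end)

    onset_age = np.where(outcome == 1,
                         age_start + u_demo[:, 6] * (age_end - age_start),
                         np.nan)

    col = {v: i for i, v in enumerate(spec.node_names)}
    counts = {}
    for v in spec.phenotypes:
        rate = spec.count_rate.get(v, 1.0)
        if rate > 1.0:
            k = 1 + poisson.ppf(u_count[:, col[v]], rate - 1.0)
        else:
            k = np.ones(n)
        counts[v] = (presence[v] * k).astype(np.int64)

    data = pd.DataFrame(
        {
            "group": np.array(GROUPS)[group_idx],
            "sex": sex.astype(np.int64),
            "age_start": age_start,
            "age_end": age_end,
            "outcome": outcome.astype(np.int64),
            "onset_age": onset_age,
            **counts,
        },
        index=pd.RangeIndex(n, name="subject_id"),
    )
    return CohortTable(data=data, tiers=dict(spec.tier_of),
                       phenotypes=list(spec.phenotypes))


# ---------------------------------------------------------------------------
# do-operator oracle
# ---------------------------------------------------------------------------

def true_effect(
    spec: SyntheticSpec,
    treatment_node: str,
    mc_reps: int = 200_000,
    seed: int = 0,
) -> OracleOutcomes:
    """Interventional risk difference of ``treatment_node`` on the outcome.

    Simulates each replicate twice from shared uniforms — once with the
    treatment clamped present (do(T=1)) and once absent (do(T=0)) — so
    non-descendants are identical across the two arms and the paired
    difference has low Monte-Carlo variance.
    """
    _require_valid(spec)
    if treatment_node == spec.outcome:
        raise ValueError("treatment_node must not be the outcome node")
    if treatment_node not in spec.node_names:
        raise ValueError(f"unknown treatment node {treatment_node!r}")
    if mc_reps < 1:
        raise ValueError("mc_reps must be >= 1")

    rng = np.random.default_rng(seed)
    m = len(spec.node_names)
    u = rng.random((mc_reps, 2 + m))
    group_idx = (u[:, 0] >= spec.group_fractions[0]).astype(np.int8)
    sex = (u[:, 1] < 0.5).astype(np.int8)
    u_presence = u[:, 2:]

    y1 = _draw_presence(spec, u_presence, group_idx, sex,
                        clamp={treatment_node: 1})[spec.outcome]
    y0 = _draw_presence(spec, u_presence, group_idx, sex,
                        clamp={treatment_node: 0})[spec.outcome]
    diff = y1.astype(float) - y0.astype(float)
    se = float(diff.std(ddof=1) / np.sqrt(mc_reps)) if mc_reps > 1 else float("inf")
    return OracleOutcomes(
        treatment_node=treatment_node,
        y1_mean=float(y1.mean()),
        y0_mean=float(y0.mean()),
        true_ate=float(diff.mean()),
        mc_reps=mc_reps,
        mc_se=max(se, np.finfo(float).tiny),
    )


# ---------------------------------------------------------------------------
# packaged study specs
# ---------------------------------------------------------------------------

def default_spec(n_subjects: int = 10_000, seed: int = 7) -> SyntheticSpec:
    """The packaged 12-phenotype demo model.

    Six tier-1 chronic comorbidities with established dementia risk
    (hypertension, diabetes, obesity, heart disease, vascular disease, head
    injury), five tier-2 comorbidities under investigation, and the ADRD
    outcome. Edge weights are on the log-odds scale and sized like strong
    epidemiological associations (odds ratios roughly 2–3); group A carries
    higher baseline prevalence of hypertension, diabetes and obesity, which
    confounds naive cross-group comparisons. ``respiratory_infection`` is
    deliberately disconnected as a negative control.
    """
    tier1 = ["hypertension", "diabetes", "obesity", "heart_disease",
             "vascular_disease", "head_injury"]
    tier2 = ["cvd_late_effects", "transient_ischemia", "depression",
             "urinary_tract_infection", "respiratory_infection"]
    outcome = "adrd"
    nodes = tier1 + tier2 + [outcome]
    tier_of = {**{v: 1 for v in tier1}, **{v: 2 for v in tier2}, outcome: 3}

    parents_of = {
        "cvd_late_effects": ["hypertension", "diabetes", "heart_disease"],
        "transient_ischemia": ["hypertension", "vascular_disease"],
        "depression": ["head_injury", "obesity"],
        "urinary_tract_infection": ["diabetes"],
        outcome: ["cvd_late_effects", "transient_ischemia", "depression",
                  "urinary_tract_infection"],
    }
    edge_weights = {
        "cvd_late_effects": [1.1, 0.8, 0.9],
        "transient_ischemia": [0.9, 1.1],
        "depression": [0.8, 0.7],
        "urinary_tract_infection": [0.9],
        outcome: [1.0, 0.8, 0.9, 0.7],
    }
    intercepts = {
        "hypertension": -0.4, "diabetes": -1.0, "obesity": -1.0,
        "heart_disease": -1.2, "vascular_disease": -1.4, "head_injury": -2.0,
        "cvd_late_effects": -2.5, "transient_ischemia": -2.5,
        "depression": -2.0, "urinary_tract_infection": -2.0,
        "respiratory_infection": -1.5,
        outcome: -2.5,
    }
    # group A: higher baseline prevalence of the metabolic/vascular tier-1 set
    group_shift = {"A": {"hypertension": 0.7, "diabetes": 0.6, "obesity": 0.4}}
    count_rate = {
        "hypertension": 4.0, "diabetes": 4.0, "obesity": 2.0,
        "heart_disease": 3.0, "vascular_disease": 2.5, "head_injury": 1.5,
        "cvd_late_effects": 2.5, "transient_ischemia": 2.0, "depression": 3.0,
        "urinary_tract_infection": 2.0, "respiratory_infection": 2.0,
    }
    return SyntheticSpec(
        node_names=nodes, tier_of=tier_of, parents_of=parents_of,
        intercepts=intercepts, edge_weights=edge_weights,
        group_shift=group_shift, count_rate=count_rate,
        n_subjects=n_subjects, seed=seed,
    )


def confounded_spec(n_subjects: int = 20_000, seed: int = 7) -> SyntheticSpec:
    """A compact confounded model for effect-recovery studies.

    Hypertension and diabetes confound the treatment (late effects of
    cerebrovascular disease) and the ADRD outcome; the direct T→Y weight is
    calibrated so the do-operator risk difference is ≈ 0.25 while the naive
    exposed-minus-unexposed outcome difference is biased upward by the
    shared tier-1 causes.
    """
    tier1 = ["hypertension", "diabetes"]
    t, y = "cvd_late_effects", "adrd"
    nodes = tier1 + [t, y]
    return SyntheticSpec(
        node_names=nodes,
        tier_of={"hypertension": 1, "diabetes": 1, t: 2, y: 3},
        parents_of={t: tier1, y: tier1 + [t]},
        intercepts={"hypertension": 0.0, "diabetes": -0.5, t: -1.5, y: -2.2},
        edge_weights={t: [1.0, 0.8], y: [1.0, 0.8, 1.25]},
        count_rate={"hypertension": 4.0, "diabetes": 4.0, t: 2.5},
        n_subjects=n_subjects,
        seed=seed,
    )


def null_effect_spec(n_subjects: int = 2_000, seed: int = 7) -> SyntheticSpec:
    """A model in which the treatment has no path to the outcome.

    Hypertension drives the treatment but nothing drives the outcome, so T
    and Y are exactly independent — the reference condition for permutation
    type-I calibration.
    """
    t, y = "cvd_late_effects", "adrd"
    nodes = ["hypertension", t, y]
    return SyntheticSpec(
        node_names=nodes,
        tier_of={"hypertension": 1, t: 2, y: 3},
        parents_of={t: ["hypertension"]},
        intercepts={"hypertension": 0.0, t: -1.0, y: -1.5},
        edge_weights={t: [1.0]},
        count_rate={"hypertension": 3.0, t: 2.0},
        n_subjects=n_subjects,
        seed=seed,
    )
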
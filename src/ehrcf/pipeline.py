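"""End-to-end study pipeline: cohort → features → matching → structure →
effects → refutation → report.

The pipeline reproduces, on any conforming input (a synthetic model
specification or real long-format diagnosis events plus demographics), the
full counterfactual comorbidity analysis: eligibility filtering,
outcome/control matching with observation truncation, phenotype feature
construction, cross-group propensity matching with balance checks,
per-group tiered Bayesian-network learning with a subsample voting
ensemble, selection of outcome-parent comorbidities, ATE/ATT/ATC
estimation with bootstrap intervals, permutation refutation, and a
cross-group graph comparison (SHD, GED, shared-edge fractions).

Every stage draws its randomness from a labelled sub-stream of the master
seed, so a rerun with the same config is bit-identical at the JSON-report
level, and per-group analyses are independent yet reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ehrcf import features, matching, structure, effects, refute, synthetic
from ehrcf.synthetic import CohortTable, SyntheticSpec

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "eligibility_filter"]


@dataclass
class PipelineConfig:
    """All tunables of one study run (target-trial style protocol surface)."""

    # inputs: either a synthetic spec, or events+demographics(+code map)
    spec: SyntheticSpec | None = None
    events_path: str | None = None
    demographics_path: str | None = None
    code_map_path: str | None = None

    # eligibility
    min_age: float = 65.0
    min_observation_years: float = 0.5

    # features
    min_prevalence: float = 0.05
    top_k: int = 100

    # structure learning
    alpha: float = 0.05
    K: int = 10
    holdout_fraction: float = 0.1
    vote_threshold: float = 0.5
    min_votes: int = 9
    ci_test: str = "fisher_z"
    max_cond_size: int | None = 3

    # matching
    caliper_sd: float = 0.2
    radius: float | None = None
    known_risk_covariates: list[str] | None = None
    reference_group: str = "A"
    run_group_matching: bool = True
    run_outcome_matching: bool = True

    # effects
    treatments: list[str] | None = None      # default: selected outcome parents
    estimands: tuple = ("ate", "att", "atc")
    strategies: tuple = ("iptw", "ps_matching", "ps_stratification")
    bootstrap: int = 100
    permutation_reps: int = 100
    clip: tuple = (0.01, 0.99)

    seed: int = 7

    def validate(self) -> list[str]:
        msgs = []
        if self.min_votes > self.K:
            msgs.append(f"min_votes {self.min_votes} exceeds K {self.K}")
        if not 0 < self.vote_threshold <= 1:
            msgs.append("vote_threshold must lie in (0, 1]")
        if not 0 <= self.min_prevalence < 1:
            msgs.append("min_prevalence must lie in [0, 1)")
        if not 0 < self.alpha < 1:
            msgs.append("alpha must lie in (0, 1)")
        if self.bootstrap < 0 or self.permutation_reps < 0:
            msgs.append("bootstrap and permutation_reps must be >= 0")
        if self.spec is None and (self.events_path is None
                                  or self.demographics_path is None):
            msgs.append("need a synthetic spec or events + demographics paths")
        for e in (self.estimands or ()):
            if e not in effects.ESTIMANDS:
                msgs.append(f"unknown estimand {e!r}")
        for s in (self.strategies or ()):
            if s not in effects.STRATEGIES:
                msgs.append(f"unknown strategy {s!r}")
        return msgs

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        import yaml
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        if "spec" in payload and payload["spec"] is not None:
            spec = payload["spec"]
            if isinstance(spec, str):
                payload["spec"] = SyntheticSpec.from_json(spec)
            else:
                spec["group_fractions"] = tuple(spec.get("group_fractions", (0.5, 0.5)))
                payload["spec"] = SyntheticSpec(**spec)
        for key in ("estimands", "strategies", "clip"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class RunReport:
    """JSON-serializable record of everything a run computed."""

    config_echo: dict
    stages: dict = field(default_factory=dict)
    cohort_sizes: dict = field(default_factory=dict)
    balance: dict = field(default_factory=dict)
    structure: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    refutation: dict = field(default_factory=dict)
    graph_comparison: dict = field(default_factory=dict)
    version: str = ""
    elapsed_seconds: float = 0.0
    error: str | None = None

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_jsonify, sort_keys=True)
        if path:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return str(obj)


def _stage_seed(master: int, label: str) -> int:
    """Deterministic per-stage sub-seed below 2**31 (stable across runs)."""
    import zlib
    h = np.random.SeedSequence([int(master), zlib.crc32(label.encode())])
    return int(h.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def eligibility_filter(
    cohort: CohortTable,
    min_age: float = 65.0,
    min_observation_years: float = 0.5,
) -> CohortTable:
    """Keep subjects observed after ``min_age`` with a window of at least
    ``min_observation_years``."""
    df = cohort.data
    keep = (df.age_end >= min_age) & (
        (df.age_end - df.age_start) >= min_observation_years)
    return CohortTable(df[keep].copy(), dict(cohort.tiers),
                       list(cohort.phenotypes))


def _load_cohort(cfg: PipelineConfig) -> CohortTable:
    if cfg.spec is not None:
        return synthetic.simulate_cohort(cfg.spec)
    demo = pd.read_csv(cfg.demographics_path, index_col="subject_id")
    events = pd.read_csv(cfg.events_path)
    cmap = (features.CodeMap.from_tsv(cfg.code_map_path)
            if cfg.code_map_path else features.CodeMap.identity())
    counts = features.aggregate_codes(events, cmap, demo)
    data = demo.join(counts.values)
    phenos = list(counts.values.columns)
    tiers = {p: 2 for p in phenos}
    if "onset_age" not in data.columns:
        data["onset_age"] = np.nan
    return CohortTable(data, tiers, phenos)


def _feature_matrix(cohort: CohortTable, cfg: PipelineConfig):
    """Prevalence-filtered raw counts and their log transform + outcome."""
    raw = features.CodeMatrix(cohort.counts().copy())
    kept = features.prevalence_filter(raw, cfg.min_prevalence, cfg.top_k)
    logged = features.log_transform(kept)
    analysis = logged.values.copy()
    analysis[cohort.outcome_label] = cohort.data.outcome.astype(float)
    return kept, logged, analysis


def _group_structure(analysis: pd.DataFrame, tiers: dict, cfg: PipelineConfig,
                     seed: int) -> structure.EdgeVoteGraph:
    return structure.ensemble_pc(
        analysis, tiers, K=cfg.K, holdout_fraction=cfg.holdout_fraction,
        alpha=cfg.alpha, vote_threshold=cfg.vote_threshold, seed=seed,
        test=cfg.ci_test, max_cond_size=cfg.max_cond_size)


def _estimate_for_treatment(
    cohort: CohortTable,
    kept: features.CodeMatrix,
    logged: features.CodeMatrix,
    votes: structure.EdgeVoteGraph,
    treatment: str,
    cfg: PipelineConfig,
    seed: int,
):
    outcome = cohort.outcome_label
    adj = effects.adjustment_set(votes, treatment, outcome)
    adj = [a for a in adj if a in logged.values.columns]
    T = effects.binarize_treatment(kept.values[treatment].to_numpy())
    Y = cohort.data.outcome.to_numpy()
    design = effects.hurdle_design(kept.values, adj)
    X = design.to_numpy() if adj else np.empty((len(Y), 0))
    frame = effects.PotentialOutcomeFrame(T, Y, X,
                                          covariates=list(design.columns))

    results, refutes = {}, {}
    for strategy in cfg.strategies:
        for estimand in cfg.estimands:
            est = effects.CausalEffectEstimator(
                estimand=estimand, strategy=strategy, clip=cfg.clip,
                B=cfg.bootstrap, seed=_stage_seed(seed, f"{strategy}:{estimand}"))
            est.fit(design, Y, treatment=T)
            rec = (est.estimate_.as_dict() if est.estimate_ is not None
                   else {"estimand": estimand, "strategy": strategy,
                         "point": est.point_})
            results[f"{strategy}:{estimand}"] = rec
    if cfg.permutation_reps:
        base = effects.CausalEffectEstimator(estimand="ate", strategy="iptw",
                                             clip=cfg.clip, B=0)
        res = refute.permutation_test(base._single, frame,
                                      B=cfg.permutation_reps,
                                      seed=_stage_seed(seed, "permute"))
        refutes = res.as_dict()
    return {"adjustment_set": adj, "n": frame.n, "n_exposed": frame.n1,
            "estimates": results}, refutes


def _graph_overlap(g1: structure.TieredGraph, g2: structure.TieredGraph) -> dict:
    e1, e2 = set(g1.directed), set(g2.directed)
    return {
        "shared_fraction_of_first": (len(e1 & e2) / len(e1)) if e1 else float("nan"),
        "shared_fraction_of_second": (len(e1 & e2) / len(e2)) if e2 else float("nan"),
        "n_edges_first": len(e1), "n_edges_second": len(e2),
    }


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, out_dir: str | None = None) -> RunReport:
    """Execute every stage per demographic group plus the cross-group
    comparison; on stage failure, return the report up to the failure with
    a structured error."""
    t0 = time.time()
    problems = cfg.validate()
    echo = {k: v for k, v in asdict(cfg).items() if k != "spec"}
    echo["has_spec"] = cfg.spec is not None
    report = RunReport(config_echo=echo)
    from ehrcf import __version__
    report.version = __version__
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))

    outp = None
    if out_dir is not None:
        import pathlib
        outp = pathlib.Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)

    try:
        cohort = _load_cohort(cfg)
        report.cohort_sizes["raw"] = len(cohort)
        report.stages["load"] = "ok"

        cohort = eligibility_filter(cohort, cfg.min_age,
                                    cfg.min_observation_years)
        report.cohort_sizes["eligible"] = len(cohort)

        if cfg.run_outcome_matching:
            pairs1, cohort = matching.match_outcome_controls(
                cohort, cfg.min_observation_years)
            report.cohort_sizes["outcome_matched"] = len(cohort)
            report.stages["matching1"] = {
                "pairs": len(pairs1),
                "unmatched_cases": len(pairs1.unmatched_left)}
            if outp is not None:
                pairs1.to_tsv(outp / "matching1_pairs.tsv")

        if cfg.run_group_matching and cohort.data.group.nunique() > 1:
            covs = cfg.known_risk_covariates
            matcher = matching.GroupPropensityMatcher(
                covariates=covs, group_label=cfg.reference_group,
                caliper_sd=cfg.caliper_sd, radius=cfg.radius,
                seed=_stage_seed(cfg.seed, "matching2"))
            matcher.fit(cohort)
            cohort = matcher.matched_cohort_
            report.cohort_sizes["group_matched"] = len(cohort)
            report.balance = json.loads(
                matcher.balance_.table.to_json(orient="index"))
            report.stages["matching2"] = {
                "pairs": len(matcher.pairs_),
                "balance_pass": matcher.balance_.passed}
            if outp is not None:
                matcher.pairs_.to_tsv(outp / "matching2_pairs.tsv")
                matcher.balance_.to_csv(outp / "balance.csv")

        group_votes: dict[str, structure.EdgeVoteGraph] = {}
        group_features: dict[str, tuple] = {}
        for gname in sorted(cohort.data.group.unique()):
            sub = CohortTable(cohort.data[cohort.data.group == gname].copy(),
                              dict(cohort.tiers), list(cohort.phenotypes))
            kept, logged, analysis = _feature_matrix(sub, cfg)
            tiers = {c: sub.tiers.get(c, 2) for c in analysis.columns}
            votes = _group_structure(analysis, tiers, cfg,
                                     _stage_seed(cfg.seed, f"pc:{gname}"))
            group_votes[gname] = votes
            group_features[gname] = (sub, kept, logged)
            parents = structure.select_outcome_parents(
                votes, sub.outcome_label, cfg.min_votes)
            report.structure[gname] = {
                "n_subjects": len(sub),
                "n_features": len(analysis.columns) - 1,
                "consensus_edges": sorted(votes.consensus().directed),
                "outcome_parents": parents,
                "tier_violations": votes.consensus().tier_violations(),
            }
            if outp is not None:
                votes.to_tsv(outp / f"votes_{gname}.tsv")
                with open(outp / f"consensus_{gname}.dot", "w",
                          encoding="utf-8") as fh:
                    fh.write(votes.consensus().to_dot())
        report.stages["structure"] = "ok"

        for gname, votes in group_votes.items():
            sub, kept, logged = group_features[gname]
            chosen = cfg.treatments
            if chosen is None:
                chosen = [p for p, _ in
                          report.structure[gname]["outcome_parents"]]
            report.effects[gname] = {}
            report.refutation[gname] = {}
            for treatment in chosen:
                if treatment not in kept.values.columns:
                    logger.warning("treatment %r absent from %s features",
                                   treatment, gname)
                    continue
                eff, ref = _estimate_for_treatment(
                    sub, kept, logged, votes, treatment, cfg,
                    _stage_seed(cfg.seed, f"effects:{gname}:{treatment}"))
                report.effects[gname][treatment] = eff
                report.refutation[gname][treatment] = ref
        report.stages["effects"] = "ok"

        gnames = sorted(group_votes)
        if len(gnames) == 2:
            c1 = group_votes[gnames[0]].consensus()
            c2 = group_votes[gnames[1]].consensus()
            shared_nodes = sorted(set(c1.nodes) & set(c2.nodes))
            r1 = structure.TieredGraph(
                shared_nodes, c1.tiers,
                {e for e in c1.directed if set(e) <= set(shared_nodes)})
            r2 = structure.TieredGraph(
                shared_nodes, c2.tiers,
                {e for e in c2.directed if set(e) <= set(shared_nodes)})
            report.graph_comparison = {
                "groups": gnames,
                "shd": structure.shd(r1, r2),
                "ged": structure.ged(r1, r2,
                                     exact_node_limit=min(10, len(shared_nodes))),
                **_graph_overlap(c1, c2),
            }
        report.stages["graph_comparison"] = "ok"
    except Exception as exc:
        logger.exception("pipeline stage failed")
        report.error = f"{type(exc).__name__}: {exc}"

    report.elapsed_seconds = round(time.time() - t0, 3)
    if outp is not None:
        report.to_json(outp / "report.json")
        with open(outp / "report.md", "w", encoding="utf-8") as fh:
            fh.write(_markdown_summary(report))
    return report


def _markdown_summary(report: RunReport) -> str:
    lines = ["# Pipeline run summary", ""]
    lines.append(f"- version: {report.version}")
    lines.append(f"- elapsed: {report.elapsed_seconds}s")
    for stage, n in report.cohort_sizes.items():
        lines.append(f"- cohort after {stage}: {n}")
    for g, s in report.structure.items():
        lines.append(f"\n## Group {g}")
        lines.append(f"- features: {s['n_features']}, "
                     f"consensus edges: {len(s['consensus_edges'])}")
        lines.append(f"- outcome parents: {s['outcome_parents']}")
        for t, eff in report.effects.get(g, {}).items():
            for key, rec in eff["estimates"].items():
                ci = rec.get("ci")
                ci_txt = (f" (95% CI {ci[0]:.4f}, {ci[1]:.4f})" if ci else "")
                lines.append(f"  - {t} {key}: {rec['point']:.4f}{ci_txt}")
    if report.graph_comparison:
        gc = report.graph_comparison
        lines.append("\n## Cross-group comparison")
        lines.append(f"- SHD = {gc['shd']}, GED = {gc['ged']}")
        lines.append(f"- shared edge fractions: "
                     f"{gc['shared_fraction_of_first']:.3f} / "
                     f"{gc['shared_fraction_of_second']:.3f}")
    if report.error:
        lines.append(f"\n**ERROR**: {report.error}")
    return "\n".join(lines) + "\n"
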
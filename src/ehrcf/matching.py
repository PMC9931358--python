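"""Cohort matching with balance diagnostics.

Two matching stages mirror a target-trial cohort construction:

* **Outcome/control matching** (:func:`match_outcome_controls`) — each
  outcome case is paired 1:1 with a control of the same sex whose
  observation window is nearest in (start age, end age); the matched
  control's window is then truncated to the case's end age so that cases
  and controls are compared over equal-opportunity observation periods.

* **Cross-group propensity matching** (:func:`match_groups_nn`) — a
  logistic model of group membership on age, sex and the tier-1 known-risk
  comorbidity indicators yields propensity scores; greedy 1:1
  nearest-neighbour matching on the logit scale, without replacement, with
  a caliper of 0.2 logit standard deviations (optionally an absolute
  radius), builds comparable cohorts across the two demographic groups.

Balance is reported as the standardized bias |mean difference| / SD in the
designated reference group, with the conventional < 0.10 cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from ehrcf.synthetic import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedPairs", "BalanceTable", "match_outcome_controls",
    "fit_group_propensity", "match_groups_nn", "standardized_bias",
    "balance_report", "GroupPropensityMatcher",
]

SCORE_CLIP = (1e-6, 1.0 - 1e-6)


@dataclass
class MatchedPairs:
    """1:1 pairing between a left and a right id set."""

    pairs: list[tuple]                    # (left_id, right_id, distance)
    unmatched_left: list = field(default_factory=list)
    unmatched_right: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def left_ids(self) -> list:
        return [p[0] for p in self.pairs]

    @property
    def right_ids(self) -> list:
        return [p[1] for p in self.pairs]

    def matched_ids(self) -> list:
        return self.left_ids + self.right_ids

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("left_id\tright_id\tdistance\n")
            for l, r, d in self.pairs:
                fh.write(f"{l}\t{r}\t{d:.6g}\n")


@dataclass
class BalanceTable:
    """Per-variable standardized bias before and after matching."""

    table: pd.DataFrame        # columns: mean_left, mean_right, sd_reference,
                               # bias_before, bias_after
    cutoff: float = 0.10

    @property
    def passed(self) -> bool:
        after = self.table["bias_after"].dropna()
        return bool((after < self.cutoff).all())

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index_label="variable")


# ---------------------------------------------------------------------------
# Matching stage 1: outcome cases vs controls on age/sex + truncation
# ---------------------------------------------------------------------------

def _greedy_nn(left: pd.DataFrame, right: pd.DataFrame, coords: list[str],
               order: np.ndarray, caliper: float | None = None):
    """Greedy 1:1 nearest-neighbour without replacement.

    ``left``/``right`` are indexed by subject id; ties in distance break on
    the lowest right id. Returns (pairs, unmatched_left_ids).
    """
    rx = right[coords].to_numpy(dtype=float)
    rid = right.index.to_numpy()
    available = np.ones(len(right), dtype=bool)
    pairs, unmatched = [], []
    lx = left[coords].to_numpy(dtype=float)
    lid = left.index.to_numpy()
    for pos in order:
        if not available.any():
            unmatched.append(lid[pos])
            continue
        d = np.linalg.norm(rx[available] - lx[pos], axis=1)
        cand_ids = rid[available]
        best = np.lexsort((cand_ids, d))[0]
        if caliper is not None and d[best] > caliper:
            unmatched.append(lid[pos])
            continue
        chosen = cand_ids[best]
        pairs.append((lid[pos], chosen, float(d[best])))
        available[np.searchsorted(rid, chosen) if np.all(np.diff(rid) > 0)
                  else int(np.where(rid == chosen)[0][0])] = False
    return pairs, unmatched


def match_outcome_controls(
    cohort: CohortTable,
    min_observation_years: float = 0.5,
) -> tuple[MatchedPairs, CohortTable]:
    """Pair each outcome case with a same-sex control nearest in
    (age_start, age_end); truncate the control's window to the case's end.

    Controls whose truncated window falls below ``min_observation_years``
    are rejected and the case is re-matched in a single repair pass;
    remaining failures are reported as unmatched. Returns the pairing and a
    new cohort restricted to matched subjects with truncated control
    windows. Count columns are retained as-is — re-windowing of raw events
    belongs to :func:`ehrcf.features.aggregate_codes`.
    """
    df = cohort.data.sort_index()
    cases = df[df.outcome == 1]
    controls = df[df.outcome == 0]
    if cases.empty or controls.empty:
        raise ValueError("need both outcome cases and controls")

    pairs: list[tuple] = []
    unmatched_cases: list = []
    truncated_end: dict = {}
    for sex_value, case_block in cases.groupby("sex"):
        ctrl_block = controls[controls.sex == sex_value]
        remaining = case_block
        banned: set = set()
        for _ in range(2):  # initial pass + one repair pass
            if remaining.empty:
                break
            elig = ctrl_block.drop(index=[c for c in banned
                                          if c in ctrl_block.index])
            elig = elig[~elig.index.isin([p[1] for p in pairs])]
            order = np.arange(len(remaining))  # already sorted by id
            got, miss = _greedy_nn(remaining, elig, ["age_start", "age_end"],
                                   order)
            retry_ids = []
            for case_id, ctrl_id, dist in got:
                case_end = df.at[case_id, "age_end"]
                new_end = min(df.at[ctrl_id, "age_end"], case_end)
                if new_end - df.at[ctrl_id, "age_start"] < min_observation_years:
                    banned.add(ctrl_id)
                    retry_ids.append(case_id)
                    continue
                pairs.append((case_id, ctrl_id, dist))
                truncated_end[ctrl_id] = new_end
            unmatched_cases.extend(miss)
            remaining = case_block.loc[retry_ids]
        unmatched_cases.extend(remaining.index.difference(
            [p[0] for p in pairs]).difference(unmatched_cases).tolist())

    matched = MatchedPairs(
        pairs=sorted(pairs),
        unmatched_left=sorted(set(unmatched_cases)),
        unmatched_right=sorted(set(controls.index)
                               - {p[1] for p in pairs}),
        config={"stage": "outcome", "exact": ["sex"],
                "distance": "euclidean(age_start, age_end)",
                "min_observation_years": min_observation_years},
    )
    keep = sorted({p[0] for p in pairs} | {p[1] for p in pairs})
    out = df.loc[keep].copy()
    for cid, end in truncated_end.items():
        out.at[cid, "age_end"] = end
    return matched, CohortTable(out, dict(cohort.tiers), list(cohort.phenotypes))


# ---------------------------------------------------------------------------
# Matching stage 2: cross-group propensity matching
# ---------------------------------------------------------------------------

def fit_group_propensity(
    cohort: CohortTable,
    covariates: list[str],
    group_label: str = "A",
) -> pd.Series:
    """Logistic propensity of belonging to ``group_label`` given covariates.

    Count covariates are used as binary presence indicators (the known-risk
    comorbidity list); ``age_start``/``age_end``/``sex`` enter as-is. An L2
    penalty keeps the fit bounded under complete separation; scores are
    clipped away from {0, 1}.
    """
    df = cohort.data
    X = pd.DataFrame(index=df.index)
    for c in covariates:
        if c in cohort.phenotypes:
            X[c] = (df[c] > 0).astype(float)
        else:
            X[c] = df[c].astype(float)
    y = (df.group == group_label).astype(int)
    if y.nunique() < 2:
        raise ValueError("cohort contains a single group")
    model = LogisticRegression(C=1e4, max_iter=2000)
    model.fit(X.to_numpy(), y.to_numpy())
    scores = model.predict_proba(X.to_numpy())[:, 1]
    scores = np.clip(scores, *SCORE_CLIP)
    return pd.Series(scores, index=df.index, name="propensity")


def match_groups_nn(
    scores: pd.Series,
    left_mask: pd.Series,
    caliper_sd: float = 0.2,
    radius: float | None = None,
    seed: int = 0,
) -> MatchedPairs:
    """Greedy 1:1 nearest-neighbour matching on the logit-propensity scale.

    ``left_mask`` flags the reference group. The caliper is
    ``caliper_sd × SD(logit scores)`` (pooled); an optional absolute
    ``radius`` on the logit scale pre-restricts candidates. Left subjects
    are processed by descending |logit score| (hardest-to-match first),
    ties and equal distances breaking on subject id, so the pairing is
    deterministic and row-order invariant.
    """
    lscore = pd.Series(logit(np.clip(scores.to_numpy(), *SCORE_CLIP)),
                       index=scores.index).sort_index()
    left_mask = left_mask.reindex(lscore.index)
    left = lscore[left_mask.astype(bool)]
    right = lscore[~left_mask.astype(bool)]
    sd = float(lscore.std(ddof=1))
    caliper = caliper_sd * sd if caliper_sd is not None else None
    limit = caliper
    if radius is not None:
        limit = radius if limit is None else min(limit, radius)

    order = np.lexsort((left.index.to_numpy(), -np.abs(left.to_numpy())))
    lframe = left.to_frame("s")
    rframe = right.to_frame("s")
    pairs, unmatched = _greedy_nn(lframe, rframe, ["s"], order, caliper=limit)
    return MatchedPairs(
        pairs=sorted(pairs),
        unmatched_left=sorted(unmatched),
        unmatched_right=sorted(set(right.index) - {p[1] for p in pairs}),
        config={"stage": "group", "caliper_sd": caliper_sd,
                "caliper": limit, "radius": radius, "replacement": False,
                "seed": seed},
    )


# ---------------------------------------------------------------------------
# balance diagnostics
# ---------------------------------------------------------------------------

def standardized_bias(values_left, values_right, sd_reference: float | None = None) -> float:
    """|mean(left) − mean(right)| / SD(reference group = left).

    Returns 0 when both groups are constant and equal; NaN (flagged
    undefined) when the reference SD is 0 but the means differ.
    """
    vl = np.asarray(values_left, dtype=float)
    vr = np.asarray(values_right, dtype=float)
    if vl.size == 0 or vr.size == 0:
        raise ValueError("empty group in standardized_bias")
    diff = abs(vl.mean() - vr.mean())
    sd = float(np.std(vl, ddof=1)) if sd_reference is None else float(sd_reference)
    if sd == 0:
        return 0.0 if diff == 0 else float("nan")
    return float(diff / sd)


def balance_report(
    matched: MatchedPairs,
    cohort: CohortTable,
    variables: list[str],
    cutoff: float = 0.10,
    binarize_counts: bool = True,
) -> BalanceTable:
    """Standardized bias per variable, before and after matching.

    "Before" compares the full left/right groups (pair lefts + unmatched
    lefts vs pair rights + unmatched rights); "after" compares matched
    pairs only. The reference SD is taken in the left (reference) group of
    the *unmatched* cohort, so before/after are on the same scale.
    """
    df = cohort.data
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise ValueError(f"variables not in cohort: {missing}")

    def col(ids, v):
        x = df.loc[[i for i in ids if i in df.index], v].astype(float)
        if binarize_counts and v in cohort.phenotypes:
            x = (x > 0).astype(float)
        return x

    all_left = list(matched.left_ids) + list(matched.unmatched_left)
    all_right = list(matched.right_ids) + list(matched.unmatched_right)
    rows = {}
    for v in variables:
        bl, br = col(all_left, v), col(all_right, v)
        ml, mr = col(matched.left_ids, v), col(matched.right_ids, v)
        sd_ref = float(bl.std(ddof=1))
        rows[v] = {
            "mean_left": ml.mean() if len(ml) else np.nan,
            "mean_right": mr.mean() if len(mr) else np.nan,
            "sd_reference": sd_ref,
            "bias_before": standardized_bias(bl, br, sd_ref),
            "bias_after": (standardized_bias(ml, mr, sd_ref)
                           if len(ml) and len(mr) else np.nan),
        }
    return BalanceTable(pd.DataFrame(rows).T, cutoff=cutoff)


class GroupPropensityMatcher(BaseEstimator):
    """Cross-group propensity matcher in scikit-learn estimator form.

    ``fit`` computes scores, runs nearest-neighbour matching (optionally
    stratified by outcome status so case/control composition is preserved
    across groups), and the balance table.

    Attributes
    ----------
    scores_ : pd.Series of group-membership propensities.
    pairs_ : MatchedPairs.
    balance_ : BalanceTable over the matching covariates.
    matched_cohort_ : CohortTable restricted to matched subjects.
    """

    def __init__(self, covariates: list[str] | None = None,
                 group_label: str = "A", caliper_sd: float = 0.2,
                 radius: float | None = None, cutoff: float = 0.10,
                 stratify_by_outcome: bool = True, seed: int = 0):
        self.covariates = covariates
        self.group_label = group_label
        self.caliper_sd = caliper_sd
        self.radius = radius
        self.cutoff = cutoff
        self.stratify_by_outcome = stratify_by_outcome
        self.seed = seed

    def fit(self, cohort: CohortTable, y=None):
        covs = self.covariates
        if covs is None:
            covs = (["age_start", "age_end", "sex"]
                    + [p for p in cohort.phenotypes
                       if cohort.tiers.get(p) == 1])
        self.scores_ = fit_group_propensity(cohort, covs, self.group_label)
        left_mask = cohort.data.group == self.group_label

        if self.stratify_by_outcome:
            blocks = []
            for _, idx in cohort.data.groupby("outcome").groups.items():
                sub = self.scores_.loc[idx]
                blocks.append(match_groups_nn(
                    sub, left_mask.loc[idx], self.caliper_sd, self.radius,
                    self.seed))
            self.pairs_ = MatchedPairs(
                pairs=sorted(p for b in blocks for p in b.pairs),
                unmatched_left=sorted(i for b in blocks for i in b.unmatched_left),
                unmatched_right=sorted(i for b in blocks for i in b.unmatched_right),
                config={**blocks[0].config, "stratified_by": "outcome"},
            )
        else:
            self.pairs_ = match_groups_nn(self.scores_, left_mask,
                                          self.caliper_sd, self.radius,
                                          self.seed)
        self.balance_ = balance_report(self.pairs_, cohort, covs, self.cutoff)
        keep = sorted(self.pairs_.matched_ids())
        self.matched_cohort_ = CohortTable(cohort.data.loc[keep].copy(),
                                           dict(cohort.tiers),
                                           list(cohort.phenotypes))
        return self
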
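"""ATE/ATT/ATC estimation for a binary comorbidity exposure.

Potential-outcome notation: Y_i(1), Y_i(0) are subject i's outcomes under
exposure and non-exposure to the comorbidity of interest; the individual
effect is τ_i = Y_i(1) − Y_i(0) and the estimands are its averages over
everyone (ATE), the exposed (ATT) and the unexposed (ATC). With a binary
outcome these are risk differences in [−1, 1].

Exposure T_i = 1{count_i > 0}; the propensity score e(X_i) = P(T=1 | X) is
fit by logistic regression on the adjustment covariates X (log-count
features of the graph-derived adjustment set: the parents of the treatment
and of the outcome in the learned consensus network). Three estimation
strategies share the frame:

* **IPTW** with Hájek self-normalization — each arm's weighted outcome sum
  divided by that arm's weight sum (weights 1/e and 1/(1−e) for ATE;
  1 and e/(1−e) for ATT; (1−e)/e and 1 for ATC). The unnormalised
  Horvitz–Thompson form (dividing by n or n₁ directly) is available via
  ``normalize=False``.
* **Propensity-score matching** — 1-nearest-neighbour on the logit score
  with replacement, averaging within-pair outcome differences over the
  estimand's reference arm.
* **Propensity-score stratification** — score-quantile strata, stratum
  differences pooled with estimand-appropriate weights.

Confidence intervals are percentile bootstrap over subjects, refitting the
propensity model in every replicate (the learned graph is held fixed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.linear_model import LogisticRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.base import BaseEstimator

from ehrcf.features import CodeMatrix, RAW
from ehrcf.structure import EdgeVoteGraph, TieredGraph

logger = logging.getLogger(__name__)

__all__ = [
    "PotentialOutcomeFrame", "PropensityModel", "EffectEstimate",
    "binarize_treatment", "adjustment_set", "hurdle_design",
    "fit_propensity", "effect_iptw",
    "effect_ps_matching", "effect_stratification", "bootstrap_ci",
    "CausalEffectEstimator",
]

ESTIMANDS = ("ate", "att", "atc")
STRATEGIES = ("iptw", "ps_matching", "ps_stratification")


@dataclass
class PotentialOutcomeFrame:
    """Exposure T, outcome Y, and adjustment covariates X per subject."""

    T: np.ndarray
    Y: np.ndarray
    X: np.ndarray          # (n, p); p may be 0
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=np.int8)
        self.Y = np.asarray(self.Y, dtype=np.int8)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(-1, 1)
        if not set(np.unique(self.T)) <= {0, 1}:
            raise ValueError("T must be binary")
        if not set(np.unique(self.Y)) <= {0, 1}:
            raise ValueError("Y must be binary")
        if len(self.T) != len(self.Y) or len(self.T) != len(self.X):
            raise ValueError("T, Y, X must share length")

    @property
    def n(self) -> int:
        return len(self.T)

    @property
    def n1(self) -> int:
        return int(self.T.sum())

    def take(self, idx: np.ndarray) -> "PotentialOutcomeFrame":
        return PotentialOutcomeFrame(self.T[idx], self.Y[idx], self.X[idx],
                                     list(self.covariates))


@dataclass
class PropensityModel:
    """Fitted logistic propensity with clipped scores."""

    coef: np.ndarray
    intercept: float
    scores: np.ndarray
    clip: tuple[float, float]

    def predict(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit
        z = self.intercept + (np.asarray(X, dtype=float) @ self.coef
                              if self.coef.size else 0.0)
        return np.clip(expit(z), *self.clip)


@dataclass
class EffectEstimate:
    """Point estimate with percentile-bootstrap interval."""

    estimand: str
    strategy: str
    point: float
    ci_low: float
    ci_high: float
    bootstrap_draws: np.ndarray
    B: int
    level: float
    seed: int
    n_failures: int = 0

    def as_dict(self) -> dict:
        return {
            "estimand": self.estimand, "strategy": self.strategy,
            "point": self.point, "ci": [self.ci_low, self.ci_high],
            "B": self.B, "level": self.level, "seed": self.seed,
            "bootstrap_failures": self.n_failures,
        }


# ---------------------------------------------------------------------------
# frame construction
# ---------------------------------------------------------------------------

def binarize_treatment(counts) -> np.ndarray:
    """T = 1{count > 0}; refuses log-transformed input."""
    if isinstance(counts, CodeMatrix):
        raise ValueError("pass a single column, not a CodeMatrix")
    if isinstance(counts, pd.Series) and counts.attrs.get("provenance") not in (None, RAW):
        raise ValueError("binarize_treatment requires raw counts")
    arr = np.asarray(counts)
    if np.issubdtype(arr.dtype, np.floating) and not np.allclose(arr, np.rint(arr)):
        raise ValueError("non-integer values: input looks log-transformed; "
                         "binarize raw counts instead")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    T = (arr > 0).astype(np.int8)
    if T.sum() == 0:
        warnings.warn("no exposed subjects in treatment column", stacklevel=2)
    return T


def hurdle_design(raw_counts: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Zero-inflated count covariates for the propensity/adjustment model.

    Each adjustment comorbidity enters twice: as ``log2(1 + count)`` and as
    a presence indicator ``1{count > 0}`` — the hurdle treatment of
    zero-inflated counts, letting a logistic model capture both the
    has-the-condition step and the recording-intensity slope.
    """
    out = {}
    for c in columns:
        col = raw_counts[c].to_numpy(dtype=float)
        out[c] = np.log2(1.0 + col)
        out[f"{c}__present"] = (col > 0).astype(float)
    return pd.DataFrame(out, index=raw_counts.index)


def adjustment_set(votes, treatment: str, outcome: str) -> list[str]:
    """Parents of the treatment plus parents of the outcome in the consensus
    graph, excluding treatment and outcome; sorted for determinism."""
    graph = votes.consensus() if isinstance(votes, EdgeVoteGraph) else votes
    if not isinstance(graph, TieredGraph):
        raise TypeError("expected an EdgeVoteGraph or TieredGraph")
    if treatment not in graph.nodes:
        raise KeyError(f"treatment {treatment!r} not in graph")
    if outcome not in graph.nodes:
        raise KeyError(f"outcome {outcome!r} not in graph")
    parents = graph.parents(treatment) | graph.parents(outcome)
    parents -= {treatment, outcome}
    return sorted(parents)


# ---------------------------------------------------------------------------
# propensity model
# ---------------------------------------------------------------------------

def fit_propensity(
    X: np.ndarray,
    T: np.ndarray,
    clip: tuple[float, float] = (0.01, 0.99),
    max_dim_fraction: float = 0.1,
) -> PropensityModel:
    """Maximum-likelihood logistic fit of T on X with score clipping.

    An empty X yields the intercept-only model (scores = mean(T)). A mild
    L2 penalty is retried when the unpenalized fit fails to converge
    (complete separation), with a warning rather than unbounded scores.
    """
    T = np.asarray(T, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    n, p = X.shape if X.size else (len(T), 0)
    if p >= max(2, int(max_dim_fraction * n)):
        raise ValueError(f"{p} covariates for {n} subjects exceeds the "
                         f"overfit guard ({max_dim_fraction:.0%} of n)")
    if p == 0 or T.min() == T.max():
        score = float(np.clip(T.mean(), *clip))
        return PropensityModel(np.zeros(0), float(logit(score)),
                               np.full(len(T), score), clip)
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            model = LogisticRegression(C=np.inf, max_iter=500)
            model.fit(X, T)
        # perfect in-sample classification means the data are separable, so
        # the unpenalized MLE diverges even if the optimizer "converged"
        separated = bool(((model.predict_proba(X)[:, 1] > 0.5) == T).all())
    except ConvergenceWarning:
        separated = True
    if separated:
        warnings.warn("propensity fit unstable (separation?); "
                      "refitting with an L2 penalty", stacklevel=2)
        model = LogisticRegression(C=1.0, max_iter=2000)
        model.fit(X, T)
    scores = np.clip(model.predict_proba(X)[:, 1], *clip)
    return PropensityModel(model.coef_.ravel(), float(model.intercept_[0]),
                           scores, clip)


# ---------------------------------------------------------------------------
# estimation strategies
# ---------------------------------------------------------------------------

def _check_estimand(estimand: str) -> str:
    estimand = estimand.lower()
    if estimand not in ESTIMANDS:
        raise ValueError(f"estimand must be one of {ESTIMANDS}")
    return estimand


def effect_iptw(
    frame: PotentialOutcomeFrame,
    model: PropensityModel,
    estimand: str = "ate",
    normalize: bool = True,
) -> float:
    """Inverse-probability-weighted risk difference.

    ``normalize=True`` (default) gives the Hájek self-normalized form:
    each arm's weighted mean outcome uses that arm's own weight total, so
    rescaling all weights by a positive constant cannot move the estimate.
    ``normalize=False`` gives the raw Horvitz–Thompson sums divided by n
    (ATE) or n₁/n₀ (ATT/ATC).
    """
    estimand = _check_estimand(estimand)
    T, Y, e = frame.T.astype(float), frame.Y.astype(float), model.scores
    if estimand == "ate":
        w1, w0 = T / e, (1 - T) / (1 - e)
    elif estimand == "att":
        w1, w0 = T, (1 - T) * e / (1 - e)
    else:  # atc
        w1, w0 = T * (1 - e) / e, (1 - T)
    s1, s0 = w1.sum(), w0.sum()
    if s1 == 0 or s0 == 0:
        raise ZeroDivisionError(
            f"zero total weight in the {'exposed' if s1 == 0 else 'unexposed'} arm")
    if normalize:
        return float((w1 * Y).sum() / s1 - (w0 * Y).sum() / s0)
    denom = {"ate": frame.n, "att": frame.n1, "atc": frame.n - frame.n1}[estimand]
    return float(((w1 * Y).sum() - (w0 * Y).sum()) / denom)


def effect_ps_matching(
    frame: PotentialOutcomeFrame,
    model: PropensityModel,
    estimand: str = "ate",
) -> float:
    """1-NN matching on the logit score, with replacement.

    Every reference-arm subject is paired with the nearest opposite-arm
    subject; individual effects Ŷ(1) − Ŷ(0) are averaged over the
    estimand's reference population.
    """
    estimand = _check_estimand(estimand)
    T, Y = frame.T, frame.Y
    ls = logit(model.scores)
    treated, control = np.flatnonzero(T == 1), np.flatnonzero(T == 0)
    if treated.size == 0 or control.size == 0:
        raise ZeroDivisionError("an exposure arm is empty")

    def nearest(src, pool):
        ps = np.sort(ls[pool])
        porder = pool[np.argsort(ls[pool], kind="stable")]
        pos = np.clip(np.searchsorted(ps, ls[src]), 0, len(ps) - 1)
        left = np.clip(pos - 1, 0, len(ps) - 1)
        pick = np.where(np.abs(ps[pos] - ls[src]) <= np.abs(ps[left] - ls[src]),
                        pos, left)
        return porder[pick]

    tau = np.empty(frame.n, dtype=float)
    tau[treated] = Y[treated] - Y[nearest(treated, control)]
    tau[control] = Y[nearest(control, treated)] - Y[control]
    if estimand == "ate":
        return float(tau.mean())
    if estimand == "att":
        return float(tau[treated].mean())
    return float(tau[control].mean())


def effect_stratification(
    frame: PotentialOutcomeFrame,
    model: PropensityModel,
    estimand: str = "ate",
    n_strata: int = 5,
) -> float:
    """Score-quantile stratification estimate.

    Within-stratum exposed-minus-unexposed outcome differences are pooled
    with stratum weights: stratum size for the ATE, exposed count for the
    ATT, unexposed count for the ATC. Strata missing an arm are dropped
    (logged); degenerate scores collapse to a single stratum (the plain
    difference of means).
    """
    estimand = _check_estimand(estimand)
    T, Y, e = frame.T, frame.Y, model.scores
    qs = np.quantile(e, np.linspace(0, 1, n_strata + 1))
    edges = np.unique(qs)
    if len(edges) < 2:
        strata = np.zeros(frame.n, dtype=int)
    else:
        strata = np.clip(np.searchsorted(edges, e, side="right") - 1,
                         0, len(edges) - 2)
    diffs, weights, dropped = [], [], 0
    for s in np.unique(strata):
        m = strata == s
        n1, n0 = T[m].sum(), (1 - T[m]).sum()
        if n1 == 0 or n0 == 0:
            dropped += 1
            continue
        diffs.append(Y[m][T[m] == 1].mean() - Y[m][T[m] == 0].mean())
        weights.append({"ate": m.sum(), "att": n1, "atc": n0}[estimand])
    if not diffs:
        raise ZeroDivisionError("every stratum lacks an exposure arm")
    if dropped:
        logger.info("stratification dropped %d strata missing an arm", dropped)
    w = np.asarray(weights, dtype=float)
    return float(np.average(np.asarray(diffs), weights=w))


_STRATEGY_FN = {
    "iptw": effect_iptw,
    "ps_matching": effect_ps_matching,
    "ps_stratification": effect_stratification,
}


def estimate_effect(
    frame: PotentialOutcomeFrame,
    estimand: str = "ate",
    strategy: str = "iptw",
    clip: tuple[float, float] = (0.01, 0.99),
    **kwargs,
) -> float:
    """Fit the propensity model and apply one strategy (single pass)."""
    model = fit_propensity(frame.X, frame.T, clip=clip)
    return _STRATEGY_FN[strategy](frame, model, estimand, **kwargs)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    estimator,
    frame: PotentialOutcomeFrame,
    B: int = 100,
    level: float = 0.95,
    seed: int = 0,
    max_failure_fraction: float = 0.2,
) -> EffectEstimate:
    """Percentile bootstrap over subjects.

    ``estimator`` is a closure ``frame -> float`` that re-runs the *whole*
    downstream estimation (propensity refit included). Replicates that
    raise are dropped and counted; more than ``max_failure_fraction``
    failures aborts.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    point = float(estimator(frame))
    rng = np.random.default_rng(seed)
    draws, failures = [], 0
    for _ in range(B):
        idx = rng.integers(0, frame.n, size=frame.n)
        try:
            draws.append(float(estimator(frame.take(idx))))
        except Exception as exc:
            failures += 1
            logger.debug("bootstrap replicate failed: %s", exc)
    if failures > max_failure_fraction * B:
        raise RuntimeError(f"{failures}/{B} bootstrap replicates failed")
    draws = np.asarray(draws)
    lo, hi = np.percentile(draws, [100 * (1 - level) / 2,
                                   100 * (1 + level) / 2])
    est = EffectEstimate(
        estimand=getattr(estimator, "estimand", "ate"),
        strategy=getattr(estimator, "strategy", "custom"),
        point=point, ci_low=float(lo), ci_high=float(hi),
        bootstrap_draws=draws, B=B, level=level, seed=seed,
        n_failures=failures)
    return est


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class CausalEffectEstimator(BaseEstimator):
    """One-treatment causal effect estimator in scikit-learn form.

    Parameters
    ----------
    estimand : "ate" | "att" | "atc"
    strategy : "iptw" | "ps_matching" | "ps_stratification"
    normalize : Hájek self-normalization for IPTW.
    B, level, seed : bootstrap settings (``B=0`` skips the bootstrap).

    ``fit(X, y, treatment=...)`` takes the adjustment covariates X
    (DataFrame or array of log counts), binary outcome y, and the binary
    exposure vector. Fitted attributes: ``propensity_``, ``point_``,
    ``estimate_`` (an :class:`EffectEstimate` when B > 0).
    """

    def __init__(self, estimand: str = "ate", strategy: str = "iptw",
                 normalize: bool = True, clip: tuple = (0.01, 0.99),
                 n_strata: int = 5, B: int = 100, level: float = 0.95,
                 seed: int = 0):
        self.estimand = estimand
        self.strategy = strategy
        self.normalize = normalize
        self.clip = clip
        self.n_strata = n_strata
        self.B = B
        self.level = level
        self.seed = seed

    def _single(self, frame: PotentialOutcomeFrame) -> float:
        model = fit_propensity(frame.X, frame.T, clip=self.clip)
        kwargs = {}
        if self.strategy == "iptw":
            kwargs["normalize"] = self.normalize
        elif self.strategy == "ps_stratification":
            kwargs["n_strata"] = self.n_strata
        return _STRATEGY_FN[self.strategy](frame, model, self.estimand,
                                           **kwargs)

    def fit(self, X, y, treatment=None):
        if treatment is None:
            raise ValueError("fit requires the binary treatment vector")
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else []
        frame = PotentialOutcomeFrame(np.asarray(treatment), np.asarray(y),
                                      np.asarray(X, dtype=float)
                                      if np.size(X) else
                                      np.empty((len(y), 0)),
                                      covariates=cols)
        self.frame_ = frame
        self.propensity_ = fit_propensity(frame.X, frame.T, clip=self.clip)
        self.point_ = self._single(frame)
        if self.B and self.B > 0:
            closure = self._single
            est = bootstrap_ci(closure, frame, B=self.B, level=self.level,
                               seed=self.seed)
            est.estimand, est.strategy = self.estimand, self.strategy
            est.point = self.point_
            self.estimate_ = est
        else:
            self.estimate_ = None
        return self
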
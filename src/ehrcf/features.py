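"""Diagnosis events → analysis feature matrix.

Raw EHR diagnosis events (one row per billed code occurrence) are condensed
into clinically meaningful phenotype features in three steps: many-to-one
code grouping through a user-supplied code map (PheWAS-style hierarchies are
the canonical source, but any mapping table works), a prevalence filter that
keeps only phenotypes recorded in more than a minimum fraction of subjects
(capped at a top-k by prevalence), and the variance-stabilising
``log2(1 + count)`` transform for the skewed occurrence counts.

A :class:`CodeMatrix` carries a provenance flag (``raw_counts`` vs
``log_transformed``) so the transform cannot be applied twice and treatment
binarisation cannot silently run on transformed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CodeMap", "CodeMatrix", "aggregate_codes", "prevalence_filter",
    "log_transform", "inverse_log_transform", "PrevalenceFilter",
    "LogCountTransformer",
]

RAW = "raw_counts"
LOGGED = "log_transformed"


@dataclass
class CodeMap:
    """Many-to-one map from raw diagnosis codes to phenotype labels.

    ``unmapped`` policy: ``"drop"`` discards events whose code is absent
    from the map; ``"passthrough"`` keeps the raw code as its own phenotype.
    """

    mapping: dict[str, str]
    unmapped: str = "drop"

    def __post_init__(self):
        if self.unmapped not in ("drop", "passthrough"):
            raise ValueError(f"unknown unmapped policy {self.unmapped!r}")

    @classmethod
    def identity(cls) -> "CodeMap":
        return cls(mapping={}, unmapped="passthrough")

    @classmethod
    def from_tsv(cls, path: str, unmapped: str = "drop") -> "CodeMap":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                         names=["raw_code", "phenotype"], comment="#")
        return cls(mapping=dict(zip(df.raw_code, df.phenotype)), unmapped=unmapped)

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(sorted(self.mapping.items()),
                     columns=["raw_code", "phenotype"]).to_csv(
            path, sep="\t", header=False, index=False)


@dataclass
class CodeMatrix:
    """Subjects × phenotypes matrix with count provenance.

    ``values`` is indexed by subject id; entries are raw occurrence counts
    (``provenance == "raw_counts"``) or ``log2(1+count)``
    (``provenance == "log_transformed"``).
    """

    values: pd.DataFrame
    provenance: str = RAW

    def __post_init__(self):
        if self.provenance not in (RAW, LOGGED):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        # tag the frame so derived Series carry provenance to consumers
        self.values.attrs["provenance"] = self.provenance

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def phenotypes(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path: str) -> None:
        out = self.values.copy()
        out.attrs = {}
        out.to_csv(path, index=True, index_label="subject_id")

    @classmethod
    def from_csv(cls, path: str, provenance: str = RAW) -> "CodeMatrix":
        return cls(pd.read_csv(path, index_col="subject_id"), provenance=provenance)


def aggregate_codes(
    events: pd.DataFrame,
    code_map: CodeMap,
    windows: pd.DataFrame,
) -> CodeMatrix:
    """Count mapped events falling inside each subject's observation window.

    Parameters
    ----------
    events : DataFrame with columns ``subject_id``, ``raw_code``, ``event_age``.
    code_map : CodeMap
    windows : DataFrame indexed by subject id with ``age_start``/``age_end``
        columns (a cohort table's demographic block works directly). Every
        subject in ``windows`` gets a row, even with zero events.

    Raises
    ------
    KeyError
        If events reference subjects missing from ``windows`` (ids listed).
    """
    required = {"subject_id", "raw_code", "event_age"}
    if not required.issubset(events.columns):
        raise ValueError(f"events must have columns {sorted(required)}")
    unknown = set(events.subject_id) - set(windows.index)
    if unknown:
        raise KeyError(
            "events reference subjects absent from the window table: "
            + ", ".join(map(str, sorted(unknown)[:20])))

    ev = events.copy()
    ev["phenotype"] = ev.raw_code.astype(str).map(code_map.mapping)
    if code_map.unmapped == "passthrough":
        ev["phenotype"] = ev.phenotype.fillna(ev.raw_code.astype(str))
    else:
        ev = ev.dropna(subset=["phenotype"])

    start = windows.age_start.reindex(ev.subject_id).to_numpy()
    end = windows.age_end.reindex(ev.subject_id).to_numpy()
    inside = (ev.event_age.to_numpy() >= start) & (ev.event_age.to_numpy() <= end)
    ev = ev[inside]

    counts = (ev.groupby(["subject_id", "phenotype"]).size()
                .unstack(fill_value=0)
                .reindex(windows.index, fill_value=0))
    counts.columns.name = None
    counts.index.name = windows.index.name or "subject_id"
    return CodeMatrix(counts.astype(np.int64), provenance=RAW)


def prevalence_filter(
    matrix: CodeMatrix,
    min_prevalence: float = 0.05,
    top_k: int | None = 100,
) -> CodeMatrix:
    """Keep phenotypes present (count > 0) in *more than* ``min_prevalence``
    of subjects; if more than ``top_k`` survive, keep the ``top_k`` most
    prevalent. Columns come back ordered by descending prevalence, ties
    broken by label.
    """
    if matrix.provenance != RAW:
        raise ValueError("prevalence_filter expects raw counts")
    if not 0.0 <= min_prevalence < 1.0:
        raise ValueError("min_prevalence must lie in [0, 1)")
    prev = (matrix.values > 0).mean(axis=0)
    if min_prevalence > 0:
        prev = prev[prev > min_prevalence]
    else:
        prev = prev[prev > 0]
    order = sorted(prev.index, key=lambda c: (-prev[c], c))
    if top_k is not None:
        order = order[:top_k]
    return CodeMatrix(matrix.values[order].copy(), provenance=RAW)


def log_transform(matrix: CodeMatrix) -> CodeMatrix:
    """Elementwise ``log2(1 + count)``; refuses already-transformed input."""
    if matrix.provenance == LOGGED:
        raise ValueError("matrix is already log-transformed")
    return CodeMatrix(np.log2(1.0 + matrix.values), provenance=LOGGED)


def inverse_log_transform(matrix: CodeMatrix) -> CodeMatrix:
    """Recover integer counts via ``2**x - 1`` (exact on integer counts)."""
    if matrix.provenance != LOGGED:
        raise ValueError("matrix is not log-transformed")
    counts = np.rint(np.exp2(matrix.values) - 1.0).astype(np.int64)
    return CodeMatrix(counts, provenance=RAW)


class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """scikit-learn transformer over raw-count DataFrames.

    ``fit`` learns the surviving column set (strict ``> min_prevalence``
    presence fraction, then top-``top_k`` by prevalence); ``transform``
    subsets and reorders columns accordingly.
    """

    def __init__(self, min_prevalence: float = 0.05, top_k: int | None = 100):
        self.min_prevalence = min_prevalence
        self.top_k = top_k

    def fit(self, X: pd.DataFrame, y=None):
        kept = prevalence_filter(CodeMatrix(pd.DataFrame(X)),
                                 self.min_prevalence, self.top_k)
        self.columns_ = kept.phenotypes
        self.prevalence_ = (pd.DataFrame(X) > 0).mean(axis=0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.columns_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.columns_, dtype=object)


class LogCountTransformer(BaseEstimator, TransformerMixin):
    """Stateless ``log2(1+count)`` transformer with exact inverse."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        if (X.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        return np.log2(1.0 + X)

    def inverse_transform(self, X):
        return np.rint(np.exp2(pd.DataFrame(X)) - 1.0).astype(np.int64)
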
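"""Composite drug-likeness: the summed z-score index and tail quadrants.

The five drug-similarity components — mean quantitative Jaccard, mean
combined Tanimoto index, RDL, ADMET-score and the (negated) rule-of-five
count — are each z-standardized over the compound set being ranked and
summed. QED is kept out of the sum and reported alongside it; the joint
tails of (summed index, QED) define the corner quadrants used for triage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

COMPONENTS = ("jaccard", "tanimoto", "rdl", "admet", "ro5")

QUADRANT_LABELS = (
    "consistent_druglike",
    "druglike_low_qed",
    "least_druglike",
    "qed_only",
    "interior",
)


class CompositeError(ValueError):
    pass


def zstandardize(values: Sequence[float], name: str = "component") -> np.ndarray:
    """Standardize to mean 0, SD 1 using the population (n) SD."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise CompositeError(f"{name}: need >= 2 values to standardize")
    sd = arr.std(ddof=0)
    if sd == 0:
        raise CompositeError(f"{name}: zero standard deviation")
    return (arr - arr.mean()) / sd


def summed_index(components: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize the five components and sum them per compound.

    ``components`` must carry the columns jaccard, tanimoto, rdl, admet and
    ro5 (the raw rule-of-five count — its z-score is negated internally so
    that fewer Lipinski exceedances push the summed index up). The summed
    index has dataset mean 0 by construction.
    """
    missing = [c for c in COMPONENTS if c not in components.columns]
    if missing:
        raise CompositeError(f"missing component columns: {missing}")
    lengths = components[list(COMPONENTS)].notna().sum()
    if (lengths != len(components)).any():
        bad = lengths.index[lengths != len(components)].tolist()
        raise CompositeError(f"missing values in components: {bad}")
    out = pd.DataFrame(index=components.index)
    for c in ("jaccard", "tanimoto", "rdl", "admet"):
        out[f"z_{c}"] = zstandardize(components[c], name=c)
    out["z_negro5"] = -zstandardize(components["ro5"], name="ro5")
    out["summed"] = out[["z_jaccard", "z_tanimoto", "z_rdl", "z_admet", "z_negro5"]].sum(axis=1)
    return out


@dataclass(frozen=True)
class QuadrantRule:
    """One corner region in the (summed index, QED) plane.

    ``qed_op`` is ``">"`` (QED above ``qed_cut``) or ``"=0"`` (QED rounds
    to 0.00 at two decimals); ``summed_op`` is ``">"`` or ``"<"``.
    """

    label: str
    summed_op: str
    summed_cut: float
    qed_op: str
    qed_cut: float = 0.0

    def matches(self, summed: np.ndarray, qed: np.ndarray) -> np.ndarray:
        if self.summed_op == ">":
            s = summed > self.summed_cut
        elif self.summed_op == "<":
            s = summed < self.summed_cut
        else:
            raise CompositeError(f"bad summed_op {self.summed_op!r}")
        if self.qed_op == ">":
            q = qed > self.qed_cut
        elif self.qed_op == "=0":
            q = np.round(qed, 2) == 0.0
        else:
            raise CompositeError(f"bad qed_op {self.qed_op!r}")
        return s & q


#: Default corner thresholds; they correspond to distribution tails of one
#: particular library and are replaceable (e.g. by percentile-based cuts).
DEFAULT_QUADRANTS = (
    QuadrantRule("consistent_druglike", ">", 2.42, ">", 0.55),
    QuadrantRule("druglike_low_qed", ">", 2.06, "=0"),
    QuadrantRule("least_druglike", "<", -12.94, "=0"),
    QuadrantRule("qed_only", "<", -2.6, ">", 0.53),
)


def _qed_overlap(a: QuadrantRule, b: QuadrantRule) -> bool:
    if a.qed_op == "=0" and b.qed_op == "=0":
        return True
    if a.qed_op == "=0" or b.qed_op == "=0":
        gt = a if a.qed_op == ">" else b
        return gt.qed_cut < 0.005  # qed > cut can still round to 0.00
    return True  # two ">" conditions always share high-QED compounds


def _summed_overlap(a: QuadrantRule, b: QuadrantRule) -> bool:
    if a.summed_op == b.summed_op:
        return True
    lo = a if a.summed_op == "<" else b
    hi = b if a.summed_op == "<" else a
    return hi.summed_cut < lo.summed_cut


def validate_quadrants(rules: Sequence[QuadrantRule]) -> None:
    """Reject corner configurations in which two regions can both match."""
    labels = [r.label for r in rules]
    if len(set(labels)) != len(labels):
        raise CompositeError("duplicate quadrant labels")
    for i, a in enumerate(rules):
        for b in rules[i + 1:]:
            if _qed_overlap(a, b) and _summed_overlap(a, b):
                raise CompositeError(
                    f"overlapping quadrant definitions: {a.label} and {b.label}"
                )


def classify_quadrants(
    summed: Sequence[float],
    qed: Sequence[float],
    rules: Sequence[QuadrantRule] = DEFAULT_QUADRANTS,
) -> np.ndarray:
    """Assign each compound exactly one quadrant label.

    Corners take precedence over the interior; the rule set is validated
    for overlaps first so the assignment is unambiguous.
    """
    validate_quadrants(rules)
    summed = np.asarray(summed, dtype=float)
    qed = np.asarray(qed, dtype=float)
    if summed.shape != qed.shape:
        raise CompositeError("summed and qed lengths differ")
    labels = np.full(summed.shape, "interior", dtype=object)
    for rule in rules:
        labels[rule.matches(summed, qed)] = rule.label
    return labels


class CompositeIndex(BaseEstimator):
    """Summed drug-likeness index with quadrant classification.

    ``fit_transform`` takes a DataFrame with the five component columns
    (jaccard, tanimoto, rdl, admet, ro5) plus ``qed`` and returns the
    z-scores, the summed index (dataset mean 0) and the quadrant label.
    Standardization is over the supplied compound set — normally the NP
    library being ranked; pass drugs/toxins in the same frame for the
    pooled alternative.
    """

    def __init__(self, rules: Sequence[QuadrantRule] = DEFAULT_QUADRANTS):
        self.rules = rules

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        if "qed" not in X.columns:
            raise CompositeError("missing qed column")
        out = summed_index(X)
        out["qed"] = X["qed"]
        out["quadrant"] = classify_quadrants(
            out["summed"].to_numpy(), out["qed"].to_numpy(), self.rules
        )
        self.components_ = list(COMPONENTS)
        return out

    fit = fit_transform


def rank_report(*tables: pd.DataFrame) -> pd.DataFrame:
    """Merge id-aligned score tables and rank by summed index.

    All tables must cover the same ids; the merge is lossless (every input
    column appears). Rows sort by descending summed index with a stable
    lexicographic id tie-break.
    """
    if not tables:
        raise CompositeError("no tables to merge")
    base_ids = set(tables[0].index)
    for t in tables[1:]:
        missing = sorted(base_ids.symmetric_difference(t.index))
        if missing:
            raise CompositeError(f"id mismatch across inputs: {missing[:10]}")
    merged = pd.concat([t.loc[sorted(base_ids)] for t in tables], axis=1)
    dup = merged.columns[merged.columns.duplicated()].tolist()
    if dup:
        merged = merged.loc[:, ~merged.columns.duplicated()]
    if "summed" not in merged.columns:
        raise CompositeError("no summed column to rank by")
    merged = merged.sort_index()  # stable id order for ties
    return merged.sort_values("summed", ascending=False, kind="stable")
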
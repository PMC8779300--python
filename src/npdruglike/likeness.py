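"""Drug-likeness indices: QED, RDL, rule-of-five violations, ADMET-score.

All four indices are fitted on a reference drug set and then applied to any
compound library:

* QED — geometric mean of eight per-property desirability scores, each a
  smoothed, peak-normalized histogram of the property over reference drugs.
* RDL — relative drug likelihood: geometric mean over the eight properties
  of ``f_drug / (f_drug + f_ref)``, the relative likelihood that a compound
  with that property value is a drug rather than a member of a non-drug
  reference set (here, toxins).
* Ro5 — count of Lipinski rule-of-five thresholds exceeded (0 best, 4 worst).
* ADMET-score — weighted sum of 18 binary ADMET endpoint predictions
  (1 beneficial / 0 harmful), standardized to the drug range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from numbers import Real
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .descriptors import PROPERTY_NAMES, PropertyVector
from .io import EndpointTable

logger = logging.getLogger(__name__)


class LikenessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Desirability models and QED


@dataclass
class DesirabilityModel:
    """Peak-normalized, floored desirability over a property grid.

    ``d[i]`` applies on ``edges[i] <= x < edges[i+1]``; outside the grid the
    desirability is the floor (an undesirable tail value).
    """

    property_name: str
    edges: np.ndarray
    d: np.ndarray
    floor: float

    def __post_init__(self) -> None:
        if not math.isclose(float(self.d.max()), 1.0, rel_tol=0, abs_tol=1e-12):
            raise LikenessError(f"{self.property_name}: max desirability must be 1")
        if (self.d < self.floor - 1e-15).any():
            raise LikenessError(f"{self.property_name}: desirability below floor")

    def __call__(self, x) -> np.ndarray | float:
        x_arr = np.atleast_1d(np.asarray(x, dtype=float))
        idx = np.searchsorted(self.edges, x_arr, side="right") - 1
        inside = (idx >= 0) & (idx < len(self.d))
        # right edge belongs to the last cell
        at_right = np.isclose(x_arr, self.edges[-1]) & (idx == len(self.d))
        idx = np.where(at_right, len(self.d) - 1, idx)
        inside = inside | at_right
        out = np.full(x_arr.shape, self.floor)
        out[inside] = self.d[idx[inside]]
        return out if np.ndim(x) else float(out[0])


def _histogram_grid(values: np.ndarray, bins) -> np.ndarray:
    if isinstance(bins, (str, int)):
        return np.histogram_bin_edges(values, bins=bins)
    return np.asarray(bins, dtype=float)


def _smooth(counts: np.ndarray) -> np.ndarray:
    """3-cell moving average with edge reflection."""
    if len(counts) < 3:
        return counts.astype(float)
    padded = np.concatenate([counts[:1], counts, counts[-1:]])
    kernel = np.array([0.25, 0.5, 0.25])
    return np.convolve(padded, kernel, mode="valid")


def fit_desirability(
    drug_values: Sequence[float],
    property_name: str,
    bins="fd",
    floor: float = 1e-6,
    smooth: bool = True,
    min_n: int = 30,
) -> DesirabilityModel:
    """Fit a desirability model from reference-drug property values.

    Histogram (Freedman-Diaconis bins by default), lightly smoothed,
    normalized so the modal cell scores 1, and floored at ``floor`` so
    the geometric mean in QED never collapses to exactly 0.
    """
    values = np.asarray(drug_values, dtype=float)
    if len(values) < min_n:
        raise LikenessError(
            f"{property_name}: need >= {min_n} drug values, got {len(values)}"
        )
    if np.ptp(values) == 0:
        v = values[0]
        width = max(abs(v) * 1e-6, 0.5)
        edges = np.array([v - width, v + width])
        d = np.array([1.0])
        return DesirabilityModel(property_name, edges, d, floor)
    edges = _histogram_grid(values, bins)
    counts, _ = np.histogram(values, bins=edges)
    heights = _smooth(counts.astype(float)) if smooth else counts.astype(float)
    d = heights / heights.max()
    d = np.maximum(d, floor)
    d /= d.max()  # flooring cannot shift the peak below 1
    return DesirabilityModel(property_name, edges, d, floor)


def qed(
    pv: PropertyVector | Mapping[str, float],
    models: Mapping[str, DesirabilityModel],
) -> float:
    """Geometric mean of the eight desirability scores: ``(prod d_i)^(1/8)``."""
    if isinstance(pv, PropertyVector):
        pv = pv.as_dict()
    missing = [p for p in PROPERTY_NAMES if p not in models]
    if missing:
        raise LikenessError(f"missing desirability models for: {missing}")
    logs = [math.log(float(models[p](pv[p]))) for p in PROPERTY_NAMES]
    return math.exp(sum(logs) / len(PROPERTY_NAMES))


class QEDScorer(BaseEstimator):
    """Quantitative estimate of drug-likeness fitted on a reference drug set.

    ``fit`` takes a DataFrame of the eight properties over drugs; ``score``
    returns the per-compound geometric mean of desirabilities in (0, 1].
    """

    def __init__(self, bins="fd", floor: float = 1e-6, smooth: bool = True, min_n: int = 30):
        self.bins = bins
        self.floor = floor
        self.smooth = smooth
        self.min_n = min_n

    def fit(self, X: pd.DataFrame, y=None) -> "QEDScorer":
        self._check_columns(X)
        self.models_ = {
            p: fit_desirability(
                X[p].to_numpy(), p, bins=self.bins, floor=self.floor,
                smooth=self.smooth, min_n=self.min_n,
            )
            for p in PROPERTY_NAMES
        }
        return self

    def score_samples(self, X: pd.DataFrame) -> pd.Series:
        self._check_fitted()
        self._check_columns(X)
        log_sum = np.zeros(len(X))
        for p in PROPERTY_NAMES:
            log_sum += np.log(self.models_[p](X[p].to_numpy(dtype=float)))
        return pd.Series(np.exp(log_sum / len(PROPERTY_NAMES)), index=X.index, name="qed")

    def transform(self, X: pd.DataFrame) -> pd.Series:
        return self.score_samples(X)

    def _check_fitted(self) -> None:
        if not hasattr(self, "models_"):
            raise LikenessError("QEDScorer is not fitted")

    @staticmethod
    def _check_columns(X: pd.DataFrame) -> None:
        missing = [p for p in PROPERTY_NAMES if p not in X.columns]
        if missing:
            raise LikenessError(f"property table lacks columns: {missing}")


# ---------------------------------------------------------------------------
# Relative drug likelihood (RDL)


@dataclass
class RdlPropertyModel:
    """Drug and reference density estimates on one shared grid."""

    property_name: str
    edges: np.ndarray
    f_drug: np.ndarray
    f_ref: np.ndarray
    eps: float

    def relative_likelihood(self, x) -> np.ndarray | float:
        """``f_drug / (f_drug + f_ref)`` at x; outside the grid the boundary
        cell is used (flagged in the log)."""
        x_arr = np.atleast_1d(np.asarray(x, dtype=float))
        idx = np.searchsorted(self.edges, x_arr, side="right") - 1
        n_out = int(((idx < 0) | (idx > len(self.f_drug) - 1)).sum())
        if n_out:
            logger.info(
                "%s: %d value(s) outside the fitted grid evaluated at boundary",
                self.property_name, n_out,
            )
        idx = np.clip(idx, 0, len(self.f_drug) - 1)
        rl = self.f_drug[idx] / (self.f_drug[idx] + self.f_ref[idx])
        return rl if np.ndim(x) else float(rl[0])


@dataclass
class RdlModel:
    models: dict[str, RdlPropertyModel]


def fit_rdl_model(
    drug_values: Sequence[float],
    reference_values: Sequence[float],
    property_name: str,
    bins="fd",
    eps: float = 1e-9,
    min_n: int = 30,
) -> RdlPropertyModel:
    """Estimate drug and reference densities for one property on one grid.

    The grid spans both samples; its bin width follows the drug sample
    (Freedman-Diaconis by default). A pseudocount ``eps`` is added to both
    densities so the relative likelihood stays strictly inside (0, 1).
    """
    drug = np.asarray(drug_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if len(drug) < min_n or len(ref) < min_n:
        raise LikenessError(
            f"{property_name}: need >= {min_n} values per set "
            f"(got drug={len(drug)}, reference={len(ref)})"
        )
    lo = min(drug.min(), ref.min())
    hi = max(drug.max(), ref.max())
    if hi == lo:
        edges = np.array([lo - 0.5, hi + 0.5])
    else:
        drug_edges = _histogram_grid(drug, bins)
        width = drug_edges[1] - drug_edges[0] if len(drug_edges) > 1 else (hi - lo)
        n_bins = max(1, min(500, int(np.ceil((hi - lo) / width))))
        edges = np.linspace(lo, hi, n_bins + 1)
    f_drug, _ = np.histogram(drug, bins=edges, density=True)
    f_ref, _ = np.histogram(ref, bins=edges, density=True)
    return RdlPropertyModel(property_name, edges, f_drug + eps, f_ref + eps, eps)


def rdl(pv: PropertyVector | Mapping[str, float], model: RdlModel) -> float:
    """Geometric mean over the eight properties of the relative likelihood
    that the compound is a drug; values nearer 1 mean more drug-like."""
    if isinstance(pv, PropertyVector):
        pv = pv.as_dict()
    missing = [p for p in PROPERTY_NAMES if p not in model.models]
    if missing:
        raise LikenessError(f"missing RDL models for: {missing}")
    logs = [
        math.log(float(model.models[p].relative_likelihood(pv[p])))
        for p in PROPERTY_NAMES
    ]
    return math.exp(sum(logs) / len(PROPERTY_NAMES))


class RDLScorer(BaseEstimator):
    """Relative drug likelihood fitted on drug and non-drug reference sets."""

    def __init__(self, bins="fd", eps: float = 1e-9, min_n: int = 30):
        self.bins = bins
        self.eps = eps
        self.min_n = min_n

    def fit(self, X: pd.DataFrame, X_reference: pd.DataFrame) -> "RDLScorer":
        QEDScorer._check_columns(X)
        QEDScorer._check_columns(X_reference)
        self.model_ = RdlModel(
            {
                p: fit_rdl_model(
                    X[p].to_numpy(), X_reference[p].to_numpy(), p,
                    bins=self.bins, eps=self.eps, min_n=self.min_n,
                )
                for p in PROPERTY_NAMES
            }
        )
        return self

    def score_samples(self, X: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "model_"):
            raise LikenessError("RDLScorer is not fitted")
        QEDScorer._check_columns(X)
        log_sum = np.zeros(len(X))
        for p in PROPERTY_NAMES:
            log_sum += np.log(
                self.model_.models[p].relative_likelihood(X[p].to_numpy(dtype=float))
            )
        return pd.Series(np.exp(log_sum / len(PROPERTY_NAMES)), index=X.index, name="rdl")


# ---------------------------------------------------------------------------
# Rule of five


def ro5_violations(mw: float, logp: float, hbd: float, hba: float) -> int:
    """Count of Lipinski thresholds NOT satisfied, in [0, 4].

    Thresholds are strict: log P < 5, MW < 500 Da, HBD < 5, HBA < 10;
    a boundary value counts as a violation. All four inputs are required —
    there is no partial scoring.
    """
    vals = (mw, logp, hbd, hba)
    if any(v is None or (isinstance(v, Real) and math.isnan(float(v))) for v in vals):
        raise LikenessError(f"ro5_violations requires all four values, got {vals}")
    return int(not mw < 500) + int(not logp < 5) + int(not hbd < 5) + int(not hba < 10)


def ro5_violations_table(X: pd.DataFrame) -> pd.Series:
    """Vectorized rule-of-five score over a property table."""
    for col in ("MW", "ALOGP", "HBD", "HBA"):
        if col not in X.columns:
            raise LikenessError(f"property table lacks column {col!r}")
        if X[col].isna().any():
            raise LikenessError(f"missing {col} values; no partial Ro5 scoring")
    score = (
        (~(X["MW"] < 500)).astype(int)
        + (~(X["ALOGP"] < 5)).astype(int)
        + (~(X["HBD"] < 5)).astype(int)
        + (~(X["HBA"] < 10)).astype(int)
    )
    return score.rename("ro5")


# ---------------------------------------------------------------------------
# ADMET-score


@dataclass
class AdmetWeights:
    """Per-endpoint weights: ``w1`` = beneficial-value frequency among
    reference drugs; ``w2`` = QSAR model performance; ``w3`` = endpoint
    importance. ``w2``/``w3`` default to ones when no table is supplied."""

    w1: pd.Series
    w2: pd.Series
    w3: pd.Series

    def __post_init__(self) -> None:
        if ((self.w1 < 0) | (self.w1 > 1)).any():
            raise LikenessError("w1 must lie in [0, 1]")
        if (self.w2 <= 0).any() or (self.w3 <= 0).any():
            raise LikenessError("w2 and w3 must be positive")

    @property
    def combined(self) -> pd.Series:
        return self.w1 * self.w2 * self.w3


def derive_admet_weights(
    drug_endpoints: EndpointTable | pd.DataFrame,
    w2: Mapping[str, float] | None = None,
    w3: Mapping[str, float] | None = None,
) -> AdmetWeights:
    """Derive per-endpoint weights from the reference drug endpoint table.

    ``w1_i`` is the column mean (frequency of the beneficial value among
    drugs). ``w2``/``w3`` come from configuration; absent entries default
    to 1 and the fallback is logged.
    """
    values = drug_endpoints.values if isinstance(drug_endpoints, EndpointTable) else drug_endpoints
    if values.empty:
        raise LikenessError("drug endpoint table is empty")
    w1 = values.mean(axis=0)
    ones = pd.Series(1.0, index=values.columns)
    if w2 is None:
        logger.info("no w2 (QSAR performance) table supplied; using all-ones default")
        w2_s = ones.copy()
    else:
        w2_s = ones.copy()
        w2_s.update(pd.Series(w2, dtype=float))
    if w3 is None:
        logger.info("no w3 (endpoint importance) table supplied; using all-ones default")
        w3_s = ones.copy()
    else:
        w3_s = ones.copy()
        w3_s.update(pd.Series(w3, dtype=float))
    return AdmetWeights(w1=w1, w2=w2_s, w3=w3_s)


def admet_score(
    endpoints: pd.Series | pd.DataFrame,
    weights: AdmetWeights,
    drug_raw_min: float,
    drug_raw_max: float,
) -> tuple:
    """Raw and drug-range-standardized ADMET-score.

    ``raw = sum_i w1_i * w2_i * w3_i * v_i``; the standardized score maps
    the drug raw range onto [0, 1]. Non-drug compounds may fall outside
    [0, 1] and are not clipped.
    """
    if drug_raw_min >= drug_raw_max:
        raise LikenessError("drug raw min must be < drug raw max")
    w = weights.combined
    if isinstance(endpoints, pd.Series):
        raw = float((endpoints.reindex(w.index) * w).sum())
    else:
        raw = endpoints[w.index].to_numpy() @ w.to_numpy()
    std = (raw - drug_raw_min) / (drug_raw_max - drug_raw_min)
    return raw, std


class AdmetScorer(BaseEstimator):
    """ADMET-score fitted on a reference drug endpoint table.

    Fitting derives ``w1`` (beneficial frequency over drugs) and the drug
    raw-score range used to standardize all other compounds.
    """

    def __init__(self, w2: Mapping[str, float] | None = None,
                 w3: Mapping[str, float] | None = None):
        self.w2 = w2
        self.w3 = w3

    def fit(self, X: EndpointTable | pd.DataFrame, y=None) -> "AdmetScorer":
        values = X.values if isinstance(X, EndpointTable) else X
        self.weights_ = derive_admet_weights(values, self.w2, self.w3)
        raw = values.to_numpy() @ self.weights_.combined.to_numpy()
        self.drug_raw_min_ = float(raw.min())
        self.drug_raw_max_ = float(raw.max())
        if self.drug_raw_min_ == self.drug_raw_max_:
            raise LikenessError("drug raw scores are constant; cannot standardize")
        return self

    def score_samples(self, X: EndpointTable | pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "weights_"):
            raise LikenessError("AdmetScorer is not fitted")
        values = X.values if isinstance(X, EndpointTable) else X
        raw = pd.Series(
            values[self.weights_.combined.index].to_numpy()
            @ self.weights_.combined.to_numpy(),
            index=values.index,
        )
        std = (raw - self.drug_raw_min_) / (self.drug_raw_max_ - self.drug_raw_min_)
        return pd.DataFrame({"admet_raw": raw, "admet_std": std})


# ---------------------------------------------------------------------------
# Combined per-molecule profile


@dataclass
class LikenessProfile:
    """Per-molecule drug-likeness scores."""

    id: str
    qed: float
    rdl: float
    ro5: int
    admet_raw: float
    admet_std: float


def likeness_table(
    properties: pd.DataFrame,
    categories: pd.Series,
    endpoints: pd.DataFrame | None = None,
    reference_category: str = "toxin",
    qed_scorer: QEDScorer | None = None,
    rdl_scorer: RDLScorer | None = None,
    admet_scorer: AdmetScorer | None = None,
) -> pd.DataFrame:
    """Fit all likeness scorers on the drug subset and score every compound.

    Returns an id-indexed DataFrame with columns qed, rdl, ro5 and — when
    an endpoint table is given — admet_raw, admet_std.
    """
    categories = categories.reindex(properties.index)
    drugs = properties.loc[categories == "drug"]
    reference = properties.loc[categories == reference_category]
    qs = (qed_scorer or QEDScorer()).fit(drugs)
    rs = (rdl_scorer or RDLScorer()).fit(drugs, reference)
    out = pd.DataFrame(
        {
            "qed": qs.score_samples(properties),
            "rdl": rs.score_samples(properties),
            "ro5": ro5_violations_table(properties),
        }
    )
    if endpoints is not None:
        drugs_e = endpoints.loc[categories.reindex(endpoints.index) == "drug"]
        asc = (admet_scorer or AdmetScorer()).fit(drugs_e)
        out = out.join(asc.score_samples(endpoints))
    return out
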
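"""Chemical-space analysis: drug-range scaling, PCA, PERMANOVA and
per-compound similarity to the reference drug cloud.

Descriptor-space similarity uses the quantitative Jaccard (Ruzicka)
coefficient on drug-range-scaled descriptors; structural similarity uses
atom-pair fingerprint Tanimoto and maximum-common-substructure (MCS)
Tanimoto, combined into a single index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFMCS, rdFingerprintGenerator
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .io import DescriptorTable, MoleculeRecord

logger = logging.getLogger(__name__)


class ChemSpaceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Drug-range scaling


class DrugRangeScaler(BaseEstimator, TransformerMixin):
    """Min-max scale every descriptor by the reference drug subset's range.

    ``fit`` on drug rows only; ``transform`` any compound table: drug values
    then span [0, 1] while other categories may fall outside (counted and
    logged, not clipped). A variable constant over drugs raises by default;
    ``lenient=True`` drops it with a warning instead.
    """

    def __init__(self, lenient: bool = False):
        self.lenient = lenient

    def fit(self, X: pd.DataFrame, y=None) -> "DrugRangeScaler":
        mins = X.min(axis=0)
        maxs = X.max(axis=0)
        constant = mins.index[mins == maxs].tolist()
        if constant:
            if not self.lenient:
                raise ChemSpaceError(
                    f"variables constant over drugs: {constant}"
                )
            logger.warning("dropping variables constant over drugs: %s", constant)
            mins = mins.drop(constant)
            maxs = maxs.drop(constant)
        self.min_ = mins
        self.max_ = maxs
        self.columns_ = mins.index.tolist()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "min_"):
            raise ChemSpaceError("DrugRangeScaler is not fitted")
        out = (X[self.columns_] - self.min_) / (self.max_ - self.min_)
        n_out = int(((out < 0) | (out > 1)).to_numpy().sum())
        if n_out:
            logger.info("%d scaled cell(s) fall outside [0, 1]", n_out)
        return out


def drug_range_scale(
    table: DescriptorTable, drug_ids: Sequence[str] | None = None, lenient: bool = False
) -> DescriptorTable:
    """Scale a labelled descriptor table by its drug subset's range."""
    if drug_ids is None:
        drugs = table.subset("drug")
    else:
        drugs = table.values.loc[list(drug_ids)]
    scaler = DrugRangeScaler(lenient=lenient).fit(drugs)
    return DescriptorTable(values=scaler.transform(table.values), categories=table.categories)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    """Scores plus per-axis variable diagnostics.

    ``axis_variance_pct`` always covers every principal axis (it sums to
    100); ``scores``, ``variable_correlations`` and
    ``variable_contributions_pct`` are restricted to the requested axes.
    """

    scores: pd.DataFrame
    axis_variance_pct: pd.Series
    variable_correlations: pd.DataFrame
    variable_contributions_pct: pd.DataFrame


def run_pca(scaled: DescriptorTable | pd.DataFrame, n_axes: int | None = None) -> PcaResult:
    """Covariance-matrix PCA of drug-range-scaled descriptors.

    The data are centred but not re-standardized (the drug-range scaling
    already put variables on comparable ranges). Per-axis variable
    contributions are ``100 * loading^2`` and sum to 100 on each axis.
    """
    X = scaled.values if isinstance(scaled, DescriptorTable) else scaled
    arr = X.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ChemSpaceError("descriptor matrix contains non-finite entries")
    k_full = min(arr.shape)
    pca = PCA(n_components=k_full)
    scores = pca.fit_transform(arr)
    axes_full = [f"PC{i + 1}" for i in range(k_full)]
    variance_pct = pd.Series(pca.explained_variance_ratio_ * 100, index=axes_full)

    k = k_full if n_axes is None else min(n_axes, k_full)
    axes = axes_full[:k]
    # eigenvector components are unit-norm per axis, so squares sum to 1
    contrib = pd.DataFrame(
        100 * pca.components_[:k].T ** 2, index=X.columns, columns=axes
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        sd_var = arr.std(axis=0)
        sd_score = scores[:, :k].std(axis=0)
        centred = arr - arr.mean(axis=0)
        cov = centred.T @ scores[:, :k] / arr.shape[0]
        corr = cov / np.outer(sd_var, sd_score)
    correlations = pd.DataFrame(corr, index=X.columns, columns=axes)
    return PcaResult(
        scores=pd.DataFrame(scores[:, :k], index=X.index, columns=axes),
        axis_variance_pct=variance_pct,
        variable_correlations=correlations,
        variable_contributions_pct=contrib,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    F: float
    r2: float
    p: float
    df_among: int
    df_within: int
    n_perm: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> tuple:
    n = len(labels)
    ss_total = d2.sum() / (2 * n)  # d2 is the full square matrix
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    return ss_total, ss_within


def permanova(
    data: pd.DataFrame | np.ndarray,
    labels: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
    is_distance: bool = False,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on Euclidean distances.

    Partitions the sum of squared inter-point distances among and within
    groups; the pseudo-F is referenced to the distribution obtained by
    permuting group labels. The p-value uses the ``(1 + b) / (1 + m)``
    estimator for sampled permutations and is therefore never exactly 0.
    ``exhaustive=True`` enumerates every label ordering instead (small n
    only) and reports ``#{F_perm >= F_obs} / n!`` with the identity
    ordering included.
    """
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ChemSpaceError("need >= 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise ChemSpaceError(f"groups with a single member: {small}")

    if is_distance:
        d = np.asarray(data, dtype=float)
        if d.shape[0] != d.shape[1]:
            raise ChemSpaceError("distance matrix must be square")
    else:
        X = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, dtype=float)
        if not np.isfinite(X).all():
            raise ChemSpaceError("non-finite entries in data matrix")
        d = squareform(pdist(X, metric="euclidean"))
    if len(labels) != d.shape[0]:
        raise ChemSpaceError("labels length does not match data")

    d2 = d**2
    n, k = len(labels), len(groups)
    ss_total, ss_within = _permanova_ss(d2, labels, groups)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    f_obs = (ss_among / df_among) / (ss_within / df_within)
    r2 = ss_among / ss_total

    if exhaustive:
        from itertools import permutations as iter_permutations

        if n > 9:
            raise ChemSpaceError("exhaustive enumeration is limited to n <= 9")
        exceed = 0
        total = 0
        for order in iter_permutations(range(n)):
            perm = labels[list(order)]
            ss_t, ss_w = _permanova_ss(d2, perm, groups)
            f_perm = ((ss_t - ss_w) / df_among) / (ss_w / df_within)
            if f_perm >= f_obs - 1e-12:
                exceed += 1
            total += 1
        p = exceed / total
        n_perm = total
    else:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            ss_t, ss_w = _permanova_ss(d2, perm, groups)
            f_perm = ((ss_t - ss_w) / df_among) / (ss_w / df_within)
            if f_perm >= f_obs:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
    return PermanovaResult(
        F=float(f_obs), r2=float(r2), p=float(p),
        df_among=df_among, df_within=df_within, n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Quantitative Jaccard (Ruzicka) similarity


def ruzicka(x: np.ndarray, y: np.ndarray) -> float:
    """Quantitative Jaccard similarity ``sum(min) / sum(max)`` for
    non-negative vectors; an all-zero pair is defined as identical (1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ChemSpaceError("vectors must have the same length")
    if (x < 0).any() or (y < 0).any():
        raise ChemSpaceError("quantitative Jaccard requires non-negative values")
    denom = np.maximum(x, y).sum()
    if denom == 0:
        logger.info("all-zero vector pair: similarity defined as 1")
        return 1.0
    return float(np.minimum(x, y).sum() / denom)


def mean_jaccard_to_drugs(x: np.ndarray, drugs: pd.DataFrame | np.ndarray) -> float:
    """Mean quantitative Jaccard similarity of one scaled descriptor row to
    every reference drug; values near 1 put the compound at the centre of
    the drug cloud. Scaled values are clipped to [0, 1] first."""
    D = drugs.to_numpy(dtype=float) if isinstance(drugs, pd.DataFrame) else np.asarray(drugs, dtype=float)
    x = np.asarray(x, dtype=float)
    n_clip = int((x < 0).sum() + (x > 1).sum() + (D < 0).sum() + (D > 1).sum())
    if n_clip:
        logger.info("clipped %d out-of-range scaled value(s) before Jaccard", n_clip)
    x = np.clip(x, 0, 1)
    D = np.clip(D, 0, 1)
    mins = np.minimum(x, D).sum(axis=1)
    maxs = np.maximum(x, D).sum(axis=1)
    sims = np.where(maxs == 0, 1.0, mins / np.where(maxs == 0, 1.0, maxs))
    return float(sims.mean())


# ---------------------------------------------------------------------------
# Fingerprint and MCS Tanimoto


def compute_fingerprint(
    mol: Chem.Mol, scheme: str = "atompair", n_bits: int = 1024
) -> np.ndarray:
    """Binary substructure fingerprint as a 0/1 array.

    Atom-pair (default) or Morgan radius-2, folded to ``n_bits``.
    """
    if scheme == "atompair":
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits)
    elif scheme == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    else:
        raise ChemSpaceError(f"unknown fingerprint scheme {scheme!r}")
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def fingerprint_tanimoto(fpA: np.ndarray, fpB: np.ndarray) -> float:
    """Tanimoto ``c / (a + b - c)`` on binary fingerprints; two empty
    fingerprints are defined as identical (1)."""
    fpA = np.asarray(fpA, dtype=bool)
    fpB = np.asarray(fpB, dtype=bool)
    if fpA.shape != fpB.shape:
        raise ChemSpaceError(
            f"fingerprint length mismatch: {fpA.shape} vs {fpB.shape}"
        )
    a, b = int(fpA.sum()), int(fpB.sum())
    c = int((fpA & fpB).sum())
    if a + b == 0:
        logger.info("two empty fingerprints: similarity defined as 1")
        return 1.0
    return c / (a + b - c)


@dataclass
class McsStatus:
    tanimoto: float
    n_mcs_atoms: int
    exact: bool


def mcs_tanimoto(
    molA: Chem.Mol, molB: Chem.Mol, time_cap: float = 5.0, return_status: bool = False
):
    """Maximum-common-substructure Tanimoto: ``|MCS| / (|A| + |B| - |MCS|)``
    with sizes in heavy atoms.

    Atoms match by element; bonds by connectivity regardless of order or
    ring membership. The search is exact under ``time_cap`` seconds; on
    timeout the best substructure found so far gives a flagged lower bound
    (``exact=False`` when ``return_status``).
    """
    for name, m in (("A", molA), ("B", molB)):
        if m is None or m.GetNumAtoms() == 0:
            raise ChemSpaceError(f"molecule {name} is empty")
    res = rdFMCS.FindMCS(
        [molA, molB],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareAny,
        ringMatchesRingOnly=False,
        timeout=max(1, int(round(time_cap))),
    )
    n_mcs = res.numAtoms
    if res.canceled:
        logger.warning("MCS search hit the %.0fs cap; similarity is a lower bound", time_cap)
    t = n_mcs / (molA.GetNumAtoms() + molB.GetNumAtoms() - n_mcs)
    if return_status:
        return McsStatus(tanimoto=float(t), n_mcs_atoms=int(n_mcs), exact=not res.canceled)
    return float(t)


def tanimoto_index(fp_t: float, mcs_t: float, mode: str = "sum_sq") -> float:
    """Combine fingerprint and MCS Tanimoto into one index.

    ``sum_sq`` (default) returns ``fp_t**2 + mcs_t**2``; ``euclid`` returns
    its square root (the Euclidean norm of the similarity pair).
    """
    for name, v in (("fingerprint", fp_t), ("MCS", mcs_t)):
        if not 0 <= v <= 1:
            raise ChemSpaceError(f"{name} Tanimoto {v} outside [0, 1]")
    s = fp_t**2 + mcs_t**2
    if mode == "sum_sq":
        return s
    if mode == "euclid":
        return float(np.sqrt(s))
    raise ChemSpaceError(f"unknown mode {mode!r}")


@dataclass
class SimilarityResult:
    """Per-compound mean similarity to the reference drug set."""

    id: str
    mean_jaccard: float | None
    mean_fp_tanimoto: float
    mean_mcs_tanimoto: float
    tanimoto_index: float


def mean_tanimoto_to_drugs(
    mol: Chem.Mol,
    drug_mols: Sequence[Chem.Mol],
    scheme: str = "atompair",
    n_bits: int = 1024,
    time_cap: float = 5.0,
    index_mode: str = "sum_sq",
    mol_id: str = "",
    drug_fps: Sequence[np.ndarray] | None = None,
) -> SimilarityResult:
    """Average the per-drug combined Tanimoto index (and its components)
    over the whole reference drug set."""
    if len(drug_mols) == 0:
        raise ChemSpaceError("reference drug set is empty")
    fp = compute_fingerprint(mol, scheme, n_bits)
    if drug_fps is None:
        drug_fps = [compute_fingerprint(d, scheme, n_bits) for d in drug_mols]
    fp_ts, mcs_ts, indices = [], [], []
    for d_mol, d_fp in zip(drug_mols, drug_fps):
        ft = fingerprint_tanimoto(fp, d_fp)
        mt = mcs_tanimoto(mol, d_mol, time_cap=time_cap)
        fp_ts.append(ft)
        mcs_ts.append(mt)
        indices.append(tanimoto_index(ft, mt, mode=index_mode))
    return SimilarityResult(
        id=mol_id,
        mean_jaccard=None,
        mean_fp_tanimoto=float(np.mean(fp_ts)),
        mean_mcs_tanimoto=float(np.mean(mcs_ts)),
        tanimoto_index=float(np.mean(indices)),
    )


class DrugSimilarity(BaseEstimator):
    """Per-compound similarity to the drug cloud, sklearn-style.

    ``fit`` takes the drug-range-scaled drug descriptor rows and (optionally)
    the drug structures; ``transform`` returns, per query compound, the mean
    quantitative Jaccard over drugs and — when structures are available —
    mean fingerprint Tanimoto, mean MCS Tanimoto and the combined index.
    ``subsample`` caps the number of reference drugs used for the structural
    similarities (seeded; the descriptor Jaccard always uses all drugs).
    """

    def __init__(
        self,
        scheme: str = "atompair",
        n_bits: int = 1024,
        time_cap: float = 5.0,
        index_mode: str = "sum_sq",
        subsample: int | None = None,
        seed: int | None = None,
    ):
        self.scheme = scheme
        self.n_bits = n_bits
        self.time_cap = time_cap
        self.index_mode = index_mode
        self.subsample = subsample
        self.seed = seed

    def fit(
        self,
        X: pd.DataFrame,
        drug_mols: Sequence[Chem.Mol] | None = None,
    ) -> "DrugSimilarity":
        self.drug_scaled_ = X
        self.drug_mols_ = list(drug_mols) if drug_mols is not None else None
        if self.drug_mols_ is not None and self.subsample is not None and len(self.drug_mols_) > self.subsample:
            rng = np.random.default_rng(self.seed)
            idx = rng.choice(len(self.drug_mols_), size=self.subsample, replace=False)
            logger.info("subsampling %d of %d drugs for structural similarity (seed=%s)",
                        self.subsample, len(self.drug_mols_), self.seed)
            self.drug_mols_ = [self.drug_mols_[i] for i in idx]
        if self.drug_mols_ is not None:
            self.drug_fps_ = [
                compute_fingerprint(m, self.scheme, self.n_bits) for m in self.drug_mols_
            ]
        return self

    def transform(
        self,
        X: pd.DataFrame,
        mols: Sequence[Chem.Mol] | None = None,
    ) -> pd.DataFrame:
        if not hasattr(self, "drug_scaled_"):
            raise ChemSpaceError("DrugSimilarity is not fitted")
        rows = []
        for i, (mid, row) in enumerate(X.iterrows()):
            mj = mean_jaccard_to_drugs(row.to_numpy(), self.drug_scaled_)
            rec = {"id": mid, "mean_jaccard": mj}
            if mols is not None and self.drug_mols_ is not None:
                sim = mean_tanimoto_to_drugs(
                    mols[i], self.drug_mols_, self.scheme, self.n_bits,
                    self.time_cap, self.index_mode, mol_id=str(mid),
                    drug_fps=self.drug_fps_,
                )
                rec.update(
                    mean_fp_tanimoto=sim.mean_fp_tanimoto,
                    mean_mcs_tanimoto=sim.mean_mcs_tanimoto,
                    tanimoto_index=sim.tanimoto_index,
                )
            rows.append(rec)
        return pd.DataFrame(rows).set_index("id")
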
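"""Synthetic drug / NP / toxin compound sets.

Generators for the three kinds of input the scoring pipeline consumes:

* descriptor tables — multivariate Gaussian clouds per category with a
  configurable mean shift ``group_shift`` along fixed orthogonal unit
  directions, emulating partially separated groups in a 51-variable
  descriptor space (larger shifts map monotonically to larger expected
  PERMANOVA R^2);
* eight-property tables — unimodal drug-typical distributions for drugs,
  heavier molecular-weight tails for natural products, elevated
  structural-alert counts for toxins;
* binary ADMET endpoint tables — independent Bernoulli endpoints with
  category-specific beneficial probabilities (NP defaults above drug,
  toxin below, matching the observed ordering of ADMET-scores).

Everything is bit-reproducible under a fixed seed. Structures are never
generated: :func:`fixture_structures` serves a curated list of well-known
molecules for structure-path tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from rdkit import Chem

from .descriptors import PROPERTY_NAMES
from .io import CATEGORIES, DescriptorTable, EndpointTable, MoleculeRecord


class SynthError(ValueError):
    pass


#: Per-category sampling parameters for the eight properties. MW is
#: log-normal (median Da, sigma of log); ALOGP normal; PSA gamma
#: (shape, scale); the count properties are Poisson rates.
DEFAULT_PROPERTY_PARAMS: dict[str, dict] = {
    "drug": {
        "MW": {"median": 350.0, "sigma": 0.35},
        "ALOGP": {"mean": 2.5, "sd": 1.3},
        "HBD": 1.8, "HBA": 4.5,
        "PSA": {"shape": 3.0, "scale": 25.0},
        "ROTB": 5.0, "AROM": 1.8, "ALERTS": 0.4,
    },
    "np": {
        "MW": {"median": 450.0, "sigma": 0.70},
        "ALOGP": {"mean": 3.0, "sd": 2.0},
        "HBD": 2.5, "HBA": 6.0,
        "PSA": {"shape": 2.5, "scale": 40.0},
        "ROTB": 6.0, "AROM": 1.0, "ALERTS": 0.8,
    },
    "toxin": {
        "MW": {"median": 300.0, "sigma": 0.50},
        "ALOGP": {"mean": 3.0, "sd": 1.8},
        "HBD": 1.5, "HBA": 4.0,
        "PSA": {"shape": 2.4, "scale": 25.0},
        "ROTB": 4.0, "AROM": 1.5, "ALERTS": 2.0,
    },
}

#: Beneficial-endpoint probability per category. The NP rate sits above
#: the drug rate so synthetic NPs recover the "NP ADMET-score > drug"
#: ordering; toxins sit well below.
DEFAULT_ENDPOINT_PARAMS: dict[str, float] = {"drug": 0.70, "np": 0.80, "toxin": 0.45}


@dataclass
class SimConfig:
    """Study conditions for the synthetic compound sets.

    Default sizes (200 drugs / 560 NPs / 200 toxins) are a tenth-scale
    version of a realistic triage campaign; pass the full sizes for
    full-scale runs.
    """

    n_drug: int = 200
    n_np: int = 560
    n_toxin: int = 200
    seed: int = 0
    descriptor_dim: int = 51
    group_shift: float = 1.0
    n_endpoints: int = 18
    property_params: Mapping[str, Mapping] = field(
        default_factory=lambda: DEFAULT_PROPERTY_PARAMS
    )
    endpoint_params: Mapping[str, float | np.ndarray] = field(
        default_factory=lambda: DEFAULT_ENDPOINT_PARAMS
    )

    def __post_init__(self) -> None:
        for name in ("n_drug", "n_np", "n_toxin"):
            if getattr(self, name) < 2:
                raise SynthError(f"{name} must be >= 2")
        if self.group_shift < 0:
            raise SynthError("group_shift must be >= 0")
        if self.descriptor_dim < 2:
            raise SynthError("descriptor_dim must be >= 2")
        for cat, p in self.endpoint_params.items():
            arr = np.atleast_1d(np.asarray(p, dtype=float))
            if ((arr < 0) | (arr > 1)).any():
                raise SynthError(f"endpoint probability for {cat!r} outside [0, 1]")

    @property
    def counts(self) -> dict[str, int]:
        return {"drug": self.n_drug, "np": self.n_np, "toxin": self.n_toxin}


def _ids(cfg: SimConfig) -> dict[str, list[str]]:
    prefix = {"drug": "D", "np": "N", "toxin": "T"}
    return {
        cat: [f"{prefix[cat]}{i + 1:05d}" for i in range(n)]
        for cat, n in cfg.counts.items()
    }


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(stream + 1)[stream])


def generate_descriptor_tables(cfg: SimConfig) -> DescriptorTable:
    """Labelled multivariate-Gaussian descriptor table for all three groups.

    Group ``g`` is sampled from N(mu + delta * u_g, I) where the ``u_g``
    are the first three standard basis vectors — fixed orthogonal unit
    directions, so the configured shift maps monotonically to the expected
    among-group variance fraction.
    """
    rng = _rng(cfg, 0)
    d = cfg.descriptor_dim
    if d < 3:
        raise SynthError("descriptor_dim must be >= 3 for three group directions")
    directions = {cat: np.eye(d)[i] for i, cat in enumerate(CATEGORIES)}
    ids = _ids(cfg)
    frames, cats = [], []
    for cat in CATEGORIES:
        n = cfg.counts[cat]
        X = rng.standard_normal((n, d)) + cfg.group_shift * directions[cat]
        frames.append(pd.DataFrame(X, index=ids[cat],
                                   columns=[f"V{j + 1:02d}" for j in range(d)]))
        cats.extend([cat] * n)
    values = pd.concat(frames)
    return DescriptorTable(
        values=values, categories=pd.Series(cats, index=values.index, name="category")
    )


def _sample_properties(rng: np.random.Generator, n: int, params: Mapping) -> pd.DataFrame:
    try:
        mw = params["MW"]
        out = {
            "MW": rng.lognormal(mean=np.log(mw["median"]), sigma=mw["sigma"], size=n),
            "ALOGP": rng.normal(params["ALOGP"]["mean"], params["ALOGP"]["sd"], size=n),
            "HBD": rng.poisson(params["HBD"], size=n),
            "HBA": rng.poisson(params["HBA"], size=n),
            "PSA": rng.gamma(params["PSA"]["shape"], params["PSA"]["scale"], size=n),
            "ROTB": rng.poisson(params["ROTB"], size=n),
            "AROM": rng.poisson(params["AROM"], size=n),
            "ALERTS": rng.poisson(params["ALERTS"], size=n),
        }
    except (KeyError, ValueError) as exc:
        raise SynthError(f"invalid property distribution parameters: {exc}") from exc
    return pd.DataFrame(out)[list(PROPERTY_NAMES)]


def generate_property_tables(cfg: SimConfig) -> DescriptorTable:
    """Eight-property table for all three categories.

    Drugs are unimodal around drug-typical values (log-normal MW with
    median ~350 Da); NPs carry a heavier MW tail; toxins an elevated
    structural-alert rate. Count properties are non-negative integers.
    """
    rng = _rng(cfg, 1)
    ids = _ids(cfg)
    frames, cats = [], []
    for cat in CATEGORIES:
        df = _sample_properties(rng, cfg.counts[cat], cfg.property_params[cat])
        df.index = pd.Index(ids[cat])
        frames.append(df)
        cats.extend([cat] * cfg.counts[cat])
    values = pd.concat(frames)
    return DescriptorTable(
        values=values, categories=pd.Series(cats, index=values.index, name="category")
    )


def generate_endpoint_tables(cfg: SimConfig) -> dict[str, EndpointTable]:
    """Binary endpoint table per category: independent Bernoulli endpoints
    with the category's beneficial probability (scalar or per-endpoint)."""
    rng = _rng(cfg, 2)
    ids = _ids(cfg)
    names = [f"E{i + 1:02d}" for i in range(cfg.n_endpoints)]
    out = {}
    for cat in CATEGORIES:
        p = np.broadcast_to(
            np.atleast_1d(np.asarray(cfg.endpoint_params[cat], dtype=float)),
            (cfg.n_endpoints,),
        )
        vals = (rng.random((cfg.counts[cat], cfg.n_endpoints)) < p).astype(int)
        df = pd.DataFrame(vals, index=ids[cat], columns=names)
        out[cat] = EndpointTable(
            values=df, categories=pd.Series(cat, index=df.index, name="category")
        )
    return out


def combined_endpoint_table(cfg: SimConfig) -> EndpointTable:
    """All three categories' endpoints in one labelled table."""
    per_cat = generate_endpoint_tables(cfg)
    values = pd.concat([per_cat[c].values for c in CATEGORIES])
    cats = pd.concat([per_cat[c].categories for c in CATEGORIES])
    return EndpointTable(values=values, categories=cats)


def fixture_structures(n: int | None = None, category: str = "np") -> list[MoleculeRecord]:
    """Well-known, valid small-molecule structures for structure-path tests.

    Served from the curated SMILES file shipped with the package (includes
    nitro-group compounds for alert coverage); no structures are invented.
    """
    ref = importlib.resources.files("npdruglike.data") / "fixture_structures.smi"
    records = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smi, mid = line.split()
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # the fixture file is part of the package contract
            raise SynthError(f"fixture SMILES failed to parse: {smi}")
        records.append(MoleculeRecord(id=mid, structure=mol, category=category))
    if n is None:
        return records
    if n > len(records):
        raise SynthError(f"only {len(records)} fixture structures available, asked for {n}")
    return records[:n]
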
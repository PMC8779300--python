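# Methods

This note records the models behind `npdruglike`, the choices made where
the methods are genuinely underdetermined, and what the synthetic-data
tests do and do not demonstrate.

## The eight properties

QED and RDL are both built on eight molecular properties: molecular weight
(MW, Da), calculated octanol–water log-partition (ALOGP), hydrogen-bond
donors (HBD), hydrogen-bond acceptors (HBA), topological polar surface
area (PSA, Å²), rotatable bonds (ROTB), aromatic rings (AROM) and
structural-alert matches (ALERTS). Conventions that needed fixing:

* **ALOGP** uses the Crippen atomic-contribution model. Web services
  compute log P with their own parameterizations; exact agreement with any
  particular service is not a goal — self-consistency across the drug, NP
  and toxin sets scored together is, since every index compares compounds
  to drugs under the same calculator.
* **HBA** uses the Lipinski N+O count (4 for aspirin), matching the
  classic rule-of-five formulation and Open Babel's output, rather than
  RDKit's stricter acceptor perception (3 for aspirin).
* **AROM** counts SSSR rings whose bonds are all aromatic — deterministic
  for fused systems, where "number of aromatic rings" is otherwise
  ambiguous.
* **ROTB** uses the common convention: non-ring single bonds between two
  heavy atoms each bearing another heavy atom, amide C–N excluded.
* **PSA** is topological (TPSA); input structures are 2D, so no 3D surface
  is available or attempted.
* **ALERTS** counts *distinct* alert patterns with at least one match, not
  total matches; a compound with two nitro groups scores the nitro
  patterns once. The default pattern file
  (`data/alerts_curated_v1.smarts`) is a hand-curated set of ~40 widely
  recognized reactive/toxicophore substructure classes; it is deliberately
  small, versioned and user-replaceable, and RDKit's full Brenk filter
  catalog can be selected at run time (`alert_patterns(source="rdkit-brenk")`)
  when a larger published set is wanted.

Tautomer and protonation state are taken as given: each input structure is
scored as parsed, with no enumeration of neutral forms.

## QED

Desirability functions are smoothed, peak-normalized histograms of each
property over the reference drug set: Freedman–Diaconis binning on the
drug sample, a 3-cell moving-average smooth (¼, ½, ¼), division by the
modal height so the peak scores exactly 1, and a floor of ε = 1e-6 so the
geometric mean over eight properties can never collapse to exactly 0
(ε^(1/8) ≈ 0.18 bounds the penalty of a single impossible property).
Values outside the fitted grid take the floor — they are, by construction,
unlike any reference drug. A parametric desirability backend could be
plugged in place of the histogram via `DesirabilityModel`; the histogram is
the default because it is assumption-free and directly reflects the drug
sample. QED values are reported at full precision; classification rules
that test "QED = 0" round to two decimals first (see Quadrants).

The minimum drug-sample size per property is 30 (configurable): below
that, a histogram density is mostly noise.

## RDL

For each property, drug and reference (toxin) samples are histogrammed as
densities on one shared grid spanning both samples, with the bin width
taken from the drug sample. The relative likelihood at value *x* is
`f_drug(x) / (f_drug(x) + f_ref(x))` with a pseudocount ε = 1e-9 added to
both densities, bounding the ratio strictly inside (0, 1): a value in a
cell where only drugs occur approaches 1, only toxins 0, equal densities
exactly 0.5. RDL is the geometric mean of the eight relative likelihoods.
Values outside the grid are evaluated at the boundary cell and flagged in
the log rather than refused — tail behaviour then extrapolates the last
observed cell, which is conservative for ranking.

## Rule of five

The four thresholds are applied as strict inequalities (log P < 5,
MW < 500, HBD < 5, HBA < 10); a compound sitting exactly on a boundary
counts that threshold as exceeded. The score is the number of thresholds
not satisfied, 0–4, and all four inputs are required — no partial scoring.

## ADMET-score

The raw score is `Σᵢ w1ᵢ·w2ᵢ·w3ᵢ·vᵢ` over the 18 binary endpoints, where
`w1ᵢ` is the frequency of the beneficial value of endpoint *i* among
reference drugs, and `w2` (QSAR model performance) and `w3` (endpoint
importance) come from configuration. When no `w2`/`w3` tables are
supplied they default to 1 and the fallback is logged: the published
values belong to the specific QSAR models that produced a given endpoint
table and should accompany that table, not the scoring code. `w1` is
interpreted as frequency-of-beneficial (not frequency-of-majority): the
weight is meant to up-weight endpoints on which drugs are reliably good.
Raw scores are standardized by the *drug* raw minimum and maximum, so
drugs span [0, 1] while other compounds may fall outside and are not
clipped — an NP more ADMET-favourable than every drug should be visible as
such. The endpoint schema (names, beneficial encodings) is user-defined;
the scorer only requires binary columns.

## Chemical space

**Scaling.** Every descriptor is min–max scaled by the drug subset's range
(`(x − min_drug) / (max_drug − min_drug)`), applied identically to all
categories. Non-drug values may leave [0, 1]; they are counted and logged.
A variable constant over drugs has no scale and raises (or is dropped in
lenient mode). The transform is deliberately not idempotent.

**PCA** is a covariance-matrix eigendecomposition of the scaled data —
centred but *not* re-standardized, because drug-range scaling has already
put variables on comparable ranges and a second z-scoring would undo the
drug-anchored geometry. Per-axis variable contributions are
`100·loadingⱼₖ²` (eigenvectors are unit-norm, so each axis sums to 100);
with *p* variables the expected average contribution is `100/p` %, the
baseline against which a variable is called influential.

**PERMANOVA** partitions the sum of squared Euclidean inter-point
distances: `SS_total = Σᵢ<ⱼ d²ᵢⱼ / N`, `SS_within = Σ_g Σᵢ<ⱼ∈g d²ᵢⱼ / n_g`,
pseudo-F = `(SS_among/(k−1)) / (SS_within/(N−k))`. The null distribution
permutes the label vector uniformly (seeded); the p-value uses the
`(1+b)/(1+m)` estimator so it is never 0 and is floored at `1/(m+1)`. An
exhaustive mode enumerates all orderings for small n and is used to verify
the sampled estimator against brute force. Whether to run the test on all
scaled variables or on PCA scores is open in principle; scaled variables
are the default since the test needs no dimension reduction.

**Quantitative Jaccard.** Similarity of scaled rows is Ružička,
`Σⱼ min(xⱼ,yⱼ) / Σⱼ max(xⱼ,yⱼ)`, equal to `1 − 2B/(1+B)` with B the
Bray–Curtis dissimilarity; the per-compound score is the mean over all
drugs, a proxy for proximity to the centre of the drug cloud. The
coefficient requires non-negative inputs, so scaled values are clipped to
[0, 1] first (count logged). An all-zero pair is defined as identical
(similarity 1) and logged. Self-similarity is exactly 1.

**Fingerprint Tanimoto** uses atom-pair fingerprints folded to 1024 bits
by default (Morgan radius-2 available), `c/(a+b−c)` on set bits; two empty
fingerprints are defined as identical. **MCS Tanimoto** is
`|MCS|/(|A|+|B|−|MCS|)` in heavy atoms, with atoms matched by element and
bonds by connectivity only (order- and ring-agnostic); the search is exact
under a 5 s/pair cap, after which the best substructure found is a flagged
lower bound. A single shared atom is a valid MCS (methane–benzene scores
1/(1+6−1) = 1/6). The two similarities are combined as
`index = fp² + mcs²`, with the Euclidean-norm variant `√(fp² + mcs²)`
available by flag. The squared sum is the default; since the two modes
differ by a monotone transform they rank compounds identically, but their
z-scores differ, so the choice is explicit and configurable. Per-compound
scores average the pairwise index over all drugs; the drug set can be
subsampled (seeded, logged) for very large references.

## Composite index and quadrants

The five positively-oriented components — mean Jaccard, mean Tanimoto
index, RDL, ADMET-score, and Ro5 *negated after z-scoring* — are each
z-standardized with the population (n) standard deviation and summed. The
dataset mean of the summed index is 0 by construction; its SD depends on
the inter-component correlations of the library at hand.
Z-standardization is computed over the compound set being ranked (the NP
library), not pooled with the reference sets: pooling would let reference
composition shift every NP's score and break the mean-0 property on the
library. A pooled mode is available by passing a combined frame.

QED stays out of the sum — it correlates weakly or negatively with the
descriptor-space similarity measures, i.e. it carries distinct
information — and is reported alongside. Quadrants over (summed, QED) use
four corner rules (defaults: summed > 2.42 ∧ QED > 0.55
`consistent_druglike`; summed > 2.06 ∧ QED ≈ 0 `druglike_low_qed`;
summed < −12.94 ∧ QED ≈ 0 `least_druglike`; summed < −2.6 ∧ QED > 0.53
`qed_only`; otherwise `interior`). "QED ≈ 0" means rounds to 0.00 at two
decimals — internal QED values are strictly positive because of the
desirability floor. These default cut values are distribution tails of one
particular library and are dataset-specific; the rule set is configurable and validated at
load so that no two corners can claim the same compound. BindingDB-style
target-hit counts are not part of the summed index (weakly correlated,
zero-inflated) and are out of scope here entirely.

## Synthetic data

The generator emulates the three statistical features the pipeline relies
on, not chemistry:

* **Descriptor tables** — multivariate Gaussians (default 51 variables,
  shared identity covariance) with per-category means shifted by
  `group_shift · u_g` along the first three standard basis vectors. Fixed
  orthogonal directions make the shift map monotonically onto expected
  PERMANOVA R²; `group_shift = 0` is the exchangeable null used for
  type-I-error calibration. The default shift of 1.0 gives heavily
  overlapping clouds (R² ≈ 0.01 at the default sizes) — separation that a
  permutation test detects but a 2D plot barely shows.
* **Property tables** — drugs unimodal around drug-typical values
  (log-normal MW, median 350 Da, σ_log 0.35; ALOGP ≈ N(2.5, 1.3²); PSA
  gamma with mean 75 Å²; Poisson counts), NPs with a heavier MW tail
  (median 450 Da, σ_log 0.70) and more rotatable bonds, toxins with an
  elevated alert rate (Poisson mean 2.0 vs 0.4 for drugs). Values are
  drug-likeness-textbook typical rather than fitted to any dataset.
* **Endpoint tables** — independent Bernoulli endpoints with
  category-specific beneficial probabilities (drug 0.70, NP 0.80, toxin
  0.45). NP above drug reproduces the qualitative ordering in which NP
  libraries out-score drugs on predicted ADMET safety; endpoint
  independence is an idealization — real QSAR endpoint predictions
  correlate.

Structures are never generated: a curated file of two dozen well-known
small molecules (aspirin, caffeine, nitrobenzene, …) covers the
structure-dependent code paths, including nitro-group alerts.

Default sizes are 200 drugs / 560 NPs / 200 toxins — a tenth-scale triage
campaign chosen so the full suite runs in seconds; full-scale sizes
(≈2000/5600/2000) are a config change. What passing tests show: the
pipeline recovers *directions* (drug QED > NP QED, NP ADMET > drug ADMET),
calibration (PERMANOVA type-I error ≈ 5%) and analytic identities. What
they do not show: agreement with any real library's absolute values —
real descriptor panels are correlated, non-Gaussian and partly discrete,
real fingerprints are sparse and structured, and real endpoint predictions
covary.

## Numerical choices

* Desirability floor 1e-6; RDL pseudocount 1e-9; geometric means computed
  in log space.
* Population (n) SD everywhere in z-scoring; at library scale n vs n−1 is
  immaterial but must be fixed for bit-reproducibility.
* PERMANOVA permutation comparisons use `F_perm ≥ F_obs` with a 1e-12
  slack in exhaustive mode to absorb float noise at the identity
  permutation.
* Degenerate definitions: all-zero Jaccard pair → 1; empty∩empty
  fingerprints → 1; single-value desirability histogram → one peak cell;
  all logged.
* Ties in the ranked report break lexicographically by compound id.
* All stochastic components (generators, permutation tests, subsampling)
  take explicit seeds; NumPy `default_rng` throughout.

## Limitations

* The eight computed properties are the only descriptors produced locally;
  richer ADME panels (absorption, permeability, …) must arrive as CSV from
  external tools, and the chemspace results are only as good as that
  panel.
* Binary ADMET endpoints are inputs, not predictions; the package contains
  no QSAR models.
* MCS similarity is exact only within the time cap; for pathological pairs
  the reported value is a flagged lower bound.
* The quadrant default thresholds are tail values of one particular
  library; percentile-based cuts should be preferred for new libraries.
* No docking, no target inference, no structure rendering.
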
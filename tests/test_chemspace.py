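import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from npdruglike import chemspace as cs
from npdruglike.io import DescriptorTable


# ---------------------------------------------------------------------------
# Drug-range scaling


class TestDrugRangeScaler:
    def test_drug_column_spans_unit_interval(self):
        drugs = pd.DataFrame({"A": [2.0, 4.0, 6.0]})
        scaler = cs.DrugRangeScaler().fit(drugs)
        out = scaler.transform(drugs)
        np.testing.assert_allclose(out["A"], [0.0, 0.5, 1.0])

    def test_nondrug_value_outside_range(self):
        drugs = pd.DataFrame({"A": [2.0, 4.0, 6.0]})
        scaler = cs.DrugRangeScaler().fit(drugs)
        out = scaler.transform(pd.DataFrame({"A": [8.0]}))
        assert out["A"].iloc[0] == pytest.approx(1.5)

    def test_not_idempotent(self):
        drugs = pd.DataFrame({"A": [2.0, 4.0, 8.0]})
        scaler = cs.DrugRangeScaler().fit(drugs)
        once = scaler.transform(drugs)
        twice = scaler.transform(once)
        assert not np.allclose(once["A"], twice["A"])

    def test_constant_variable_named_in_error(self):
        drugs = pd.DataFrame({"A": [1.0, 1.0], "B": [0.0, 2.0]})
        with pytest.raises(cs.ChemSpaceError, match="A"):
            cs.DrugRangeScaler().fit(drugs)

    def test_lenient_mode_drops_constant(self):
        drugs = pd.DataFrame({"A": [1.0, 1.0], "B": [0.0, 2.0]})
        scaler = cs.DrugRangeScaler(lenient=True).fit(drugs)
        assert scaler.columns_ == ["B"]

    def test_table_wrapper_scales_by_drug_subset(self, descriptor_table):
        scaled = cs.drug_range_scale(descriptor_table)
        drugs = scaled.subset("drug")
        np.testing.assert_allclose(drugs.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(drugs.max(axis=0), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# PCA


class TestPca:
    def test_anisotropic_two_variable_variance_split(self):
        # closed form: eigenvalues 2 and 1 -> PC1 carries 2/3 of variance
        rng = np.random.default_rng(11)
        X = pd.DataFrame(
            rng.standard_normal((20_000, 2)) * np.sqrt([2.0, 1.0]),
            columns=["a", "b"],
        )
        res = cs.run_pca(X)
        assert res.axis_variance_pct.iloc[0] == pytest.approx(100 * 2 / 3, abs=1.5)

    def test_isotropic_gaussian_spreads_evenly(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.standard_normal((20_000, 5)))
        res = cs.run_pca(X)
        assert np.all(np.abs(res.axis_variance_pct - 20.0) < 1.5)

    def test_contributions_sum_to_100_per_axis(self, descriptor_table):
        res = cs.run_pca(descriptor_table.values, n_axes=3)
        np.testing.assert_allclose(
            res.variable_contributions_pct.sum(axis=0), 100.0, atol=1e-6
        )

    def test_variance_pct_sums_to_100(self, descriptor_table):
        res = cs.run_pca(descriptor_table.values)
        assert res.axis_variance_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_nonfinite_entries_error(self):
        X = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]})
        with pytest.raises(cs.ChemSpaceError, match="non-finite"):
            cs.run_pca(X)


# ---------------------------------------------------------------------------
# PERMANOVA


def centroid_f_oracle(X: np.ndarray, labels: np.ndarray) -> float:
    """Independent pseudo-F via group centroids (Euclidean identity)."""
    grand = X.mean(axis=0)
    groups = np.unique(labels)
    ss_total = ((X - grand) ** 2).sum()
    ss_within = sum(
        ((X[labels == g] - X[labels == g].mean(axis=0)) ** 2).sum() for g in groups
    )
    ss_among = ss_total - ss_within
    k, n = len(groups), len(labels)
    return (ss_among / (k - 1)) / (ss_within / (n - k))


class TestPermanova:
    @pytest.fixture
    def small_data(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((6, 3))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        return X, labels

    def test_f_matches_centroid_oracle(self, small_data):
        X, labels = small_data
        res = cs.permanova(X, labels, n_perm=9, seed=0)
        assert res.F == pytest.approx(centroid_f_oracle(X, labels), rel=1e-9)

    def test_exhaustive_p_matches_enumeration_oracle(self, small_data):
        """p from the implementation's exhaustive mode equals brute-force
        enumeration of every label ordering via the centroid-F oracle."""
        X, labels = small_data
        res = cs.permanova(X, labels, exhaustive=True)
        f_obs = centroid_f_oracle(X, labels)
        count = sum(
            centroid_f_oracle(X, labels[list(order)]) >= f_obs - 1e-12
            for order in itertools.permutations(range(len(labels)))
        )
        assert res.p == pytest.approx(count / math.factorial(len(labels)), rel=1e-12)
        assert res.F == pytest.approx(f_obs, rel=1e-9)

    def test_distance_matrix_route_equals_raw_route(self, small_data):
        from scipy.spatial.distance import pdist, squareform

        X, labels = small_data
        d = squareform(pdist(X))
        r1 = cs.permanova(X, labels, n_perm=99, seed=4)
        r2 = cs.permanova(d, labels, n_perm=99, seed=4, is_distance=True)
        assert r1.F == pytest.approx(r2.F, abs=1e-9)
        assert r1.r2 == pytest.approx(r2.r2, abs=1e-9)
        assert r1.p == r2.p

    def test_agrees_with_scikit_bio(self, small_data):
        from skbio.stats.distance import DistanceMatrix, permanova as skb_permanova
        from scipy.spatial.distance import pdist, squareform

        X, labels = small_data
        res = cs.permanova(X, labels, n_perm=99, seed=0)
        skb = skb_permanova(
            DistanceMatrix(squareform(pdist(X))), grouping=list(labels), permutations=99
        )
        assert res.F == pytest.approx(skb["test statistic"], rel=1e-9)

    def test_label_exchangeability(self, small_data):
        X, labels = small_data
        shuffled = labels[::-1]
        r1 = cs.permanova(X, labels, exhaustive=True)
        r2 = cs.permanova(X, shuffled, exhaustive=True)
        # same multiset of group sizes -> same exhaustive null distribution
        assert r1.n_perm == r2.n_perm

    def test_r2_bounds_and_p_floor(self, descriptor_table):
        scaled = cs.drug_range_scale(descriptor_table)
        res = cs.permanova(
            scaled.values, scaled.categories.to_numpy(), n_perm=99, seed=1
        )
        assert 0 <= res.r2 <= 1
        assert res.p >= 1 / (res.n_perm + 1)

    def test_single_member_group_errors(self):
        X = np.eye(3)
        with pytest.raises(cs.ChemSpaceError, match="single"):
            cs.permanova(X, ["a", "a", "b"], n_perm=9)

    def test_fewer_than_two_groups_errors(self):
        X = np.eye(4)
        with pytest.raises(cs.ChemSpaceError, match=">= 2 groups"):
            cs.permanova(X, ["a"] * 4, n_perm=9)


# ---------------------------------------------------------------------------
# Quantitative Jaccard


class TestRuzicka:
    def test_identical_rows_score_one(self):
        x = np.array([0.2, 0.8, 0.5])
        assert cs.ruzicka(x, x) == 1.0
        assert cs.mean_jaccard_to_drugs(x, np.tile(x, (4, 1))) == pytest.approx(1.0)

    def test_disjoint_support_scores_zero(self):
        x = np.array([1.0, 0.0, 0.0])
        drugs = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        assert cs.mean_jaccard_to_drugs(x, drugs) == 0.0

    def test_hand_calculation(self):
        # sum(min)/sum(max) = 0.5 / 1.5
        assert cs.ruzicka(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == pytest.approx(1 / 3)
        assert cs.mean_jaccard_to_drugs(
            np.array([1.0, 0.0]), np.array([[0.5, 0.5]])
        ) == pytest.approx(1 / 3)

    def test_all_zero_pair_defined_as_identical(self):
        z = np.zeros(3)
        assert cs.ruzicka(z, z) == 1.0

    def test_out_of_range_values_clipped(self):
        # NP value 1.5 clips to 1.0 before similarity
        x = np.array([1.5])
        drugs = np.array([[1.0]])
        assert cs.mean_jaccard_to_drugs(x, drugs) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=8),
        st.data(),
    )
    def test_symmetric_and_bounded(self, xs, data):
        ys = data.draw(
            st.lists(st.floats(0, 1), min_size=len(xs), max_size=len(xs))
        )
        x, y = np.array(xs), np.array(ys)
        s_xy = cs.ruzicka(x, y)
        assert s_xy == cs.ruzicka(y, x)
        assert 0 <= s_xy <= 1


# ---------------------------------------------------------------------------
# Fingerprint Tanimoto


class TestFingerprintTanimoto:
    def test_identical_nonempty_is_one(self):
        fp = np.zeros(64, dtype=np.uint8)
        fp[[1, 5, 9]] = 1
        assert cs.fingerprint_tanimoto(fp, fp) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros(64, dtype=np.uint8)
        b = np.zeros(64, dtype=np.uint8)
        a[[1, 2]] = 1
        b[[3, 4]] = 1
        assert cs.fingerprint_tanimoto(a, b) == 0.0

    def test_formula_on_overlapping_bits(self):
        a = np.zeros(8, dtype=np.uint8)
        b = np.zeros(8, dtype=np.uint8)
        a[[1, 2]] = 1
        b[[2, 3]] = 1
        assert cs.fingerprint_tanimoto(a, b) == pytest.approx(1 / 3)

    def test_empty_pair_defined_as_identical(self):
        z = np.zeros(16, dtype=np.uint8)
        assert cs.fingerprint_tanimoto(z, z) == 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(cs.ChemSpaceError, match="mismatch"):
            cs.fingerprint_tanimoto(np.zeros(8), np.zeros(16))

    def test_symmetry_on_real_molecules(self, fixture_mols):
        fps = [cs.compute_fingerprint(r.structure) for r in fixture_mols[:6]]
        for a, b in itertools.combinations(fps, 2):
            assert cs.fingerprint_tanimoto(a, b) == cs.fingerprint_tanimoto(b, a)


# ---------------------------------------------------------------------------
# MCS Tanimoto


def mol_to_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), el=atom.GetSymbol())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    return g


def brute_force_mcs_atoms(molA: Chem.Mol, molB: Chem.Mol) -> int:
    """Exhaustive common-connected-subgraph search (order-agnostic bonds)."""
    gA, gB = mol_to_graph(molA), mol_to_graph(molB)
    best = 0
    for k in range(len(gA), 0, -1):
        for nodes in itertools.combinations(gA.nodes, k):
            sub = gA.subgraph(nodes)
            if not nx.is_connected(sub):
                continue
            gm = nx.algorithms.isomorphism.GraphMatcher(
                gB, sub, node_match=lambda a, b: a["el"] == b["el"]
            )
            if gm.subgraph_is_monomorphic():
                best = k
                break
        if best:
            break
    return best


class TestMcsTanimoto:
    def test_self_similarity_is_one(self, fixture_mols):
        m = fixture_mols[3].structure  # aspirin
        assert cs.mcs_tanimoto(m, m, time_cap=5) == pytest.approx(1.0)

    def test_methane_benzene_single_atom_mcs(self):
        # hand-derived: shared C atom -> 1 / (1 + 6 - 1)
        m1 = Chem.MolFromSmiles("C")
        m2 = Chem.MolFromSmiles("c1ccccc1")
        assert cs.mcs_tanimoto(m1, m2) == pytest.approx(1 / 6)

    @pytest.mark.parametrize(
        "smiA,smiB",
        [
            ("CC", "CCO"),       # ethane vs ethanol
            ("CCO", "CCN"),      # ethanol vs ethylamine
            ("C=O", "CC(=O)O"),  # formaldehyde vs acetic acid
            ("OCO", "CCO"),
            ("CC(C)O", "CCCO"),
        ],
    )
    def test_matches_brute_force_enumeration(self, smiA, smiB):
        molA, molB = Chem.MolFromSmiles(smiA), Chem.MolFromSmiles(smiB)
        n_mcs = brute_force_mcs_atoms(molA, molB)
        expected = n_mcs / (molA.GetNumAtoms() + molB.GetNumAtoms() - n_mcs)
        assert cs.mcs_tanimoto(molA, molB) == pytest.approx(expected)

    def test_symmetry(self):
        a = Chem.MolFromSmiles("CCO")
        b = Chem.MolFromSmiles("CC(=O)O")
        assert cs.mcs_tanimoto(a, b) == pytest.approx(cs.mcs_tanimoto(b, a))

    def test_bounded_with_equality_iff_isomorphic(self):
        a = Chem.MolFromSmiles("CCO")
        b = Chem.MolFromSmiles("OCC")  # same graph, different entry order
        c = Chem.MolFromSmiles("CCN")
        assert cs.mcs_tanimoto(a, b) == pytest.approx(1.0)
        assert cs.mcs_tanimoto(a, c) < 1.0

    def test_empty_molecule_errors(self):
        with pytest.raises(cs.ChemSpaceError, match="empty"):
            cs.mcs_tanimoto(Chem.MolFromSmiles("CC"), Chem.Mol())

    def test_status_reports_exact_search(self):
        res = cs.mcs_tanimoto(
            Chem.MolFromSmiles("CCO"), Chem.MolFromSmiles("CCN"),
            time_cap=5, return_status=True,
        )
        assert res.exact
        assert res.n_mcs_atoms == 2


# ---------------------------------------------------------------------------
# Combined Tanimoto index and mean-to-drugs


class TestTanimotoIndex:
    @pytest.mark.parametrize(
        "fp_t,mcs_t,mode,expected",
        [
            (0.0, 0.0, "sum_sq", 0.0),
            (0.0, 0.0, "euclid", 0.0),
            (0.6, 0.8, "sum_sq", 1.0),
            (1.0, 1.0, "sum_sq", 2.0),
            (1.0, 1.0, "euclid", math.sqrt(2)),
        ],
    )
    def test_arithmetic(self, fp_t, mcs_t, mode, expected):
        assert cs.tanimoto_index(fp_t, mcs_t, mode) == pytest.approx(expected)

    def test_out_of_range_errors(self):
        with pytest.raises(cs.ChemSpaceError, match="outside"):
            cs.tanimoto_index(1.2, 0.5)


class TestMeanTanimotoToDrugs:
    def test_identical_to_single_drug_gives_two(self):
        mol = Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")
        res = cs.mean_tanimoto_to_drugs(mol, [mol], mol_id="self")
        assert res.tanimoto_index == pytest.approx(2.0)

    def test_mean_of_pairwise_indices(self, fixture_mols):
        mol = fixture_mols[0].structure
        drugs = [r.structure for r in fixture_mols[1:4]]
        res = cs.mean_tanimoto_to_drugs(mol, drugs)
        per_pair = []
        for d in drugs:
            ft = cs.fingerprint_tanimoto(
                cs.compute_fingerprint(mol), cs.compute_fingerprint(d)
            )
            mt = cs.mcs_tanimoto(mol, d)
            per_pair.append(cs.tanimoto_index(ft, mt))
        assert res.tanimoto_index == pytest.approx(np.mean(per_pair))

    def test_invariant_to_drug_ordering(self, fixture_mols):
        mol = fixture_mols[0].structure
        drugs = [r.structure for r in fixture_mols[1:5]]
        r1 = cs.mean_tanimoto_to_drugs(mol, drugs)
        r2 = cs.mean_tanimoto_to_drugs(mol, drugs[::-1])
        assert r1.tanimoto_index == pytest.approx(r2.tanimoto_index)

    def test_empty_drug_set_errors(self, fixture_mols):
        with pytest.raises(cs.ChemSpaceError, match="empty"):
            cs.mean_tanimoto_to_drugs(fixture_mols[0].structure, [])


class TestDrugSimilarityEstimator:
    def test_transform_reports_all_components(self, fixture_mols):
        rng = np.random.default_rng(17)
        drug_scaled = pd.DataFrame(
            rng.uniform(0, 1, (4, 6)), index=[f"d{i}" for i in range(4)]
        )
        drug_mols = [r.structure for r in fixture_mols[:4]]
        est = cs.DrugSimilarity().fit(drug_scaled, drug_mols)
        query_scaled = pd.DataFrame(
            rng.uniform(0, 1, (2, 6)), index=["n1", "n2"]
        )
        query_mols = [r.structure for r in fixture_mols[4:6]]
        out = est.transform(query_scaled, query_mols)
        assert set(out.columns) == {
            "mean_jaccard", "mean_fp_tanimoto", "mean_mcs_tanimoto", "tanimoto_index"
        }
        assert out["mean_jaccard"].between(0, 1).all()
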
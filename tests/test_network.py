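import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

import vasculonet as v
from vasculonet.network import (NetworkParams, bicor, bicor_matrix,
                                signed_adjacency, tom_similarity,
                                cluster_dendrogram, dynamic_hybrid_cut,
                                module_eigenproteins, merge_close_modules,
                                kme_table, iterative_reassignment)


def bicor_oracle(x, y):
    """Direct evaluation of the biweight midcorrelation formula,
    independent of the library implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    out = []
    for vec in (x, y):
        med = np.median(vec)
        mad = np.median(np.abs(vec - med))
        u = (vec - med) / (9 * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        out.append((vec - med) * w)
    a, b = out
    return (a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum())


def tom_oracle(A):
    """Naive triple-loop mean-denominator TOM."""
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l + A[i, j]) / ((k[i] + k[j]) / 2 + 1 - A[i, j])
    return T


class TestBicor:
    def test_self_correlation(self):
        assert bicor([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == pytest.approx(1.0)

    def test_antisymmetry(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for _ in range(20):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(size=30)
            assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_matches_direct_formula_on_gross_outlier_instance(self):
        x = np.array([1.0, 2, 3, 4, 100])
        y = np.array([1.0, 2, 3, 4, 5])
        assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_downweights_gross_outlier(self):
        # a discordant outlier wrecks Pearson but is ignored by bicor
        x = np.array([1.0, 2, 3, 4, -100])
        y = np.array([1.0, 2, 3, 4, 5])
        b = bicor(x, y)
        assert b == pytest.approx(bicor_oracle(x, y), abs=1e-12)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(b - pearson) > 0.2

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([1.0, 1, 1, 1, 2])   # MAD = 0
        y = np.array([1.0, 2, 3, 4, 5])
        with pytest.warns(UserWarning, match="Pearson"):
            b = bicor(x, y)
        assert b == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_too_few_observations(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            assert np.isnan(bicor([1, 2, 3], [4, 5, 6]))

    def test_matrix_agrees_with_scalar_under_missingness(self, rng):
        X = rng.normal(size=(8, 25))
        X[rng.random(X.shape) < 0.15] = np.nan
        df = pd.DataFrame(X, index=[f"P{i}|x" for i in range(8)])
        C = bicor_matrix(df)
        for i in range(8):
            for j in range(i + 1, 8):
                expected = bicor(X[i], X[j])
                assert C.iat[i, j] == pytest.approx(expected, abs=1e-12)


class TestAdjacencyTom:
    @pytest.mark.parametrize("cor,expected", [
        (1.0, 1.0), (-1.0, 0.0), (0.0, 0.5 ** 9)])
    def test_signed_adjacency_closed_forms(self, cor, expected):
        C = np.array([[1.0, cor], [cor, 1.0]])
        A = signed_adjacency(C, 9)
        assert A[0, 1] == pytest.approx(expected, abs=1e-15)
        assert A[0, 0] == 0.0

    def test_empty_adjacency_gives_zero_tom(self):
        A = np.zeros((5, 5))
        T = tom_similarity(A)
        assert np.all(T[~np.eye(5, dtype=bool)] == 0.0)
        assert np.all(np.diag(T) == 1.0)

    def test_three_node_hand_value(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 0.0)
        T = tom_similarity(A)
        # L = 0.25, k = 1: (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert T[0, 1] == pytest.approx(0.5, abs=1e-15)

    def test_matches_triple_loop_oracle(self, rng):
        A = rng.uniform(0, 1, (20, 20))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        assert np.max(np.abs(tom_similarity(A) - tom_oracle(A))) < 1e-12

    def test_asymmetric_input_rejected(self):
        A = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(A)


class TestDendrogram:
    def test_two_perfect_blocks_split_at_height_one(self):
        D = np.ones((6, 6))
        D[:3, :3] = 0.0
        D[3:, 3:] = 0.0
        np.fill_diagonal(D, 0.0)
        Z = cluster_dendrogram(D)
        assert Z[-1, 2] == pytest.approx(1.0)
        assert Z[:-1, 2].max() == pytest.approx(0.0)

    def test_equal_dissimilarities_merge_in_index_order(self):
        D = np.ones((3, 3)) - np.eye(3)
        Z = cluster_dendrogram(D)
        assert (int(Z[0, 0]), int(Z[0, 1])) == (0, 1)

    def test_heights_match_scipy_average_linkage(self, rng):
        X = rng.normal(size=(15, 4))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        Z = cluster_dendrogram(D)
        Z_ref = linkage(squareform(D, checks=False), method="average")
        assert np.allclose(np.sort(Z[:, 2]), np.sort(Z_ref[:, 2]), atol=1e-12)

    def test_non_finite_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            cluster_dendrogram(D)


class TestDynamicHybridCut:
    def test_three_planted_blocks_recovered_pure(self, rng):
        from conftest import make_block_matrix
        D = make_block_matrix(rng, 3, 50, 0.1, 0.9)
        D += rng.uniform(0, 0.01, D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        Z = cluster_dendrogram(D)
        labels = dynamic_hybrid_cut(Z, D, NetworkParams())
        assert len(set(labels) - {0}) == 3
        for b in range(3):
            block = labels[b * 50:(b + 1) * 50]
            assert len(set(block)) == 1 and block[0] != 0

    def test_undersized_block_never_standalone(self, rng):
        D = np.full((60, 60), 0.9)
        D[:50, :50] = 0.1
        D[50:, 50:] = 0.1      # block of 10 < min module size 20
        np.fill_diagonal(D, 0.0)
        Z = cluster_dendrogram(D)
        labels = dynamic_hybrid_cut(Z, D, NetworkParams(pam_stage=False))
        small = labels[50:]
        big_label = labels[0]
        assert all(l in (0, big_label) for l in small)
        # the 10 strays cannot form their own module
        assert len(set(labels) - {0}) == 1

    def test_structureless_input_never_splits(self):
        D = np.ones((40, 40)) - np.eye(40)
        Z = cluster_dendrogram(D)
        labels = dynamic_hybrid_cut(Z, D, NetworkParams())
        assert len(set(labels) - {0}) <= 1


class TestEigenproteins:
    def test_identical_profiles_explain_all_variance(self, rng):
        prof = rng.normal(size=20)
        X = pd.DataFrame(np.tile(prof, (5, 1)) + np.arange(5)[:, None],
                         index=[f"P{i}|x" for i in range(5)])
        labels = pd.Series("M1", index=X.index)
        eig, pve = module_eigenproteins(X, labels)
        assert pve["M1"] == pytest.approx(1.0)
        std = (prof - prof.mean()) / prof.std()
        assert np.allclose(np.abs(eig.loc["M1"]), np.abs(std), atol=1e-9)

    def test_orthogonal_profiles_split_variance(self, rng):
        # 4 exactly orthonormal zero-mean profiles: each explains 1/4
        n = 20
        basis = np.column_stack([np.ones(n), rng.normal(size=(n, 4))])
        Q, _ = np.linalg.qr(basis)
        X = pd.DataFrame(Q[:, 1:].T, index=[f"P{i}|x" for i in range(4)])
        labels = pd.Series("M1", index=X.index)
        _, pve = module_eigenproteins(X, labels)
        assert pve["M1"] == pytest.approx(1 / 4, abs=1e-9)

    def test_sign_convention_positive_mean_member_correlation(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 25)),
                         index=[f"P{i}|x" for i in range(30)])
        labels = pd.Series(["M1"] * 15 + ["M2"] * 15, index=X.index)
        eig, _ = module_eigenproteins(X, labels)
        for mod in ("M1", "M2"):
            members = X.loc[labels == mod].to_numpy()
            members = (members - members.mean(1, keepdims=True)) / \
                members.std(1, keepdims=True)
            e = eig.loc[mod].to_numpy()
            cors = members @ e / (len(e) * e.std())
            assert cors.mean() > 0


class TestMergeCloseModules:
    def _two_module_matrix(self, cor_target, rng):
        """Two modules whose eigenprofiles have *sample* correlation
        exactly ``cor_target`` (noise orthogonalized by construction)."""
        n = 40
        base = rng.normal(size=n)
        base = (base - base.mean()) / base.std()
        e = rng.normal(size=n)
        e = e - e.mean() - base * (e @ base) / (base @ base) * 1.0
        e = e / e.std()
        other = cor_target * base + np.sqrt(1 - cor_target**2) * e
        rows = []
        for src in (base, other):
            for _ in range(10):
                rows.append(src + 0.001 * rng.normal(size=n))
        X = pd.DataFrame(rows, index=[f"P{i}|x" for i in range(20)])
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=X.index)
        return X, labels

    def test_close_pair_merged(self, rng):
        # eigenprotein correlation 0.95 -> dissimilarity 0.05 < 0.07
        X, labels = self._two_module_matrix(0.95, rng)
        merged = merge_close_modules(X, labels, 0.07)
        assert merged.nunique() == 1

    def test_distant_pair_not_merged(self, rng):
        # eigenprotein correlation 0.90 -> dissimilarity 0.10 >= 0.07
        X, labels = self._two_module_matrix(0.90, rng)
        merged = merge_close_modules(X, labels, 0.07)
        assert merged.nunique() == 2

    def test_merge_fixed_point_independent_of_label_order(self, rng):
        # chain of three modules: A~B close, B~C close, A~C less so
        n = 50
        b = rng.normal(size=n)
        a = 0.97 * b + np.sqrt(1 - 0.97**2) * rng.normal(size=n)
        c = 0.97 * b + np.sqrt(1 - 0.97**2) * rng.normal(size=n)
        rows, names, labs = [], [], []
        for lab, src in (("A", a), ("B", b), ("C", c)):
            for i in range(8):
                rows.append(src + 0.01 * rng.normal(size=n))
                names.append(f"{lab}{i}|x")
                labs.append(lab)
        X = pd.DataFrame(rows, index=names)
        partitions = []
        for order in (["A", "B", "C"], ["C", "B", "A"], ["B", "A", "C"]):
            rename = {lab: order[i] for i, lab in enumerate(["A", "B", "C"])}
            labels = pd.Series([rename[l] for l in labs], index=names)
            merged = merge_close_modules(X, labels, 0.07)
            partitions.append(frozenset(
                frozenset(merged.index[merged == m]) for m in merged.unique()))
        assert len(set(partitions)) == 1


class TestKme:
    def test_member_identical_to_eigenprotein(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 30)),
                         index=[f"P{i}|x" for i in range(10)])
        labels = pd.Series("M1", index=X.index)
        eig, _ = module_eigenproteins(X, labels)
        X2 = pd.concat([X, pd.DataFrame([eig.loc["M1"]], index=["COPY|c"])])
        kme = kme_table(X2, eig)
        assert kme.loc["COPY|c", "M1"] == pytest.approx(1.0, abs=1e-9)

    def test_dimensions(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 20)),
                         index=[f"P{i}|x" for i in range(12)])
        labels = pd.Series(["M1"] * 6 + ["M2"] * 6, index=X.index)
        eig, _ = module_eigenproteins(X, labels)
        assert kme_table(X, eig).shape == (12, 2)

    def test_noise_protein_low_kme(self, rng):
        n = 500
        e = pd.DataFrame(rng.normal(size=(1, n)), index=["M1"])
        hits = 0
        for _ in range(100):
            x = pd.DataFrame(rng.normal(size=(1, n)), index=["N|n"])
            if abs(kme_table(x, e).iat[0, 0]) < 0.2:
                hits += 1
        assert hits >= 99


class TestIterativeReassignment:
    def test_rules_applied(self, rng):
        # construct data with two clear modules and probes
        n = 60
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        rows, names = [], []
        for i in range(20):
            rows.append(f1 + 0.4 * rng.normal(size=n)); names.append(f"A{i}|a")
        for i in range(20):
            rows.append(f2 + 0.4 * rng.normal(size=n)); names.append(f"B{i}|b")
        # probe clearly belonging to module B but labelled A
        rows.append(f2 + 0.2 * rng.normal(size=n)); names.append("MOVE|m")
        # pure noise probe labelled A -> should end grey
        rows.append(rng.normal(size=n)); names.append("GREY|g")
        X = pd.DataFrame(rows, index=names)
        labels = pd.Series(["A"] * 20 + ["B"] * 20 + ["A", "A"], index=names)
        part = iterative_reassignment(X, labels,
                                      NetworkParams(min_module_size=10))
        sizes = part.labels.value_counts()
        big = part.labels["B0|b"]
        assert part.labels["MOVE|m"] == big
        assert part.labels["GREY|g"] == "M0"
        assert part.converged

    def test_module_names_ordered_by_size(self, corrected_cohort, rng):
        _, m, _ = corrected_cohort
        sub = m.iloc[:350]
        net = v.CoexpressionNetwork(reassign_max_iter=10)
        net.fit(sub)
        sizes = net.labels_[net.labels_ != "M0"].value_counts()
        expected = [f"M{i+1}" for i in range(len(sizes))]
        assert sorted(sizes.index, key=lambda s: int(s[1:])) == expected
        assert list(sizes.loc[expected]) == sorted(sizes, reverse=True)

    def test_raising_assign_floor_never_assigns_more(self, corrected_cohort):
        _, m, _ = corrected_cohort
        sub = m.iloc[:300]
        base = v.build_network(sub, NetworkParams(kme_assign_min=0.30,
                                                  reassign_max_iter=10))
        strict = v.build_network(sub, NetworkParams(kme_assign_min=0.50,
                                                    reassign_max_iter=10))
        assert (strict.labels != "M0").sum() <= (base.labels != "M0").sum()
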
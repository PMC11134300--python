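"""clr transform, Cailliez PCoA, Procrustes tests and the ASV screen."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from microtrans import asv_association as aa
from microtrans import community_matrix as cm
from microtrans.pedigree_kinship import RelatednessMatrix
from microtrans.rfid_social import ContactMatrix


def counts(rows):
    rows = np.atleast_2d(rows)
    return cm.CountTable(pd.DataFrame(
        rows, index=[f"s{i}" for i in range(len(rows))],
        columns=[f"a{j}" for j in range(rows.shape[1])]))


class TestClr:
    def test_uniform_sample_is_zero(self):
        out = aa.clr_transform(counts([[7, 7, 7, 7]]))
        np.testing.assert_allclose(out.values.to_numpy(), 0.0, atol=1e-12)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        out = aa.clr_transform(counts(rng.integers(0, 50, (8, 20))))
        np.testing.assert_allclose(out.values.sum(axis=1), 0.0, atol=1e-10)

    def test_two_part_closed_form(self):
        out = aa.clr_transform(counts([[1, 3]]), pseudocount=0.5)
        m = (np.log(1.5) + np.log(3.5)) / 2
        np.testing.assert_allclose(out.values.to_numpy()[0],
                                   [np.log(1.5) - m, np.log(3.5) - m])
        assert out.values.iloc[0, 1] == pytest.approx(0.4236, abs=1e-4)


class TestAsvDissimilarity:
    def test_examples_and_line_metric(self):
        clr = aa.ClrTable(pd.DataFrame(
            {"a0": [0.0, 1.0, 3.0], "a1": [0.0, -1.0, -3.0]},
            index=["s0", "s1", "s2"]))
        D = aa.asv_dissimilarity(clr, "a0")
        np.testing.assert_allclose(D, [[0, 1, 3], [1, 0, 2], [3, 2, 0]])
        rng = np.random.default_rng(1)
        vals = rng.normal(size=12)
        Dr = np.abs(vals[:, None] - vals[None, :])
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert Dr[i, j] <= Dr[i, k] + Dr[k, j] + 1e-12


class TestPcoaCailliez:
    def test_euclidean_input_needs_no_correction(self):
        pts = np.array([[0.0], [1.0], [3.5], [7.0]])
        D = squareform(pdist(pts))
        res = aa.pcoa_cailliez(D)
        assert res.cailliez_c == 0.0
        np.testing.assert_allclose(squareform(pdist(res.scores)), D, atol=1e-8)

    def test_corrected_eigenvalues_nonnegative(self):
        rng = np.random.default_rng(2)
        # non-Euclidean: random symmetric dissimilarity violating triangle-ish
        D = squareform(rng.uniform(0.5, 1.0, 6 * 5 // 2))
        res = aa.pcoa_cailliez(D)
        assert res.cailliez_c > 0
        B = res.scores @ res.scores.T
        vals = np.linalg.eigvalsh(B)
        assert vals.min() > -1e-8

    def test_constant_matches_bisection_oracle(self):
        """Cailliez constant from the special eigenproblem equals the value
        a bisection search finds for the smallest constant with no negative
        eigenvalue (4-point non-Euclidean instance)."""
        D = np.array([
            [0.0, 1.0, 1.0, 2.9],
            [1.0, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 1.0],
            [2.9, 1.0, 1.0, 0.0],
        ])
        c_eig = aa.cailliez_constant(D)
        assert c_eig > 0

        def min_eig(c):
            Dc = D + c
            np.fill_diagonal(Dc, 0.0)
            n = len(Dc)
            J = np.eye(n) - np.ones((n, n)) / n
            B = J @ (-0.5 * Dc * Dc) @ J
            return np.linalg.eigvalsh(B).min()

        lo, hi = 0.0, 10.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if min_eig(mid) < -1e-12:
                lo = mid
            else:
                hi = mid
        assert c_eig == pytest.approx(hi, abs=1e-6)

    def test_reconstruction_after_correction(self):
        D = np.array([
            [0.0, 1.0, 1.0, 2.9],
            [1.0, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 1.0],
            [2.9, 1.0, 1.0, 0.0],
        ])
        res = aa.pcoa_cailliez(D)
        Dc = D + res.cailliez_c
        np.fill_diagonal(Dc, 0.0)
        np.testing.assert_allclose(squareform(pdist(res.scores)), Dc, atol=1e-6)

    def test_asymmetric_raises(self):
        with pytest.raises(ValueError, match="symmetric"):
            aa.pcoa_cailliez(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestPredictorConfiguration:
    def test_zero_offdiagonal_gives_regular_simplex(self):
        M = RelatednessMatrix([f"i{k}" for k in range(4)], np.eye(4))
        res = aa.predictor_configuration(M)
        d = pdist(res.scores)
        np.testing.assert_allclose(d, d[0], atol=1e-8)

    def test_full_relatedness_pair_coincides(self):
        V = np.eye(3)
        V[0, 1] = V[1, 0] = 1.0
        res = aa.predictor_configuration(
            RelatednessMatrix(["a", "b", "c"], V))
        assert np.linalg.norm(res.scores[0] - res.scores[1]) < 1e-8

    def test_contact_matrix_reconstruction(self, small_dataset):
        res = aa.predictor_configuration(small_dataset.contacts, kind="contact")
        V = small_dataset.contacts.values
        off = ~np.eye(len(V), dtype=bool)
        scaled = (V - V[off].min()) / (V[off].max() - V[off].min())
        D = 1.0 - scaled
        np.fill_diagonal(D, 0.0)
        Dc = D + res.cailliez_c
        np.fill_diagonal(Dc, 0.0)
        np.testing.assert_allclose(squareform(pdist(res.scores)), Dc, atol=1e-6)


def config_from(points):
    pts = np.asarray(points, dtype=float)
    return aa.PcoaResult([str(i) for i in range(len(pts))], pts,
                         np.ones(pts.shape[1]))


class TestProcrustes:
    def test_invariance_under_similarity_transform(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        Y = 3.2 * (X @ R)
        Y[:, 0] *= -1  # reflection
        Y += np.array([5.0, -2.0])
        m2, p = aa.procrustes_test(config_from(X), config_from(Y),
                                   n_perm=99, seed=0)
        assert m2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1 / 100, abs=1e-12)

    def test_matches_rotation_grid_oracle(self):
        """m² on 2-D five-point instances equals a brute-force search over
        rotations and reflection to 1e-4."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            X = rng.normal(size=(5, 2))
            Y = rng.normal(size=(5, 2))
            m2, _ = aa.procrustes_test(config_from(X), config_from(Y),
                                       n_perm=9, seed=0)

            Xc = X - X.mean(0)
            Xc /= np.sqrt((Xc ** 2).sum())
            Yc = Y - Y.mean(0)
            Yc /= np.sqrt((Yc ** 2).sum())
            best = np.inf
            for theta in np.linspace(0, 2 * np.pi, 40_000, endpoint=False):
                R = np.array([[np.cos(theta), -np.sin(theta)],
                              [np.sin(theta), np.cos(theta)]])
                for refl in (1.0, -1.0):
                    Rf = R @ np.diag([1.0, refl])
                    # best uniform scaling s minimising ||X - s Y Rf||²
                    num = np.sum(Xc * (Yc @ Rf))
                    best = min(best, 1.0 - max(num, 0.0) ** 2)
            assert m2 == pytest.approx(best, abs=1e-4)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            aa.procrustes_test(config_from([[0.0], [1.0]]),
                               config_from([[0.0], [1.0]]))

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for s in range(60):
            X = rng.normal(size=(20, 2))
            Y = rng.normal(size=(20, 2))
            _, p = aa.procrustes_test(config_from(X), config_from(Y),
                                      n_perm=49, seed=s)
            ps.append(p)
        assert 0.2 < np.mean(ps) < 0.8


class TestBhFdr:
    def test_q_matches_textbook_step_up(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=37)
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(p, method="fdr_bh")
        m = len(p)
        order = np.argsort(p)
        manual = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            manual[idx] = running
        np.testing.assert_allclose(q, manual, atol=1e-12)
        assert np.all(np.diff(q[order]) >= -1e-12)


def screen_inputs(rng, n_ind=25, n_asv=12):
    ids = [f"m{k}" for k in range(n_ind)]
    X = rng.integers(0, 40, size=(n_ind, n_asv)) + 1
    table = cm.CountTable(pd.DataFrame(
        X, index=[f"{m}:colon" for m in ids],
        columns=[f"a{j}" for j in range(n_asv)]))
    meta = cm.SampleMeta(pd.DataFrame({
        "sample_id": table.sample_ids, "individual": ids,
        "gut_section": "colon", "subspecies": "MMM", "sex": "F",
        "age_days": 100.0}))
    W = rng.uniform(0, 1, (n_ind, n_ind))
    V = (W + W.T) / 2
    np.fill_diagonal(V, 0.0)
    contacts = ContactMatrix(ids, V)
    return table, meta, contacts


class TestAsvScreen:
    def test_prevalence_threshold_excludes(self):
        rng = np.random.default_rng(7)
        table, meta, contacts = screen_inputs(rng, n_ind=25)
        X = table.counts.copy()
        X.iloc[:, 0] = 0
        X.iloc[:6, 0] = 5  # present in 6 < 20 samples
        table = cm.CountTable(X)
        clr = aa.clr_transform(table)
        res = aa.asv_screen(table, clr, {"contact": contacts}, meta,
                            "colon", "MMM", min_prevalence=20, n_perm=19, seed=0)
        assert "a0" not in set(res["asv"])
        assert set(res["asv"]) == {f"a{j}" for j in range(1, 12)}

    def test_invariant_to_asv_column_order(self):
        rng = np.random.default_rng(8)
        table, meta, contacts = screen_inputs(rng, n_ind=22)
        clr = aa.clr_transform(table)
        res1 = aa.asv_screen(table, clr, {"contact": contacts}, meta,
                             "colon", "MMM", min_prevalence=5, n_perm=29, seed=1)
        cols = list(table.counts.columns)[::-1]
        t2 = cm.CountTable(table.counts[cols])
        res2 = aa.asv_screen(t2, aa.clr_transform(t2), {"contact": contacts},
                             meta, "colon", "MMM", min_prevalence=5, n_perm=29,
                             seed=1)
        merged = res1.merge(res2, on=["asv", "predictor"], suffixes=("_1", "_2"))
        np.testing.assert_allclose(merged["m2_1"], merged["m2_2"], atol=1e-10)
        np.testing.assert_allclose(merged["p_1"], merged["p_2"], atol=1e-12)


class TestSubspeciesCongruence:
    def frame(self, m2):
        return pd.DataFrame({"asv": [f"a{k}" for k in range(len(m2))],
                             "m2": m2})

    def test_identical_results(self):
        r = self.frame(np.linspace(0.1, 0.9, 10))
        out = aa.subspecies_congruence(r, r)
        assert out["spearman_rho"] == pytest.approx(1.0)
        assert out["wilcoxon_p"] == pytest.approx(1.0)

    def test_antiranked(self):
        a = self.frame(np.linspace(0.1, 0.9, 10))
        b = self.frame(np.linspace(0.9, 0.1, 10))
        out = aa.subspecies_congruence(a, b)
        assert out["spearman_rho"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(9)
        x, y = rng.uniform(size=30), rng.uniform(size=30)
        out = aa.subspecies_congruence(self.frame(x), self.frame(y))
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert out["spearman_rho"] == pytest.approx(oracle, abs=1e-10)

    def test_no_shared_asvs_raises(self):
        a = self.frame([0.1, 0.2, 0.3, 0.4, 0.5])
        b = self.frame([0.1] * 5)
        b["asv"] = [f"z{k}" for k in range(5)]
        with pytest.raises(ValueError, match="no shared"):
            aa.subspecies_congruence(a, b)
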
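"""Tests of pedigree machinery, mixed-model equations and AI-REML."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from scipy.sparse.linalg import spsolve

from resilac.quantgen import (
    Pedigree,
    PedigreeError,
    _incidence_full,
    build_design,
    build_mme,
    fit_linear_covariance,
    reml_bivariate,
    reml_repeatability,
    reml_single,
    solve_ebv,
)
from resilac.synthetic import simulate_breeding_values, simulate_pedigree, simulate_trait_cohort


def random_pedigree(rng, n=40):
    """A random multi-generation pedigree of <= n animals."""
    animals, sires, dams = [], [], []
    for i in range(n):
        animals.append(f"a{i}")
        if i < 6 or rng.random() < 0.25:
            sires.append("0")
            dams.append("0")
        else:
            sires.append(f"a{rng.integers(0, i)}")
            d = rng.integers(0, i)
            dams.append(f"a{d}")
    return Pedigree(animals, sires, dams)


class TestPedigree:
    def test_unrelated_founders_identity(self):
        ped = Pedigree(["a", "b", "c"], ["0"] * 3, ["0"] * 3)
        np.testing.assert_allclose(ped.a_inverse().toarray(), np.eye(3))
        np.testing.assert_allclose(ped.relationship_matrix(), np.eye(3))

    def test_trio_closed_form(self):
        ped = Pedigree(["s", "d", "o"], ["0", "0", "s"], ["0", "0", "d"])
        A = ped.relationship_matrix()
        i, j, k = ped.index["s"], ped.index["d"], ped.index["o"]
        assert A[i, k] == 0.5 and A[j, k] == 0.5 and A[k, k] == 1.0
        Ainv = ped.a_inverse().toarray()
        np.testing.assert_allclose(Ainv @ A, np.eye(3), atol=1e-12)

    def test_sire_daughter_mating_inbreeding(self):
        ped = Pedigree(
            ["s", "d", "g", "o"], ["0", "0", "s", "s"], ["0", "0", "d", "g"]
        )
        F = ped.inbreeding()
        A = ped.relationship_matrix()
        o = ped.index["o"]
        assert F[o] == pytest.approx(0.25)
        assert A[o, o] == pytest.approx(1.25)

    def test_henderson_inverse_matches_tabular_on_random_pedigrees(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            ped = random_pedigree(rng, n=int(rng.integers(10, 51)))
            A = ped.relationship_matrix()
            err = np.abs(ped.a_inverse().toarray() @ A - np.eye(ped.n)).max()
            assert err < 1e-8

    def test_cycle_detection_names_cycle(self):
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree(["a", "b"], ["b", "a"], ["0", "0"])

    def test_relationship_submatrix(self):
        rng = np.random.default_rng(5)
        ped = random_pedigree(rng, 30)
        ids = [ped.animals[i] for i in (3, 7, 20)]
        A = ped.relationship_matrix()
        idx = [ped.index[a] for a in ids]
        np.testing.assert_allclose(
            ped.relationship_submatrix(ids), A[np.ix_(idx, idx)], atol=1e-10
        )

    def test_logdet_a(self):
        rng = np.random.default_rng(6)
        ped = random_pedigree(rng, 25)
        sign, logdet = np.linalg.slogdet(ped.relationship_matrix())
        assert sign > 0 and ped.logdet_a() == pytest.approx(logdet, abs=1e-8)


class TestMME:
    def _toy(self, seed=3):
        ped = simulate_pedigree(3, 2, seed)
        df, _ = simulate_trait_cohort(3, 2, 0.3, 0.7, seed=seed)
        return df, ped

    def test_system_dimension(self):
        df, ped = self._toy()
        y = df["trait"].to_numpy()
        X, _ = build_design(df, ["parity_class"])
        Z = sparse.csr_matrix(_incidence_full(df["cow_id"], ped))
        C, rhs = build_mme(y, X, Z, ped.a_inverse(), 0.3, 0.7)
        assert C.shape[0] == X.shape[1] + ped.n
        assert rhs.size == C.shape[0]

    def test_blup_equals_dense_gls(self):
        df, ped = self._toy()
        y = df["trait"].to_numpy()
        X, _ = build_design(df, ["parity_class"])
        Zd = _incidence_full(df["cow_id"], ped)
        sa, se = 0.3, 0.7
        C, rhs = build_mme(y, X, sparse.csr_matrix(Zd), ped.a_inverse(), sa, se)
        u_mme = spsolve(C, rhs)[X.shape[1]:]
        A = ped.relationship_matrix()
        V = sa * Zd @ A @ Zd.T + se * np.eye(y.size)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u_gls = sa * A @ Zd.T @ Vi @ (y - X @ beta)
        np.testing.assert_allclose(u_mme, u_gls, atol=1e-10)

    def test_vanishing_genetic_variance_approaches_ols(self):
        df, ped = self._toy()
        y = df["trait"].to_numpy()
        X, _ = build_design(df, ["parity_class"])
        Z = sparse.csr_matrix(_incidence_full(df["cow_id"], ped))
        C, rhs = build_mme(y, X, Z, ped.a_inverse(), 1e-10, 1.0)
        beta_mme = spsolve(C, rhs)[: X.shape[1]]
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta_mme, beta_ols, atol=1e-5)


class TestREMLSingle:
    def test_loglik_matches_dense_oracle_n20(self):
        """The engine's restricted log-likelihood at the optimum equals a
        from-scratch dense evaluation of -0.5(log|V| + log|X'V^-1 X| + y'Py)."""
        df, ped = simulate_trait_cohort(4, 5, 0.3, 0.7, seed=77)
        vc = reml_single(df, "trait", ped, fixed_factors=("parity_class",))
        y = df["trait"].to_numpy()
        X, _ = build_design(df, ["parity_class"])
        recorded = sorted(df["cow_id"].unique())
        A = ped.relationship_submatrix(recorded)
        Z = np.zeros((len(df), len(recorded)))
        Z[np.arange(len(df)), [recorded.index(c) for c in df["cow_id"]]] = 1
        V = vc.sigma_a2 * Z @ A @ Z.T + vc.sigma_e2 * np.eye(len(df))
        Vi = np.linalg.inv(V)
        M = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.solve(M, X.T @ Vi)
        ll = -0.5 * (
            np.linalg.slogdet(V)[1] + np.linalg.slogdet(M)[1] + y @ P @ y
        )
        assert vc.loglik == pytest.approx(ll, abs=1e-6)

    def test_null_heritability_estimated_near_zero(self):
        # with zero genetic variance the estimate collapses towards the
        # boundary: consistent with zero within its own sampling noise
        df, ped = simulate_trait_cohort(40, 25, 0.0, 1.0, seed=13)
        vc = reml_single(df, "trait", ped, fixed_factors=("hys", "parity_class"))
        assert vc.h2 < 2.5 * vc.se_h2
        assert vc.h2 < 0.15

    def test_h2_unbiased_over_replicates(self):
        """Mean heritability estimate over replicates at true h2 = 0.25."""
        ests = []
        for rep in range(8):
            df, ped = simulate_trait_cohort(25, 16, 0.025, 0.075, seed=100 + rep)
            vc = reml_single(df, "trait", ped, fixed_factors=("hys", "parity_class"))
            ests.append(vc.h2)
        assert np.mean(ests) == pytest.approx(0.25, abs=0.06)

    def test_loglik_non_decreasing(self):
        df, ped = simulate_trait_cohort(15, 10, 0.03, 0.08, seed=55)
        y = df["trait"].to_numpy()
        X, _ = build_design(df, ["hys", "parity_class"])
        recorded = sorted(df["cow_id"].unique())
        A = ped.relationship_submatrix(recorded)
        Z = np.zeros((len(df), len(recorded)))
        Z[np.arange(len(df)), [recorded.index(c) for c in df["cow_id"]]] = 1
        v0 = np.var(y, ddof=1)
        fit = fit_linear_covariance(
            y, X, [Z @ A @ Z.T, np.eye(len(df))], np.array([v0 / 2, v0 / 2]),
            em_ranks=[len(recorded), len(df)],
        )
        assert fit.converged
        diffs = np.diff(fit.history)
        assert np.all(diffs >= -1e-8)


class TestREMLRepeatability:
    def _repeated_cohort(self, sa, spe, se, n_sires=20, n_dps=12, reps=3, seed=0):
        rng = np.random.default_rng(seed)
        ped = simulate_pedigree(n_sires, n_dps, seed)
        bv = simulate_breeding_values(ped, sa, seed + 1)
        cows = [a for a in ped.animals if a.startswith("C")]
        rows = []
        for c in cows:
            pe = rng.normal(0, np.sqrt(spe))
            for r in range(reps):
                rows.append(
                    {
                        "cow_id": c,
                        "hys": f"H{rng.integers(4)}",
                        "parity_class": str(r + 1),
                        "trait": 10 + bv[c] + pe + rng.normal(0, np.sqrt(se)),
                    }
                )
        return pd.DataFrame(rows), ped

    def test_component_recovery(self):
        df, ped = self._repeated_cohort(0.5, 0.7, 1.25, seed=9)
        vc = reml_repeatability(df, "trait", ped, fixed_factors=("hys", "parity_class"))
        assert vc.converged
        se_sa = np.sqrt(vc.cov_theta[0, 0])
        se_spe = np.sqrt(vc.cov_theta[1, 1])
        se_se = np.sqrt(vc.cov_theta[2, 2])
        assert abs(vc.sigma_a2 - 0.5) < 2 * se_sa + 1e-6
        assert abs(vc.sigma_pe2 - 0.7) < 2 * se_spe + 1e-6
        assert abs(vc.sigma_e2 - 1.25) < 2 * se_se + 1e-6
        assert vc.repeatability == pytest.approx(
            (vc.sigma_a2 + vc.sigma_pe2) / vc.phenotypic_variance
        )

    def test_sigma_pe_non_negative(self):
        # true pe variance of zero: the estimate is floored at ~0
        df, ped = self._repeated_cohort(0.4, 0.0, 1.0, n_sires=10, n_dps=8, seed=21)
        vc = reml_repeatability(df, "trait", ped, fixed_factors=("hys",))
        assert vc.sigma_pe2 >= 0

    def test_single_record_animals_flagged(self):
        df, ped = self._repeated_cohort(0.4, 0.3, 1.0, n_sires=4, n_dps=4, reps=1, seed=3)
        with pytest.raises(ValueError, match="inestimable"):
            reml_repeatability(df, "trait", ped, fixed_factors=("hys",))


class TestREMLBivariate:
    def _bivariate_cohort(self, r_g, seed=0, n_sires=25, n_dps=14):
        rng = np.random.default_rng(seed)
        ped = simulate_pedigree(n_sires, n_dps, seed)
        G0 = np.array([[0.3, r_g * np.sqrt(0.3 * 0.4)], [r_g * np.sqrt(0.3 * 0.4), 0.4]])
        R0 = np.array([[0.7, 0.15], [0.15, 0.6]])
        b1 = simulate_breeding_values(ped, 1.0, seed + 1)
        b2 = simulate_breeding_values(ped, 1.0, seed + 2)
        L = np.linalg.cholesky(G0)
        a1 = L[0, 0] * b1
        a2 = L[1, 0] * b1 + L[1, 1] * b2
        Le = np.linalg.cholesky(R0)
        rows = []
        for c in (a for a in ped.animals if a.startswith("C")):
            e = Le @ rng.standard_normal(2)
            rows.append(
                {
                    "cow_id": c,
                    "parity": 1,
                    "hys": f"H{rng.integers(3)}",
                    "t1": 1 + a1[c] + e[0],
                    "t2": 2 + a2[c] + e[1],
                }
            )
        return pd.DataFrame(rows), ped

    def test_trait_with_jittered_self_gives_rg_near_one(self):
        rng = np.random.default_rng(2)
        df, ped = self._bivariate_cohort(0.5, seed=40)
        df["t2"] = df["t1"] + rng.normal(0, 0.05, len(df))
        res = reml_bivariate(df, ("t1", "t2"), ped, fixed_factors=("hys",))
        assert res.r_g > 0.95

    def test_independent_traits_rg_within_noise(self):
        df, ped = self._bivariate_cohort(0.0, seed=41)
        res = reml_bivariate(df, ("t1", "t2"), ped, fixed_factors=("hys",))
        assert abs(res.r_g) < max(2 * res.se_r_g, 0.3)

    def test_correlation_recovery_and_psd(self):
        df, ped = self._bivariate_cohort(0.7, seed=42)
        res = reml_bivariate(df, ("t1", "t2"), ped, fixed_factors=("hys",))
        assert res.converged
        assert abs(res.r_g - 0.7) < max(2 * res.se_r_g, 0.25)
        assert np.linalg.eigvalsh(res.G).min() > -1e-8
        assert np.linalg.eigvalsh(res.R).min() > -1e-8
        assert abs(res.r_g) <= 1 + 1e-8

    def test_marginal_variances_agree_with_single_trait(self):
        df, ped = self._bivariate_cohort(0.4, seed=43)
        res = reml_bivariate(df, ("t1", "t2"), ped, fixed_factors=("hys",))
        vc1 = reml_single(df, "t1", ped, fixed_factors=("hys",))
        tot_bi = res.G[0, 0] + res.R[0, 0]
        tot_si = vc1.sigma_a2 + vc1.sigma_e2
        assert tot_bi == pytest.approx(tot_si, rel=0.05)


class TestEBV:
    def test_unconnected_animal_zero_ebv_zero_reliability(self):
        ped = Pedigree(
            ["s", "d", "c", "lone"], ["0", "0", "s", "0"], ["0", "0", "d", "0"]
        )
        df = pd.DataFrame(
            {"cow_id": ["c"] * 4, "grp": ["g"] * 4, "trait": [1.0, 2.0, 1.5, 2.5]}
        )
        from resilac.quantgen import VarianceComponents

        vc = VarianceComponents(0.3, 0.7, 0.3, 0.1, 0.0, True, 1)
        ebv = solve_ebv(df, "trait", ped, vc, fixed_factors=("grp",))
        row = ebv[ebv.animal == "lone"].iloc[0]
        assert row["ebv"] == pytest.approx(0.0, abs=1e-12)
        assert row["reliability"] == pytest.approx(0.0, abs=1e-9)

    def test_ebv_equals_dense_gls_blup(self):
        df, ped = simulate_trait_cohort(3, 3, 0.3, 0.7, seed=31)
        from resilac.quantgen import VarianceComponents

        vc = VarianceComponents(0.3, 0.7, 0.3, 0.1, 0.0, True, 1)
        ebv = solve_ebv(df, "trait", ped, vc, fixed_factors=("parity_class",))
        y = df["trait"].to_numpy()
        X, _ = build_design(df, ["parity_class"])
        Zd = _incidence_full(df["cow_id"], ped)
        A = ped.relationship_matrix()
        V = 0.3 * Zd @ A @ Zd.T + 0.7 * np.eye(y.size)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = 0.3 * A @ Zd.T @ Vi @ (y - X @ beta)
        np.testing.assert_allclose(ebv["ebv"].to_numpy(), u, atol=1e-8)

    def test_sire_reliability_grows_with_daughters(self):
        from resilac.quantgen import VarianceComponents

        vc = VarianceComponents(0.25, 0.75, 0.25, 0.05, 0.0, True, 1)
        rels = {}
        # several sire families: with a single sire the contemporary-group
        # mean absorbs the sire contrast and its reliability is exactly 0
        for n_d in (10, 100):
            ped = simulate_pedigree(8, n_d, seed=17)
            rng = np.random.default_rng(18)
            cows = [a for a in ped.animals if a.startswith("C")]
            df = pd.DataFrame(
                {
                    "cow_id": cows,
                    "grp": "g",
                    "trait": rng.normal(0, 1, len(cows)),
                }
            )
            ebv = solve_ebv(df, "trait", ped, vc, fixed_factors=("grp",))
            rels[n_d] = float(ebv[ebv.animal == "S0000"]["reliability"].iloc[0])
        assert rels[100] > rels[10]
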
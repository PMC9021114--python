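import numpy as np
import pytest

import ggmagna as gg
from ggmagna import fit_engine as fe
from ggmagna import multigroup as mg
from ggmagna.gaussian_family import CorrelationData, SingularModelError
from ggmagna.ggm_model import corr_to_ggm
from ggmagna.matcalc import vechs, vechs_indices


def numeric_gradient(f, x, eps=1e-6):
    g = np.zeros_like(x)
    for j in range(x.size):
        e = np.zeros_like(x)
        e[j] = eps
        g[j] = (f(x + e) - f(x - e)) / (2 * eps)
    return g


def corr2(rho, n=500):
    return CorrelationData(R=np.array([[1.0, rho], [rho, 1.0]]), n=n)


class TestFullJacobian:
    def test_saturated_model_reduces_to_distribution_jacobian(self, corr_data_4):
        # with identity model and manual Jacobians the chain collapses
        from ggmagna.gaussian_family import std_gauss_jacobian

        spec = fe.saturated_correlation_spec(corr_data_4)
        psi = spec.table.start_psi() * 0.9
        P = np.eye(4)
        ri, ci = vechs_indices(4)
        P[ri, ci] = psi
        P[ci, ri] = psi
        assert np.allclose(
            fe.full_jacobian(spec, psi), std_gauss_jacobian(corr_data_4.R, P)
        )

    def test_equality_constraint_sums_gradient_entries(self, corr_data_4):
        # one column with two ones adds the two unconstrained entries
        q = 6
        free = mg.multidataset_spec([corr_data_4], "ggm", "unique").spec
        labels = free.table.labels
        psi_index = np.array([0, 0, 1, 2, 3, 4])  # edges 0 and 1 constrained equal
        table = fe.ParameterTable(labels, psi_index)
        import dataclasses

        tied = dataclasses.replace(free, table=table)
        psi_tied = np.full(5, 0.05)
        psi_free = table.theta(psi_tied)
        g_free = fe.full_jacobian(free, psi_free)
        g_tied = fe.full_jacobian(tied, psi_tied)
        assert g_tied[0] == pytest.approx(g_free[0] + g_free[1], rel=1e-12)
        assert np.allclose(g_tied[1:], g_free[2:])

    def test_matches_finite_differences_for_constrained_ggm(self, corr_data_4):
        spec = mg.multidataset_spec([corr_data_4], "ggm", "unique").spec
        table = spec.table.drop_psi([1, 4])
        import dataclasses

        spec = dataclasses.replace(spec, table=table)
        psi = spec.table.start_psi() * 0.8
        analytic = fe.full_jacobian(spec, psi)
        numeric = numeric_gradient(lambda x: fe.full_fit(spec, x), psi)
        assert np.allclose(analytic, numeric, rtol=1e-6, atol=1e-8)


class TestFitML:
    def test_saturated_correlation_recovers_R(self, corr_data_4):
        fit = fe.fit_ml(fe.saturated_correlation_spec(corr_data_4), gtol=1e-9)
        assert fit.converged
        assert np.allclose(fit.psi_hat, corr_data_4.r, atol=1e-8)

    def test_saturated_ggm_equals_transformed_R(self, corr_data_4):
        fit = mg.multidataset_ggm([corr_data_4], "unique")
        assert fit.converged
        assert np.allclose(
            mg.omega_from_fit(fit), corr_to_ggm(corr_data_4.R), atol=1e-7
        )

    def test_constrained_recovery_within_three_se(self, rng):
        # truth has one edge fixed at zero; near-asymptotic data
        p = 4
        Om_true = np.zeros((p, p))
        Om_true[1, 0] = Om_true[0, 1] = 0.4
        Om_true[2, 1] = Om_true[1, 2] = -0.3
        Om_true[3, 2] = Om_true[2, 3] = 0.25
        P_true = gg.ggm_to_corr(Om_true)
        data = CorrelationData(R=P_true, n=1_000_000)
        status = {e: "pooled" for e in range(6)}
        status[1] = "zero"  # the (2,0) pair, truly zero
        table = mg.build_multidataset_table(p, 1, status)
        spec = mg.multidataset_spec([data], "ggm", table).spec
        fit = fe.fit_ml(spec, gtol=1e-7)
        est = spec.theta(fit.psi_hat)
        truth = vechs(Om_true)
        se = np.zeros(6)
        free = spec.table.psi_index >= 0
        se[free] = fit.se[spec.table.psi_index[free]]
        for e in range(6):
            if e == 1:
                assert est[e] == 0.0
            else:
                assert abs(est[e] - truth[e]) < 3 * se[e]

    def test_empty_parameter_vector_is_valid(self, corr_data_4):
        spec = mg.multidataset_spec([corr_data_4], "ggm", "unique").spec
        import dataclasses

        empty = dataclasses.replace(spec, table=spec.table.drop_psi(range(6)))
        fit = fe.fit_ml(empty)
        assert fit.converged and fit.n_free == 0
        assert fit.F_hat >= spec.saturated_fit


class TestInference:
    def test_bivariate_closed_form_se(self):
        rho, n = 0.5, 200
        fit = fe.fit_ml(fe.saturated_correlation_spec(corr2(rho, n)), gtol=1e-10)
        expected = np.sqrt((1 - rho**2) ** 2 / ((1 + rho**2) * n))
        assert fit.se[0] == pytest.approx(expected, rel=1e-6)

    def test_zero_estimate_gives_p_one(self):
        fit = fe.fit_ml(fe.saturated_correlation_spec(corr2(0.0)), gtol=1e-10)
        assert fit.psi_hat[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.p_values[0] == pytest.approx(1.0)

    def test_duplicate_parameters_raise_singularity_error(self):
        # two free parameters entering only through their sum are not identified
        labels = [("x", 0, 0, 0), ("x", 1, 0, 0)]
        table = fe.ParameterTable(labels, np.array([0, 1]))
        z = np.array([1.0])
        spec = fe.ModelSpec(
            table=table,
            n=100,
            fit_fun=lambda th: float((z[0] - th.sum()) ** 2),
            dist_jacobian=lambda th: np.array([-2 * (z[0] - th.sum())]),
            dist_hessian=lambda th: np.array([[2.0]]),
            model_jacobian=lambda th: np.ones((1, 2)),
            df_phi=1,
        )
        info = fe.fisher_information(spec, np.array([0.5, 0.5]))
        with pytest.raises(SingularModelError, match="psi_"):
            fe.param_covariance(spec, info)

    def test_covariance_matches_inverse_numeric_hessian(self, corr_data_4):
        spec = mg.multidataset_spec([corr_data_4], "ggm", "unique").spec
        fit = fe.fit_ml(spec, gtol=1e-9)
        H_num = np.zeros((6, 6))
        eps = 1e-5
        for j in range(6):
            e = np.zeros(6)
            e[j] = eps
            gp = fe.full_jacobian(spec, fit.psi_hat + e)
            gm_ = fe.full_jacobian(spec, fit.psi_hat - e)
            H_num[:, j] = (gp - gm_) / (2 * eps)
        # V = (1/n) * (0.5 * H)^{-1} with H the numeric Hessian of F
        V_num = np.linalg.inv((H_num + H_num.T) / 4) / spec.n
        assert np.allclose(fit.covariance, V_num, rtol=1e-3)

    def test_estimates_invariant_to_variable_reordering(self, pd_corr_4):
        perm = [2, 0, 3, 1]
        d1 = CorrelationData(R=pd_corr_4, n=400)
        d2 = CorrelationData(R=pd_corr_4[np.ix_(perm, perm)], n=400)
        f1 = mg.multidataset_ggm([d1], "unique")
        f2 = mg.multidataset_ggm([d2], "unique")
        O1 = mg.omega_from_fit(f1)[np.ix_(perm, perm)]
        O2 = mg.omega_from_fit(f2)
        assert np.allclose(O1, O2, atol=1e-7)


class TestPruning:
    def test_strong_edges_survive(self, rng):
        Om = np.zeros((3, 3))
        Om[1, 0] = Om[0, 1] = 0.5
        Om[2, 1] = Om[1, 2] = 0.4
        data = CorrelationData(R=gg.ggm_to_corr(Om), n=2000)
        spec = mg.multidataset_spec([data], "ggm", "unique").spec
        fit = fe.prune(spec, alpha=0.05)
        est = spec.theta(fit.psi_hat) if fit.n_free == 3 else fit.spec.theta(fit.psi_hat)
        assert est[0] != 0 and est[2] != 0

    def test_independent_data_prunes_to_empty_model(self):
        data = CorrelationData(R=np.eye(3), n=500)
        spec = mg.multidataset_spec([data], "ggm", "unique").spec
        fit = fe.prune(spec, alpha=0.05)
        assert fit.n_free == 0

    def test_single_true_edge_power(self, rng):
        # omega = 0.3 at n = 1000 should essentially always be retained
        Om = np.zeros((3, 3))
        Om[1, 0] = Om[0, 1] = 0.3
        P = gg.ggm_to_corr(Om)
        kept = 0
        reps = 40
        for i in range(reps):
            ds = gg.simulate_studies(
                gg.TrueNetwork(Om, Om != 0, 3), np.zeros((3, 3)), 1,
                (1000, 1000), seed=rng,
            )
            spec = mg.multidataset_spec(ds, "ggm", "unique").spec
            fit = fe.prune(spec, alpha=0.05)
            est = fit.spec.theta(fit.psi_hat)
            if est[0] != 0:
                kept += 1
        assert kept >= 38  # power far above 0.95


class TestIndicesAndTests:
    def test_saturated_model_chi2_zero(self, corr_data_4):
        fit = fe.fit_ml(fe.saturated_correlation_spec(corr_data_4), gtol=1e-9)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fit.df == 0
        assert fit.rmsea == 0.0

    def test_bic_prefers_true_sparse_model(self, rng):
        Om = np.zeros((4, 4))
        Om[1, 0] = Om[0, 1] = 0.35
        Om[3, 2] = Om[2, 3] = 0.3
        net = gg.TrueNetwork(Om, Om != 0, 4)
        ds = gg.simulate_studies(net, np.zeros((6, 6)), 1, (2000, 2000), seed=rng)
        sat = mg.multidataset_ggm(ds, "unique")
        status = {e: "zero" for e in range(6)}
        status[0] = "pooled"  # pair (1,0)
        status[5] = "pooled"  # pair (3,2)
        sparse = mg.multidataset_ggm(ds, mg.build_multidataset_table(4, 1, status))
        assert sparse.bic < sat.bic

    def test_true_model_rmsea_near_zero(self, rng):
        Om = np.zeros((4, 4))
        Om[1, 0] = Om[0, 1] = 0.35
        Om[3, 2] = Om[2, 3] = 0.3
        net = gg.TrueNetwork(Om, Om != 0, 4)
        ds = gg.simulate_studies(net, np.zeros((6, 6)), 1, (5000, 5000), seed=rng)
        status = {e: ("pooled" if e in (0, 5) else "zero") for e in range(6)}
        fit = mg.multidataset_ggm(ds, mg.build_multidataset_table(4, 1, status))
        assert fit.rmsea < 0.05

    def test_lrt_between_nested_models(self, corr_data_4):
        mspec = mg.multidataset_spec([corr_data_4], "ggm", "unique")
        free = fe.fit_ml(mspec.spec)
        import dataclasses

        constrained_spec = dataclasses.replace(
            mspec.spec, table=mspec.spec.table.drop_psi([0])
        )
        constrained = fe.fit_ml(constrained_spec)
        out = fe.lrt(constrained, free)
        assert out["statistic"] >= 0 and out["df"] == 1
        with pytest.raises(ValueError):
            fe.lrt(free, constrained)

    def test_mi_requires_constrained_parameter(self, corr_data_4):
        spec = mg.multidataset_spec([corr_data_4], "ggm", "unique").spec
        fit = fe.fit_ml(spec)
        assert fe.modification_indices(spec, fit).empty  # all-free: no candidates
        with pytest.raises(ValueError, match="freely estimated"):
            fe.modification_indices(spec, fit, candidates=[0])

    def test_mi_approximates_chi2_drop(self, rng):
        # moderate misfit: constrain a truly nonzero edge to zero
        Om = np.zeros((4, 4))
        Om[1, 0] = Om[0, 1] = 0.35
        Om[2, 1] = Om[1, 2] = 0.3
        Om[3, 2] = Om[2, 3] = 0.15
        net = gg.TrueNetwork(Om, Om != 0, 4)
        ds = gg.simulate_studies(net, np.zeros((6, 6)), 1, (3000, 3000), seed=rng)
        status = {e: "pooled" for e in range(6)}
        status[5] = "zero"  # constrain pair (3,2), truly 0.15
        mspec = mg.multidataset_spec(ds, "ggm", mg.build_multidataset_table(4, 1, status))
        constrained = fe.fit_ml(mspec.spec, gtol=1e-8)
        mi = fe.modification_indices(mspec.spec, constrained, candidates=[5])
        freed = mg.multidataset_ggm(ds, "pooled")
        drop = mspec.spec.n * (constrained.F_hat - freed.F_hat)
        assert mi["mi"].iloc[0] == pytest.approx(drop, rel=0.2)

    def test_null_mi_is_chi_square_distributed(self, rng):
        # constraint true in the population: MI should look like chi2(1)
        Om = np.zeros((3, 3))
        Om[1, 0] = Om[0, 1] = 0.4
        net = gg.TrueNetwork(Om, Om != 0, 3)
        mis = []
        for _ in range(60):
            ds = gg.simulate_studies(net, np.zeros((3, 3)), 1, (800, 800), seed=rng)
            status = {0: "pooled", 1: "zero", 2: "zero"}
            mspec = mg.multidataset_spec(
                ds, "ggm", mg.build_multidataset_table(3, 1, status)
            )
            fit = fe.fit_ml(mspec.spec, gtol=1e-7)
            mi = fe.modification_indices(mspec.spec, fit, candidates=[1])
            mis.append(float(mi["mi"].iloc[0]))
        mis = np.array(mis)
        # chi2(1): mean 1, ~5% exceed 3.84
        assert 0.5 < mis.mean() < 1.8
        assert np.mean(mis > 3.84) < 0.2
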
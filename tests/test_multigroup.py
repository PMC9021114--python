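import numpy as np
import pytest
import scipy.optimize

import ggmagna as gg
from ggmagna import fit_engine as fe
from ggmagna import multigroup as mg
from ggmagna.gaussian_family import CorrelationData, std_gauss_fit
from ggmagna.matcalc import vechs


def corr2(rho, n):
    return CorrelationData(R=np.array([[1.0, rho], [rho, 1.0]]), n=n)


class TestCombined:
    def test_single_dataset_reduces_to_single_group_quantities(self, corr_data_4):
        mspec = mg.multidataset_spec([corr_data_4], "corr", "pooled")
        single = fe.saturated_correlation_spec(corr_data_4)
        psi = single.table.start_psi() * 0.9
        assert mg.combined_fit(mspec, psi) == pytest.approx(
            fe.full_fit(single, psi), rel=1e-12
        )
        assert np.allclose(
            mg.combined_gradient(mspec, psi), fe.full_jacobian(single, psi)
        )

    def test_gradient_matches_finite_differences(self, homogeneous_datasets):
        mspec = mg.multidataset_spec(homogeneous_datasets, "ggm", "pooled")
        psi = mspec.spec.table.start_psi() * 0.7
        g = mg.combined_gradient(mspec, psi)
        gn = np.zeros_like(psi)
        eps = 1e-6
        for j in range(psi.size):
            e = np.zeros_like(psi)
            e[j] = eps
            gn[j] = (
                mg.combined_fit(mspec, psi + e) - mg.combined_fit(mspec, psi - e)
            ) / (2 * eps)
        assert np.allclose(g, gn, rtol=1e-6, atol=1e-8)

    def test_split_dataset_equals_unsplit(self, pd_corr_4):
        whole = CorrelationData(R=pd_corr_4, n=800)
        halves = [CorrelationData(R=pd_corr_4, n=400) for _ in range(2)]
        f_whole = mg.multidataset_ggm([whole], "unique")
        f_split = mg.multidataset_ggm(halves, "pooled")
        assert np.allclose(
            mg.omega_from_fit(f_whole), mg.omega_from_fit(f_split), atol=1e-6
        )
        assert np.allclose(f_whole.se, f_split.se, atol=1e-6)

    def test_label_mismatch_rejected(self, pd_corr_4):
        a = CorrelationData(R=pd_corr_4, n=300, labels=["a", "b", "c", "d"])
        b = CorrelationData(R=pd_corr_4, n=300, labels=["a", "b", "c", "e"])
        with pytest.raises(ValueError, match="same variables"):
            mg.multidataset_spec([a, b])


class TestPooling:
    def test_identical_matrices_pool_to_themselves(self, pd_corr_4):
        ds = [CorrelationData(R=pd_corr_4, n=n) for n in (200, 300)]
        pooled = mg.pool_correlations(ds)
        assert np.allclose(pooled.rho_hat, vechs(pd_corr_4), atol=1e-8)

    def test_matches_brute_force_minimization(self):
        # k=2, p=2: one-dimensional problem solved by direct search
        ds = [corr2(0.4, 100), corr2(0.6, 300)]
        pooled = mg.pool_correlations(ds)

        def objective(rho):
            P = np.array([[1.0, rho], [rho, 1.0]])
            return sum(
                (d.n / 400) * std_gauss_fit(d.R, P) for d in ds
            )

        brute = scipy.optimize.minimize_scalar(
            objective, bounds=(-0.99, 0.99), method="bounded",
            options={"xatol": 1e-12},
        )
        assert pooled.rho_hat[0] == pytest.approx(brute.x, abs=1e-8)

    def test_fisher_information_matches_numeric_hessian(self):
        ds = [corr2(0.4, 100), corr2(0.6, 300)]
        pooled = mg.pool_correlations(ds)

        def objective(rho):
            P = np.array([[1.0, rho], [rho, 1.0]])
            return sum((d.n / 400) * std_gauss_fit(d.R, P) for d in ds)

        eps = 1e-5
        x = pooled.rho_hat[0]
        h_num = (objective(x + eps) - 2 * objective(x) + objective(x - eps)) / eps**2
        assert pooled.information[0, 0] == pytest.approx(0.5 * h_num, rel=1e-4)


class TestTwoStage:
    def test_saturated_agrees_with_multidataset(self, homogeneous_datasets):
        f_ts = mg.two_stage_fixed(homogeneous_datasets)
        f_md = mg.multidataset_ggm(homogeneous_datasets, "pooled")
        assert np.allclose(
            mg.omega_from_fit(f_ts), mg.omega_from_fit(f_md), atol=1e-6
        )
        assert np.allclose(f_ts.se, f_md.se, atol=1e-6)

    def test_uls_saturated_gives_same_point_estimate(self, homogeneous_datasets):
        f_w = mg.two_stage_fixed(homogeneous_datasets, weights="fisher")
        f_u = mg.two_stage_fixed(homogeneous_datasets, weights="uls")
        assert np.allclose(
            mg.omega_from_fit(f_w), mg.omega_from_fit(f_u), atol=1e-6
        )

    def test_pattern_restricts_edges(self, homogeneous_datasets):
        pattern = np.ones(10, dtype=bool)
        pattern[3] = False
        fit = mg.two_stage_fixed(homogeneous_datasets, pattern=pattern)
        theta = fit.spec.theta(fit.psi_hat)
        assert theta[3] == 0.0
        assert fit.n_free == 9


class TestMultidatasetConstraints:
    def test_fully_pooled_on_identical_data(self, pd_corr_4):
        ds = [CorrelationData(R=pd_corr_4, n=250) for _ in range(3)]
        fit = mg.multidataset_ggm(ds, "pooled")
        assert np.allclose(
            mg.omega_from_fit(fit), gg.corr_to_ggm(pd_corr_4), atol=1e-7
        )

    def test_unique_spec_equals_separate_fits(self, homogeneous_datasets):
        joint = mg.multidataset_ggm(homogeneous_datasets, "unique")
        for g, d in enumerate(homogeneous_datasets):
            sep = mg.multidataset_ggm([d], "unique")
            assert np.allclose(
                mg.omega_from_fit(joint, group=g),
                mg.omega_from_fit(sep),
                atol=1e-6,
            )

    def test_partial_equality_psi_mapping(self):
        # 2 datasets, 3 variables, first edge unique per dataset, rest pooled:
        # psi_1 = omega_21,1 ; psi_2 = omega_31,1 = omega_31,2 ;
        # psi_3 = omega_32,1 = omega_32,2 ; psi_4 = omega_21,2
        table = mg.build_multidataset_table(
            3, 2, {0: "unique", 1: "pooled", 2: "pooled"}
        )
        M = table.M.toarray()
        assert M.shape == (6, 4)
        # group-major rows: (e0,g0) (e1,g0) (e2,g0) (e0,g1) (e1,g1) (e2,g1)
        assert M[0].tolist() == [1, 0, 0, 0]
        assert M[1].tolist() == [0, 0, 1, 0]
        assert M[2].tolist() == [0, 0, 0, 1]
        assert M[3].tolist() == [0, 1, 0, 0]
        assert M[4].tolist() == [0, 0, 1, 0]
        assert M[5].tolist() == [0, 0, 0, 1]

    def test_all_zero_edges_treated_as_fixed(self, pd_corr_4):
        ds = [CorrelationData(R=pd_corr_4, n=250)]
        table = mg.build_multidataset_table(4, 1, "zero")
        fit = mg.multidataset_ggm(ds, table)
        assert fit.n_free == 0
        assert np.allclose(mg.omega_from_fit(fit), 0.0)


class TestPartialPrune:
    def test_requires_multiple_datasets(self, corr_data_4):
        with pytest.raises(ValueError, match="at least two"):
            mg.partial_prune([corr_data_4])

    def test_homogeneous_data_frees_nothing_or_little(self, rng):
        net = gg.generate_true_network(6, seed=rng)
        ds = gg.simulate_studies(net, np.zeros((15, 15)), 4, (400, 600), seed=rng)
        result = mg.partial_prune(ds, alpha=0.05)
        freed = [e for e, s in result.edge_status.items() if s == "unique"]
        assert len(freed) <= 1  # conservative under homogeneity

    def test_detects_single_differing_edge(self, rng):
        # two groups differ in exactly one edge by 0.3
        p = 5
        Om_a = np.zeros((p, p))
        for i, j, w in [(1, 0, 0.3), (2, 1, 0.3), (3, 2, 0.3), (4, 3, 0.3)]:
            Om_a[i, j] = Om_a[j, i] = w
        Om_b = Om_a.copy()
        Om_b[1, 0] = Om_b[0, 1] = 0.0  # delta of 0.3 on edge (1,0)
        net_a = gg.TrueNetwork(Om_a, Om_a != 0, p)
        net_b = gg.TrueNetwork(Om_b, Om_b != 0, p)
        ds_a = gg.simulate_studies(net_a, np.zeros((10, 10)), 1, (2000, 2000), seed=rng)
        ds_b = gg.simulate_studies(net_b, np.zeros((10, 10)), 1, (2000, 2000), seed=rng)
        result = mg.partial_prune(ds_a + ds_b, alpha=0.05)
        freed = [e for e, s in result.edge_status.items() if s == "unique"]
        assert 0 in freed  # edge (1,0) is vechs position 0
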
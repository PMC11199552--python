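"""Generator behaviour: bookkeeping, determinism, distributional checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smile.simulate import (
    SimulationScenario,
    add_measurement_noise,
    inject_relationship_errors,
    lattice_graph,
    rr_to_liability_shift,
    simulate_cohort,
    simulate_exposure_instruments,
    simulate_phenotype,
    simulate_spatial_effects,
)
from smile.spatial import SpatialSpec
from smile.vc_model import VarianceComponents
from smile.io import write_pedigree


class TestCohort:
    def test_bookkeeping_100_quads_on_5x5(self):
        sc = SimulationScenario(n_families=100, lattice=(5, 5))
        cohort, graph = simulate_cohort(sc, np.random.default_rng(0))
        assert cohort.n_individuals == 400
        assert cohort.n_families == 100
        assert graph.L == 25

    def test_same_seed_gives_identical_cohort(self, tmp_path):
        sc = SimulationScenario(n_families=60, lattice=(4, 4))
        c1, _ = simulate_cohort(sc, np.random.default_rng(123))
        c2, _ = simulate_cohort(sc, np.random.default_rng(123))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_pedigree(c1, p1)
        write_pedigree(c2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_families_per_location_median_within_claims_range(self):
        """Default allocation reproduces the heavy-tailed families-per-
        location profile: median within the (5, 50) interquartile range
        reported for the real claims cohort."""
        sc = SimulationScenario()  # defaults: 2000 families, 10x10 lattice
        cohort, graph = simulate_cohort(sc, np.random.default_rng(42))
        counts = np.bincount(cohort.family_location_index(graph.locations),
                             minlength=graph.L)
        med = np.median(counts[counts > 0])
        assert 5 <= med <= 50


class TestSpatialDraws:
    def test_rho_zero_empirical_covariance_is_sigma_M(self, two_location_graph):
        draws = simulate_spatial_effects(
            two_location_graph, SpatialSpec("CAR", 2.0, 0.0), 10_000,
            np.random.default_rng(11))
        emp = np.cov(draws.T)
        se = 3.0 * 2.0 / np.sqrt(10_000)
        np.testing.assert_allclose(emp, 2.0 * np.diag(two_location_graph.M),
                                   atol=se)

    def test_car_half_rho_matches_covariance_oracle(self, two_location_graph):
        draws = simulate_spatial_effects(
            two_location_graph, SpatialSpec("CAR", 1.0, 0.5), 10_000,
            np.random.default_rng(2))
        emp = np.cov(draws.T)
        np.testing.assert_allclose(
            emp, [[4 / 3, 2 / 3], [2 / 3, 4 / 3]], atol=3 * 1.4 / np.sqrt(10_000))

    def test_neighbors_more_correlated_than_non_neighbors(self):
        g = lattice_graph(5, 5)
        draws = simulate_spatial_effects(
            g, SpatialSpec("CAR", 1.0, 0.9), 4000, np.random.default_rng(3))
        C = np.corrcoef(draws.T)
        W = g.W.toarray().astype(bool)
        off = ~np.eye(g.L, dtype=bool)
        assert C[W].mean() > C[off & ~W].mean()


class TestPhenotype:
    def test_pure_residual_siblings_uncorrelated(self):
        vc = VarianceComponents(0, 0, 0, 0, 1.0, 0, scale="liability")
        sc = SimulationScenario(n_families=4000, lattice=(6, 6), prevalence=0.5,
                                vc=vc)
        cohort, graph = simulate_cohort(sc, np.random.default_rng(9))
        Y, _ = simulate_phenotype(cohort, graph, sc, np.random.default_rng(10))
        sib1 = Y[cohort.roles == "child"][0::2]
        sib2 = Y[cohort.roles == "child"][1::2]
        r = np.corrcoef(sib1, sib2)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(sib1))

    def test_parent_child_covariance_matches_tetrachoric_closed_form(self):
        """sigma_g2 = 0.5 only: liability parent-child correlation is 0.25;
        the observed 0/1 covariance must match the bivariate-normal orthant
        probability minus K^2."""
        K = 0.3
        vc = VarianceComponents(0.5, 0, 0, 0, 0.5, 0, scale="liability")
        sc = SimulationScenario(n_families=12_000, lattice=(5, 5), prevalence=K,
                                vc=vc)
        cohort, graph = simulate_cohort(sc, np.random.default_rng(20))
        Y, _ = simulate_phenotype(cohort, graph, sc, np.random.default_rng(21))
        fathers = Y[cohort.roles == "father"]
        fam_f = cohort.family_index[cohort.roles == "father"]
        first_child = Y[cohort.roles == "child"][0::2]
        fam_c = cohort.family_index[cohort.roles == "child"][0::2]
        assert (fam_f == fam_c).all()
        emp_cov = np.cov(fathers, first_child)[0, 1]
        t = stats.norm.ppf(1 - K)
        p11 = stats.multivariate_normal.cdf(
            [-t, -t], mean=[0, 0], cov=[[1, 0.25], [0.25, 1]])
        expected = p11 - K**2
        se = 3.0 * np.sqrt(K * (1 - K)) ** 2 / np.sqrt(len(fathers))
        assert abs(emp_cov - expected) < se

    def test_realized_prevalence_within_binomial_bound(self):
        sc = SimulationScenario(n_families=25_000, lattice=(10, 10),
                                prevalence=0.05)
        cohort, graph = simulate_cohort(sc, np.random.default_rng(30))
        Y, _ = simulate_phenotype(cohort, graph, sc, np.random.default_rng(31))
        assert cohort.n_individuals == 100_000
        assert 0.045 < Y.mean() < 0.055

    def test_gaussian_mode_returns_liability(self):
        sc = SimulationScenario(n_families=200, lattice=(4, 4), binary=False)
        cohort, graph = simulate_cohort(sc, np.random.default_rng(1))
        Y, truth = simulate_phenotype(cohort, graph, sc, np.random.default_rng(2))
        np.testing.assert_array_equal(Y, truth.liabilities)


class TestRelationshipErrors:
    def test_rate_zero_is_identity(self):
        sc = SimulationScenario(n_families=50, lattice=(3, 3))
        cohort, _ = simulate_cohort(sc, np.random.default_rng(0))
        c2, overrides, table = inject_relationship_errors(
            cohort, 0.0, np.random.default_rng(1))
        assert c2 is cohort and not overrides and table.empty

    def test_rate_bounds_enforced(self):
        sc = SimulationScenario(n_families=5, lattice=(2, 2))
        cohort, _ = simulate_cohort(sc, np.random.default_rng(0))
        with pytest.raises(ValueError):
            inject_relationship_errors(cohort, 0.7, np.random.default_rng(1))

    def test_overrides_are_valid_relationship_matrices(self):
        sc = SimulationScenario(n_families=200, lattice=(4, 4))
        cohort, _ = simulate_cohort(sc, np.random.default_rng(5))
        _, overrides, table = inject_relationship_errors(
            cohort, 0.3, np.random.default_rng(6))
        assert len(table) > 0
        for fi, G in overrides.items():
            assert np.allclose(G, G.T)
            np.testing.assert_array_equal(np.diag(G), 1.0)
            assert np.linalg.eigvalsh(G).min() > -1e-10

    def test_genetic_attenuation_monotone_in_error_rate(self):
        """Mislabeling children dilutes the apparent genetic signal: the
        fitted sigma_g2 decreases as the error rate grows."""
        from smile.vc_model import fit_smile
        vc = VarianceComponents(0.5, 0.0, 0.0, 0.0, 0.5, 0.0, scale="liability")
        sc = SimulationScenario(n_families=1500, lattice=(5, 5), binary=False,
                                vc=vc)
        means = []
        for rate in [0.0, 0.5]:
            rng = np.random.default_rng(40)
            ests = []
            for _ in range(4):
                cohort, graph = simulate_cohort(sc, rng)
                _, overrides, _ = inject_relationship_errors(cohort, rate, rng)
                Y, _ = simulate_phenotype(cohort, graph, sc, rng,
                                          kinship_overrides=overrides)
                fit = fit_smile(cohort, Y, None, "G", n_starts=1,
                                compute_se=False)
                ests.append(fit.vc.sigma_g2)
            means.append(np.mean(ests))
        assert means[1] < means[0]

    def test_moderate_errors_leave_estimates_near_truth(self):
        """At a 10% mislabeling rate the variance-component estimates still
        bracket the generating values (small bias)."""
        from smile.vc_model import fit_smile
        sc = SimulationScenario(n_families=2000, lattice=(8, 8), binary=False)
        rng = np.random.default_rng(50)
        h2 = []
        for _ in range(6):
            cohort, graph = simulate_cohort(sc, rng)
            _, overrides, _ = inject_relationship_errors(cohort, 0.1, rng)
            Y, _ = simulate_phenotype(cohort, graph, sc, rng,
                                      kinship_overrides=overrides)
            fit = fit_smile(cohort, Y, None, "GPC+S", graph=graph, n_starts=1,
                            compute_se=False)
            h2.append(fit.vc.sigma_g2)
        h2 = np.array(h2)
        ci = 2.5 * h2.std(ddof=1) / np.sqrt(len(h2))
        assert abs(h2.mean() - 0.30) < ci + 0.03


@pytest.fixture(scope="module")
def exposure_setup():
    sc = SimulationScenario(n_families=10, lattice=(12, 12))
    graph = lattice_graph(12, 12)
    rng = np.random.default_rng(7)
    exposures, instruments, conf = simulate_exposure_instruments(graph, sc, rng)
    return sc, graph, exposures, instruments, conf


class TestExposures:
    def test_schema_and_ranges(self, exposure_setup):
        _, graph, exposures, instruments, conf = exposure_setup
        assert list(exposures.columns) == ["pm25", "no2", "psum"]
        assert (instruments["wind_speed"] >= 0).all()
        assert ((instruments["wind_dir"] >= 0)
                & (instruments["wind_dir"] < 360)).all()
        assert len(conf) == graph.L

    def test_instrument_relevance_above_threshold(self):
        """cor(best instrument prediction, exposure) > 0.3 at defaults."""
        from smile.causal import first_stage_predict
        sc = SimulationScenario(n_families=10, lattice=(15, 15))
        rng = np.random.default_rng(8)
        cors = []
        for _ in range(10):
            graph = lattice_graph(15, 15)
            exposures, instruments, _ = simulate_exposure_instruments(
                graph, sc, rng)
            res = first_stage_predict(exposures["pm25"], instruments)
            cors.append(np.corrcoef(res.fitted, exposures["pm25"])[0, 1])
        assert np.mean(cors) > 0.3

    def test_zero_confounder_weight_makes_naive_equal_iv(self):
        """With no confounder loading in the exposure, naive and IV slopes
        estimate the same quantity."""
        import dataclasses
        from smile.causal import first_stage_predict, fit_smile2
        vc = VarianceComponents(0.2, 0.05, 0.05, 0.0, 0.7, 0.0,
                                scale="liability")
        sc = SimulationScenario(
            n_families=600, lattice=(14, 14), allocation="even", binary=False,
            rr=1.1, confounder_effect=0.2, confounder_weight=0.0, vc=vc)
        rng = np.random.default_rng(9)
        diffs = []
        for _ in range(10):
            cohort, graph = simulate_cohort(sc, rng)
            exposures, instruments, conf = simulate_exposure_instruments(
                graph, sc, rng)
            x = exposures["pm25"]
            ez = ((x - x.mean()) / x.std()).to_numpy()
            Y, _ = simulate_phenotype(cohort, graph, sc, rng, exposure_z=ez,
                                      confounder=conf)
            fs = first_stage_predict(x, instruments)
            iv = fit_smile2(cohort, Y, fs.fitted, exposure_sd=float(x.std()))
            naive = fit_smile2(cohort, Y, x, exposure_sd=float(x.std()))
            diffs.append(iv.beta - naive.beta)
        diffs = np.array(diffs)
        assert abs(diffs.mean()) < 3.0 * diffs.std(ddof=1) / np.sqrt(len(diffs))

    def test_measurement_noise_identity_at_zero(self, exposure_setup):
        _, _, exposures, instruments, _ = exposure_setup
        e2, i2 = add_measurement_noise(exposures, instruments, 0.0,
                                       np.random.default_rng(0))
        pd.testing.assert_frame_equal(e2, exposures)
        pd.testing.assert_frame_equal(i2, instruments)

    def test_measurement_noise_wraps_direction(self, exposure_setup):
        _, _, exposures, instruments, _ = exposure_setup
        e2, i2 = add_measurement_noise(exposures, instruments, 2.0,
                                       np.random.default_rng(1))
        assert ((i2["wind_dir"] >= 0) & (i2["wind_dir"] < 360)).all()
        assert (i2["wind_speed"] >= 0).all()
        assert not np.allclose(e2["pm25"], exposures["pm25"])


class TestLiabilityShift:
    def test_closed_form(self):
        K, rr = 0.05, 1.2
        shift = rr_to_liability_shift(rr, K)
        t = stats.norm.ppf(1 - K)
        achieved_rr = stats.norm.sf(t - shift) / K
        assert achieved_rr == pytest.approx(rr, rel=1e-10)

    def test_null_is_zero(self):
        assert rr_to_liability_shift(1.0, 0.1) == pytest.approx(0.0)

    def test_invalid_combination_rejected(self):
        with pytest.raises(ValueError):
            rr_to_liability_shift(25.0, 0.05)


class TestScenarioGrid:
    def test_grid_spans_null_and_alternative(self):
        from smile.simulate import scenario_grid
        base = SimulationScenario(n_families=100, lattice=(4, 4))
        grid = scenario_grid(base, prevalence_values=(0.01, 0.05),
                             pollutants=("pm25", "no2"))
        rrs = {s.rr for s in grid}
        assert rrs == {1.0, 1.01, 1.05, 1.1, 1.2}
        assert len(grid) == 5 * 2 * 2
        assert any(s.rr == 1.0 for s in grid) and any(s.rr > 1.0 for s in grid)


class TestMeasurementNoiseRobustness:
    def test_beta_unbiased_and_power_mildly_reduced_under_noise(self):
        """Noisy pollution/wind measurements leave the two-stage estimate
        unbiased (within 2 MC SE on Gaussian liabilities) and cost only a
        bounded share of power on binary outcomes."""
        from smile.causal import first_stage_predict, fit_smile2
        vc = VarianceComponents(0.2, 0.05, 0.05, 0.01, 0.69, 0.3,
                                scale="liability")
        base = SimulationScenario(
            n_families=600, lattice=(15, 15), allocation="even",
            prevalence=0.05, rr=1.25, confounder_effect=0.05, vc=vc)
        from smile.simulate import rr_to_liability_shift
        beta_true = rr_to_liability_shift(base.rr, base.prevalence)

        # unbiasedness on the liability scale with noisy measurements
        rng = np.random.default_rng(70)
        sc_g = SimulationScenario(**{**base.__dict__, "binary": False})
        betas = []
        for _ in range(20):
            cohort, graph = simulate_cohort(sc_g, rng)
            exposures, instruments, conf = simulate_exposure_instruments(
                graph, sc_g, rng)
            x = exposures["pm25"]
            ez = ((x - x.mean()) / x.std()).to_numpy()
            Y, _ = simulate_phenotype(cohort, graph, sc_g, rng, exposure_z=ez,
                                      confounder=conf)
            nexp, ninst = add_measurement_noise(exposures, instruments, 0.3, rng)
            fs = first_stage_predict(nexp["pm25"], ninst)
            est = fit_smile2(cohort, Y, fs.fitted,
                             exposure_sd=float(x.std()), first_stage=fs)
            betas.append(est.beta)
        betas = np.array(betas)
        mc_se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - beta_true) < 2.0 * mc_se

        # power under noise stays within a bounded factor of clean power
        rng = np.random.default_rng(71)
        rej = {"clean": 0, "noisy": 0}
        n_reps = 60
        for _ in range(n_reps):
            cohort, graph = simulate_cohort(base, rng)
            exposures, instruments, conf = simulate_exposure_instruments(
                graph, base, rng)
            x = exposures["pm25"]
            ez = ((x - x.mean()) / x.std()).to_numpy()
            Y, _ = simulate_phenotype(cohort, graph, base, rng, exposure_z=ez,
                                      confounder=conf)
            if not 0 < Y.mean() < 1:
                continue
            for label, noise in [("clean", 0.0), ("noisy", 0.3)]:
                nexp, ninst = add_measurement_noise(
                    exposures, instruments, noise, rng)
                fs = first_stage_predict(nexp["pm25"], ninst)
                est = fit_smile2(cohort, Y, fs.fitted,
                                 exposure_sd=float(x.std()), first_stage=fs)
                rej[label] += est.p_value < 0.05
        assert rej["noisy"] >= 0.8 * rej["clean"] - 3  # binomial slack
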
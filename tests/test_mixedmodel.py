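import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sibstep import (
    ModelError,
    ModelSpec,
    apply_phenotype_filters,
    build_A,
    build_A_inverse,
    build_mme,
    compute_accuracy,
    compute_heritability,
    compute_pev,
    em_reml,
    evaluate,
    read_pedigree,
    reml_components,
    solve_mme,
)
from sibstep.mixedmodel import build_design

from conftest import (
    gls_blup_oracle,
    phenotype_frame,
    random_pedigree_records,
    reml_grid_argmax,
)

# 5-animal toy (S, D founders; O1,O2 full sibs; O3 half sib): phenotypes drawn
# once from the model at h2 = 0.6 and frozen; REML grid optimum at h2 = 0.416.
TOY_PED = [("O1", "S", "D"), ("O2", "S", "D"), ("O3", "S", "0")]
TOY_Y = [2.771954, 3.644511, 0.93148, 3.22946, 2.948587]


class TestPhenotypeFilters:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {
                "animal": ["a", "b", "c", "d"],
                "cwt": [400.0, 410.0, 390.0, 405.0],
                "slaughter_age_months": [25, 36, 30, 37],
            }
        )

    def test_age_below_window_removed(self, table):
        out, report = apply_phenotype_filters(table)
        assert "a" not in out["animal"].tolist()
        assert report["n_removed_age"] == 2

    def test_age_at_upper_bound_retained(self, table):
        out, _ = apply_phenotype_filters(table)
        assert "b" in out["animal"].tolist()

    def test_in_range_retained(self, table):
        out, _ = apply_phenotype_filters(table)
        assert "c" in out["animal"].tolist()

    def test_trait_bounds(self, table):
        out, report = apply_phenotype_filters(
            table, trait_bounds={"cwt": (395.0, 500.0)}
        )
        assert "c" not in out["animal"].tolist()
        assert report["n_removed_trait"]["cwt"] == 1


class TestBuildSolveMme:
    def test_single_animal_mean_model(self):
        ped = read_pedigree([("A", "0", "0")])
        kinv = build_A_inverse(ped)
        spec = ModelSpec(trait="y", fixed_effects=(), sigma_a2=1.0, sigma_e2=2.0)
        phenos = phenotype_frame(["A"], [3.0])
        mme = build_mme(spec, phenos, kinv)
        alpha = 2.0
        assert np.allclose(mme.lhs, [[1.0, 1.0], [1.0, 1.0 + alpha]])
        assert np.allclose(mme.rhs, [3.0, 3.0])

    def test_unphenotyped_animals_keep_equations(self):
        ped = read_pedigree([("O1", "S", "D"), ("O2", "S", "D")])
        kinv = build_A_inverse(ped)
        spec = ModelSpec(trait="y", fixed_effects=(), sigma_a2=1.0, sigma_e2=1.0)
        phenos = phenotype_frame(["S"], [1.0])
        mme = build_mme(spec, phenos, kinv)
        assert mme.lhs.shape == (1 + 4, 1 + 4)
        sol = solve_mme(mme)
        assert set(sol.random.index) == {"S", "D", "O1", "O2"}

    def test_zero_phenotypes_give_zero_solutions(self):
        ped = read_pedigree(TOY_PED)
        kinv = build_A_inverse(ped)
        spec = ModelSpec(trait="y", fixed_effects=(), sigma_a2=1.0, sigma_e2=1.0)
        phenos = phenotype_frame(list(ped.ids), np.zeros(5))
        sol = solve_mme(build_mme(spec, phenos, kinv))
        assert np.allclose(sol.fixed.to_numpy(), 0.0)
        assert np.allclose(sol.random.to_numpy(), 0.0)

    def test_matches_gls_oracle_four_animals(self):
        ped = read_pedigree([("O1", "S", "D"), ("O2", "S", "D")])
        A = build_A(ped).to_dense()
        kinv = build_A_inverse(ped)
        sa2, se2 = 2.0, 3.0
        y = np.array([4.0, 6.0, 5.0, 7.0])
        phenos = phenotype_frame(list(ped.ids), y)
        spec = ModelSpec(trait="y", fixed_effects=(), sigma_a2=sa2, sigma_e2=se2)
        mme = build_mme(spec, phenos, kinv)
        sol = solve_mme(mme)
        beta, u, pev = gls_blup_oracle(y, np.ones((4, 1)), np.eye(4), A, sa2, se2)
        assert abs(sol.fixed.iloc[0] - beta[0]) < 1e-8
        assert np.abs(sol.random.to_numpy() - u).max() < 1e-8
        assert np.abs(compute_pev(mme, se2) - pev).max() < 1e-8

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_gls_oracle_random_pedigrees(self, seed):
        # solver agreement on pedigrees up to 50 animals, partial phenotyping
        rng = np.random.default_rng(seed)
        ped = read_pedigree(random_pedigree_records(rng, n=30, p_founder=0.25))
        A = build_A(ped).to_dense()
        kinv = build_A_inverse(ped)
        n_obs = 18
        obs = rng.choice(ped.n, size=n_obs, replace=False)
        y = rng.normal(5.0, 2.0, size=n_obs)
        phenos = phenotype_frame([ped.ids[i] for i in obs], y)
        sa2, se2 = 1.5, 2.5
        spec = ModelSpec(trait="y", fixed_effects=(), sigma_a2=sa2, sigma_e2=se2)
        mme = build_mme(spec, phenos, kinv)
        sol = solve_mme(mme)
        Z = np.zeros((n_obs, ped.n))
        Z[np.arange(n_obs), obs] = 1.0
        beta, u, pev = gls_blup_oracle(y, np.ones((n_obs, 1)), Z, A, sa2, se2)
        ordered = sol.random.reindex(list(ped.ids)).to_numpy()
        assert abs(sol.fixed.iloc[0] - beta[0]) < 1e-8
        assert np.abs(ordered - u).max() < 1e-8
        assert np.abs(compute_pev(mme, se2) - pev).max() < 1e-8

    def test_class_and_covariate_fixed_effects(self):
        rng = np.random.default_rng(9)
        ped = read_pedigree(random_pedigree_records(rng, n=25, p_founder=0.3))
        n = ped.n
        phenos = phenotype_frame(
            list(ped.ids),
            rng.normal(10, 3, size=n),
            birth_year=rng.integers(2015, 2018, size=n),
            slaughter_age_months=rng.integers(26, 37, size=n),
        )
        spec = ModelSpec(
            trait="y",
            fixed_effects=(("birth_year", "class"), ("slaughter_age_months", "covariate")),
            sigma_a2=1.0,
            sigma_e2=1.0,
        )
        y, X, names = build_design(phenos, spec)
        assert names[0] == "(intercept)"
        assert sum(nm.startswith("birth_year=") for nm in names) == 2  # corner point
        mme = build_mme(spec, phenos, build_A_inverse(ped))
        sol = solve_mme(mme)
        A = build_A(ped).to_dense()
        beta, u, _ = gls_blup_oracle(y, X, np.eye(n), A, 1.0, 1.0)
        assert np.abs(sol.fixed.to_numpy() - beta).max() < 1e-8
        assert np.abs(sol.random.to_numpy() - u).max() < 1e-8

    def test_rank_deficient_design_warns_and_solves(self):
        ped = read_pedigree([("O1", "S", "D"), ("O2", "S", "D")])
        phenos = phenotype_frame(
            list(ped.ids), [1.0, 2.0, 3.0, 4.0], dup=[1.0, 1.0, 1.0, 1.0]
        )
        spec = ModelSpec(
            trait="y",
            fixed_effects=(("dup", "covariate"),),  # collinear with intercept
            sigma_a2=1.0,
            sigma_e2=1.0,
        )
        with pytest.warns(UserWarning, match="rank deficient"):
            mme = build_mme(spec, phenos, build_A_inverse(ped))
        solve_mme(mme)  # generalized-inverse path must not raise


class TestPevAndAccuracy:
    def test_unconnected_animal_pev_is_sigma_a2(self):
        ped = read_pedigree([("LONER", "0", "0"), ("X", "0", "0")])
        kinv = build_A_inverse(ped)
        sa2, se2 = 2.0, 4.0
        spec = ModelSpec(trait="y", fixed_effects=(), sigma_a2=sa2, sigma_e2=se2)
        phenos = phenotype_frame(["X"], [1.0])
        mme = build_mme(spec, phenos, kinv)
        pev = compute_pev(mme, se2)
        loner = list(mme.animal_ids).index("LONER")
        assert pev[loner] == pytest.approx(sa2)

    def test_own_phenotype_reduces_pev(self):
        # needs >1 record so the intercept does not absorb all information
        ped = read_pedigree([("X", "0", "0"), ("Y", "0", "0"), ("Z", "0", "0")])
        kinv = build_A_inverse(ped)
        sa2, se2 = 2.0, 4.0
        spec = ModelSpec(trait="y", fixed_effects=(), sigma_a2=sa2, sigma_e2=se2)
        phenos = phenotype_frame(["X", "Y", "Z"], [1.0, 2.0, 3.0])
        mme = build_mme(spec, phenos, kinv)
        assert (compute_pev(mme, se2) < sa2).all()

    def test_accuracy_endpoints(self):
        assert compute_accuracy(np.array([0.0]), 2.0)[0] == 1.0
        assert compute_accuracy(np.array([2.0]), 2.0)[0] == 0.0

    def test_sqrt_mode(self):
        acc = compute_accuracy(np.array([1.0]), 2.0, mode="sqrt")
        assert acc[0] == pytest.approx(np.sqrt(0.5))

    def test_overshoot_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            acc = compute_accuracy(np.array([2.5]), 2.0)
        assert acc[0] == 0.0


class TestHeritability:
    @pytest.mark.parametrize(
        "sa2,se2,expected_h2",
        [(603.79, 1455.60, 0.29), (1.51, 1.70, 0.47)],
    )
    def test_reported_pairs(self, sa2, se2, expected_h2):
        h2, _ = compute_heritability(sa2, se2)
        assert round(h2, 2) == expected_h2

    def test_zero_residual_gives_one(self):
        h2, sp2 = compute_heritability(1.7, 0.0)
        assert h2 == 1.0
        assert sp2 == 1.7

    def test_zero_total_variance_errors(self):
        with pytest.raises(ModelError):
            compute_heritability(0.0, 0.0)

    @settings(max_examples=30, deadline=None)
    @given(
        st.floats(0.0, 1e6, allow_nan=False),
        st.floats(1e-6, 1e6, allow_nan=False),
    )
    def test_bounds_and_additivity(self, sa2, se2):
        h2, sp2 = compute_heritability(sa2, se2)
        assert 0.0 <= h2 <= 1.0
        assert sp2 == sa2 + se2


class TestEmReml:
    def test_toy_matches_grid_oracle(self):
        ped = read_pedigree(TOY_PED)
        A = build_A(ped).to_dense()
        y = np.array(TOY_Y)
        X = np.ones((5, 1))
        est = em_reml(y, X, A, max_iter=20_000)
        grid_h2 = reml_grid_argmax(y, X, A, resolution=1e-4)
        assert est.converged
        assert abs(est.h2 - grid_h2) < 1e-3

    def test_loglik_non_decreasing(self):
        ped = read_pedigree(TOY_PED)
        A = build_A(ped).to_dense()
        est = em_reml(np.array(TOY_Y), np.ones((5, 1)), A, max_iter=500)
        diffs = np.diff(est.loglik_path)
        assert (diffs >= -1e-9).all()

    def test_invariant_to_animal_reordering(self):
        rng = np.random.default_rng(12)
        ped = read_pedigree(random_pedigree_records(rng, n=20, p_founder=0.3))
        A = build_A(ped).to_dense()
        y = rng.normal(0, 1, size=20) + np.linalg.cholesky(A) @ rng.normal(size=20)
        X = np.ones((20, 1))
        est = em_reml(y, X, A, max_iter=5000)
        perm = rng.permutation(20)
        est_p = em_reml(y[perm], X[perm], A[np.ix_(perm, perm)], max_iter=5000)
        assert est_p.sigma_a2 == pytest.approx(est.sigma_a2, rel=1e-6)
        assert est_p.sigma_e2 == pytest.approx(est.sigma_e2, rel=1e-6)

    def test_needs_two_records(self):
        with pytest.raises(ModelError):
            em_reml(np.array([1.0]), np.ones((1, 1)), np.eye(1))

    def test_zero_variance_response_errors(self):
        with pytest.raises(ModelError):
            em_reml(np.full(4, 2.0), np.ones((4, 1)), np.eye(4))

    def test_reml_components_wrapper(self):
        ped = read_pedigree(TOY_PED)
        kinv = build_A_inverse(ped)
        phenos = phenotype_frame(list(ped.ids), TOY_Y)
        est = reml_components(
            ModelSpec(trait="y", fixed_effects=()), phenos, kinv, max_iter=20_000
        )
        assert abs(est.h2 - 0.416) < 1e-2


class TestEvaluate:
    def test_full_result_shape(self):
        rng = np.random.default_rng(13)
        ped = read_pedigree(random_pedigree_records(rng, n=15, p_founder=0.3))
        phenos = phenotype_frame(list(ped.ids)[:10], rng.normal(5, 1, 10))
        spec = ModelSpec(trait="y", fixed_effects=(), sigma_a2=1.0, sigma_e2=1.0)
        res = evaluate(spec, phenos, build_A_inverse(ped))
        assert len(res.table) == ped.n
        assert set(res.table.columns) == {"animal", "breeding_value", "pev", "accuracy"}
        assert ((res.table.accuracy >= 0) & (res.table.accuracy <= 1)).all()
        assert res.h2 == pytest.approx(0.5)
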
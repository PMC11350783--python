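import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ssgblup.hmatrix import HInverse, h_inverse
from ssgblup.mixed_model import (
    ModelError,
    ModelSpec,
    VarianceComponents,
    build_design,
    genetic_correlation,
    heritability,
    reml,
    solve_mme,
    solve_mme_multi,
)
from ssgblup.pedigree import a22, a_inverse, pedigree_from_records
from ssgblup.genotypes import blend_tune, g_from_genotypes

from conftest import small_sim
from ssgblup.simulate import simulate_dataset


def identity_hinv(ids):
    n = len(ids)
    return HInverse(list(ids), sp.identity(n, format="csr"),
                    np.zeros((0, 0)), np.array([], dtype=np.int64))


def sim_hinv(ds, alpha=0.95):
    genotyped = list(ds.geno.animal_ids)
    A22 = a22(ds.ped, genotyped)
    G = blend_tune(g_from_genotypes(ds.geno), A22, alpha=alpha, tune=True)
    return h_inverse(a_inverse(ds.ped), G, A22, genotyped, list(ds.ped.ids))


class TestVarianceComponents:
    def test_heritability_printed_example(self):
        vc = VarianceComponents.univariate(0.61, 1.55)
        assert round(float(heritability(vc).iloc[0]), 2) == 0.28

    def test_heritability_zero_additive(self):
        vc = VarianceComponents.univariate(0.0, 1.0)
        assert float(heritability(vc).iloc[0]) == 0.0

    def test_heritability_half(self):
        vc = VarianceComponents.univariate(0.7, 0.7)
        assert float(heritability(vc).iloc[0]) == pytest.approx(0.5)

    def test_heritability_includes_pe(self):
        vc = VarianceComponents.univariate(1.0, 2.0, sigma2_p=1.0)
        assert float(heritability(vc).iloc[0]) == pytest.approx(0.25)

    def test_zero_total_errors(self):
        vc = VarianceComponents.univariate(0.0, 0.0)
        with pytest.raises(ModelError):
            heritability(vc)

    def test_rg_arithmetic(self):
        vc = VarianceComponents(
            ["a", "b"], np.array([[0.4, 0.3], [0.3, 0.5]]), np.eye(2)
        )
        assert genetic_correlation(vc, "a", "b") == pytest.approx(
            0.3 / np.sqrt(0.2), abs=1e-10
        )

    def test_rg_zero_cov(self):
        vc = VarianceComponents(["a", "b"], np.diag([0.4, 0.5]), np.eye(2))
        assert genetic_correlation(vc, "a", "b") == 0.0

    def test_rg_same_trait_is_one(self):
        vc = VarianceComponents(["a", "b"], np.diag([0.4, 0.5]), np.eye(2))
        assert genetic_correlation(vc, "a", "a") == 1.0

    def test_rg_zero_variance_errors(self):
        vc = VarianceComponents(["a", "b"], np.diag([0.0, 0.5]), np.eye(2))
        with pytest.raises(ModelError):
            genetic_correlation(vc, "a", "b")


class TestBuildDesign:
    def _pheno(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "animal": [f"a{i}" for i in range(n)],
                "y": rng.standard_normal(n),
                "sex": rng.integers(1, 3, size=n),
                "age": rng.integers(1, 3, size=n),
                "coat": rng.integers(1, 5, size=n),
                "area": rng.integers(1, 5, size=n),
                "F": rng.random(n) * 0.1,
            }
        )

    def test_column_count_all_factors(self):
        ph = self._pheno(40, seed=1)
        ids = [f"a{i}" for i in range(40)]
        spec = ModelSpec(
            traits=["y"],
            fixed_factors={"sex": None, "age": None, "coat": None, "area": None},
            covariates=["F"],
        )
        d = build_design(ph, spec, ids)
        # intercept + (2-1) + (2-1) + (4-1) + (4-1) + 1 covariate = 10
        assert d.X[0].shape[1] == 10
        assert np.linalg.matrix_rank(d.X[0]) == 10

    def test_sex_only_reference_coding(self):
        ph = self._pheno(4, seed=2)
        ph["sex"] = [1, 2, 1, 2]
        spec = ModelSpec(traits=["y"], fixed_factors={"sex": None})
        d = build_design(ph, spec, [f"a{i}" for i in range(4)])
        assert d.x_cols[0] == ["intercept", "sex[1]"]
        assert d.X[0][:, 1].tolist() == [1, 0, 1, 0]

    def test_repeated_records_map(self):
        ph = pd.DataFrame(
            {"animal": ["a0", "a1", "a1"], "y": [1.0, 2.0, 3.0]}
        )
        spec = ModelSpec(traits=["y"])
        d = build_design(ph, spec, ["a0", "a1"])
        assert d.rec_animal[0].tolist() == [0, 1, 1]
        assert d.has_repeats()

    def test_unknown_animal_errors(self):
        ph = self._pheno(3)
        with pytest.raises(ModelError, match="absent"):
            build_design(ph, ModelSpec(traits=["y"]), ["a0", "a1"])

    def test_unseen_level_errors(self):
        ph = self._pheno(5)
        spec = ModelSpec(traits=["y"], fixed_factors={"sex": ["1"]})
        ph["sex"] = [1, 1, 2, 1, 1]
        with pytest.raises(ModelError, match="unseen"):
            build_design(ph, spec, [f"a{i}" for i in range(5)])

    def test_missing_trait_rows_excluded(self):
        ph = self._pheno(6)
        ph.loc[2, "y"] = np.nan
        d = build_design(ph, ModelSpec(traits=["y"]), [f"a{i}" for i in range(6)])
        assert len(d.y[0]) == 5


class TestSolveMme:
    def test_huge_lambda_approaches_ols(self):
        rng = np.random.default_rng(3)
        n = 40
        ids = [f"a{i}" for i in range(n)]
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 2.0]) + rng.standard_normal(n)
        Z = sp.identity(n, format="csr")
        vc = VarianceComponents.univariate(1e-12, 1.0)  # lambda = 1e12
        sol = solve_mme(X, Z, None, identity_hinv(ids), vc, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(sol.b[0] - ols).max() < 1e-4
        assert sol.residual_norm < 1e-8

    def test_one_way_shrinkage_closed_form(self):
        # H = I, single record per animal, intercept-only fixed part:
        # a_i = (sigma_a / (sigma_a + sigma_e)) * (y_i - mean(y))
        rng = np.random.default_rng(4)
        n = 25
        ids = [f"a{i}" for i in range(n)]
        y = rng.standard_normal(n) * 2 + 5
        X = np.ones((n, 1))
        Z = sp.identity(n, format="csr")
        sa, se = 0.7, 1.3
        sol = solve_mme(X, Z, None, identity_hinv(ids), vc := VarianceComponents.univariate(sa, se), y)
        k = sa / (sa + se)
        expect = k * (y - y.mean())
        assert np.abs(sol.a[:, 0] - expect).max() < 1e-8

    def test_solvers_agree(self, default_dataset):
        ds = default_dataset
        h_inv = sim_hinv(ds)
        spec = ModelSpec(traits=["T1"], fixed_factors={"sex": None}, covariates=["F"])
        d = build_design(ds.pheno, spec, h_inv.ids)
        Z = sp.coo_matrix(
            (np.ones(len(d.y[0])), (np.arange(len(d.y[0])), d.rec_animal[0])),
            shape=(len(d.y[0]), len(h_inv.ids)),
        ).tocsr()
        vc = VarianceComponents.univariate(0.3, 0.7)
        s1 = solve_mme(d.X[0], Z, None, h_inv, vc, d.y[0], solver="sparse")
        s2 = solve_mme(d.X[0], Z, None, h_inv, vc, d.y[0], solver="dense")
        s3 = solve_mme(d.X[0], Z, None, h_inv, vc, d.y[0], solver="cg")
        assert np.abs(s1.a - s2.a).max() < 1e-6
        assert np.abs(s1.a - s3.a).max() < 1e-6

    def test_multi_matches_univariate(self, default_dataset):
        ds = default_dataset
        h_inv = sim_hinv(ds)
        spec = ModelSpec(traits=["T1"], fixed_factors={"sex": None}, covariates=["F"])
        d = build_design(ds.pheno, spec, h_inv.ids)
        Z = sp.coo_matrix(
            (np.ones(len(d.y[0])), (np.arange(len(d.y[0])), d.rec_animal[0])),
            shape=(len(d.y[0]), len(h_inv.ids)),
        ).tocsr()
        vc = VarianceComponents.univariate(0.3, 0.7)
        s1 = solve_mme(d.X[0], Z, None, h_inv, vc, d.y[0])
        s2 = solve_mme_multi(d, h_inv, vc)
        assert np.abs(s1.a[:, 0] - s2.a[:, 0]).max() < 1e-8

    def test_confounded_fixed_block_errors(self):
        n = 10
        ids = [f"a{i}" for i in range(n)]
        X = np.column_stack([np.ones(n), np.ones(n)])  # duplicated column
        Z = sp.identity(n, format="csr")
        vc = VarianceComponents.univariate(0.5, 0.5)
        with pytest.raises(ModelError, match="singular"):
            solve_mme(X, Z, None, identity_hinv(ids), vc, np.ones(n))

    def test_mme_residual_small(self, default_dataset):
        ds = default_dataset
        h_inv = sim_hinv(ds)
        spec = ModelSpec(traits=["T1"], fixed_factors={"sex": None}, covariates=["F"])
        d = build_design(ds.pheno, spec, h_inv.ids)
        vc = VarianceComponents.univariate(0.3, 0.7)
        sol = solve_mme_multi(d, h_inv, vc)
        assert sol.residual_norm < 1e-8


class TestReml:
    def test_null_sim_boundary(self):
        # a single null REML estimate has sampling sd ~0.03 at this size;
        # average three seeds for a stable boundary check
        spec = ModelSpec(traits=["T1"], fixed_factors={"sex": None}, covariates=["F"])
        ratios = []
        for seed in (42, 43, 44):
            cfg = small_sim(
                seed=seed, h2_targets=(0.0,), n_founders=160,
                n_generations=3, n_snps=500, genotyped_fraction=0.5,
            )
            ds = simulate_dataset(cfg)
            fit = reml(ds.pheno, spec, sim_hinv(ds), method="ai",
                       max_iter=100, tol=1e-6)
            ratios.append(float(fit.vc.G0[0, 0] / fit.vc.R0[0, 0]))
        assert float(np.mean(ratios)) < 0.02

    def test_em_loglik_monotone(self, default_dataset):
        ds = default_dataset
        h_inv = sim_hinv(ds)
        spec = ModelSpec(traits=["T1"], fixed_factors={"sex": None}, covariates=["F"])
        fit = reml(ds.pheno, spec, h_inv, method="em", max_iter=40, tol=1e-10)
        ll = np.array(fit.loglik_trace)
        assert np.all(np.diff(ll) > -1e-8)

    def test_em_and_ai_agree(self):
        # needs an interior, well-determined optimum: use a mid-size sim
        cfg = small_sim(seed=31, n_founders=80, n_snps=400, h2_targets=(0.4,))
        ds = simulate_dataset(cfg)
        h_inv = sim_hinv(ds)
        spec = ModelSpec(traits=["T1"], fixed_factors={"sex": None}, covariates=["F"])
        ai = reml(ds.pheno, spec, h_inv, method="ai", max_iter=100, tol=1e-8)
        em = reml(ds.pheno, spec, h_inv, method="em", max_iter=1500, tol=1e-8)
        # both maximise the same restricted likelihood
        assert ai.loglik_trace[-1] == pytest.approx(em.loglik_trace[-1], abs=1e-3)
        assert ai.vc.G0[0, 0] == pytest.approx(em.vc.G0[0, 0], rel=0.05, abs=1e-3)
        assert ai.vc.R0[0, 0] == pytest.approx(em.vc.R0[0, 0], rel=0.05)

    def test_relabelling_invariance(self):
        cfg = small_sim(seed=13, n_founders=30, n_generations=3, n_snps=150)
        ds = simulate_dataset(cfg)
        h_inv = sim_hinv(ds)
        spec = ModelSpec(traits=["T1"], fixed_factors={"sex": None})
        fit1 = reml(ds.pheno, spec, h_inv, method="ai", max_iter=60, tol=1e-8)

        # relabel animals (prefix swap) and rebuild everything from scratch
        ren = {a: f"z_{a}" for a in ds.ped.ids}
        frame = ds.ped.to_frame()
        for col in ("animal", "sire", "dam"):
            frame[col] = frame[col].map(lambda v: ren.get(v, v))
        from ssgblup.pedigree import pedigree_from_records

        ped2 = pedigree_from_records(
            frame["animal"].tolist(), frame["sire"].tolist(), frame["dam"].tolist()
        )
        from ssgblup.genotypes import GenotypeSet

        geno2 = GenotypeSet(
            [ren[a] for a in ds.geno.animal_ids], ds.geno.snp_ids,
            ds.geno.chrom, ds.geno.pos_bp, ds.geno.calls, ds.geno.a1, ds.geno.a2,
        )
        pheno2 = ds.pheno.copy()
        pheno2["animal"] = pheno2["animal"].map(ren)
        A22b = a22(ped2, list(geno2.animal_ids))
        Gb = blend_tune(g_from_genotypes(geno2), A22b, alpha=0.95, tune=True)
        h2b = h_inverse(a_inverse(ped2), Gb, A22b, list(geno2.animal_ids),
                        list(ped2.ids))
        fit2 = reml(pheno2, spec, h2b, method="ai", max_iter=60, tol=1e-8)
        assert fit1.vc.G0[0, 0] == pytest.approx(fit2.vc.G0[0, 0], abs=1e-6)
        assert fit1.vc.R0[0, 0] == pytest.approx(fit2.vc.R0[0, 0], abs=1e-6)

    def test_pe_separated_with_repeated_records(self):
        # repeated records per animal allow splitting PE from residual
        rng = np.random.default_rng(77)
        n, reps = 150, 4
        ids = [f"a{i}" for i in range(n)]
        h_inv = identity_hinv(ids)
        sa, spe, se = 0.5, 0.8, 1.0
        a = rng.standard_normal(n) * np.sqrt(sa)
        pe = rng.standard_normal(n) * np.sqrt(spe)
        rows = []
        for i in range(n):
            for _ in range(reps):
                rows.append(
                    {"animal": ids[i],
                     "y": a[i] + pe[i] + rng.standard_normal() * np.sqrt(se)}
                )
        pheno = pd.DataFrame(rows)
        spec = ModelSpec(traits=["y"], permanent_env="auto")
        fit = reml(pheno, spec, h_inv, method="ai", max_iter=100, tol=1e-6)
        assert fit.vc.P0 is not None
        # PE + additive separation is weak with H=I; check totals and PE scale
        assert fit.vc.P0[0, 0] + fit.vc.G0[0, 0] == pytest.approx(sa + spe, abs=0.5)
        assert fit.vc.R0[0, 0] == pytest.approx(se, abs=0.25)

    def test_single_record_pe_dropped_with_warning(self, default_dataset, caplog):
        ds = default_dataset
        h_inv = sim_hinv(ds)
        spec = ModelSpec(traits=["T1"], fixed_factors={"sex": None},
                         covariates=["F"], permanent_env=True)
        import logging

        with caplog.at_level(logging.WARNING):
            fit = reml(ds.pheno, spec, h_inv, method="ai", max_iter=30, tol=1e-5)
        assert fit.vc.P0 is None
        assert any("confounded" in m for m in caplog.messages)

    def test_nonconvergence_flagged(self, default_dataset):
        ds = default_dataset
        h_inv = sim_hinv(ds)
        spec = ModelSpec(traits=["T1"], fixed_factors={"sex": None}, covariates=["F"])
        fit = reml(ds.pheno, spec, h_inv, method="em", max_iter=3, tol=1e-12)
        assert not fit.converged

    def test_trivariate_with_missing_trait_records(self):
        # trait-wise residual indexing: half the VM records are missing
        cfg = small_sim(
            seed=88, n_founders=80, n_snps=300,
            traits=("VE", "VM", "VN"), h2_targets=(0.17, 0.13, 0.28),
            pe_variance=(0.0, 0.0, 0.0),
            rg_matrix=(
                (1.0, 0.55, 0.52), (0.55, 1.0, 0.79), (0.52, 0.79, 1.0)
            ),
            observed_scale="score",
        )
        ds = simulate_dataset(cfg)
        pheno = ds.pheno.copy()
        drop = pheno.sample(frac=0.5, random_state=1).index
        pheno.loc[drop, "VM"] = np.nan
        spec = ModelSpec(traits=["VE", "VM", "VN"],
                         fixed_factors={"sex": None}, covariates=["F"])
        fit = reml(pheno, spec, sim_hinv(ds), method="ai", max_iter=60,
                   tol=1e-5)
        assert fit.converged
        assert np.all(np.linalg.eigvalsh(fit.vc.G0) > -1e-10)
        assert np.all(np.linalg.eigvalsh(fit.vc.R0) > 0)
        h2 = fit.heritability()
        assert np.all((h2 >= 0) & (h2 <= 1))
        for t1, t2 in (("VE", "VM"), ("VE", "VN"), ("VM", "VN")):
            assert -1 <= fit.genetic_correlation(t1, t2) <= 1

    def test_a_hat_covers_all_pedigree_animals(self, default_dataset):
        ds = default_dataset
        h_inv = sim_hinv(ds)
        spec = ModelSpec(traits=["T1"], fixed_factors={"sex": None}, covariates=["F"])
        fit = reml(ds.pheno, spec, h_inv, method="ai", max_iter=30, tol=1e-5)
        assert list(fit.a_hat.index) == list(ds.ped.ids)
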
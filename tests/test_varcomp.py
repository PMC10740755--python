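"""REML against a brute-force likelihood oracle; PCs; phenotype correction."""

import numpy as np
import pytest
from scipy import optimize

from gfblup import (
    Kinship,
    MixedModelSpec,
    SimConfig,
    build_grm,
    correct_phenotypes,
    estimate_reml,
    principal_components,
    simulate_genotypes,
    simulate_phenotypes,
)
from gfblup.exceptions import IdentifiabilityError, ZeroVarianceError
from gfblup.varcomp import gls_fixed_effects


def restricted_loglik(y, X, Gs, sigmas):
    """Independent restricted log-likelihood: direct dense formula."""
    n = len(y)
    V = sigmas[-1] * np.eye(n)
    for s, G in zip(sigmas[:-1], Gs):
        V = V + s * G
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vinv = np.linalg.inv(V)
    XtViX = X.T @ Vinv @ X
    sign_x, logdet_x = np.linalg.slogdet(XtViX)
    if sign_x <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vinv @ y)
    r = y - X @ beta
    return -0.5 * (logdet_v + logdet_x + r @ Vinv @ r)


def brute_force_reml(y, X, Gs):
    """Maximize the restricted likelihood by direct numerical optimization
    in log-variance space (Nelder-Mead, multiple starts), over the same
    domain the estimator searches (variances >= 1e-8 * var(y))."""
    k = len(Gs) + 1
    vy = y.var(ddof=1)
    floor = 1e-8 * vy

    def objective(ls):
        return -restricted_loglik(y, X, Gs, np.maximum(np.exp(ls), floor))

    best = None
    for start_frac in (0.2, 0.5, 0.8):
        x0 = np.log(np.r_[[start_frac * vy / (k - 1)] * (k - 1), (1 - start_frac) * vy])
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return np.maximum(np.exp(best.x), floor), -best.fun


def _random_instance(rng, n, n_fixed=2):
    m = 3 * n
    dosage = rng.binomial(2, rng.uniform(0.2, 0.5, size=m), size=(n, m)).astype(float)
    p = dosage.mean(axis=0) / 2
    poly = (p > 0) & (p < 1)
    w = (dosage[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    G = w @ w.T / poly.sum()
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(n_fixed - 1)])
    u = np.linalg.cholesky(G + 1e-6 * np.eye(n)) @ rng.standard_normal(n)
    y = X @ rng.standard_normal(n_fixed) + u + rng.standard_normal(n)
    return y, X, G


class TestEstimateReml:
    def test_matches_brute_force_oracle_on_tiny_instances(self, rng):
        for trial in range(8):
            n = int(rng.integers(15, 26))
            y, X, G = _random_instance(rng, n)
            k = Kinship(G, [f"i{i}" for i in range(n)], 100)
            vc = estimate_reml(MixedModelSpec(y, X, [k]))
            sig_bf, ll_bf = brute_force_reml(y, X, [G])
            est = np.array([vc.components["sigma2_g"], vc.components["sigma2_e"]])
            # the AI optimum must not fall below the brute-force one (to the
            # precision the dense likelihood formula retains when a variance
            # sits at the floor and V is near-singular), and the estimates
            # must agree relative to the total-variance scale
            assert vc.loglik >= ll_bf - 1e-3
            assert np.abs(est - sig_bf).max() / sig_bf.sum() < 1e-4

    def test_two_kernel_matches_oracle(self, rng):
        n = 25
        y, X, G = _random_instance(rng, n)
        G2 = np.diag(np.linspace(0.5, 1.5, n))
        ks = [
            Kinship(G, [f"i{i}" for i in range(n)], 10, role="feature"),
            Kinship(G2, [f"i{i}" for i in range(n)], 10, role="remainder"),
        ]
        vc = estimate_reml(MixedModelSpec(y, X, ks))
        _, ll_bf = brute_force_reml(y, X, [G, G2])
        assert vc.loglik >= ll_bf - 1e-5

    def test_identity_kernel_raises_identifiability_error(self, rng):
        n = 30
        y = rng.standard_normal(n)
        k = Kinship(np.eye(n), [f"i{i}" for i in range(n)], 10)
        with pytest.raises(IdentifiabilityError):
            estimate_reml(MixedModelSpec(y, np.ones((n, 1)), [k]))

    def test_constant_response_raises(self, rng):
        n = 30
        y, X, G = _random_instance(rng, n)
        k = Kinship(G, [f"i{i}" for i in range(n)], 10)
        with pytest.raises(ZeroVarianceError):
            estimate_reml(MixedModelSpec(np.ones(n), X, [k]))

    def test_confounded_split_conserves_total_variance(self):
        n = 60
        # seed chosen to give an interior optimum (both variances positive)
        y, X, G = _random_instance(np.random.default_rng(2), n)
        ids = [f"i{i}" for i in range(n)]
        single = estimate_reml(MixedModelSpec(y, X, [Kinship(G, ids, 10)]))
        double = estimate_reml(
            MixedModelSpec(
                y,
                X,
                [
                    Kinship(G, ids, 10, role="feature"),
                    Kinship(G.copy(), ids, 10, role="remainder"),
                ],
            )
        )
        total2 = double.components["sigma2_f"] + double.components["sigma2_r"]
        assert total2 == pytest.approx(single.components["sigma2_g"], rel=1e-3)
        assert double.loglik == pytest.approx(single.loglik, abs=1e-5)

    def test_heritability_recovery_moderate_scale(self):
        # mean estimated h2 near truth over a few replicates
        h2_hats = []
        for seed in range(4):
            cfg = SimConfig(
                n_discovery=400, n_target=10, n_snps=1500, n_qtls=150,
                h2_trait=0.45, seed=100 + seed,
            )
            disc, _ = simulate_genotypes(cfg)
            pheno, _ = simulate_phenotypes(disc, cfg)
            k = build_grm(disc)
            X = np.column_stack(
                [np.ones(len(pheno)), pheno.sex, pheno.age - pheno.age.mean()]
            )
            vc = estimate_reml(MixedModelSpec(pheno.value, X, [k]))
            h2_hats.append(vc.h2)
        assert abs(np.mean(h2_hats) - 0.45) < 0.10

    def test_reported_se_is_finite_and_positive(self, rng):
        y, X, G = _random_instance(rng, 60)
        k = Kinship(G, [f"i{i}" for i in range(60)], 10)
        vc = estimate_reml(MixedModelSpec(y, X, [k]))
        assert vc.se["sigma2_g"] > 0
        assert vc.se["h2"] > 0
        assert 0 <= vc.h2 <= 1


class TestPrincipalComponents:
    def test_deterministic_sign_convention(self, target_grm):
        a = principal_components(target_grm, 3)
        b = principal_components(target_grm, 3)
        assert np.array_equal(a, b)
        for j in range(3):
            i = np.argmax(np.abs(a[:, j] / np.sqrt((a[:, j] ** 2).sum())))
            assert a[i, j] > 0

    def test_unrelated_cohort_has_no_dominant_axis(self, rng):
        n, m = 500, 2000
        dosage = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        p = dosage.mean(axis=0) / 2
        w = (dosage - 2 * p) / np.sqrt(2 * p * (1 - p))
        G = w @ w.T / m
        k = Kinship(G, [f"i{i}" for i in range(n)], m)
        vals = np.linalg.eigvalsh(G)
        assert vals[-1] / np.trace(G) < 3 / n

    def test_two_cluster_cohort_separates_on_pc1(self, rng):
        n, m = 120, 800
        labels = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        p1 = rng.uniform(0.1, 0.9, size=m)
        p2 = np.clip(p1 + rng.normal(0, 0.25, size=m), 0.02, 0.98)
        dosage = np.where(
            labels[:, None] == 0,
            rng.binomial(2, p1, size=(n, m)),
            rng.binomial(2, p2, size=(n, m)),
        ).astype(float)
        p = dosage.mean(axis=0) / 2
        ok = (p > 0.01) & (p < 0.99)
        w = (dosage[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
        k = Kinship(w @ w.T / ok.sum(), [f"i{i}" for i in range(n)], int(ok.sum()))
        pc1 = principal_components(k, 1)[:, 0]
        assert abs(np.corrcoef(pc1, labels)[0, 1]) > 0.9

    def test_out_of_range_n_pc_raises(self, target_grm):
        with pytest.raises(ValueError):
            principal_components(target_grm, 0)
        with pytest.raises(ValueError):
            principal_components(target_grm, target_grm.n)


class TestCorrectPhenotypes:
    def _spec(self, study, extra_cols=True):
        g = study["discovery"]
        pheno = study["discovery_pheno"]
        k = build_grm(g)
        cols = [np.ones(len(pheno))]
        if extra_cols:
            cols += [pheno.sex.astype(float), pheno.age - pheno.age.mean()]
        X = np.column_stack(cols)
        return MixedModelSpec(pheno.value, X, [k], ids=list(g.iids)), pheno

    def test_intercept_only_correction_subtracts_mean_estimate(self, small_study):
        spec, pheno = self._spec(small_study, extra_cols=False)
        out = correct_phenotypes(spec)
        shift = pheno.value - out.corrected
        assert np.allclose(shift, shift[0])  # constant intercept removed

    def test_sex_effect_removed(self):
        cfg = SimConfig(
            n_discovery=651, n_target=10, n_snps=1200, n_qtls=100,
            sex_effect=2.0, seed=31,
        )
        disc, _ = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(disc, cfg)
        k = build_grm(disc)
        X = np.column_stack(
            [np.ones(len(pheno)), pheno.sex.astype(float), pheno.age - pheno.age.mean()]
        )
        spec = MixedModelSpec(pheno.value, X, [k], ids=list(disc.iids))
        out = correct_phenotypes(spec)
        males = out.corrected[pheno.sex == 0]
        females = out.corrected[pheno.sex == 1]
        raw_gap = pheno.value[pheno.sex == 1].mean() - pheno.value[pheno.sex == 0].mean()
        assert abs(raw_gap) > 1.0  # effect present before correction
        assert abs(females.mean() - males.mean()) < 0.1

    def test_gls_normal_equation_identity(self, small_study):
        # X' V^-1 (y - X b_hat) = 0 at the REML variances
        spec, _ = self._spec(small_study)
        vc = estimate_reml(spec)
        b = gls_fixed_effects(spec, vc)
        n = spec.response.size
        V = vc.components["sigma2_g"] * spec.kernels[0].matrix + vc.components[
            "sigma2_e"
        ] * np.eye(n)
        resid = spec.response - spec.fixed_design @ b
        lhs = spec.fixed_design.T @ np.linalg.solve(V, resid)
        assert np.abs(lhs).max() < 1e-8 * np.abs(spec.response).sum()
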
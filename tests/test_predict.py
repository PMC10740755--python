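"""GBLUP/GFBLUP prediction: limits, SNP-BLUP duality, cross-validation."""

import numpy as np
import pytest

from gfblup import (
    Kinship,
    SimConfig,
    build_grm,
    cross_validate,
    gblup_predict,
    gfblup_predict,
    simulate_genotypes,
    simulate_phenotypes,
)
from gfblup.exceptions import EmptyPanelError
from gfblup.predict import CvResult, accuracy_report, make_folds
from gfblup.varcomp import VarianceComponents


def _vc(components):
    gen = sum(v for k, v in components.items() if k != "sigma2_e")
    return VarianceComponents(
        components=components,
        h2=gen / sum(components.values()),
        se={},
        loglik=0.0,
        n_iter=0,
        converged=True,
    )


@pytest.fixture(scope="module")
def cohort():
    cfg = SimConfig(
        n_discovery=10, n_target=150, n_snps=600, n_qtls=60, h2_trait=0.45, seed=29
    )
    _, targ = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(targ, cfg)
    return targ, pheno, truth


class TestGblupPredict:
    def test_noise_free_limit_reproduces_reference_phenotypes(self, cohort):
        targ, pheno, _ = cohort
        k = build_grm(targ)
        # regularize so G is invertible, then let s2_e -> 0
        k = Kinship(k.matrix + 1e-6 * np.eye(k.n), list(k.ids), k.n_snps_used)
        ref_ids = list(targ.iids[:100])
        y_ref = pheno.value[:100]
        vc = _vc({"sigma2_g": 1.0, "sigma2_e": 1e-12})
        fit = gblup_predict(k, y_ref, ref_ids, vc=vc)
        pred_ref = fit.gebv.loc[ref_ids].to_numpy()
        assert np.allclose(pred_ref, y_ref - fit.mu_hat, atol=1e-4)

    def test_snp_blup_duality(self):
        # GEBV from the GRM equals ridge-regression marker BLUP when the
        # GRM comes from the same standardized markers (30 x 200 instance)
        rng = np.random.default_rng(7)
        n, m = 30, 200
        dosage = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m)).astype(float)
        p = dosage.mean(axis=0) / 2
        ok = (p > 0) & (p < 1)
        w = (dosage[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
        m_used = int(ok.sum())
        G = w @ w.T / m_used
        y = rng.standard_normal(n) + w[:, :20] @ rng.standard_normal(20) * 0.2
        ids = [f"i{i}" for i in range(n)]
        s2_u, s2_e = 1.3, 0.9
        fit = gblup_predict(
            Kinship(G, ids, m_used), y, ids, vc=_vc({"sigma2_g": s2_u, "sigma2_e": s2_e})
        )
        # marker-effect ridge BLUP: a_hat = W'(WW' + m*s2e/s2u I)^-1 (y-mu),
        # with the same GLS intercept, then GEBV = W a_hat
        ones = np.ones(n)
        V = s2_u * G + s2_e * np.eye(n)
        Vi = np.linalg.inv(V)
        mu = (ones @ Vi @ y) / (ones @ Vi @ ones)
        lam = m_used * s2_e / s2_u
        a_hat = w.T @ np.linalg.solve(w @ w.T + lam * np.eye(n), y - mu)
        gebv_snp = w @ a_hat
        assert np.abs(fit.gebv.to_numpy() - gebv_snp).max() < 1e-6

    def test_reference_block_only_is_used(self, cohort):
        # altering held-out phenotypes must not change predictions
        targ, pheno, _ = cohort
        k = build_grm(targ)
        ref_ids = list(targ.iids[:100])
        y_ref = pheno.value[:100]
        vc = _vc({"sigma2_g": 10.0, "sigma2_e": 12.0})
        fit1 = gblup_predict(k, y_ref, ref_ids, vc=vc)
        fit2 = gblup_predict(k, y_ref.copy(), ref_ids, vc=vc)
        assert np.array_equal(fit1.gebv.to_numpy(), fit2.gebv.to_numpy())


class TestGfblupPredict:
    def test_identical_kernels_match_gblup_at_same_total_variance(self, cohort):
        targ, pheno, _ = cohort
        k = build_grm(targ)
        kf = Kinship(k.matrix.copy(), list(k.ids), k.n_snps_used, role="feature")
        kr = Kinship(k.matrix.copy(), list(k.ids), k.n_snps_used, role="remainder")
        ref_ids = list(targ.iids[:100])
        y_ref = pheno.value[:100]
        vc_g = _vc({"sigma2_g": 11.0, "sigma2_e": 13.0})
        vc_fr = _vc({"sigma2_f": 4.0, "sigma2_r": 7.0, "sigma2_e": 13.0})
        fit_g = gblup_predict(k, y_ref, ref_ids, vc=vc_g)
        fit_fr = gfblup_predict(kf, kr, y_ref, ref_ids, vc=vc_fr)
        assert np.abs(fit_g.gebv - fit_fr.gebv).max() < 1e-6
        assert fit_fr.lam == pytest.approx(4.0 / 11.0)

    def test_exact_two_kernel_route_agrees_with_collapsed(self, cohort):
        targ, pheno, _ = cohort
        keys = targ.keys()
        kf = build_grm(targ, snp_subset=set(keys[:150]), role="feature")
        kr = build_grm(targ, snp_subset=set(keys[150:]), role="remainder")
        ref_ids = list(targ.iids[:100])
        y_ref = pheno.value[:100]
        vc = _vc({"sigma2_f": 5.0, "sigma2_r": 6.0, "sigma2_e": 12.0})
        a = gfblup_predict(kf, kr, y_ref, ref_ids, vc=vc)
        b = gfblup_predict(kf, kr, y_ref, ref_ids, vc=vc, exact_two_kernel=True)
        assert np.abs(a.gebv - b.gebv).max() < 1e-8

    def test_empty_feature_kernel_refused(self, cohort):
        targ, pheno, _ = cohort
        k = build_grm(targ)
        empty = Kinship(k.matrix.copy(), list(k.ids), 0, role="feature")
        with pytest.raises(EmptyPanelError):
            gfblup_predict(empty, k, pheno.value[:50], list(targ.iids[:50]))


class TestCrossValidate:
    def test_fold_sizes_for_651_individuals(self, rng):
        folds = make_folds(651, 5, rng)
        assert sorted(len(f) for f in folds) == [130, 130, 130, 130, 131]
        all_idx = np.sort(np.concatenate(folds))
        assert np.array_equal(all_idx, np.arange(651))  # disjoint + exhaustive

    def test_result_has_25_splits_and_is_deterministic(self, cohort):
        targ, pheno, _ = cohort
        k = build_grm(targ)
        y = pheno.value - pheno.value.mean()
        a = cross_validate(y, kinship=k, model="gblup", seed=3)
        b = cross_validate(y, kinship=k, model="gblup", seed=3)
        assert len(a.accuracies) == 25
        assert a.accuracies == b.accuracies
        assert a.mean_accuracy == b.mean_accuracy

    def test_permuted_phenotypes_give_null_accuracy(self, cohort):
        # one permutation gives correlated splits (all share the same
        # broken phenotype vector), so average over several permutations:
        # each contributes a null draw with spread ~ 1/sqrt(n)
        targ, pheno, _ = cohort
        k = build_grm(targ)
        rng = np.random.default_rng(11)
        means = []
        for _ in range(6):
            y = rng.permutation(pheno.value)
            res = cross_validate(
                y - y.mean(), kinship=k, model="gblup", n_repeats=2, seed=5
            )
            means.append(res.mean_accuracy)
        n = len(pheno.value)
        assert abs(np.mean(means)) < 2.5 / np.sqrt(n * len(means))

    def test_heldout_gebv_frame_covers_cohort_each_repeat(self, cohort):
        targ, pheno, _ = cohort
        k = build_grm(targ)
        res = cross_validate(pheno.value, kinship=k, model="gblup", seed=4)
        assert list(res.gebv.columns) == ["iid", "gebv", "fold", "repeat"]
        for _, grp in res.gebv.groupby("repeat"):
            # folds partition the cohort: every individual held out once
            assert sorted(grp["iid"]) == sorted(targ.iids)

    def test_mean_and_se_recompute_from_stored_values(self, cohort):
        targ, pheno, _ = cohort
        k = build_grm(targ)
        res = cross_validate(pheno.value, kinship=k, model="gblup", seed=7)
        a = np.asarray(res.accuracies)
        assert res.mean_accuracy == pytest.approx(a.mean())
        assert res.se_accuracy == pytest.approx(a.std(ddof=1) / np.sqrt(a.size))

    def test_wrong_length_count_raises(self):
        with pytest.raises(ValueError):
            CvResult(n_folds=5, n_repeats=5, accuracies=[0.1] * 24, seed=0)

    def test_accuracy_report_layout(self, cohort):
        targ, pheno, _ = cohort
        k = build_grm(targ)
        res = cross_validate(pheno.value, kinship=k, model="gblup", seed=2)
        rep = accuracy_report({"gblup/all": res, "gfblup/0.05": res})
        assert list(rep.columns) == [
            "model", "p_value_bin", "mean_accuracy", "se_accuracy", "n_splits",
        ]
        assert set(rep["model"]) == {"gblup", "gfblup"}
        assert (rep["n_splits"] == 25).all()


class TestCalibration:
    def test_gblup_accuracy_at_study_design(self):
        # at the emulated study design (n = 651, m = 5000, 500 QTLs,
        # h2 = 0.45) single-kernel accuracy lands in the range livestock
        # cohorts show, and cannot exceed sqrt(h2) systematically
        cfg = SimConfig(n_discovery=2, h2_trait=0.45, seed=37)
        _, targ = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(targ, cfg)
        k = build_grm(targ)
        y = pheno.value - pheno.value.mean()
        res = cross_validate(y, kinship=k, model="gblup", seed=13)
        assert 0.30 < res.mean_accuracy < 0.60
        assert res.mean_accuracy < np.sqrt(0.45) + 2 * res.se_accuracy
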
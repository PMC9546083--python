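import math

import numpy as np
import pandas as pd
import pytest

from prepost_ma.ancova_models import (
    ModelError,
    OneStageSpec,
    fit_onestage,
    fit_trial_ancova,
    reml_loglik,
    twostage,
)
from prepost_ma.data_model import MetaDataset, as_complete
from prepost_ma.effects_ad import compute_effects
from prepost_ma.pooling import pool_re
from prepost_ma.pseudo_ipd import generate_dataset
from prepost_ma.synthetic import ResidSpec, aggregate_ipd, simulate_ipd

from conftest import random_arm_summaries


class TestTrialAncova:
    def test_toy_closed_form(self, toy_dataset):
        ipd = generate_dataset(toy_dataset, seed=2)
        fit = fit_trial_ancova(ipd, "toy")
        assert fit.treatment == pytest.approx(-1.5, abs=1e-10)
        assert fit.slope == pytest.approx(0.5, abs=1e-10)
        assert fit.resid_var == pytest.approx(3.6, abs=1e-9)
        assert fit.df_resid == 5

    def test_identical_arms_zero_effect(self):
        rng = np.random.default_rng(0)
        b = rng.normal(10, 2, size=12)
        y = 0.5 * b + rng.normal(0, 1, size=12)
        frame = pd.DataFrame(
            {
                "trial_id": "s",
                "arm": ["control"] * 6 + ["treatment"] * 6,
                "y_baseline": np.concatenate([b[:6], b[:6]]),
                "y_final": np.concatenate([y[:6], y[:6]]),
            }
        )
        fit = fit_trial_ancova(frame)
        assert fit.treatment == pytest.approx(0.0, abs=1e-10)

    def test_centring_invariance(self, pseudo_5):
        tid = pseudo_5.frame["trial_id"].iloc[0]
        a = fit_trial_ancova(pseudo_5, tid, center=True)
        b = fit_trial_ancova(pseudo_5, tid, center=False)
        assert a.treatment == pytest.approx(b.treatment, abs=1e-9)
        assert a.treatment_se == pytest.approx(b.treatment_se, abs=1e-9)

    def test_insufficient_df(self, toy_dataset):
        ipd = generate_dataset(toy_dataset, seed=2)
        sub = ipd.frame.groupby(["trial_id", "arm"]).head(1)
        with pytest.raises(ModelError):
            fit_trial_ancova(sub)


class TestTwoStage:
    def test_matches_ad_recovered_estimates(self, complete_ds):
        ipd = generate_dataset(complete_ds, seed=31)
        ts = twostage(ipd, model="RE")
        ad_effects = compute_effects(complete_ds, "ancova_recovered")
        ad = pool_re(ad_effects)
        assert ts.theta.estimate == pytest.approx(ad.estimate, abs=1e-8)
        assert ts.theta.se == pytest.approx(ad.se, abs=1e-8)
        assert ts.theta.tau2 == pytest.approx(ad.tau2, abs=1e-8)
        for eff, rec in zip(ad_effects, ts.per_trial.itertuples()):
            assert rec.treatment == pytest.approx(eff.estimate, abs=1e-8)
            assert rec.treatment_se == pytest.approx(eff.se, abs=1e-8)

    def test_single_trial_ce(self, toy_dataset):
        ipd = generate_dataset(toy_dataset, seed=2)
        res = twostage(ipd, model="CE")
        fit = fit_trial_ancova(ipd, "toy")
        assert res.theta.estimate == pytest.approx(fit.treatment)
        assert res.theta.se == pytest.approx(fit.treatment_se)

    def test_hk_flag(self, pseudo_5):
        plain = twostage(pseudo_5, model="RE", hk=False)
        hk = twostage(pseudo_5, model="RE", hk=True)
        assert hk.theta.hk and not plain.theta.hk
        assert hk.theta.estimate == pytest.approx(plain.theta.estimate, abs=1e-10)

    def test_interaction_null_coverage(self):
        reps, cover = 200, 0
        for i in range(reps):
            sim = simulate_ipd(k=4, n_per_arm=20, theta=-0.5, tau2=0.0,
                               gamma_w=0.0, seed=1000 + i)
            res = twostage(sim.frame, model="RE", interaction=True)
            ci = res.interaction
            cover += ci.ci_low <= 0.0 <= ci.ci_high
        assert cover / reps == pytest.approx(0.95, abs=0.05)


def _dense_restricted_loglik(frame, sigmas_by_row, tau2, X):
    """Independent full-matrix REML evaluation (oracle)."""
    y = frame["y_final"].to_numpy(float)
    n, p = X.shape
    V = np.diag(sigmas_by_row**2)
    for tid in frame["trial_id"].unique():
        t = ((frame["trial_id"] == tid) & (frame["arm"] == "treatment")).to_numpy(float)
        V += tau2 * np.outer(t, t)
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    _, ld_V = np.linalg.slogdet(V)
    _, ld_A = np.linalg.slogdet(XtVX)
    return -0.5 * (ld_V + ld_A + r @ Vinv @ r + (n - p) * math.log(2 * math.pi))


def _design(frame):
    """Test-side reconstruction of the one-stage fixed-effect design."""
    tids = list(dict.fromkeys(frame["trial_id"]))
    t = (frame["arm"] == "treatment").to_numpy(float)
    b = frame["y_baseline"].to_numpy(float)
    cols = []
    bc = np.empty_like(b)
    for tid in tids:
        m = (frame["trial_id"] == tid).to_numpy()
        bc[m] = b[m] - b[m].mean()
        cols.append(m.astype(float))
    for tid in tids:
        m = (frame["trial_id"] == tid).to_numpy()
        cols.append(np.where(m, bc, 0.0))
    cols.append(t)
    return np.column_stack(cols)


class TestRemlLoglik:
    def test_dense_matrix_oracle(self):
        sim = simulate_ipd(k=3, n_per_arm=8, seed=9, tau2=0.2)
        frame = sim.frame
        spec = OneStageSpec(resid_structure="study", model="RE")
        tids = list(dict.fromkeys(frame["trial_id"]))
        sig = {f"sigma[{tid}]": 0.8 + 0.2 * i for i, tid in enumerate(tids)}
        ll = reml_loglik({"tau2": 0.3, "sigmas": sig}, frame, spec)
        sig_rows = frame["trial_id"].map(
            {tid: sig[f"sigma[{tid}]"] for tid in tids}
        ).to_numpy(float)
        dense = _dense_restricted_loglik(frame, sig_rows, 0.3, _design(frame))
        assert ll == pytest.approx(dense, abs=1e-8)

    def test_optimum_beats_perturbations(self, pseudo_5):
        spec = OneStageSpec(resid_structure="study", model="RE")
        fit = fit_onestage(pseudo_5, spec)
        params = {"tau2": fit.tau2, "sigmas": fit.sigma_estimates}
        ll_star = reml_loglik(params, pseudo_5, spec)
        assert ll_star == pytest.approx(fit.loglik_restricted, abs=1e-6)
        rng = np.random.default_rng(12)
        for _ in range(50):
            pert = {
                "tau2": max(fit.tau2 * math.exp(rng.normal(0, 0.3)), 1e-10),
                "sigmas": {
                    k: v * math.exp(rng.normal(0, 0.2))
                    for k, v in fit.sigma_estimates.items()
                },
            }
            assert reml_loglik(pert, pseudo_5, spec) <= ll_star + 1e-8

    def test_monotone_decrease_for_inflated_sigma(self, pseudo_5):
        spec = OneStageSpec(resid_structure="single", model="CE")
        fit = fit_onestage(pseudo_5, spec)
        sigma0 = fit.sigma_estimates["sigma"]
        lls = [
            reml_loglik({"tau2": 0.0, "sigmas": sigma0 * f}, pseudo_5, spec)
            for f in (1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a > b for a, b in zip(lls, lls[1:]))


class TestOneStage:
    def test_single_trial_collapse(self, toy_dataset):
        ipd = generate_dataset(toy_dataset, seed=2)
        fit = fit_onestage(ipd, OneStageSpec(resid_structure="single", model="CE"))
        ols = fit_trial_ancova(ipd, "toy")
        assert fit.theta == pytest.approx(ols.treatment, abs=1e-8)
        assert fit.converged

    def test_seed_invariance(self, complete_ds):
        spec = OneStageSpec(resid_structure="study", model="RE")
        f1 = fit_onestage(generate_dataset(complete_ds, seed=1), spec)
        f2 = fit_onestage(generate_dataset(complete_ds, seed=2), spec)
        assert f1.theta == pytest.approx(f2.theta, abs=1e-8)
        assert f1.se == pytest.approx(f2.se, abs=1e-8)
        assert f1.tau2 == pytest.approx(f2.tau2, abs=1e-6)

    def test_structure_nesting_monotone_loglik(self, pseudo_5):
        lls = {}
        for structure in ("single", "arm", "study", "arm_study"):
            fit = fit_onestage(pseudo_5, OneStageSpec(resid_structure=structure, model="RE"))
            assert fit.converged
            lls[structure] = fit.loglik_restricted
        tol = 1e-6
        assert lls["arm"] >= lls["single"] - tol
        assert lls["study"] >= lls["single"] - tol
        assert lls["arm_study"] >= lls["arm"] - tol
        assert lls["arm_study"] >= lls["study"] - tol

    def test_one_vs_two_stage_agreement(self):
        sim = simulate_ipd(k=5, n_per_arm=50, seed=19, tau2=0.1,
                           baseline_imbalance_sd=0.5)
        ds = aggregate_ipd(sim)
        ipd = generate_dataset(ds, seed=4)
        one = fit_onestage(ipd, OneStageSpec(resid_structure="study", model="RE"))
        two = twostage(ipd, model="RE")
        assert abs(one.theta - two.theta.estimate) < 0.1 * two.theta.se

    def test_arm_specific_sd_recovery(self):
        sim = simulate_ipd(
            k=10, n_per_arm=100, seed=23, tau2=0.0,
            resid_spec=ResidSpec("arm", (1.0, 2.0)),
        )
        fit = fit_onestage(sim.frame, OneStageSpec(resid_structure="arm", model="CE"))
        assert fit.sigma_estimates["sigma[control]"] == pytest.approx(1.0, rel=0.10)
        assert fit.sigma_estimates["sigma[treatment]"] == pytest.approx(2.0, rel=0.10)

    def test_interaction_reporting(self, pseudo_5):
        fit = fit_onestage(
            pseudo_5, OneStageSpec(resid_structure="study", model="RE", interaction=True)
        )
        assert fit.gamma_within is not None and fit.gamma_within_se > 0
        assert fit.gamma_between is not None and fit.gamma_between_se > 0
        lo, hi = fit.gamma_within_ci
        assert lo < fit.gamma_within < hi

    def test_arm_study_needs_enough_per_arm(self, toy_dataset):
        ipd = generate_dataset(toy_dataset, seed=2)
        frame = ipd.frame.groupby(["trial_id", "arm"]).head(2)
        with pytest.raises(ModelError):
            fit_onestage(frame, OneStageSpec(resid_structure="arm_study", model="CE"))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            OneStageSpec(resid_structure="bogus")
        with pytest.raises(ValueError):
            OneStageSpec(model="mixed")

    def test_use_t_widens_ci(self, pseudo_5):
        spec_n = OneStageSpec(resid_structure="single", model="CE")
        spec_t = OneStageSpec(resid_structure="single", model="CE", use_t=True)
        fn = fit_onestage(pseudo_5, spec_n)
        ft = fit_onestage(pseudo_5, spec_t)
        assert ft.ci_high - ft.ci_low > fn.ci_high - fn.ci_low
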
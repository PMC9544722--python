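"""Animal-model MCMC machinery: diagnostics, summaries, samplers, calibration."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import pedfit as pf
from pedfit import model as M
from pedfit._polya_gamma import pg_vector, seed_polya_gamma
from pedfit._sparse_chol import PedigreePrecisionSolver
from pedfit.synthetic import PedigreeSimConfig

from conftest import random_pedigree


def _quiet_fit(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return M.fit(*args, **kwargs)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def test_ess_iid_normal():
    x = np.random.default_rng(1).standard_normal(5000)
    ess, ac1, hw = pf.diagnostics(x)
    assert abs(ess - 5000) / 5000 < 0.15
    assert abs(ac1) < 0.05
    assert hw


def test_ess_ar1_closed_form():
    rng = np.random.default_rng(2)
    n, phi = 20000, 0.9
    x = np.empty(n)
    x[0] = 0.0
    eps = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    ess, ac1, _ = pf.diagnostics(x)
    expected = n * (1 - phi) / (1 + phi)
    assert abs(ess - expected) / expected < 0.25
    assert ac1 == pytest.approx(phi, abs=0.03)


def test_heidelberger_welch_detects_drift():
    rng = np.random.default_rng(3)
    drift = rng.standard_normal(4000) + np.linspace(0, 4, 4000)
    assert not pf.heidelberger_welch(drift)
    assert pf.heidelberger_welch(rng.standard_normal(4000))


def test_constant_chain_flagged_degenerate():
    with pytest.warns(UserWarning, match="degenerate"):
        ess, ac1, hw = pf.diagnostics(np.full(500, 3.0))
    assert ess == 500 and hw


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def test_summary_constant_draws():
    s = pf.summarize_posterior(np.full(200, 1.7))
    assert s.mode == s.hpd_low == s.hpd_high == 1.7
    assert s.mean == pytest.approx(1.7, rel=1e-12)


def test_summary_normal_draws():
    x = np.random.default_rng(4).normal(2.0, 1.0, 100_000)
    s = pf.summarize_posterior(x)
    assert s.mode == pytest.approx(2.0, abs=0.1)
    assert s.hpd_low == pytest.approx(2 - 1.96, abs=0.08)
    assert s.hpd_high == pytest.approx(2 + 1.96, abs=0.08)


def test_summary_exponential_hpd_starts_at_zero():
    x = np.random.default_rng(5).exponential(1.0, 50_000)
    s = pf.summarize_posterior(x)
    equal_tail = np.quantile(x, [0.025, 0.975])
    assert s.hpd_low < 0.01  # HPD of a decreasing density starts at the boundary
    assert (s.hpd_high - s.hpd_low) < (equal_tail[1] - equal_tail[0])


# ---------------------------------------------------------------------------
# sampler building blocks
# ---------------------------------------------------------------------------


def test_polya_gamma_moments():
    seed_polya_gamma(42)
    for z in (0.0, 1.0, 3.5):
        out = np.empty(100_000)
        pg_vector(np.full(100_000, z), out)
        true_mean = 0.25 if z == 0 else np.tanh(z / 2) / (2 * z)
        assert out.mean() == pytest.approx(true_mean, abs=4 * out.std() / np.sqrt(len(out)))
        assert out.min() > 0


@pytest.mark.parametrize("seed", [0, 6])
def test_sparse_precision_solver_matches_dense(seed):
    ped = random_pedigree(seed, n=120, p_known=0.85)
    rel = pf.additive_relationship(ped, dense=True)
    solver = PedigreePrecisionSolver(rel.A_inv)
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.1, 4.0, len(ped))
    s2 = 0.37
    solver.factor(s2, d)
    b = rng.standard_normal(len(ped))
    dense = rel.A_inv.toarray() / s2 + np.diag(d)
    assert np.allclose(solver.solve(b), np.linalg.solve(dense, b), atol=1e-10)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _sim_poisson_trait(ped, va, ve, mu, seed):
    rng = np.random.default_rng(seed)
    a = pf.drop_breeding_values(ped, va, rng)
    eta = mu + a + rng.standard_normal(len(ped)) * np.sqrt(ve)
    return pd.DataFrame(
        {"individual_id": ped.ids, "y": rng.poisson(np.exp(eta))}
    )


def test_poisson_recovery_across_replicates():
    """Simulate-and-refit a log-link trait: the posterior modes of the
    additive variance centre on the simulated value."""
    ped = pf.simulate_pedigree(
        PedigreeSimConfig(seed=1, founders_per_generation=50, initial_marked=30,
                          recruitment_prob=0.3)
    )
    spec = M.ModelSpec(
        family="poisson", response="y",
        random=(M.RandomTerm("animal", "pedigree", "individual_id"),),
    )
    modes = []
    for rep in range(6):
        df = _sim_poisson_trait(ped, va=0.3, ve=0.2, mu=0.5, seed=100 + rep)
        s = _quiet_fit(df, ped, spec, M.McmcConfig(n_iter=4500, burn_in=1500, thin=3, seed=rep))
        modes.append(s.summarize("va").mode)
        assert (s.draws["va"] >= 0).all()
    assert np.mean(modes) == pytest.approx(0.3, abs=0.12)


def test_gaussian_posterior_agrees_with_reml():
    """On a Gaussian trait the posterior mean of (va, ve) matches an
    independent dense REML fit within Monte Carlo error."""
    ped = pf.simulate_pedigree(
        PedigreeSimConfig(seed=4, founders_per_generation=25, initial_marked=15,
                          recruitment_prob=0.3)
    )
    n = len(ped)
    rng = np.random.default_rng(7)
    a = pf.drop_breeding_values(ped, 0.5, rng)
    y = 1.0 + a + rng.standard_normal(n) * np.sqrt(0.5)
    df = pd.DataFrame({"individual_id": ped.ids, "y": y})
    spec = M.ModelSpec(
        family="gaussian", response="y",
        random=(M.RandomTerm("animal", "pedigree", "individual_id"),),
    )
    s = _quiet_fit(df, ped, spec, M.McmcConfig(n_iter=6000, burn_in=1000, thin=5, seed=0))

    A = pf.additive_relationship(ped, dense=True).dense_A()
    X = np.ones((n, 1))

    def neg_reml(theta):
        va, ve = np.exp(theta)
        V = va * A + ve * np.eye(n)
        Vi = np.linalg.inv(V)
        XVX = X.T @ Vi @ X
        beta = np.linalg.solve(XVX, X.T @ Vi @ y)
        r = y - X @ beta
        _, ld = np.linalg.slogdet(V)
        _, ldx = np.linalg.slogdet(XVX)
        return 0.5 * (ld + ldx + r @ Vi @ r)

    res = optimize.minimize(neg_reml, np.log([0.3, 0.3]), method="Nelder-Mead")
    va_reml, ve_reml = np.exp(res.x)
    assert s.draws["va"].mean() == pytest.approx(va_reml, abs=0.2)
    assert s.draws["v_resid"].mean() == pytest.approx(ve_reml, abs=0.15)


def test_row_order_invariance():
    ped = pf.simulate_pedigree(
        PedigreeSimConfig(seed=2, founders_per_generation=30, initial_marked=20,
                          recruitment_prob=0.3)
    )
    df = _sim_poisson_trait(ped, 0.2, 0.2, 0.3, seed=5)
    spec = M.ModelSpec(
        family="poisson", response="y",
        random=(M.RandomTerm("animal", "pedigree", "individual_id"),),
    )
    mcmc = M.McmcConfig(n_iter=800, burn_in=300, thin=1, seed=3)
    s1 = _quiet_fit(df, ped, spec, mcmc)
    shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
    s2 = _quiet_fit(shuffled, ped, spec, mcmc)
    pd.testing.assert_frame_equal(s1.draws, s2.draws)


def test_missing_individual_raises():
    ped = pf.Pedigree(["a", "b"], [None, None], [None, None])
    df = pd.DataFrame({"individual_id": ["a", "ghost"], "y": [1, 2]})
    spec = M.ModelSpec(
        family="poisson", response="y",
        random=(M.RandomTerm("animal", "pedigree", "individual_id"),),
    )
    with pytest.raises(ValueError, match="ghost"):
        M.fit(df, ped, spec, M.McmcConfig(n_iter=200, burn_in=100, thin=1))


def test_large_mean_poisson_degenerates_safely():
    ped = pf.Pedigree([f"i{k}" for k in range(80)], [None] * 80, [None] * 80)
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {"individual_id": ped.ids, "y": rng.poisson(np.exp(3.0), 80)}
    )
    spec = M.ModelSpec(
        family="poisson", response="y",
        random=(M.RandomTerm("animal", "pedigree", "individual_id"),),
    )
    s = _quiet_fit(df, ped, spec, M.McmcConfig(n_iter=600, burn_in=200, thin=1, seed=1))
    assert np.isfinite(s.draws.to_numpy()).all()


def test_zip_fit_has_both_components():
    ped = pf.simulate_pedigree(
        PedigreeSimConfig(seed=5, founders_per_generation=40, initial_marked=25,
                          recruitment_prob=0.3)
    )
    table = pf.simulate_lifetime(ped, pf.study_default_trait_params(), seed=1)
    df = M.prepare_lifetime(table)
    s = _quiet_fit(df, ped, M.lifetime_model_spec(),
                   M.McmcConfig(n_iter=700, burn_in=300, thin=1, seed=1))
    for col in ("va_zi", "va_pois", "v_hatch_year_zi", "v_resid_pois",
                "b_Intercept_zi", "b_is_alive_pois"):
        assert col in s.draws.columns
    assert (s.draws[["va_zi", "va_pois"]] >= 0).all().all()
    assert s.fixed_resid == {"zi": 1.0, "pois": None}


def test_low_ess_warns():
    ped = pf.simulate_pedigree(
        PedigreeSimConfig(seed=2, founders_per_generation=30, initial_marked=20,
                          recruitment_prob=0.3)
    )
    df = _sim_poisson_trait(ped, 0.2, 0.2, 0.3, seed=5)
    spec = M.ModelSpec(
        family="poisson", response="y",
        random=(M.RandomTerm("animal", "pedigree", "individual_id"),),
    )
    with pytest.warns(UserWarning, match="ESS"):
        M.fit(df, ped, spec, M.McmcConfig(n_iter=700, burn_in=300, thin=1, seed=0,
                                          target_min_ess=1000))


# ---------------------------------------------------------------------------
# simulation-based calibration ("getting it right")
# ---------------------------------------------------------------------------


def test_simulation_based_calibration_rank_uniformity():
    """Draw (parameters, data) from the prior-and-likelihood, refit with the
    same priors, and check the rank of the true additive variance among the
    posterior draws is uniform (the sampler targets the right posterior)."""
    ped = random_pedigree(13, n=25, p_known=0.9)
    prior = M.VariancePrior(kind="inverse_gamma", shape=3.0, scale=1.0)
    spec = M.ModelSpec(
        family="poisson", response="y",
        random=(M.RandomTerm("animal", "pedigree", "individual_id", prior=prior),),
        prior=prior, resid_nu=6.0, resid_scale=0.5, beta_prior_var=1.0,
    )
    rng = np.random.default_rng(99)
    n_rank = 16
    ranks = []
    for rep in range(32):
        va_true = 1.0 / rng.gamma(3.0, 1.0)  # InvGamma(3, 1)
        ve_true = 1.5 / rng.gamma(3.0)  # InvGamma(3, 1.5) = prior on residual
        mu_true = rng.standard_normal()
        a = pf.drop_breeding_values(ped, va_true, rng)
        eta = mu_true + a + rng.standard_normal(len(ped)) * np.sqrt(ve_true)
        df = pd.DataFrame({"individual_id": ped.ids, "y": rng.poisson(np.exp(eta))})
        s = _quiet_fit(df, ped, spec,
                       M.McmcConfig(n_iter=3700, burn_in=500, thin=8, seed=rep))
        draws = s.draws["va"].to_numpy()[::25][:n_rank]
        ranks.append(int((draws < va_true).sum()))
    counts = np.bincount(ranks, minlength=n_rank + 1)
    from scipy.stats import chisquare

    stat, pval = chisquare(counts)
    assert pval > 0.01, f"rank histogram not uniform: {counts}"
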
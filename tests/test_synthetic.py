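"""Synthetic pedigree and phenotype generators: calibration and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import pedfit as pf
from pedfit.synthetic import PedigreeSimConfig

from conftest import random_pedigree


def small_cfg(seed=0, **kw):
    base = dict(
        seed=seed, founders_per_generation=60, initial_marked=40,
        recruitment_prob=0.28,
    )
    base.update(kw)
    return PedigreeSimConfig(**base)


def founders_only(n: int) -> pf.Pedigree:
    ids = [f"f{k}" for k in range(n)]
    return pf.Pedigree(ids, [None] * n, [None] * n, [1.0] * n)


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------


def test_single_generation_gives_founders_only():
    ped = pf.simulate_pedigree(small_cfg(n_generations=1))
    s = pf.summarize(ped)
    assert s.max_depth == 1
    assert s.n_paternities == 0 and s.n_fullsib_pairs == 0


def test_same_seed_same_pedigree():
    a = pf.simulate_pedigree(small_cfg(3))
    b = pf.simulate_pedigree(small_cfg(3))
    assert a == b
    assert a != pf.simulate_pedigree(small_cfg(4))


def test_default_config_matches_study_structure():
    """Default generator reproduces the study pedigree's headline counts
    (~6290 records, depth 5, ~2417 paternities) within a 20% envelope."""
    ped = pf.simulate_pedigree(pf.study_default_pedigree_config(seed=1))
    s = pf.summarize(ped)
    assert abs(s.n_records - 6290) / 6290 < 0.20
    assert s.max_depth == 5
    assert abs(s.n_paternities - 2417) / 2417 < 0.20
    assert abs(s.n_maternities - 2520) / 2520 < 0.20


def test_extinction_raises_helpful_error():
    cfg = small_cfg(
        founders_per_generation=1, initial_marked=1, recruitment_prob=0.0,
        n_generations=4,
    )
    with pytest.raises(RuntimeError, match="founders_per_generation"):
        pf.simulate_pedigree(cfg)


def test_extend_pedigree_identity_and_growth():
    cfg = small_cfg(5)
    ped = pf.simulate_pedigree(cfg)
    assert pf.extend_pedigree(ped, 0, cfg) is ped
    ext = pf.extend_pedigree(ped, 4, cfg)
    assert set(ped.ids) <= set(ext.ids)
    assert len(ext) > 1.5 * len(ped)
    assert pf.summarize(ext).max_depth > pf.summarize(ped).max_depth


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


def test_gene_drop_zero_variance_is_zero(rand_ped):
    assert np.all(pf.drop_breeding_values(rand_ped, 0.0, seed=1) == 0)
    with pytest.raises(ValueError):
        pf.drop_breeding_values(rand_ped, -0.1)


def test_gene_drop_founder_variance_matches():
    ped = founders_only(50)
    reps = np.array([pf.drop_breeding_values(ped, 2.0, seed=s) for s in range(400)])
    # variance of founder draws ~ va within 3 standard errors
    v = reps.var(ddof=1, axis=0).mean()
    se = 2.0 * np.sqrt(2 / (400 * 50 - 1))
    assert abs(v - 2.0) < 3 * se


def test_gene_drop_covariance_equals_va_times_A():
    ped = random_pedigree(3, n=10, p_known=0.95)
    A = pf.additive_relationship(ped, dense=True).dense_A()
    va = 1.5
    rng = np.random.default_rng(0)
    reps = np.array([pf.drop_breeding_values(ped, va, rng) for _ in range(4000)])
    emp = np.cov(reps.T)
    se = va * np.sqrt(2.0 / 4000) * np.sqrt(np.outer(np.diag(A), np.diag(A)))
    assert np.all(np.abs(emp - va * A) < 4 * se + 0.02)


# ---------------------------------------------------------------------------
# lifetime fitness
# ---------------------------------------------------------------------------


def test_lifetime_deterministic_under_seed():
    ped = pf.simulate_pedigree(small_cfg(2))
    p = pf.study_default_trait_params()
    a = pf.simulate_lifetime(ped, p, seed=9)
    b = pf.simulate_lifetime(ped, p, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_lifetime_all_structural_zero():
    ped = founders_only(200)
    p = pf.study_default_trait_params(mu_zi=40.0, v_resid_zi=0.0, v_cohort=0.0)
    table = pf.simulate_lifetime(ped, p, seed=0)
    assert (table["lifetime_fitness"] == 0).all()


def test_lifetime_zero_variance_closed_form_moments():
    """With all variances off, the zero fraction and mean follow the
    two-part mixture arithmetic exactly."""
    p_zero, lam = 0.8714, 5.62
    ped = founders_only(100_000)
    p = pf.study_default_trait_params(
        mu_zi=float(logit(p_zero)), mu_pois=float(np.log(lam)),
        v_cohort=0.0, v_resid_pois=0.0, v_resid_zi=0.0,
    )
    table = pf.simulate_lifetime(ped, p, seed=123)
    fit = table["lifetime_fitness"].to_numpy()
    expected_zero = p_zero + (1 - p_zero) * np.exp(-lam)
    expected_mean = (1 - p_zero) * lam
    assert (fit == 0).mean() == pytest.approx(expected_zero, abs=0.004)
    assert fit.mean() == pytest.approx(expected_mean, abs=0.025)


def test_lifetime_default_range_reaches_high_counts():
    ped = pf.simulate_pedigree(pf.study_default_pedigree_config(seed=2))
    table = pf.simulate_lifetime(ped, pf.study_default_trait_params(), seed=5)
    assert table["lifetime_fitness"].max() >= 20


def test_latent_parent_offspring_resemblance():
    """Midparent regression of emitted breeding values has slope ~1;
    single-parent regression ~1/2 (transmission of additive values)."""
    ped = pf.simulate_pedigree(small_cfg(8, founders_per_generation=150, initial_marked=80))
    table = pf.simulate_lifetime(
        ped, pf.study_default_trait_params(va_zi=1.0), seed=2, emit_latent=True
    )
    bv = table.set_index("individual_id")["breeding_value_zi"]
    pairs = []
    for i in range(len(ped)):
        d = ped.dam[i]
        if d >= 0:
            pairs.append((bv[ped.ids[d]], bv[ped.ids[i]]))
    x, y = np.array(pairs).T
    slope = np.cov(x, y)[0, 1] / np.var(x)
    assert slope == pytest.approx(0.5, abs=0.12)


# ---------------------------------------------------------------------------
# inclusion filter
# ---------------------------------------------------------------------------


def test_inclusion_filter_rules():
    table = pd.DataFrame(
        {
            "individual_id": ["dead_young", "alive_young", "alive_old"],
            "hatch_year": [2010.0, 2011.0, 2005.0],
            "lifetime_fitness": [0, 2, 5],
            "status": ["dead", "alive", "alive"],
            "last_seen_year": [2012.0, 2019.0, 2019.0],
        }
    )
    out = pf.apply_inclusion_filter(table, study_end_year=2019, min_age=11)
    kept = set(out["individual_id"])
    assert kept == {"dead_young", "alive_old"}
    assert (out.loc[out.individual_id == "alive_old", "status"] == "alive").all()


# ---------------------------------------------------------------------------
# annual components
# ---------------------------------------------------------------------------


def test_annual_invariants_and_determinism():
    ped = pf.simulate_pedigree(small_cfg(4))
    p = pf.study_default_annual_params()
    a = pf.simulate_annual(ped, p, seed=3)
    b = pf.simulate_annual(ped, p, seed=3)
    pd.testing.assert_frame_equal(a, b)
    assert a["ars"].between(0, 3).all()
    assert set(a["aas"].unique()) <= {0, 1}
    for _, grp in a.groupby("individual_id"):
        ages = grp["age"].to_numpy()
        assert (np.diff(ages) == 1).all() and ages[0] == 1
        assert (grp["aas"].to_numpy()[:-1] == 1).all()
        assert grp["aas"].to_numpy()[-1] == 0


def test_annual_all_survive_to_max_age():
    ped = founders_only(30)
    p = pf.study_default_annual_params(mu_aas=60.0, v_resid_aas=0.0,
                                       v_pe_aas=0.0, v_year_aas=0.0, beta_age_aas=0.0)
    table = pf.simulate_annual(ped, p, seed=1)
    assert (table.groupby("individual_id")["age"].max() == p.max_age).all()


def test_annual_zero_variance_truncated_poisson_mean():
    """With variances and age effects off, mean ARS equals the closed-form
    mean of a Poisson truncated at the maximum brood size."""
    lam = 0.8
    ped = founders_only(4000)
    p = pf.study_default_annual_params(
        mu_ars=float(np.log(lam)), beta_age_ars=0.0,
        v_pe_ars=0.0, v_year_ars=0.0, v_resid_ars=0.0,
    )
    table = pf.simulate_annual(ped, p, seed=11)
    from scipy.stats import poisson

    k = np.arange(0, 3)
    expected = float((k * poisson.pmf(k, lam)).sum() + 3 * poisson.sf(2, lam))
    assert table["ars"].mean() == pytest.approx(expected, abs=0.02)
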
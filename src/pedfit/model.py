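"""Bayesian animal models for non-Gaussian fitness data.

Implements Markov chain Monte Carlo fitting of univariate animal models with
pedigree-structured additive genetic effects for

* zero-inflated Poisson responses (lifetime fitness: a logit-linked
  structural-zero component and a log-linked, overdispersed Poisson count
  component, each with its own latent linear predictor),
* Poisson responses with a log link (annual reproductive success),
* binary responses with a logit link (annual survival; residual variance
  fixed to one, the usual identifiability constraint), and
* a Gaussian family used internally for validation against restricted
  maximum likelihood.

The sampler is a Metropolis-within-Gibbs scheme on the latent scale.  Each
observation carries a latent value ``eta`` (linear predictor plus residual);
given ``eta`` the model is linear-Gaussian, so fixed effects, random
effects and variance components have conjugate updates — all breeding
values are drawn jointly each iteration by perturb-and-solve sampling with
a fixed-pattern sparse Cholesky of the mixed-model precision (the sparse
inverse relationship matrix plus a diagonal data term), which is what makes
the variance components mix.  Logit-linked latents are Gibbs-updated
exactly via Polya-Gamma augmentation; log-linked (count) latents use
element-wise adaptive random-walk Metropolis steps (tuned during burn-in
only), which leaves the correct stationary distribution.
Variance components use parameter expansion: a random effect enters the
predictor as ``xi * u`` with ``u ~ N(0, s2 * structure)``; with
``xi ~ N(0, scale^2)`` and ``s2 ~ InvGamma(nu/2, nu/2)`` the implied prior
on the effect's standard deviation ``|xi| sqrt(s2)`` is half-t with ``nu``
degrees of freedom (half-Cauchy for ``nu = 1``), and the global ``xi`` move
greatly improves mixing of near-zero variance components.

Zero-inflated models are fitted by data augmentation: each zero observation
carries an indicator of whether it is a structural zero, sampled from its
conditional probability each iteration; the indicator is the response of
the logit component while the count likelihood applies only to
non-structural rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse, stats
from scipy.special import expit, kv, gammaln

from ._polya_gamma import pg_vector, seed_polya_gamma
from ._sparse_chol import PedigreePrecisionSolver
from .pedigree import Pedigree, additive_relationship

__all__ = [
    "VariancePrior",
    "RandomTerm",
    "ModelSpec",
    "McmcConfig",
    "PosteriorSamples",
    "PosteriorSummary",
    "fit",
    "diagnostics",
    "effective_sample_size",
    "heidelberger_welch",
    "summarize_posterior",
    "hpd_interval",
    "posterior_mode",
    "lifetime_model_spec",
    "ars_model_spec",
    "aas_model_spec",
    "prepare_lifetime",
    "prepare_annual",
]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariancePrior:
    """Prior on one variance component.

    ``kind="px_half_t"``: parameter-expanded half-t prior on the standard
    deviation with ``nu`` degrees of freedom and the given ``scale``
    (``nu=1`` gives a half-Cauchy).  ``kind="px_half_normal"``: parameter
    expansion with the mixing scale fixed, giving a half-normal prior on the
    standard deviation — a non-centred parameterisation that regularises the
    weakly identified latent scale of near-saturated binary traits.
    ``kind="inverse_gamma"``: a plain conjugate inverse-gamma(shape, scale)
    prior without parameter expansion (useful for calibration studies where
    the prior must be easy to sample).
    """

    kind: str = "px_half_t"
    nu: float = 1.0
    scale: float = 1.0
    shape: float = 3.0  # inverse_gamma only

    def __post_init__(self):
        if self.kind not in ("px_half_t", "px_half_normal", "inverse_gamma"):
            raise ValueError(f"unknown prior kind {self.kind!r}")


@dataclass(frozen=True)
class RandomTerm:
    """One random-intercept term.

    ``structure`` is "pedigree" (covariance proportional to the additive
    relationship matrix ``A``; the grouping column must hold pedigree ids)
    or "iid".  For zero-inflated models ``applies_to`` selects the
    component(s) the term enters; an independent effect vector is fitted per
    component (no cross-component covariance).
    """

    name: str
    structure: str
    column: str
    applies_to: str = "both"
    prior: VariancePrior | None = None

    def __post_init__(self):
        if self.structure not in ("pedigree", "iid"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.applies_to not in ("both", "zi", "pois"):
            raise ValueError(f"unknown applies_to {self.applies_to!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Family, fixed terms and random terms of an animal model."""

    family: str
    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[RandomTerm, ...] = ()
    prior: VariancePrior = VariancePrior()
    resid_nu: float = 0.002  # inverse-gamma prior df for estimated residuals
    resid_scale: float = 1.0
    beta_prior_var: float = 100.0

    def __post_init__(self):
        if self.family not in ("zipoisson", "poisson", "binary", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        n_ped = {}
        for comp in self.components:
            n_ped[comp] = sum(
                1 for t in self.random
                if t.structure == "pedigree" and _applies(t, comp)
            )
        if self.random and any(v > 1 for v in n_ped.values()):
            raise ValueError("at most one pedigree-structured term per component")

    @property
    def components(self) -> tuple[str, ...]:
        return ("zi", "pois") if self.family == "zipoisson" else ("single",)

    def residual_fixed(self, comp: str) -> bool:
        """Residual variance fixed to 1? (binary likelihood / logit latent)."""
        if self.family == "zipoisson":
            return comp == "zi"
        return self.family == "binary"


def _applies(term: RandomTerm, comp: str) -> bool:
    return comp == "single" or term.applies_to in ("both", comp)


@dataclass(frozen=True)
class McmcConfig:
    """Chain length and bookkeeping for one MCMC run."""

    n_iter: int = 23000
    burn_in: int = 5000
    thin: int = 18
    seed: int = 0
    target_min_ess: float = 1000.0
    n_eta_updates: int = 4  # Metropolis sweeps per iteration for count latents

    def __post_init__(self):
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


# -- canonical model builders ------------------------------------------------


def lifetime_model_spec(
    extra_random: tuple[RandomTerm, ...] = (),
    prior: VariancePrior = VariancePrior(),
) -> ModelSpec:
    """Zero-inflated Poisson model of lifetime fitness.

    Fixed effects: intercept and dead/alive status; random effects: additive
    genetic (pedigree) and hatch-cohort intercepts on both components.
    ``extra_random`` can add e.g. iid parental or brood effects.
    """
    return ModelSpec(
        family="zipoisson",
        response="lifetime_fitness",
        fixed=("is_alive",),
        random=(
            RandomTerm("animal", "pedigree", "individual_id", "both"),
            RandomTerm("hatch_year", "iid", "hatch_cohort", "both"),
        )
        + tuple(extra_random),
        prior=prior,
    )


def ars_model_spec(prior: VariancePrior = VariancePrior()) -> ModelSpec:
    """Poisson (log link) model of annual reproductive success."""
    return ModelSpec(
        family="poisson",
        response="ars",
        fixed=("age_c",),
        random=(
            RandomTerm("animal", "pedigree", "individual_id"),
            RandomTerm("pe", "iid", "individual_id"),
            RandomTerm("year", "iid", "year"),
        ),
        prior=prior,
    )


def aas_model_spec(prior: VariancePrior = VariancePrior()) -> ModelSpec:
    """Binary (logit link) model of adult annual survival."""
    return ModelSpec(
        family="binary",
        response="aas",
        fixed=("age_c",),
        random=(
            RandomTerm("animal", "pedigree", "individual_id"),
            RandomTerm("pe", "iid", "individual_id"),
            RandomTerm("year", "iid", "year"),
        ),
        prior=prior,
    )


def prepare_lifetime(table: pd.DataFrame) -> pd.DataFrame:
    """Add the model columns for the lifetime spec (is_alive, hatch_cohort)."""
    out = table.copy()
    out["is_alive"] = (out["status"] == "alive").astype(float)
    out["hatch_cohort"] = out["hatch_year"].map(
        lambda v: "prestudy" if pd.isna(v) else str(int(v))
    )
    return out


def prepare_annual(table: pd.DataFrame) -> pd.DataFrame:
    """Add the model columns for the annual specs (age_c = age - 1)."""
    out = table.copy()
    out["age_c"] = out["age"].astype(float) - 1.0
    return out


# ---------------------------------------------------------------------------
# Posterior containers and summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PosteriorSummary:
    """Kernel-density posterior mode, 95% HPD interval and mean."""

    mode: float
    hpd_low: float
    hpd_high: float
    mean: float


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing *prob* of the draws (HPD)."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def posterior_mode(draws: np.ndarray, grid_size: int = 1024) -> float:
    """Mode of a Gaussian-kernel density estimate (Silverman bandwidth).

    Near-boundary variance posteriors make the mode bandwidth-sensitive;
    Silverman's rule on the retained draws is used throughout so modes are
    comparable across models.
    """
    x = np.asarray(draws, dtype=float)
    if np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])


def summarize_posterior(draws: np.ndarray, prob: float = 0.95) -> PosteriorSummary:
    """Posterior mode (KDE argmax), HPD interval and mean of a draw vector."""
    x = np.asarray(draws, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 draws")
    lo, hi = hpd_interval(x, prob)
    return PosteriorSummary(
        mode=posterior_mode(x), hpd_low=lo, hpd_high=hi, mean=float(x.mean())
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS of a single chain (autocorrelation-based, via arviz)."""
    x = np.asarray(chain, dtype=float)
    if np.ptp(x) == 0:
        return float(len(x))
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x[None, :]))


def _pcramer(q: float, n_terms: int = 12) -> float:
    """CDF of the limiting Cramer-von Mises distribution at *q*."""
    if q <= 0:
        return 0.0
    if q >= 3.0:
        return 1.0  # limit distribution has negligible mass above 3
    total = 0.0
    for k in range(n_terms):
        z = (4 * k + 1) ** 2 / (16.0 * q)
        term = (
            np.exp(gammaln(k + 0.5) - gammaln(k + 1))
            * np.sqrt(4 * k + 1)
            / (np.pi**1.5 * np.sqrt(q))
            * np.exp(-z)
            * kv(0.25, z)
        )
        total += term
    return float(min(max(total, 0.0), 1.0))


def heidelberger_welch(chain: np.ndarray, alpha: float = 0.05) -> bool:
    """Stationarity test of Heidelberger & Welch (Cramer-von Mises form).

    The cumulative-sum Brownian bridge of the whole retained chain is
    compared against the Cramer-von Mises limit distribution, with the
    spectral density at zero estimated from the final half of the chain
    (presumed closest to stationarity, so an initial transient inflates the
    bridge rather than the normalisation).  Returns ``True`` when the chain
    is consistent with stationarity at level *alpha*.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 draws")
    if np.ptp(x) == 0:
        return True
    tail = x[n // 2:]
    s0 = np.var(tail) * len(tail) / max(effective_sample_size(tail), 1.0)
    if s0 <= 0:
        return True
    csum = np.cumsum(x) - np.arange(1, n + 1) * x.mean()
    cvm = float(np.mean((csum / np.sqrt(n * s0)) ** 2))
    return 1.0 - _pcramer(cvm) >= alpha


def diagnostics(chain: np.ndarray) -> tuple[float, float, bool]:
    """(ESS, lag-1 autocorrelation, Heidelberger-Welch pass) for one chain."""
    x = np.asarray(chain, dtype=float)
    if len(x) < 100:
        raise ValueError("need at least 100 draws")
    if np.ptp(x) == 0:
        warnings.warn("constant chain: reporting ESS = draw count (degenerate)")
        return float(len(x)), 0.0, True
    ess = effective_sample_size(x)
    ac1 = float(np.corrcoef(x[:-1], x[1:])[0, 1])
    return ess, ac1, heidelberger_welch(x)


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

_FAM_POISSON = 0
_FAM_BINARY = 1


@njit(cache=True)
def _loglik(y, eta, fam):  # pragma: no cover - exercised via sampler
    if fam == _FAM_POISSON:
        return y * eta - np.exp(eta)
    # binary, logit link: y*eta - log(1 + e^eta), numerically stable
    if eta > 0.0:
        return y * eta - eta - np.log1p(np.exp(-eta))
    return y * eta - np.log1p(np.exp(eta))


@njit(cache=True)
def _mh_eta(eta, m, ve, y, active, fam, step, zn, zu, acc):  # pragma: no cover
    """Element-wise random-walk MH update of latent values (active rows)."""
    n = eta.shape[0]
    for i in range(n):
        if not active[i]:
            continue
        prop = eta[i] + step[i] * zn[i]
        d_prior = ((prop - m[i]) ** 2 - (eta[i] - m[i]) ** 2) / (2.0 * ve)
        d_lik = _loglik(y[i], prop, fam) - _loglik(y[i], eta[i], fam)
        if np.log(zu[i]) < d_lik - d_prior:
            eta[i] = prop
            acc[i] += 1


@njit(cache=True)
def _gene_drop(dam, sire, d, s2, zn):  # pragma: no cover
    """Prior draw a ~ N(0, s2 A) down the pedigree (Mendelian sampling)."""
    n = dam.shape[0]
    a = np.empty(n)
    for i in range(n):
        mid = 0.0
        if sire[i] >= 0:
            mid += 0.5 * a[sire[i]]
        if dam[i] >= 0:
            mid += 0.5 * a[dam[i]]
        a[i] = mid + np.sqrt(s2 * d[i]) * zn[i]
    return a


@njit(cache=True)
def _draw_eta_given_zero(m, ve, rows, eta):  # pragma: no cover
    """Draw eta ~ N(m, ve) tilted by the Poisson zero likelihood e^-exp(eta).

    Exact rejection sampling (acceptance probability e^-exp(eta) <= 1) with
    a Laplace-approximation fallback for pathologically unlikely rows.
    """
    sd = np.sqrt(ve)
    for k in range(rows.shape[0]):
        r = rows[k]
        done = False
        for _ in range(300):
            e = m[r] + sd * np.random.standard_normal()
            if np.log(np.random.random()) < -np.exp(e):
                eta[r] = e
                done = True
                break
        if not done:
            # Newton solve for the mode of N(m, ve) * e^-exp(eta)
            x = min(m[r], 0.0)
            for _ in range(30):
                g = -(x - m[r]) / ve - np.exp(x)
                h = -1.0 / ve - np.exp(x)
                x -= g / h
            eta[r] = x + np.random.standard_normal() / np.sqrt(-h)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(21)


def _prob_zero_marginal(m: np.ndarray, ve: float) -> np.ndarray:
    """E[exp(-exp(eta))] for eta ~ N(m, ve), by Gauss-Hermite quadrature."""
    x = m[None, :] + np.sqrt(2.0 * ve) * _GH_NODES[:, None]
    return (_GH_WEIGHTS[:, None] * np.exp(-np.exp(x))).sum(axis=0) / np.sqrt(np.pi)


# ---------------------------------------------------------------------------
# Sampler internals
# ---------------------------------------------------------------------------


class _PedigreeMachinery:
    """Shared sparse solver and gene-dropping arrays for pedigree terms."""

    def __init__(self, ped: Pedigree, rel):
        self.solver = PedigreePrecisionSolver(rel.A_inv)
        self.Q = rel.A_inv
        self.dam = ped.dam
        self.sire = ped.sire
        self.d = rel.mendelian_variance


class _TermState:
    """Runtime state of one random term within one model component.

    All updates condition on Gaussian working observations with per-row
    precision ``d`` (homoscedastic 1/ve for count latents; Polya-Gamma
    pseudo-data precision for logit components, where the latent has been
    integrated out analytically).
    """

    def __init__(self, term: RandomTerm, codes, q, machinery, prior, rng):
        self.term = term
        self.codes_full = codes  # level per row of the full table
        self.codes = codes  # level per currently-active row
        self.q = q
        self.ped = machinery  # _PedigreeMachinery or None for iid
        self.prior = prior
        self.u = np.zeros(q)
        self.px = prior.kind in ("px_half_t", "px_half_normal")
        self.fixed_s2 = prior.kind == "px_half_normal"
        self.xi = 1.0 if not self.px else 0.3 * prior.scale
        self.s2 = 1.0 if self.fixed_s2 else 0.1
        self.rw_step = 1.0
        self.rw_acc = 0
        self.rw_tries = 0

    def set_active(self, idx: np.ndarray) -> None:
        self.codes = self.codes_full[idx]

    @property
    def variance(self) -> float:
        return self.xi * self.xi * self.s2

    def _log_prior_s2(self, s2: float) -> float:
        if self.px:
            shape, rate = 0.5 * self.prior.nu, 0.5 * self.prior.nu
        else:
            shape, rate = self.prior.shape, self.prior.scale
        return -(shape + 1.0) * np.log(s2) - rate / s2

    def _marginal_loglik(self, s2, zy, dsum):
        """log p(working data | s2, xi) with the term's effects integrated out.

        ``zy = Z' D y`` and ``dsum = Z' D 1`` are the weighted sufficient
        statistics; uses the determinant/Woodbury identities on the
        mixed-model precision ``C = Q/s2 + xi^2 Z'DZ``.  Additive constants
        not involving ``s2`` are dropped.
        """
        b = self.xi * zy
        dvec = self.xi * self.xi * dsum
        if self.ped is not None:
            self.ped.solver.factor(s2, dvec)
            logdet_c = 2.0 * np.sum(
                np.log(self.ped.solver.pattern.lx[self.ped.solver.diag_pos])
            )
            quad = float(b @ self.ped.solver.solve(b))
        else:
            c = dvec + 1.0 / s2
            logdet_c = float(np.sum(np.log(c)))
            quad = float(b @ (b / c))
        return -0.5 * (logdet_c + self.q * np.log(s2) - quad)

    def update_scale_marginal(self, resid, d, rng, adapt: bool):
        """Marginal random-walk MH on the term's scale, effects integrated out.

        For free-scale priors the move is on log s2; for fixed-scale
        (half-normal) parameter expansion it is on log |xi| — the centred
        companion step that keeps strongly informed components mixing.
        """
        if self.fixed_s2:
            self._update_xi_marginal(resid, d, rng, adapt)
            return
        partial = resid + self.xi * self.u[self.codes]
        zy = np.bincount(self.codes, weights=d * partial, minlength=self.q)
        dsum = np.bincount(self.codes, weights=d, minlength=self.q)
        cur = self._marginal_loglik(self.s2, zy, dsum) + self._log_prior_s2(self.s2)
        prop = self.s2 * np.exp(self.rw_step * rng.standard_normal())
        new = self._marginal_loglik(prop, zy, dsum) + self._log_prior_s2(prop)
        self.rw_tries += 1
        # log(prop/s2) is the Jacobian of the log-scale random walk
        if np.log(rng.random()) < new - cur + np.log(prop) - np.log(self.s2):
            self.s2 = prop
            self.rw_acc += 1
        if adapt and self.rw_tries >= 50:
            rate = self.rw_acc / self.rw_tries
            self.rw_step = float(
                np.clip(self.rw_step * np.exp(0.9 * (rate - 0.44)), 0.05, 5.0)
            )
            self.rw_acc = 0
            self.rw_tries = 0

    def _update_xi_marginal(self, resid, d, rng, adapt: bool):
        partial = resid + self.xi * self.u[self.codes]
        zy = np.bincount(self.codes, weights=d * partial, minlength=self.q)
        dsum = np.bincount(self.codes, weights=d, minlength=self.q)

        def mll(xi):
            b = xi * zy
            dvec = xi * xi * dsum
            if self.ped is not None:
                self.ped.solver.factor(self.s2, dvec)
                logdet_c = 2.0 * np.sum(
                    np.log(self.ped.solver.pattern.lx[self.ped.solver.diag_pos])
                )
                quad = float(b @ self.ped.solver.solve(b))
            else:
                c = dvec + 1.0 / self.s2
                logdet_c = float(np.sum(np.log(c)))
                quad = float(b @ (b / c))
            prior = -0.5 * xi * xi / (self.prior.scale**2)
            return -0.5 * (logdet_c - quad) + prior

        cur = mll(self.xi)
        prop = self.xi * np.exp(self.rw_step * rng.standard_normal())
        new = mll(prop)
        self.rw_tries += 1
        if np.log(rng.random()) < new - cur + np.log(abs(prop)) - np.log(abs(self.xi)):
            self.xi = prop
            self.rw_acc += 1
        if adapt and self.rw_tries >= 50:
            rate = self.rw_acc / self.rw_tries
            self.rw_step = float(
                np.clip(self.rw_step * np.exp(0.9 * (rate - 0.44)), 0.05, 5.0)
            )
            self.rw_acc = 0
            self.rw_tries = 0

    def update_u(self, resid, d, rng):
        """Joint draw of the effect vector by perturb-and-solve."""
        partial = resid + self.xi * self.u[self.codes]
        dsum = np.bincount(self.codes, weights=d, minlength=self.q)
        if self.ped is not None:
            zn = rng.standard_normal(self.q)
            a0 = _gene_drop(self.ped.dam, self.ped.sire, self.ped.d, self.s2, zn)
            e1 = rng.standard_normal(len(partial)) / np.sqrt(d)
            yv = partial - self.xi * a0[self.codes] + e1
            rhs = self.xi * np.bincount(self.codes, weights=d * yv, minlength=self.q)
            self.ped.solver.factor(self.s2, self.xi * self.xi * dsum)
            new = a0 + self.ped.solver.solve(rhs)
        else:
            sums = np.bincount(self.codes, weights=d * partial, minlength=self.q)
            prec = self.xi * self.xi * dsum + 1.0 / self.s2
            mean = self.xi * sums / prec
            new = mean + rng.standard_normal(self.q) / np.sqrt(prec)
        self.u = new
        np.subtract(partial, self.xi * new[self.codes], out=resid)

    def update_xi(self, resid, d, rng):
        if not self.px:
            return
        w = self.u[self.codes]
        partial = resid + self.xi * w
        prec = w @ (d * w) + 1.0 / (self.prior.scale**2)
        mean = (w @ (d * partial)) / prec
        new = mean + rng.standard_normal() / np.sqrt(prec)
        np.subtract(partial, new * w, out=resid)
        self.xi = new

    def update_s2(self, rng):
        if self.fixed_s2:
            return
        if self.ped is not None:
            qf = float(self.u @ (self.ped.Q @ self.u))
        else:
            qf = float(self.u @ self.u)
        if self.px:
            shape = 0.5 * (self.prior.nu + self.q)
            rate = 0.5 * (self.prior.nu + qf)
        else:
            shape = self.prior.shape + 0.5 * self.q
            rate = self.prior.scale + 0.5 * qf
        self.s2 = rate / rng.gamma(shape)


class _CompState:
    """Runtime state of one model component (zi / pois / single)."""

    def __init__(self, comp, X, y, fam, resid_fixed, terms, rng):
        n = len(y)
        self.comp = comp
        self.X = X
        self.y = y.astype(np.float64)
        self.fam = fam
        self.resid_fixed = resid_fixed
        self.terms = terms
        self.beta = np.zeros(X.shape[1])
        self.ve = 1.0 if resid_fixed else 0.5
        self.active = np.ones(n, dtype=np.bool_)
        self.idx = np.arange(n)
        if fam == _FAM_POISSON:
            self.eta = np.log(self.y + 0.5)
        else:
            self.eta = np.where(self.y > 0, 0.5, -0.5)
        self.step = np.full(n, 1.2)
        self.acc = np.zeros(n, dtype=np.int64)
        self.pg_w = np.full(n, 0.25)
        self.ridge_step = 0.1
        self.ridge_acc = 0
        self.ridge_tries = 0

    def fitted(self):
        """Linear predictor for every row (full table)."""
        m = self.X @ self.beta
        for t in self.terms:
            m = m + t.xi * t.u[t.codes_full]
        return m

    def label(self, base: str) -> str:
        return base if self.comp == "single" else f"{base}_{self.comp}"

    def ridge_move(self, beta_prior_var, rng, adapt: bool):
        """Joint rescaling of all location effects for logit components.

        For strongly heritable binary traits the likelihood is nearly
        invariant to a common rescaling of the linear predictor (only the
        unit residual anchors the latent scale), producing a posterior ridge
        that element-wise updates traverse extremely slowly.  This Metropolis
        move proposes (beta, u, s2) -> (c beta, c u, c^2 s2) with the latent
        residual kept fixed, with the exact Jacobian/prior correction, and
        mixes the chain along the ridge.
        """
        m = self.fitted()
        logc = self.ridge_step * rng.standard_normal()
        c = np.exp(logc)
        eta_prop = self.eta + (c - 1.0) * m
        y = self.y
        # Bernoulli-logit log-likelihood difference, stable form
        def _ll(e):
            return y @ e - np.logaddexp(0.0, e).sum()
        delta = _ll(eta_prop) - _ll(self.eta)
        delta += (1.0 - c * c) * (self.beta @ self.beta) / (2.0 * beta_prior_var)
        delta += len(self.beta) * logc
        for t in self.terms:
            delta += t._log_prior_s2(c * c * t.s2) - t._log_prior_s2(t.s2)
            delta += 2.0 * logc
        self.ridge_tries += 1
        if np.log(rng.random()) < delta:
            self.beta = c * self.beta
            for t in self.terms:
                t.u = c * t.u
                t.s2 = c * c * t.s2
            self.eta = eta_prop
            self.ridge_acc += 1
        if adapt and self.ridge_tries >= 50:
            rate = self.ridge_acc / self.ridge_tries
            self.ridge_step = float(
                np.clip(self.ridge_step * np.exp(0.9 * (rate - 0.35)), 0.005, 1.0)
            )
            self.ridge_acc = 0
            self.ridge_tries = 0


def _factorize_column(values) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(values, sort=True)
    if (codes < 0).any():
        raise ValueError("missing values in a random-term grouping column")
    return codes.astype(np.int64), len(uniques)


def fit(
    phenotypes: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
    mcmc: McmcConfig,
    gaussian_response: bool = False,
) -> "PosteriorSamples":
    """Fit an animal model by MCMC and return retained posterior draws.

    Rows are re-sorted internally to a canonical order (pedigree index,
    then remaining columns), so the result is invariant to the input row
    order.  Every phenotyped individual must appear in the pedigree.
    Warns (but still returns) if any parameter's ESS falls short of
    ``mcmc.target_min_ess``.
    """
    rng = np.random.default_rng(mcmc.seed)
    seed_polya_gamma(int(rng.integers(2**31 - 1)))

    df = phenotypes.copy()
    missing = [i for i in df["individual_id"].astype(str) if i not in ped]
    if missing:
        raise ValueError(
            f"{len(missing)} phenotyped individual(s) missing from pedigree "
            f"(first: {missing[0]!r})"
        )
    df["_ped_idx"] = ped.indices_of(df["individual_id"])
    sort_cols = ["_ped_idx"] + (["year"] if "year" in df.columns else [])
    df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    n = len(df)

    y = df[spec.response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(n)] + [df[c].to_numpy(dtype=float) for c in spec.fixed]
    )

    machinery = None
    comps = []
    for comp in spec.components:
        terms = []
        for term in spec.random:
            if not _applies(term, comp):
                continue
            prior = term.prior or spec.prior
            if term.structure == "pedigree":
                if machinery is None:
                    machinery = _PedigreeMachinery(ped, additive_relationship(ped))
                codes = df["_ped_idx"].to_numpy(dtype=np.int64)
                terms.append(_TermState(term, codes, len(ped), machinery, prior, rng))
            else:
                codes, q = _factorize_column(df[term.column])
                terms.append(_TermState(term, codes, q, None, prior, rng))
        if spec.family == "zipoisson":
            fam = _FAM_BINARY if comp == "zi" else _FAM_POISSON
            y_comp = (y == 0).astype(float) if comp == "zi" else y
        elif spec.family == "binary":
            fam, y_comp = _FAM_BINARY, y
        else:
            fam, y_comp = _FAM_POISSON, y
        comps.append(
            _CompState(comp, X, y_comp, fam, spec.residual_fixed(comp), terms, rng)
        )

    is_zip = spec.family == "zipoisson"
    is_gauss = spec.family == "gaussian" or gaussian_response
    if is_gauss:
        for c in comps:
            c.eta = y.copy()
    if is_zip:
        zi, po = comps
        z = (y == 0).astype(np.float64)  # structural-zero indicator
        zi.y = z
        po.idx = np.flatnonzero(z == 0.0)
        po.active = z == 0.0
        for t in po.terms:
            t.set_active(po.idx)
    zero_rows = np.flatnonzero(y == 0)

    fixed_names = ("Intercept",) + spec.fixed
    records: dict[str, np.ndarray] = {}
    n_draws = mcmc.n_draws
    for c in comps:
        for name in fixed_names:
            records[c.label(f"b_{name}")] = np.empty(n_draws)
        for t in c.terms:
            records[c.label(_var_name(t.term))] = np.empty(n_draws)
        if not c.resid_fixed:
            records[c.label("v_resid")] = np.empty(n_draws)

    adapt_block = 100
    k = 0
    for it in range(mcmc.n_iter):
        # 1. structural-zero augmentation, with the count latent of zero
        #    rows integrated out (collapsed), then imputed by rejection
        if is_zip and len(zero_rows):
            m_po = po.fitted()
            g = _prob_zero_marginal(m_po[zero_rows], po.ve)
            p = expit(zi.eta[zero_rows])
            prob = p / (p + (1.0 - p) * g)
            znew = rng.random(len(zero_rows)) < prob
            z[zero_rows] = znew
            zi.y[zero_rows] = znew
            po.active[zero_rows] = ~znew
            po.idx = np.flatnonzero(po.active)
            for t in po.terms:
                t.set_active(po.idx)
            fresh = zero_rows[~znew]
            _draw_eta_given_zero(m_po, po.ve, fresh, po.eta)

        # 2. count latents by adaptive element-wise Metropolis (active rows)
        if not is_gauss:
            for c in comps:
                if c.fam != _FAM_POISSON:
                    continue
                m = c.fitted()
                for _ in range(mcmc.n_eta_updates):
                    zn = rng.standard_normal(n)
                    zu = rng.random(n)
                    _mh_eta(
                        c.eta, m, c.ve, c.y, c.active, c.fam, c.step, zn, zu, c.acc
                    )
                if it < mcmc.burn_in and (it + 1) % adapt_block == 0:
                    rate = c.acc / (adapt_block * mcmc.n_eta_updates)
                    c.step *= np.exp(0.8 * (rate - 0.44))
                    np.clip(c.step, 0.05, 10.0, out=c.step)
                    c.acc[:] = 0

        # 3. linear-Gaussian block on the working observations.
        #    Logit components: w ~ PG(1, eta), then the latent is integrated
        #    out, leaving pseudo-data (y - 1/2)/w with variance ve + 1/w.
        #    Count components: the working observation is eta itself.
        for c in comps:
            idx = c.idx
            whole = len(idx) == n
            if is_gauss:
                work_y = y
                d = np.full(n, 1.0 / c.ve)
            elif c.fam == _FAM_BINARY:
                m = c.fitted()
                pg_vector(c.eta, c.pg_w)
                work_y = (c.y - 0.5) / c.pg_w
                d = 1.0 / (c.ve + 1.0 / c.pg_w)
            else:
                work_y = c.eta if whole else c.eta[idx]
                d = np.full(len(idx), 1.0 / c.ve)
            Xa = c.X if whole else c.X[idx]
            ra = work_y - (c.fitted() if whole else c.fitted()[idx])

            partial = ra + Xa @ c.beta
            wX = Xa * d[:, None]
            prec = Xa.T @ wX + np.eye(Xa.shape[1]) / spec.beta_prior_var
            mean = np.linalg.solve(prec, wX.T @ partial)
            L = np.linalg.cholesky(np.linalg.inv(prec))
            c.beta = mean + L @ rng.standard_normal(len(mean))
            ra = partial - Xa @ c.beta
            for t in c.terms:
                t.update_scale_marginal(ra, d, rng, adapt=it < mcmc.burn_in)
                t.update_u(ra, d, rng)
                t.update_xi(ra, d, rng)
                t.update_s2(rng)
            if not c.resid_fixed and c.fam == _FAM_POISSON:
                sse = float(ra @ ra)
                shape = 0.5 * (len(idx) + spec.resid_nu)
                rate = 0.5 * (sse + spec.resid_nu * spec.resid_scale)
                c.ve = rate / rng.gamma(shape)
            elif is_gauss and not c.resid_fixed:
                sse = float(ra @ ra)
                shape = 0.5 * (n + spec.resid_nu)
                rate = 0.5 * (sse + spec.resid_nu * spec.resid_scale)
                c.ve = rate / rng.gamma(shape)

            if c.fam == _FAM_BINARY and not is_gauss:
                # re-impute the logit latent given the Polya-Gamma weights
                m = c.fitted()
                prec_e = c.pg_w + 1.0 / c.ve
                mean_e = (c.y - 0.5 + m / c.ve) / prec_e
                c.eta = mean_e + rng.standard_normal(n) / np.sqrt(prec_e)
                if all(not t.fixed_s2 for t in c.terms):
                    c.ridge_move(spec.beta_prior_var, rng, adapt=it < mcmc.burn_in)

        # 4. record
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and k < n_draws:
            for c in comps:
                for j, name in enumerate(fixed_names):
                    records[c.label(f"b_{name}")][k] = c.beta[j]
                for t in c.terms:
                    records[c.label(_var_name(t.term))][k] = t.variance
                if not c.resid_fixed:
                    records[c.label("v_resid")][k] = c.ve
            k += 1

    draws = pd.DataFrame({name: col[:k] for name, col in records.items()})
    samples = PosteriorSamples(
        draws=draws,
        family=spec.family,
        components=spec.components,
        fixed_resid={
            c.comp: (1.0 if c.resid_fixed else None) for c in comps
        },
        meta={
            "n_obs": int(n),
            "n_pedigree": len(ped),
            "n_iter": mcmc.n_iter,
            "burn_in": mcmc.burn_in,
            "thin": mcmc.thin,
            "seed": mcmc.seed,
            "response": spec.response,
            "fixed": list(fixed_names),
            "random": [
                [t.name, t.structure, t.column, t.applies_to] for t in spec.random
            ],
        },
    )
    samples.compute_diagnostics()
    low = samples.diagnostics[samples.diagnostics["ess"] < mcmc.target_min_ess]
    if len(low):
        worst = low["ess"].idxmin()
        warnings.warn(
            f"{len(low)} parameter(s) below target ESS {mcmc.target_min_ess:g} "
            f"(worst: {worst} at {low.loc[worst, 'ess']:.0f}); "
            "consider a longer chain",
            stacklevel=2,
        )
    return samples


def _var_name(term: RandomTerm) -> str:
    return "va" if term.structure == "pedigree" else f"v_{term.name}"


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus diagnostics for a fitted animal model.

    ``draws`` columns follow the naming scheme ``b_<fixed>`` for
    location effects, ``va`` for the additive genetic variance,
    ``v_<term>`` for other variance components and ``v_resid`` for an
    estimated residual, suffixed with ``_zi`` / ``_pois`` in zero-inflated
    models.
    """

    draws: pd.DataFrame
    family: str
    components: tuple[str, ...]
    fixed_resid: dict
    meta: dict = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None

    def compute_diagnostics(self) -> pd.DataFrame:
        rows = {}
        for col in self.draws.columns:
            x = self.draws[col].to_numpy()
            if np.ptp(x) == 0:
                rows[col] = (float(len(x)), 0.0, True, True)
                continue
            ess = effective_sample_size(x)
            ac1 = float(np.corrcoef(x[:-1], x[1:])[0, 1])
            hw = heidelberger_welch(x) if len(x) >= 100 else True
            rows[col] = (ess, ac1, hw, False)
        self.diagnostics = pd.DataFrame.from_dict(
            rows, orient="index", columns=["ess", "lag1_autocorr", "hw_pass", "degenerate"]
        )
        return self.diagnostics

    def summarize(self, param: str) -> PosteriorSummary:
        return summarize_posterior(self.draws[param].to_numpy())

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for col in self.draws.columns:
            s = self.summarize(col)
            rows.append((col, s.mode, s.hpd_low, s.hpd_high, s.mean))
        return pd.DataFrame(
            rows, columns=["parameter", "mode", "hpd_low", "hpd_high", "mean"]
        ).set_index("parameter")

    # -- serialisation -----------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(d / "draws.tsv", sep="\t", index=False)
        if self.diagnostics is not None:
            self.diagnostics.to_csv(d / "diagnostics.tsv", sep="\t")
        meta = dict(self.meta)
        meta["family"] = self.family
        meta["components"] = list(self.components)
        meta["fixed_resid"] = self.fixed_resid
        (d / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        draws = pd.read_csv(d / "draws.tsv", sep="\t")
        diag = None
        if (d / "diagnostics.tsv").exists():
            diag = pd.read_csv(d / "diagnostics.tsv", sep="\t", index_col=0)
        return cls(
            draws=draws,
            family=meta.pop("family"),
            components=tuple(meta.pop("components")),
            fixed_resid=meta.pop("fixed_resid"),
            meta=meta,
            diagnostics=diag,
        )
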
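"""Bayesian hierarchical profiling gold standard.

The public-report comparator models the log-odds of 30-day mortality as a
linear function of patient risk factors plus a hospital-specific intercept,

    O_ij ~ Bernoulli(inv-logit(x_ij' beta + phi_j)),   phi_j ~ Normal(mu, tau^2),

with weakly informative priors: Normal(0, 10^2) on each regression
coefficient and on mu, Half-Normal(1) on the between-hospital standard
deviation tau.  Posterior draws come from an adaptive Metropolis-within-Gibbs
sampler (block random-walk update for beta with a proposal shaped by the
pooled-MLE covariance, vectorised per-hospital random-walk updates for the
phi_j, a conjugate Gibbs draw for mu, and a log-scale random-walk for tau);
convergence is checked with split-chain R-hat.

A hospital-period is declared an outlier when either

* the lower limit of the 95% posterior interval of its risk-standardised
  mortality rate exceeds the unadjusted statewide rate, or
* the leave-one-hospital-out cross-validation posterior predictive p-value
  (probability, under a model fit without the hospital, of at least the
  observed death count at its case mix) is 0.01 or smaller.

The risk-standardised rate is (predicted deaths with the hospital's own
intercept) / (expected deaths with the population-average intercept mu),
multiplied by the statewide unadjusted mortality rate.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .registry import RiskFactorSchema, as_frame, default_schema

__all__ = [
    "McmcSettings",
    "HierarchicalModelSpec",
    "PosteriorDraws",
    "PosteriorSummary",
    "HospitalYearVerdict",
    "fit_hierarchical",
    "standardized_rates",
    "crossvalidation_pvalue",
    "classify_outliers",
    "gold_standard_analysis",
]

logger = logging.getLogger(__name__)

#: split-chain potential-scale-reduction threshold for declaring convergence
RHAT_THRESHOLD = 1.05

#: cross-validation flagging threshold ("0.01 or smaller")
CV_PVALUE_THRESHOLD = 0.01


@dataclass(frozen=True)
class McmcSettings:
    """Sampler budget.  ``keep`` counts post-burn-in draws per chain."""

    chains: int = 3
    burn_in: int = 2000
    keep: int = 5000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.burn_in < 0 or self.keep < 1 or self.thin < 1:
            raise ValueError("invalid MCMC settings")


@dataclass(frozen=True)
class HierarchicalModelSpec:
    """Covariate schema, prior scales and sampler settings."""

    schema: RiskFactorSchema = field(default_factory=default_schema)
    coef_prior_sd: float = 10.0
    mu_prior_sd: float = 10.0
    tau_prior_scale: float = 1.0
    mcmc: McmcSettings = field(default_factory=McmcSettings)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws (chains kept separate) plus diagnostics.

    Covariates are mean-centred before sampling (the column means are stored)
    so that mu is interpretable as the population-average log-odds at the
    average case mix and mixes independently of the coefficients.
    """

    hospitals: tuple[str, ...]
    design_columns: tuple[str, ...]
    column_means: np.ndarray
    beta: np.ndarray          # (chains, kept, p)
    phi: np.ndarray           # (chains, kept, J)
    mu: np.ndarray            # (chains, kept)
    tau: np.ndarray           # (chains, kept)
    rhat: dict[str, float]
    converged: bool
    spec: HierarchicalModelSpec

    @property
    def beta_flat(self) -> np.ndarray:
        c, k, p = self.beta.shape
        return self.beta.reshape(c * k, p)

    @property
    def phi_flat(self) -> np.ndarray:
        c, k, j = self.phi.shape
        return self.phi.reshape(c * k, j)

    @property
    def mu_flat(self) -> np.ndarray:
        return self.mu.reshape(-1)

    @property
    def tau_flat(self) -> np.ndarray:
        return self.tau.reshape(-1)

    def centered_design(self, frame: pd.DataFrame, schema: RiskFactorSchema) -> np.ndarray:
        x = schema.design_matrix(frame, add_intercept=False)
        return x - self.column_means


def _bernoulli_loglik_terms(y: np.ndarray, lp: np.ndarray) -> np.ndarray:
    return y * lp - np.logaddexp(0.0, lp)


def _warm_start(y: np.ndarray, xc: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Pooled-MLE start values and a beta proposal Cholesky factor."""
    design = np.column_stack([np.ones(len(y)), xc])
    p = xc.shape[1]
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())[1:, 1:]
        if not (np.all(np.isfinite(params)) and np.all(np.isfinite(cov))):
            raise np.linalg.LinAlgError
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(p))
        return params[1:], float(params[0]), chol
    except Exception:
        logger.warning("pooled-MLE warm start failed; falling back to diagonal proposal")
        rate = max(y.mean(), 1e-3)
        return np.zeros(p), float(np.log(rate / (1 - rate))), 0.05 * np.eye(p)


def _run_chain(y, xc, hidx, n_hosp, spec, rng, beta0, mu0, chol):
    """One adaptive Metropolis-within-Gibbs chain; returns kept draws."""
    mc = spec.mcmc
    p = xc.shape[1]
    beta = beta0 + 0.1 * (chol @ rng.standard_normal(p))
    mu = mu0 + 0.3 * rng.standard_normal()
    phi = np.full(n_hosp, mu) + 0.2 * rng.standard_normal(n_hosp)
    tau = float(np.exp(rng.normal(np.log(0.3), 0.3)))

    scale_beta, scale_tau = 1.0, 0.5
    scale_phi = np.full(n_hosp, 0.3)
    acc_beta = acc_tau = 0.0
    try_beta = 0
    acc_phi = np.zeros(n_hosp)
    ADAPT_BLOCK = 50

    eta = xc @ beta
    terms = _bernoulli_loglik_terms(y, eta + phi[hidx])
    coef_prec = 1.0 / spec.coef_prior_sd**2
    mu_prec = 1.0 / spec.mu_prior_sd**2

    # independence-proposal machinery for beta: multivariate normal with the
    # MLE-shaped covariance (mildly inflated), centred on the running mean of
    # the first half of burn-in; used on alternate iterations after that
    # point, with the shaped random walk in between
    ind_infl = 1.1
    prec_chol = np.linalg.inv(chol)          # Sigma^{-1/2} up to orthogonal factor
    ind_center = beta0.copy()
    ind_ready = False
    burn_beta_sum = np.zeros(p)
    burn_beta_n = 0

    def _ind_logq(b: np.ndarray) -> float:
        z = prec_chol @ (b - ind_center)
        return float(-0.5 * (z @ z) / ind_infl**2)

    total = mc.burn_in + mc.keep * mc.thin
    kept_beta = np.empty((mc.keep, p))
    kept_phi = np.empty((mc.keep, n_hosp))
    kept_mu = np.empty(mc.keep)
    kept_tau = np.empty(mc.keep)
    k = 0

    for it in range(total):
        # --- beta block: alternate a recentred independence proposal with a
        # covariance-shaped random walk (the walk guards against a posterior
        # the independence proposal misses)
        independence = ind_ready and it % 2 == 0
        if independence:
            prop = ind_center + ind_infl * (chol @ rng.standard_normal(p))
        else:
            prop = beta + scale_beta * (chol @ rng.standard_normal(p))
        eta_p = xc @ prop
        terms_p = _bernoulli_loglik_terms(y, eta_p + phi[hidx])
        logr = (terms_p.sum() - terms.sum()) - 0.5 * coef_prec * (prop @ prop - beta @ beta)
        if independence:
            logr += _ind_logq(beta) - _ind_logq(prop)
        else:
            try_beta += 1
        if np.log(rng.random()) < logr:
            beta, eta, terms = prop, eta_p, terms_p
            if not independence:
                acc_beta += 1
        if not ind_ready:
            burn_beta_sum += beta
            burn_beta_n += 1
            if it + 1 >= max(mc.burn_in // 2, 50):
                ind_center = burn_beta_sum / burn_beta_n
                ind_ready = True

        # --- hospital intercepts (independent random walks, vectorised)
        prop_phi = phi + scale_phi * rng.standard_normal(n_hosp)
        terms_p = _bernoulli_loglik_terms(y, eta + prop_phi[hidx])
        delta_ll = np.bincount(hidx, weights=terms_p - terms, minlength=n_hosp)
        delta_prior = ((phi - mu) ** 2 - (prop_phi - mu) ** 2) / (2.0 * tau**2)
        acc = np.log(rng.random(n_hosp)) < delta_ll + delta_prior
        if acc.any():
            phi = np.where(acc, prop_phi, phi)
            terms = np.where(acc[hidx], terms_p, terms)
        acc_phi += acc

        # --- mu (conjugate normal given phi and tau)
        prec = n_hosp / tau**2 + mu_prec
        mean = (phi.sum() / tau**2) / prec
        mu = mean + rng.standard_normal() / np.sqrt(prec)

        # --- tau (random walk on log tau; Half-Normal(scale) prior); these
        # updates cost O(J), so several per sweep sharpen the mixing of the
        # weakly identified between-hospital scale
        ss = float(((phi - mu) ** 2).sum())

        def _lp(t: float) -> float:
            return (
                -n_hosp * np.log(t)
                - ss / (2.0 * t**2)
                - t**2 / (2.0 * spec.tau_prior_scale**2)
                + np.log(t)  # Jacobian of the log transform
            )

        for _ in range(3):
            tau_p = float(np.exp(np.log(tau) + scale_tau * rng.standard_normal()))
            if np.log(rng.random()) < _lp(tau_p) - _lp(tau):
                tau = tau_p
                acc_tau += 1 / 3

        # --- proposal adaptation during burn-in
        if it < mc.burn_in and (it + 1) % ADAPT_BLOCK == 0:
            if try_beta:
                scale_beta *= float(np.exp(acc_beta / try_beta - 0.30))
            scale_tau *= float(np.exp(acc_tau / ADAPT_BLOCK - 0.44))
            scale_phi *= np.exp(acc_phi / ADAPT_BLOCK - 0.44)
            acc_beta = acc_tau = 0.0
            try_beta = 0
            acc_phi = np.zeros(n_hosp)

        if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0:
            kept_beta[k] = beta
            kept_phi[k] = phi
            kept_mu[k] = mu
            kept_tau[k] = tau
            k += 1

    return kept_beta[:k], kept_phi[:k], kept_mu[:k], kept_tau[:k]


def _split_rhat_dict(mu, tau, beta) -> dict[str, float]:
    import arviz as az

    data = az.from_dict(posterior={"mu": mu, "tau": tau, "beta": beta})
    rh = az.rhat(data)
    out = {
        "mu": float(rh["mu"].values),
        "tau": float(rh["tau"].values),
        "beta_max": float(np.max(rh["beta"].values)) if beta.shape[-1] else 1.0,
    }
    return out


def fit_hierarchical(cases, spec: HierarchicalModelSpec | None = None) -> PosteriorDraws:
    """Fit the hierarchical logistic model on one reporting period's cases.

    Requires at least two hospitals and at least one death.  Non-convergence
    by the split R-hat criterion is flagged on the result (and logged), never
    silent.  Fully reproducible from ``spec.mcmc.seed``.
    """
    spec = spec if spec is not None else HierarchicalModelSpec()
    frame = as_frame(cases, spec.schema)
    hospitals = tuple(sorted(frame["hospital_id"].astype(str).unique()))
    if len(hospitals) < 2:
        raise ValueError("hierarchical fit requires at least 2 hospitals")
    y = frame["outcome"].to_numpy(dtype=float)
    if y.sum() < 1:
        raise ValueError("hierarchical fit requires at least one death")

    x = spec.schema.design_matrix(frame, add_intercept=False)
    col_means = x.mean(axis=0) if x.size else np.zeros(x.shape[1])
    xc = x - col_means
    hidx = pd.Categorical(frame["hospital_id"].astype(str), categories=hospitals).codes

    beta0, mu0, chol = _warm_start(y, xc)
    mc = spec.mcmc
    chains_beta, chains_phi, chains_mu, chains_tau = [], [], [], []
    for c in range(mc.chains):
        rng = np.random.default_rng((int(mc.seed) + 104729 * (c + 1)) % (2**31 - 1))
        kb, kp, km, kt = _run_chain(y, xc, hidx, len(hospitals), spec, rng, beta0, mu0, chol)
        chains_beta.append(kb)
        chains_phi.append(kp)
        chains_mu.append(km)
        chains_tau.append(kt)

    beta = np.stack(chains_beta)
    phi = np.stack(chains_phi)
    mu = np.stack(chains_mu)
    tau = np.stack(chains_tau)

    if mc.chains >= 2:
        rhat = _split_rhat_dict(mu, tau, beta)
    else:
        rhat = {"mu": float("nan"), "tau": float("nan"), "beta_max": float("nan")}
    converged = mc.chains < 2 or max(rhat.values()) < RHAT_THRESHOLD
    if not converged:
        logger.warning("hierarchical fit did not reach R-hat < %.2f: %s", RHAT_THRESHOLD, rhat)

    return PosteriorDraws(
        hospitals=hospitals,
        design_columns=tuple(spec.schema.design_columns()),
        column_means=col_means,
        beta=beta, phi=phi, mu=mu, tau=tau,
        rhat=rhat, converged=converged, spec=spec,
    )


def standardized_rates(draws: PosteriorDraws, cases, chunk: int = 2000) -> pd.DataFrame:
    """Per-hospital risk-standardised mortality rates with 95% intervals.

    For every retained draw, a hospital's predicted deaths (own intercept)
    are divided by its expected deaths (population-average intercept mu) and
    scaled by the statewide unadjusted mortality rate; the per-draw rates are
    summarised into a posterior mean and 2.5th/97.5th percentiles.  The
    statewide rate is stored in ``DataFrame.attrs['statewide_rate']``.
    """
    frame = as_frame(cases, draws.spec.schema)
    statewide = float(frame["outcome"].mean())
    xc = draws.centered_design(frame, draws.spec.schema)
    hosp = frame["hospital_id"].astype(str).to_numpy()

    beta = draws.beta_flat
    mu = draws.mu_flat
    phi = draws.phi_flat
    n_draws = beta.shape[0]

    rows = []
    for j, hospital in enumerate(draws.hospitals):
        xj = xc[hosp == hospital]
        if len(xj) == 0:
            rows.append((hospital, np.nan, np.nan, np.nan, 0, 0))
            continue
        pred = np.empty(n_draws)
        exp_ = np.empty(n_draws)
        for lo in range(0, n_draws, chunk):
            b = beta[lo:lo + chunk]
            eta = xj @ b.T                                  # (n_j, chunk)
            pred[lo:lo + chunk] = expit(eta + phi[lo:lo + chunk, j]).sum(axis=0)
            exp_[lo:lo + chunk] = expit(eta + mu[lo:lo + chunk]).sum(axis=0)
        rates = pred / exp_ * statewide
        obs = int(frame.loc[hosp == hospital, "outcome"].sum())
        rows.append((
            hospital, float(rates.mean()),
            float(np.percentile(rates, 2.5)), float(np.percentile(rates, 97.5)),
            len(xj), obs,
        ))

    table = pd.DataFrame(rows, columns=["hospital_id", "mean", "lower", "upper", "n", "deaths"])
    table.attrs["statewide_rate"] = statewide
    return table


def crossvalidation_pvalue(
    cases,
    spec: HierarchicalModelSpec | None = None,
    hospital_id: str | None = None,
    draws: PosteriorDraws | None = None,
) -> float:
    """Leave-one-hospital-out posterior predictive p-value for ``hospital_id``.

    The model is refit without the hospital; for each retained draw a fresh
    hospital effect is drawn from Normal(mu, tau^2) and deaths are simulated
    at the held-out hospital's observed case mix.  The p-value is the
    fraction of predictive draws with at least the observed death count (ties
    count, so a hospital with zero observed deaths gets p = 1).  Pass
    ``draws`` to reuse an existing leave-one-out fit.
    """
    spec = spec if spec is not None else HierarchicalModelSpec()
    if hospital_id is None:
        raise ValueError("hospital_id is required")
    frame = as_frame(cases, spec.schema)
    frame["hospital_id"] = frame["hospital_id"].astype(str)
    if frame["hospital_id"].nunique() < 3:
        raise ValueError("cross-validation requires at least 3 hospitals")
    held = frame.loc[frame["hospital_id"] == hospital_id]
    if held.empty:
        raise ValueError(f"unknown hospital {hospital_id!r}")
    rest = frame.loc[frame["hospital_id"] != hospital_id]

    if draws is None:
        draws = fit_hierarchical(rest, spec)
    obs = int(held["outcome"].sum())

    xh = draws.centered_design(held, spec.schema)
    beta = draws.beta_flat
    mu = draws.mu_flat
    tau = draws.tau_flat
    n_draws = beta.shape[0]

    seed = (int(spec.mcmc.seed) + zlib.crc32(hospital_id.encode())) % (2**31 - 1)
    rng = np.random.default_rng(seed)
    phi_new = rng.normal(mu, tau)
    deaths = np.empty(n_draws, dtype=int)
    chunk = 2000
    for lo in range(0, n_draws, chunk):
        b = beta[lo:lo + chunk]
        p = expit(xh @ b.T + phi_new[lo:lo + chunk])        # (n_held, chunk)
        deaths[lo:lo + chunk] = (rng.random(p.shape) < p).sum(axis=0)
    return float(np.mean(deaths >= obs))


@dataclass(frozen=True)
class HospitalYearVerdict:
    """Flag for one hospital in one reporting period, with its basis."""

    hospital_id: str
    period_label: str
    source: str                     # "gold_standard" or "ra_sprt"
    flagged: bool
    basis: tuple[str, ...] = ()     # interval_rule / crossvalidation_rule / h1_crossing

    def __post_init__(self) -> None:
        if self.flagged and not self.basis:
            raise ValueError("a flagged verdict requires a basis")


@dataclass
class PosteriorSummary:
    """Per-hospital posterior rates, intervals and cross-validation p-values."""

    period_label: str
    table: pd.DataFrame             # hospital_id, mean, lower, upper, n, deaths, cv_pvalue
    statewide_rate: float
    rhat: dict[str, float]
    converged: bool


def classify_outliers(summary: PosteriorSummary) -> list[HospitalYearVerdict]:
    """Apply the interval rule then the cross-validation rule per hospital.

    Flagged iff the 95% interval's lower limit exceeds the statewide
    unadjusted rate, or the cross-validation p-value is 0.01 or smaller; a
    missing (NaN) p-value simply disables the second rule for that hospital.
    """
    verdicts = []
    for row in summary.table.itertuples(index=False):
        basis: list[str] = []
        if np.isfinite(row.lower) and row.lower > summary.statewide_rate:
            basis.append("interval_rule")
        pv = getattr(row, "cv_pvalue", float("nan"))
        if np.isfinite(pv) and pv <= CV_PVALUE_THRESHOLD + 1e-12:
            basis.append("crossvalidation_rule")
        verdicts.append(
            HospitalYearVerdict(
                hospital_id=str(row.hospital_id),
                period_label=summary.period_label,
                source="gold_standard",
                flagged=bool(basis),
                basis=tuple(basis),
            )
        )
    return verdicts


def gold_standard_analysis(
    cases,
    spec: HierarchicalModelSpec | None = None,
    period_label: str = "",
    cv: str | list[str] = "all",
) -> PosteriorSummary:
    """Full gold-standard run for one period: fit, rates and p-values.

    ``cv`` selects which hospitals get the leave-one-out p-value: ``"all"``,
    ``"none"``, or an explicit hospital list (others get NaN, disabling the
    cross-validation rule for them).
    """
    spec = spec if spec is not None else HierarchicalModelSpec()
    draws = fit_hierarchical(cases, spec)
    table = standardized_rates(draws, cases)

    if cv == "all":
        cv_hospitals = list(draws.hospitals)
    elif cv == "none":
        cv_hospitals = []
    else:
        cv_hospitals = list(cv)
    pvals = {}
    for hospital in cv_hospitals:
        pvals[hospital] = crossvalidation_pvalue(cases, spec, hospital)
    table = table.copy()
    table["cv_pvalue"] = [pvals.get(h, float("nan")) for h in table["hospital_id"]]

    return PosteriorSummary(
        period_label=period_label,
        table=table,
        statewide_rate=table.attrs["statewide_rate"],
        rhat=draws.rhat,
        converged=draws.converged,
    )
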
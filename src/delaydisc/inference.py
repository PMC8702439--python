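"""Hierarchical Bayesian hyperbolic discounting.

Model
-----
For participant *i* on trial *j* the present values of the two options are

    V = A / (1 + k_i * t)

with *t* the objective delay in days or, under the subjective time basis,
the perceived duration T = alpha_hat * t**beta_hat from that participant and
condition's power-law perception fit (t = 0 maps to T = 0).  The choice rule
is a logistic (softmax over two options):

    P(LL) = logistic(temp_i * (V_LL - V_SS))

Participant parameters are partially pooled:

    log k_i[,c] ~ Normal(mu_k[c], sigma_k)      (one k per participant, or
                                                 one per delay condition when
                                                 k_structure = split)
    log temp_i ~ Normal(mu_t, sigma_t)

with weakly informative hyper-priors: mu_k ~ Normal(log 0.05, 1.5^2),
mu_t ~ Normal(0, 1), half-normal scales.

Sampling uses an adaptive Metropolis-within-Gibbs scheme: participant-level
parameters are updated by vectorized random-walk Metropolis (participants are
conditionally independent given the hyper-parameters), hyper-means by exact
conjugate Gibbs draws, and hyper-scales by random-walk Metropolis on the log
scale.  Proposal scales adapt toward a 0.44 acceptance rate during warm-up
and are frozen afterwards.  Convergence is assessed with the Gelman-Rubin
potential scale reduction factor (threshold 1.1) and models are compared with
WAIC (lower is better; a difference above 10 is treated as decisive).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConvergenceWarning, FitError, ValidationError

CONDITIONS = ("immediate", "non_immediate")
RHAT_THRESHOLD = 1.1
DELTA_WAIC_THRESHOLD = 10.0


# ---------------------------------------------------------------------------
# elementary operations


def hyperbolic_value(amount, delay, k):
    """Present value A / (1 + k t) of amount A delayed t days at rate k."""
    amount = np.asarray(amount, dtype=float)
    delay = np.asarray(delay, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValidationError("discount rate k must be non-negative")
    if np.any(amount < 0) or np.any(delay < 0):
        raise ValidationError("amounts and delays must be non-negative")
    out = amount / (1.0 + k * delay)
    return float(out) if out.ndim == 0 else out


def choice_probability(v_ss, v_ll, temperature):
    """P(choose LL) under the logistic rule with inverse temperature."""
    temperature = np.asarray(temperature, dtype=float)
    if np.any(temperature < 0):
        raise ValidationError("temperature must be non-negative")
    x = temperature * (np.asarray(v_ll, dtype=float) - np.asarray(v_ss, dtype=float))
    out = 1.0 / (1.0 + np.exp(-x))
    return float(out) if out.ndim == 0 else out


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor sqrt(Var+ / W) for one parameter.

    ``chains`` is an (m, n) array of m >= 2 equal-length draw sequences.
    W is the mean within-chain variance (n-1 denominator), B = n * variance
    of the chain means (m-1 denominator), Var+ = ((n-1)/n) W + B/n.  No
    chain-splitting is applied here; callers may pre-split.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValidationError("need at least 2 equal-length chains")
    m, n = arr.shape
    if n < 2:
        raise ValidationError("chains must contain at least 2 draws")
    w = arr.var(axis=1, ddof=1).mean()
    if w == 0:
        raise ValidationError("within-chain variance is zero; R-hat undefined")
    b = n * arr.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def waic(pointwise_loglik) -> dict:
    """WAIC from a draws x observations pointwise log-likelihood matrix.

    lppd_i uses a log-mean-exp over draws (overflow-safe); the effective
    number of parameters is the sum of per-observation posterior variances
    of the log-likelihood (sample variance, S-1 denominator).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.size == 0:
        raise ValidationError("pointwise log-likelihood must be a non-empty 2-D matrix")
    s = ll.shape[0]
    if s < 2:
        raise ValidationError("need at least 2 draws for WAIC")
    lppd_i = logsumexp(ll, axis=0) - math.log(s)
    p_i = ll.var(axis=0, ddof=1)
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return {"lppd": lppd, "p_waic": p_waic, "waic": -2.0 * (lppd - p_waic)}


# ---------------------------------------------------------------------------
# model and sampler configuration


@dataclass(frozen=True)
class DiscountModelSpec:
    """Structure and priors of the hierarchical discounting model."""

    k_structure: str = "split_by_condition"  # or "joint"
    time_basis: str = "objective"  # or "subjective"
    mu_logk_loc: float = math.log(0.05)
    mu_logk_scale: float = 1.5
    mu_logtemp_loc: float = 0.0
    mu_logtemp_scale: float = 1.0
    sigma_k_scale: float = 1.0
    sigma_t_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.k_structure not in ("joint", "split_by_condition"):
            raise ValidationError(f"unknown k_structure {self.k_structure!r}")
        if self.time_basis not in ("objective", "subjective"):
            raise ValidationError(f"unknown time_basis {self.time_basis!r}")


@dataclass(frozen=True)
class McmcConfig:
    """Chain geometry: retained draws = n_chains x n_samples_per_chain."""

    n_chains: int = 4
    n_samples_per_chain: int = 1000
    n_warmup: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValidationError("need at least 2 chains for convergence diagnostics")
        if self.n_samples_per_chain < 2 or self.n_warmup < 1:
            raise ValidationError("invalid chain lengths")


#: reduced profile for quick runs; full profile matches the 4 x 1000 default
REDUCED_MCMC = McmcConfig(n_chains=4, n_samples_per_chain=500, n_warmup=500)


@dataclass
class _TrialData:
    part_idx: np.ndarray  # (n_trials,) participant index
    col_idx: np.ndarray  # (n_trials,) k-column index (0 for joint)
    ss_amt: np.ndarray
    ss_t: np.ndarray
    ll_amt: np.ndarray
    ll_t: np.ndarray
    y: np.ndarray  # 1 = chose LL
    participants: list[str]
    k_cols: list[str]
    trial_order: np.ndarray  # original row order of `trials`

    @property
    def n_p(self) -> int:
        return len(self.participants)

    @property
    def n_trials(self) -> int:
        return self.part_idx.size


@dataclass
class PosteriorFit:
    """Posterior draws, diagnostics, and pointwise log-likelihood of one fit."""

    spec: DiscountModelSpec
    mcmc: McmcConfig
    participants: list[str]
    k_cols: list[str]
    draws: dict[str, np.ndarray]  # name -> (chains, draws, ...) arrays
    rhat: dict[str, float]
    pointwise_loglik: np.ndarray  # (total draws, n_trials)
    waic: dict
    converged: bool

    def summary(self) -> pd.DataFrame:
        """Posterior summary table (parameter, mean, sd, 2.5%, 97.5%, rhat)."""
        rows = []
        for name, arr in self.draws.items():
            flat = arr.reshape(-1, *arr.shape[2:])
            if flat.ndim == 1:
                flat = flat[:, None]
                labels = [name]
            elif name in ("log_k",):
                labels = [
                    f"{name}[{p},{c}]"
                    for p in self.participants
                    for c in self.k_cols
                ]
                flat = flat.reshape(flat.shape[0], -1)
            elif name in ("log_temp",):
                labels = [f"{name}[{p}]" for p in self.participants]
            else:
                labels = [f"{name}[{c}]" for c in self.k_cols]
            for j, label in enumerate(labels):
                v = flat[:, j]
                rows.append(
                    {
                        "parameter": label,
                        "mean": v.mean(),
                        "sd": v.std(ddof=1),
                        "hdi_2.5%": np.quantile(v, 0.025),
                        "hdi_97.5%": np.quantile(v, 0.975),
                        "rhat": self.rhat.get(label, np.nan),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# data preparation


def _prepare_data(
    trials: pd.DataFrame,
    spec: DiscountModelSpec,
    perception: pd.DataFrame | None,
) -> _TrialData:
    required = {"participant_id", "condition", "ss_amount", "ss_delay", "ll_amount", "ll_delay", "choice"}
    missing = required - set(trials.columns)
    if missing:
        raise ValidationError(f"trials table missing columns: {sorted(missing)}")
    if len(trials) == 0:
        raise ValidationError("empty trials table")
    participants = sorted(trials["participant_id"].unique())
    p_index = {p: i for i, p in enumerate(participants)}
    conds = trials["condition"].to_numpy()
    unknown = set(conds) - set(CONDITIONS)
    if unknown:
        raise ValidationError(f"unknown conditions: {sorted(unknown)}")

    part_idx = trials["participant_id"].map(p_index).to_numpy(dtype=np.int64)
    cond_idx = np.asarray([CONDITIONS.index(c) for c in conds], dtype=np.int64)
    if spec.k_structure == "split_by_condition":
        col_idx = cond_idx
        k_cols = list(CONDITIONS)
    else:
        col_idx = np.zeros_like(cond_idx)
        k_cols = ["all"]

    ss_t = trials["ss_delay"].to_numpy(dtype=float)
    ll_t = trials["ll_delay"].to_numpy(dtype=float)
    if spec.time_basis == "subjective":
        if perception is None:
            raise ValidationError("subjective time basis requires perception estimates")
        key = perception.set_index(["participant_id", "condition"])
        alpha = np.empty(len(trials))
        beta = np.empty(len(trials))
        for i, (p, c) in enumerate(zip(trials["participant_id"], conds)):
            try:
                row = key.loc[(p, c)]
            except KeyError:
                raise ValidationError(
                    f"missing perception fit for participant {p!r}, condition {c!r}"
                ) from None
            alpha[i] = row["alpha"]
            beta[i] = row["beta"]
        ss_t = np.where(ss_t > 0, alpha * np.power(np.maximum(ss_t, 1e-12), beta), 0.0)
        ll_t = np.where(ll_t > 0, alpha * np.power(np.maximum(ll_t, 1e-12), beta), 0.0)

    y = (trials["choice"].to_numpy() == "LL").astype(float)
    return _TrialData(
        part_idx=part_idx,
        col_idx=col_idx,
        ss_amt=trials["ss_amount"].to_numpy(dtype=float),
        ss_t=ss_t,
        ll_amt=trials["ll_amount"].to_numpy(dtype=float),
        ll_t=ll_t,
        y=y,
        participants=participants,
        k_cols=k_cols,
        trial_order=np.arange(len(trials)),
    )


# ---------------------------------------------------------------------------
# likelihood


def _trial_loglik(
    data: _TrialData,
    logk: np.ndarray,
    logtemp: np.ndarray,
    rows: np.ndarray | slice = slice(None),
) -> np.ndarray:
    """Log-likelihood of each selected trial given participant parameters."""
    pi = data.part_idx[rows]
    k = np.exp(logk[pi, data.col_idx[rows]])
    v_ss = data.ss_amt[rows] / (1.0 + k * data.ss_t[rows])
    v_ll = data.ll_amt[rows] / (1.0 + k * data.ll_t[rows])
    x = np.exp(logtemp[pi]) * (v_ll - v_ss)
    # log P(y): y*x - log(1 + e^x), stable via logaddexp
    return data.y[rows] * x - np.logaddexp(0.0, x)


def _participant_loglik(
    data: _TrialData,
    logk: np.ndarray,
    logtemp: np.ndarray,
    rows: np.ndarray | slice = slice(None),
) -> np.ndarray:
    ll = _trial_loglik(data, logk, logtemp, rows)
    return np.bincount(data.part_idx[rows], weights=ll, minlength=data.n_p)


# ---------------------------------------------------------------------------
# sampler


def _run_chain(
    data: _TrialData,
    spec: DiscountModelSpec,
    mcmc: McmcConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    n_p, n_cols = data.n_p, len(data.k_cols)
    col_rows = [np.where(data.col_idx == c)[0] for c in range(n_cols)]

    # initial state, jittered per chain
    logk = np.full((n_p, n_cols), spec.mu_logk_loc) + 0.5 * rng.standard_normal((n_p, n_cols))
    logtemp = np.full(n_p, math.log(0.3)) + 0.3 * rng.standard_normal(n_p)
    mu_k = np.full(n_cols, spec.mu_logk_loc) + 0.2 * rng.standard_normal(n_cols)
    sigma_k = 0.5 * math.exp(0.2 * rng.standard_normal())
    mu_t = math.log(0.3) + 0.2 * rng.standard_normal()
    sigma_t = 0.4 * math.exp(0.2 * rng.standard_normal())

    step_k = np.full((n_p, n_cols), 0.3)
    step_t = np.full(n_p, 0.3)
    step_sk = 0.3
    step_st = 0.3
    step_rk = 0.2
    step_rt = 0.2

    n_iter = mcmc.n_warmup + mcmc.n_samples_per_chain
    out = {
        "log_k": np.empty((mcmc.n_samples_per_chain, n_p, n_cols)),
        "log_temp": np.empty((mcmc.n_samples_per_chain, n_p)),
        "mu_log_k": np.empty((mcmc.n_samples_per_chain, n_cols)),
        "sigma_log_k": np.empty(mcmc.n_samples_per_chain),
        "mu_log_temp": np.empty(mcmc.n_samples_per_chain),
        "sigma_log_temp": np.empty(mcmc.n_samples_per_chain),
    }

    def halfnormal_logpdf(x: float, scale: float) -> float:
        return -0.5 * (x / scale) ** 2

    for it in range(n_iter):
        adapting = it < mcmc.n_warmup
        gamma = 1.0 / (1.0 + it) ** 0.6 if adapting else 0.0

        # --- participant log k, one column (condition) at a time
        for c in range(n_cols):
            rows = col_rows[c]
            ll_old = _participant_loglik(data, logk, logtemp, rows)
            prop = logk.copy()
            eps = step_k[:, c] * rng.standard_normal(n_p)
            prop[:, c] = logk[:, c] + eps
            ll_new = _participant_loglik(data, prop, logtemp, rows)
            dprior = (
                -0.5 * ((prop[:, c] - mu_k[c]) / sigma_k) ** 2
                + 0.5 * ((logk[:, c] - mu_k[c]) / sigma_k) ** 2
            )
            accept = np.log(rng.random(n_p)) < (ll_new - ll_old + dprior)
            logk[accept, c] = prop[accept, c]
            if adapting:
                step_k[:, c] *= np.exp(gamma * (accept.astype(float) - 0.44))

        # --- participant log temperature (touches every trial)
        ll_old = _participant_loglik(data, logk, logtemp)
        prop_t = logtemp + step_t * rng.standard_normal(n_p)
        ll_new = _participant_loglik(data, logk, prop_t)
        dprior = (
            -0.5 * ((prop_t - mu_t) / sigma_t) ** 2
            + 0.5 * ((logtemp - mu_t) / sigma_t) ** 2
        )
        accept = np.log(rng.random(n_p)) < (ll_new - ll_old + dprior)
        logtemp[accept] = prop_t[accept]
        if adapting:
            step_t *= np.exp(gamma * (accept.astype(float) - 0.44))

        # --- hyper means: exact conjugate Gibbs draws
        for c in range(n_cols):
            prec = 1.0 / spec.mu_logk_scale**2 + n_p / sigma_k**2
            mean = (
                spec.mu_logk_loc / spec.mu_logk_scale**2
                + logk[:, c].sum() / sigma_k**2
            ) / prec
            mu_k[c] = mean + math.sqrt(1.0 / prec) * rng.standard_normal()
        prec = 1.0 / spec.mu_logtemp_scale**2 + n_p / sigma_t**2
        mean = (
            spec.mu_logtemp_loc / spec.mu_logtemp_scale**2 + logtemp.sum() / sigma_t**2
        ) / prec
        mu_t = mean + math.sqrt(1.0 / prec) * rng.standard_normal()

        # --- hyper scales: random-walk Metropolis on log sigma
        def scale_logpost(sigma: float, resid_ss: float, n_obs: int, prior_scale: float) -> float:
            # normal likelihood + half-normal prior + log-Jacobian of log param
            return (
                -n_obs * math.log(sigma)
                - 0.5 * resid_ss / sigma**2
                + halfnormal_logpdf(sigma, prior_scale)
                + math.log(sigma)
            )

        resid_k = float(((logk - mu_k[None, :]) ** 2).sum())
        prop_s = sigma_k * math.exp(step_sk * rng.standard_normal())
        lp_new = scale_logpost(prop_s, resid_k, n_p * n_cols, spec.sigma_k_scale)
        lp_old = scale_logpost(sigma_k, resid_k, n_p * n_cols, spec.sigma_k_scale)
        acc = math.log(rng.random()) < lp_new - lp_old
        if acc:
            sigma_k = prop_s
        if adapting:
            step_sk *= math.exp(gamma * (float(acc) - 0.44))

        resid_t = float(((logtemp - mu_t) ** 2).sum())
        prop_s = sigma_t * math.exp(step_st * rng.standard_normal())
        lp_new = scale_logpost(prop_s, resid_t, n_p, spec.sigma_t_scale)
        lp_old = scale_logpost(sigma_t, resid_t, n_p, spec.sigma_t_scale)
        acc = math.log(rng.random()) < lp_new - lp_old
        if acc:
            sigma_t = prop_s
        if adapting:
            step_st *= math.exp(gamma * (float(acc) - 0.44))

        # --- parameter-expansion rescale moves: jointly scale a hyper sd and
        # its residuals, breaking the funnel for weakly identified participants.
        # MH log-ratio: delta loglik + delta halfnormal prior + log f
        # (prior normal term cancels against all but one power of the Jacobian).
        f = math.exp(step_rt * rng.standard_normal())
        prop_t = mu_t + f * (logtemp - mu_t)
        ll_old = float(_trial_loglik(data, logk, logtemp).sum())
        ll_new = float(_trial_loglik(data, logk, prop_t).sum())
        dlp = (
            ll_new
            - ll_old
            + halfnormal_logpdf(f * sigma_t, spec.sigma_t_scale)
            - halfnormal_logpdf(sigma_t, spec.sigma_t_scale)
            + math.log(f)
        )
        acc = math.log(rng.random()) < dlp
        if acc:
            logtemp = prop_t
            sigma_t *= f
        if adapting:
            step_rt *= math.exp(gamma * (float(acc) - 0.44))

        f = math.exp(step_rk * rng.standard_normal())
        prop_k = mu_k[None, :] + f * (logk - mu_k[None, :])
        ll_old = float(_trial_loglik(data, logk, logtemp).sum())
        ll_new = float(_trial_loglik(data, prop_k, logtemp).sum())
        dlp = (
            ll_new
            - ll_old
            + halfnormal_logpdf(f * sigma_k, spec.sigma_k_scale)
            - halfnormal_logpdf(sigma_k, spec.sigma_k_scale)
            + math.log(f)
        )
        acc = math.log(rng.random()) < dlp
        if acc:
            logk = prop_k
            sigma_k *= f
        if adapting:
            step_rk *= math.exp(gamma * (float(acc) - 0.44))

        if not adapting:
            s = it - mcmc.n_warmup
            out["log_k"][s] = logk
            out["log_temp"][s] = logtemp
            out["mu_log_k"][s] = mu_k
            out["sigma_log_k"][s] = sigma_k
            out["mu_log_temp"][s] = mu_t
            out["sigma_log_temp"][s] = sigma_t

    return out


def _pointwise_loglik(
    data: _TrialData, logk_draws: np.ndarray, logtemp_draws: np.ndarray, batch: int = 200
) -> np.ndarray:
    """(draws, trials) log-likelihood matrix, computed in batches."""
    s_total = logk_draws.shape[0]
    out = np.empty((s_total, data.n_trials))
    for start in range(0, s_total, batch):
        lk = logk_draws[start : start + batch]  # (B, n_p, n_cols)
        lt = logtemp_draws[start : start + batch]  # (B, n_p)
        k = np.exp(lk[:, data.part_idx, data.col_idx])  # (B, n_trials)
        v_ss = data.ss_amt[None, :] / (1.0 + k * data.ss_t[None, :])
        v_ll = data.ll_amt[None, :] / (1.0 + k * data.ll_t[None, :])
        x = np.exp(lt[:, data.part_idx]) * (v_ll - v_ss)
        out[start : start + batch] = data.y[None, :] * x - np.logaddexp(0.0, x)
    return out


def fit_hierarchical(
    trials: pd.DataFrame,
    spec: DiscountModelSpec | None = None,
    mcmc: McmcConfig | None = None,
    perception: pd.DataFrame | None = None,
) -> PosteriorFit:
    """Fit the hierarchical discounting model to one group's trial table.

    Returns draws for every sampled parameter, Gelman-Rubin diagnostics, the
    pointwise log-likelihood matrix and WAIC.  An unconverged fit (any R-hat
    at or above 1.1) is flagged (``converged = False``) and a
    ConvergenceWarning is emitted; it is never silently reported as success.
    """
    spec = spec or DiscountModelSpec()
    mcmc = mcmc or McmcConfig()
    data = _prepare_data(trials, spec, perception)

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chains = [
        _run_chain(data, spec, mcmc, np.random.default_rng(s)) for s in seeds
    ]

    draws = {
        name: np.stack([c[name] for c in chains], axis=0) for name in chains[0]
    }

    rhat: dict[str, float] = {}

    def _rhat_safe(mat: np.ndarray) -> float:
        try:
            return gelman_rubin(mat)
        except ValidationError:
            return float("nan")

    for c, cond in enumerate(data.k_cols):
        rhat[f"mu_log_k[{cond}]"] = _rhat_safe(draws["mu_log_k"][:, :, c])
        for i, p in enumerate(data.participants):
            rhat[f"log_k[{p},{cond}]"] = _rhat_safe(draws["log_k"][:, :, i, c])
    for i, p in enumerate(data.participants):
        rhat[f"log_temp[{p}]"] = _rhat_safe(draws["log_temp"][:, :, i])
    rhat["sigma_log_k"] = _rhat_safe(draws["sigma_log_k"])
    rhat["mu_log_temp"] = _rhat_safe(draws["mu_log_temp"])
    rhat["sigma_log_temp"] = _rhat_safe(draws["sigma_log_temp"])

    flat_logk = draws["log_k"].reshape(-1, data.n_p, len(data.k_cols))
    flat_logtemp = draws["log_temp"].reshape(-1, data.n_p)
    pointwise = _pointwise_loglik(data, flat_logk, flat_logtemp)
    waic_parts = waic(pointwise)

    worst = np.nanmax(list(rhat.values()))
    converged = bool(worst < RHAT_THRESHOLD)
    if not converged:
        warnings.warn(
            f"fit not converged: max R-hat {worst:.3f} >= {RHAT_THRESHOLD}",
            ConvergenceWarning,
            stacklevel=2,
        )

    return PosteriorFit(
        spec=spec,
        mcmc=mcmc,
        participants=data.participants,
        k_cols=data.k_cols,
        draws=draws,
        rhat=rhat,
        pointwise_loglik=pointwise,
        waic=waic_parts,
        converged=converged,
    )


@dataclass(frozen=True)
class ModelComparison:
    """WAIC comparison of two fits on the same observations."""

    waic_a: float
    waic_b: float
    delta_waic: float
    preferred: str  # "a", "b", or "indistinguishable"


def compare_models(fit_a: PosteriorFit, fit_b: PosteriorFit) -> ModelComparison:
    """Prefer the lower-WAIC model only when the difference exceeds 10."""
    if fit_a.pointwise_loglik.shape[1] != fit_b.pointwise_loglik.shape[1]:
        raise ValidationError("fits cover different numbers of observations")
    wa, wb = fit_a.waic["waic"], fit_b.waic["waic"]
    delta = abs(wa - wb)
    if delta > DELTA_WAIC_THRESHOLD:
        preferred = "a" if wa < wb else "b"
    else:
        preferred = "indistinguishable"
    return ModelComparison(waic_a=wa, waic_b=wb, delta_waic=delta, preferred=preferred)


def extract_k_estimates(
    fit: PosteriorFit, by_condition: bool | None = None
) -> pd.DataFrame:
    """Posterior-mean discount rate per participant (and condition for split fits)."""
    split = fit.spec.k_structure == "split_by_condition"
    if by_condition is True and not split:
        raise ValidationError("joint fit has no condition-wise discount rates")
    k_draws = np.exp(fit.draws["log_k"])  # (chains, draws, n_p, n_cols)
    k_mean = k_draws.reshape(-1, *k_draws.shape[2:]).mean(axis=0)
    rows = []
    for i, p in enumerate(fit.participants):
        for c, cond in enumerate(fit.k_cols):
            rows.append({"participant_id": p, "condition": cond, "k": float(k_mean[i, c])})
    return pd.DataFrame(rows)
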
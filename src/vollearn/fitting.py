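"""Fitting the agent family to choice data.

Parameters are estimated on an unconstrained transformed scale (logit for
learning rates, log for the inverse temperature, identity for the bias)
with independent normal priors.  Three routes are provided:

* ``fit_map`` — multi-restart quasi-Newton maximisation of the log
  posterior; the workhorse for recovery harnesses and cohort-scale runs.
* ``sample_posterior`` — adaptive random-walk Metropolis sampling of the
  per-subject posterior.
* ``integrated_bic`` / ``compare_models`` — group-level model comparison:
  an empirical-Bayes normal prior is fitted to the cohort (iterating
  subject MAP fits and prior-moment updates), each subject's marginal
  likelihood is estimated by Monte-Carlo integration over that prior, and
  models are scored by iBIC = -2 * sum log-marginals + k * log(total
  choices), where k counts the group-level prior hyperparameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .agents import (
    MODEL_FAMILY,
    WINNING_MODEL,
    AgentParams,
    ModelSpec,
    SubjectDataset,
    log_likelihood,
    simulate_agent,
)
from .schedule import ScheduleConfig, generate_schedule

__all__ = [
    "PriorSpec",
    "FitResult",
    "ModelComparison",
    "default_prior",
    "log_marginal",
    "fit_map",
    "sample_posterior",
    "integrated_bic",
    "compare_models",
    "parameter_recovery",
    "posterior_predictive_check",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors on the transformed parameter scale.

    Layout matches the model's free parameter vector:
    [logit(alpha)..., log(beta), bias?].
    """

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape:
            raise ValueError("prior mean and sd must have the same shape")
        if np.any(self.sd <= 0):
            raise ValueError("prior sds must be positive")

    @property
    def n_hyper(self) -> int:
        """Number of group-level hyperparameters (a mean and sd per param)."""
        return 2 * self.mean.size

    def log_pdf(self, theta: np.ndarray) -> float:
        z = (theta - self.mean) / self.sd
        return float(-0.5 * np.sum(z * z) - np.sum(np.log(self.sd)) - 0.5 * theta.size * np.log(2 * np.pi))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.mean + self.sd * rng.standard_normal((n, self.mean.size))


def default_prior(spec: ModelSpec) -> PriorSpec:
    """Weakly informative default: learning rates centred at 0.5 (logit 0,
    sd 2 covers [0.02, 0.98]); log-beta centred at log 6 with sd 1; bias
    standard normal."""
    mean = np.concatenate([np.zeros(spec.n_alpha), [np.log(6.0)], [0.0] if spec.include_bias else []])
    sd = np.concatenate([np.full(spec.n_alpha, 2.0), [1.0], [1.0] if spec.include_bias else []])
    return PriorSpec(mean=mean, sd=sd)


def theta_to_params(theta: np.ndarray, spec: ModelSpec) -> AgentParams:
    """Transformed vector -> natural-scale AgentParams."""
    theta = np.asarray(theta, dtype=float)
    alphas = expit(theta[: spec.n_alpha])
    beta = float(np.exp(theta[spec.n_alpha]))
    bias = float(theta[spec.n_alpha + 1]) if spec.include_bias else 0.0
    return AgentParams.from_free(spec, alphas, beta, bias)


def params_to_theta(params: AgentParams, spec: ModelSpec) -> np.ndarray:
    a = np.clip(params.free_alphas(spec), 1e-6, 1 - 1e-6)
    parts = [logit(a), [np.log(max(params.beta, 1e-10))]]
    if spec.include_bias:
        parts.append([params.bias])
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# fast likelihood kernels


class _TrialCache:
    """Numpy views of a dataset's outcomes and choices, grouped by block."""

    def __init__(self, dataset: SubjectDataset) -> None:
        t = dataset.schedule.trials.reset_index(drop=True)
        self.blocks = []
        for bi, sub in t.groupby("block", sort=True):
            self.blocks.append(
                (
                    int(bi) - 1,
                    sub.index.to_numpy(),
                    sub["win_on_A"].to_numpy(dtype=float),
                    sub["loss_on_A"].to_numpy(dtype=float),
                )
            )
        self.chose_A = dataset.choices["chose_A"].to_numpy(dtype=bool)
        self.n_trials = len(t)


def _values_many(outcomes: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Pre-choice values (D, T) for D learning rates over one outcome
    sequence.  Few draws go through the scalar linear-filter kernel; many
    draws use the delta-rule recursion vectorised across draws."""
    from .agents import _block_values

    alphas = np.atleast_1d(alphas)
    D = alphas.size
    if D <= 8:
        return np.stack([_block_values(outcomes, float(a)) for a in alphas])
    T = outcomes.size
    v = np.full(D, 0.5)
    out = np.empty((D, T))
    for t in range(T):
        out[:, t] = v
        v = v + alphas * (outcomes[t] - v)
    return out


def _loglik_thetas(thetas: np.ndarray, spec: ModelSpec, cache: _TrialCache) -> np.ndarray:
    """Log likelihood for a (D, n_free) matrix of transformed params."""
    thetas = np.atleast_2d(thetas)
    D = thetas.shape[0]
    alphas = expit(thetas[:, : spec.n_alpha])
    beta = np.exp(thetas[:, spec.n_alpha])
    bias = thetas[:, spec.n_alpha + 1] if spec.include_bias else np.zeros(D)

    # expand free alphas to the (block, valence) grid per draw
    grid = np.empty((D, 3, 2))
    if spec.split_block and spec.split_valence:
        grid[:] = alphas.reshape(D, 3, 2)
    elif spec.split_valence:
        grid[:] = alphas.reshape(D, 1, 2)
    elif spec.split_block:
        grid[:] = alphas.reshape(D, 3, 1)
    else:
        grid[:] = alphas.reshape(D, 1, 1)

    v_win = np.empty((D, cache.n_trials))
    v_loss = np.empty((D, cache.n_trials))
    for b, idx, win_on, loss_on in cache.blocks:
        v_win[:, idx] = _values_many(win_on, grid[:, b, 0])
        v_loss[:, idx] = _values_many(loss_on, grid[:, b, 1])

    x = 2.0 * beta[:, None] * (v_win - v_loss) + bias[:, None]
    p_A = expit(x)
    p = np.where(cache.chose_A[None, :], p_A, 1.0 - p_A)
    return np.sum(np.log(np.maximum(p, 1e-10)), axis=1)


# ---------------------------------------------------------------------------
# MAP fitting


@dataclass
class FitResult:
    subject_id: str
    model: str
    spec: ModelSpec
    params: AgentParams
    theta: np.ndarray
    log_lik: float
    log_post: float
    converged: bool
    draws: np.ndarray | None = None  # (n, n_free) natural-scale posterior draws
    diagnostics: dict = field(default_factory=dict)


def fit_map(
    dataset: SubjectDataset,
    spec: ModelSpec = WINNING_MODEL,
    prior: PriorSpec | None = None,
    n_restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Maximum a-posteriori fit from ``n_restarts`` random starts.

    Starts are the prior mean plus unit-scale perturbations; the best
    converged optimum (highest log posterior) is returned.
    """
    prior = prior or default_prior(spec)
    rng = rng or np.random.default_rng(0)
    cache = _TrialCache(dataset)

    def neg_log_post(theta: np.ndarray) -> float:
        return -(float(_loglik_thetas(theta[None, :], spec, cache)[0]) + prior.log_pdf(theta))

    best = None
    any_converged = False
    for r in range(max(1, n_restarts)):
        start = prior.mean.copy() if r == 0 else prior.mean + rng.standard_normal(prior.mean.size)
        res = minimize(neg_log_post, start, method="L-BFGS-B")
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        warnings.warn(f"no MAP restart converged for subject {dataset.subject_id}", RuntimeWarning)

    theta_hat = best.x
    params = theta_to_params(theta_hat, spec)
    ll = log_likelihood(dataset, params)
    return FitResult(
        subject_id=dataset.subject_id,
        model=spec.name,
        spec=spec,
        params=params,
        theta=theta_hat,
        log_lik=ll,
        log_post=-float(best.fun),
        converged=any_converged,
        diagnostics={"n_restarts": n_restarts, "nfev": int(best.nfev)},
    )


# ---------------------------------------------------------------------------
# MCMC


def sample_posterior(
    dataset: SubjectDataset,
    spec: ModelSpec = WINNING_MODEL,
    prior: PriorSpec | None = None,
    n_samples: int = 2000,
    rng: np.random.Generator | None = None,
    burn_in: int = 1000,
    init: np.ndarray | None = None,
) -> FitResult:
    """Adaptive random-walk Metropolis sampling on the transformed scale.

    The proposal scale adapts every 50 burn-in steps toward a 20-45 %
    acceptance rate; post-burn-in draws are returned on the natural scale
    (columns: free alphas..., beta, bias?).  Acceptance below 5 % after
    adaptation raises a diagnostic error.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    prior = prior or default_prior(spec)
    rng = rng or np.random.default_rng(0)
    cache = _TrialCache(dataset)

    def log_post(theta: np.ndarray) -> float:
        return float(_loglik_thetas(theta[None, :], spec, cache)[0]) + prior.log_pdf(theta)

    theta = init.copy() if init is not None else prior.mean.copy()
    lp = log_post(theta)
    scale = 0.2
    n_free = prior.mean.size

    accepted_window = 0
    draws = np.empty((n_samples, n_free))
    accepted_total = 0
    for i in range(burn_in + n_samples):
        prop = theta + scale * rng.standard_normal(n_free)
        lp_prop = log_post(prop)
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            accepted_window += 1
            if i >= burn_in:
                accepted_total += 1
        if i < burn_in and (i + 1) % 50 == 0:
            rate = accepted_window / 50
            if rate < 0.20:
                scale *= 0.7
            elif rate > 0.45:
                scale *= 1.4
            accepted_window = 0
        elif i == burn_in:
            accepted_window = 0
        if i >= burn_in:
            draws[i - burn_in] = theta

    acc_rate = accepted_total / n_samples
    if acc_rate < 0.05:
        raise RuntimeError(
            f"Metropolis acceptance rate {acc_rate:.3f} below 5% after adaptation "
            f"for subject {dataset.subject_id}"
        )

    natural = draws.copy()
    natural[:, : spec.n_alpha] = expit(draws[:, : spec.n_alpha])
    natural[:, spec.n_alpha] = np.exp(draws[:, spec.n_alpha])
    post_mean_theta = draws.mean(axis=0)
    params = theta_to_params(post_mean_theta, spec)
    return FitResult(
        subject_id=dataset.subject_id,
        model=spec.name,
        spec=spec,
        params=params,
        theta=post_mean_theta,
        log_lik=log_likelihood(dataset, params),
        log_post=lp,
        converged=True,
        draws=natural,
        diagnostics={"acceptance_rate": acc_rate, "n_draws": n_samples, "proposal_scale": scale},
    )


# ---------------------------------------------------------------------------
# integrated BIC


def log_marginal(
    dataset: SubjectDataset,
    spec: ModelSpec,
    prior: PriorSpec,
    n_mc: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo estimate of log p(data) = log E_prior[likelihood]."""
    rng = rng or np.random.default_rng(0)
    cache = _TrialCache(dataset)
    ll = _loglik_thetas(prior.sample(n_mc, rng), spec, cache)
    m = np.max(ll)
    return float(m + np.log(np.mean(np.exp(ll - m))))


@dataclass
class ModelComparison:
    table: pd.DataFrame  # one row per model: model, sum_log_marginal, k_prior, penalty, ibic
    winner: str

    def __repr__(self) -> str:  # pragma: no cover
        return f"ModelComparison(winner={self.winner!r})\n{self.table}"


def integrated_bic(
    datasets: list[SubjectDataset],
    spec: ModelSpec,
    prior: PriorSpec | None = None,
    n_mc: int = 2000,
    rng: np.random.Generator | None = None,
    em_iters: int = 3,
    n_restarts: int = 2,
    sd_floor: float = 0.1,
    return_prior: bool = False,
):
    """iBIC score for one model over a cohort.

    Empirical-Bayes scheme: starting from the default prior, subjects are
    fitted by MAP, the prior's moments are refitted to the transformed
    estimates (sds floored at ``sd_floor``), and the cycle repeats
    ``em_iters`` times.  Per-subject marginal likelihoods are then
    estimated by averaging the likelihood over ``n_mc`` prior draws
    (log-sum-exp), and

        iBIC = -2 * sum_s log p(data_s | prior) + k * log(N_choices)

    with k = number of prior hyperparameters (a mean and sd per free
    parameter).
    """
    if len(datasets) < 2:
        raise ValueError("integrated_bic needs at least 2 subjects")
    rng = rng or np.random.default_rng(0)
    prior = prior or default_prior(spec)

    for _ in range(max(1, em_iters)):
        thetas = np.stack(
            [fit_map(d, spec, prior, n_restarts=n_restarts, rng=rng).theta for d in datasets]
        )
        sd = np.std(thetas, axis=0, ddof=1)
        if np.any(sd < sd_floor):
            warnings.warn("degenerate group prior variance floored", RuntimeWarning)
        prior = PriorSpec(mean=np.mean(thetas, axis=0), sd=np.maximum(sd, sd_floor))

    total_log_marg = 0.0
    draws = prior.sample(n_mc, rng)
    for d in datasets:
        cache = _TrialCache(d)
        ll = _loglik_thetas(draws, spec, cache)
        # log mean exp of the likelihood over prior draws
        m = np.max(ll)
        total_log_marg += m + np.log(np.mean(np.exp(ll - m)))

    n_choices = sum(len(d.choices) for d in datasets)
    penalty = prior.n_hyper * np.log(n_choices)
    ibic = -2.0 * total_log_marg + penalty
    row = {
        "model": spec.name,
        "sum_log_marginal": total_log_marg,
        "k_prior": prior.n_hyper,
        "penalty": penalty,
        "ibic": ibic,
    }
    if return_prior:
        return row, prior
    return row


def compare_models(
    datasets: list[SubjectDataset],
    specs: tuple[ModelSpec, ...] = MODEL_FAMILY,
    n_mc: int = 2000,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> ModelComparison:
    """iBIC table across a model family; the winner minimises iBIC."""
    rng = rng or np.random.default_rng(0)
    rows = [integrated_bic(datasets, spec, n_mc=n_mc, rng=rng, **kwargs) for spec in specs]
    table = pd.DataFrame(rows).sort_values("ibic").reset_index(drop=True)
    return ModelComparison(table=table, winner=str(table["model"].iloc[0]))


# ---------------------------------------------------------------------------
# recovery and posterior-predictive harnesses


def parameter_recovery(
    spec: ModelSpec = WINNING_MODEL,
    true_params: list[AgentParams] | None = None,
    n_reps: int = 30,
    rng: np.random.Generator | None = None,
    schedule_config: ScheduleConfig | None = None,
    prior: PriorSpec | None = None,
    corr_threshold: float = 0.5,
) -> pd.DataFrame:
    """Simulate-and-refit recovery table.

    If ``true_params`` is not given, ``n_reps`` parameter sets are drawn
    with learning rates uniform on [0.05, 0.8] and beta uniform on
    [1, 15].  Returns one row per free parameter with the true-vs-
    recovered Pearson correlation, mean bias and RMSE; parameters with
    correlation below ``corr_threshold`` (or undefined) are flagged.
    """
    rng = rng or np.random.default_rng(0)
    if true_params is None:
        true_params = []
        for _ in range(n_reps):
            alphas = rng.uniform(0.05, 0.8, size=spec.n_alpha)
            beta = rng.uniform(1.0, 15.0)
            bias = rng.normal(0, 0.5) if spec.include_bias else 0.0
            true_params.append(AgentParams.from_free(spec, alphas, beta, bias))

    true_rows, fit_rows = [], []
    for i, params in enumerate(true_params):
        cfg = schedule_config or ScheduleConfig()
        cfg = ScheduleConfig(**{**cfg.__dict__, "seed": int(rng.integers(2**31))})
        sched = generate_schedule(cfg)
        ds = simulate_agent(sched, params, rng, subject_id=f"rec{i}")
        fit = fit_map(ds, spec, prior, rng=rng)
        true_rows.append(np.concatenate([params.free_alphas(spec), [params.beta], [params.bias] if spec.include_bias else []]))
        fit_rows.append(np.concatenate([fit.params.free_alphas(spec), [fit.params.beta], [fit.params.bias] if spec.include_bias else []]))

    true_m = np.stack(true_rows)
    fit_m = np.stack(fit_rows)
    names = [f"alpha_{i}" for i in range(spec.n_alpha)] + ["beta"] + (["bias"] if spec.include_bias else [])
    out = []
    for j, name in enumerate(names):
        if len(true_params) < 2 or np.std(true_m[:, j]) == 0 or np.std(fit_m[:, j]) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(true_m[:, j], fit_m[:, j])[0, 1])
        err = fit_m[:, j] - true_m[:, j]
        out.append(
            {
                "parameter": name,
                "correlation": r,
                "bias": float(np.mean(err)),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "flagged": bool(np.isnan(r) or r < corr_threshold),
            }
        )
    return pd.DataFrame(out)


def _stay_props(chose: np.ndarray, received: np.ndarray, cell_mask: np.ndarray, last_of_block: np.ndarray) -> np.ndarray:
    """Raw stay proportions per row of a (S, T) choice matrix for one cell."""
    use = received & cell_mask[None, :] & ~last_of_block[None, :]
    stay = np.zeros_like(chose, dtype=bool)
    stay[:, :-1] = chose[:, 1:] == chose[:, :-1]
    n = use.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, (stay & use).sum(axis=1) / np.maximum(n, 1), np.nan)


def posterior_predictive_check(
    fits: list[FitResult],
    datasets: list[SubjectDataset],
    rng: np.random.Generator | None = None,
    n_sims: int = 100,
) -> pd.DataFrame:
    """Simulate each fitted subject and compare stay statistics.

    For every subject x (valence, volatility) cell, reports the observed
    stay proportion, the mean over ``n_sims`` simulations at the fitted
    parameters, the simulated 95 % interval, and whether the observation
    falls inside it.  A row per subject also reports total wins received.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rng = rng or np.random.default_rng(0)
    from .agents import choice_probabilities  # local to avoid re-export noise

    rows = []
    for fit, ds in zip(fits, datasets):
        t = ds.schedule.trials
        win_on = t["win_on_A"].to_numpy(dtype=bool)
        loss_on = t["loss_on_A"].to_numpy(dtype=bool)
        block = t["block"].to_numpy()
        last_of_block = np.zeros(len(t), dtype=bool)
        last_of_block[np.flatnonzero(np.diff(block) != 0)] = True
        last_of_block[-1] = True
        spec_by_block = {b.index: b for b in ds.schedule.blocks}
        vol_win = np.array([spec_by_block[int(b)].win_condition == "volatile" for b in block])
        vol_loss = np.array([spec_by_block[int(b)].loss_condition == "volatile" for b in block])

        p_A = choice_probabilities(t, fit.params)
        sim_chose = rng.random((n_sims, len(t))) < p_A[None, :]
        obs_chose = ds.choices["chose_A"].to_numpy(dtype=bool)[None, :]
        cells = [
            ("win", "volatile", win_on, vol_win),
            ("win", "stable", win_on, ~vol_win),
            ("loss", "volatile", loss_on, vol_loss),
            ("loss", "stable", loss_on, ~vol_loss),
        ]
        for valence, vol, on_A, mask in cells:
            sim_received = sim_chose == on_A[None, :]
            obs_received = obs_chose == on_A[None, :]
            sim_p = _stay_props(sim_chose, sim_received, mask, last_of_block)
            obs_p = _stay_props(obs_chose, obs_received, mask, last_of_block)[0]
            sim_p = sim_p[np.isfinite(sim_p)]
            lo, hi = (np.percentile(sim_p, [2.5, 97.5]) if sim_p.size else (np.nan, np.nan))
            rows.append(
                {
                    "subject_id": ds.subject_id,
                    "statistic": f"stay_{valence}_{vol}",
                    "observed": obs_p,
                    "simulated_mean": float(np.mean(sim_p)) if sim_p.size else np.nan,
                    "lo95": float(lo),
                    "hi95": float(hi),
                    "inside": bool(np.isfinite(obs_p) and lo <= obs_p <= hi),
                }
            )
        sim_wins = (sim_chose == win_on[None, :]).sum(axis=1)
        obs_wins = int((obs_chose[0] == win_on).sum())
        lo, hi = np.percentile(sim_wins, [2.5, 97.5])
        rows.append(
            {
                "subject_id": ds.subject_id,
                "statistic": "total_wins",
                "observed": obs_wins,
                "simulated_mean": float(np.mean(sim_wins)),
                "lo95": float(lo),
                "hi95": float(hi),
                "inside": bool(lo <= obs_wins <= hi),
            }
        )
    return pd.DataFrame(rows)
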
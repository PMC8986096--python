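"""Likelihood evaluation, model fitting, and WAIC model comparison.

Two fitting routes are provided:

* :func:`fit_mle` — per-animal maximum likelihood (bounded L-BFGS-B with
  random multistarts).  Point fits carry an AIC-style criterion
  (``-2 ll + 2k``) since WAIC needs a posterior.
* :func:`fit_hierarchical` — hierarchical Bayesian fit in which each
  animal's parameters are drawn from group-level Normal distributions on
  transformed scales (logit for [0,1]-bounded parameters, log for the
  inverse temperature, identity for bias and perseveration).  Sampling uses
  an affine-invariant ensemble sampler (emcee); WAIC and its standard error
  are computed from the posterior pointwise log-likelihood matrix.

Model comparison (:func:`compare_models`) reports criterion differences
against a baseline with standard errors from paired per-trial contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from . import _kernels
from .models import MODELS, ModelParams
from .task import TrialRecord, records_to_frame

_LOGIT_PARAMS = ("eta", "gamma", "lapse", "w4", "rho")

#: free parameters, their box bounds, and ranges for random restarts
_BASE_SPEC = [
    ("eta", (1e-6, 1.0), (0.05, 0.6)),
    ("gamma", (1e-6, 1.0), (0.3, 0.99)),
    ("beta", (1e-3, 20.0), (0.5, 8.0)),
    ("bias_b", (-5.0, 5.0), (-1.0, 1.0)),
    ("persev_p", (-5.0, 5.0), (-1.0, 1.0)),
    ("lapse", (0.0, 1.0), (0.01, 0.2)),
]


def param_spec(model: str, fixed: Mapping[str, float] | None = None):
    """Ordered (name, bounds, init-range) triples of free parameters."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    spec = list(_BASE_SPEC)
    if model == "hybrid_value":
        spec.append(("w4", (0.0, 1.0), (0.05, 0.95)))
    elif model == "hybrid_learning":
        # eta_g = eta * rho keeps eta_g <= eta by construction
        spec.append(("rho", (0.0, 1.0), (0.05, 0.95)))
    fixed = fixed or {}
    unknown = set(fixed) - {name for name, _, _ in spec}
    if unknown:
        raise ValueError(f"fixed parameters {sorted(unknown)} not free in {model}")
    return [s for s in spec if s[0] not in fixed]


def vector_to_params(
    model: str, x: Sequence[float], fixed: Mapping[str, float] | None = None
) -> ModelParams:
    fixed = dict(fixed or {})
    names = [name for name, _, _ in param_spec(model, fixed)]
    kw = dict(zip(names, map(float, x)))
    kw.update(fixed)
    rho = kw.pop("rho", None)
    if model == "hybrid_learning":
        kw["eta_g"] = kw["eta"] * (rho if rho is not None else 0.0)
    return ModelParams(**kw)


def params_to_vector(
    model: str, params: ModelParams, fixed: Mapping[str, float] | None = None
) -> np.ndarray:
    vals = {
        "eta": params.eta,
        "gamma": params.gamma,
        "beta": params.beta,
        "bias_b": params.bias_b,
        "persev_p": params.persev_p,
        "lapse": params.lapse,
        "w4": params.w4 if params.w4 is not None else 0.0,
        "rho": (params.eta_g / params.eta) if (params.eta_g and params.eta) else 0.0,
    }
    return np.array([vals[name] for name, _, _ in param_spec(model, fixed)])


# ---------------------------------------------------------------------------
# data encoding


_ODOR_CODE = {"left_forced": 0, "right_forced": 1, "free": 2}
_CHOICE_CODE = {"left": 0, "right": 1}


@dataclass(frozen=True)
class EncodedTrials:
    """Trial log flattened into kernel-ready arrays (session-reset flags set
    at every (animal, session) boundary, in row order)."""

    odor: np.ndarray
    choice: np.ndarray
    valid: np.ndarray
    r: np.ndarray
    d: np.ndarray
    new_sess: np.ndarray
    animal: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.odor)


def as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def encode_trials(records) -> EncodedTrials:
    df = as_frame(records)
    if len(df) == 0:
        raise ValueError("no trials to encode")
    odor = df["odor"].map(_ODOR_CODE)
    choice = df["choice"].map(_CHOICE_CODE)
    if odor.isna().any() or choice.isna().any():
        raise ValueError("records contain unknown odor or missing choice values")
    key = df["animal_id"].astype(str) + "\x00" + df["session_id"].astype(str)
    new_sess = np.ones(len(df), dtype=np.bool_)
    new_sess[1:] = key.to_numpy()[1:] != key.to_numpy()[:-1]
    d = df["reward_delay_s"].to_numpy(dtype=np.float64).copy()
    d[~np.isfinite(d)] = 0.5  # irrelevant when r = 0
    return EncodedTrials(
        odor=odor.to_numpy(dtype=np.int64),
        choice=choice.to_numpy(dtype=np.int64),
        valid=df["valid"].to_numpy(dtype=np.bool_),
        r=df["reward_drops"].to_numpy(dtype=np.float64),
        d=d,
        new_sess=new_sess,
        animal=df["animal_id"].astype(str).to_numpy(),
    )


def p_left_trials(model: str, params: ModelParams, enc: EncodedTrials) -> np.ndarray:
    """Per-trial P(left) via the compiled kernels."""
    common = (enc.odor, enc.choice, enc.valid, enc.r, enc.d, enc.new_sess)
    if model == "hybrid_learning":
        return _kernels.hybrid_learning_p_left(
            *common,
            params.eta,
            params.gamma,
            params.beta,
            params.bias_b,
            params.persev_p,
            params.eta_g or 0.0,
            params.lapse,
        )
    if model == "four_state":
        w4 = 1.0
    elif model == "six_state":
        w4 = 0.0
    elif model == "hybrid_value":
        w4 = params.w4 if params.w4 is not None else 0.0
    else:
        raise ValueError(f"unknown model {model!r}")
    return _kernels.hybrid_value_p_left(
        *common,
        params.eta,
        params.gamma,
        params.beta,
        params.bias_b,
        params.persev_p,
        w4,
        params.lapse,
    )


def per_trial_probabilities(model: str, params: ModelParams, records) -> pd.DataFrame:
    """Per-trial probability dump for oracle testing: one row per trial with
    the model's pre-choice P(left), the chosen side, and its log-likelihood."""
    df = as_frame(records)
    enc = encode_trials(df)
    pl = p_left_trials(model, params, enc)
    p_chosen = np.where(enc.choice == 0, pl, 1.0 - pl)
    return pd.DataFrame(
        {
            "animal_id": df["animal_id"].to_numpy(),
            "session_id": df["session_id"].to_numpy(),
            "trial_index": df["trial_index"].to_numpy(),
            "p_left": pl,
            "chosen": df["choice"].to_numpy(),
            "loglik": np.log(np.clip(p_chosen, 1e-300, 1.0)),
        }
    )


def session_loglik(
    model: str, params: ModelParams, records
) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood of the recorded choices."""
    enc = records if isinstance(records, EncodedTrials) else encode_trials(records)
    pl = p_left_trials(model, params, enc)
    p_chosen = np.where(enc.choice == 0, pl, 1.0 - pl)
    per_trial = np.log(np.clip(p_chosen, 1e-300, 1.0))
    return float(per_trial.sum()), per_trial


# ---------------------------------------------------------------------------
# WAIC


@dataclass(frozen=True)
class WAICResult:
    waic: float
    waic_se: float
    p_waic: float
    lppd: float
    pointwise: np.ndarray  # per-trial -2*(lppd_i - p_i) contributions


def compute_waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """WAIC = -2 (lppd - p_waic) from an (S samples x T trials) log-lik matrix.

    lppd_i = log mean_s exp(ll_si); p_i = Var_s(ll_si) (unbiased); the
    standard error scales the per-trial contribution SD by sqrt(T).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be 2-D (samples x trials)")
    s, t = ll.shape
    if s < 2:
        raise ValueError("WAIC needs at least 2 posterior samples (p_waic undefined)")
    if np.any(ll > 1e-9):
        raise ValueError("log-likelihood entries must be non-positive")
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    pointwise = -2.0 * elpd_i
    waic = float(pointwise.sum())
    se = float(np.sqrt(t * pointwise.var(ddof=1))) if t > 1 else 0.0
    return WAICResult(waic, se, float(p_i.sum()), float(lppd_i.sum()), pointwise)


# ---------------------------------------------------------------------------
# fit results


@dataclass
class FitResult:
    """Outcome of an MLE or hierarchical fit (lower ``ic`` = better fit)."""

    model: str
    method: str
    ic_kind: str  # "waic" (posterior fits) or "aic" (point fits)
    ic: float
    ic_se: float
    p_eff: float
    loglik: float
    n_trials: int
    n_free: int
    pointwise_ll: np.ndarray  # (samples x trials)
    pointwise_ic: np.ndarray  # per-trial criterion contributions
    animal_per_trial: np.ndarray
    params: ModelParams | None = None
    params_by_animal: dict[str, ModelParams] | None = None
    samples: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True

    # lower-waic-is-better convention preserved end-to-end
    @property
    def waic(self) -> float:
        return self.ic

    @property
    def waic_se(self) -> float:
        return self.ic_se


def fit_mle(
    model: str,
    records,
    n_restarts: int = 10,
    seed: int = 0,
    fixed: Mapping[str, float] | None = None,
    init: ModelParams | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one agent's trial log.

    Bounded L-BFGS-B from ``n_restarts`` random starts (plus a midpoint
    start and, if given, ``init``); the best optimum is kept.  Sessions are
    processed in order with values reset at each session start.
    Non-convergence across all restarts is flagged in ``diagnostics`` and
    ``converged``, never silent.
    """
    enc = records if isinstance(records, EncodedTrials) else encode_trials(records)
    spec = param_spec(model, fixed)
    bounds = [b for _, b, _ in spec]
    rng = np.random.default_rng(seed)

    def neg_ll(x):
        params = vector_to_params(model, x, fixed)
        total, _ = session_loglik(model, params, enc)
        return -total

    starts = [np.array([(lo + hi) / 2.0 for lo, hi in bounds])]
    if init is not None:
        starts.append(np.clip(params_to_vector(model, init, fixed), *zip(*bounds)))
    while len(starts) < max(n_restarts, 1) + 1:
        starts.append(np.array([rng.uniform(lo, hi) for _, _, (lo, hi) in spec]))

    best, any_success = None, False
    for x0 in starts:
        res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = vector_to_params(model, best.x, fixed)
    total, per_trial = session_loglik(model, params, enc)
    k = len(spec)
    aic = -2.0 * total + 2.0 * k
    pointwise_ic = -2.0 * per_trial + 2.0 * k / enc.n_trials
    ic_se = (
        float(np.sqrt(enc.n_trials * pointwise_ic.var(ddof=1)))
        if enc.n_trials > 1
        else 0.0
    )
    if not any_success:
        warnings.warn(f"MLE fit of {model} did not converge in any restart")
    return FitResult(
        model=model,
        method="mle",
        ic_kind="aic",
        ic=float(aic),
        ic_se=ic_se,
        p_eff=float(k),
        loglik=float(total),
        n_trials=enc.n_trials,
        n_free=k,
        pointwise_ll=per_trial[None, :],
        pointwise_ic=pointwise_ic,
        animal_per_trial=enc.animal,
        params=params,
        diagnostics={"n_restarts": len(starts), "optimizer_success": any_success},
        converged=any_success,
    )


# ---------------------------------------------------------------------------
# hierarchical Bayesian fitting (ensemble MCMC)


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler settings; defaults mirror 2000 iterations with 1500
    warm-up.  ``n_walkers`` defaults to 2*dim + 2."""

    n_steps: int = 2000
    n_warmup: int = 1500
    n_walkers: int | None = None
    thin: int = 4
    seed: int = 0
    fixed: Mapping[str, float] | None = None
    init_from_mle: bool = True
    mle_restarts: int = 3
    max_pointwise_samples: int = 200
    mu_prior_scale: float = 2.5
    sigma_prior_scale: float = 1.0


def _to_unconstrained(name: str, x: float) -> float:
    if name in _LOGIT_PARAMS:
        return float(logit(np.clip(x, 1e-6, 1 - 1e-6)))
    if name == "beta":
        return float(np.log(max(x, 1e-6)))
    return float(x)


def _to_constrained(name: str, z):
    if name in _LOGIT_PARAMS:
        return expit(z)
    if name == "beta":
        return np.exp(np.clip(z, -20.0, 6.0))
    return z


def hdi(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Highest-density interval of a 1-D sample (95% convention)."""
    import arviz as az

    lo, hi = az.hdi(np.asarray(samples, dtype=float), hdi_prob=prob)
    return float(lo), float(hi)


def fit_hierarchical(
    model: str, records, config: SamplerConfig | None = None
) -> FitResult:
    """Hierarchical Bayesian fit: per-animal parameters drawn from group
    Normals on transformed scales, sampled with emcee.

    Returns posterior samples on the constrained scale per animal
    (``"<param>[<animal>]"``), the group mean back-transformed to the
    constrained scale (``"group_<param>"``) and the group SD on the
    transformed scale (``"group_sigma_<param>"``), plus WAIC from the
    posterior pointwise log-likelihood.  Convergence problems are flagged in
    ``diagnostics``; the result is still returned.
    """
    import emcee

    config = config or SamplerConfig()
    df = as_frame(records)
    animals = list(dict.fromkeys(df["animal_id"].astype(str)))
    if len(animals) < 2:
        raise ValueError("hierarchical fit needs at least 2 animals")
    encs = {a: encode_trials(df[df["animal_id"].astype(str) == a]) for a in animals}
    fixed = dict(config.fixed or {})
    spec = param_spec(model, fixed)
    names = [name for name, _, _ in spec]
    P, A = len(names), len(animals)
    dim = 2 * P + A * P
    mu_scale, sig_scale = config.mu_prior_scale, config.sigma_prior_scale

    def log_prob(theta):
        mu = theta[:P]
        log_sig = theta[P : 2 * P]
        if np.any(np.abs(theta) > 50):
            return -np.inf
        sigma = np.exp(log_sig)
        z = theta[2 * P :].reshape(A, P)
        lp = -0.5 * np.sum((mu / mu_scale) ** 2)
        lp += np.sum(-0.5 * (sigma / sig_scale) ** 2 + log_sig)  # HalfNormal + jacobian
        lp += np.sum(-0.5 * ((z - mu) / sigma) ** 2 - log_sig)
        for i, a in enumerate(animals):
            x = [_to_constrained(n, z[i, j]) for j, n in enumerate(names)]
            try:
                params = vector_to_params(model, x, fixed)
            except ValueError:
                return -np.inf
            ll, _ = session_loglik(model, params, encs[a])
            lp += ll
        return lp if np.isfinite(lp) else -np.inf

    # initialize near per-animal MLEs (cheap, improves mixing markedly)
    z0 = np.zeros((A, P))
    if config.init_from_mle:
        for i, a in enumerate(animals):
            fit = fit_mle(
                model, encs[a], n_restarts=config.mle_restarts, seed=config.seed + i,
                fixed=fixed,
            )
            vec = params_to_vector(model, fit.params, fixed)
            z0[i] = [_to_unconstrained(n, v) for n, v in zip(names, vec)]
    mu0 = z0.mean(axis=0)
    sig0 = np.log(z0.std(axis=0) + 0.2)
    center = np.concatenate([mu0, sig0, z0.ravel()])

    n_walkers = config.n_walkers or (2 * dim + 2)
    rng = np.random.default_rng(config.seed)
    p0 = center[None, :] + 0.05 * rng.standard_normal((n_walkers, dim))
    np.random.seed(config.seed % (2**32 - 1))
    sampler = emcee.EnsembleSampler(n_walkers, dim, log_prob)
    sampler.run_mcmc(p0, config.n_steps, progress=False)

    chain = sampler.get_chain(discard=config.n_warmup, thin=config.thin)
    kept = chain.reshape(-1, dim)  # (draws*walkers, dim)

    cols = {}
    for j, n in enumerate(names):
        cols[f"group_{n}"] = _to_constrained(n, kept[:, j])
        cols[f"group_sigma_{n}"] = np.exp(kept[:, P + j])
    for i, a in enumerate(animals):
        for j, n in enumerate(names):
            cols[f"{n}[{a}]"] = _to_constrained(n, kept[:, 2 * P + i * P + j])
    samples = pd.DataFrame(cols)

    # posterior pointwise log-likelihood (thinned draws), trials in df order
    enc_all = encode_trials(df)
    take = np.linspace(
        0, len(kept) - 1, min(config.max_pointwise_samples, len(kept))
    ).astype(int)
    pw = np.empty((len(take), enc_all.n_trials))
    animal_index = {a: i for i, a in enumerate(animals)}
    row_animal = df["animal_id"].astype(str).to_numpy()
    for s_i, k in enumerate(take):
        z = kept[k, 2 * P :].reshape(A, P)
        for a in animals:
            x = [_to_constrained(n, z[animal_index[a], j]) for j, n in enumerate(names)]
            params = vector_to_params(model, x, fixed)
            _, pt = session_loglik(model, params, encs[a])
            pw[s_i, row_animal == a] = pt
    w = compute_waic(pw)

    params_by_animal = {}
    for a in animals:
        x = [samples[f"{n}[{a}]"].mean() for n in names]
        params_by_animal[a] = vector_to_params(model, x, fixed)

    diagnostics = {
        "n_walkers": n_walkers,
        "n_steps": config.n_steps,
        "n_warmup": config.n_warmup,
        "mean_acceptance": float(np.mean(sampler.acceptance_fraction)),
    }
    converged = True
    try:
        import arviz as az

        mu_chain = chain[:, :, :P]  # (draws, walkers, P)
        rhats = [float(az.rhat(mu_chain[:, :, j].T)) for j in range(P)]
        diagnostics["max_rhat_group_mu"] = max(rhats)
        converged = max(rhats) < 1.2
    except Exception as exc:  # diagnostics must never void the result
        diagnostics["rhat_error"] = repr(exc)
    diagnostics["converged"] = converged

    return FitResult(
        model=model,
        method="hierarchical_mcmc",
        ic_kind="waic",
        ic=w.waic,
        ic_se=w.waic_se,
        p_eff=w.p_waic,
        loglik=w.lppd,
        n_trials=enc_all.n_trials,
        n_free=P * (A + 2),
        pointwise_ll=pw,
        pointwise_ic=w.pointwise,
        animal_per_trial=enc_all.animal,
        params_by_animal=params_by_animal,
        samples=samples,
        diagnostics=diagnostics,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# model comparison


@dataclass(frozen=True)
class ComparisonResult:
    """ΔIC table against a baseline plus per-animal per-trial differences."""

    table: pd.DataFrame
    per_animal: pd.DataFrame
    baseline: str


def compare_models(fits: Sequence[FitResult], baseline: str) -> ComparisonResult:
    """Criterion differences (model − baseline) with paired-difference SEs.

    All fits must cover the identical trial set; the SE of each difference
    comes from the per-trial paired contributions, sd * sqrt(T).
    """
    by_model = {f.model: f for f in fits}
    if baseline not in by_model:
        raise ValueError(f"baseline {baseline!r} not among fitted models")
    base = by_model[baseline]
    rows, pa_rows = [], []
    for f in fits:
        if f.n_trials != base.n_trials or not np.array_equal(
            f.animal_per_trial, base.animal_per_trial
        ):
            raise ValueError(f"fit of {f.model} covers a different trial set")
        delta_i = f.pointwise_ic - base.pointwise_ic
        d = float(delta_i.sum())
        d_se = (
            float(np.sqrt(f.n_trials * delta_i.var(ddof=1))) if f.n_trials > 1 else 0.0
        )
        rows.append(
            {
                "model": f.model,
                "ic_kind": f.ic_kind,
                "ic": f.ic,
                "ic_se": f.ic_se,
                "d_ic": d,
                "d_ic_se": d_se,
            }
        )
        for a in dict.fromkeys(f.animal_per_trial):
            mask = f.animal_per_trial == a
            pa_rows.append(
                {
                    "model": f.model,
                    "animal_id": a,
                    "d_ic_per_trial": float(delta_i[mask].mean()),
                    "n_trials": int(mask.sum()),
                }
            )
    return ComparisonResult(pd.DataFrame(rows), pd.DataFrame(pa_rows), baseline)
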
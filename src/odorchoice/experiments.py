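"""Desk-scale simulation studies validating the modeling pipeline.

The real cohort's data are not public, so the questions the fitted models
answer there are re-posed here on synthetic agents with known parameters:

* :func:`reward_vs_w4` — how much reward does a shared (four-state)
  representation actually buy?  Simulate the hybrid-value "average rat"
  across a grid of w4 and measure drops per trial.
* :func:`recovery_study` — simulate a population of agents, refit each by
  maximum likelihood, and report true-vs-recovered correlations and biases.
* :func:`identifiability_matrix` — simulate from each generator model, fit
  all candidates, and tabulate which model wins (lowest criterion).
* :func:`split_half_analysis` — fit a model pair to the first and second
  halves of each animal's sessions and report per-animal changes in fit
  advantage and in w4.

Every entry point takes a single integer seed; all child streams derive
from it via ``numpy.random.SeedSequence``, and each returns a manifest
recording the seeds used.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import compare_models, fit_mle
from .models import MODELS, ModelParams, simulate_agent
from .task import SessionConfig, build_session_schedule, records_to_frame

logger = logging.getLogger(__name__)

#: "average rat" defaults for forward simulations.  eta is the center of a
#: plausible group range; the remaining values are documented choices, not
#: fitted estimates (the original cohort's posteriors are unavailable).
AVERAGE_RAT = ModelParams(
    eta=0.25, gamma=0.8, beta=3.0, bias_b=0.0, persev_p=0.2, lapse=0.02
)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def simulate_dataset(
    model: str,
    params_by_animal: Mapping[str, ModelParams],
    n_sessions: int,
    seed: int,
    session_config: SessionConfig | None = None,
) -> pd.DataFrame:
    """Closed-loop trial logs for a cohort of agents, as one DataFrame."""
    session_config = session_config or SessionConfig()
    animals = list(params_by_animal)
    seeds = _child_seeds(seed, 2 * len(animals) * n_sessions)
    frames, k = [], 0
    for animal in animals:
        for s in range(n_sessions):
            schedule = build_session_schedule(session_config, seeds[k])
            recs = simulate_agent(
                model,
                params_by_animal[animal],
                schedule,
                seeds[k + 1],
                staircase_config=session_config.staircase,
                animal_id=animal,
                session_id=f"s{s:03d}",
            )
            frames.append(records_to_frame(recs))
            k += 2
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# reward yield as a function of the representation weight


def reward_vs_w4(
    params: ModelParams | None = None,
    w4_grid: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_sessions: int = 200,
    seed: int = 0,
    session_config: SessionConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Mean reward drops per trial for hybrid-value agents across a w4 grid.

    Session schedules and agent choice randomness reuse the same child seeds
    at every grid point, so the w4 = 0 and w4 = 1 endpoints coincide exactly
    with direct six-state / four-state simulations at the same seed.
    """
    params = params or AVERAGE_RAT
    if any(not 0.0 <= w <= 1.0 for w in w4_grid):
        raise ValueError("w4 grid must lie in [0, 1]")
    session_config = session_config or SessionConfig()
    seeds = _child_seeds(seed, 2 * n_sessions)
    rows = []
    for w4 in w4_grid:
        pw = ModelParams(
            eta=params.eta,
            gamma=params.gamma,
            beta=params.beta,
            bias_b=params.bias_b,
            persev_p=params.persev_p,
            lapse=params.lapse,
            w4=float(w4),
        )
        per_session = []
        for s in range(n_sessions):
            schedule = build_session_schedule(session_config, seeds[2 * s])
            recs = simulate_agent(
                "hybrid_value",
                pw,
                schedule,
                seeds[2 * s + 1],
                staircase_config=session_config.staircase,
            )
            per_session.append(float(np.mean([r.reward_drops for r in recs])))
        per_session = np.array(per_session)
        rows.append(
            {
                "w4": float(w4),
                "mean_reward_per_trial": float(per_session.mean()),
                "sem": float(per_session.std(ddof=1) / np.sqrt(n_sessions)),
            }
        )
    manifest = {"seed": seed, "n_sessions": n_sessions, "w4_grid": list(map(float, w4_grid))}
    return pd.DataFrame(rows), manifest


# ---------------------------------------------------------------------------
# parameter recovery


def sample_parameter_population(
    model: str, n_animals: int, rng: np.random.Generator
) -> dict[str, ModelParams]:
    """Spread of realistic agent parameters for recovery studies."""
    out = {}
    for i in range(n_animals):
        kw = dict(
            eta=float(rng.uniform(0.1, 0.5)),
            gamma=float(rng.uniform(0.5, 0.95)),
            beta=float(np.exp(rng.uniform(np.log(1.5), np.log(6.0)))),
            bias_b=float(rng.normal(0.0, 0.3)),
            persev_p=float(rng.normal(0.0, 0.3)),
            lapse=float(rng.uniform(0.0, 0.1)),
        )
        if model == "hybrid_value":
            kw["w4"] = float(rng.uniform(0.05, 0.95))
        elif model == "hybrid_learning":
            kw["eta_g"] = kw["eta"] * float(rng.uniform(0.05, 0.95))
        out[f"agent{i:02d}"] = ModelParams(**kw)
    return out


def _params_dict(model: str, p: ModelParams) -> dict[str, float]:
    d = {
        "eta": p.eta,
        "gamma": p.gamma,
        "beta": p.beta,
        "bias_b": p.bias_b,
        "persev_p": p.persev_p,
        "lapse": p.lapse,
    }
    if model == "hybrid_value":
        d["w4"] = p.w4 if p.w4 is not None else np.nan
    elif model == "hybrid_learning":
        d["eta_g"] = p.eta_g if p.eta_g is not None else np.nan
    return d


def recovery_study(
    model: str,
    n_animals: int = 20,
    n_sessions: int = 20,
    seed: int = 0,
    population: Mapping[str, ModelParams] | None = None,
    n_restarts: int = 5,
    session_config: SessionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate known agents, refit by MLE, and summarize recovery.

    Returns (per-animal true/recovered table, per-parameter summary with
    Pearson correlation and mean bias, manifest).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    population = dict(
        population or sample_parameter_population(model, n_animals, rng)
    )
    df = simulate_dataset(model, population, n_sessions, seed + 1, session_config)
    fit_seeds = _child_seeds(seed + 2, len(population))
    rows = []
    for i, (animal, true_p) in enumerate(population.items()):
        sub = df[df["animal_id"] == animal]
        fit = fit_mle(model, sub, n_restarts=n_restarts, seed=fit_seeds[i])
        row = {"animal_id": animal, "n_trials": len(sub), "converged": fit.converged}
        for k, v in _params_dict(model, true_p).items():
            row[f"true_{k}"] = v
        for k, v in _params_dict(model, fit.params).items():
            row[f"recovered_{k}"] = v
        rows.append(row)
    table = pd.DataFrame(rows)
    summary_rows = []
    for k in _params_dict(model, next(iter(population.values()))):
        t = table[f"true_{k}"].to_numpy()
        r = table[f"recovered_{k}"].to_numpy()
        corr = float(np.corrcoef(t, r)[0, 1]) if len(t) > 2 else np.nan
        summary_rows.append(
            {"parameter": k, "correlation": corr, "bias": float(np.mean(r - t))}
        )
    manifest = {
        "model": model,
        "seed": seed,
        "n_animals": len(population),
        "n_sessions": n_sessions,
        "n_restarts": n_restarts,
        "fit_seeds": fit_seeds,
    }
    return table, pd.DataFrame(summary_rows), manifest


# ---------------------------------------------------------------------------
# model identifiability


def identifiability_matrix(
    generators: Mapping[str, ModelParams],
    n_replicates: int = 20,
    n_sessions: int = 30,
    seed: int = 0,
    candidates: Sequence[str] | None = None,
    n_restarts: int = 4,
    session_config: SessionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Fraction of replicates each candidate model wins per generator.

    Each replicate simulates one agent from the generator, fits every
    candidate by MLE, and awards the win to the lowest information
    criterion.  Returns (row-stochastic confusion matrix, per-replicate
    details, manifest).
    """
    candidates = list(candidates or generators)
    unknown = set(candidates) | set(generators)
    if not unknown <= set(MODELS):
        raise ValueError(f"unknown models {sorted(unknown - set(MODELS))}")
    rep_seeds = _child_seeds(seed, len(generators) * n_replicates * 2)
    details, k = [], 0
    for gen_name, gen_params in generators.items():
        for rep in range(n_replicates):
            df = simulate_dataset(
                gen_name, {"a0": gen_params}, n_sessions, rep_seeds[k], session_config
            )
            fits = [
                fit_mle(m, df, n_restarts=n_restarts, seed=rep_seeds[k + 1] + j)
                for j, m in enumerate(candidates)
            ]
            comp = compare_models(fits, baseline=candidates[0])
            ics = {f.model: f.ic for f in fits}
            winner = min(ics, key=ics.get)
            row = {"generator": gen_name, "replicate": rep, "winner": winner}
            for m in candidates:
                row[f"ic_{m}"] = ics[m]
            dd = comp.table.set_index("model")
            for m in candidates:
                row[f"d_ic_{m}"] = float(dd.loc[m, "d_ic"])
            details.append(row)
            k += 2
    details = pd.DataFrame(details)
    confusion = (
        details.groupby("generator")["winner"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(index=list(generators), columns=candidates, fill_value=0.0)
    )
    manifest = {
        "seed": seed,
        "n_replicates": n_replicates,
        "n_sessions": n_sessions,
        "candidates": candidates,
        "replicate_seeds": rep_seeds,
    }
    return confusion, details, manifest


# ---------------------------------------------------------------------------
# split-half refitting


def split_half_analysis(
    records,
    model_pair: tuple[str, str] = ("six_state", "hybrid_value"),
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Fit ``model_pair`` to each animal's first and second half of sessions.

    ΔIC is (second model − first model), so a negative value favors the
    second model of the pair.  Animals with fewer than 2 sessions are
    excluded with a logged notice.  The summary includes the cross-animal
    correlation between the change in w4 and the change in ΔIC when the
    second model is hybrid_value.
    """
    from .inference import as_frame

    df = as_frame(records)
    base_model, alt_model = model_pair
    rows, excluded = [], []
    fit_seeds = _child_seeds(seed, 4 * df["animal_id"].nunique())
    k = 0
    for animal, grp in df.groupby("animal_id", sort=False):
        sessions = list(dict.fromkeys(grp["session_id"]))
        if len(sessions) < 2:
            excluded.append(str(animal))
            logger.info("animal %s excluded from split-half (<2 sessions)", animal)
            continue
        half = len(sessions) // 2
        first = grp[grp["session_id"].isin(sessions[:half])]
        second = grp[grp["session_id"].isin(sessions[half:])]
        row = {"animal_id": str(animal)}
        for tag, sub in (("first", first), ("second", second)):
            fb = fit_mle(base_model, sub, n_restarts=n_restarts, seed=fit_seeds[k])
            fa = fit_mle(alt_model, sub, n_restarts=n_restarts, seed=fit_seeds[k + 1])
            row[f"d_ic_{tag}"] = fa.ic - fb.ic
            if alt_model == "hybrid_value":
                row[f"w4_{tag}"] = fa.params.w4
            elif alt_model == "hybrid_learning":
                row[f"eta_g_{tag}"] = fa.params.eta_g
            k += 2
        rows.append(row)
    table = pd.DataFrame(rows)
    manifest = {
        "seed": seed,
        "model_pair": list(model_pair),
        "excluded_animals": excluded,
    }
    if len(table) > 2 and "w4_first" in table:
        d_w4 = table["w4_second"] - table["w4_first"]
        d_dic = table["d_ic_second"] - table["d_ic_first"]
        manifest["corr_dw4_ddic"] = float(np.corrcoef(d_w4, d_dic)[0, 1])
    return table, manifest
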
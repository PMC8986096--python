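"""Model-agnostic behavioral statistics.

Two analyses:

* Block-aligned learning curves — accuracy (choosing the better option for
  that trial type) in the last 10 and first 10 trials around each
  contingency reversal, averaged within animal then across animals.
* The generalization regression — a hierarchical logistic regression asking
  whether the accuracy of the first free-choice trial after an incorrect
  free choice increases with the number of intervening correct (rewarded)
  forced-choice trials.  A positive group-mean slope is the behavioral
  signature of generalization from forced to free trials; an agent that
  learns the two trial types separately predicts a slope of zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import as_frame, hdi

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneralizationCase:
    """One (incorrect free choice -> next free choice) episode.

    ``outcome`` is the accuracy of the closing free-choice trial;
    ``n_rewarded_forced`` counts the valid (rewarded) forced-choice trials
    strictly between the two free choices.
    """

    animal_id: str
    session_id: str
    outcome: bool
    n_rewarded_forced: int
    trial_index_in_block: int


def extract_generalization_cases(
    records, span_blocks: bool = False
) -> list[GeneralizationCase]:
    """Scan ordered trial logs for generalization cases.

    Each incorrect free choice opens at most one case, closed by the next
    free-choice trial.  Invalid (unrewarded) forced trials in between are
    not counted.  By default an open case is discarded at a block switch,
    since "better option" changes meaning there; ``span_blocks=True`` lets
    cases cross switches.
    """
    df = as_frame(records)
    cases: list[GeneralizationCase] = []
    for (animal, session), grp in df.groupby(["animal_id", "session_id"], sort=False):
        open_count: int | None = None
        prev_block = None
        block_start = {}
        for row in grp.itertuples(index=False):
            if row.block_index not in block_start:
                block_start[row.block_index] = row.trial_index
            if prev_block is not None and row.block_index != prev_block:
                if not span_blocks:
                    open_count = None
            prev_block = row.block_index
            if row.odor == "free":
                if open_count is not None:
                    cases.append(
                        GeneralizationCase(
                            animal_id=str(animal),
                            session_id=str(session),
                            outcome=bool(row.correct),
                            n_rewarded_forced=open_count,
                            trial_index_in_block=int(
                                row.trial_index - block_start[row.block_index] + 1
                            ),
                        )
                    )
                open_count = 0 if not row.correct else None
            elif open_count is not None and row.valid:
                open_count += 1
    return cases


def cases_to_frame(cases: Sequence[GeneralizationCase]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cases])


@dataclass
class RegressionResult:
    """Posterior (or point) summary of the generalization regression."""

    group_theta_mean: float
    group_theta_hdi: tuple[float, float]
    theta_by_animal: pd.DataFrame  # animal_id, mean, hdi_lo, hdi_hi
    samples: pd.DataFrame | None = None
    with_trial_index: bool = False
    method: str = "bayes"
    diagnostics: dict = field(default_factory=dict)


def fit_generalization_regression(
    cases: Sequence[GeneralizationCase] | pd.DataFrame,
    with_trial_index: bool = False,
    n_steps: int = 1500,
    n_warmup: int = 1000,
    thin: int = 4,
    seed: int = 0,
    method: str = "bayes",
) -> RegressionResult:
    """Hierarchical logistic regression of case outcomes on the count of
    intervening rewarded forced-choice trials (raw count scale).

    logit P(correct) = alpha_a + theta_a * n_rewarded_forced
                       (+ kappa_a * trial_index_in_block / 10)

    with animal-level coefficients drawn from group Normals; fit with an
    affine-invariant ensemble sampler.  ``method="mle"`` gives a fast
    non-hierarchical per-animal logistic fallback (group mean with a normal
    interval) for smoke tests.
    """
    df = cases if isinstance(cases, pd.DataFrame) else cases_to_frame(list(cases))
    if len(df) == 0:
        raise ValueError("no generalization cases to fit")
    animals = list(dict.fromkeys(df["animal_id"].astype(str)))
    y = df["outcome"].to_numpy(dtype=float)
    x = df["n_rewarded_forced"].to_numpy(dtype=float)
    # scale keeps the covariate O(1) without changing theta's (raw) scale
    z = df["trial_index_in_block"].to_numpy(dtype=float) / 10.0
    a_idx = df["animal_id"].astype(str).map({a: i for i, a in enumerate(animals)})
    a_idx = a_idx.to_numpy()
    for a in animals:
        ya = y[a_idx == animals.index(a)]
        if len(set(ya)) == 1:
            logger.info("animal %s has all-identical outcomes; intercept weakly identified", a)

    if method == "mle":
        return _regression_mle(df, animals, with_trial_index)

    import emcee

    A = len(animals)
    n_coef = 3 if with_trial_index else 2  # alpha, theta (, kappa)
    dim = 2 * n_coef + A * n_coef

    def log_prob(vec):
        if np.any(np.abs(vec) > 50):
            return -np.inf
        mu = vec[:n_coef]
        log_sig = vec[n_coef : 2 * n_coef]
        sigma = np.exp(log_sig)
        coefs = vec[2 * n_coef :].reshape(A, n_coef)
        lp = -0.5 * np.sum((mu / 2.5) ** 2)
        lp += np.sum(-0.5 * (sigma / 1.0) ** 2 + log_sig)
        lp += np.sum(-0.5 * ((coefs - mu) / sigma) ** 2 - log_sig)
        eta = coefs[a_idx, 0] + coefs[a_idx, 1] * x
        if with_trial_index:
            eta = eta + coefs[a_idx, 2] * z
        pr = expit(eta)
        pr = np.clip(pr, 1e-12, 1 - 1e-12)
        lp += float(np.sum(y * np.log(pr) + (1 - y) * np.log(1 - pr)))
        return lp if np.isfinite(lp) else -np.inf

    rng = np.random.default_rng(seed)
    n_walkers = 2 * dim + 2
    base_rate = float(np.clip(y.mean(), 0.05, 0.95))
    center = np.zeros(dim)
    center[0] = np.log(base_rate / (1 - base_rate))
    center[n_coef : 2 * n_coef] = np.log(0.3)
    center[2 * n_coef :: n_coef] = center[0]
    p0 = center[None, :] + 0.1 * rng.standard_normal((n_walkers, dim))
    np.random.seed(seed % (2**32 - 1))
    sampler = emcee.EnsembleSampler(n_walkers, dim, log_prob)
    sampler.run_mcmc(p0, n_steps, progress=False)
    kept = sampler.get_chain(discard=n_warmup, thin=thin).reshape(-1, dim)

    cols = {"group_alpha": kept[:, 0], "group_theta": kept[:, 1]}
    if with_trial_index:
        cols["group_kappa"] = kept[:, 2]
    for i, a in enumerate(animals):
        cols[f"theta[{a}]"] = kept[:, 2 * n_coef + i * n_coef + 1]
        cols[f"alpha[{a}]"] = kept[:, 2 * n_coef + i * n_coef]
    samples = pd.DataFrame(cols)

    rows = []
    for a in animals:
        s = samples[f"theta[{a}]"].to_numpy()
        lo, hi = hdi(s)
        rows.append(
            {"animal_id": a, "theta_mean": float(s.mean()), "hdi_lo": lo, "hdi_hi": hi}
        )
    g = samples["group_theta"].to_numpy()
    return RegressionResult(
        group_theta_mean=float(g.mean()),
        group_theta_hdi=hdi(g),
        theta_by_animal=pd.DataFrame(rows),
        samples=samples,
        with_trial_index=with_trial_index,
        method="bayes",
        diagnostics={
            "mean_acceptance": float(np.mean(sampler.acceptance_fraction)),
            "n_cases": len(df),
            "n_animals": A,
        },
    )


def _regression_mle(df: pd.DataFrame, animals, with_trial_index: bool):
    """Per-animal logistic fits; group mean theta with a normal interval."""
    import statsmodels.api as sm

    rows, thetas = [], []
    for a in animals:
        sub = df[df["animal_id"].astype(str) == a]
        X = [np.ones(len(sub)), sub["n_rewarded_forced"].to_numpy(dtype=float)]
        if with_trial_index:
            X.append(sub["trial_index_in_block"].to_numpy(dtype=float) / 10.0)
        X = np.column_stack(X)
        yv = sub["outcome"].to_numpy(dtype=float)
        try:
            res = sm.Logit(yv, X).fit(disp=0, maxiter=200)
            theta, se = float(res.params[1]), float(res.bse[1])
        except Exception:
            theta, se = np.nan, np.nan
        if np.isfinite(theta):
            thetas.append(theta)
        rows.append(
            {
                "animal_id": a,
                "theta_mean": theta,
                "hdi_lo": theta - 1.96 * se if np.isfinite(theta) else np.nan,
                "hdi_hi": theta + 1.96 * se if np.isfinite(theta) else np.nan,
            }
        )
    thetas = np.array(thetas)
    sem = thetas.std(ddof=1) / np.sqrt(len(thetas)) if len(thetas) > 1 else np.nan
    m = float(thetas.mean()) if len(thetas) else np.nan
    return RegressionResult(
        group_theta_mean=m,
        group_theta_hdi=(m - 1.96 * sem, m + 1.96 * sem),
        theta_by_animal=pd.DataFrame(rows),
        samples=None,
        with_trial_index=with_trial_index,
        method="mle",
        diagnostics={"n_cases": len(df), "n_animals": len(animals)},
    )


@dataclass(frozen=True)
class LearningCurve:
    """Mean accuracy at offsets -10..-1, 1..10 around block switches.

    ``table`` columns: offset, trial_type ("forced"/"free"), accuracy, sem,
    n_animals.  Offsets with no trials are NaN, never zero.
    """

    table: pd.DataFrame
    n_trials_each_side: int = 10


def compute_learning_curves(records, n_trials: int = 10) -> LearningCurve:
    """Block-switch-aligned accuracy curves for forced and free trials.

    Offset k in 1..n is the k-th trial of the post-switch block; offset -k
    the k-th-from-last trial of the pre-switch block.  Accuracy is averaged
    within animal first; dispersion is the s.e.m. across animals.
    """
    df = as_frame(records)
    per_animal: dict[tuple[int, str, str], list[float]] = {}
    for (animal, _), grp in df.groupby(["animal_id", "session_id"], sort=False):
        for block_idx, blk in grp.groupby("block_index", sort=True):
            blk = blk.sort_values("trial_index")
            n = len(blk)
            for pos, row in enumerate(blk.itertuples(index=False)):
                offsets = []
                if block_idx > 1 and pos < n_trials:
                    offsets.append(pos + 1)  # after the switch into this block
                if block_idx < grp["block_index"].max() and pos >= n - n_trials:
                    offsets.append(pos - n)  # before the switch out (-n..-1)
                if not offsets:
                    continue
                trial_type = "free" if row.odor == "free" else "forced"
                acc = float(row.correct)
                for off in offsets:
                    per_animal.setdefault((off, trial_type, str(animal)), []).append(acc)

    rows = []
    offsets = list(range(-n_trials, 0)) + list(range(1, n_trials + 1))
    for off in offsets:
        for trial_type in ("forced", "free"):
            animal_means = [
                float(np.mean(v))
                for (o, t, _), v in per_animal.items()
                if o == off and t == trial_type
            ]
            if animal_means:
                acc = float(np.mean(animal_means))
                sem = (
                    float(np.std(animal_means, ddof=1) / np.sqrt(len(animal_means)))
                    if len(animal_means) > 1
                    else np.nan
                )
            else:
                acc, sem = np.nan, np.nan
            rows.append(
                {
                    "offset": off,
                    "trial_type": trial_type,
                    "accuracy": acc,
                    "sem": sem,
                    "n_animals": len(animal_means),
                }
            )
    return LearningCurve(pd.DataFrame(rows), n_trials)
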
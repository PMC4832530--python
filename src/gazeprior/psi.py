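"""Psi Bayesian adaptive procedure for noise-contrast thresholds.

The Psi method maintains a posterior over the parameters (alpha, beta) of a
psychometric function for the left/right gaze-detection task and, on every
trial, presents the stimulus level that minimises the expected posterior
entropy after the response (Kontsevich & Tyler, 1999 style).  After a run it
reads out the noise contrast at which the posterior-mean psychometric
function attains a criterion proportion correct (default 80.3 %).

The psychometric family is a criterion-referenced logistic in log noise
contrast with guess rate 0.5 (two-alternative task) and a small fixed
lapse.  With span = 1 - gamma - lambda and F_c = (criterion - gamma)/span,

    psi(x; a, b) = gamma + span * expit(-b (x - a) + logit(F_c)),

decreasing in x = log contrast (more noise, worse detection).  Alpha is the
log contrast at which the function attains the criterion proportion correct
(80.3 % by default), so the threshold readout is simply the posterior mean
of alpha and is insensitive to the poorly constrained slope; beta is the
slope per log unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .observer import GazeObserver, StimulusSpec, respond_lr_detection

__all__ = [
    "PsychometricModel",
    "PsiState",
    "CalibrationResult",
    "default_model",
    "psi_init",
    "psi_next_level",
    "psi_update",
    "psi_threshold",
    "run_calibration",
]

DEFAULT_CRITERION = 0.803


@dataclass
class PsychometricModel:
    """Grid-encoded psychometric family for the detection task.

    ``alpha_grid`` holds candidate midpoints in log-contrast units,
    ``beta_grid`` candidate slopes (per log unit), and ``levels`` the noise
    contrasts the procedure may present.
    """

    alpha_grid: np.ndarray
    beta_grid: np.ndarray
    levels: np.ndarray
    guess_rate: float = 0.5
    lapse_rate: float = 0.02
    criterion: float = DEFAULT_CRITERION
    _table: np.ndarray | None = field(default=None, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        self.beta_grid = np.asarray(self.beta_grid, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        for name, g in (("alpha_grid", self.alpha_grid), ("beta_grid", self.beta_grid)):
            if g.ndim != 1 or g.size == 0 or not np.isfinite(g).all():
                raise ValueError(f"{name} must be a finite, non-empty 1-d grid")
            if g.size > 1 and not (np.diff(g) > 0).all():
                raise ValueError(f"{name} must be strictly increasing")
        if self.levels.ndim != 1 or self.levels.size == 0:
            raise ValueError("levels must be a non-empty 1-d array")
        if not ((self.levels > 0) & np.isfinite(self.levels)).all():
            raise ValueError("levels must be positive finite contrasts")
        if self.levels.size > 1 and not (np.diff(self.levels) > 0).all():
            raise ValueError("levels must be strictly increasing")
        if (self.beta_grid <= 0).any():
            raise ValueError("beta_grid must be positive")
        if not 0 < self.guess_rate < 1 - self.lapse_rate:
            raise ValueError("require 0 < guess_rate < 1 - lapse_rate")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must lie in [0, 0.5)")
        if not self.guess_rate < self.criterion < 1 - self.lapse_rate:
            raise ValueError("criterion must lie in (guess_rate, 1 - lapse_rate)")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.alpha_grid.size, self.beta_grid.size)

    def success_probabilities(self) -> np.ndarray:
        """P(correct | level, alpha, beta), shape (n_levels, n_alpha * n_beta).

        Cached: the table depends only on the grids and levels.
        """
        if self._table is None:
            x = np.log(self.levels)[:, None]
            a = np.repeat(self.alpha_grid, self.beta_grid.size)[None, :]
            b = np.tile(self.beta_grid, self.alpha_grid.size)[None, :]
            span = 1.0 - self.guess_rate - self.lapse_rate
            shift = logit((self.criterion - self.guess_rate) / span)
            self._table = self.guess_rate + span * expit(-b * (x - a) + shift)
        return self._table


def default_model(
    level_min: float = 0.02,
    level_max: float = 1.0,
    n_levels: int = 25,
    n_alpha: int = 31,
    alpha_min: float = 0.02,
    alpha_max: float = 1.0,
    n_beta: int = 15,
    beta_min: float = 0.5,
    beta_max: float = 16.0,
    lapse_rate: float = 0.02,
    criterion: float = DEFAULT_CRITERION,
) -> PsychometricModel:
    """Default grids spanning the plausible noise-contrast range [0.02, 1]."""
    return PsychometricModel(
        alpha_grid=np.log(np.geomspace(alpha_min, alpha_max, n_alpha)),
        beta_grid=np.geomspace(beta_min, beta_max, n_beta),
        levels=np.geomspace(level_min, level_max, n_levels),
        lapse_rate=lapse_rate,
        criterion=criterion,
    )


@dataclass(frozen=True)
class PsiState:
    """Posterior mass over the (alpha, beta) grid plus the trial history."""

    posterior: np.ndarray
    history: tuple[tuple[float, int], ...] = ()

    @property
    def trial_count(self) -> int:
        return len(self.history)


def psi_init(model: PsychometricModel, prior: np.ndarray | None = None) -> PsiState:
    """Fresh state: uniform posterior unless an explicit prior mass is given."""
    shape = model.grid_shape
    if prior is None:
        post = np.full(shape, 1.0 / (shape[0] * shape[1]))
    else:
        post = np.asarray(prior, dtype=float)
        if post.shape != shape:
            raise ValueError(f"prior must have shape {shape}, got {post.shape}")
        total = post.sum()
        if (post < 0).any() or not np.isfinite(total) or total <= 0:
            raise ValueError("prior must be non-negative and normalisable")
        post = post / total
    return PsiState(posterior=post)


def _row_entropies(joint: np.ndarray, totals: np.ndarray) -> np.ndarray:
    # entropy of each row of `joint` after normalising by `totals`
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(joint > 0, joint * np.log(joint), 0.0).sum(axis=1)
        h = np.where(totals > 0, -t / totals + np.log(totals), 0.0)
    return h


def psi_next_level(state: PsiState, model: PsychometricModel) -> float:
    """Stimulus level minimising the expected posterior entropy.

    The expectation is over the two responses weighted by the
    posterior-predictive probability of each; exact ties resolve to the
    lowest level (argmin over ascending levels).
    """
    post = state.posterior.ravel()
    table = model.success_probabilities()
    p_succ = table @ post
    p_fail = 1.0 - p_succ
    joint_s = table * post
    joint_f = (1.0 - table) * post
    expected_h = p_succ * _row_entropies(joint_s, p_succ) + p_fail * _row_entropies(
        joint_f, p_fail
    )
    return float(model.levels[int(np.argmin(expected_h))])


def psi_update(
    state: PsiState, level: float, response: bool, model: PsychometricModel
) -> PsiState:
    """Bayes update of the posterior after observing one response."""
    idx = int(np.argmin(np.abs(model.levels - level)))
    if not math.isclose(model.levels[idx], level, rel_tol=1e-9, abs_tol=1e-12):
        raise ValueError(f"level {level!r} is not in the model's level set")
    table = model.success_probabilities()
    lik = table[idx] if response else 1.0 - table[idx]
    post = state.posterior.ravel() * lik
    total = post.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("zero total likelihood: posterior degenerated")
    post = (post / total).reshape(model.grid_shape)
    return PsiState(
        posterior=post, history=state.history + ((float(level), int(response)),)
    )


def psi_threshold(
    state: PsiState,
    model: PsychometricModel,
    criterion: float = DEFAULT_CRITERION,
    readout: str = "mean",
) -> float:
    """Noise contrast at which the fitted function attains `criterion`.

    Evaluates the psychometric family at the posterior mean (default) or
    mode of (alpha, beta) and inverts it analytically.
    """
    gamma, lam = model.guess_rate, model.lapse_rate
    if not gamma < criterion < 1 - lam:
        raise ValueError(
            f"criterion must lie in ({gamma}, {1 - lam}) for this family"
        )
    post = state.posterior
    if readout == "mean":
        alpha = float(post.sum(axis=1) @ model.alpha_grid)
        beta = float(post.sum(axis=0) @ model.beta_grid)
    elif readout == "mode":
        i, j = np.unravel_index(int(np.argmax(post)), post.shape)
        alpha = float(model.alpha_grid[i])
        beta = float(model.beta_grid[j])
    else:
        raise ValueError("readout must be 'mean' or 'mode'")
    span = 1.0 - gamma - lam
    shift = float(logit((model.criterion - gamma) / span))
    frac = (criterion - gamma) / span
    # invert gamma + span * expit(-beta (x - alpha) + shift) = criterion
    x = alpha + (shift - float(logit(frac))) / beta
    return math.exp(x)


@dataclass(frozen=True)
class CalibrationResult:
    """Median threshold over runs, the per-run estimates, and the trial log."""

    threshold: float
    run_thresholds: tuple[float, ...]
    trials: pd.DataFrame


def run_calibration(
    observer: GazeObserver,
    model: PsychometricModel | None = None,
    n_runs: int = 4,
    n_trials: int = 30,
    rng: np.random.Generator | None = None,
    criterion: float = DEFAULT_CRITERION,
    baseline_deviation_deg: float = 15.0,
    readout: str = "mean",
) -> CalibrationResult:
    """Run the full adaptive calibration against a simulated observer.

    Each run presents ``n_trials`` adaptively chosen noise contrasts on the
    left/right detection task (gaze deviation ``+-baseline_deviation_deg``,
    side randomised) and reads out the criterion-level contrast; the final
    threshold is the median of the per-run estimates (for an even number of
    runs, the mean of the two middle ones).
    """
    if n_runs < 1 or n_trials < 1:
        raise ValueError("n_runs and n_trials must be >= 1")
    if rng is None:
        raise ValueError("an explicit seeded rng is required")
    if model is None:
        model = default_model()
    rows = []
    run_thresholds = []
    for run in range(1, n_runs + 1):
        state = psi_init(model)
        for trial in range(1, n_trials + 1):
            level = psi_next_level(state, model)
            side = 1.0 if rng.random() < 0.5 else -1.0
            stim = StimulusSpec(
                direction_deg=side * baseline_deviation_deg,
                has_noise=True,
                noise_contrast=level,
            )
            correct = respond_lr_detection(observer, stim, rng)
            state = psi_update(state, level, correct, model)
            rows.append(
                {"run": run, "trial": trial, "level": level, "response": int(correct)}
            )
        run_thresholds.append(psi_threshold(state, model, criterion, readout))
    return CalibrationResult(
        threshold=float(np.median(run_thresholds)),
        run_thresholds=tuple(run_thresholds),
        trials=pd.DataFrame(rows),
    )
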
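"""Maximum-likelihood logistic fits of the bias (PSE) from binary responses.

For each participant x test deviation x noise-placement cell, the
proportion of "comparator right" responses as a function of comparator
offset is fit with a two-parameter logistic

    P(right | offset) = 1 / (1 + exp(-(offset - mu) / s)),

whose location ``mu`` is the offset producing 50 % right responses -- the
point of subjective equality, the study's "bias".  Degenerate cells
(separable or uninformative responses) yield flagged non-converged fits
rather than exceptions so that cohort pipelines never abort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "InsufficientDataError",
    "PsychometricFit",
    "proportion_table",
    "fit_logistic",
    "fit_condition_table",
]

logger = logging.getLogger(__name__)

_SPREAD_LO, _SPREAD_HI = 1e-3, 1e3


class InsufficientDataError(ValueError):
    """Raised when fewer than two informative offsets are available."""


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic fit: PSE (deg), spread (deg), log-likelihood and status."""

    pse_deg: float
    spread_deg: float
    log_likelihood: float
    converged: bool
    n_trials: int


def proportion_table(
    trials: pd.DataFrame,
    keys: tuple[str, ...] = ("participant_id", "test_deviation_deg", "noise_on"),
) -> pd.DataFrame:
    """Per-offset response counts (n_right, n_total) for each key group."""
    required = set(keys) | {"offset_deg", "response_right"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    grouped = (
        trials.groupby(list(keys) + ["offset_deg"], sort=True)["response_right"]
        .agg(n_right="sum", n_total="count")
        .reset_index()
    )
    return grouped


def _nll_and_grad(params, offsets, n_right, n_total):
    mu, log_s = params
    s = math.exp(log_s)
    z = (offsets - mu) / s
    p = expit(z)
    pc = np.clip(p, 1e-12, 1 - 1e-12)
    nll = -(n_right * np.log(pc) + (n_total - n_right) * np.log(1 - pc)).sum()
    # d(loglik)/dz = n_right - n_total * p
    dz = n_right - n_total * p
    dmu = dz.sum() / s          # -d(loglik)/dmu
    dlogs = (dz * z).sum()      # -d(loglik)/dlog_s
    return nll, np.array([dmu, dlogs])


def fit_logistic(
    offsets: np.ndarray, n_right: np.ndarray, n_total: np.ndarray
) -> PsychometricFit:
    """ML fit of the two-parameter logistic under independent binomial counts.

    Uses multi-start L-BFGS-B on (mu, log spread).  Separable data (all
    responses one way) return ``converged=False`` with a sign-appropriate
    infinite PSE; non-identifiable data (flat response profile driving the
    spread to its bound) return ``converged=False`` with ``mu = nan``.
    """
    offsets = np.asarray(offsets, dtype=float)
    n_right = np.asarray(n_right, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    keep = n_total > 0
    offsets, n_right, n_total = offsets[keep], n_right[keep], n_total[keep]
    if np.unique(offsets).size < 2:
        raise InsufficientDataError("need >= 2 distinct offsets with observations")
    if ((n_right < 0) | (n_right > n_total)).any():
        raise ValueError("require 0 <= n_right <= n_total")
    n_trials = int(n_total.sum())
    if n_right.sum() == n_total.sum():  # everything "right": PSE below the range
        return PsychometricFit(-math.inf, math.nan, 0.0, False, n_trials)
    if n_right.sum() == 0:  # everything "left": PSE above the range
        return PsychometricFit(math.inf, math.nan, 0.0, False, n_trials)

    span = offsets.max() - offsets.min()
    prop = n_right / n_total
    # crude 50 %-crossing start from the response profile
    order = np.argsort(offsets)
    crossing = float(np.interp(0.5, np.clip(prop[order], 0.001, 0.999), offsets[order]))
    starts = [
        (crossing, math.log(span / 8)),
        (crossing, math.log(span / 2)),
        (float(np.average(offsets, weights=n_total)), math.log(span / 4)),
        (0.0, math.log(span)),
    ]
    bounds = [
        (offsets.min() - 2 * span, offsets.max() + 2 * span),
        (math.log(_SPREAD_LO), math.log(_SPREAD_HI)),
    ]
    best = None
    for x0 in starts:
        res = minimize(
            _nll_and_grad,
            x0=np.array(x0),
            args=(offsets, n_right, n_total),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, log_s = best.x
    spread = math.exp(log_s)
    at_bounds = (
        spread <= _SPREAD_LO * 1.5
        or spread >= _SPREAD_HI / 1.5
        or mu <= bounds[0][0] + 1e-9
        or mu >= bounds[0][1] - 1e-9
    )
    converged = bool(best.success) and not at_bounds
    if not converged and spread >= _SPREAD_HI / 1.5:
        mu = math.nan  # flat profile: location not identifiable
    return PsychometricFit(
        pse_deg=float(mu),
        spread_deg=float(spread),
        log_likelihood=float(-best.fun),
        converged=converged,
        n_trials=n_trials,
    )


def fit_condition_table(
    trials: pd.DataFrame,
    keys: tuple[str, ...] = ("participant_id", "test_deviation_deg", "noise_on"),
) -> pd.DataFrame:
    """Fit every key cell of a trial table; one row per fit."""
    counts = proportion_table(trials, keys=keys)
    rows = []
    for key_vals, cell in counts.groupby(list(keys), sort=True):
        fit = fit_logistic(
            cell["offset_deg"].to_numpy(),
            cell["n_right"].to_numpy(),
            cell["n_total"].to_numpy(),
        )
        row = dict(zip(keys, key_vals))
        row.update(
            pse_deg=fit.pse_deg,
            spread_deg=fit.spread_deg,
            log_likelihood=fit.log_likelihood,
            converged=fit.converged,
            n_trials=fit.n_trials,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    n_bad = int((~out["converged"]).sum()) if len(out) else 0
    if n_bad:
        logger.info("fit_condition_table: %d non-converged cell(s) flagged", n_bad)
    return out
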
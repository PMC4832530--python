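"""Group-level statistics, implemented from first principles.

Three tools carry the study-level conclusions:

* a 2 (noise condition, within) x 2 (group, between) mixed ANCOVA with the
  calibrated noise threshold as a grand-mean-centred covariate, computed by
  the exact sum/difference decomposition for a two-level within factor;
* Pearson product-moment correlations with two-sided p from the t
  transform;
* the JZS default-Cauchy Bayes factor for an independent-samples t test,
  computed by numerical integration of the noncentral-t likelihood over the
  Cauchy effect-size prior (two-sided or directional by prior truncation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad

__all__ = [
    "DEFAULT_PRIOR_SCALE",
    "CorrelationResult",
    "BayesFactorResult",
    "mixed_ancova_2x2",
    "pearson_correlation",
    "jzs_bf_from_t",
    "jzs_bf_two_sample",
]

DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0


# ---------------------------------------------------------------------------
# mixed ANCOVA
# ---------------------------------------------------------------------------

def _ols_effects(X: np.ndarray, y: np.ndarray):
    """OLS with per-coefficient partial F tests (1-df Type III sums)."""
    n, p = X.shape
    xtx = X.T @ X
    if np.linalg.cond(xtx) > 1e10:
        raise np.linalg.LinAlgError("singular design: collinear predictors")
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ X.T @ y
    resid = y - X @ coef
    sse = float(resid @ resid)
    dfe = n - p
    if dfe <= 0:
        raise ValueError("not enough observations for the requested model")
    mse = sse / dfe
    # for a 1-df term, the drop-one (partial) SS is coef^2 / [(X'X)^-1]_jj
    ss = coef**2 / np.diag(xtx_inv)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ss == 0, 0.0, ss / mse)  # zero effect SS: F = 0 by convention
        eta = np.where(ss == 0, 0.0, ss / (ss + sse))
    p_val = stats.f.sf(F, 1, dfe)
    return coef, F, p_val, eta, dfe


def mixed_ancova_2x2(
    data: pd.DataFrame,
    subject: str = "participant_id",
    group: str = "group_label",
    condition: str = "condition",
    value: str = "slope",
    covariate: str | None = "threshold",
) -> pd.DataFrame:
    """2 x 2 mixed ANCOVA via the exact sum/difference decomposition.

    Per-subject condition means are regressed on effect-coded group (+1 for
    the first sorted label) and the centred covariate to give the
    between-subject effects; per-subject condition differences (second
    sorted condition minus first) are regressed on the same design, where
    the intercept is the condition main effect, the group coefficient the
    condition x group interaction, and the covariate coefficient the
    condition x covariate interaction.  Each effect has 1 numerator df and
    N - p error df (p = 3 with a covariate, 2 without).  Passing
    ``covariate=None`` reproduces the plain mixed ANOVA.

    Returns a table with columns effect, F, df1, df2, p, eta_p2.
    """
    cols = [subject, group, condition, value] + ([covariate] if covariate else [])
    missing = set(cols) - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    d = data[cols].dropna()
    conds = sorted(d[condition].unique())
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    wide = d.pivot_table(index=subject, columns=condition, values=value)
    if wide.isna().any().any() or wide.shape[1] != 2:
        raise ValueError("each participant needs exactly one value per condition")
    meta = d.drop_duplicates(subject).set_index(subject).loc[wide.index]
    groups = sorted(meta[group].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    n = len(wide)
    if n < 4:
        raise ValueError("need at least 4 participants")

    mean_y = wide[conds].mean(axis=1).to_numpy()
    diff_y = (wide[conds[1]] - wide[conds[0]]).to_numpy()
    g = np.where(meta[group].to_numpy() == groups[0], 1.0, -1.0)
    columns = [np.ones(n), g]
    if covariate is not None:
        per_subj = d.groupby(subject)[covariate].nunique()
        if (per_subj > 1).any():
            raise ValueError("covariate must be constant within participant")
        z = meta[covariate].to_numpy(dtype=float)
        if np.ptp(z) == 0:
            raise np.linalg.LinAlgError("covariate has zero variance")
        columns.append(z - z.mean())
    X = np.column_stack(columns)

    _, F_b, p_b, eta_b, dfe = _ols_effects(X, mean_y)
    _, F_w, p_w, eta_w, _ = _ols_effects(X, diff_y)

    rows = [
        ("condition", F_w[0], p_w[0], eta_w[0]),
        ("group", F_b[1], p_b[1], eta_b[1]),
        ("condition * group", F_w[1], p_w[1], eta_w[1]),
    ]
    if covariate is not None:
        rows.append((covariate, F_b[2], p_b[2], eta_b[2]))
        rows.append((f"condition * {covariate}", F_w[2], p_w[2], eta_w[2]))
    return pd.DataFrame(
        [
            {"effect": e, "F": float(F), "df1": 1, "df2": dfe, "p": float(p),
             "eta_p2": float(eta)}
            for e, F, p, eta in rows
        ]
    )


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment r with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, p=p, n=n)


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    t_statistic: float
    df: int
    prior_scale: float
    sidedness: str


def _normalise_sidedness(sidedness: str) -> str:
    s = sidedness.lower().replace("_", "-")
    if s in ("two", "two-sided"):
        return "two-sided"
    if s in ("greater", "directional"):
        return "greater"
    if s == "less":
        return "less"
    raise ValueError(f"unknown sidedness {sidedness!r}")


def jzs_bf_from_t(
    t: float,
    n1: int,
    n2: int,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    sidedness: str = "two-sided",
) -> float:
    """JZS Bayes factor BF10 for an independent-samples t statistic.

    Marginalises the noncentral-t likelihood over a Cauchy(0, r) prior on
    the standardised effect size (the scale-mixture form of the
    Zellner-Siow prior); directional variants truncate and renormalise the
    prior to one sign.  ``greater`` means the first group's mean exceeds
    the second's under the alternative.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    side = _normalise_sidedness(sidedness)
    nu = n1 + n2 - 2
    scale = math.sqrt(n1 * n2 / (n1 + n2))  # ncp = delta * scale

    def integrand(phi: float) -> float:
        delta = prior_scale * math.tan(phi)
        return stats.nct.pdf(t, nu, delta * scale)

    # substitution delta = r tan(phi) turns the Cauchy-weighted integral into
    # a plain integral over (-pi/2, pi/2) with weight 1/pi
    peak = math.atan(t / (scale * prior_scale))
    if side == "two-sided":
        num = quad(integrand, -math.pi / 2, math.pi / 2, points=[peak], limit=200)[0] / math.pi
    elif side == "greater":
        pts = [peak] if peak > 0 else []
        num = 2.0 * quad(integrand, 0, math.pi / 2, points=pts, limit=200)[0] / math.pi
    else:  # less
        pts = [peak] if peak < 0 else []
        num = 2.0 * quad(integrand, -math.pi / 2, 0, points=pts, limit=200)[0] / math.pi
    return num / float(stats.t.pdf(t, nu))


def jzs_bf_two_sample(
    group_a,
    group_b,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    sidedness: str = "two-sided",
) -> BayesFactorResult:
    """JZS Bayes factor comparing two independent samples.

    Computes the pooled-variance t statistic and passes it to
    :func:`jzs_bf_from_t`; the result is invariant to a common rescaling of
    all observations.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    nu = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / nu
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = float((a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2)))
    side = _normalise_sidedness(sidedness)
    bf = jzs_bf_from_t(t, n1, n2, prior_scale=prior_scale, sidedness=side)
    return BayesFactorResult(
        bf10=float(bf), t_statistic=t, df=nu, prior_scale=prior_scale, sidedness=side
    )
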
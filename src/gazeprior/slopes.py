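"""Bias slopes and the direct-gaze-bias index.

With only two test deviations (-9 and +9 deg) the linear fit through the
two per-deviation biases is exact, so the slope is simply

    slope = (bias(+9) - bias(-9)) / 18.

A prior for direct gaze drags uncertain percepts toward 0 deg, which makes
the comparator-noise slope positive and the test-noise slope negative; the
direct-gaze-bias index (comparator slope minus test slope) is therefore
positive exactly when the prior operates, and zero for a flat prior.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ConditionSlopes",
    "compute_bias_slope",
    "direct_gaze_index",
    "slope_table",
    "slopes_to_long",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConditionSlopes:
    """Per-participant condition slopes and the derived index."""

    participant_id: str
    slope_test: float
    slope_comparator: float
    dgb_index: float
    threshold: float = math.nan
    group_label: str | None = None


def compute_bias_slope(
    bias_at_minus9: float, bias_at_plus9: float, deviation_deg: float = 9.0
) -> float:
    """Slope of the exact two-point linear fit through the biases.

    Non-finite biases (from excluded, non-converged fits) propagate as NaN
    so downstream tables can drop the participant rather than abort.
    """
    if not (math.isfinite(bias_at_minus9) and math.isfinite(bias_at_plus9)):
        return math.nan
    return (bias_at_plus9 - bias_at_minus9) / (2.0 * deviation_deg)


def direct_gaze_index(slopes: ConditionSlopes) -> float:
    """Comparator-noise slope minus test-noise slope.

    Positive when the direct-gaze-bias signature is present; invariant to
    adding a common constant to both slopes.
    """
    return slopes.slope_comparator - slopes.slope_test


def slope_table(
    fits: pd.DataFrame, participants: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Analysis-ready per-participant slope table.

    Expects the fit table from :func:`gazeprior.fitting.fit_condition_table`
    with exactly two test deviations and the noise conditions "test" and
    "comparator".  Participants with any non-converged fit are excluded
    (logged).  If ``participants`` is given, threshold and group label are
    joined in.
    """
    devs = sorted(fits["test_deviation_deg"].unique())
    if len(devs) != 2:
        raise ValueError(f"expected exactly 2 test deviations, got {devs}")
    d_lo, d_hi = devs
    half_span = (d_hi - d_lo) / 2.0

    ok = fits[fits["converged"]]
    excluded = sorted(
        set(fits["participant_id"]) - set(_complete_participants(ok, devs))
    )
    if excluded:
        logger.info("slope_table: excluding %d participant(s): %s", len(excluded), excluded)
    ok = ok[~ok["participant_id"].isin(excluded)]

    wide = ok.pivot_table(
        index=["participant_id", "noise_on"],
        columns="test_deviation_deg",
        values="pse_deg",
    )
    slope = (wide[d_hi] - wide[d_lo]) / (2.0 * half_span)
    slope = slope.unstack("noise_on")
    out = pd.DataFrame(
        {
            "participant_id": slope.index,
            "slope_test": slope["test"].to_numpy(),
            "slope_comparator": slope["comparator"].to_numpy(),
        }
    ).reset_index(drop=True)
    out["dgb_index"] = out["slope_comparator"] - out["slope_test"]
    if participants is not None:
        out = out.merge(
            participants[["participant_id", "threshold", "group_label"]],
            on="participant_id",
            how="left",
        )
    return out


def _complete_participants(ok_fits: pd.DataFrame, devs) -> list[str]:
    # participants with a converged fit in all 2 deviations x 2 conditions
    counts = ok_fits.groupby("participant_id").size()
    return [pid for pid, n in counts.items() if n == 2 * len(devs)]


def slopes_to_long(slope_df: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide slope table into long format for the mixed ANCOVA."""
    id_vars = [c for c in ("participant_id", "group_label", "threshold") if c in slope_df]
    long = slope_df.melt(
        id_vars=id_vars,
        value_vars=["slope_test", "slope_comparator"],
        var_name="condition",
        value_name="slope",
    )
    long["condition"] = long["condition"].str.replace("slope_", "", regex=False)
    return long
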
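"""End-to-end study runner: calibrate, simulate, fit, analyse, serialise.

``run_study`` executes the whole chain from a :class:`StudyConfig` with
per-stage seeded generators derived from the master seed, so identical
configs produce byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import StudyConfig
from .design import CohortData, simulate_cohort
from .fitting import fit_condition_table
from .inference import (
    BayesFactorResult,
    jzs_bf_two_sample,
    mixed_ancova_2x2,
    pearson_correlation,
)
from .psi import default_model
from .slopes import slope_table, slopes_to_long

__all__ = ["StudyResult", "run_study", "write_study_result", "assign_groups_median_split"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyResult:
    """All study tables plus the inferential results and provenance."""

    participants: pd.DataFrame
    trials: pd.DataFrame
    calibration_trials: pd.DataFrame
    fits: pd.DataFrame
    slopes: pd.DataFrame
    ancova: pd.DataFrame
    correlations: pd.DataFrame
    bayes: BayesFactorResult
    provenance: dict


def assign_groups_median_split(scores, labels: tuple[str, str] = ("low", "high")) -> pd.Series:
    """Median-split group labels with a balanced tie rule.

    Scores strictly below the median go to the first label, strictly above
    to the second; scores equal to the median are assigned, in index order,
    to whichever group is currently smaller (first label on exact balance).
    """
    s = pd.Series(scores, dtype=float)
    if s.isna().any():
        raise ValueError("scores must be numeric and non-missing")
    if len(s) < 2:
        raise ValueError("need at least 2 participants")
    if s.nunique() == 1:
        raise ValueError("degenerate split: all scores identical")
    med = float(s.median())
    lab = pd.Series(index=s.index, dtype=object)
    lab[s < med] = labels[0]
    lab[s > med] = labels[1]
    for idx in s.index[s == med]:
        n_low = int((lab == labels[0]).sum())
        n_high = int((lab == labels[1]).sum())
        lab[idx] = labels[0] if n_low <= n_high else labels[1]
    return lab


def _psi_model_from(config: StudyConfig):
    p = config.psi
    return default_model(
        level_min=p.level_min,
        level_max=p.level_max,
        n_levels=p.n_levels,
        n_alpha=p.n_alpha,
        alpha_min=p.alpha_min,
        alpha_max=p.alpha_max,
        n_beta=p.n_beta,
        beta_min=p.beta_min,
        beta_max=p.beta_max,
        lapse_rate=p.lapse_rate,
        criterion=p.criterion,
    )


def simulate_study_data(config: StudyConfig) -> CohortData:
    """Stages 1-2: calibration and session simulation for every cohort."""
    return simulate_cohort(
        list(config.cohorts),
        seed=config.seed,
        offsets_deg=config.design.offsets_deg,
        reps_per_offset=config.design.reps_per_offset,
        test_deviations=config.design.test_deviations,
        psi_model=_psi_model_from(config),
        n_runs=config.psi.n_runs,
        n_trials=config.psi.n_trials,
        criterion=config.psi.criterion,
        baseline_deviation_deg=config.psi.baseline_deviation_deg,
    )


def analyse_study_data(
    config: StudyConfig, participants: pd.DataFrame, trials: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, BayesFactorResult]:
    """Stages 3-5: fits, slopes, ANCOVA, correlations, Bayes factor."""
    participants = participants.copy()
    if config.analysis.group_assignment == "median_split":
        participants["group_label"] = assign_groups_median_split(
            participants.set_index("participant_id")["trait_score"]
        ).to_numpy()
        group_order = ["low", "high"]
    elif config.analysis.group_assignment == "labels":
        group_order = [c.group_label for c in config.cohorts]
    else:
        raise ValueError(f"unknown group_assignment {config.analysis.group_assignment!r}")

    logger.info("fitting psychometric functions (%d trials)", len(trials))
    fits = fit_condition_table(trials)
    slopes = slope_table(fits, participants)
    logger.info("slope table: %d of %d participants retained", len(slopes), len(participants))
    long = slopes_to_long(slopes)
    ancova = mixed_ancova_2x2(long)

    corr_rows = []
    for cond in ("comparator", "test"):
        res = pearson_correlation(slopes["threshold"], slopes[f"slope_{cond}"])
        corr_rows.append({"condition": cond, "r": res.r, "p": res.p, "n": res.n})
    correlations = pd.DataFrame(corr_rows)

    a = slopes.loc[slopes["group_label"] == group_order[0], "dgb_index"]
    b = slopes.loc[slopes["group_label"] == group_order[1], "dgb_index"]
    bayes = jzs_bf_two_sample(
        a, b, prior_scale=config.analysis.prior_scale, sidedness=config.analysis.sidedness
    )
    return fits, slopes, ancova, correlations, bayes


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the full study chain; deterministic given config + seed."""
    data = simulate_study_data(config)
    participants = data.participants.drop(columns=[], errors="ignore")
    fits, slopes, ancova, correlations, bayes = analyse_study_data(
        config, participants, data.trials
    )
    if config.analysis.group_assignment == "median_split":
        # surface the reassigned labels in the participant table as well
        participants = participants.copy()
        participants["group_label"] = assign_groups_median_split(
            participants.set_index("participant_id")["trait_score"]
        ).to_numpy()
    provenance = {
        "config_sha256": config.sha256(),
        "seed": int(config.seed),
        "version": __version__,
        "n_participants": int(len(participants)),
        "n_slope_rows": int(len(slopes)),
    }
    return StudyResult(
        participants=participants,
        trials=data.trials,
        calibration_trials=data.calibration_trials,
        fits=fits,
        slopes=slopes,
        ancova=ancova,
        correlations=correlations,
        bayes=bayes,
        provenance=provenance,
    )


def write_study_result(result: StudyResult, outdir: str | Path) -> None:
    """Write every table as CSV plus a machine-readable results.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("participants", "trials", "calibration_trials", "fits", "slopes",
                 "ancova", "correlations"):
        getattr(result, name).to_csv(outdir / f"{name}.csv", index=False)
    payload = {
        "ancova": result.ancova.to_dict(orient="records"),
        "correlations": result.correlations.to_dict(orient="records"),
        "bayes": dataclasses.asdict(result.bayes),
        "provenance": result.provenance,
    }
    (outdir / "results.json").write_text(json.dumps(payload, indent=2))
    logger.info("study results written to %s", outdir)
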
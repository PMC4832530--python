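"""Mixed gaze-discrimination design: runs, sessions and synthetic cohorts.

A session consists of two runs, one per test deviation (-9 and +9 deg by
default).  Within a run, every comparator offset from the standard set
(-20, -10, -5, -2, 2, 5, 10, 20 deg) appears 12 times in randomised order,
half the repetitions with noise on the test face and half with noise on the
comparator.  The test face always occupies interval 1 and the comparator
interval 2, so the noisy face appears equally often in the two intervals.

Cohort simulation draws observer parameters per participant, calibrates the
noise contrast with the Psi task, and simulates a full counterbalanced
session, producing tidy tables keyed by ``participant_id``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observer import GazeObserver, simulate_2ifc_trials
from .psi import DEFAULT_CRITERION, PsychometricModel, default_model, run_calibration

__all__ = [
    "DEFAULT_OFFSETS",
    "RunDesign",
    "CohortSpec",
    "CohortData",
    "build_run",
    "simulate_session",
    "simulate_cohort",
    "calibrate_cohort",
]

DEFAULT_OFFSETS: tuple[float, ...] = (-20.0, -10.0, -5.0, -2.0, 2.0, 5.0, 10.0, 20.0)
DEFAULT_DEVIATIONS: tuple[float, float] = (-9.0, 9.0)


@dataclass(frozen=True)
class RunDesign:
    """One run: a fixed test deviation and the comparator offset schedule."""

    test_deviation_deg: float
    noise_contrast: float
    offsets_deg: tuple[float, ...] = DEFAULT_OFFSETS
    reps_per_offset: int = 12

    def __post_init__(self) -> None:
        if self.reps_per_offset < 2 or self.reps_per_offset % 2 != 0:
            raise ValueError("reps_per_offset must be an even number >= 2")
        offs = tuple(float(o) for o in self.offsets_deg)
        if len(offs) == 0 or len(set(offs)) != len(offs):
            raise ValueError("offsets_deg must be non-empty and unique")
        if any(o == 0 for o in offs):
            raise ValueError("offsets_deg must exclude 0")
        if self.noise_contrast < 0:
            raise ValueError("noise_contrast must be non-negative")
        object.__setattr__(self, "offsets_deg", offs)


def build_run(design: RunDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Randomised trial list for one run.

    Exactly ``reps_per_offset`` trials per offset, split evenly between
    noise on the test face and noise on the comparator; noise interval
    follows the fixed test-first convention (1 = test, 2 = comparator).
    """
    half = design.reps_per_offset // 2
    offsets = np.repeat(design.offsets_deg, design.reps_per_offset)
    noise_on = np.tile(
        np.array(["test"] * half + ["comparator"] * half), len(design.offsets_deg)
    )
    order = rng.permutation(offsets.size)
    df = pd.DataFrame(
        {
            "offset_deg": offsets[order],
            "noise_on": noise_on[order],
        }
    )
    df["noise_interval"] = np.where(df["noise_on"] == "test", 1, 2)
    return df


def simulate_session(
    observer: GazeObserver,
    threshold: float,
    rng: np.random.Generator,
    order: tuple[float, float] = DEFAULT_DEVIATIONS,
    offsets_deg: tuple[float, ...] = DEFAULT_OFFSETS,
    reps_per_offset: int = 12,
    participant_id: str | None = None,
) -> pd.DataFrame:
    """Simulate one session: one run per test deviation, in the given order.

    The comparator direction is test deviation + offset; the noisy face is
    shown at the calibrated ``threshold`` contrast.  Returns one tidy row
    per trial.
    """
    if len(order) != 2 or order[0] == order[1]:
        raise ValueError("order must contain two distinct test deviations")
    frames = []
    for run_index, deviation in enumerate(order, start=1):
        design = RunDesign(
            test_deviation_deg=float(deviation),
            noise_contrast=float(threshold),
            offsets_deg=offsets_deg,
            reps_per_offset=reps_per_offset,
        )
        plan = build_run(design, rng)
        test_noise = (plan["noise_on"] == "test").to_numpy()
        responses = simulate_2ifc_trials(
            observer,
            test_dirs=np.full(len(plan), design.test_deviation_deg),
            comp_dirs=design.test_deviation_deg + plan["offset_deg"].to_numpy(),
            test_has_noise=test_noise,
            comp_has_noise=~test_noise,
            noise_contrast=design.noise_contrast,
            rng=rng,
        )
        frame = plan.copy()
        frame.insert(0, "run_index", run_index)
        frame.insert(1, "trial", np.arange(1, len(plan) + 1))
        frame.insert(2, "test_deviation_deg", design.test_deviation_deg)
        frame["noise_contrast"] = design.noise_contrast
        frame["response_right"] = responses.astype(int)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    if participant_id is not None:
        out.insert(0, "participant_id", participant_id)
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Distribution of observer parameters for one simulated group.

    Positive parameters are drawn from normals truncated at a small floor;
    ``prior_sd_mean = inf`` yields a flat-prior (hypo-prior) group, in which
    case ``prior_sd_sd`` is ignored.  ``trait_score_*`` describe an
    AQ-style trait questionnaire score used only for group assignment.
    """

    group_label: str
    n_participants: int
    prior_sd_mean: float = 20.0
    prior_sd_sd: float = 4.0
    clean_sd_mean: float = 2.0
    clean_sd_sd: float = 0.4
    noise_gain_mean: float = 75.0
    noise_gain_sd: float = 12.0
    lapse_rate: float = 0.0
    trait_score_mean: float = 0.0
    trait_score_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not self.prior_sd_mean > 0:
            raise ValueError("prior_sd_mean must be positive (inf allowed)")
        if self.clean_sd_mean <= 0 or self.noise_gain_mean <= 0:
            raise ValueError("parameter means must be positive")
        if not 0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    if sd == 0:
        return max(mean, floor)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > floor:
            return float(v)
    return floor


def draw_observer(spec: CohortSpec, rng: np.random.Generator) -> GazeObserver:
    """Draw one observer's generative parameters from a cohort spec."""
    if math.isinf(spec.prior_sd_mean):
        prior_sd = math.inf
    else:
        prior_sd = _draw_truncated(rng, spec.prior_sd_mean, spec.prior_sd_sd, 1.0)
    return GazeObserver(
        prior_sd_deg=prior_sd,
        clean_sensory_sd_deg=_draw_truncated(rng, spec.clean_sd_mean, spec.clean_sd_sd, 0.3),
        noise_gain=_draw_truncated(rng, spec.noise_gain_mean, spec.noise_gain_sd, 5.0),
        lapse_rate=spec.lapse_rate,
    )


def _participant_streams(
    seed: int, group_index: int, participant_index: int
) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    # Sub-seeds keyed by (seed, group, participant) so that changing the
    # cohort size never perturbs earlier participants' data.
    ss = np.random.SeedSequence(entropy=[int(seed), group_index, participant_index])
    draw_ss, calib_ss, session_ss = ss.spawn(3)
    return (
        np.random.default_rng(draw_ss),
        np.random.default_rng(calib_ss),
        np.random.default_rng(session_ss),
    )


@dataclass(frozen=True)
class CohortData:
    """Joinable cohort tables, all keyed by ``participant_id``."""

    participants: pd.DataFrame
    trials: pd.DataFrame
    calibration_trials: pd.DataFrame


def calibrate_cohort(
    specs: list[CohortSpec],
    seed: int,
    psi_model: PsychometricModel | None = None,
    n_runs: int = 4,
    n_trials: int = 30,
    criterion: float = DEFAULT_CRITERION,
    baseline_deviation_deg: float = 15.0,
) -> CohortData:
    """Draw every participant and run the Psi threshold calibration only."""
    if len(specs) == 0:
        raise ValueError("at least one cohort spec is required")
    if psi_model is None:
        psi_model = default_model()
    p_rows, calib_frames = [], []
    observers: dict[str, GazeObserver] = {}
    for gi, spec in enumerate(specs):
        for pi in range(spec.n_participants):
            rng_draw, rng_calib, _ = _participant_streams(seed, gi, pi)
            pid = f"{spec.group_label}-{pi + 1:02d}"
            obs = draw_observer(spec, rng_draw)
            trait = float(rng_draw.normal(spec.trait_score_mean, spec.trait_score_sd))
            calib = run_calibration(
                obs,
                model=psi_model,
                n_runs=n_runs,
                n_trials=n_trials,
                rng=rng_calib,
                criterion=criterion,
                baseline_deviation_deg=baseline_deviation_deg,
            )
            observers[pid] = obs
            log = calib.trials.copy()
            log.insert(0, "participant_id", pid)
            calib_frames.append(log)
            order = DEFAULT_DEVIATIONS if pi % 2 == 0 else DEFAULT_DEVIATIONS[::-1]
            p_rows.append(
                {
                    "participant_id": pid,
                    "group_label": spec.group_label,
                    "trait_score": trait,
                    "prior_sd_deg": obs.prior_sd_deg,
                    "clean_sensory_sd_deg": obs.clean_sensory_sd_deg,
                    "noise_gain": obs.noise_gain,
                    "lapse_rate": obs.lapse_rate,
                    "threshold": calib.threshold,
                    "deviation_order": "|".join(f"{d:g}" for d in order),
                }
            )
    participants = pd.DataFrame(p_rows)
    participants.attrs["observers"] = observers
    return CohortData(
        participants=participants,
        trials=pd.DataFrame(),
        calibration_trials=pd.concat(calib_frames, ignore_index=True),
    )


def simulate_cohort(
    specs: list[CohortSpec],
    seed: int,
    offsets_deg: tuple[float, ...] = DEFAULT_OFFSETS,
    reps_per_offset: int = 12,
    test_deviations: tuple[float, float] = DEFAULT_DEVIATIONS,
    psi_model: PsychometricModel | None = None,
    n_runs: int = 4,
    n_trials: int = 30,
    criterion: float = DEFAULT_CRITERION,
    baseline_deviation_deg: float = 15.0,
) -> CohortData:
    """Full synthetic cohort: calibration plus a counterbalanced session each.

    The two deviation orders alternate across participants within each
    group, so their counts differ by at most one.
    """
    if len(test_deviations) != 2 or test_deviations[0] == test_deviations[1]:
        raise ValueError("test_deviations must be two distinct values")
    calibrated = calibrate_cohort(
        specs,
        seed,
        psi_model=psi_model,
        n_runs=n_runs,
        n_trials=n_trials,
        criterion=criterion,
        baseline_deviation_deg=baseline_deviation_deg,
    )
    observers = calibrated.participants.attrs["observers"]
    trial_frames = []
    for gi, spec in enumerate(specs):
        for pi in range(spec.n_participants):
            _, _, rng_session = _participant_streams(seed, gi, pi)
            pid = f"{spec.group_label}-{pi + 1:02d}"
            row = calibrated.participants.loc[
                calibrated.participants["participant_id"] == pid
            ].iloc[0]
            order = (
                tuple(test_deviations) if pi % 2 == 0 else tuple(test_deviations[::-1])
            )
            trial_frames.append(
                simulate_session(
                    observers[pid],
                    threshold=float(row["threshold"]),
                    rng=rng_session,
                    order=order,
                    offsets_deg=offsets_deg,
                    reps_per_offset=reps_per_offset,
                    participant_id=pid,
                )
            )
    return CohortData(
        participants=calibrated.participants,
        trials=pd.concat(trial_frames, ignore_index=True),
        calibration_trials=calibrated.calibration_trials,
    )
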
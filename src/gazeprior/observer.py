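"""Generative Bayesian observer of gaze direction.

The observer carries a zero-centred Gaussian prior over gaze direction
(width ``prior_sd_deg``, the belief that gaze tends to be directed at the
viewer) and receives a noisy sensory measurement ``m ~ N(theta, sigma_s^2)``
of the true direction ``theta``.  Its percept is the posterior mean

    percept = k * m + (1 - k) * prior_mean,
    k = sigma_p^2 / (sigma_p^2 + sigma_s^2),

so uncertain stimuli are pulled toward direct gaze.  Adding noise to the eye
region of a face raises ``sigma_s`` linearly with the noise contrast, which
shrinks ``k`` and strengthens the pull.  Setting ``prior_sd_deg = inf``
yields an unbiased (flat-prior) observer: the "hypo-priors" limit.

Sign convention throughout: positive degrees are rightward from the
observer's viewpoint; 0 deg is direct gaze.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "GazeObserver",
    "StimulusSpec",
    "sensory_sd",
    "shrinkage_factor",
    "perceive",
    "respond_2ifc",
    "respond_lr_detection",
    "detection_probability",
    "closed_form_pse",
    "simulate_2ifc_trials",
]


@dataclass(frozen=True)
class GazeObserver:
    """Generative parameters of one simulated participant.

    Parameters
    ----------
    prior_sd_deg
        Width sigma_p of the direct-gaze prior, in degrees.  May be
        ``inf`` to encode a flat (fully attenuated) prior.
    clean_sensory_sd_deg
        Sensory noise sigma_0 for a noise-free face, in degrees.
    noise_gain
        Degrees of additional sensory noise per unit of stimulus noise
        contrast.
    lapse_rate
        Probability of an attention lapse (random response) on any trial.
    prior_mean_deg
        Centre of the prior; 0 (direct gaze) in every standard use.
    """

    prior_sd_deg: float
    clean_sensory_sd_deg: float
    noise_gain: float
    lapse_rate: float = 0.0
    prior_mean_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.prior_sd_deg > 0:
            raise ValueError("prior_sd_deg must be positive (inf allowed)")
        if not (0 < self.clean_sensory_sd_deg < math.inf):
            raise ValueError("clean_sensory_sd_deg must be positive and finite")
        if not (0 <= self.noise_gain < math.inf):
            raise ValueError("noise_gain must be non-negative and finite")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if not math.isfinite(self.prior_mean_deg):
            raise ValueError("prior_mean_deg must be finite")


@dataclass(frozen=True)
class StimulusSpec:
    """One gaze stimulus: a true direction plus optional eye-region noise.

    ``noise_contrast`` is the pupil/sclera contrast of the added noise and
    is ignored when ``has_noise`` is false.
    """

    direction_deg: float
    has_noise: bool = False
    noise_contrast: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.direction_deg):
            raise ValueError("direction_deg must be finite")
        if self.has_noise and self.noise_contrast < 0:
            raise ValueError("noise_contrast must be non-negative")


def sensory_sd(observer: GazeObserver, stimulus: StimulusSpec) -> float:
    """Effective sensory noise (degrees) for a stimulus.

    sigma_s = sigma_0 for a clean face, sigma_0 + gain * contrast for a
    noisy one; strictly increasing in contrast whenever gain > 0.
    """
    if not stimulus.has_noise:
        return observer.clean_sensory_sd_deg
    if stimulus.noise_contrast < 0:
        raise ValueError("noise_contrast must be non-negative")
    return observer.clean_sensory_sd_deg + observer.noise_gain * stimulus.noise_contrast


def shrinkage_factor(prior_sd_deg: float, sensory_sd_deg: float) -> float:
    """Posterior-mean weight k = sigma_p^2 / (sigma_p^2 + sigma_s^2).

    k -> 1 for a flat prior (sigma_p = inf) or noiseless measurement, and
    decreases toward 0 as sensory noise grows relative to the prior width.
    """
    if not prior_sd_deg > 0:
        raise ValueError("prior_sd_deg must be positive")
    if not (0 < sensory_sd_deg < math.inf):
        raise ValueError("sensory_sd_deg must be positive and finite")
    if math.isinf(prior_sd_deg):
        return 1.0
    p2 = prior_sd_deg * prior_sd_deg
    s2 = sensory_sd_deg * sensory_sd_deg
    return p2 / (p2 + s2)


def perceive(
    observer: GazeObserver, stimulus: StimulusSpec, rng: np.random.Generator
) -> float:
    """Draw one percept: the posterior mean given a noisy measurement."""
    sd = sensory_sd(observer, stimulus)
    k = shrinkage_factor(observer.prior_sd_deg, sd)
    m = stimulus.direction_deg + sd * rng.standard_normal()
    return k * m + (1.0 - k) * observer.prior_mean_deg


def respond_2ifc(
    observer: GazeObserver,
    test: StimulusSpec,
    comparator: StimulusSpec,
    rng: np.random.Generator,
) -> bool:
    """Two-interval forced choice: is the comparator perceived right of the test?

    With probability ``lapse_rate`` the response is a fair coin flip.
    Percept ties (measure zero) are also resolved by a fair coin.
    """
    if observer.lapse_rate > 0 and rng.random() < observer.lapse_rate:
        return bool(rng.integers(2))
    p_test = perceive(observer, test, rng)
    p_comp = perceive(observer, comparator, rng)
    if p_comp == p_test:
        return bool(rng.integers(2))
    return bool(p_comp > p_test)


def respond_lr_detection(
    observer: GazeObserver, stimulus: StimulusSpec, rng: np.random.Generator
) -> bool:
    """Left/right gaze detection: True when the judged side is correct.

    The stimulus direction must be nonzero (otherwise there is no correct
    answer).  With a zero-mean prior, shrinkage never flips the sign of the
    measurement, so accuracy depends on the sensory noise alone.
    """
    if stimulus.direction_deg == 0:
        raise ValueError("direction_deg must be nonzero for a left/right judgement")
    if observer.lapse_rate > 0 and rng.random() < observer.lapse_rate:
        return bool(rng.integers(2))
    percept = perceive(observer, stimulus, rng)
    if percept == 0.0:
        return bool(rng.integers(2))
    return bool((percept > 0) == (stimulus.direction_deg > 0))


def detection_probability(
    observer: GazeObserver, noise_contrast: float, direction_deg: float = 15.0
) -> float:
    """Analytic P(correct) of :func:`respond_lr_detection`.

    For a zero-mean prior this is ``(1 - lapse) * Phi(|theta| / sigma_s(c))
    + lapse / 2``; a nonzero prior mean shifts the sign-flip boundary of the
    percept and is handled exactly.
    """
    if direction_deg == 0:
        raise ValueError("direction_deg must be nonzero")
    if noise_contrast < 0:
        raise ValueError("noise_contrast must be non-negative")
    sd = observer.clean_sensory_sd_deg + observer.noise_gain * noise_contrast
    k = shrinkage_factor(observer.prior_sd_deg, sd)
    # percept > 0  iff  m > -(1 - k) * prior_mean / k
    boundary = -(1.0 - k) * observer.prior_mean_deg / k
    if direction_deg > 0:
        p_correct = ndtr((direction_deg - boundary) / sd)
    else:
        p_correct = ndtr((boundary - direction_deg) / sd)
    lam = observer.lapse_rate
    return (1.0 - lam) * float(p_correct) + lam / 2.0


def closed_form_pse(test_dev_deg: float, k_test: float, k_comp: float) -> float:
    """Comparator offset at which P("comparator right") = 0.5.

    For percepts ``k_t (T + n_t)`` and ``k_c (T + offset + n_c)`` with
    zero-mean Gaussian noise, the median of the percept difference crosses
    zero at ``offset* = T (k_t / k_c - 1)``: the analytic point of
    subjective equality for the Gaussian observer.
    """
    for name, k in (("k_test", k_test), ("k_comp", k_comp)):
        if not 0 < k <= 1:
            raise ValueError(f"{name} must lie in (0, 1]")
    return test_dev_deg * (k_test / k_comp - 1.0)


def simulate_2ifc_trials(
    observer: GazeObserver,
    test_dirs: np.ndarray,
    comp_dirs: np.ndarray,
    test_has_noise: np.ndarray,
    comp_has_noise: np.ndarray,
    noise_contrast: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised batch of 2IFC responses (used by the session simulator).

    Returns a boolean array: comparator perceived right of test, with the
    same lapse and tie conventions as :func:`respond_2ifc`.
    """
    test_dirs = np.asarray(test_dirs, dtype=float)
    comp_dirs = np.asarray(comp_dirs, dtype=float)
    test_has_noise = np.asarray(test_has_noise, dtype=bool)
    comp_has_noise = np.asarray(comp_has_noise, dtype=bool)
    if noise_contrast < 0:
        raise ValueError("noise_contrast must be non-negative")
    n = test_dirs.size
    s0 = observer.clean_sensory_sd_deg
    noisy_sd = s0 + observer.noise_gain * noise_contrast
    sd_t = np.where(test_has_noise, noisy_sd, s0)
    sd_c = np.where(comp_has_noise, noisy_sd, s0)
    if math.isinf(observer.prior_sd_deg):
        k_t = np.ones(n)
        k_c = np.ones(n)
    else:
        p2 = observer.prior_sd_deg**2
        k_t = p2 / (p2 + sd_t**2)
        k_c = p2 / (p2 + sd_c**2)
    pm = observer.prior_mean_deg
    m_t = test_dirs + sd_t * rng.standard_normal(n)
    m_c = comp_dirs + sd_c * rng.standard_normal(n)
    p_t = k_t * m_t + (1.0 - k_t) * pm
    p_c = k_c * m_c + (1.0 - k_c) * pm
    right = p_c > p_t
    ties = p_c == p_t
    if ties.any():
        right[ties] = rng.integers(2, size=int(ties.sum())).astype(bool)
    if observer.lapse_rate > 0:
        lapses = rng.random(n) < observer.lapse_rate
        if lapses.any():
            right[lapses] = rng.integers(2, size=int(lapses.sum())).astype(bool)
    return right
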
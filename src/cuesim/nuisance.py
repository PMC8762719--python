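"""Correction for "single-cue" sensitivities measured under a constant nuisance cue.

When a supposedly single-cue discrimination experiment leaves a second,
conflicting cue present and constant (signalling "no change" across
intervals), every presented increment dS_A is attenuated to
dS_c = w_A * dS_A before it reaches the decision variable.  The measured
psychometric function is therefore a stretched copy of the true one: the
stimulus axis must be warped by k = 1/w_A, the measured spread is
sigma' = sigma_A / w_A, and — because each cue's weight itself depends on
the two variances — the ratio of two sigmas measured this way (each
against the other held constant) equals the *cube* of the true sigma
ratio.  The cube-root correction recovers the true ratio; without it,
a measured ratio of 1/27 would be reported where the true ratio is 1/3,
a misestimation by a factor of 9.

All weights here are reliability weights (w = (1/sigma^2) normalised);
the nuisance cue is fixed at zero signalled change.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "attenuated_increment",
    "warp_factor",
    "measured_sigma",
    "measured_sigma_ratio",
    "true_ratio_from_measured",
    "misestimation_factor",
    "true_density",
    "measured_density",
]


def _check_weight(w_target: float) -> None:
    if not (0.0 < w_target <= 1.0):
        raise ValueError(f"target-cue weight must lie in (0, 1], got {w_target}")


def attenuated_increment(delta_S_A: float, w_target: float) -> float:
    """Effective stimulus change when a zero-change nuisance cue is present.

    dS_c = w_target * dS_A: the nuisance term contributes nothing to the
    change (it is constant at zero) but its weight dilutes the intended
    increment.
    """
    _check_weight(w_target)
    return w_target * delta_S_A


def warp_factor(w_target: float) -> float:
    """Stimulus-axis scale factor k = 1 / w_target.

    The factor by which presented increments must be stretched so the
    attenuated change equals the intended one; k = 1 when the target cue
    takes all the weight, and grows as the nuisance cue gains weight.
    """
    _check_weight(w_target)
    return 1.0 / w_target


def measured_sigma(sigma_target: float, w_target: float) -> float:
    """Spread of the psychometric function measured under the nuisance cue.

    sigma' = sigma_target / w_target >= sigma_target, with equality only
    when the nuisance cue receives zero weight.
    """
    if not (sigma_target > 0):
        raise ValueError(f"sigma must be positive, got {sigma_target}")
    _check_weight(w_target)
    return sigma_target / w_target


def measured_sigma_ratio(sigmaA: float, sigmaB: float) -> float:
    """Sigma ratio an experimenter infers when each cue is measured
    against the other held constant.

    Because w_A and w_B are themselves set by the two variances, the
    attenuation compounds: sigma'_A / sigma'_B = (sigmaA / sigmaB)**3.
    """
    if not (sigmaA > 0 and sigmaB > 0):
        raise ValueError(f"sigmas must be positive, got ({sigmaA}, {sigmaB})")
    return (sigmaA / sigmaB) ** 3


def true_ratio_from_measured(measured_ratio: float) -> float:
    """Cube-root correction recovering the true sigma ratio.

    Inverse of :func:`measured_sigma_ratio`; round-trips to machine
    precision.
    """
    if not (measured_ratio > 0):
        raise ValueError(f"measured ratio must be positive, got {measured_ratio}")
    return measured_ratio ** (1.0 / 3.0)


def misestimation_factor(measured_ratio: float) -> float:
    """Factor by which the measured ratio misstates the true one.

    true / measured = measured_ratio**(-2/3); 9 for a measured ratio of
    1/27 (true ratio 1/3).
    """
    return true_ratio_from_measured(measured_ratio) / measured_ratio


def true_density(x, mu: float, sigma_target: float):
    """Gaussian density of the target cue's true estimator."""
    if not (sigma_target > 0):
        raise ValueError(f"sigma must be positive, got {sigma_target}")
    x = np.asarray(x, dtype=float)
    return np.exp(-((mu - x) ** 2) / (2.0 * sigma_target**2)) / (
        sigma_target * math.sqrt(2.0 * math.pi)
    )


def measured_density(x, mu: float, sigma_target: float, w_target: float):
    """Experimentally inferred density under the nuisance cue.

    Change of variables y = x * k with k = 1/w_target applied to the true
    Gaussian density:

        F_Y(y) = (w / (sigma sqrt(2 pi))) exp(-(mu - w y)^2 / (2 sigma^2))

    It integrates to one and has mean mu / w and standard deviation
    sigma / w (the value :func:`measured_sigma` returns).
    """
    if not (sigma_target > 0):
        raise ValueError(f"sigma must be positive, got {sigma_target}")
    _check_weight(w_target)
    x = np.asarray(x, dtype=float)
    return (
        w_target
        * np.exp(-((mu - w_target * x) ** 2) / (2.0 * sigma_target**2))
        / (sigma_target * math.sqrt(2.0 * math.pi))
    )
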
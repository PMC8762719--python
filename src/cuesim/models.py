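"""Closed-form observer models for two-cue integration.

Each sensory cue is modelled as a Gaussian estimator of a world property
(e.g. object size in mm) with a mean and a standard deviation (sigma).
Three candidate rules for forming a single percept from two cues are
implemented:

* **MVUE** (minimum-variance unbiased estimator): a reliability-weighted
  average.  Weights are proportional to the inverse variances, and the
  combined sigma is always at or below the better single cue's sigma —
  the "optimal integration" benchmark.
* **MS** (minimum sigma): use only the more reliable cue.
* **PCS** (probabilistic cue switching): use one cue at a time, switching
  between cues with fixed probabilities; the resulting response
  distribution is a two-component Gaussian mixture.

Also provided: the perturbation-analysis bias algebra (how much bias in
one cue erases the PSE shift an imposed cue conflict would otherwise
produce) and the JND convention used throughout (sigma * sqrt(2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CueEstimate",
    "Weights",
    "SwitchProbs",
    "ConflictSpec",
    "ModelPrediction",
    "BiasResult",
    "weights_from_sigmas",
    "mvue_combine",
    "ms_select",
    "pcs_combine",
    "required_bias",
    "jnd",
]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class CueEstimate:
    """One cue's Gaussian estimator: mean and sigma in stimulus units (mm)."""

    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValueError(f"cue mean must be finite, got {self.mean}")
        if not (self.sigma > 0) or not math.isfinite(self.sigma):
            raise ValueError(f"cue sigma must be positive and finite, got {self.sigma}")


@dataclass(frozen=True)
class Weights:
    """Reliability weights for cues A and B; must sum to one."""

    wA: float
    wB: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.wA <= 1.0 and 0.0 <= self.wB <= 1.0):
            raise ValueError(f"weights must lie in [0, 1], got ({self.wA}, {self.wB})")
        if abs(self.wA + self.wB - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights must sum to 1, got {self.wA + self.wB}")


@dataclass(frozen=True)
class SwitchProbs:
    """Cue-switching probabilities for PCS; pA + pB = 1."""

    pA: float
    pB: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pA <= 1.0 and 0.0 <= self.pB <= 1.0):
            raise ValueError(f"probabilities must lie in [0, 1], got ({self.pA}, {self.pB})")
        if abs(self.pA + self.pB - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"probabilities must sum to 1, got {self.pA + self.pB}")


@dataclass(frozen=True)
class ConflictSpec:
    """An experimentally imposed cue conflict.

    The total conflict ``delta`` (mm) is split symmetrically around
    ``base``: cue A is placed at base + delta/2 and cue B at
    base - delta/2.
    """

    delta: float
    base: float = 55.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"conflict delta must be >= 0, got {self.delta}")

    @property
    def mean_a(self) -> float:
        return self.base + self.delta / 2.0

    @property
    def mean_b(self) -> float:
        return self.base - self.delta / 2.0


@dataclass(frozen=True)
class ModelPrediction:
    """A model's predicted integrated-cue percept: (model, mean, sigma)."""

    model: str
    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if self.model not in ("MVUE", "MS", "PCS"):
            raise ValueError(f"unknown model {self.model!r}")
        if not (self.sigma > 0):
            raise ValueError(f"predicted sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class BiasResult:
    """Bias (mm) in cue A required to null the conflict-induced PSE shift."""

    beta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")


def weights_from_sigmas(sigmaA: float, sigmaB: float) -> Weights:
    """Reliability weights from single-cue sigmas.

    Reliability is inverse variance, r = 1/sigma**2, and
    wA = rA / (rA + rB).
    """
    if not (sigmaA > 0 and sigmaB > 0):
        raise ValueError(f"sigmas must be positive, got ({sigmaA}, {sigmaB})")
    rA = 1.0 / (sigmaA * sigmaA)
    rB = 1.0 / (sigmaB * sigmaB)
    wA = rA / (rA + rB)
    return Weights(wA=wA, wB=1.0 - wA)


def mvue_combine(A: CueEstimate, B: CueEstimate) -> ModelPrediction:
    """Minimum-variance unbiased combination of two cues.

    mean = wA*meanA + wB*meanB with reliability weights;
    sigma = sqrt(sigmaA^2 sigmaB^2 / (sigmaA^2 + sigmaB^2)), which never
    exceeds the smaller single-cue sigma.
    """
    w = weights_from_sigmas(A.sigma, B.sigma)
    mean = w.wA * A.mean + w.wB * B.mean
    va, vb = A.sigma**2, B.sigma**2
    sigma = math.sqrt(va * vb / (va + vb))
    return ModelPrediction(model="MVUE", mean=mean, sigma=sigma)


def ms_select(A: CueEstimate, B: CueEstimate) -> ModelPrediction:
    """Minimum-sigma selection: return the more reliable cue's (mean, sigma).

    Ties (sigmaA == sigmaB exactly) select cue A; ties have measure zero
    under the continuous fitted sigmas arising in simulation.
    """
    chosen = A if A.sigma <= B.sigma else B
    return ModelPrediction(model="MS", mean=chosen.mean, sigma=chosen.sigma)


def pcs_combine(
    A: CueEstimate, B: CueEstimate, p: SwitchProbs | None = None
) -> ModelPrediction:
    """Probabilistic cue switching: Gaussian-mixture mean and sigma.

    The observer uses cue A with probability pA and cue B with pB, so the
    response distribution is the mixture pA*N(meanA, sigmaA^2) +
    pB*N(meanB, sigmaB^2) with

        mean  = pA*meanA + pB*meanB
        var   = pA*sigmaA^2 + pB*sigmaB^2 + pA*pB*(meanA - meanB)^2

    When the means are equal and p equals the reliability weights this
    reduces to sigma = sqrt(2 sigmaA^2 sigmaB^2 / (sigmaA^2 + sigmaB^2)),
    i.e. sqrt(2) times the MVUE sigma.  By default p is set to the
    reliability weights, the convention used when PCS predictions are
    derived from measured single-cue functions.
    """
    if p is None:
        w = weights_from_sigmas(A.sigma, B.sigma)
        p = SwitchProbs(pA=w.wA, pB=w.wB)
    mean = p.pA * A.mean + p.pB * B.mean
    var = (
        p.pA * A.sigma**2
        + p.pB * B.sigma**2
        + p.pA * p.pB * (A.mean - B.mean) ** 2
    )
    return ModelPrediction(model="PCS", mean=mean, sigma=math.sqrt(var))


def required_bias(delta: float, sigmaA: float, sigmaB: float) -> BiasResult:
    """Bias in cue A that nulls a perturbation analysis.

    With a perturbation delta applied to cue B, a bias
    beta = -delta * sigmaA^2 / sigmaB^2 in cue A makes the integrated
    percept equal its unperturbed value, erasing all evidence of
    reliability-weighted integration.
    """
    if not (sigmaA > 0 and sigmaB > 0):
        raise ValueError(f"sigmas must be positive, got ({sigmaA}, {sigmaB})")
    return BiasResult(beta=-delta * (sigmaA * sigmaA) / (sigmaB * sigmaB))


def jnd(sigma: float) -> float:
    """Just-noticeable difference for a cumulative-Gaussian discriminator.

    The convention used here is JND = sigma * sqrt(2).
    """
    if not (sigma > 0):
        raise ValueError(f"sigma must be positive, got {sigma}")
    return sigma * math.sqrt(2.0)
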
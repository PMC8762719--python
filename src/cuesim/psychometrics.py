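"""Constant-stimuli designs, simulated binary responses, and ML psychometric fits.

The measurement model throughout is a lapse-free cumulative Gaussian: an
observer whose internal estimate is N(mu, sigma^2) responds "larger" to a
comparison at level x with probability Phi((x - mu) / sigma).  Responses
are sampled with the method of constant stimuli (a fixed, linearly spaced
set of comparison levels, each presented a fixed number of times) and the
two parameters (mu = PSE, sigma = threshold spread) are recovered by
maximising the binomial log-likelihood.

The fitting interface follows the model/results idiom: build a
:class:`CumulativeGaussianPsychometric` from response counts, call
``fit()``, and read estimates, standard errors and fit status off the
returned :class:`PsychometricFitResults`.  ``fit_pf`` is a functional
shorthand for the same thing.

Fits that a practitioner would discard are flagged rather than silently
returned: data at or around chance at every level ("flat", the slope is
statistically indistinguishable from zero or the fitted sigma is absurdly
large), perfectly separated data ("step", fitted sigma collapses far below
the stimulus resolution), and optimizer failures.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri
from scipy.stats import chi2

from .seeding import child_rng

__all__ = [
    "ConstantStimuliDesign",
    "PFParams",
    "ResponseSet",
    "RejectionThresholds",
    "PsychometricFitResults",
    "CumulativeGaussianPsychometric",
    "make_design",
    "simulate_responses",
    "fit_pf",
    "handle_rejection",
]

STATUS_OK = "ok"
STATUS_FLAT = "rejected_flat"
STATUS_STEP = "rejected_step"
STATUS_NONCONVERGED = "rejected_nonconverged"

_P_CLIP = 1e-12


@dataclass(frozen=True)
class PFParams:
    """True (or fitted) cumulative-Gaussian parameters: PSE and spread, in mm."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def prob_larger(self, levels: np.ndarray | float) -> np.ndarray:
        """P("larger") at the given comparison levels."""
        return ndtr((np.asarray(levels, dtype=float) - self.mu) / self.sigma)


@dataclass(frozen=True)
class ConstantStimuliDesign:
    """A method-of-constant-stimuli design.

    ``n_levels`` comparison values linearly spaced over ``span`` mm,
    centred on ``center``, each presented ``reps_per_level`` times.
    """

    center: float
    reps_per_level: int
    span: float = 20.0
    n_levels: int = 9

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"need at least 2 levels, got {self.n_levels}")
        if not (self.span > 0):
            raise ValueError(f"span must be positive, got {self.span}")
        if self.reps_per_level < 1:
            raise ValueError(f"reps_per_level must be >= 1, got {self.reps_per_level}")

    @property
    def levels(self) -> np.ndarray:
        return np.linspace(
            self.center - self.span / 2.0, self.center + self.span / 2.0, self.n_levels
        )

    @property
    def spacing(self) -> float:
        return self.span / (self.n_levels - 1)

    @property
    def n_trials(self) -> int:
        return self.n_levels * self.reps_per_level


def make_design(
    center: float, reps_per_level: int, span: float = 20.0, n_levels: int = 9
) -> ConstantStimuliDesign:
    """Constant-stimuli design centred on ``center`` (usually the true PSE)."""
    return ConstantStimuliDesign(
        center=center, reps_per_level=reps_per_level, span=span, n_levels=n_levels
    )


@dataclass(frozen=True)
class ResponseSet:
    """Binomial response counts per comparison level."""

    levels: np.ndarray
    n_larger: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        n_larger = np.asarray(self.n_larger, dtype=int)
        n_total = np.asarray(self.n_total, dtype=int)
        if not (levels.shape == n_larger.shape == n_total.shape):
            raise ValueError("levels, n_larger and n_total must have equal length")
        if np.any(n_larger < 0) or np.any(n_larger > n_total):
            raise ValueError("require 0 <= n_larger <= n_total at every level")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "n_larger", n_larger)
        object.__setattr__(self, "n_total", n_total)

    @property
    def n_trials(self) -> int:
        return int(self.n_total.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level_mm": self.levels, "n_larger": self.n_larger, "n_total": self.n_total}
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseSet":
        missing = {"level_mm", "n_larger", "n_total"} - set(df.columns)
        if missing:
            raise ValueError(f"response table missing columns: {sorted(missing)}")
        return cls(
            levels=df["level_mm"].to_numpy(dtype=float),
            n_larger=df["n_larger"].to_numpy(dtype=int),
            n_total=df["n_total"].to_numpy(dtype=int),
        )

    @classmethod
    def from_csv(cls, path_or_buf) -> "ResponseSet":
        return cls.from_frame(pd.read_csv(path_or_buf))


def simulate_responses(
    pf: PFParams,
    design: ConstantStimuliDesign,
    seed: int | np.random.Generator,
) -> ResponseSet:
    """Sample binomial "larger" counts from a true cumulative-Gaussian observer.

    At level x_i the count is Binomial(reps_per_level, Phi((x_i - mu)/sigma)).
    Passing the same integer seed twice yields identical counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(int(seed))
    levels = design.levels
    p = pf.prob_larger(levels)
    counts = rng.binomial(design.reps_per_level, p)
    return ResponseSet(
        levels=levels,
        n_larger=counts,
        n_total=np.full(design.n_levels, design.reps_per_level),
    )


@dataclass(frozen=True)
class RejectionThresholds:
    """Operational criteria for discarding un-fittable psychometric data.

    flat — performance at or around chance across all levels: the ML fit
    degenerates toward the constant-probability boundary (sigma -> inf),
    which is the maximum-likelihood solution exactly when the sampled
    proportions carry a non-positive slope.  Detected as a fitted sigma
    above ``flat_sigma_span_factor`` times the sampling span (the
    optimizer's sigma bound sits a further 10x above the default factor,
    so genuine degeneracy always crosses it).  Optionally, setting
    ``flat_slope_pvalue`` additionally rejects fits whose likelihood-ratio
    test against a constant-probability model (1 df) has p above the given
    value; this is off by default because it also discards a few percent
    of legitimately fittable shallow functions in the leanest
    data-collection regime.

    step — perfectly separated (step-function) data: fitted sigma below
    ``step_sigma_spacing_factor`` times the inter-level spacing.
    """

    flat_sigma_span_factor: float = 100.0
    flat_slope_pvalue: float | None = None
    step_sigma_spacing_factor: float = 0.01


@dataclass
class PsychometricFitResults:
    """ML fit of a lapse-free cumulative Gaussian to binomial counts.

    Carries the point estimates, their standard errors (from the observed
    information), the log-likelihood, the fit status, and an excluded
    flag set by downstream rejection handling.  When ``status != "ok"``
    the parameter estimates must not be consumed downstream.
    """

    mu: float
    sigma: float
    loglik: float
    status: str
    n_trials: int
    n_levels: int
    bse_mu: float = np.nan
    bse_sigma: float = np.nan
    excluded: bool = False

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK

    @property
    def params(self) -> np.ndarray:
        return np.array([self.mu, self.sigma])

    @property
    def bse(self) -> np.ndarray:
        return np.array([self.bse_mu, self.bse_sigma])

    @property
    def pf_params(self) -> PFParams:
        if not self.ok:
            raise ValueError(f"fit was rejected (status={self.status}); no usable parameters")
        return PFParams(mu=self.mu, sigma=self.sigma)

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Cumulative Gaussian psychometric fit (ML, lapse rate fixed at 0)\n")
        buf.write("=" * 64 + "\n")
        buf.write(f"{'status':<14}{self.status:>18}\n")
        buf.write(f"{'n trials':<14}{self.n_trials:>18d}\n")
        buf.write(f"{'n levels':<14}{self.n_levels:>18d}\n")
        buf.write(f"{'log-likelihood':<14}{self.loglik:>18.4f}\n")
        buf.write("-" * 64 + "\n")
        buf.write(f"{'param':<10}{'estimate':>14}{'std err':>14}\n")
        buf.write(f"{'mu (PSE)':<10}{self.mu:>14.4f}{self.bse_mu:>14.4f}\n")
        buf.write(f"{'sigma':<10}{self.sigma:>14.4f}{self.bse_sigma:>14.4f}\n")
        buf.write("=" * 64)
        return buf.getvalue()


def _neg_loglik_and_grad(theta, x, k, n):
    """Binomial negative log-likelihood and gradient in (mu, log sigma)."""
    mu, logsig = theta
    sig = np.exp(logsig)
    z = (x - mu) / sig
    p = np.clip(ndtr(z), _P_CLIP, 1.0 - _P_CLIP)
    nll = -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))
    g = k / p - (n - k) / (1.0 - p)
    phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    dmu = np.sum(g * phi) / sig
    dlogsig = np.sum(g * phi * z)
    return nll, np.array([dmu, dlogsig])


def _loglik(mu, sigma, x, k, n):
    p = np.clip(ndtr((x - mu) / sigma), _P_CLIP, 1.0 - _P_CLIP)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _const_loglik(k, n):
    """Log-likelihood of the best constant-probability (slope-zero) model."""
    ktot, ntot = k.sum(), n.sum()
    phat = np.clip(ktot / ntot, _P_CLIP, 1.0 - _P_CLIP)
    return float(ktot * np.log(phat) + (ntot - ktot) * np.log1p(-phat))


class CumulativeGaussianPsychometric:
    """Binomial ML model for a lapse-free cumulative-Gaussian psychometric function.

    Parameters
    ----------
    responses
        Observed counts per comparison level.
    thresholds
        Fit-rejection criteria; defaults to :class:`RejectionThresholds`.

    Examples
    --------
    >>> design = make_design(55.0, 55)
    >>> resp = simulate_responses(PFParams(55.0, 4.86), design, seed=7)
    >>> res = CumulativeGaussianPsychometric(resp).fit()
    >>> res.status
    'ok'
    """

    def __init__(
        self,
        responses: ResponseSet,
        thresholds: RejectionThresholds | None = None,
    ) -> None:
        if len(responses.levels) < 2:
            raise ValueError("need responses at >= 2 levels to fit a psychometric function")
        self.responses = responses
        self.thresholds = thresholds or RejectionThresholds()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CumulativeGaussianPsychometric":
        return cls(ResponseSet.from_frame(df), **kwargs)

    def loglike(self, mu: float, sigma: float) -> float:
        r = self.responses
        return _loglik(mu, sigma, r.levels, r.n_larger, r.n_total)

    def _starts(self, x, k, n, span, center):
        # probit-regression start plus a fallback at the design centre
        phat = (k + 0.5) / (n + 1.0)
        zhat = ndtri(phat)
        slope, intercept = np.polyfit(x, zhat, 1)
        starts = [(center, span / 4.0)]
        if slope > 1e-9:
            sig0 = 1.0 / slope
            starts.insert(0, (-intercept * sig0, sig0))
        return starts

    def fit(self) -> PsychometricFitResults:
        r = self.responses
        x, k, n = r.levels, r.n_larger, r.n_total
        span = float(x.max() - x.min())
        spacing = span / (len(x) - 1)
        center = float(x.mean())
        lo_sig = spacing * 1e-4
        hi_sig = span * 10.0 * max(self.thresholds.flat_sigma_span_factor, 10.0)
        bounds = [
            (center - 10.0 * span, center + 10.0 * span),
            (np.log(lo_sig), np.log(hi_sig)),
        ]
        best = None
        for mu0, sig0 in self._starts(x, k, n, span, center):
            mu0 = float(np.clip(mu0, *bounds[0]))
            sig0 = float(np.clip(sig0, lo_sig * 1.01, hi_sig * 0.99))
            res = minimize(
                _neg_loglik_and_grad,
                x0=np.array([mu0, np.log(sig0)]),
                args=(x, k, n),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 200},
            )
            if best is None or res.fun < best.fun:
                best = res
        n_trials = int(n.sum())
        if best is None or not np.isfinite(best.fun):
            return PsychometricFitResults(
                mu=np.nan, sigma=np.nan, loglik=np.nan,
                status=STATUS_NONCONVERGED, n_trials=n_trials, n_levels=len(x),
            )
        mu_hat = float(best.x[0])
        sigma_hat = float(np.exp(best.x[1]))
        ll = -float(best.fun)
        status = self._classify(mu_hat, sigma_hat, ll, x, k, n, span, spacing, best.success)
        bse_mu, bse_sigma = self._standard_errors(mu_hat, sigma_hat, x, k, n)
        return PsychometricFitResults(
            mu=mu_hat, sigma=sigma_hat, loglik=ll, status=status,
            n_trials=n_trials, n_levels=len(x), bse_mu=bse_mu, bse_sigma=bse_sigma,
        )

    def _classify(self, mu, sigma, ll, x, k, n, span, spacing, converged):
        t = self.thresholds
        if not converged:
            return STATUS_NONCONVERGED
        if sigma < t.step_sigma_spacing_factor * spacing:
            return STATUS_STEP
        if sigma > t.flat_sigma_span_factor * span:
            return STATUS_FLAT
        if t.flat_slope_pvalue is not None:
            lr = max(0.0, 2.0 * (ll - _const_loglik(k, n)))
            if chi2.sf(lr, df=1) > t.flat_slope_pvalue:
                return STATUS_FLAT
        return STATUS_OK

    @staticmethod
    def _standard_errors(mu, sigma, x, k, n):
        # observed information via central differences of the analytic score
        h = np.array([1e-4 * max(1.0, abs(mu)), 1e-4])
        theta = np.array([mu, np.log(sigma)])
        H = np.empty((2, 2))
        for j in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h[j]
            tm[j] -= h[j]
            _, gp = _neg_loglik_and_grad(tp, x, k, n)
            _, gm = _neg_loglik_and_grad(tm, x, k, n)
            H[:, j] = (gp - gm) / (2.0 * h[j])
        try:
            cov = np.linalg.inv(0.5 * (H + H.T))
            var_mu = cov[0, 0]
            var_sigma = cov[1, 1] * sigma**2  # delta method: log sigma -> sigma
            if var_mu <= 0 or var_sigma <= 0:
                return np.nan, np.nan
            return float(np.sqrt(var_mu)), float(np.sqrt(var_sigma))
        except np.linalg.LinAlgError:
            return np.nan, np.nan


def fit_pf(
    responses: ResponseSet, thresholds: RejectionThresholds | None = None
) -> PsychometricFitResults:
    """ML cumulative-Gaussian fit of a response set (functional shorthand)."""
    return CumulativeGaussianPsychometric(responses, thresholds=thresholds).fit()


def handle_rejection(
    fit: PsychometricFitResults,
    policy: str = "drop",
    simulate: Callable[[], PsychometricFitResults] | None = None,
    max_retries: int = 10,
) -> PsychometricFitResults:
    """Apply the rejected-fit policy.

    ``drop`` (the main analysis) marks the fit excluded so the observer is
    removed from downstream statistics; ``resimulate`` draws fresh
    observers via ``simulate()`` until one fits, up to ``max_retries``.
    """
    if policy not in ("drop", "resimulate"):
        raise ValueError(f"unknown rejection policy {policy!r}")
    if fit.ok:
        return fit
    if policy == "drop":
        return dataclasses.replace(fit, excluded=True)
    if simulate is None:
        raise ValueError("resimulate policy requires a simulate() callable")
    for _ in range(max_retries):
        fresh = simulate()
        if fresh.ok:
            return fresh
    raise RuntimeError(f"no acceptable fit within {max_retries} resimulations")
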
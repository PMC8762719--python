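"""Simulation Set 1: factorial grid of homogeneous-population experiments.

Every simulated experiment follows the standard cue-integration recipe:
a population of observers who truly integrate cues by MVUE (or,
optionally, behave by minimum-sigma selection) is measured on three
psychometric functions — single-cue A, single-cue B, and the integrated
condition — by the method of constant stimuli; each function is fitted by
ML; model predictions (MS, PCS, MVUE) are derived from each observer's
*fitted* single-cue parameters; and the observed integrated-condition
values (PSE and sigma) across observers are compared against the mean
per-observer prediction with a one-sample test.

The grid axes are the sigma ratio between cues, the number of observers
per experiment, the data-collection regime (trials per stimulus level)
and the imposed cue conflict.  Cell percentages of significant
experiments quantify the probability of distinguishing the generating
model from each alternative; at zero conflict every significant PSE test
is a false positive, inflated above the nominal alpha because the point
prediction is itself estimated from the same noisy single-cue fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    ConflictSpec,
    CueEstimate,
    ModelPrediction,
    SwitchProbs,
    ms_select,
    mvue_combine,
    pcs_combine,
    weights_from_sigmas,
)
from .psychometrics import (
    PFParams,
    PsychometricFitResults,
    RejectionThresholds,
    fit_pf,
    make_design,
    simulate_responses,
)
from .seeding import child_rng

__all__ = [
    "ExperimentConfig",
    "ObserverRecord",
    "TestResult",
    "ExperimentOutcome",
    "Set1Grid",
    "GridSummary",
    "true_observer_functions",
    "run_observer",
    "one_sample_t",
    "one_sample_wilcoxon",
    "run_experiment",
    "run_grid",
    "grid_counts",
    "oracle_significance_rate",
]

log = logging.getLogger(__name__)

MEASURES = ("pse", "sigma")
COMPARISONS = ("MS", "PCS")
FIT_STATUSES = ("ok", "rejected_flat", "rejected_step", "rejected_nonconverged")


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one simulated experiment.

    sigma_a is fixed (default 4.86 mm, roughly a haptic size cue);
    sigma_b = sigma_a * ratio.  The conflict splits the 55 mm base mean
    symmetrically between the cues.
    """

    ratio: float
    n_observers: int
    reps_per_level: int
    conflict: ConflictSpec = ConflictSpec(delta=0.0)
    sigma_a: float = 4.86
    observer_model: str = "MVUE"
    span: float = 20.0
    n_levels: int = 9
    alpha: float = 0.05
    test: str = "t"
    rejection_policy: str = "drop"
    max_retries: int = 10
    thresholds: RejectionThresholds = field(default_factory=RejectionThresholds)

    def __post_init__(self) -> None:
        if not (self.ratio > 0):
            raise ValueError(f"ratio must be positive, got {self.ratio}")
        if self.n_observers < 2:
            raise ValueError(f"need >= 2 observers, got {self.n_observers}")
        if self.observer_model not in ("MVUE", "MS"):
            raise ValueError(f"observer_model must be MVUE or MS, got {self.observer_model}")
        if self.test not in ("t", "wilcoxon"):
            raise ValueError(f"test must be 't' or 'wilcoxon', got {self.test}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def sigma_b(self) -> float:
        return self.sigma_a * self.ratio


def true_observer_functions(
    cfg: ExperimentConfig, ratio: float | None = None
) -> tuple[PFParams, PFParams, PFParams]:
    """True psychometric parameters for the three measured conditions.

    Single-cue A sits at base + delta/2 with sigma_a; single-cue B at
    base - delta/2 with sigma_b; the integrated condition follows the
    generating model (MVUE combination or minimum-sigma selection).
    """
    r = cfg.ratio if ratio is None else ratio
    a = CueEstimate(mean=cfg.conflict.mean_a, sigma=cfg.sigma_a)
    b = CueEstimate(mean=cfg.conflict.mean_b, sigma=cfg.sigma_a * r)
    combined = mvue_combine(a, b) if cfg.observer_model == "MVUE" else ms_select(a, b)
    return (
        PFParams(mu=a.mean, sigma=a.sigma),
        PFParams(mu=b.mean, sigma=b.sigma),
        PFParams(mu=combined.mean, sigma=combined.sigma),
    )


@dataclass
class ObserverRecord:
    """Fits and model predictions for one simulated observer.

    Predictions are present only when all three fits are usable; an
    excluded observer contributes nothing downstream except rejection
    bookkeeping.
    """

    fit_a: PsychometricFitResults
    fit_b: PsychometricFitResults
    fit_c: PsychometricFitResults
    pred_mvue: ModelPrediction | None
    pred_ms: ModelPrediction | None
    pred_pcs: ModelPrediction | None
    excluded: bool
    statuses: tuple[str, str, str]


def _fit_one_function(
    pf: PFParams, cfg: ExperimentConfig, root_seed: int, key: tuple[int, ...]
) -> PsychometricFitResults:
    design = make_design(pf.mu, cfg.reps_per_level, span=cfg.span, n_levels=cfg.n_levels)

    def attempt(i: int) -> PsychometricFitResults:
        rng = child_rng(root_seed, *key, i)
        return fit_pf(simulate_responses(pf, design, rng), thresholds=cfg.thresholds)

    fit = attempt(0)
    if fit.ok or cfg.rejection_policy == "drop":
        return fit
    for i in range(1, cfg.max_retries + 1):
        fit = attempt(i)
        if fit.ok:
            return fit
    raise RuntimeError(f"no acceptable fit within {cfg.max_retries} resimulations")


def run_observer(
    cfg: ExperimentConfig, root_seed: int, key: tuple[int, ...] = (), ratio: float | None = None
) -> ObserverRecord:
    """Simulate and fit one observer's three functions; derive predictions.

    Model predictions use the observer's *fitted* single-cue parameters,
    exactly as an experimenter would: MS takes the lower-fitted-sigma
    cue, PCS mixes the fitted cues with switching probabilities equal to
    the fitted reliability weights, MVUE applies the weighted average.
    """
    pf_a, pf_b, pf_c = true_observer_functions(cfg, ratio=ratio)
    fit_a = _fit_one_function(pf_a, cfg, root_seed, key + (0,))
    fit_b = _fit_one_function(pf_b, cfg, root_seed, key + (1,))
    fit_c = _fit_one_function(pf_c, cfg, root_seed, key + (2,))
    statuses = (fit_a.status, fit_b.status, fit_c.status)
    excluded = not (fit_a.ok and fit_b.ok and fit_c.ok)
    pred_mvue = pred_ms = pred_pcs = None
    if not excluded:
        est_a = CueEstimate(mean=fit_a.mu, sigma=fit_a.sigma)
        est_b = CueEstimate(mean=fit_b.mu, sigma=fit_b.sigma)
        w = weights_from_sigmas(est_a.sigma, est_b.sigma)
        pred_mvue = mvue_combine(est_a, est_b)
        pred_ms = ms_select(est_a, est_b)
        pred_pcs = pcs_combine(est_a, est_b, SwitchProbs(pA=w.wA, pB=w.wB))
    return ObserverRecord(
        fit_a=fit_a, fit_b=fit_b, fit_c=fit_c,
        pred_mvue=pred_mvue, pred_ms=pred_ms, pred_pcs=pred_pcs,
        excluded=excluded, statuses=statuses,
    )


@dataclass(frozen=True)
class TestResult:
    t: float
    p: float
    significant: bool


def one_sample_t(values: Sequence[float], point: float, alpha: float = 0.05) -> TestResult:
    """Two-sided one-sample t-test of ``values`` against the scalar ``point``.

    Zero-variance samples are resolved by convention: p = 1 when the
    common value equals the point, p = 0 otherwise.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("one-sample t-test needs at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0.0:
        if v[0] == point:
            return TestResult(t=0.0, p=1.0, significant=False)
        return TestResult(t=math.inf if v[0] > point else -math.inf, p=0.0, significant=True)
    res = stats.ttest_1samp(v, point)
    return TestResult(t=float(res.statistic), p=float(res.pvalue), significant=bool(res.pvalue < alpha))


def one_sample_wilcoxon(values: Sequence[float], point: float, alpha: float = 0.05) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of ``values`` against ``point``."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("Wilcoxon test needs at least 2 values")
    d = v - point
    if np.all(d == 0.0):
        return TestResult(t=0.0, p=1.0, significant=False)
    res = stats.wilcoxon(d, zero_method="wilcox")
    return TestResult(t=float(res.statistic), p=float(res.pvalue), significant=bool(res.pvalue < alpha))


@dataclass
class ExperimentOutcome:
    """Model-comparison statistics of one simulated experiment.

    ``tests`` maps (measure, comparison) — measure in {pse, sigma},
    comparison in {MS, PCS} — to the one-sample test of observed
    integrated-condition values against the mean per-observer prediction.
    """

    tests: dict[tuple[str, str], TestResult]
    n_retained: int
    n_observers: int
    valid: bool
    status_counts: dict[str, int]

    @property
    def n_excluded(self) -> int:
        return self.n_observers - self.n_retained


def run_experiment(
    cfg: ExperimentConfig,
    root_seed: int,
    key: tuple[int, ...] = (),
    ratios: Sequence[float] | None = None,
) -> ExperimentOutcome:
    """Run one experiment: simulate observers, test observed vs predicted.

    For each comparison model and measure, the vector of observed
    integrated-condition values across retained observers is tested
    against the scalar mean of the per-observer predictions.  Experiments
    with fewer than two retained observers are flagged invalid.
    ``ratios`` optionally gives a per-observer sigma ratio (used by the
    heterogeneous-population engine); by default all observers share
    ``cfg.ratio``.
    """
    records = [
        run_observer(cfg, root_seed, key + (i,), ratio=None if ratios is None else ratios[i])
        for i in range(cfg.n_observers)
    ]
    status_counts = {s: 0 for s in FIT_STATUSES}
    for rec in records:
        for s in rec.statuses:
            status_counts[s] += 1
    retained = [r for r in records if not r.excluded]
    n_retained = len(retained)
    tests: dict[tuple[str, str], TestResult] = {}
    valid = n_retained >= 2
    if valid:
        obs_pse = [r.fit_c.mu for r in retained]
        obs_sigma = [r.fit_c.sigma for r in retained]
        preds = {"MS": [r.pred_ms for r in retained], "PCS": [r.pred_pcs for r in retained]}
        test_fn = one_sample_t if cfg.test == "t" else one_sample_wilcoxon
        for comparison, plist in preds.items():
            point_pse = float(np.mean([p.mean for p in plist]))
            point_sigma = float(np.mean([p.sigma for p in plist]))
            tests[("pse", comparison)] = test_fn(obs_pse, point_pse, cfg.alpha)
            tests[("sigma", comparison)] = test_fn(obs_sigma, point_sigma, cfg.alpha)
    return ExperimentOutcome(
        tests=tests, n_retained=n_retained, n_observers=cfg.n_observers,
        valid=valid, status_counts=status_counts,
    )


@dataclass(frozen=True)
class Set1Grid:
    """Axes of the Set-1 factorial.

    Defaults reproduce the full published grid: 27 sigma ratios linearly
    spaced over [1, 4], 4-30 observers, four data-collection regimes,
    three conflicts, 100 repetitions per cell.
    """

    ratios: tuple[float, ...] = tuple(np.linspace(1.0, 4.0, 27))
    observer_counts: tuple[int, ...] = tuple(range(4, 31))
    regimes: tuple[int, ...] = (10, 25, 40, 55)
    deltas: tuple[float, ...] = (0.0, 3.0, 6.0)
    repetitions: int = 100

    def cells(self) -> Iterable[tuple[int, float, int, int, int, int, int, float]]:
        for i_r, ratio in enumerate(self.ratios):
            for i_n, n_obs in enumerate(self.observer_counts):
                for i_reg, reps in enumerate(self.regimes):
                    for i_d, delta in enumerate(self.deltas):
                        yield (i_r, float(ratio), i_n, int(n_obs), i_reg, int(reps), i_d, float(delta))


def grid_counts(grid: Set1Grid | None = None) -> tuple[int, int]:
    """(experiments, observers) enumerated by a Set-1 grid, without simulating.

    The default grid enumerates 874,800 experiments containing
    14,871,600 simulated observers.
    """
    g = grid or Set1Grid()
    n_cells = len(g.ratios) * len(g.observer_counts) * len(g.regimes) * len(g.deltas)
    n_experiments = n_cells * g.repetitions
    obs_per_cellset = sum(g.observer_counts)
    n_observers = (
        len(g.ratios) * len(g.regimes) * len(g.deltas) * g.repetitions * obs_per_cellset
    )
    return n_experiments, n_observers


@dataclass
class GridSummary:
    """Per-experiment outcomes of a Set-1 run plus rejection bookkeeping.

    ``experiments`` is a long table with one row per experiment per
    (measure, comparison); ``summary_table()`` aggregates it to the
    per-cell percent-significant values that the grid figures display.
    """

    experiments: pd.DataFrame
    functions_simulated: int
    status_counts: dict[str, int]
    observers_simulated: int
    observers_rejected: int
    seed: int

    def summary_table(self) -> pd.DataFrame:
        grp = self.experiments[self.experiments["valid"]].groupby(
            ["ratio", "n_observers", "reps_per_level", "delta", "comparison", "measure"],
            as_index=False,
        )
        out = grp.agg(
            pct_significant=("significant", lambda s: 100.0 * s.mean()),
            n_valid=("significant", "size"),
        )
        return out

    def false_positive_rate(
        self, measure: str, comparison: str, reps_per_level: int | None = None
    ) -> float:
        """Percent significant pooled over all valid zero-conflict experiments."""
        df = self.experiments
        mask = (
            (df["delta"] == 0.0)
            & df["valid"]
            & (df["measure"] == measure)
            & (df["comparison"] == comparison)
        )
        if reps_per_level is not None:
            mask &= df["reps_per_level"] == reps_per_level
        sel = df[mask]
        if len(sel) == 0:
            raise ValueError("no zero-conflict experiments matching the query")
        return 100.0 * float(sel["significant"].mean())

    @property
    def rejected_fraction_pct(self) -> float:
        """Rejected observers as a percentage of all simulated observers."""
        return 100.0 * self.observers_rejected / self.observers_simulated

    def rejected_fraction_by_regime(self) -> pd.Series:
        df = self.experiments.drop_duplicates(
            subset=["ratio", "n_observers", "reps_per_level", "delta", "rep"]
        )
        grp = df.groupby("reps_per_level")
        return 100.0 * grp["n_excluded"].sum() / grp["n_simulated"].sum()


def _run_cell(grid: Set1Grid, cell, root_seed: int, base_cfg: ExperimentConfig):
    i_r, ratio, i_n, n_obs, i_reg, reps, i_d, delta = cell
    cfg = replace(
        base_cfg,
        ratio=ratio,
        n_observers=n_obs,
        reps_per_level=reps,
        conflict=ConflictSpec(delta=delta, base=base_cfg.conflict.base),
    )
    rows = []
    statuses = {s: 0 for s in FIT_STATUSES}
    obs_sim = 0
    obs_rej = 0
    for rep in range(grid.repetitions):
        outcome = run_experiment(cfg, root_seed, key=(i_r, i_n, i_reg, i_d, rep))
        obs_sim += outcome.n_observers
        obs_rej += outcome.n_excluded
        for s, c in outcome.status_counts.items():
            statuses[s] += c
        for measure in MEASURES:
            for comparison in COMPARISONS:
                tr = outcome.tests.get((measure, comparison))
                rows.append(
                    {
                        "ratio": ratio,
                        "n_observers": n_obs,
                        "reps_per_level": reps,
                        "delta": delta,
                        "rep": rep,
                        "comparison": comparison,
                        "measure": measure,
                        "significant": bool(tr.significant) if tr else False,
                        "p": tr.p if tr else np.nan,
                        "valid": outcome.valid,
                        "n_retained": outcome.n_retained,
                        "n_simulated": outcome.n_observers,
                        "n_excluded": outcome.n_excluded,
                    }
                )
    return rows, statuses, obs_sim, obs_rej


def run_grid(
    grid: Set1Grid,
    seed: int,
    base_cfg: ExperimentConfig | None = None,
    n_jobs: int = 1,
) -> GridSummary:
    """Run every cell of a Set-1 grid, fully seeded and order-invariant.

    Each (cell, repetition, observer, function) derives its RNG from the
    root seed and its grid coordinates, so identical (grid, seed) yield
    byte-identical summaries regardless of execution order or worker
    count.
    """
    if base_cfg is None:
        base_cfg = ExperimentConfig(ratio=1.0, n_observers=4, reps_per_level=10)
    cells = list(grid.cells())
    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_run_cell)(grid, cell, seed, base_cfg) for cell in cells
        )
    else:
        results = []
        for i, cell in enumerate(cells):
            results.append(_run_cell(grid, cell, seed, base_cfg))
            if (i + 1) % max(1, len(cells) // 20) == 0:
                log.info("set1 grid: %d/%d cells done", i + 1, len(cells))
    all_rows: list[dict] = []
    statuses = {s: 0 for s in FIT_STATUSES}
    obs_sim = 0
    obs_rej = 0
    for rows, st, n_sim, n_rej in results:
        all_rows.extend(rows)
        for s, c in st.items():
            statuses[s] += c
        obs_sim += n_sim
        obs_rej += n_rej
    experiments = pd.DataFrame(all_rows)
    return GridSummary(
        experiments=experiments,
        functions_simulated=sum(statuses.values()),
        status_counts=statuses,
        observers_simulated=obs_sim,
        observers_rejected=obs_rej,
        seed=seed,
    )


def oracle_significance_rate(
    n_observers: int,
    n_repetitions: int,
    seed: int,
    alpha: float = 0.05,
    test: str = "t",
    noise_sd: float = 1.0,
) -> float:
    """Calibration oracle: significance rate when the point is truly constant.

    Observed values are drawn directly around a fixed true value and
    tested against that value, bypassing fitting and prediction
    estimation entirely; the rate equals alpha up to binomial error.
    This isolates the test calibration from the prediction-noise
    inflation seen in the full pipeline.
    """
    test_fn = one_sample_t if test == "t" else one_sample_wilcoxon
    n_sig = 0
    for rep in range(n_repetitions):
        rng = child_rng(seed, 9001, rep)
        values = 55.0 + noise_sd * rng.standard_normal(n_observers)
        if test_fn(values, 55.0, alpha).significant:
            n_sig += 1
    return 100.0 * n_sig / n_repetitions
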
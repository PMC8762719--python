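"""Simulation Set 2: heterogeneous populations and R-squared overlap analysis.

Here each observer in an experiment has their own relative cue
reliability, drawn as r = 2**x with x ~ Uniform[-1, 1] (so r spans
[0.5, 2] symmetrically on a log scale), mimicking the between-observer
variation real studies exploit.  Populations behave according to either
MVUE or minimum-sigma (MS) selection; observed PSEs and sigmas are
regressed on the predictions each candidate model derives from the same
fitted single-cue functions.

The quantity of interest is the distribution over experiments of the
regression R-squared — the statistic the literature actually reports —
for "consistent" pairings (data and predictions from the same model) and
"inconsistent" ones (data from one model, predictions from the other).
Distributions are smoothed with a Gaussian kernel density on [0, 1] and
compared via the overlap coefficient eta, the integral of the pointwise
minimum of the two densities: eta = 1 means the R-squared statistic
cannot distinguish the models at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ConflictSpec
from .engine_set1 import ExperimentConfig, run_observer
from .seeding import child_rng

log = logging.getLogger(__name__)

__all__ = [
    "PopulationConfig",
    "Set2Grid",
    "RegressionResult",
    "DensityEstimate",
    "OverlapResult",
    "sample_ratio",
    "run_population_experiment",
    "fit_regression",
    "kde_smooth",
    "overlap",
    "run_set2",
    "set2_counts",
    "Set2Result",
]


def sample_ratio(rng: np.random.Generator) -> float:
    """Draw one observer's sigma ratio: 2**x with x ~ Uniform[-1, 1].

    Ratios lie in [0.5, 2] with median 1, symmetric on the log scale.
    """
    return float(2.0 ** rng.uniform(-1.0, 1.0))


@dataclass(frozen=True)
class PopulationConfig:
    """One heterogeneous-population experiment's design."""

    n_observers: int
    reps_per_level: int
    delta: float
    behaving_model: str = "MVUE"
    sigma_a: float = 4.86
    base: float = 55.0

    def __post_init__(self) -> None:
        if self.behaving_model not in ("MVUE", "MS"):
            raise ValueError(f"behaving_model must be MVUE or MS, got {self.behaving_model}")
        if self.n_observers < 2:
            raise ValueError(f"need >= 2 observers, got {self.n_observers}")

    def to_experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            ratio=1.0,  # placeholder; per-observer ratios are drawn separately
            n_observers=self.n_observers,
            reps_per_level=self.reps_per_level,
            conflict=ConflictSpec(delta=self.delta, base=self.base),
            sigma_a=self.sigma_a,
            observer_model=self.behaving_model,
        )


def run_population_experiment(
    cfg: PopulationConfig, root_seed: int, key: tuple[int, ...] = ()
) -> pd.DataFrame:
    """Simulate one experiment with per-observer sigma ratios.

    Returns one row per retained observer with the observed integrated
    PSE and sigma and the MVUE and MS predictions derived from that
    observer's fitted single-cue functions.  Excluded (rejected-fit)
    observers are dropped.
    """
    ecfg = cfg.to_experiment_config()
    rows = []
    for i in range(cfg.n_observers):
        ratio = sample_ratio(child_rng(root_seed, *key, i, 999))
        rec = run_observer(ecfg, root_seed, key + (i,), ratio=ratio)
        if rec.excluded:
            continue
        rows.append(
            {
                "observer": i,
                "ratio": ratio,
                "observed_pse": rec.fit_c.mu,
                "observed_sigma": rec.fit_c.sigma,
                "pred_MVUE_pse": rec.pred_mvue.mean,
                "pred_MVUE_sigma": rec.pred_mvue.sigma,
                "pred_MS_pse": rec.pred_ms.mean,
                "pred_MS_sigma": rec.pred_ms.sigma,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionResult:
    """First-order least-squares fit of observed on predicted values.

    ``r_squared`` is the coefficient of determination of the fitted line
    itself — not agreement with the identity line.  A perfect line far
    from the identity still yields R-squared = 1, which is precisely why
    the statistic cannot certify a cue-integration model.
    """

    slope: float
    intercept: float
    r_squared: float
    comparison: str = ""
    measure: str = ""

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def fit_regression(
    x: Sequence[float], y: Sequence[float], comparison: str = "", measure: str = ""
) -> RegressionResult:
    """Least-squares line of ``y`` (observed) on ``x`` (predicted)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0.0:
        raise ValueError("constant predictor: R-squared undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        comparison=comparison,
        measure=measure,
    )


@dataclass(frozen=True)
class DensityEstimate:
    """A kernel density evaluated on a fixed grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


def _silverman_bandwidth(values: np.ndarray) -> float:
    n = values.size
    sd = values.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        return 1e-3
    return 0.9 * scale * n ** (-0.2)


def kde_smooth(
    values: Sequence[float],
    bandwidth: float | None = None,
    support: tuple[float, float] = (0.0, 1.0),
    n_grid: int = 2001,
    reflect: bool = True,
) -> DensityEstimate:
    """Gaussian-kernel density of ``values`` on a uniform grid.

    F(x) = (1/(n h)) sum_i K((x - x_i) / h) with a Gaussian kernel K.
    The bandwidth defaults to Silverman's rule of thumb.  With
    ``reflect`` (the default, appropriate for R-squared values living on
    [0, 1]) kernel mass falling outside the support is reflected back at
    both boundaries so the density integrates to one on the support.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("kde_smooth requires at least one value")
    lo, hi = support
    if not hi > lo:
        raise ValueError("support must be an increasing interval")
    h = _silverman_bandwidth(v) if bandwidth is None else float(bandwidth)
    if not h > 0:
        raise ValueError(f"bandwidth must be positive, got {h}")
    grid = np.linspace(lo, hi, n_grid)

    def base(points: np.ndarray) -> np.ndarray:
        z = (points[:, None] - v[None, :]) / h
        return np.exp(-0.5 * z * z).sum(axis=1) / (v.size * h * np.sqrt(2.0 * np.pi))

    density = base(grid)
    if reflect:
        density = density + base(2.0 * lo - grid) + base(2.0 * hi - grid)
    return DensityEstimate(grid=grid, density=density, bandwidth=h)


@dataclass(frozen=True)
class OverlapResult:
    """Overlap coefficient eta of two densities; 1 = indistinguishable."""

    eta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError(f"eta out of [0, 1]: {self.eta}")


def overlap(F: DensityEstimate, G: DensityEstimate) -> OverlapResult:
    """Trapezoidal integral of the pointwise minimum of two densities.

    Both estimates must share the same evaluation grid.
    """
    if F.grid.shape != G.grid.shape or not np.allclose(F.grid, G.grid):
        raise ValueError("densities must share a common evaluation grid")
    eta = float(np.trapezoid(np.minimum(F.density, G.density), F.grid))
    return OverlapResult(eta=min(max(eta, 0.0), 1.0))


@dataclass(frozen=True)
class Set2Grid:
    """Axes of the Set-2 factorial.

    Defaults reproduce the full published design: four data-collection
    regimes, populations of 4/12/36 observers, conflicts of 3 and 6 mm,
    both behaving models, 1000 experiments per combination.
    """

    regimes: tuple[int, ...] = (10, 25, 40, 55)
    observer_counts: tuple[int, ...] = (4, 12, 36)
    deltas: tuple[float, ...] = (3.0, 6.0)
    behaving_models: tuple[str, ...] = ("MVUE", "MS")
    n_experiments: int = 1000


def set2_counts(grid: Set2Grid | None = None) -> tuple[int, int]:
    """(experiments, observers) enumerated by a Set-2 grid per behaving model.

    The default grid enumerates 24,000 experiments containing 416,000
    simulated observers (4 regimes x {4, 12, 36} observers x 2 conflicts
    x 1000 experiments).
    """
    g = grid or Set2Grid()
    per_model_cells = len(g.regimes) * len(g.deltas) * g.n_experiments
    n_experiments = per_model_cells * len(g.observer_counts)
    n_observers = per_model_cells * sum(g.observer_counts)
    return n_experiments, n_observers


@dataclass
class Set2Result:
    """Long R-squared table plus pairwise overlap coefficients."""

    r2_long: pd.DataFrame
    overlaps: pd.DataFrame
    n_degenerate: int
    seed: int


def run_set2(grid: Set2Grid, seed: int, n_grid: int = 2001) -> Set2Result:
    """Run the Set-2 factorial and compute R-squared overlap coefficients.

    For every cell and behaving model, ``n_experiments`` experiments are
    simulated; each contributes an R-squared per measure (PSE, sigma) and
    per prediction model (MVUE, MS).  For each (cell, behaving, measure),
    eta is computed between the consistent distribution (predictions from
    the behaving model) and the inconsistent one.  Experiments whose
    predictor is degenerate (constant) are dropped and counted.
    """
    r2_rows: list[dict] = []
    n_degenerate = 0
    for i_b, behaving in enumerate(grid.behaving_models):
        for i_reg, reps in enumerate(grid.regimes):
            for i_n, n_obs in enumerate(grid.observer_counts):
                for i_d, delta in enumerate(grid.deltas):
                    cfg = PopulationConfig(
                        n_observers=n_obs, reps_per_level=reps,
                        delta=delta, behaving_model=behaving,
                    )
                    log.info(
                        "set2 cell: behaving=%s reps=%d n_obs=%d delta=%g (%d experiments)",
                        behaving, reps, n_obs, delta, grid.n_experiments,
                    )
                    for exp in range(grid.n_experiments):
                        key = (i_b, i_reg, i_n, i_d, exp)
                        table = run_population_experiment(cfg, seed, key)
                        if len(table) < 3:
                            n_degenerate += 1
                            continue
                        try:
                            regs = [
                                fit_regression(
                                    table[f"pred_{pred}_{measure}"],
                                    table[f"observed_{measure}"],
                                    comparison=f"{pred}_vs_{behaving}",
                                    measure=measure,
                                )
                                for pred in ("MVUE", "MS")
                                for measure in ("pse", "sigma")
                            ]
                        except ValueError:
                            n_degenerate += 1
                            continue
                        for reg in regs:
                            r2_rows.append(
                                {
                                    "reps_per_level": reps,
                                    "n_observers": n_obs,
                                    "delta": delta,
                                    "behaving": behaving,
                                    "predicted": reg.comparison.split("_vs_")[0],
                                    "comparison": reg.comparison,
                                    "measure": reg.measure,
                                    "experiment": exp,
                                    "r_squared": reg.r_squared,
                                    "slope": reg.slope,
                                    "intercept": reg.intercept,
                                }
                            )
    r2_long = pd.DataFrame(r2_rows)
    overlaps = _overlap_table(r2_long, n_grid=n_grid)
    return Set2Result(r2_long=r2_long, overlaps=overlaps, n_degenerate=n_degenerate, seed=seed)


def _overlap_table(r2_long: pd.DataFrame, n_grid: int = 2001) -> pd.DataFrame:
    rows = []
    if len(r2_long) == 0:
        return pd.DataFrame(
            columns=["reps_per_level", "n_observers", "delta", "behaving", "measure", "eta"]
        )
    keys = ["reps_per_level", "n_observers", "delta", "behaving", "measure"]
    for vals, sub in r2_long.groupby(keys):
        cell = dict(zip(keys, vals))
        behaving = cell["behaving"]
        other = "MS" if behaving == "MVUE" else "MVUE"
        consistent = sub.loc[sub["predicted"] == behaving, "r_squared"].to_numpy()
        inconsistent = sub.loc[sub["predicted"] == other, "r_squared"].to_numpy()
        if consistent.size < 2 or inconsistent.size < 2:
            continue
        F = kde_smooth(consistent, n_grid=n_grid)
        G = kde_smooth(inconsistent, n_grid=n_grid)
        rows.append({**cell, "eta": overlap(F, G).eta})
    return pd.DataFrame(rows)
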
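"""Run configuration, hashing, result serialization and fixture generation.

A run is fully described by a :class:`RunConfig` (YAML/JSON serializable,
round-trip lossless) plus one root seed.  Outputs are long-format CSV
tables (UTF-8, header row, '.' decimal) and a JSON manifest carrying the
config hash, the seed and rejection bookkeeping; identical (config, seed)
reproduce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .psychometrics import PFParams, make_design, simulate_responses
from .seeding import child_rng

__all__ = [
    "Set1Settings",
    "Set2Settings",
    "RunConfig",
    "load_config",
    "config_hash",
    "write_results",
    "generate_fixture",
]


def _from_dict(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class Set1Settings:
    """Grid definition for the homogeneous-population factorial."""

    ratio_range: tuple[float, float] = (1.0, 4.0)
    n_ratios: int = 27
    observer_counts: tuple[int, ...] = tuple(range(4, 31))
    regimes: tuple[int, ...] = (10, 25, 40, 55)
    deltas: tuple[float, ...] = (0.0, 3.0, 6.0)
    repetitions: int = 100

    def __post_init__(self) -> None:
        if self.n_ratios < 1:
            raise ValueError(f"n_ratios must be >= 1, got {self.n_ratios}")
        if self.ratio_range[0] <= 0 or self.ratio_range[1] < self.ratio_range[0]:
            raise ValueError(f"invalid ratio_range {self.ratio_range}")
        if any(n < 2 for n in self.observer_counts):
            raise ValueError("observer counts must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    @property
    def ratios(self) -> tuple[float, ...]:
        return tuple(np.linspace(self.ratio_range[0], self.ratio_range[1], self.n_ratios))


@dataclass(frozen=True)
class Set2Settings:
    """Grid definition for the heterogeneous-population factorial."""

    regimes: tuple[int, ...] = (10, 25, 40, 55)
    observer_counts: tuple[int, ...] = (4, 12, 36)
    deltas: tuple[float, ...] = (3.0, 6.0)
    behaving_models: tuple[str, ...] = ("MVUE", "MS")
    n_experiments: int = 1000

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if any(m not in ("MVUE", "MS") for m in self.behaving_models):
            raise ValueError(f"invalid behaving_models {self.behaving_models}")


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of a simulation run."""

    sigma_a: float = 4.86
    base: float = 55.0
    span: float = 20.0
    n_levels: int = 9
    alpha: float = 0.05
    test: str = "t"
    rejection_policy: str = "drop"
    set1: Set1Settings = field(default_factory=Set1Settings)
    set2: Set2Settings = field(default_factory=Set2Settings)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.sigma_a <= 0 or self.span <= 0:
            raise ValueError("sigma_a and span must be positive")
        if self.n_levels < 2:
            raise ValueError(f"n_levels must be >= 2, got {self.n_levels}")
        if self.test not in ("t", "wilcoxon"):
            raise ValueError(f"test must be 't' or 'wilcoxon', got {self.test}")
        if self.rejection_policy not in ("drop", "resimulate"):
            raise ValueError(f"invalid rejection_policy {self.rejection_policy}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists, canonical types

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        set1 = data.pop("set1", {})
        set2 = data.pop("set2", {})

        def tup(d: dict) -> dict:
            return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

        known = {f.name for f in dataclasses.fields(cls)} - {"set1", "set2"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            **data,
            set1=_from_dict(Set1Settings, tup(set1), "set1"),
            set2=_from_dict(Set2Settings, tup(set2), "set2"),
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Missing keys take the standard defaults (sigma_a = 4.86 mm, base
    55 mm, 20 mm span, 9 levels, alpha 0.05); unknown keys raise with
    their names; ``None`` or an empty file yields the full defaults.
    """
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 of the canonical JSON form; changes iff any field changes."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def write_results(
    tables: dict[str, pd.DataFrame], manifest: dict, out_dir: str | Path
) -> list[Path]:
    """Write long-format CSV tables and an atomically-replaced JSON manifest.

    Returns the written paths.  Floats are serialized with repr-level
    precision so re-running an identical (config, seed) pair reproduces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        path = out / f"{name}.csv"
        _atomic_write_text(path, df.to_csv(index=False))
        written.append(path)
    manifest_path = out / "run_meta.json"
    _atomic_write_text(manifest_path, json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written


def build_manifest(cfg: RunConfig, seed: int, **counts) -> dict:
    return {
        "config_hash": config_hash(cfg),
        "seed": int(seed),
        "version": __version__,
        **{k: (int(v) if isinstance(v, (int, np.integer)) else v) for k, v in counts.items()},
    }


def generate_fixture(kind: str, seed: int, out_path: str | Path) -> list[Path]:
    """Write small deterministic CSV fixtures for tests and docs.

    kinds: ``responses`` (one 90-trial response table), ``observer``
    (three tables: cue A, cue B, integrated), ``experiment`` (a
    four-observer experiment, 3 tables each).  Identical (kind, seed)
    produce byte-identical files.
    """
    from .engine_set1 import ExperimentConfig, true_observer_functions

    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    def write_table(pf: PFParams, key: tuple[int, ...], name: str) -> None:
        design = make_design(pf.mu, 10)
        resp = simulate_responses(pf, design, child_rng(seed, *key))
        path = out / name
        _atomic_write_text(path, resp.to_frame().to_csv(index=False))
        paths.append(path)

    if kind == "responses":
        write_table(PFParams(55.0, 4.86), (0,), "responses.csv")
    elif kind == "observer":
        cfg = ExperimentConfig(ratio=2.0, n_observers=2, reps_per_level=10)
        for j, (pf, label) in enumerate(zip(true_observer_functions(cfg), "abc")):
            write_table(pf, (0, j), f"observer_{label}.csv")
    elif kind == "experiment":
        cfg = ExperimentConfig(ratio=2.0, n_observers=4, reps_per_level=10)
        pfs = true_observer_functions(cfg)
        for i in range(4):
            for j, (pf, label) in enumerate(zip(pfs, "abc")):
                write_table(pf, (i, j), f"observer{i}_{label}.csv")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return paths
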
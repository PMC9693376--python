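"""Hyperparameter search over the model's discrete tuning space.

The searched space is the Cartesian product of five discrete choices
(convolution filter count, dropout rate, L2 factor, convolution
padding, and conv depth), 4*4*3*2*2 = 192 configurations in total.
Search is sequential model-based with a tree-structured Parzen
estimator (TPE): after a block of random startup trials, observed
trials are split at the gamma-quantile of the objective into "good"
and "bad" sets, each modelled per dimension as a smoothed categorical
density (l and g); candidates drawn from l are ranked by the density
ratio l/g and the best candidate is evaluated next.  Because the space
is small and finite, an exhaustive mode enumerates every configuration
and serves as an exact oracle for the TPE path.

The objective is any callable mapping an :class:`HnnConfig` to a
finite real to be minimised (validation RMSE, typically).  Trials are
appended to a JSON-lines log as they finish, so an interrupted search
resumes from the log.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .hnn_core import (
    CONV_LAYER_CHOICES,
    DROPOUT_CHOICES,
    FILTER_CHOICES,
    L2_CHOICES,
    PADDING_CHOICES,
    HnnConfig,
)

#: searched dimension name -> HnnConfig field it sets
PARAM_FIELDS = {
    "filters": "conv_filters",
    "dropout": "dropout_rate",
    "l2": "l2_lambda",
    "padding": "conv_padding",
    "n_conv_layers": "n_conv_layers",
}


@dataclass(frozen=True)
class SearchSpace:
    filters: tuple = FILTER_CHOICES
    dropout: tuple = DROPOUT_CHOICES
    l2: tuple = L2_CHOICES
    padding: tuple = PADDING_CHOICES
    n_conv_layers: tuple = CONV_LAYER_CHOICES

    def dimensions(self) -> dict[str, tuple]:
        return {name: getattr(self, name) for name in PARAM_FIELDS}

    def grid(self) -> list[dict]:
        """All configurations in deterministic order."""
        dims = self.dimensions()
        return [
            dict(zip(dims, combo))
            for combo in itertools.product(*dims.values())
        ]

    def size(self) -> int:
        return math.prod(len(v) for v in self.dimensions().values())

    def contains(self, params: dict) -> bool:
        dims = self.dimensions()
        return set(params) == set(dims) and all(
            params[k] in dims[k] for k in dims
        )


@dataclass
class Trial:
    params: dict
    objective: float | None
    status: str  # "ok" | "failed"

    def to_json(self) -> str:
        return json.dumps({"params": self.params, "objective": self.objective,
                           "status": self.status})

    @classmethod
    def from_json(cls, line: str) -> "Trial":
        d = json.loads(line)
        return cls(params=d["params"], objective=d["objective"],
                   status=d["status"])


@dataclass
class SearchResult:
    best_config: HnnConfig
    best_params: dict
    best_objective: float
    trials: list[Trial]
    max_evals: int


def config_from_params(params: dict, base: HnnConfig | None = None) -> HnnConfig:
    """Apply a sampled point of the search space to a base configuration."""
    base = base or HnnConfig()
    cfg = replace(base, **{PARAM_FIELDS[k]: v for k, v in params.items()})
    cfg.validate()
    return cfg


class _Tpe:
    """Categorical tree-structured Parzen estimator on a finite space."""

    def __init__(self, space: SearchSpace, rng: np.random.Generator,
                 n_startup: int = 10, gamma: float = 0.25,
                 n_candidates: int = 24):
        self.dims = space.dimensions()
        self.rng = rng
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    def _random_point(self) -> dict:
        return {k: v[self.rng.integers(len(v))] for k, v in self.dims.items()}

    def _density(self, points: list[dict]) -> dict[str, np.ndarray]:
        """Laplace-smoothed per-dimension categorical frequencies."""
        out = {}
        for k, choices in self.dims.items():
            counts = np.ones(len(choices))  # +1 smoothing prior
            for p in points:
                counts[choices.index(p[k])] += 1
            out[k] = counts / counts.sum()
        return out

    def suggest(self, trials: list[Trial]) -> dict:
        done = [t for t in trials if t.status == "ok"]
        if len(done) < self.n_startup:
            return self._random_point()
        done.sort(key=lambda t: t.objective)
        n_good = max(1, int(np.ceil(self.gamma * len(done))))
        good = self._density([t.params for t in done[:n_good]])
        bad = self._density([t.params for t in done[n_good:]] or
                            [t.params for t in done])
        best_point, best_score = None, -np.inf
        for _ in range(self.n_candidates):
            point = {
                k: choices[self.rng.choice(len(choices), p=good[k])]
                for k, choices in self.dims.items()
            }
            score = sum(
                np.log(good[k][self.dims[k].index(point[k])])
                - np.log(bad[k][self.dims[k].index(point[k])])
                for k in self.dims
            )
            if score > best_score:
                best_point, best_score = point, score
        return best_point


def optimize(
    objective_fn: Callable[[HnnConfig], float],
    space: SearchSpace | None = None,
    max_evals: int = 20,
    seed: int = 0,
    mode: str = "tpe",
    base_config: HnnConfig | None = None,
    trial_log: str | Path | None = None,
    n_startup: int = 10,
) -> SearchResult:
    """Minimise ``objective_fn`` over the discrete search space.

    ``mode="tpe"`` runs the Parzen-estimator search; ``mode="exhaustive"``
    walks the full grid in deterministic order (an exact oracle for the
    finite space).  A non-finite objective marks the trial failed and
    the search continues; if every trial fails the search errors.  With
    ``trial_log`` set, completed trials are appended as JSON lines and
    a restarted search resumes after the logged trials.
    """
    if max_evals < 1:
        raise ValueError("max_evals must be >= 1")
    if mode not in ("tpe", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    space = space or SearchSpace()
    trials: list[Trial] = []
    log_path = Path(trial_log) if trial_log else None
    if log_path and log_path.exists():
        trials = [Trial.from_json(line)
                  for line in log_path.read_text().splitlines() if line.strip()]
    rng = np.random.default_rng(seed)
    sampler = _Tpe(space, rng, n_startup=n_startup)
    grid = space.grid()

    while len(trials) < max_evals:
        if mode == "exhaustive":
            i = len(trials)
            if i >= len(grid):
                break
            params = grid[i]
        else:
            params = sampler.suggest(trials)
        if not space.contains(params):
            raise RuntimeError(f"sampled point outside the space: {params}")
        config = config_from_params(params, base_config)
        try:
            value = float(objective_fn(config))
        except Exception:
            value = float("nan")
        if math.isfinite(value):
            trial = Trial(params=params, objective=value, status="ok")
        else:
            trial = Trial(params=params, objective=None, status="failed")
        trials.append(trial)
        if log_path:
            with log_path.open("a") as fh:
                fh.write(trial.to_json() + "\n")

    done = [t for t in trials if t.status == "ok"]
    if not done:
        raise RuntimeError("all trials failed; no finite objective observed")
    best = min(done, key=lambda t: t.objective)
    return SearchResult(
        best_config=config_from_params(best.params, base_config),
        best_params=best.params,
        best_objective=best.objective,
        trials=trials,
        max_evals=max_evals,
    )
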
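"""Seeded hyperparameter search: random sampling and a TPE sampler.

The tree-structured Parzen estimator (TPE) models the densities of
"good" and "bad" trials separately.  After ``n_startup`` random trials,
observed trials are split at the γ-quantile of the objective (here
maximized); candidate values are drawn from a Parzen (Gaussian-mixture)
estimate of the good density l(x) and scored by the ratio l(x)/g(x),
independently per dimension.  With ``n_startup >= n_trials`` the sampler
degenerates exactly to random search, which the tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence, Union

import numpy as np


class SearchError(ValueError):
    """Invalid search space or a search whose every trial failed."""


@dataclass(frozen=True)
class FloatRange:
    low: float
    high: float
    log: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise SearchError(f"empty range [{self.low}, {self.high}]")
        if self.log and self.low <= 0:
            raise SearchError("log-uniform range requires low > 0")


@dataclass(frozen=True)
class IntRange:
    low: int
    high: int  # inclusive

    def __post_init__(self) -> None:
        if not self.low <= self.high:
            raise SearchError(f"empty range [{self.low}, {self.high}]")


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def __post_init__(self) -> None:
        if len(self.choices) == 0:
            raise SearchError("empty categorical")


ParamSpec = Union[FloatRange, IntRange, Categorical]


@dataclass(frozen=True)
class SearchSpace:
    """Named hyperparameter ranges plus the trial budget and sampler."""

    params: Mapping[str, ParamSpec]
    n_trials: int = 10
    sampler: str = "tpe"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.params) == 0:
            raise SearchError("search space has no parameters")
        if self.n_trials < 1:
            raise SearchError("n_trials must be >= 1")
        if self.sampler not in ("tpe", "random"):
            raise SearchError(f"unknown sampler {self.sampler!r}")


def default_search_space(n_trials: int = 10, seed: int = 0, sampler: str = "tpe") -> SearchSpace:
    """Learning rate (log-uniform), batch size and dropout defaults."""
    return SearchSpace(
        {
            "lr": FloatRange(1e-5, 1e-2, log=True),
            "batch_size": Categorical((8, 16, 32)),
            "dropout": FloatRange(0.0, 0.3),
        },
        n_trials=n_trials,
        sampler=sampler,
        seed=seed,
    )


@dataclass
class Trial:
    number: int
    params: dict
    value: float


@dataclass
class SearchResult:
    best_params: dict
    best_value: float
    trials: list[Trial] = field(default_factory=list)

    @property
    def best_trial(self) -> Trial:
        return max(self.trials, key=lambda t: (t.value, -t.number))


# -- unit-interval transforms ------------------------------------------------

def _to_unit(spec: ParamSpec, x) -> float:
    if isinstance(spec, FloatRange):
        if spec.log:
            return (math.log(x) - math.log(spec.low)) / (
                math.log(spec.high) - math.log(spec.low)
            )
        return (x - spec.low) / (spec.high - spec.low)
    if isinstance(spec, IntRange):
        return (x - spec.low + 0.5) / (spec.high - spec.low + 1)
    raise TypeError("categoricals have no unit transform")


def _from_unit(spec: ParamSpec, u: float):
    u = min(max(u, 0.0), 1.0)
    if isinstance(spec, FloatRange):
        if spec.log:
            return math.exp(
                math.log(spec.low) + u * (math.log(spec.high) - math.log(spec.low))
            )
        return spec.low + u * (spec.high - spec.low)
    if isinstance(spec, IntRange):
        return min(spec.high, spec.low + int(u * (spec.high - spec.low + 1)))
    raise TypeError("categoricals have no unit transform")


def _random_draw(rng: np.random.Generator, params: Mapping[str, ParamSpec]) -> dict:
    out = {}
    for name in params:  # insertion order: deterministic
        spec = params[name]
        if isinstance(spec, Categorical):
            out[name] = spec.choices[int(rng.integers(len(spec.choices)))]
        else:
            out[name] = _from_unit(spec, float(rng.random()))
    return out


class RandomSampler:
    def suggest(self, rng, params, history):
        return _random_draw(rng, params)


class TPESampler:
    """Per-dimension Parzen-density TPE with uniform prior component."""

    def __init__(self, n_startup: int = 5, gamma: float = 0.25, n_candidates: int = 24):
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    def suggest(self, rng, params, history: Sequence[Trial]):
        if len(history) < self.n_startup:
            return _random_draw(rng, params)
        ordered = sorted(history, key=lambda t: t.value, reverse=True)
        n_good = max(1, math.ceil(self.gamma * len(ordered)))
        good, bad = ordered[:n_good], ordered[n_good:] or ordered[n_good - 1 :]
        out = {}
        for name in params:
            spec = params[name]
            if isinstance(spec, Categorical):
                out[name] = self._suggest_categorical(rng, spec, good, bad, name)
            else:
                out[name] = self._suggest_numeric(rng, spec, good, bad, name)
        return out

    @staticmethod
    def _parzen(obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mixture centres with per-point bandwidths on the unit interval.

        Each observation's bandwidth is its largest gap to a neighbouring
        observation (the interval endpoints count as neighbours), so
        isolated points get wide kernels and clustered points narrow ones.
        """
        order = np.argsort(obs)
        srt = obs[order]
        ext = np.concatenate([[0.0], srt, [1.0]])
        gaps = np.maximum(ext[1:-1] - ext[:-2], ext[2:] - ext[1:-1])
        sigma = np.empty_like(obs)
        sigma[order] = np.clip(gaps, 0.03, 1.0)
        return obs, sigma

    @staticmethod
    def _density(x: np.ndarray, centres: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        # Gaussian mixture plus a uniform prior component on [0, 1].
        z = (x[:, None] - centres[None, :]) / sigma[None, :]
        kern = np.exp(-0.5 * z * z) / (sigma[None, :] * math.sqrt(2 * math.pi))
        n = len(centres)
        return (kern.sum(axis=1) + 1.0) / (n + 1)

    def _suggest_numeric(self, rng, spec, good, bad, name):
        g_obs = np.array([_to_unit(spec, t.params[name]) for t in good])
        b_obs = np.array([_to_unit(spec, t.params[name]) for t in bad])
        g_c, g_s = self._parzen(g_obs)
        b_c, b_s = self._parzen(b_obs)
        # Candidates from l(x): pick a mixture component (or the uniform
        # prior) and perturb; clip into the unit interval.
        comp = rng.integers(-1, len(g_c), size=self.n_candidates)
        safe = np.clip(comp, 0, None)
        cand = np.where(
            comp < 0,
            rng.random(self.n_candidates),
            np.clip(g_c[safe] + g_s[safe] * rng.standard_normal(self.n_candidates), 0, 1),
        )
        score = self._density(cand, g_c, g_s) / np.maximum(
            self._density(cand, b_c, b_s), 1e-12
        )
        return _from_unit(spec, float(cand[int(np.argmax(score))]))

    def _suggest_categorical(self, rng, spec, good, bad, name):
        k = len(spec.choices)

        def weights(trials):
            counts = np.ones(k)  # add-one smoothing (uniform prior)
            for t in trials:
                counts[spec.choices.index(t.params[name])] += 1
            return counts / counts.sum()

        ratio = weights(good) / weights(bad)
        return spec.choices[int(np.argmax(ratio + 1e-9 * rng.random(k)))]


def tpe_search(
    space: SearchSpace,
    objective: Callable[[dict], float],
    seed: int | None = None,
) -> SearchResult:
    """Run exactly ``space.n_trials`` evaluations; return the best trial.

    The objective is maximized.  Fully reproducible for a fixed seed;
    trials whose objective is non-finite are recorded but never selected,
    and a search where every trial is non-finite raises.
    """
    rng = np.random.default_rng(space.seed if seed is None else seed)
    sampler = TPESampler() if space.sampler == "tpe" else RandomSampler()
    history: list[Trial] = []
    finite: list[Trial] = []
    for t in range(space.n_trials):
        params = sampler.suggest(rng, space.params, finite)
        value = float(objective(params))
        trial = Trial(t, params, value)
        history.append(trial)
        if math.isfinite(value):
            finite.append(trial)
    if not finite:
        raise SearchError("all trials returned non-finite objectives")
    best = max(finite, key=lambda t: (t.value, -t.number))
    return SearchResult(dict(best.params), best.value, history)
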
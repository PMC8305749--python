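"""Tree-structured Parzen Estimator (TPE) for mixed search spaces.

Sequential model-based optimization: past trials are split at the gamma
quantile of the objective into a "good" set and a "bad" set, and each
parameter gets two one-dimensional Parzen density estimates, l(x) over the
good values and g(x) over the bad ones.  Candidates are drawn from l and the
one maximising l(x)/g(x) is suggested — the classic factorized TPE scheme.

Numeric parameters use truncated-Gaussian mixtures (one component per
observation, bandwidth from the neighbour spacing, plus a flat prior
component); categorical parameters use smoothed count distributions.
Conditional parameters (e.g. the focal focusing parameter, active only when
the focal loss is chosen) are sampled hierarchically: a parameter's
``condition`` inspects the partial configuration and the Parzen estimates
are built only from trials where the parameter was active.

The optimizer is maximising and fully deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass
class Uniform:
    """Continuous parameter on [lo, hi]; set ``q`` for quantised, ``integer``
    for integer-valued, ``condition`` for conditional activation."""

    name: str
    lo: float
    hi: float
    q: float | None = None
    integer: bool = False
    condition: Callable[[dict], bool] | None = None

    def round(self, v: float):
        if self.q:
            v = self.lo + round((v - self.lo) / self.q) * self.q
        v = min(max(v, self.lo), self.hi)
        return int(round(v)) if self.integer else float(v)

    def sample_prior(self, rng) -> float:
        return self.round(rng.uniform(self.lo, self.hi))


@dataclass
class Categorical:
    name: str
    choices: list
    condition: Callable[[dict], bool] | None = None

    def sample_prior(self, rng):
        return self.choices[rng.integers(0, len(self.choices))]


Param = Uniform | Categorical


def _adaptive_bandwidths(points: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-point Gaussian bandwidths from neighbour spacing, clipped."""
    span = hi - lo
    if len(points) == 1:
        return np.array([span / 2.0])
    order = np.argsort(points)
    srt = points[order]
    gaps = np.empty(len(srt))
    gaps[0] = srt[1] - srt[0]
    gaps[-1] = srt[-1] - srt[-2]
    if len(srt) > 2:
        gaps[1:-1] = np.maximum(srt[1:-1] - srt[:-2], srt[2:] - srt[1:-1])
    bw = np.empty(len(points))
    bw[order] = gaps
    return np.clip(bw, span / 100.0, span)


class _NumericParzen:
    """Truncated-Gaussian mixture over observed values plus a flat prior."""

    def __init__(self, values: np.ndarray, lo: float, hi: float):
        self.lo, self.hi = lo, hi
        self.mu = np.asarray(values, dtype=float)
        self.sigma = _adaptive_bandwidths(self.mu, lo, hi)
        # prior component gets one pseudo-observation
        self.w_prior = 1.0 / (len(self.mu) + 1.0)
        self.w_obs = (1.0 - self.w_prior) / len(self.mu)

    def sample(self, rng, n: int) -> np.ndarray:
        out = np.empty(n)
        comp = rng.integers(-1, len(self.mu), size=n)  # -1 = prior
        for i, c in enumerate(comp):
            if c < 0:
                out[i] = rng.uniform(self.lo, self.hi)
            else:
                for _ in range(50):
                    v = rng.normal(self.mu[c], self.sigma[c])
                    if self.lo <= v <= self.hi:
                        break
                out[i] = min(max(v, self.lo), self.hi)
        return out

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        span = self.hi - self.lo
        dens = np.full(len(x), self.w_prior / span)
        for m, s in zip(self.mu, self.sigma):
            dens += (
                self.w_obs
                * np.exp(-0.5 * ((x - m) / s) ** 2)
                / (s * math.sqrt(2 * math.pi))
            )
        return np.log(dens)


class _CategoricalParzen:
    def __init__(self, values: list, choices: list):
        counts = np.ones(len(choices))  # add-one smoothing toward the prior
        index = {c: i for i, c in enumerate(choices)}
        for v in values:
            counts[index[v]] += 1.0
        self.choices = choices
        self.p = counts / counts.sum()

    def sample(self, rng, n: int) -> list:
        idx = rng.choice(len(self.choices), size=n, p=self.p)
        return [self.choices[i] for i in idx]

    def logpdf_one(self, v) -> float:
        return float(np.log(self.p[self.choices.index(v)]))


@dataclass
class Trial:
    config: dict
    objective: float


class TPEOptimizer:
    """Maximising TPE over a list of (possibly conditional) parameters.

    Parameters are suggested in list order so conditions may inspect earlier
    choices.  The first ``n_startup`` trials are drawn from the prior.
    """

    def __init__(
        self,
        space: list[Param],
        seed: int = 0,
        n_startup: int = 20,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ):
        self.space = list(space)
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.trials: list[Trial] = []

    # -- history handling -------------------------------------------------
    def observe(self, config: dict, objective: float) -> None:
        self.trials.append(Trial(dict(config), float(objective)))

    def _split(self, history: list[Trial]) -> tuple[list[Trial], list[Trial]]:
        ordered = sorted(history, key=lambda t: t.objective, reverse=True)
        n_good = max(1, math.ceil(self.gamma * len(ordered)))
        return ordered[:n_good], ordered[n_good:]

    # -- suggestion --------------------------------------------------------
    def suggest(self) -> dict:
        config: dict = {}
        finite = [t for t in self.trials if np.isfinite(t.objective)]
        for param in self.space:
            if param.condition is not None and not param.condition(config):
                config[param.name] = None
                continue
            history = [t for t in finite if t.config.get(param.name) is not None]
            if len(history) < self.n_startup:
                config[param.name] = param.sample_prior(self.rng)
                continue
            good, bad = self._split(history)
            good_v = [t.config[param.name] for t in good]
            bad_v = [t.config[param.name] for t in bad] or good_v
            if isinstance(param, Categorical):
                l = _CategoricalParzen(good_v, param.choices)
                g = _CategoricalParzen(bad_v, param.choices)
                cands = l.sample(self.rng, self.n_candidates)
                best = max(cands, key=lambda c: l.logpdf_one(c) - g.logpdf_one(c))
                config[param.name] = best
            else:
                l = _NumericParzen(np.array(good_v, dtype=float), param.lo, param.hi)
                g = _NumericParzen(np.array(bad_v, dtype=float), param.lo, param.hi)
                cands = l.sample(self.rng, self.n_candidates)
                score = l.logpdf(cands) - g.logpdf(cands)
                config[param.name] = param.round(float(cands[int(np.argmax(score))]))
        return config

    @property
    def best(self) -> Trial:
        finite = [t for t in self.trials if np.isfinite(t.objective)]
        if not finite:
            raise ValueError("no successful trials")
        return max(finite, key=lambda t: t.objective)
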
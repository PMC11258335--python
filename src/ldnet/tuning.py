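"""Hyperparameter search: TPE sampling with ASHA early stopping and K-fold
cross-validation.

The search space is a hypercube sampled log-uniformly.  Candidate
configurations are proposed by a Tree-structured Parzen Estimator: after a
random start-up phase, completed trials are split at a quantile into
"good" and "bad" sets, per-dimension Parzen (Gaussian-mixture) densities
l(x) and g(x) are fitted to each in log space, and the candidate
maximizing l(x)/g(x) among draws from l is evaluated next.  Trials are
trained in rungs of increasing budget; the Asynchronous Successive Halving
rule stops a trial at a rung when its score is not within the top 1/eta
fraction of scores recorded at that rung so far.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, split_kfold

__all__ = ["SearchSpace", "TPESampler", "AshaScheduler", "tune", "kfold_validation_metric"]


@dataclass
class SearchSpace:
    """Log-uniform ranges per hyperparameter; integer dims rounded."""

    ranges: dict  # name -> (low, high)
    int_params: tuple = ()
    K: int = 3  # cross-validation folds
    n_trials: int = 20
    n_startup: int = 8
    # ASHA rung schedule (budgets in trainer units, e.g. epochs)
    min_budget: int = 25
    max_budget: int = 100
    eta: int = 2

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not (0 < lo < hi):
                raise ValueError(f"range for '{name}' must satisfy 0 < low < high")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")

    def rungs(self) -> list[int]:
        out = []
        b = self.min_budget
        while b < self.max_budget:
            out.append(int(b))
            b *= self.eta
        out.append(int(self.max_budget))
        return out


class TPESampler:
    """Minimal Tree-structured Parzen Estimator over a log hypercube."""

    def __init__(self, space: SearchSpace, seed: int, gamma: float = 0.25, n_candidates: int = 24):
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.names = list(space.ranges)
        self.lo = np.log([space.ranges[n][0] for n in self.names])
        self.hi = np.log([space.ranges[n][1] for n in self.names])

    def _decode(self, z: np.ndarray) -> dict:
        cfg = {}
        for j, name in enumerate(self.names):
            lo, hi = self.space.ranges[name]
            v = min(max(float(np.exp(z[j])), lo), hi)  # guard exp/log round-off
            if name in self.space.int_params:
                v = int(round(v))
            cfg[name] = v
        return cfg

    def _parzen_logpdf(self, z: np.ndarray, centers: np.ndarray, bw: np.ndarray) -> np.ndarray:
        # mixture of axis-aligned Gaussians, uniform weights
        d2 = ((z[:, None, :] - centers[None, :, :]) / bw) ** 2
        logk = -0.5 * d2.sum(axis=2) - np.log(bw).sum()
        m = logk.max(axis=1)
        return m + np.log(np.mean(np.exp(logk - m[:, None]), axis=1))

    def suggest(self, history: list[tuple[np.ndarray, float]]) -> tuple[dict, np.ndarray]:
        if len(history) < self.space.n_startup:
            z = self.rng.uniform(self.lo, self.hi)
            return self._decode(z), z
        Z = np.array([h[0] for h in history])
        scores = np.array([h[1] for h in history])
        n_good = max(2, int(np.ceil(self.gamma * len(history))))
        order = np.argsort(scores)
        good, bad = Z[order[:n_good]], Z[order[n_good:]]
        if bad.shape[0] < 2:
            z = self.rng.uniform(self.lo, self.hi)
            return self._decode(z), z
        span = self.hi - self.lo
        bw_good = np.maximum(span / max(len(good), 2), 1e-3 * span)
        bw_bad = np.maximum(span / max(len(bad), 2), 1e-3 * span)
        idx = self.rng.integers(0, len(good), size=self.n_candidates)
        cand = np.clip(good[idx] + self.rng.normal(size=(self.n_candidates, len(self.names))) * bw_good, self.lo, self.hi)
        ei = self._parzen_logpdf(cand, good, bw_good) - self._parzen_logpdf(cand, bad, bw_bad)
        z = cand[int(np.argmax(ei))]
        return self._decode(z), z


class AshaScheduler:
    """Sequential implementation of the asynchronous successive-halving rule."""

    def __init__(self, rungs: list[int], eta: int):
        self.rungs = rungs
        self.eta = eta
        self.rung_scores: list[list[float]] = [[] for _ in rungs]

    def should_continue(self, rung_idx: int, score: float) -> bool:
        """Record the score at this rung; True if the trial is promoted."""
        scores = self.rung_scores[rung_idx]
        scores.append(score)
        if rung_idx == len(self.rungs) - 1:
            return False  # final rung: nothing left to promote to
        k = max(1, len(scores) // self.eta)
        threshold = np.sort(scores)[k - 1]
        return score <= threshold


def kfold_validation_metric(trainer, config: dict, dataset: Dataset, K: int, seed: int, budget: int) -> float:
    """Mean validation discrepancy of a config across K folds."""
    from .data import SpatialDomain

    folds = split_kfold(dataset, K, seed)
    vals = []
    for f, (tr_idx, va_idx) in enumerate(folds):
        train_ds = Dataset(
            [dataset.samples[i] for i in tr_idx], dataset.domain, dataset.horizon, dict(dataset.metadata)
        )
        val_ds = Dataset(
            [dataset.samples[i] for i in va_idx], dataset.domain, dataset.horizon, dict(dataset.metadata)
        )
        vals.append(float(trainer(config, train_ds, val_ds, budget, seed + f)))
    return float(np.mean(vals))


def tune(space: SearchSpace, dataset: Dataset, trainer, seed: int = 0):
    """TPE + ASHA search; returns (best config, trial table).

    ``trainer(config, train_ds, val_ds, budget, seed) -> float`` trains a
    model under ``config`` for the given budget and returns the validation
    discrepancy (lower is better).  Each trial is scored by K-fold
    cross-validation at every rung; unpromoted trials stop early.
    """
    sampler = TPESampler(space, seed)
    rungs = space.rungs()
    scheduler = AshaScheduler(rungs, space.eta)
    history: list[tuple[np.ndarray, float]] = []
    records = []
    failures = 0
    for trial in range(space.n_trials):
        config, z = sampler.suggest(history)
        metric = np.inf
        stopped_at = None
        try:
            for r, budget in enumerate(rungs):
                metric = kfold_validation_metric(trainer, config, dataset, space.K, seed + 1000 * trial, budget)
                if not scheduler.should_continue(r, metric):
                    stopped_at = budget if r < len(rungs) - 1 else None
                    break
        except Exception as exc:  # noqa: BLE001 - a failed trial is data, not fatal
            failures += 1
            records.append({"trial": trial, **config, "metric": np.nan, "error": str(exc)})
            continue
        history.append((z, metric))
        records.append({"trial": trial, **config, "metric": metric, "stopped_at_budget": stopped_at})
    table = pd.DataFrame(records)
    if not history:
        raise RuntimeError(f"all {failures} trials failed")
    completed = table.dropna(subset=["metric"])
    # select among trials that reached the final rung if any did
    full = completed[completed.get("stopped_at_budget").isna()] if "stopped_at_budget" in completed else completed
    pool = full if len(full) else completed
    best_row = pool.loc[pool["metric"].idxmin()]
    best_config = {name: best_row[name] for name in space.ranges}
    for name in space.int_params:
        best_config[name] = int(best_config[name])
    return best_config, table
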
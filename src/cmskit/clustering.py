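"""Severity levels from composite scores via repeated 1-D k-means.

Per resampling run, k-means is fit on an 80% training subsample of the
composite scores, the boundary between each pair of adjacent clusters is
summarized by the midpoint of the two flanking scores ("outer values"), and
ALL animals are assigned a severity level by those thresholds. Across runs
the per-boundary thresholds are aggregated into a mean and a percentile 95%
confidence interval — wide intervals flag variance instability due to
random sampling.

Severity labels follow the low-is-worse composite convention: level ``k``
(worst) is the cluster with the LOWEST centroid, level 1 (best) the highest.

The 1-D k-means solver is exact: for sorted one-dimensional data every
optimal k-means partition is contiguous, so the global within-cluster
sum-of-squares optimum is found by dynamic programming over contiguous
partitions rather than by Lloyd iteration with random restarts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import STAGE_CLUSTER
from .score import CompositeScores
from .selection import ResampleConfig, draw_subsample


@dataclass
class ClusterConfig:
    k: int = 3
    n_runs: int = 100
    train_fraction: float = 0.80
    seed: int = 0
    n_init: int = 10  # interface compatibility; the exact solver ignores restarts
    full_data: bool = False  # fit on all animals each run instead of the subsample

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class ThresholdSet:
    """k-1 severity thresholds on the composite-score scale.

    ``mean[i]`` separates level ``k - i`` (below) from level ``k - i - 1``
    (at or above); thresholds are strictly increasing from the
    worst-severity boundary to the best. CIs are percentile (2.5th/97.5th)
    across runs; per-run values are retained for audit.
    """

    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    per_run: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    @property
    def k(self) -> int:
        return len(self.mean) + 1

    def to_dict(self) -> dict:
        labels = [f"{self.k - i} to {self.k - i - 1}" for i in range(len(self.mean))]
        return {
            "k": self.k,
            "thresholds": [
                {
                    "boundary": lab,
                    "mean": float(m),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
                for lab, m, lo, hi in zip(labels, self.mean, self.ci_low, self.ci_high)
            ],
            "per_run": self.per_run.tolist(),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "ThresholdSet":
        mean = np.array([t["mean"] for t in data["thresholds"]])
        return cls(
            mean=mean,
            ci_low=np.array([t["ci_low"] for t in data["thresholds"]]),
            ci_high=np.array([t["ci_high"] for t in data["thresholds"]]),
            per_run=np.asarray(data.get("per_run", [])),
        )

    @classmethod
    def read(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_values(cls, thresholds) -> "ThresholdSet":
        """Wrap frozen published threshold values (no run history)."""
        t = np.sort(np.asarray(thresholds, dtype=float))
        return cls(mean=t, ci_low=t.copy(), ci_high=t.copy())


def kmeans_1d(
    scores, k: int, n_init: int = 10, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal k-means on one-dimensional data.

    Returns ``(centroids, labels)`` with centroids in ascending order and
    labels indexing them (label 0 = lowest-centroid cluster). The partition
    is contiguous in sorted order and attains the minimum within-cluster sum
    of squares (dynamic programming over contiguous partitions).

    ``n_init`` and ``rng`` are accepted for interface compatibility with
    restart-based solvers; the exact solver needs neither.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1:
        raise ValueError("scores must be one-dimensional")
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct score values for k={k}")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    cs = np.concatenate([[0.0], np.cumsum(xs)])
    cs2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # within-cluster SS of xs[i:j] for a vector of starts i
        m = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    INF = np.inf
    D = np.full((k + 1, n + 1), INF)
    B = np.zeros((k + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            starts = np.arange(kk - 1, j)
            costs = D[kk - 1, starts] + seg_cost(starts, j)
            best = int(np.argmin(costs))
            D[kk, j] = costs[best]
            B[kk, j] = starts[best]
    # recover boundaries and label sorted points
    labels_sorted = np.empty(n, dtype=int)
    centroids = np.empty(k)
    j = n
    for kk in range(k, 0, -1):
        i = B[kk, j]
        labels_sorted[i:j] = kk - 1
        centroids[kk - 1] = xs[i:j].mean()
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return centroids, labels


def extract_thresholds(scores, labels) -> np.ndarray:
    """Midpoint thresholds between adjacent clusters.

    The threshold between clusters c and c+1 (by ascending centroid) is the
    midpoint of the two "outer values" flanking the boundary: the maximum
    score in c and the minimum score in c+1.
    """
    x = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    k = int(lab.max()) + 1
    out = np.empty(k - 1)
    for c in range(k - 1):
        lo_max = x[lab == c].max()
        hi_min = x[lab == c + 1].min()
        out[c] = 0.5 * (lo_max + hi_min)
    return out


def aggregate_thresholds(per_run) -> ThresholdSet:
    """Mean and percentile 95% CI of each boundary across runs."""
    arr = np.atleast_2d(np.asarray(per_run, dtype=float))
    if arr.shape[0] < 1:
        raise ValueError("need at least one run")
    mean = arr.mean(axis=0)
    if arr.shape[0] == 1:
        lo = hi = arr[0].copy()
    else:
        lo = np.percentile(arr, 2.5, axis=0)
        hi = np.percentile(arr, 97.5, axis=0)
    return ThresholdSet(mean=mean, ci_low=lo, ci_high=hi, per_run=arr)


def assign_levels(scores, thresholds, k: int | None = None) -> np.ndarray:
    """Map scores to severity levels via strictly increasing thresholds.

    Below the lowest threshold -> worst level (k); at or above the highest
    -> best level (1). A score exactly on a boundary goes to the LESS
    severe side (conservative against over-reporting severity).
    """
    t = thresholds.mean if isinstance(thresholds, ThresholdSet) else np.asarray(thresholds, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    k = k or (len(t) + 1)
    x = np.asarray(scores, dtype=float)
    return k - np.searchsorted(t, x, side="right")


@dataclass
class SeverityAssignment:
    """Per-animal severity level with run-to-run stability."""

    frame: pd.DataFrame  # index animal_id; group, model, score, severity_level, stability
    memberships: pd.DataFrame | None = None  # animal x run levels

    def write_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "animal_id"
        out.to_csv(path)


def run_severity_clustering(
    scores: CompositeScores, config: ClusterConfig | None = None
) -> tuple[ThresholdSet, pd.DataFrame]:
    """Repeated subsampled k-means over the composite scores.

    Per run: draw an 80% training subsample, fit exact 1-D k-means on the
    training scores, extract the boundary thresholds, and assign every
    animal (training and held-out) a severity level by those thresholds.
    Returns the aggregated :class:`ThresholdSet` and the animal x run level
    membership matrix.
    """
    config = config or ClusterConfig()
    x = scores.scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("composite scores must be finite")
    rconf = ResampleConfig(
        n_runs=config.n_runs, train_fraction=config.train_fraction, seed=config.seed
    )
    per_run = np.empty((config.n_runs, config.k - 1))
    memb = np.empty((len(x), config.n_runs), dtype=int)
    for r in range(config.n_runs):
        if config.full_data:
            train = np.arange(len(x))
        else:
            train, _ = draw_subsample(len(x), rconf, r, stage=STAGE_CLUSTER)
        _, labels = kmeans_1d(x[train], config.k, n_init=config.n_init)
        thr = extract_thresholds(x[train], labels)
        per_run[r] = thr
        memb[:, r] = assign_levels(x, thr, k=config.k)
    thresholds = aggregate_thresholds(per_run)
    memberships = pd.DataFrame(
        memb, index=scores.animal_ids, columns=[f"run_{r}" for r in range(config.n_runs)]
    )
    return thresholds, memberships


def assign_severity(
    scores: CompositeScores,
    thresholds: ThresholdSet,
    memberships: pd.DataFrame | None = None,
) -> SeverityAssignment:
    """Final per-animal severity from the aggregated mean thresholds.

    When per-run memberships are available, each animal's stability is the
    fraction of runs agreeing with its modal per-run level (reported
    alongside the threshold-based level).
    """
    levels = assign_levels(scores.scores.to_numpy(dtype=float), thresholds)
    frame = scores.frame[["group", "model", "score"]].copy()
    frame["severity_level"] = levels
    if memberships is not None:
        m = memberships.to_numpy()
        modal = np.array([np.bincount(row).argmax() for row in m])
        frame["stability"] = (m == modal[:, None]).mean(axis=1)
    else:
        frame["stability"] = np.nan
    return SeverityAssignment(frame=frame, memberships=memberships)


def group_distribution(
    memberships: pd.DataFrame,
    models: pd.Series,
    groups: pd.Series,
    k: int,
) -> pd.DataFrame:
    """Mean and SD across runs of per-(model, group) level percentages.

    For each run and each (model, group) cell, the percentage of that
    cell's animals at each severity level is computed (summing to 100 per
    cell per run); the table reports the across-run mean and SD (n-1).
    """
    models = models.loc[memberships.index]
    groups = groups.loc[memberships.index]
    rows = []
    for (mod, grp), idx in memberships.groupby([models, groups]).groups.items():
        sub = memberships.loc[idx].to_numpy()
        n = sub.shape[0]
        for level in range(1, k + 1):
            pct = (sub == level).sum(axis=0) / n * 100.0
            rows.append(
                {
                    "model": mod,
                    "group": grp,
                    "severity_level": level,
                    "mean_pct": pct.mean(),
                    "sd_pct": pct.std(ddof=1) if pct.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
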
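"""Resampling-based parameter stability selection via PCA loadings.

The informative parameters of a pooled behavioral battery are found by
running a PCA on repeated random 80% subsamples of the animals, picking in
each run the group-separating component (largest one-way between-group
F-statistic among the leading components, or a user-fixed index), and
tallying how often each parameter ranks among the ``top_k`` absolute
loadings of that component. Parameters that stay in the top ranks across
resampling are robust to sampling variation; the ``n_selected`` most
frequent ones form the selected set.

Also provides the exploratory Spearman correlation matrix (pairwise
complete, tie-corrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import STAGE_SELECT, stage_rng
from .io import ParameterTable
from .preprocess import ScaledMatrix


@dataclass
class ResampleConfig:
    n_runs: int = 100
    train_fraction: float = 0.80
    seed: int = 0
    stratify_by_group: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class SelectionConfig:
    top_k: int = 4
    component: int | str = "auto"  # "auto" or fixed 1-based index
    n_selected: int = 4
    n_candidate_components: int = 3  # components examined in auto mode

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if isinstance(self.component, int) and self.component < 1:
            raise ValueError("fixed component index is 1-based and must be >= 1")


@dataclass
class PCARunRecord:
    run_index: int
    explained_variance_fraction: np.ndarray
    loadings: pd.DataFrame  # parameter x component, columns "PC1", "PC2", ...
    chosen_component: int  # 1-based
    top_parameters: list[str]
    component_f_stats: np.ndarray | None = None
    unstable_component_choice: bool = False
    train_index: np.ndarray | None = None
    test_index: np.ndarray | None = None


@dataclass
class StabilitySelectionResult:
    frequency: pd.Series  # parameter -> runs appearing in top_parameters
    mean_explained_variance: pd.DataFrame  # component x [mean, sd]
    selected: list[str]
    runs: list[PCARunRecord] = field(default_factory=list)
    mean_abs_loading: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "frequency": {p: int(v) for p, v in self.frequency.items()},
            "selected": list(self.selected),
            "mean_abs_loading": (
                None
                if self.mean_abs_loading is None
                else {p: float(v) for p, v in self.mean_abs_loading.items()}
            ),
            "explained_variance": {
                comp: {"mean": float(row["mean"]), "sd": float(row["sd"])}
                for comp, row in self.mean_explained_variance.iterrows()
            },
            "runs": [
                {
                    "run_index": r.run_index,
                    "chosen_component": r.chosen_component,
                    "top_parameters": r.top_parameters,
                    "unstable_component_choice": r.unstable_component_choice,
                }
                for r in self.runs
            ],
        }


def draw_subsample(
    n_animals: int,
    config: ResampleConfig,
    run_index: int,
    groups: pd.Series | None = None,
    stage: int = STAGE_SELECT,
) -> tuple[np.ndarray, np.ndarray]:
    """Split animal indices into an 80/20 training/test partition.

    The draw is sampled without replacement and is fully determined by
    ``(config.seed, run_index)``. With stratification on, group proportions
    are preserved within rounding.
    """
    if n_animals < 5:
        raise ValueError("need at least 5 animals to subsample")
    rng = stage_rng(config.seed, stage, run_index)
    if config.stratify_by_group:
        if groups is None:
            raise ValueError("stratified subsampling requires group labels")
        codes = np.asarray(groups)
        train: list[np.ndarray] = []
        for g in pd.unique(codes):
            idx = np.flatnonzero(codes == g)
            n_tr = int(np.floor(config.train_fraction * idx.size + 0.5))
            train.append(rng.permutation(idx)[:n_tr])
        train_idx = np.sort(np.concatenate(train))
    else:
        n_tr = int(np.floor(config.train_fraction * n_animals + 0.5))
        train_idx = np.sort(rng.permutation(n_animals)[:n_tr])
    test_idx = np.setdiff1d(np.arange(n_animals), train_idx)
    return train_idx, test_idx


def pca_decompose(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the covariance matrix of the rows.

    Returns ``(explained_variance_fraction, loadings)`` with components in
    decreasing-eigenvalue order and each loading column's sign fixed so its
    largest-magnitude entry is positive (removes eigen-solver sign
    ambiguity). Eigenvalues below numerical zero (rank deficiency) are
    clipped to 0 and reported, not fatal.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >=3 animals and >=2 parameters")
    if np.isnan(X).any():
        raise ValueError("missing cells present; impute before PCA")
    cov = np.cov(X, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    loadings = eigvec[:, order]
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    total = eigval.sum()
    evr = eigval / total if total > 0 else eigval
    return evr, loadings


def choose_component(
    component_scores: np.ndarray,
    group_labels: np.ndarray | None,
    config: SelectionConfig,
) -> tuple[int, np.ndarray | None, bool]:
    """Pick the group-separating component.

    Fixed mode returns the configured 1-based index unconditionally. Auto
    mode computes a one-way between-group F-statistic for each of the first
    ``n_candidate_components`` component score vectors and returns the
    maximizer; the choice is flagged unstable when even the best F is below
    the 5% critical value (no real group separation to latch onto).
    """
    if isinstance(config.component, int):
        return config.component, None, False
    if group_labels is None:
        raise ValueError(
            "component='auto' requires group labels; use a fixed component index otherwise"
        )
    scores = np.asarray(component_scores, dtype=float)
    labels = np.asarray(group_labels)
    n_cand = min(config.n_candidate_components, scores.shape[1])
    uniq = pd.unique(labels)
    fstats = np.full(n_cand, np.nan)
    for j in range(n_cand):
        samples = [scores[labels == g, j] for g in uniq]
        if len(samples) < 2 or any(len(s) < 2 for s in samples):
            continue
        fstats[j] = stats.f_oneway(*samples).statistic
    if np.all(np.isnan(fstats)):
        raise ValueError("cannot compute between-group F-statistics for any component")
    best = int(np.nanargmax(fstats))
    dfn = len(uniq) - 1
    dfd = scores.shape[0] - len(uniq)
    crit = stats.f.ppf(0.95, dfn, dfd) if dfd > 0 else np.inf
    unstable = bool(np.nanmax(fstats) < crit)
    return best + 1, fstats, unstable


def run_stability_selection(
    scaled: ScaledMatrix,
    rconf: ResampleConfig | None = None,
    sconf: SelectionConfig | None = None,
    keep_runs: bool = True,
) -> StabilitySelectionResult:
    """Tally top-``top_k`` loading membership over resampled PCA runs.

    Per run: draw the training subsample, eigendecompose its covariance,
    choose the group-separating component, rank parameters by absolute
    loading on it, and record the ``top_k``. Frequencies are tallied over
    all runs; the ``n_selected`` most frequent parameters are selected, ties
    broken by higher mean absolute loading across runs, then input column
    order.
    """
    rconf = rconf or ResampleConfig()
    sconf = sconf or SelectionConfig()
    params = scaled.parameters
    if sconf.top_k > len(params):
        raise ValueError("top_k exceeds the number of parameters")
    X = scaled.values.to_numpy(dtype=float)
    labels = scaled.groups.to_numpy()
    freq = pd.Series(0, index=params, dtype=int)
    abs_loading_sum = pd.Series(0.0, index=params)
    evr_runs = []
    runs: list[PCARunRecord] = []
    for r in range(rconf.n_runs):
        train_idx, test_idx = draw_subsample(
            len(X), rconf, r, groups=scaled.groups if rconf.stratify_by_group else None
        )
        Xtr = X[train_idx]
        evr, loadings = pca_decompose(Xtr)
        comp_scores = (Xtr - Xtr.mean(axis=0)) @ loadings
        chosen, fstats, unstable = choose_component(comp_scores, labels[train_idx], sconf)
        if chosen > loadings.shape[1]:
            raise ValueError(f"fixed component {chosen} exceeds available components")
        absload = np.abs(loadings[:, chosen - 1])
        order = np.argsort(-absload, kind="stable")
        top = [params[i] for i in order[: sconf.top_k]]
        freq[top] += 1
        abs_loading_sum += absload
        evr_runs.append(evr)
        if keep_runs:
            runs.append(
                PCARunRecord(
                    run_index=r,
                    explained_variance_fraction=evr,
                    loadings=pd.DataFrame(
                        loadings,
                        index=params,
                        columns=[f"PC{j + 1}" for j in range(loadings.shape[1])],
                    ),
                    chosen_component=chosen,
                    top_parameters=top,
                    component_f_stats=fstats,
                    unstable_component_choice=unstable,
                    train_index=train_idx,
                    test_index=test_idx,
                )
            )
    evr_arr = np.vstack(evr_runs)
    mean_evr = pd.DataFrame(
        {
            "mean": evr_arr.mean(axis=0),
            "sd": evr_arr.std(axis=0, ddof=1) if len(evr_runs) > 1 else 0.0,
        },
        index=[f"PC{j + 1}" for j in range(evr_arr.shape[1])],
    )
    mean_abs = abs_loading_sum / rconf.n_runs
    col_order = {p: i for i, p in enumerate(params)}
    ranked = sorted(params, key=lambda p: (-freq[p], -mean_abs[p], col_order[p]))
    selected = ranked[: sconf.n_selected]
    return StabilitySelectionResult(
        frequency=freq,
        mean_explained_variance=mean_evr,
        selected=selected,
        runs=runs,
        mean_abs_loading=mean_abs,
    )


def spearman_correlation_matrix(table: ParameterTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete, tie-corrected Spearman correlations.

    Pairs with fewer than 3 complete observations get a missing entry and a
    warning.
    """
    values = table.values if isinstance(table, ParameterTable) else table
    n_complete = (~values.isna()).astype(int).T @ (~values.isna()).astype(int)
    corr = values.corr(method="spearman", min_periods=3)
    sparse_pairs = [
        (a, b)
        for i, a in enumerate(values.columns)
        for b in values.columns[i + 1 :]
        if n_complete.loc[a, b] < 3
    ]
    if sparse_pairs:
        warnings.warn(
            f"parameter pairs with <3 complete observations left missing: {sparse_pairs}",
            stacklevel=2,
        )
    return corr
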
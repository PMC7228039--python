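"""Scale transforms: Box-Cox normalization, z-scaling, mean imputation.

Pipeline order is fixed and configuration-visible: Box-Cox on the raw
(offset-shifted) values, then centering/scaling to zero mean and unit SD
(n-1 denominator), then column-mean imputation of remaining missing cells
(which on the scaled scale is imputation with 0). Every fitted quantity
(lambda, offset, mean, SD) is kept in a :class:`PreprocessManifest` so the
identical transform can be replayed on new animals without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import ParameterTable

_LAMBDA_BOUNDS = (-5.0, 5.0)
_LAMBDA_TOL = 1e-4


def boxcox_transform(
    column, lmbda: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform a single parameter column.

    If the column minimum is <= 0, an offset of ``1 - min`` is added first so
    all values are strictly positive. When ``lmbda`` is None it is fitted by
    profile maximum likelihood: a coarse grid scan over [-5, 5] followed by
    bounded scalar refinement (tolerance 1e-4). The transform is
    ``(x**lam - 1) / lam`` for lam != 0 and ``log(x)`` for lam == 0.

    Returns ``(transformed, lambda, offset)``; missing cells stay missing.
    """
    x = np.asarray(column, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 3:
        raise ValueError("Box-Cox needs at least 3 non-missing values")
    if np.ptp(obs) == 0:
        raise ValueError("zero variance, cannot transform")
    mn = obs.min()
    offset = 1.0 - mn if mn <= 0 else 0.0
    shifted = obs + offset
    if lmbda is None:
        grid = np.linspace(*_LAMBDA_BOUNDS, 101)
        llf = np.array([stats.boxcox_llf(l, shifted) for l in grid])
        i = int(np.argmax(llf))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            lambda l: -stats.boxcox_llf(l, shifted),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": _LAMBDA_TOL},
        )
        lmbda = float(res.x)
    out = np.full_like(x, np.nan)
    out[~np.isnan(x)] = special.boxcox(shifted, lmbda)
    return out, float(lmbda), float(offset)


def zscale(column, name: str | None = None) -> np.ndarray:
    """Center to mean 0 and scale to SD 1 (n-1 denominator).

    Computed over non-missing cells only; missing cells stay missing.
    """
    x = np.asarray(column, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValueError(f"parameter {name or '<column>'}: need >=2 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError(f"parameter {name or '<column>'}: zero standard deviation")
    return (x - obs.mean()) / sd


@dataclass
class PreprocessManifest:
    """Frozen per-parameter transform constants.

    Holds, for each parameter: the Box-Cox lambda and offset (NaN offset/
    lambda when the transform is disabled), and the post-transform mean and
    SD used for scaling. Replaying the manifest reproduces any score
    bit-for-bit on new animals.
    """

    parameters: list[str]
    boxcox: bool
    impute: str
    lambdas: dict[str, float] = field(default_factory=dict)
    offsets: dict[str, float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pipeline": ["boxcox" if self.boxcox else None, "zscale",
                         self.impute if self.impute != "none" else None],
            "boxcox": self.boxcox,
            "impute": self.impute,
            "parameters": {
                p: {
                    "lambda": self.lambdas.get(p),
                    "offset": self.offsets.get(p),
                    "mean": self.means[p],
                    "sd": self.sds[p],
                }
                for p in self.parameters
            },
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "PreprocessManifest":
        params = list(data["parameters"])
        m = cls(parameters=params, boxcox=bool(data["boxcox"]), impute=data["impute"])
        for p, blk in data["parameters"].items():
            if blk.get("lambda") is not None:
                m.lambdas[p] = float(blk["lambda"])
                m.offsets[p] = float(blk["offset"])
            m.means[p] = float(blk["mean"])
            m.sds[p] = float(blk["sd"])
        return m

    @classmethod
    def read(cls, path) -> "PreprocessManifest":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ScaledMatrix:
    """Dimensionless z-value matrix with its fitting provenance.

    ``values`` has the same shape and labels as the input parameter matrix;
    ``imputation_mask`` flags cells that were filled in (True = imputed).
    """

    values: pd.DataFrame
    groups: pd.Series
    models: pd.Series
    manifest: PreprocessManifest
    imputation_mask: pd.DataFrame

    @property
    def column_means(self) -> pd.Series:
        return pd.Series(self.manifest.means)[self.values.columns]

    @property
    def column_sds(self) -> pd.Series:
        return pd.Series(self.manifest.sds)[self.values.columns]

    @property
    def boxcox_lambdas(self) -> pd.Series | None:
        if not self.manifest.boxcox:
            return None
        return pd.Series(self.manifest.lambdas)[self.values.columns]

    @property
    def animal_ids(self) -> pd.Index:
        return self.values.index

    @property
    def parameters(self) -> list[str]:
        return list(self.values.columns)


def fit_preprocess(
    table: ParameterTable, boxcox: bool = True, impute: str = "column_mean"
) -> ScaledMatrix:
    """Fit and apply the preprocessing pipeline to a parameter table.

    Parameters
    ----------
    boxcox : apply the Box-Cox step (default on); off reproduces a plain
        z-score pipeline.
    impute : ``"column_mean"`` (default) fills missing cells with the scaled
        column mean (0); ``"none"`` leaves them missing.
    """
    if impute not in ("column_mean", "none"):
        raise ValueError(f"unknown imputation strategy {impute!r}")
    manifest = PreprocessManifest(parameters=table.parameters, boxcox=boxcox, impute=impute)
    scaled = pd.DataFrame(index=table.animal_ids)
    for p in table.parameters:
        col = table.values[p].to_numpy(dtype=float)
        if boxcox:
            col, lam, off = boxcox_transform(col)
            manifest.lambdas[p] = lam
            manifest.offsets[p] = off
        obs = col[~np.isnan(col)]
        manifest.means[p] = float(obs.mean())
        manifest.sds[p] = float(obs.std(ddof=1))
        scaled[p] = zscale(col, name=p)
    sm = ScaledMatrix(
        values=scaled,
        groups=table.groups,
        models=table.models,
        manifest=manifest,
        imputation_mask=pd.DataFrame(False, index=scaled.index, columns=scaled.columns),
    )
    if impute == "column_mean":
        sm = impute_missing(sm)
    return sm


def impute_missing(sm: ScaledMatrix, strategy: str = "column_mean") -> ScaledMatrix:
    """Fill missing cells with the scaled column mean (0) and record them."""
    if strategy != "column_mean":
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    if (sm.values.notna().sum(axis=0) < 1).any():
        raise ValueError("every column needs at least one non-missing value")
    mask = sm.values.isna()
    return ScaledMatrix(
        values=sm.values.fillna(0.0),
        groups=sm.groups,
        models=sm.models,
        manifest=sm.manifest,
        imputation_mask=sm.imputation_mask | mask,
    )


def apply_preprocess(table: ParameterTable, manifest: PreprocessManifest) -> ScaledMatrix:
    """Replay a frozen manifest on new animals — no refitting anywhere."""
    missing_cols = [p for p in manifest.parameters if p not in table.parameters]
    if missing_cols:
        raise ValueError(f"input table lacks required parameter column(s): {missing_cols}")
    scaled = pd.DataFrame(index=table.animal_ids)
    for p in manifest.parameters:
        col = table.values[p].to_numpy(dtype=float)
        if manifest.boxcox:
            obs = ~np.isnan(col)
            out = np.full_like(col, np.nan)
            out[obs] = special.boxcox(col[obs] + manifest.offsets[p], manifest.lambdas[p])
            col = out
        scaled[p] = (col - manifest.means[p]) / manifest.sds[p]
    sm = ScaledMatrix(
        values=scaled,
        groups=table.groups,
        models=table.models,
        manifest=manifest,
        imputation_mask=pd.DataFrame(False, index=scaled.index, columns=scaled.columns),
    )
    if manifest.impute == "column_mean":
        sm = impute_missing(sm)
    return sm
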
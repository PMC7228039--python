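"""Synthetic behavioral-battery data with planted, recoverable structure.

Generates animals x parameters tables with the statistical features the
severity pipeline assumes: several models x treatment groups, inter-
parameter rank correlation (Gaussian copula on the latent scale),
standardized group effects (Cohen's d) on a planted informative subset,
and per-parameter missingness completely at random. Every draw returns a
ground-truth record (informative set, per-animal labels/strata, effect
table) so tests can score recovery against planted truth.

Also provides the paper-shaped reference design used as the tutorial
dataset: 3 epilepsy-style models x 3 groups, 17 raw parameters of which 2
are mostly missing (exercising the missingness filter), 2 are flagged for
manual exclusion, and 4 of the remaining 13 carry treated-group effects in
the post-SE-like models only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._rng import STAGE_SIMULATE, stage_rng
from .io import ParameterSpec, ParameterTable


@dataclass
class ParameterDef:
    """Marginal definition of one simulated parameter (raw units)."""

    name: str
    direction: int = 1
    mean: float = 0.0
    sd: float = 1.0
    missing: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be > 0")
        if not 0 <= self.missing <= 0.5:
            raise ValueError(f"{self.name}: missingness must be in [0, 0.5]")


@dataclass
class SimulationDesign:
    """Full specification of a synthetic battery draw.

    ``models`` maps model name -> {group name -> animal count}; ``effects``
    maps (parameter, model, group) -> standardized latent mean shift
    (Cohen's d, signed: a negative shift lowers the raw value);
    ``correlation`` lists (param_a, param_b, target Spearman rho) pairs,
    converted to latent Pearson correlations via the Gaussian-copula
    relation r = 2 sin(pi * rho / 6).
    """

    models: dict[str, dict[str, int]]
    parameters: list[ParameterDef]
    effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    correlation: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in design")
        for model, grps in self.models.items():
            for grp, n in grps.items():
                if n < 1:
                    raise ValueError(f"{model}/{grp}: count must be >= 1")
        for (p, m, g) in self.effects:
            if p not in names:
                raise ValueError(f"effect on unknown parameter {p!r}")

    @property
    def parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def informative_parameters(self) -> list[str]:
        """Parameters carrying any nonzero planted effect, in design order."""
        hit = {p for (p, _, _), d in self.effects.items() if d != 0}
        return [p for p in self.parameter_names if p in hit]

    def latent_correlation(self) -> np.ndarray:
        """Latent Pearson correlation matrix implied by the Spearman targets."""
        names = self.parameter_names
        idx = {n: i for i, n in enumerate(names)}
        R = np.eye(len(names))
        for a, b, rho in self.correlation:
            r = 2.0 * np.sin(np.pi * rho / 6.0)
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
        return R


def simulate_battery(
    design: SimulationDesign, seed: int | None = None
) -> tuple[ParameterTable, dict]:
    """Draw one battery table plus its ground-truth record.

    Latent per-animal vectors are multivariate normal with the design's
    copula correlation; group/model effect shifts are applied on the latent
    (standardized) scale; raw values are ``mean + sd * latent``; missing
    cells are injected MCAR at the per-parameter fractions.
    """
    seed = design.seed if seed is None else seed
    R = design.latent_correlation()
    eigval = np.linalg.eigvalsh(R)
    if eigval.min() <= 0:
        raise ValueError(
            f"correlation matrix not positive-definite (min eigenvalue {eigval.min():.3g})"
        )
    L = np.linalg.cholesky(R)
    rng = stage_rng(seed, STAGE_SIMULATE)
    names = design.parameter_names
    ids, models_col, groups_col, rows = [], [], [], []
    for model in design.models:
        for group, n in design.models[model].items():
            shift = np.array([design.effects.get((p, model, group), 0.0) for p in names])
            Z = rng.standard_normal((n, len(names))) @ L.T + shift
            rows.append(Z)
            ids += [f"{model}-{group}-{i + 1:03d}" for i in range(n)]
            models_col += [model] * n
            groups_col += [group] * n
    Z = np.vstack(rows)
    X = np.empty_like(Z)
    for j, p in enumerate(design.parameters):
        X[:, j] = p.mean + p.sd * Z[:, j]
    for j, p in enumerate(design.parameters):
        if p.missing > 0:
            X[rng.random(len(X)) < p.missing, j] = np.nan
    values = pd.DataFrame(X, index=pd.Index(ids, name="animal_id"), columns=names)
    table = ParameterTable(
        values=values,
        groups=pd.Series(groups_col, index=values.index, name="group"),
        models=pd.Series(models_col, index=values.index, name="model"),
    )
    truth = {
        "informative": design.informative_parameters(),
        "effects": {f"{p}|{m}|{g}": d for (p, m, g), d in design.effects.items()},
        "seed": seed,
        "n_animals": len(values),
    }
    return table, truth


# ---------------------------------------------------------------------------
# canned designs


def reference_design(seed: int = 0) -> SimulationDesign:
    """Paper-shaped tutorial design: 3 models x 3 groups, 204 animals.

    17 raw parameters: 13 battery parameters measured everywhere (small
    missingness), 2 measured only in a minority of animals (>20% missing,
    removed by the filter), and 2 disease-phenotype-style parameters meant
    for manual exclusion. Treated groups of the two post-SE-like models are
    shifted d = -1.5 on the four informative parameters (burrowing,
    open-field distance, social interaction, saccharin preference); the
    kindling-like model carries no planted effect.
    """
    p = ParameterDef
    parameters = [
        p("burrowing", 1, 2500, 600, 0.05),          # g gravel displaced
        p("of_distance", 1, 3200, 800, 0.02),        # cm moved in open field
        p("of_rearing", 1, 28, 8, 0.02),             # rearing postures
        p("of_immobility", -1, 95, 30, 0.02),        # s immobile
        p("of_center_time", 1, 40, 14, 0.05),        # s in center
        p("social_interaction", 1, 55, 16, 0.05),    # s active interaction
        p("saccharin_pref", 1, 85, 12, 0.08),        # % preference
        p("nest_building", 1, 4.2, 1.1, 0.10),       # complexity score
        p("bwb_latency", -1, 35, 15, 0.10),          # s to enter black box
        p("bwb_entries", 1, 9, 3, 0.10),             # white-box entries
        p("bwb_time_white", 1, 70, 25, 0.10),        # s in white box
        p("bdnf", 1, 18, 5, 0.15),                   # ng/mL serum
        p("corticosterone", -1, 120, 40, 0.15),      # fecal metabolites ng/g
        # removed by the >20% missingness filter:
        p("upet_uptake", -1, 1.4, 0.3, 0.45),        # tracer uptake ratio
        p("telemetry_hr", -1, 360, 40, 0.40),        # beats/min
        # manually excluded (disease-phenotype / confounded parameters):
        p("bodyweight_change", -1, 6.0, 4.0, 0.05),  # % gain
        p("seizure_frequency", -1, 5.0, 6.0, 0.10),  # seizures/week
    ]
    informative = ["burrowing", "of_distance", "social_interaction", "saccharin_pref"]
    effects: dict[tuple[str, str, str], float] = {}
    for model in ("chemical_post_SE", "electrical_post_SE"):
        for param in informative:
            effects[(param, model, "treated")] = -1.5
        effects[("seizure_frequency", model, "treated")] = 2.0
        effects[("bodyweight_change", model, "treated")] = 1.0
    correlation = [
        ("burrowing", "social_interaction", 0.50),
        ("of_distance", "of_rearing", 0.65),
        ("of_distance", "of_immobility", -0.54),
        ("of_immobility", "of_rearing", -0.53),
    ]
    counts = {"naive": 20, "sham": 22, "treated": 26}
    models = {m: dict(counts) for m in ("kindling", "chemical_post_SE", "electrical_post_SE")}
    return SimulationDesign(
        models=models, parameters=parameters, effects=effects,
        correlation=correlation, seed=seed,
    )


def reference_specs() -> list[ParameterSpec]:
    """Directionality + exclusion specs matching :func:`reference_design`."""
    design = reference_design()
    manual_exclusions = {
        "bodyweight_change": "confounded: seizure activity drives hyperphagia and weight gain",
        "seizure_frequency": "disease phenotype, present only in epileptic animals",
    }
    return [
        ParameterSpec(
            name=p.name,
            direction=p.direction,
            excluded=p.name in manual_exclusions,
            note=manual_exclusions.get(p.name, ""),
        )
        for p in design.parameters
    ]


def stability_battery_design(seed: int = 0, d: float = 1.5, n_per_group: int = 100) -> SimulationDesign:
    """Planted-truth harness for stability selection.

    13 uncorrelated parameters, 200 animals in two groups, with a
    standardized shift of magnitude ``d`` on 4 planted informative
    parameters in the treated group.
    """
    design = reference_design(seed)
    parameters = [
        ParameterDef(p.name, p.direction, p.mean, p.sd, 0.0)
        for p in design.parameters[:13]
    ]
    informative = ["burrowing", "of_distance", "social_interaction", "saccharin_pref"]
    effects = {(param, "battery", "treated"): -d for param in informative}
    return SimulationDesign(
        models={"battery": {"control": n_per_group, "treated": n_per_group}},
        parameters=parameters,
        effects=effects,
        seed=seed,
    )


def simulate_strata_scores(
    seed: int = 0,
    means: tuple[float, ...] = (-4.0, 0.0, 2.0),
    sd: float = 0.8,
    n_per_stratum: int = 60,
):
    """Composite-scale scores from planted severity strata.

    Stratum levels follow the low-is-worse convention: the lowest-mean
    stratum is the worst level (k), the highest-mean stratum level 1.
    Returns ``(CompositeScores, planted_levels)``.
    """
    from .score import CompositeScores

    rng = stage_rng(seed, STAGE_SIMULATE)
    k = len(means)
    scores, levels, ids = [], [], []
    for s, mu in enumerate(sorted(means)):
        level = k - s
        scores.append(rng.normal(mu, sd, n_per_stratum))
        levels += [level] * n_per_stratum
        ids += [f"stratum{level}-{i + 1:03d}" for i in range(n_per_stratum)]
    frame = pd.DataFrame(
        {
            "group": [f"stratum{lv}" for lv in levels],
            "model": "synthetic",
            "score": np.concatenate(scores),
            "n_contributing": k,
            "unreliable": False,
        },
        index=pd.Index(ids, name="animal_id"),
    )
    return (
        CompositeScores(frame=frame, parameters_used=[]),
        pd.Series(levels, index=frame.index, name="planted_level"),
    )


def simulate_reference_fixture(seed: int = 0, path=None) -> tuple[ParameterTable, dict]:
    """Draw the reference tutorial fixture; optionally write it as CSV.

    Regenerating with the same seed yields a byte-identical file.
    """
    table, truth = simulate_battery(reference_design(seed))
    if path is not None:
        table.write_csv(path, float_format="%.10g")
    return table, truth


# ---------------------------------------------------------------------------
# design file round-trip


def design_from_yaml(path) -> SimulationDesign:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    parameters = [
        ParameterDef(
            name=blk["name"],
            direction=int(blk.get("direction", 1)),
            mean=float(blk.get("mean", 0.0)),
            sd=float(blk.get("sd", 1.0)),
            missing=float(blk.get("missing", 0.0)),
        )
        for blk in data["parameters"]
    ]
    effects = {
        (e["parameter"], e["model"], e["group"]): float(e["d"])
        for e in data.get("effects", [])
    }
    correlation = [
        (c["a"], c["b"], float(c["rho"])) for c in data.get("correlation", [])
    ]
    return SimulationDesign(
        models={m: {g: int(n) for g, n in grps.items()} for m, grps in data["models"].items()},
        parameters=parameters,
        effects=effects,
        correlation=correlation,
        seed=int(data.get("seed", 0)),
    )


def design_to_yaml(design: SimulationDesign, path) -> None:
    data = {
        "models": {m: dict(g) for m, g in design.models.items()},
        "parameters": [
            {"name": p.name, "direction": p.direction, "mean": p.mean, "sd": p.sd,
             "missing": p.missing}
            for p in design.parameters
        ],
        "effects": [
            {"parameter": p, "model": m, "group": g, "d": d}
            for (p, m, g), d in design.effects.items()
        ],
        "correlation": [{"a": a, "b": b, "rho": r} for a, b, r in design.correlation],
        "seed": design.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
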
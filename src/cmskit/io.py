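"""Reading, validating and filtering the animal-parameter table.

The central container is :class:`ParameterTable`: one row per animal, a
treatment-group label and a model label per row, and an arbitrary number of
numeric behavioral/biochemical parameter columns with missing cells allowed.
Parameter-level metadata (severity directionality, manual exclusion) lives in
:class:`ParameterSpec` entries, typically loaded from a YAML file.

Filtering follows the candidate-parameter funnel used when pooling
multi-study batteries: parameters with more than ``max_missing_fraction``
missing cells (strictly greater; exactly the threshold survives) are dropped
first, then user-declared exclusions are applied. Animals are never removed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: cell contents treated as missing in parameter columns
MISSING_TOKENS = ("", "NA", "NaN", "nan", "na", "N/A")


class ValidationError(ValueError):
    """Raised when an input table or spec violates the data contract."""


@dataclass
class ParameterSpec:
    """Per-parameter metadata.

    direction: +1 means a LOW raw value indicates HIGHER severity (the
    low-is-worse convention used by the composite score); -1 the reverse.
    excluded: manual, domain-based exclusion flag — purely user-declared,
    the tool makes no domain judgement of its own.
    """

    name: str
    direction: int
    excluded: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValidationError(
                f"parameter {self.name!r}: direction must be +1 or -1, got {self.direction!r}"
            )


@dataclass
class FilterReport:
    """Accounting of one filtering pass over the parameter columns."""

    n_input_parameters: int
    missingness_per_parameter: dict[str, float]
    removed_by_missingness: list[str] = field(default_factory=list)
    removed_by_exclusion: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_parameters": self.n_input_parameters,
            "missingness_per_parameter": self.missingness_per_parameter,
            "removed_by_missingness": list(self.removed_by_missingness),
            "removed_by_exclusion": list(self.removed_by_exclusion),
            "retained": list(self.retained),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ParameterTable:
    """Animals x parameters matrix with group/model labels.

    ``values`` is indexed by animal id; ``groups`` and ``models`` are
    aligned Series. Labels are free strings — no fixed vocabulary is
    enforced, so the container works for any model/group design.
    """

    values: pd.DataFrame
    groups: pd.Series
    models: pd.Series
    parse_report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.values.index
        if ids.duplicated().any():
            dups = sorted(set(ids[ids.duplicated()].astype(str)))
            raise ValidationError(f"duplicate animal_id values: {dups}")
        if len(ids) < 2:
            raise ValidationError("need at least 2 animals")
        if self.values.shape[1] < 1:
            raise ValidationError("need at least 1 parameter column")
        for name, lab in (("group", self.groups), ("model", self.models)):
            if lab.isna().any() or (lab.astype(str).str.strip() == "").any():
                bad = list(ids[lab.isna() | (lab.astype(str).str.strip() == "")].astype(str))
                raise ValidationError(f"animals with missing {name} label: {bad}")

    @property
    def animal_ids(self) -> pd.Index:
        return self.values.index

    @property
    def parameters(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_animals(self) -> int:
        return len(self.values)

    def missing_fraction(self) -> pd.Series:
        """Fraction of missing cells per parameter, over all animals pooled."""
        return self.values.isna().mean(axis=0)

    def with_values(self, values: pd.DataFrame) -> "ParameterTable":
        return ParameterTable(values, self.groups, self.models, dict(self.parse_report))

    def to_frame(self, id_column="animal_id", group_column="group", model_column="model") -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, model_column, self.models)
        out.insert(0, group_column, self.groups)
        out.index.name = id_column
        return out.reset_index()

    def write_csv(self, path, **kwargs) -> None:
        self.to_frame().to_csv(path, index=False, **kwargs)


def read_parameter_table(
    path,
    id_column: str = "animal_id",
    group_column: str = "group",
    model_column: str = "model",
    delimiter: str = ",",
) -> ParameterTable:
    """Read and validate a delimited animal-parameter table.

    Non-numeric cells in parameter columns are coerced to missing and the
    per-parameter coercion counts are kept in ``parse_report`` (cells that
    are standard missing tokens are not counted as coercions).
    """
    raw = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, skipinitialspace=True
    )
    for col in (id_column, group_column, model_column):
        if col not in raw.columns:
            raise ValidationError(f"mandatory column {col!r} not found in {path}")
    raw = raw.set_index(id_column)
    raw.index = raw.index.astype(str).str.strip()
    groups = raw[group_column].replace(list(MISSING_TOKENS), np.nan)
    models = raw[model_column].replace(list(MISSING_TOKENS), np.nan)
    param_cols = [c for c in raw.columns if c not in (group_column, model_column)]

    values = pd.DataFrame(index=raw.index)
    parse_report: dict[str, int] = {}
    for col in param_cols:
        cells = raw[col].astype(str).str.strip()
        token_missing = cells.isin(MISSING_TOKENS)
        numeric = pd.to_numeric(cells.mask(token_missing), errors="coerce")
        n_coerced = int((numeric.isna() & ~token_missing).sum())
        if n_coerced:
            parse_report[col] = n_coerced
            warnings.warn(
                f"parameter {col!r}: {n_coerced} non-numeric cell(s) treated as missing",
                stacklevel=2,
            )
        values[col] = numeric.astype(float)
    return ParameterTable(values, groups, models, parse_report)


def filter_by_missingness(
    table: ParameterTable, max_missing_fraction: float = 0.20
) -> tuple[ParameterTable, FilterReport]:
    """Drop parameters whose missing fraction exceeds the threshold.

    Removal requires the fraction to be STRICTLY greater than
    ``max_missing_fraction``; a parameter missing exactly the threshold
    fraction is retained. Missingness is computed over all animals in the
    pooled table, never per model or group.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    frac = table.missing_fraction()
    removed = [p for p in table.parameters if frac[p] > max_missing_fraction]
    retained = [p for p in table.parameters if p not in removed]
    if not retained:
        raise ValidationError(
            "all parameters exceed the missingness threshold "
            f"({max_missing_fraction:.0%}); review the threshold or the input data"
        )
    report = FilterReport(
        n_input_parameters=len(table.parameters),
        missingness_per_parameter={p: float(frac[p]) for p in table.parameters},
        removed_by_missingness=removed,
        retained=retained,
    )
    return table.with_values(table.values[retained]), report


def apply_exclusions(
    table: ParameterTable, specs: list[ParameterSpec]
) -> tuple[ParameterTable, FilterReport]:
    """Drop manually excluded parameters.

    An exclusion naming an absent column (e.g. one already removed by the
    missingness filter) is a warning, not an error.
    """
    excluded_names = [s.name for s in specs if s.excluded]
    removed, absent = [], []
    for name in excluded_names:
        (removed if name in table.parameters else absent).append(name)
    for name in absent:
        warnings.warn(f"excluded parameter {name!r} not present; ignoring", stacklevel=2)
    retained = [p for p in table.parameters if p not in removed]
    if not retained:
        raise ValidationError("exclusions removed every parameter")
    frac = table.missing_fraction()
    report = FilterReport(
        n_input_parameters=len(table.parameters),
        missingness_per_parameter={p: float(frac[p]) for p in table.parameters},
        removed_by_exclusion=removed,
        retained=retained,
    )
    return table.with_values(table.values[retained]), report


def filter_parameters(
    table: ParameterTable,
    specs: list[ParameterSpec] | None = None,
    max_missing_fraction: float = 0.20,
) -> tuple[ParameterTable, FilterReport]:
    """Full funnel: missingness filter, then manual exclusions.

    The combined report partitions the original parameter set into
    retained / removed-by-missingness / removed-by-exclusion.
    """
    filtered, rep_miss = filter_by_missingness(table, max_missing_fraction)
    if specs:
        filtered, rep_excl = apply_exclusions(filtered, specs)
        removed_excl = rep_excl.removed_by_exclusion
    else:
        removed_excl = []
    report = FilterReport(
        n_input_parameters=rep_miss.n_input_parameters,
        missingness_per_parameter=rep_miss.missingness_per_parameter,
        removed_by_missingness=rep_miss.removed_by_missingness,
        removed_by_exclusion=removed_excl,
        retained=list(filtered.parameters),
    )
    return filtered, report


def read_parameter_specs(path) -> list[ParameterSpec]:
    """Load parameter specs from a YAML mapping.

    Format: one block per parameter::

        burrowing:
          direction: 1
          excluded: false
          note: g of gravel displaced; reduced under distress
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    specs = []
    for name, block in data.items():
        block = block or {}
        specs.append(
            ParameterSpec(
                name=str(name),
                direction=int(block.get("direction", 1)),
                excluded=bool(block.get("excluded", False)),
                note=str(block.get("note", "")),
            )
        )
    return specs


def write_parameter_specs(specs: list[ParameterSpec], path) -> None:
    data = {
        s.name: {"direction": s.direction, "excluded": s.excluded, "note": s.note}
        for s in specs
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
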
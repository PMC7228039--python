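"""Composite severity score: sum of selected, aligned z-values.

Each selected parameter enters with unit weight after directionality
alignment: a parameter whose LOW raw values indicate higher severity
(direction +1) keeps its sign; one whose HIGH values indicate higher
severity (direction -1) is negated. On the aligned scale a LOWER composite
score means putatively HIGHER severity for every contributing parameter,
which is what makes the plain sum meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ParameterSpec
from .preprocess import ScaledMatrix

#: an animal missing more than this fraction of the selected parameters is
#: still scored but flagged unreliable
UNRELIABLE_MISSING_FRACTION = 0.5


@dataclass
class CompositeScores:
    """One dimensionless score per animal, with contribution accounting."""

    frame: pd.DataFrame  # index animal_id; columns group, model, score, n_contributing, unreliable
    parameters_used: list[str]

    @property
    def scores(self) -> pd.Series:
        return self.frame["score"]

    @property
    def animal_ids(self) -> pd.Index:
        return self.frame.index

    def write_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "animal_id"
        out.to_csv(path)

    @classmethod
    def read_csv(cls, path, parameters_used: list[str] | None = None) -> "CompositeScores":
        frame = pd.read_csv(path, index_col="animal_id")
        return cls(frame=frame, parameters_used=parameters_used or [])


def build_composite(
    scaled: ScaledMatrix,
    selected: list[str],
    specs: list[ParameterSpec],
) -> CompositeScores:
    """Sum the selected aligned z-columns into one score per animal.

    Imputed cells contribute their imputed value (0, the neutral element of
    the sum) but are not counted in ``n_contributing``.
    """
    if not selected:
        raise ValueError("selected parameter list is empty")
    directions = {s.name: s.direction for s in specs}
    missing_spec = [p for p in selected if p not in directions]
    if missing_spec:
        raise ValueError(f"selected parameter(s) without a direction spec: {missing_spec}")
    absent = [p for p in selected if p not in scaled.parameters]
    if absent:
        raise ValueError(f"selected parameter(s) absent from scaled matrix: {absent}")

    aligned = scaled.values[selected].copy()
    for p in selected:
        if directions[p] == -1:
            aligned[p] = -aligned[p]
    score = aligned.sum(axis=1)
    n_imputed = scaled.imputation_mask[selected].sum(axis=1)
    n_contributing = len(selected) - n_imputed
    unreliable = n_imputed > UNRELIABLE_MISSING_FRACTION * len(selected)
    frame = pd.DataFrame(
        {
            "group": scaled.groups,
            "model": scaled.models,
            "score": score,
            "n_contributing": n_contributing.astype(int),
            "unreliable": unreliable,
        },
        index=scaled.animal_ids,
    )
    return CompositeScores(frame=frame, parameters_used=list(selected))
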
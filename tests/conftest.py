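import numpy as np
import pandas as pd
import pytest

import cmskit


@pytest.fixture
def csv_writer(tmp_path):
    """Write a small delimited table and return its path."""

    def _write(text: str, name: str = "table.csv"):
        path = tmp_path / name
        path.write_text(text.strip() + "\n")
        return path

    return _write


@pytest.fixture
def tiny_table():
    """10 animals x 4 parameters with hand-placed missing cells."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(size=(10, 4)),
        index=pd.Index([f"R{i:02d}" for i in range(10)], name="animal_id"),
        columns=["a", "b", "c", "d"],
    )
    # b: 3/10 missing (30%, removed); c: exactly 2/10 (20%, retained)
    values.iloc[[0, 3, 7], 1] = np.nan
    values.iloc[[2, 5], 2] = np.nan
    labels = ["g1"] * 5 + ["g2"] * 5
    return cmskit.ParameterTable(
        values,
        pd.Series(labels, index=values.index),
        pd.Series(["m1"] * 10, index=values.index),
    )


@pytest.fixture(scope="session")
def reference_run(tmp_path_factory):
    """One full pipeline run on the simulated reference battery."""
    td = tmp_path_factory.mktemp("reference")
    table, truth = cmskit.simulate_reference_fixture(1, td / "battery.csv")
    cmskit.write_parameter_specs(cmskit.reference_specs(), td / "specs.yaml")
    result = cmskit.run_pipeline(td / "battery.csv", td / "specs.yaml", td / "out", seed=7)
    return {"dir": td, "table": table, "truth": truth, "result": result}


def brute_force_kmeans_1d(x, k):
    """Exhaustive minimum within-cluster SS over contiguous partitions.

    Independent oracle: enumerates every placement of k-1 breakpoints in the
    sorted data and returns the minimal total within-cluster sum of squares.
    Only feasible for small n.
    """
    from itertools import combinations

    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    best = np.inf
    for cuts in combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        ss = 0.0
        for i, j in zip(bounds[:-1], bounds[1:]):
            seg = xs[i:j]
            ss += ((seg - seg.mean()) ** 2).sum()
        best = min(best, ss)
    return best


def within_cluster_ss(x, labels):
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    return sum(
        ((x[labels == c] - x[labels == c].mean()) ** 2).sum() for c in np.unique(labels)
    )
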
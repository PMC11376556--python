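import numpy as np
import pandas as pd
import pytest

from tcdiv.data_model import OrthologMap, SampleSheet, TimeCourseMatrix


@pytest.fixture
def small_sheet() -> SampleSheet:
    """Two groups x three times x two replicates."""
    rows = [
        {"sample_id": f"{g}_t{t}_r{r}", "group": g, "time": float(t), "replicate": r}
        for g in ("A", "B")
        for t in (0, 1, 2)
        for r in (1, 2)
    ]
    return SampleSheet.from_frame(pd.DataFrame(rows))


def matrix_from_means(
    means: dict[str, list[float]],
    sheet: SampleSheet,
    group: str = "A",
    layer: str = "protein",
) -> TimeCourseMatrix:
    """Matrix whose replicates at each time all equal the given mean."""
    sub = sheet.frame[sheet.frame["group"] == group]
    cols = {}
    times = sorted(sub["time"].unique())
    for _, row in sub.iterrows():
        j = times.index(row["time"])
        cols[row["sample_id"]] = [means[f][j] for f in means]
    values = pd.DataFrame(cols, index=list(means))
    return TimeCourseMatrix(
        layer=layer, values=values, samples=sheet.restrict(list(cols)),
    )


@pytest.fixture
def identity_map() -> OrthologMap:
    return OrthologMap.from_pairs([(f"g{i}", f"g{i}") for i in range(8)])


def riemann_area(curve_a, curve_b, times, n_steps: int = 10_000) -> float:
    """Independent fine-grid oracle for the area between two piecewise-
    linear interpolants: trapezoid rule on |difference| over a dense grid."""
    t = np.asarray(times, dtype=float)
    grid = np.linspace(t[0], t[-1], n_steps + 1)
    d = np.interp(grid, t, np.asarray(curve_a, float)) - np.interp(
        grid, t, np.asarray(curve_b, float)
    )
    return float(np.trapezoid(np.abs(d), grid))


def bh_stepup_bruteforce(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, in
    the original order, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
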
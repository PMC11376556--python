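"""Over-representation of a feature selection against user-supplied gene sets.

One-sided Fisher's exact test: given a universe of N features of which n
are selected, and a gene set covering K universe members of which k are
selected, the p-value is the hypergeometric upper tail P(X >= k).
p-values are BH-adjusted across the sets actually tested.  The universe
should be the features scored in the run, not the union of the GMT —
testing against an inflated universe is a classic artifact source.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data_model import GeneSetCollection, SchemaError
from .timecourse_de import bh_adjust

__all__ = ["fisher_enrichment"]


def fisher_enrichment(
    selection: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Rank gene sets by over-representation of ``selection`` in ``universe``.

    Returns one row per set with K > 0 members in the universe, columns
    ``set_name, k, K, n, N, odds_ratio, fold_enrichment, p, q``, sorted
    by p ascending (ties by set name).  ``alternative="two-sided"``
    switches to the two-sided Fisher test.
    """
    universe = set(universe)
    selection = set(selection)
    if not universe:
        raise SchemaError("universe is empty")
    offenders = selection - universe
    if offenders:
        raise SchemaError(
            f"selection is not a subset of the universe: {sorted(offenders)[:10]}"
            + ("..." if len(offenders) > 10 else "")
        )
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    N, n = len(universe), len(selection)
    rows = []
    for name in sets.names():
        members = sets[name] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selection)
        if alternative == "greater":
            p = float(hypergeom.sf(k - 1, N, K, n))
        else:
            from scipy.stats import fisher_exact

            table = [[k, n - k], [K - k, N - K - (n - k)]]
            p = float(fisher_exact(table, alternative="two-sided")[1])
        num, den = k * (N - K - n + k), (n - k) * (K - k)
        odds = np.inf if den == 0 and num > 0 else (num / den if den else np.nan)
        fold = (k / n) / (K / N) if n > 0 else np.nan
        rows.append(
            {"set_name": name, "k": k, "K": K, "n": n, "N": N,
             "odds_ratio": odds, "fold_enrichment": fold,
             "p": min(max(p, float(np.finfo(float).tiny)), 1.0)}
        )
    result = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N",
                       "odds_ratio", "fold_enrichment", "p"]
    )
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result = result.sort_values(["p", "set_name"]).reset_index(drop=True)
    else:
        result["q"] = pd.Series(dtype=float)
    return result
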
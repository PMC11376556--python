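#!/usr/bin/env python
"""Test the flagged divergence set for archetype over-representation.

Builds one gene set per planted archetype from the truth labels, takes
the flagged pairs from 03_score_divergence.py as the selection and all
scored pairs as the universe, and runs one-sided Fisher tests with BH
correction.  The divergent archetype should dominate the flagged set.
"""

from pathlib import Path

import pandas as pd

from tcdiv.data_model import GeneSetCollection, write_table
from tcdiv.enrichment import fisher_enrichment

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(ROOT / "scores_protein.tsv", sep="\t")
    truth = pd.read_csv(ROOT / "data" / "truth_labels.tsv", sep="\t",
                        index_col="feature_id")["archetype"]
    sets = GeneSetCollection(
        sets={name: frozenset(truth.index[truth == name])
              for name in sorted(truth.unique())}
    )
    flagged = set(table.loc[table["flagged"], "feature_a"])
    universe = set(table["feature_a"])
    enr = fisher_enrichment(flagged, sets, universe)
    write_table(enr, ROOT / "enrichment.tsv", index=False)
    print(f"selection: {len(flagged)} flagged of {len(universe)} scored pairs")
    for _, row in enr.iterrows():
        print(f"  {row['set_name']:15s} k={row['k']:4d}/{row['K']:4d} "
              f"fold={row['fold_enrichment']:5.2f} p={row['p']:.3g} q={row['q']:.3g}")


if __name__ == "__main__":
    main()
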
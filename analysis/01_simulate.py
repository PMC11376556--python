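#!/usr/bin/env python
"""Generate the synthetic two-group, two-layer anoxia-style time course.

Writes the RNA count and protein intensity matrices for both groups
(5 time points x 3 replicates), the sample sheet, the one-to-one ortholog
map and the planted archetype truth labels under results/data/.
"""

from pathlib import Path

from tcdiv.data_model import write_matrix, write_ortholog_map, write_sample_sheet, write_table
from tcdiv.synthetic import simulate_timecourse

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sim = simulate_timecourse(seed=SEED)
    write_sample_sheet(sim.sheet, OUT / "sample_sheet.tsv")
    for layer, mats in (("rna", sim.rna), ("protein", sim.protein)):
        for g, mat in mats.items():
            write_matrix(mat, OUT / f"{layer}_{g}.tsv")
    write_ortholog_map(sim.ortholog_map, OUT / "ortholog_map.tsv")
    truth = sim.truth.labels.rename_axis("feature_id").reset_index()
    write_table(truth, OUT / "truth_labels.tsv", index=False)
    counts = truth["archetype"].value_counts()
    print(f"simulated {len(truth)} ortholog pairs (seed {SEED}):")
    for name, n in counts.items():
        print(f"  {name:15s} {n}")
    print(f"matrices, sample sheet, map and truth written to {OUT}")


if __name__ == "__main__":
    main()
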
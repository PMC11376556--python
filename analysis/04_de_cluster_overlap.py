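#!/usr/bin/env python
"""Per-timepoint differential calls, profile clusters, cross-layer overlap.

Welch tests each non-baseline time against t=0 within each group and
layer (BH FDR < 0.05), cuts the Ward tree of paired protein profiles
into 4 clusters, and intersects the RNA and protein call sets per
(group, time) through the ortholog map.
"""

from pathlib import Path

import pandas as pd

from tcdiv.data_model import read_matrix, read_ortholog_map, read_sample_sheet, write_table
from tcdiv.timecourse_de import cluster_profiles, cross_layer_overlap, per_timepoint_de

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"


def main() -> None:
    sheet = read_sample_sheet(DATA / "sample_sheet.tsv")
    omap = read_ortholog_map(DATA / "ortholog_map.tsv")

    de = {}
    for layer, pc in (("rna", 1.0), ("protein", 0.0)):
        frames = []
        for g in ("A", "B"):
            mat = read_matrix(DATA / f"{layer}_{g}.tsv", sheet, layer)
            frames.append(per_timepoint_de(mat, fdr_alpha=0.05, pseudocount=pc))
        de[layer] = pd.concat(frames, ignore_index=True)
        write_table(de[layer], ROOT / f"de_{layer}.tsv", index=False)
        calls = de[layer].groupby(["group", "time"])["called"].sum()
        print(f"{layer} calls per (group, time):")
        print(calls.to_string())

    profiles = {
        g: pd.read_csv(ROOT / f"profiles_protein_{g}.tsv", sep="\t", index_col=0)
        for g in ("A", "B")
    }
    assign = cluster_profiles(profiles["A"], profiles["B"], omap, k=4)
    lab = assign.labels.rename_axis("feature_id").reset_index()
    write_table(lab, ROOT / "clusters_protein.tsv", index=False)
    write_table(assign.mean_profiles, ROOT / "cluster_mean_profiles.tsv")
    print("protein profile clusters:",
          dict(assign.labels.value_counts().sort_index()))

    rows = []
    for g in ("A", "B"):
        for t in sheet.times(g)[1:]:
            res = cross_layer_overlap(de["rna"], de["protein"], omap, g, t)
            rows.append({"group": g, "time": t, "n_rna": res.n_rna,
                         "n_protein": res.n_protein, "n_overlap": res.n_overlap})
    overlap = pd.DataFrame(rows)
    write_table(overlap, ROOT / "overlap.tsv", index=False)
    print("cross-layer overlap (calls in both RNA and protein):")
    print(overlap.to_string(index=False))


if __name__ == "__main__":
    main()
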
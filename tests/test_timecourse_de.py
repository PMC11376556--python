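"""Per-timepoint tests, BH adjustment, profile clustering, overlap."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import bh_stepup_bruteforce, matrix_from_means
from tcdiv.data_model import OrthologMap, SchemaError, TimeCourseMatrix
from tcdiv.synthetic import simulate_cluster_archetypes
from tcdiv.timecourse_de import (
    bh_adjust,
    cluster_profiles,
    cross_layer_overlap,
    per_timepoint_de,
)


def replicate_matrix(reps: dict[str, dict[float, list[float]]], sheet,
                     group="A", layer="protein"):
    """Matrix from explicit per-(feature, time) replicate values."""
    cols = {}
    sub = sheet.frame[sheet.frame["group"] == group]
    for _, row in sub.iterrows():
        t, r = float(row["time"]), int(row["replicate"])
        cols[row["sample_id"]] = [reps[f][t][r - 1] for f in reps]
    values = pd.DataFrame(cols, index=list(reps))
    return TimeCourseMatrix(layer, values, sheet.restrict(list(cols)))


@pytest.fixture
def triplicate_sheet():
    from tcdiv.data_model import SampleSheet

    rows = [
        {"sample_id": f"{g}_t{t}_r{r}", "group": g, "time": float(t), "replicate": r}
        for g in ("A", "B") for t in (0, 1) for r in (1, 2, 3)
    ]
    return SampleSheet.from_frame(pd.DataFrame(rows))


class TestPerTimepointDE:
    def test_identical_replicates_not_called(self, triplicate_sheet):
        mat = replicate_matrix(
            {"f1": {0.0: [4, 4, 4], 1.0: [4, 4, 4]}}, triplicate_sheet
        )
        out = per_timepoint_de(mat, pseudocount=0.0)
        row = out.iloc[0]
        assert row["effect"] == 0.0
        assert row["p"] == 1.0
        assert not row["called"]

    def test_variance_floor_makes_exact_shift_significant(self, triplicate_sheet):
        mat = replicate_matrix(
            {"f1": {0.0: [2, 2, 2], 1.0: [8, 8, 8]}}, triplicate_sheet
        )
        out = per_timepoint_de(mat, pseudocount=0.0)
        row = out.iloc[0]
        assert row["effect"] == pytest.approx(2.0)  # log2 8 - log2 2
        assert row["called"]

    def test_welch_statistic_worked_example(self, triplicate_sheet):
        # log2 values 0.9/1.1/1.0 vs 1.9/2.1/2.0: sd 0.1 each, n 3 each
        base = [2 ** v for v in (0.9, 1.1, 1.0)]
        late = [2 ** v for v in (1.9, 2.1, 2.0)]
        mat = replicate_matrix({"f1": {0.0: base, 1.0: late}}, triplicate_sheet)
        out = per_timepoint_de(mat, pseudocount=0.0)
        row = out.iloc[0]
        assert row["effect"] == pytest.approx(1.0)
        assert row["statistic"] == pytest.approx(12.247, abs=5e-4)
        assert row["df"] == pytest.approx(4.0)

    def test_matches_scipy_welch_on_nondegenerate_data(self, triplicate_sheet):
        from scipy import stats

        rng = np.random.default_rng(4)
        reps = {
            f"f{i}": {0.0: list(rng.lognormal(3, 0.4, 3)),
                      1.0: list(rng.lognormal(3.5, 0.4, 3))}
            for i in range(10)
        }
        mat = replicate_matrix(reps, triplicate_sheet)
        out = per_timepoint_de(mat, pseudocount=0.0).set_index("feature_id")
        for f, d in reps.items():
            x = np.log2(d[0.0])
            y = np.log2(d[1.0])
            t_ref, p_ref = stats.ttest_ind(y, x, equal_var=False)
            assert out.loc[f, "statistic"] == pytest.approx(t_ref, rel=1e-9)
            assert out.loc[f, "p"] == pytest.approx(p_ref, rel=1e-9)

    def test_single_replicate_gives_feature_level_na(self):
        from tcdiv.data_model import SampleSheet

        rows = [
            {"sample_id": f"A_t{t}_r{r}", "group": "A", "time": float(t),
             "replicate": r}
            for t, nrep in ((0, 1), (1, 3)) for r in range(1, nrep + 1)
        ] + [
            {"sample_id": f"B_t{t}_r1", "group": "B", "time": float(t),
             "replicate": 1} for t in (0, 1)
        ]
        sheet = SampleSheet.from_frame(pd.DataFrame(rows))
        values = pd.DataFrame(
            {s["sample_id"]: [1.0] for s in rows if s["group"] == "A"},
            index=["f1"],
        )
        mat = TimeCourseMatrix("protein", values,
                               sheet.restrict(values.columns))
        out = per_timepoint_de(mat)
        assert out["p"].isna().all()
        assert not out["called"].any()

    def test_calls_anti_monotone_in_alpha(self, triplicate_sheet):
        rng = np.random.default_rng(5)
        reps = {
            f"f{i}": {0.0: list(rng.lognormal(3, 0.3, 3)),
                      1.0: list(rng.lognormal(3 + rng.normal(0, 1), 0.3, 3))}
            for i in range(40)
        }
        mat = replicate_matrix(reps, triplicate_sheet)
        strict = per_timepoint_de(mat, fdr_alpha=0.01)
        loose = per_timepoint_de(mat, fdr_alpha=0.2)
        called_strict = set(strict.loc[strict["called"], "feature_id"])
        called_loose = set(loose.loc[loose["called"], "feature_id"])
        assert called_strict <= called_loose


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0], [1.0]),
            ([0.05, 0.05], [0.05, 0.05]),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_bruteforce_stepup_exactly(self):
        rng = np.random.default_rng(6)
        for _ in range(500):
            n = rng.integers(1, 40)
            p = rng.uniform(np.finfo(float).tiny, 1.0, size=n)
            assert np.array_equal(bh_adjust(p), bh_stepup_bruteforce(p))

    def test_agrees_with_statsmodels_fdr_bh(self):
        # independent cross-check against an established implementation
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(16)
        p = rng.uniform(0.001, 1.0, size=200)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1],
                           rtol=0, atol=1e-12)

    def test_monotone_in_p_and_at_least_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.0001, 1.0, size=50)
        q = bh_adjust(p)
        assert np.all(q >= p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [np.nan]])
    def test_out_of_domain_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestClusterProfiles:
    def test_duplicated_features_always_cocluster(self):
        ca, cb, _ = simulate_cluster_archetypes(n_per_archetype=3, noise_sd=0.3,
                                                seed=9)
        dup_a = pd.concat([ca, ca.set_axis([f + "_dup" for f in ca.index])])
        dup_b = pd.concat([cb, cb.set_axis([f + "_dup" for f in cb.index])])
        omap = OrthologMap.from_pairs([(f, f) for f in dup_a.index])
        assign = cluster_profiles(dup_a, dup_b, omap, k=4)
        for f in ca.index:
            assert assign.labels[f] == assign.labels[f + "_dup"]

    def test_noiseless_archetypes_recovered_perfectly(self):
        ca, cb, truth = simulate_cluster_archetypes(n_per_archetype=10,
                                                    noise_sd=0.0, seed=0)
        omap = OrthologMap.from_pairs([(f, f) for f in ca.index])
        assign = cluster_profiles(ca, cb, omap, k=4)
        ari = adjusted_rand_score(truth.loc[assign.labels.index],
                                  assign.labels)
        assert ari == pytest.approx(1.0)

    def test_k_equals_one_labels_everything_I(self):
        ca, cb, _ = simulate_cluster_archetypes(n_per_archetype=3, seed=1)
        omap = OrthologMap.from_pairs([(f, f) for f in ca.index])
        assign = cluster_profiles(ca, cb, omap, k=1)
        assert set(assign.labels) == {"I"}

    def test_k_larger_than_n_rejected(self):
        ca, cb, _ = simulate_cluster_archetypes(n_per_archetype=1, seed=1)
        omap = OrthologMap.from_pairs([(f, f) for f in ca.index])
        with pytest.raises(ValueError):
            cluster_profiles(ca, cb, omap, k=5)

    def test_labels_deterministic_across_runs(self):
        ca, cb, _ = simulate_cluster_archetypes(n_per_archetype=8, noise_sd=0.25,
                                                seed=2)
        omap = OrthologMap.from_pairs([(f, f) for f in ca.index])
        a1 = cluster_profiles(ca, cb, omap, k=4)
        a2 = cluster_profiles(ca, cb, omap, k=4)
        assert a1.labels.equals(a2.labels)
        assert a1.mean_profiles.equals(a2.mean_profiles)

    def test_labels_ordered_by_cluster_size(self):
        ca, cb, _ = simulate_cluster_archetypes(n_per_archetype=4, seed=3)
        # drop one archetype down to a single member: it must get label IV
        keep = [f for f in ca.index if not f.startswith("a_down_b_up")] + \
               ["a_down_b_up_000"]
        ca, cb = ca.loc[keep], cb.loc[keep]
        omap = OrthologMap.from_pairs([(f, f) for f in keep])
        assign = cluster_profiles(ca, cb, omap, k=4)
        assert assign.labels["a_down_b_up_000"] == "IV"


class TestCrossLayerOverlap:
    def de_table(self, called: dict[str, bool], group="A", time=3.0):
        rows = [
            {"feature_id": f, "group": group, "time": time, "effect": 1.0,
             "statistic": 1.0, "df": 4.0, "p": 0.01, "q": 0.01, "called": c}
            for f, c in called.items()
        ]
        return pd.DataFrame(rows)

    def test_plain_intersection(self, identity_map):
        rna = self.de_table({"g1": True, "g2": True, "g3": True, "g4": False})
        prot = self.de_table({"g1": False, "g2": True, "g3": True, "g4": True})
        res = cross_layer_overlap(rna, prot, identity_map, "A", 3.0)
        assert (res.n_rna, res.n_protein, res.n_overlap) == (3, 3, 2)
        assert list(res.pairs["feature_a"]) == ["g2", "g3"]

    def test_disjoint_sets_overlap_zero(self, identity_map):
        rna = self.de_table({"g1": True, "g2": False})
        prot = self.de_table({"g1": False, "g2": True})
        res = cross_layer_overlap(rna, prot, identity_map, "A", 3.0)
        assert res.n_overlap == 0

    def test_empty_protein_calls(self, identity_map):
        rna = self.de_table({"g1": True, "g2": True})
        prot = self.de_table({"g1": False, "g2": False})
        res = cross_layer_overlap(rna, prot, identity_map, "A", 3.0)
        assert (res.n_rna, res.n_protein, res.n_overlap) == (2, 0, 0)

    def test_missing_time_is_an_error(self, identity_map):
        rna = self.de_table({"g1": True})
        prot = self.de_table({"g1": True})
        with pytest.raises(SchemaError):
            cross_layer_overlap(rna, prot, identity_map, "A", 4.0)

    def test_permutation_invariance(self, identity_map):
        rna = self.de_table({"g3": True, "g1": True, "g2": False})
        prot = self.de_table({"g2": True, "g3": True, "g1": True})
        r1 = cross_layer_overlap(rna, prot, identity_map, "A", 3.0)
        r2 = cross_layer_overlap(rna.iloc[::-1], prot.sample(frac=1, random_state=0),
                                 identity_map, "A", 3.0)
        assert r1.n_overlap == r2.n_overlap
        assert r1.pairs.equals(r2.pairs)
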
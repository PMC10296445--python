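import warnings

import numpy as np
import pytest

from spglearn import (
    GeneScoreTable,
    build_score_table,
    cross_slide_scores,
    importance_cluster_markers,
    mean_importance,
    mni_pni,
    select_spgs,
    spg_svg_contingency,
)
from conftest import make_importance


# -- brute-force oracles (independent loop implementations) -------------------

def oracle_mean_imp(V):
    return [sum(V[s][g] for s in range(len(V))) / len(V) for g in range(len(V[0]))]


def oracle_mni_pni(V, tol=0.0):
    n = len(V)
    mni, pni = [], []
    for g in range(len(V[0])):
        vals = [V[s][g] for s in range(n) if V[s][g] > tol]
        mni.append(sum(vals) / len(vals) if vals else 0.0)
        pni.append(100.0 * len(vals) / n)
    return mni, pni


def oracle_cross_slide(mats):
    h = len(mats)
    return [sum(m[g] for m in mats) / h for g in range(len(mats[0]))]


class TestMeanImportance:
    def test_worked_example(self):
        imp = make_importance(np.array([[0.0], [0.0], [2.0], [4.0]]))
        assert mean_importance(imp)[0] == 1.5

    def test_all_zero_gene(self):
        imp = make_importance(np.zeros((5, 2)))
        np.testing.assert_array_equal(mean_importance(imp), [0.0, 0.0])

    def test_matches_loop_oracle(self, rng):
        V = rng.uniform(size=(20, 5))
        got = mean_importance(make_importance(V))
        np.testing.assert_allclose(got, oracle_mean_imp(V.tolist()), atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_importance(make_importance(np.zeros((0, 3))))


class TestMniPni:
    def test_worked_example(self):
        imp = make_importance(np.array([[0.0], [0.0], [2.0], [4.0]]))
        mni, pni = mni_pni(imp)
        assert mni[0] == 3.0 and pni[0] == 50.0

    def test_quarter_detection(self):
        V = np.zeros((20, 1))
        V[:5, 0] = 1.0
        _, pni = mni_pni(make_importance(V))
        assert pni[0] == 25.0

    def test_all_zero_gene_convention(self):
        mni, pni = mni_pni(make_importance(np.zeros((4, 1))))
        assert mni[0] == 0.0 and pni[0] == 0.0

    def test_matches_loop_oracle_with_zeros(self, rng):
        V = rng.uniform(size=(20, 6))
        V[V < 0.4] = 0.0
        mni, pni = mni_pni(make_importance(V))
        omni, opni = oracle_mni_pni(V.tolist())
        np.testing.assert_allclose(mni, omni, atol=1e-12)
        np.testing.assert_allclose(pni, opni, atol=1e-12)


class TestCrossSlideScores:
    def test_mean_of_three_slides(self):
        mi = np.array([[0.1, 0.2, 0.3]])
        csmi, _, _ = cross_slide_scores(mi, mi, np.zeros((1, 3)))
        assert csmi[0] == pytest.approx(0.2)

    def test_single_slide_identity(self):
        mi = np.array([[0.7], [0.1]])
        csmi, csmni, cspni = cross_slide_scores(mi, mi * 2, mi * 10)
        np.testing.assert_allclose(csmi, mi[:, 0])

    def test_matches_loop_oracle(self, rng):
        mats = [rng.uniform(size=15) for _ in range(3)]
        stacked = np.column_stack(mats)
        csmi, _, _ = cross_slide_scores(stacked, stacked, stacked)
        np.testing.assert_allclose(csmi, oracle_cross_slide([m.tolist() for m in mats]), atol=1e-12)


def table_from_scores(csmi, csmni, cspni):
    n = len(csmi)
    return GeneScoreTable(
        gene_ids=[chr(ord("A") + i) for i in range(n)],
        slide_ids=["s1"],
        per_slide_mean_imp=np.asarray(csmi, dtype=float)[:, None],
        per_slide_mni=np.asarray(csmni, dtype=float)[:, None],
        per_slide_pni=np.asarray(cspni, dtype=float)[:, None],
        csmi=np.asarray(csmi, dtype=float),
        csmni=np.asarray(csmni, dtype=float),
        cspni=np.asarray(cspni, dtype=float),
    )


class TestSelectSpgs:
    def test_worked_two_stage_example(self):
        table = table_from_scores(
            csmi=[0.2, 0.16, 0.05, 0.05],
            csmni=[0.5, 0.3, 0.4, 0.2],
            cspni=[50.0, 10.0, 30.0, 40.0],
        )
        out = select_spgs(table)
        assert list(out.spg_reason) == ["csmi_seed", "csmi_seed", "mni_rescue", "none"]
        assert [g for g, f in zip(out.gene_ids, out.is_spg) if f] == ["A", "B", "C"]

    def test_empty_seed_warns_and_calls_nothing(self):
        table = table_from_scores([0.1, 0.15], [9.9, 9.9], [99.0, 99.0])
        with pytest.warns(UserWarning, match="no gene exceeds"):
            out = select_spgs(table)
        assert not out.is_spg.any()

    def test_threshold_is_strict(self):
        table = table_from_scores([0.15], [1.0], [99.0])
        with pytest.warns(UserWarning):
            out = select_spgs(table)
        assert not out.is_spg.any()

    def test_negative_threshold_selects_everything_as_seed(self):
        table = table_from_scores([0.0, 0.01], [0.0, 0.1], [0.0, 5.0])
        out = select_spgs(table, csmi_threshold=-1)
        assert list(out.spg_reason) == ["csmi_seed", "csmi_seed"]

    def test_lowering_threshold_never_drops_a_seed(self, rng):
        csmi = rng.uniform(0, 0.4, size=30)
        table = table_from_scores(csmi, rng.uniform(size=30), rng.uniform(0, 100, 30))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            high = select_spgs(table, csmi_threshold=0.2)
            low = select_spgs(table, csmi_threshold=0.1)
        high_seeds = {g for g, r in zip(high.gene_ids, high.spg_reason) if r == "csmi_seed"}
        low_spgs = {g for g, f in zip(low.gene_ids, low.is_spg) if f}
        assert high_seeds <= low_spgs


class TestScoringOracleEquivalence:
    def test_full_pipeline_matches_oracles_on_random_matrices(self, rng):
        """MeanImp/MNI/PNI and the cross-slide means agree with explicit
        loop implementations on random 3-slide importance sets."""
        for _ in range(20):
            slides = [rng.uniform(size=(20, 15)) for _ in range(3)]
            for V in slides:
                V[V < 0.3] = 0.0
            table = build_score_table(
                {f"sl{j}": make_importance(V) for j, V in enumerate(slides)}
            )
            o_mi = [oracle_mean_imp(V.tolist()) for V in slides]
            o_mni = [oracle_mni_pni(V.tolist())[0] for V in slides]
            o_pni = [oracle_mni_pni(V.tolist())[1] for V in slides]
            np.testing.assert_allclose(table.csmi, oracle_cross_slide(o_mi), atol=1e-12)
            np.testing.assert_allclose(table.csmni, oracle_cross_slide(o_mni), atol=1e-12)
            np.testing.assert_allclose(table.cspni, oracle_cross_slide(o_pni), atol=1e-12)

    def test_median_mode_correlates_with_mean_mode(self, rng):
        """Median-based aggregation gives a CSMI vector strongly related to
        the mean-based one on smooth importance data (reported, not asserted
        tightly)."""
        base = rng.uniform(0.5, 2.0, size=15)
        slides = {f"sl{j}": make_importance(base * rng.uniform(0.8, 1.2, size=(20, 15)))
                  for j in range(3)}
        mean_t = build_score_table(slides, agg="mean")
        med_t = build_score_table(slides, agg="median")
        r = np.corrcoef(mean_t.csmi, med_t.csmi)[0, 1]
        assert r > 0.9


class TestClusterMarkers:
    def test_single_cluster_equals_meanimp_ranking(self, rng):
        V = rng.uniform(size=(10, 5))
        imp = make_importance(V)
        labels = {s: "all" for s in imp.spot_ids}
        markers = importance_cluster_markers(imp, labels, top_n=5)
        expected = [imp.gene_ids[i] for i in np.argsort(-mean_importance(imp), kind="stable")]
        assert [g for g, _ in markers["all"]] == expected

    def test_cluster_restricted_gene_ranks_first(self):
        V = np.ones((6, 3)) * 0.1
        V[:3, 2] = 5.0  # strong only inside cluster "c"
        imp = make_importance(V)
        labels = {f"s{i}": ("c" if i < 3 else "d") for i in range(6)}
        markers = importance_cluster_markers(imp, labels, top_n=3)
        assert markers["c"][0][0] == "g2"

    def test_identical_clusters_identical_rankings(self, rng):
        V = np.tile(rng.uniform(size=(1, 4)), (8, 1))
        imp = make_importance(V)
        labels = {f"s{i}": ("a" if i < 4 else "b") for i in range(8)}
        markers = importance_cluster_markers(imp, labels, top_n=4)
        assert markers["a"] == markers["b"]

    def test_unlabeled_spot_rejected(self, rng):
        imp = make_importance(rng.uniform(size=(4, 2)))
        with pytest.raises(ValueError, match="unlabeled"):
            importance_cluster_markers(imp, {"s0": "a"}, top_n=1)


class TestContingency:
    def test_empty_sets(self):
        out = spg_svg_contingency(set(), set(), {"a", "b", "c"})
        assert out == {"neither": 3, "spg_only": 0, "svg_only": 0, "both": 0}

    def test_identical_sets(self):
        out = spg_svg_contingency({"a"}, {"a"}, {"a", "b"})
        assert out["spg_only"] == 0 and out["svg_only"] == 0 and out["both"] == 1

    def test_enumerated_example(self):
        out = spg_svg_contingency({"a", "b"}, {"b", "c"}, {"a", "b", "c", "d"})
        assert out == {"neither": 1, "spg_only": 1, "svg_only": 1, "both": 1}
        assert sum(out.values()) == 4

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            spg_svg_contingency({"z"}, set(), {"a"})
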
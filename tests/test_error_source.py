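"""Patient-centric integration: verdicts and corrections."""

import numpy as np
import pandas as pd
import pytest

from omicmatch import (
    AlignmentResult,
    CisCandidateMap,
    apply_correction,
    build_patient_view,
    correction_gain,
    infer_error_source,
)
from omicmatch.error_source import CORRECT, MISLABELED, SWAPPED, UNRESOLVED

from conftest import make_matrix


def make_result(rows, ta, tb):
    """rows: (sample_a, sample_b, status) triples."""
    df = pd.DataFrame(rows, columns=["sample_a", "sample_b", "status"])
    return AlignmentResult(table=df, method="probabilistic", data_type_a=ta, data_type_b=tb)


def self_rows(patients):
    return [(p, p, "self_aligned") for p in patients]


class TestPatientView:
    def test_all_self_gives_complete_red_graph(self):
        pats = ["p1", "p2"]
        results = [
            make_result(self_rows(pats), "rna", "mirna"),
            make_result(self_rows(pats), "rna", "cnv"),
            make_result(self_rows(pats), "mirna", "cnv"),
        ]
        view = build_patient_view(results)
        assert all(d["status"] == "self" for _, _, d in view.graph.edges(data=True))
        verdicts = infer_error_source(view)
        assert all(v[0] == CORRECT for v in verdicts.values())

    def test_reciprocal_cross_pattern_encoded(self):
        res = make_result(
            [("pi", "pj", "cross_aligned"), ("pj", "pi", "cross_aligned")], "agilent", "mirna"
        )
        view = build_patient_view([res])
        assert view.graph.edges[("pi", "agilent"), ("pj", "mirna")]["status"] == "cross"
        assert view.graph.edges[("pj", "agilent"), ("pi", "mirna")]["status"] == "cross"

    def test_empty_results_give_empty_graph(self):
        view = build_patient_view([])
        assert len(view.graph.nodes) == 0

    def test_conflicting_duplicate_edges_error(self):
        r1 = make_result([("p1", "p1", "self_aligned")], "rna", "mirna")
        r2 = make_result([("p1", "p1", "unaligned")], "rna", "mirna")
        with pytest.raises(ValueError, match="conflict"):
            build_patient_view([r1, r2])


class TestVerdicts:
    def _swap_scenario(self):
        """Swap of the 'agilent' profiles of pi and pj: their agilent columns
        cross-align to the other patient's miRNA, everything else is self."""
        results = [
            make_result(
                [("pi", "pj", "cross_aligned"), ("pj", "pi", "cross_aligned"),
                 *self_rows(["pk"])],
                "agilent", "mirna",
            ),
            make_result(self_rows(["pi", "pj", "pk"]), "rnaseq", "mirna"),
            make_result(self_rows(["pi", "pj", "pk"]), "rnaseq", "cnv"),
        ]
        return build_patient_view(results)

    def test_swap_verdict_on_implicated_type(self):
        view = self._swap_scenario()
        verdicts = infer_error_source(view)
        assert verdicts[("pi", "agilent")][0] == SWAPPED
        assert verdicts[("pi", "agilent")][1] == ("pj", "agilent")
        assert verdicts[("pj", "agilent")][1] == ("pi", "agilent")
        assert verdicts[("pk", "agilent")][0] == CORRECT
        assert verdicts[("pi", "rnaseq")][0] == CORRECT

    def test_single_profile_mislabel(self):
        # pi's miRNA profile cross-aligns to pj's mRNA profiles (both
        # platforms), with no reciprocal pattern: mislabeled miRNA
        results = [
            make_result([("pj", "pi", "cross_aligned"), ("pi", "pj", "unaligned")], "rnaseq", "mirna"),
            make_result([("pj", "pi", "cross_aligned")], "agilent", "mirna"),
            make_result(self_rows(["pi", "pj"]), "rnaseq", "cnv"),
            make_result(self_rows(["pi", "pj"]), "agilent", "cnv"),
        ]
        view = build_patient_view(results)
        verdicts = infer_error_source(view)
        assert verdicts[("pi", "mirna")][0] == MISLABELED
        assert verdicts[("pi", "mirna")][1] == ("pj", "mirna")

    def test_isolated_cross_without_corroboration_unresolved(self):
        results = [
            make_result([("pi", "pj", "cross_aligned")], "rnaseq", "mirna"),
        ]
        view = build_patient_view(results)
        verdicts = infer_error_source(view)
        assert verdicts[("pi", "rnaseq")][0] == UNRESOLVED


class TestApplyCorrection:
    def test_swap_exchanges_columns(self):
        m = make_matrix([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]], sample_ids=["pi", "pj", "pk"],
                        data_type="agilent")
        verdicts = {
            ("pi", "agilent"): (SWAPPED, ("pj", "agilent"), 1),
            ("pj", "agilent"): (SWAPPED, ("pi", "agilent"), 1),
        }
        out, log = apply_correction({"agilent": m}, verdicts)
        np.testing.assert_array_equal(out["agilent"].values[:, 0], [2.0, 5.0])
        np.testing.assert_array_equal(out["agilent"].values[:, 1], [1.0, 4.0])
        assert log[0]["action"] == "swap"
        np.testing.assert_array_equal(m.values[0], [1.0, 2.0, 3.0])  # input untouched

    def test_no_verdicts_leaves_matrices_unchanged(self):
        m = make_matrix([[1.0, 2.0]], data_type="rna")
        out, log = apply_correction({"rna": m}, {})
        np.testing.assert_array_equal(out["rna"].values, m.values)
        assert log == []

    def test_ambiguous_mislabel_dropped_and_logged(self):
        m = make_matrix([[1.0, 2.0]], sample_ids=["pi", "pj"], data_type="mirna")
        verdicts = {("pi", "mirna"): (MISLABELED, None, 2)}
        out, log = apply_correction({"mirna": m}, verdicts)
        assert out["mirna"].sample_ids == ["pj"]
        assert log[0]["action"] == "drop"

    def test_relabel_collision_aborts(self):
        m = make_matrix([[1.0, 2.0]], sample_ids=["pi", "pj"], data_type="mirna")
        verdicts = {("pi", "mirna"): (MISLABELED, ("pj", "mirna"), 2)}
        with pytest.raises(ValueError, match="collision"):
            apply_correction({"mirna": m}, verdicts)


class TestCorrectionGain:
    def test_equal_pair_sets_give_near_zero_gain(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.normal(size=(5, n))
        y = x + 0.3 * rng.normal(size=(5, n))
        a = make_matrix(x)
        b = make_matrix(y, feature_ids=[f"h{i}" for i in range(5)])
        pairs = [(f"s{j}", f"s{j}") for j in range(n)]
        cand = CisCandidateMap([(f"g{i}", f"h{i}") for i in range(5)])
        df = correction_gain(a, b, cand, pairs, pairs, n_resample=100, seed=1)
        assert np.all(np.abs(df["gain"]) <= 0.02)

    def test_seeded_resampling_reproducible(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 40))
        a = make_matrix(x)
        b = make_matrix(x + rng.normal(size=(3, 40)), feature_ids=["h0", "h1", "h2"])
        pairs = [(f"s{j}", f"s{j}") for j in range(40)]
        sub = pairs[:30]
        cand = CisCandidateMap([(f"g{i}", f"h{i}") for i in range(3)])
        d1 = correction_gain(a, b, cand, pairs, sub, seed=5)
        d2 = correction_gain(a, b, cand, pairs, sub, seed=5)
        pd.testing.assert_frame_equal(d1, d2)

    def test_invalid_resample_count(self):
        a = make_matrix([[1.0, 2.0]])
        with pytest.raises(ValueError):
            correction_gain(a, a, CisCandidateMap([("g0", "g0")]), [("s0", "s0")], [("s0", "s0")], n_resample=0)
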
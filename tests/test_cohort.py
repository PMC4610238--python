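"""Sample ranking, rank-sum group comparison and co-addiction discovery."""

import numpy as np
import pandas as pd
import pytest

import tascore as tc
from tascore.cohort import exact_rank_sum_p
from tascore.errors import InvalidConfigError, LookupError_, UndefinedCorrelationError


def tas_frame(data, samples=None):
    df = pd.DataFrame(data)
    if samples:
        df.index = samples
    return df


class TestRankSamples:
    def test_descending_order(self):
        df = tas_frame({"T1": [5.0, 9.0, 7.0]}, ["s1", "s2", "s3"])
        ranked = tc.rank_samples_by_target(df, "T1")
        assert list(ranked["sample_id"]) == ["s2", "s3", "s1"]

    def test_missing_ranks_last_and_flagged(self):
        df = tas_frame({"T1": [5.0, np.nan, 7.0]}, ["s1", "s2", "s3"])
        ranked = tc.rank_samples_by_target(df, "T1")
        assert list(ranked["sample_id"]) == ["s3", "s1", "s2"]
        assert bool(ranked.iloc[-1]["missing"])

    def test_ties_preserve_input_order(self):
        df = tas_frame({"T1": [4.0, 4.0, 4.0]}, ["s1", "s2", "s3"])
        ranked = tc.rank_samples_by_target(df, "T1")
        assert list(ranked["sample_id"]) == ["s1", "s2", "s3"]

    def test_unknown_target_rejected(self):
        with pytest.raises(LookupError_):
            tc.rank_samples_by_target(tas_frame({"T1": [1.0]}, ["s"]), "T9")


class TestCompareGroups:
    def test_exact_small_group_value(self):
        # {1,2,3} vs {4,5,6}: most extreme split, two-sided p = 2/C(6,3) = 0.1
        res = tc.compare_groups(
            [1, 2, 3, 4, 5, 6], ["b", "b", "b", "a", "a", "a"]
        )
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        res = tc.compare_groups([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
        # tie-free values so the exact branch is taken
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        labels = ["pos"] * n1 + ["neg"] * n2
        res = tc.compare_groups(vals, labels)
        assert res.method == "exact"
        expected = exact_rank_sum_p(vals[:n1], vals[n1:])
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=40)
        labels = ["a"] * 20 + ["b"] * 20
        res = tc.compare_groups(vals, labels)
        assert res.method == "normal-approximation-with-tie-correction"

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidConfigError):
            tc.compare_groups([1.0, 2.0], ["a", "a"])


class TestCoaddiction:
    def test_duplicated_anchor_column_is_partner(self):
        rng = np.random.default_rng(1)
        anchor = rng.normal(10, 3, 20)
        df = tas_frame({"FLT3": anchor, "COPY": anchor, "OTHER": rng.normal(10, 3, 20)})
        table = tc.coaddiction(df, "FLT3", rho_threshold=0.94, alpha=0.01)
        row = table.set_index("target_id")
        assert row.at["COPY", "rho"] == pytest.approx(1.0)
        assert bool(row.at["COPY", "partner"])
        assert not bool(row.at["OTHER", "partner"])

    def test_identical_compound_sets_force_rho_one(self):
        from tascore.network import make_edge_frame

        edges = make_edge_frame(
            [
                {"compound_id": c, "target_id": t, "source": "curated"}
                for c in ("c1", "c2", "c3")
                for t in ("TA", "TB")
            ]
        ).assign(sources="curated")[["compound_id", "target_id", "sources"]]
        net = tc.TargetNetwork(edges=edges)
        rng = np.random.default_rng(2)
        dr = pd.DataFrame(
            rng.uniform(0, 30, (10, 3)),
            index=[f"s{i}" for i in range(10)],
            columns=["c1", "c2", "c3"],
        )
        tas = tc.compute_tas(tc.ResponseMatrix(data=dr, metric="DSS"), net)
        table = tc.coaddiction(tas, "TA", network=net).set_index("target_id")
        assert table.at["TB", "rho"] == pytest.approx(1.0)
        assert table.at["TB", "shared_compounds"] == 3

    def test_rho_is_symmetric_between_anchor_choices(self):
        rng = np.random.default_rng(3)
        df = tas_frame({"T1": rng.normal(size=30), "T2": rng.normal(size=30)})
        ab = tc.coaddiction(df, "T1", min_samples=5).set_index("target_id").at["T2", "rho"]
        ba = tc.coaddiction(df, "T2", min_samples=5).set_index("target_id").at["T1", "rho"]
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_bonferroni_never_decreases_and_caps(self):
        rng = np.random.default_rng(4)
        df = tas_frame({f"T{i}": rng.normal(size=15) for i in range(8)})
        table = tc.coaddiction(df, "T0")
        assert (table["p_bonferroni"] >= table["p_raw"] - 1e-15).all()
        assert (table["p_bonferroni"] <= 1.0).all()

    def test_constant_anchor_rejected(self):
        df = tas_frame({"T1": [1.0] * 6, "T2": [1, 2, 3, 4, 5, 6]})
        with pytest.raises(UndefinedCorrelationError):
            tc.coaddiction(df, "T1")

    def test_pairwise_complete_skips_sparse_targets(self, caplog):
        rng = np.random.default_rng(5)
        df = tas_frame({"T1": rng.normal(size=10), "T2": rng.normal(size=10)})
        df.loc[df.index[:7], "T2"] = np.nan
        with caplog.at_level("WARNING", logger="tascore.cohort"):
            with pytest.raises(InvalidConfigError):
                tc.coaddiction(df, "T1")  # only sparse T2 to test -> nothing testable
        assert "shared samples" in caplog.text
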
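"""Synapse filtering and connectivity-matrix construction."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from synvar.filtering import (
    SYNAPSE_COLUMNS,
    UNKNOWN,
    aggregate_counts,
    apply_partner_threshold,
    build_connectivity_matrix,
    deduplicate_synapses,
    filter_by_cleft_score,
    filter_by_presence,
    run_pipeline,
)

from conftest import matrix_from_frame, random_synapse_table


def _table(rows):
    return pd.DataFrame(rows, columns=SYNAPSE_COLUMNS)


def _syn(pre, post, x, score, y=0.0, z=0.0):
    return {
        "pre_segment_id": pre,
        "post_cell_id": post,
        "x_nm": x,
        "y_nm": y,
        "z_nm": z,
        "cleft_score": score,
        "compartment": "dendritic",
    }


class TestCleftFilter:
    def test_boundary_is_inclusive(self):
        t = _table([_syn("a", "T", 0, 49.9), _syn("a", "T", 200, 50.0),
                    _syn("a", "T", 400, 80.0)])
        out = filter_by_cleft_score(t, 50.0)
        assert out["cleft_score"].tolist() == [50.0, 80.0]

    def test_zero_threshold_is_identity(self):
        t = _table([_syn("a", "T", 0, 10), _syn("b", "T", 100, 90)])
        assert_frame_equal(filter_by_cleft_score(t, 0.0), t)

    def test_all_below_gives_empty(self):
        t = _table([_syn("a", "T", 0, 10)])
        assert filter_by_cleft_score(t, 50).empty


def brute_force_dedup(table, radius):
    """Exhaustive all-pairs greedy oracle: per connection, retain in
    descending score order any synapse >= radius from all retained."""
    keep = []
    for (pre, post), grp in table.groupby(
        ["pre_segment_id", "post_cell_id"], sort=False
    ):
        order = sorted(
            grp.index, key=lambda i: (-table.loc[i, "cleft_score"], i)
        )
        retained = []
        for i in order:
            pi = table.loc[i, ["x_nm", "y_nm", "z_nm"]].to_numpy(float)
            if all(
                np.linalg.norm(
                    pi - table.loc[j, ["x_nm", "y_nm", "z_nm"]].to_numpy(float)
                )
                >= radius
                for j in retained
            ):
                retained.append(i)
        keep.extend(retained)
    return table.loc[sorted(keep)]


class TestDeduplication:
    def test_keeps_higher_score_of_close_pair(self):
        t = _table([_syn("a", "T", 0, 60), _syn("a", "T", 50, 90)])
        out = deduplicate_synapses(t, 100)
        assert out["cleft_score"].tolist() == [90]

    def test_exact_radius_pair_both_retained(self):
        t = _table([_syn("a", "T", 0, 60), _syn("a", "T", 100, 90)])
        assert len(deduplicate_synapses(t, 100)) == 2

    def test_different_connections_never_interact(self):
        t = _table([_syn("a", "T", 0, 60), _syn("b", "T", 10, 90)])
        assert len(deduplicate_synapses(t, 100)) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = random_synapse_table(rng, int(rng.integers(5, 31)))
        out = deduplicate_synapses(t, 100)
        oracle = brute_force_dedup(t, 100)
        assert_frame_equal(out, oracle)

    def test_idempotent(self):
        rng = np.random.default_rng(99)
        t = random_synapse_table(rng, 30)
        once = deduplicate_synapses(t, 100)
        assert_frame_equal(deduplicate_synapses(once, 100), once)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            deduplicate_synapses(_table([]), -1.0)


class TestAggregation:
    def test_two_cells_sum_to_type_count_and_multiplicity(self):
        rows = [_syn("d1", "T", i * 200, 80) for i in range(4)]
        rows += [_syn("d2", "T", 5000 + i * 200, 80) for i in range(6)]
        ann = pd.DataFrame(
            {"segment_id": ["d1", "d2"], "type_label": ["Dm12", "Dm12"],
             "hemisphere": ["R", "R"]}
        )
        agg = aggregate_counts(_table(rows), ann)
        assert agg.type_counts.loc["T", "Dm12"] == 10
        assert agg.multiplicity.loc["T", "Dm12"] == 2

    def test_empty_table_gives_zero_counts(self):
        agg = aggregate_counts(
            _table([]), pd.DataFrame({"segment_id": [], "type_label": []})
        )
        assert agg.total_synapses == 0

    def test_unannotated_segments_go_to_unknown(self):
        rows = [_syn("x", "T", i * 200, 80) for i in range(3)]
        agg = aggregate_counts(
            _table(rows), pd.DataFrame({"segment_id": [], "type_label": []})
        )
        assert agg.type_counts.loc["T", UNKNOWN] == 3


class TestPartnerThreshold:
    def test_zeroes_counts_below_threshold(self):
        rows = (
            [_syn("a", "T", i * 200, 80) for i in range(2)]
            + [_syn("b", "T", 2000 + i * 200, 80) for i in range(3)]
            + [_syn("c", "T", 4000 + i * 200, 80) for i in range(5)]
        )
        ann = pd.DataFrame(
            {"segment_id": list("abc"), "type_label": ["A", "B", "C"]}
        )
        agg = apply_partner_threshold(aggregate_counts(_table(rows), ann), 3)
        assert sorted(agg.cell_counts["count"].tolist()) == [0, 3, 5]
        assert agg.type_counts.loc["T"].sum() == 8

    def test_min_one_is_identity(self):
        rows = [_syn("a", "T", 0, 80)]
        ann = pd.DataFrame({"segment_id": ["a"], "type_label": ["A"]})
        agg = aggregate_counts(_table(rows), ann)
        assert_frame_equal(
            apply_partner_threshold(agg, 1).type_counts, agg.type_counts
        )

    def test_invalid_threshold_rejected(self):
        rows = [_syn("a", "T", 0, 80)]
        ann = pd.DataFrame({"segment_id": ["a"], "type_label": ["A"]})
        with pytest.raises(ValueError):
            apply_partner_threshold(aggregate_counts(_table(rows), ann), 0)


class TestConnectivityMatrix:
    def _agg(self):
        rows = (
            [_syn("l", "T", i * 200, 80) for i in range(25)]
            + [_syn("m", "T", 20000 + i * 200, 80) for i in range(13)]
            + [_syn("c", "T", 40000 + i * 200, 80) for i in range(15)]
        )
        ann = pd.DataFrame(
            {"segment_id": ["l", "m", "c"], "type_label": ["L3", "Mi4", "CT1"]}
        )
        return aggregate_counts(_table(rows), ann)

    def test_relative_mode_divides_by_row_total(self):
        m = build_connectivity_matrix(self._agg(), "relative")
        row = m.data.loc["T"]
        assert row["L3"] == pytest.approx(25 / 53, abs=5e-4)
        assert row["Mi4"] == pytest.approx(13 / 53, abs=5e-4)
        assert row["CT1"] == pytest.approx(15 / 53, abs=5e-4)
        assert row.sum() == pytest.approx(1.0)

    def test_binary_mode_is_presence_indicator(self):
        m = build_connectivity_matrix(self._agg(), "binary")
        assert set(m.data.loc["T"]) == {1}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            build_connectivity_matrix(self._agg(), "fancy")


class TestPresenceFilter:
    def test_drops_rare_types(self):
        data = pd.DataFrame(
            {"common": [1] * 100, "rare": [1] * 4 + [0] * 96}
        )
        out = filter_by_presence(matrix_from_frame(data), 0.05)
        assert out.types == ["common"]

    def test_boundary_fraction_retained(self):
        data = pd.DataFrame({"a": [1] * 5 + [0] * 95, "b": [1] * 100})
        out = filter_by_presence(matrix_from_frame(data), 0.05)
        assert "a" in out.types

    def test_zero_cut_is_identity(self):
        data = pd.DataFrame({"a": [0, 1], "b": [1, 1]})
        out = filter_by_presence(matrix_from_frame(data), 0.0)
        assert out.types == ["a", "b"]


class TestPipelineOnSyntheticData:
    def test_counts_match_planted_ground_truth(self, small_pipeline):
        matrix, agg, deduped, truth = small_pipeline
        tc = agg.type_counts.drop(columns=[UNKNOWN], errors="ignore")
        planted = truth.planted_counts.reindex(
            index=tc.index, columns=tc.columns
        ).fillna(0).astype(int)
        assert_frame_equal(tc, planted, check_names=False)

    def test_multiplicities_match_ground_truth(self, small_pipeline):
        matrix, agg, _, truth = small_pipeline
        mult = agg.multiplicity.drop(columns=[UNKNOWN], errors="ignore")
        planted = truth.cell_multiplicity.reindex(
            index=mult.index, columns=mult.columns
        ).fillna(0).astype(int)
        assert_frame_equal(mult, planted, check_names=False)

    def test_conservation_identity(self, small_pipeline):
        # matrix total + UNKNOWN + sub-threshold = post-dedup synapse count
        _, agg, deduped, truth = small_pipeline
        dropped = truth.subthreshold_total
        assert agg.type_counts.to_numpy().sum() + dropped == len(deduped)

    def test_dedup_restores_planted_synapse_count(self, small_pipeline):
        _, _, deduped, truth = small_pipeline
        assert len(deduped) == truth.n_true_synapses

    def test_pipeline_idempotent_on_own_output(self, small_pipeline):
        _, _, deduped, _ = small_pipeline
        again = deduplicate_synapses(
            filter_by_cleft_score(deduped, 50), 100
        )
        assert_frame_equal(again, deduped)

    def test_all_synapses_annotated_when_no_unknown_planted(self, small_pipeline):
        _, agg, _, _ = small_pipeline
        if UNKNOWN in agg.type_counts.columns:
            assert agg.type_counts[UNKNOWN].sum() == 0
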
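import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ptyrlink import preprocess
from ptyrlink.preprocess import (
    FilterThresholds,
    PresenceRule,
    basal_log2fc,
    bridge_normalize,
    bridge_ratio,
    filter_psms,
    loading_normalize,
    presence_filter,
    replicate_mean,
    rollup_peptides,
)
from ptyrlink.types import BRIDGE, PhosphoMatrix, PlexDesign, PtyrlinkError, \
    sample_columns

from conftest import make_psm, simple_design


class TestFilterPsms:
    @pytest.mark.parametrize(
        "kwargs,kept,rules",
        [
            # boundary enumeration: all thresholds are strict
            (dict(score=15.0), False, ["score"]),
            (dict(score=15.0 + 1e-9), True, []),
            (dict(interference=40.0), False, ["interference"]),
            (dict(interference=39.9), True, []),
            (dict(rank=2), False, ["rank"]),
            (dict(intensities=(1000.0,) * 10), False, ["low_signal"]),
            (dict(intensities=(1001.0,) * 10), True, []),
            (dict(intensities=(float("nan"),) + (5000.0,) * 9), False,
             ["missing_channel"]),
            # one record can fail several rules at once
            (dict(rank=3, score=2.0), False, ["rank", "score"]),
        ],
    )
    def test_threshold_boundaries(self, kwargs, kept, rules):
        record = make_psm(**kwargs)
        result, audit = filter_psms([record])
        assert (len(result) == 1) is kept
        for rule in rules:
            assert audit.rejections[rule] == 1
        untouched = set(preprocess.FILTER_RULES) - set(rules)
        assert all(audit.rejections[r] == 0 for r in untouched)

    def test_borderline_keeper(self):
        # passes every rule with minimal margin on all four
        record = make_psm(rank=1, score=40.0, interference=39.9,
                          intensities=(1001.0,) * 10)
        kept, audit = filter_psms([record])
        assert len(kept) == 1 and audit.n_kept == 1

    def test_empty_input(self):
        kept, audit = filter_psms([])
        assert kept == []
        assert audit.n_input == 0
        assert all(v == 0 for v in audit.rejections.values())

    def test_missing_channel_rule_can_be_disabled(self):
        record = make_psm(intensities=(float("nan"),) + (5000.0,) * 9)
        kept, _ = filter_psms(
            [record], FilterThresholds(drop_any_missing_channel=False)
        )
        assert len(kept) == 1

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 3),
                st.floats(0, 100, allow_nan=False),
                st.floats(0, 100, allow_nan=False),
                st.floats(1, 1e7, allow_nan=False),
            ),
            max_size=30,
        )
    )
    def test_filter_is_idempotent(self, raw):
        psms = [
            make_psm(peptide=f"P{i}_Y1", rank=r, score=s, interference=f,
                     intensities=(sig,) * 10)
            for i, (r, s, f, sig) in enumerate(raw)
        ]
        once, _ = filter_psms(psms)
        twice, audit = filter_psms(once)
        assert twice == once
        assert audit.n_kept == audit.n_input


class TestRollup:
    def test_single_psm_row_equals_reporter_vector(self):
        design = simple_design()
        psm = make_psm()
        matrix = rollup_peptides([psm], design)
        np.testing.assert_array_equal(
            matrix.values.loc[psm.peptide_id].to_numpy(),
            np.asarray(psm.reporter_intensity),
        )

    def test_same_peptide_psms_are_summed(self):
        design = simple_design()
        a = make_psm(intensities=(100.0,) * 10)
        b = make_psm(intensities=(250.0,) * 10)
        matrix = rollup_peptides([a, b], design)
        assert matrix.values.loc[a.peptide_id, 0] == 350.0

    def test_site_isoforms_stay_distinct(self):
        design = simple_design()
        single = make_psm(peptide="SEQ_Y187")
        double = make_psm(peptide="SEQ_T185_Y187")
        matrix = rollup_peptides([single, double], design)
        assert sorted(matrix.values.index) == ["SEQ_T185_Y187", "SEQ_Y187"]

    def test_run_mismatch_raises(self):
        design = simple_design(run="runA")
        with pytest.raises(PtyrlinkError, match="runB"):
            rollup_peptides([make_psm(run="runB")], design)

    def test_row_order_invariance(self):
        design = simple_design()
        psms = [
            make_psm(peptide=f"P{i % 3}_Y1", intensities=(float(i + 1),) * 10)
            for i in range(6)
        ]
        forward = rollup_peptides(psms, design)
        backward = rollup_peptides(psms[::-1], design)
        pd.testing.assert_frame_equal(forward.values, backward.values)

    def test_protein_rollup_keyed_by_protein(self):
        design = simple_design()
        psms = [
            make_psm(peptide="A_Y1", protein="P1",
                     intensities=(10.0,) * 10),
            make_psm(peptide="B_Y2", protein="P1",
                     intensities=(5.0,) * 10),
        ]
        matrix = rollup_peptides(psms, design, key="protein_id")
        assert list(matrix.values.index) == ["P1"]
        assert matrix.values.loc["P1", 0] == 15.0


class TestLoadingNormalize:
    def _matrix(self, values):
        return PhosphoMatrix(
            values=pd.DataFrame(values, index=["pep_Y1"], columns=range(10)),
            stage="raw_intensity",
            run_id="run1",
        )

    def test_equal_medians_identity(self):
        m = self._matrix([[float(i + 1) for i in range(10)]])
        out = loading_normalize(m, np.full(10, 7.0))
        pd.testing.assert_frame_equal(out.values, m.values)
        assert out.stage == "loading_normalized"

    def test_double_loaded_channel_is_corrected(self):
        # equal-abundance peptide; channel 0 loaded at 2x the others
        med = np.ones(10)
        med[0] = 2.0
        intensities = np.ones(10) * 1e4
        intensities[0] *= 2.0
        m = self._matrix([list(intensities)])
        out = loading_normalize(m, med)
        vals = out.values.to_numpy()[0]
        assert np.allclose(vals, vals[0])

    def test_nonpositive_median_errors(self):
        m = self._matrix([[1.0] * 10])
        med = np.ones(10)
        med[3] = 0.0
        with pytest.raises(PtyrlinkError, match="positive"):
            loading_normalize(m, med)


def _run_matrix(peptides, values, run_id="run1"):
    return PhosphoMatrix(
        values=pd.DataFrame(values, index=peptides, columns=range(10),
                            dtype=float),
        stage="loading_normalized",
        run_id=run_id,
    )


class TestBridgeAndBasal:
    def test_bridge_channel_becomes_one(self):
        design = simple_design(bridge_channel=9)
        m = _run_matrix(["p_Y1"], [[float(100 + i) for i in range(10)]])
        ratio = bridge_ratio(m, design)
        assert ratio.values.loc["p_Y1", 9] == 1.0

    def test_global_run_scaling_cancels(self):
        # run B is a 3x-scaled duplicate of run A
        base = [[float((i + 1) * 10) for i in range(10)]]
        designs = {
            "A": simple_design(run="A", replicate=1),
            "B": simple_design(run="B", replicate=2),
        }
        runs = {
            "A": _run_matrix(["p_Y1"], base, run_id="A"),
            "B": _run_matrix(["p_Y1"], [[3.0 * v for v in base[0]]],
                             run_id="B"),
        }
        merged = bridge_normalize(runs, designs)
        rep1 = merged.values.xs(1, axis=1, level="replicate")
        rep2 = merged.values.xs(2, axis=1, level="replicate")
        np.testing.assert_allclose(rep1.to_numpy(), rep2.to_numpy(),
                                   rtol=1e-12)

    def test_peptide_absent_from_one_run_is_missing_there(self):
        designs = {
            "A": simple_design(run="A", replicate=1),
            "B": simple_design(run="B", replicate=2),
        }
        runs = {
            "A": _run_matrix(["p_Y1", "q_Y2"],
                             [[1000.0] * 10, [500.0] * 10], run_id="A"),
            "B": _run_matrix(["p_Y1"], [[1000.0] * 10], run_id="B"),
        }
        merged = bridge_normalize(runs, designs)
        q = merged.values.loc["q_Y2"]
        assert q.xs(1, level="replicate").notna().all()
        assert q.xs(2, level="replicate").isna().all()

    def test_missing_bridge_value_blanks_run(self):
        design = simple_design(bridge_channel=9)
        vals = [[1000.0] * 9 + [np.nan]]
        m = _run_matrix(["p_Y1"], vals)
        ratio = bridge_ratio(m, design)
        assert ratio.values.loc["p_Y1"].isna().all()

    def _bridged(self, data, keys):
        return PhosphoMatrix(
            values=pd.DataFrame(data, index=["p_Y1"],
                                columns=sample_columns(keys)),
            stage="bridged",
        )

    def test_log2fc_hand_values(self):
        keys = [("WT", 0, 1), ("WT", 30, 1), ("WT", 60, 1)]
        m = self._bridged([[4.0, 8.0, 1.0]], keys)
        out = basal_log2fc(m)
        row = out.values.loc["p_Y1"]
        assert row[("WT", 0, 1)] == 0.0
        assert row[("WT", 30, 1)] == 1.0  # ratio 2
        assert row[("WT", 60, 1)] == -2.0  # ratio 0.25

    def test_missing_basal_blanks_trajectory(self):
        keys = [("WT", 30, 1), ("WT", 60, 1), ("M", 0, 1), ("M", 30, 1)]
        m = self._bridged([[8.0, 2.0, 1.0, 2.0]], keys)
        out = basal_log2fc(m)
        row = out.values.loc["p_Y1"]
        assert row[("WT", 30, 1)] != row[("WT", 30, 1)] or \
            math.isnan(row[("WT", 30, 1)])
        assert row[("M", 30, 1)] == 1.0

    def test_scale_invariance_of_log2fc(self, clean_study):
        """Multiplying one run's intensities by c>0 leaves log2FC unchanged."""
        from conftest import preprocess_study

        ref_fc, _ = preprocess_study(clean_study)
        rid = clean_study.run_ids()[0]
        scaled_tables = dict(clean_study.psm_tables)
        scaled_tables[rid] = [
            make_psm(
                peptide=r.peptide_id, run=r.run_id, rank=r.search_rank,
                score=r.ion_score, interference=r.isolation_interference_pct,
                intensities=tuple(4.0 * v for v in r.reporter_intensity),
                protein=r.protein_id,
            )
            for r in clean_study.psm_tables[rid]
        ]

        class _Scaled:
            psm_tables = scaled_tables
            designs = clean_study.designs
            crude_medians = clean_study.crude_medians

        fc, _ = preprocess_study(_Scaled)
        pd.testing.assert_frame_equal(fc.values, ref_fc.values)


class TestReplicateMeanAndPresence:
    def _log2fc(self, data, keys, peptides=None):
        return PhosphoMatrix(
            values=pd.DataFrame(data, index=peptides or ["p_Y1"],
                                columns=sample_columns(keys)),
            stage="log2fc",
        )

    def test_mean_and_counts(self):
        keys = [("WT", 30, 1), ("WT", 30, 2), ("WT", 30, 3)]
        m = self._log2fc([[0.5, 1.5, np.nan]], keys)
        out = replicate_mean(m)
        assert out.values.loc["p_Y1", ("WT", 30)] == 1.0
        assert out.replicate_counts.loc["p_Y1", ("WT", 30)] == 2

    def test_all_missing_stays_missing(self):
        keys = [("WT", 30, 1), ("WT", 30, 2)]
        m = self._log2fc([[np.nan, np.nan]], keys)
        out = replicate_mean(m)
        assert math.isnan(out.values.loc["p_Y1", ("WT", 30)])

    def test_presence_filter_against_exhaustive_count(self):
        rng = np.random.default_rng(17)
        lines = ["WT", "M1", "M2"]
        tps = [0, 30, 60]
        reps = [1, 2, 3]
        keys = [(l, t, r) for l in lines for t in tps for r in reps]
        peptides = [f"pep{i}_Y1" for i in range(40)]
        data = rng.normal(size=(40, len(keys)))
        drop = rng.random(data.shape) < 0.25
        data[drop] = np.nan
        m = self._log2fc(data, keys, peptides=peptides)
        rule = PresenceRule(min_replicates_per_condition=2,
                            require_all_conditions=True)
        kept = set(presence_filter(m, rule).values.index)

        expected = set()
        for i, pep in enumerate(peptides):
            ok = True
            for l in lines:
                for t in tps:
                    n = sum(
                        not math.isnan(data[i, keys.index((l, t, r))])
                        for r in reps
                    )
                    if n < 2:
                        ok = False
            if ok:
                expected.add(pep)
        assert kept == expected

    def test_fully_absent_condition_drops_peptide(self):
        keys = [("WT", 0, 1), ("WT", 30, 1), ("M", 0, 1), ("M", 30, 1)]
        data = [[0.0, 1.0, np.nan, np.nan], [0.0, 1.0, 0.0, 0.5]]
        m = self._log2fc(data, keys, peptides=["gone_Y1", "kept_Y1"])
        rule = PresenceRule(min_replicates_per_condition=1,
                            require_all_conditions=True)
        out = presence_filter(m, rule)
        assert list(out.values.index) == ["kept_Y1"]
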
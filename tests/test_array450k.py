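import numpy as np
import pandas as pd
import pytest

from clustermeth.array450k import ProbeMatrix, differential_cpgs, merge_flagged_cpgs, qc_filter_probes
from clustermeth.params import PipelineParams


def small_matrix(betas, det_p=None, beads=None, n_carrier=None):
    betas = pd.DataFrame(betas)
    betas.index = [f"cg{i:03d}" for i in range(len(betas))]
    betas.columns = [f"s{j}" for j in range(betas.shape[1])]
    if det_p is None:
        det_p = pd.DataFrame(0.001, index=betas.index, columns=betas.columns)
    else:
        det_p = pd.DataFrame(np.asarray(det_p), index=betas.index, columns=betas.columns)
    if beads is None:
        beads = pd.DataFrame(10, index=betas.index, columns=betas.columns)
    else:
        beads = pd.DataFrame(np.asarray(beads), index=betas.index, columns=betas.columns)
    n_carrier = betas.shape[1] // 2 if n_carrier is None else n_carrier
    groups = pd.Series(
        ["carrier"] * n_carrier + ["control"] * (betas.shape[1] - n_carrier),
        index=betas.columns,
    )
    return ProbeMatrix(betas=betas, det_p=det_p, beads=beads, groups=groups)


class TestQcFilter:
    def test_detection_p_above_threshold_masked_boundary_kept(self):
        m = small_matrix([[0.5, 0.6]], det_p=[[0.02, 0.01]])
        filtered, report = qc_filter_probes(m, max_missing_frac=0.99)
        assert np.isnan(filtered.betas.iloc[0, 0])
        assert filtered.betas.iloc[0, 1] == 0.6
        assert report["n_entries_masked_detection_p"] == 1

    def test_bead_count_below_three_masked_boundary_kept(self):
        m = small_matrix([[0.5, 0.6]], beads=[[2, 3]])
        filtered, report = qc_filter_probes(m, max_missing_frac=0.99)
        assert np.isnan(filtered.betas.iloc[0, 0])
        assert filtered.betas.iloc[0, 1] == 0.6
        assert report["n_entries_masked_beads"] == 1

    def test_fully_missing_probe_dropped(self):
        m = small_matrix([[0.5] * 20, [0.4] * 20], det_p=[[0.5] * 20, [0.001] * 20])
        filtered, report = qc_filter_probes(m)
        assert list(filtered.betas.index) == ["cg001"]
        assert report["n_probes_removed_low_success"] == 1

    def test_ambiguous_probes_removed_entirely(self):
        m = small_matrix([[0.5, 0.5], [0.4, 0.4]])
        filtered, report = qc_filter_probes(m, ambiguous={"cg000"})
        assert list(filtered.betas.index) == ["cg001"]
        assert report["n_probes_removed_ambiguous"] == 1

    def test_surviving_values_never_altered(self):
        rng = np.random.default_rng(0)
        betas = rng.random((50, 8))
        det_p = np.where(rng.random((50, 8)) < 0.2, 0.05, 0.001)
        m = small_matrix(betas, det_p=det_p)
        filtered, _ = qc_filter_probes(m)
        vals = filtered.betas.to_numpy()
        orig = m.betas.loc[filtered.betas.index].to_numpy()
        surviving = ~np.isnan(vals)
        assert (vals[surviving] == orig[surviving]).all()

    def test_missingness_evaluated_after_masking(self):
        # detection-P failures alone push the probe over 95% missing
        det_p = [[0.05] * 20]
        m = small_matrix([[0.5] * 20], det_p=det_p)
        filtered, report = qc_filter_probes(m)
        assert len(filtered.betas) == 0
        assert report["n_probes_removed_low_success"] == 1


class TestProbeMatrixInvariants:
    def test_beta_range_checked(self):
        with pytest.raises(ValueError, match="beta"):
            small_matrix([[1.5, 0.2]])

    def test_shape_mismatch_checked(self):
        betas = pd.DataFrame([[0.5, 0.5]], index=["cg0"], columns=["a", "b"])
        det_p = pd.DataFrame([[0.001]], index=["cg0"], columns=["a"])
        beads = pd.DataFrame([[10, 10]], index=["cg0"], columns=["a", "b"])
        groups = pd.Series(["carrier", "control"], index=["a", "b"])
        with pytest.raises(ValueError, match="shape"):
            ProbeMatrix(betas=betas, det_p=det_p, beads=beads, groups=groups)


class TestDifferentialCpgs:
    def test_delta_below_5_percent_never_flagged(self):
        rng = np.random.default_rng(1)
        betas = np.clip(
            np.concatenate(
                [rng.normal(0.50, 0.001, (1, 10)), rng.normal(0.47, 0.001, (1, 10))], axis=1
            ),
            0, 1,
        )
        m = small_matrix(betas, n_carrier=10)
        res = differential_cpgs(m)
        assert res["fdr"].iloc[0] < 0.05  # highly significant...
        assert abs(res["delta"].iloc[0]) < 0.05  # ...but below the delta rule
        assert not res["is_differential"].iloc[0]

    def test_zero_variance_equal_groups_get_p_one(self):
        m = small_matrix([[0.5] * 10, [0.2] * 5 + [0.8] * 5], n_carrier=5)
        res = differential_cpgs(m)
        assert res["p_value"].loc["cg000"] == 1.0
        assert not res["is_differential"].loc["cg000"]

    def test_untestable_probe_reported_with_missing_p(self):
        betas = pd.DataFrame(
            [[np.nan, np.nan, 0.5, 0.5, 0.6, 0.6], [0.9, 0.9, 0.9, 0.2, 0.2, 0.2]],
            index=["cg000", "cg001"],
            columns=[f"s{j}" for j in range(6)],
        ).astype(float)
        m = small_matrix(betas.to_numpy(), n_carrier=3)
        res = differential_cpgs(m)
        assert np.isnan(res["p_value"].loc["cg000"]) and not res["is_differential"].loc["cg000"]
        assert res["is_differential"].loc["cg001"]

    def test_all_untestable_is_an_error(self):
        betas = np.full((3, 6), np.nan)
        betas[:, 3:] = 0.5
        m = small_matrix(betas, n_carrier=3)
        with pytest.raises(ValueError, match="testable"):
            differential_cpgs(m)

    def test_null_probes_rarely_flagged_under_bh(self):
        rng = np.random.default_rng(2)
        betas = np.clip(rng.normal(0.5, 0.03, (100, 20)), 0, 1)
        res = differential_cpgs(small_matrix(betas, n_carrier=10))
        assert res["is_differential"].sum() == 0

    def test_bh_is_monotone_in_raw_p(self):
        rng = np.random.default_rng(3)
        betas = np.clip(rng.normal(0.5, 0.05, (200, 12)), 0, 1)
        res = differential_cpgs(small_matrix(betas, n_carrier=6)).dropna()
        by_p = res.sort_values("p_value")["fdr"].to_numpy()
        assert (np.diff(by_p) >= -1e-12).all()

    def test_mvalue_scale_agrees_on_strong_signal(self):
        rng = np.random.default_rng(4)
        betas = np.clip(rng.normal(0.7, 0.02, (50, 20)), 0, 1)
        betas[:5, :10] -= 0.3  # carriers hypomethylated at 5 probes
        m = small_matrix(betas, n_carrier=10)
        flagged_beta = set(differential_cpgs(m).query("is_differential").index)
        flagged_m = set(differential_cpgs(m, value_scale="mvalue").query("is_differential").index)
        assert flagged_beta == flagged_m == {f"cg{i:03d}" for i in range(5)}


class TestMergeFlaggedCpgs:
    def test_proximity_grouping_of_flagged_probes(self):
        res = pd.DataFrame(
            {"is_differential": [True, True, False, True]},
            index=["cg000", "cg001", "cg002", "cg003"],
        )
        probes = pd.DataFrame(
            {"chrom": ["chr1"] * 4, "pos": [1000, 3000, 5000, 20000]},
            index=res.index,
        )
        out = merge_flagged_cpgs(res, probes, merge_bp=5000)
        assert out.to_dict("records") == [
            {"chrom": "chr1", "start": 1000, "end": 3000, "n_cpgs": 2},
            {"chrom": "chr1", "start": 20000, "end": 20000, "n_cpgs": 1},
        ]
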
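import warnings

import numpy as np
import pandas as pd
import pytest

import nucleoquant as nq
from nucleoquant.errors import ContractError
from nucleoquant.synthetic import _ellipse_mask


def _square_cell(shape=(48, 48)):
    nuc = np.zeros(shape, dtype=np.int32)
    nuc[8:40, 8:40] = 1
    nol = np.zeros(shape, dtype=np.int32)
    nol[18:28, 18:28] = 1
    return nq.LabelMask(nuc), nq.LabelMask(nol)


class TestDetectNucleoliPhase:
    def test_uniform_phase_gives_none(self):
        nuc, _ = _square_cell()
        phase = np.full((48, 48), 120.0)
        nols, parent = nq.detect_nucleoli_phase(phase, nuc)
        assert nols.n_objects == 0 and parent == {}

    def test_dark_disk_area_within_10pct(self):
        shape = (96, 96)
        nuc = np.zeros(shape, dtype=np.int32)
        nuc[_ellipse_mask(shape, 48, 48, 38, 38)] = 1
        phase = np.where(nuc > 0, 150.0, 120.0)
        disk = _ellipse_mask(shape, 48, 48, 10, 10)
        phase[disk] = 60.0
        nols, parent = nq.detect_nucleoli_phase(phase, nq.LabelMask(nuc))
        assert nols.n_objects == 1
        assert parent == {1: 1}
        assert (nols.labels > 0).sum() == pytest.approx(disk.sum(), rel=0.10)

    def test_two_disks_share_one_parent(self):
        shape = (96, 96)
        nuc = np.zeros(shape, dtype=np.int32)
        nuc[_ellipse_mask(shape, 48, 48, 40, 40)] = 1
        phase = np.where(nuc > 0, 150.0, 120.0)
        phase[_ellipse_mask(shape, 36, 36, 8, 8)] = 60.0
        phase[_ellipse_mask(shape, 62, 58, 8, 8)] = 60.0
        nols, parent = nq.detect_nucleoli_phase(phase, nq.LabelMask(nuc))
        assert nols.n_objects == 2
        assert set(parent.values()) == {1}


class TestExcludeObjects:
    def _features(self):
        rows = []
        for cid, areas in [(1, [400, 398, 401]), (2, [420, 415, 418]),
                           (3, [410, 200, 150])]:  # cell 3 collapses
            for f, a in enumerate(areas):
                rows.append({"cell_id": cid, "frame": f, "area": a,
                             "eccentricity": 0.5, "mean_intensity": 100.0})
        return pd.DataFrame(rows)

    def test_identity_when_within_bounds(self):
        feats = self._features()[lambda d: d.cell_id != 3]
        out, log = nq.exclude_objects(feats, {"max_area_drop": 0.4})
        pd.testing.assert_frame_equal(out, feats)
        assert log.empty

    def test_area_collapse_excluded_for_all_frames(self):
        out, log = nq.exclude_objects(self._features(), {"max_area_drop": 0.4})
        assert 3 not in out.cell_id.values
        assert log.cell_id.tolist() == [3]
        assert "area_collapse" in log.reason.iloc[0]

    def test_exclusion_leaves_other_cells_untouched(self):
        feats = self._features()
        out, _ = nq.exclude_objects(feats, {"max_area_drop": 0.4})
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True),
            feats[feats.cell_id != 3].reset_index(drop=True),
        )

    def test_unknown_rule_rejected(self):
        with pytest.raises(ContractError):
            nq.exclude_objects(self._features(), {"bogus": 1})


class TestRatioTimeseries:
    def test_uniform_fluorescence_gives_ratio_one(self):
        nuc, nol = _square_cell()
        fluor = np.full((4, 48, 48), 55.0)
        out = nq.ratio_timeseries(fluor, [nuc] * 4, [nol] * 4)
        assert len(out) == 4
        np.testing.assert_allclose(out.ratio, 1.0)

    def test_invariant_to_per_frame_rescaling(self):
        nuc, nol = _square_cell()
        rng = np.random.default_rng(8)
        fluor = rng.uniform(50, 150, (3, 48, 48))
        a = nq.ratio_timeseries(fluor, [nuc] * 3, [nol] * 3)
        scale = np.array([2.0, 0.5, 17.0])[:, None, None]
        b = nq.ratio_timeseries(fluor * scale, [nuc] * 3, [nol] * 3)
        np.testing.assert_allclose(a.ratio, b.ratio)

    def test_tracking_assigns_stable_ids(self):
        nuc, nol = _square_cell()
        fluor = np.full((5, 48, 48), 10.0)
        out = nq.ratio_timeseries(fluor, [nuc] * 5, [nol] * 5)
        assert out.nucleolus_id.nunique() == 1
        assert out.cell_id.nunique() == 1

    def test_pipeline_recovers_programmed_enrichment(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack, truth = nq.gen_timelapse(
                4, 8, r0=1.4, group="control", shape=(192, 192), seed=51
            )
            fluor = stack.channel("gfp")[:, 0]
            phase = stack.channel("phase")[:, 0]
            nuc_frames, nol_frames = [], []
            for f in range(8):
                nuclei = nq.segment_nuclei(fluor[f])
                nols, _ = nq.detect_nucleoli_phase(phase[f], nuclei)
                nuc_frames.append(nuclei)
                nol_frames.append(nols)
            out = nq.ratio_timeseries(fluor, nuc_frames, nol_frames)
        assert out.ratio.mean() == pytest.approx(1.4, abs=0.05)

    def test_depletion_conserves_total_and_raises_nucleoplasm(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack, truth = nq.gen_timelapse(
                2, 16, t0=4, tau=4, group="treated", shape=(128, 128),
                seed=52, noise_sigma=0.0,
            )
        gfp = stack.channel("gfp")[:, 0]
        cell = truth.object_params["cells"][0]
        nuc = _ellipse_mask((128, 128), *cell["center"], *cell["radii"])
        nol = np.zeros((128, 128), bool)
        for sub in cell["nucleoli"]:
            nol |= _ellipse_mask((128, 128), *sub["center"], sub["radius"], sub["radius"])
        nol &= nuc
        nucleoplasm = gfp[:, nuc & ~nol].mean(axis=1)
        nucleolar = gfp[:, nol].mean(axis=1)
        assert nucleoplasm[-1] > nucleoplasm[0]
        assert nucleolar[-1] < nucleolar[0]
        totals = gfp[:, nuc].sum(axis=1)
        assert np.ptp(totals) / totals[0] < 1e-6


def _balanced_example():
    """Small balanced split-plot dataset with fixed seeded values."""
    rng = np.random.default_rng(123)
    rows = []
    for gi, grp in enumerate(("control", "treated")):
        for s in range(4):
            base = 1.4 + 0.05 * gi + rng.normal(0, 0.03)
            for f in range(3):
                rows.append(
                    {
                        "cell_id": s,
                        "nucleolus_id": 0,
                        "frame": f,
                        "time_min": 5.0 * f,
                        "ratio": base + 0.02 * gi * f + rng.normal(0, 0.01),
                        "group": grp,
                    }
                )
    return pd.DataFrame(rows)


def _split_plot_F_by_hand(df):
    """Direct sum-of-squares arithmetic for the balanced mixed design."""
    wide = df.pivot_table(index=["group", "cell_id"], columns="frame", values="ratio")
    data = wide.to_numpy()  # (a*n, b) with groups stacked
    groups = wide.index.get_level_values("group")
    levels = groups.unique()
    a, b = len(levels), data.shape[1]
    n = data.shape[0] // a
    grand = data.mean()
    subj_means = data.mean(axis=1)
    group_means = np.array([data[groups == g].mean() for g in levels])
    time_means = data.mean(axis=0)
    ss_between_subj = b * ((subj_means - grand) ** 2).sum()
    ss_group = n * b * ((group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_time = a * n * ((time_means - grand) ** 2).sum()
    cell_means = np.array([data[groups == g].mean(axis=0) for g in levels])
    ss_inter = n * (
        (cell_means - group_means[:, None] - time_means[None, :] + grand) ** 2
    ).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_between_subj - ss_time - ss_inter
    df_group, df_subj = a - 1, a * (n - 1)
    df_time, df_inter, df_err = b - 1, (a - 1) * (b - 1), a * (n - 1) * (b - 1)
    f_group = (ss_group / df_group) / (ss_subj_within / df_subj)
    f_time = (ss_time / df_time) / (ss_err / df_err)
    f_inter = (ss_inter / df_inter) / (ss_err / df_err)
    return f_group, f_time, f_inter


class TestRmAnovaOnset:
    def test_reproduces_hand_computed_split_plot_F(self):
        df = _balanced_example()
        res = nq.rm_anova_onset(df)
        f_group, f_time, f_inter = _split_plot_F_by_hand(df)
        aov = res.anova.set_index("Source")
        assert aov.loc["group", "F"] == pytest.approx(f_group, rel=1e-6)
        assert aov.loc["frame", "F"] == pytest.approx(f_time, rel=1e-6)
        assert aov.loc["Interaction", "F"] == pytest.approx(f_inter, rel=1e-6)

    def test_identical_groups_report_no_onset(self):
        df = _balanced_example()
        clone = df[df.group == "control"].copy()
        clone["group"] = "treated"
        clone["cell_id"] += 100
        res = nq.rm_anova_onset(pd.concat([df[df.group == "control"], clone]))
        assert res.first_significant is None

    def test_zero_noise_is_degenerate_not_significant(self):
        reps = nq.gen_null_ratio_dataset(4, 4, 0.0, 1, seed=3)
        with pytest.warns(UserWarning, match="zero residual variance"):
            res = nq.rm_anova_onset(reps[0])
        assert res.degenerate and res.first_significant is None

    def test_small_group_rejected(self):
        df = _balanced_example()
        df = df[(df.group == "control") | (df.cell_id == 0)]
        with pytest.raises(ContractError):
            nq.rm_anova_onset(df)

    def test_incomplete_tracks_dropped_and_counted(self):
        df = _balanced_example()
        df = df.drop(df[(df.group == "treated") & (df.cell_id == 3)
                        & (df.frame == 2)].index)
        res = nq.rm_anova_onset(df)
        assert res.n_dropped == 1
        assert res.n_subjects == 7

    def test_type_one_error_controlled_small_batch(self):
        reps = nq.gen_null_ratio_dataset(8, 6, 0.05, 60, seed=17)
        rej = 0
        for rep in reps:
            res = nq.rm_anova_onset(rep)
            p = float(res.anova.set_index("Source").loc["Interaction", "p_unc"])
            rej += p < 0.05
        # 60 draws from Binomial(0.05): >=9 rejections has p < 1e-3
        assert rej <= 8


def test_programmed_onset_detected_near_t0(timelapse_series):
    """Full imaging pipeline: onset at frame 36 flagged within frames 34-40."""
    res = nq.rm_anova_onset(timelapse_series)
    assert res.first_significant is not None
    assert 34 <= res.first_significant <= 40
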
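import numpy as np
import pandas as pd
import pytest

from sharplight.cluster import Cluster, ClusterSet
from sharplight.design import make_design
from sharplight.simulate import BetaSet, PopulationSpec, VolumeGrid, simulate_betas
from sharplight.tuning import (
    preference_signal_table,
    sharpening_signature,
    univariate_congruency,
    voxel_preference,
)

from conftest import analytic_spec


def _betas(spec, seed=0, n_runs=2, trials=12, grid_shape=(4, 4, 4)):
    grid = VolumeGrid(grid_shape)
    design = make_design(1, n_runs, trials, seed=seed)[0]
    return simulate_betas(design, grid, spec, seed=seed)


def _roi_over_informative(spec):
    return ClusterSet(clusters=[Cluster("c1", list(spec.informative_region), len(spec.informative_region), 5.0)])


class TestVoxelPreference:
    def test_noiseless_recovery_of_generating_preferences(self, sharp_spec):
        betas = _betas(sharp_spec)
        tuning = voxel_preference(betas)
        want = {"index": 1, "little": -1}
        for vox, pref in sharp_spec.preference_assignment.items():
            assert tuning.preference[vox] == want[pref]
        assert tuning.preferred_label((1, 1, 1)) == "index"

    def test_tied_voxels_excluded(self, sharp_spec):
        betas = _betas(sharp_spec)
        # non-informative voxels respond identically to both stimuli
        assert voxel_preference(betas).preference[0, 0, 0] == 0

    def test_too_few_cells_rejected(self, sharp_spec):
        betas = _betas(sharp_spec)
        only = {k: v for k, v in betas.data.items() if k[0] == 1 and k[1] == "congruent"}
        small = BetaSet(grid=betas.grid, data=only, subject_id="s")
        with pytest.raises(ValueError, match=">= 2 paired cells"):
            voxel_preference(small)

    def test_move_only_mode_drops_no_move_cells(self, sharp_spec):
        betas = _betas(sharp_spec)
        a = voxel_preference(betas, include_no_move=True)
        b = voxel_preference(betas, include_no_move=False)
        # same signs in the noiseless case, different cell counts → different t
        vox = (1, 1, 1)
        assert np.sign(a.t_map[vox]) == np.sign(b.t_map[vox])


class TestPreferenceSignalTable:
    @pytest.mark.parametrize(
        "hypothesis,expected",
        [
            (
                "sharpening",
                {("congruent", "preferred"): 2.0, ("congruent", "nonpreferred"): 0.5,
                 ("incongruent", "preferred"): 2.0, ("incongruent", "nonpreferred"): 1.0},
            ),
            (
                "cancellation",
                {("congruent", "preferred"): 1.0, ("congruent", "nonpreferred"): 1.0,
                 ("incongruent", "preferred"): 2.0, ("incongruent", "nonpreferred"): 1.0},
            ),
        ],
    )
    def test_noiseless_cell_means_match_population_model(self, hypothesis, expected):
        spec = analytic_spec(hypothesis)
        betas = _betas(spec)
        tuning = voxel_preference(betas)
        table = preference_signal_table({"s1": betas}, {"s1": tuning}, _roi_over_informative(spec))
        for (cond, status), val in expected.items():
            row = table[(table["congruency"] == cond) & (table["preference"] == status)]
            assert row["value"].iloc[0] == pytest.approx(val)

    def test_label_symmetry(self):
        """Relabelling index↔little flips preferences but leaves every
        preferred/non-preferred cell mean unchanged."""
        spec = analytic_spec("sharpening", noise_sd=0.3)
        betas = _betas(spec, seed=7)
        swap = {"index": "little", "little": "index"}
        relabelled = BetaSet(
            grid=betas.grid,
            data={(r, c, swap[s]): v for (r, c, s), v in betas.data.items()},
            subject_id=betas.subject_id,
        )
        rois = _roi_over_informative(spec)
        t_a, t_b = voxel_preference(betas), voxel_preference(relabelled)
        np.testing.assert_array_equal(t_a.preference, -t_b.preference)
        a = preference_signal_table({"s": betas}, {"s": t_a}, rois)
        b = preference_signal_table({"s": relabelled}, {"s": t_b}, rois)
        pd.testing.assert_frame_equal(a, b)

    def test_fully_excluded_cluster_rejected(self, sharp_spec):
        betas = _betas(sharp_spec)
        rois = ClusterSet(clusters=[Cluster("dead", [(0, 0, 0)], 1, 0.0)])
        with pytest.raises(ValueError, match="all voxels excluded"):
            preference_signal_table({"s": betas}, {"s": voxel_preference(betas)}, rois)


def _multi_subject_cells(hypothesis, n_sub=8, noise_sd=1.0, seed0=100):
    spec_template = analytic_spec(hypothesis)
    rows = []
    tables = []
    for i in range(n_sub):
        spec = PopulationSpec(
            informative_region=spec_template.informative_region,
            preference_assignment=spec_template.preference_assignment,
            baseline=0.0,
            amp_preferred=2.0,
            amp_nonpreferred=1.0,
            gain=0.5,
            hypothesis=hypothesis,
            noise_sd=noise_sd,
        )
        betas = _betas(spec, seed=seed0 + i, n_runs=4, trials=24)
        tuning = voxel_preference(betas)
        t = preference_signal_table({f"s{i}": betas}, {f"s{i}": tuning}, _roi_over_informative(spec))
        tables.append(t)
    return pd.concat(tables, ignore_index=True)


class TestSignature:
    def test_sharpening_data_yield_sharpening_verdict(self):
        cells = _multi_subject_cells("sharpening")
        res = sharpening_signature(cells)
        assert res.verdict == "sharpening"
        assert res.t_nonpreferred.t < 0

    def test_cancellation_data_yield_cancellation_verdict(self):
        cells = _multi_subject_cells("cancellation")
        res = sharpening_signature(cells)
        assert res.verdict == "cancellation"
        assert res.t_preferred.t < 0

    def test_baseline_shift_leaves_interaction_invariant(self):
        cells = _multi_subject_cells("sharpening")
        shifted = cells.assign(value=cells["value"] + 57.0)
        a = sharpening_signature(cells).anova.effect("congruency x preference")
        b = sharpening_signature(shifted).anova.effect("congruency x preference")
        assert a["F"] == pytest.approx(b["F"], rel=1e-9)

    def test_selection_is_orthogonal_to_congruency_contrast(self):
        """Classifying preference and extracting congruency cells from the
        same noisy data must not inflate the congruency × preference
        interaction under the null: the false-positive rate stays ≈ α."""
        rng = np.random.default_rng(0)
        grid = VolumeGrid((3, 3, 3))
        design = make_design(1, 2, 12, seed=0)[0]
        hits = 0
        R = 200
        roi = ClusterSet(clusters=[Cluster("c1", [(i, j, k) for i in range(3) for j in range(3) for k in range(3)], 27, 1.0)])
        for rep in range(R):
            tables = []
            for s in range(6):
                spec = PopulationSpec(baseline=0.0, noise_sd=1.0, hypothesis="null")
                betas = simulate_betas(design, grid, spec, seed=int(rng.integers(2**31)))
                tuning = voxel_preference(betas)
                tables.append(preference_signal_table({f"s{s}": betas}, {f"s{s}": tuning}, roi))
            cells = pd.concat(tables, ignore_index=True)
            res = sharpening_signature(cells)
            hits += res.anova.effect("congruency x preference")["p"] < 0.05
        se = np.sqrt(0.05 * 0.95 / R)
        assert abs(hits / R - 0.05) < 1.96 * se + 1e-9

    def test_univariate_congruency_contrast_runs(self):
        cells = _multi_subject_cells("sharpening")
        res = univariate_congruency(cells)
        assert np.isfinite(res.t)
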
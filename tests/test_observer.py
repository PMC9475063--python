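"""Synthetic observer: experiment design and response generation."""

import numpy as np
import pandas as pd
import pytest

import distcapture as dc
from distcapture.observer import DesignError, ExperimentDesign, ParameterError

from conftest import log_sd_diff, one_block_design


class TestDesign:
    def test_default_design_cardinalities(self, design):
        # 17-point measurement grid, 11 auditory distances per block,
        # 30 trials x 11 subjects = 330 pooled trials per point
        assert len(design.measurement_grid) == 17
        assert all(len(g) == 11 for g in design.auditory_grids)
        assert design.trials_per_stimulus * design.n_subjects == 330
        assert design.visual_targets == (1.5, 3.0, 4.5)
        assert design.absolute_auditory_distances == tuple(np.arange(1.0, 5.01, 0.5))
        assert design.absolute_visual_distances == (1.0, 2.0, 3.0)

    def test_block_grids_stay_inside_measured_range(self, design):
        for grid in design.auditory_grids:
            assert min(grid) >= 1.0 and max(grid) <= 5.0
            assert np.allclose(np.diff(grid), 0.25)
        # central block is centered; edge blocks are shifted inward
        assert design.grid_for(3.0)[5] == 3.0
        assert design.grid_for(1.5)[0] == 1.0
        assert design.grid_for(4.5)[-1] == 5.0

    @pytest.mark.parametrize(
        "kw",
        [
            dict(visual_targets=()),
            dict(trials_per_stimulus=0),
            dict(n_subjects=0),
            dict(auditory_grids=((2.0, 1.0),)),
            dict(auditory_grids=((1.0, 1.0),)),
            dict(visual_targets=(-1.0,)),
        ],
    )
    def test_invalid_designs_rejected(self, kw):
        base = dict(
            visual_targets=(3.0,),
            auditory_grids=((2.0, 3.0, 4.0),),
            trials_per_stimulus=5,
            n_subjects=2,
            absolute_auditory_distances=(1.0,),
            absolute_visual_distances=(1.0,),
        )
        if "visual_targets" in kw and kw["visual_targets"] == (-1.0,):
            kw = dict(kw, auditory_grids=((2.0, 3.0),))
        with pytest.raises(DesignError):
            ExperimentDesign(**{**base, **kw})


class TestObserverParams:
    @pytest.mark.parametrize(
        "kw", [dict(k_aud=0.0), dict(s_aud=-0.1), dict(r=1.5), dict(criterion_c=0.0)]
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ParameterError):
            dc.ObserverParams(**kw)


class TestAbsoluteJudgments:
    def test_noiseless_identity_observer(self):
        d = dc.default_design()
        p = dc.ObserverParams(k_aud=1, a_aud=1, k_vis=1, a_vis=1, s_aud=0, s_vis=0)
        out = dc.simulate_absolute_judgments(d, p)
        assert np.allclose(out["judged_m"], out["target_m"])

    def test_seeded_determinism(self, design):
        p = dc.ObserverParams(seed=42)
        a = dc.simulate_absolute_judgments(design, p)
        b = dc.simulate_absolute_judgments(design, p)
        pd.testing.assert_frame_equal(a, b)

    def test_geometric_mean_converges_to_power_law(self):
        # k=1, a=0.5 at x=4: geometric mean of many replicate judgments -> 2
        d = one_block_design(1.0, (1.0, 2.0), trials=1, n_subjects=10_000)
        d = ExperimentDesign(
            visual_targets=d.visual_targets,
            auditory_grids=d.auditory_grids,
            trials_per_stimulus=1,
            n_subjects=10_000,
            absolute_auditory_distances=(4.0,),
            absolute_visual_distances=(1.0,),
        )
        p = dc.ObserverParams(k_aud=1.0, a_aud=0.5, s_aud=0.2, seed=9)
        out = dc.simulate_absolute_judgments(d, p)
        aud = out[out["modality"] == "aud"]["judged_m"]
        assert dc.geometric_mean(aud) == pytest.approx(2.0, rel=0.01)

    def test_schema(self, judgments, design):
        assert list(judgments.columns) == ["subject_id", "modality", "target_m", "judged_m"]
        assert set(judgments["modality"]) == {"aud", "vis"}
        n_cells = len(design.absolute_auditory_distances) + len(design.absolute_visual_distances)
        assert len(judgments) == design.n_subjects * n_cells
        assert (judgments["judged_m"] > 0).all()


class TestCoincidenceResponses:
    def test_saturated_criterion_always_coincident(self):
        d = one_block_design(3.0, (2.0, 3.0, 4.0), trials=10, n_subjects=2)
        p = dc.ObserverParams(criterion_c=1e6)
        out = dc.simulate_coincidence_responses(d, p)
        assert (out["response"] == 1).all()

    def test_noiseless_matched_means_always_coincident(self):
        d = one_block_design(3.0, (3.0, 4.0), trials=10, n_subjects=2)
        p = dc.ObserverParams(k_aud=1, a_aud=1, k_vis=1, a_vis=1, s_aud=0, s_vis=0,
                              criterion_c=0.1)
        out = dc.simulate_coincidence_responses(d, p)
        matched = out[out["auditory_m"] == 3.0]
        assert (matched["response"] == 1).all()

    def test_perfectly_correlated_equal_noise_matched_means(self):
        # r=1 with equal log SDs: A - V is deterministic, pc = 1 at the match
        d = one_block_design(3.0, (2.0, 3.0), trials=20, n_subjects=3)
        p = dc.ObserverParams(k_aud=1, a_aud=1, k_vis=1, a_vis=1,
                              s_aud=0.4, s_vis=0.4, r=1.0, criterion_c=0.05)
        out = dc.simulate_coincidence_responses(d, p)
        assert (out[out["auditory_m"] == 3.0]["response"] == 1).all()

    def test_trial_counts_and_schema(self, responses, design):
        counts = responses.groupby(["visual_m", "auditory_m"]).size()
        assert (counts == 330).all()
        assert len(counts) == 33
        assert responses["response"].isin([0, 1]).all()
        key = ["subject_id", "visual_m", "auditory_m", "trial_idx"]
        assert not responses.duplicated(key).any()

    def test_seeded_determinism_and_subject_substreams(self, design):
        p = dc.ObserverParams(seed=13)
        a = dc.simulate_coincidence_responses(design, p)
        b = dc.simulate_coincidence_responses(design, p)
        pd.testing.assert_frame_equal(a, b)
        # a smaller-subject design reproduces the shared subjects exactly
        small = ExperimentDesign(
            visual_targets=design.visual_targets,
            auditory_grids=design.auditory_grids,
            trials_per_stimulus=design.trials_per_stimulus,
            n_subjects=3,
            absolute_auditory_distances=design.absolute_auditory_distances,
            absolute_visual_distances=design.absolute_visual_distances,
        )
        c = dc.simulate_coincidence_responses(small, p)
        pd.testing.assert_frame_equal(
            c, a[a["subject_id"] < 3].reset_index(drop=True)
        )

    def test_empirical_pc_matches_closed_form(self):
        # Monte-Carlo pc vs the analytic differencing-observer probability
        p = dc.ObserverParams(seed=7)
        d = one_block_design(3.0, (2.0, 3.0, 4.0), trials=100_000, n_subjects=1)
        out = dc.simulate_coincidence_responses(d, p)
        pc = dc.proportion_coincident(out)
        sd = log_sd_diff(p)
        for _, row in pc.iterrows():
            mu = p.log_mean("aud", row.auditory_m) - p.log_mean("vis", 3.0)
            analytic = dc.predict_pc(mu, sd, p.criterion_c)
            se = np.sqrt(analytic * (1 - analytic) / row.n_trials)
            assert abs(row.pc - analytic) <= 3 * se
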
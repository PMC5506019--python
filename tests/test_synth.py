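"""Generator: atlas construction, session/cohort simulation, on-disk format."""

import numpy as np
import pytest
from scipy import ndimage

from brainheart import synth
from brainheart.coupling import window_grid
from brainheart.synth import (
    INTERVENTIONS,
    SESSION_ORDERS,
    AtlasCapacityError,
    CouplingSpec,
    make_network_atlas,
    simulate_cohort,
    simulate_session,
    write_dataset,
)


# ---------------------------------------------------------------------------
# atlas

class TestAtlas:
    def test_capacity_error(self):
        # 4x4x1 grid holds a single 3^3-less cell: cannot fit 7 blocks
        with pytest.raises(AtlasCapacityError):
            make_network_atlas((4, 4, 1), n_networks=5, seed=0)

    def test_network_sizes_and_contiguity(self, atlas_small):
        for k in range(1, atlas_small.n_networks + 1):
            mask = atlas_small.network_mask(k)
            assert mask.sum() >= 27
            _, n_comp = ndimage.label(mask)
            assert n_comp == 1  # spatially contiguous

    def test_networks_disjoint_from_tissue(self, atlas_small):
        labelled = atlas_small.labels > 0
        assert not (labelled & atlas_small.wm_mask).any()
        assert not (labelled & atlas_small.csf_mask).any()

    def test_seed_points_inside_networks(self, atlas_small):
        for name, vox in atlas_small.seed_points.items():
            assert atlas_small.labels[vox] in range(1, atlas_small.n_networks + 1)

    def test_deterministic(self):
        a = make_network_atlas((12, 12, 6), seed=9)
        b = make_network_atlas((12, 12, 6), seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert a.seed_points == b.seed_points

    def test_analysis_mask_excludes_tissue(self, atlas_small):
        m = atlas_small.analysis_mask
        assert not (m & atlas_small.wm_mask).any()
        assert not (m & atlas_small.csf_mask).any()
        assert (m & (atlas_small.labels > 0)).sum() == (atlas_small.labels > 0).sum()


# ---------------------------------------------------------------------------
# single sessions

class TestSimulateSession:
    def test_same_network_voxels_perfectly_correlated(self, atlas_small, clean_spec):
        # [TRIVIAL] noise_sd=0, no leakage: identical latent source up to scale
        b = simulate_session(atlas_small, clean_spec, "rest_baseline", seed=1)
        vox = np.argwhere(atlas_small.network_mask(1))[:2]
        s1 = b.image.data[tuple(vox[0])]
        s2 = b.image.data[tuple(vox[1])]
        r = np.corrcoef(s1, s2)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_sync_rho_09_realized_correlation(self, atlas_small):
        # [DERIVED] realized windowed corr computed from the generated series
        spec = CouplingSpec(sync_rho=0.9, noise_sd=0.0, random_seed=2)
        b = simulate_session(atlas_small, spec, "gratitude", seed=7, include_image=False)
        t = b.truth
        r = np.corrcoef(t.window_hr_bpm, t.window_fc_z)[0, 1]
        assert t.window_fc_z.size == 25
        assert r >= 0.85
        assert t.sync_r == pytest.approx(r)

    def test_mean_hr_injection(self, atlas_small):
        # [DERIVED] baseline 70, delta -3 for gratitude -> mean inst. HR ~ 67
        spec = CouplingSpec(hr_baseline_bpm=70.0, hr_condition_delta_bpm=-3.0,
                            random_seed=4)
        b = simulate_session(atlas_small, spec, "gratitude", seed=3,
                             include_image=False)
        assert b.truth.mean_hr_bpm == pytest.approx(67.0, abs=1.0)

    def test_sync_edge_absent_from_atlas(self, atlas_small):
        spec = CouplingSpec(sync_edge=(1, 9), random_seed=0)
        with pytest.raises(ValueError, match="absent"):
            simulate_session(atlas_small, spec, "gratitude", seed=0)

    def test_session_shorter_than_window(self, atlas_small):
        spec = CouplingSpec(n_volumes=30, random_seed=0)  # 60 s total, 5 discarded
        with pytest.raises(ValueError, match="shorter"):
            simulate_session(atlas_small, spec, "rest_baseline", seed=0)

    def test_deterministic_given_seed(self, atlas_small):
        spec = CouplingSpec(random_seed=0)
        a = simulate_session(atlas_small, spec, "gratitude", seed=42)
        b = simulate_session(atlas_small, spec, "gratitude", seed=42)
        assert np.array_equal(a.image.data, b.image.data)
        assert np.array_equal(a.ppg.samples, b.ppg.samples)
        assert np.array_equal(a.truth.latents, b.truth.latents)

    def test_ppg_only_for_interventions(self, atlas_small, clean_spec):
        rest = simulate_session(atlas_small, clean_spec, "rest_baseline", seed=1,
                                include_image=False)
        grat = simulate_session(atlas_small, clean_spec, "gratitude", seed=1,
                                include_image=False)
        assert rest.ppg is None
        assert grat.ppg is not None
        assert grat.ppg.rate_hz == 50.0

    def test_latents_band_limited(self, atlas_small, clean_spec):
        b = simulate_session(atlas_small, clean_spec, "rest_baseline", seed=6,
                             include_image=False)
        x = b.truth.latents[:, 0]
        freqs = np.fft.rfftfreq(x.size, d=clean_spec.tr_s)
        power = np.abs(np.fft.rfft(x - x.mean())) ** 2
        in_band = (freqs >= 0.009) & (freqs <= 0.08)
        assert power[in_band].sum() / power.sum() > 0.9

    def test_fc_effect_recovered_from_latents(self, atlas_small):
        # injected +0.25 on edge (4,5) during gratitude: brute-force recovery
        # by averaging realized latent correlations across sessions
        spec = CouplingSpec(random_seed=8)
        r_grat, r_rest = [], []
        for s in range(12):
            g = simulate_session(atlas_small, spec, "gratitude", seed=100 + s,
                                 include_image=False)
            r = simulate_session(atlas_small, spec, "rest_baseline", seed=200 + s,
                                 include_image=False)
            r_grat.append(g.truth.realized_corr[3, 4])
            r_rest.append(r.truth.realized_corr[3, 4])
        injected = np.mean(r_grat) - np.mean(r_rest)
        assert injected == pytest.approx(0.25, abs=0.15)

    def test_windowed_truth_on_analysis_grid(self, atlas_small):
        spec = CouplingSpec(random_seed=1)
        b = simulate_session(atlas_small, spec, "gratitude", seed=5,
                             include_image=False)
        grid = window_grid(spec.n_volumes - spec.n_discard, spec.tr_s)
        assert b.truth.window_fc_z.size == grid.n_windows
        assert b.truth.window_hr_bpm.size == grid.n_windows


# ---------------------------------------------------------------------------
# cohorts

class TestSimulateCohort:
    def test_cohort_invariants(self, tiny_cohort):
        assert tiny_cohort.n_subjects == 4
        for subj in tiny_cohort.subjects:
            assert len(subj.sessions) == 5
            for cond, bundle in subj.sessions.items():
                assert bundle.image.n_volumes == 155
                assert bundle.image.tr_s == 2.0
                has_ppg = bundle.ppg is not None
                assert has_ppg == (cond in INTERVENTIONS)

    def test_counterbalanced_orders(self, tiny_cohort):
        sets = [s.order_set for s in tiny_cohort.subjects]
        assert sets == ["I", "II", "I", "II"]
        assert SESSION_ORDERS["I"].index("gratitude") < SESSION_ORDERS["I"].index("resentment")
        assert SESSION_ORDERS["II"].index("resentment") < SESSION_ORDERS["II"].index("gratitude")

    def test_behavior_ranges(self, tiny_cohort):
        b = tiny_cohort.behaviors
        for col in ("hads_anxiety", "hads_depression"):
            assert b[col].dtype.kind == "i"
            assert b[col].between(0, 21).all()
        for col in ("sdt_autonomy", "sdt_competence", "sdt_relatedness"):
            assert b[col].between(1.0, 7.0).all()

    def test_min_subjects(self, atlas_small, clean_spec):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_cohort(1, clean_spec, atlas_small)

    def test_condition_subset_matches_full_cohort(self, atlas_small):
        spec = CouplingSpec(random_seed=7)
        full = simulate_cohort(2, spec, atlas_small, seed=7, include_images=False)
        sub = simulate_cohort(2, spec, atlas_small, seed=7, include_images=False,
                              conditions=["gratitude"])
        for s_full, s_sub in zip(full.subjects, sub.subjects):
            assert list(s_sub.sessions) == ["gratitude"]
            np.testing.assert_array_equal(
                s_full.sessions["gratitude"].truth.latents,
                s_sub.sessions["gratitude"].truth.latents,
            )

    def test_deterministic(self, atlas_small):
        spec = CouplingSpec(random_seed=3)
        a = simulate_cohort(3, spec, atlas_small, seed=3, include_images=False)
        b = simulate_cohort(3, spec, atlas_small, seed=3, include_images=False)
        assert a.behaviors.equals(b.behaviors)
        np.testing.assert_array_equal(
            a.subjects[2].sessions["resentment"].truth.latents,
            b.subjects[2].sessions["resentment"].truth.latents,
        )


# ---------------------------------------------------------------------------
# on-disk round trip

class TestWriteDataset:
    def test_round_trip(self, atlas_small, tmp_path):
        spec = CouplingSpec(random_seed=2)
        cohort = simulate_cohort(2, spec, atlas_small, seed=2)
        manifest = write_dataset(cohort, tmp_path / "ds")
        assert manifest["n_subjects"] == 2
        # every manifest file exists; spot-check an image round trip
        for rel in manifest["files"]:
            assert (tmp_path / "ds" / rel).exists()
        subj = cohort.subjects[0]
        cond = subj.session_order[0]
        img = synth.read_image(
            tmp_path / "ds" / subj.subject_id / f"ses-1_{cond}_bold.nii"
        )
        np.testing.assert_allclose(img.data, subj.sessions[cond].image.data)

    def test_refuses_nonempty_dir(self, atlas_small, tmp_path):
        spec = CouplingSpec(random_seed=2)
        cohort = simulate_cohort(2, spec, atlas_small, seed=2, include_images=False)
        (tmp_path / "ds").mkdir()
        (tmp_path / "ds" / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_dataset(cohort, tmp_path / "ds")
        write_dataset(cohort, tmp_path / "ds", overwrite=True)  # no raise


class TestCouplingSpecInvariants:
    def test_sync_rho_bound(self):
        with pytest.raises(ValueError):
            CouplingSpec(sync_rho=1.5)

    def test_noise_sd_nonnegative(self):
        with pytest.raises(ValueError):
            CouplingSpec(noise_sd=-0.1)

    def test_hr_baseline_range(self):
        with pytest.raises(ValueError):
            CouplingSpec(hr_baseline_bpm=20.0)
        with pytest.raises(ValueError):
            CouplingSpec(hr_baseline_bpm=250.0)

    def test_sync_edge_normalized(self):
        spec = CouplingSpec(sync_edge=(3, 1))
        assert spec.sync_edge == (1, 3)
        with pytest.raises(ValueError):
            CouplingSpec(sync_edge=(2, 2))
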
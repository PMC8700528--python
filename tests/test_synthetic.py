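import numpy as np
import pytest

from cvmstage.landmark_io import ANATOMIC_NAMES, compute_scale, read_labelme
from cvmstage.staging import CVMStage, StageThresholds, stage_record
from cvmstage.synthetic import (
    STAGE_FREQUENCIES,
    SyntheticParams,
    generate_dataset,
    jitter_landmarks,
    render_image,
    sample_case,
)


class TestSampleCase:
    @pytest.mark.parametrize("s", list(CVMStage))
    def test_stage_recovered_without_jitter(self, s, clean_cases_per_stage):
        assert stage_record(clean_cases_per_stage[s].record).stage is s

    def test_cs6_has_a_vertical_body(self, clean_cases_per_stage):
        tm = clean_cases_per_stage[CVMStage.CS6].true_measurements
        assert min(tm.c3bar, tm.c4bar) <= StageThresholds().vertical_upper_bar

    def test_fixed_seed_reproducible(self):
        a = sample_case(CVMStage.CS3, np.random.default_rng(5))
        b = sample_case(CVMStage.CS3, np.random.default_rng(5))
        for n in a.record.landmarks:
            assert a.record[n].x == b.record[n].x
        assert np.array_equal(a.image, b.image)

    def test_margins_respected(self):
        t = StageThresholds()
        p = SyntheticParams()
        rng = np.random.default_rng(8)
        for _ in range(20):
            tm = sample_case(CVMStage.CS5, rng, render=False).true_measurements
            for conc in (tm.c2conc, tm.c3conc, tm.c4conc):
                assert abs(conc - t.concavity_mm) >= p.conc_margin_mm - 1e-12
            for bar in (tm.c3bar, tm.c4bar):
                assert abs(bar - t.square_upper_bar) >= p.bar_margin - 1e-12
                assert abs(bar - t.vertical_upper_bar) >= p.bar_margin - 1e-12

    def test_impossible_thresholds_rejected(self):
        bad = StageThresholds(concavity_mm=0.1)  # flat region < margin
        with pytest.raises(ValueError, match="stage-consistent"):
            sample_case(CVMStage.CS1, np.random.default_rng(0),
                        thresholds=bad, render=False)


class TestJitter:
    def test_zero_sigma_identity(self, clean_cases_per_stage):
        rec = clean_cases_per_stage[CVMStage.CS2].record
        out = jitter_landmarks(rec, 0.0, np.random.default_rng(0))
        for n in rec.landmarks:
            assert out[n].x == rec[n].x and out[n].y == rec[n].y

    def test_references_untouched_scale_preserved(self, clean_cases_per_stage):
        rec = clean_cases_per_stage[CVMStage.CS2].record
        out = jitter_landmarks(rec, 2.0, np.random.default_rng(1))
        for n in ("R1", "R2"):
            assert out[n].x == rec[n].x and out[n].y == rec[n].y
        assert compute_scale(out).mm_per_pixel == compute_scale(rec).mm_per_pixel
        assert any(out[n].x != rec[n].x for n in ANATOMIC_NAMES)

    def test_negative_sigma_rejected(self, clean_cases_per_stage):
        with pytest.raises(ValueError):
            jitter_landmarks(clean_cases_per_stage[CVMStage.CS1].record, -0.1)

    def test_mean_displacement_matches_rayleigh(self, clean_cases_per_stage):
        """Isotropic Gaussian jitter with sigma produces displacements with
        the Rayleigh mean sigma * sqrt(pi/2)."""
        rec = clean_cases_per_stage[CVMStage.CS4].record
        scale = compute_scale(rec)
        rng = np.random.default_rng(12)
        sigma = 0.4
        dists = []
        for _ in range(400):
            out = jitter_landmarks(rec, sigma, rng)
            for n in ANATOMIC_NAMES:
                d_px = np.hypot(out[n].x - rec[n].x, out[n].y - rec[n].y)
                dists.append(scale.to_mm(d_px))
        expected = sigma * np.sqrt(np.pi / 2)  # 0.5013
        assert np.mean(dists) == pytest.approx(expected, abs=0.01)


class TestRender:
    def test_clean_render_hits_exact_intensities(self, clean_cases_per_stage):
        case = clean_cases_per_stage[CVMStage.CS1]
        p = SyntheticParams(noise_sigma=0.0, blur_px=0.0)
        img = render_image(case, p, np.random.default_rng(0))
        # centre of the C3 body is interior foreground
        c3 = (case.record.point("C3ua") + case.record.point("C3lp")) / 2
        assert img[int(c3[1]), int(c3[0])] == p.foreground
        assert img[2, 2] == p.background

    def test_concave_notch_carved_out(self, clean_cases_per_stage):
        case = clean_cases_per_stage[CVMStage.CS4]
        p = SyntheticParams(noise_sigma=0.0, blur_px=0.0)
        img = render_image(case, p, np.random.default_rng(0))
        m = case.record.point("C3m")
        # just below the deepest point (inside the notch) is background
        assert img[int(m[1]) + 2, int(round(m[0]))] == p.background

    def test_two_seeds_differ_only_in_noise(self, clean_cases_per_stage):
        case = clean_cases_per_stage[CVMStage.CS2]
        p = SyntheticParams(noise_sigma=0.05, blur_px=1.0)
        img1 = render_image(case, p, np.random.default_rng(1))
        img2 = render_image(case, p, np.random.default_rng(2))
        clean = render_image(case, SyntheticParams(noise_sigma=0.0, blur_px=1.0))
        assert not np.array_equal(img1, img2)
        # residuals are zero-mean noise around the same clean render
        assert abs((img1 - clean).mean()) < 0.01
        assert abs((img2 - clean).mean()) < 0.01


class TestGenerateDataset:
    def test_explicit_counts_and_determinism(self):
        _, m1 = generate_dataset([2] * 6, seed=7, render=False)
        _, m2 = generate_dataset([2] * 6, seed=7, render=False)
        assert len(m1) == 12
        assert m1["true_stage"].value_counts().tolist() == [2] * 6
        assert m1.equals(m2)

    def test_total_split_matches_default_frequencies(self):
        _, manifest = generate_dataset(980, seed=1, render=False)
        counts = manifest["true_stage"].value_counts()
        for s in CVMStage:
            assert counts[str(s)] == round(STAGE_FREQUENCIES[s] * 980)

    def test_written_outputs_round_trip(self, tmp_path):
        generate_dataset([1, 0, 0, 0, 0, 1], seed=3, out_dir=tmp_path)
        pngs = sorted(tmp_path.glob("*.png"))
        jsons = sorted(tmp_path.glob("*.json"))
        assert len(pngs) == 2 and len(jsons) == 2
        rec = read_labelme(jsons[0].read_text())
        assert rec.is_stageable
        assert rec.gold_stage is CVMStage.CS1
        manifest = (tmp_path / "manifest.csv").read_text().strip().splitlines()
        assert manifest[0] == "image_id,true_stage"
        assert len(manifest) == 3
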
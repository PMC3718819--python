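"""Detection, linking, and cargo classification."""

import numpy as np
import pytest

import kymoflux as kf
from kymoflux.pipeline import match_tracks_to_truth
from kymoflux.track import CalibrationMismatchError, ParticleTrajectory


def _kymo(matrix):
    return kf.Kymograph(matrix=np.asarray(matrix, float), pixel_size=0.16, frame_interval=15.0)


def _gauss_row(w, center_px, amp=10.0, bg=20.0, sigma_px=2.5):
    cols = np.arange(w)
    return bg + amp * np.exp(-((cols - center_px) ** 2) / (2 * sigma_px**2))


def _make_track(positions, frames=None, intensities=None, **kw):
    positions = np.asarray(positions, float)
    frames = np.arange(len(positions)) if frames is None else np.asarray(frames)
    if intensities is None:
        intensities = np.ones(len(positions))
    defaults = dict(channel="rna", frame_interval=15.0, pixel_size=0.16)
    defaults.update(kw)
    return ParticleTrajectory(
        particle_id=0, frames=frames, positions=positions, intensities=intensities, **defaults
    )


# ---------------------------------------------------------------------------
# detection


def test_constant_row_no_peaks():
    k = _kymo(np.full((5, 50), 20.0))
    dets = kf.detect_peaks(k, kf.DetectionConfig())
    assert all(len(d) == 0 for d in dets)


def test_single_noiseless_ridge_subpixel_accuracy():
    """Sub-pixel localization of an isolated Gaussian ridge within 0.25 px."""
    w = 100
    for true_px in (40.0, 40.3, 40.5, 41.7):
        k = _kymo(np.tile(_gauss_row(w, true_px), (6, 1)))
        dets = kf.detect_peaks(k, kf.DetectionConfig(min_prominence=3.0))
        for d in dets:
            assert len(d) == 1
            assert abs(d[0, 0] / 0.16 - true_px) < 0.25


def test_two_separated_ridges_two_peaks():
    row = _gauss_row(120, 30.0) + _gauss_row(120, 80.0) - 20.0
    k = _kymo(np.tile(row, (4, 1)))
    dets = kf.detect_peaks(k, kf.DetectionConfig(min_prominence=3.0))
    assert all(len(d) == 2 for d in dets)


# ---------------------------------------------------------------------------
# linking


def _detections_from_positions(pos_lists, intensity=10.0):
    out = []
    for pts in pos_lists:
        arr = np.array([[p, intensity] for p in pts]) if pts else np.empty((0, 2))
        out.append(arr[np.argsort(arr[:, 0])] if len(arr) else arr)
    return out


def test_single_particle_full_trajectory():
    pos = [[10.0 + 0.3 * f] for f in range(20)]
    tracks = kf.link_trajectories(_detections_from_positions(pos), kf.DetectionConfig())
    assert len(tracks) == 1
    assert len(tracks[0].frames) == 20
    assert np.allclose(tracks[0].positions, 10.0 + 0.3 * np.arange(20))


def test_crossing_particles_cost_minimizing_assignment():
    """At a crossing, the linker takes the per-step cost-minimizing
    assignment of detections to tracks (verified by enumerating both
    pairings at every step)."""
    n = 30
    xa = 10.0 + 0.6 * np.arange(n)  # fast, anterograde
    xb = 25.0 - 0.2 * np.arange(n)  # slow, retrograde
    dets = _detections_from_positions([[a, b] for a, b in zip(xa, xb)])
    tracks = kf.link_trajectories(dets, kf.DetectionConfig(min_track_len=5))
    assert len(tracks) == 2
    t0, t1 = sorted(tracks, key=lambda t: t.positions[0])
    assert len(t0.frames) == len(t1.frames) == n
    for f in range(1, n):
        # both detections used exactly once per frame
        assert {round(t0.positions[f], 9), round(t1.positions[f], 9)} == {
            round(xa[f], 9), round(xb[f], 9)
        }
        chosen = abs(t0.positions[f] - t0.positions[f - 1]) + abs(
            t1.positions[f] - t1.positions[f - 1]
        )
        swapped = abs(t0.positions[f] - t1.positions[f - 1]) + abs(
            t1.positions[f] - t0.positions[f - 1]
        )
        assert chosen <= swapped


def test_gap_closing_bridges_single_dropout():
    pos = [[10.0 + 0.3 * f] if f != 7 else [] for f in range(15)]
    cfg = kf.DetectionConfig(max_gap=2, min_track_len=5)
    tracks = kf.link_trajectories(_detections_from_positions(pos), cfg)
    assert len(tracks) == 1
    assert len(tracks[0].frames) == 14
    assert 7 not in tracks[0].frames


def test_short_tracks_discarded():
    pos = [[10.0] for _ in range(4)]
    tracks = kf.link_trajectories(_detections_from_positions(pos), kf.DetectionConfig(min_track_len=10))
    assert tracks == []


def test_no_chimeras_on_well_separated_particles():
    """Noiseless, far-apart simulated particles map one-to-one to tracks."""
    kin = kf.KineticParams(fraction_stationary=0.3, fraction_wiggler=0.3)
    truth = kf.simulate_particles(
        kin, 5, seed=12, start_positions=np.linspace(10, 90, 5)
    )
    movie = kf.render_movie(
        truth, kf.PhotometryParams(gaussian_noise_sd=0.0, bleach_rate=0.0), seed=0
    )
    path = kf.NeuritePath.straight(row=5, col_start=0, col_end=movie.frames.shape[2] - 1)
    kymo = kf.build_kymograph(movie, path)
    cfg = kf.DetectionConfig(min_prominence=3.0)
    tracks = kf.link_trajectories(kf.detect_peaks(kymo, cfg), cfg)
    assert len(tracks) == 5
    matches = match_tracks_to_truth(tracks, truth, "rna", match_radius=0.5)
    assert len(matches) == 5
    for ti, gi in matches:
        err = tracks[ti].positions - truth.positions[gi][tracks[ti].frames]
        assert np.max(np.abs(err)) < 0.25 * 0.16  # 0.25 px at every frame


def test_trajectory_frame_monotonicity_enforced():
    with pytest.raises(ValueError):
        _make_track([1.0, 2.0], frames=np.array([3, 3]))


# ---------------------------------------------------------------------------
# classification


def test_identical_rna_and_mito_tracks_colocalize():
    mito = _make_track(np.linspace(10, 15, 20), channel="mito")
    rna = _make_track(np.linspace(10, 15, 20))
    out = kf.classify_mitochondrial([rna], [mito], kf.DetectionConfig())
    assert out[0].cargo_class == "mito"


def test_distant_rna_track_unclassified():
    cfg = kf.DetectionConfig()
    mito = _make_track(np.full(20, 10.0), channel="mito")
    rna = _make_track(np.full(20, 10.0 + 6 * cfg.coloc_radius))
    out = kf.classify_mitochondrial([rna], [mito], cfg)
    assert out[0].cargo_class == "unclassified"


def test_colocalization_fraction_threshold():
    cfg = kf.DetectionConfig(coloc_fraction=0.5)
    mito = _make_track(np.full(20, 10.0), channel="mito")
    near = np.full(20, 10.0)
    near[:9] = 50.0  # 11/20 = 55% of frames within radius
    out = kf.classify_mitochondrial([_make_track(near)], [mito], cfg)
    assert out[0].cargo_class == "mito"
    near2 = np.full(20, 10.0)
    near2[:11] = 50.0  # 45% within radius
    out2 = kf.classify_mitochondrial([_make_track(near2)], [mito], cfg)
    assert out2[0].cargo_class == "unclassified"


def test_calibration_mismatch_raises():
    mito = _make_track(np.full(20, 10.0), channel="mito", pixel_size=0.32)
    rna = _make_track(np.full(20, 10.0))
    with pytest.raises(CalibrationMismatchError):
        kf.classify_mitochondrial([rna], [mito], kf.DetectionConfig())


def test_brightness_split_paper_intensities():
    tracks = [
        _make_track(np.full(15, 10.0), intensities=np.full(15, 9.26)),
        _make_track(np.full(15, 30.0), intensities=np.full(15, 0.98)),
    ]
    out = kf.classify_brightness(tracks, kf.DetectionConfig())
    assert out[0].cargo_class == "bright_mrna"
    assert out[1].cargo_class == "dim_mrna"


def test_brightness_split_bimodal_recovery():
    """10x separated pools with 20% CV split perfectly."""
    rng = np.random.default_rng(0)
    tracks = []
    labels = []
    for i in range(40):
        bright = i % 2 == 0
        mean = 9.26 if bright else 0.926
        intens = rng.normal(mean, 0.2 * mean, 20).clip(0.05)
        tracks.append(_make_track(np.full(20, float(i)), intensities=intens))
        labels.append("bright_mrna" if bright else "dim_mrna")
    out = kf.classify_brightness(tracks, kf.DetectionConfig())
    assert [t.cargo_class for t in out] == labels


def test_brightness_degenerate_all_identical(caplog):
    tracks = [_make_track(np.full(10, float(i)), intensities=np.full(10, 5.0)) for i in range(4)]
    with caplog.at_level("WARNING"):
        out = kf.classify_brightness(tracks, kf.DetectionConfig())
    assert all(t.cargo_class == "bright_mrna" for t in out)
    assert any("degenerate" in r.message for r in caplog.records)


def test_classification_permutation_invariant():
    rng = np.random.default_rng(1)
    tracks = [
        _make_track(np.full(10, float(5 * i)), intensities=rng.normal(9.26 if i % 2 else 0.9, 0.1, 10))
        for i in range(10)
    ]
    out_fwd = kf.classify_brightness(tracks, kf.DetectionConfig())
    out_rev = kf.classify_brightness(tracks[::-1], kf.DetectionConfig())
    fwd = {t.positions[0]: t.cargo_class for t in out_fwd}
    rev = {t.positions[0]: t.cargo_class for t in out_rev}
    assert fwd == rev


def test_mito_recovery_at_snr5():
    """Partner labels recovered for >= 95% of matched tracks at SNR 5."""
    from kymoflux.pipeline import RunConfig, analyze_scene

    phot = kf.PhotometryParams(gaussian_noise_sd=9.26 / 5)
    cfg = RunConfig(
        photometry=phot,
        scene=kf.SceneParams(n_mito=5, n_partnered_mrna=4, n_free_bright=4, n_free_dim=0),
        detection_rna=kf.DetectionConfig(min_prominence=4.0),
    )
    correct = total = 0
    root = np.random.SeedSequence(21)
    for ss in root.spawn(6):
        s_sim, s_ren = ss.spawn(2)
        truth = kf.simulate_two_channel_scene(cfg.scene, s_sim)
        rna, _, _ = analyze_scene(truth, cfg, s_ren)
        for ti, gi in match_tracks_to_truth(rna, truth, "rna"):
            want = "mito" if truth.cargo_class[gi] == "mito" else "non_mito"
            got = "mito" if rna[ti].cargo_class == "mito" else "non_mito"
            total += 1
            correct += want == got
    assert total >= 40
    assert correct / total >= 0.95
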
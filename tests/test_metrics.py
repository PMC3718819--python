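"""Transport parameters: step labels, velocities, durations, directionality,
net velocity, and group aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kymoflux as kf
from kymoflux.metrics import DIRECTIONALITY_CLASSES, TransportProfile
from kymoflux.track import ParticleTrajectory

PX = 0.16
DT = 15.0


def _traj(positions, frames=None):
    positions = np.asarray(positions, float)
    frames = np.arange(len(positions)) if frames is None else np.asarray(frames)
    return ParticleTrajectory(
        particle_id=0,
        frames=frames,
        positions=positions,
        intensities=np.ones(len(positions)),
        channel="rna",
        frame_interval=DT,
        pixel_size=PX,
    )


def _profile(**kw):
    base = dict(
        particle_id=0, v_max_antero=0.0, v_max_retro=0.0, v_avg_antero=0.0,
        v_avg_retro=0.0, t_antero=0.0, t_retro=0.0, lifetime=900.0,
        d_antero=0.0, d_retro=0.0, net_displacement=0.0,
        v_dir_antero=0.0, v_dir_retro=0.0,
    )
    base.update(kw)
    return TransportProfile(**base)


# ---------------------------------------------------------------------------
# step decomposition


def test_constant_position_all_pauses():
    steps = kf.step_decompose(_traj(np.full(10, 5.0)), kf.MetricsConfig())
    assert (steps["label"] == "pause").all()


def test_monotone_pixel_steps_all_antero():
    steps = kf.step_decompose(_traj(5.0 + PX * np.arange(10)), kf.MetricsConfig())
    assert (steps["label"] == "antero").all()
    assert np.allclose(steps["dx"], PX)


def test_alternating_pixel_steps_alternate_labels():
    pos = 5.0 + PX * (np.arange(10) % 2)
    steps = kf.step_decompose(_traj(pos), kf.MetricsConfig())
    assert list(steps["label"]) == ["antero", "retro"] * 4 + ["antero"]


def test_subpixel_jitter_is_pause():
    eps = kf.MetricsConfig().resolve_epsilon(PX)
    pos = 5.0 + 0.9 * eps * (np.arange(10) % 2)
    steps = kf.step_decompose(_traj(pos), kf.MetricsConfig())
    assert (steps["label"] == "pause").all()


def test_gap_bridged_interval_keeps_bridged_dt():
    steps = kf.step_decompose(
        _traj([0.0, 1.0, 4.0], frames=[0, 1, 4]), kf.MetricsConfig()
    )
    assert list(steps["dt"]) == [DT, 3 * DT]


# ---------------------------------------------------------------------------
# profiles


def test_pure_anterograde_profile():
    pos = 10.0 + 0.05 * DT * np.arange(11)  # 0.05 µm/s for 10 intervals
    p = kf.compute_profile(_traj(pos))
    assert p.v_max_antero == pytest.approx(0.05)
    assert p.v_avg_antero == pytest.approx(0.05)
    assert p.t_antero == pytest.approx(150.0)
    assert p.t_retro == 0.0
    assert p.directionality == "anterograde"
    assert p.net_velocity == pytest.approx(0.05)  # pure mover: net = ν_a


def test_stationary_profile_all_zero():
    p = kf.compute_profile(_traj(np.full(12, 30.0)))
    assert p.v_max_antero == p.v_max_retro == 0.0
    assert p.v_avg_antero == p.v_avg_retro == 0.0
    assert p.directionality == "stationary"
    assert p.net_velocity == 0.0


def test_hand_computed_two_step_profile():
    """+0.75 µm then −0.30 µm, 15 s each."""
    p = kf.compute_profile(_traj([0.0, 0.75, 0.45]))
    assert p.v_avg_antero == pytest.approx(0.05)
    assert p.v_avg_retro == pytest.approx(0.02)
    assert p.t_antero == pytest.approx(15.0)
    assert p.t_retro == pytest.approx(15.0)
    assert p.net_displacement == pytest.approx(0.45)
    # (0.05*15 - 0.02*15) / 30
    assert p.net_velocity == pytest.approx(0.015)


def test_net_velocity_equation_hand_arithmetic():
    p = _profile(
        v_avg_antero=0.05, v_avg_retro=0.02, t_antero=300.0, t_retro=100.0,
        v_dir_antero=0.01, directionality="anterograde",
    )
    assert kf.net_velocity(p) == pytest.approx((15.0 - 2.0) / 400.0)  # 0.0325


def test_net_velocity_symmetry_zero():
    p = _profile(
        v_avg_antero=0.05, v_avg_retro=0.05, t_antero=200.0, t_retro=200.0,
        v_dir_antero=0.01, directionality="bidirectional",
    )
    assert kf.net_velocity(p) == 0.0


def test_stationary_reports_zero_net_velocity():
    p = _profile(v_avg_antero=0.05, t_antero=100.0, directionality="stationary")
    assert kf.net_velocity(p) == 0.0


# ---------------------------------------------------------------------------
# directionality


def test_below_cutoff_is_stationary():
    p = _profile(v_dir_antero=0.0005, v_dir_retro=0.0005, t_antero=100.0, t_retro=100.0)
    assert kf.classify_directionality(p) == "stationary"


def test_unidirectional_time_fraction_rule():
    p = _profile(v_dir_antero=0.01, t_antero=95.0, t_retro=5.0)
    assert kf.classify_directionality(p) == "anterograde"
    p = _profile(v_dir_retro=0.01, t_antero=5.0, t_retro=95.0)
    assert kf.classify_directionality(p) == "retrograde"


def test_wiggler_zero_net_displacement_bidirectional():
    p = _profile(
        v_dir_antero=0.01, v_dir_retro=0.01, t_antero=100.0, t_retro=100.0,
        net_displacement=0.0,
    )
    assert kf.classify_directionality(p) == "bidirectional"


def test_wiggler_above_displacement_threshold_takes_sign():
    p = _profile(
        v_dir_antero=0.01, v_dir_retro=0.01, t_antero=100.0, t_retro=100.0,
        net_displacement=0.5,
    )
    assert kf.classify_directionality(p) == "anterograde"
    p.net_displacement = -0.5
    assert kf.classify_directionality(p) == "retrograde"


def test_moving_with_zero_directional_time_is_inconsistent():
    from kymoflux.metrics import InconsistentProfileError

    p = _profile(v_dir_antero=0.01)
    with pytest.raises(InconsistentProfileError):
        kf.classify_directionality(p)


# ---------------------------------------------------------------------------
# invariants


def test_displacement_oracle_on_simulated_trajectories():
    """ν_a·T_a − ν_r·T_r == d_a − d_r and net velocity == net disp / moving
    time, on simulated paths with random frame dropouts."""
    rng = np.random.default_rng(0)
    kin = kf.KineticParams(fraction_stationary=0.2, fraction_wiggler=0.3)
    truth = kf.simulate_particles(kin, 100, seed=13)
    cfg = kf.MetricsConfig()
    for i in range(truth.n_particles):
        keep = np.sort(rng.choice(61, size=45, replace=False))
        tr = _traj(truth.positions[i][keep], frames=keep)
        p = kf.compute_profile(tr, cfg)
        lhs = p.v_avg_antero * p.t_antero - p.v_avg_retro * p.t_retro
        assert lhs == pytest.approx(p.d_antero - p.d_retro, abs=1e-9)
        t_move = p.t_antero + p.t_retro
        if t_move > 0:
            assert p.net_velocity == pytest.approx(p.net_displacement / t_move, abs=1e-9)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    scale=st.floats(min_value=0.1, max_value=10.0),
    seed=st.integers(min_value=0, max_value=50),
)
def test_scale_covariance(scale, seed):
    """Scaling positions by c scales every velocity field by c."""
    rng = np.random.default_rng(seed)
    pos = np.cumsum(rng.normal(0, 0.5, 20))
    cfg = kf.MetricsConfig(step_epsilon=0.0)
    p1 = kf.compute_profile(_traj(pos), cfg)
    p2 = kf.compute_profile(_traj(scale * pos), cfg)
    for f in ("v_max_antero", "v_max_retro", "v_avg_antero", "v_avg_retro"):
        assert getattr(p2, f) == pytest.approx(scale * getattr(p1, f), rel=1e-9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_directionality_partition_exhaustive(seed):
    rng = np.random.default_rng(seed)
    pos = np.cumsum(rng.normal(0, rng.uniform(0.01, 1.0), 15))
    p = kf.compute_profile(_traj(pos))
    assert p.directionality in DIRECTIONALITY_CLASSES


# ---------------------------------------------------------------------------
# aggregation


def _profiles_df(rows):
    return pd.DataFrame(rows)


def test_aggregate_mean_sem_two_particles():
    df = _profiles_df(
        [
            dict(cell_id="c0", day=4, neurite_class="axon", cargo_class="bright_mrna",
                 net_velocity=0.01, directionality="anterograde"),
            dict(cell_id="c0", day=4, neurite_class="axon", cargo_class="bright_mrna",
                 net_velocity=0.03, directionality="stationary"),
        ]
    )
    vel, _ = kf.aggregate_group(df, keys=["neurite_class", "day", "cargo_class"])
    assert vel.loc[0, "mean_net_velocity"] == pytest.approx(0.02)
    assert vel.loc[0, "sem_net_velocity"] == pytest.approx(0.01)
    assert vel.loc[0, "n_particles"] == 2


def test_aggregate_single_particle_sem_zero():
    df = _profiles_df(
        [dict(cell_id="c0", day=4, neurite_class="axon", cargo_class="mito",
              net_velocity=0.02, directionality="anterograde")]
    )
    vel, _ = kf.aggregate_group(df, keys=["neurite_class", "day", "cargo_class"])
    assert vel.loc[0, "sem_net_velocity"] == 0.0
    assert vel.loc[0, "n_particles"] == 1


def test_aggregate_per_cell_directionality_percentages():
    rows = []
    for i in range(8):
        rows.append(
            dict(cell_id="c0", day=4, neurite_class="axon", cargo_class="bright_mrna",
                 net_velocity=0.0, directionality="anterograde" if i < 4 else "stationary")
        )
    _, direc = kf.aggregate_group(_profiles_df(rows), keys=["neurite_class", "day", "cargo_class"])
    assert direc.loc[0, "mean_pct_anterograde"] == pytest.approx(50.0)
    assert direc.loc[0, "mean_pct_stationary"] == pytest.approx(50.0)
    assert direc.loc[0, "n_cells"] == 1


def test_aggregate_empty_returns_empty():
    vel, direc = kf.aggregate_group(pd.DataFrame(), keys=["day"])
    assert vel.empty and direc.empty
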
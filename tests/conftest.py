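import numpy as np
import pytest

from epbdsim import ParameterSet, SimulationConfig, TrajectoryEnsemble, encode_sequence


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet.default()


def make_ensemble(frames, seq=None, frame_interval_fs=100.0, params=None):
    """Wrap a hand-built (M, n_frames, N) array as a TrajectoryEnsemble.

    The configuration is made consistent with the array shape so that the
    feature layer's metadata checks pass.
    """
    frames = np.asarray(frames, dtype=float)
    m, n_frames, n = frames.shape
    if seq is None:
        seq = encode_sequence("A" * n, id="synthetic")
    stride = int(frame_interval_fs)  # dt = 1 fs
    cfg = SimulationConfig(
        dt=1.0,
        preheat_duration=0.0,
        production_duration=n_frames * frame_interval_fs / 1e6,
        sampling_stride=stride,
        ensemble_size=m,
        seed=0,
    )
    return TrajectoryEnsemble(
        sequence_id=seq.id,
        sequence=seq,
        frames=frames,
        frame_times=(np.arange(n_frames) + 1) * frame_interval_fs,
        config_used=cfg,
        parameters_used=params or ParameterSet.default(),
    )
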
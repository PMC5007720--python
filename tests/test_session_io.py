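"""Session container validation and round-trip I/O in both dialects."""

import numpy as np
import pytest
import scipy.io

from emgpr.errors import DataError, StructuralError
from emgpr.session import (
    RecordingSession,
    read_session,
    write_session,
)


def make_session(rng, n_time=600, n_ch=2, movements=("open", "rest"),
                 fs=100.0, reps=3, contraction=2.0):
    return RecordingSession(
        sampling_rate=fs,
        contraction_time=contraction,
        n_repetitions=reps,
        channel_count=n_ch,
        movement_names=list(movements),
        samples=rng.standard_normal((n_time, n_ch, len(movements))),
        subject_id="s01",
    )


@pytest.mark.parametrize("dialect,path_name", [("fixture", "sess_dir"),
                                               ("mat", "sess.mat")])
def test_round_trip_preserves_every_field(tmp_path, rng, dialect, path_name):
    s = make_session(rng)
    path = tmp_path / path_name
    write_session(s, path, dialect)
    back = read_session(path, dialect)
    assert back.movement_names == s.movement_names
    assert back.subject_id == s.subject_id
    assert back.n_repetitions == s.n_repetitions
    assert back.channel_count == s.channel_count
    assert back.sampling_rate == pytest.approx(s.sampling_rate, rel=1e-12)
    if dialect == "fixture":
        # text dialect round-trips float64 bit for bit via %.17g
        assert np.array_equal(back.samples, s.samples)
    else:
        assert np.allclose(back.samples, s.samples, rtol=1e-12, atol=0)


def test_protocol_arithmetic_full_scale(rng):
    # 3 repetitions x 3 s at 2 kHz concatenate to 18000 time samples
    fs, reps, ct = 2000.0, 3, 3.0
    n_time = int(fs * ct * reps)
    s = RecordingSession(fs, ct, reps, 2, ["a", "b", "c"],
                         rng.standard_normal((n_time, 2, 3)))
    s.validate()
    assert s.samples.shape[0] == 18000
    assert s.effective_boundaries() == (0, 6000, 12000)


def test_missing_metadata_field_is_structural_error(tmp_path, rng):
    s = make_session(rng)
    write_session(s, tmp_path / "d", "fixture")
    meta = tmp_path / "d" / "metadata.json"
    import json

    raw = json.loads(meta.read_text())
    del raw["sampling_rate"]
    meta.write_text(json.dumps(raw))
    with pytest.raises(StructuralError, match="sampling_rate"):
        read_session(tmp_path / "d", "fixture")


def test_non_finite_samples_rejected(rng):
    s = make_session(rng)
    s.samples[3, 0, 0] = np.nan
    with pytest.raises(DataError, match="non-finite"):
        s.validate()


def test_dimension_mismatch_rejected(rng):
    s = make_session(rng)
    s.channel_count = 5
    with pytest.raises(DataError, match="channel"):
        s.validate()
    s = make_session(rng)
    s.movement_names.append("extra")
    with pytest.raises(DataError, match="movement"):
        s.validate()


def test_too_short_time_axis_rejected(rng):
    s = make_session(rng, n_time=599)  # needs 100 Hz * 2 s * 3 reps = 600
    with pytest.raises(DataError, match="shorter"):
        s.validate()


def test_refuses_to_write_invalid_session(tmp_path, rng):
    s = make_session(rng)
    s.movement_names = []
    s.samples = s.samples[:, :, :0]
    with pytest.raises(StructuralError):
        write_session(s, tmp_path / "bad", "fixture")


def test_mat_dialect_readable_by_generic_mat_reader(tmp_path, rng):
    s = make_session(rng)
    path = tmp_path / "sess.mat"
    write_session(s, path, "mat")
    contents = scipy.io.loadmat(str(path))
    (name,) = [k for k in contents if not k.startswith("__")]
    struct = contents[name]
    assert set(struct.dtype.names) >= {"sF", "cT", "nR", "nCh", "mvs", "tdata"}


def test_configurable_field_map(tmp_path, rng):
    legacy = {
        "sampling_rate": "fs",
        "contraction_time": "tc",
        "n_repetitions": "nrep",
        "channel_count": "nch",
        "movement_names": "names",
        "samples": "data",
        "subject_id": "id",
    }
    s = make_session(rng)
    path = tmp_path / "legacy.mat"
    write_session(s, path, "mat", field_map=legacy)
    with pytest.raises(StructuralError):
        read_session(path, "mat")  # default map does not match
    back = read_session(path, "mat", field_map=legacy)
    assert back.movement_names == s.movement_names
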
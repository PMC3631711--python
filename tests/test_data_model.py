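"""Trial/session data model and on-disk format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sonoreach as sr
from sonoreach.data_model import FormatError

from conftest import identity_params, make_trial, minjerk_positions


def _random_trial(rng: np.random.Generator, n: int, condition: str) -> sr.TrialRecord:
    hand = rng.uniform(-1.0, 1.0, (n, 3))
    head = rng.uniform(-1.0, 1.0, (n, 3))
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return sr.TrialRecord(
        meta=sr.TrialMeta(
            subject_id="Sxy",
            condition=condition,
            target_azimuth_deg=float(rng.choice(sr.TARGET_AZIMUTHS_DEG)),
            trial_index=int(rng.integers(0, 100)),
        ),
        hand=sr.TrajectorySeries(p=hand, fs=100.0),
        head=sr.HeadPoseSeries(p=head, q=q, fs=100.0),
        start_marker=rng.uniform(-1.0, 1.0, 3),
    )


class TestTrialRoundTrip:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(2, 40),
        condition=st.sampled_from(sr.CONDITIONS),
    )
    def test_write_read_identity(self, tmp_path_factory, seed, n, condition):
        """read_trial inverts write_trial to 1e-9 on every field."""
        trial = _random_trial(np.random.default_rng(seed), n, condition)
        path = tmp_path_factory.mktemp("rt") / "trial.csv"
        back = sr.read_trial(sr.write_trial(trial, path))
        assert back.meta == trial.meta
        np.testing.assert_allclose(back.hand.p, trial.hand.p, atol=1e-9)
        np.testing.assert_allclose(back.head.p, trial.head.p, atol=1e-9)
        np.testing.assert_allclose(back.head.q, trial.head.q, atol=1e-9)
        np.testing.assert_allclose(back.start_marker, trial.start_marker, atol=1e-9)
        assert back.hand.fs == trial.hand.fs
        assert len(back.hand) == len(trial.hand)

    def test_two_writes_identical_bytes(self, tmp_path):
        trial = _random_trial(np.random.default_rng(3), 17, "B")
        p1 = sr.write_trial(trial, tmp_path / "a.csv")
        p2 = sr.write_trial(trial, tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_minimal_two_sample_trial(self, tmp_path):
        trial = _random_trial(np.random.default_rng(0), 2, "A")
        back = sr.read_trial(sr.write_trial(trial, tmp_path / "t.csv"))
        assert len(back.hand) == 2


class TestFormatErrors:
    def test_nan_coordinate_names_row(self, tmp_path):
        trial = _random_trial(np.random.default_rng(1), 8, "A")
        path = sr.write_trial(trial, tmp_path / "t.csv")
        lines = path.read_text().splitlines()
        first_data = next(i for i, ln in enumerate(lines) if ln.startswith("3,"))
        parts = lines[first_data].split(",")
        parts[2] = "nan"
        lines[first_data] = ",".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="row 3"):
            sr.read_trial(path)

    def test_non_uniform_grid_detected(self, tmp_path):
        trial = _random_trial(np.random.default_rng(2), 8, "A")
        path = sr.write_trial(trial, tmp_path / "t.csv")
        text = path.read_text().replace("\n5,", "\n7,", 1)
        path.write_text(text)
        with pytest.raises(FormatError, match="non-uniform time grid"):
            sr.read_trial(path)

    def test_missing_header_key(self, tmp_path):
        trial = _random_trial(np.random.default_rng(2), 4, "A")
        path = sr.write_trial(trial, tmp_path / "t.csv")
        text = "\n".join(
            ln for ln in path.read_text().splitlines() if not ln.startswith("# fs=")
        )
        path.write_text(text)
        with pytest.raises(FormatError, match="fs"):
            sr.read_trial(path)

    def test_condition_d_header_records_shift(self, tmp_path):
        """Conflicting-avatar trials carry the -18.5 deg shift in the header."""
        trial = _random_trial(np.random.default_rng(4), 5, "D")
        path = sr.write_trial(trial, tmp_path / "t.csv")
        assert "# avatar_shift_deg=-18.5" in path.read_text()
        assert sr.read_trial(path).meta.avatar_shift_deg == -18.5


class TestTrialMetaInvariants:
    @pytest.mark.parametrize(
        "condition,expected_ms", [("A", 250), ("B", 2000), ("C", 250), ("D", 250)]
    )
    def test_stimulus_duration_follows_condition(self, condition, expected_ms):
        meta = sr.TrialMeta(subject_id="s", condition=condition, target_azimuth_deg=0.0)
        assert meta.stimulus_duration_ms == expected_ms
        shift = -18.5 if condition == "D" else 0.0
        assert meta.avatar_shift_deg == shift

    def test_inconsistent_stimulus_rejected(self):
        with pytest.raises(ValueError):
            sr.TrialMeta(
                subject_id="s", condition="A", target_azimuth_deg=0.0,
                stimulus_duration_ms=2000,
            )

    def test_shift_only_in_condition_d(self):
        with pytest.raises(ValueError):
            sr.TrialMeta(
                subject_id="s", condition="C", target_azimuth_deg=0.0,
                avatar_shift_deg=-18.5,
            )


class TestSessionIO:
    def test_generated_default_session_has_128_trials(self, tmp_path):
        config = sr.SessionConfig(subject_id="S01", seed=5)
        trials, _ = sr.generate_session(config, identity_params(), out_dir=tmp_path)
        assert len(trials) == 4 * 32
        loaded, cfg = sr.load_session(tmp_path)
        assert len(loaded) == 128
        assert cfg.subject_id == "S01"
        # manifest order preserved exactly
        for a, b in zip(loaded, trials):
            assert a.meta.condition == b.meta.condition
            assert a.meta.trial_index == b.meta.trial_index
            assert a.meta.target_azimuth_deg == b.meta.target_azimuth_deg

    def test_empty_manifest_gives_empty_list(self, tmp_path):
        config = sr.SessionConfig(subject_id="S09")
        sr.save_session([], config, tmp_path)
        trials, cfg = sr.load_session(tmp_path)
        assert trials == []
        assert cfg.subject_id == "S09"

    def test_missing_trial_file_named(self, tmp_path):
        trial = make_trial(minjerk_positions(0.45, 1.0))
        sr.save_session([trial], sr.SessionConfig(subject_id="S02"), tmp_path)
        (tmp_path / "trial_0000_A.csv").unlink()
        with pytest.raises(FileNotFoundError, match="trial_0000_A.csv"):
            sr.load_session(tmp_path)
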
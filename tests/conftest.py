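import warnings

import numpy as np
import pytest

from uplimb import synthetic as syn
from uplimb.datamodel import AngleWaveform, TrialRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def body():
    return syn.BodyModel()


@pytest.fixture(scope="session")
def profiles():
    return syn.default_task_profiles()


def make_trial(task="t3_comb_hair", gain=1.0, master_seed=1, subject=0,
               offset=0.4):
    """One synthetic trial with a controllable error gain."""
    profiles = syn.default_task_profiles()
    profile = profiles[task]
    body = syn.BodyModel()
    truth = syn.generate_truth(profile, seed=master_seed)
    mocap, kinect_clean, static = syn.forward_kinematics(
        truth, body, start_offset_s=offset)
    err = syn.SensorErrorModel(gain=gain)
    kinect = syn.corrupt(kinect_clean, err, seed=master_seed + 1)
    return TrialRecord(subject_id=f"S{subject:02d}", task=task, trial_id="T1",
                       kinect_stream=kinect, mocap_stream=mocap,
                       static_trial=static, truth_angles=truth)


@pytest.fixture(scope="session")
def clean_trial():
    return make_trial(gain=0.0)


@pytest.fixture(scope="session")
def zero_error_corpus():
    """Small noise-free corpus: any downstream disagreement is pipeline error."""
    err = syn.SensorErrorModel(gain=0.0)
    return syn.generate_corpus(n_subjects=4, tasks=("t2_hand_to_mouth",),
                               trials_per_task=2, err=err, master_seed=3)


@pytest.fixture(scope="session")
def default_corpus_small():
    """Default-error corpus used by learnability tests (6 subjects)."""
    return syn.generate_corpus(n_subjects=6, tasks=("t3_comb_hair",),
                               trials_per_task=2, master_seed=11)


def reach_waveform(n=900, rate=300.0, amplitude=90.0, lead=1.0, dur=1.5):
    """A reaching-like 4-channel waveform: hold, minimum-jerk rise, hold."""
    t = np.arange(n) / rate
    s = syn.minimum_jerk(np.clip((t - lead) / dur, 0.0, 1.0))
    x = amplitude * s
    return AngleWaveform(values=np.column_stack([x * 0.5, x * 0.2, x * 0.3, x]),
                         rate_hz=rate)


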
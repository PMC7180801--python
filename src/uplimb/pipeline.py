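"""Trial-level glue: raw paired streams -> aligned, filtered, 101-point
angle-waveform pairs ready for training or evaluation."""

from __future__ import annotations

from .datamodel import TrialRecord
from .kinect import kinematics_kinect
from .preprocess import lowpass_zero_lag, resample, synchronize, time_normalize
from .uwa import kinematics_uwa


def prepare_pair(trial: TrialRecord, *, elbow_convention="flexion",
                 sync_channel="EFE", fc=6.0, target_hz=300.0):
    """Compute the (depth-sensor, gold-standard) waveform pair for one trial.

    Both outputs are time-normalized 101x4 waveforms in degrees, aligned by
    cross-correlation at ``target_hz`` and low-pass filtered at ``fc`` Hz.
    Returns ``(k_phi, k_gamma)``.
    """
    k_phi = kinematics_kinect(trial.kinect_stream, elbow_convention=elbow_convention)
    k_phi.task = trial.task
    k_phi.subject_id = trial.subject_id
    k_phi.trial_id = trial.trial_id
    k_gamma = kinematics_uwa(trial)

    k_phi = resample(k_phi, target_hz)
    k_gamma = resample(k_gamma, target_hz)
    _, k_gamma, k_phi = synchronize(k_gamma, k_phi, channel=sync_channel)
    k_phi = lowpass_zero_lag(k_phi, fc=fc)
    k_gamma = lowpass_zero_lag(k_gamma, fc=fc)
    k_phi = time_normalize(k_phi)
    k_gamma = time_normalize(k_gamma)
    return k_phi, k_gamma
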
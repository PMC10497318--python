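"""Synthetic sEMG session generator.

Real surface-EMG recordings from the study protocol are not available, so
this module generates protocol-faithful stand-ins.  The signal model is the
standard amplitude-modulated band-limited Gaussian surrogate for interference
sEMG: each channel is

    x_c(t) = noise_c(t) + s * g[movement, c] * e(t) * carrier_c(t)

where ``noise_c`` is white Gaussian instrumentation/rest noise,
``carrier_c`` is unit-variance Gaussian noise band-passed to the EMG energy
band (20-450 Hz by default), ``e(t)`` is a trapezoidal contraction envelope
driven by the binary movement indicator, ``g`` is the movement-by-channel
gain matrix, and ``s`` is a global amplitude scale calibrated analytically
so the session-level contraction/rest power ratio matches the electrode's
target SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ConfigurationError, ValidationError
from .protocol import ActivationModel, ElectrodeProfile, ProtocolConfig

SeedLike = int | Sequence[int]


@dataclass
class RecordingTrial:
    """One continuous multi-channel recording with per-sample MVC indicator."""

    samples: np.ndarray  # (n_samples, n_channels), mV
    movement_indicator: np.ndarray  # (n_samples,), values {0, 1}
    sample_rate: float
    subject_id: str
    electrode: str
    movement: str
    trial_index: int  # 1-based

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.movement_indicator = np.asarray(self.movement_indicator)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 2-D (n_samples, n_channels)")
        if self.movement_indicator.shape[0] != self.samples.shape[0]:
            raise ValidationError("indicator length must match sample count")
        if not np.isin(self.movement_indicator, (0, 1)).all():
            raise ValidationError("movement_indicator values must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def build_indicator(protocol: ProtocolConfig) -> np.ndarray:
    """Per-sample binary MVC indicator for one trial.

    The pattern is ``baseline_duration`` of 0s followed by
    ``cycles_per_trial`` repetitions of (``contraction_duration`` of 1s,
    ``rest_duration`` of 0s).
    """
    parts = [np.zeros(protocol.baseline_samples, dtype=np.int8)]
    one = np.ones(protocol.contraction_samples, dtype=np.int8)
    zero = np.zeros(protocol.rest_samples, dtype=np.int8)
    for _ in range(protocol.cycles_per_trial):
        parts.append(one)
        parts.append(zero)
    return np.concatenate(parts)


def contraction_envelope(indicator: np.ndarray, ramp_samples: int) -> np.ndarray:
    """Trapezoidal envelope: 0 at rest, linear ramps of ``ramp_samples`` at
    the start and end of each contraction run, 1 on the plateau.

    Ramps lie entirely inside the contraction run, so rest samples stay at
    exactly zero; runs shorter than two ramps become triangular.
    """
    env = np.zeros(indicator.shape[0], dtype=float)
    if ramp_samples < 0:
        raise ConfigurationError("ramp_samples must be >= 0")
    # run-length encode the indicator
    ind = np.asarray(indicator)
    boundaries = np.flatnonzero(np.diff(ind) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [ind.shape[0]]))
    for s, e in zip(starts, ends):
        if ind[s] != 1:
            continue
        n = e - s
        if ramp_samples == 0:
            env[s:e] = 1.0
            continue
        i = np.arange(n, dtype=float)
        up = (i + 1) / ramp_samples
        down = (n - i) / ramp_samples
        env[s:e] = np.minimum(1.0, np.minimum(up, down))
    return env


def _carrier_sos(protocol: ProtocolConfig, activation: ActivationModel):
    lo, hi = activation.carrier_band
    hi = min(hi, activation.acquisition_lowpass)
    nyq = protocol.sample_rate / 2.0
    if hi >= nyq:
        hi = 0.99 * nyq
    if not lo < hi:
        raise ConfigurationError("carrier band collapses under the sampling rate")
    # order-2 Butterworth applied forward-backward -> 4th-order zero-phase
    return butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def amplitude_scale(
    protocol: ProtocolConfig,
    activation: ActivationModel,
    electrode: ElectrodeProfile,
) -> float:
    """Global carrier amplitude ``s`` that hits the electrode's target SNR.

    The session SNR statistic is the mean per-segment power over contraction
    segments (averaged over channels and movements, equal counts each)
    divided by the same average over rest segments.  In expectation,

        rest power        = sigma_n^2
        contraction power = sigma_n^2 + s^2 * E[e^2] * mean(g^2)

    with ``sigma_n`` the baseline noise RMS, ``E[e^2]`` the mean-square
    envelope over contraction samples and ``mean(g^2)`` the mean squared gain
    over all movement/channel pairs.  Solving 10*log10(ratio) = target gives
    ``s`` in closed form.
    """
    gm = activation.gain_matrix
    mean_g2 = float(np.mean(gm**2))
    if mean_g2 == 0.0:
        return 0.0
    indicator = build_indicator(protocol)
    ramp = int(round(activation.ramp_duration * protocol.sample_rate))
    env = contraction_envelope(indicator, ramp)
    env_ms = float(np.mean(env[indicator == 1] ** 2))
    ratio = 10.0 ** (electrode.target_snr_db / 10.0)
    noise_var = electrode.baseline_noise_rms**2
    excess = max(ratio - 1.0, 0.0)
    return float(np.sqrt(excess * noise_var / (env_ms * mean_g2)))


def synth_trial(
    protocol: ProtocolConfig,
    activation: ActivationModel,
    electrode: ElectrodeProfile,
    movement: str,
    seed: SeedLike,
    subject_id: str = "S1",
    trial_index: int = 1,
) -> RecordingTrial:
    """Generate one trial recording; bit-identical for identical arguments."""
    if movement not in protocol.movements:
        raise ConfigurationError(
            f"unknown movement {movement!r}; protocol defines {protocol.movements}"
        )
    m_idx = protocol.movements.index(movement)
    gm = activation.gain_matrix
    if gm.shape != (len(protocol.movements), protocol.n_channels):
        raise ConfigurationError(
            f"gain_matrix shape {gm.shape} does not match "
            f"({len(protocol.movements)}, {protocol.n_channels})"
        )
    indicator = build_indicator(protocol)
    n = indicator.shape[0]
    ramp = int(round(activation.ramp_duration * protocol.sample_rate))
    env = contraction_envelope(indicator, ramp)
    scale = amplitude_scale(protocol, activation, electrode)
    sos = _carrier_sos(protocol, activation)

    rng = np.random.default_rng(seed)
    samples = np.empty((n, protocol.n_channels), dtype=float)
    for c in range(protocol.n_channels):
        white = rng.standard_normal(n)
        noise = rng.standard_normal(n) * electrode.baseline_noise_rms
        carrier = sosfiltfilt(sos, white)
        sd = carrier.std()
        if sd > 0:
            carrier = carrier / sd
        samples[:, c] = noise + scale * gm[m_idx, c] * env * carrier
    return RecordingTrial(
        samples=samples,
        movement_indicator=indicator,
        sample_rate=protocol.sample_rate,
        subject_id=subject_id,
        electrode=electrode.name,
        movement=movement,
        trial_index=trial_index,
    )


def generate_session(
    protocol: ProtocolConfig,
    activation: ActivationModel,
    electrode: ElectrodeProfile,
    subject_id: str,
    seed: int,
) -> list[RecordingTrial]:
    """All trials of one subject/electrode session.

    Sub-seeds follow a counter scheme: trial (movement index ``m``, 1-based
    trial ``t``) is generated from entropy ``(seed, m, t)``, so any single
    trial is reproducible without generating the whole session.
    """
    trials = []
    for m_idx, movement in enumerate(protocol.movements):
        for t in range(1, protocol.trials_per_movement + 1):
            trials.append(
                synth_trial(
                    protocol,
                    activation,
                    electrode,
                    movement,
                    seed=(int(seed), m_idx, t),
                    subject_id=subject_id,
                    trial_index=t,
                )
            )
    return trials


def trial_with_samples(trial: RecordingTrial, samples: np.ndarray) -> RecordingTrial:
    """Copy of ``trial`` with the signal matrix replaced, metadata preserved."""
    return replace(trial, samples=np.asarray(samples, dtype=float))
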
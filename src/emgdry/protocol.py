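"""Experiment protocol, electrode and muscle-activation configuration.

The recording protocol mirrors a standard forearm sEMG acquisition session:
a baseline rest period followed by repeated cycles of a maximal voluntary
contraction (MVC) and a rest period, repeated over several trials for each
of four hand/wrist movements recorded on four bipolar channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError

#: Canonical movement order. The activation gain matrix rows follow this order.
MOVEMENTS: tuple[str, ...] = ("extension", "open", "fist", "flexion")

#: Canonical 5-class label order used by the classifier output layer.
CLASS_ORDER: tuple[str, ...] = ("rest",) + MOVEMENTS


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing structure of one recording session.

    Parameters
    ----------
    sample_rate : float
        ADC sampling rate in samples/s. Default 2000.
    baseline_duration : float
        Initial rest period in seconds used to establish baseline activity.
    contraction_duration, rest_duration : float
        Length in seconds of each MVC and of the rest period that follows it.
    cycles_per_trial : int
        Number of MVC/rest cycles in one continuous trial recording.
    trials_per_movement : int
        Trials recorded per movement; the last trial is conventionally held
        out for testing.
    movements : tuple of str
        Ordered movement labels.
    n_channels : int
        Number of bipolar recording channels.
    """

    sample_rate: float = 2000.0
    baseline_duration: float = 6.0
    contraction_duration: float = 3.0
    rest_duration: float = 3.0
    cycles_per_trial: int = 30
    trials_per_movement: int = 5
    movements: tuple[str, ...] = MOVEMENTS
    n_channels: int = 4

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        for name in ("baseline_duration", "contraction_duration", "rest_duration"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.cycles_per_trial < 1:
            raise ConfigurationError("cycles_per_trial must be >= 1")
        if self.trials_per_movement < 1:
            raise ConfigurationError("trials_per_movement must be >= 1")
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if not self.movements:
            raise ConfigurationError("at least one movement label is required")
        object.__setattr__(self, "movements", tuple(self.movements))

    # -- derived sample counts ------------------------------------------------
    def _samples(self, seconds: float) -> int:
        return int(round(seconds * self.sample_rate))

    @property
    def baseline_samples(self) -> int:
        return self._samples(self.baseline_duration)

    @property
    def contraction_samples(self) -> int:
        return self._samples(self.contraction_duration)

    @property
    def rest_samples(self) -> int:
        return self._samples(self.rest_duration)

    @property
    def samples_per_trial(self) -> int:
        cycle = self.contraction_samples + self.rest_samples
        return self.baseline_samples + self.cycles_per_trial * cycle

    @property
    def contraction_segments_per_movement(self) -> int:
        return self.cycles_per_trial * self.trials_per_movement


@dataclass(frozen=True)
class ElectrodeProfile:
    """Electrode type with its target recording quality.

    ``target_snr_db`` is the contraction-over-rest power ratio (in dB) that
    generated sessions are calibrated to; ``baseline_noise_rms`` is the RMS
    amplitude (mV) of the additive instrumentation/rest noise floor.
    """

    name: str
    target_snr_db: float
    baseline_noise_rms: float = 0.01

    def __post_init__(self) -> None:
        if not np.isfinite(self.target_snr_db):
            raise ConfigurationError("target_snr_db must be finite")
        if self.baseline_noise_rms <= 0:
            raise ConfigurationError("baseline_noise_rms must be positive")


def _matched_noise_rms(
    target_snr_db: float, ref_snr_db: float = 18.2, ref_noise_rms: float = 0.01
) -> float:
    """Noise floor giving this SNR at the *same* muscle signal amplitude as a
    reference electrode.

    The muscle signal is a property of the subject, not of the electrode, so
    the two electrode types should record (nearly) identical contraction
    amplitudes and differ in their noise floor; feature-magnitude tables
    measured with both electrode types on the same subjects show almost equal
    per-movement amplitudes despite the SNR gap.  The calibrated signal scale
    is proportional to ``noise_rms * sqrt(10**(snr/10) - 1)``, so holding it
    equal across electrodes fixes the noise floor in closed form.
    """
    ratio = 10.0 ** (target_snr_db / 10.0)
    ref_ratio = 10.0 ** (ref_snr_db / 10.0)
    return ref_noise_rms * float(np.sqrt((ref_ratio - 1.0) / (ratio - 1.0)))


#: Built-in profiles: wet silver/silver-chloride and dry conductive-elastomer
#: (PEDOT:PSS in polyurethane) electrodes, with their measured session SNRs.
#: The lower-SNR wet electrode gets a proportionally higher noise floor so
#: both record the same underlying signal amplitude.
ELECTRODES: dict[str, ElectrodeProfile] = {
    "AgAgCl": ElectrodeProfile(
        "AgAgCl", target_snr_db=15.7, baseline_noise_rms=_matched_noise_rms(15.7)
    ),
    "CE": ElectrodeProfile("CE", target_snr_db=18.2),
}


def get_electrode(name: str) -> ElectrodeProfile:
    try:
        return ELECTRODES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown electrode {name!r}; known: {sorted(ELECTRODES)}"
        ) from None


# Relative per-channel amplitude gains, rows in MOVEMENTS order. Each movement
# dominates a different channel (circumferential placement: each movement's
# prime mover sits under a different electrode pair) and overall intensity is
# ordered flexion > fist > open > extension on every channel, reflecting the
# relative recruited muscle mass of the four movements.
DEFAULT_GAIN_MATRIX = np.array(
    [
        [0.50, 0.20, 0.15, 0.20],  # extension  -> ch1 dominant
        [0.60, 0.90, 0.40, 0.35],  # open       -> ch2 dominant
        [0.80, 1.10, 1.60, 0.90],  # fist       -> ch3 dominant
        [1.30, 1.60, 2.00, 2.60],  # flexion    -> ch4 dominant
    ]
)


@dataclass(frozen=True)
class ActivationModel:
    """How each movement drives each channel in the synthetic generator.

    ``gain_matrix`` (movements x channels) holds dimensionless amplitude
    multipliers applied to a unit-variance band-limited carrier; the absolute
    scale is set separately by SNR calibration (see
    :func:`emgdry.simulate.amplitude_scale`). ``ramp_duration`` is the linear
    rise/fall time (s) of the contraction envelope. ``carrier_band`` is the
    EMG energy band in Hz; ``acquisition_lowpass`` models the anti-aliasing
    filter of the acquisition chain as an upper band limit.
    """

    gain_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_GAIN_MATRIX.copy()
    )
    ramp_duration: float = 0.1
    carrier_band: tuple[float, float] = (20.0, 450.0)
    acquisition_lowpass: float = 700.0

    def __post_init__(self) -> None:
        gm = np.asarray(self.gain_matrix, dtype=float)
        if gm.ndim != 2:
            raise ConfigurationError("gain_matrix must be 2-D (movements x channels)")
        if not np.all(np.isfinite(gm)) or np.any(gm < 0):
            raise ConfigurationError("gains must be finite and >= 0")
        object.__setattr__(self, "gain_matrix", gm)
        if self.ramp_duration < 0:
            raise ConfigurationError("ramp_duration must be >= 0")
        lo, hi = self.carrier_band
        if not (0 < lo < hi):
            raise ConfigurationError("carrier_band must satisfy 0 < low < high")
        if self.acquisition_lowpass <= lo:
            raise ConfigurationError("acquisition_lowpass must exceed the band low edge")

    def dominant_channel(self, movement_index: int) -> int:
        """0-based index of the channel with the largest gain for a movement."""
        return int(np.argmax(self.gain_matrix[movement_index]))


# -- YAML helpers -------------------------------------------------------------

def protocol_from_dict(d: dict) -> ProtocolConfig:
    known = {f for f in ProtocolConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown protocol keys: {sorted(unknown)}")
    if "movements" in d:
        d = {**d, "movements": tuple(d["movements"])}
    return ProtocolConfig(**d)


def activation_from_dict(d: dict) -> ActivationModel:
    known = {f for f in ActivationModel.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown activation keys: {sorted(unknown)}")
    d = dict(d)
    if "gain_matrix" in d:
        d["gain_matrix"] = np.asarray(d["gain_matrix"], dtype=float)
    if "carrier_band" in d:
        d["carrier_band"] = tuple(d["carrier_band"])
    return ActivationModel(**d)


def electrode_from_dict(d: dict) -> ElectrodeProfile:
    return ElectrodeProfile(**d)


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a YAML mapping")
    return data
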